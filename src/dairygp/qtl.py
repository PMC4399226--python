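"""Local-GEBV sliding-window QTL mapping and pleiotropy classification.

The genome is tiled with 250 kb windows whose starts are 50 kb apart.  A
window's local GEBV is the slice W_{j1:j2} v_{j1:j2} of the genomic
prediction over the markers it contains; its variance across animals
(within breed) measures how much genetic variance the window captures.  A
window whose variance exceeds 50x the average window is called a QTL;
windows above 3x contribute to pleiotropy patterns.  Flagged windows with
midpoints closer than 0.5 Mb and matching effect-sign patterns merge into
regions, each labelled with one of nine classes: the yield trait (FY, MY,
PY) with the largest effect, suffixed by the sign of its correlation with
the remaining yield traits (- / + / n).  Regions whose only
supra-threshold trait is protein percentage are grouped with MYn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MarkerMap

__all__ = ["WindowGrid", "QTLRegion", "make_windows", "local_gebv",
           "window_variance", "call_qtl_windows", "pleiotropy_correlations",
           "merge_windows_to_regions", "classify_pleiotropy",
           "map_qtl_regions"]

YIELD_TRAITS = ("FY", "MY", "PY")
DEFAULT_SPAN = 250_000
DEFAULT_STEP = 50_000
QTL_THRESHOLD = 50.0
PLEIO_THRESHOLD = 3.0
MERGE_GAP = 500_000


@dataclass
class WindowGrid:
    """Sliding windows (0-based half-open) with their marker index ranges."""

    chrom: np.ndarray
    start: np.ndarray
    stop: np.ndarray
    first_marker: np.ndarray   # index into the map; -1 when empty
    n_markers: np.ndarray

    def __len__(self) -> int:
        return len(self.start)

    @property
    def midpoint(self) -> np.ndarray:
        return (self.start + self.stop) / 2.0

    def marker_slice(self, w: int) -> slice:
        f = self.first_marker[w]
        return slice(f, f + self.n_markers[w]) if f >= 0 else slice(0, 0)


def make_windows(map_: MarkerMap, span: int = DEFAULT_SPAN,
                 step: int = DEFAULT_STEP) -> WindowGrid:
    """Tile each chromosome with [s, s+span) windows, s = 0, step, 2 step,
    ... while s+span fits within the chromosome extent (last marker
    position); a chromosome shorter than span gets one covering window."""
    if len(map_) == 0:
        raise ValueError("empty marker map")
    chroms, starts, stops, firsts, counts = [], [], [], [], []
    pos0 = map_.pos0
    for c in pd.unique(map_.chrom):
        on_c = np.nonzero(map_.chrom == c)[0]
        p = pos0[on_c]
        extent = int(p[-1]) + 1
        if extent <= span:
            win_starts = [0]
            win_stops = [extent]
        else:
            win_starts = list(range(0, extent - span + 1, step))
            win_stops = [s + span for s in win_starts]
        for s, e in zip(win_starts, win_stops):
            lo = int(np.searchsorted(p, s, side="left"))
            hi = int(np.searchsorted(p, e, side="left"))
            chroms.append(c)
            starts.append(s)
            stops.append(e)
            firsts.append(on_c[lo] if hi > lo else -1)
            counts.append(hi - lo)
    return WindowGrid(np.asarray(chroms, dtype=object),
                      np.asarray(starts, dtype=np.int64),
                      np.asarray(stops, dtype=np.int64),
                      np.asarray(firsts, dtype=np.int64),
                      np.asarray(counts, dtype=np.int64))


def local_gebv(W: np.ndarray, v_hat: np.ndarray, grid: WindowGrid
               ) -> np.ndarray:
    """Animals x windows matrix of local GEBV W_{j1:j2} v_{j1:j2}."""
    W = np.asarray(W, float)
    v_hat = np.asarray(v_hat, float).ravel()
    if W.shape[1] != len(v_hat):
        raise ValueError("v_hat not aligned to genotype columns")
    out = np.zeros((W.shape[0], len(grid)))
    for w in range(len(grid)):
        sl = grid.marker_slice(w)
        if sl.stop > sl.start:
            out[:, w] = W[:, sl] @ v_hat[sl]
    return out


def window_variance(lg: np.ndarray, grid: WindowGrid,
                    breed: np.ndarray | None = None
                    ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Sample variance of local GEBV per window within each breed, plus the
    per-breed mean over windows that contain at least one marker.

    Breed groups of fewer than 2 animals are excluded with a warning.
    """
    import logging
    breed = (np.asarray(breed, dtype=object) if breed is not None
             else np.asarray(["all"] * lg.shape[0], dtype=object))
    has_marker = grid.n_markers > 0
    rows = {}
    means = {}
    for br in pd.unique(breed):
        mask = breed == br
        if mask.sum() < 2:
            logging.getLogger(__name__).warning(
                "breed %s has < 2 animals; excluded from window variance", br)
            continue
        var = lg[mask].var(axis=0, ddof=1)
        rows[br] = var
        means[br] = float(var[has_marker].mean()) if has_marker.any() else 0.0
    df = pd.DataFrame(rows)
    df.insert(0, "chrom", grid.chrom)
    df.insert(1, "start", grid.start)
    df.insert(2, "stop", grid.stop)
    df.insert(3, "n_markers", grid.n_markers)
    return df, means


def call_qtl_windows(variances: np.ndarray, mean_var: float,
                     threshold: float = QTL_THRESHOLD) -> np.ndarray:
    """Windows with variance strictly greater than threshold x mean."""
    if mean_var <= 0:
        raise ValueError("mean window variance must be positive")
    return np.asarray(variances, float) > threshold * mean_var


def pleiotropy_correlations(lg_by_trait: dict[str, np.ndarray],
                            var_by_trait: dict[str, np.ndarray],
                            mean_by_trait: dict[str, float],
                            w: int,
                            threshold: float = PLEIO_THRESHOLD
                            ) -> dict[tuple[str, str], float | None]:
    """Pairwise local-GEBV correlations in window w for trait pairs where
    both traits exceed threshold x their average window variance; pairs
    failing the filter yield None ("no effect")."""
    traits = list(lg_by_trait)
    passing = {t: var_by_trait[t][w] > threshold * mean_by_trait[t]
               for t in traits}
    out: dict[tuple[str, str], float | None] = {}
    for i, t1 in enumerate(traits):
        for t2 in traits[i + 1:]:
            if passing[t1] and passing[t2]:
                x, yv = lg_by_trait[t1][:, w], lg_by_trait[t2][:, w]
                if np.std(x) == 0 or np.std(yv) == 0:
                    out[(t1, t2)] = None
                else:
                    out[(t1, t2)] = float(np.corrcoef(x, yv)[0, 1])
            else:
                out[(t1, t2)] = None
    return out


@dataclass
class QTLRegion:
    chrom: str
    start: int
    stop: int
    member_windows: list[int]
    var_ratio: dict[str, dict[str, float]]  # trait -> breed -> max ratio
    correlations: dict[tuple[str, str], float | None]
    class_label: str = ""
    breed_specific: str = ""


def merge_windows_to_regions(grid: WindowGrid, flagged: np.ndarray,
                             patterns: list[dict[str, str]],
                             max_gap: int = MERGE_GAP) -> list[list[int]]:
    """Chain-merge flagged windows into regions.

    Successive flagged windows on one chromosome join the same region when
    their midpoints are < max_gap apart AND their effect-sign patterns
    agree on every trait (the "similar patterns" rule).  Returns lists of
    window indices.
    """
    idx = np.nonzero(np.asarray(flagged, bool))[0]
    if len(idx) == 0:
        return []
    mids = grid.midpoint
    order = idx[np.lexsort((mids[idx],
                            np.asarray([str(c) for c in grid.chrom[idx]])))]
    regions: list[list[int]] = [[int(order[0])]]
    for w in order[1:]:
        prev = regions[-1][-1]
        same_chrom = grid.chrom[w] == grid.chrom[prev]
        close = abs(mids[w] - mids[prev]) < max_gap
        similar = patterns[w] == patterns[prev]
        if same_chrom and close and similar:
            regions[-1].append(int(w))
        else:
            regions.append([int(w)])
    return regions


def classify_pleiotropy(var_ratio: dict[str, float],
                        correlations: dict[tuple[str, str], float | None],
                        threshold: float = PLEIO_THRESHOLD,
                        pct_traits: tuple[str, ...] = ("Fpct", "Ppct"),
                        ) -> str:
    """Nine-class label from a region's trait variance ratios and
    pairwise local-GEBV correlations.

    The head is the yield trait (FY/MY/PY) with the largest variance
    ratio; the suffix is "-" if the correlation with either remaining
    yield trait (both passing the 3x filter) is negative, "+" if any is
    positive, "n" when neither passes.  A region whose only
    supra-threshold trait is protein percentage is grouped with MYn.
    """
    supra = {t for t, r in var_ratio.items() if r > threshold}
    yield_supra = [t for t in YIELD_TRAITS if t in supra]
    if not yield_supra:
        if "Ppct" in supra or (supra and supra <= set(pct_traits)):
            return "MYn"
        return "unclassified"
    head = max(yield_supra, key=lambda t: var_ratio[t])
    corrs = []
    for other in YIELD_TRAITS:
        if other == head:
            continue
        pair = (head, other) if (head, other) in correlations else \
            (other, head)
        c = correlations.get(pair)
        if c is not None:
            corrs.append(c)
    if any(c < 0 for c in corrs):
        return f"{head}-"
    if any(c > 0 for c in corrs):
        return f"{head}+"
    return f"{head}n"


def map_qtl_regions(lg_by_trait: dict[str, np.ndarray], grid: WindowGrid,
                    breed: np.ndarray | None = None,
                    qtl_threshold: float = QTL_THRESHOLD,
                    pleio_threshold: float = PLEIO_THRESHOLD,
                    max_gap: int = MERGE_GAP) -> pd.DataFrame:
    """End-to-end window QTL mapping over a set of traits.

    Returns a BED-like region table (0-based half-open) with per-trait
    maximal variance ratios, the nine-class pleiotropy label and a
    breed-specificity flag ("H"/"J"-style: flagged in exactly one breed).
    """
    traits = list(lg_by_trait)
    breeds_arr = (np.asarray(breed, dtype=object) if breed is not None
                  else None)
    var_t: dict[str, np.ndarray] = {}
    mean_t: dict[str, float] = {}
    var_t_breed: dict[str, pd.DataFrame] = {}
    mean_t_breed: dict[str, dict[str, float]] = {}
    for t in traits:
        df_all, m_all = window_variance(lg_by_trait[t], grid, None)
        var_t[t] = df_all["all"].to_numpy()
        mean_t[t] = m_all["all"]
        if breeds_arr is not None:
            dfb, mb = window_variance(lg_by_trait[t], grid, breeds_arr)
            var_t_breed[t] = dfb
            mean_t_breed[t] = mb

    # flag pooled-population QTL windows for any trait
    flagged = np.zeros(len(grid), bool)
    for t in traits:
        if mean_t[t] > 0:
            flagged |= call_qtl_windows(var_t[t], mean_t[t], qtl_threshold)

    patterns = []
    for w in range(len(grid)):
        patterns.append({t: ("+" if mean_t[t] > 0 and var_t[t][w]
                             > pleio_threshold * mean_t[t] else "n")
                         for t in traits})
    groups = merge_windows_to_regions(grid, flagged, patterns, max_gap)

    rows = []
    for wins in groups:
        ratio = {t: max(var_t[t][w] / mean_t[t] for w in wins)
                 if mean_t[t] > 0 else 0.0 for t in traits}
        # correlations from the window with the largest overall ratio
        top_w = max(wins, key=lambda w: max(
            var_t[t][w] / mean_t[t] for t in traits if mean_t[t] > 0))
        corrs = pleiotropy_correlations(lg_by_trait, var_t, mean_t, top_w,
                                        pleio_threshold)
        label = classify_pleiotropy(ratio, corrs, pleio_threshold)
        spec_flag = ""
        if breeds_arr is not None:
            brs = [b for b in pd.unique(breeds_arr)
                   if all(b in mean_t_breed[t] for t in traits)]
            flagged_in = []
            for b in brs:
                hit = any(
                    mean_t_breed[t][b] > 0
                    and max(var_t_breed[t][b].iloc[w] for w in wins)
                    > qtl_threshold * mean_t_breed[t][b]
                    for t in traits)
                if hit:
                    flagged_in.append(str(b))
            if len(flagged_in) == 1:
                spec_flag = flagged_in[0]
        rows.append({
            "chrom": grid.chrom[wins[0]],
            "start": int(min(grid.start[w] for w in wins)),
            "stop": int(max(grid.stop[w] for w in wins)),
            "class_label": label,
            "breed_specific": spec_flag,
            "traits": ",".join(traits),
            "variance_ratios": ",".join(f"{ratio[t]:.4g}" for t in traits),
            "n_windows": len(wins),
            "midpoint_mb": round(float(np.mean(
                [grid.midpoint[w] for w in wins])) / 1e6, 3),
        })
    return pd.DataFrame(rows, columns=[
        "chrom", "start", "stop", "class_label", "breed_specific", "traits",
        "variance_ratios", "n_windows", "midpoint_mb"])
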