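"""Readers and writers for genotypes, phenotypes, pedigrees and result tables.

On-disk dialects
----------------
* genotypes: PLINK .bed/.bim/.fam triples (SNP-major bed) or a dosage TSV
  (rows = animals, header = marker ids, first column = animal id);
* phenotypes: TSV with columns animal_id, trait, value, record_type, d, r,
  breed, sex;
* pedigree: TSV with columns id, sire, dam ("0" or empty = unknown parent);
* SNP effects and QTL regions: TSV written by this module.

Positions are 1-based bp in files (PLINK .bim convention) and converted to
0-based half-open coordinates internally.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMap",
    "GenotypeSet",
    "PhenotypeTable",
    "PedigreeTable",
    "read_genotypes",
    "write_genotypes_tsv",
    "write_genotypes_plink",
    "read_phenotypes",
    "write_phenotypes",
    "read_pedigree",
    "write_pedigree",
    "write_snp_effects",
    "read_snp_effects",
    "write_qtl_regions",
    "read_qtl_regions",
]


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class MarkerMap:
    """Per-marker chromosome, 1-based bp position and id.

    Positions must be strictly increasing within a chromosome and marker
    ids unique.
    """

    chrom: np.ndarray  # str labels
    pos: np.ndarray    # int64, 1-based bp
    marker_id: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.marker_id = np.asarray(self.marker_id, dtype=object)
        if not (len(self.chrom) == len(self.pos) == len(self.marker_id)):
            raise FormatError("marker map fields have unequal lengths")
        if len(set(self.marker_id)) != len(self.marker_id):
            raise FormatError("duplicate marker ids in map")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise FormatError(
                    f"positions not strictly increasing on chromosome {c}")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def pos0(self) -> np.ndarray:
        """0-based positions for internal window arithmetic."""
        return self.pos - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"marker_id": self.marker_id, "chrom": self.chrom, "pos": self.pos})


@dataclass
class GenotypeSet:
    """Animals x markers dosage matrix with map and breed labels.

    Dosages are real-valued allele counts in [0, 2] (imputed dosages are
    admitted); no missing values remain after load.
    """

    dosages: np.ndarray
    animal_ids: list[str]
    map: MarkerMap
    breed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        self.animal_ids = [str(a) for a in self.animal_ids]
        if len(set(self.animal_ids)) != len(self.animal_ids):
            raise FormatError("animal ids not unique")
        n, m = self.dosages.shape
        if n != len(self.animal_ids):
            raise FormatError("row count != number of animal ids")
        if m != len(self.map):
            raise FormatError("column count != marker map length")
        if np.isnan(self.dosages).any():
            raise FormatError("missing dosages after load")
        if self.dosages.size and (
                self.dosages.min() < 0 or self.dosages.max() > 2):
            raise FormatError("dosage outside [0, 2]")
        if self.breed is None:
            self.breed = np.asarray(["unknown"] * n, dtype=object)
        else:
            self.breed = np.asarray(self.breed, dtype=object)
            if len(self.breed) != n:
                raise FormatError("breed labels length != animal count")

    @property
    def n_animals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def subset_animals(self, ids: list[str]) -> "GenotypeSet":
        index = {a: i for i, a in enumerate(self.animal_ids)}
        rows = [index[a] for a in ids]
        return GenotypeSet(self.dosages[rows], list(ids), self.map,
                           self.breed[rows])


def _impute_missing(d: np.ndarray) -> np.ndarray:
    """Per-marker mean imputation of NaN entries."""
    if not np.isnan(d).any():
        return d
    col_mean = np.nanmean(d, axis=0)
    col_mean = np.where(np.isnan(col_mean), 1.0, col_mean)
    idx = np.where(np.isnan(d))
    d[idx] = col_mean[idx[1]]
    return d


def _read_dosage_tsv(path: Path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise FormatError(f"{path}: dosage TSV needs an id column and markers")
    ids = df.iloc[:, 0].tolist()
    marker_ids = list(df.columns[1:])
    try:
        d = df.iloc[:, 1:].to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric dosage entry ({exc})") from exc
    finite = d[np.isfinite(d)]
    if finite.size and (finite.min() < 0 or finite.max() > 2):
        j = np.where((d < 0) | (d > 2))[1][0]
        raise FormatError(
            f"{path}: dosage outside [0, 2] at marker {marker_ids[j]}")
    return d, ids, marker_ids


# ---------------------------------------------------------------------------
# PLINK .bed/.bim/.fam codec (SNP-major)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit codes, SNP-major: 00 = hom A1 (dosage 2), 01 = missing,
# 10 = het (dosage 1), 11 = hom A2 (dosage 0)
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def _read_plink(prefix: Path) -> tuple[np.ndarray, list[str], MarkerMap]:
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "id": str})
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype=str)
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes (not SNP-major bed)")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != bytes_per_snp * m:
        raise FormatError(f"{prefix}.bed: truncated ({body.size} body bytes, "
                          f"expected {bytes_per_snp * m})")
    codes = body.reshape(m, bytes_per_snp)
    # unpack 2-bit fields, individual-minor within byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    unpacked = (codes[:, :, None] >> shifts[None, None, :]) & 0b11
    unpacked = unpacked.reshape(m, bytes_per_snp * 4)[:, :n]
    dosages = _CODE_TO_DOSAGE[unpacked].T.copy()  # animals x markers
    mm = MarkerMap(bim["chrom"].to_numpy(), bim["pos"].to_numpy(),
                   bim["id"].to_numpy())
    return dosages, fam["iid"].tolist(), mm


def write_genotypes_plink(g: GenotypeSet, prefix: str | Path) -> None:
    """Write a GenotypeSet as a PLINK bed/bim/fam triple.

    Non-integer dosages are not representable and raise.
    """
    prefix = Path(prefix)
    d = g.dosages
    if not np.allclose(d, np.round(d)):
        raise FormatError("PLINK bed stores hard genotypes only; "
                          "dosage matrix has non-integer entries")
    di = np.round(d).astype(np.int64)
    code = np.full(di.shape, 3, dtype=np.uint8)  # dosage 0 -> 11
    code[di == 1] = 2
    code[di == 2] = 0
    n, m = di.shape
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = code.T
    # dosage-0 padding would decode as dosage 2; pad with missing (01)
    padded[:, n:] = 1
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (padded.reshape(m, bytes_per_snp, 4) << shifts).sum(
        axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    mm = g.map
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for c, mid, p in zip(mm.chrom, mm.marker_id, mm.pos):
            fh.write(f"{c}\t{mid}\t0\t{p}\tA\tB\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for aid in g.animal_ids:
            fh.write(f"0\t{aid}\t0\t0\t0\t-9\n")


def write_genotypes_tsv(g: GenotypeSet, path: str | Path) -> None:
    df = pd.DataFrame(g.dosages, columns=list(g.map.marker_id))
    df.insert(0, "animal_id", g.animal_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_genotypes(path: str | Path, fmt: str = "auto",
                   map_: MarkerMap | None = None,
                   breed: np.ndarray | None = None) -> GenotypeSet:
    """Load genotypes from a PLINK triple or dosage TSV, order-preserving.

    Missing entries are mean-imputed per marker.  For the TSV dialect a
    marker map may be supplied; otherwise a synthetic single-chromosome map
    with unit spacing is created from the header order.
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "plink" if (path.with_suffix(".bed").exists()
                          and path.suffix != ".tsv") else "tsv"
    if fmt == "plink":
        dosages, ids, mm = _read_plink(path)
    elif fmt == "tsv":
        if not path.exists():
            raise FileNotFoundError(path)
        dosages, ids, marker_ids = _read_dosage_tsv(path)
        if map_ is not None:
            if list(map_.marker_id) != marker_ids:
                raise FormatError("marker map does not match TSV header")
            mm = map_
        else:
            mm = MarkerMap(["1"] * len(marker_ids),
                           np.arange(1, len(marker_ids) + 1), marker_ids)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")
    dosages = _impute_missing(dosages)
    return GenotypeSet(dosages, ids, mm, breed)


# ---------------------------------------------------------------------------
# Phenotypes

_PHENO_COLS = ["animal_id", "trait", "value", "record_type", "d", "r",
               "breed", "sex"]


@dataclass
class PhenotypeTable:
    """Per-animal trait deviations with the metadata driving record weights.

    Bulls carry daughter trait deviations with an effective daughter count
    ``d``; cows carry their own trait deviations with a record count ``r``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _PHENO_COLS if c not in self.df.columns]
        if missing:
            raise FormatError(f"phenotype table missing column(s): "
                              f"{', '.join(missing)}")
        df = self.df.copy()
        df["animal_id"] = df["animal_id"].astype(str)
        bad = ~df["record_type"].isin(["bull", "cow"])
        if bad.any():
            raise FormatError("unknown record_type "
                              f"{df.loc[bad, 'record_type'].iloc[0]!r}")
        cows = df["record_type"] == "cow"
        if (cows & (df["r"].fillna(0) < 1)).any():
            raise FormatError("cow record with r < 1")
        if (~cows & (df["d"].fillna(0) < 0)).any():
            raise FormatError("bull record with d < 0")
        if df.duplicated(["animal_id", "trait"]).any():
            dup = df[df.duplicated(["animal_id", "trait"])].iloc[0]
            raise FormatError(f"duplicate record for animal "
                              f"{dup['animal_id']} trait {dup['trait']}")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def for_trait(self, trait: str) -> "PhenotypeTable":
        return PhenotypeTable(self.df[self.df["trait"] == trait]
                              .reset_index(drop=True))


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str})
    return PhenotypeTable(df)


def write_phenotypes(tab: PhenotypeTable, path: str | Path) -> None:
    tab.df.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Pedigree

UNKNOWN_PARENT = "0"


@dataclass
class PedigreeTable:
    """Topologically sorted pedigree; unknown parents are founders' "0"."""

    df: pd.DataFrame  # columns id, sire, dam; parents precede offspring

    def __post_init__(self) -> None:
        df = self.df.copy()
        for c in ("id", "sire", "dam"):
            df[c] = df[c].fillna(UNKNOWN_PARENT).astype(str)
            df.loc[df[c] == "", c] = UNKNOWN_PARENT
        if df["id"].duplicated().any():
            raise FormatError("duplicate animal id in pedigree")
        self.df = _toposort(df)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> list[str]:
        return self.df["id"].tolist()


def _toposort(df: pd.DataFrame) -> pd.DataFrame:
    """Kahn topological sort, parents before offspring; stable on ties."""
    ids = df["id"].tolist()
    known = set(ids)
    parents = {r.id: [p for p in (r.sire, r.dam)
                      if p != UNKNOWN_PARENT and p in known]
               for r in df.itertuples()}
    for r in df.itertuples():
        if r.id in (r.sire, r.dam):
            raise FormatError(f"animal {r.id} is its own parent")
    children: dict[str, list[str]] = {i: [] for i in ids}
    indeg = {i: 0 for i in ids}
    for child, ps in parents.items():
        for p in ps:
            children[p].append(child)
            indeg[child] += 1
    queue = [i for i in ids if indeg[i] == 0]
    order: list[str] = []
    while queue:
        nxt: list[str] = []
        for i in queue:
            order.append(i)
            for c in children[i]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    nxt.append(c)
        queue = nxt
    if len(order) != len(ids):
        cyc = sorted(set(ids) - set(order))
        raise FormatError(f"pedigree contains a cycle involving: "
                          f"{', '.join(cyc)}")
    return df.set_index("id").loc[order].reset_index()


def read_pedigree(path: str | Path) -> PedigreeTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    try:
        df = df.rename(columns={cols["id"]: "id", cols["sire"]: "sire",
                                cols["dam"]: "dam"})
    except KeyError as exc:
        raise FormatError(f"pedigree TSV missing column {exc}") from exc
    return PedigreeTable(df[["id", "sire", "dam"]])


def write_pedigree(ped: PedigreeTable, path: str | Path) -> None:
    ped.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SNP effects and QTL regions

def write_snp_effects(effects: np.ndarray, map_: MarkerMap,
                      path: str | Path,
                      class_probs: np.ndarray | None = None) -> None:
    """SNP-effect TSV: marker_id, chrom, pos (1-based bp), effect, and
    per-component posterior inclusion probabilities when available."""
    effects = np.asarray(effects, dtype=np.float64)
    if len(effects) != len(map_):
        raise FormatError(f"effect vector length {len(effects)} != "
                          f"map length {len(map_)}")
    df = map_.to_frame()
    df["effect"] = effects
    if class_probs is not None:
        class_probs = np.asarray(class_probs, dtype=np.float64)
        if class_probs.shape[0] != len(map_):
            raise FormatError("class probability rows != map length")
        for k in range(class_probs.shape[1]):
            df[f"p_class{k}"] = class_probs[:, k]
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_snp_effects(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"marker_id": str, "chrom": str})


_REGION_COLS = ["chrom", "start", "stop", "class_label", "breed_specific",
                "traits", "variance_ratios"]


def write_qtl_regions(regions: pd.DataFrame, path: str | Path) -> None:
    """QTL regions as a BED-like TSV (0-based half-open start/stop)."""
    cols = [c for c in _REGION_COLS if c in regions.columns]
    extra = [c for c in regions.columns if c not in cols]
    regions[cols + extra].to_csv(path, sep="\t", index=False,
                                 float_format="%.12g")


def read_qtl_regions(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
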