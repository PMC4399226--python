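"""Record weights for heterogeneous residual variance, and composition traits.

Phenotypes enter the analysis with record-specific precision: a bull's
daughter trait deviation is an average over d effective daughters, a cow's
trait deviation averages r own records.  Residuals are modelled
e ~ N(0, E sigma2_e) with E = diag(1/w_i), so w_i is the information
carried by record i relative to a single own-performance record (w = 1
exactly for a cow with r = 1).

The weights follow the deregressed-proof weighting of Garrick-style
genomic evaluation:

    bulls:  w = d (1 - h2) / (4 - h2)
    cows:   w = r (1 - h2) / (1 + (r - 1) t - r h2)

with h2 the single-record heritability and t the repeatability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import PhenotypeTable

__all__ = ["TraitParams", "TRAIT_PRESETS", "bull_weight", "cow_weight",
           "residual_weight_diagonal", "composition_deviation"]


@dataclass(frozen=True)
class TraitParams:
    """Heritability h2 in (0, 1] and repeatability t in [h2, 1]."""

    h2: float
    t: float

    def __post_init__(self) -> None:
        if not 0 <= self.h2 <= 1:
            raise ValueError(f"h2={self.h2} outside [0, 1]")
        if self.h2 > 0 and not self.h2 <= self.t <= 1:
            raise ValueError(f"need h2 <= t <= 1, got h2={self.h2}, t={self.t}")


# Default dairy-trait parameters (milk traits share one set; stature,
# fertility and survival have their own).
TRAIT_PRESETS: dict[str, TraitParams] = {
    "FY": TraitParams(0.33, 0.56),
    "MY": TraitParams(0.33, 0.56),
    "PY": TraitParams(0.33, 0.56),
    "Fpct": TraitParams(0.33, 0.56),
    "Ppct": TraitParams(0.33, 0.56),
    "STAT": TraitParams(0.45, 0.45),
    "FERT": TraitParams(0.03, 0.05),
    "SURV": TraitParams(0.025, 0.035),
}


def bull_weight(d: float, params: TraitParams) -> float:
    """Weight of a bull record with d effective daughters: d(1-h2)/(4-h2)."""
    if d < 0:
        raise ValueError(f"effective daughter count d={d} < 0")
    if not 0 <= params.h2 <= 1:
        raise ValueError("h2 outside [0, 1]")
    return d * (1.0 - params.h2) / (4.0 - params.h2)


def cow_weight(r: float, params: TraitParams) -> float:
    """Weight of a cow record with r own records: r(1-h2)/(1+(r-1)t-r h2).

    Equals 1 exactly at r = 1, anchoring the residual variance scale.
    """
    if r < 1:
        raise ValueError(f"cow record count r={r} < 1")
    denom = 1.0 + (r - 1.0) * params.t - r * params.h2
    if denom <= 0:
        raise ValueError(f"invalid parameter combination: denominator "
                         f"{denom:.6g} <= 0 at r={r}, h2={params.h2}, "
                         f"t={params.t}")
    return r * (1.0 - params.h2) / denom


def record_weights(phenos: PhenotypeTable,
                   params: dict[str, TraitParams] | TraitParams,
                   ) -> pd.Series:
    """Per-record weight w_i, in input order (0 for bulls with d = 0)."""
    out = np.empty(len(phenos))
    for i, row in enumerate(phenos.df.itertuples()):
        p = params if isinstance(params, TraitParams) else params[row.trait]
        if row.record_type == "bull":
            out[i] = bull_weight(float(row.d), p)
        else:
            out[i] = cow_weight(float(row.r), p)
    return pd.Series(out, index=phenos.df.index, name="w")


def residual_weight_diagonal(
        phenos: PhenotypeTable,
        params: dict[str, TraitParams] | TraitParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Diagonal of E = diag(1/w_i) for records carrying information.

    Returns (E_ii vector, boolean keep mask in input order).  Records with
    w = 0 (bulls without daughters) carry infinite error variance and are
    dropped from the analysis; dropping every record is an error.
    """
    import logging
    w = record_weights(phenos, params).to_numpy()
    keep = w > 0
    if not keep.any():
        raise ValueError("all records have zero weight; nothing to analyse")
    n_drop = int((~keep).sum())
    if n_drop:
        logging.getLogger(__name__).warning(
            "dropping %d zero-weight record(s) (bulls with d=0)", n_drop)
    return 1.0 / w[keep], keep


def composition_deviation(yield_dev: float, milk_dev: float,
                          yield_mean: float, milk_mean: float) -> float:
    """Linearised milk-composition deviation (fraction scale).

    Fat (or protein) percentage is the ratio of a solids yield to milk
    volume; around the population means (FY_P, MY_P) the deviation is
    approximated linearly as

        (FY_P / MY_P) * [FY / FY_P - MY / MY_P]

    with FY = FY_P + yield_dev, MY = MY_P + milk_dev.  The result is on
    the fraction scale; multiply by 100 for percent.
    """
    if yield_mean <= 0 or milk_mean <= 0:
        raise ValueError("population means must be positive")
    fy = yield_mean + yield_dev
    my = milk_mean + milk_dev
    return (yield_mean / milk_mean) * (fy / yield_mean - my / milk_mean)
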