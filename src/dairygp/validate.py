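"""GEBV prediction for validation animals and accuracy/bias scoring.

Predictions come in two flavours: the SNP-only genomic value y_v = W v-hat
and total genetic merit y = a-hat + W v-hat.  Accuracy is the Pearson
correlation between prediction and phenotype; bias is the slope of the
regression of phenotype on prediction (1 = unbiased); the approximate
standard error of an accuracy over n validation animals is 1/sqrt(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PredictionSet", "predict_gebv", "accuracy", "bias",
           "accuracy_se", "validation_report"]


@dataclass
class PredictionSet:
    animal_id: list[str]
    y_hat_v: np.ndarray          # SNP-only: W v
    y_hat: np.ndarray            # total: a + W v
    breed: np.ndarray | None = None


def predict_gebv(W_val: np.ndarray, v_hat: np.ndarray,
                 a_hat: np.ndarray | None = None,
                 animal_id: list[str] | None = None,
                 breed: np.ndarray | None = None) -> PredictionSet:
    """GEBV for validation animals; ``W_val`` must be standardized with the
    training population's allele frequencies."""
    W_val = np.asarray(W_val, dtype=np.float64)
    v_hat = np.asarray(v_hat, dtype=np.float64).ravel()
    if W_val.shape[1] != len(v_hat):
        raise ValueError(f"marker mismatch: W has {W_val.shape[1]} columns, "
                         f"v_hat has {len(v_hat)}")
    yv = W_val @ v_hat
    if a_hat is None:
        a = np.zeros(len(yv))
    else:
        a = np.asarray(a_hat, dtype=np.float64).ravel()
        if len(a) != len(yv):
            raise ValueError("a_hat length != number of validation animals")
    ids = animal_id or [str(i) for i in range(len(yv))]
    return PredictionSet(ids, yv, a + yv, breed)


def accuracy(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Pearson correlation r(y, y_hat); NaN if either vector is constant."""
    y = np.asarray(y, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    if len(y) < 3:
        raise ValueError("need at least 3 validation animals")
    if np.std(y) == 0 or np.std(y_hat) == 0:
        return float("nan")
    return float(np.corrcoef(y, y_hat)[0, 1])


def bias(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Regression slope of phenotype on prediction, cov(y,yhat)/var(yhat)."""
    y = np.asarray(y, float).ravel()
    y_hat = np.asarray(y_hat, float).ravel()
    vy = np.var(y_hat)
    if vy == 0:
        return float("nan")
    return float(np.cov(y, y_hat, ddof=1)[0, 1] / np.var(y_hat, ddof=1))


def accuracy_se(n: int) -> float:
    """Approximate SE of a correlation over n animals, 1/sqrt(n), reported
    to 3 decimals."""
    if n < 2:
        raise ValueError("need n >= 2")
    return round(1.0 / np.sqrt(n), 3)


def validation_report(y: np.ndarray, preds: PredictionSet, trait: str,
                      reference: str, method: str) -> pd.DataFrame:
    """Per-breed accuracy/bias table for both prediction flavours."""
    y = np.asarray(y, float).ravel()
    breeds = (preds.breed if preds.breed is not None
              else np.asarray(["all"] * len(y), dtype=object))
    rows = []
    for br in pd.unique(breeds):
        mask = breeds == br
        n = int(mask.sum())
        for flavour, yh in (("snp_only", preds.y_hat_v[mask]),
                            ("total", preds.y_hat[mask])):
            rows.append({
                "trait": trait, "reference": reference, "method": method,
                "breed": br, "flavour": flavour, "n": n,
                "accuracy": accuracy(y[mask], yh),
                "bias": bias(y[mask], yh),
                "approx_se": accuracy_se(n),
            })
    return pd.DataFrame(rows)
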