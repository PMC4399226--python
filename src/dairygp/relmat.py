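"""Standardized genotypes, genomic and pedigree relationship matrices.

The genomic relationship matrix follows Yang et al.'s estimator: columns of
the genotype matrix are centred and scaled by the binomial standard
deviation sqrt(2p(1-p)), off-diagonals are the mean standardized
cross-product over markers, and the diagonal uses the within-individual
estimator (x^2 - (1+2p)x + 2p^2) / (2p(1-p)) which equals 1 + F-hat.  A
"plain" mode uses W W'/m throughout; algebraic identities (SNP-effect
back-solving, two-route prediction) are exact in plain mode.

The pedigree numerator relationship matrix A is built by the tabular
method; its sparse inverse comes from Henderson's rules with inbreeding
coefficients computed by the Meuwissen-Luo recursion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .io_formats import GenotypeSet, PedigreeTable, UNKNOWN_PARENT

__all__ = ["StandardizedGenotypes", "GRM", "NRM", "standardize_genotypes",
           "compute_grm", "compute_nrm", "compute_nrm_inverse",
           "inbreeding_coefficients"]

log = logging.getLogger(__name__)


@dataclass
class StandardizedGenotypes:
    """Centred, unit-variance genotype columns w = (x - 2p)/sqrt(2p(1-p)).

    Monomorphic markers cannot be standardized and are excluded; the kept
    mask maps columns of W back to the source marker map.
    """

    W: np.ndarray
    freq: np.ndarray            # allele frequency of kept markers
    marker_kept_mask: np.ndarray
    raw: np.ndarray | None = None  # kept raw dosage columns (Yang diagonal)

    @property
    def m(self) -> int:
        return self.W.shape[1]


def standardize_genotypes(g: GenotypeSet | np.ndarray,
                          freq: np.ndarray | None = None,
                          ) -> StandardizedGenotypes:
    """Standardize dosages; frequencies default to the input population's.

    Passing ``freq`` standardizes validation animals with the training
    population's allele frequencies.
    """
    d = g.dosages if isinstance(g, GenotypeSet) else np.asarray(g, float)
    if freq is None:
        freq = d.mean(axis=0) / 2.0
    else:
        freq = np.asarray(freq, dtype=np.float64)
    kept = (freq > 0) & (freq < 1)
    if not kept.any():
        raise ValueError("all markers monomorphic; nothing to standardize")
    p = freq[kept]
    x = d[:, kept]
    W = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return StandardizedGenotypes(W, p, kept, raw=x)


@dataclass
class GRM:
    """Genomic relationship matrix over ``m`` markers."""

    G: np.ndarray
    m: int
    mode: str = "yang"
    _inv: np.ndarray | None = None  # cached inverse (see invert_grm)


def compute_grm(sg: StandardizedGenotypes, mode: str = "yang") -> GRM:
    """G = W W'/m with, in "yang" mode, the adjusted self-relationship
    diagonal 1 + F-hat from (x^2 - (1+2p)x + 2p^2)/(2p(1-p))."""
    if sg.m < 1:
        raise ValueError("need at least one kept marker")
    G = sg.W @ sg.W.T / sg.m
    if mode == "yang":
        if sg.raw is None:
            raise ValueError("Yang diagonal needs raw dosages")
        p = sg.freq
        x = sg.raw
        diag = ((x * x - (1.0 + 2.0 * p) * x + 2.0 * p * p)
                / (2.0 * p * (1.0 - p))).mean(axis=1) + 1.0
        np.fill_diagonal(G, diag)
    elif mode != "plain":
        raise ValueError(f"unknown GRM mode {mode!r}")
    return GRM(G, sg.m, mode)


def invert_grm(grm: GRM, ridge: float = 1e-6) -> np.ndarray:
    """Inverse of G, ridge-stabilised on the diagonal if near-singular.

    The inverse is cached on the GRM object; repeated solver calls reuse it.
    """
    if grm._inv is not None:
        return grm._inv
    G = grm.G
    try:
        c = np.linalg.cond(G)
    except np.linalg.LinAlgError:  # pragma: no cover
        c = np.inf
    if not np.isfinite(c) or c > 1e12:
        log.warning("GRM numerically singular (cond=%.3g); adding %g ridge",
                    c, ridge)
        G = G + ridge * np.eye(G.shape[0])
    grm._inv = np.linalg.inv(G)
    return grm._inv


# ---------------------------------------------------------------------------
# Pedigree relationship matrices


@dataclass
class NRM:
    A: np.ndarray
    ids: list[str]


def _parent_indices(ped: PedigreeTable) -> tuple[np.ndarray, np.ndarray]:
    idx = {a: i for i, a in enumerate(ped.ids)}
    sire = np.array([idx.get(s, -1) if s != UNKNOWN_PARENT else -1
                     for s in ped.df["sire"]], dtype=np.int64)
    dam = np.array([idx.get(d_, -1) if d_ != UNKNOWN_PARENT else -1
                    for d_ in ped.df["dam"]], dtype=np.int64)
    return sire, dam


def compute_nrm(ped: PedigreeTable) -> NRM:
    """Numerator relationship matrix by the recursive tabular method."""
    n = len(ped)
    sire, dam = _parent_indices(ped)
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            A[i, i] = 1.0 + 0.5 * A[s, d]
        else:
            A[i, i] = 1.0
        for j in range(i):
            a = 0.0
            if s >= 0:
                a += 0.5 * A[j, s]
            if d >= 0:
                a += 0.5 * A[j, d]
            A[i, j] = A[j, i] = a
    return NRM(A, ped.ids)


def inbreeding_coefficients(ped: PedigreeTable) -> np.ndarray:
    """Inbreeding F by the Meuwissen-Luo recursion (A_ii - 1)."""
    n = len(ped)
    sire, dam = _parent_indices(ped)
    F = np.zeros(n)
    L = np.zeros(n)  # scratch: contribution of ancestor to animal i
    D = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        D[i] = 0.5 - 0.25 * ((F[s] if s >= 0 else -1.0)
                             + (F[d] if d >= 0 else -1.0))
        if s < 0 and d < 0:
            F[i] = 0.0
            continue
        # accumulate L over ancestors processed in reverse order
        L[:] = 0.0
        L[i] = 1.0
        f = 0.0
        for j in range(i, -1, -1):
            if L[j] == 0.0:
                continue
            f += L[j] * L[j] * D[j]
            if sire[j] >= 0:
                L[sire[j]] += 0.5 * L[j]
            if dam[j] >= 0:
                L[dam[j]] += 0.5 * L[j]
        F[i] = f - 1.0
    return F


def compute_nrm_inverse(ped: PedigreeTable) -> sp.csr_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding.

    Mendelian sampling variances use the parents' inbreeding coefficients
    (Meuwissen-Luo), so the inverse is exact for inbred pedigrees.
    """
    n = len(ped)
    sire, dam = _parent_indices(ped)
    F = inbreeding_coefficients(ped)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(i: int, j: int, v: float) -> None:
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(n):
        s, d = sire[i], dam[i]
        d_i = 0.5 - 0.25 * ((F[s] if s >= 0 else -1.0)
                            + (F[d] if d >= 0 else -1.0))
        alpha = 1.0 / d_i
        add(i, i, alpha)
        for p in (s, d):
            if p >= 0:
                add(i, p, -0.5 * alpha)
                add(p, i, -0.5 * alpha)
        for p in (s, d):
            if p >= 0:
                for q in (s, d):
                    if q >= 0:
                        add(p, q, 0.25 * alpha)
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
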