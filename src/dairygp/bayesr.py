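"""Extended BayesR Gibbs sampler with heterogeneous residual weights.

SNP effects follow a four-component normal mixture: a point mass at zero
and three normal components whose variances are fixed multiples (1e-4,
1e-3, 1e-2) of the pedigree additive variance sigma2_a2.  The sampler
cycles, each iteration:

1. error variance       sigma2_e ~ (e' E^-1 e) / chi2_{n-2}
2. fixed effects        b ~ N([X'R-1X]^-1 X'R-1 y*, [X'R-1X]^-1)
3. polygenic effects    single-site conditional per animal, using A^-1
4. polygenic variance   sigma2_a ~ (a' A^-1 a) / chi2_{q-2}
5. SNP effects          per marker: sample a mixture component from the
   softmax of the component log-posteriors, then the effect from its
   conditional normal; the zero component sets the effect to exactly 0
6. mixture proportions  pr ~ Dirichlet(alpha + component counts)

Residuals e = y - Xb - Za - Wv are maintained incrementally and refreshed
from scratch every 1000 iterations to bound float drift.  Markers are
visited in a fresh random permutation each iteration.  All randomness
derives from a single seed; a chain is bit-reproducible.

The heavy loops (steps 3 and 5) are numba-compiled; the genotype matrix is
held column-major so per-marker columns are contiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from numba import njit

__all__ = ["MixtureSpec", "BayesRData", "ChainSummary", "PosteriorSummary",
           "run_chain", "run_bayesr", "sample_error_variance",
           "sample_polygenic_variance", "sample_fixed_effects",
           "update_mixture_proportions", "snp_component_logposterior"]

RESIDUAL_REFRESH = 1000


@dataclass
class MixtureSpec:
    """Component variance multipliers of sigma2_a2 and Dirichlet priors.

    The first multiplier must be 0 (the null component) and multipliers
    non-decreasing; alpha defaults to one marker per component.
    """

    multipliers: tuple[float, ...] = (0.0, 1e-4, 1e-3, 1e-2)
    dirichlet_alpha: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        m = np.asarray(self.multipliers, dtype=np.float64)
        a = np.asarray(self.dirichlet_alpha, dtype=np.float64)
        if len(m) != len(a):
            raise ValueError("multipliers and alphas differ in length")
        if m[0] != 0.0 or np.any(np.diff(m) < 0):
            raise ValueError("multipliers must start at 0 and be "
                             "non-decreasing")
        if np.any(a <= 0):
            raise ValueError("Dirichlet alphas must be positive")

    @property
    def K(self) -> int:
        return len(self.multipliers)


@dataclass
class BayesRData:
    """Inputs for one BayesR analysis.

    ``W`` is the standardized genotype matrix aligned to the phenotype
    records, ``weights`` the diagonal of E^-1 (w_i per record), and
    ``sigma2_a2`` the pedigree additive variance scaling the mixture.
    The polygenic term is active when ``Z``/``Ainv`` are given.
    """

    y: np.ndarray
    X: np.ndarray
    W: np.ndarray
    weights: np.ndarray | None = None
    Z: np.ndarray | None = None
    Ainv: sp.spmatrix | np.ndarray | None = None
    sigma2_a2: float = 1.0

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
        self.W = np.asfortranarray(self.W, dtype=np.float64)
        n = len(self.y)
        if self.X.shape[0] != n or self.W.shape[0] != n:
            raise ValueError("X/W rows must match length of y")
        if self.weights is None:
            self.weights = np.ones(n)
        else:
            self.weights = np.asarray(self.weights, dtype=np.float64)
            if (self.weights <= 0).any():
                raise ValueError("record weights must be positive")
        if self.sigma2_a2 <= 0:
            raise ValueError("sigma2_a2 must be positive")

    @property
    def has_polygenic(self) -> bool:
        return self.Z is not None and self.Ainv is not None


@dataclass
class ChainSummary:
    """Post-burn-in posterior means from one Gibbs chain."""

    v_mean: np.ndarray
    b_mean: np.ndarray
    a_mean: np.ndarray
    sigma2_e_mean: float
    sigma2_a_mean: float
    pr_mean: np.ndarray
    comp_count_mean: np.ndarray   # average markers per mixture component
    comp_freq: np.ndarray         # markers x K posterior inclusion freq.
    seed: int
    n_iter: int
    burn_in: int


@dataclass
class PosteriorSummary:
    """Across-chain averages plus the per-chain summaries."""

    chains: list[ChainSummary]
    v_mean: np.ndarray = field(init=False)
    b_mean: np.ndarray = field(init=False)
    a_mean: np.ndarray = field(init=False)
    sigma2_e_mean: float = field(init=False)
    sigma2_a_mean: float = field(init=False)
    pr_mean: np.ndarray = field(init=False)
    comp_count_mean: np.ndarray = field(init=False)
    comp_freq: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.v_mean = np.mean([c.v_mean for c in self.chains], axis=0)
        self.b_mean = np.mean([c.b_mean for c in self.chains], axis=0)
        self.a_mean = np.mean([c.a_mean for c in self.chains], axis=0)
        self.sigma2_e_mean = float(
            np.mean([c.sigma2_e_mean for c in self.chains]))
        self.sigma2_a_mean = float(
            np.mean([c.sigma2_a_mean for c in self.chains]))
        self.pr_mean = np.mean([c.pr_mean for c in self.chains], axis=0)
        self.comp_count_mean = np.mean(
            [c.comp_count_mean for c in self.chains], axis=0)
        self.comp_freq = np.mean([c.comp_freq for c in self.chains], axis=0)


# ---------------------------------------------------------------------------
# Individual conditional draws (exposed for unit testing; the chain uses the
# same formulas inside the numba kernels)

def sample_error_variance(resid: np.ndarray, weights: np.ndarray, df: int,
                          rng: np.random.Generator) -> float:
    """sigma2_e = e'E^-1 e / chi2_df (scale parameterisation)."""
    S = float(resid @ (weights * resid))
    if S < 0:
        raise ValueError("negative residual quadratic form (corruption)")
    if S == 0.0:
        return 0.0
    return S / rng.chisquare(df)


def sample_polygenic_variance(a: np.ndarray, Ainv, df: int,
                              rng: np.random.Generator) -> float:
    """sigma2_a = a'A^-1 a / chi2_df."""
    Aa = Ainv @ a
    S = float(a @ Aa)
    if S < 0:
        raise ValueError("negative polygenic quadratic form")
    if S == 0.0:
        return 0.0
    return S / rng.chisquare(df)


def sample_fixed_effects(X: np.ndarray, ystar: np.ndarray,
                         weights: np.ndarray, sigma2_e: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Joint draw b ~ N([X'R-1X]^-1 X'R-1 y*, [X'R-1X]^-1)."""
    Rinv = weights / sigma2_e
    XtRX = X.T * Rinv @ X
    cov = np.linalg.inv(XtRX)
    mean = cov @ (X.T @ (Rinv * ystar))
    L = np.linalg.cholesky(cov)
    return mean + L @ rng.standard_normal(len(mean))


def snp_component_logposterior(wj: np.ndarray, ystar: np.ndarray,
                               weights: np.ndarray, sigma2_e: float,
                               sigma2_k: np.ndarray, pr: np.ndarray,
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Per-component log-scores and shrunken conditional means for one SNP.

    L_k = -0.5 ln(1 + W'R-1W sigma2_k) + 0.5 (W'R-1 y*) v_jk + ln pr_k
    with v_jk = (W'R-1W + 1/sigma2_k)^-1 W'R-1 y*; the term y*'R-1 y*,
    constant over components, is dropped.
    """
    Rinv = weights / sigma2_e
    cj = float(wj @ (Rinv * wj))
    rhs = float(wj @ (Rinv * ystar))
    K = len(sigma2_k)
    scores = np.empty(K)
    means = np.empty(K)
    for k in range(K):
        if sigma2_k[k] == 0.0:
            means[k] = 0.0
            scores[k] = np.log(pr[k]) if pr[k] > 0 else -np.inf
        else:
            vjk = rhs / (cj + 1.0 / sigma2_k[k])
            means[k] = vjk
            scores[k] = (-0.5 * np.log1p(cj * sigma2_k[k]) + 0.5 * rhs * vjk
                         + (np.log(pr[k]) if pr[k] > 0 else -np.inf))
    return scores, means


def update_mixture_proportions(counts: np.ndarray, alpha: np.ndarray,
                               rng: np.random.Generator) -> np.ndarray:
    """pr ~ Dirichlet(alpha + counts)."""
    return rng.dirichlet(np.asarray(alpha, float) + np.asarray(counts, float))


# ---------------------------------------------------------------------------
# numba kernels

@njit(cache=True)
def _seed_numba(seed):  # pragma: no cover - trivial
    np.random.seed(seed)


@njit(cache=True)
def _snp_sweep(W, resid, weights, v, comp, sigma2_e, sigma2_k, logpr, order):
    """One Gibbs sweep over markers in the given order.

    resid and v are updated in place; returns the component counts.
    """
    n, m = W.shape
    K = sigma2_k.shape[0]
    counts = np.zeros(K, dtype=np.int64)
    scores = np.empty(K)
    means = np.empty(K)
    for t in range(m):
        j = order[t]
        v_old = v[j]
        # cj = W_j' R^-1 W_j and rhs = W_j' R^-1 y*  (y* = resid + W_j v_old)
        cj = 0.0
        dot = 0.0
        for i in range(n):
            wij = W[i, j]
            rw = wij * weights[i]
            cj += rw * wij
            dot += rw * resid[i]
        cj /= sigma2_e
        rhs = dot / sigma2_e + cj * v_old
        best = -1.0e308
        for k in range(K):
            if sigma2_k[k] == 0.0:
                means[k] = 0.0
                scores[k] = logpr[k]
            else:
                vjk = rhs / (cj + 1.0 / sigma2_k[k])
                means[k] = vjk
                scores[k] = (-0.5 * np.log(1.0 + cj * sigma2_k[k])
                             + 0.5 * rhs * vjk + logpr[k])
            if scores[k] > best:
                best = scores[k]
        tot = 0.0
        for k in range(K):
            scores[k] = np.exp(scores[k] - best)
            tot += scores[k]
        u = np.random.random() * tot
        acc = 0.0
        knew = K - 1
        for k in range(K):
            acc += scores[k]
            if u <= acc:
                knew = k
                break
        if sigma2_k[knew] == 0.0:
            v_new = 0.0
        else:
            sd = np.sqrt(1.0 / (cj + 1.0 / sigma2_k[knew]))
            v_new = means[knew] + sd * np.random.standard_normal()
        comp[j] = knew
        counts[knew] += 1
        delta = v_new - v_old
        if delta != 0.0:
            v[j] = v_new
            for i in range(n):
                resid[i] -= W[i, j] * delta
    return counts


@njit(cache=True)
def _polygenic_sweep(resid, weights, a, zrow, rec_of, n_rec_of,
                     Ainv_indptr, Ainv_indices, Ainv_data,
                     sigma2_e, sigma2_a):
    """Single-site Gibbs update of polygenic effects, in place.

    rec_of/n_rec_of give, per animal, the records it owns (CSR-like flat
    layout); animals without records are updated from the prior
    conditional alone.
    """
    q = a.shape[0]
    inv_sa = 1.0 / sigma2_a
    for i in range(q):
        # data part: sum over i's records of w/sigma2_e * (resid + a_i)
        zrz = 0.0
        zry = 0.0
        for t in range(zrow[i], zrow[i] + n_rec_of[i]):
            r = rec_of[t]
            wr = weights[r] / sigma2_e
            zrz += wr
            zry += wr * (resid[r] + a[i])
        # prior part: -inv_sa * sum_{j != i} Ainv_ij a_j ; diag Ainv_ii
        off = 0.0
        dii = 0.0
        for ptr in range(Ainv_indptr[i], Ainv_indptr[i + 1]):
            j = Ainv_indices[ptr]
            if j == i:
                dii += Ainv_data[ptr]
            else:
                off += Ainv_data[ptr] * a[j]
        prec = zrz + dii * inv_sa
        mean = (zry - inv_sa * off) / prec
        a_new = mean + np.random.standard_normal() / np.sqrt(prec)
        delta = a_new - a[i]
        if delta != 0.0:
            a[i] = a_new
            for t in range(zrow[i], zrow[i] + n_rec_of[i]):
                resid[rec_of[t]] -= delta
    return a


def _records_by_animal(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray,
                                               np.ndarray]:
    """Flat CSR-like map animal -> record indices from incidence Z."""
    q = Z.shape[1]
    rec_lists = [np.nonzero(Z[:, i])[0] for i in range(q)]
    n_rec = np.array([len(r) for r in rec_lists], dtype=np.int64)
    zrow = np.concatenate(([0], np.cumsum(n_rec)[:-1])).astype(np.int64)
    rec_of = (np.concatenate(rec_lists).astype(np.int64)
              if rec_lists else np.zeros(0, dtype=np.int64))
    return zrow, rec_of, n_rec


def run_chain(data: BayesRData, spec: MixtureSpec | None = None,
              n_iter: int = 30_000, burn_in: int = 20_000,
              seed: int = 0, fixed_pr: np.ndarray | None = None,
              snp_order: str = "permute") -> ChainSummary:
    """Run one Gibbs chain and summarise the post-burn-in iterations.

    ``fixed_pr`` freezes the mixture proportions (skipping the Dirichlet
    update), used for the ridge-limit oracle check.  ``snp_order`` is
    "permute" (fresh permutation per iteration) or "fixed" for debugging.
    """
    spec = spec or MixtureSpec()
    if burn_in >= n_iter:
        raise ValueError("burn_in must be < n_iter")
    n, m = data.W.shape
    if n <= 2:
        raise ValueError("need more than 2 records")
    K = spec.K
    sigma2_k = np.asarray(spec.multipliers, float) * data.sigma2_a2
    alpha = np.asarray(spec.dirichlet_alpha, float)
    rng = np.random.default_rng(seed)
    _seed_numba(int(rng.integers(0, 2**31 - 1)))

    y = data.y
    X = data.X
    W = data.W
    weights = data.weights
    vary = float(np.var(y))
    poly = data.has_polygenic
    if poly:
        Ainv = sp.csr_matrix(data.Ainv)
        q = Ainv.shape[0]
        Z = np.asarray(data.Z, dtype=np.float64)
        zrow, rec_of, n_rec = _records_by_animal(Z)
    else:
        q = 0

    b = np.zeros(X.shape[1])
    a = np.zeros(q)
    v = np.zeros(m)
    comp = np.zeros(m, dtype=np.int64)
    pr = (np.asarray(fixed_pr, float) if fixed_pr is not None
          else np.full(K, 1.0 / K))
    sigma2_e = max(vary, 1e-12)
    sigma2_a = data.sigma2_a2
    resid = y - X @ b

    keep = n_iter - burn_in
    v_sum = np.zeros(m)
    b_sum = np.zeros(X.shape[1])
    a_sum = np.zeros(q)
    pr_sum = np.zeros(K)
    count_sum = np.zeros(K)
    freq = np.zeros((m, K))
    s2e_sum = 0.0
    s2a_sum = 0.0

    for it in range(n_iter):
        # 1. error variance
        sigma2_e = sample_error_variance(resid, weights, n - 2, rng)
        if sigma2_e <= 0 or sigma2_e > 1e6 * max(vary, 1e-12):
            raise RuntimeError(
                f"chain diverged at iteration {it}: sigma2_e={sigma2_e:.4g} "
                f"(phenotypic variance {vary:.4g})")
        # 2. fixed effects
        ystar = resid + X @ b
        b_new = sample_fixed_effects(X, ystar, weights, sigma2_e, rng)
        resid -= X @ (b_new - b)
        b = b_new
        # 3/4. polygenic effects and variance
        if poly:
            _polygenic_sweep(resid, weights, a, zrow, rec_of, n_rec,
                             Ainv.indptr.astype(np.int64),
                             Ainv.indices.astype(np.int64), Ainv.data,
                             sigma2_e, sigma2_a)
            sigma2_a = sample_polygenic_variance(a, Ainv, max(q - 2, 1), rng)
            sigma2_a = max(sigma2_a, 1e-10 * max(vary, 1e-12))
        # 5. SNP effects
        if snp_order == "permute":
            order = rng.permutation(m).astype(np.int64)
        else:
            order = np.arange(m, dtype=np.int64)
        with np.errstate(divide="ignore"):
            logpr = np.log(pr)
        counts = _snp_sweep(W, resid, weights, v, comp, sigma2_e,
                            sigma2_k, logpr, order)
        # 6. mixture proportions
        if fixed_pr is None:
            pr = update_mixture_proportions(counts, alpha, rng)
        # periodic full residual refresh against float drift
        if (it + 1) % RESIDUAL_REFRESH == 0:
            resid = y - X @ b - W @ v
            if poly:
                resid -= Z @ a
        if it >= burn_in:
            v_sum += v
            b_sum += b
            a_sum += a
            pr_sum += pr
            count_sum += counts
            s2e_sum += sigma2_e
            s2a_sum += sigma2_a
            for k in range(K):
                freq[comp == k, k] += 1.0

    return ChainSummary(
        v_mean=v_sum / keep, b_mean=b_sum / keep, a_mean=a_sum / keep,
        sigma2_e_mean=s2e_sum / keep, sigma2_a_mean=s2a_sum / keep,
        pr_mean=pr_sum / keep, comp_count_mean=count_sum / keep,
        comp_freq=freq / keep, seed=seed, n_iter=n_iter, burn_in=burn_in)


def run_bayesr(data: BayesRData, spec: MixtureSpec | None = None,
               n_iter: int = 30_000, burn_in: int = 20_000,
               n_chains: int = 5, base_seed: int = 0,
               **kwargs) -> PosteriorSummary:
    """Run replicate Gibbs chains (seeds base_seed + chain index) and
    average their posterior means."""
    chains = []
    for c in range(n_chains):
        try:
            chains.append(run_chain(data, spec, n_iter, burn_in,
                                    seed=base_seed + c, **kwargs))
        except RuntimeError as exc:
            raise RuntimeError(f"chain {c} failed: {exc}") from exc
    return PosteriorSummary(chains)
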