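"""Weighted GBLUP: EM-REML variance components, mixed-model equations,
and SNP-effect back-solving.

The model is y = Xb + Za + Qg + e with a ~ N(0, A sigma2_a) the pedigree
polygenic term, g ~ N(0, G sigma2_g) the genomic values, and
e ~ N(0, E sigma2_e) with heterogeneous record weights E = diag(1/w_i).
The coefficient matrix is the standard three-block MME with
R^-1 = E^-1 / sigma2_e:

    [X'R-1X        X'R-1Z                X'R-1Q              ] [b]   [X'R-1y]
    [Z'R-1X  Z'R-1Z + A^-1/sigma2_a      Z'R-1Q              ] [a] = [Z'R-1y]
    [Q'R-1X        Q'R-1Z          Q'R-1Q + G^-1/sigma2_g    ] [g]   [Q'R-1y]

SNP effects are recovered from genomic values as v = W' G^-1 g / m, which
reconstructs W v = g exactly when G = W W'/m (plain mode).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve

from .relmat import GRM, StandardizedGenotypes, invert_grm

__all__ = ["MixedModelSpec", "VarianceComponents", "MMESolution",
           "estimate_variance_components", "solve_mme",
           "backsolve_snp_effects", "reml_loglik"]

log = logging.getLogger(__name__)

MAX_EQUATIONS = 20_000


@dataclass
class MixedModelSpec:
    """Data bundle for one weighted animal-model analysis.

    ``Z``/``Q`` are incidence matrices from records to polygenic/genomic
    levels; ``Einv_diag`` holds the record weights w_i (the diagonal of
    E^-1).  Either random term may be omitted by leaving its relationship
    matrix as None.
    """

    y: np.ndarray
    X: np.ndarray
    Einv_diag: np.ndarray | None = None
    Z: np.ndarray | None = None
    Ainv: sp.spmatrix | np.ndarray | None = None
    A: np.ndarray | None = None
    Q: np.ndarray | None = None
    G: GRM | np.ndarray | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
        n = len(self.y)
        if self.X.shape[0] != n:
            raise ValueError("X rows != length of y")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("X is rank deficient; drop a reference level")
        if self.Einv_diag is None:
            self.Einv_diag = np.ones(n)
        else:
            self.Einv_diag = np.asarray(self.Einv_diag, dtype=np.float64)
            if len(self.Einv_diag) != n or (self.Einv_diag <= 0).any():
                raise ValueError("Einv_diag must be positive, length n")

    @property
    def has_polygenic(self) -> bool:
        return self.Z is not None and (self.Ainv is not None
                                       or self.A is not None)

    @property
    def has_genomic(self) -> bool:
        return self.Q is not None and self.G is not None

    def g_matrix(self) -> np.ndarray:
        return self.G.G if isinstance(self.G, GRM) else self.G


@dataclass
class VarianceComponents:
    sigma2_e: float
    sigma2_a: float = 0.0
    sigma2_g: float = 0.0
    converged: bool = True
    n_iter: int = 0
    loglik: float = np.nan


@dataclass
class MMESolution:
    b_hat: np.ndarray
    a_hat: np.ndarray
    g_hat: np.ndarray
    v_hat: np.ndarray | None = None


def _covariances(spec: MixedModelSpec) -> list[np.ndarray]:
    """Per-random-term covariance structures Z K Z' on the record scale."""
    out = []
    if spec.has_polygenic:
        A = spec.A
        if A is None:
            Ainv = spec.Ainv
            Ainv = Ainv.toarray() if sp.issparse(Ainv) else np.asarray(Ainv)
            A = np.linalg.inv(Ainv)
        out.append(spec.Z @ A @ spec.Z.T)
    if spec.has_genomic:
        out.append(spec.Q @ spec.g_matrix() @ spec.Q.T)
    return out


def reml_loglik(spec: MixedModelSpec, vc: VarianceComponents) -> float:
    """Restricted log-likelihood -0.5(ln|V| + ln|X'V-1X| + y'Py)."""
    n = len(spec.y)
    E = np.diag(1.0 / spec.Einv_diag)
    V = vc.sigma2_e * E
    comps = []
    if spec.has_polygenic:
        comps.append(vc.sigma2_a)
    if spec.has_genomic:
        comps.append(vc.sigma2_g)
    for s2, ZKZ in zip(comps, _covariances(spec)):
        V = V + s2 * ZKZ
    sign, logdetV = np.linalg.slogdet(V)
    Vinv = np.linalg.inv(V)
    XtVX = spec.X.T @ Vinv @ spec.X
    sign2, logdetX = np.linalg.slogdet(XtVX)
    P = Vinv - Vinv @ spec.X @ np.linalg.solve(XtVX, spec.X.T @ Vinv)
    return -0.5 * (logdetV + logdetX + spec.y @ P @ spec.y)


def _build_mme(spec: MixedModelSpec, vc: VarianceComponents
               ) -> tuple[np.ndarray, np.ndarray, list[tuple[str, slice]]]:
    """Assemble the blocked coefficient matrix and right-hand side."""
    Rinv = spec.Einv_diag / vc.sigma2_e
    designs: list[tuple[str, np.ndarray]] = [("b", spec.X)]
    if spec.has_polygenic:
        designs.append(("a", spec.Z))
    if spec.has_genomic:
        designs.append(("g", spec.Q))
    sizes = [M.shape[1] for _, M in designs]
    total = sum(sizes)
    if total > MAX_EQUATIONS:
        raise ValueError(
            f"{total} equations exceeds the dense-solver limit "
            f"{MAX_EQUATIONS}; reduce the problem or solve blocks "
            f"iteratively outside this desk-scale tool")
    C = np.zeros((total, total))
    rhs = np.zeros(total)
    offs = np.cumsum([0] + sizes)
    slices = [(name, slice(offs[i], offs[i + 1]))
              for i, (name, _) in enumerate(designs)]
    for i, (_, Mi) in enumerate(designs):
        MiR = Mi.T * Rinv
        rhs[slices[i][1]] = MiR @ spec.y
        for j, (_, Mj) in enumerate(designs):
            if j < i:
                continue
            blk = MiR @ Mj
            C[slices[i][1], slices[j][1]] = blk
            if j > i:
                C[slices[j][1], slices[i][1]] = blk.T
    for name, sl in slices:
        if name == "a":
            Ainv = spec.Ainv
            if Ainv is None:
                Ainv = np.linalg.inv(spec.A)
            Ainv = Ainv.toarray() if sp.issparse(Ainv) else np.asarray(Ainv)
            C[sl, sl] += Ainv / vc.sigma2_a
        elif name == "g":
            Ginv = (invert_grm(spec.G) if isinstance(spec.G, GRM)
                    else np.linalg.inv(spec.G))
            C[sl, sl] += Ginv / vc.sigma2_g
    return C, rhs, slices


def solve_mme(spec: MixedModelSpec, vc: VarianceComponents) -> MMESolution:
    """Solve the weighted mixed-model equations by dense factorisation."""
    for name, s2 in (("sigma2_a", vc.sigma2_a), ("sigma2_g", vc.sigma2_g)):
        term = "a" if name == "sigma2_a" else "g"
        included = spec.has_polygenic if term == "a" else spec.has_genomic
        if included and s2 <= 0:
            raise ValueError(f"{name} must be > 0 for the included term")
    C, rhs, slices = _build_mme(spec, vc)
    try:
        sol = cho_solve(cho_factor(C), rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular MME coefficient matrix; check design-matrix rank or "
            "add a small ridge to G") from exc
    by_name = dict(slices)
    q = spec.Z.shape[1] if spec.has_polygenic else 0
    ng = spec.Q.shape[1] if spec.has_genomic else 0
    return MMESolution(
        b_hat=sol[by_name["b"]],
        a_hat=sol[by_name["a"]] if "a" in by_name else np.zeros(q),
        g_hat=sol[by_name["g"]] if "g" in by_name else np.zeros(ng),
    )


def _single_term_reml(spec: MixedModelSpec, which: str) -> VarianceComponents:
    """Exact REML for one random term: V = S sigma2_u + E sigma2_e.

    Whitening by E^-1/2 and eigendecomposing the whitened covariance
    structure reduces each likelihood evaluation to O(n^2), so the
    variance ratio can be profiled out and maximised in one dimension.
    """
    from scipy.optimize import minimize_scalar

    n = len(spec.y)
    p = spec.X.shape[1]
    S = _covariances(spec)[0]
    es = np.sqrt(spec.Einv_diag)
    yt = es * spec.y
    Xt = es[:, None] * spec.X
    St = es[:, None] * S * es[None, :]
    d, U = np.linalg.eigh(St)
    d = np.clip(d, 0.0, None)
    yr = U.T @ yt
    Xr = U.T @ Xt

    def profile(log_lam: float) -> tuple[float, float]:
        lam = np.exp(log_lam)
        w = 1.0 / (lam * d + 1.0)
        XtWX = (Xr.T * w) @ Xr
        beta = np.linalg.solve(XtWX, Xr.T @ (w * yr))
        r = yr - Xr @ beta
        rss = float(r @ (w * r))
        s2e = rss / (n - p)
        _, ldx = np.linalg.slogdet(XtWX)
        crit = 0.5 * ((n - p) * np.log(s2e)
                      + float(np.sum(np.log(lam * d + 1.0))) + ldx)
        return crit, s2e

    res = minimize_scalar(lambda t: profile(t)[0], bounds=(-25.0, 25.0),
                          method="bounded",
                          options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    _, s2e = profile(res.x)
    vc = VarianceComponents(sigma2_e=s2e)
    if which == "a":
        vc.sigma2_a = lam * s2e
    else:
        vc.sigma2_g = lam * s2e
    vc.converged = bool(res.success)
    vc.n_iter = int(res.nfev)
    vc.loglik = reml_loglik(spec, vc)
    return vc


def estimate_variance_components(spec: MixedModelSpec,
                                 max_iter: int = 200,
                                 tol: float = 1e-6,
                                 start: VarianceComponents | None = None,
                                 method: str = "auto",
                                 ) -> VarianceComponents:
    """REML for any of the models {e}, {a,e}, {g,e}, {a,g,e}.

    Single-random-term models use exact one-dimensional profiled REML in
    the eigenbasis of the whitened covariance structure ("auto"); the
    general model, or ``method="em"``, runs EM-REML, whose updates are
    monotone in the restricted likelihood.  Convergence of EM is declared
    when every component's relative change drops below ``tol``;
    non-convergence returns the last iterate with ``converged=False``.
    """
    n = len(spec.y)
    p = spec.X.shape[1]
    vary = float(np.var(spec.y))
    if vary == 0:
        log.warning("zero-variance phenotype vector; degenerate components")
        return VarianceComponents(0.0, 0.0, 0.0, converged=True, n_iter=0)
    n_terms = int(spec.has_polygenic) + int(spec.has_genomic)
    if n_terms == 1 and method == "auto":
        return _single_term_reml(spec, "a" if spec.has_polygenic else "g")
    init = vary / (n_terms + 1)
    vc = start or VarianceComponents(
        sigma2_e=init,
        sigma2_a=init if spec.has_polygenic else 0.0,
        sigma2_g=init if spec.has_genomic else 0.0)
    floor = 1e-8 * vary
    vc.sigma2_e = max(vc.sigma2_e, floor)
    if spec.has_polygenic:
        vc.sigma2_a = max(vc.sigma2_a, floor)
    if spec.has_genomic:
        vc.sigma2_g = max(vc.sigma2_g, floor)

    if n_terms == 0:
        # GLS residual variance, closed form
        Rw = spec.Einv_diag
        XtRX = spec.X.T * Rw @ spec.X
        b = np.linalg.solve(XtRX, spec.X.T @ (Rw * spec.y))
        e = spec.y - spec.X @ b
        s2 = float(e @ (Rw * e) / (n - p))
        return VarianceComponents(s2, 0.0, 0.0, True, 1,
                                  reml_loglik(spec, VarianceComponents(s2)))

    Ainv_d = None
    if spec.has_polygenic:
        Ainv_d = spec.Ainv if spec.Ainv is not None else np.linalg.inv(spec.A)
        Ainv_d = (Ainv_d.toarray() if sp.issparse(Ainv_d)
                  else np.asarray(Ainv_d))
    Ginv_d = None
    if spec.has_genomic:
        Ginv_d = (invert_grm(spec.G) if isinstance(spec.G, GRM)
                  else np.linalg.inv(spec.G))

    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        C, rhs, slices = _build_mme(spec, vc)
        Cinv = np.linalg.inv(C)
        sol = Cinv @ rhs
        by_name = dict(slices)
        new = VarianceComponents(vc.sigma2_e, vc.sigma2_a, vc.sigma2_g)
        # EM updates: sigma2_u = (u'K^-1 u + tr(K^-1 C_uu)) / q
        if spec.has_polygenic:
            sl = by_name["a"]
            a = sol[sl]
            q = len(a)
            new.sigma2_a = float(
                (a @ Ainv_d @ a + np.trace(Ainv_d @ Cinv[sl, sl])) / q)
        if spec.has_genomic:
            sl = by_name["g"]
            gsol = sol[sl]
            qg = len(gsol)
            new.sigma2_g = float(
                (gsol @ Ginv_d @ gsol
                 + np.trace(Ginv_d @ Cinv[sl, sl])) / qg)
        # residual: sigma2_e = y'E^-1 e_hat / (n - p)
        fitted = spec.X @ sol[by_name["b"]]
        if spec.has_polygenic:
            fitted = fitted + spec.Z @ sol[by_name["a"]]
        if spec.has_genomic:
            fitted = fitted + spec.Q @ sol[by_name["g"]]
        e = spec.y - fitted
        new.sigma2_e = float(spec.y @ (spec.Einv_diag * e) / (n - p))
        new.sigma2_e = max(new.sigma2_e, floor)
        rel = max(
            abs(new.sigma2_e - vc.sigma2_e) / max(vc.sigma2_e, floor),
            abs(new.sigma2_a - vc.sigma2_a) / max(vc.sigma2_a, floor)
            if spec.has_polygenic else 0.0,
            abs(new.sigma2_g - vc.sigma2_g) / max(vc.sigma2_g, floor)
            if spec.has_genomic else 0.0)
        vc = new
        if rel < tol:
            converged = True
            break
    if not converged:
        log.warning("EM-REML did not converge in %d iterations", max_iter)
    vc.converged = converged
    vc.n_iter = it
    vc.loglik = reml_loglik(spec, vc)
    return vc


def backsolve_snp_effects(sol: MMESolution, sg: StandardizedGenotypes,
                          grm: GRM) -> np.ndarray:
    """SNP effects from genomic values: v = W' G^-1 g / m.

    With the plain G = W W'/m this satisfies W v = g exactly; with the
    Yang-adjusted diagonal the identity is approximate.
    """
    if sg.W.shape[0] != len(sol.g_hat):
        raise ValueError("genomic-value vector does not match W rows")
    Ginv = invert_grm(grm)
    return sg.W.T @ (Ginv @ sol.g_hat) / grm.m
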