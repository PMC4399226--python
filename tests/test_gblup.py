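"""EM-REML, mixed-model equations, and SNP-effect back-solving."""

import numpy as np
import pytest

from dairygp.gblup import (MixedModelSpec, VarianceComponents,
                           backsolve_snp_effects,
                           estimate_variance_components, reml_loglik,
                           solve_mme)
from dairygp.io_formats import GenotypeSet, MarkerMap
from dairygp.relmat import compute_grm, standardize_genotypes


def _hwe_genotypes(n, m, seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, m)
    d = rng.binomial(2, p, size=(n, m)).astype(float)
    mm = MarkerMap(["1"] * m, np.arange(1, m + 1),
                   [f"m{j}" for j in range(m)])
    return GenotypeSet(d, [f"a{i}" for i in range(n)], mm)


def _ref_sg(n_ref, m, seed, n_extra=40):
    """Standardized genotypes for a reference subset, using allele
    frequencies from a larger standardising population so the subset GRM
    is invertible (own-sample frequencies centre the columns exactly and
    make G singular)."""
    g = _hwe_genotypes(n_ref + n_extra, m, seed)
    freq = g.dosages.mean(axis=0) / 2.0
    return standardize_genotypes(g.dosages[:n_ref], freq=freq)


def _sim_genomic(n=500, m=2000, s2g=1.0, s2e=1.0, seed=0):
    rng = np.random.default_rng(seed)
    sg = standardize_genotypes(_hwe_genotypes(n, m, seed))
    grm = compute_grm(sg, mode="plain")
    v = rng.standard_normal(sg.m) * np.sqrt(s2g / sg.m)
    g = sg.W @ v
    y = 2.0 + g + rng.standard_normal(n) * np.sqrt(s2e)
    X = np.ones((n, 1))
    return MixedModelSpec(y=y, X=X, Q=np.eye(n), G=grm), g


class TestREML:
    def test_genomic_variance_recovery(self):
        """Simulated sigma2_g = sigma2_e = 1 recovered within a wide
        simulation band."""
        spec, _ = _sim_genomic(seed=3)
        vc = estimate_variance_components(spec)
        assert vc.converged
        assert 0.6 < vc.sigma2_g < 1.4
        assert 0.6 < vc.sigma2_e < 1.4

    def test_constant_phenotype_degenerate(self):
        spec = MixedModelSpec(y=np.ones(20), X=np.ones((20, 1)),
                              Q=np.eye(20), G=np.eye(20))
        vc = estimate_variance_components(spec)
        assert vc.sigma2_g == 0.0
        assert vc.sigma2_e == 0.0

    def test_pedigree_only_h2_recovery(self):
        """Half-sib families give the relatedness needed to separate the
        additive and residual variances; true h2 = 0.5."""
        rng = np.random.default_rng(4)
        n_sires, n_off = 50, 10
        n = n_sires * n_off
        sire_of = np.repeat(np.arange(n_sires), n_off)
        # a_offspring = 0.5 a_sire + mendelian, var(a) = 1
        a_sire = rng.standard_normal(n_sires)
        a = 0.5 * a_sire[sire_of] + np.sqrt(0.75) * rng.standard_normal(n)
        y = a + rng.standard_normal(n)
        A = np.eye(n)
        for s in range(n_sires):
            rows = np.nonzero(sire_of == s)[0]
            for i in rows:
                for j in rows:
                    if i != j:
                        A[i, j] = 0.25
        spec = MixedModelSpec(y=y, X=np.ones((n, 1)), Z=np.eye(n), A=A)
        vc = estimate_variance_components(spec)
        h2 = vc.sigma2_a / (vc.sigma2_a + vc.sigma2_e)
        assert 0.35 < h2 < 0.65

    def test_em_loglik_monotone(self):
        """EM iterates never decrease the restricted likelihood."""
        spec, _ = _sim_genomic(n=80, m=120, seed=5)
        lls = []
        vc = None
        for it in range(1, 15):
            vc = estimate_variance_components(spec, max_iter=it, tol=0.0,
                                              method="em")
            lls.append(reml_loglik(spec, vc))
        diffs = np.diff(lls)
        assert (diffs > -1e-6).all()

    def test_em_agrees_with_profiled_reml(self):
        spec, _ = _sim_genomic(n=100, m=150, seed=6)
        vc_fast = estimate_variance_components(spec)
        vc_em = estimate_variance_components(spec, method="em",
                                             max_iter=500, tol=1e-10)
        assert vc_em.sigma2_g == pytest.approx(vc_fast.sigma2_g, rel=1e-2)
        assert vc_em.sigma2_e == pytest.approx(vc_fast.sigma2_e, rel=1e-2)


class TestSolveMME:
    def test_hand_solved_two_animal_system(self):
        """G=I, equal variances, y=[0,2]: mean 1, genomic values -+0.5."""
        spec = MixedModelSpec(y=np.array([0.0, 2.0]), X=np.ones((2, 1)),
                              Q=np.eye(2), G=np.eye(2))
        sol = solve_mme(spec, VarianceComponents(sigma2_e=1.0, sigma2_g=1.0))
        assert sol.b_hat[0] == pytest.approx(1.0)
        np.testing.assert_allclose(sol.g_hat, [-0.5, 0.5], atol=1e-12)

    def test_unit_weights_equal_no_weights(self):
        spec, _ = _sim_genomic(n=60, m=100, seed=7)
        vc = VarianceComponents(sigma2_e=1.0, sigma2_g=0.5)
        s1 = solve_mme(spec, vc)
        spec_w = MixedModelSpec(y=spec.y, X=spec.X, Einv_diag=np.ones(60),
                                Q=spec.Q, G=spec.G)
        s2 = solve_mme(spec_w, vc)
        np.testing.assert_allclose(s1.g_hat, s2.g_hat, atol=1e-10)

    def test_doubling_weights_equals_halving_sigma2e(self):
        rng = np.random.default_rng(8)
        spec, _ = _sim_genomic(n=60, m=100, seed=9)
        w = rng.uniform(0.5, 4.0, 60)
        base = MixedModelSpec(y=spec.y, X=spec.X, Einv_diag=w,
                              Q=spec.Q, G=spec.G)
        doubled = MixedModelSpec(y=spec.y, X=spec.X, Einv_diag=2 * w,
                                 Q=spec.Q, G=spec.G)
        s1 = solve_mme(doubled, VarianceComponents(1.0, sigma2_g=0.5))
        s2 = solve_mme(base, VarianceComponents(0.5, sigma2_g=0.5))
        np.testing.assert_allclose(s1.b_hat, s2.b_hat, atol=1e-10)
        np.testing.assert_allclose(s1.g_hat, s2.g_hat, atol=1e-10)

    def test_fixed_point_identities(self):
        """Substituting the solutions back into each block equation
        reproduces it: the three-block fixed point of the MME."""
        rng = np.random.default_rng(10)
        n = 80
        sg = _ref_sg(n, 150, 11)
        grm = compute_grm(sg, mode="plain")
        w = rng.uniform(0.5, 3.0, n)
        y = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n)])
        A = np.eye(n)
        spec = MixedModelSpec(y=y, X=X, Einv_diag=w, Z=np.eye(n),
                              A=A, Ainv=np.eye(n), Q=np.eye(n), G=grm)
        vc = VarianceComponents(sigma2_e=1.0, sigma2_a=0.3, sigma2_g=0.7)
        sol = solve_mme(spec, vc)
        Rinv = np.diag(w / vc.sigma2_e)
        from dairygp.relmat import invert_grm
        Ginv = invert_grm(grm)  # the same inverse the solver used
        b, a, g = sol.b_hat, sol.a_hat, sol.g_hat
        b2 = np.linalg.solve(X.T @ Rinv @ X, X.T @ Rinv @ (y - a - g))
        a2 = np.linalg.solve(Rinv + np.eye(n) / vc.sigma2_a,
                             Rinv @ (y - X @ b - g))
        g2 = np.linalg.solve(Rinv + Ginv / vc.sigma2_g,
                             Rinv @ (y - X @ b - a))
        assert np.abs(b2 - b).max() < 1e-8
        assert np.abs(a2 - a).max() < 1e-8
        assert np.abs(g2 - g).max() < 1e-8

    def test_missing_variance_rejected(self):
        spec = MixedModelSpec(y=np.zeros(5), X=np.ones((5, 1)),
                              Q=np.eye(5), G=np.eye(5))
        with pytest.raises(ValueError, match="sigma2_g"):
            solve_mme(spec, VarianceComponents(sigma2_e=1.0, sigma2_g=0.0))


class TestBacksolve:
    def _fit(self, n=60, m=200, seed=12):
        rng = np.random.default_rng(seed)
        sg = _ref_sg(n, m, seed)
        grm = compute_grm(sg, mode="plain")
        y = rng.standard_normal(n)
        spec = MixedModelSpec(y=y, X=np.ones((n, 1)), Q=np.eye(n), G=grm)
        sol = solve_mme(spec, VarianceComponents(1.0, sigma2_g=0.5))
        return sol, sg, grm

    def test_reconstruction_identity_plain_mode(self):
        sol, sg, grm = self._fit()
        v = backsolve_snp_effects(sol, sg, grm)
        assert np.abs(sg.W @ v - sol.g_hat).max() < 1e-8

    def test_zero_gebv_zero_effects(self):
        sol, sg, grm = self._fit()
        sol.g_hat = np.zeros_like(sol.g_hat)
        np.testing.assert_allclose(backsolve_snp_effects(sol, sg, grm), 0.0)

    def test_single_marker_closed_form(self):
        rng = np.random.default_rng(13)
        d = rng.integers(0, 3, size=(30, 1)).astype(float)
        mm = MarkerMap(["1"], [1], ["m0"])
        sg = standardize_genotypes(GenotypeSet(d, [str(i) for i in
                                                   range(30)], mm))
        grm = compute_grm(sg, mode="plain")
        g_hat = rng.standard_normal(30)
        sol_v = backsolve_snp_effects(
            type("S", (), {"g_hat": g_hat})(), sg, grm)
        x = sg.W[:, 0]
        # v = x'G^-1 g / m with G = xx'/1: regression of g on the column
        expected = x @ np.linalg.solve(grm.G + 1e-9 * np.eye(30), g_hat)
        assert sol_v[0] == pytest.approx(expected, rel=1e-3)

    def test_two_route_prediction_equivalence(self):
        """Predicting validation animals through W_val v-hat equals the
        G-block regression route on the same data (plain mode)."""
        rng = np.random.default_rng(14)
        n_ref, n_val, m = 60, 15, 200
        g_all = _hwe_genotypes(n_ref + n_val, m, 15)
        sg_all = standardize_genotypes(g_all)
        W = sg_all.W
        W_ref, W_val = W[:n_ref], W[n_ref:]
        from dairygp.relmat import GRM
        grm_ref = GRM(W_ref @ W_ref.T / sg_all.m, sg_all.m, "plain")
        y = rng.standard_normal(n_ref)
        spec = MixedModelSpec(y=y, X=np.ones((n_ref, 1)), Q=np.eye(n_ref),
                              G=grm_ref)
        sol = solve_mme(spec, VarianceComponents(1.0, sigma2_g=0.5))
        sg_ref = type(sg_all)(W_ref, sg_all.freq, sg_all.marker_kept_mask)
        v = backsolve_snp_effects(sol, sg_ref, grm_ref)
        route1 = W_val @ v
        G_vr = W_val @ W_ref.T / sg_all.m
        route2 = G_vr @ np.linalg.solve(grm_ref.G, sol.g_hat)
        assert np.abs(route1 - route2).max() < 1e-8
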