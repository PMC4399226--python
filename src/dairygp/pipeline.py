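"""End-to-end analysis plumbing: design matrices, aligned data bundles,
and the GBLUP / BayesR fits used by the CLI and the validation harness."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayesr import BayesRData, MixtureSpec, PosteriorSummary, run_bayesr
from .gblup import (MMESolution, MixedModelSpec, VarianceComponents,
                    backsolve_snp_effects, estimate_variance_components,
                    solve_mme)
from .io_formats import GenotypeSet, PhenotypeTable
from .relmat import GRM, StandardizedGenotypes, compute_grm, \
    standardize_genotypes
from .validate import PredictionSet, predict_gebv
from .weights import TraitParams, residual_weight_diagonal

__all__ = ["build_design", "AnalysisData", "prepare_analysis",
           "fit_gblup", "fit_bayesr", "predict_validation"]


def build_design(df: pd.DataFrame) -> np.ndarray:
    """Fixed-effect design: overall mean, breed, sex nested within breed.

    Reference-level dummy coding: the first breed and, within each breed,
    the first sex level are absorbed into the mean.  Degenerate columns
    (single-level factors) are dropped so X stays full rank.
    """
    n = len(df)
    cols = [np.ones(n)]
    breeds = sorted(df["breed"].astype(str).unique())
    for br in breeds[1:]:
        cols.append((df["breed"].astype(str) == br).to_numpy(float))
    for br in breeds:
        in_br = df["breed"].astype(str) == br
        sexes = sorted(df.loc[in_br, "sex"].astype(str).unique())
        for sx in sexes[1:]:
            cols.append((in_br & (df["sex"].astype(str) == sx))
                        .to_numpy(float))
    return np.column_stack(cols)


@dataclass
class AnalysisData:
    """Phenotype records aligned to standardized genotypes.

    Rows of ``W`` correspond one-to-one with kept phenotype records; the
    training allele frequencies are retained to standardize validation
    animals identically.
    """

    y: np.ndarray
    X: np.ndarray
    W: np.ndarray
    weights: np.ndarray          # w_i = diagonal of E^-1
    animal_ids: list[str]
    sg_freq: np.ndarray
    marker_kept_mask: np.ndarray
    grm: GRM
    sigma2_a2: float


def prepare_analysis(genos: GenotypeSet, phen: PhenotypeTable,
                     params: TraitParams,
                     grm_mode: str = "plain",
                     sigma2_a2: float | str = "estimate",
                     ) -> AnalysisData:
    """Align records with genotypes, standardize, weight, and fix the
    BayesR prior scale.

    sigma2_a2 = "estimate" fits the genotype-free animal model
    y = Xb + Za + e by REML with A = I over the phenotyped animals (the
    additive variance determined prior to the mixture analysis); a float
    supplies it directly.
    """
    einv, keep = residual_weight_diagonal(phen, params)
    df = phen.df[keep].reset_index(drop=True)
    g = genos.subset_animals(df["animal_id"].tolist())
    # allele frequencies from the full standardising population (reference
    # plus validation), so validation animals standardize identically and
    # the reference-subset GRM is not made singular by exact centring
    freq_all = genos.dosages.mean(axis=0) / 2.0
    sg = standardize_genotypes(g, freq=freq_all)
    X = build_design(df)
    y = df["value"].to_numpy(float)
    weights = 1.0 / einv
    grm = compute_grm(sg, mode=grm_mode)
    if sigma2_a2 == "estimate":
        n = len(y)
        spec = MixedModelSpec(y=y, X=X, Einv_diag=weights,
                              Z=np.eye(n), A=np.eye(n))
        vc = estimate_variance_components(spec)
        s2a2 = max(vc.sigma2_a, 1e-6 * float(np.var(y)))
    else:
        s2a2 = float(sigma2_a2)
    return AnalysisData(y=y, X=X, W=sg.W, weights=weights,
                        animal_ids=df["animal_id"].tolist(),
                        sg_freq=sg.freq, marker_kept_mask=sg.marker_kept_mask,
                        grm=grm, sigma2_a2=s2a2)


def fit_gblup(data: AnalysisData,
              vc: VarianceComponents | None = None,
              ) -> tuple[MMESolution, VarianceComponents]:
    """Weighted GBLUP fit (genomic term only; identity Q) with back-solved
    SNP effects."""
    n = len(data.y)
    spec = MixedModelSpec(y=data.y, X=data.X, Einv_diag=data.weights,
                          Q=np.eye(n), G=data.grm)
    if vc is None:
        vc = estimate_variance_components(spec)
        vc.sigma2_g = max(vc.sigma2_g, 1e-8 * float(np.var(data.y)))
    sol = solve_mme(spec, vc)
    sg = StandardizedGenotypes(data.W, data.sg_freq, data.marker_kept_mask)
    sol.v_hat = backsolve_snp_effects(sol, sg, data.grm)
    return sol, vc


def fit_bayesr(data: AnalysisData, spec: MixtureSpec | None = None,
               n_iter: int = 30_000, burn_in: int = 20_000,
               n_chains: int = 5, seed: int = 0) -> PosteriorSummary:
    bd = BayesRData(y=data.y, X=data.X, W=data.W, weights=data.weights,
                    sigma2_a2=data.sigma2_a2)
    return run_bayesr(bd, spec, n_iter=n_iter, burn_in=burn_in,
                      n_chains=n_chains, base_seed=seed)


def predict_validation(genos: GenotypeSet, ids: list[str],
                       data: AnalysisData, v_hat: np.ndarray,
                       ) -> PredictionSet:
    """SNP-only GEBV for validation animals, standardized with the
    training allele frequencies."""
    gv = genos.subset_animals(ids)
    d = gv.dosages[:, data.marker_kept_mask]
    p = data.sg_freq
    W_val = (d - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    return predict_gebv(W_val, v_hat, animal_id=ids, breed=gv.breed)
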