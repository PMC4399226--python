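"""Synthetic multi-breed dairy data with known ground truth.

The generator emulates the structure the estimators care about, at desk
scale:

* founder haplotypes with first-order Markov linkage disequilibrium;
* three breeds derived from the founders by independent bottleneck
  resampling with recombination, so breeds share QTL but diverge in
  allele frequency and LD phase (breed C plays the held-out-breed role
  and never enters the reference population);
* SNP effects drawn from the four-component normal mixture (point mass at
  zero plus three variance classes), with an option to plant a fixed
  number of large QTL;
* bull records simulated directly as genetic value + heteroscedastic
  noise with variance sigma2_e / w(d), and cow records likewise with
  w(r), matching the record-weight model;
* known fixed effects (breed mean, sex within breed) injected.

Everything is deterministic given the seed, and the returned bundle
carries the full simulated truth for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenotypeSet, MarkerMap, PedigreeTable, PhenotypeTable
from .weights import TraitParams, bull_weight, cow_weight
from .relmat import standardize_genotypes

__all__ = ["SimulationConfig", "SimulatedTruth", "DatasetBundle",
           "simulate_genotypes", "simulate_effects", "simulate_phenotypes",
           "simulate_dataset", "simulate_planted_qtl",
           "reference_phenotypes"]


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic three-breed design."""

    # population sizes (reference = breeds A+B; C is validation-only)
    n_cows: dict[str, int] = field(default_factory=lambda: {
        "A": 600, "B": 400, "C": 100})
    n_bulls: dict[str, int] = field(default_factory=lambda: {
        "A": 300, "B": 200, "C": 50})
    n_validation: dict[str, int] = field(default_factory=lambda: {
        "A": 100, "B": 100})
    # genome: m markers split over chromosomes of equal marker count,
    # ~50 kb marker spacing so 250 kb windows hold ~5 markers
    m: int = 5000
    n_chrom: int = 5
    marker_spacing: int = 50_000
    # LD and breed divergence
    ld: float = 0.7                 # adjacent-haplotype copying probability
    divergence_generations: int = 30
    ne: int = 100                   # haplotypes per breed bottleneck pool
    recomb: float = 0.001           # crossover prob. per 50 kb interval
    # drop causal markers from the genotype panel, so prediction works
    # through LD tagging (as with a real SNP chip) and across-breed
    # accuracy degrades with LD-phase divergence
    hidden_qtl: bool = False
    # genetic architecture
    mixture_proportions: tuple[float, ...] = (0.0, 0.006, 0.003, 0.0)
    multipliers: tuple[float, ...] = (0.0, 1e-4, 1e-3, 1e-2)
    n_large_qtl: int = 20           # markers forced into the largest class
    sigma2_a2: float = 1.0
    # trait model (milk-trait preset)
    h2: float = 0.33
    t: float = 0.56
    polygenic_frac: float = 0.0     # fraction of genetic variance off-SNP
    breed_means: dict[str, float] = field(default_factory=lambda: {
        "A": 0.0, "B": 1.0, "C": 0.5})
    sex_effect: float = 0.3
    d_mean: float = 100.0           # bull effective-daughter scale
    r_max: int = 3                  # cow records drawn uniform on 1..r_max
    seed: int = 0

    def __post_init__(self) -> None:
        pr = np.asarray(self.mixture_proportions, float)
        if pr.sum() > 1 + 1e-12 or (pr < 0).any():
            raise ValueError("mixture proportions invalid")
        if not 0 < self.h2 <= self.t <= 1:
            raise ValueError("need 0 < h2 <= t <= 1")
        if min(self.n_cows.values()) <= 0 or min(self.n_bulls.values()) <= 0:
            raise ValueError("population counts must be positive")


@dataclass
class SimulatedTruth:
    v: np.ndarray                 # true standardized-scale SNP effects
    component: np.ndarray         # mixture class per marker
    g: np.ndarray                 # total genetic value per animal
    a: np.ndarray                 # polygenic part (0 unless configured)
    realized_h2: float
    weights: np.ndarray           # per-record w_i in phenotype order
    sigma2_e: float


@dataclass
class DatasetBundle:
    genotypes: GenotypeSet
    phenotypes: PhenotypeTable
    pedigree: PedigreeTable
    truth: SimulatedTruth
    reference_ids: list[str]
    validation_ids: dict[str, list[str]]   # breed -> held-out animal ids
    config: SimulationConfig


def _marker_map(cfg: SimulationConfig) -> MarkerMap:
    per = cfg.m // cfg.n_chrom
    counts = [per] * cfg.n_chrom
    counts[-1] += cfg.m - per * cfg.n_chrom
    chrom, pos, ids = [], [], []
    j = 0
    for c, k in enumerate(counts, start=1):
        for t in range(k):
            chrom.append(str(c))
            pos.append((t + 1) * cfg.marker_spacing)
            ids.append(f"snp{j}")
            j += 1
    return MarkerMap(np.array(chrom, object), np.array(pos), np.array(ids))


def _founder_haplotypes(cfg: SimulationConfig, n_hap: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Markov-LD haplotypes: marker j copies marker j-1's allele state
    with probability ld, else draws Bernoulli(p_j)."""
    p = rng.uniform(0.1, 0.9, size=cfg.m)
    h = np.empty((n_hap, cfg.m), dtype=np.int8)
    h[:, 0] = rng.random(n_hap) < p[0]
    copy = rng.random((n_hap, cfg.m)) < cfg.ld
    fresh = rng.random((n_hap, cfg.m)) < p
    for j in range(1, cfg.m):
        h[:, j] = np.where(copy[:, j], h[:, j - 1], fresh[:, j])
    return h


def _drift_breed(pool: np.ndarray, cfg: SimulationConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Bottleneck resampling with crossover for the configured generations."""
    n_hap, m = pool.shape
    for _ in range(cfg.divergence_generations):
        pa = pool[rng.integers(0, n_hap, size=n_hap)]
        pb = pool[rng.integers(0, n_hap, size=n_hap)]
        cross = rng.random((n_hap, m)) < cfg.recomb
        use_a = np.logical_xor.accumulate(cross, axis=1)
        use_a[:, 0] = rng.random(n_hap) < 0.5
        pool = np.where(use_a, pa, pb).astype(np.int8)
    return pool


def _sample_diploids(pool: np.ndarray, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    a = pool[rng.integers(0, pool.shape[0], size=n)]
    b = pool[rng.integers(0, pool.shape[0], size=n)]
    return (a + b).astype(np.float64)


def simulate_genotypes(cfg: SimulationConfig) -> GenotypeSet:
    """Three-breed genotype panel; deterministic given cfg.seed."""
    rng = np.random.default_rng(cfg.seed)
    mm = _marker_map(cfg)
    base = _founder_haplotypes(cfg, 2 * cfg.ne, rng)
    dosages, ids, breeds = [], [], []
    for br in sorted(set(cfg.n_cows) | set(cfg.n_bulls)):
        pool = _drift_breed(base.copy(), cfg, rng)
        n_br = (cfg.n_cows.get(br, 0) + cfg.n_bulls.get(br, 0)
                + cfg.n_validation.get(br, 0))
        d = _sample_diploids(pool, n_br, rng)
        dosages.append(d)
        ids.extend(f"{br}{i:05d}" for i in range(n_br))
        breeds.extend([br] * n_br)
    return GenotypeSet(np.vstack(dosages), ids, mm,
                       np.asarray(breeds, object))


def simulate_effects(cfg: SimulationConfig,
                     rng: np.random.Generator | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """True SNP effects and component labels from the normal mixture.

    ``n_large_qtl`` markers are planted in the largest class; the
    remaining markers are allocated by the mixture proportions (whose
    first entry is treated as the remainder).
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    pr = np.asarray(cfg.mixture_proportions, float).copy()
    mult = np.asarray(cfg.multipliers, float)
    pr[0] = 1.0 - pr[1:].sum()
    comp = rng.choice(len(pr), size=cfg.m, p=pr)
    if cfg.n_large_qtl > 0:
        planted = rng.choice(cfg.m, size=cfg.n_large_qtl, replace=False)
        comp[planted] = len(mult) - 1
    sd = np.sqrt(mult[comp] * cfg.sigma2_a2)
    v = rng.standard_normal(cfg.m) * sd
    v[comp == 0] = 0.0
    return v, comp


def simulate_phenotypes(genos: GenotypeSet, v: np.ndarray, comp: np.ndarray,
                        cfg: SimulationConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[PhenotypeTable, SimulatedTruth]:
    """Bull/cow records with heterogeneous error variance.

    Record error variance is sigma2_e / w_i where w_i comes from the
    bull/cow weight formulas; sigma2_e is set so a single cow record
    (w = 1) has the configured heritability given the realized genetic
    variance.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    sg = standardize_genotypes(genos)
    g = sg.W @ v[sg.marker_kept_mask]
    var_g = float(np.var(g))
    params = TraitParams(cfg.h2, cfg.t)
    sigma2_e = var_g * (1.0 - cfg.h2) / cfg.h2 if var_g > 0 else 1.0

    ids = np.asarray(genos.animal_ids, object)
    breeds = genos.breed
    rows = []
    weights = []
    for br in pd.unique(breeds):
        idx = np.nonzero(breeds == br)[0]
        nc = cfg.n_cows.get(br, 0)
        nb = cfg.n_bulls.get(br, 0)
        cow_idx = idx[:nc]
        bull_idx = idx[nc:nc + nb]
        for i in cow_idx:
            r = int(rng.integers(1, cfg.r_max + 1))
            w = cow_weight(r, params)
            e = rng.normal(0.0, np.sqrt(sigma2_e / w))
            yv = cfg.breed_means.get(br, 0.0) + g[i] + e
            rows.append((ids[i], "MY", yv, "cow", np.nan, r, br, "F"))
            weights.append(w)
        for i in bull_idx:
            d = float(np.round(rng.gamma(2.0, cfg.d_mean / 2.0)))
            w = bull_weight(d, params)
            if w > 0:
                e = rng.normal(0.0, np.sqrt(sigma2_e / w))
            else:
                e = rng.normal(0.0, np.sqrt(sigma2_e * 100.0))
            yv = (cfg.breed_means.get(br, 0.0) + cfg.sex_effect
                  + g[i] + e)
            rows.append((ids[i], "MY", yv, "bull", d, np.nan, br, "M"))
            weights.append(w)
    df = pd.DataFrame(rows, columns=["animal_id", "trait", "value",
                                     "record_type", "d", "r", "breed",
                                     "sex"])
    phen = PhenotypeTable(df)
    w_arr = np.asarray(weights, float)
    # realized h2 of a single own record: var(g) / (var(g) + sigma2_e)
    realized = var_g / (var_g + sigma2_e)
    truth = SimulatedTruth(v=v, component=comp, g=g,
                           a=np.zeros(len(ids)), realized_h2=realized,
                           weights=w_arr, sigma2_e=sigma2_e)
    return phen, truth


def simulate_dataset(cfg: SimulationConfig) -> DatasetBundle:
    """Full three-breed bundle with a reference/validation split.

    Breed C never enters the reference (the held-out-breed design); each
    of breeds A and B additionally holds out ``n_validation`` genotyped,
    unphenotyped animals for within-breed validation.
    """
    genos = simulate_genotypes(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    v, comp = simulate_effects(cfg, rng)
    phen, truth = simulate_phenotypes(genos, v, comp, cfg, rng)
    if cfg.hidden_qtl:
        keep = comp == 0
        mm = genos.map
        genos = GenotypeSet(genos.dosages[:, keep], genos.animal_ids,
                            MarkerMap(mm.chrom[keep], mm.pos[keep],
                                      mm.marker_id[keep]), genos.breed)
        truth.v = v[keep]              # panel-aligned; causal are off-panel
        truth.component = comp[keep]

    ids = np.asarray(genos.animal_ids, object)
    breeds = genos.breed
    reference: list[str] = []
    validation: dict[str, list[str]] = {}
    for br in pd.unique(breeds):
        idx = np.nonzero(breeds == br)[0]
        nc, nb = cfg.n_cows.get(br, 0), cfg.n_bulls.get(br, 0)
        phenotyped = list(ids[idx[:nc + nb]])
        held = list(ids[idx[nc + nb:]])
        if br == "C":
            validation[br] = phenotyped + held
        else:
            reference.extend(phenotyped)
            if held:
                validation[br] = held
    ped = PedigreeTable(pd.DataFrame({
        "id": list(ids), "sire": "0", "dam": "0"}))
    return DatasetBundle(genos, phen, ped, truth, reference,
                         validation, cfg)


def simulate_planted_qtl(cfg: SimulationConfig, var_frac: float = 0.10
                         ) -> tuple[DatasetBundle, int]:
    """Bundle with exactly one QTL explaining ``var_frac`` of the
    phenotypic variance of a single-record cow.

    The QTL marker is chosen near the genome midpoint among markers with
    pooled allele frequency in [0.2, 0.8]; its effect is fixed at 1 on
    the standardized scale and the error variance is set so the QTL's
    variance share equals ``var_frac``.  Returns the bundle and the
    planted marker index.
    """
    from dataclasses import replace

    genos = simulate_genotypes(cfg)
    freq = genos.dosages.mean(axis=0) / 2.0
    eligible = np.nonzero((freq >= 0.2) & (freq <= 0.8))[0]
    if len(eligible) == 0:
        raise ValueError("no common marker available to plant the QTL")
    j = int(eligible[np.argmin(np.abs(eligible - cfg.m // 2))])
    v = np.zeros(cfg.m)
    v[j] = 1.0
    comp = np.zeros(cfg.m, dtype=np.int64)
    comp[j] = len(cfg.multipliers) - 1
    cfg_h2 = replace(cfg, h2=var_frac, t=max(var_frac, cfg.t))
    rng = np.random.default_rng(cfg.seed + 2)
    phen, truth = simulate_phenotypes(genos, v, comp, cfg_h2, rng)

    ids = np.asarray(genos.animal_ids, object)
    breeds = genos.breed
    reference: list[str] = []
    validation: dict[str, list[str]] = {}
    for br in pd.unique(breeds):
        idx = np.nonzero(breeds == br)[0]
        nc, nb = cfg.n_cows.get(br, 0), cfg.n_bulls.get(br, 0)
        phenotyped = list(ids[idx[:nc + nb]])
        held = list(ids[idx[nc + nb:]])
        if br == "C":
            validation[br] = phenotyped + held
        else:
            reference.extend(phenotyped)
            if held:
                validation[br] = held
    ped = PedigreeTable(pd.DataFrame({"id": list(ids), "sire": "0",
                                      "dam": "0"}))
    return (DatasetBundle(genos, phen, ped, truth, reference, validation,
                          cfg), j)


def reference_phenotypes(bundle: DatasetBundle) -> PhenotypeTable:
    """Records of reference animals only (breed C and held-out animals of
    A/B are excluded by the split manifest)."""
    ref = set(bundle.reference_ids)
    df = bundle.phenotypes.df
    return PhenotypeTable(
        df[df["animal_id"].isin(ref)].reset_index(drop=True))
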