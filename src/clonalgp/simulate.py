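"""Synthetic genotypes, trial structure and phenotypes with known truth.

The generator emulates the structure of a clonal sugarcane breeding data set:
biallelic pseudo-diploid SNPs (optionally out of Hardy-Weinberg equilibrium),
clones assigned to region x series-year final-assessment trials harvested as
plant and two ratoon crops with partial replication, and traits built from
additive, (directional) dominance and additive-by-additive epistatic effects
plus trial-design fixed effects and i.i.d. residual noise.  Every realized
effect is recorded so estimation can be tested against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_io import CROP_LEVELS, MISSING, GenotypeMatrix
from .kernels import incidence_matrix


@dataclass
class SimConfig:
    """Study-design and genetic-architecture settings for one simulation."""

    n_clones: int = 500
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    inbreeding_f: float = 0.0
    n_regions: int = 4
    years: tuple[int, ...] = (2013, 2014, 2015, 2016, 2017)
    crops: tuple[str, ...] = CROP_LEVELS
    replication_rate: float = 0.22
    var_a: float = 50.0
    var_d: float = 30.0
    var_aa: float = 40.0
    directional_dominance_mean: float = 0.0
    n_epistatic_pairs: int = 300
    var_e: float = 36.0
    fixed_effect_sds: dict = field(default_factory=lambda: {
        "year": 5.0, "crop": 3.0, "region": 4.0, "trial": 2.0,
    })
    missing_rate: float = 0.0
    trait_name: str = "trait"
    mean: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.inbreeding_f < 1.0:
            raise ValueError("inbreeding_f must be in [0, 1)")
        for name in ("var_a", "var_d", "var_aa", "var_e"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SimulationTruth:
    """Realized effects and genetic values underlying a simulated trait."""

    additive_effects: np.ndarray
    dominance_effects: np.ndarray
    epistatic_pairs: np.ndarray  # (n_pairs, 2) locus indices
    epistatic_effects: np.ndarray
    breeding_values: np.ndarray
    dominance_deviations: np.ndarray
    epistatic_values: np.ndarray
    total_genetic_values: np.ndarray
    realized_variances: dict[str, float]
    factor_effects: dict[str, dict[str, float]]
    clone_ids: list[str]


def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw independent biallelic loci with a controlled heterozygote deficit.

    Alternate-allele frequencies are Uniform(maf_range); genotype classes
    follow p_AA = p^2 + f p q, p_Aa = (1 - f) 2 p q, p_aa = q^2 + f p q, so
    inbreeding_f = 0 is exactly Hardy-Weinberg.  Missing calls are sprinkled
    at missing_rate.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    q = rng.uniform(*cfg.maf_range, size=cfg.n_snps)  # alternate allele
    p = 1.0 - q
    f = cfg.inbreeding_f
    probs = np.column_stack([
        p * p + f * p * q,
        (1.0 - f) * 2.0 * p * q,
        q * q + f * p * q,
    ])
    u = rng.random((cfg.n_clones, cfg.n_snps))
    cum = np.cumsum(probs, axis=1)
    codes = (u[..., None] > cum[None, :, :]).sum(axis=2).astype(np.int8)
    if cfg.missing_rate > 0:
        miss = rng.random(codes.shape) < cfg.missing_rate
        codes[miss] = MISSING
    clone_ids = [f"C{i:05d}" for i in range(cfg.n_clones)]
    snp_ids = [f"S{j:06d}" for j in range(cfg.n_snps)]
    return GenotypeMatrix(clone_ids, snp_ids, codes)


def _scaled(values: np.ndarray, target_var: float) -> tuple[np.ndarray, float]:
    """Centre and rescale a component to hit its target variance exactly."""
    v = values - values.mean()
    sd = v.std()
    if target_var <= 0 or sd == 0:
        return np.zeros_like(v), 0.0
    scale = np.sqrt(target_var) / sd
    return v * scale, scale


def simulate_phenotypes(
    g: GenotypeMatrix,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """Build trial records and trait values from marker effects.

    Breeding values use the orthogonal additive coding with per-locus effects
    ~ N(0, 1); dominance deviations use the dominance coding with effects
    ~ N(directional_dominance_mean, 1), so a positive mean makes genome-wide
    heterozygosity predictive of performance; epistatic values are sums over
    random locus pairs of products of centred additive codes.  Each component
    is rescaled to its target variance across clones.  Clones are assigned to
    one region and one series-year, recorded once per crop, and a
    replication_rate fraction gain a second trial.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    n = g.n_clones
    p = g.n_snps

    ha = incidence_matrix(g, "additive")
    hd = incidence_matrix(g, "dominance")

    a_eff = rng.standard_normal(p)
    bv_raw = ha.values @ a_eff
    bv, a_scale = _scaled(bv_raw, cfg.var_a)

    d_eff = rng.standard_normal(p) + cfg.directional_dominance_mean
    dd_raw = hd.values @ d_eff
    dd, d_scale = _scaled(dd_raw, cfg.var_d)

    max_pairs = p * (p - 1) // 2
    if cfg.n_epistatic_pairs > max_pairs:
        raise ValueError("more epistatic pairs than locus pairs available")
    if cfg.var_aa > 0 and cfg.n_epistatic_pairs > 0:
        loci = rng.choice(p, size=(cfg.n_epistatic_pairs, 2))
        same = loci[:, 0] == loci[:, 1]
        while same.any():
            loci[same, 1] = rng.choice(p, size=same.sum())
            same = loci[:, 0] == loci[:, 1]
        e_eff = rng.standard_normal(cfg.n_epistatic_pairs)
        prod = ha.values[:, loci[:, 0]] * ha.values[:, loci[:, 1]]
        ep_raw = prod @ e_eff
        ep, e_scale = _scaled(ep_raw, cfg.var_aa)
    else:
        loci = np.empty((0, 2), dtype=int)
        e_eff = np.empty(0)
        ep, e_scale = np.zeros(n), 0.0

    tgv = bv + dd + ep

    # trial structure: one region and series-year per clone
    regions = [f"R{r + 1}" for r in range(cfg.n_regions)]
    clone_region = rng.choice(len(regions), size=n)
    clone_year = rng.choice(len(cfg.years), size=n)
    n_trials = 2  # trials available per region-year
    clone_trial = rng.integers(0, n_trials, size=n)
    replicated = rng.random(n) < cfg.replication_rate

    factor_effects: dict[str, dict[str, float]] = {}
    sds = cfg.fixed_effect_sds
    factor_effects["year"] = {
        str(yv): rng.normal(0.0, sds.get("year", 0.0)) for yv in cfg.years
    }
    factor_effects["crop"] = {
        c: rng.normal(0.0, sds.get("crop", 0.0)) for c in cfg.crops
    }
    factor_effects["region"] = {
        r: rng.normal(0.0, sds.get("region", 0.0)) for r in regions
    }
    trial_names = [
        f"{r}_{yv}_T{t + 1}"
        for r in regions for yv in cfg.years for t in range(n_trials)
    ]
    factor_effects["trial"] = {
        t: rng.normal(0.0, sds.get("trial", 0.0)) for t in trial_names
    }

    records = []
    for i, clone in enumerate(g.clone_ids):
        region = regions[clone_region[i]]
        year = cfg.years[clone_year[i]]
        trials = [clone_trial[i]]
        if replicated[i]:
            trials.append((clone_trial[i] + 1) % n_trials)
        for t in trials:
            trial = f"{region}_{year}_T{t + 1}"
            for crop in cfg.crops:
                mean = (
                    cfg.mean
                    + factor_effects["year"][str(year)]
                    + factor_effects["crop"][crop]
                    + factor_effects["region"][region]
                    + factor_effects["trial"][trial]
                    + tgv[i]
                )
                records.append((clone, year, crop, region, trial, mean))
    ph = pd.DataFrame(records, columns=["clone", "year", "crop", "region", "trial", cfg.trait_name])
    ph[cfg.trait_name] += rng.normal(0.0, np.sqrt(cfg.var_e), size=len(ph))

    truth = SimulationTruth(
        additive_effects=a_eff * a_scale,
        dominance_effects=d_eff * d_scale,
        epistatic_pairs=loci,
        epistatic_effects=e_eff * e_scale,
        breeding_values=bv,
        dominance_deviations=dd,
        epistatic_values=ep,
        total_genetic_values=tgv,
        realized_variances={
            "var_a": float(bv.var()),
            "var_d": float(dd.var()),
            "var_aa": float(ep.var()),
            "var_e": cfg.var_e,
        },
        factor_effects=factor_effects,
        clone_ids=list(g.clone_ids),
    )
    return ph, truth


def simulate_dataset(cfg: SimConfig) -> tuple[GenotypeMatrix, pd.DataFrame, SimulationTruth]:
    """Genotypes plus phenotypes from one seed."""
    rng = np.random.default_rng(cfg.seed)
    g = simulate_genotypes(cfg, rng)
    ph, truth = simulate_phenotypes(g, cfg, rng)
    return g, ph, truth


# trait architectures mirroring the three analysed cane traits:
# a complex yield trait with substantial dominance and epistasis, a mostly
# additive sugar-content trait, and a high-heritability fibre trait
TRAIT_PRESETS = {
    "TCH": dict(var_a=50.0, var_d=30.0, var_aa=40.0, var_e=36.0,
                directional_dominance_mean=1.0, mean=80.0),
    "CCS": dict(var_a=0.4, var_d=0.01, var_aa=0.11, var_e=0.134,
                directional_dominance_mean=0.0, mean=13.0),
    "Fibre": dict(var_a=1.5, var_d=0.05, var_aa=0.2, var_e=0.16,
                  directional_dominance_mean=0.0, mean=17.0),
}


def breeding_program_preset(scale: str = "mini", trait: str = "TCH", seed: int = 0) -> SimConfig:
    """Deterministic preset configs at two scales.

    ``mini`` is 500 clones x 2,000 SNPs; ``full`` is 3,000 clones x 25,000
    SNPs, the scale of a commercial final-assessment-trial data set.  Trait
    presets set the target variance decomposition.
    """
    if scale == "mini":
        n_clones, n_snps, n_pairs = 500, 2000, 300
    elif scale == "full":
        n_clones, n_snps, n_pairs = 3000, 25000, 2000
    else:
        raise ValueError(f"unknown scale {scale!r}")
    if trait not in TRAIT_PRESETS:
        raise ValueError(f"unknown trait preset {trait!r}")
    return SimConfig(
        n_clones=n_clones,
        n_snps=n_snps,
        n_epistatic_pairs=n_pairs,
        trait_name=trait,
        seed=seed,
        **TRAIT_PRESETS[trait],
    )
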