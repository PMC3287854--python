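"""Phenotype composition: Q1, Q2, Q4, latent liability, disease status.

Each quantitative trait is the sum of (a) additive SNP effects from its
effect table (each minor-allele copy shifts the mean by beta; KDR effects
on Q1 are multiplied by 1.5 in smokers), (b) fixed covariate effects (age,
sex, smoking, per trait), (c) a residual polygenic deviation correlated
between relatives through twice the kinship matrix and across (Q1, Q2,
latent liability) through a genetic correlation matrix, and (d) an
individual-specific environmental deviation weakly correlated across
traits.  Per trait the residual variance is 1, split h2 : (1 - h2).  Q4
carries no sequenced-SNP term and its genetic component is independent of
the other traits.

Disease liability is latent + Q1 + Q2 - Q4; the top 30% of the liability
distribution in each replicate is declared affected, so every replicate has
the same affected count while the affected identities vary.  Genotypes,
ages and sexes stay fixed across replicates; smoking, polygenic and
environmental deviations are redrawn per replicate.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .effect_model import (
    GXE_GENE,
    EffectTable,
    TraitModelConfig,
    validate_config,
)
from .genotype_synth import GenotypeMatrix, HaplotypePanel
from .pedigree import KinshipMatrix, Pedigree, gene_drop, kinship

__all__ = [
    "CovariateSet",
    "VarianceModel",
    "TraitReplicate",
    "simulate_covariates",
    "genetic_value",
    "covariate_effect",
    "build_variance_model",
    "simulate_polygenic",
    "simulate_environment",
    "compose_traits",
    "assign_affection",
    "run_replicates",
    "write_phenotype_csv",
]

#: ordering of the correlated residual components
CORR_TRAITS = ("Q1", "Q2", "LATENT")


@dataclass(frozen=True)
class CovariateSet:
    """Fixed (age, sex) and per-replicate (smoking) covariates."""

    age: np.ndarray          # years
    sex: np.ndarray          # 'M'/'F'
    smoker: np.ndarray       # 0/1

    def __post_init__(self) -> None:
        if not (len(self.age) == len(self.sex) == len(self.smoker)):
            raise ValueError("covariate arrays must share one length")

    def __len__(self) -> int:
        return len(self.age)

    def with_smoker(self, smoker: np.ndarray) -> "CovariateSet":
        return replace(self, smoker=np.asarray(smoker, dtype=np.int8))


def simulate_covariates(
    n: int | None = None,
    cfg: TraitModelConfig | None = None,
    seed: int | np.random.Generator = 0,
    ped: Pedigree | None = None,
) -> CovariateSet:
    """Draw ages (truncated normal by rejection, support [age_min, age_max],
    mean ~41.8y), sexes (from the pedigree when given, else Bernoulli(1/2))
    and an initial smoking indicator at the configured prevalence."""
    cfg = cfg or TraitModelConfig()
    if not (0.0 <= cfg.smoking_prevalence <= 1.0):
        raise ValueError("smoking prevalence outside [0, 1]")
    if ped is not None:
        n = len(ped)
        sex = ped.sexes
    elif n is None or n <= 0:
        raise ValueError("need n > 0 or a pedigree")
    else:
        sex = None
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    age = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(cfg.age_mean, cfg.age_sd, size=2 * (n - filled))
        draw = draw[(draw >= cfg.age_min) & (draw <= cfg.age_max)]
        take = min(draw.size, n - filled)
        age[filled:filled + take] = draw[:take]
        filled += take
    if sex is None:
        sex = np.where(rng.random(n) < 0.5, "M", "F")
    smoker = (rng.random(n) < cfg.smoking_prevalence).astype(np.int8)
    return CovariateSet(age=age, sex=np.asarray(sex), smoker=smoker)


def draw_smoking(n: int, cfg: TraitModelConfig,
                 rng: np.random.Generator) -> np.ndarray:
    return (rng.random(n) < cfg.smoking_prevalence).astype(np.int8)


# --------------------------------------------------------------------------
# Additive SNP effects
# --------------------------------------------------------------------------

def genetic_value(
    trait: str,
    g: GenotypeMatrix,
    table: EffectTable,
    cov: CovariateSet,
    cfg: TraitModelConfig,
) -> np.ndarray:
    """Per-individual additive genetic value: sum of beta * dosage, with the
    smoking multiplier applied to KDR variants on Q1 for smokers."""
    dos = g.dosages_for(table.snp_ids).astype(float)  # KeyError lists absences
    betas = np.array([v.beta for v in table.variants])
    if trait == "Q1":
        is_gxe = np.array([v.gene == GXE_GENE for v in table.variants])
        if is_gxe.any():
            mult = np.ones((len(cov), len(table)))
            mult[np.ix_(cov.smoker == 1, is_gxe)] = cfg.gxe_smoking_multiplier
            return (dos * mult) @ betas
    return dos @ betas


def covariate_effect(trait: str, cov: CovariateSet,
                     cfg: TraitModelConfig) -> np.ndarray:
    """Fixed-effect contribution of age/sex/smoking for one trait.

    Age enters centered at the sample mean age.
    """
    eff = np.zeros(len(cov))
    age_c = cov.age - cov.age.mean()
    for (t, covariate), beta in cfg.covariate_betas.items():
        if t != trait:
            continue
        if covariate == "age":
            eff += beta * age_c
        elif covariate == "smoking":
            eff += beta * cov.smoker
        elif covariate == "female":
            eff += beta * (cov.sex == "F")
        else:
            raise ValueError(f"unknown covariate {covariate!r}")
    return eff


# --------------------------------------------------------------------------
# Residual variance structure
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class VarianceModel:
    """Genetic and environmental covariance over (Q1, Q2, LATENT) plus the
    independent Q4 split.  Per trait sigma_g^2 + sigma_e^2 = 1."""

    sigma_g: np.ndarray
    sigma_e: np.ndarray
    q4_h2: float


def build_variance_model(cfg: TraitModelConfig) -> VarianceModel:
    h2 = np.array([cfg.h2_residual[t] for t in CORR_TRAITS])
    dg = np.sqrt(h2)
    de = np.sqrt(1.0 - h2)
    sigma_g = np.outer(dg, dg) * cfg.rho_g
    sigma_e = np.outer(de, de) * cfg.rho_e
    return VarianceModel(sigma_g, sigma_e, cfg.h2_residual["Q4"])


def _psd_factor(m: np.ndarray) -> np.ndarray:
    """Lower factor C with C @ C.T = m; tolerates singular PSD input."""
    try:
        return np.linalg.cholesky(m)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh((m + m.T) / 2)
        if w.min() < -1e-8:
            raise ValueError("matrix is not positive semidefinite")
        return v @ np.diag(np.sqrt(np.clip(w, 0, None)))


def simulate_polygenic(
    kin: KinshipMatrix | None,
    vm: VarianceModel,
    seed: int | np.random.Generator = 0,
    n: int | None = None,
    chol_2phi: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw correlated polygenic deviations.

    Returns (n x 3 matrix over (Q1, Q2, LATENT) with covariance
    (2 Phi) kron sigma_g, and the independent Q4 deviation with covariance
    (2 Phi) * q4_h2).  ``kin=None`` means unrelated individuals (2 Phi = I,
    ``n`` required).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if kin is None:
        if n is None:
            raise ValueError("n required when kin is None")
        L = None
    else:
        n = len(kin.ids)
        L = chol_2phi if chol_2phi is not None else _psd_factor(kin.expected_sharing)
    C = _psd_factor(vm.sigma_g)
    z = rng.standard_normal((n, 3))
    poly = z @ C.T if L is None else L @ (z @ C.T)
    z4 = rng.standard_normal(n) * np.sqrt(vm.q4_h2)
    poly_q4 = z4 if L is None else L @ z4
    return poly, poly_q4


def simulate_environment(
    n: int,
    vm: VarianceModel,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Individual-specific environmental deviations: rows independent,
    cross-trait covariance sigma_e; plus the independent Q4 component."""
    if n <= 0:
        raise ValueError("n must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    C = _psd_factor(vm.sigma_e)
    env = rng.standard_normal((n, 3)) @ C.T
    env_q4 = rng.standard_normal(n) * np.sqrt(1.0 - vm.q4_h2)
    return env, env_q4


# --------------------------------------------------------------------------
# Trait composition and affection
# --------------------------------------------------------------------------

def compose_traits(
    gvals: Mapping[str, np.ndarray],
    poly: np.ndarray,
    env: np.ndarray,
    poly_q4: np.ndarray,
    env_q4: np.ndarray,
    cov: CovariateSet,
    cfg: TraitModelConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Assemble (Q1, Q2, Q4, latent liability) for one replicate.

    Q1 = SNPs + age + smoking + polygenic + environment; Q2 = SNPs +
    polygenic + environment (no covariates); Q4 = age + sex + smoking +
    polygenic + environment (no sequenced-SNP term); latent = SNPs + age +
    smoking + polygenic + environment.
    """
    n = len(cov)
    for name, arr in (("poly", poly), ("env", env)):
        if arr.shape != (n, 3):
            raise ValueError(f"{name} must be ({n}, 3), got {arr.shape}")
    for t in ("Q1", "Q2", "LIABILITY"):
        if len(gvals[t]) != n:
            raise ValueError(f"genetic values for {t} have wrong length")
    q1 = gvals["Q1"] + covariate_effect("Q1", cov, cfg) + poly[:, 0] + env[:, 0]
    q2 = gvals["Q2"] + covariate_effect("Q2", cov, cfg) + poly[:, 1] + env[:, 1]
    q4 = covariate_effect("Q4", cov, cfg) + poly_q4 + env_q4
    latent = (
        gvals["LIABILITY"]
        + covariate_effect("LATENT", cov, cfg)
        + poly[:, 2]
        + env[:, 2]
    )
    return q1, q2, q4, latent


def assign_affection(
    q1: np.ndarray,
    q2: np.ndarray,
    q4: np.ndarray,
    latent: np.ndarray,
    cfg: TraitModelConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Liability = latent + Q1 + Q2 - Q4; the top round(prevalence * N)
    individuals by liability are affected (ties broken by stable input
    order), so the affected count is identical in every replicate."""
    liability = latent + q1 + q2 - q4
    n = len(liability)
    k = int(np.rint(cfg.disease_prevalence * n))
    order = np.argsort(-liability, kind="stable")
    affected = np.zeros(n, dtype=np.int8)
    affected[order[:k]] = 1
    return liability, affected


# --------------------------------------------------------------------------
# Replicates
# --------------------------------------------------------------------------

@dataclass
class TraitReplicate:
    """One replicate's phenotypes plus the simulator-known components that
    validation estimators may subtract (SNP genetic values, covariate
    effects)."""

    replicate_index: int
    ids: list[str]
    q1: np.ndarray
    q2: np.ndarray
    q4: np.ndarray
    latent: np.ndarray
    liability: np.ndarray
    affected: np.ndarray
    smoker: np.ndarray
    components: dict = field(default_factory=dict)


def _digest(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()


@dataclass
class SimulationInputs:
    """Fixed-across-replicates scaffold for one design."""

    design: str
    genotypes: GenotypeMatrix
    covariates: CovariateSet
    kin: KinshipMatrix | None
    genotype_digest: str
    ped: Pedigree | None = None


def prepare_inputs(
    design: str,
    panel: HaplotypePanel,
    cfg: TraitModelConfig,
    master_seed: int,
    ped: Pedigree | None = None,
) -> SimulationInputs:
    """Fix the genotype/covariate scaffold for a run.

    ``unrelated``: dosages straight from the panel, no kinship.
    ``family``: the panel supplies the pedigree founders (one per founder,
    in pedigree order); haplotypes are gene-dropped once and kinship
    computed from the pedigree.
    """
    from .cli_io import derive_substream

    if design == "unrelated":
        geno = panel.to_dosage()
        kin = None
        cov_ped = None
    elif design == "family":
        if ped is None:
            raise ValueError("family design requires a pedigree")
        geno, _vectors = gene_drop(
            ped, panel, seed=derive_substream(master_seed, "genedrop", 0)
        )
        kin = kinship(ped)
        cov_ped = ped
    else:
        raise ValueError(f"unknown design {design!r}")
    cov = simulate_covariates(
        n=geno.n_individuals, cfg=cfg,
        seed=derive_substream(master_seed, "covariates", 0), ped=cov_ped,
    )
    return SimulationInputs(
        design=design,
        genotypes=geno,
        covariates=cov,
        kin=kin,
        genotype_digest=_digest(geno.dosage),
        ped=ped,
    )


def run_replicates(
    design: str,
    panel: HaplotypePanel,
    cfg: TraitModelConfig,
    effect_tables: Mapping[str, EffectTable],
    ped: Pedigree | None = None,
    n_replicates: int | None = None,
    master_seed: int | None = None,
    inputs: SimulationInputs | None = None,
) -> Iterator[TraitReplicate]:
    """Stream ``n_replicates`` phenotype replicates for one design.

    Genotypes, ages and sexes are fixed across replicates (the genotype
    digest is attached to every replicate's components for verification);
    smoking (unless ``cfg.resample_smoking`` is off), polygenic and
    environmental deviations come from per-replicate substreams derived
    from the master seed, so any replicate is reproducible in isolation.
    """
    from .cli_io import derive_substream

    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    master_seed = cfg.seed if master_seed is None else master_seed
    n_replicates = cfg.n_replicates if n_replicates is None else n_replicates

    if inputs is None:
        inputs = prepare_inputs(design, panel, cfg, master_seed, ped=ped)
    vm = build_variance_model(cfg)
    chol = None
    if inputs.kin is not None:
        chol = _psd_factor(inputs.kin.expected_sharing)

    n = inputs.genotypes.n_individuals
    for r in range(n_replicates):
        rng = np.random.default_rng(derive_substream(master_seed, "replicate", r))
        if cfg.resample_smoking:
            cov = inputs.covariates.with_smoker(draw_smoking(n, cfg, rng))
        else:
            cov = inputs.covariates
        gvals = {
            t: genetic_value(t, inputs.genotypes, effect_tables[t], cov, cfg)
            for t in ("Q1", "Q2", "LIABILITY")
        }
        poly, poly_q4 = simulate_polygenic(
            inputs.kin, vm, seed=rng, n=n, chol_2phi=chol
        )
        env, env_q4 = simulate_environment(n, vm, seed=rng)
        q1, q2, q4, latent = compose_traits(
            gvals, poly, env, poly_q4, env_q4, cov, cfg
        )
        liability, affected = assign_affection(q1, q2, q4, latent, cfg)
        yield TraitReplicate(
            replicate_index=r,
            ids=list(inputs.genotypes.sample_ids),
            q1=q1, q2=q2, q4=q4,
            latent=latent, liability=liability,
            affected=affected, smoker=cov.smoker,
            components={
                "gvals": gvals,
                "covariate_effects": {
                    t: covariate_effect(t, cov, cfg)
                    for t in ("Q1", "Q2", "Q4", "LATENT")
                },
                "poly": poly, "poly_q4": poly_q4,
                "env": env, "env_q4": env_q4,
                "genotype_digest": inputs.genotype_digest,
                "covariates": cov,
            },
        )


def write_phenotype_csv(
    rep: TraitReplicate,
    path: str | Path,
    cov: CovariateSet | None = None,
    ped: Pedigree | None = None,
    emit_latent: bool = False,
) -> None:
    """Per-replicate CSV: ID, FAMID (family design only), SEX, AGE, SMOKE,
    Q1, Q2, Q4, AFFECTED; latent liability is withheld unless asked for."""
    cov = cov or rep.components.get("covariates")
    data: dict[str, object] = {"ID": rep.ids}
    if ped is not None:
        data["FAMID"] = [m.family_id for m in ped.members]
    data.update(
        SEX=[1 if s == "M" else 2 for s in cov.sex],
        AGE=np.round(cov.age, 1),
        SMOKE=rep.smoker,
        Q1=np.round(rep.q1, 6),
        Q2=np.round(rep.q2, 6),
        Q4=np.round(rep.q4, 6),
        AFFECTED=rep.affected,
    )
    if emit_latent:
        data["LATENT"] = np.round(rep.latent, 6)
        data["LIABILITY"] = np.round(rep.liability, 6)
    pd.DataFrame(data).to_csv(path, index=False)
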