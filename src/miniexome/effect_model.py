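"""Functional-variant effect tables and the global trait-model configuration.

Three quantitative phenotypes (Q1, Q2) and a latent disease liability are
driven by per-SNP additive effects: each copy of a variant's minor allele
shifts the trait mean by ``beta`` (expressed in units of the trait's
residual standard deviation).  The packaged tables list every functional
variant per trait with its gene, marker label, reference minor allele
frequency and effect size.  This module loads and validates those tables
and holds the model-wide configuration (residual heritabilities, disease
and smoking prevalence, covariate effects, cross-trait correlation
structure, replicate count and seeding).
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FunctionalVariant",
    "EffectTable",
    "TraitModelConfig",
    "load_effect_table",
    "packaged_effect_table",
    "write_effect_table",
    "summarize_effects",
    "validate_config",
    "TRAITS",
    "QUANT_TRAITS",
]

#: traits carrying SNP effect tables; Q4 has no sequenced-SNP component.
TRAITS = ("Q1", "Q2", "LIABILITY")
#: quantitative traits delivered to analysts.
QUANT_TRAITS = ("Q1", "Q2", "Q4")

_SNP_ID_RE = re.compile(r"^C(\d+)S(\d+)$")

#: gene whose variants interact with smoking on Q1.
GXE_GENE = "KDR"


class EffectTableError(ValueError):
    """Malformed or invalid effect-table input."""


@dataclass(frozen=True)
class FunctionalVariant:
    """One trait-influencing variant.

    ``beta`` is the displacement of the trait mean per copy of the minor
    allele, on a scale where the trait's residual (polygenic plus
    environmental) variance is 1.  All packaged effects are positive: the
    minor allele always raises the mean.
    """

    gene: str
    snp_id: str
    maf_ref: float
    beta: float

    def __post_init__(self) -> None:
        if not _SNP_ID_RE.match(self.snp_id):
            raise EffectTableError(
                f"snp_id {self.snp_id!r} does not match the C#S# pattern"
            )
        if not (0.0 < self.maf_ref <= 0.5):
            raise EffectTableError(
                f"{self.snp_id}: maf_ref {self.maf_ref} outside (0, 0.5]"
            )
        if self.beta <= 0:
            raise EffectTableError(f"{self.snp_id}: beta {self.beta} must be > 0")

    @property
    def chrom(self) -> int:
        return int(_SNP_ID_RE.match(self.snp_id).group(1))

    @property
    def s_index(self) -> int:
        return int(_SNP_ID_RE.match(self.snp_id).group(2))


@dataclass(frozen=True)
class EffectTable:
    """Ordered list of functional variants for one trait."""

    trait: str
    variants: tuple[FunctionalVariant, ...]

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise EffectTableError(f"unknown trait {self.trait!r}")
        ids = [v.snp_id for v in self.variants]
        dupes = {s for s in ids if ids.count(s) > 1}
        if dupes:
            raise EffectTableError(
                f"duplicate snp_ids within {self.trait} table: {sorted(dupes)}"
            )

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def snp_ids(self) -> tuple[str, ...]:
        return tuple(v.snp_id for v in self.variants)

    @property
    def genes(self) -> tuple[str, ...]:
        """Distinct gene symbols, in order of first appearance."""
        seen: dict[str, None] = {}
        for v in self.variants:
            seen.setdefault(v.gene, None)
        return tuple(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [v.gene for v in self.variants],
                "snp": [v.snp_id for v in self.variants],
                "maf": [v.maf_ref for v in self.variants],
                "beta": [v.beta for v in self.variants],
            }
        )


def _sniff_sep(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def load_effect_table(path: str | Path, trait: str) -> EffectTable:
    """Read a tab- or comma-separated effect table (header gene,snp,maf,beta).

    Raises :class:`EffectTableError` naming the offending line for malformed
    rows and for duplicated snp_ids.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise EffectTableError(f"{path}: empty file, expected a header row")
    sep = _sniff_sep(lines[0])
    header = [c.strip().lower() for c in lines[0].split(sep)]
    if header != ["gene", "snp", "maf", "beta"]:
        raise EffectTableError(
            f"{path}: line 1: expected header gene{sep}snp{sep}maf{sep}beta, got {lines[0]!r}"
        )
    variants = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cells = line.split(sep)
        if len(cells) != 4:
            raise EffectTableError(
                f"{path}: line {lineno}: expected 4 fields, got {len(cells)}"
            )
        gene, snp, maf_s, beta_s = (c.strip() for c in cells)
        try:
            maf, beta = float(maf_s), float(beta_s)
        except ValueError as exc:
            raise EffectTableError(f"{path}: line {lineno}: {exc}") from exc
        try:
            variants.append(FunctionalVariant(gene, snp, maf, beta))
        except EffectTableError as exc:
            raise EffectTableError(f"{path}: line {lineno}: {exc}") from exc
    return EffectTable(trait=trait, variants=tuple(variants))


_PACKAGED = {
    "Q1": "effects_q1.tsv",
    "Q2": "effects_q2.tsv",
    "LIABILITY": "effects_liability.tsv",
}


def packaged_fixture_path(trait: str) -> Path:
    """Filesystem path of the packaged effect table for ``trait``."""
    if trait not in _PACKAGED:
        raise EffectTableError(f"no packaged effect table for trait {trait!r}")
    return Path(resources.files("miniexome").joinpath("data", _PACKAGED[trait]))


def packaged_effect_table(trait: str) -> EffectTable:
    """Load the packaged effect table for Q1, Q2 or LIABILITY."""
    return load_effect_table(packaged_fixture_path(trait), trait)


def write_effect_table(table: EffectTable, path: str | Path) -> None:
    """Write a table as TSV so that ``load_effect_table`` round-trips it."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tsnp\tmaf\tbeta\n")
        for v in table.variants:
            fh.write(f"{v.gene}\t{v.snp_id}\t{v.maf_ref:.10g}\t{v.beta:.10g}\n")


def summarize_effects(table: EffectTable) -> dict:
    """Counts and extrema over an effect table.

    Returns ``n_snps``, ``n_genes``, MAF and beta extrema, and the
    per-gene variant counts (``snps_per_gene``).
    """
    if len(table) == 0:
        raise EffectTableError(f"cannot summarize empty {table.trait} table")
    mafs = [v.maf_ref for v in table.variants]
    betas = [v.beta for v in table.variants]
    per_gene: dict[str, int] = {}
    for v in table.variants:
        per_gene[v.gene] = per_gene.get(v.gene, 0) + 1
    return {
        "n_snps": len(table),
        "n_genes": len(per_gene),
        "maf_min": min(mafs),
        "maf_max": max(mafs),
        "beta_min": min(betas),
        "beta_max": max(betas),
        "snps_per_gene": per_gene,
    }


# --------------------------------------------------------------------------
# Trait-model configuration
# --------------------------------------------------------------------------

def _default_h2() -> dict[str, float]:
    return {"Q1": 0.44, "Q2": 0.29, "Q4": 0.70, "LATENT": 0.0}


def _default_covariate_betas() -> dict[tuple[str, str], float]:
    # Directions follow the trait descriptions (Q1 and latent liability rise
    # with age and smoking; Q4 falls with age, smoking, and is lower in
    # females); magnitudes are package defaults, configurable.
    return {
        ("Q1", "age"): 0.01,
        ("Q1", "smoking"): 0.3,
        ("Q4", "age"): -0.01,
        ("Q4", "female"): -0.5,
        ("Q4", "smoking"): -0.3,
        ("LATENT", "age"): 0.01,
        ("LATENT", "smoking"): 0.3,
    }


def _corr(off: float) -> np.ndarray:
    m = np.full((3, 3), off)
    np.fill_diagonal(m, 1.0)
    return m


@dataclass
class TraitModelConfig:
    """All knobs of the phenotype model.

    Correlation matrices are ordered (Q1, Q2, LATENT).  ``rho_g``/``rho_e``
    defaults (0.5 / 0.2 off-diagonal) encode "correlated" polygenic and
    "weakly correlated" environmental components; they are package defaults,
    not published values.
    """

    h2_residual: dict[str, float] = field(default_factory=_default_h2)
    disease_prevalence: float = 0.30
    smoking_prevalence: float = 0.25
    gxe_smoking_multiplier: float = 1.5
    covariate_betas: dict[tuple[str, str], float] = field(
        default_factory=_default_covariate_betas
    )
    rho_g: np.ndarray = field(default_factory=lambda: _corr(0.5))
    rho_e: np.ndarray = field(default_factory=lambda: _corr(0.2))
    n_replicates: int = 200
    seed: int = 17
    #: mean / range of the fixed age covariate (years)
    age_mean: float = 41.8
    age_sd: float = 12.0
    age_min: float = 16.0
    age_max: float = 91.0
    #: redraw smoking per replicate (genotype/age/sex always stay fixed)
    resample_smoking: bool = True

    def __post_init__(self) -> None:
        self.rho_g = np.asarray(self.rho_g, dtype=float)
        self.rho_e = np.asarray(self.rho_e, dtype=float)

    # -- (de)serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["rho_g"] = self.rho_g.tolist()
        d["rho_e"] = self.rho_e.tolist()
        d["covariate_betas"] = {
            f"{trait}.{cov}": beta for (trait, cov), beta in self.covariate_betas.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TraitModelConfig":
        d = dict(d)
        if "covariate_betas" in d:
            cb = {}
            for key, beta in d["covariate_betas"].items():
                trait, cov = key.split(".") if isinstance(key, str) else key
                cb[(trait, cov)] = float(beta)
            d["covariate_betas"] = cb
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TraitModelConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _is_correlation(m: np.ndarray) -> list[str]:
    problems = []
    if m.shape != (3, 3):
        problems.append("must be 3x3 over (Q1, Q2, LATENT)")
        return problems
    if not np.allclose(m, m.T):
        problems.append("not symmetric")
    if not np.allclose(np.diag(m), 1.0):
        problems.append("diagonal must be 1")
    if np.any(np.abs(m) > 1.0 + 1e-12):
        problems.append("entries outside [-1, 1] are not correlations")
    elif np.linalg.eigvalsh((m + m.T) / 2).min() < -1e-8:
        problems.append("not positive semidefinite")
    return problems


def validate_config(cfg: TraitModelConfig) -> list[str]:
    """Return the list of invariant violations (empty means valid)."""
    violations: list[str] = []
    for trait, h2 in cfg.h2_residual.items():
        if not (0.0 <= h2 <= 1.0):
            violations.append(f"h2_residual[{trait}]={h2} outside [0, 1]")
    for name in ("disease_prevalence", "smoking_prevalence"):
        val = getattr(cfg, name)
        if not (0.0 <= val <= 1.0):
            violations.append(f"{name}={val} outside [0, 1]")
    if cfg.gxe_smoking_multiplier <= 0:
        violations.append(
            f"gxe_smoking_multiplier={cfg.gxe_smoking_multiplier} must be > 0"
        )
    for name, m in (("rho_g", cfg.rho_g), ("rho_e", cfg.rho_e)):
        for problem in _is_correlation(m):
            violations.append(f"{name}: {problem}")
    if cfg.n_replicates < 1:
        violations.append(f"n_replicates={cfg.n_replicates} must be >= 1")
    if not (cfg.age_min < cfg.age_max):
        violations.append("age_min must be < age_max")
    return violations
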