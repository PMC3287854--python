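"""Validation-side estimators that recover simulation parameters.

These close the loop on the generative model without external tools:
Haseman–Elston regression recovers residual heritabilities from the family
design, an interaction regression recovers the smoking uplift of the KDR
effects on Q1, and a prevalence check verifies the fixed affected count
and the turnover of affected identities across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm

from .pedigree import KinshipMatrix
from .phenosim import TraitReplicate

__all__ = [
    "HeritabilityEstimate",
    "haseman_elston_h2",
    "gxe_ratio",
    "prevalence_check",
]


@dataclass(frozen=True)
class HeritabilityEstimate:
    h2_hat: float        # clamped to [0, 1]
    se: float
    n_pairs: int
    slope_raw: float     # unclamped regression slope


def haseman_elston_h2(
    trait: Sequence[float],
    kin: KinshipMatrix,
    covariates: np.ndarray | None = None,
) -> HeritabilityEstimate:
    """Pairwise cross-product regression for narrow-sense heritability.

    The trait is optionally residualized on a covariate design matrix,
    standardized, and the products z_i * z_j over all pairs with Phi > 0
    are regressed on the expected allele sharing 2*Phi.  The slope
    estimates h2 of the (residualized) trait; pairs with Phi = 0 carry no
    signal and are excluded.

    Centering at the grand mean couples every individual to the sample
    average, which attenuates the slope in small samples with a few large
    families (the attenuation term is linear in the pair's kinship row
    sums); the regression therefore includes the summed row relatedness of
    each pair as a nuisance covariate, which removes that bias.  The OLS
    standard error treats pairs as independent, which overlapping pairs
    violate mildly; it is indicative, not exact.
    """
    y = np.asarray(trait, dtype=float)
    n = y.size
    if n != len(kin.ids):
        raise ValueError("trait length does not match kinship matrix")
    if covariates is not None:
        X = sm.add_constant(np.asarray(covariates, dtype=float))
        y = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    z = (y - y.mean()) / y.std(ddof=1)

    iu, ju = np.triu_indices(n, k=1)
    phi = kin.phi[iu, ju]
    informative = phi > 0
    if not informative.any():
        raise ValueError(
            "no related pairs: Haseman-Elston is undefined in an unrelated design"
        )
    x = 2.0 * phi[informative]
    prod = z[iu[informative]] * z[ju[informative]]
    sharing = kin.expected_sharing
    row_sum = sharing.sum(axis=1) - np.diag(sharing)
    pair_relatedness = row_sum[iu[informative]] + row_sum[ju[informative]]
    design = sm.add_constant(np.column_stack([x, pair_relatedness]))
    model = sm.OLS(prod, design).fit()
    slope = float(model.params[1])
    se = float(model.bse[1])
    return HeritabilityEstimate(
        h2_hat=float(np.clip(slope, 0.0, 1.0)),
        se=se,
        n_pairs=int(informative.sum()),
        slope_raw=slope,
    )


@dataclass(frozen=True)
class GxERatio:
    uplift: float        # multiplicative excess: interaction / main effect
    se: float            # delta-method standard error
    beta_dosage: float
    beta_interaction: float


def gxe_ratio(
    q1: Sequence[float],
    dosage: Sequence[float],
    smoker: Sequence[int],
) -> GxERatio:
    """Estimate the smoking uplift of a per-allele effect.

    Fits Q1 ~ dosage + smoker + dosage:smoker and returns the ratio of the
    interaction to the main dosage coefficient (0.5 means the allele effect
    is 50% larger in smokers).  Requires variant carriers in both smoking
    strata, otherwise the interaction is inestimable.
    """
    q1 = np.asarray(q1, dtype=float)
    d = np.asarray(dosage, dtype=float)
    s = np.asarray(smoker, dtype=float)
    for stratum, name in ((s == 1, "smokers"), (s == 0, "nonsmokers")):
        if not (d[stratum] > 0).any():
            raise ValueError(f"no variant carriers among {name}")
    X = sm.add_constant(np.column_stack([d, s, d * s]))
    fit = sm.OLS(q1, X).fit()
    b1, b3 = fit.params[1], fit.params[3]
    cov = fit.cov_params()
    var = (
        cov[3, 3] / b1**2
        + cov[1, 1] * b3**2 / b1**4
        - 2.0 * cov[1, 3] * b3 / b1**3
    )
    return GxERatio(
        uplift=float(b3 / b1),
        se=float(np.sqrt(max(var, 0.0))),
        beta_dosage=float(b1),
        beta_interaction=float(b3),
    )


def prevalence_check(replicates: Iterable[TraitReplicate]) -> dict:
    """Affected fractions per replicate and identity-overlap statistics.

    All fractions must be equal (the rank-based rule fixes the count); the
    mean pairwise Jaccard overlap of affected sets must be < 1 whenever the
    model is stochastic.
    """
    fractions = []
    affected_sets = []
    for rep in replicates:
        affected_sets.append({i for i, a in zip(rep.ids, rep.affected) if a})
        fractions.append(len(affected_sets[-1]) / len(rep.ids))
    if len(fractions) < 2:
        raise ValueError("need at least 2 replicates")
    overlaps = [
        len(a & b) / len(a | b) if (a | b) else 1.0
        for a, b in combinations(affected_sets, 2)
    ]
    return {
        "fractions": fractions,
        "all_equal": len(set(fractions)) == 1,
        "mean_jaccard": float(np.mean(overlaps)),
        "min_jaccard": float(np.min(overlaps)),
        "max_jaccard": float(np.max(overlaps)),
    }
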