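"""Phenotype composition: covariates, SNP effects, variance components,
affection assignment and replicate streaming."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from miniexome.effect_model import EffectTable, FunctionalVariant, TraitModelConfig
from miniexome.genotype_synth import GenotypeMatrix, MarkerMap
from miniexome.phenosim import (
    CovariateSet,
    assign_affection,
    build_variance_model,
    compose_traits,
    covariate_effect,
    genetic_value,
    run_replicates,
    simulate_covariates,
    simulate_environment,
    simulate_polygenic,
    write_phenotype_csv,
)


def single_marker_geno(dosages, snp_id="C4S4935"):
    chrom = int(snp_id[1:].split("S")[0])
    m = MarkerMap(
        pd.DataFrame(
            {"snp_id": [snp_id], "chrom": chrom, "pos": [100], "gene": None}
        )
    )
    return GenotypeMatrix(np.asarray(dosages).reshape(-1, 1), m)


def fixed_cov(n, smoker=None, sex=None, age=None):
    return CovariateSet(
        age=np.full(n, 41.8) if age is None else np.asarray(age, dtype=float),
        sex=np.array(["M"] * n) if sex is None else np.asarray(sex),
        smoker=np.zeros(n, dtype=np.int8) if smoker is None else
        np.asarray(smoker, dtype=np.int8),
    )


# -- covariates -------------------------------------------------------------

def test_covariate_support_and_means(cfg):
    cov = simulate_covariates(n=5_000, cfg=cfg, seed=1)
    assert cov.age.min() >= 16 and cov.age.max() <= 91
    assert cov.age.mean() == pytest.approx(41.8, abs=1.0)
    assert cov.smoker.mean() == pytest.approx(0.25, abs=0.02)


def test_covariates_zero_prevalence(cfg):
    import dataclasses

    quiet = dataclasses.replace(cfg, smoking_prevalence=0.0)
    cov = simulate_covariates(n=200, cfg=quiet, seed=2)
    assert cov.smoker.sum() == 0


def test_covariates_deterministic(cfg):
    a = simulate_covariates(n=100, cfg=cfg, seed=5)
    b = simulate_covariates(n=100, cfg=cfg, seed=5)
    assert np.array_equal(a.age, b.age) and np.array_equal(a.smoker, b.smoker)


def test_covariates_sexes_from_pedigree(cfg, default_ped):
    cov = simulate_covariates(cfg=cfg, seed=3, ped=default_ped)
    assert np.array_equal(cov.sex, default_ped.sexes)


# -- additive SNP effects ---------------------------------------------------

def test_genetic_value_single_copy_matches_beta(tables, cfg):
    g = single_marker_geno([1, 0], "C4S4935")
    table = EffectTable("Q1", tuple(
        v for v in tables["Q1"].variants if v.snp_id == "C4S4935"
    ))
    val = genetic_value("Q1", g, table, fixed_cov(2), cfg)
    assert val[0] == pytest.approx(1.40529)
    assert val[1] == 0.0


def test_genetic_value_kdr_smoking_uplift(tables, cfg):
    g = single_marker_geno([1, 1], "C4S1878")
    table = EffectTable("Q1", tuple(
        v for v in tables["Q1"].variants if v.snp_id == "C4S1878"
    ))
    val = genetic_value("Q1", g, table, fixed_cov(2, smoker=[1, 0]), cfg)
    assert val[0] == pytest.approx(0.149975 * 1.5)  # = 0.2249625 in smokers
    assert val[1] == pytest.approx(0.149975)
    # the uplift applies to Q1 only
    val_lia = genetic_value(
        "LIABILITY", g, EffectTable("LIABILITY", table.variants),
        fixed_cov(2, smoker=[1, 0]), cfg,
    )
    assert val_lia[0] == val_lia[1]


def test_genetic_value_missing_marker_lists_it(tables, cfg):
    g = single_marker_geno([0], "C1S1")
    with pytest.raises(KeyError, match="C4S4935"):
        genetic_value("Q1", g, tables["Q1"], fixed_cov(1), cfg)


@given(st.integers(0, 2), st.floats(0.01, 2.0))
def test_genetic_value_linear_in_dosage_and_beta(dosage, beta):
    cfg = TraitModelConfig()
    table = EffectTable("Q2", (FunctionalVariant("G1", "C1S1", 0.1, beta),))
    g = single_marker_geno([dosage, 0], "C1S1")
    val = genetic_value("Q2", g, table, fixed_cov(2), cfg)
    assert val[0] == pytest.approx(dosage * beta)


# -- variance components ----------------------------------------------------

def test_polygenic_unrelated_recovers_rho_g(cfg):
    vm = build_variance_model(cfg)
    poly, _ = simulate_polygenic(None, vm, seed=7, n=40_000)
    # latent has 0 residual h2 by default, so check the Q1-Q2 block
    c = np.corrcoef(poly[:, 0], poly[:, 1])[0, 1]
    assert c == pytest.approx(0.5, abs=0.02)
    assert poly[:, 0].var() == pytest.approx(0.44, rel=0.05)
    assert poly[:, 1].var() == pytest.approx(0.29, rel=0.05)


def test_polygenic_zero_variance(cfg):
    import dataclasses

    flat = dataclasses.replace(
        cfg, h2_residual={"Q1": 0.0, "Q2": 0.0, "Q4": 0.0, "LATENT": 0.0}
    )
    vm = build_variance_model(flat)
    poly, poly_q4 = simulate_polygenic(None, vm, seed=1, n=50)
    assert np.allclose(poly, 0.0) and np.allclose(poly_q4, 0.0)


def test_polygenic_parent_offspring_covariance(cfg, default_ped, default_kin):
    """Across seeds, parent-offspring polygenic covariance ~= sigma_g^2 / 2."""
    vm = build_variance_model(cfg)
    pairs = [
        (default_ped.index_of(m.person_id), default_ped.index_of(m.father_id))
        for m in default_ped.members if not m.is_founder
    ][:200]
    i, j = np.array(pairs).T
    prods = []
    for seed in range(150):
        poly, _ = simulate_polygenic(default_kin, vm, seed=seed)
        prods.append((poly[i, 0] * poly[j, 0]).mean())
    assert np.mean(prods) == pytest.approx(0.5 * 0.44, abs=0.02)


def test_environment_variance_and_independence(cfg):
    vm = build_variance_model(cfg)
    env, env_q4 = simulate_environment(40_000, vm, seed=3)
    assert env[:, 0].var() == pytest.approx(1 - 0.44, rel=0.05)
    assert env[:, 1].var() == pytest.approx(1 - 0.29, rel=0.05)
    assert env_q4.var() == pytest.approx(0.30, rel=0.05)
    c = np.corrcoef(env[:, 0], env[:, 1])[0, 1]
    assert c == pytest.approx(0.2, abs=0.02)


def test_environment_deterministic(cfg):
    vm = build_variance_model(cfg)
    a, a4 = simulate_environment(100, vm, seed=9)
    b, b4 = simulate_environment(100, vm, seed=9)
    assert np.array_equal(a, b) and np.array_equal(a4, b4)


# -- composition ------------------------------------------------------------

def test_compose_deterministic_path(cfg):
    """With all random parts and covariate betas zeroed, Q1 equals its SNP
    genetic value exactly."""
    import dataclasses

    bare = dataclasses.replace(cfg, covariate_betas={})
    n = 3
    gvals = {
        "Q1": np.array([1.40529, 0.0, 0.0]),
        "Q2": np.zeros(n),
        "LIABILITY": np.zeros(n),
    }
    zeros3 = np.zeros((n, 3))
    q1, q2, q4, latent = compose_traits(
        gvals, zeros3, zeros3, np.zeros(n), np.zeros(n), fixed_cov(n), bare
    )
    assert q1[0] == pytest.approx(1.40529) and q1[1] == 0.0
    assert np.allclose(q2, 0) and np.allclose(q4, 0) and np.allclose(latent, 0)


def test_covariate_directions(cfg):
    n = 1000
    rng = np.random.default_rng(0)
    cov = fixed_cov(
        n,
        smoker=rng.integers(0, 2, n),
        sex=np.where(rng.random(n) < 0.5, "F", "M"),
        age=rng.uniform(16, 91, n),
    )
    q1_eff = covariate_effect("Q1", cov, cfg)
    q4_eff = covariate_effect("Q4", cov, cfg)
    q2_eff = covariate_effect("Q2", cov, cfg)
    assert np.allclose(q2_eff, 0.0)  # Q2 has no covariate effects
    sm = cov.smoker == 1
    assert q1_eff[sm].mean() > q1_eff[~sm].mean()   # Q1 higher in smokers
    assert q4_eff[sm].mean() < q4_eff[~sm].mean()   # Q4 lower in smokers
    fem = cov.sex == "F"
    assert q4_eff[fem].mean() < q4_eff[~fem].mean()  # Q4 lower in females


# -- affection --------------------------------------------------------------

def test_affection_count_and_threshold(cfg):
    rng = np.random.default_rng(4)
    n = 697
    q1, q2, q4, latent = (rng.normal(size=n) for _ in range(4))
    liability, affected = assign_affection(q1, q2, q4, latent, cfg)
    assert affected.sum() == 209  # round(0.30 * 697)
    assert liability[affected == 1].min() >= liability[affected == 0].max()


def test_affection_q4_is_protective(cfg):
    n = 10
    base = np.zeros(n)
    liab1, _ = assign_affection(base, base, base.copy(), base, cfg)
    bumped = base.copy()
    bumped[3] = 2.0
    liab2, _ = assign_affection(base, base, bumped, base, cfg)
    assert liab2[3] < liab1[3]


def test_affection_tie_break_stable(cfg):
    n = 10
    zeros = np.zeros(n)
    _, affected = assign_affection(zeros, zeros, zeros, zeros, cfg)
    k = int(np.rint(cfg.disease_prevalence * n))
    assert affected[:k].all() and not affected[k:].any()


@given(st.integers(2, 400), st.floats(0.0, 1.0))
def test_affection_count_matches_rounded_prevalence(n, prev):
    import dataclasses

    cfg = dataclasses.replace(TraitModelConfig(), disease_prevalence=prev)
    rng = np.random.default_rng(n)
    vals = rng.normal(size=n)
    _, affected = assign_affection(vals, vals, vals, vals, cfg)
    assert affected.sum() == int(np.rint(prev * n))


# -- replicates -------------------------------------------------------------

@pytest.fixture(scope="module")
def unrelated_reps(functional_panel, tables, cfg):
    panel, _ = functional_panel
    return list(
        run_replicates("unrelated", panel, cfg, tables,
                       n_replicates=10, master_seed=77)
    )


def test_replicates_fixed_scaffold_varying_noise(unrelated_reps):
    digests = {r.components["genotype_digest"] for r in unrelated_reps}
    assert len(digests) == 1
    counts = {int(r.affected.sum()) for r in unrelated_reps}
    assert counts == {209}
    ident = {tuple(np.flatnonzero(r.affected)) for r in unrelated_reps}
    assert len(ident) > 1  # identities vary across replicates


def test_replicates_deterministic(functional_panel, tables, cfg):
    panel, _ = functional_panel
    a = list(run_replicates("unrelated", panel, cfg, tables,
                            n_replicates=2, master_seed=5))
    b = list(run_replicates("unrelated", panel, cfg, tables,
                            n_replicates=2, master_seed=5))
    for ra, rb in zip(a, b):
        assert np.array_equal(ra.q1, rb.q1)
        assert np.array_equal(ra.affected, rb.affected)
        assert np.array_equal(ra.smoker, rb.smoker)


def test_q2_unaffected_by_covariates(functional_panel, tables, cfg):
    """Regressing Q2 on age/sex/smoking recovers ~zero coefficients."""
    import statsmodels.api as sm

    panel, _ = functional_panel
    betas = []
    for rep in run_replicates("unrelated", panel, cfg, tables,
                              n_replicates=30, master_seed=123):
        cov = rep.components["covariates"]
        X = sm.add_constant(np.column_stack(
            [cov.age, (cov.sex == "F").astype(float), rep.smoker]
        ))
        betas.append(sm.OLS(rep.q2, X).fit().params[1:])
    mean_beta = np.mean(betas, axis=0)
    assert np.all(np.abs(mean_beta) < 0.05)


def test_q1_q4_smoking_signs(functional_panel, tables, cfg):
    panel, _ = functional_panel
    dq1, dq4 = [], []
    for rep in run_replicates("unrelated", panel, cfg, tables,
                              n_replicates=30, master_seed=321):
        sm_ = rep.smoker == 1
        dq1.append(rep.q1[sm_].mean() - rep.q1[~sm_].mean())
        dq4.append(rep.q4[sm_].mean() - rep.q4[~sm_].mean())
    assert np.mean(dq1) > 0
    assert np.mean(dq4) < 0


def test_phenotype_csv_round_trip(tmp_path, unrelated_reps):
    rep = unrelated_reps[0]
    path = tmp_path / "rep.csv"
    write_phenotype_csv(rep, path)
    df = pd.read_csv(path)
    assert list(df.columns) == ["ID", "SEX", "AGE", "SMOKE", "Q1", "Q2", "Q4", "AFFECTED"]
    assert len(df) == 697
    assert df["AFFECTED"].sum() == 209
    assert "LATENT" not in df.columns  # withheld by default
    write_phenotype_csv(rep, path, emit_latent=True)
    assert "LATENT" in pd.read_csv(path).columns
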