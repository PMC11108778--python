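import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hlamap.association import (
    AssocResult,
    ModelSpec,
    analytic_power,
    associate,
    benjamini_hochberg,
    bidirectional_stepwise_bic,
    compare_models,
    enumerate_nested_models,
    fixed_effects_meta,
    hwe_chisq_pvalue,
    hwe_exact_pvalue,
    inverse_normal_transform,
    lmm_associate,
    lrt_nested,
    monte_carlo_power,
    qc_filter,
    stepwise_conditional,
    variance_explained,
)


def test_inverse_normal_blom_example():
    out = inverse_normal_transform([1.2, 3.4, 2.2])
    assert out == pytest.approx([-0.8694, 0.8694, 0.0], abs=1e-3)


def test_inverse_normal_preserves_order_and_is_rank_idempotent():
    rng = np.random.default_rng(3)
    x = rng.lognormal(size=50)
    z = inverse_normal_transform(x)
    assert np.all(np.argsort(z) == np.argsort(x))
    assert np.allclose(inverse_normal_transform(z), z)
    with pytest.raises(ValueError):
        inverse_normal_transform([2.0, 2.0, 2.0])


def test_hwe_chi_square_hand_example():
    # counts (90, 0, 10): p=0.9, expected (81, 18, 1) -> chi2 = 1+18+81 = 100
    p = hwe_chisq_pvalue(90, 0, 10)
    assert p == pytest.approx(stats.chi2.sf(100, 1))
    assert p < 1e-8
    # exact test agrees qualitatively and is sane on equilibrium counts
    assert hwe_exact_pvalue(90, 0, 10) < 1e-8
    assert hwe_exact_pvalue(81, 18, 1) > 0.5


def test_qc_filter_drops_hwe_violating_variant():
    rng = np.random.default_rng(5)
    n = 100
    good = rng.binomial(2, 0.4, size=n).astype(float)
    bad = np.array([0.0] * 90 + [2.0] * 10)
    d = pd.DataFrame({"good": good, "bad": bad},
                     index=[f"i{k}" for k in range(n)])
    res = qc_filter(d)
    assert "bad" not in res.dosages.columns
    assert "good" in res.dosages.columns
    assert (res.exclusions["stage"] == "hwe").sum() == 1


def test_qc_filter_duplicate_rule_drops_lower_call_rate_member():
    rng = np.random.default_rng(6)
    n, m = 40, 60
    d = pd.DataFrame(
        rng.binomial(2, 0.5, size=(n, m)).astype(float),
        index=[f"i{k}" for k in range(n)],
    )
    d.loc["i1"] = d.loc["i0"]          # duplicate pair
    d.iloc[1, :1] = np.nan             # i1 has the lower call rate
    rel = pd.DataFrame(np.eye(n), index=d.index, columns=d.index)
    rel.loc["i0", "i1"] = rel.loc["i1", "i0"] = 0.95
    res = qc_filter(d, relatedness=rel, variant_call_rate=0.9)
    assert "i1" not in res.dosages.index
    assert "i0" in res.dosages.index
    # known twins are spared
    res2 = qc_filter(d, relatedness=rel, known_twins=[("i0", "i1")],
                     variant_call_rate=0.9)
    assert "i1" in res2.dosages.index


def test_qc_perfect_data_passes_untouched():
    rng = np.random.default_rng(7)
    d = pd.DataFrame(rng.binomial(2, 0.5, size=(80, 30)).astype(float))
    d.index = [f"i{k}" for k in range(80)]
    res = qc_filter(d)
    assert res.dosages.shape == d.shape
    assert len(res.exclusions) == 0


def test_ols_closed_form_example():
    res = associate([0, 1, 2, 2], [1, 2, 2, 3])
    assert res.beta == pytest.approx(8 / 11)
    assert res.n == 4


def test_ols_collinear_covariates_error_names_pair():
    rng = np.random.default_rng(8)
    x = rng.binomial(2, 0.5, 50).astype(float)
    y = rng.standard_normal(50)
    cov = pd.DataFrame({"pc1": rng.standard_normal(50)})
    cov["pc1_copy"] = cov["pc1"]
    with pytest.raises(ValueError, match="pc1"):
        associate(x, y, cov)


def test_ols_null_betas_small_and_planted_beta_recovered():
    rng = np.random.default_rng(9)
    n = 2499
    x = rng.binomial(2, 0.2, n).astype(float)
    y = 0.33 * x + rng.standard_normal(n)
    res = associate(x, y)
    assert res.beta == pytest.approx(0.33, abs=3 * res.se)
    y0 = rng.standard_normal(n)
    res0 = associate(x, y0)
    assert abs(res0.beta) < 4 * res0.se


def test_lmm_with_identity_kinship_matches_ols():
    rng = np.random.default_rng(10)
    n = 120
    x = rng.binomial(2, 0.3, n).astype(float)
    cov = pd.DataFrame({"t": rng.uniform(0, 1, n)})
    y = 0.4 * x - 0.5 * cov["t"].to_numpy() + rng.standard_normal(n)
    ols = associate(x, y, cov)
    lmm = lmm_associate(x, y, np.eye(n), cov)
    assert lmm.beta == pytest.approx(ols.beta, abs=1e-4)
    assert lmm.se == pytest.approx(ols.se, rel=1e-3)


def test_lmm_block_structure_inflates_se_over_ols():
    rng = np.random.default_rng(11)
    n = 60
    base_x = rng.binomial(2, 0.3, n // 2).astype(float)
    x = np.repeat(base_x, 2)  # every individual duplicated
    K = np.kron(np.eye(n // 2), np.ones((2, 2)))
    shared = np.repeat(rng.standard_normal(n // 2), 2)
    y = 0.2 * x + shared + 0.3 * rng.standard_normal(n)
    ols = associate(x, y)
    lmm = lmm_associate(x, y, K)
    assert lmm.se > ols.se


def test_lmm_rejects_bad_relatedness():
    with pytest.raises(ValueError, match="symmetric"):
        lmm_associate([0, 1, 2], [0.0, 1.0, 2.0],
                      np.array([[1, 0.5, 0], [0, 1, 0], [0, 0, 1.0]]))


def test_meta_hand_example_and_invariants():
    a = AssocResult("v", 0.5, 0.1, 0.01, 100, population="p1")
    b = AssocResult("v", 0.3, 0.2, 0.1, 100, population="p2")
    m = fixed_effects_meta([a, b])
    assert m.beta == pytest.approx(0.46)
    assert m.se == pytest.approx(1 / np.sqrt(125))
    assert m.q == pytest.approx(0.8)
    assert m.se <= min(a.se, b.se)
    # identical studies: beta unchanged, Q = 0
    m2 = fixed_effects_meta([a, a])
    assert m2.beta == pytest.approx(a.beta)
    assert m2.q == pytest.approx(0.0, abs=1e-12)
    # single study passes through with Q absent
    m1 = fixed_effects_meta([a])
    assert (m1.beta, m1.se, m1.q) == (a.beta, a.se, None)
    # heterogeneity flag at P_Q <= 1e-3
    c = AssocResult("v", -1.5, 0.05, 0.5, 100)
    d = AssocResult("v", 1.5, 0.05, 0.5, 100)
    assert fixed_effects_meta([c, d]).heterogeneous
    assert not m.heterogeneous


def test_stepwise_empty_without_planted_effects():
    rng = np.random.default_rng(12)
    d = pd.DataFrame(rng.binomial(2, 0.3, size=(300, 10)).astype(float))
    d.columns = [f"v{j}" for j in range(10)]
    y = rng.standard_normal(300)
    assert stepwise_conditional(d, y, threshold=5e-9) == []


def test_stepwise_conditioning_removes_tag():
    rng = np.random.default_rng(13)
    n = 3000
    causal = rng.binomial(2, 0.3, n).astype(float)
    # tag in high LD (copy with a few swaps)
    tag = causal.copy()
    flip = rng.random(n) < 0.03
    tag[flip] = rng.binomial(2, 0.3, flip.sum())
    d = pd.DataFrame({"causal": causal, "tag": tag})
    y = 0.5 * causal + rng.standard_normal(n)
    hits = stepwise_conditional(d, y, threshold=5e-9)
    assert len(hits) == 1


def test_stepwise_invariant_to_column_order():
    rng = np.random.default_rng(14)
    n = 1500
    a = rng.binomial(2, 0.3, n).astype(float)
    b = rng.binomial(2, 0.4, n).astype(float)
    y = 0.4 * a + 0.4 * b + rng.standard_normal(n)
    d1 = pd.DataFrame({"a": a, "b": b, "noise": rng.binomial(2, 0.5, n).astype(float)})
    d2 = d1[["noise", "b", "a"]]
    h1 = [r.variant for r in stepwise_conditional(d1, y, threshold=1e-4)]
    h2 = [r.variant for r in stepwise_conditional(d2, y, threshold=1e-4)]
    assert h1 == h2


def test_enumerate_nested_models_drb1_74arg(drb1_74_table):
    specs = enumerate_nested_models(drb1_74_table, "DRB1", 74, "Arg")
    assert specs["residue"].terms == ("DRB1-74Arg",)
    # minimal covering group: the two 03 alleles differ at two fields but
    # share the one-field group DRB1*03
    assert specs["allele_group"].terms == ("DRB1*03",)
    assert set(specs["alleles"].terms) == {"DRB1*03:01:01G", "DRB1*03:02:01"}
    with pytest.raises(ValueError, match="no allele carries"):
        enumerate_nested_models(drb1_74_table, "DRB1", 74, "Trp")


def test_single_carrier_residue_and_allele_models_coincide(drb1_74_table):
    specs = enumerate_nested_models(drb1_74_table, "DRB1", 74, "Gln")
    assert specs["alleles"].terms == ("DRB1*13:02:01",)
    assert len(specs["allele_group"].terms) == 1


def test_compare_models_noise_term_raises_bic():
    rng = np.random.default_rng(15)
    n = 2000
    x = rng.binomial(2, 0.3, n).astype(float)
    noise = rng.binomial(2, 0.3, n).astype(float)
    d = pd.DataFrame({"x": x, "noise": noise})
    y = 0.3 * x + rng.standard_normal(n)
    ledger, best = compare_models(
        [ModelSpec("x", ("x",)), ModelSpec("x+noise", ("x", "noise"))], d, y
    )
    by_name = {m.spec.name: m for m in ledger}
    assert by_name["x"].bic < by_name["x+noise"].bic
    assert best.name == "x"
    assert by_name["x"].bic == pytest.approx(
        by_name["x"].k * np.log(n) - 2 * by_name["x"].loglik
    )
    # nested LRT between the two is valid and non-significant
    p = lrt_nested(by_name["x"], by_name["x+noise"])
    assert p > 1e-4


def test_bidirectional_bic_search_recovers_generating_terms():
    rng = np.random.default_rng(16)
    n = 1500
    cols = {f"v{j}": rng.binomial(2, 0.3, n).astype(float) for j in range(6)}
    d = pd.DataFrame(cols)
    y = 0.4 * d["v1"] + 0.4 * d["v4"] + rng.standard_normal(n)
    spec = bidirectional_stepwise_bic(list(d.columns), d, y)
    assert set(spec.terms) == {"v1", "v4"}


def test_variance_explained_recovery_and_population_skipping():
    rng = np.random.default_rng(17)
    n = 2000
    x = rng.binomial(2, 0.3, n).astype(float)
    g = np.sqrt(0.05) * (x - x.mean()) / x.std()
    y = g + np.sqrt(0.95) * rng.standard_normal(n)
    d = pd.DataFrame({"x": x})
    pops = ["p1"] * (n // 2) + ["p2"] * (n // 2)
    out = variance_explained(["x"], d, y, populations=pops)
    assert set(out["population"]) == {"p1", "p2"}
    assert out.attrs["mean_delta_r2"] == pytest.approx(0.05, abs=0.015)
    # a trait absent in one population is skipped with a warning
    y2 = y.copy()
    y2[: n // 2] = np.nan
    with pytest.warns(UserWarning, match="absent"):
        out2 = variance_explained(["x"], d, y2, populations=pops)
    assert list(out2["population"]) == ["p2"]


def test_benjamini_hochberg_worked_example():
    adj = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(adj, 0.04)


def test_power_study_configuration_band():
    p = analytic_power(2500, 0.02, 1e-8)
    assert 0.90 <= p <= 0.96


def test_zero_effect_variants_explain_nothing():
    rng = np.random.default_rng(18)
    d = pd.DataFrame({"x": rng.binomial(2, 0.3, 1000).astype(float)})
    y = rng.standard_normal(1000)
    out = variance_explained(["x"], d, y)
    assert out["delta_r2"].iloc[0] == pytest.approx(0.0, abs=0.01)
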