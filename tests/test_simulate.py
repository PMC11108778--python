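import numpy as np
import pandas as pd
import pytest

from hlamap.diversity import differentiation
from hlamap.expression import build_allele_contig, count_hla_reads
from hlamap.imputation import locus_concordance
from hlamap.simulate import (
    EffectMap,
    PopulationModel,
    SnvTag,
    allele_dosage_frame,
    exact_align,
    simulate_cohort,
    simulate_imputation_posteriors,
    simulate_paired_gwas,
    simulate_phenotypes,
    simulate_population_frequencies,
    simulate_rnaseq_reads,
)

BASE_FREQS = {"A": {"A*01:01": 0.4, "A*02:01": 0.35, "A*03:01": 0.25}}


def model(concentration, seed=0, n_pops=2):
    return PopulationModel(
        populations=tuple(f"p{i}" for i in range(n_pops)),
        frequencies=BASE_FREQS,
        concentration=concentration,
        seed=seed,
    )


def test_frequencies_valid_and_seed_reproducible():
    out = simulate_population_frequencies(model(20.0, seed=1))
    again = simulate_population_frequencies(model(20.0, seed=1))
    assert out == again
    for pop in out:
        total = sum(out[pop]["A"].values())
        assert total == pytest.approx(1.0)
        assert all(v >= 0 for v in out[pop]["A"].values())


def test_large_concentration_approaches_ancestral():
    out = simulate_population_frequencies(model(1e7, seed=2))
    for pop in out:
        for a, f in BASE_FREQS["A"].items():
            assert out[pop]["A"][a] == pytest.approx(f, abs=5e-3)
    r = differentiation({p: out[p]["A"] for p in out}, locus="A")
    assert r.g_st < 1e-4


def test_differentiation_monotone_in_concentration():
    def mean_gst(conc, seeds=range(8)):
        vals = []
        for s in seeds:
            out = simulate_population_frequencies(model(conc, seed=s))
            vals.append(
                differentiation({p: out[p]["A"] for p in out}, locus="A").g_st
            )
        return np.mean(vals)

    assert mean_gst(1.0) > mean_gst(500.0)


def test_perfect_tag_r2_approaches_one():
    freqs = {"pop": BASE_FREQS}
    cohort = simulate_cohort(
        freqs, 3000,
        snv_tags=[SnvTag("rs1", "A", "A*01:01", r2=1.0)], seed=3,
    )
    allele_dos = allele_dosage_frame(cohort.typing)["A*01:01"]
    snv = cohort.snv_dosages["rs1"]
    r2 = np.corrcoef(allele_dos, snv)[0, 1] ** 2
    assert r2 == pytest.approx(1.0, abs=1e-9)


def test_configured_tag_r2_recovered():
    freqs = {"pop": BASE_FREQS}
    cohort = simulate_cohort(
        freqs, 5000,
        snv_tags=[SnvTag("rs1", "A", "A*01:01", r2=0.5)], seed=4,
    )
    allele_dos = allele_dosage_frame(cohort.typing)["A*01:01"]
    r2 = np.corrcoef(allele_dos, cohort.snv_dosages["rs1"])[0, 1] ** 2
    assert r2 == pytest.approx(0.5, abs=0.1)


def test_infeasible_tag_reports_bound():
    freqs = {"pop": {"A": {"A*01:01": 1.0}}}
    with pytest.raises(ValueError, match="attainable"):
        simulate_cohort(
            freqs, 100, snv_tags=[SnvTag("rs1", "A", "A*01:01", r2=0.5)], seed=5
        )


def test_planted_duplicates_visible_in_relatedness():
    cohort = simulate_cohort({"pop": BASE_FREQS}, 50, seed=6, n_duplicate_pairs=2)
    off = cohort.relatedness.to_numpy() - np.eye(50)
    assert (off > 0.9).sum() == 4  # two symmetric pairs


def test_posteriors_zero_error_gives_perfect_concordance():
    cohort = simulate_cohort({"pop": BASE_FREQS}, 200, seed=7)
    observed = simulate_imputation_posteriors(cohort.typing, 0.0, seed=8)
    assert locus_concordance(cohort.typing, observed)["A"] == 1.0
    assert observed[["posterior_1", "posterior_2"]].notna().all().all()


def test_posterior_error_rate_matches_binomial():
    cohort = simulate_cohort({"pop": BASE_FREQS}, 1000, seed=9)  # 2000 chromosomes
    observed = simulate_imputation_posteriors(cohort.typing, 0.1, seed=10)
    conc = locus_concordance(cohort.typing, observed, n_fields=None)["A"]
    # a wrong draw can collide with the other chromosome slot under
    # unordered matching, so allow ~3 binomial SDs plus slack
    assert conc == pytest.approx(0.9, abs=0.025)


def test_phenotype_zero_noise_is_linear_in_dosage():
    dosages = pd.DataFrame({"v": [0.0, 1.0, 2.0, 1.0]},
                           index=["a", "b", "c", "d"])
    em = EffectMap(effects={"v": 0.5}, target_r2=None, noise_sd=0.0,
                   time_slope=0.0)
    ph = simulate_phenotypes(dosages, em, seed=11)
    assert np.allclose(ph["latent"], 0.5 * dosages["v"].to_numpy())


def test_phenotype_target_variance_recovered():
    rng = np.random.default_rng(12)
    dosages = pd.DataFrame({"v": rng.binomial(2, 0.3, 2000).astype(float)})
    dosages.index = [f"i{k}" for k in range(2000)]
    em = EffectMap(effects={"v": 0.3}, target_r2=0.05, time_slope=0.0)
    ph = simulate_phenotypes(dosages, em, seed=13)
    resid = ph["latent"] - ph["genetic_value"]
    r2 = ph["genetic_value"].var() / ph["latent"].var()
    assert r2 == pytest.approx(0.05, abs=0.015)


def test_censoring_caps_raw_titres():
    rng = np.random.default_rng(14)
    dosages = pd.DataFrame({"v": rng.binomial(2, 0.3, 500).astype(float)})
    em = EffectMap(effects={"v": 0.3}, target_r2=0.05, censor_limit=1000.0)
    ph = simulate_phenotypes(dosages, em, seed=15)
    assert ph["raw_titre"].max() <= 1000.0
    assert (ph["raw_titre"] == 1000.0).any()  # the ceiling is actually hit


def test_phenotype_infeasible_target_errors():
    dosages = pd.DataFrame({"v": [1.0, 1.0, 1.0]})
    with pytest.raises(ValueError, match="infeasible"):
        simulate_phenotypes(dosages, EffectMap(effects={"v": 0.3}, target_r2=0.1))
    with pytest.raises(KeyError):
        simulate_phenotypes(dosages, EffectMap(effects={"w": 0.3}))


def _toy_reference():
    rng = np.random.default_rng(16)

    def seq(n):
        return "".join(rng.choice(list("ACGT"), n))

    shared = seq(150)
    unique1, unique2 = seq(150), seq(150)
    c1 = build_allele_contig("DRB1*03:01", "DRB1", [shared, unique1], spacer_len=20)
    c2 = build_allele_contig("DRB1*15:01", "DRB1", [shared, unique2], spacer_len=20)
    refs = {
        "DRB1*03:01": c1.sequence,
        "DRB1*15:01": c2.sequence,
        "background": seq(2000),
    }
    genes = {"DRB1*03:01": "DRB1", "DRB1*15:01": "DRB1"}
    return refs, genes, shared, unique1


def test_rnaseq_unique_and_shared_hits():
    refs, genes, shared, unique1 = _toy_reference()
    # a read from the unique exon hits one contig only
    hits = exact_align(unique1[:75], refs, genes)
    assert [h.contig for h in hits] == ["DRB1*03:01"]
    # a read from the shared exon hits both contigs, never the background
    hits = exact_align(shared[:75], refs, genes)
    assert sorted(h.contig for h in hits) == ["DRB1*03:01", "DRB1*15:01"]
    assert all(h.is_hla for h in hits)
    # reads containing N (spacers) never align
    assert exact_align("N" * 75, refs, genes) == []


def test_rnaseq_counts_track_expression():
    refs, genes, *_ = _toy_reference()
    expr = {"DRB1*03:01": 3.0, "DRB1*15:01": 1.0}
    reads, records = simulate_rnaseq_reads(refs, genes, expr, 4000, seed=17)
    res = count_hla_reads(records)
    # every read comes from a DRB1 contig: gene count = reads kept
    assert res.gene_counts["DRB1"] == pytest.approx(4000, abs=1)
    # unique-exon reads split 3:1 between the alleles (Poisson tolerance)
    a, b = res.allele_counts["DRB1*03:01"], res.allele_counts["DRB1*15:01"]
    assert a / (a + b) == pytest.approx(0.75, abs=3 * np.sqrt(0.75 * 0.25 / (a + b)))


def test_rnaseq_expression_on_absent_contig_errors():
    refs, genes, *_ = _toy_reference()
    with pytest.raises(KeyError, match="missing"):
        simulate_rnaseq_reads(refs, genes, {"missing": 1.0}, 10, seed=18)


def test_rnaseq_seed_reproducibility_and_paired_mode():
    refs, genes, *_ = _toy_reference()
    expr = {"DRB1*03:01": 1.0}
    r1, h1 = simulate_rnaseq_reads(refs, genes, expr, 100, seed=19)
    r2, h2 = simulate_rnaseq_reads(refs, genes, expr, 100, seed=19)
    assert r1 == r2 and h1 == h2
    reads, records = simulate_rnaseq_reads(
        refs, genes, expr, 50, paired=True, insert_size=120, seed=20
    )
    assert len(reads) == 100  # two mates per fragment
    assert all(r.hits for r in records)


def test_paired_gwas_rho_one_and_reproducibility():
    e1, _ = simulate_paired_gwas(500, rho=1.0, seed=21)
    r = np.corrcoef(e1["beta_a"], e1["beta_b"])[0, 1]
    assert r == pytest.approx(1.0, abs=1e-9)
    e2, _ = simulate_paired_gwas(500, rho=1.0, seed=21)
    assert e1.equals(e2)
    with pytest.raises(ValueError):
        simulate_paired_gwas(10, rho=1.5)


def test_paired_gwas_ld_blocks_induce_similarity():
    effects, ld = simulate_paired_gwas(
        200, rho=0.0, ld_block_size=10, ld_block_r=0.8, seed=22
    )
    b = effects["beta_a"].to_numpy()
    # same-block pairs share a component of weight 0.8: the mean product
    # over within-block pairs estimates that covariance (betas have mean 0)
    blocks = b.reshape(20, 10)
    iu = np.triu_indices(10, 1)
    within_cov = np.mean([
        (blocks[k][:, None] * blocks[k][None, :])[iu].mean() for k in range(20)
    ])
    assert within_cov > 0.4
    assert (ld.to_numpy()[:10, :10] >= 0.8 - 1e-12).all()
    assert ld.iloc[0, 15] == 0.0
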