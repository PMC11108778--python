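import numpy as np
import pandas as pd
import pytest

from hlamap.expression import (
    Hit,
    ReadHit,
    build_allele_contig,
    build_personalized_reference,
    cis_eqtl,
    count_hla_reads,
    fill_missing_exons,
    meta_eqtl,
    normalize_expression,
    read_sam_hits,
)


def hit(contig, gene=None, pos=0):
    return Hit(contig=contig, position=pos, is_hla=gene is not None, gene=gene)


def rh(rid, *hits):
    return ReadHit(read_id=rid, hits=tuple(hits))


def test_contig_length_formula():
    rng = np.random.default_rng(0)

    def seq(n):
        return "".join(rng.choice(list("ACGT"), n))

    contig = build_allele_contig("A*01:01", "A", [seq(100), seq(270), seq(282)])
    assert len(contig.sequence) == 1052  # 100+270+282 + 2*200
    # single exon: contig equals the exon, no spacer
    e = seq(80)
    single = build_allele_contig("A*02:01", "A", [e])
    assert single.sequence == e
    # spacer regions are all N
    s0, e0 = contig.exon_intervals[0]
    s1, _ = contig.exon_intervals[1]
    assert set(contig.sequence[e0:s1]) == {"N"}


def test_contig_length_property_random_exon_sets():
    rng = np.random.default_rng(1)
    for _ in range(20):
        k = int(rng.integers(1, 6))
        lens = rng.integers(30, 400, size=k)
        exons = ["".join(rng.choice(list("ACGT"), L)) for L in lens]
        c = build_allele_contig("B*07:02", "B", exons, spacer_len=200)
        assert len(c.sequence) == int(lens.sum()) + 200 * (k - 1)


def test_fill_missing_exons_closest_allele_and_tie_break():
    db = {
        "X": {1: "AAAA", 2: "CCCC", 3: "GGGG"},
        "Y": {1: "AATT", 2: "CCGG", 3: "TTTT"},
        "target": {1: "AAAA", 2: "CCCC", 3: None},
    }
    complete, prov = fill_missing_exons("target", db["target"], db)
    # X matches the typed exons exactly (0 mismatches); Y has 4
    assert complete[3] == "GGGG"
    assert prov[3] == "X"
    assert prov[1] == "target"  # typed exons keep their own provenance
    # tie in distance -> lexicographically smaller name
    db2 = {
        "B_allele": {1: "AAAA", 2: "TTTT"},
        "A_allele": {1: "AAAA", 2: "GGGG"},
        "t": {1: "AAAA", 2: None},
    }
    _, prov2 = fill_missing_exons("t", db2["t"], db2)
    assert prov2[2] == "A_allele"
    # typed-everywhere allele is the identity
    done, prov3 = fill_missing_exons("X", db["X"], db)
    assert done == db["X"] and set(prov3.values()) == {"X"}
    with pytest.raises(ValueError, match="exon 2"):
        fill_missing_exons("t", {1: "AAAA", 2: None}, {"t": {1: "AAAA", 2: None}})


def test_personalized_reference_masking_and_contig_counts():
    rng = np.random.default_rng(2)
    background = "".join(rng.choice(list("ACGT"), 500))
    db = {
        "DRB1*03:01": {1: "ACGTACGTAC", 2: "GGGGCCCC"},
        "DRB1*15:01": {1: "ACGTACGTTT", 2: "GGGGCCAA"},
        "DQB1*05:01": {1: "TTTTACGT"},
    }
    genes = {"DRB1*03:01": "DRB1", "DRB1*15:01": "DRB1", "DQB1*05:01": "DQB1"}
    typing = {"DRB1": ["DRB1*03:01", "DRB1*15:01"], "DQB1": ["DQB1*05:01", "DQB1*05:01"]}
    fasta, contigs, annotation = build_personalized_reference(
        typing, db, genes, background, [(100, 150)], spacer_len=20
    )
    assert set(fasta["background"][100:150]) == {"N"}
    assert fasta["background"][:100] == background[:100]
    # heterozygote -> 2 contigs, homozygote -> 1; total = distinct alleles
    assert len(contigs) == 3
    assert sorted(c.allele for c in contigs) == [
        "DQB1*05:01", "DRB1*03:01", "DRB1*15:01"
    ]
    assert (annotation["feature"] == "exon").all()
    with pytest.raises(ValueError):
        build_personalized_reference(typing, db, genes, background, [(490, 600)])


def test_counting_criteria():
    records = [
        rh("unique", hit("DRB1*15:01", "DRB1")),
        rh("multi_same_gene", hit("DRB1*15:01", "DRB1"), hit("DRB1*03:01", "DRB1")),
        rh("with_background", hit("DQA1*01:01", "DQA1"), hit("background")),
        rh("multi_gene", hit("DRB1*15:01", "DRB1"), hit("DRB5*01:01", "DRB5")),
    ]
    res = count_hla_reads(records)
    assert res.allele_counts["DRB1*15:01"] == 1
    assert res.gene_counts["DRB1"] == 2  # unique + multi-hit-one-gene
    assert "DQA1" not in res.gene_counts
    assert res.discarded["background_hit"] == 1
    assert res.discarded["multi_gene"] == 1
    # per-allele counts never exceed per-gene counts
    assert res.allele_counts.sum() <= res.gene_counts.sum()


def test_counting_fractional_mode_and_multimap_cap():
    records = [
        rh("multi_gene", hit("DRB1*15:01", "DRB1"), hit("DRB5*01:01", "DRB5")),
        rh("too_many", *[hit(f"c{k}", "DRB1") for k in range(301)]),
    ]
    res = count_hla_reads(records, multi_gene="fractional")
    assert res.gene_counts["DRB1"] == pytest.approx(0.5)
    assert res.gene_counts["DRB5"] == pytest.approx(0.5)
    assert res.discarded["too_many_hits"] == 1


def test_sam_ingest_round_trip(tmp_path):
    sam = tmp_path / "toy.sam"
    sam.write_text(
        "@HD\tVN:1.6\n"
        "@SQ\tSN:DRB1*15:01\tLN:1000\n"
        "@SQ\tSN:background\tLN:5000\n"
        "r1\t0\tDRB1*15:01\t10\t60\t20M\t*\t0\t0\tACGTACGTACGTACGTACGT\t*\n"
        "r2\t0\tbackground\t99\t60\t20M\t*\t0\t0\tACGTACGTACGTACGTACGT\t*\n"
        "r2\t256\tDRB1*15:01\t50\t0\t20M\t*\t0\t0\t*\t*\n"
    )
    records = read_sam_hits(sam, {"DRB1*15:01": "DRB1"})
    res = count_hla_reads(records)
    assert res.allele_counts["DRB1*15:01"] == 1  # r1 only; r2 hits background
    assert res.discarded["background_hit"] == 1


def test_normalization_median_of_ratios():
    counts = pd.DataFrame(
        {"s1": [100, 200, 300], "s2": [200, 400, 600]},
        index=["g1", "g2", "g3"],
    )
    norm = normalize_expression(counts)
    # library B is exactly 2x A: size factors differ 2-fold, values equalize
    assert np.allclose(norm["s1"], norm["s2"], atol=1e-6)
    # identical libraries: size factors 1 -> log2(count + 1)
    same = pd.DataFrame({"s1": [10, 20], "s2": [10, 20]}, index=["g1", "g2"])
    assert np.allclose(normalize_expression(same), np.log2(same + 1.0))


def test_normalization_is_per_population():
    counts = pd.DataFrame(
        {"a1": [10, 20], "a2": [10, 20], "b1": [5, 8], "b2": [50, 80]},
        index=["g1", "g2"],
    )
    pops = ["A", "A", "B", "B"]
    norm1 = normalize_expression(counts, pops)
    counts2 = counts.copy()
    counts2[["b1", "b2"]] = counts2[["b2", "b1"]].to_numpy()  # permute pop B
    norm2 = normalize_expression(counts2, pops)
    assert np.allclose(norm1[["a1", "a2"]], norm2[["a1", "a2"]])


def test_all_zero_gene_excluded_with_warning():
    counts = pd.DataFrame({"s1": [0, 10], "s2": [0, 12]}, index=["dead", "g"])
    with pytest.warns(UserWarning, match="all-zero"):
        norm = normalize_expression(counts)
    assert list(norm.index) == ["g"]


def test_cis_window_rule():
    rng = np.random.default_rng(4)
    n = 50
    ids = [f"i{k}" for k in range(n)]
    dosages = pd.DataFrame(
        {"near": rng.binomial(2, 0.4, n).astype(float),
         "far": rng.binomial(2, 0.4, n).astype(float)},
        index=ids,
    )
    expr = pd.DataFrame({"G": rng.standard_normal(n)}, index=ids)
    positions = pd.DataFrame(
        {"chromosome": ["6", "6"],
         "position": [2_000_000 - 900_000, 2_000_000 - 1_100_000]},
        index=pd.Index(["near", "far"], name="id"),
    )
    coords = pd.DataFrame(
        {"chromosome": ["6"], "start": [2_000_000], "end": [2_010_000]},
        index=pd.Index(["G"], name="gene"),
    )
    out = cis_eqtl(expr, dosages, positions, coords)
    assert list(out["variant"]) == ["near"]


def test_meta_eqtl_matches_association_worked_example():
    rows = lambda pop, beta, se: pd.DataFrame(
        [{"gene": "G", "variant": "v", "beta": beta, "se": se,
          "p": 0.5, "n": 100, "population": pop}]
    )
    meta = meta_eqtl([rows("p1", 0.5, 0.1), rows("p2", 0.3, 0.2)])
    assert meta.loc[0, "beta"] == pytest.approx(0.46)
    assert meta.loc[0, "q"] == pytest.approx(0.8)
    # single population passes through with Q absent
    single = meta_eqtl([rows("p1", 0.5, 0.1)])
    assert single.loc[0, "beta"] == 0.5
    assert pd.isna(single.loc[0, "q"])
    # identical populations -> Q = 0
    same = meta_eqtl([rows("p1", 0.5, 0.1), rows("p2", 0.5, 0.1)])
    assert same.loc[0, "q"] == pytest.approx(0.0, abs=1e-12)
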