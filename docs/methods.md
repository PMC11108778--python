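# Methods

This note records the models implemented in `hlamap`, their assumptions,
the defaults that matter, and the design choices made where more than one
reasonable convention exists. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Nomenclature and residue nesting

Classical alleles follow the colon-separated field grammar (optional
`HLA-` prefix, gene, `*`, 1–3 numeric fields of 2–3 digits, optional `G`
suffix for G groups). Field strings keep leading zeros and parsing/
formatting are exact inverses. Reducing resolution truncates fields and
drops the G flag whenever fields are actually removed, because a G group
is only defined at its full stated resolution. Ambiguity strings
(`a/b/c`) collapse to their first (common, well-documented) entry before
any comparison; the reserved token `XX` marks a missing or novel allele.

Residue tables use **coding-sequence position numbering** in a single
integer namespace per gene. Mature-protein numbering is not supported:
the offset between the two conventions is signal-peptide dependent and
maintaining both invites silent off-by-k errors; callers using
mature-protein sources must shift positions on input. Residue variants
are biallelic indicators nested inside the multi-allelic classical
alleles; the nesting map (residue → carrying alleles) is what links
residue-level and allele-level association models.

G-group membership is an explicit input table, not fetched from any
database; the bundled fixtures are synthetic.

## Imputation evaluation

Best-guess calling retains a per-chromosome allele iff its posterior is
≥ the threshold (default 0.7). The threshold is applied **per
chromosome**; a `per_genotype` flag switches to requiring both
chromosomes, since either reading of a diploid thresholding rule is
defensible.

Truth/test genotypes are unordered multisets; they are paired to maximize
agreement (multiset intersection), which is the standard convention for
unphased HLA comparison and unique up to ties. Per allele, over
chromosome slots: matched slots are TP; unmatched test slots FP; displaced
truth slots FN; TN is the remainder, so TP+FP+FN+TN equals the scoreable
slots exactly and the metric identities hold in integer arithmetic. A
homozygote contributes two slots (a half-right homozygote→heterozygote
call scores 1 TP + 1 FN). Individuals with any missing allele on either
platform are excluded and counted, never silently dropped. Locus
concordance is the matched-slot fraction, equal to the TP mass over
scoreable slots.

Cross-validation shuffles individuals once under the given seed and
splits into k disjoint, exhaustive folds (remainder to the first folds).
The frequency-baseline imputer deterministically assigns the modal
training allele with its training frequency as posterior: it is the
no-genotype-information floor, and its expected concordance has the
closed form p(modal), used as an oracle in tests.

## Population differentiation

G_ST = (H_T − H_S)/H_T with H_S the **equal-weight** mean within-
population expected heterozygosity and H_T computed on the equal-weight
mean frequency vector; Jost's D = [(H_T − H_S)/(1 − H_S)]·n/(n−1).
Equal weighting is the default because estimator variants differ across
packages and the unweighted form is the cleanest baseline; a
size-weighted mean and the Nei–Chesser small-sample correction are
available behind flags but off by default. Monomorphic loci (H_T = 0)
return G_ST = 0 with a warning rather than NaN. Allelic richness is the
bootstrap mean ± SE of the distinct-allele count in fixed-size
subsamples (1000 resamples by default), making richness comparable across
populations of different sizes.

## Association and fine-mapping

Traits are rank-transformed by Φ⁻¹((rank − 3/8)/(n + 1/4)) — the Blom
offset, chosen as the most common convention where only "inverse normal
transformation" is specified.

QC is sequential, each stage seeing the survivors of the previous:
sample call rate ≥ 0.97 → heterozygosity within ±3 SD → duplicate pairs
(relatedness > 0.9, not known twins; drop the lower-call-rate member) →
variant call rate ≥ 0.97 → Hardy–Weinberg P ≥ 1e-8 on founders (all
pairwise relatedness < 0.05) → MAF > 0.01. HWE uses the 1-df chi-square
by default (a conditional exact test is available behind a flag).
Relatedness matrices are **inputs**; their estimation is out of scope.

Single-variant tests are OLS with covariates (two-sided t), or a
single-random-effect LMM y = Xb + g + e, g ~ N(0, σg²K): K is
eigendecomposed, the model rotated, and δ = σe²/σg² estimated by REML on
a 1-d profile (coarse log-grid then bounded scalar minimization). With
K = I the LMM reduces exactly to OLS — a tested degenerate case. Missing
dosages may be mean-imputed by callers for association only, never for QC
statistics.

Fixed-effects meta-analysis uses inverse-variance weights; Cochran's
Q = Σw(b − b_meta)² on k−1 df, with heterogeneity flagged at
P_Q ≤ 1e-3. Stepwise forward conditioning adds the smallest-conditional-P
variant while P ≤ 5×10⁻⁹, with a deterministic tie-break (P, then |beta|,
then variant id) so results are invariant to input column order.

Model comparison fits Gaussian ML on identical case-complete rows
(differing row sets are refused), with k counting mean parameters plus
the residual variance; BIC = k·ln(n) − 2·logL; LRT applies only to nested
term sets. `enumerate_nested_models` emits, for a residue: the residue
term, the minimal covering allele group (carriers truncated to two
fields, then one, stopping at a single covering name), and the
constituent alleles as separate terms. A bidirectional add/drop BIC
search over a term pool provides the automated counterpart. Variance
explained is Δr² = r²(covariates+variants) − r²(covariates) per
population, with mean and range over populations where the trait exists
(absent-trait populations are skipped with a warning).

Analytic power for a 1-df additive test uses the noncentral chi-square
with NCP = n·q²/(1 − q²), q² the variance explained; a vectorized
Monte-Carlo power simulation provides the independent check (the
acceptance suite requires agreement within one percentage point, and
n = 2,500 / q² = 0.02 / α = 1e-8 to land in [0.90, 0.96]; the analytic
value computed here is ≈ 0.92).

## Effect-architecture correlation

LD pruning is greedy: variants visited by ascending association P (ties
by id), kept iff r² < 0.35 against everything already kept. The
permutation test shuffles the second study's variant labels and counts
permutations with |r_perm| ≥ |r_obs| — **two-sided by default**, because
"more extreme than observed" is ambiguous when the observed r is signed;
a one-sided mode is a flag. P = (k+1)/(n_perm+1) (add-one, never exactly
zero), and when k = 0 the result also carries the frequency-style bound
`< 1/n_perm`. When fewer than 10 exceedances are seen, the permutation
count doubles up to a cap, mirroring the practice of escalating
permutations until P is reliably estimated. Both pruned-set and full-set
permutation are possible — pruning is a separate call, so either order is
the caller's choice.

## Expression quantification and cis-eQTL

Allele contigs concatenate ordered exon sequences with 200-base N
spacers; the length identity len = Σexons + 200·(n_exons − 1) is enforced
at construction and property-tested. Untyped exons are filled from the
closest allele — fewest summed mismatches over exons typed in both, ties
to the lexicographically smaller name — with fill provenance recorded per
exon. The background genome has the HLA genes hard-masked to N, so no
HLA-derived read can hit it, and one contig is built per **distinct**
allele carried (homozygotes yield one).

Read counting: any background hit discards the read ("no other regions in
the genome" read strictly); more than 300 reported hits discards it (an
ingest cap mirroring a bounded multimap setting); a unique allele-contig
hit counts for that allele and its gene; multiple contigs of one gene
count once for the gene. Reads spanning contigs of **different** genes
(DRB1/DRB5-type paralogs) are discarded by default — the conservative
reading where no stated rule exists — with a fractional 1/n_genes mode
available. Unique-read counts are never redistributed to alleles. All
discards are logged by reason.

Normalization is median-of-ratios size factors followed by log2(x+1),
per population. This is a deliberate, documented stand-in for a
variance-stabilizing transform: it is monotone and variance-flattening at
the planted effect sizes the pipeline is tested at, and keeps the eQTL
stage free of a heavy model fit. Confounder adjustment is by top
expression principal components supplied as covariates rather than
surrogate-variable analysis — the same linear-adjustment idea with a
simpler, deterministic construction. Divergences from the full VST/SVA
machinery matter mainly for low-count genes and subtle batch structure,
neither of which the synthetic data exhibits.

cis-eQTL testing regresses normalized expression on dosage for variants
with position within [gene start − 1 Mb, gene end + 1 Mb] on the same
chromosome; BH correction is applied within the tested set; populations
combine by the same fixed-effects meta-analysis as the association
module. Coordinates are 0-based half-open internally; emitted annotation
is 1-based inclusive (GTF convention).

## Peptide grouping

Residues are filtered to P < 0.05 before counting; an allele is
positive-excess iff its positive-beta residue count exceeds 1.5× the
negative count (and vice versa), else unclassified; 0-vs-0 is
unclassified. Positions without residue data for an allele are skipped
and surfaced in a coverage column. Best binder is the minimum percentile
rank; breadth the fraction ≤ the top 5th percentile. Group comparison is
a two-tailed Mann–Whitney U — exact for small tie-free samples,
normal approximation with tie correction otherwise — validated against
full label-permutation enumeration for n ≤ 8. Binding predictions are
inputs (allele, peptide, percentile TSVs); no predictor is called.

## Synthetic data: what it emulates and what it does not

Per-population allele frequencies are Dirichlet draws around a shared
ancestral vector; the concentration parameter is the differentiation
dial (large → G_ST → 0). Cohorts are simulated at the **haplotype**
level so that SNVs placed on allele-defined haplotypes are in
mechanically real LD with the classical alleles: a tag SNV is a superset
of its allele's haplotypes with off-haplotype rate solved from
q = p/(r²(1−p)+p), giving the configured r² in expectation. Relatedness
is identity plus optional planted duplicate pairs (entry 0.95),
exercising the duplicate-removal rule. Imputation output flips each
chromosome with the configured error rate to a frequency-weighted wrong
allele and draws posteriors from a Beta with mean `confidence`.
Phenotypes are additive variant effects plus a time-since-vaccination
slope (uniform over 4–52 weeks, negative slope by default — antibody
wanes with time) and Gaussian noise scaled to a target variance
explained; raw titres are exponentiated and censored at 1,000 (an assay
upper limit of detection) **on the raw scale, before** any
inverse-normal transform. RNA-seq reads are 75-base (optionally paired)
exact substrings of expressed contigs, aligned by exhaustive exact
substring search — the toy aligner is the ground-truth oracle for hit
sets, not a model of a spliced aligner; real alignments enter through
the SAM ingest path instead.

Not emulated: recombination/coalescent structure, sequencing errors and
base qualities, splice-aware alignment, genotyping batch effects, and
population-specific covariate distributions. Passing tests therefore
demonstrate the correctness of the statistical machinery and its
behaviour under the planted generative models — not robustness to
artefacts real cohorts carry.

## Problem sizes and determinism

The test suite and acceptance script use deliberately modest problem
sizes — cohorts of 200–3,000, 40-variant effect vectors, 2,000-permutation
nulls, tens of recovery seeds — chosen so the whole pipeline re-runs
comfortably on a single CPU while keeping binomial/Monte-Carlo error well
inside the asserted tolerances. Every stochastic step takes an explicit
seed and uses its own `numpy.random.default_rng`, so all outputs are
bit-reproducible; the acceptance script derives per-stage seeds from its
single `--seed` via `SeedSequence.spawn`.

## Known limitations

- The LMM profiles a single variance ratio; multiple random effects and
  exact mixed-model score tests are out of scope.
- Random-effects meta-analysis beyond Q reporting is not provided.
- The exact-substring aligner cannot model mismatches or indels, so
  allele-specific counts from real (error-bearing) reads should come in
  via SAM ingest from a real aligner.
- G_ST/Jost's D carry no confidence intervals or exact differentiation
  tests.
- Residue positions support one numbering namespace; sources using
  mature-protein numbering must be shifted on input.
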