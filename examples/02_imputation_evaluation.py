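"""Evaluate imputed HLA calls against typed truth with five-fold CV.

Simulates a 1,000-individual typed panel, perturbs it at a 10% per-
chromosome error rate with posteriors around 0.9, and scores best-guess
calls: the mean locus concordance should sit near 0.90 (= 1 - error rate).
"""

from hlamap.imputation import call_best_guess, kfold_crossvalidate, locus_concordance
from hlamap.simulate import simulate_cohort, simulate_imputation_posteriors

freqs = {"pop": {"A": {"A*01:01": 0.4, "A*02:01": 0.35, "A*03:01": 0.25}}}
cohort = simulate_cohort(freqs, 1000, seed=1)
observed = simulate_imputation_posteriors(cohort.typing, error_rate=0.10,
                                          confidence=0.9, seed=2)


class TableImputer:
    """Hands back the simulated imputation output for held-out individuals."""

    def fit(self, training):
        return self

    def predict(self, ids):
        sel = observed["individual_id"].isin(list(ids))
        return observed[sel].reset_index(drop=True)


reports, mean_conc = kfold_crossvalidate(cohort.typing, TableImputer, k=5, seed=3)
print(f"five-fold mean concordance at locus A: {mean_conc['A']:.3f} "
      "(fraction of chromosome slots called identically; ~0.90 expected)")

called = call_best_guess(observed, threshold=0.7)
conc = locus_concordance(cohort.typing, called)["A"]
print(f"after the 0.7 posterior threshold: concordance {conc:.3f} among "
      "retained calls (thresholding trades call count for quality)")
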