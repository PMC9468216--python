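"""Punch MCAR holes into a complete synthetic cohort and impute them back.

The imputer is the iterative missForest scheme: mode-fill initialization,
then per-column random-forest refits until the imputed cells stop changing.
Accuracy is judged against the held-out true values and compared with the
mode-fill baseline.
"""

from mmdbn import (
    MissingnessSpec,
    ancestral_sample,
    charls_like_network,
    imputation_accuracy,
    initialize_fill,
    inject_missingness,
    rf_impute,
)

truth = ancestral_sample(charls_like_network(), n=5_000, seed=3)
masked, mask = inject_missingness(
    truth, MissingnessSpec(mechanism="MCAR", rate=0.1, seed=4, exclude=("mmd",))
)
print(f"masked {int(mask.to_numpy().sum())} of {mask.size} cells (10% MCAR, outcome kept)")

result = rf_impute(masked, trees=50, seed=5)
rf_acc = imputation_accuracy(truth, result, mask)
mode_acc = imputation_accuracy(truth, initialize_fill(masked), mask)
print(f"converged after {result.iterations} iteration(s); disagreement per pass: "
      f"{[round(d, 4) for d in result.disagreement]}")
print(f"forest accuracy {rf_acc:.3f} vs mode-fill baseline {mode_acc:.3f}")
# the forest beats the baseline because it exploits the dependence structure
# (e.g. smoking predicts alcohol); both are far above chance for 2-5 codes
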