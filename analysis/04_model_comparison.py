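"""Compare classifiers pairwise with the Wilcoxon signed-rank test.

Reads the per-repeat tables produced by 02/03 and tests, per scheme, whether
the per-split macro-F1 of each deep model differs from each classical one.
Requires both upstream scripts to have been run with the same seed so the
splits are paired.
"""

from itertools import product
from pathlib import Path

import pandas as pd

import voltclass as vc

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    classical = pd.read_csv(OUT / "classical-per-repeat.csv")
    deep = pd.read_csv(OUT / "deep-per-repeat.csv")
    rows = []
    for scheme in sorted(set(classical.scheme) & set(deep.scheme)):
        c_sub = classical[classical.scheme == scheme]
        d_sub = deep[deep.scheme == scheme]
        for a, b in product(sorted(d_sub.model.unique()), sorted(c_sub.model.unique())):
            sa = d_sub[d_sub.model == a].sort_values("repeat")["macro_f1"]
            sb = c_sub[c_sub.model == b].sort_values("repeat")["macro_f1"]
            n = min(len(sa), len(sb))
            if n < 3:
                continue
            p = vc.compare_models(sa.iloc[:n].to_numpy(), sb.iloc[:n].to_numpy())
            rows.append({"scheme": scheme, "model_a": a, "model_b": b,
                         "n_pairs": n, "wilcoxon_p": p})
            print(f"{scheme}: {a} vs {b} (n={n}) p = {p:.4f}")
    pd.DataFrame(rows).to_csv(OUT / "model-comparison.csv", index=False)
    print(f"table -> {OUT / 'model-comparison.csv'}")


if __name__ == "__main__":
    main()
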