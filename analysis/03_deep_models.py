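"""Train and score the four deep classifiers on the seawater libraries.

The dimension-shuffled LSTM is cheap (one matmul per scan) and runs the
full 300-epoch desk protocol over repeated stratified splits; the three
convolutional models are surveyed at the single-CPU scale (30-epoch cap,
one split each — their recurrent branches already carry them to the
near-perfect regime there, while the pure FCN is still mid-optimization;
see docs/methods.md).  Writes per-repeat and summary tables under
results/.
"""

import sys
from pathlib import Path

import pandas as pd

import voltclass as vc
from voltclass.config import resolve_library
from voltclass.nn.training import acceptance_scale_config

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
LSTM_REPEATS = 3
HYBRID_CELLS = vc.LSTMConfig(cells=64, dropout=0.8)  # cell sweep's choice


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows, summaries = [], []
    for scheme in ("4-SW", "11-SW"):
        ds = vc.generate_dataset(resolve_library(scheme), seed=SEED)

        plan = vc.SplitPlan.for_scheme(scheme, n_repeats=LSTM_REPEATS, seed=SEED)
        desk = vc.TrainConfig(epochs=300, batch_size=4, seed=SEED, saturation_patience=10)
        runs = [("lstm", plan, desk, None)]

        survey_plan = vc.SplitPlan.for_scheme(scheme, n_repeats=1, seed=SEED)
        survey = acceptance_scale_config(epochs=30, seed=SEED)
        for kind in ("fcn", "lstm_fcn", "alstm_fcn"):
            runs.append((kind, survey_plan, survey,
                         None if kind == "fcn" else HYBRID_CELLS))

        for kind, p, cfg, lstm_cfg in runs:
            s = vc.repeated_eval(kind, ds, p, deep_cfg=cfg, lstm_cfg=lstm_cfg)
            rows.append(s.per_repeat.assign(model=kind, scheme=scheme))
            summaries.append(s.aggregate().assign(model=kind, scheme=scheme))
            print(f"{scheme} {kind:10s}: median micro ROC-AUC "
                  f"{s.median('micro_roc_auc'):.4f}, median macro-F1 "
                  f"{s.median('macro_f1'):.3f}", flush=True)
    pd.concat(rows).to_csv(OUT / "deep-per-repeat.csv", index=False)
    pd.concat(summaries).to_csv(OUT / "deep-summary.csv", index=False)
    print(f"tables -> {OUT}/deep-*.csv")


if __name__ == "__main__":
    main()
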