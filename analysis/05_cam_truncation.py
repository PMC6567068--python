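"""Class-activation-map interpretation and the CAM-guided truncation run.

Trains the convolutional model on the 4-class seawater library and exports
the heavy-metal-class CAM for one scan of each single-analyte heavy metal:
the activation maximum sits on that metal's anodic stripping peak.  Then
reruns training on the library truncated to the 400-point anodic stripping
window (drop 502 head / 100 tail samples) and compares accuracy against
full-length training on the same split.

Note the truncated problem has a structural accuracy ceiling on this
emulation: methyl parathion and blank seawater carry no programmed anodic
features, so they become indistinguishable once the cathodic branch is
removed (docs/methods.md discusses this).
"""

import sys
from pathlib import Path

import pandas as pd

import voltclass as vc
from voltclass.cam import cam_table
from voltclass.config import resolve_library
from voltclass.nn.training import acceptance_scale_config, fit_deep

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
SINGLE_ANALYTE = {"Hg": 0.06, "Cu": -0.20, "Pb": -0.58, "Cd": -0.78}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ds4 = vc.generate_dataset(resolve_library("4-SW"), seed=SEED)
    plan = vc.SplitPlan.for_scheme("4-SW", n_repeats=1, seed=SEED)
    tr, te = vc.stratified_split(ds4, plan, 0)
    fcn = fit_deep("fcn", tr, te, acceptance_scale_config(epochs=80, seed=SEED))
    print(f"FCN on 4-SW: final val accuracy {fcn.history.val_accuracy.iloc[-1]:.3f}")

    cam_dir = OUT / "cams"
    cam_dir.mkdir(exist_ok=True)
    grid = ds4.grid
    for metal, E_p in SINGLE_ANALYTE.items():
        scan = next(s for s in te if s.label == "HM" and f"-{metal}-" in s.sample_id)
        tbl = cam_table(fcn, scan, "HM")
        tbl.to_csv(cam_dir / f"cam-HM-{metal}.csv", index=False)
        peak_idx = grid.index_of(E_p, "anodic")
        cam_argmax = int(tbl.activation.idxmax())
        print(f"  {metal}: CAM argmax index {cam_argmax} "
              f"(programmed stripping peak at {peak_idx}, {E_p:+.2f} V)")

    # truncation retraining with the fast recurrent model on the same split
    cfg = vc.TrainConfig(epochs=300, batch_size=4, seed=SEED, saturation_patience=10)
    _, report = vc.cam_guided_truncation(ds4, "lstm", cfg, drop_head=502,
                                         drop_tail=100, plan=plan)
    print(f"truncation 1002 -> {report.truncated_length} points: "
          f"accuracy {report.full_accuracy:.3f} (full) vs "
          f"{report.truncated_accuracy:.3f} (truncated)")
    pd.DataFrame(report.full_confusion, index=report.class_names,
                 columns=report.class_names).to_csv(OUT / "confusion-full.csv")
    pd.DataFrame(report.truncated_confusion, index=report.class_names,
                 columns=report.class_names).to_csv(OUT / "confusion-truncated.csv")
    print(f"confusion matrices -> {OUT}/confusion-*.csv")


if __name__ == "__main__":
    main()
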