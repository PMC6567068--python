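"""Generate the four synthetic scan libraries and write them to results/data.

Emits the 11-class and 4-class seawater libraries (377 scans each; the same
scans under two labelings) and the two explosives-like layouts, plus a
manifest recording seeds and class inventories.
"""

import json
import sys
from pathlib import Path

import voltclass as vc
from voltclass.config import resolve_library

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": SEED, "libraries": {}}
    for name in ("11-SW", "4-SW", "3-EXP", "11-EXP"):
        spec = resolve_library(name)
        ds = vc.generate_dataset(spec, seed=SEED)
        path = OUT / f"scans-{name}.csv"
        vc.write_scans(ds, path)
        manifest["libraries"][name] = {
            "n_scans": len(ds),
            "classes": ds.class_counts(),
            "n_points": ds.n_points,
            "file": path.name,
        }
        print(f"{name}: {len(ds)} scans, {len(ds.class_names)} classes -> {path}")
    with open(OUT / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    print(f"manifest -> {OUT / 'manifest.json'}")


if __name__ == "__main__":
    main()
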