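"""Synthetic CSWV scan libraries.

The experimental seawater library behind this pipeline is not public, so the
classifiers are exercised on simulated voltammograms that reproduce its
statistical structure: each contaminant class contributes Gaussian peaks (in
potential space) at its published peak potentials, superimposed on a broad
oxygen-reduction background near -0.9 V on the cathodic branch, a small random
linear baseline drift, and additive white noise.  Peak amplitude scales with a
per-scan concentration proxy drawn log-uniformly from the 50-2000 ppb range
used when the library was assembled, and the finished dataset is z-scored as a
whole so traces live near mean 0 / sd 1, the regime the classifiers assume.

Class inventory of the 11-class seawater scheme (``11-SW``), with anodic
stripping peak potentials in V vs. Ag/AgCl:

======  ===========================================  =======
class   signature                                    n
======  ===========================================  =======
DQ      cathodic -0.52; broad anodic -0.56           14
MeP     cathodic -0.71 (oxygen shoulder)             50
PQ      cathodic -0.51; broad anodic -0.55           8
Cd      anodic stripping -0.78                       36
Cu      anodic stripping -0.20                       23
Hg      anodic stripping +0.06                       22
Pb      anodic stripping -0.58                       38
HMM     Cd + Hg + Pb stripping peaks                 68
BPA     cathodic 0.036; anodic 0.044 and 0.41        4
NP      cathodic 0.016; anodic 0.041 and 0.48        34
SW      blank seawater: oxygen background only       80
======  ===========================================  =======

The 4-class grouping (``4-SW``) merges these into HM / Ind / HandP / SW.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import ScanDataset
from .grid import ANODIC, CATHODIC, PotentialGrid, build_seawater_grid

__all__ = [
    "PeakSpec",
    "ClassSpec",
    "LibrarySpec",
    "seawater_library_spec",
    "collapse_to_4sw",
    "generic_library_spec",
    "generate_dataset",
]

#: map 11-SW class -> 4-SW group
FOUR_CLASS_GROUPS = {
    "Cd": "HM", "Cu": "HM", "Hg": "HM", "Pb": "HM", "HMM": "HM",
    "BPA": "Ind", "NP": "Ind",
    "DQ": "HandP", "PQ": "HandP", "MeP": "HandP",
    "SW": "SW",
}
FOUR_CLASS_ORDER = ("HM", "Ind", "HandP", "SW")


@dataclass(frozen=True)
class PeakSpec:
    """One faradaic peak: Gaussian in potential on a single branch.

    ``sign`` is +1 for anodic (oxidation) current and -1 for cathodic
    (reduction) current, matching how the concatenated traces are plotted.
    """

    E_p: float
    branch: str
    width_sigma: float = 0.030
    amplitude_scale: float = 1.0
    sign: int | None = None

    def __post_init__(self) -> None:
        if self.width_sigma <= 0:
            raise ValueError("width_sigma must be positive")
        if self.branch not in (CATHODIC, ANODIC):
            raise ValueError(f"unknown branch {self.branch!r}")
        if self.sign is None:
            object.__setattr__(self, "sign", 1 if self.branch == ANODIC else -1)


@dataclass(frozen=True)
class ClassSpec:
    name: str
    peaks: tuple[PeakSpec, ...] = ()
    include_oxygen_background: bool = True
    n_samples: int = 1
    concentration_range: tuple[float, float] = (50.0, 2000.0)

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        lo, hi = self.concentration_range
        if not (0 < lo <= hi):
            raise ValueError("invalid concentration range")


@dataclass(frozen=True)
class LibrarySpec:
    """Full recipe for one synthetic scan library."""

    scheme: str
    classes: tuple[ClassSpec, ...]
    grid: PotentialGrid = field(default_factory=build_seawater_grid)
    noise_sigma: float = 0.05
    baseline_slope_sigma: float = 0.1
    oxygen_E_p: float = -0.9
    oxygen_sigma: float = 0.080
    oxygen_amplitude: float = 1.0
    oxygen_jitter: float = 0.2
    #: peak amplitude per ppb of concentration proxy (pre-standardization units)
    amplitude_per_ppb: float = 1.0 / 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate class names in library spec")
        if not self.classes:
            raise ValueError("library spec needs at least one class")

    @property
    def class_names(self) -> list[str]:
        return [c.name for c in self.classes]

    def class_counts(self) -> dict[str, int]:
        return {c.name: c.n_samples for c in self.classes}


# -- published seawater signatures ----------------------------------------

_STRIPPING = {  # anodic stripping peak potentials, V vs Ag/AgCl
    "Cd": -0.78,
    "Cu": -0.20,
    "Hg": 0.06,
    "Pb": -0.58,
}


def _metal_peaks(*metals: str) -> tuple[PeakSpec, ...]:
    return tuple(PeakSpec(E_p=_STRIPPING[m], branch=ANODIC) for m in metals)


def seawater_library_spec() -> LibrarySpec:
    """The default 11-class seawater library (377 scans)."""
    broad = dict(width_sigma=0.050, amplitude_scale=0.4)
    classes = (
        ClassSpec("DQ", (PeakSpec(-0.52, CATHODIC), PeakSpec(-0.56, ANODIC, **broad)), n_samples=14),
        ClassSpec("MeP", (PeakSpec(-0.71, CATHODIC),), n_samples=50),
        ClassSpec("PQ", (PeakSpec(-0.51, CATHODIC), PeakSpec(-0.55, ANODIC, **broad)), n_samples=8),
        ClassSpec("Cd", _metal_peaks("Cd"), n_samples=36),
        ClassSpec("Cu", _metal_peaks("Cu"), n_samples=23),
        ClassSpec("Hg", _metal_peaks("Hg"), n_samples=22),
        ClassSpec("Pb", _metal_peaks("Pb"), n_samples=38),
        ClassSpec("HMM", _metal_peaks("Cd", "Hg", "Pb"), n_samples=68),
        ClassSpec(
            "BPA",
            (
                PeakSpec(0.036, CATHODIC),
                PeakSpec(0.044, ANODIC, amplitude_scale=0.7),
                PeakSpec(0.41, ANODIC, amplitude_scale=0.7),
            ),
            n_samples=4,
        ),
        ClassSpec(
            "NP",
            (
                PeakSpec(0.016, CATHODIC),
                PeakSpec(0.041, ANODIC, amplitude_scale=0.7),
                PeakSpec(0.48, ANODIC, amplitude_scale=0.7),
            ),
            n_samples=34,
        ),
        ClassSpec("SW", (), n_samples=80),
    )
    return LibrarySpec(scheme="11-SW", classes=classes)


def collapse_to_4sw(spec: LibrarySpec) -> LibrarySpec:
    """Regroup the 11-class seawater spec into the 4-class scheme.

    Scans are unchanged in nature; only labels merge (HM 187, Ind 38,
    HandP 72, SW 80).  Merged classes keep their member signatures, so the
    4-class dataset is a relabeling of the same generative mixture.
    """
    unknown = [c.name for c in spec.classes if c.name not in FOUR_CLASS_GROUPS]
    if unknown:
        raise ValueError(f"classes without a 4-SW group: {unknown}")
    # keep one ClassSpec per 11-SW member but rename to its group; the
    # generator treats same-named specs as strata of one class
    classes = tuple(
        replace(c, name=f"{FOUR_CLASS_GROUPS[c.name]}::{c.name}") for c in spec.classes
    )
    return replace(spec, scheme="4-SW", classes=classes)


def generic_library_spec(config: dict) -> LibrarySpec:
    """Build a library spec from a plain dict (explosives-like layouts).

    ``config`` keys: ``scheme``, ``classes`` (list of dicts with ``name``,
    ``n_samples``, optional ``peaks`` as [E_p, branch(, sigma, scale)] rows,
    optional ``oxygen_background``), optional ``grid`` dict and noise fields.

    Two stock layouts mirror the explosives libraries: a 3-class one with
    36/24/6 scans and an 11-class one with 6 scans per class.
    """
    if not config.get("classes"):
        raise ValueError("config must list at least one class")
    gcfg = config.get("grid")
    grid = PotentialGrid(**gcfg) if gcfg else build_seawater_grid()
    classes = []
    for ccfg in config["classes"]:
        peaks = tuple(
            PeakSpec(
                E_p=float(row[0]),
                branch=str(row[1]),
                width_sigma=float(row[2]) if len(row) > 2 else 0.030,
                amplitude_scale=float(row[3]) if len(row) > 3 else 1.0,
            )
            for row in ccfg.get("peaks", ())
        )
        classes.append(
            ClassSpec(
                name=str(ccfg["name"]),
                peaks=peaks,
                include_oxygen_background=bool(ccfg.get("oxygen_background", True)),
                n_samples=int(ccfg["n_samples"]),
                concentration_range=tuple(ccfg.get("concentration_range", (50.0, 2000.0))),
            )
        )
    kwargs = {
        k: config[k]
        for k in ("noise_sigma", "baseline_slope_sigma", "seed", "amplitude_per_ppb")
        if k in config
    }
    return LibrarySpec(scheme=str(config.get("scheme", "custom")), classes=tuple(classes), grid=grid, **kwargs)


def explosives_3class_config() -> dict:
    """3-class explosives-like layout: A 36 / B 24 / C (blank buffer) 6."""
    return {
        "scheme": "3-EXP",
        "classes": [
            {"name": "A", "n_samples": 36,
             "peaks": [[-0.45, CATHODIC], [-0.62, CATHODIC, 0.030, 0.8]]},
            {"name": "B", "n_samples": 24,
             "peaks": [[-0.30, CATHODIC], [-0.76, ANODIC, 0.030, 0.6]]},
            {"name": "C", "n_samples": 6, "peaks": []},
        ],
    }


def explosives_11class_config() -> dict:
    """11-class explosives-like layout: 6 scans per class, one cathodic peak each."""
    E_ps = np.round(np.linspace(-0.85, 0.35, 11), 3)
    return {
        "scheme": "11-EXP",
        "classes": [
            {"name": f"X{k:02d}", "n_samples": 6, "peaks": [[float(E), CATHODIC]]}
            for k, E in enumerate(E_ps)
        ],
    }


# -- trace synthesis -------------------------------------------------------

def _peak_profile(peak: PeakSpec, grid: PotentialGrid) -> np.ndarray:
    """Unit-amplitude Gaussian profile of one peak on the full concatenated grid."""
    E = grid.potentials()
    prof = np.zeros(grid.n_points)
    if peak.branch == CATHODIC:
        sl = slice(0, grid.boundary_index)
    else:
        sl = slice(grid.boundary_index, grid.n_points)
    if sl.stop - sl.start == 0:
        return prof
    lo = float(np.min(E[sl]))
    hi = float(np.max(E[sl]))
    if not (lo <= peak.E_p <= hi):
        raise ValueError(
            f"peak at {peak.E_p} V outside the {peak.branch} range [{lo}, {hi}] V"
        )
    prof[sl] = peak.sign * peak.amplitude_scale * np.exp(
        -0.5 * ((E[sl] - peak.E_p) / peak.width_sigma) ** 2
    )
    return prof


def expected_trace(spec: LibrarySpec, class_name: str, concentration: float) -> np.ndarray:
    """Noise-free expected trace of one class at a given concentration proxy."""
    cls = next(c for c in spec.classes if c.name == class_name)
    trace = np.zeros(spec.grid.n_points)
    if cls.include_oxygen_background:
        trace += spec.oxygen_amplitude * _peak_profile(
            PeakSpec(spec.oxygen_E_p, CATHODIC, spec.oxygen_sigma), spec.grid
        )
    amp = spec.amplitude_per_ppb * concentration
    for pk in cls.peaks:
        trace += amp * _peak_profile(pk, spec.grid)
    return trace


def _strip_stratum(name: str) -> str:
    """Merged classes are encoded 'GROUP::member'; the label is the group."""
    return name.split("::", 1)[0]


def generate_dataset(spec: LibrarySpec, seed: int | None = None) -> ScanDataset:
    """Draw one labeled ScanDataset from a library spec.

    Reproducible: every scan gets its own counter-derived substream, so the
    dataset is invariant to generation order.  After synthesis the whole
    current table is z-scored (single global mean/sd), emulating raw data
    that already sits near mean 0 / sd 1.
    """
    master = spec.seed if seed is None else seed
    grid = spec.grid
    class_names: list[str] = []
    for c in spec.classes:
        lbl = _strip_stratum(c.name)
        if lbl not in class_names:
            class_names.append(lbl)

    profiles = {c.name: [_peak_profile(p, grid) for p in c.peaks] for c in spec.classes}
    oxy = (
        _peak_profile(PeakSpec(spec.oxygen_E_p, CATHODIC, spec.oxygen_sigma), grid)
        if any(c.include_oxygen_background for c in spec.classes)
        else None
    )
    x = np.linspace(-0.5, 0.5, grid.n_points)

    rows, labels, ids, concs = [], [], [], []
    scan_counter = 0
    for c in spec.classes:
        lbl = _strip_stratum(c.name)
        lo, hi = c.concentration_range
        for j in range(c.n_samples):
            rng = np.random.default_rng([master, scan_counter])
            conc = float(np.exp(rng.uniform(np.log(lo), np.log(hi)))) if c.peaks else np.nan
            trace = np.zeros(grid.n_points)
            if c.include_oxygen_background:
                trace += (
                    spec.oxygen_amplitude
                    * (1.0 + spec.oxygen_jitter * rng.uniform(-1.0, 1.0))
                    * oxy
                )
            if c.peaks:
                amp = spec.amplitude_per_ppb * conc
                for prof in profiles[c.name]:
                    # per-peak relative height jitter (electrode-to-electrode variation)
                    trace += amp * (1.0 + 0.1 * rng.uniform(-1.0, 1.0)) * prof
            trace += rng.normal(0.0, spec.baseline_slope_sigma) * x
            if spec.noise_sigma > 0:
                trace += rng.normal(0.0, spec.noise_sigma, grid.n_points)
            rows.append(trace)
            labels.append(lbl)
            ids.append(f"{spec.scheme}-{c.name.replace('::', '-')}-{j:03d}")
            concs.append(conc)
            scan_counter += 1

    currents = np.asarray(rows)
    mu = float(currents.mean())
    sd = float(currents.std())
    if sd > 0:
        currents = (currents - mu) / sd
    return ScanDataset(
        currents=currents,
        labels=labels,
        scheme=spec.scheme,
        class_names=class_names,
        grid=grid,
        sample_ids=ids,
        concentrations=concs,
    )
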