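"""Synthetic library generator: class inventories, peak placement, scaling."""

import numpy as np
import pytest

import voltclass as vc
from voltclass.grid import ANODIC, CATHODIC, build_seawater_grid
from voltclass.simulate import (
    ClassSpec,
    PeakSpec,
    expected_trace,
    explosives_11class_config,
    explosives_3class_config,
    generic_library_spec,
    seawater_library_spec,
)

SW11_COUNTS = {
    "DQ": 14, "MeP": 50, "PQ": 8, "Cd": 36, "Cu": 23, "Hg": 22,
    "Pb": 38, "HMM": 68, "BPA": 4, "NP": 34, "SW": 80,
}
SW4_COUNTS = {"HM": 187, "Ind": 38, "HandP": 72, "SW": 80}


class TestSeawaterSpec:
    def test_class_counts(self, seawater_spec):
        assert seawater_spec.class_counts() == SW11_COUNTS
        assert sum(SW11_COUNTS.values()) == 377

    def test_hg_single_anodic_peak(self, seawater_spec):
        hg = next(c for c in seawater_spec.classes if c.name == "Hg")
        assert len(hg.peaks) == 1
        assert hg.peaks[0].E_p == pytest.approx(0.06)
        assert hg.peaks[0].branch == ANODIC

    def test_blank_is_background_only(self, seawater_spec):
        sw = next(c for c in seawater_spec.classes if c.name == "SW")
        assert sw.peaks == ()
        assert sw.include_oxygen_background

    def test_heavy_metal_mixture_is_union(self, seawater_spec):
        by_name = {c.name: c for c in seawater_spec.classes}
        mixture = {(p.E_p, p.branch) for p in by_name["HMM"].peaks}
        singles = {
            (p.E_p, p.branch)
            for m in ("Cd", "Hg", "Pb")
            for p in by_name[m].peaks
        }
        assert mixture == singles

    def test_collapse_counts_and_total(self, seawater_spec):
        spec4 = vc.collapse_to_4sw(seawater_spec)
        counts = {}
        for c in spec4.classes:
            counts[c.name.split("::")[0]] = counts.get(c.name.split("::")[0], 0) + c.n_samples
        assert counts == SW4_COUNTS
        assert sum(counts.values()) == sum(SW11_COUNTS.values())

    def test_collapse_rejects_unknown_class(self, seawater_spec):
        from dataclasses import replace

        bad = replace(
            seawater_spec,
            classes=seawater_spec.classes + (ClassSpec("XX", (), n_samples=2),),
        )
        with pytest.raises(ValueError):
            vc.collapse_to_4sw(bad)


class TestGeneratedDatasets:
    def test_generated_counts_11sw(self, sw11):
        assert sw11.class_counts() == SW11_COUNTS

    def test_generated_counts_4sw(self, sw4):
        assert sw4.class_counts() == SW4_COUNTS

    def test_determinism(self, seawater_spec):
        a = vc.generate_dataset(seawater_spec, seed=123)
        b = vc.generate_dataset(seawater_spec, seed=123)
        assert a.equals(b)

    def test_seed_changes_data(self, seawater_spec, sw11):
        other = vc.generate_dataset(seawater_spec, seed=1)
        assert not np.allclose(other.currents, sw11.currents)

    def test_standardization(self, sw11):
        assert abs(sw11.currents.mean()) < 0.05
        assert abs(sw11.currents.std() - 1.0) < 0.05

    def test_peak_location_recovery(self, seawater_spec):
        """Every seawater peak appears at its programmed grid index (±2)."""
        grid = seawater_spec.grid
        for cls in seawater_spec.classes:
            trace = expected_trace(seawater_spec, cls.name, concentration=1000.0)
            for pk in cls.peaks:
                target = grid.index_of(pk.E_p, pk.branch)
                sl = (
                    slice(0, grid.boundary_index)
                    if pk.branch == CATHODIC
                    else slice(grid.boundary_index, grid.n_points)
                )
                window = np.zeros(grid.n_points)
                window[sl] = (pk.sign * trace)[sl]
                lo = max(target - 8, sl.start)
                hi = min(target + 8, sl.stop)
                local = lo + int(np.argmax(window[lo:hi]))
                assert abs(local - target) <= 2, (cls.name, pk.E_p)

    def test_hg_scan_argmax_near_programmed_index(self, sw11):
        grid = sw11.grid
        hg = sw11.currents[sw11.labels == "Hg"]
        anodic_argmax = grid.boundary_index + np.argmax(hg[:, grid.boundary_index :], axis=1)
        # individual noisy scans: median over the class pins the peak
        assert abs(np.median(anodic_argmax) - 767) <= 2

    def test_blank_cathodic_minimum_near_oxygen(self, sw11):
        sw = sw11.currents[sw11.labels == "SW"]
        argmin = np.argmin(sw[:, :502], axis=1)
        assert abs(np.median(argmin) - 475) <= 5

    def test_concentration_monotonicity(self, seawater_spec):
        lo = expected_trace(seawater_spec, "Hg", concentration=100.0)
        hi = expected_trace(seawater_spec, "Hg", concentration=1500.0)
        i = seawater_spec.grid.index_of(0.06, ANODIC)
        assert hi[i] > lo[i]

    def test_class_separability_noise_free(self, seawater_spec):
        """At zero noise every pair of expected traces is distinct."""
        names = seawater_spec.class_names
        traces = {n: expected_trace(seawater_spec, n, 1000.0) for n in names}
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                d = np.linalg.norm(traces[a] - traces[b])
                assert d > 0.5, (a, b, d)


class TestGenericLibraries:
    def test_3exp_layout(self):
        spec = generic_library_spec(explosives_3class_config())
        assert spec.class_counts() == {"A": 36, "B": 24, "C": 6}

    def test_11exp_layout(self):
        spec = generic_library_spec(explosives_11class_config())
        counts = spec.class_counts()
        assert len(counts) == 11
        assert all(n == 6 for n in counts.values())
        ds = vc.generate_dataset(spec, seed=3)
        assert len(ds) == 66

    def test_empty_class_list_rejected(self):
        with pytest.raises(ValueError):
            generic_library_spec({"scheme": "x", "classes": []})

    def test_peak_outside_grid_rejected(self):
        spec = generic_library_spec(
            {
                "scheme": "x",
                "classes": [
                    {"name": "A", "n_samples": 2, "peaks": [[0.9, "anodic"]]},
                    {"name": "B", "n_samples": 2, "peaks": [[5.0, "anodic"]]},
                ],
            }
        )
        with pytest.raises(ValueError):
            vc.generate_dataset(spec, seed=0)


class TestPeakSpecValidation:
    def test_bad_width(self):
        with pytest.raises(ValueError):
            PeakSpec(E_p=0.0, branch=ANODIC, width_sigma=0.0)

    def test_default_signs(self):
        assert PeakSpec(0.0, ANODIC).sign == 1
        assert PeakSpec(0.0, CATHODIC).sign == -1
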