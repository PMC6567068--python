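"""Shared fixtures: generated datasets (nothing is stored on disk)."""

from __future__ import annotations

import numpy as np
import pytest

import voltclass as vc
from voltclass.grid import CATHODIC
from voltclass.simulate import generic_library_spec


@pytest.fixture(scope="session")
def seawater_spec():
    return vc.seawater_library_spec()


@pytest.fixture(scope="session")
def sw11(seawater_spec):
    """Default-noise 11-class seawater dataset, seed 0."""
    return vc.generate_dataset(seawater_spec, seed=0)


@pytest.fixture(scope="session")
def sw4(seawater_spec):
    """Default-noise 4-class seawater dataset, seed 0 (same scans, merged labels)."""
    return vc.generate_dataset(vc.collapse_to_4sw(seawater_spec), seed=0)


def tiny_library_spec(n_per_class: int = 12, noise_sigma: float = 0.05):
    """Three well-separated classes on a short 80-point grid.

    Small enough that deep models train in seconds; used for smoke and
    behavioural tests that do not need the full seawater geometry.
    """
    grid = dict(n_points=80, boundary_index=40, cathodic_start=0.40,
                anodic_start=-0.40, step=0.02)
    return generic_library_spec(
        {
            "scheme": "custom",
            "grid": grid,
            "noise_sigma": noise_sigma,
            "classes": [
                # concentrations bounded away from the noise floor so the
                # three classes stay unambiguous at this tiny sample size
                {"name": "A", "n_samples": n_per_class, "peaks": [[-0.20, "cathodic"]],
                 "oxygen_background": False, "concentration_range": (300.0, 2000.0)},
                {"name": "B", "n_samples": n_per_class, "peaks": [[0.10, "anodic"]],
                 "oxygen_background": False, "concentration_range": (300.0, 2000.0)},
                {"name": "C", "n_samples": n_per_class,
                 "peaks": [[0.25, "anodic", 0.05, 0.5]], "oxygen_background": False,
                 "concentration_range": (300.0, 2000.0)},
            ],
        }
    )


@pytest.fixture(scope="session")
def tiny_ds():
    return vc.generate_dataset(tiny_library_spec(), seed=7)
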