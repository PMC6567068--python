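"""Labeled voltammogram containers and the on-disk CSV scan format.

A :class:`ScanDataset` is the pipeline's in-memory table: one standardized
current trace per row, a class label per row, and a shared
:class:`~voltclass.grid.PotentialGrid`.  On disk a dataset is a single CSV
with columns ``sample_id, label, concentration_proxy, i_0000 .. i_NNNN``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .grid import PotentialGrid, build_seawater_grid

__all__ = ["Voltammogram", "ScanDataset", "read_scans", "write_scans", "truncate_dataset"]

SCHEMES = ("4-SW", "11-SW", "3-EXP", "11-EXP", "custom")


@dataclass(frozen=True)
class Voltammogram:
    """One concatenated cathodic+anodic current trace with its metadata.

    ``currents`` are dimensionless, approximately z-scored units;
    ``concentration_proxy`` is a ppb-scale analyte level (NaN when the class
    has no analyte, e.g. blank seawater).
    """

    currents: np.ndarray
    label: str
    sample_id: str
    grid: PotentialGrid
    concentration_proxy: float = float("nan")

    def __post_init__(self) -> None:
        arr = np.asarray(self.currents, dtype=float)
        object.__setattr__(self, "currents", arr)
        if arr.ndim != 1 or arr.size != self.grid.n_points:
            raise ValueError(
                f"trace length {arr.size} does not match grid ({self.grid.n_points})"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"non-finite current in scan {self.sample_id!r}")


class ScanDataset:
    """Table of voltammograms sharing one grid and one label scheme."""

    def __init__(
        self,
        currents: np.ndarray,
        labels: Sequence[str],
        scheme: str,
        class_names: Sequence[str],
        grid: PotentialGrid | None = None,
        sample_ids: Sequence[str] | None = None,
        concentrations: Sequence[float] | None = None,
    ) -> None:
        self.currents = np.atleast_2d(np.asarray(currents, dtype=float))
        if self.currents.size == 0:
            self.currents = self.currents.reshape(0, grid.n_points if grid else 0)
        n = self.currents.shape[0]
        self.labels = np.asarray(labels, dtype=object)
        if self.labels.shape != (n,):
            raise ValueError("labels length does not match number of traces")
        self.scheme = scheme
        self.class_names = list(class_names)
        if len(set(self.class_names)) != len(self.class_names):
            raise ValueError("duplicate class names")
        unknown = set(self.labels) - set(self.class_names)
        if unknown:
            raise ValueError(f"labels outside class_names: {sorted(unknown)}")
        self.grid = grid if grid is not None else build_seawater_grid()
        if n and self.currents.shape[1] != self.grid.n_points:
            raise ValueError(
                f"trace length {self.currents.shape[1]} does not match grid "
                f"({self.grid.n_points})"
            )
        if not np.all(np.isfinite(self.currents)):
            raise ValueError("non-finite currents")
        self.sample_ids = (
            list(sample_ids)
            if sample_ids is not None
            else [f"scan{i:04d}" for i in range(n)]
        )
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")
        self.concentrations = np.asarray(
            concentrations if concentrations is not None else [np.nan] * n, dtype=float
        )
        if self.concentrations.shape != (n,):
            raise ValueError("concentrations length mismatch")

    # -- container protocol ------------------------------------------------
    def __len__(self) -> int:
        return self.currents.shape[0]

    @property
    def n_points(self) -> int:
        return self.grid.n_points

    def __getitem__(self, i: int) -> Voltammogram:
        return Voltammogram(
            currents=self.currents[i],
            label=str(self.labels[i]),
            sample_id=self.sample_ids[i],
            grid=self.grid,
            concentration_proxy=float(self.concentrations[i]),
        )

    def __iter__(self) -> Iterator[Voltammogram]:
        return (self[i] for i in range(len(self)))

    # -- helpers -----------------------------------------------------------
    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in self.class_names}

    def y_indices(self) -> np.ndarray:
        """Integer class index per scan, following ``class_names`` order."""
        lut = {c: k for k, c in enumerate(self.class_names)}
        return np.array([lut[l] for l in self.labels], dtype=int)

    def subset(self, indices: Sequence[int]) -> "ScanDataset":
        idx = np.asarray(indices, dtype=int)
        return ScanDataset(
            currents=self.currents[idx],
            labels=self.labels[idx],
            scheme=self.scheme,
            class_names=self.class_names,
            grid=self.grid,
            sample_ids=[self.sample_ids[i] for i in idx],
            concentrations=self.concentrations[idx],
        )

    def equals(self, other: "ScanDataset", rtol: float = 1e-9) -> bool:
        return (
            self.scheme == other.scheme
            and self.class_names == other.class_names
            and self.sample_ids == other.sample_ids
            and list(self.labels) == list(other.labels)
            and self.grid == other.grid
            and np.allclose(self.currents, other.currents, rtol=rtol, atol=1e-12)
            and np.allclose(
                self.concentrations, other.concentrations, rtol=rtol, equal_nan=True
            )
        )


def truncate_dataset(ds: ScanDataset, drop_head: int, drop_tail: int) -> ScanDataset:
    """Drop leading/trailing samples from every trace (grid sliced to match).

    Dropping the first 502 and last 100 points of the default 1002-point
    seawater trace keeps exactly the anodic indices 502..901 and yields
    400-point traces — the stripping-peak window.
    """
    if drop_head == 0 and drop_tail == 0:
        return ds
    if drop_head < 0 or drop_tail < 0:
        raise ValueError("drop counts must be nonnegative")
    if drop_head + drop_tail >= ds.n_points:
        raise ValueError("truncation exceeds trace length")
    new_grid = ds.grid.sliced(drop_head, drop_tail)  # enforces >= 2 points
    stop = ds.n_points - drop_tail
    return ScanDataset(
        currents=ds.currents[:, drop_head:stop],
        labels=ds.labels,
        scheme=ds.scheme,
        class_names=ds.class_names,
        grid=new_grid,
        sample_ids=ds.sample_ids,
        concentrations=ds.concentrations,
    )


# -- CSV I/O ---------------------------------------------------------------

def write_scans(ds: ScanDataset, path: str | Path) -> None:
    """Write a dataset to the scan CSV format (one row per scan)."""
    path = Path(path)
    width = len(str(max(ds.n_points - 1, 0)))
    cols = [f"i_{i:0{max(width, 4)}d}" for i in range(ds.n_points)]
    df = pd.DataFrame(ds.currents, columns=cols)
    df.insert(0, "sample_id", ds.sample_ids)
    df.insert(1, "label", ds.labels)
    df.insert(2, "concentration_proxy", ds.concentrations)
    with open(path, "w") as fh:
        fh.write(f"# scheme={ds.scheme} classes={','.join(ds.class_names)}\n")
        fh.write(
            f"# grid n_points={ds.grid.n_points} boundary={ds.grid.boundary_index} "
            f"cathodic_start={ds.grid.cathodic_start:.6f} "
            f"anodic_start={ds.grid.anodic_start:.6f} step={ds.grid.step:.6f}\n"
        )
        df.to_csv(fh, index=False, float_format="%.9g")


def _parse_header(lines: list[str]) -> tuple[str, list[str], PotentialGrid]:
    scheme, classes, grid = "custom", [], None
    for ln in lines:
        body = ln.lstrip("# ").strip()
        if body.startswith("scheme="):
            parts = dict(p.split("=", 1) for p in body.split(" ") if "=" in p)
            scheme = parts.get("scheme", "custom")
            classes = [c for c in parts.get("classes", "").split(",") if c]
        elif body.startswith("grid "):
            parts = dict(p.split("=", 1) for p in body.split(" ")[1:] if "=" in p)
            grid = PotentialGrid(
                n_points=int(parts["n_points"]),
                boundary_index=int(parts["boundary"]),
                cathodic_start=float(parts["cathodic_start"]),
                anodic_start=float(parts["anodic_start"]),
                step=float(parts["step"]),
            )
    if grid is None:
        grid = build_seawater_grid()
    return scheme, classes, grid


def read_scans(path: str | Path) -> ScanDataset:
    """Read a scan CSV written by :func:`write_scans`."""
    path = Path(path)
    header_lines: list[str] = []
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            header_lines.append(line)
            pos = fh.tell()
            line = fh.readline()
    scheme, classes, grid = _parse_header(header_lines)
    if scheme not in SCHEMES and not classes:
        raise ValueError(f"unknown label scheme {scheme!r} with no class list")
    df = pd.read_csv(path, comment="#")
    if df.empty and df.columns.size <= 1:
        return ScanDataset(
            currents=np.empty((0, grid.n_points)),
            labels=[],
            scheme=scheme,
            class_names=classes,
            grid=grid,
        )
    current_cols = [c for c in df.columns if c.startswith("i_")]
    if len(current_cols) != grid.n_points:
        raise ValueError(
            f"{len(current_cols)} current columns but grid declares {grid.n_points}"
        )
    currents = df[current_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(currents)):
        raise ValueError("non-numeric or missing current values")
    labels = df["label"].astype(str).tolist()
    if not classes:
        classes = sorted(set(labels))
    return ScanDataset(
        currents=currents,
        labels=labels,
        scheme=scheme,
        class_names=classes,
        grid=grid,
        sample_ids=df["sample_id"].astype(str).tolist(),
        concentrations=df["concentration_proxy"].to_numpy(dtype=float),
    )
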