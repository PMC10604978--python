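"""Spherical ROIs, voxel-mean BOLD series and the ACTIVE feature.

A region of interest is a named sphere in scanner millimetre space. Voxel
membership is decided by the voxel *centre*: a voxel belongs to the mask iff
the Euclidean distance from its affine-mapped centre to the ROI centre is at
most the radius (closed ball). Per-volume node signals are the arithmetic
mean of the masked voxels, and the activation feature is

    ACTIVE_r(t) = mean BOLD in ROI r at volume t - rest baseline of ROI r,

updated once per volume. Two screening rules are provided: dropping the
first volumes of a run (magnetisation not yet at steady state) and trimming
the first volumes of every constant-condition block (hemodynamic
transition).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RoiSpec",
    "VolumeGrid",
    "RoiSeriesMatrix",
    "ActivationFeature",
    "build_sphere_mask",
    "extract_mean_series",
    "compute_active",
    "rest_baseline_from_series",
    "discard_initial",
    "trim_transitions",
]


@dataclass(frozen=True)
class RoiSpec:
    """A named sphere in scanner mm coordinates.

    Coordinates are taken at face value in the image's affine frame; keeping
    them consistent with the volume's space (MNI, Talairach, native) is the
    caller's responsibility.
    """

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError(f"ROI {self.name!r}: radius_mm must be positive")
        if len(self.center_mm) != 3:
            raise ValueError(f"ROI {self.name!r}: center_mm must be (x, y, z)")


@dataclass(frozen=True)
class VolumeGrid:
    """A voxel lattice with its voxel-index -> mm affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 transform")
        object.__setattr__(self, "affine", affine)

    @classmethod
    def centered(cls, shape: Sequence[int], voxel_size_mm: float) -> "VolumeGrid":
        """RAS+ grid with isotropic voxels and mm origin at the grid centre."""
        shape = tuple(int(s) for s in shape)
        affine = np.diag([voxel_size_mm] * 3 + [1.0])
        affine[:3, 3] = -(np.array(shape) - 1) / 2.0 * voxel_size_mm
        return cls(shape=shape, affine=affine)

    def voxel_centers_mm(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of voxel-centre mm coordinates."""
        idx = np.indices(self.shape, dtype=float)
        ijk = np.stack([idx[0], idx[1], idx[2], np.ones(self.shape)], axis=-1)
        return ijk @ self.affine.T[:, :3]


def build_sphere_mask(roi: RoiSpec, grid: VolumeGrid) -> np.ndarray:
    """Boolean voxel mask of a spherical ROI (closed ball on voxel centres).

    Raises ``ValueError`` (naming the ROI) if no voxel centre falls inside
    the sphere.
    """
    centers = grid.voxel_centers_mm()
    d2 = np.sum((centers - np.asarray(roi.center_mm, dtype=float)) ** 2, axis=-1)
    mask = d2 <= roi.radius_mm**2 + 1e-9
    if not mask.any():
        raise ValueError(
            f"ROI {roi.name!r} at {roi.center_mm} (r={roi.radius_mm} mm) "
            "does not intersect the volume grid"
        )
    return mask


@dataclass
class RoiSeriesMatrix:
    """Per-volume mean BOLD values for a set of ROIs plus condition labels."""

    values: pd.DataFrame  # volumes x ROIs
    tr_seconds: float
    condition_labels: np.ndarray

    def __post_init__(self) -> None:
        self.condition_labels = np.asarray(self.condition_labels, dtype=str)
        if len(self.condition_labels) != len(self.values):
            raise ValueError(
                f"{len(self.condition_labels)} labels for {len(self.values)} volumes"
            )
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("ROI series contains non-finite values")

    @property
    def roi_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_volumes(self) -> int:
        return len(self.values)

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out["condition"] = self.condition_labels
        out.to_csv(path, index_label="volume")

    @classmethod
    def from_csv(cls, path: str | Path, tr_seconds: float) -> "RoiSeriesMatrix":
        df = pd.read_csv(path, index_col="volume")
        labels = df.pop("condition").to_numpy()
        return cls(values=df, tr_seconds=tr_seconds, condition_labels=labels)


@dataclass(frozen=True)
class ActivationFeature:
    """Per-volume, per-ROI ACTIVE values (BOLD units)."""

    values: pd.DataFrame  # volumes x ROIs
    baseline: pd.Series = field(default=None)  # type: ignore[assignment]


def extract_mean_series(
    volumes: np.ndarray,
    masks: Mapping[str, np.ndarray],
    tr_seconds: float = 2.0,
    condition_labels: Sequence[str] | None = None,
) -> RoiSeriesMatrix:
    """Average each volume over each ROI mask.

    Parameters
    ----------
    volumes
        4D array, last axis time, or an iterable of 3D volumes.
    masks
        Mapping ROI name -> boolean mask with the volumes' spatial shape.
    """
    volumes = np.asarray(volumes, dtype=float)
    if volumes.ndim != 4:
        raise ValueError(f"expected 4D (x, y, z, t) data, got shape {volumes.shape}")
    spatial = volumes.shape[:3]
    n_t = volumes.shape[3]
    if n_t < 1:
        raise ValueError("need at least one volume")
    cols = {}
    for name, mask in masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != spatial:
            raise ValueError(
                f"mask {name!r} shape {mask.shape} != volume shape {spatial}"
            )
        # per-volume reduction over the contiguous masked voxels; matches the
        # streaming path bit for bit
        cols[name] = np.array([volumes[..., t][mask].mean() for t in range(n_t)])
    labels = (
        np.asarray(condition_labels, dtype=str)
        if condition_labels is not None
        else np.full(n_t, "unknown")
    )
    return RoiSeriesMatrix(
        values=pd.DataFrame(cols), tr_seconds=tr_seconds, condition_labels=labels
    )


def rest_baseline_from_series(
    series: RoiSeriesMatrix,
    n_transition: int = 4,
    rest_label: str = "rest",
    up_to_volume: int | None = None,
) -> pd.Series:
    """Per-ROI mean over transition-trimmed rest volumes.

    ``up_to_volume`` restricts the baseline to volumes seen so far (used to
    freeze the baseline after the first rest block in streaming mode).
    """
    labels = series.condition_labels
    stable = trim_transitions(labels, n_transition)
    stable = stable[labels[stable] == rest_label]
    if up_to_volume is not None:
        stable = stable[stable < up_to_volume]
    if stable.size == 0:
        raise ValueError("no stable rest volumes available for the baseline")
    return series.values.iloc[stable].mean(axis=0)


def compute_active(
    series: RoiSeriesMatrix, rest_baseline: Mapping[str, float] | pd.Series
) -> ActivationFeature:
    """ACTIVE_r(t) = mean BOLD of ROI r at volume t minus its rest baseline."""
    baseline = pd.Series(dict(rest_baseline), dtype=float)
    missing = [r for r in series.roi_names if r not in baseline.index]
    if missing:
        raise ValueError(f"rest baseline missing for ROIs: {missing}")
    if not np.isfinite(baseline.to_numpy()).all():
        raise ValueError("rest baseline contains non-finite values")
    active = series.values - baseline[series.roi_names]
    return ActivationFeature(values=active, baseline=baseline[series.roi_names])


def discard_initial(series: RoiSeriesMatrix, n_discard: int) -> RoiSeriesMatrix:
    """Drop the first ``n_discard`` volumes (pre-steady-state magnetisation)."""
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if n_discard >= series.n_volumes:
        raise ValueError(
            f"cannot discard {n_discard} of {series.n_volumes} volumes"
        )
    return dataclasses.replace(
        series,
        values=series.values.iloc[n_discard:].reset_index(drop=True),
        condition_labels=series.condition_labels[n_discard:],
    )


def trim_transitions(
    condition_labels: Sequence[str], n_transition: int
) -> np.ndarray:
    """Indices of hemodynamically stable volumes.

    For every maximal run of a constant condition label the first
    ``n_transition`` volumes are excluded; runs no longer than the trim
    simply contribute nothing.
    """
    if n_transition < 0:
        raise ValueError("n_transition must be >= 0")
    labels = np.asarray(condition_labels, dtype=str)
    keep: list[int] = []
    run_start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[run_start]:
            keep.extend(range(run_start + n_transition, i))
            run_start = i
    return np.asarray(keep, dtype=int)
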