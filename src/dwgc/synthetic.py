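"""Synthetic block-design BOLD runs with known directed-coupling ground truth.

The generator produces data in three stages:

1. **Latent neural signals** -- a first-order vector autoregression whose
   cross-coupling matrix switches with the experimental condition:

       x_i(t) = a_i x_i(t-1) + sum_j C[cond(t)]_{i<-j} x_j(t-1)
                + m_i(cond(t)) + eps_i(t),   eps ~ N(0, noise_sd^2)

   Condition-dependent coupling (``coupling_schedule``) and condition-
   dependent mean drive (``amplitude_schedule``) are independent knobs, so a
   run can modulate directed connectivity without touching signal amplitude
   and vice versa.
2. **Hemodynamics** -- each node's latent series is convolved with a causal,
   truncated, unit-sum double-gamma hemodynamic response function (HRF)
   peaking a few seconds after stimulation.
3. **Observation** -- the HRF-convolved node signals are painted into
   spherical ROIs of a voxel grid with i.i.d. Gaussian observation noise and
   can be written as NIfTI-1 volumes.

Every stage is fully determined by the configuration seed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats

from dwgc.paradigm import Paradigm, REST
from dwgc.roi import (
    RoiSeriesMatrix,
    RoiSpec,
    VolumeGrid,
    build_sphere_mask,
)

__all__ = [
    "matched_noise_schedule",
    "HrfParams",
    "SimulationConfig",
    "GroundTruth",
    "double_gamma_kernel",
    "simulate_latent_signals",
    "apply_hrf",
    "simulate_roi_series",
    "render_volumes",
    "write_nifti",
]


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma HRF parameters (seconds).

    Defaults follow the canonical shape: response gamma peaking at
    ``peak_delay_s - dispersion_s`` = 5 s (inside the physiological 2-6 s
    window), a late undershoot, kernel truncated at ``duration_s`` and
    normalised to unit sum so convolution preserves a constant input.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration_s: float = 30.0


def double_gamma_kernel(tr_seconds: float, params: HrfParams = HrfParams()) -> np.ndarray:
    """Sampled, causal, unit-sum double-gamma HRF kernel.

    Warns if the kernel's peak falls outside [0 s, 30 s].
    """
    if tr_seconds <= 0:
        raise ValueError("tr_seconds must be positive")
    t = np.arange(0.0, params.duration_s + tr_seconds / 2, tr_seconds)
    peak = stats.gamma.pdf(
        t, a=params.peak_delay_s / params.dispersion_s, scale=params.dispersion_s
    )
    undershoot = stats.gamma.pdf(
        t,
        a=params.undershoot_delay_s / params.undershoot_dispersion_s,
        scale=params.undershoot_dispersion_s,
    )
    kernel = peak - params.undershoot_ratio * undershoot
    peak_time = t[int(np.argmax(kernel))]
    if not 0.0 <= peak_time <= 30.0:
        warnings.warn(
            f"HRF kernel peaks at {peak_time:.1f} s, outside [0, 30] s",
            stacklevel=2,
        )
    total = kernel.sum()
    if abs(total) < 1e-12:
        raise ValueError("degenerate HRF kernel (zero sum)")
    return kernel / total


@dataclass
class SimulationConfig:
    """Configuration of the condition-switched latent VAR(1) generator.

    ``coupling_schedule[cond][i, j]`` is the weight with which node ``j``'s
    previous value enters node ``i``'s update while ``cond`` is active
    (``j -> i``). Conditions absent from a schedule fall back to the rest
    entry of that schedule (or zeros). ``amplitude_schedule`` adds a
    condition-dependent mean drive; ``noise_sd_schedule`` sets per-condition,
    per-node innovation standard deviations (see
    :func:`matched_noise_schedule` for keeping marginal variances flat while
    coupling switches -- coupling feeds source variance into the target, so
    without compensation a "coupling-only" manipulation also raises the
    target's variance).
    """

    n_nodes: int
    base_ar_coeffs: np.ndarray
    coupling_schedule: dict[str, np.ndarray] = field(default_factory=dict)
    amplitude_schedule: dict[str, np.ndarray] = field(default_factory=dict)
    noise_sd: float = 1.0
    noise_sd_schedule: dict[str, np.ndarray] = field(default_factory=dict)
    hrf_params: HrfParams = field(default_factory=HrfParams)
    observation_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        self.base_ar_coeffs = np.asarray(self.base_ar_coeffs, dtype=float)
        if self.base_ar_coeffs.shape != (self.n_nodes,):
            raise ValueError("base_ar_coeffs must have one entry per node")
        if np.any(np.abs(self.base_ar_coeffs) >= 1):
            raise ValueError("per-node AR coefficients must satisfy |a| < 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.observation_noise_sd < 0:
            raise ValueError("observation_noise_sd must be >= 0")
        for cond, mat in list(self.coupling_schedule.items()):
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (self.n_nodes, self.n_nodes):
                raise ValueError(f"coupling matrix for {cond!r} has wrong shape")
            self.coupling_schedule[cond] = mat
        for cond, amp in list(self.amplitude_schedule.items()):
            amp = np.asarray(amp, dtype=float)
            if amp.shape != (self.n_nodes,):
                raise ValueError(f"amplitude vector for {cond!r} has wrong shape")
            self.amplitude_schedule[cond] = amp
        for cond, sd in list(self.noise_sd_schedule.items()):
            sd = np.asarray(sd, dtype=float)
            if sd.shape != (self.n_nodes,) or np.any(sd <= 0):
                raise ValueError(f"noise sd vector for {cond!r} must be positive per node")
            self.noise_sd_schedule[cond] = sd

    def transition_matrix(self, condition: str) -> np.ndarray:
        """diag(a) + C[condition]; the VAR(1) companion matrix."""
        coupling = self.coupling_schedule.get(
            condition,
            self.coupling_schedule.get(REST, np.zeros((self.n_nodes, self.n_nodes))),
        )
        return np.diag(self.base_ar_coeffs) + coupling

    def amplitude(self, condition: str) -> np.ndarray:
        return self.amplitude_schedule.get(condition, np.zeros(self.n_nodes))


@dataclass
class GroundTruth:
    """Per-volume labels and the true directed adjacency per condition."""

    condition_labels: np.ndarray
    adjacency: dict[str, np.ndarray]  # condition -> boolean (target, source)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "condition_labels": list(map(str, self.condition_labels)),
            "adjacency": {
                cond: np.asarray(mat, dtype=bool).tolist()
                for cond, mat in self.adjacency.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            condition_labels=np.asarray(payload["condition_labels"], dtype=str),
            adjacency={
                cond: np.asarray(mat, dtype=bool)
                for cond, mat in payload["adjacency"].items()
            },
        )


def matched_noise_schedule(
    config: SimulationConfig, conditions: Sequence[str], tol: float = 1e-10
) -> dict[str, np.ndarray]:
    """Per-condition innovation SDs that hold every node's variance flat.

    Directed coupling feeds the source's variance into the target, so a
    coupling switch alone also modulates the target's marginal variance --
    an amplitude-like cue. This solves, per condition, for diagonal
    innovation variances whose stationary (Lyapunov) solution reproduces the
    rest-state variances, isolating the cross-lag structure as the only
    condition-dependent signal.
    """
    from scipy.linalg import solve_discrete_lyapunov

    n = config.n_nodes
    A_rest = config.transition_matrix(REST)
    target = np.diag(
        solve_discrete_lyapunov(A_rest, np.eye(n) * config.noise_sd**2)
    )
    out: dict[str, np.ndarray] = {}
    for cond in conditions:
        A = config.transition_matrix(cond)
        q = np.full(n, config.noise_sd**2)
        for _ in range(200):
            sigma = np.diag(solve_discrete_lyapunov(A, np.diag(q)))
            err = target - sigma
            if np.max(np.abs(err)) < tol:
                break
            q = np.maximum(q + err, 1e-6)
        out[cond] = np.sqrt(q)
    return out


def _check_stability(config: SimulationConfig, conditions: Sequence[str]) -> None:
    for cond in conditions:
        mat = config.transition_matrix(cond)
        radius = float(np.max(np.abs(np.linalg.eigvals(mat))))
        if radius >= 1.0:
            raise ValueError(
                f"coupled system for condition {cond!r} is unstable "
                f"(spectral radius {radius:.3f} >= 1)"
            )


def simulate_latent_signals(
    config: SimulationConfig, paradigm: Paradigm
) -> tuple[np.ndarray, GroundTruth]:
    """Simulate the condition-switched latent VAR(1).

    Returns a (n_nodes, n_volumes) matrix and the matching ground truth.
    Raises before simulating if any per-condition system is unstable.
    """
    labels = paradigm.condition_labels()
    conditions = sorted(set(labels))
    _check_stability(config, conditions)

    rng = np.random.default_rng(config.seed)
    n, T = config.n_nodes, len(labels)
    mats = {cond: config.transition_matrix(cond) for cond in conditions}
    amps = {cond: config.amplitude(cond) for cond in conditions}
    default_sd = np.full(n, config.noise_sd)
    sds = {cond: config.noise_sd_schedule.get(cond, default_sd) for cond in conditions}
    eps = rng.normal(0.0, 1.0, size=(n, T))
    x = np.zeros((n, T))
    x[:, 0] = amps[labels[0]] + sds[labels[0]] * eps[:, 0]
    for t in range(1, T):
        cond = labels[t]
        x[:, t] = mats[cond] @ x[:, t - 1] + amps[cond] + sds[cond] * eps[:, t]

    adjacency = {
        cond: (mats[cond] - np.diag(np.diag(mats[cond]))) != 0 for cond in conditions
    }
    truth = GroundTruth(condition_labels=labels, adjacency=adjacency)
    return x, truth


def apply_hrf(
    latent_matrix: np.ndarray,
    tr_seconds: float,
    hrf_params: HrfParams = HrfParams(),
) -> np.ndarray:
    """Convolve each node's latent series with the causal truncated HRF.

    Output has the same shape as the input (the convolution tail is cut).
    """
    latent = np.asarray(latent_matrix, dtype=float)
    if not np.isfinite(latent).all():
        raise ValueError("latent matrix contains non-finite values")
    kernel = double_gamma_kernel(tr_seconds, hrf_params)
    T = latent.shape[-1]
    out = np.empty_like(latent)
    for i in range(latent.shape[0]):
        out[i] = np.convolve(latent[i], kernel)[:T]
    return out


def simulate_roi_series(
    config: SimulationConfig,
    paradigm: Paradigm,
    roi_names: Sequence[str] | None = None,
) -> tuple[RoiSeriesMatrix, GroundTruth]:
    """Latent VAR -> HRF convolution, packaged as a labelled ROI series."""
    latent, truth = simulate_latent_signals(config, paradigm)
    bold = apply_hrf(latent, paradigm.tr_seconds, config.hrf_params)
    names = (
        list(roi_names)
        if roi_names is not None
        else [f"node{i}" for i in range(config.n_nodes)]
    )
    if len(names) != config.n_nodes:
        raise ValueError("need one ROI name per node")
    series = RoiSeriesMatrix(
        values=pd.DataFrame(bold.T, columns=names),
        tr_seconds=paradigm.tr_seconds,
        condition_labels=truth.condition_labels,
    )
    return series, truth


def render_volumes(
    roi_series: np.ndarray,
    roi_specs: Sequence[RoiSpec],
    grid_shape: Sequence[int] = (32, 32, 32),
    voxel_size_mm: float = 2.0,
    observation_noise_sd: float = 0.0,
    seed: int = 0,
    baseline: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Paint ROI signals into a voxel grid, one 3D volume per time point.

    Voxels inside ROI ``r`` carry ``baseline + roi_series[t, r]`` plus
    i.i.d. N(0, observation_noise_sd^2) noise; background voxels carry the
    baseline plus noise. Returns ``(data_4d, affine)`` with a diagonal RAS+
    affine centring the grid at mm origin.

    Raises if any ROI sphere pokes outside the grid or if two spheres
    overlap (the voxel-to-node assignment would be ambiguous).
    """
    roi_series = np.atleast_2d(np.asarray(roi_series, dtype=float))
    if roi_series.shape[1] != len(roi_specs):
        raise ValueError(
            f"{roi_series.shape[1]} series columns for {len(roi_specs)} ROIs"
        )
    grid = VolumeGrid.centered(grid_shape, voxel_size_mm)
    half_extent = (np.array(grid.shape) - 1) / 2.0 * voxel_size_mm

    masks = []
    for spec in roi_specs:
        lo = np.asarray(spec.center_mm) - spec.radius_mm
        hi = np.asarray(spec.center_mm) + spec.radius_mm
        if np.any(lo < -half_extent) or np.any(hi > half_extent):
            raise ValueError(
                f"ROI {spec.name!r} (r={spec.radius_mm} mm at {spec.center_mm}) "
                "does not fit inside the volume grid"
            )
        masks.append(build_sphere_mask(spec, grid))
    stacked = np.sum(masks, axis=0)
    if np.any(stacked > 1):
        raise ValueError("ROI spheres overlap; ground truth would be ambiguous")

    rng = np.random.default_rng(seed)
    T = roi_series.shape[0]
    data = np.full((*grid.shape, T), baseline, dtype=float)
    if observation_noise_sd > 0:
        data += rng.normal(0.0, observation_noise_sd, size=data.shape)
    for r, mask in enumerate(masks):
        data[mask, :] += roi_series[:, r]
    return data, grid.affine


def write_nifti(path: str | Path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), str(path))
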