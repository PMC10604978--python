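"""Volume-by-volume replay of the real-time decoding loop.

The replay harness emulates a scanner feed by iterating the volumes of a
stored run in acquisition order. Per arriving volume it extracts the ROI
means, updates the ACTIVE feature against a frozen rest baseline, computes
the newest complete DWGC window for every ordered node pair, assembles the
feature vector and asks the pre-trained classifier for a decision --
logging the elapsed seconds of every stage. Decisions at volume ``n``
depend only on volumes ``<= n``, and the emitted label sequence is
bit-identical to running the batch pipeline over the full run.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from dwgc.classify import TrainedDecoder, assemble_features
from dwgc.model import ArModelSpec, dwgc_sequence, window_gc, window_starts
from dwgc.paradigm import REST, Paradigm
from dwgc.roi import (
    ActivationFeature,
    RoiSeriesMatrix,
    RoiSpec,
    VolumeGrid,
    build_sphere_mask,
    compute_active,
    discard_initial,
    extract_mean_series,
    trim_transitions,
)

__all__ = [
    "PipelineConfig",
    "StreamState",
    "StreamDecision",
    "stream_replay",
    "batch_replay",
    "frozen_rest_baseline",
]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything the per-TR loop needs besides the volumes themselves."""

    rois: list[RoiSpec]
    tr_seconds: float = 2.0
    n_discard: int = 10
    n_transition: int = 4
    spec: ArModelSpec = field(default_factory=ArModelSpec)
    k: int = 4
    epsilon: float = 1e-12
    omega: "dict[tuple[str, str], float] | float" = 0.0
    mode: str = "dwgc"
    rest_label: str = REST
    rest_baseline: pd.Series | None = None
    paradigm: Paradigm | None = None
    affine: np.ndarray | None = None
    alpha: float = 0.05
    n_surrogates: int = 500
    classifier_family: str = "svm_rbf"
    classifier_params: dict = field(default_factory=lambda: {"C": 19.0, "gamma": "scale"})
    seed: int = 0

    @property
    def roi_names(self) -> list[str]:
        return [r.name for r in self.rois]

    # ------------------------------------------------------------- YAML I/O
    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "version": 1,
            "tr_seconds": self.tr_seconds,
            "n_discard": self.n_discard,
            "n_transition": self.n_transition,
            "k": self.k,
            "alpha": self.alpha,
            "n_surrogates": self.n_surrogates,
            "mode": self.mode,
            "seed": self.seed,
            "rois": [
                {
                    "name": r.name,
                    "x": float(r.center_mm[0]),
                    "y": float(r.center_mm[1]),
                    "z": float(r.center_mm[2]),
                    "radius": float(r.radius_mm),
                }
                for r in self.rois
            ],
            "model": {
                "order_p": self.spec.order_p,
                "basis": self.spec.basis,
                "degree": self.spec.degree,
                "train_span": self.spec.train_span,
            },
            "classifier": {
                "family": self.classifier_family,
                "params": dict(self.classifier_params),
            },
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if payload.get("version", 1) != 1:
            raise ValueError(f"unsupported config version {payload.get('version')}")
        rois = [
            RoiSpec(r["name"], (r["x"], r["y"], r["z"]), r["radius"])
            for r in payload["rois"]
        ]
        model = payload.get("model", {})
        clf = payload.get("classifier", {})
        return cls(
            rois=rois,
            tr_seconds=float(payload.get("tr_seconds", 2.0)),
            n_discard=int(payload.get("n_discard", 10)),
            n_transition=int(payload.get("n_transition", 4)),
            spec=ArModelSpec(
                order_p=int(model.get("order_p", 1)),
                basis=model.get("basis", "linear"),
                degree=int(model.get("degree", 2)),
                train_span=int(model.get("train_span", 40)),
            ),
            k=int(payload.get("k", 4)),
            mode=payload.get("mode", "dwgc"),
            alpha=float(payload.get("alpha", 0.05)),
            n_surrogates=int(payload.get("n_surrogates", 500)),
            classifier_family=clf.get("family", "svm_rbf"),
            classifier_params=dict(clf.get("params", {"C": 19.0, "gamma": "scale"})),
            seed=int(payload.get("seed", 0)),
        )


@dataclass
class StreamDecision:
    """One per-volume classification decision with stage timings."""

    volume_index: int
    window_start: int
    predicted_label: str
    features: dict[str, float]
    extract_s: float
    dwgc_s: float
    classify_s: float

    @property
    def total_s(self) -> float:
        return self.extract_s + self.dwgc_s + self.classify_s


@dataclass
class StreamState:
    """Mutable state of the per-TR loop (pure function of volumes seen)."""

    buffer: list[np.ndarray] = field(default_factory=list)  # post-discard ROI rows
    rest_baseline: pd.Series | None = None
    volumes_processed: int = 0
    decisions: list[StreamDecision] = field(default_factory=list)


def frozen_rest_baseline(
    series: RoiSeriesMatrix, n_transition: int = 4, rest_label: str = REST
) -> pd.Series:
    """Per-ROI mean over the stable volumes of the *first* rest block.

    Mirrors the pre-task baseline of an online session: after the first
    completed rest block the baseline is frozen and never updated.
    """
    labels = series.condition_labels
    first_run_end = 0
    while first_run_end < len(labels) and labels[first_run_end] == labels[0]:
        first_run_end += 1
    if labels[0] != rest_label:
        raise ValueError("run does not start with a rest block")
    stable = trim_transitions(labels[:first_run_end], n_transition)
    if stable.size == 0:
        raise ValueError("first rest block too short to form a baseline")
    return series.values.iloc[stable].mean(axis=0)


def _iter_volumes(
    volume_source, config: PipelineConfig
) -> tuple[Iterator[np.ndarray], np.ndarray | None]:
    """Normalise the volume source to (iterator over 3D volumes, affine)."""
    if isinstance(volume_source, (str, Path)):
        img = nib.load(str(volume_source))
        data = np.asarray(img.get_fdata(), dtype=float)
        return iter(np.moveaxis(data, -1, 0)), np.asarray(img.affine)
    if isinstance(volume_source, tuple) and len(volume_source) == 2:
        data, affine = volume_source
        return iter(np.moveaxis(np.asarray(data, dtype=float), -1, 0)), np.asarray(affine)
    if isinstance(volume_source, np.ndarray) and volume_source.ndim == 4:
        if config.affine is None:
            raise ValueError("4D array source needs config.affine")
        return iter(np.moveaxis(volume_source.astype(float), -1, 0)), config.affine
    return iter(volume_source), config.affine


def _expected_feature_names(config: PipelineConfig) -> list[str]:
    names = []
    rois = config.roi_names
    if config.mode in ("dwgc", "both"):
        names += [f"F[{s}->{t}]" for t in rois for s in rois if s != t]
    if config.mode in ("activation", "both"):
        names += [f"ACTIVE[{r}]" for r in rois]
    return names


def _omega_for(config: PipelineConfig, source: str, target: str) -> float:
    if isinstance(config.omega, dict):
        return float(config.omega[(source, target)])
    return float(config.omega)


def stream_replay(
    volume_source,
    rois: list[RoiSpec] | None,
    config: PipelineConfig,
    decoder: TrainedDecoder,
    max_volumes: int | None = None,
) -> list[StreamDecision]:
    """Replay a run through the per-TR loop with a pre-trained decoder.

    ``volume_source`` may be a NIfTI path, a ``(4D array, affine)`` pair, a
    4D array (with ``config.affine`` set) or any iterable of 3D volumes.
    Decisions start once the warmup (initial discard plus training span
    plus lags plus one full window) has passed; one decision is emitted per
    subsequent volume. A source failing mid-run yields a partial decision
    log with a warning rather than an exception.
    """
    rois = rois if rois is not None else config.rois
    expected = _expected_feature_names(config)
    if expected != decoder.feature_names:
        raise ValueError(
            "feature layout mismatch between config and trained decoder: "
            f"{expected} vs {decoder.feature_names}"
        )

    iterator, affine = _iter_volumes(volume_source, config)
    masks = None
    roi_names = [r.name for r in rois]
    spec, k, p = config.spec, config.k, config.spec.order_p
    first_start = spec.train_span + p
    state = StreamState()
    if config.rest_baseline is not None:
        state.rest_baseline = config.rest_baseline

    baseline_labels: np.ndarray | None = None
    if config.paradigm is not None:
        baseline_labels = config.paradigm.condition_labels()[config.n_discard :]

    n = -1
    while True:
        if max_volumes is not None and state.volumes_processed >= max_volumes:
            break
        try:
            volume = next(iterator)
        except StopIteration:
            break
        except Exception as exc:  # truncated/corrupt source: keep partial log
            warnings.warn(f"volume source failed after {n + 1} volumes: {exc}")
            break
        n += 1
        t0 = time.perf_counter()
        volume = np.asarray(volume, dtype=float)
        if masks is None:
            if affine is None:
                raise ValueError("no affine available to place ROI masks")
            grid = VolumeGrid(shape=volume.shape, affine=np.asarray(affine))
            masks = {r.name: build_sphere_mask(r, grid) for r in rois}
        row = np.asarray([volume[masks[name]].mean() for name in roi_names])
        state.volumes_processed += 1
        if n < config.n_discard:
            continue
        state.buffer.append(row)
        idx = len(state.buffer) - 1  # analysed-series index (post-discard)
        t1 = time.perf_counter()

        # freeze the rest baseline once the first rest block has passed
        if (
            state.rest_baseline is None
            and baseline_labels is not None
            and config.mode in ("activation", "both")
        ):
            run_len = 0
            while (
                run_len < len(baseline_labels)
                and baseline_labels[run_len] == baseline_labels[0]
            ):
                run_len += 1
            if idx + 1 >= run_len:
                block = np.asarray(state.buffer[:run_len])
                stable = np.arange(config.n_transition, run_len)
                if stable.size == 0:
                    raise ValueError("first rest block too short for a baseline")
                state.rest_baseline = pd.Series(
                    block[stable].mean(axis=0), index=roi_names
                )

        w0 = idx - k + 1  # newest complete window
        if w0 < first_start:
            continue

        series = np.asarray(state.buffer)
        feats: dict[str, float] = {}
        if config.mode in ("dwgc", "both"):
            for ti, target in enumerate(roi_names):
                for si, source in enumerate(roi_names):
                    if si == ti:
                        continue
                    val = window_gc(
                        series[:, si],
                        series[:, ti],
                        w0,
                        k,
                        spec,
                        epsilon=config.epsilon,
                        omega=_omega_for(config, source, target),
                        source_name=source,
                        target_name=target,
                    )
                    feats[f"F[{source}->{target}]"] = val.F_thresholded
        if config.mode in ("activation", "both"):
            if state.rest_baseline is None:
                raise ValueError(
                    "activation features need a rest baseline "
                    "(set config.rest_baseline or config.paradigm)"
                )
            for r_i, name in enumerate(roi_names):
                feats[f"ACTIVE[{name}]"] = float(
                    series[w0, r_i] - state.rest_baseline[name]
                )
        t2 = time.perf_counter()

        vector = np.asarray([feats[name] for name in decoder.feature_names])
        label = decoder.predict_row(vector)
        t3 = time.perf_counter()
        state.decisions.append(
            StreamDecision(
                volume_index=n,
                window_start=w0,
                predicted_label=label,
                features=feats,
                extract_s=t1 - t0,
                dwgc_s=t2 - t1,
                classify_s=t3 - t2,
            )
        )
    return state.decisions


def batch_replay(
    volume_source,
    rois: list[RoiSpec] | None,
    config: PipelineConfig,
    decoder: TrainedDecoder,
) -> list[StreamDecision]:
    """Run the identical pipeline in one batch pass (reference for streaming)."""
    rois = rois if rois is not None else config.rois
    iterator, affine = _iter_volumes(volume_source, config)
    volumes = np.stack(list(iterator), axis=-1)
    if affine is None:
        raise ValueError("no affine available to place ROI masks")
    grid = VolumeGrid(shape=volumes.shape[:3], affine=np.asarray(affine))
    masks = {r.name: build_sphere_mask(r, grid) for r in rois}
    labels = (
        config.paradigm.condition_labels()[: volumes.shape[-1]]
        if config.paradigm is not None
        else np.full(volumes.shape[-1], "unknown")
    )
    series = extract_mean_series(
        volumes, masks, tr_seconds=config.tr_seconds, condition_labels=labels
    )
    series = discard_initial(series, config.n_discard)

    connectivity = dwgc_sequence(
        series, config.spec, config.k, omega=config.omega, epsilon=config.epsilon
    )
    activation = None
    if config.mode in ("activation", "both"):
        baseline = (
            config.rest_baseline
            if config.rest_baseline is not None
            else frozen_rest_baseline(series, config.n_transition, config.rest_label)
        )
        activation = compute_active(series, baseline)
    features = assemble_features(
        connectivity, activation, series.condition_labels, mode=config.mode
    )
    decisions = []
    for i in range(features.n_samples):
        vector = features.X.iloc[i][decoder.feature_names].to_numpy(dtype=float)
        label = decoder.predict_row(vector)
        w0 = int(features.volume_index[i])
        decisions.append(
            StreamDecision(
                volume_index=w0 + config.k - 1 + config.n_discard,
                window_start=w0,
                predicted_label=label,
                features={name: float(v) for name, v in zip(decoder.feature_names, vector)},
                extract_s=0.0,
                dwgc_s=0.0,
                classify_s=0.0,
            )
        )
    return decisions


def decisions_to_tsv(decisions: list[StreamDecision], path: str | Path) -> None:
    rows = [
        {
            "volume": d.volume_index,
            "window_start": d.window_start,
            "label": d.predicted_label,
            "extract_s": d.extract_s,
            "dwgc_s": d.dwgc_s,
            "classify_s": d.classify_s,
            "total_s": d.total_s,
        }
        for d in decisions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
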