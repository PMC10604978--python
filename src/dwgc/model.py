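"""Dynamic window-level Granger causality (DWGC).

For an ordered node pair (source -> target) and a sliding window of ``k``
volumes starting at volume ``t``, two autoregressive predictors of the
target are fitted by least squares on a trailing training span that ends
strictly before the window:

* the **restricted** predictor regresses the target's next value on its own
  last ``p`` (basis-expanded) values;
* the **full** predictor additionally uses the source's last ``p`` values.

Both predictors forecast the ``k`` window samples one step ahead from the
actually observed lags, and their mean squared errors ``L1`` (restricted)
and ``L2`` (full) are compared through

    F = L1 / max(L2, epsilon).

F materially above 1 on a window means the source's past improved the
out-of-sample prediction of the target there -- windowed Granger causality.
A detection threshold ``omega`` is calibrated from circular-shift
surrogates (which destroy cross-lag structure while preserving each
series' autocorrelation): F values below ``omega`` are zeroed, values at or
above it are kept.

"Nonlinear autoregression" is realised as polynomial expansion of the
lagged values (powers 1..degree, no cross terms); the linear basis is the
degree-1 special case and the default.

:class:`DynamicWindowGC` / :class:`DWGCResults` wrap these primitives in a
model/results pair: construct the model from a labelled ROI series, call
:meth:`DynamicWindowGC.fit` to calibrate the threshold and sweep all
ordered pairs and windows, and read the thresholded F tensor, per-pair
thresholds and summary table off the results object.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from dwgc.roi import RoiSeriesMatrix

__all__ = [
    "ArModelSpec",
    "WindowGcValue",
    "ConnectivitySequence",
    "DynamicWindowGC",
    "DWGCResults",
    "fit_window_predictors",
    "window_gc",
    "calibrate_threshold",
    "apply_threshold",
    "dwgc_sequence",
]

logger = logging.getLogger(__name__)

#: Ridge penalty used when the least-squares design is rank deficient.
RIDGE_PENALTY = 1e-8


@dataclass(frozen=True)
class ArModelSpec:
    """Autoregressive predictor specification.

    Parameters
    ----------
    order_p
        Number of lags of each series entering the predictors.
    basis
        ``"linear"`` or ``"polynomial"``; the polynomial basis expands every
        lagged value into powers ``1..degree``.
    degree
        Polynomial degree (ignored for the linear basis).
    train_span
        Number of past samples, ending immediately before the window, on
        which predictor coefficients are fitted. Must be at least twice the
        number of predictor terms of the full model.
    """

    order_p: int = 1
    basis: str = "linear"
    degree: int = 2
    train_span: int = 40

    def __post_init__(self) -> None:
        if self.order_p < 1:
            raise ValueError("order_p must be >= 1")
        if self.basis not in ("linear", "polynomial"):
            raise ValueError(f"unknown basis {self.basis!r}")
        if self.basis == "polynomial" and self.degree < 1:
            raise ValueError("polynomial degree must be >= 1")
        n_full = self.n_terms(n_series=2)
        if self.train_span < 2 * n_full:
            raise ValueError(
                f"train_span={self.train_span} must be >= twice the "
                f"{n_full} full-model terms"
            )

    @property
    def basis_per_lag(self) -> int:
        return 1 if self.basis == "linear" else self.degree

    def n_terms(self, n_series: int) -> int:
        """Predictor terms (including intercept) when n_series series enter."""
        return 1 + n_series * self.order_p * self.basis_per_lag


@dataclass(frozen=True)
class WindowGcValue:
    """One directed pair's DWGC evaluation on one window."""

    source: str
    target: str
    window_start_t: int
    window_len_k: int
    L1: float
    L2: float
    F: float
    F_thresholded: float
    saturated: bool = False


@dataclass(frozen=True)
class ArPredictor:
    """A fitted one-step-ahead autoregressive predictor."""

    coef: np.ndarray
    spec: ArModelSpec
    uses_source: bool
    target_loc: float
    target_scale: float
    source_loc: float = 0.0
    source_scale: float = 1.0

    def predict(
        self, target: np.ndarray, source: np.ndarray | None, samples: np.ndarray
    ) -> np.ndarray:
        """Predict (standardised) target values at the given sample indices."""
        tgt_std = (np.asarray(target, float) - self.target_loc) / self.target_scale
        src_std = None
        if self.uses_source:
            if source is None:
                raise ValueError("full predictor needs the source series")
            src_std = (np.asarray(source, float) - self.source_loc) / self.source_scale
        X = _design_matrix(tgt_std, src_std, np.asarray(samples, int), self.spec)
        return X @ self.coef


def _standardize_params(x: np.ndarray) -> tuple[float, float]:
    loc = float(np.mean(x))
    scale = float(np.std(x))
    return loc, (scale if scale > 1e-12 else 1.0)


def _expand(lags: np.ndarray, spec: ArModelSpec) -> np.ndarray:
    """Basis-expand a (samples, lags) block."""
    if spec.basis == "linear":
        return lags
    return np.concatenate([lags**d for d in range(1, spec.degree + 1)], axis=1)


def _design_matrix(
    target: np.ndarray,
    source: np.ndarray | None,
    samples: np.ndarray,
    spec: ArModelSpec,
) -> np.ndarray:
    """Regression design for predicting ``target[s]`` at each sample ``s``.

    Rows hold an intercept, the target's last ``p`` values and (optionally)
    the source's last ``p`` values, basis-expanded.
    """
    p = spec.order_p
    if samples.size and samples.min() < p:
        raise ValueError("sample index precedes available lags")
    offsets = np.arange(1, p + 1)
    blocks = [np.ones((samples.size, 1))]
    blocks.append(_expand(target[samples[:, None] - offsets], spec))
    if source is not None:
        blocks.append(_expand(source[samples[:, None] - offsets], spec))
    return np.concatenate(blocks, axis=1)


def _fit_ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        # rank-deficient design: refit with a tiny ridge penalty
        logger.debug(
            "rank-deficient design (%d < %d); ridge fallback with penalty %.0e",
            rank,
            X.shape[1],
            RIDGE_PENALTY,
        )
        gram = X.T @ X + RIDGE_PENALTY * np.eye(X.shape[1])
        coef = np.linalg.solve(gram, X.T @ y)
    return coef


def fit_window_predictors(
    target_history: np.ndarray,
    source_history: np.ndarray,
    t: int,
    spec: ArModelSpec = ArModelSpec(),
    in_sample_window: tuple[int, int] | None = None,
) -> tuple[ArPredictor, ArPredictor]:
    """Fit the restricted and full predictors for a window starting at ``t``.

    Coefficients are fitted by least squares on the ``train_span`` samples
    strictly before ``t`` (no leakage into the window). Both series are
    standardised to the training span's mean and variance first, making the
    F ratio comparable across ROIs with different BOLD scales. Passing
    ``in_sample_window=(t, k)`` instead fits on the window samples
    themselves (used by oracle checks).

    Returns ``(restricted, full)``.
    """
    target = np.asarray(target_history, dtype=float)
    source = np.asarray(source_history, dtype=float)
    if target.shape != source.shape or target.ndim != 1:
        raise ValueError("target and source histories must be equal-length 1D")
    p = spec.order_p
    if in_sample_window is not None:
        w0, k = in_sample_window
        samples = np.arange(w0, w0 + k)
        if w0 < p:
            raise ValueError("window start leaves no room for the lags")
    else:
        if t - spec.train_span - p < 0:
            raise ValueError(
                f"window start {t} leaves fewer than train_span={spec.train_span} "
                f"+ p={p} samples of history"
            )
        samples = np.arange(t - spec.train_span, t)

    t_loc, t_scale = _standardize_params(target[samples])
    s_loc, s_scale = _standardize_params(source[samples])
    tgt_std = (target - t_loc) / t_scale
    src_std = (source - s_loc) / s_scale

    y = tgt_std[samples]
    X_r = _design_matrix(tgt_std, None, samples, spec)
    X_f = _design_matrix(tgt_std, src_std, samples, spec)
    restricted = ArPredictor(
        coef=_fit_ols(X_r, y),
        spec=spec,
        uses_source=False,
        target_loc=t_loc,
        target_scale=t_scale,
    )
    full = ArPredictor(
        coef=_fit_ols(X_f, y),
        spec=spec,
        uses_source=True,
        target_loc=t_loc,
        target_scale=t_scale,
        source_loc=s_loc,
        source_scale=s_scale,
    )
    return restricted, full


def window_gc(
    source: np.ndarray,
    target: np.ndarray,
    t: int,
    k: int = 4,
    spec: ArModelSpec = ArModelSpec(),
    epsilon: float = 1e-12,
    omega: float = 0.0,
    in_sample: bool = False,
    source_name: str = "source",
    target_name: str = "target",
) -> WindowGcValue:
    """Evaluate source -> target DWGC on the window ``[t, t+k-1]``.

    ``L1``/``L2`` are the restricted/full one-step-ahead mean squared errors
    over the ``k`` window samples; ``F = L1 / max(L2, epsilon)``. A window
    whose full-model error underruns ``epsilon`` (noise-free coupling) is
    reported at the resulting cap with ``saturated=True``.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if k < 1:
        raise ValueError("window length k must be >= 1")
    if t + k > target.size:
        raise ValueError(f"window [{t}, {t + k - 1}] overruns series of length {target.size}")
    restricted, full = fit_window_predictors(
        target, source, t, spec, in_sample_window=(t, k) if in_sample else None
    )
    samples = np.arange(t, t + k)
    y = (target - restricted.target_loc) / restricted.target_scale
    err_r = y[samples] - restricted.predict(target, None, samples)
    err_f = y[samples] - full.predict(target, source, samples)
    L1 = float(np.mean(err_r**2))
    L2 = float(np.mean(err_f**2))
    saturated = L2 < epsilon
    F = L1 / max(L2, epsilon)
    return WindowGcValue(
        source=source_name,
        target=target_name,
        window_start_t=int(t),
        window_len_k=int(k),
        L1=L1,
        L2=L2,
        F=F,
        F_thresholded=apply_threshold(F, omega),
        saturated=saturated,
    )


def apply_threshold(F: float, omega: float) -> float:
    """Keep F at or above the threshold, zero it below (boundary inclusive)."""
    if F < 0 or omega < 0:
        raise ValueError("F and omega must be non-negative")
    return F if F >= omega else 0.0


def window_starts(
    n_volumes: int, k: int, spec: ArModelSpec, stride: int = 1
) -> np.ndarray:
    """Admissible sliding-window start indices.

    The earliest start leaves ``train_span`` training samples plus ``p``
    lags before it; the last window must end inside the series.
    """
    first = spec.train_span + spec.order_p
    last = n_volumes - k
    return np.arange(first, last + 1, stride, dtype=int)


def _as_frame(series: "RoiSeriesMatrix | pd.DataFrame") -> pd.DataFrame:
    if isinstance(series, RoiSeriesMatrix):
        return series.values
    return pd.DataFrame(series)


@dataclass
class ConnectivitySequence:
    """Time-indexed directed-F tensor over all ordered node pairs.

    ``F[w, i, j]`` is the (thresholded) source ``nodes[j]`` -> target
    ``nodes[i]`` value on the window starting at ``window_starts[w]``;
    diagonal entries are NaN.
    """

    nodes: list[str]
    window_starts: np.ndarray
    k: int
    F: np.ndarray
    F_thresholded: np.ndarray
    L1: np.ndarray
    L2: np.ndarray
    saturated: np.ndarray
    omega: dict[tuple[str, str], float]
    spec: ArModelSpec = field(default_factory=ArModelSpec)

    @property
    def n_windows(self) -> int:
        return len(self.window_starts)

    def pairs(self) -> list[tuple[str, str]]:
        """Ordered (source, target) pairs."""
        return [
            (s, t) for t in self.nodes for s in self.nodes if s != t
        ]

    def pair_values(self, source: str, target: str, thresholded: bool = True) -> np.ndarray:
        i = self.nodes.index(target)
        j = self.nodes.index(source)
        tensor = self.F_thresholded if thresholded else self.F
        return tensor[:, i, j]

    def mean_log_f(self) -> pd.Series:
        """Per ordered pair, the mean of log F across windows."""
        out = {}
        for s, t in self.pairs():
            f = self.pair_values(s, t, thresholded=False)
            out[f"{s}->{t}"] = float(np.mean(np.log(np.maximum(f, 1e-300))))
        return pd.Series(out, name="mean_log_F")

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for w, t0 in enumerate(self.window_starts):
            for s, t in self.pairs():
                i, j = self.nodes.index(t), self.nodes.index(s)
                rows.append(
                    (
                        int(t0),
                        s,
                        t,
                        self.L1[w, i, j],
                        self.L2[w, i, j],
                        self.F[w, i, j],
                        self.F_thresholded[w, i, j],
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "window_start",
                "source",
                "target",
                "L1",
                "L2",
                "F",
                "F_thresholded",
            ],
        )

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        self.to_dataframe().to_csv(path, index=False)
        if sidecar is not None:
            payload = {
                "k": self.k,
                "nodes": self.nodes,
                "omega": {f"{s}->{t}": w for (s, t), w in self.omega.items()},
                "spec": dataclasses.asdict(self.spec),
            }
            Path(sidecar).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path, sidecar: str | Path) -> "ConnectivitySequence":
        df = pd.read_csv(path)
        meta = json.loads(Path(sidecar).read_text())
        nodes = list(meta["nodes"])
        spec = ArModelSpec(**meta["spec"])
        starts = np.asarray(sorted(df["window_start"].unique()), dtype=int)
        n = len(nodes)
        shape = (len(starts), n, n)
        F = np.full(shape, np.nan)
        F_thr = np.full(shape, np.nan)
        L1 = np.full(shape, np.nan)
        L2 = np.full(shape, np.nan)
        w_of = {t0: w for w, t0 in enumerate(starts)}
        idx = {name: i for i, name in enumerate(nodes)}
        for r in df.itertuples():
            w, i, j = w_of[r.window_start], idx[r.target], idx[r.source]
            F[w, i, j] = r.F
            F_thr[w, i, j] = r.F_thresholded
            L1[w, i, j] = r.L1
            L2[w, i, j] = r.L2
        omega = {
            tuple(key.split("->")): float(v) for key, v in meta["omega"].items()
        }
        return cls(
            nodes=nodes,
            window_starts=starts,
            k=int(meta["k"]),
            F=F,
            F_thresholded=F_thr,
            L1=L1,
            L2=L2,
            saturated=np.zeros(shape, dtype=bool),
            omega=omega,
            spec=spec,
        )


def calibrate_threshold(
    series: "RoiSeriesMatrix | pd.DataFrame",
    spec: ArModelSpec = ArModelSpec(),
    k: int = 4,
    alpha: float = 0.05,
    n_surrogates: int = 500,
    seed: int = 0,
    windows_per_surrogate: int = 20,
    per_pair: bool = True,
    epsilon: float = 1e-12,
) -> dict[tuple[str, str], float]:
    """Calibrate the detection threshold omega from circular-shift surrogates.

    For every ordered pair the source series is circularly shifted by a
    seeded random offset (destroying source->target cross-lag structure
    while preserving both autocorrelations), F is evaluated on a random
    subsample of admissible windows, and omega is the empirical
    ``1 - alpha`` quantile of the pooled surrogate F values. With
    ``per_pair=False`` a single pooled threshold is assigned to all pairs.

    Offsets are drawn away from 0 (mod T) by a margin of ``k + p`` samples
    so no surrogate retains the original alignment.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_surrogates < 100:
        raise ValueError("need at least 100 surrogates for a stable quantile")
    frame = _as_frame(series)
    nodes = list(frame.columns)
    data = frame.to_numpy(dtype=float).T
    T = data.shape[1]
    starts = window_starts(T, k, spec)
    if starts.size == 0:
        raise ValueError(
            f"series of {T} volumes is too short for any window "
            f"(train_span={spec.train_span}, p={spec.order_p}, k={k})"
        )
    margin = k + spec.order_p
    if T <= 2 * margin:
        raise ValueError("series too short for decorrelating circular shifts")

    rng = np.random.default_rng(seed)
    pools: dict[tuple[str, str], list[float]] = {}
    for i, tgt in enumerate(nodes):
        for j, src in enumerate(nodes):
            if i == j:
                continue
            pool: list[float] = []
            for _ in range(n_surrogates):
                offset = int(rng.integers(margin, T - margin))
                shifted = np.roll(data[j], offset)
                chosen = rng.choice(
                    starts,
                    size=min(windows_per_surrogate, starts.size),
                    replace=False,
                )
                for t0 in chosen:
                    val = window_gc(
                        shifted, data[i], int(t0), k, spec, epsilon=epsilon
                    )
                    pool.append(val.F)
            pools[(src, tgt)] = pool

    if per_pair:
        return {
            pair: float(np.quantile(np.asarray(pool), 1.0 - alpha))
            for pair, pool in pools.items()
        }
    merged = np.concatenate([np.asarray(p) for p in pools.values()])
    shared = float(np.quantile(merged, 1.0 - alpha))
    return {pair: shared for pair in pools}


def dwgc_sequence(
    series: "RoiSeriesMatrix | pd.DataFrame",
    spec: ArModelSpec = ArModelSpec(),
    k: int = 4,
    omega: "Mapping[tuple[str, str], float] | float | None" = None,
    stride: int = 1,
    epsilon: float = 1e-12,
    in_sample: bool = False,
) -> ConnectivitySequence:
    """Sweep every ordered node pair over every admissible sliding window.

    ``omega`` may be a per-pair mapping (as returned by
    :func:`calibrate_threshold`), a single scalar, or ``None`` for an
    unthresholded sequence.
    """
    frame = _as_frame(series)
    nodes = list(frame.columns)
    if len(nodes) < 2:
        raise ValueError("need at least 2 nodes for directed connectivity")
    data = frame.to_numpy(dtype=float).T
    T = data.shape[1]
    starts = window_starts(T, k, spec, stride)
    if starts.size == 0:
        raise ValueError(
            f"series of {T} volumes is too short for any window "
            f"(train_span={spec.train_span}, p={spec.order_p}, k={k})"
        )

    if omega is None:
        omega_map = {(s, t): 0.0 for t in nodes for s in nodes if s != t}
    elif isinstance(omega, Mapping):
        omega_map = {
            (s, t): float(omega[(s, t)]) for t in nodes for s in nodes if s != t
        }
    else:
        omega_map = {
            (s, t): float(omega) for t in nodes for s in nodes if s != t
        }

    n = len(nodes)
    shape = (starts.size, n, n)
    F = np.full(shape, np.nan)
    F_thr = np.full(shape, np.nan)
    L1 = np.full(shape, np.nan)
    L2 = np.full(shape, np.nan)
    saturated = np.zeros(shape, dtype=bool)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            om = omega_map[(nodes[j], nodes[i])]
            for w, t0 in enumerate(starts):
                val = window_gc(
                    data[j],
                    data[i],
                    int(t0),
                    k,
                    spec,
                    epsilon=epsilon,
                    omega=om,
                    in_sample=in_sample,
                )
                F[w, i, j] = val.F
                F_thr[w, i, j] = val.F_thresholded
                L1[w, i, j] = val.L1
                L2[w, i, j] = val.L2
                saturated[w, i, j] = val.saturated
    return ConnectivitySequence(
        nodes=nodes,
        window_starts=starts,
        k=k,
        F=F,
        F_thresholded=F_thr,
        L1=L1,
        L2=L2,
        saturated=saturated,
        omega=omega_map,
        spec=spec,
    )


class DynamicWindowGC:
    """DWGC model over a labelled multi-ROI BOLD series.

    Parameters
    ----------
    series
        :class:`~dwgc.roi.RoiSeriesMatrix` or a volumes x ROIs DataFrame.
    spec
        Autoregressive predictor specification.
    k
        Sliding-window length in volumes.
    stride
        Step between successive window starts.
    epsilon
        Floor applied to the full-model MSE in the F ratio.

    Examples
    --------
    >>> model = DynamicWindowGC(series, k=4)
    >>> res = model.fit(alpha=0.05, seed=0)
    >>> res.connectivity.pair_values("node0", "node1")
    """

    def __init__(
        self,
        series: "RoiSeriesMatrix | pd.DataFrame",
        spec: ArModelSpec = ArModelSpec(),
        k: int = 4,
        stride: int = 1,
        epsilon: float = 1e-12,
    ) -> None:
        self.series = series
        self.frame = _as_frame(series)
        if len(self.frame.columns) < 2:
            raise ValueError("need at least 2 ROIs")
        self.spec = spec
        self.k = k
        self.stride = stride
        self.epsilon = epsilon

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, tr_seconds: float = 2.0, **kwargs
    ) -> "DynamicWindowGC":
        labels = np.full(len(frame), "unknown")
        series = RoiSeriesMatrix(
            values=frame.reset_index(drop=True),
            tr_seconds=tr_seconds,
            condition_labels=labels,
        )
        return cls(series, **kwargs)

    def fit(
        self,
        omega: "Mapping[tuple[str, str], float] | float | None" = None,
        alpha: float = 0.05,
        n_surrogates: int = 500,
        windows_per_surrogate: int = 20,
        per_pair: bool = True,
        seed: int = 0,
    ) -> "DWGCResults":
        """Calibrate omega (unless given) and compute the full F tensor."""
        if omega is None:
            omega = calibrate_threshold(
                self.frame,
                self.spec,
                self.k,
                alpha=alpha,
                n_surrogates=n_surrogates,
                windows_per_surrogate=windows_per_surrogate,
                per_pair=per_pair,
                seed=seed,
                epsilon=self.epsilon,
            )
        connectivity = dwgc_sequence(
            self.frame,
            self.spec,
            self.k,
            omega=omega,
            stride=self.stride,
            epsilon=self.epsilon,
        )
        return DWGCResults(model=self, connectivity=connectivity)


@dataclass
class DWGCResults:
    """Fitted DWGC tensor with per-pair thresholds and diagnostics."""

    model: DynamicWindowGC
    connectivity: ConnectivitySequence

    @property
    def omega(self) -> dict[tuple[str, str], float]:
        return self.connectivity.omega

    def summary(self) -> pd.DataFrame:
        """Per ordered pair: omega, mean F, mean log F, detection fraction."""
        rows = []
        for s, t in self.connectivity.pairs():
            f = self.connectivity.pair_values(s, t, thresholded=False)
            f_thr = self.connectivity.pair_values(s, t, thresholded=True)
            rows.append(
                {
                    "source": s,
                    "target": t,
                    "omega": self.omega[(s, t)],
                    "mean_F": float(np.mean(f)),
                    "mean_log_F": float(np.mean(np.log(np.maximum(f, 1e-300)))),
                    "detect_frac": float(np.mean(f_thr > 0)),
                }
            )
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        header = (
            f"DWGC: {len(self.connectivity.nodes)} nodes, "
            f"k={self.connectivity.k}, "
            f"{self.connectivity.n_windows} windows, "
            f"spec={self.connectivity.spec}"
        )
        return header + "\n" + self.summary().to_string(index=False)
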