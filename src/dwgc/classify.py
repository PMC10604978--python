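"""Feature assembly, classifier suite and decoding evaluation.

Per-volume feature vectors are assembled from the thresholded directed-F
tensor (one column per ordered ROI pair) and optionally the per-ROI ACTIVE
activation values. The classifier suite (Gaussian naive Bayes, polynomial-
and RBF-kernel SVMs, and the two gradient-boosting families) is evaluated
with block-grouped, class-stratified K-fold cross-validation: all samples
of one task block share a fold, so temporally adjacent volumes never
straddle the train/test split. Reports carry the pooled confusion matrix,
accuracy, Cohen's kappa, per-fold metrics and the held-out per-volume
predictions from which per-TR decoding-accuracy (DA) curves are built.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from dwgc.model import ConnectivitySequence
from dwgc.paradigm import Paradigm, REST
from dwgc.roi import ActivationFeature

__all__ = [
    "FeatureMatrix",
    "ClassifierSpec",
    "EvaluationReport",
    "DaCurve",
    "FeatureComparison",
    "TrainedDecoder",
    "fit_decoder",
    "default_classifier_grid",
    "assemble_features",
    "kfold_evaluate",
    "cohen_kappa",
    "decoding_accuracy_curve",
    "compare_feature_sets",
]


@dataclass
class FeatureMatrix:
    """Sample-by-feature table with labels and block grouping.

    ``volume_index`` ties each row to the window-start volume it describes;
    ``block_id`` indexes the maximal constant-label run containing that
    volume and drives the grouped cross-validation folds.
    """

    X: pd.DataFrame
    labels: np.ndarray
    volume_index: np.ndarray
    block_id: np.ndarray
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=str)
        self.volume_index = np.asarray(self.volume_index, dtype=int)
        self.block_id = np.asarray(self.block_id, dtype=int)
        n = len(self.X)
        if not (len(self.labels) == len(self.volume_index) == len(self.block_id) == n):
            raise ValueError("labels/volume_index/block_id must match row count")
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return len(self.X)

    def select(self, mask: np.ndarray) -> "FeatureMatrix":
        mask = np.asarray(mask)
        return FeatureMatrix(
            X=self.X.loc[mask].reset_index(drop=True),
            labels=self.labels[mask],
            volume_index=self.volume_index[mask],
            block_id=self.block_id[mask],
            provenance=dict(self.provenance),
        )

    def drop_rest(self, rest_label: str = REST) -> "FeatureMatrix":
        return self.select(self.labels != rest_label)

    def to_csv(self, path: str | Path) -> None:
        out = self.X.copy()
        out.insert(0, "volume", self.volume_index)
        out.insert(1, "block_id", self.block_id)
        out["label"] = self.labels
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy()
        vols = df.pop("volume").to_numpy()
        blocks = df.pop("block_id").to_numpy()
        return cls(X=df, labels=labels, volume_index=vols, block_id=blocks)


def _block_ids(labels: np.ndarray) -> np.ndarray:
    """Index of the maximal constant-label run each volume belongs to."""
    labels = np.asarray(labels, dtype=str)
    ids = np.zeros(len(labels), dtype=int)
    current = 0
    for i in range(1, len(labels)):
        if labels[i] != labels[i - 1]:
            current += 1
        ids[i] = current
    return ids


def assemble_features(
    connectivity: ConnectivitySequence | None,
    activation: ActivationFeature | None,
    labels: Sequence[str],
    mode: str = "dwgc",
) -> FeatureMatrix:
    """Build the classifier's sample matrix, one row per admissible window.

    ``mode`` selects the feature set: ``"dwgc"`` (thresholded directed-F
    columns), ``"activation"`` (per-ROI ACTIVE columns) or ``"both"``. All
    modes share the same rows -- the connectivity sequence's window starts
    -- so accuracies are directly comparable across feature sets. The label
    attached to a window is the condition at its start volume.
    """
    if mode not in ("dwgc", "activation", "both"):
        raise ValueError(f"unknown mode {mode!r}")
    if connectivity is None or connectivity.n_windows == 0:
        raise ValueError("empty connectivity sequence; no windows to featurise")
    labels = np.asarray(labels, dtype=str)
    starts = connectivity.window_starts
    if starts.max() >= len(labels):
        raise ValueError(
            f"labels cover {len(labels)} volumes but window start "
            f"{int(starts.max())} needs a label"
        )

    cols: dict[str, np.ndarray] = {}
    provenance: dict[str, str] = {}
    if mode in ("dwgc", "both"):
        for s, t in connectivity.pairs():
            name = f"F[{s}->{t}]"
            cols[name] = connectivity.pair_values(s, t, thresholded=True)
            provenance[name] = "dwgc"
    if mode in ("activation", "both"):
        if activation is None:
            raise ValueError(f"mode {mode!r} needs the activation stream")
        act = activation.values
        if len(act) <= starts.max():
            raise ValueError(
                f"activation stream has {len(act)} volumes but window start "
                f"{int(starts.max())} needs a value"
            )
        for roi in act.columns:
            name = f"ACTIVE[{roi}]"
            cols[name] = act[roi].to_numpy()[starts]
            provenance[name] = "activation"

    block_ids = _block_ids(labels)
    return FeatureMatrix(
        X=pd.DataFrame(cols),
        labels=labels[starts],
        volume_index=starts.copy(),
        block_id=block_ids[starts],
        provenance=provenance,
    )


@dataclass(frozen=True)
class ClassifierSpec:
    """One classifier family plus its hyperparameters.

    Families: ``gaussian_nb``, ``svm_poly`` (polynomial kernel, default
    exponent 1), ``svm_rbf`` (default C=19, gamma="scale"), ``gbdt_light``
    and ``gbdt_xg`` (gradient boosting; optional extras).
    """

    family: str
    params: Mapping[str, object] = field(default_factory=dict)

    def build(self, seed: int = 0):
        p = dict(self.params)
        if self.family == "gaussian_nb":
            est = GaussianNB(**p)
        elif self.family == "svm_poly":
            est = SVC(kernel="poly", degree=int(p.pop("degree", 1)), C=float(p.pop("C", 1.0)), **p)
        elif self.family == "svm_rbf":
            est = SVC(kernel="rbf", C=float(p.pop("C", 19.0)), gamma=p.pop("gamma", "scale"), **p)
        elif self.family == "gbdt_light":
            import lightgbm

            est = lightgbm.LGBMClassifier(
                max_depth=int(p.pop("max_depth", 5)),
                learning_rate=float(p.pop("learning_rate", 0.8)),
                n_estimators=int(p.pop("n_estimators", 1000)),
                random_state=seed,
                verbose=-1,
                **p,
            )
        elif self.family == "gbdt_xg":
            import xgboost

            est = xgboost.XGBClassifier(
                max_depth=int(p.pop("max_depth", 8)),
                learning_rate=float(p.pop("learning_rate", 0.08)),
                n_estimators=int(p.pop("n_estimators", 1000)),
                random_state=seed,
                verbosity=0,
                **p,
            )
        else:
            raise ValueError(f"unknown classifier family {self.family!r}")
        return Pipeline([("scale", StandardScaler()), ("clf", est)])


def default_classifier_grid() -> dict[str, ClassifierSpec]:
    """The standard suite with its printed training parameters."""
    return {
        "gaussian_nb": ClassifierSpec("gaussian_nb"),
        "svm_poly": ClassifierSpec("svm_poly", {"degree": 1}),
        "svm_rbf": ClassifierSpec("svm_rbf", {"C": 19.0, "gamma": "scale"}),
        "gbdt_light": ClassifierSpec(
            "gbdt_light", {"max_depth": 5, "learning_rate": 0.8, "n_estimators": 1000}
        ),
        "gbdt_xg": ClassifierSpec(
            "gbdt_xg", {"max_depth": 8, "learning_rate": 0.08, "n_estimators": 1000}
        ),
    }


def cohen_kappa(confusion: "np.ndarray | pd.DataFrame") -> float:
    """Chance-corrected agreement from a class-by-class confusion matrix.

    kappa = (p_o - p_e) / (1 - p_e) with p_o = trace/N and
    p_e = sum_c row_c * col_c / N^2. A degenerate matrix whose expected
    agreement is 1 (all mass in one cell) yields 0 with a warning.
    """
    mat = np.asarray(confusion, dtype=float)
    total = mat.sum()
    if total <= 0:
        raise ValueError("confusion matrix must have positive total count")
    p_o = np.trace(mat) / total
    p_e = float(np.sum(mat.sum(axis=1) * mat.sum(axis=0)) / total**2)
    if np.isclose(p_e, 1.0):
        warnings.warn("degenerate confusion matrix (expected agreement 1); kappa set to 0")
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def _stratified_block_folds(
    features: FeatureMatrix, K: int, seed: int
) -> np.ndarray:
    """Assign each row to a fold so blocks stay intact and classes spread."""
    rng = np.random.default_rng(seed)
    fold_of_block: dict[int, int] = {}
    blocks = pd.DataFrame(
        {"block": features.block_id, "label": features.labels}
    ).drop_duplicates()
    for label in sorted(set(blocks["label"])):
        ids = blocks.loc[blocks["label"] == label, "block"].to_numpy()
        rng.shuffle(ids)
        for pos, b in enumerate(ids):
            fold_of_block[int(b)] = pos % K
    return np.asarray([fold_of_block[int(b)] for b in features.block_id])


@dataclass
class EvaluationReport:
    """Pooled K-fold evaluation of one classifier on one feature matrix."""

    confusion: pd.DataFrame
    accuracy: float
    kappa: float
    per_fold: list[dict]
    K: int
    seed: int
    predictions: pd.DataFrame  # volume, block_id, true, pred, fold
    classes: list[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "accuracy": self.accuracy,
            "kappa": self.kappa,
            "K": self.K,
            "seed": self.seed,
            "classes": self.classes,
            "confusion": self.confusion.to_numpy().tolist(),
            "per_fold": self.per_fold,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def kfold_evaluate(
    features: FeatureMatrix,
    spec: ClassifierSpec = ClassifierSpec("svm_rbf", {"C": 19.0, "gamma": "scale"}),
    K: int = 5,
    seed: int = 0,
) -> EvaluationReport:
    """Block-grouped, class-stratified K-fold cross-validation.

    Blocks (maximal constant-label runs) are shuffled within each class and
    dealt round-robin over the K folds, so no task block is split between
    training and test. Feature standardisation uses training-fold
    statistics only. Deterministic given the seed (for deterministic
    classifier families).
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    classes = sorted(set(features.labels))
    counts = {c: int(np.sum(features.labels == c)) for c in classes}
    thin = [c for c, n in counts.items() if n < K]
    if thin:
        raise ValueError(f"classes {thin} have fewer than K={K} samples")

    fold = _stratified_block_folds(features, K, seed)
    class_to_idx = {c: i for i, c in enumerate(classes)}
    y = np.asarray([class_to_idx[c] for c in features.labels])
    X = features.X.to_numpy(dtype=float)

    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    per_fold: list[dict] = []
    pred_rows: list[pd.DataFrame] = []
    for f in range(K):
        train, test = fold != f, fold == f
        if test.sum() == 0:
            continue
        missing = [c for c in classes if not np.any(features.labels[train] == c)]
        if missing:
            raise ValueError(
                f"fold {f}: classes {missing} absent from the training split; "
                "use more blocks per class or a smaller K"
            )
        est = spec.build(seed=seed)
        est.fit(X[train], y[train])
        y_pred = np.asarray(est.predict(X[test]), dtype=int)
        fold_conf = np.zeros_like(confusion)
        for yt, yp in zip(y[test], y_pred):
            fold_conf[yt, yp] += 1
        confusion += fold_conf
        per_fold.append(
            {
                "fold": f,
                "n_test": int(test.sum()),
                "accuracy": float(np.trace(fold_conf) / fold_conf.sum()),
                "kappa": cohen_kappa(fold_conf) if fold_conf.sum() else float("nan"),
            }
        )
        pred_rows.append(
            pd.DataFrame(
                {
                    "volume": features.volume_index[test],
                    "block_id": features.block_id[test],
                    "true": features.labels[test],
                    "pred": [classes[i] for i in y_pred],
                    "fold": f,
                }
            )
        )

    predictions = pd.concat(pred_rows, ignore_index=True).sort_values("volume")
    conf_df = pd.DataFrame(confusion, index=classes, columns=classes)
    return EvaluationReport(
        confusion=conf_df,
        accuracy=float(np.trace(confusion) / confusion.sum()),
        kappa=cohen_kappa(confusion),
        per_fold=per_fold,
        K=K,
        seed=seed,
        predictions=predictions.reset_index(drop=True),
        classes=classes,
    )


@dataclass
class DaCurve:
    """Decoding accuracy per within-block volume position (0-based)."""

    values: np.ndarray
    feature_set: str = ""
    n_blocks: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("DA values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.values)

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pos = np.arange(1, len(self.values) + 1)
        ax.plot(pos, 100 * self.values, marker="o", label=self.feature_set or None, **kwargs)
        ax.set_xlabel("volume within block")
        ax.set_ylabel("decoding accuracy (%)")
        ax.set_xticks(pos)
        ax.set_ylim(0, 100)
        return ax

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "position": np.arange(1, len(self.values) + 1),
                "accuracy": self.values,
                "feature_set": self.feature_set,
            }
        ).to_csv(path, index=False)


def decoding_accuracy_curve(
    predictions: pd.DataFrame,
    paradigm: Paradigm,
    volume_offset: int = 0,
    feature_set: str = "",
) -> DaCurve:
    """Per-TR decoding accuracy within task blocks.

    ``predictions`` must hold columns ``volume`` (index into the analysed
    series), ``true`` and ``pred``. ``volume_offset`` maps analysed-series
    indices back to paradigm volumes (the number of initially discarded
    volumes). Position ``m``'s accuracy is the fraction of task blocks
    whose ``m``-th volume was classified correctly; only blocks whose every
    in-block volume has a prediction contribute. Task blocks of unequal
    length are rejected.
    """
    n_pos = paradigm.volumes_per_task_block()
    by_volume = {
        int(v) + volume_offset: (str(t), str(p))
        for v, t, p in zip(predictions["volume"], predictions["true"], predictions["pred"])
    }
    correct = np.zeros(n_pos, dtype=int)
    covered = 0
    for block in paradigm.task_blocks():
        i0 = int(round(block.onset_s / paradigm.tr_seconds))
        vols = [i0 + m for m in range(n_pos)]
        if not all(v in by_volume for v in vols):
            continue
        covered += 1
        for m, v in enumerate(vols):
            true, pred = by_volume[v]
            correct[m] += int(true == pred)
    if covered == 0:
        raise ValueError("no task block is fully covered by the predictions")
    return DaCurve(values=correct / covered, feature_set=feature_set, n_blocks=covered)


@dataclass
class TrainedDecoder:
    """A classifier fitted on a full feature matrix, ready for streaming."""

    pipeline: object
    feature_names: list[str]
    classes: list[str]
    mode: str

    def predict_row(self, row: np.ndarray) -> str:
        idx = int(self.pipeline.predict(np.asarray(row, dtype=float).reshape(1, -1))[0])
        return self.classes[idx]

    def predict(self, X: "np.ndarray | pd.DataFrame") -> np.ndarray:
        arr = np.asarray(X, dtype=float)
        idx = np.asarray(self.pipeline.predict(arr), dtype=int)
        return np.asarray([self.classes[i] for i in idx], dtype=str)

    def save(self, path: str | Path) -> None:
        import joblib

        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedDecoder":
        import joblib

        return joblib.load(path)


def fit_decoder(
    features: FeatureMatrix,
    spec: ClassifierSpec = ClassifierSpec("svm_rbf", {"C": 19.0, "gamma": "scale"}),
    seed: int = 0,
    mode: str = "dwgc",
) -> TrainedDecoder:
    """Fit one classifier on every row of the feature matrix."""
    classes = sorted(set(features.labels))
    class_to_idx = {c: i for i, c in enumerate(classes)}
    y = np.asarray([class_to_idx[c] for c in features.labels])
    est = spec.build(seed=seed)
    est.fit(features.X.to_numpy(dtype=float), y)
    return TrainedDecoder(
        pipeline=est,
        feature_names=list(features.X.columns),
        classes=classes,
        mode=mode,
    )


@dataclass
class FeatureComparison:
    """Paired comparison of two feature sets under repeated K-fold CV."""

    accuracies_a: np.ndarray
    accuracies_b: np.ndarray
    mean_difference: float
    t_statistic: float
    p_value: float
    n_repeats: int
    label_a: str = "a"
    label_b: str = "b"


def compare_feature_sets(
    features_a: FeatureMatrix,
    features_b: FeatureMatrix,
    spec: ClassifierSpec = ClassifierSpec("svm_rbf", {"C": 19.0, "gamma": "scale"}),
    K: int = 5,
    n_repeats: int = 20,
    seed: int = 0,
    label_a: str = "a",
    label_b: str = "b",
) -> FeatureComparison:
    """Repeated paired K-fold accuracies plus a paired t-test.

    Both feature matrices must describe exactly the same samples (same
    window starts and labels); each repeat reshuffles the block-to-fold
    assignment with a fresh seed and evaluates both sets on identical
    folds. A single repeat yields an undefined t statistic (reported as
    NaN).
    """
    if features_a.n_samples != features_b.n_samples or not np.array_equal(
        features_a.volume_index, features_b.volume_index
    ):
        raise ValueError("feature sets must cover identical sample rows")
    if not np.array_equal(features_a.labels, features_b.labels):
        raise ValueError("feature sets must share labels")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")

    acc_a, acc_b = [], []
    for r in range(n_repeats):
        fold_seed = (seed + 7919 * r) % (2**31 - 1)
        acc_a.append(kfold_evaluate(features_a, spec, K, fold_seed).accuracy)
        acc_b.append(kfold_evaluate(features_b, spec, K, fold_seed).accuracy)
    acc_a, acc_b = np.asarray(acc_a), np.asarray(acc_b)
    diff = float(np.mean(acc_a - acc_b))
    if n_repeats == 1 or np.allclose(acc_a, acc_b):
        t_stat, p_val = (float("nan"), float("nan"))
        if np.allclose(acc_a, acc_b) and n_repeats > 1:
            t_stat, p_val = 0.0, 1.0
    else:
        t_stat, p_val = sps.ttest_rel(acc_a, acc_b)
    return FeatureComparison(
        accuracies_a=acc_a,
        accuracies_b=acc_b,
        mean_difference=diff,
        t_statistic=float(t_stat),
        p_value=float(p_val),
        n_repeats=n_repeats,
        label_a=label_a,
        label_b=label_b,
    )
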