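"""Cross-validated evaluation of the LFDA-GMM decoding pipeline.

Random sub-sampling cross validation draws, per iteration and per class, an
equal number of training rows (a percentage of the least populated class) and
an equally balanced disjoint test set, refits the full LFDA + per-class GMM
stack on the training rows only, and scores the held-out rows. Forward
channel selection greedily grows a selected-channels list by cross-validated
accuracy; the training-size sweep repeats the CV across training percentages.

Note that rows are sampled without regard to temporal adjacency. With
autocorrelated signals this interleaves train and test rows in time and can
flatter accuracy relative to a session-split design; the shuffled-label
chance guard in the test suite bounds label leakage but not this optimism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UsageError
from .gmm import GMMClassifier
from .types import FeatureMatrix

__all__ = ["ConfusionMatrix", "ClassMetrics", "CVResult", "confusion",
           "metrics", "random_subsample_cv", "forward_select",
           "training_size_sweep"]


@dataclass
class ConfusionMatrix:
    """Counts with rows = actual class, columns = predicted class."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise UsageError("counts must be square in the label count")
        if (self.counts < 0).any():
            raise UsageError("confusion counts must be nonnegative")

    @property
    def normalized(self) -> np.ndarray:
        """Row-normalized percentages; all-zero rows stay zero."""
        rowsum = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = 100.0 * self.counts / rowsum
        return np.where(rowsum > 0, out, 0.0)

    @property
    def accuracy(self) -> float:
        total = self.counts.sum()
        return float(np.trace(self.counts) / total) if total else float("nan")

    def to_frame(self, normalized: bool = False) -> pd.DataFrame:
        data = self.normalized if normalized else self.counts
        return pd.DataFrame(data, index=self.labels, columns=self.labels)

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if self.labels != other.labels:
            raise UsageError("cannot add confusion matrices over different labels")
        return ConfusionMatrix(self.labels, self.counts + other.counts)


def confusion(y_true, y_pred, labels: list[str] | None = None) -> ConfusionMatrix:
    """Confusion matrix over the union of observed labels (sorted)."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise UsageError("y_true and y_pred must have the same length")
    if labels is None:
        labels = sorted(set(y_true.tolist()) | set(y_pred.tolist()))
    index = {c: i for i, c in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(list(labels), counts)


@dataclass
class ClassMetrics:
    """Per-class sensitivity (recall), precision and F score."""

    frame: pd.DataFrame  # columns: sensitivity, precision, f
    beta: float = 1.0

    def __getitem__(self, cls: str) -> pd.Series:
        return self.frame.loc[cls]

    @property
    def f1(self) -> pd.Series:
        return self.frame["f"]


def f_score(sensitivity: float, precision: float, beta: float = 1.0,
            form: str = "standard") -> float:
    """Weighted harmonic mean of sensitivity and precision.

    ``form="standard"`` uses the usual F_beta denominator
    ``beta^2 * precision + sensitivity``; ``form="linear-beta"`` uses
    ``beta * precision + sensitivity``. The two coincide at beta = 1,
    the only weighting used here.
    """
    if form == "standard":
        denom = beta ** 2 * precision + sensitivity
    elif form == "linear-beta":
        denom = beta * precision + sensitivity
    else:
        raise UsageError(f"unknown F form {form!r}")
    if denom == 0 or sensitivity * precision == 0:
        return 0.0
    return (1.0 + beta ** 2) * sensitivity * precision / denom


def metrics(cm: ConfusionMatrix, beta: float = 1.0,
            form: str = "standard") -> ClassMetrics:
    """Sensitivity, precision and F per class from a confusion matrix.

    Precision of a class never predicted is set to 0 with a warning.
    """
    counts = cm.counts.astype(float)
    diag = np.diag(counts)
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    empty = [c for c, s in zip(cm.labels, cols) if s == 0]
    if empty:
        warnings.warn(f"classes never predicted (precision set to 0): {empty}")
    with np.errstate(invalid="ignore", divide="ignore"):
        sens = np.where(rows > 0, diag / rows, 0.0)
        prec = np.where(cols > 0, diag / cols, 0.0)
    f = np.array([f_score(s, p, beta, form) for s, p in zip(sens, prec)])
    frame = pd.DataFrame({"sensitivity": sens, "precision": prec, "f": f},
                         index=cm.labels)
    return ClassMetrics(frame=frame, beta=beta)


@dataclass
class CVResult:
    """Outcome of repeated random sub-sampling cross validation."""

    accuracies: np.ndarray
    confusion: ConfusionMatrix
    params: dict

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1))

    @property
    def se(self) -> float:
        return self.sd / np.sqrt(len(self.accuracies))


def _balanced_split(y: np.ndarray, pct_train: float, rng: np.random.Generator):
    classes = sorted(np.unique(y).tolist())
    sizes = {c: int(np.sum(y == c)) for c in classes}
    min_size = min(sizes.values())
    n_train = int(np.floor(pct_train / 100.0 * min_size))
    if n_train < 1:
        raise UsageError(f"pct_train={pct_train} yields no training rows "
                         f"(least populated class has {min_size})")
    n_test = min(sizes[c] - n_train for c in classes)
    if n_test < 1:
        raise UsageError(f"pct_train={pct_train} leaves no test rows")
    train_idx, test_idx = [], []
    for c in classes:
        perm = rng.permutation(np.flatnonzero(y == c))
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:n_train + n_test])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def random_subsample_cv(fm: FeatureMatrix, *, pct_train: float = 50.0,
                        n_iter: int = 10, r: int, k_nn: int = 7,
                        K_max: int = 10, seed: int = 0,
                        **fit_kwargs) -> CVResult:
    """Repeated balanced random sub-sampling CV of the LFDA-GMM pipeline.

    Per iteration, ``floor(pct_train% * least-populated-class size)`` rows
    per class train the full stack and an equally balanced disjoint set is
    scored; confusion counts are pooled over iterations.
    """
    if fm.y is None:
        raise UsageError("feature matrix has no labels")
    if not 0 < pct_train < 100:
        raise UsageError("pct_train must lie in (0, 100)")
    y = np.asarray(fm.y, dtype=object)
    labels = sorted(np.unique(y).tolist())
    accs = np.empty(n_iter)
    pooled = ConfusionMatrix(labels, np.zeros((len(labels), len(labels)), int))
    ss = np.random.SeedSequence(seed)
    iter_seeds = ss.generate_state(n_iter) >> 12  # keep derived seeds small
    for i in range(n_iter):
        rng = np.random.default_rng(iter_seeds[i])
        tr, te = _balanced_split(y, pct_train, rng)
        clf = GMMClassifier.fit(fm.X[tr], y[tr], r=r, k_nn=k_nn, K_max=K_max,
                                seed=int(iter_seeds[i]), **fit_kwargs)
        pred = clf.predict(fm.X[te])
        cm = confusion(y[te], pred, labels=labels)
        accs[i] = cm.accuracy
        pooled = pooled + cm
    return CVResult(accuracies=accs, confusion=pooled,
                    params={"pct_train": pct_train, "n_iter": n_iter, "r": r,
                            "k_nn": k_nn, "K_max": K_max, "seed": seed})


@dataclass
class ForwardSelectionResult:
    """Greedy channel ranking with its cross-validated accuracy curve."""

    order: list[str]
    curve: pd.DataFrame  # one row per SCL size: channel, mean, sd, se


def forward_select(fm: FeatureMatrix, *, r: int = 10, k_nn: int = 7,
                   K_max: int = 10, pct_train: float = 50.0,
                   inner_iter: int = 3, final_iter: int = 30,
                   seed: int = 0, **fit_kwargs) -> ForwardSelectionResult:
    """Greedy forward selection of EEG channels by CV accuracy.

    Each candidate set is scored with a light inner CV (``inner_iter``
    iterations); the accuracy curve along the final ranking is re-estimated
    with ``final_iter`` iterations. A channel contributes all ``l`` of its
    lag columns at once. Ties break to the earlier channel label.
    The reduced dimension is capped at the candidate set's column count.
    """
    if len(fm.channel_labels) < 2:
        raise UsageError("forward selection needs at least 2 channels")
    remaining = list(fm.channel_labels)
    selected: list[str] = []
    while remaining:
        best_lab, best_acc = None, -np.inf
        for lab in remaining:
            sub = fm.restrict_channels(selected + [lab])
            res = random_subsample_cv(
                sub, pct_train=pct_train, n_iter=inner_iter,
                r=min(r, sub.X.shape[1]), k_nn=k_nn, K_max=K_max,
                seed=seed, **fit_kwargs)
            if res.mean > best_acc:
                best_lab, best_acc = lab, res.mean
        selected.append(best_lab)
        remaining.remove(best_lab)
    rows = []
    for i in range(1, len(selected) + 1):
        sub = fm.restrict_channels(selected[:i])
        res = random_subsample_cv(
            sub, pct_train=pct_train, n_iter=final_iter,
            r=min(r, sub.X.shape[1]), k_nn=k_nn, K_max=K_max,
            seed=seed + 1, **fit_kwargs)
        rows.append({"channel": selected[i - 1], "n_channels": i,
                     "mean": res.mean, "sd": res.sd, "se": res.se})
    return ForwardSelectionResult(order=selected, curve=pd.DataFrame(rows))


def training_size_sweep(fm: FeatureMatrix, *,
                        pcts=tuple(range(20, 100, 10)),
                        n_iter: int = 10, r: int, k_nn: int = 7,
                        K_max: int = 10, seed: int = 0,
                        **fit_kwargs) -> pd.DataFrame:
    """Mean +/- SD CV accuracy as a function of the training percentage."""
    rows = []
    for pct in pcts:
        if not 0 < pct < 100:
            raise UsageError(f"training percentage {pct} outside (0, 100)")
        res = random_subsample_cv(fm, pct_train=pct, n_iter=n_iter, r=r,
                                  k_nn=k_nn, K_max=K_max, seed=seed,
                                  **fit_kwargs)
        rows.append({"pct_train": pct, "mean": res.mean, "sd": res.sd,
                     "se": res.se})
    return pd.DataFrame(rows)
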