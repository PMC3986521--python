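"""Per-class Gaussian mixture models with EM fitting and BIC order selection.

Each class is modeled as ``p(x) = sum_k alpha_k phi_k(x)`` with full-covariance
Gaussian components ``phi_k``. For every candidate component count
``K in {1..K_max}`` the parameters are initialized from a seeded k-means
partition and refined by expectation-maximization until the log-likelihood
improvement falls below a relative tolerance; the ``K`` minimizing the BIC is
retained. Classification assigns a point to the class whose mixture density
is largest (equal class priors; the cross-validation design keeps classes
balanced).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .errors import FitError, NumericError, UsageError
from .lfda import LFDAModel, fit_lfda

__all__ = ["GaussianComponent", "ClassGMM", "GMMClassifier",
           "log_likelihood", "bic", "fit_class_gmm"]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class GaussianComponent:
    """One mixture component: weight ``alpha``, mean ``mu``, covariance
    ``Sigma`` (symmetric positive definite)."""

    weight: float
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        if not 0.0 < self.weight <= 1.0 + 1e-12:
            raise UsageError(f"mixing weight {self.weight} outside (0, 1]")
        if self.cov.shape != (self.mean.size, self.mean.size):
            raise UsageError("covariance shape does not match mean")


@dataclass
class ClassGMM:
    """Gaussian mixture for one class."""

    components: list[GaussianComponent]
    class_label: str | None = None
    #: (K, log-likelihood, BIC) rows of the model-order search, if selected.
    selection: list[tuple[int, float, float]] = field(default_factory=list)

    def __post_init__(self):
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise UsageError(f"mixing weights sum to {total}, not 1")

    @property
    def K(self) -> int:
        return len(self.components)

    @property
    def dim(self) -> int:
        return self.components[0].mean.size


def _chol_logdet(cov: np.ndarray, jitter: float = 1e-6):
    """Cholesky factor and log-determinant, with diagonal jitter fallback."""
    try:
        L = linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError:
        scale = np.mean(np.diag(cov))
        if not np.isfinite(scale) or scale <= 0:
            raise NumericError("covariance is not positive definite "
                               f"(mean diagonal {scale})")
        try:
            L = linalg.cholesky(cov + jitter * scale * np.eye(cov.shape[0]),
                                lower=True)
        except linalg.LinAlgError:
            raise NumericError("covariance remains singular after jitter")
    return L, 2.0 * np.sum(np.log(np.diag(L)))


def _log_gauss(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    L, logdet = _chol_logdet(cov)
    z = linalg.solve_triangular(L, (X - mean).T, lower=True)
    return -0.5 * (X.shape[1] * _LOG2PI + logdet + np.sum(z * z, axis=0))


def _log_components(gmm: ClassGMM, X: np.ndarray) -> np.ndarray:
    """log(alpha_k phi_k(x_i)) as an (n, K) array."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != gmm.dim:
        raise UsageError(f"X has {X.shape[1]} columns; model is {gmm.dim}-D")
    out = np.empty((X.shape[0], gmm.K))
    for k, comp in enumerate(gmm.components):
        out[:, k] = np.log(comp.weight) + _log_gauss(X, comp.mean, comp.cov)
    return out


def log_density(gmm: ClassGMM, X: np.ndarray) -> np.ndarray:
    """Per-row log mixture density ``log p(x_i)``."""
    return logsumexp(_log_components(gmm, X), axis=1)


def log_likelihood(gmm: ClassGMM, X: np.ndarray) -> float:
    """Total log-likelihood ``sum_i log p(x_i)`` of the rows of X."""
    return float(np.sum(log_density(gmm, X)))


def n_free_parameters(K: int, r: int) -> int:
    """Free parameters of a K-component full-covariance mixture in r dims."""
    return (K - 1) + K * r + K * r * (r + 1) // 2


def bic(gmm: ClassGMM, X: np.ndarray, mode: str = "standard") -> float:
    """Bayesian information criterion of a fitted mixture on data X.

    ``mode="standard"`` uses ``-2 L + p log n`` with the full free-parameter
    count ``p``. ``mode="as-printed"`` uses ``-2 L + 2 log n``, a fixed
    complexity term independent of K that therefore never penalizes larger
    mixtures; it is kept selectable for comparability but is not the default.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise UsageError("BIC needs at least 2 samples")
    L = log_likelihood(gmm, X)
    if mode == "standard":
        p = n_free_parameters(gmm.K, gmm.dim)
        return -2.0 * L + p * np.log(n)
    if mode == "as-printed":
        return -2.0 * L + 2.0 * np.log(n)
    raise UsageError(f"unknown BIC mode {mode!r}")


def _kmeans_init(X: np.ndarray, K: int, seed: int, jitter: float):
    n, r = X.shape
    seed = int(seed) % (2 ** 31)
    if K == 1:
        labels = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=K, n_init=1, random_state=seed)
        labels = km.fit_predict(X)
    comps = []
    fallback = np.cov(X.T, ddof=0) + jitter * np.eye(r)
    fallback = np.atleast_2d(fallback)
    for k in range(K):
        rows = X[labels == k]
        if rows.shape[0] == 0:
            comps.append((1.0 / (10 * n), X[np.random.default_rng(seed + k)
                                            .integers(n)], fallback))
            continue
        mean = rows.mean(axis=0)
        if rows.shape[0] > r:
            cov = np.cov(rows.T, ddof=0) + jitter * np.eye(r)
        else:
            cov = fallback
        comps.append((rows.shape[0] / n, mean, np.atleast_2d(cov)))
    total = sum(w for w, _, _ in comps)
    return [(w / total, m, c) for w, m, c in comps]


def _em(X: np.ndarray, init, tol: float, max_iter: int, jitter: float):
    """Run EM from an initial (weight, mean, cov) list; returns params + LL.

    The log-likelihood is asserted non-decreasing at every iteration.
    """
    n, r = X.shape
    weights = np.array([w for w, _, _ in init])
    means = np.array([m for _, m, _ in init])
    covs = np.array([c for _, _, c in init])
    prev_ll = -np.inf
    ll = -np.inf
    for _ in range(max_iter):
        # E step
        log_wp = np.empty((n, len(weights)))
        for k in range(len(weights)):
            log_wp[:, k] = np.log(weights[k]) + _log_gauss(X, means[k], covs[k])
        log_norm = logsumexp(log_wp, axis=1)
        ll = float(np.sum(log_norm))
        if not np.isfinite(ll):
            raise NumericError("EM log-likelihood became non-finite")
        if ll < prev_ll - 1e-8 * (1.0 + abs(prev_ll)):
            raise NumericError(
                f"EM log-likelihood decreased: {prev_ll} -> {ll}")
        if np.isfinite(prev_ll) and (ll - prev_ll) <= tol * abs(ll):
            break
        prev_ll = ll
        resp = np.exp(log_wp - log_norm[:, None])
        # M step
        Nk = resp.sum(axis=0) + 1e-300
        weights = Nk / n
        means = (resp.T @ X) / Nk[:, None]
        for k in range(len(weights)):
            diff = X - means[k]
            covs[k] = (diff.T * resp[:, k]) @ diff / Nk[k]
            covs[k].flat[:: r + 1] += 1e-12  # numerical floor
    return weights, means, covs, ll


def fit_class_gmm(X: np.ndarray, K_max: int = 10, seed: int = 0, *,
                  n_restarts: int = 1, tol: float = 1e-6, max_iter: int = 500,
                  jitter: float = 1e-6, bic_mode: str = "standard",
                  class_label: str | None = None,
                  init: str = "kmeans") -> ClassGMM:
    """Fit mixtures for ``K = 1..K_max`` and return the BIC-minimizing one.

    ``n_restarts`` seeded k-means initializations are tried per K and the
    best log-likelihood kept. ``init="greedy"`` instead grows the mixture by
    component insertion at the lowest-density training point.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, r = X.shape
    if n < 2:
        raise FitError("need at least 2 rows to fit a mixture")
    if np.allclose(X, X[0], atol=1e-12):
        raise NumericError("all rows identical: covariance is degenerate")
    if n < K_max * (r + 1):
        warnings.warn(f"only {n} rows for K_max={K_max} in {r} dims; "
                      "large-K fits may be ill-conditioned")
    best = None
    selection: list[tuple[int, float, float]] = []
    prev_params = None
    for K in range(1, K_max + 1):
        best_k = None
        if init == "greedy" and K > 1 and prev_params is not None:
            inits = [_insert_component(X, prev_params, jitter)]
        else:
            inits = [_kmeans_init(X, K, seed * 1000 + K * 10 + t, jitter)
                     for t in range(n_restarts)]
        for start in inits:
            try:
                params = _em(X, start, tol, max_iter, jitter)
            except NumericError:
                if K == 1:
                    raise
                continue
            if best_k is None or params[3] > best_k[3]:
                best_k = params
        if best_k is None:
            continue
        prev_params = best_k
        weights, means, covs, ll = best_k
        model = ClassGMM(
            components=[GaussianComponent(w, m, c)
                        for w, m, c in zip(weights, means, covs)],
            class_label=class_label)
        crit = bic(model, X, mode=bic_mode)
        selection.append((K, ll, crit))
        if best is None or crit < best[0]:
            best = (crit, model)
    assert best is not None
    best[1].selection = selection
    return best[1]


def _insert_component(X, params, jitter):
    """Greedy insertion: seed a new component at the worst-explained point."""
    weights, means, covs, _ = params
    model = ClassGMM([GaussianComponent(w, m, c)
                      for w, m, c in zip(weights, means, covs)])
    worst = int(np.argmin(log_density(model, X)))
    K = len(weights)
    new_w = 1.0 / (K + 1)
    scaled = [(w * (1 - new_w), m, c) for w, m, c in zip(weights, means, covs)]
    pooled = np.cov(X.T, ddof=0) + jitter * np.eye(X.shape[1])
    return scaled + [(new_w, X[worst], np.atleast_2d(pooled))]


@dataclass
class GMMClassifier:
    """One mixture per class on top of a shared LFDA transform."""

    models: dict[str, ClassGMM]
    lfda: LFDAModel | None
    K_max: int = 10

    def __post_init__(self):
        dims = {g.dim for g in self.models.values()}
        if len(dims) > 1:
            raise UsageError(f"class models disagree on dimension: {dims}")

    @property
    def class_labels(self) -> list[str]:
        return sorted(self.models)

    @classmethod
    def fit(cls, X: np.ndarray, y: np.ndarray, *, r: int, k_nn: int = 7,
            K_max: int = 10, seed: int = 0, lfda_affinity: str = "local",
            **gmm_kwargs) -> "GMMClassifier":
        """Fit LFDA on the training rows, then one mixture per class on the
        reduced rows of that class."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = sorted(np.unique(y).tolist())
        if len(classes) < 2:
            raise FitError("training labels contain fewer than 2 classes")
        model = fit_lfda(X, y, r=r, k_nn=k_nn, affinity=lfda_affinity,
                         seed=seed)
        Z = model.transform(X)
        models: dict[str, ClassGMM] = {}
        for i, c in enumerate(classes):
            models[str(c)] = fit_class_gmm(
                Z[y == c], K_max=K_max, seed=seed * 100 + i,
                class_label=str(c), **gmm_kwargs)
        return cls(models=models, lfda=model, K_max=K_max)

    def _log_joint(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.lfda is not None:
            X = self.lfda.transform(X)
        out = np.empty((X.shape[0], len(self.class_labels)))
        for j, c in enumerate(self.class_labels):
            out[:, j] = log_density(self.models[c], X)
        return out

    def posterior(self, X: np.ndarray) -> np.ndarray:
        """Per-class posterior probabilities (equal priors), rows sum to 1.

        Columns follow ``class_labels`` (lexicographic order).
        """
        lj = self._log_joint(X)
        return np.exp(lj - logsumexp(lj, axis=1, keepdims=True))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Maximum-posterior class per row; ties break to the
        lexicographically smallest label."""
        lj = self._log_joint(X)
        labels = np.asarray(self.class_labels, dtype=object)
        return labels[np.argmax(lj, axis=1)]

    def save(self, path) -> None:
        payload = {
            "K_max": self.K_max,
            "lfda": None if self.lfda is None else {
                "T": self.lfda.T.tolist(), "r": self.lfda.r,
                "k_nn": self.lfda.k_nn, "d": self.lfda.d,
                "class_labels": self.lfda.class_labels},
            "models": {
                c: [{"weight": comp.weight, "mean": comp.mean.tolist(),
                     "cov": comp.cov.tolist()} for comp in g.components]
                for c, g in self.models.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "GMMClassifier":
        with open(path) as fh:
            payload = json.load(fh)
        lf = payload["lfda"]
        lfda_model = None if lf is None else LFDAModel(
            T=np.asarray(lf["T"]), r=lf["r"], k_nn=lf["k_nn"],
            class_labels=lf["class_labels"], d=lf["d"])
        models = {
            c: ClassGMM([GaussianComponent(p["weight"], np.asarray(p["mean"]),
                                           np.asarray(p["cov"]))
                         for p in comps], class_label=c)
            for c, comps in payload["models"].items()}
        return cls(models=models, lfda=lfda_model, K_max=payload["K_max"])
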