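"""Regression surrogates for shuffle-null statistics.

Estimating a folding Z score honestly means shuffling a sequence many times
and folding every shuffle — far too slow inside a genome scan.  Because the
null mean and standard deviation of both statistics (MFE free energy and
normalized ensemble defect) depend only on sequence length and composition,
they can be regressed once and reused: two epsilon-SVR machines with RBF
kernels per statistic, one for mu and one for sigma, taking
(length, GC, G/(G+C), A/(A+U)) as input.

Hyperparameters are chosen by 5-fold cross-validated grid search; features
are min-max scaled to [-1, 1] and targets standardized before fitting.
Models persist as JSON (support vectors, dual coefficients, intercept and
all scaling metadata), so prediction needs nothing but numpy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVR

from .datagen import random_sequence
from .energy import EnergyModel, default_model
from .features import CompositionFeatures, composition_features, sample_null, z_score
from .rna import RnaSequence

__all__ = [
    "SurrogateModel",
    "generate_training_grid",
    "train_surrogate",
    "evaluate_surrogate",
]

SIGMA_FLOOR = 1e-6

#: 5-fold CV grid (powers of two, stride 2, per standard RBF practice)
DEFAULT_GRID = {
    "C": [2.0 ** e for e in range(-5, 16, 2)],
    "gamma": [2.0 ** e for e in range(-15, 4, 2)],
    "epsilon": [0.01, 0.05, 0.1, 0.2],
}


@dataclass
class _Regressor:
    """A fitted RBF epsilon-SVR, stored as plain arrays."""

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    C: float
    epsilon: float
    y_mean: float
    y_std: float

    def predict(self, x_scaled: np.ndarray) -> np.ndarray:
        d2 = ((self.support_vectors[None, :, :] - x_scaled[:, None, :]) ** 2).sum(axis=2)
        k = np.exp(-self.gamma * d2)
        return (k @ self.dual_coef + self.intercept) * self.y_std + self.y_mean

    def to_dict(self) -> dict:
        return {
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "gamma": self.gamma,
            "C": self.C,
            "epsilon": self.epsilon,
            "y_mean": self.y_mean,
            "y_std": self.y_std,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "_Regressor":
        return cls(
            np.asarray(d["support_vectors"]),
            np.asarray(d["dual_coef"]),
            d["intercept"], d["gamma"], d["C"], d["epsilon"], d["y_mean"], d["y_std"],
        )


@dataclass
class SurrogateModel:
    """mu- and sigma-regressors for one statistic kind plus their metadata."""

    statistic: str                    # "energy" | "defect"
    mu_model: _Regressor
    sigma_model: _Regressor
    feature_min: np.ndarray           # scaling of (length, gc, g/gc, a/au)
    feature_max: np.ndarray
    n_shuffles: int
    n_training: int

    def _scale(self, feats: np.ndarray) -> np.ndarray:
        span = np.where(self.feature_max > self.feature_min, self.feature_max - self.feature_min, 1.0)
        return 2.0 * (feats - self.feature_min) / span - 1.0

    def in_range(self, feats: CompositionFeatures, slack: float = 0.25) -> bool:
        """Whether a sequence's features lie within (or near) the trained box."""
        x = feats.as_array()
        span = np.maximum(self.feature_max - self.feature_min, 1e-12)
        return bool(np.all(x >= self.feature_min - slack * span)
                    and np.all(x <= self.feature_max + slack * span))

    def predict_mu_sigma(self, feats: CompositionFeatures):
        """Deterministic (mu_hat, sigma_hat); a pure function of composition,
        with sigma_hat clipped to a positive floor."""
        x = self._scale(feats.as_array()[None, :])
        mu = float(self.mu_model.predict(x)[0])
        sigma = max(float(self.sigma_model.predict(x)[0]), SIGMA_FLOOR)
        return mu, sigma

    def predict_z(self, seq: RnaSequence, value: float) -> float:
        mu, sigma = self.predict_mu_sigma(composition_features(seq))
        return (value - mu) / sigma

    # -- persistence --------------------------------------------------------
    def to_json(self, path) -> None:
        doc = {
            "kind": "multifind-zsurrogate",
            "statistic": self.statistic,
            "mu_model": self.mu_model.to_dict(),
            "sigma_model": self.sigma_model.to_dict(),
            "feature_min": self.feature_min.tolist(),
            "feature_max": self.feature_max.tolist(),
            "n_shuffles": self.n_shuffles,
            "n_training": self.n_training,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "SurrogateModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            statistic=doc["statistic"],
            mu_model=_Regressor.from_dict(doc["mu_model"]),
            sigma_model=_Regressor.from_dict(doc["sigma_model"]),
            feature_min=np.asarray(doc["feature_min"]),
            feature_max=np.asarray(doc["feature_max"]),
            n_shuffles=doc["n_shuffles"],
            n_training=doc["n_training"],
        )


# ---------------------------------------------------------------------------
# training data

def generate_training_grid(
    n_seqs: int = 500,
    length_range: tuple = (30, 150),
    gc_range: tuple = (0.25, 0.75),
    g_of_gc_range: tuple = (0.25, 0.75),
    a_of_au_range: tuple = (0.25, 0.75),
    rng: np.random.Generator | None = None,
) -> list:
    """Random sequences stratified over the 4-D (length, GC, G/GC, A/AU) box.

    Uses a scrambled lattice: each axis is divided evenly and strata visited
    in shuffled order, so marginals span the requested ranges at any count.
    """
    rng = rng if rng is not None else np.random.default_rng()
    axes = []
    for lo, hi in (length_range, gc_range, g_of_gc_range, a_of_au_range):
        u = (np.arange(n_seqs) + rng.random(n_seqs)) / n_seqs
        rng.shuffle(u)
        axes.append(lo + u * (hi - lo))
    seqs = []
    for k in range(n_seqs):
        length = int(round(axes[0][k]))
        seqs.append(
            random_sequence(length, axes[1][k], axes[2][k], axes[3][k], rng, id=f"grid{k}")
        )
    return seqs


def _null_table(seqs, statistic, n_shuffles, model, rng):
    feats = np.array([composition_features(s).as_array() for s in seqs])
    mus, sigmas = [], []
    for seq in seqs:
        null = sample_null(seq, statistic, n_shuffles, model, rng)
        mus.append(null.mu)
        sigmas.append(null.sigma)
    return feats, np.array(mus), np.array(sigmas)


def _fit_svr(x_scaled, y, grid, cv=5) -> _Regressor:
    y_mean, y_std = float(y.mean()), float(y.std())
    if y_std < 1e-12:
        raise ValueError("degenerate target variance; cannot train surrogate")
    yz = (y - y_mean) / y_std
    # iteration cap bounds the few pathological large-C grid cells; the
    # winning cells converge far below it
    search = GridSearchCV(SVR(kernel="rbf", max_iter=100_000), grid, cv=cv, n_jobs=None)
    with np.errstate(all="ignore"):
        import warnings as _warnings

        with _warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            _warnings.simplefilter("ignore", ConvergenceWarning)
            search.fit(x_scaled, yz)
    best = search.best_estimator_
    if getattr(best, "fit_status_", 0) != 0 or best.n_iter_ >= 100_000:
        best = SVR(kernel="rbf", **search.best_params_)
        best.fit(x_scaled, yz)
    return _Regressor(
        support_vectors=best.support_vectors_.copy(),
        dual_coef=best.dual_coef_.ravel().copy(),
        intercept=float(best.intercept_[0]),
        gamma=float(best._gamma),
        C=float(best.C),
        epsilon=float(best.epsilon),
        y_mean=y_mean,
        y_std=y_std,
    )


def train_surrogate(
    seqs: list,
    statistic: str,
    n_shuffles: int = 100,
    model: EnergyModel | None = None,
    rng: np.random.Generator | None = None,
    grid: dict | None = None,
) -> SurrogateModel:
    """Sample nulls for every training sequence and fit the mu/sigma SVRs."""
    if len(seqs) < 50:
        raise ValueError("need at least 50 training sequences")
    model = model or default_model()
    rng = rng if rng is not None else np.random.default_rng()
    grid = grid or DEFAULT_GRID

    feats, mus, sigmas = _null_table(seqs, statistic, n_shuffles, model, rng)
    fmin, fmax = feats.min(axis=0), feats.max(axis=0)
    span = np.where(fmax > fmin, fmax - fmin, 1.0)
    x = 2.0 * (feats - fmin) / span - 1.0

    return SurrogateModel(
        statistic=statistic,
        mu_model=_fit_svr(x, mus, grid),
        sigma_model=_fit_svr(x, sigmas, grid),
        feature_min=fmin,
        feature_max=fmax,
        n_shuffles=n_shuffles,
        n_training=len(seqs),
    )


def evaluate_surrogate(
    surrogate: SurrogateModel,
    test_seqs: list,
    n_shuffles: int = 100,
    model: EnergyModel | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Pearson correlation between surrogate-predicted and shuffle-sampled
    Z scores on held-out sequences."""
    if len(test_seqs) < 10:
        raise ValueError("need at least 10 test sequences")
    model = model or default_model()
    rng = rng if rng is not None else np.random.default_rng()
    from .features import _statistic  # statistic evaluator shared with sampling

    sampled, predicted = [], []
    for seq in test_seqs:
        value = _statistic(seq, surrogate.statistic, model)
        null = sample_null(seq, surrogate.statistic, n_shuffles, model, rng)
        sampled.append(z_score(value, null))
        predicted.append(surrogate.predict_z(seq, value))
    return float(np.corrcoef(sampled, predicted)[0, 1])
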