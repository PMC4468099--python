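"""ncRNA group classification.

A C-SVC with RBF kernel, trained on FeatureVectors of positive (structured)
and negative (column-shuffled) groups, emitting the probability that a
group of aligned sequences is a conserved structured ncRNA.  Probability
calibration uses the standard libsvm-style sigmoid (Platt) fit provided by
scikit-learn's ``probability=True``; the fitted machine is persisted as
JSON (support vectors, dual coefficients, sigmoid parameters) so a stored
model reproduces its probabilities without pickle.

The ``use_defect=False`` variant drops the ensemble-defect Z feature,
training the three-feature machine for ablation comparisons.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import GridSearchCV
from sklearn.svm import SVC

from .features import FeatureVector

__all__ = ["ClassifierModel", "train_classifier", "cross_validate"]

def _centered(exponents, middle):
    """Powers of two ordered by distance from a sensible middle, so that
    cross-validation ties (common on cleanly separable data) resolve to a
    moderate model instead of a grid corner."""
    return [2.0 ** e for e in sorted(exponents, key=lambda e: (abs(e - middle), e))]


#: 5-fold CV grid for (C, gamma), powers of two
DEFAULT_GRID = {
    "C": _centered(range(-5, 16, 2), 3),
    "gamma": _centered(range(-15, 4, 2), -1),
}

FULL_FEATURES = ("sci", "energy_z", "defect_z", "entropy")
NO_DEFECT_FEATURES = ("sci", "energy_z", "entropy")


@dataclass
class ClassifierModel:
    """A probability-calibrated RBF SVC stored as plain arrays."""

    use_defect: bool
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    C: float
    prob_a: float
    prob_b: float
    feature_min: np.ndarray
    feature_max: np.ndarray
    positive_is_class1: bool

    @property
    def feature_names(self) -> tuple:
        return FULL_FEATURES if self.use_defect else NO_DEFECT_FEATURES

    def _scale(self, x: np.ndarray) -> np.ndarray:
        span = np.where(self.feature_max > self.feature_min, self.feature_max - self.feature_min, 1.0)
        return 2.0 * (x - self.feature_min) / span - 1.0

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        xs = self._scale(np.atleast_2d(x))
        d2 = ((self.support_vectors[None, :, :] - xs[:, None, :]) ** 2).sum(axis=2)
        return np.exp(-self.gamma * d2) @ self.dual_coef + self.intercept

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """P(ncRNA) per row of x (feature matrix in this model's order)."""
        f = self.decision_function(x)
        p1 = 1.0 / (1.0 + np.exp(self.prob_a * f + self.prob_b))
        return p1 if self.positive_is_class1 else 1.0 - p1

    def classify(self, fv: FeatureVector, threshold: float = 0.5):
        """Probability that the group is a structured ncRNA, plus the label
        at the given threshold."""
        x = fv.as_array(self.use_defect)
        if x.shape[-1] != self.support_vectors.shape[1]:
            raise ValueError("feature-count mismatch with trained model")
        p = float(self.predict_proba(x)[0])
        return p, p >= threshold

    # -- persistence --------------------------------------------------------
    def to_json(self, path) -> None:
        doc = {
            "kind": "multifind-classifier",
            "use_defect": self.use_defect,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "gamma": self.gamma,
            "C": self.C,
            "prob_a": self.prob_a,
            "prob_b": self.prob_b,
            "feature_min": self.feature_min.tolist(),
            "feature_max": self.feature_max.tolist(),
            "positive_is_class1": self.positive_is_class1,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_json(cls, path) -> "ClassifierModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            use_defect=doc["use_defect"],
            support_vectors=np.asarray(doc["support_vectors"]),
            dual_coef=np.asarray(doc["dual_coef"]),
            intercept=doc["intercept"],
            gamma=doc["gamma"],
            C=doc["C"],
            prob_a=doc["prob_a"],
            prob_b=doc["prob_b"],
            feature_min=np.asarray(doc["feature_min"]),
            feature_max=np.asarray(doc["feature_max"]),
            positive_is_class1=doc["positive_is_class1"],
        )


def _to_matrix(fvs, use_defect: bool) -> np.ndarray:
    return np.array([fv.as_array(use_defect) for fv in fvs])


def train_classifier(
    positives,
    negatives,
    grid: dict | None = None,
    use_defect: bool = True,
    rng: np.random.Generator | None = None,
    min_each: int = 50,
) -> ClassifierModel:
    """Fit the probability-calibrated RBF SVC on labeled FeatureVectors.

    Features are min-max scaled to [-1, 1] on the training data; (C, gamma)
    chosen by 5-fold cross-validated grid search.  Warns (does not fail) on
    class imbalance beyond 10%.
    """
    grid = grid or DEFAULT_GRID
    if min(len(positives), len(negatives)) < min_each:
        raise ValueError(f"need at least {min_each} examples per class")
    n_p, n_n = len(positives), len(negatives)
    if abs(n_p - n_n) > 0.1 * max(n_p, n_n):
        warnings.warn(f"class imbalance: {n_p} positives vs {n_n} negatives")

    x = np.vstack([_to_matrix(positives, use_defect), _to_matrix(negatives, use_defect)])
    y = np.concatenate([np.ones(n_p, dtype=int), np.zeros(n_n, dtype=int)])
    fmin, fmax = x.min(axis=0), x.max(axis=0)
    span = np.where(fmax > fmin, fmax - fmin, 1.0)
    xs = 2.0 * (x - fmin) / span - 1.0

    seed = int(rng.integers(0, 2**31 - 1)) if rng is not None else 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        search = GridSearchCV(SVC(kernel="rbf"), grid, cv=5, n_jobs=None)
        search.fit(xs, y)
        best = SVC(
            kernel="rbf", C=search.best_params_["C"], gamma=search.best_params_["gamma"],
            probability=True, random_state=seed,
        )
        best.fit(xs, y)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        model = ClassifierModel(
            use_defect=use_defect,
            support_vectors=best.support_vectors_.copy(),
            dual_coef=best.dual_coef_.ravel().copy(),
            intercept=float(best.intercept_[0]),
            gamma=float(best._gamma),
            C=float(best.C),
            prob_a=float(best.probA_[0]),
            prob_b=float(best.probB_[0]),
            feature_min=fmin,
            feature_max=fmax,
            positive_is_class1=True,
        )
    # orient the sigmoid against sklearn's own calibrated output
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        ref = best.predict_proba(xs)[:, list(best.classes_).index(1)]
    ours = model.predict_proba(x)
    if np.abs(ours - ref).mean() > np.abs((1.0 - ours) - ref).mean():
        model.positive_is_class1 = False
    return model


def classify(model: ClassifierModel, fv: FeatureVector, threshold: float = 0.5):
    """Module-level convenience wrapper over :meth:`ClassifierModel.classify`."""
    return model.classify(fv, threshold)


def cross_validate(
    family_ids,
    k_rounds: int = 4,
    test_fraction: float = 0.1,
    rng: np.random.Generator | None = None,
):
    """Family-disjoint train/test splits.

    ``family_ids`` assigns a family label to every group.  Families are
    shuffled once; each round claims whole families for its test set until
    about ``test_fraction`` of all groups is reached, so no family appears
    in two test sets nor on both sides of one split.  Returns a list of
    (train_indices, test_indices) pairs.
    """
    rng = rng if rng is not None else np.random.default_rng()
    family_ids = np.asarray(family_ids)
    families = list(dict.fromkeys(family_ids))  # stable unique order
    if len(families) < k_rounds:
        raise ValueError("fewer families than rounds")
    order = list(rng.permutation(families))
    n_total = len(family_ids)
    target = test_fraction * n_total

    splits, cursor = [], 0
    for _ in range(k_rounds):
        test_fams, count = [], 0
        while cursor < len(order) and count < target:
            fam = order[cursor]
            size = int((family_ids == fam).sum())
            # stop short when adding the family would overshoot the target
            # by more than staying under it
            if test_fams and (count + size) - target >= target - count:
                break
            cursor += 1
            test_fams.append(fam)
            count += size
        if not test_fams:
            raise ValueError("ran out of families while building test sets")
        mask = np.isin(family_ids, test_fams)
        splits.append((np.flatnonzero(~mask), np.flatnonzero(mask)))
    return splits
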