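"""Reproducible benchmark protocols.

Two self-contained experiments exercise the pipeline end to end on
synthetic data, at sizes chosen for a single desktop CPU:

* :func:`surrogate_recovery` — train the mu/sigma regression surrogate for
  one null statistic on composition-stratified random sequences (500
  sequences, 100 shuffles each by default) and measure the Pearson
  correlation between surrogate-predicted and shuffle-sampled Z scores on
  fresh sequences.  Held-out reference Z scores use 1,000-shuffle nulls, the
  sampling depth at which the reference itself is precise enough for
  correlations in the 0.99+ range to be resolved.
* :func:`classifier_separation` — generate structured families and their
  column-shuffled negatives, compute feature vectors, train the classifier
  on a family-disjoint split, and report held-out AUC for the four-feature
  and the no-defect-Z variants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import cross_validate, train_classifier
from .datagen import random_family_template, sample_structured_family, shuffle_alignment_columns
from .energy import default_model
from .features import feature_vector
from .genomescan import roc_curve
from .zsurrogate import evaluate_surrogate, generate_training_grid, train_surrogate


@dataclass
class SurrogateRecoveryResult:
    statistic: str
    r: float
    n_train: int
    n_test: int
    train_shuffles: int
    eval_shuffles: int


def surrogate_recovery(
    statistic: str,
    seed: int,
    n_train: int = 500,
    n_test: int = 100,
    train_shuffles: int = 100,
    eval_shuffles: int = 1000,
    length_range: tuple = (30, 60),
) -> SurrogateRecoveryResult:
    """Train a Z-score surrogate and correlate predicted against sampled Z
    on held-out composition-stratified sequences."""
    model = default_model()
    rng = np.random.default_rng(seed)
    train = generate_training_grid(n_train, length_range, rng=rng)
    test = generate_training_grid(n_test, length_range, rng=rng)
    surrogate = train_surrogate(train, statistic, n_shuffles=train_shuffles,
                                model=model, rng=rng)
    r = evaluate_surrogate(surrogate, test, n_shuffles=eval_shuffles, model=model, rng=rng)
    return SurrogateRecoveryResult(
        statistic, r, n_train, n_test, train_shuffles, eval_shuffles
    )


@dataclass
class SeparationResult:
    auc_with_defect: float
    auc_without_defect: float
    n_train_groups: int
    n_test_groups: int
    model: object = None  # the trained four-feature ClassifierModel


def classifier_separation(
    seed: int,
    n_families: int = 12,
    groups_per_family: int = 10,
    n_shuffles: int = 30,
    test_fraction: float = 0.25,
) -> SeparationResult:
    """Structured families versus column-shuffled negatives, evaluated on
    held-out families.

    Feature vectors use shuffle-sampled nulls.  One family-disjoint split
    holds out ``test_fraction`` of the groups; both classifier variants
    (with and without the ensemble-defect Z feature) are trained on the
    remainder and scored on the held-out groups by ROC AUC.
    """
    rng = np.random.default_rng(seed)
    model = default_model()

    features_pos, features_neg, families = [], [], []
    for f in range(n_families):
        tpl = random_family_template(rng, family_id=f"fam{f}")
        for _ in range(groups_per_family):
            n_seqs = int(rng.integers(3, 7))
            pos = sample_structured_family(tpl, n_seqs, rng)
            neg = shuffle_alignment_columns(pos, rng)
            features_pos.append(feature_vector(pos, z_source="sampled",
                                               n_shuffles=n_shuffles, model=model, rng=rng))
            features_neg.append(feature_vector(neg, z_source="sampled",
                                               n_shuffles=n_shuffles, model=model, rng=rng))
            families.append(tpl.family_id)

    (train_idx, test_idx), = cross_validate(families, k_rounds=1,
                                            test_fraction=test_fraction, rng=rng)
    train_pos = [features_pos[i] for i in train_idx]
    train_neg = [features_neg[i] for i in train_idx]
    test_fvs = [features_pos[i] for i in test_idx] + [features_neg[i] for i in test_idx]
    labels = [True] * len(test_idx) + [False] * len(test_idx)

    aucs, models = {}, {}
    for use_defect in (True, False):
        clf = train_classifier(train_pos, train_neg, use_defect=use_defect, rng=rng)
        scores = [clf.classify(fv)[0] for fv in test_fvs]
        aucs[use_defect] = roc_curve(scores, labels).auc
        models[use_defect] = clf
    return SeparationResult(
        aucs[True], aucs[False], 2 * len(train_idx), 2 * len(test_idx), models[True]
    )
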