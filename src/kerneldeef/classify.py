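"""Supervised donor classification on theta coordinates.

Workflow: subsample cells from every donor (train and test jointly — the
embedding is unsupervised), build one Gram matrix, decompose, keep the
positive-eigenvalue axes, grid-search a gradient-boosted-tree classifier over
tree depth and the number of leading axes, and repeat the whole loop over
independent cell resamplings, combining test predictions by majority vote.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.model_selection import StratifiedKFold

from .deef import deef_decompose, positive_axes
from .io_preprocess import DonorProfile
from .kernel_embedding import (
    build_gram_matrix,
    default_gamma,
    subsample_cells,
    subsampling_seed,
)

__all__ = [
    "ClassifierConfig",
    "PredictionResult",
    "select_and_fit",
    "ensemble_predict",
    "concatenate_conditions",
    "train_test_split_donors",
]


def _default_learner(n_estimators: int, max_depth: int, seed: int):
    # Reference configuration uses a gradient-boosted tree ensemble with the
    # same (n_estimators, max_depth) knobs as the published settings.
    return GradientBoostingClassifier(
        n_estimators=n_estimators, max_depth=max_depth, random_state=seed
    )


@dataclass(frozen=True)
class ClassifierConfig:
    """Knobs of the supervised workflow.

    ``learner_factory(n_estimators, max_depth, seed)`` must return an object
    with sklearn-style ``fit``/``predict``; the default is a gradient-boosted
    tree classifier.
    """

    n_estimators: int = 5000
    max_depth_grid: tuple[int, ...] = (2, 3, 4, 5)
    cv_folds: int = 5
    patience: int = 11
    n_resamplings: int = 25
    n_cells: int = 1000
    gamma: float | None = None
    max_k: int | None = None  # optional cap on the axis search (None = all axes)
    learner_factory: Callable = _default_learner

    def __post_init__(self) -> None:
        if self.n_resamplings % 2 == 0:
            raise ValueError(
                "n_resamplings must be odd so a binary majority vote cannot tie"
            )
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class PredictionResult:
    """Per-resampling and majority-vote ensemble predictions."""

    donor_ids: list[str]
    per_resampling_labels: np.ndarray  # (n_resamplings, n_test) object array
    ensemble_labels: np.ndarray
    chosen_hyperparams: list[dict]  # per resampling: max_depth, k_coords, cv score
    per_resampling_accuracy: np.ndarray | None = None
    ensemble_accuracy: float | None = None
    tie_broken: list[str] = field(default_factory=list)


def _cv_accuracy(
    X: np.ndarray, y: np.ndarray, depth: int, config: ClassifierConfig, seed: int
) -> float:
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True, random_state=seed)
    accs = []
    for tr, va in skf.split(X, y):
        model = config.learner_factory(config.n_estimators, depth, seed)
        model.fit(X[tr], y[tr])
        accs.append(float(np.mean(model.predict(X[va]) == y[va])))
    return float(np.mean(accs))


def select_and_fit(
    theta_train: np.ndarray,
    labels_train: Sequence[str],
    config: ClassifierConfig | None = None,
    seed: int = 0,
):
    """Incremental search over the number of leading axes with early stop.

    For k = 1, 2, ... the first k columns are cross-validated over the tree
    depth grid; the search stops once the best score seen has gone more than
    ``patience`` consecutive k values without improving.  Ties favour the
    smaller depth, then the smaller k.  Returns
    ``(fitted model, {"max_depth", "k_coords", "cv_score"})``.
    """
    config = config or ClassifierConfig()
    X = np.asarray(theta_train, dtype=np.float64)
    y = np.asarray(labels_train)
    counts = Counter(y)
    if len(counts) < 2:
        raise ValueError("training labels contain a single class")
    if min(counts.values()) < config.cv_folds:
        raise ValueError(
            f"stratified {config.cv_folds}-fold CV impossible: smallest class "
            f"has {min(counts.values())} donors"
        )
    best_score = -np.inf
    best_k = best_depth = None
    since_improve = 0
    k_max = X.shape[1] if config.max_k is None else min(config.max_k, X.shape[1])
    for k in range(1, k_max + 1):
        for depth in sorted(config.max_depth_grid):
            score = _cv_accuracy(X[:, :k], y, depth, config, seed)
            if score > best_score:
                best_score, best_k, best_depth = score, k, depth
                since_improve = -1  # reset; bumped to 0 below
        since_improve += 1
        if since_improve > config.patience:
            break
    model = config.learner_factory(config.n_estimators, best_depth, seed)
    model.fit(X[:, :best_k], y)
    return model, {"max_depth": best_depth, "k_coords": best_k, "cv_score": best_score}


def _majority_vote(votes: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Column-wise mode of a (n_reps, n_test) label array.

    Multi-class ties are broken by the highest mean class frequency across
    all test donors, then lexicographically; tied donors are reported.
    """
    n_reps, n_test = votes.shape
    overall = Counter(votes.ravel().tolist())
    out = np.empty(n_test, dtype=object)
    tied: list[str] = []
    for j in range(n_test):
        c = Counter(votes[:, j].tolist())
        top = max(c.values())
        cands = sorted([lab for lab, v in c.items() if v == top])
        if len(cands) > 1:
            cands.sort(key=lambda lab: (-overall[lab], lab))
            tied.append(str(j))
        out[j] = cands[0]
    return out, tied


def ensemble_predict(
    train_profiles: Sequence[DonorProfile],
    train_labels: Sequence[str],
    test_profiles: Sequence[DonorProfile],
    config: ClassifierConfig | None = None,
    master_seed: int = 0,
    test_labels: Sequence[str] | None = None,
) -> PredictionResult:
    """Resampling-ensemble prediction of test-donor labels.

    Every repetition redraws cells from all donors (train and test), rebuilds
    the joint embedding, reselects hyper-parameters on the training rows and
    predicts the test rows; the final label is the per-donor majority vote.
    A failing repetition aborts the run — repetitions are never silently
    skipped.
    """
    config = config or ClassifierConfig()
    profiles = list(train_profiles) + list(test_profiles)
    n_train = len(train_profiles)
    y_train = np.asarray(train_labels)
    all_votes = np.empty((config.n_resamplings, len(test_profiles)), dtype=object)
    chosen = []
    for rep in range(config.n_resamplings):
        samples = [
            subsample_cells(prof, config.n_cells, subsampling_seed(master_seed, i, rep))
            for i, prof in enumerate(profiles)
        ]
        gamma = config.gamma if config.gamma is not None else default_gamma(samples[0].p)
        gram = build_gram_matrix(samples, gamma)
        theta_pos = positive_axes(deef_decompose(gram))
        fit_seed = int(
            np.random.SeedSequence([master_seed, rep, 10**6]).generate_state(1)[0]
            % (2**31 - 1)
        )
        model, params = select_and_fit(
            theta_pos[:n_train], y_train, config, seed=fit_seed
        )
        k = params["k_coords"]
        all_votes[rep] = model.predict(theta_pos[n_train:, :k])
        chosen.append(params)
    ensemble, tie_broken = _majority_vote(all_votes)
    per_acc = ens_acc = None
    if test_labels is not None:
        y_test = np.asarray(test_labels)
        per_acc = np.array(
            [float(np.mean(all_votes[r] == y_test)) for r in range(config.n_resamplings)]
        )
        ens_acc = float(np.mean(ensemble == y_test))
    return PredictionResult(
        donor_ids=[prof.donor_id for prof in test_profiles],
        per_resampling_labels=all_votes,
        ensemble_labels=ensemble,
        chosen_hyperparams=chosen,
        per_resampling_accuracy=per_acc,
        ensemble_accuracy=ens_acc,
        tie_broken=tie_broken,
    )


def concatenate_conditions(theta_by_condition: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Column-stack per-condition theta matrices into one feature matrix.

    Input frames are indexed by donor_id with identical row order; conditions
    are stacked in sorted name order and columns prefixed by condition.
    """
    if not theta_by_condition:
        raise ValueError("no conditions given")
    conditions = sorted(theta_by_condition)
    ref = theta_by_condition[conditions[0]]
    for cond in conditions[1:]:
        idx = theta_by_condition[cond].index
        if not ref.index.equals(idx):
            for a, b in zip(ref.index, idx):
                if a != b:
                    raise ValueError(
                        f"donor row order mismatch in condition {cond!r}: "
                        f"{a!r} vs {b!r}"
                    )
            raise ValueError(
                f"condition {cond!r} has {len(idx)} donors, expected {len(ref.index)}"
            )
    blocks = [
        theta_by_condition[cond].add_prefix(f"{cond}:") for cond in conditions
    ]
    return pd.concat(blocks, axis=1)


def train_test_split_donors(
    donors: Sequence[str],
    labels: Sequence[str],
    train_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Stratified-by-label random split at the donor level."""
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must lie in (0, 1), got {train_fraction}")
    donors = list(donors)
    labels = list(labels)
    if len(donors) != len(labels):
        raise ValueError("donors and labels must have equal length")
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[str]] = {}
    for d, lab in zip(donors, labels):
        by_class.setdefault(lab, []).append(d)
    train: list[str] = []
    test: list[str] = []
    for lab in sorted(by_class):
        members = by_class[lab]
        if len(members) < 2:
            raise ValueError(f"class {lab!r} has only {len(members)} donor(s)")
        perm = rng.permutation(len(members))
        n_tr = int(np.floor(train_fraction * len(members) + 0.5))
        n_tr = min(max(n_tr, 1), len(members) - 1)
        train.extend(members[i] for i in perm[:n_tr])
        test.extend(members[i] for i in perm[n_tr:])
    return train, test
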