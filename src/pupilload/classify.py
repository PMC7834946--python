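"""Participant-wise splitting and random-forest difficulty classification.

Registers from the same participant are strongly correlated, so the train /
test split is made at the participant level: a small random subset of
participants (3 of 20 by default, mirroring a 15% training share) trains the
forest and every register of the remaining participants is scored.  Because
single tiny-training-set splits are highly variable, the set-comparison
experiment repeats the split over many seeds and reports mean accuracy per
feature set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import ALL_FEATURES, GAME_FEATURES, PUPIL_FEATURES
from .stats import FeatureSets, select_features

__all__ = [
    "SplitPlan",
    "ClassifierReport",
    "RfConfig",
    "split_by_participant",
    "train_difficulty_rf",
    "evaluate",
    "feature_set_experiment",
]


@dataclass(frozen=True)
class RfConfig:
    """Random-forest settings, pinned for reproducibility."""

    n_trees: int = 100
    max_features: str = "sqrt"
    seed: int = 0


@dataclass(frozen=True)
class SplitPlan:
    train_participants: tuple[str, ...]
    test_participants: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        overlap = set(self.train_participants) & set(self.test_participants)
        if overlap:
            raise ValueError(f"participants in both train and test: {overlap}")


@dataclass(frozen=True)
class ClassifierReport:
    feature_set: str
    features: tuple[str, ...]
    accuracy: float
    confusion: dict[tuple[str, str], int]  # (true, predicted) -> count
    n_test: int
    seed: int


def split_by_participant(dataset: pd.DataFrame, n_train: int = 3,
                         seed: int = 0) -> SplitPlan:
    """Uniformly pick ``n_train`` participants for training; rest test.

    All of a participant's registers stay on one side, so no identity leaks
    across the split.
    """
    participants = np.array(sorted(dataset["participant_id"].astype(str).unique()))
    if n_train < 1:
        raise ValueError("n_train must be >= 1")
    if n_train >= participants.size:
        raise ValueError(
            f"n_train={n_train} leaves no test participants out of {participants.size}"
        )
    rng = np.random.default_rng(seed)
    train = rng.choice(participants, size=n_train, replace=False)
    train_set = set(train.tolist())
    test = tuple(p for p in participants if p not in train_set)
    return SplitPlan(tuple(sorted(train.tolist())), test, seed)


def train_difficulty_rf(train_records: pd.DataFrame, feature_set,
                        rf_config: RfConfig = RfConfig()) -> RandomForestClassifier:
    """Fit a random forest restricted to the named feature columns."""
    features = tuple(feature_set)
    if not features:
        raise ValueError("empty feature set")
    unknown = set(features) - set(ALL_FEATURES)
    if unknown:
        raise ValueError(f"unknown features {sorted(unknown)}")
    y = train_records["world"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("training data contain a single class")
    x = train_records[list(features)].to_numpy(dtype=float)
    model = RandomForestClassifier(
        n_estimators=rf_config.n_trees,
        max_features=rf_config.max_features,
        random_state=rf_config.seed,
    )
    model.fit(x, y)
    model.feature_set_ = features
    return model


def evaluate(model: RandomForestClassifier, test_records: pd.DataFrame,
             set_name: str = "", seed: int = 0) -> ClassifierReport:
    """Accuracy and confusion counts of a fitted model on test registers."""
    if test_records.empty:
        raise ValueError("empty test set")
    features = model.feature_set_
    x = test_records[list(features)].to_numpy(dtype=float)
    y_true = test_records["world"].to_numpy()
    y_pred = model.predict(x)
    acc = float(np.mean(y_true == y_pred))
    confusion: dict[tuple[str, str], int] = {}
    for t, p in zip(y_true, y_pred):
        confusion[(t, p)] = confusion.get((t, p), 0) + 1
    return ClassifierReport(set_name, features, acc, confusion,
                            len(test_records), seed)


def _named_sets(selection: FeatureSets) -> dict[str, tuple[str, ...]]:
    return {
        "G": GAME_FEATURES,
        "G'": selection.g_selected,
        "P": PUPIL_FEATURES,
        "P'": selection.p_selected,
        "G'uP'": selection.union_selected,
    }


def feature_set_experiment(
    dataset: pd.DataFrame,
    alpha: float = 0.05,
    rf_config: RfConfig = RfConfig(),
    n_train: int = 3,
    n_seeds: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Compare classifier accuracy across the five canonical feature sets.

    Runs Wilcoxon feature selection once on the full dataset (selection is a
    property of the cohort, as in the original design), then trains and
    evaluates a forest for each of G, G', P, P' and G' u P' on ``n_seeds``
    independent participant-wise splits.  Returns one row per set with mean
    and SD accuracy; a set that comes back empty from selection is reported
    with NaN accuracy.
    """
    selection = select_features(dataset, alpha=alpha)
    split_seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    rows = []
    for name, feats in _named_sets(selection).items():
        accs = []
        for i, s in enumerate(split_seeds):
            plan = split_by_participant(dataset, n_train=n_train, seed=int(s))
            train = dataset[dataset["participant_id"].isin(plan.train_participants)]
            test = dataset[dataset["participant_id"].isin(plan.test_participants)]
            if not feats:
                accs = [np.nan]
                break
            cfg = RfConfig(rf_config.n_trees, rf_config.max_features,
                           seed=rf_config.seed + i)
            model = train_difficulty_rf(train, feats, cfg)
            accs.append(evaluate(model, test, name, int(s)).accuracy)
        rows.append(
            {
                "set": name,
                "features": ", ".join(feats) if feats else "(none)",
                "mean_accuracy": float(np.mean(accs)),
                "sd_accuracy": float(np.std(accs, ddof=1)) if len(accs) > 1 else 0.0,
                "n_splits": len(accs),
            }
        )
    return pd.DataFrame(rows)
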