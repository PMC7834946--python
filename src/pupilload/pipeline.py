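"""End-to-end drivers wiring simulation, preprocessing, features, statistics
and classification together.  These are what the ``experiment1`` /
``experiment2`` CLI subcommands call, and they are equally usable from
Python for power/calibration studies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import RfConfig, feature_set_experiment
from .features import Trial, build_dataset
from .preprocess import clean_trace, estimate_baseline, extract_interval
from .simulate import (
    EXP1_CONDITIONS,
    Cohort,
    SimConfig,
    simulate_experiment1_cohort,
    simulate_experiment2_cohort,
)
from .stats import (
    FeatureSets,
    PosthocResult,
    RmAnovaResult,
    bonferroni_pairwise,
    rm_anova_gg,
    select_features,
)

__all__ = [
    "Experiment1Result",
    "Experiment2Result",
    "mpdc_matrix_exp1",
    "run_experiment1",
    "extract_dataset",
    "run_experiment2",
]


@dataclass
class Experiment1Result:
    """Baseline-image comparison: MPDC per participant and condition, the
    within-subject ANOVA, and the Bonferroni grouping."""

    mpdc: pd.DataFrame  # participants x conditions
    anova: RmAnovaResult
    posthoc: PosthocResult


@dataclass
class Experiment2Result:
    """Difficulty study: the labelled dataset, the Wilcoxon selection, and
    the per-feature-set classification table."""

    dataset: pd.DataFrame
    selection: FeatureSets
    table: pd.DataFrame


def _mpdc_of_pair(traces, window_ms: float = 2000.0,
                  hampel_half_window: int = 5) -> float:
    """MPDC between the last-2-s windows of a baseline/test viewing pair."""
    cb = clean_trace(traces.baseline, hampel_half_window)
    cm = clean_trace(traces.measurement, hampel_half_window)
    baseline = estimate_baseline(cb, window_ms)
    t_end = cm.t[-1] + 1000.0 / cm.rate_hz
    test = extract_interval(cm, t_end - window_ms, t_end, "measurement")
    d = test.d
    return float(np.nanmean(d) - baseline.mean_d)


def mpdc_matrix_exp1(cohort: Cohort, window_ms: float = 2000.0) -> pd.DataFrame:
    """Participants x conditions MPDC table from a baseline-image cohort."""
    if cohort.experiment1 is None:
        raise ValueError("cohort has no experiment-1 records")
    rows: dict[str, dict[str, float]] = {}
    for rec in cohort.experiment1:
        rows.setdefault(rec.participant_id, {})[rec.condition] = \
            _mpdc_of_pair(rec.traces, window_ms)
    df = pd.DataFrame.from_dict(rows, orient="index")[list(EXP1_CONDITIONS)]
    df.index.name = "participant_id"
    return df.sort_index()


def run_experiment1(config: SimConfig = SimConfig(),
                    alpha: float = 0.05) -> Experiment1Result:
    """Simulate the baseline-image cohort and run its full analysis."""
    cohort = simulate_experiment1_cohort(config)
    mpdc = mpdc_matrix_exp1(cohort)
    values = mpdc.to_numpy()
    anova = rm_anova_gg(values, alpha=alpha)
    posthoc = bonferroni_pairwise(values, alpha=alpha,
                                  condition_names=mpdc.columns)
    return Experiment1Result(mpdc, anova, posthoc)


def extract_dataset(cohort: Cohort, baseline_window_ms: float = 2000.0,
                    hampel_half_window: int = 5,
                    max_gap_ms: float = 500.0) -> pd.DataFrame:
    """Run the preprocessing + feature pipeline over a difficulty cohort."""
    if cohort.experiment2 is None:
        raise ValueError("cohort has no experiment-2 records")
    trials = []
    for part in cohort.experiment2:
        pid = part.profile.participant_id
        baselines = {
            world: estimate_baseline(
                clean_trace(trace, hampel_half_window, max_gap_ms=max_gap_ms),
                baseline_window_ms,
            )
            for world, trace in part.baselines.items()
        }
        for trial in part.trials:
            measurement = clean_trace(trial.measurement, hampel_half_window,
                                      max_gap_ms=max_gap_ms)
            trials.append(
                Trial(pid, trial.level_id, measurement,
                      baselines[trial.world], trial.log)
            )
    return build_dataset(trials)


def run_experiment2(
    config: SimConfig = SimConfig(),
    alpha: float = 0.05,
    rf_config: RfConfig = RfConfig(),
    n_train: int = 3,
    n_seeds: int = 50,
    split_seed: int = 0,
) -> Experiment2Result:
    """Simulate the difficulty cohort, build the dataset, select features,
    and compare classifier feature sets."""
    cohort = simulate_experiment2_cohort(config)
    dataset = extract_dataset(cohort)
    selection = select_features(dataset, alpha=alpha)
    table = feature_set_experiment(dataset, alpha=alpha, rf_config=rf_config,
                                   n_train=n_train, n_seeds=n_seeds,
                                   seed=split_seed)
    return Experiment2Result(dataset, selection, table)
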