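"""Split-half cross-validation, evaluation metrics and subgroup transfers.

The validation protocol randomly halves a cohort into estimation and
validation sets, fits the mapping (five per-domain ordinal fits, or the
linear comparator) on one half, predicts utilities on the other, then swaps
the halves -- so five random splits yield ten complete modelling exercises.
Per exercise, predicted and observed utilities are compared via the mean
difference (predicted minus observed cohort mean), mean square error, mean
absolute error, the share of subjects predicted within 0.1/0.2/0.3 of their
observed utility, and a fixed-bin histogram of per-subject differences.
Aggregate metrics are the unweighted mean over exercises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import fit_proportional_odds
from .instruments import EQ5D_DOMAINS
from .io import ID_COL, dlqi_totals
from .olr import MappingModel
from .prediction import (
    fit_linear_cc_cohort,
    observed_utilities,
    predict_linear_cc,
    predict_utility_mc,
)
from .valuesets import UK_TTO, ValueSet

#: Comparison used for "within t": non-strict (<=), with a 1e-12 guard for
#: floating rounding.  Recorded in report metadata.
WITHIN_TOLERANCES = (0.1, 0.2, 0.3)
HIST_EDGES = np.round(np.linspace(-1.6, 1.6, 33), 10)


@dataclass(frozen=True)
class SplitPlan:
    """Random halvings of a cohort into estimation (A) and validation (B) sets.

    Within each split A and B partition the subject ids and differ in size by
    at most one (odd cohorts give the extra subject to A).
    """

    n_splits: int
    assignments: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    seed: int


def make_split_plan(cohort: pd.DataFrame, n_splits: int = 5, seed: int = 0) -> SplitPlan:
    """Draw ``n_splits`` independent uniform random halvings; deterministic
    given the seed."""
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    ids = cohort[ID_COL].astype(str).to_numpy()
    n = len(ids)
    if n < 2:
        raise ValueError("cohort must contain at least two subjects")
    n_a = (n + 1) // 2
    assignments = []
    for s in range(n_splits):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101, s]))
        perm = rng.permutation(n)
        a = tuple(ids[np.sort(perm[:n_a])])
        b = tuple(ids[np.sort(perm[n_a:])])
        assignments.append((a, b))
    return SplitPlan(n_splits=n_splits, assignments=tuple(assignments), seed=seed)


@dataclass(frozen=True)
class MetricsRecord:
    """Agreement metrics between predicted and observed utilities."""

    n: int
    mean_difference: float  # mean(predicted) - mean(observed)
    mse: float
    mae: float
    pct_within: dict[float, float]  # tolerance -> percent of subjects
    histogram: np.ndarray  # counts in the fixed HIST_EDGES bins

    def as_dict(self) -> dict:
        d = {
            "n": self.n,
            "mean_difference": self.mean_difference,
            "mse": self.mse,
            "mae": self.mae,
        }
        for t, v in self.pct_within.items():
            d[f"pct_within_{str(t).replace('.', '_')}"] = v
        return d


def evaluate(predicted: Sequence[float], observed: Sequence[float]) -> MetricsRecord:
    """Compare paired predicted and observed utility vectors.

    Differences are binned left-closed/right-open on fixed width-0.1 edges
    over [-1.6, 1.6] so histograms are reproducible bit-identically.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("predicted and observed must be equal-length vectors")
    if len(pred) == 0:
        raise ValueError("empty utility vectors")
    d = pred - obs
    pct = {
        t: float((np.abs(d) <= t + 1e-12).mean() * 100.0) for t in WITHIN_TOLERANCES
    }
    counts, _ = np.histogram(d, bins=HIST_EDGES)
    return MetricsRecord(
        n=len(pred),
        mean_difference=float(pred.mean() - obs.mean()),
        mse=float(np.mean(d**2)),
        mae=float(np.mean(np.abs(d))),
        pct_within=pct,
        histogram=counts,
    )


@dataclass
class ExerciseResult:
    """One of the ten (train, test) modelling exercises."""

    index: int
    split: int
    reversed: bool
    n_train: int
    n_test: int
    metrics: Optional[MetricsRecord]
    error: Optional[str] = None
    warnings: list[str] = field(default_factory=list)


@dataclass
class ValidationReport:
    """Per-exercise and aggregate cross-validation metrics."""

    method: str
    seed: int
    reps: int
    valueset_name: str
    exercises: list[ExerciseResult]
    aggregate: Optional[MetricsRecord]
    metadata: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "seed": self.seed,
            "reps": self.reps,
            "valueset_name": self.valueset_name,
            "metadata": dict(self.metadata),
            "exercises": [
                {
                    "index": e.index,
                    "split": e.split,
                    "reversed": e.reversed,
                    "n_train": e.n_train,
                    "n_test": e.n_test,
                    "error": e.error,
                    "warnings": e.warnings,
                    **({} if e.metrics is None else e.metrics.as_dict()),
                    "histogram": None
                    if e.metrics is None
                    else e.metrics.histogram.tolist(),
                }
                for e in self.exercises
            ],
            "aggregate": None
            if self.aggregate is None
            else {
                **self.aggregate.as_dict(),
                "histogram": self.aggregate.histogram.tolist(),
            },
            "histogram_edges": HIST_EDGES.tolist(),
        }


def _exercise_seed(seed: int, index: int) -> int:
    """Documented counter scheme: substream (seed, 202, index), truncated to
    32 bits so any single exercise can be rerun in isolation."""
    return int(np.random.SeedSequence([int(seed), 202, index]).generate_state(1)[0])


def fit_mapping_model(
    cohort: pd.DataFrame,
    covariate_set: str = "age_sex_dlqi",
    valueset_name: str = "UK-TTO",
) -> tuple[MappingModel, list[str]]:
    """Fit all five domain models on a cohort; returns model and warnings."""
    domains = {}
    warnings_out: list[str] = []
    for d in EQ5D_DOMAINS:
        fr = fit_proportional_odds(cohort, d, covariate_set)
        domains[d] = fr.model
        warnings_out.extend(fr.warnings)
    model = MappingModel(
        domains=domains,
        valueset_name=valueset_name,
        provenance={"n": int(len(cohort)), "covariates": covariate_set},
    )
    return model, warnings_out


def _predict_exercise(
    method: str,
    train: pd.DataFrame,
    test: pd.DataFrame,
    reps: int,
    ex_seed: int,
    valueset: ValueSet,
) -> tuple[np.ndarray, list[str]]:
    if method == "olr":
        model, warns = fit_mapping_model(train, valueset_name=valueset.name)
        preds = predict_utility_mc(model, test, reps=reps, seed=ex_seed, valueset=valueset)
        return np.array([p.mean_utility for p in preds]), warns
    if method == "linear":
        lm = fit_linear_cc_cohort(train, valueset)
        return np.asarray(predict_linear_cc(lm, dlqi_totals(test))), []
    raise ValueError(f"unknown method {method!r} (choose 'olr' or 'linear')")


def cross_validate(
    cohort: pd.DataFrame,
    method: str = "olr",
    plan: Optional[SplitPlan] = None,
    n_splits: int = 5,
    reps: int = 5,
    seed: int = 0,
    valueset: ValueSet = UK_TTO,
) -> ValidationReport:
    """Split-half cross-validation of a mapping method.

    Each split contributes two exercises (halves swapped), so the default
    five splits give ten fitted-and-tested models.  A fit failure marks only
    that exercise as failed; the aggregate is the unweighted mean over
    successful exercises, with histogram counts summed.
    """
    obs_all = observed_utilities(cohort, valueset)  # validates EQ-5D presence
    del obs_all
    if plan is None:
        plan = make_split_plan(cohort, n_splits=n_splits, seed=seed)
    ids = cohort[ID_COL].astype(str)
    exercises: list[ExerciseResult] = []
    for s, (ids_a, ids_b) in enumerate(plan.assignments):
        for rev, (train_ids, test_ids) in enumerate(((ids_a, ids_b), (ids_b, ids_a))):
            index = 2 * s + rev
            train = cohort.loc[ids.isin(train_ids)]
            test = cohort.loc[ids.isin(test_ids)]
            ex = ExerciseResult(
                index=index,
                split=s,
                reversed=bool(rev),
                n_train=len(train),
                n_test=len(test),
                metrics=None,
            )
            try:
                pred, warns = _predict_exercise(
                    method, train, test, reps, _exercise_seed(seed, index), valueset
                )
                ex.warnings = warns
                ex.metrics = evaluate(pred, observed_utilities(test, valueset))
            except Exception as exc:  # fit failure: mark, keep going
                ex.error = f"{type(exc).__name__}: {exc}"
            exercises.append(ex)

    ok = [e.metrics for e in exercises if e.metrics is not None]
    aggregate = None
    if ok:
        aggregate = MetricsRecord(
            n=int(sum(m.n for m in ok)),
            mean_difference=float(np.mean([m.mean_difference for m in ok])),
            mse=float(np.mean([m.mse for m in ok])),
            mae=float(np.mean([m.mae for m in ok])),
            pct_within={
                t: float(np.mean([m.pct_within[t] for m in ok]))
                for t in WITHIN_TOLERANCES
            },
            histogram=np.sum([m.histogram for m in ok], axis=0),
        )
    return ValidationReport(
        method=method,
        seed=seed,
        reps=reps,
        valueset_name=valueset.name,
        exercises=exercises,
        aggregate=aggregate,
        metadata={
            "n_splits": plan.n_splits,
            "within_comparison": "non-strict (<=)",
            "aggregation": "unweighted mean over exercises; histogram counts summed",
        },
    )


def subgroup_transfer(
    cohort: pd.DataFrame,
    train_filter,
    test_filter,
    method: str = "olr",
    reps: int = 5,
    seed: int = 0,
    valueset: ValueSet = UK_TTO,
) -> ExerciseResult:
    """Fit on one subgroup, evaluate on a disjoint subgroup.

    Filters are boolean masks aligned with the cohort (or callables mapping
    the cohort to such masks).  Degenerate-threshold warnings from the
    training fit (e.g. a subgroup with no 'extreme' responses in a domain)
    are propagated on the result.
    """
    train_mask = np.asarray(train_filter(cohort) if callable(train_filter) else train_filter, bool)
    test_mask = np.asarray(test_filter(cohort) if callable(test_filter) else test_filter, bool)
    if train_mask.shape != (len(cohort),) or test_mask.shape != (len(cohort),):
        raise ValueError("filters must produce one boolean per subject")
    if np.any(train_mask & test_mask):
        raise ValueError("train and test filters overlap")
    if not train_mask.any() or not test_mask.any():
        raise ValueError("train and test subsets must be non-empty")
    train = cohort.loc[train_mask]
    test = cohort.loc[test_mask]
    ex = ExerciseResult(
        index=0, split=0, reversed=False, n_train=len(train), n_test=len(test), metrics=None
    )
    try:
        pred, warns = _predict_exercise(
            method, train, test, reps, _exercise_seed(seed, 0), valueset
        )
        ex.warnings = warns
        ex.metrics = evaluate(pred, observed_utilities(test, valueset))
    except Exception as exc:
        ex.error = f"{type(exc).__name__}: {exc}"
    return ex
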