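"""From per-domain probabilities to simulated EQ-5D states and utilities.

Two routes to a health utility estimate from a fitted mapping model:

* **Monte Carlo** -- for each subject, draw each of the five domain responses
  independently from its predicted category probabilities (inverse-CDF
  draws), assemble the EQ-5D state, apply the tariff, and average over a
  small number of repetitions (default 5, enough to stabilize cohort means).
* **Analytic expectation** -- the exact expected utility under the model,
  summing utility x joint probability over all 243 states (domains treated
  as independent given covariates, exactly as the simulation does).  This is
  the oracle the Monte Carlo estimate converges to.

A deliberately simple linear comparator is also provided: ordinary least
squares of observed utility on the DLQI total score, reported in the
``Utility = a - b * total`` convention.  Its predictions are bounded above by
the intercept ``a``, so -- unlike the ordinal route -- it can never emit a
full-health utility of exactly 1.

Randomness is reproducible and order-independent: a single cohort-level seed
is combined with a per-subject key (derived from the subject id) to give each
subject its own counter-based substream.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .instruments import EQ5D_DOMAINS
from .io import AGE_COL, SEX_COL, dlqi_item_matrix, dlqi_totals, eq5d_level_matrix, ID_COL
from .olr import CovariateVector, MappingModel, probability_matrix
from .valuesets import UK_TTO, ValueSet, utility_from_levels, utility_table


def _subject_key(subject_id: str) -> int:
    """Stable 64-bit stream key for a subject id."""
    digest = hashlib.sha256(str(subject_id).encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big")


def subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    """Per-subject random stream, independent of subject ordering."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _subject_key(subject_id)]))


def sample_domain(
    p1: float, p2: float, p3: float, rng: np.random.Generator
) -> int:
    """Inverse-CDF draw of one domain response category.

    u < p1 -> 1;  u < p1 + p2 -> 2;  else 3.
    """
    if min(p1, p2, p3) < -1e-12:
        raise ValueError(f"negative probability in ({p1}, {p2}, {p3})")
    if abs(p1 + p2 + p3 - 1.0) > 1e-9:
        raise ValueError(f"probabilities ({p1}, {p2}, {p3}) do not sum to 1")
    u = rng.random()
    if u < p1:
        return 1
    if u < p1 + p2:
        return 2
    return 3


@dataclass
class UtilityPrediction:
    """Monte Carlo utility prediction for one subject."""

    subject_id: str
    states: np.ndarray  # (reps, 5) integer levels
    utilities: np.ndarray  # (reps,)
    mean_utility: float
    analytic_expected_utility: float

    @property
    def reps(self) -> int:
        return len(self.utilities)


def _covariate_arrays(cohort: pd.DataFrame):
    age = cohort[AGE_COL].to_numpy(dtype=float)
    sex = cohort[SEX_COL].to_numpy(dtype=float)
    items = dlqi_item_matrix(cohort)
    return age, sex, items


def _analytic_from_probs(probs: np.ndarray, vs: ValueSet) -> np.ndarray:
    """Exact expected utility per subject from a (n, 5, 3) probability array."""
    utable = utility_table(vs).reshape(3, 3, 3, 3, 3)
    return np.einsum(
        "na,nb,nc,nd,ne,abcde->n",
        probs[:, 0], probs[:, 1], probs[:, 2], probs[:, 3], probs[:, 4],
        utable,
        optimize=True,
    )


def predict_utility_mc(
    model: MappingModel,
    cohort: pd.DataFrame,
    reps: int = 5,
    seed: int = 0,
    valueset: ValueSet = UK_TTO,
) -> list[UtilityPrediction]:
    """Monte Carlo utility predictions for every subject in a cohort.

    Per repetition the five domains are drawn independently from their
    predicted probabilities, the resulting state is valued under the tariff,
    and ``mean_utility`` averages the per-rep utilities.  Bit-reproducible
    for a fixed seed, regardless of subject ordering.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    age, sex, items = _covariate_arrays(cohort)
    probs = probability_matrix(model, age, sex, items)  # (n, 5, 3)
    cum = np.cumsum(probs, axis=2)  # (n, 5, 3)
    analytic = _analytic_from_probs(probs, valueset)
    ids = cohort[ID_COL].astype(str).to_numpy()

    out = []
    for i, sid in enumerate(ids):
        rng = subject_rng(seed, sid)
        u = rng.random((reps, len(EQ5D_DOMAINS)))
        levels = 1 + (u >= cum[i, :, 0]) + (u >= cum[i, :, 1])
        utils = utility_from_levels(levels, valueset)
        out.append(
            UtilityPrediction(
                subject_id=sid,
                states=levels.astype(int),
                utilities=utils,
                mean_utility=float(utils.mean()),
                analytic_expected_utility=float(analytic[i]),
            )
        )
    return out


def expected_utility_analytic(
    model: MappingModel,
    covariates: Union[CovariateVector, pd.DataFrame],
    valueset: ValueSet = UK_TTO,
) -> Union[float, np.ndarray]:
    """Exact expected utility under the mapping model.

    Sums utility x product of domain probabilities over the 243 states.
    Accepts a single covariate vector (returns a float) or a cohort table
    (returns an array).
    """
    if isinstance(covariates, CovariateVector):
        probs = probability_matrix(
            model,
            np.array([covariates.age]),
            np.array([covariates.sex]),
            np.array([covariates.items]),
        )
        return float(_analytic_from_probs(probs, valueset)[0])
    age, sex, items = _covariate_arrays(covariates)
    probs = probability_matrix(model, age, sex, items)
    return _analytic_from_probs(probs, valueset)


def observed_utilities(cohort: pd.DataFrame, valueset: ValueSet = UK_TTO) -> np.ndarray:
    """Tariff utilities of the observed EQ-5D states (NaN rows rejected)."""
    levels = eq5d_level_matrix(cohort)
    if np.isnan(levels).any():
        raise ValueError("cohort contains missing EQ-5D responses")
    return utility_from_levels(levels.astype(int), valueset)


# ---------------------------------------------------------------------------
# Linear comparator (total-score regression)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinearModel:
    """Utility = a - b * DLQI total."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.a) and np.isfinite(self.b)):
            raise ValueError("linear model coefficients must be finite")


def fit_linear_cc(
    dlqi_total: Sequence[float], utility: Sequence[float]
) -> LinearModel:
    """Ordinary least squares of observed utility on the DLQI total score.

    Returned in the ``a - b * total`` sign convention (b > 0 means utility
    falls as the DLQI total rises).  Requires at least two distinct totals.
    """
    t = np.asarray(dlqi_total, dtype=float)
    u = np.asarray(utility, dtype=float)
    if t.shape != u.shape or t.ndim != 1:
        raise ValueError("dlqi_total and utility must be equal-length vectors")
    if len(np.unique(t)) < 2:
        raise ValueError("slope non-estimable: all DLQI totals identical")
    design = np.column_stack([np.ones_like(t), t])
    coef, *_ = np.linalg.lstsq(design, u, rcond=None)
    return LinearModel(a=float(coef[0]), b=float(-coef[1]))


def fit_linear_cc_cohort(
    cohort: pd.DataFrame, valueset: ValueSet = UK_TTO
) -> LinearModel:
    """Fit the linear comparator on a cohort with observed EQ-5D states."""
    return fit_linear_cc(dlqi_totals(cohort), observed_utilities(cohort, valueset))


def predict_linear_cc(
    model: LinearModel, dlqi_total: Union[float, np.ndarray]
) -> Union[float, np.ndarray]:
    """a - b * total.  No clamping: the unbounded-below tail is a documented
    property of the comparator, not corrected."""
    t = np.asarray(dlqi_total, dtype=float)
    if np.any(t < 0) or np.any(t > 30):
        raise ValueError("DLQI total must lie in [0, 30]")
    out = model.a - model.b * t
    return float(out) if out.ndim == 0 else out
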