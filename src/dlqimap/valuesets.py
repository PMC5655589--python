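"""EQ-5D-3L value sets (tariffs) and utility computation.

A value set converts an EQ-5D-3L health state into a health utility estimate
(dimensionless, 1 = full health, values below 0 mean worse than dead).  The
additive tariff structure implemented here is

    U(state) = full_health
               - constant            if any domain > level 1
               - sum of per-domain level-2/level-3 decrements
               - N3                  if any domain = level 3

The bundled default is the UK time-trade-off (TTO) tariff from the MVH study
(Dolan 1997), whose worst state (3,3,3,3,3) values at -0.594.  Other
country-specific additive tariffs can be loaded from JSON without code
changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np

from .instruments import EQ5D_DOMAINS, N_STATES, Eq5dState, state_from_index

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ValueSet:
    """An additive EQ-5D-3L tariff.

    ``level_decrements`` maps each domain name to a ``(level2, level3)`` pair
    of utility decrements.  All decrements must be non-negative and the
    level-3 decrement must be at least the level-2 decrement, which makes
    utility monotone non-increasing in every domain level.
    """

    name: str
    full_health_value: float
    constant_decrement: float
    level_decrements: Mapping[str, tuple[float, float]]
    n3_decrement: float
    source: str = ""

    def __post_init__(self) -> None:
        missing = set(EQ5D_DOMAINS) - set(self.level_decrements)
        if missing:
            raise ValueError(f"value set {self.name!r} missing domains: {sorted(missing)}")
        if self.constant_decrement < 0 or self.n3_decrement < 0:
            raise ValueError("decrements must be non-negative")
        for domain, (l2, l3) in self.level_decrements.items():
            if l2 < 0 or l3 < l2:
                raise ValueError(
                    f"value set {self.name!r}, domain {domain}: need 0 <= level-2 "
                    f"decrement <= level-3 decrement, got ({l2}, {l3})"
                )

    def _decrement_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        l2 = np.array([self.level_decrements[d][0] for d in EQ5D_DOMAINS])
        l3 = np.array([self.level_decrements[d][1] for d in EQ5D_DOMAINS])
        return l2, l3


#: Dolan (1997) UK MVH time-trade-off tariff.  Coefficients are from the
#: published value set (Dolan P., "Modeling valuations for EuroQol health
#: states", Medical Care 1997;35(11):1095-1108), not re-estimated here.
UK_TTO = ValueSet(
    name="UK-TTO",
    full_health_value=1.0,
    constant_decrement=0.081,
    level_decrements={
        "mobility": (0.069, 0.314),
        "self_care": (0.104, 0.214),
        "usual_activities": (0.036, 0.094),
        "pain_discomfort": (0.123, 0.386),
        "anxiety_depression": (0.071, 0.236),
    },
    n3_decrement=0.269,
    source=(
        "Dolan P. Modeling valuations for EuroQol health states. "
        "Med Care 1997;35(11):1095-1108 (MVH TTO tariff, states elicited 1993)."
    ),
)

_REGISTRY: dict[str, ValueSet] = {UK_TTO.name: UK_TTO}


def get_valueset(name: str) -> ValueSet:
    """Look up a registered value set by name."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown value set {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def register_valueset(vs: ValueSet) -> None:
    _REGISTRY[vs.name] = vs


def utility_from_levels(levels: np.ndarray, vs: ValueSet = UK_TTO) -> np.ndarray:
    """Vectorized tariff application.

    ``levels`` is an integer array whose last axis has length 5 (domain
    levels in canonical order); the return drops that axis.  Every scalar
    utility in this package flows through this one function, so per-state
    calls and table lookups agree bit for bit.
    """
    lv = np.asarray(levels)
    if lv.shape[-1] != 5:
        raise ValueError("last axis must hold the five domain levels")
    l2, l3 = vs._decrement_arrays()
    any_problem = (lv > 1).any(axis=-1)
    any_extreme = (lv == 3).any(axis=-1)
    u = (
        vs.full_health_value
        - vs.constant_decrement * any_problem
        - ((lv == 2) * l2).sum(axis=-1)
        - ((lv == 3) * l3).sum(axis=-1)
        - vs.n3_decrement * any_extreme
    )
    return u


def utility(state: Eq5dState, vs: ValueSet = UK_TTO) -> float:
    """Health utility estimate of a single EQ-5D-3L state under a tariff."""
    return float(utility_from_levels(np.array(state.levels), vs))


def utility_table(vs: ValueSet = UK_TTO) -> np.ndarray:
    """Utilities of all 243 states, indexed by ``state_index``."""
    levels = np.array([state_from_index(i).levels for i in range(N_STATES)])
    return utility_from_levels(levels, vs)


def load_valueset(path: Union[str, "os.PathLike[str]"]) -> ValueSet:  # noqa: F821
    """Load a value set from its JSON interchange form and register it."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    try:
        vs = ValueSet(
            name=doc["name"],
            full_health_value=float(doc["full_health_value"]),
            constant_decrement=float(doc["constant_decrement"]),
            level_decrements={
                d: (float(v["l2"]), float(v["l3"]))
                for d, v in doc["level_decrements"].items()
            },
            n3_decrement=float(doc["n3_decrement"]),
            source=doc.get("source", ""),
        )
    except KeyError as exc:
        raise ValueError(f"value-set JSON missing field {exc}") from None
    register_valueset(vs)
    return vs


def save_valueset(vs: ValueSet, path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "name": vs.name,
        "full_health_value": vs.full_health_value,
        "constant_decrement": vs.constant_decrement,
        "level_decrements": {
            d: {"l2": l2, "l3": l3} for d, (l2, l3) in vs.level_decrements.items()
        },
        "n3_decrement": vs.n3_decrement,
        "source": vs.source,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
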