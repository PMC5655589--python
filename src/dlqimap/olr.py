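"""Proportional-odds (cumulative-logit) models mapping DLQI items to EQ-5D-3L.

For each EQ-5D domain, a latent score

    Z = b_age * age + b_sex * sex + sum_i b_i * item_i

is cut by two thresholds a1 < a2 into the three ordinal response categories.
Assuming logistic noise on the latent scale gives the cumulative
probabilities

    P(Y = 1)          = 1 / (1 + exp(Z - a1))
    P(Y = 1) + P(Y=2) = 1 / (1 + exp(Z - a2))
    P(Y = 3)          = 1 - P(Y <= 2)

so higher Z pushes probability mass toward the worse categories.  Sex is
coded 0 = male / 1 = female, age enters linearly, and the ten DLQI items
enter as numeric 0-3 scores with one slope each.

The module bundles the final fitted model (one proportional-odds model per
domain, estimated on 3542 European dermatology outpatients) so cohorts can be
mapped to EQ-5D response probabilities without refitting.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Union

import numpy as np
from scipy.special import expit

from .instruments import EQ5D_DOMAINS, N_ITEMS

MODEL_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class CovariateVector:
    """Covariates of one subject: age (years), sex (0/1), ten DLQI items."""

    age: float
    sex: int
    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.sex not in (0, 1):
            raise ValueError(f"sex must be 0 or 1, got {self.sex!r}")
        if len(self.items) != N_ITEMS:
            raise ValueError(f"expected {N_ITEMS} DLQI items")
        for i, s in enumerate(self.items):
            if s not in (0, 1, 2, 3):
                raise ValueError(f"DLQI item {i + 1} score {s!r} outside {{0,1,2,3}}")

    def as_array(self) -> np.ndarray:
        return np.concatenate(([self.age, self.sex], self.items)).astype(float)


@dataclass(frozen=True)
class DomainModel:
    """A fitted proportional-odds model for one EQ-5D domain.

    Thresholds satisfy ``a1 < a2`` strictly.  An infinite threshold encodes a
    degenerate fit where one outcome category was unobserved (``a2 = +inf``:
    the model never predicts level 3); slopes must be finite.
    """

    domain: str
    a1: float
    a2: float
    b_age: float
    b_sex: float
    b_items: tuple[float, ...]
    se_a1: Optional[float] = None
    se_a2: Optional[float] = None
    se_b_age: Optional[float] = None
    se_b_sex: Optional[float] = None
    se_b_items: Optional[tuple[float, ...]] = None

    def __post_init__(self) -> None:
        if self.domain not in EQ5D_DOMAINS:
            raise ValueError(f"unknown EQ-5D domain {self.domain!r}")
        if not self.a1 < self.a2:
            raise ValueError(
                f"{self.domain}: thresholds must satisfy a1 < a2, got "
                f"a1={self.a1}, a2={self.a2}"
            )
        if len(self.b_items) != N_ITEMS:
            raise ValueError("b_items must have ten entries")
        slopes = (self.b_age, self.b_sex, *self.b_items)
        if not np.all(np.isfinite(slopes)):
            raise ValueError(f"{self.domain}: slope coefficients must be finite")

    @property
    def slopes(self) -> np.ndarray:
        """Slope vector in design order (age, sex, items 1-10)."""
        return np.concatenate(([self.b_age, self.b_sex], self.b_items))


def linear_predictor(model: DomainModel, cov: CovariateVector) -> float:
    """Latent score Z = b_age*age + b_sex*sex + sum b_i*item_i."""
    return float(model.slopes @ cov.as_array())


def cumulative_probabilities(
    a1: float, a2: float, Z: Union[float, np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Category probabilities (p1, p2, p3) from thresholds and latent score.

    Evaluated through the stable sigmoid so |Z - a| up to ~700 cannot
    overflow, and arranged so p1 + p2 + p3 = 1 to floating rounding.
    """
    if not a1 < a2:
        raise ValueError(f"thresholds must satisfy a1 < a2, got a1={a1}, a2={a2}")
    Z = np.asarray(Z, dtype=float)
    p1 = expit(a1 - Z)
    c2 = expit(a2 - Z) if np.isfinite(a2) else np.ones_like(Z)
    p2 = c2 - p1
    p3 = 1.0 - c2
    return p1, p2, p3


def domain_probabilities(
    model: DomainModel, cov: CovariateVector
) -> tuple[float, float, float]:
    """Probabilities of the three EQ-5D responses for one subject."""
    Z = linear_predictor(model, cov)
    p1, p2, p3 = cumulative_probabilities(model.a1, model.a2, Z)
    return float(p1), float(p2), float(p3)


@dataclass(frozen=True)
class MappingModel:
    """Five per-domain models plus the tariff reference and provenance."""

    domains: Mapping[str, DomainModel]
    valueset_name: str = "UK-TTO"
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.domains) != set(EQ5D_DOMAINS):
            raise ValueError(
                f"mapping model must contain exactly the domains {EQ5D_DOMAINS}, "
                f"got {sorted(self.domains)}"
            )
        for name, m in self.domains.items():
            if m.domain != name:
                raise ValueError(f"domain model under key {name!r} is for {m.domain!r}")

    def __getitem__(self, domain: str) -> DomainModel:
        return self.domains[domain]


def predict_all_domains(
    model: MappingModel, cov: CovariateVector
) -> tuple[tuple[float, float, float], ...]:
    """Probability triples for all five domains, in canonical domain order."""
    return tuple(domain_probabilities(model[d], cov) for d in EQ5D_DOMAINS)


def probability_matrix(
    model: MappingModel,
    age: np.ndarray,
    sex: np.ndarray,
    items: np.ndarray,
) -> np.ndarray:
    """Vectorized response probabilities for a cohort.

    ``items`` has shape (n, 10); the return has shape (n, 5, 3) with domains
    in canonical order.
    """
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    items = np.asarray(items, dtype=float)
    X = np.column_stack([age, sex, items])
    out = np.empty((len(age), len(EQ5D_DOMAINS), 3))
    for d, name in enumerate(EQ5D_DOMAINS):
        m = model[name]
        Z = X @ m.slopes
        p1, p2, p3 = cumulative_probabilities(m.a1, m.a2, Z)
        out[:, d, 0], out[:, d, 1], out[:, d, 2] = p1, p2, p3
    return out


# ---------------------------------------------------------------------------
# Bundled final model: estimates (standard errors) per EQ-5D domain, fitted on
# the 3542-subject European dermatology cohort.  Row order: a1, a2, age, sex,
# DLQI items 1-10; column order = canonical domain order.
# ---------------------------------------------------------------------------

_FINAL_ESTIMATES = {
    #                 mobility        self_care       usual_act       pain            anxiety
    "a1":       ((4.500, 0.190), (4.854, 0.251), (3.574, 0.171), (2.204, 0.133), (1.469, 0.128)),
    "a2":       ((9.506, 0.368), (9.074, 0.438), (7.231, 0.237), (6.052, 0.178), (4.775, 0.162)),
    "age":      ((0.051, 0.003), (0.033, 0.004), (0.027, 0.003), (0.025, 0.002), (0.003, 0.002)),
    "sex":      ((0.046, 0.089), (-0.213, 0.120), (0.133, 0.087), (0.177, 0.073), (0.465, 0.073)),
    "dlqi1":    ((0.087, 0.055), (0.176, 0.074), (0.270, 0.052), (0.685, 0.047), (0.035, 0.044)),
    "dlqi2":    ((0.013, 0.061), (0.052, 0.079), (-0.114, 0.059), (0.014, 0.049), (0.378, 0.048)),
    "dlqi3":    ((0.209, 0.068), (0.278, 0.085), (0.351, 0.063), (0.199, 0.060), (0.107, 0.057)),
    "dlqi4":    ((0.071, 0.058), (0.053, 0.072), (0.051, 0.055), (0.097, 0.050), (-0.099, 0.048)),
    "dlqi5":    ((0.113, 0.075), (0.064, 0.095), (0.209, 0.070), (-0.122, 0.064), (0.205, 0.062)),
    "dlqi6":    ((0.116, 0.060), (0.014, 0.071), (0.215, 0.055), (0.310, 0.054), (-0.075, 0.052)),
    "dlqi7":    ((0.251, 0.053), (0.236, 0.063), (0.283, 0.049), (-0.048, 0.046), (0.186, 0.044)),
    "dlqi8":    ((-0.008, 0.076), (-0.013, 0.091), (-0.081, 0.071), (0.163, 0.066), (0.121, 0.064)),
    "dlqi9":    ((-0.094, 0.065), (0.002, 0.075), (0.068, 0.060), (0.132, 0.057), (0.194, 0.054)),
    "dlqi10":   ((0.233, 0.061), (0.478, 0.071), (0.210, 0.057), (0.245, 0.054), (0.155, 0.052)),
}


def bundled_model() -> MappingModel:
    """The bundled final mapping model (five fitted domain models).

    Returns an immutable :class:`MappingModel` populated with every printed
    estimate and standard error of the published fit (n = 3542).
    """
    domains = {}
    item_rows = [f"dlqi{i}" for i in range(1, N_ITEMS + 1)]
    for d, name in enumerate(EQ5D_DOMAINS):
        domains[name] = DomainModel(
            domain=name,
            a1=_FINAL_ESTIMATES["a1"][d][0],
            a2=_FINAL_ESTIMATES["a2"][d][0],
            b_age=_FINAL_ESTIMATES["age"][d][0],
            b_sex=_FINAL_ESTIMATES["sex"][d][0],
            b_items=tuple(_FINAL_ESTIMATES[r][d][0] for r in item_rows),
            se_a1=_FINAL_ESTIMATES["a1"][d][1],
            se_a2=_FINAL_ESTIMATES["a2"][d][1],
            se_b_age=_FINAL_ESTIMATES["age"][d][1],
            se_b_sex=_FINAL_ESTIMATES["sex"][d][1],
            se_b_items=tuple(_FINAL_ESTIMATES[r][d][1] for r in item_rows),
        )
    return MappingModel(
        domains=domains,
        valueset_name="UK-TTO",
        provenance={
            "fit": "published final estimates, 3542 European dermatology outpatients",
            "n": 3542,
        },
    )


# ---------------------------------------------------------------------------
# JSON round-trip
# ---------------------------------------------------------------------------


def _domain_to_doc(m: DomainModel) -> dict:
    return {
        "a1": m.a1,
        "a2": m.a2,
        "b_age": m.b_age,
        "b_sex": m.b_sex,
        "b_items": list(m.b_items),
        "se_a1": m.se_a1,
        "se_a2": m.se_a2,
        "se_b_age": m.se_b_age,
        "se_b_sex": m.se_b_sex,
        "se_b_items": None if m.se_b_items is None else list(m.se_b_items),
    }


def write_model(model: MappingModel, path) -> None:
    """Serialize a mapping model to its JSON interchange form."""
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "domains": {d: _domain_to_doc(model[d]) for d in EQ5D_DOMAINS},
        "valueset_name": model.valueset_name,
        "provenance": dict(model.provenance),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)


def read_model(path) -> MappingModel:
    """Load a mapping model from JSON; write -> read is the identity.

    Schema violations are reported with the offending field path, and
    ``a1 >= a2`` is rejected at load time.
    """
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if "domains" not in doc:
        raise ValueError("model JSON: missing field 'domains'")
    domains = {}
    for name in EQ5D_DOMAINS:
        if name not in doc["domains"]:
            raise ValueError(f"model JSON: missing domain 'domains.{name}'")
        d = doc["domains"][name]
        for key in ("a1", "a2", "b_age", "b_sex", "b_items"):
            if key not in d:
                raise ValueError(f"model JSON: missing field 'domains.{name}.{key}'")
        if len(d["b_items"]) != N_ITEMS:
            raise ValueError(f"model JSON: 'domains.{name}.b_items' must have 10 entries")
        se_items = d.get("se_b_items")
        domains[name] = DomainModel(
            domain=name,
            a1=float(d["a1"]),
            a2=float(d["a2"]),
            b_age=float(d["b_age"]),
            b_sex=float(d["b_sex"]),
            b_items=tuple(float(v) for v in d["b_items"]),
            se_a1=d.get("se_a1"),
            se_a2=d.get("se_a2"),
            se_b_age=d.get("se_b_age"),
            se_b_sex=d.get("se_b_sex"),
            se_b_items=None if se_items is None else tuple(se_items),
        )
    return MappingModel(
        domains=domains,
        valueset_name=doc.get("valueset_name", "UK-TTO"),
        provenance=doc.get("provenance", {}),
    )


def stamp_provenance(model: MappingModel, **extra) -> MappingModel:
    """Return a copy of the model with provenance metadata merged in."""
    prov = dict(model.provenance)
    prov.setdefault("created", _dt.datetime.now(_dt.timezone.utc).isoformat())
    prov.update(extra)
    return replace(model, provenance=prov)
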