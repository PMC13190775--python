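"""Synthetic parameter sets for property testing.

The generator perturbs the shipped base case multiplicatively, field class
by field class, inside configurable relative ranges chosen to stay within
what registry data for an elderly European population could plausibly
show: incidence within roughly half to one-and-a-half times the Stockholm
rates, mortality within +/-20%, utilities within +/-10% (clipped below 1),
costs within a broad 0.6-1.6x band, efficacy scaled down toward the
observational end.  Every generated set passes full validation, so the
generator doubles as a randomised smoke-test harness for the model: with
all ranges degenerate at (1, 1) it reproduces the fixture exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Tuple

import numpy as np

from .fixtures import basecase_fixture
from .parameters import (
    AGE_BANDS,
    PAIN_STATES,
    PHN_BANDS,
    SEXES,
    UTILITY_BANDS,
    ParameterError,
    ParameterSet,
    load_parameters,
)

__all__ = ["SyntheticSpec", "random_parameter_set"]

_PROB_CEIL = 0.999


@dataclass(frozen=True)
class SyntheticSpec:
    """Relative perturbation ranges applied to the base-case values.

    Each field is a ``(low, high)`` multiplicative factor range; draws are
    uniform on it.  Degenerate ranges ``(1, 1)`` leave the corresponding
    values untouched.
    """

    size_factor: Tuple[float, float] = (0.5, 2.0)
    death_factor: Tuple[float, float] = (0.8, 1.2)
    incidence_factor: Tuple[float, float] = (0.5, 1.5)
    phn_factor: Tuple[float, float] = (0.7, 1.3)
    utility_factor: Tuple[float, float] = (0.9, 1.1)
    multiplier_factor: Tuple[float, float] = (0.8, 1.2)
    cost_factor: Tuple[float, float] = (0.6, 1.6)
    ve_factor: Tuple[float, float] = (0.8, 1.0)
    waning_factor: Tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "seed":
                continue
            lo, hi = getattr(self, f.name)
            if not (0 < lo <= hi):
                raise ParameterError(f"{f.name} range must satisfy 0 < low <= high")

    @classmethod
    def point_masses(cls) -> "SyntheticSpec":
        """All ranges degenerate at 1: reproduces the fixture exactly."""
        one = (1.0, 1.0)
        return cls(one, one, one, one, one, one, one, one, one)


def _u(rng: np.random.Generator, rng_pair: Tuple[float, float]) -> float:
    lo, hi = rng_pair
    return float(rng.uniform(lo, hi)) if hi > lo else lo


def random_parameter_set(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> ParameterSet:
    """Draw one fully valid :class:`ParameterSet` within ``spec``'s ranges."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    cfg = basecase_fixture().to_dict()
    cfg["fixture_id"] = "synthetic"

    for band in AGE_BANDS:
        for sex in SEXES:
            cfg["demography"]["cohort_size"][band][sex] *= _u(rng, spec.size_factor)
            cfg["demography"]["death_probability"][band][sex] = min(
                _PROB_CEIL,
                cfg["demography"]["death_probability"][band][sex] * _u(rng, spec.death_factor),
            )
            cfg["epidemiology"]["hz_incidence"][band][sex] = min(
                _PROB_CEIL,
                cfg["epidemiology"]["hz_incidence"][band][sex] * _u(rng, spec.incidence_factor),
            )
    # independent per-band factors can break the monotone-mortality
    # invariant, so restore it by sorting within sex
    for sex in SEXES:
        probs = sorted(cfg["demography"]["death_probability"][b][sex] for b in AGE_BANDS)
        for b, p in zip(AGE_BANDS, probs):
            cfg["demography"]["death_probability"][b][sex] = p

    for band in PHN_BANDS:
        entry = cfg["epidemiology"]["phn_given_hz"][band]
        entry["mean"] = min(_PROB_CEIL, entry["mean"] * _u(rng, spec.phn_factor))
        if entry.get("se") is not None:
            # keep the Beta well defined: se^2 < mean (1 - mean)
            cap = 0.5 * np.sqrt(entry["mean"] * (1.0 - entry["mean"]))
            entry["se"] = min(entry["se"], float(cap))

    for band in UTILITY_BANDS:
        for sex in SEXES:
            entry = cfg["utilities"]["baseline"][band][sex]
            entry["mean"] = min(_PROB_CEIL, entry["mean"] * _u(rng, spec.utility_factor))
            if entry.get("se") is not None:
                cap = 0.5 * np.sqrt(entry["mean"] * (1.0 - entry["mean"]))
                entry["se"] = min(entry["se"], float(cap))

    mults = [
        min(_PROB_CEIL, cfg["utilities"]["pain_multipliers"][s]["mean"] * _u(rng, spec.multiplier_factor))
        for s in PAIN_STATES
    ]
    for s, m in zip(PAIN_STATES, sorted(mults, reverse=True)):
        cfg["utilities"]["pain_multipliers"][s]["mean"] = m

    for name in (
        "vaccine_price_per_dose",
        "administration_per_dose",
        "primary_care_visit",
        "inpatient_episode",
        "antiviral_course",
        "analgesic_per_month",
    ):
        cfg["costs"][name] *= _u(rng, spec.cost_factor)
    for cat in cfg["costs"]["outpatient_visit"]:
        cfg["costs"]["outpatient_visit"][cat] *= _u(rng, spec.cost_factor)

    for sid in cfg["scenarios"]:
        entry = cfg["scenarios"][sid]
        entry["ve_year1_two_dose"] = min(1.0, entry["ve_year1_two_dose"] * _u(rng, spec.ve_factor))
        entry["one_dose_ve_year1"] = min(1.0, entry["one_dose_ve_year1"] * _u(rng, spec.ve_factor))
        entry["waning_per_year"] *= _u(rng, spec.waning_factor)

    return load_parameters(cfg)
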