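"""Model parameters, uncertainty distributions and configuration I/O.

Everything the model needs lives in one immutable :class:`ParameterSet`:
demography and HZ epidemiology on five-year age bands, health-state
utilities, healthcare utilisation per zoster ICD-10 category, unit costs in
2021 EUR, the vaccination programme, economic settings and the two efficacy
scenarios.  Quantities with published uncertainty (Beta-distributed
proportions and utilities, Binomial visit counts) carry enough information
to be re-drawn for probabilistic sensitivity analysis via
:func:`draw_parameters`; everything else is treated as fixed.

Configuration round-trips through a single hierarchical YAML/JSON document
(see ``data/basecase.yaml``) and, for spreadsheet workflows, through a tidy
``(path, value)`` CSV.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field, replace
from typing import Any, Iterator, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

from .protection import EfficacyScenario

__all__ = [
    "AGE_BANDS",
    "PHN_BANDS",
    "UTILITY_BANDS",
    "SEXES",
    "SEVERITIES",
    "PAIN_STATES",
    "HZ_CATEGORIES",
    "ParameterError",
    "DistributionSpec",
    "beta_from_mean_se",
    "DemographySchedule",
    "EpidemiologySchedule",
    "UtilityTable",
    "UtilizationTable",
    "CostTable",
    "VaccineProgram",
    "EconomicSettings",
    "StrokeAddOn",
    "ParameterSet",
    "load_parameters",
    "draw_parameters",
    "strip_uncertainty",
    "get_path",
    "with_path",
]

AGE_BANDS = ("65-69", "70-74", "75-79", "80-84", "85-89", "90-94", "95-99", "100+")
PHN_BANDS = ("65-69", "70-74", "75-79", "80-84", "85+")
UTILITY_BANDS = ("65-69", "70-79", "80+")
SEXES = ("female", "male")
SEVERITIES = ("no_pain", "mild", "moderate", "severe")
PAIN_STATES = ("mild", "moderate", "severe")
HZ_CATEGORIES = ("B02.9", "B02.2", "B02.3", "B02.7", "B02.8")

#: tolerance on published severity rows summing to 1 (the under-70 acute row
#: sums to 1.01 as printed; rows within tolerance are renormalised on load)
SEVERITY_SUM_TOL = 0.02


class ParameterError(ValueError):
    """A model input violates its declared invariants."""


def band_for_age(age: int) -> str:
    """Five-year demography/incidence band containing ``age``."""
    if age < 65:
        raise ParameterError(f"model covers ages 65+, got {age}")
    if age >= 100:
        return "100+"
    lo = (age // 5) * 5
    return f"{lo}-{lo + 4}"


def phn_band_for_age(age: int) -> str:
    if age < 65:
        raise ParameterError(f"model covers ages 65+, got {age}")
    return "85+" if age >= 85 else band_for_age(age)


def utility_band_for_age(age: int) -> str:
    if age < 65:
        raise ParameterError(f"model covers ages 65+, got {age}")
    if age < 70:
        return "65-69"
    if age < 80:
        return "70-79"
    return "80+"  # ages 100+ reuse the 80+ values (no older row published)


def severity_group_for_age(age: int) -> str:
    return "under70" if age < 70 else "70plus"


# ---------------------------------------------------------------------------
# uncertainty distributions
# ---------------------------------------------------------------------------


def beta_from_mean_se(mean: float, se: float) -> Tuple[float, float]:
    """Method-of-moments Beta shape parameters for a mean and standard error.

    Solves ``alpha / (alpha + beta) = mean`` and
    ``alpha * beta / ((alpha + beta)^2 (alpha + beta + 1)) = se^2``.
    Requires ``0 < mean < 1`` and ``se^2 < mean (1 - mean)``.
    """
    if not 0.0 < mean < 1.0:
        raise ParameterError(f"beta mean must be in (0, 1), got {mean}")
    if se <= 0.0:
        raise ParameterError(f"standard error must be > 0, got {se}")
    var = se * se
    if var >= mean * (1.0 - mean):
        raise ParameterError(
            f"beta distribution undefined: se^2 = {var:g} >= mean(1-mean) = "
            f"{mean * (1.0 - mean):g}"
        )
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


@dataclass(frozen=True)
class DistributionSpec:
    """Uncertainty distribution attached to one scalar model input.

    ``kind`` is one of ``fixed`` (point mass at ``mean``), ``beta_mean_se``
    (Beta via method of moments from ``mean``/``se``), ``beta_shape``
    (explicit ``alpha``/``beta``) or ``binomial`` (visit-count means
    re-drawn as a single Binomial(``n``, ``mean/n``) draw, which preserves
    the mean).
    """

    kind: str
    mean: Optional[float] = None
    se: Optional[float] = None
    alpha: Optional[float] = None
    beta: Optional[float] = None
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind == "fixed":
            if self.mean is None:
                raise ParameterError("fixed spec requires a mean")
        elif self.kind == "beta_mean_se":
            if self.mean is None or self.se is None:
                raise ParameterError("beta_mean_se spec requires mean and se")
            beta_from_mean_se(self.mean, self.se)  # validates
        elif self.kind == "beta_shape":
            if self.alpha is None or self.beta is None:
                raise ParameterError("beta_shape spec requires alpha and beta")
            if self.alpha <= 0.0 or self.beta <= 0.0:
                raise ParameterError(
                    f"beta shapes must be > 0, got ({self.alpha}, {self.beta})"
                )
        elif self.kind == "binomial":
            if self.mean is None or self.n is None:
                raise ParameterError("binomial spec requires mean and n")
            if not (isinstance(self.n, (int, np.integer)) and self.n > 0):
                raise ParameterError(f"binomial n must be a positive integer, got {self.n}")
            if not 0.0 <= self.mean <= self.n:
                raise ParameterError("binomial mean must lie in [0, n]")
        else:
            raise ParameterError(f"unknown distribution kind {self.kind!r}")

    def sample(self, rng: np.random.Generator) -> float:
        """One draw on the scale of the underlying quantity."""
        if self.kind == "fixed":
            return float(self.mean)
        if self.kind == "beta_mean_se":
            a, b = beta_from_mean_se(self.mean, self.se)
            return float(rng.beta(a, b))
        if self.kind == "beta_shape":
            return float(rng.beta(self.alpha, self.beta))
        # binomial: one draw from Binomial(n, mean/n); E = mean
        return float(rng.binomial(self.n, self.mean / self.n))


# ---------------------------------------------------------------------------
# parameter tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DemographySchedule:
    """Cohort sizes and annual all-cause death probabilities per band x sex."""

    cohort_size: dict  # band -> {sex: persons}
    death_probability: dict  # band -> {sex: probability}

    def size(self, band: str, sex: str) -> float:
        return self.cohort_size[band][sex]

    def death_prob(self, age: int, sex: str) -> float:
        return self.death_probability[band_for_age(age)][sex]


@dataclass(frozen=True)
class EpidemiologySchedule:
    """HZ incidence, PHN risk, pain-severity mixes and episode durations."""

    hz_incidence: dict  # band -> {sex: annual probability}
    phn_given_hz: dict  # phn band -> {"mean": p, "se": optional}
    hz_pain_severity: dict  # {"under70"/"70plus" -> {severity: p}}
    phn_pain_severity: dict  # {mild/moderate/severe: p}
    duration_months: dict  # {"hz": 1, "mild": 7, "moderate": 10, "severe": 13}

    def incidence(self, age: int, sex: str) -> float:
        return self.hz_incidence[band_for_age(age)][sex]

    def phn_mean(self, age: int) -> float:
        return self.phn_given_hz[phn_band_for_age(age)]["mean"]

    def phn_se(self, age: int) -> Optional[float]:
        return self.phn_given_hz[phn_band_for_age(age)].get("se")

    def hz_severity(self, age: int) -> dict:
        return self.hz_pain_severity[severity_group_for_age(age)]

    def expected_phn_months(self) -> float:
        """Mean PHN pain duration across the PHN severity mix."""
        return sum(
            self.phn_pain_severity[s] * self.duration_months[s] for s in PAIN_STATES
        )


@dataclass(frozen=True)
class UtilityTable:
    """Baseline HRQoL and pain-state utility multipliers.

    Pain multipliers give the fraction of baseline utility retained while in
    a pain state; "no pain" implicitly retains everything.
    """

    baseline: dict  # utility band -> sex -> {"mean": u, "se": optional}
    pain_multipliers: dict  # state -> {"mean": m, "alpha": opt, "beta": opt}

    def baseline_utility(self, age: int, sex: str) -> float:
        return self.baseline[utility_band_for_age(age)][sex]["mean"]

    def multiplier(self, state: str) -> float:
        if state == "no_pain":
            return 1.0
        return self.pain_multipliers[state]["mean"]


@dataclass(frozen=True)
class UtilizationTable:
    """Visit counts per case and medication uptake, by zoster category."""

    visits: dict  # category -> {"primary"/"outpatient"/"inpatient": mean}
    medication_uptake: dict  # {"uncomplicated"/"complicated" -> {drug: p}}
    category_mix: dict  # category -> share of HZ episodes (sums to 1)
    binomial_n: Optional[int] = None  # PSA n for visit counts; None = fixed

    @staticmethod
    def uptake_class(category: str) -> str:
        return "uncomplicated" if category == "B02.9" else "complicated"

    def uptake(self, category: str, drug: str) -> float:
        return self.medication_uptake[self.uptake_class(category)][drug]


@dataclass(frozen=True)
class CostTable:
    """Unit costs, 2021 EUR."""

    vaccine_price_per_dose: float
    administration_per_dose: float
    primary_care_visit: float
    outpatient_visit: dict  # category -> EUR per visit
    inpatient_episode: float
    antiviral_course: float  # per treated HZ case (one-week course)
    analgesic_per_month: float  # per month of pain
    per_dose_metadata: dict = field(default_factory=dict)  # informational only
    currency: str = "EUR-2021"


@dataclass(frozen=True)
class VaccineProgram:
    """Two-dose vaccination programme delivered at model start."""

    coverage: float  # first-dose coverage of the cohort
    compliance_second_dose: float  # completers among first-dose recipients
    doses_per_completer: int = 2

    @property
    def doses_per_first_dose_recipient(self) -> float:
        """Expected doses per vaccinated person (1 + q * (d - 1))."""
        return 1.0 + self.compliance_second_dose * (self.doses_per_completer - 1)


@dataclass(frozen=True)
class EconomicSettings:
    discount_rate: float = 0.03
    wtp_per_qaly: float = 80000.0
    max_age: int = 105
    cycle_length_years: float = 1.0


@dataclass(frozen=True)
class StrokeAddOn:
    """Optional first-year-after-HZ stroke add-on (disabled in the base case).

    Numeric inputs are user-supplied: each incident HZ episode generates
    ``(RR - 1) * baseline incidence`` excess strokes, each charged
    ``cost_per_stroke`` and one year at the reduced utility multiplier.
    """

    enabled: bool = False
    relative_risk_first_year: float = 1.0
    cost_per_stroke: float = 0.0
    utility_multiplier_first_year: float = 1.0
    baseline_incidence: Optional[dict] = None  # band -> {sex: probability}

    def incidence(self, age: int, sex: str) -> float:
        if not self.baseline_incidence:
            return 0.0
        return self.baseline_incidence[band_for_age(age)][sex]


# ---------------------------------------------------------------------------
# the full parameter set
# ---------------------------------------------------------------------------


def _require(table: Mapping, key: str, context: str):
    try:
        return table[key]
    except (KeyError, TypeError):
        raise ParameterError(f"missing {context!r} entry {key!r}") from None


def _check_prob(value: float, name: str) -> None:
    if not 0.0 <= value <= 1.0:
        raise ParameterError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class ParameterSet:
    """Immutable bundle of all model inputs.

    Build one with :func:`load_parameters` (which validates and renormalises)
    rather than directly.
    """

    demography: DemographySchedule
    epidemiology: EpidemiologySchedule
    utilities: UtilityTable
    utilization: UtilizationTable
    costs: CostTable
    program: VaccineProgram
    economics: EconomicSettings
    scenarios: dict  # scenario_id -> EfficacyScenario
    stroke: StrokeAddOn = field(default_factory=StrokeAddOn)
    fixture_id: str = "unnamed"

    # -- validation --------------------------------------------------------

    def validate(self) -> "ParameterSet":
        dem, epi, util, ut, c = (
            self.demography,
            self.epidemiology,
            self.utilities,
            self.utilization,
            self.costs,
        )
        for band in AGE_BANDS:
            for sex in SEXES:
                size = _require(_require(dem.cohort_size, band, "cohort_size"), sex, band)
                if size < 0:
                    raise ParameterError(f"cohort_size[{band}][{sex}] must be >= 0")
                _check_prob(
                    _require(_require(dem.death_probability, band, "death_probability"), sex, band),
                    f"death_probability[{band}][{sex}]",
                )
                _check_prob(
                    _require(_require(epi.hz_incidence, band, "hz_incidence"), sex, band),
                    f"hz_incidence[{band}][{sex}]",
                )
        for sex in SEXES:
            probs = [dem.death_probability[b][sex] for b in AGE_BANDS]
            if any(b < a for a, b in zip(probs, probs[1:])):
                raise ParameterError(
                    f"death_probability must be non-decreasing with age band ({sex})"
                )
        for band in PHN_BANDS:
            entry = _require(epi.phn_given_hz, band, "phn_given_hz")
            _check_prob(entry["mean"], f"phn_given_hz[{band}].mean")
            se = entry.get("se")
            if se is not None and se <= 0:
                raise ParameterError(f"phn_given_hz[{band}].se must be > 0")
        for group, row in epi.hz_pain_severity.items():
            total = sum(_require(row, s, f"hz_pain_severity[{group}]") for s in SEVERITIES)
            if abs(total - 1.0) > 1e-6:
                raise ParameterError(
                    f"hz_pain_severity[{group}] sums to {total:.4f} after loading"
                )
            for s, p in row.items():
                _check_prob(p, f"hz_pain_severity[{group}][{s}]")
        phn_total = sum(epi.phn_pain_severity[s] for s in PAIN_STATES)
        if abs(phn_total - 1.0) > 1e-6:
            raise ParameterError(f"phn_pain_severity sums to {phn_total:.4f}")
        for s in ("hz",) + PAIN_STATES:
            if _require(epi.duration_months, s, "duration_months") <= 0:
                raise ParameterError(f"duration_months[{s}] must be > 0")
        for band in UTILITY_BANDS:
            for sex in SEXES:
                entry = _require(_require(util.baseline, band, "utilities.baseline"), sex, band)
                _check_prob(entry["mean"], f"utilities.baseline[{band}][{sex}].mean")
                se = entry.get("se")
                if se is not None and se <= 0:
                    raise ParameterError(f"utilities.baseline[{band}][{sex}].se must be > 0")
        mults = []
        for state in PAIN_STATES:
            entry = _require(util.pain_multipliers, state, "pain_multipliers")
            _check_prob(entry["mean"], f"pain_multipliers[{state}].mean")
            mults.append(entry["mean"])
            if (entry.get("alpha") is None) != (entry.get("beta") is None):
                raise ParameterError(f"pain_multipliers[{state}] needs both alpha and beta")
            if entry.get("alpha") is not None and (entry["alpha"] <= 0 or entry["beta"] <= 0):
                raise ParameterError(f"pain_multipliers[{state}] shapes must be > 0")
        if not mults[0] > mults[1] > mults[2]:
            raise ParameterError(
                "pain multipliers must satisfy mild > moderate > severe, got "
                f"{mults}"
            )
        mix_total = 0.0
        for cat in HZ_CATEGORIES:
            row = _require(ut.visits, cat, "utilization.visits")
            for level in ("primary", "outpatient", "inpatient"):
                if _require(row, level, f"visits[{cat}]") < 0:
                    raise ParameterError(f"visits[{cat}][{level}] must be >= 0")
            share = _require(ut.category_mix, cat, "category_mix")
            _check_prob(share, f"category_mix[{cat}]")
            mix_total += share
            _require(c.outpatient_visit, cat, "costs.outpatient_visit")
        if abs(mix_total - 1.0) > 1e-6:
            raise ParameterError(f"category_mix sums to {mix_total:.6f}, expected 1")
        if ut.binomial_n is not None and not (
            isinstance(ut.binomial_n, (int, np.integer)) and ut.binomial_n > 0
        ):
            raise ParameterError("utilization.binomial_n must be a positive integer")
        for cls in ("uncomplicated", "complicated"):
            for drug in ("antivirals", "analgesics"):
                _check_prob(
                    _require(_require(ut.medication_uptake, cls, "medication_uptake"), drug, cls),
                    f"medication_uptake[{cls}][{drug}]",
                )
        for name in (
            "vaccine_price_per_dose",
            "administration_per_dose",
            "primary_care_visit",
            "inpatient_episode",
            "antiviral_course",
            "analgesic_per_month",
        ):
            if getattr(c, name) < 0:
                raise ParameterError(f"costs.{name} must be >= 0")
        for cat, v in c.outpatient_visit.items():
            if v < 0:
                raise ParameterError(f"costs.outpatient_visit[{cat}] must be >= 0")
        _check_prob(self.program.coverage, "program.coverage")
        _check_prob(self.program.compliance_second_dose, "program.compliance_second_dose")
        if self.program.doses_per_completer < 1:
            raise ParameterError("program.doses_per_completer must be >= 1")
        econ = self.economics
        if econ.discount_rate < 0:
            raise ParameterError("economics.discount_rate must be >= 0")
        if econ.wtp_per_qaly <= 0:
            raise ParameterError("economics.wtp_per_qaly must be > 0")
        if econ.max_age <= 100:
            raise ParameterError("economics.max_age must exceed the oldest start age (100)")
        if self.stroke.relative_risk_first_year < 1.0:
            raise ParameterError("stroke.relative_risk_first_year must be >= 1")
        _check_prob(
            self.stroke.utility_multiplier_first_year,
            "stroke.utility_multiplier_first_year",
        )
        if self.stroke.enabled and not self.stroke.baseline_incidence:
            raise ParameterError("stroke add-on enabled without baseline_incidence")
        if not self.scenarios:
            raise ParameterError("at least one efficacy scenario is required")
        return self

    # -- uncertainty -------------------------------------------------------

    def distributions(self) -> dict:
        """Mapping from '/'-separated parameter path to its distribution.

        Only stochastic quantities appear; anything absent is fixed.
        """
        specs: dict = {}
        for band in PHN_BANDS:
            entry = self.epidemiology.phn_given_hz[band]
            if entry.get("se") is not None:
                specs[f"epidemiology/phn_given_hz/{band}/mean"] = DistributionSpec(
                    "beta_mean_se", mean=entry["mean"], se=entry["se"]
                )
        for band in UTILITY_BANDS:
            for sex in SEXES:
                entry = self.utilities.baseline[band][sex]
                if entry.get("se") is not None:
                    specs[f"utilities/baseline/{band}/{sex}/mean"] = DistributionSpec(
                        "beta_mean_se", mean=entry["mean"], se=entry["se"]
                    )
        for state in PAIN_STATES:
            entry = self.utilities.pain_multipliers[state]
            if entry.get("alpha") is not None:
                specs[f"utilities/pain_multipliers/{state}/mean"] = DistributionSpec(
                    "beta_shape", alpha=entry["alpha"], beta=entry["beta"]
                )
        n = self.utilization.binomial_n
        if n is not None:
            for cat in HZ_CATEGORIES:
                for level in ("primary", "outpatient", "inpatient"):
                    specs[f"utilization/visits/{cat}/{level}"] = DistributionSpec(
                        "binomial", mean=self.utilization.visits[cat][level], n=n
                    )
        return specs

    # -- config I/O --------------------------------------------------------

    def to_dict(self) -> dict:
        """Plain nested-dict form suitable for YAML/JSON round-tripping."""
        scen = {
            sid: {k: (list(v) if isinstance(v, tuple) else v)
                  for k, v in dataclasses.asdict(s).items() if v is not None}
            for sid, s in self.scenarios.items()
        }
        return {
            "fixture_id": self.fixture_id,
            "demography": dataclasses.asdict(self.demography),
            "epidemiology": dataclasses.asdict(self.epidemiology),
            "utilities": dataclasses.asdict(self.utilities),
            "utilization": dataclasses.asdict(self.utilization),
            "costs": dataclasses.asdict(self.costs),
            "program": dataclasses.asdict(self.program),
            "economics": dataclasses.asdict(self.economics),
            "scenarios": scen,
            "stroke": dataclasses.asdict(self.stroke),
        }

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "ParameterSet":
        """Build (without validating) from a nested configuration mapping.

        Acute pain-severity rows within :data:`SEVERITY_SUM_TOL` of one are
        renormalised here; rows further off raise :class:`ParameterError`.
        """

        def _table(name: str) -> Mapping:
            return _require(cfg, name, "configuration")

        epi_cfg = dict(_table("epidemiology"))
        severity = {}
        for group, row in _require(epi_cfg, "hz_pain_severity", "epidemiology").items():
            total = sum(_require(row, s, f"hz_pain_severity[{group}]") for s in SEVERITIES)
            if abs(total - 1.0) > SEVERITY_SUM_TOL:
                raise ParameterError(
                    f"hz_pain_severity[{group}] sums to {total:.4f}, beyond "
                    f"tolerance {SEVERITY_SUM_TOL}"
                )
            severity[group] = {s: row[s] / total for s in SEVERITIES}
        phn_sev = dict(_require(epi_cfg, "phn_pain_severity", "epidemiology"))
        phn_total = sum(phn_sev[s] for s in PAIN_STATES)
        if abs(phn_total - 1.0) > SEVERITY_SUM_TOL:
            raise ParameterError(
                f"phn_pain_severity sums to {phn_total:.4f}, beyond tolerance"
            )
        phn_sev = {s: phn_sev[s] / phn_total for s in PAIN_STATES}

        scen_cfg = _table("scenarios")
        scenarios = {}
        for sid, entry in scen_cfg.items():
            kwargs = dict(entry)
            kwargs.setdefault("scenario_id", sid)
            if kwargs.get("explicit_ve") is not None:
                kwargs["explicit_ve"] = tuple(kwargs["explicit_ve"])
            scenarios[sid] = EfficacyScenario(**kwargs)

        stroke_cfg = dict(cfg.get("stroke") or {})
        ut_cfg = _table("utilization")
        return cls(
            demography=DemographySchedule(
                cohort_size=_require(_table("demography"), "cohort_size", "demography"),
                death_probability=_require(
                    _table("demography"), "death_probability", "demography"
                ),
            ),
            epidemiology=EpidemiologySchedule(
                hz_incidence=_require(epi_cfg, "hz_incidence", "epidemiology"),
                phn_given_hz=_require(epi_cfg, "phn_given_hz", "epidemiology"),
                hz_pain_severity=severity,
                phn_pain_severity=phn_sev,
                duration_months=_require(epi_cfg, "duration_months", "epidemiology"),
            ),
            utilities=UtilityTable(
                baseline=_require(_table("utilities"), "baseline", "utilities"),
                pain_multipliers=_require(
                    _table("utilities"), "pain_multipliers", "utilities"
                ),
            ),
            utilization=UtilizationTable(
                visits=_require(ut_cfg, "visits", "utilization"),
                medication_uptake=_require(ut_cfg, "medication_uptake", "utilization"),
                category_mix=_require(ut_cfg, "category_mix", "utilization"),
                binomial_n=ut_cfg.get("binomial_n"),
            ),
            costs=CostTable(**_table("costs")),
            program=VaccineProgram(**_table("program")),
            economics=EconomicSettings(**_table("economics")),
            scenarios=scenarios,
            stroke=StrokeAddOn(**stroke_cfg),
            fixture_id=cfg.get("fixture_id", "unnamed"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def load_parameters(source) -> ParameterSet:
    """Load, renormalise and validate a :class:`ParameterSet`.

    ``source`` may be a nested mapping, a path to a YAML or JSON document,
    or an open text stream.  Raises :class:`ParameterError` naming the
    offending field on any invariant violation.
    """
    if isinstance(source, Mapping):
        cfg = source
    elif isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    elif isinstance(source, io.TextIOBase) or hasattr(source, "read"):
        cfg = yaml.safe_load(source)
    else:
        raise TypeError(f"cannot load parameters from {type(source)!r}")
    if not isinstance(cfg, Mapping):
        raise ParameterError("configuration document must be a mapping")
    return ParameterSet.from_dict(cfg).validate()


# ---------------------------------------------------------------------------
# path access (used by the PSA and the one-way sensitivity runner)
# ---------------------------------------------------------------------------


def _split(path: str) -> Sequence[str]:
    segs = path.split("/")
    if not segs or any(not s for s in segs):
        raise ParameterError(f"malformed parameter path {path!r}")
    return segs


def get_path(obj: Any, path: str) -> Any:
    """Fetch a value by '/'-separated path through dataclasses and dicts."""
    node = obj
    for seg in _split(path):
        if dataclasses.is_dataclass(node):
            if not hasattr(node, seg):
                raise ParameterError(f"path segment {seg!r} not found in {path!r}")
            node = getattr(node, seg)
        elif isinstance(node, Mapping):
            if seg not in node:
                raise ParameterError(f"path segment {seg!r} not found in {path!r}")
            node = node[seg]
        else:
            raise ParameterError(f"cannot descend into {type(node).__name__} at {seg!r}")
    return node


def _set(node: Any, segs: Sequence[str], value: Any, path: str) -> Any:
    if not segs:
        return value
    head = segs[0]
    if dataclasses.is_dataclass(node):
        if not hasattr(node, head):
            raise ParameterError(f"path segment {head!r} not found in {path!r}")
        return replace(node, **{head: _set(getattr(node, head), segs[1:], value, path)})
    if isinstance(node, Mapping):
        if head not in node:
            raise ParameterError(f"path segment {head!r} not found in {path!r}")
        out = dict(node)
        out[head] = _set(node[head], segs[1:], value, path)
        return out
    raise ParameterError(f"cannot descend into {type(node).__name__} at {head!r}")


def with_path(params: Any, path: str, value: Any) -> Any:
    """Return a copy of ``params`` with the value at ``path`` replaced."""
    return _set(params, _split(path), value, path)


# ---------------------------------------------------------------------------
# PSA sampling
# ---------------------------------------------------------------------------


def draw_parameters(params: ParameterSet, rng: np.random.Generator) -> ParameterSet:
    """One probabilistic-sensitivity-analysis draw of the parameter set.

    Fixed quantities pass through untouched; Beta-distributed proportions,
    utilities and multipliers and Binomial visit counts are re-sampled from
    their declared distributions.  Paths are visited in sorted order from a
    single stream, so the draw is reproducible for a given generator state.
    """
    out = params
    specs = params.distributions()
    for path in sorted(specs):
        out = with_path(out, path, specs[path].sample(rng))
    return out


def strip_uncertainty(params: ParameterSet) -> ParameterSet:
    """All-fixed variant of ``params`` (every PSA distribution removed)."""
    out = params
    for band in PHN_BANDS:
        entry = dict(out.epidemiology.phn_given_hz[band])
        entry.pop("se", None)
        out = with_path(out, f"epidemiology/phn_given_hz/{band}", entry)
    for band in UTILITY_BANDS:
        for sex in SEXES:
            entry = dict(out.utilities.baseline[band][sex])
            entry.pop("se", None)
            out = with_path(out, f"utilities/baseline/{band}/{sex}", entry)
    for state in PAIN_STATES:
        entry = dict(out.utilities.pain_multipliers[state])
        entry.pop("alpha", None)
        entry.pop("beta", None)
        out = with_path(out, f"utilities/pain_multipliers/{state}", entry)
    out = replace(out, utilization=replace(out.utilization, binomial_n=None))
    return out


# ---------------------------------------------------------------------------
# tidy CSV export / import
# ---------------------------------------------------------------------------


def iter_numeric_leaves(tree: Any, prefix: str = "") -> Iterator[Tuple[str, float]]:
    """Yield ``(path, value)`` for every numeric scalar in a config tree."""
    if isinstance(tree, Mapping):
        for key, sub in tree.items():
            yield from iter_numeric_leaves(sub, f"{prefix}{key}/")
    elif isinstance(tree, (list, tuple)):
        for i, sub in enumerate(tree):
            yield from iter_numeric_leaves(sub, f"{prefix}{i}/")
    elif isinstance(tree, bool) or tree is None or isinstance(tree, str):
        return
    elif isinstance(tree, (int, float)):
        yield prefix[:-1], float(tree)


def to_tidy_frame(params: ParameterSet):
    """Tidy one-row-per-quantity table: columns ``table``, ``path``, ``value``."""
    import pandas as pd

    rows = [
        {"table": path.split("/", 1)[0], "path": path, "value": value}
        for path, value in iter_numeric_leaves(params.to_dict())
    ]
    return pd.DataFrame(rows)


def from_tidy_frame(base: ParameterSet, frame) -> ParameterSet:
    """Apply a tidy ``(path, value)`` table onto ``base`` and revalidate."""
    out = base
    for path, value in zip(frame["path"], frame["value"]):
        current = get_path(out, path)
        if isinstance(current, (int, np.integer)) and not isinstance(current, bool):
            value = int(round(value))
        else:
            value = float(value)
        out = with_path(out, path, value)
    return out.validate()
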