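"""Vaccine efficacy trajectories and population-level protection profiles.

Two efficacy scenarios are modelled.  The ``rct`` scenario starts from the
two-dose year-1 efficacy reported in long-term randomised-trial follow-up
(97.7%); the ``observational`` scenario starts from the pooled two-dose
effectiveness seen in register-based studies (79.2%).  Both wane by an
absolute 3.1 percentage points per model year and are floored at zero.  A
single dose protects in year 1 only.  A conservative structural switch sets
two-dose protection to zero after year 10.

Coverage and second-dose compliance convert the efficacy curves into a
per-cycle incidence multiplier for the vaccinated arm:

    multiplier(t) = 1 - c * (q * VE2(t) + (1 - q) * VE1(t))

with ``c`` first-dose coverage and ``q`` the share of first-dose recipients
completing the second dose.  The multiplier applies to first and recurrent
HZ incidence alike.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

if TYPE_CHECKING:  # pragma: no cover
    from .parameters import VaccineProgram


@dataclass(frozen=True)
class EfficacyScenario:
    """Definition of one vaccine-protection curve.

    Parameters
    ----------
    scenario_id
        Short label, conventionally ``"rct"`` or ``"observational"``.
    ve_year1_two_dose
        Two-dose vaccine efficacy/effectiveness in model year 1 (proportion).
    waning_per_year
        Absolute (percentage-point) annual decline applied from year 2 on.
    one_dose_ve_year1
        Protection of first-dose-only recipients during year 1.  Not
        published for this model; the shipped default (0.70) is a
        reconstruction and is configurable.
    one_dose_ve_later
        One-dose protection after year 1 (zero: waning is too uncertain).
    zero_after_10_years
        Structural sensitivity switch: no protection beyond year 10.
    explicit_ve
        Optional year-by-year two-dose VE vector (year 1 first) overriding
        the parametric rule; beyond its last entry the parametric waning
        continues from the last value.
    """

    scenario_id: str
    ve_year1_two_dose: float
    waning_per_year: float = 0.031
    one_dose_ve_year1: float = 0.70
    one_dose_ve_later: float = 0.0
    zero_after_10_years: bool = False
    explicit_ve: Optional[tuple] = None

    def __post_init__(self) -> None:
        for name in ("ve_year1_two_dose", "one_dose_ve_year1", "one_dose_ve_later"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.scenario_id}.{name} must be in [0, 1], got {v}")
        if self.waning_per_year < 0.0:
            raise ValueError("waning_per_year must be >= 0")
        if self.explicit_ve is not None:
            object.__setattr__(self, "explicit_ve", tuple(float(v) for v in self.explicit_ve))
            ve = self.explicit_ve
            if any(not 0.0 <= v <= 1.0 for v in ve):
                raise ValueError("explicit_ve values must be in [0, 1]")
            if any(b > a for a, b in zip(ve, ve[1:])):
                pass  # non-increasing holds; pairs checked below
            if any(later > earlier for earlier, later in zip(ve, ve[1:])):
                raise ValueError("explicit_ve must be non-increasing over years")


def ve_two_dose(scenario: EfficacyScenario, year: int) -> float:
    """Two-dose protection in model year ``year`` (1-based).

    Linear absolute waning from the year-1 value, floored at zero; under the
    ``zero_after_10_years`` switch, zero from year 11 on.  An explicit
    year-by-year vector, when supplied, takes precedence within its length.
    """
    if year < 1:
        raise ValueError(f"model year must be >= 1, got {year}")
    if scenario.zero_after_10_years and year > 10:
        return 0.0
    ve = scenario.explicit_ve
    if ve is not None:
        if year <= len(ve):
            return ve[year - 1]
        return max(0.0, ve[-1] - scenario.waning_per_year * (year - len(ve)))
    return max(0.0, scenario.ve_year1_two_dose - scenario.waning_per_year * (year - 1))


def ve_one_dose(scenario: EfficacyScenario, year: int) -> float:
    """Protection of first-dose-only recipients in model year ``year``."""
    if year < 1:
        raise ValueError(f"model year must be >= 1, got {year}")
    return scenario.one_dose_ve_year1 if year == 1 else scenario.one_dose_ve_later


@dataclass(frozen=True)
class ProtectionProfile:
    """Per-year incidence multipliers for the vaccinated arm.

    ``multipliers[t - 1]`` is the factor applied to HZ incidence in model
    year ``t``.  Unvaccinated persons contribute weight ``1 - c``, one-dose
    recipients ``c * (1 - q)``, completers ``c * q``.
    """

    scenario_id: str
    multipliers: tuple

    def __len__(self) -> int:
        return len(self.multipliers)

    def multiplier(self, year: int) -> float:
        if year < 1:
            raise ValueError(f"model year must be >= 1, got {year}")
        if year > len(self.multipliers):
            raise ValueError(
                f"protection profile covers {len(self.multipliers)} years, "
                f"year {year} requested"
            )
        return self.multipliers[year - 1]


def build_protection_profile(
    scenario: EfficacyScenario, program: "VaccineProgram", horizon: int
) -> ProtectionProfile:
    """Combine an efficacy scenario with programme coverage and compliance.

    ``horizon`` is the number of model years to cover (>= 1).
    """
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    c = program.coverage
    q = program.compliance_second_dose
    mult = tuple(
        1.0 - c * (q * ve_two_dose(scenario, t) + (1.0 - q) * ve_one_dose(scenario, t))
        for t in range(1, horizon + 1)
    )
    return ProtectionProfile(scenario_id=scenario.scenario_id, multipliers=mult)
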