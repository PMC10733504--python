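"""Model inputs and economic derivations for the deafness-screening CEA.

Every numeric input of the decision model lives here: per-person screening
costs, downstream intervention costs, lifetime income/expenditure figures,
couple genotype prevalences, family decision probabilities, birth-outcome
probabilities and the utility/willingness-to-pay constants.  All monetary
values are 2021 USD.  Each parameter carries a provenance tag
(``survey`` / ``literature`` / ``mendelian`` / ``expert``) that downstream
sensitivity analyses use to pick perturbation spans.

The module also provides the small set of economic primitives the model's
constants were derived with: annuity-style discounted lifetime factors,
geometric growth projection, lifetime present values, the GDP-multiple
willingness-to-pay threshold and the utility-weighted deaf QALY.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "ScreeningCosts",
    "InterventionCosts",
    "FutureFinancials",
    "GenotypePrevalence",
    "BehaviorProbs",
    "OutcomeProbs",
    "UtilityParams",
    "ParameterSet",
    "ParameterValidationError",
    "UnknownParameterError",
    "default_parameters",
    "load_parameters",
    "per_person_screening_cost",
    "discounted_lifetime_factor",
    "project_growth",
    "growth_rate_from_endpoints",
    "lifetime_value",
    "derive_wtp",
    "derive_deaf_qaly",
    "DEFAULT_LIFETIME_FACTOR",
]

_SUM_TOL = 1e-9

#: Calibrated discounted lifetime factor (years of annual value per lifetime).
#: Back-solved from the lifetime income of a healthy individual (115,622.00)
#: and the 2021 per-capita disposable income (5,243.00/yr) so that all four
#: lifetime figures and the 22.1 healthy QALY are reproduced; the underlying
#: national life table is not an input of this package.
DEFAULT_LIFETIME_FACTOR = 115622.00 / 5243.00


class ParameterValidationError(ValueError):
    """Raised when a parameter set violates an invariant; lists offenders."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__("invalid parameter set:\n  " + "\n  ".join(problems))


class UnknownParameterError(KeyError):
    """Raised when a configuration names a parameter id that does not exist."""


@dataclass
class ScreeningCosts:
    """Per-person cost components of one genetic screening test (USD)."""

    test_cost: float = 52.20
    labor_cost: float = 9.00
    promotion_cost: float = 3.00


@dataclass
class InterventionCosts:
    """Per-case costs of downstream interventions and of giving birth (USD)."""

    art_pgt: float = 11940.30
    amniocentesis: float = 2686.60
    art_productivity_loss: float = 28.70
    amnio_productivity_loss: float = 14.40
    reproductive: float = 651.00


@dataclass
class FutureFinancials:
    """Discounted lifetime income and medical expenditure (USD/lifetime)."""

    income_healthy: float = 115622.00
    income_disabled: float = 65996.00
    medical_healthy: float = 6961.40
    medical_disabled: float = 11142.40


@dataclass
class GenotypePrevalence:
    """Marginal carrier-genotype frequencies of wives and husbands.

    ``bi`` = bi-allelic pathogenic genotype, ``mono`` = mono-allelic
    (heterozygous carrier), ``neg`` = screen-negative wild type.  Each
    spouse's triple must lie on the probability simplex.
    """

    wife_bi: float = 0.0050
    wife_mono: float = 0.1572
    wife_neg: float = 0.8378
    husband_bi: float = 0.0074
    husband_mono: float = 0.1370
    husband_neg: float = 0.8556


@dataclass
class BehaviorProbs:
    """Family reproductive decisions conditional on risk information."""

    high_risk_birth: float = 0.1930
    high_risk_none: float = 0.8070
    med_art: float = 0.1774
    med_amnio: float = 0.7096
    med_natural: float = 0.0565
    med_none: float = 0.0565
    post_amnio_positive_birth: float = 0.1930
    post_amnio_positive_terminate: float = 0.8070


@dataclass
class OutcomeProbs:
    """Probability that a birth is deaf, conditional on path taken.

    The medium-risk natural-birth and amniocentesis-positive rates follow
    Mendelian segregation for recessive disease (0.5 when one parent is
    bi-allelic and the other a carrier, 0.25 for carrier x carrier).
    """

    deaf_given_low_natural: float = 0.0010
    deaf_given_high_natural: float = 0.9990
    deaf_given_medhigh_natural: float = 0.5000
    deaf_given_medlow_natural: float = 0.2500
    deaf_given_art: float = 0.0010
    deaf_given_amnio_positive_birth: float = 0.9990
    deaf_given_amnio_negative_birth: float = 0.0010
    amnio_positive_medhigh: float = 0.5000
    amnio_positive_medlow: float = 0.2500


@dataclass
class UtilityParams:
    """Lifetime utilities, discounting and willingness-to-pay constants.

    ``deaf_qaly`` defaults to the reporting-rounded 20.1 (= 22.1 x 0.91
    rounded to one decimal); :func:`derive_deaf_qaly` gives the unrounded
    product for users who prefer it.
    """

    healthy_qaly: float = 22.1
    deaf_utility_weight: float = 0.91
    deaf_qaly: float = 20.1
    discount_rate: float = 0.05
    gdp_per_capita: float = 12086.00
    wtp_multiplier: float = 3.0
    wtp_lifetime: float = 801302.0


@dataclass
class ParameterSet:
    """The complete calibrated input of the screening decision model."""

    screening_costs: ScreeningCosts = field(default_factory=ScreeningCosts)
    intervention_costs: InterventionCosts = field(default_factory=InterventionCosts)
    future: FutureFinancials = field(default_factory=FutureFinancials)
    prevalence: GenotypePrevalence = field(default_factory=GenotypePrevalence)
    behavior: BehaviorProbs = field(default_factory=BehaviorProbs)
    outcomes: OutcomeProbs = field(default_factory=OutcomeProbs)
    utility: UtilityParams = field(default_factory=UtilityParams)
    lifetime_factor: float = DEFAULT_LIFETIME_FACTOR

    # -- flat-key access -------------------------------------------------

    def get(self, key: str) -> float:
        section, attr = _resolve(key)
        obj = self if section is None else getattr(self, section)
        return getattr(obj, attr)

    def set(self, key: str, value: float) -> None:
        section, attr = _resolve(key)
        obj = self if section is None else getattr(self, section)
        setattr(obj, attr, float(value))

    @property
    def provenance(self) -> dict[str, str]:
        """Provenance tag per flat parameter id."""
        return {key: tag for key, (_, _, tag) in _REGISTRY.items()}

    def to_config(self) -> dict[str, float]:
        """Flat ``{parameter id: value}`` mapping (round-trips exactly)."""
        return {key: self.get(key) for key in _REGISTRY}

    def copy(self) -> "ParameterSet":
        fresh = ParameterSet()
        for key, value in self.to_config().items():
            fresh.set(key, value)
        return fresh

    def validate(self) -> None:
        """Raise :class:`ParameterValidationError` on any invariant breach."""
        problems: list[str] = []

        for key in _REGISTRY:
            v = self.get(key)
            if not math.isfinite(v):
                problems.append(f"{key}: not finite ({v})")
            elif key.startswith("p.") and not (0.0 <= v <= 1.0):
                problems.append(f"{key}: probability outside [0,1] ({v})")
            elif key.startswith("c.") and v < 0:
                problems.append(f"{key}: negative cost ({v})")

        for name, keys in PROBABILITY_BLOCKS.items():
            s = sum(self.get(k) for k in keys)
            if abs(s - 1.0) > _SUM_TOL:
                problems.append(f"{name}: probabilities {keys} sum to {s!r}, not 1")

        fin = self.future
        if not fin.income_healthy > fin.income_disabled >= 0:
            problems.append("future income: need income_healthy > income_disabled >= 0")
        if not fin.medical_disabled > fin.medical_healthy >= 0:
            problems.append("future medical: need medical_disabled > medical_healthy >= 0")

        u = self.utility
        if not 0 < u.deaf_utility_weight <= 1:
            problems.append("u.deaf_utility_weight: must lie in (0, 1]")
        if u.deaf_qaly > u.healthy_qaly:
            problems.append("u.deaf_qaly: exceeds u.healthy_qaly")
        if u.discount_rate < 0:
            problems.append("u.discount_rate: negative")
        if self.lifetime_factor < 0:
            problems.append("econ.lifetime_factor: negative")

        if problems:
            raise ParameterValidationError(problems)


# Flat parameter registry: id -> (section attribute, field name, provenance).
# Ids use c.* for costs, p.* for probabilities, u.* for utility constants.
_REGISTRY: dict[str, tuple[str | None, str, str]] = {
    "c.screening.test": ("screening_costs", "test_cost", "survey"),
    "c.screening.labor": ("screening_costs", "labor_cost", "survey"),
    "c.screening.promotion": ("screening_costs", "promotion_cost", "survey"),
    "c.intervention.art_pgt": ("intervention_costs", "art_pgt", "survey"),
    "c.intervention.amniocentesis": ("intervention_costs", "amniocentesis", "survey"),
    "c.intervention.art_productivity_loss": ("intervention_costs", "art_productivity_loss", "literature"),
    "c.intervention.amnio_productivity_loss": ("intervention_costs", "amnio_productivity_loss", "literature"),
    "c.intervention.reproductive": ("intervention_costs", "reproductive", "literature"),
    "c.future.income_healthy": ("future", "income_healthy", "literature"),
    "c.future.income_disabled": ("future", "income_disabled", "literature"),
    "c.future.medical_healthy": ("future", "medical_healthy", "literature"),
    "c.future.medical_disabled": ("future", "medical_disabled", "literature"),
    "p.wife_bi": ("prevalence", "wife_bi", "survey"),
    "p.wife_mono": ("prevalence", "wife_mono", "survey"),
    "p.wife_neg": ("prevalence", "wife_neg", "survey"),
    "p.husband_bi": ("prevalence", "husband_bi", "survey"),
    "p.husband_mono": ("prevalence", "husband_mono", "survey"),
    "p.husband_neg": ("prevalence", "husband_neg", "survey"),
    "p.high_risk_birth": ("behavior", "high_risk_birth", "literature"),
    "p.high_risk_none": ("behavior", "high_risk_none", "literature"),
    "p.med_art": ("behavior", "med_art", "expert"),
    "p.med_amnio": ("behavior", "med_amnio", "expert"),
    "p.med_natural": ("behavior", "med_natural", "expert"),
    "p.med_none": ("behavior", "med_none", "expert"),
    "p.post_amnio_positive_birth": ("behavior", "post_amnio_positive_birth", "literature"),
    "p.post_amnio_positive_terminate": ("behavior", "post_amnio_positive_terminate", "literature"),
    "p.deaf_given_low_natural": ("outcomes", "deaf_given_low_natural", "literature"),
    "p.deaf_given_high_natural": ("outcomes", "deaf_given_high_natural", "expert"),
    "p.deaf_given_medhigh_natural": ("outcomes", "deaf_given_medhigh_natural", "mendelian"),
    "p.deaf_given_medlow_natural": ("outcomes", "deaf_given_medlow_natural", "expert"),
    "p.deaf_given_art": ("outcomes", "deaf_given_art", "literature"),
    "p.deaf_given_amnio_positive_birth": ("outcomes", "deaf_given_amnio_positive_birth", "expert"),
    "p.deaf_given_amnio_negative_birth": ("outcomes", "deaf_given_amnio_negative_birth", "literature"),
    "p.amnio_positive_medhigh": ("outcomes", "amnio_positive_medhigh", "mendelian"),
    "p.amnio_positive_medlow": ("outcomes", "amnio_positive_medlow", "mendelian"),
    "u.healthy_qaly": ("utility", "healthy_qaly", "literature"),
    "u.deaf_utility_weight": ("utility", "deaf_utility_weight", "literature"),
    "u.deaf_qaly": ("utility", "deaf_qaly", "literature"),
    "u.discount_rate": ("utility", "discount_rate", "literature"),
    "u.gdp_per_capita": ("utility", "gdp_per_capita", "literature"),
    "u.wtp_multiplier": ("utility", "wtp_multiplier", "literature"),
    "u.wtp_lifetime": ("utility", "wtp_lifetime", "literature"),
    "econ.lifetime_factor": (None, "lifetime_factor", "literature"),
}

#: Probability blocks that must each sum to 1 (and are renormalized together
#: by sensitivity analyses).
PROBABILITY_BLOCKS: dict[str, tuple[str, ...]] = {
    "wife genotype": ("p.wife_bi", "p.wife_mono", "p.wife_neg"),
    "husband genotype": ("p.husband_bi", "p.husband_mono", "p.husband_neg"),
    "high-risk decision": ("p.high_risk_birth", "p.high_risk_none"),
    "medium-risk decision": ("p.med_art", "p.med_amnio", "p.med_natural", "p.med_none"),
    "post-amnio decision": ("p.post_amnio_positive_birth", "p.post_amnio_positive_terminate"),
}


def _resolve(key: str) -> tuple[str | None, str]:
    try:
        section, attr, _ = _REGISTRY[key]
    except KeyError:
        raise UnknownParameterError(f"unknown parameter id: {key!r}") from None
    return section, attr


def default_parameters() -> ParameterSet:
    """A freshly built, validated default parameter set."""
    p = ParameterSet()
    p.validate()
    return p


def load_parameters(config: str | Path | dict | None = None) -> ParameterSet:
    """Build a :class:`ParameterSet` from defaults plus optional overrides.

    Parameters
    ----------
    config
        ``None`` for pure defaults, a mapping of flat parameter ids to
        values, or a path to a JSON file containing such a mapping
        (keys starting with ``#`` are treated as comments and ignored).

    Raises
    ------
    UnknownParameterError
        If a key is not a published parameter id.
    ParameterValidationError
        If the resulting set violates any invariant.
    """
    p = ParameterSet()
    if config is None:
        overrides: dict[str, float] = {}
    elif isinstance(config, dict):
        overrides = config
    else:
        overrides = json.loads(Path(config).read_text())
    for key, value in overrides.items():
        if key.startswith("#"):
            continue
        p.set(key, value)
    p.validate()
    return p


def save_parameters(p: ParameterSet, path: str | Path, annotate: bool = True) -> None:
    """Write a parameter set as flat JSON; optionally embed provenance tags."""
    payload: dict[str, object] = {}
    if annotate:
        payload["#provenance"] = p.provenance
    payload.update(p.to_config())
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


# ---------------------------------------------------------------------------
# Economic primitives


def per_person_screening_cost(c: ScreeningCosts) -> float:
    """Total cost of screening one person: test + labor + promotion."""
    return c.test_cost + c.labor_cost + c.promotion_cost


def discounted_lifetime_factor(
    rate: float, horizon: float, timing: str = "start"
) -> float:
    """Present-value factor turning an annual amount into a lifetime amount.

    With discount rate ``r`` over ``horizon`` life years the factor is the
    annuity sum of discount weights: ``sum_{t=0}^{h-1} (1+r)^-t`` for
    start-of-year timing (annuity-due), ``sum_{t=1}^{h} (1+r)^-t`` for
    end-of-year timing.  ``horizon=math.inf`` gives the perpetuity limits
    ``(1+r)/r`` and ``1/r``.
    """
    if rate < 0:
        raise ValueError(f"discount rate must be >= 0, got {rate}")
    if horizon < 0:
        raise ValueError(f"horizon must be >= 0, got {horizon}")
    if timing not in ("start", "end"):
        raise ValueError(f"timing must be 'start' or 'end', got {timing!r}")
    if rate == 0:
        return float(horizon)
    if math.isinf(horizon):
        base = 1.0 / rate
    else:
        base = (1.0 - (1.0 + rate) ** -horizon) / rate
    return base * (1.0 + rate) if timing == "start" else base


def project_growth(base: float, annual_rate: float, years: float) -> float:
    """Project a value forward at a constant geometric growth rate."""
    if years < 0:
        raise ValueError(f"years must be >= 0, got {years}")
    return base * (1.0 + annual_rate) ** years


def growth_rate_from_endpoints(start: float, end: float, years: float) -> float:
    """Average annual geometric growth rate between two observed values."""
    if years <= 0 or start <= 0:
        raise ValueError("need years > 0 and start > 0")
    return (end / start) ** (1.0 / years) - 1.0


def lifetime_value(annual: float, factor: float) -> float:
    """Lifetime present value of an annual amount under a discount factor."""
    if factor < 0:
        raise ValueError(f"factor must be >= 0, got {factor}")
    return annual * factor


def derive_wtp(gdp_per_capita: float, multiplier: float, lifetime_qaly: float) -> int:
    """Willingness-to-pay for a whole life: GDP x multiplier x lifetime QALY."""
    if gdp_per_capita <= 0 or multiplier <= 0 or lifetime_qaly <= 0:
        raise ValueError("all WTP inputs must be positive")
    return round(gdp_per_capita * multiplier * lifetime_qaly)


def derive_deaf_qaly(healthy_qaly: float, weight: float) -> float:
    """Lifetime QALY of a deaf individual: healthy QALY x utility weight."""
    if not 0 < weight <= 1:
        raise ValueError(f"utility weight must lie in (0, 1], got {weight}")
    return healthy_qaly * weight


def parameter_digest(p: ParameterSet) -> str:
    """Stable hex digest of a parameter set (canonical JSON, SHA-256)."""
    import hashlib

    blob = json.dumps(p.to_config(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


# keep dataclasses' field list importable for tests without private access
PARAMETER_IDS: tuple[str, ...] = tuple(_REGISTRY)
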