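"""Deterministic, threshold and probabilistic sensitivity analyses.

* :func:`one_way` / :func:`tornado` — one-way deterministic sensitivity:
  each parameter is pushed to the ends of its span (plus/minus 10% for
  literature-, expert- and Mendelian-sourced values, plus/minus 20% for
  survey-derived ones, both configurable) with complementary probabilities
  renormalized, and the resulting ICER swing recorded.
* :func:`art_uptake_sweep` — threshold analysis over the medium-risk
  ART-with-PGT uptake, locating the break-even uptake at which screening
  stops reducing the number of healthy births.
* :func:`sample_parameters` / :func:`run_psa` — probabilistic sensitivity:
  gamma-distributed costs, beta-distributed probabilities (complementary
  pairs renormalized), a Dirichlet draw for the four-way medium-risk
  decision, genotype prevalences held fixed; per-draw incremental cost and
  effect, the cost-effectiveness acceptability curve and a 95% coverage
  ellipse of the incremental-effect / incremental-cost cloud.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy import optimize, stats

from .model import ModelRun, ModelVariant, icer_magnitude, run_model
from .parameters import PROBABILITY_BLOCKS, ParameterSet

__all__ = [
    "DsaSpan",
    "TornadoEntry",
    "ThresholdCurve",
    "DistSpec",
    "PsaResult",
    "CeacCurve",
    "EllipseSummary",
    "span_for",
    "perturb",
    "one_way",
    "tornado",
    "art_uptake_sweep",
    "sample_parameters",
    "run_psa",
    "ceac",
    "fit_coverage_ellipse",
    "ellipse_contains",
]

# members of each block, keyed by member id
_BLOCK_OF: dict[str, tuple[str, ...]] = {
    member: keys for keys in PROBABILITY_BLOCKS.values() for member in keys
}


@dataclass
class DsaSpan:
    parameter: str
    low: float
    base: float
    high: float
    span_rule: str = "explicit"

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(f"span must satisfy low <= base <= high: {self}")


@dataclass
class TornadoEntry:
    parameter: str
    icer_low: float
    icer_base: float
    icer_high: float
    span: DsaSpan

    @property
    def swing(self) -> float:
        return abs(self.icer_high - self.icer_low)


@dataclass
class ThresholdCurve:
    uptake: np.ndarray
    incr_healthy: np.ndarray
    incr_deaf: np.ndarray
    icer: np.ndarray
    break_even_uptake: float | None
    rule: str


@dataclass
class CeacCurve:
    wtp: np.ndarray
    probability: np.ndarray


@dataclass
class EllipseSummary:
    """Mean vector and covariance of the (dE, dC) cloud with a chi-square
    coverage radius; points inside satisfy Mahalanobis^2 <= radius2."""

    mean: np.ndarray
    cov: np.ndarray
    level: float
    radius2: float


@dataclass
class PsaResult:
    variant: ModelVariant
    delta_cost: np.ndarray
    delta_eff: np.ndarray
    wtp: float
    ceac: CeacCurve
    ellipse: EllipseSummary
    seed: int

    @property
    def n(self) -> int:
        return self.delta_cost.size

    @property
    def mean_delta_cost(self) -> float:
        return float(self.delta_cost.mean())

    @property
    def mean_delta_eff(self) -> float:
        return float(self.delta_eff.mean())

    @property
    def frac_acceptable(self) -> float:
        """Fraction of draws with non-negative net monetary benefit."""
        return float((self.wtp * self.delta_eff - self.delta_cost >= 0).mean())


# ---------------------------------------------------------------------------
# one-way deterministic sensitivity


def span_for(p: ParameterSet, parameter: str, span_rule: str | None = None) -> DsaSpan:
    """Perturbation span for a parameter.

    ``span_rule`` is ``"pm10"``, ``"pm20"`` or ``None`` to pick by
    provenance (survey-derived values get the wider plus/minus 20%).
    Probability spans are clipped to [0, 1] with a warning.
    """
    base = p.get(parameter)
    if span_rule is None:
        span_rule = "pm20" if p.provenance[parameter] == "survey" else "pm10"
    frac = {"pm10": 0.10, "pm20": 0.20}.get(span_rule)
    if frac is None:
        raise ValueError(f"unknown span rule {span_rule!r}")
    low, high = base * (1 - frac), base * (1 + frac)
    if parameter.startswith("p.") and high > 1.0:
        warnings.warn(
            f"{parameter}: upper span {high:.4f} clipped to 1.0", stacklevel=2
        )
        high = 1.0
    if low < 0.0:
        warnings.warn(f"{parameter}: lower span {low:.4f} clipped to 0.0", stacklevel=2)
        low = 0.0
    return DsaSpan(parameter, low, base, high, span_rule)


def perturb(p: ParameterSet, parameter: str, value: float) -> ParameterSet:
    """Copy of ``p`` with one parameter moved and its block renormalized.

    If the parameter belongs to a probability block, the remaining members
    are rescaled proportionally so the block still sums to 1.
    """
    q = p.copy()
    q.set(parameter, value)
    block = _BLOCK_OF.get(parameter)
    if block is not None:
        others = [k for k in block if k != parameter]
        rest_base = sum(p.get(k) for k in others)
        rest_target = 1.0 - value
        if rest_target < 0:
            raise ValueError(f"{parameter}={value} leaves negative complement mass")
        if rest_base > 0:
            for k in others:
                q.set(k, p.get(k) * rest_target / rest_base)
        else:
            for k in others:
                q.set(k, rest_target / len(others))
    q.validate()
    return q


def one_way(
    p: ParameterSet,
    parameter: str,
    v: ModelVariant,
    span_rule: str | None = None,
) -> TornadoEntry:
    """Re-run the model at the low/base/high values of one parameter.

    The reported quantity is the sign-folded ICER (incremental cost per
    unit of incremental-effect magnitude), which stays meaningful when the
    screening strategy is dominated.
    """
    span = span_for(p, parameter, span_rule)
    icers = {}
    for tag, value in (("low", span.low), ("base", span.base), ("high", span.high)):
        icers[tag] = icer_magnitude(run_model(perturb(p, parameter, value), v).comparison)
    return TornadoEntry(parameter, icers["low"], icers["base"], icers["high"], span)


def tornado(
    p: ParameterSet,
    parameters: Sequence[str],
    v: ModelVariant,
    span_rule: str | None = None,
) -> list[TornadoEntry]:
    """One-way entries for several parameters, sorted by swing descending."""
    if not parameters:
        raise ValueError("tornado needs at least one parameter id")
    entries = [one_way(p, pid, v, span_rule) for pid in parameters]
    entries.sort(key=lambda e: (np.isnan(e.swing), -e.swing))
    return entries


# ---------------------------------------------------------------------------
# ART-uptake threshold analysis


def _uptake_parameters(p: ParameterSet, u: float, rule: str) -> ParameterSet:
    """Medium-risk decision mix at ART uptake ``u`` under a reallocation rule.

    ``none_absorbing`` holds amniocentesis and natural birth at base and
    lets the no-children mass absorb the change; if that mass would go
    negative, it is clipped to zero and the remaining (1-u) is split
    proportionally between amniocentesis and natural birth.
    ``proportional`` rescales all three non-ART choices by (1-u)/(1-base).
    """
    b = p.behavior
    q = p.copy()
    if rule == "none_absorbing":
        none = 1.0 - u - b.med_amnio - b.med_natural
        if none >= 0:
            amnio, natural = b.med_amnio, b.med_natural
        else:
            none = 0.0
            rest = b.med_amnio + b.med_natural
            if rest <= 0:
                raise ValueError("infeasible reallocation: no mass to rescale")
            amnio = b.med_amnio * (1.0 - u) / rest
            natural = b.med_natural * (1.0 - u) / rest
    elif rule == "proportional":
        rest_base = 1.0 - b.med_art
        if rest_base <= 0 and u < 1.0:
            raise ValueError("infeasible reallocation: base non-ART mass is zero")
        scale = (1.0 - u) / rest_base if rest_base > 0 else 0.0
        amnio = b.med_amnio * scale
        natural = b.med_natural * scale
        none = b.med_none * scale
    else:
        raise ValueError(f"unknown reallocation rule {rule!r}")
    q.set("p.med_art", u)
    q.set("p.med_amnio", amnio)
    q.set("p.med_natural", natural)
    q.set("p.med_none", none)
    q.validate()
    return q


def art_uptake_sweep(
    p: ParameterSet,
    grid: Sequence[float] | None = None,
    reallocation_rule: str = "none_absorbing",
    v: ModelVariant = ModelVariant.HEALTHY_COUNT,
) -> ThresholdCurve:
    """Sweep medium-risk ART-with-PGT uptake over [0, 1].

    Records the incremental healthy- and deaf-birth probabilities and the
    sign-folded ICER at every grid point, and locates the break-even
    uptake (incremental healthy births = 0) by root bracketing to 1e-6.
    """
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a strictly increasing 1-D sequence")
    if grid[0] < 0 or grid[-1] > 1:
        raise ValueError("grid must lie inside [0, 1]")

    def run_at(u: float) -> ModelRun:
        return run_model(_uptake_parameters(p, u, reallocation_rule), v)

    incr_h = np.empty(grid.size)
    incr_d = np.empty(grid.size)
    icer = np.empty(grid.size)
    for i, u in enumerate(grid):
        mr = run_at(float(u))
        incr_h[i] = mr.screening.expected["eff_healthy"] - mr.status_quo.expected["eff_healthy"]
        incr_d[i] = mr.screening.expected["eff_deaf"] - mr.status_quo.expected["eff_deaf"]
        icer[i] = icer_magnitude(mr.comparison)

    def f(u: float) -> float:
        mr = run_at(u)
        return mr.screening.expected["eff_healthy"] - mr.status_quo.expected["eff_healthy"]

    break_even = None
    f0, f1 = f(0.0), f(1.0)
    if f0 == 0.0:
        break_even = 0.0
    elif f1 == 0.0:
        break_even = 1.0
    elif f0 * f1 < 0:
        break_even = float(optimize.brentq(f, 0.0, 1.0, xtol=1e-6))
    return ThresholdCurve(grid, incr_h, incr_d, icer, break_even, reallocation_rule)


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


@dataclass
class DistSpec:
    """Sampling distributions for the PSA.

    Costs are gamma-distributed with coefficient of variation ``cost_cv``
    (method of moments on the base value).  Probabilities are beta with
    standard deviation ``prob_cv * min(m, 1-m)`` around base ``m`` — for
    small probabilities this is the usual cv-times-mean rule, and it stays
    feasible for probabilities near one.  Complement probabilities are
    renormalized; the four-way medium-risk decision is a Dirichlet draw
    whose concentration is set so its largest component has that relative
    spread.  Genotype prevalences and Mendelian segregation ratios are
    never sampled.
    """

    cost_cv: float = 0.20
    prob_cv: float = 0.10
    cost_ids: tuple[str, ...] = (
        "c.screening.test",
        "c.screening.labor",
        "c.screening.promotion",
        "c.intervention.art_pgt",
        "c.intervention.amniocentesis",
    )
    pair_ids: tuple[str, ...] = ("p.high_risk_birth", "p.post_amnio_positive_birth")
    scalar_prob_ids: tuple[str, ...] = (
        "p.deaf_given_low_natural",
        "p.deaf_given_high_natural",
        "p.deaf_given_art",
        "p.deaf_given_amnio_positive_birth",
        "p.deaf_given_amnio_negative_birth",
    )
    sample_utility_weight: bool = True

    def __post_init__(self) -> None:
        if self.cost_cv < 0 or self.prob_cv < 0:
            raise ValueError("coefficients of variation must be >= 0")
        if self.cost_cv >= 1 or self.prob_cv >= 1:
            raise ValueError("coefficients of variation must be < 1")


def _beta_draw(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv == 0 or mean in (0.0, 1.0):
        return mean
    sd = cv * min(mean, 1.0 - mean)
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    return float(rng.beta(mean * nu, (1.0 - mean) * nu))


def _gamma_draw(rng: np.random.Generator, mean: float, cv: float) -> float:
    if cv == 0 or mean == 0:
        return mean
    shape = 1.0 / cv**2
    return float(rng.gamma(shape, mean * cv**2))


def sample_parameters(
    p: ParameterSet,
    seed: int,
    n: int,
    dist_spec: DistSpec | None = None,
) -> Iterator[ParameterSet]:
    """Yield ``n`` sampled parameter sets (reproducible under ``seed``)."""
    spec = dist_spec or DistSpec()
    rng = np.random.default_rng(seed)
    b = p.behavior
    base_weight = p.utility.deaf_utility_weight
    base_deaf_qaly = p.utility.deaf_qaly

    four_way = ("p.med_art", "p.med_amnio", "p.med_natural", "p.med_none")
    base_mix = np.array([p.get(k) for k in four_way])
    m_max = base_mix.max()
    if spec.prob_cv > 0:
        alpha0 = (1.0 - m_max) / (spec.prob_cv**2 * m_max) - 1.0
        alpha = base_mix * alpha0
    else:
        alpha = None

    for _ in range(n):
        q = p.copy()
        for cid in spec.cost_ids:
            q.set(cid, _gamma_draw(rng, p.get(cid), spec.cost_cv))
        for pid in spec.pair_ids:
            base = p.get(pid)
            x = _beta_draw(rng, base, spec.prob_cv)
            if x == base:  # degenerate draw: keep both stored values exact
                continue
            block = _BLOCK_OF[pid]
            other = next(k for k in block if k != pid)
            q.set(pid, x)
            q.set(other, 1.0 - x)
        for pid in spec.scalar_prob_ids:
            q.set(pid, _beta_draw(rng, p.get(pid), spec.prob_cv))
        if alpha is not None:
            mix = rng.dirichlet(alpha)
            for k, x in zip(four_way, mix):
                q.set(k, float(x))
        if spec.sample_utility_weight:
            w = _beta_draw(rng, base_weight, spec.prob_cv)
            if w != base_weight:
                q.utility.deaf_utility_weight = w
                # scale the (reporting-rounded) base deaf QALY so the cv->0
                # limit reproduces the deterministic model exactly
                q.utility.deaf_qaly = base_deaf_qaly * w / base_weight
        yield q


def ceac(
    delta_cost: np.ndarray, delta_eff: np.ndarray, wtp_grid: Sequence[float]
) -> CeacCurve:
    """Acceptability curve: P(net monetary benefit >= 0) per WTP value."""
    dc = np.asarray(delta_cost, dtype=float)
    de = np.asarray(delta_eff, dtype=float)
    if dc.size == 0 or dc.shape != de.shape:
        raise ValueError("need equal-length, non-empty draw arrays")
    grid = np.asarray(wtp_grid, dtype=float)
    prob = np.array([float((w * de - dc >= 0).mean()) for w in grid])
    return CeacCurve(grid, prob)


def fit_coverage_ellipse(
    delta_eff: np.ndarray, delta_cost: np.ndarray, level: float = 0.95
) -> EllipseSummary:
    """Normal-theory coverage ellipse of the (dE, dC) scatter."""
    pts = np.column_stack([delta_eff, delta_cost])
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 draws to fit an ellipse")
    mean = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    radius2 = float(stats.chi2.ppf(level, df=2))
    return EllipseSummary(mean, cov, level, radius2)


def ellipse_contains(
    ellipse: EllipseSummary, delta_eff: np.ndarray, delta_cost: np.ndarray
) -> np.ndarray:
    """Boolean mask of draws inside the ellipse (squared Mahalanobis)."""
    pts = np.column_stack([delta_eff, delta_cost]) - ellipse.mean
    sol = np.linalg.solve(ellipse.cov, pts.T)
    d2 = np.einsum("ij,ji->i", pts, sol)
    return d2 <= ellipse.radius2


def run_psa(
    p: ParameterSet,
    v: ModelVariant,
    n: int = 10_000,
    seed: int = 0,
    wtp: float | None = None,
    dist_spec: DistSpec | None = None,
    wtp_grid: Sequence[float] | None = None,
) -> PsaResult:
    """Probabilistic sensitivity analysis of screening vs status quo.

    Rebuilds both strategy trees for every sampled parameter set and
    records the incremental cost and incremental effect under the payoff
    model ``v``; returns the draw cloud with its acceptability curve
    (net-monetary-benefit rule) and 95% coverage ellipse.
    """
    if n < 2:
        raise ValueError("PSA needs n >= 2 draws")
    v = ModelVariant(v)
    if wtp is None:
        wtp = p.utility.wtp_lifetime
    dc = np.empty(n)
    de = np.empty(n)
    for i, q in enumerate(sample_parameters(p, seed, n, dist_spec)):
        cmp_ = run_model(q, v).comparison
        dc[i] = cmp_.delta_cost
        de[i] = cmp_.delta_eff
    if wtp_grid is None:
        wtp_grid = np.linspace(0.0, 2.0 * wtp if wtp > 0 else 1.0, 41)
    curve = ceac(dc, de, wtp_grid)
    ellipse = fit_coverage_ellipse(de, dc)
    return PsaResult(v, dc, de, float(wtp), curve, ellipse, seed)
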