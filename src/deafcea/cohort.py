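"""Synthetic individual-level screening cohorts.

Emulates the study population: women planning pregnancy receive carrier
screening for the recessive deafness genes; partners of screen-positive
women are screened in a second step (the cascade).  Couples then follow the
family-level decision distributions of the analytic model — so a large
simulated cohort is an end-to-end Monte Carlo oracle for the screening
strategy tree: outcome fractions and mean per-couple costs converge to the
tree rollback values.

Spousal genotypes are drawn independently from the two marginal frequency
triples (no assortative mating), matching the analytic model's
product-of-marginals joint distribution.  Because mono-allelic husbands of
screen-negative wives are never tested, husband genotype summaries are
reported both for the tested subset (comparable to an observed male sample)
and for the latent truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .model import ModelVariant, PathContext, RiskCategory, assign_payoffs, classify_couple
from .parameters import ParameterSet, per_person_screening_cost

__all__ = [
    "GENOTYPE_LABELS",
    "ScreeningLog",
    "CohortSummary",
    "PrevalenceEstimate",
    "generate_cohort",
    "two_step_screen",
    "estimate_prevalence",
    "simulate_families",
]

#: wild = screen-negative wild type; mono = heterozygous carrier;
#: bi = bi-allelic pathogenic genotype.
GENOTYPE_LABELS = ("wild", "mono", "bi")

_TO_MODEL = {"wild": "neg", "mono": "mono", "bi": "bi"}


@dataclass
class ScreeningLog:
    n_female_tests: int
    n_male_tests: int
    cost_per_test: float

    @property
    def total_cost(self) -> float:
        return (self.n_female_tests + self.n_male_tests) * self.cost_per_test


@dataclass
class PrevalenceEstimate:
    """Genotype proportions with Wilson 95% confidence intervals."""

    n: int
    proportions: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]


@dataclass
class CohortSummary:
    n_couples: int
    wife_genotype_counts: dict[str, int]
    husband_genotype_counts_latent: dict[str, int]
    husband_genotype_counts_tested: dict[str, int]
    risk_counts: dict[str, int]
    outcome_counts: dict[str, int]
    mean_cost: float
    total_cost: float

    @property
    def outcome_fractions(self) -> dict[str, float]:
        return {k: v / self.n_couples for k, v in self.outcome_counts.items()}


def generate_cohort(
    n_females: int,
    female_freqs: tuple[float, float, float] | None = None,
    male_freqs: tuple[float, float, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw couple genotypes (wild, mono, bi order) independently per spouse.

    Frequencies default to the analytic model's marginal prevalences.
    Returns a data frame with one row per couple.
    """
    if n_females < 1:
        raise ValueError("n_females must be >= 1")
    defaults = ParameterSet().prevalence
    if female_freqs is None:
        female_freqs = (defaults.wife_neg, defaults.wife_mono, defaults.wife_bi)
    if male_freqs is None:
        male_freqs = (defaults.husband_neg, defaults.husband_mono, defaults.husband_bi)
    for name, freqs in (("female", female_freqs), ("male", male_freqs)):
        arr = np.asarray(freqs, dtype=float)
        if arr.min() < 0 or abs(arr.sum() - 1.0) > 1e-9:
            raise ValueError(f"{name} frequencies must lie on the simplex: {freqs}")
    rng = np.random.default_rng(seed)
    labels = np.array(GENOTYPE_LABELS)
    wife = labels[rng.choice(3, size=n_females, p=np.asarray(female_freqs) / np.sum(female_freqs))]
    husband = labels[rng.choice(3, size=n_females, p=np.asarray(male_freqs) / np.sum(male_freqs))]
    return pd.DataFrame(
        {
            "couple_id": np.arange(n_females),
            "wife_genotype": wife,
            "husband_genotype": husband,
        }
    )


def two_step_screen(cohort: pd.DataFrame, p: ParameterSet) -> tuple[pd.DataFrame, ScreeningLog]:
    """Apply the cascade: test every wife, and the husband iff she is positive.

    Returns the cohort with ``husband_tested`` and ``risk`` columns plus a
    cost ledger charging one per-person screening cost per test performed.
    """
    out = cohort.copy()
    wife_positive = out["wife_genotype"].isin(("mono", "bi")).to_numpy()
    out["husband_tested"] = wife_positive
    risk = [
        classify_couple(
            _TO_MODEL[w], _TO_MODEL[h] if tested else None
        ).value
        for w, h, tested in zip(
            out["wife_genotype"], out["husband_genotype"], wife_positive
        )
    ]
    out["risk"] = risk
    log = ScreeningLog(
        n_female_tests=len(out),
        n_male_tests=int(wife_positive.sum()),
        cost_per_test=per_person_screening_cost(p.screening_costs),
    )
    return out, log


def estimate_prevalence(counts: dict[str, int] | pd.Series) -> PrevalenceEstimate:
    """Maximum-likelihood genotype proportions with Wilson 95% intervals."""
    c = {g: int(counts.get(g, 0)) for g in GENOTYPE_LABELS}
    n = sum(c.values())
    if n == 0:
        raise ValueError("zero total count; cannot estimate prevalence")
    props, lo, hi = {}, {}, {}
    for g, k in c.items():
        props[g] = k / n
        interval = stats.binomtest(k, n).proportion_ci(confidence_level=0.95, method="wilson")
        lo[g], hi[g] = float(interval.low), float(interval.high)
    return PrevalenceEstimate(n, props, lo, hi)


def _leaf_cost(ctx: PathContext, p: ParameterSet, v: ModelVariant) -> float:
    return assign_payoffs(ctx, p, v).payoffs["cost"]


def simulate_families(
    screened: pd.DataFrame,
    p: ParameterSet,
    v: ModelVariant = ModelVariant.DEAF_COUNT,
    seed: int = 0,
) -> tuple[pd.DataFrame, CohortSummary]:
    """Sample each couple's decision path and birth outcome.

    Decisions are drawn sequentially — high-risk birth/no-children,
    medium-risk four-way choice, Mendelian amniocentesis result, post-amnio
    birth/termination — and each couple's accumulated cost is exactly the
    terminal payoff the analytic tree assigns to that path.
    """
    v = ModelVariant(v)
    if "risk" not in screened.columns:
        raise ValueError("cohort must be screened first (two_step_screen)")
    rng = np.random.default_rng(seed)
    n = len(screened)
    b, o = p.behavior, p.outcomes

    risk = screened["risk"].to_numpy()
    tested = screened["husband_tested"].to_numpy()
    outcome = np.empty(n, dtype=object)
    decision = np.empty(n, dtype=object)
    deaf_prob = np.zeros(n)
    art = np.zeros(n, dtype=bool)
    amnio = np.zeros(n, dtype=bool)
    childless = np.zeros(n, dtype=bool)

    # low risk: natural conception
    low = risk == RiskCategory.LOW.value
    decision[low] = "natural"
    deaf_prob[low] = o.deaf_given_low_natural

    # high risk: birth or no children
    high = risk == RiskCategory.HIGH.value
    gives_birth = rng.random(high.sum()) < b.high_risk_birth
    idx_high = np.flatnonzero(high)
    decision[idx_high] = np.where(gives_birth, "natural", "no_children")
    childless[idx_high[~gives_birth]] = True
    deaf_prob[idx_high[gives_birth]] = o.deaf_given_high_natural

    # medium risk: four-way decision
    for cat, mend, nat_deaf in (
        (RiskCategory.MEDIUM_HIGH, o.amnio_positive_medhigh, o.deaf_given_medhigh_natural),
        (RiskCategory.MEDIUM_LOW, o.amnio_positive_medlow, o.deaf_given_medlow_natural),
    ):
        idx = np.flatnonzero(risk == cat.value)
        if idx.size == 0:
            continue
        probs = np.array([b.med_art, b.med_amnio, b.med_natural, b.med_none])
        choice = rng.choice(4, size=idx.size, p=probs / probs.sum())
        labels = np.array(["art_pgt", "amniocentesis", "natural", "no_children"])
        decision[idx] = labels[choice]

        i_art = idx[choice == 0]
        art[i_art] = True
        deaf_prob[i_art] = o.deaf_given_art

        i_amnio = idx[choice == 1]
        amnio[i_amnio] = True
        positive = rng.random(i_amnio.size) < mend
        i_pos, i_neg = i_amnio[positive], i_amnio[~positive]
        deaf_prob[i_neg] = o.deaf_given_amnio_negative_birth
        keeps = rng.random(i_pos.size) < b.post_amnio_positive_birth
        deaf_prob[i_pos[keeps]] = o.deaf_given_amnio_positive_birth
        childless[i_pos[~keeps]] = True

        deaf_prob[idx[choice == 2]] = nat_deaf
        childless[idx[choice == 3]] = True

    born = ~childless
    deaf = np.zeros(n, dtype=bool)
    deaf[born] = rng.random(born.sum()) < deaf_prob[born]
    outcome[childless] = "no_birth"
    outcome[born & deaf] = "deaf_birth"
    outcome[born & ~deaf] = "healthy_birth"

    # costs via the analytic payoff assignment, grouped by path context
    cost = np.zeros(n)
    ctx_key = list(
        zip(tested, art, amnio, outcome)
    )  # wife always screened in this arm
    for key in set(ctx_key):
        h_tested, is_art, is_amnio, out_label = key
        ctx = PathContext(
            outcome=out_label,
            wife_screened=True,
            husband_screened=bool(h_tested),
            art=bool(is_art),
            amnio=bool(is_amnio),
        )
        mask = np.array([k == key for k in ctx_key])
        cost[mask] = _leaf_cost(ctx, p, v)

    records = screened.copy()
    records["decision"] = decision
    records["outcome"] = outcome
    records["cost"] = cost

    def counts(series: pd.Series, labels) -> dict[str, int]:
        vc = series.value_counts()
        return {lab: int(vc.get(lab, 0)) for lab in labels}

    summary = CohortSummary(
        n_couples=n,
        wife_genotype_counts=counts(records["wife_genotype"], GENOTYPE_LABELS),
        husband_genotype_counts_latent=counts(records["husband_genotype"], GENOTYPE_LABELS),
        husband_genotype_counts_tested=counts(
            records.loc[records["husband_tested"], "husband_genotype"], GENOTYPE_LABELS
        ),
        risk_counts=counts(records["risk"], [c.value for c in RiskCategory]),
        outcome_counts=counts(records["outcome"], ("healthy_birth", "deaf_birth", "no_birth")),
        mean_cost=float(cost.mean()),
        total_cost=float(cost.sum()),
    )
    return records, summary
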