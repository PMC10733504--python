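"""Construction of the screening and status-quo strategy trees.

The intervention under study is two-step (cascade) pre-pregnancy carrier
screening for autosomal-recessive deafness: the woman is genotyped first and
her partner only if she carries at least one pathogenic allele.  Couples are
classified into four risk categories from the pair of genotypes:

* ``high`` — both bi-allelic: an affected child is near certain;
* ``medium_high`` — bi-allelic x carrier: 1/2 risk per pregnancy;
* ``medium_low`` — carrier x carrier: 1/4 risk per pregnancy;
* ``low`` — at least one spouse screen-negative.

High-risk couples decide only whether to attempt pregnancy; medium-risk
couples choose between ART with PGT (embryo selection), natural pregnancy
with diagnostic amniocentesis (and a birth/termination decision after a
positive result), unassisted natural pregnancy, or no children.  The
comparator ("status quo") is universal natural conception with no screening
and no intervention.

Three payoff models share one tree topology and differ only in what the
terminal nodes carry: model ``deaf`` counts deaf births, ``healthy`` counts
healthy births, and ``utility`` is a lifetime cost-utility model whose costs
additionally include discounted lifetime medical expenditure minus lifetime
income of the born individual.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .parameters import ParameterSet, per_person_screening_cost
from .tree import (
    Branch,
    CEAComparison,
    ChanceNode,
    DecisionTree,
    StrategyResult,
    TerminalNode,
    compare,
    strategy_result,
)

__all__ = [
    "RiskCategory",
    "ModelVariant",
    "PathContext",
    "Table4Row",
    "ModelRun",
    "classify_couple",
    "assign_payoffs",
    "build_status_quo_tree",
    "build_screening_tree",
    "run_model",
    "families_needed",
]

GENOTYPES = ("bi", "mono", "neg")


class RiskCategory(str, enum.Enum):
    HIGH = "high"
    MEDIUM_HIGH = "medium_high"
    MEDIUM_LOW = "medium_low"
    LOW = "low"


class ModelVariant(str, enum.Enum):
    """Payoff model: which effectiveness measure the analysis counts."""

    DEAF_COUNT = "deaf"
    HEALTHY_COUNT = "healthy"
    UTILITY = "utility"

    @property
    def effect_key(self) -> str:
        return {
            ModelVariant.DEAF_COUNT: "eff_deaf",
            ModelVariant.HEALTHY_COUNT: "eff_healthy",
            ModelVariant.UTILITY: "eff_utility",
        }[self]


def classify_couple(wife: str, husband: str | None = None) -> RiskCategory:
    """Risk category from the two genotypes under cascade screening.

    ``husband=None`` means untested, which the cascade permits only when
    the wife screened negative.
    """
    if wife not in GENOTYPES:
        raise ValueError(f"unknown wife genotype {wife!r}")
    if husband is None:
        if wife != "neg":
            raise ValueError(
                "cascade violation: husband untested although wife screened positive"
            )
        return RiskCategory.LOW
    if husband not in GENOTYPES:
        raise ValueError(f"unknown husband genotype {husband!r}")
    if wife == "neg" or husband == "neg":
        return RiskCategory.LOW
    if wife == "bi" and husband == "bi":
        return RiskCategory.HIGH
    if wife == "mono" and husband == "mono":
        return RiskCategory.MEDIUM_LOW
    return RiskCategory.MEDIUM_HIGH


@dataclass
class PathContext:
    """What happened along one root-to-leaf path, for payoff assignment."""

    outcome: str  # healthy_birth | deaf_birth | no_birth
    wife_screened: bool = False
    husband_screened: bool = False
    art: bool = False
    amnio: bool = False


@dataclass
class Table4Row:
    """One strategy row of the headline cost-effectiveness table."""

    strategy: str
    cost: float
    effectiveness: float
    incr_cost: float | None = None
    incr_eff: float | None = None
    icer_or_dominated: str | float | None = None


@dataclass
class ModelRun:
    """Full output of one payoff model: both strategies plus comparison."""

    variant: ModelVariant
    status_quo: StrategyResult
    screening: StrategyResult
    comparison: CEAComparison
    rows: list[Table4Row] = field(default_factory=list)


def assign_payoffs(ctx: PathContext, p: ParameterSet, v: ModelVariant) -> TerminalNode:
    """Terminal node for a path: accumulated cost plus effect payoffs.

    Costs: one per-person screening cost per spouse actually screened;
    ART+PGT or amniocentesis costs (with their productivity losses) when
    taken; the reproductive (delivery) cost on every path that ends in a
    birth.  Under the utility variant, birth leaves additionally carry the
    individual's discounted lifetime medical expenditure minus lifetime
    income; childless leaves carry no future terms.
    """
    if ctx.art and ctx.amnio:
        raise ValueError("inconsistent path: both ART and amniocentesis taken")
    if ctx.husband_screened and not ctx.wife_screened:
        raise ValueError("inconsistent path: husband screened before wife")
    if (ctx.art or ctx.amnio) and not (ctx.wife_screened and ctx.husband_screened):
        raise ValueError("inconsistent path: intervention without full cascade screening")

    screen = per_person_screening_cost(p.screening_costs)
    ic = p.intervention_costs
    cost = 0.0
    if ctx.wife_screened:
        cost += screen
    if ctx.husband_screened:
        cost += screen
    if ctx.art:
        cost += ic.art_pgt + ic.art_productivity_loss
    if ctx.amnio:
        cost += ic.amniocentesis + ic.amnio_productivity_loss

    born = ctx.outcome in ("healthy_birth", "deaf_birth")
    if born:
        cost += ic.reproductive
    if v is ModelVariant.UTILITY:
        if ctx.outcome == "healthy_birth":
            cost += p.future.medical_healthy - p.future.income_healthy
        elif ctx.outcome == "deaf_birth":
            cost += p.future.medical_disabled - p.future.income_disabled

    utility = {
        "healthy_birth": p.utility.healthy_qaly,
        "deaf_birth": p.utility.deaf_qaly,
        "no_birth": 0.0,
    }[ctx.outcome]

    return TerminalNode(
        ctx.outcome,
        {
            "cost": cost,
            "eff_deaf": 1.0 if ctx.outcome == "deaf_birth" else 0.0,
            "eff_healthy": 1.0 if ctx.outcome == "healthy_birth" else 0.0,
            "eff_utility": utility,
        },
    )


def _birth_node(
    deaf_prob: float, p: ParameterSet, v: ModelVariant, **ctx_flags
) -> ChanceNode:
    """Chance node over deaf/healthy birth at a given conditional risk."""
    deaf = assign_payoffs(PathContext("deaf_birth", **ctx_flags), p, v)
    healthy = assign_payoffs(PathContext("healthy_birth", **ctx_flags), p, v)
    return ChanceNode(
        [Branch(deaf_prob, deaf, "deaf"), Branch(1.0 - deaf_prob, healthy, "healthy")]
    )


def _natural_deaf_prob(cat: RiskCategory, p: ParameterSet) -> float:
    o = p.outcomes
    return {
        RiskCategory.HIGH: o.deaf_given_high_natural,
        RiskCategory.MEDIUM_HIGH: o.deaf_given_medhigh_natural,
        RiskCategory.MEDIUM_LOW: o.deaf_given_medlow_natural,
        RiskCategory.LOW: o.deaf_given_low_natural,
    }[cat]


def _joint_genotype_matrix(p: ParameterSet, concordance: float) -> dict[tuple[str, str], float]:
    """Joint couple genotype distribution.

    The default is the product of the two marginal distributions.  A
    ``concordance`` factor > 1 up-weights carrier x carrier pairings (both
    spouses positive, e.g. same-gene assortment) before renormalizing; the
    default 1.0 reproduces the independent-marginals model.
    """
    prev = p.prevalence
    wife = {"bi": prev.wife_bi, "mono": prev.wife_mono, "neg": prev.wife_neg}
    husb = {"bi": prev.husband_bi, "mono": prev.husband_mono, "neg": prev.husband_neg}
    joint = {}
    for wg in GENOTYPES:
        for hg in GENOTYPES:
            w = wife[wg] * husb[hg]
            if concordance != 1.0 and wg != "neg" and hg != "neg":
                w *= concordance
            joint[(wg, hg)] = w
    total = sum(joint.values())
    return {k: v / total for k, v in joint.items()}


def _conditional_husband(
    joint: dict[tuple[str, str], float], wife_genotype: str
) -> dict[str, float]:
    row = {hg: joint[(wife_genotype, hg)] for hg in GENOTYPES}
    total = sum(row.values())
    if total == 0:  # zero-mass wife genotype: any proper conditional works
        return {hg: 1.0 / len(row) for hg in row}
    return {hg: w / total for hg, w in row.items()}


def build_status_quo_tree(
    p: ParameterSet, v: ModelVariant, concordance: float = 1.0
) -> DecisionTree:
    """No-screening comparator: every couple conceives naturally.

    The couple's (latent) genotype pair fixes the Mendelian deaf-birth
    probability; there is no screening cost, no intervention and no
    childless leaf.
    """
    joint = _joint_genotype_matrix(p, concordance)
    wife_branches = []
    for wg in GENOTYPES:
        cond = _conditional_husband(joint, wg)
        wife_mass = sum(joint[(wg, hg)] for hg in GENOTYPES)
        husband_branches = []
        for hg in GENOTYPES:
            cat = classify_couple(wg, hg)
            husband_branches.append(
                Branch(
                    cond[hg],
                    _birth_node(_natural_deaf_prob(cat, p), p, v),
                    f"husband_{hg}",
                )
            )
        wife_branches.append(Branch(wife_mass, ChanceNode(husband_branches), f"wife_{wg}"))
    return DecisionTree(ChanceNode(wife_branches), "status_quo")


def _medium_risk_subtree(
    cat: RiskCategory, p: ParameterSet, v: ModelVariant
) -> ChanceNode:
    """Decision mix of a medium-risk couple (both spouses screened)."""
    b = p.behavior
    o = p.outcomes
    screened = dict(wife_screened=True, husband_screened=True)
    mendelian = (
        o.amnio_positive_medhigh if cat is RiskCategory.MEDIUM_HIGH else o.amnio_positive_medlow
    )

    art_node = _birth_node(o.deaf_given_art, p, v, art=True, **screened)

    amnio_flags = dict(amnio=True, **screened)
    pos_birth = _birth_node(o.deaf_given_amnio_positive_birth, p, v, **amnio_flags)
    pos_term = assign_payoffs(PathContext("no_birth", **amnio_flags), p, v)
    positive = ChanceNode(
        [
            Branch(b.post_amnio_positive_birth, pos_birth, "birth"),
            Branch(b.post_amnio_positive_terminate, pos_term, "terminate"),
        ]
    )
    negative = _birth_node(o.deaf_given_amnio_negative_birth, p, v, **amnio_flags)
    amnio_node = ChanceNode(
        [Branch(mendelian, positive, "positive"), Branch(1.0 - mendelian, negative, "negative")]
    )

    natural = _birth_node(_natural_deaf_prob(cat, p), p, v, **screened)
    none = assign_payoffs(PathContext("no_birth", **screened), p, v)

    return ChanceNode(
        [
            Branch(b.med_art, art_node, "art_pgt"),
            Branch(b.med_amnio, amnio_node, "amniocentesis"),
            Branch(b.med_natural, natural, "natural"),
            Branch(b.med_none, none, "no_children"),
        ]
    )


def build_screening_tree(
    p: ParameterSet, v: ModelVariant, concordance: float = 1.0
) -> DecisionTree:
    """Two-step cascade screening strategy tree.

    Wife screened first; a negative result ends the cascade (natural birth
    at low risk, one screening cost).  A positive wife triggers partner
    screening: a negative husband again means low-risk natural birth (two
    screening costs); a positive pair enters the risk-category subtree
    (high: birth-or-not; medium: the four-way intervention choice).
    """
    joint = _joint_genotype_matrix(p, concordance)
    b = p.behavior
    o = p.outcomes

    # wife negative: cascade complete after one test
    low_after_wife = _birth_node(o.deaf_given_low_natural, p, v, wife_screened=True)

    wife_branches = []
    for wg in ("bi", "mono"):
        cond = _conditional_husband(joint, wg)
        wife_mass = sum(joint[(wg, hg)] for hg in GENOTYPES)
        husband_branches = []
        for hg in GENOTYPES:
            cat = classify_couple(wg, hg)
            screened = dict(wife_screened=True, husband_screened=True)
            if cat is RiskCategory.LOW:
                child: ChanceNode | TerminalNode = _birth_node(
                    o.deaf_given_low_natural, p, v, **screened
                )
            elif cat is RiskCategory.HIGH:
                child = ChanceNode(
                    [
                        Branch(
                            b.high_risk_birth,
                            _birth_node(o.deaf_given_high_natural, p, v, **screened),
                            "birth",
                        ),
                        Branch(
                            b.high_risk_none,
                            assign_payoffs(PathContext("no_birth", **screened), p, v),
                            "no_children",
                        ),
                    ]
                )
            else:
                child = _medium_risk_subtree(cat, p, v)
            husband_branches.append(Branch(cond[hg], child, f"husband_{hg}"))
        wife_branches.append(Branch(wife_mass, ChanceNode(husband_branches), f"wife_{wg}"))

    wife_neg_mass = sum(joint[("neg", hg)] for hg in GENOTYPES)
    wife_branches.append(Branch(wife_neg_mass, low_after_wife, "wife_neg"))
    return DecisionTree(ChanceNode(wife_branches), "screening")


def run_model(
    p: ParameterSet, v: ModelVariant, concordance: float = 1.0
) -> ModelRun:
    """Build both strategy trees, roll back and compare.

    Returns the two :class:`StrategyResult` objects, the incremental
    comparison under the variant's effect key and a two-row table in the
    headline layout (cost, incremental cost, effectiveness, incremental
    effectiveness, ICER or dominance tag).
    """
    v = ModelVariant(v)
    sq = strategy_result(build_status_quo_tree(p, v, concordance))
    sc = strategy_result(build_screening_tree(p, v, concordance))
    cmp_ = compare(sq, sc, v.effect_key)

    if cmp_.dominance == "alt_dominated":
        tag: str | float | None = "Dominated"
    elif cmp_.dominance == "alt_dominant":
        tag = "Dominant"
    else:
        tag = cmp_.icer
    rows = [
        Table4Row("status_quo", sq.cost, sq.expected[v.effect_key]),
        Table4Row(
            "screening",
            sc.cost,
            sc.expected[v.effect_key],
            incr_cost=cmp_.delta_cost,
            incr_eff=cmp_.delta_eff,
            icer_or_dominated=tag,
        ),
    ]
    return ModelRun(v, sq, sc, cmp_, rows)


def families_needed(cmp_: CEAComparison) -> int:
    """Families screened per one unit of incremental effect (rounded)."""
    if cmp_.delta_eff == 0:
        raise ZeroDivisionError("incremental effect is zero; families-needed undefined")
    return round(1.0 / abs(cmp_.delta_eff))


def icer_magnitude(cmp_: CEAComparison) -> float:
    """|dC| / |dE| sign-folded ratio: dC per unit |dE|.

    The conventional single number for tornado/threshold curves: equals the
    ICER for trade-offs with positive dE, and the cost per adverse event
    averted when the effect measure falls while cost rises.  NaN when
    dE = 0.
    """
    if cmp_.delta_eff == 0:
        return float("nan")
    return cmp_.delta_cost / abs(cmp_.delta_eff)
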