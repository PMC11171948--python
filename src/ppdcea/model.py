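"""The three postpartum-depression strategy trees.

The structural model compares, over a two-year postnatal horizon:

``routine_care``
    no active screening; women with PPD enter care only by self-referral;
``early_postnatal_screening``
    universal EPDS screening within eight weeks postpartum; screen-positive
    women are referred for SCID confirmation and treatment;
``prenatal_psychological_intervention``
    an antenatal EPDS screen identifies high-risk pregnant women, who
    receive group cognitive-behavioural therapy that halves their PPD risk
    (``p_int_effect``); everyone then goes through the postnatal screening
    pathway.

Treatment follows national guidance: structured psychotherapy is first-line
(cure probability ``p_cure_psycho``, with relapse risk
``p_relapse_nonpharm`` after cure); a fraction ``p_pharm`` of treated women
receive pharmaceutical/mixed treatment (cost of psychotherapy plus
medication, cure probability ``p_cure_pharm``).  Women whose depression is
never resolved incur the PPD care cost ``c_care`` and face the suicidal
ideation / suicidal behaviour chance nodes.

Costs accrue on branches (events); utilities attach to terminal health
states.  QALYs are expressed on a normalized horizon (1 = perfect health
for the whole horizon); multiply by ``horizon_years`` for raw
QALY accounting.
"""

from __future__ import annotations

from importlib import resources
from typing import Mapping

import pandas as pd

from .params import ParameterSet
from .tree import Branch, Node, chance, decision, terminal, validate, evaluate, from_dict

import yaml

ROUTINE = "routine_care"
SCREENING = "early_postnatal_screening"
PRENATAL = "prenatal_psychological_intervention"

STRATEGIES = (ROUTINE, SCREENING, PRENATAL)

#: terminal health states; the first three are the reported columns of the
#: health-state distribution table, the last two the unreported remainder.
HEALTH_STATES = (
    "suicidal_ideation",
    "ppd_recovered",
    "ppd_unrecovered",
    "no_ppd",
    "suicide_death",
)

#: terminal payoff expressions per health state (cost expression, utility
#: expression).  c_care is charged on the branch *entering* the unrecovered
#: pool, so unrecovered/ideation/suicide terminals all carry it without
#: repeating it here.
PAYOFF_EXPRS = {
    "no_ppd": ("0", "u_healthy"),
    "ppd_recovered": ("0", "f_pre * u_ppd + (1 - f_pre) * u_cured"),
    "ppd_unrecovered": ("0", "u_ppd"),
    "suicidal_ideation": ("0", "u_ideation"),
    "suicide_death": ("0", "u_death"),
}


class ModelError(ValueError):
    pass


def _terminal(tag: str) -> Node:
    cost, effect = PAYOFF_EXPRS[tag]
    return terminal(tag, cost, effect, tag)


def _sick_subtree() -> Node:
    """Unrecovered PPD: suicidal ideation and suicidal behaviour risks."""
    suicide = chance("suicide", [
        Branch("suicidal_behavior", "p_suicide", "0", _terminal("suicide_death")),
        Branch("no_suicidal_behavior", "1 - p_suicide", "0", _terminal("suicidal_ideation")),
    ])
    return chance("ideation", [
        Branch("ideation", "p_ideation", "0", suicide),
        Branch("no_ideation", "1 - p_ideation", "0", _terminal("ppd_unrecovered")),
    ])


def _untreated_subtree(sick: Node) -> Node:
    """PPD without treatment: spontaneous recovery or the unrecovered pool."""
    return chance("spontaneous_recovery", [
        Branch("spontaneous_recovery", "p_spont", "0", _terminal("ppd_recovered")),
        Branch("remains_depressed", "1 - p_spont", "c_care", sick),
    ])


def _treatment_subtree(untreated: Node, sick: Node) -> Node:
    """Diagnosed PPD: refusal, modality, cure and relapse."""
    pharm = chance("pharm_cure", [
        Branch("cured", "p_cure_pharm", "0", _terminal("ppd_recovered")),
        Branch("not_cured", "1 - p_cure_pharm", "c_care", sick),
    ])
    relapse = chance("relapse", [
        Branch("relapse", "p_relapse_nonpharm", "c_care", sick),
        Branch("sustained_recovery", "1 - p_relapse_nonpharm", "0", _terminal("ppd_recovered")),
    ])
    psycho = chance("psycho_cure", [
        Branch("cured", "p_cure_psycho", "0", relapse),
        Branch("not_cured", "1 - p_cure_psycho", "c_care", sick),
    ])
    modality = chance("treatment_modality", [
        Branch("pharmaceutical_mixed", "p_pharm", "c_psychother + c_med", pharm),
        Branch("psychotherapy_only", "1 - p_pharm", "c_psychother", psycho),
    ])
    return chance("treatment_refusal", [
        Branch("refuses_treatment", "p_refuse", "0", untreated),
        Branch("accepts_treatment", "1 - p_refuse", "0", modality),
    ])


class _SubtreePool:
    """Shared subtrees for one strategy tree (a rooted DAG, still acyclic)."""

    def __init__(self):
        self.sick = _sick_subtree()
        self.untreated = _untreated_subtree(self.sick)
        self.treatment = _treatment_subtree(self.untreated, self.sick)

    def diagnosis(self, p_dx: str) -> Node:
        """SCID assessment of a presenting woman (c_diag paid upstream)."""
        return chance("diagnosis", [
            Branch("confirmed", p_dx, "0", self.treatment),
            Branch("not_confirmed", f"1 - {p_dx}", "0", self.untreated),
        ])

    def self_referral(self, p_selfref: str, p_dx: str) -> Node:
        return chance("self_referral", [
            Branch("seeks_care", p_selfref, "c_diag", self.diagnosis(p_dx)),
            Branch("no_care_seeking", f"1 - {p_selfref}", "0", self.untreated),
        ])

    def postnatal_screen_ppd(self) -> Node:
        """Postnatal EPDS for a woman with PPD: referral chain or self-referral."""
        referral = chance("referral", [
            Branch("attends_referral", "p_ref_high", "c_diag", self.diagnosis("p_dx_high")),
            Branch("declines_referral", "1 - p_ref_high", "0", self.untreated),
        ])
        return chance("postnatal_screen", [
            Branch("screen_positive", "sens_epds", "0", referral),
            Branch("screen_negative", "1 - sens_epds", "0",
                   self.self_referral("p_selfref_low", "p_dx_low")),
        ])


def _postnatal_screen_healthy() -> Node:
    """Postnatal EPDS for a woman without PPD: false positives incur c_diag
    if they attend the referral, then exit healthy."""
    fp_referral = chance("referral", [
        Branch("attends_referral", "p_ref_high", "c_diag", _terminal("no_ppd")),
        Branch("declines_referral", "1 - p_ref_high", "0", _terminal("no_ppd")),
    ])
    return chance("postnatal_screen", [
        Branch("screen_positive", "1 - spec_epds", "0", fp_referral),
        Branch("screen_negative", "spec_epds", "0", _terminal("no_ppd")),
    ])


def _routine_tree() -> Node:
    pool = _SubtreePool()
    return chance("ppd_onset", [
        Branch("ppd", "p_ppd", "0",
               pool.self_referral("p_selfref_unscreened", "p_dx_low")),
        Branch("no_ppd", "1 - p_ppd", "0", _terminal("no_ppd")),
    ])


def _screening_tree() -> Node:
    pool = _SubtreePool()
    return chance("ppd_onset", [
        Branch("ppd", "p_ppd", "c_screen", pool.postnatal_screen_ppd()),
        Branch("no_ppd", "1 - p_ppd", "c_screen", _postnatal_screen_healthy()),
    ])


def _prenatal_tree() -> Node:
    # Antenatal EPDS: "ppd_onset" here is the liability to develop PPD absent
    # any intervention, so the label (and its uniform draw) is shared with
    # the other arms.  Flagged liable women receive the group intervention,
    # which averts PPD with probability p_int_effect; everyone then pays the
    # postnatal screen (second c_screen) and follows the screening pathway.
    pool = _SubtreePool()
    post_ppd = pool.postnatal_screen_ppd()
    post_healthy = _postnatal_screen_healthy()
    intervention = chance("intervention_effect", [
        Branch("ppd_averted", "p_int_effect", "c_screen", post_healthy),
        Branch("ppd_persists", "1 - p_int_effect", "c_screen", post_ppd),
    ])
    ante_ppd = chance("antenatal_screen", [
        Branch("flagged_high_risk", "sens_epds", "c_prenatal_int", intervention),
        Branch("not_flagged", "1 - sens_epds", "c_screen", post_ppd),
    ])
    ante_healthy = chance("antenatal_screen", [
        Branch("flagged_high_risk", "1 - spec_epds", "c_prenatal_int + c_screen",
               post_healthy),
        Branch("not_flagged", "spec_epds", "c_screen", post_healthy),
    ])
    return chance("ppd_onset", [
        Branch("ppd_prone", "p_ppd", "c_screen", ante_ppd),
        Branch("not_prone", "1 - p_ppd", "c_screen", ante_healthy),
    ])


_BUILDERS = {ROUTINE: _routine_tree, SCREENING: _screening_tree, PRENATAL: _prenatal_tree}


def build_strategy_tree(strategy: str, params: ParameterSet | None = None) -> Node:
    """Construct (and validate, when params are given) one strategy tree.

    The build is pure: the tree references parameters by name and carries no
    values, so the same structure serves every realization.
    """
    try:
        build = _BUILDERS[strategy]
    except KeyError:
        raise ModelError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    tree = build()
    if params is not None:
        report = validate(tree, params.env())
        if not report.ok:
            raise ModelError(f"{strategy}: invalid tree: {report.errors}")
    return tree


def build_strategy_trees(params: ParameterSet | None = None) -> dict[str, Node]:
    return {s: build_strategy_tree(s, params) for s in STRATEGIES}


def build_comparison_tree() -> Node:
    """Decision root over the three strategies (decision nodes appear only here)."""
    return decision("strategy", [
        Branch(s, None, "0", build_strategy_tree(s)) for s in STRATEGIES
    ])


def assign_payoffs(tag: str, params: ParameterSet) -> tuple[float, float]:
    """Numeric terminal payoff (state-linked cost, QALY weight) for a state.

    The QALY weight is the state utility on the normalized horizon;
    recovered women blend pre-cure (``f_pre`` of the horizon at ``u_ppd``)
    and post-cure (``u_cured``) time.  The unrecovered-episode care cost
    accrues on the branch entering the unrecovered pool, not here.
    """
    if tag not in PAYOFF_EXPRS:
        raise ModelError(f"unknown health state {tag!r}")
    cost, effect = PAYOFF_EXPRS[tag]
    env = params.env()
    return float(evaluate(cost, env)), float(evaluate(effect, env))


def classify_cohort(result) -> pd.Series:
    """Health-state counts of a microsimulated cohort, reported-columns first.

    Returns a Series over all five states (zeros filled in) whose values sum
    to the cohort size.
    """
    counts = pd.Series({s: result.counts.get(s, 0) for s in HEALTH_STATES}, dtype=int)
    if counts.sum() != result.n:
        raise ModelError("counts do not sum to cohort size")
    return counts


#: event labels ordered by how strongly their interactions drive the
#: *incremental* outcomes between arms (care-pathway gates first); used as
#: the Sobol dimension assignment for cohort comparisons
EVENT_PRIORITY = (
    "ppd_onset", "postnatal_screen", "referral", "diagnosis", "self_referral",
    "treatment_refusal", "treatment_modality", "psycho_cure", "pharm_cure",
    "relapse", "spontaneous_recovery", "antenatal_screen", "intervention_effect",
    "ideation", "suicide",
)


def simulate_cohorts(
    trees: Mapping[str, "Node"],
    params: ParameterSet | Mapping[str, float],
    n: int,
    seed: int,
    method: str = "qmc",
):
    """Microsimulate one cohort through every strategy arm.

    Thin wrapper over :func:`ppdcea.tree.microsimulate_strategies` that
    applies the model's event-priority Sobol dimension order, so the
    incremental costs and effects between arms are estimated with low
    Monte-Carlo noise.
    """
    from .tree import microsimulate_strategies

    env = params.env() if isinstance(params, ParameterSet) else dict(params)
    return microsimulate_strategies(
        trees, env, n, seed, method=method, label_order=EVENT_PRIORITY
    )


# -- shipped tree files ----------------------------------------------------

def load_shipped_tree(strategy: str) -> Node:
    """Read the serialized (reviewable) tree file bundled with the package."""
    if strategy not in STRATEGIES:
        raise ModelError(f"unknown strategy {strategy!r}")
    text = resources.files("ppdcea").joinpath(f"data/trees/{strategy}.yaml").read_text()
    return from_dict(yaml.safe_load(text))
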