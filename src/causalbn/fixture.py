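"""A 45-variable synthetic vaccine-intention network for testing.

The variable names, levels and causal-factor categories follow the published
codebook of the COVID-19 vaccine-hesitancy survey domain (45 categorical
variables, at most 3 levels).  The edge set is a hand-encoded *plausible*
topology: beliefs in social responsibility, anticipated regret, vaccine
unsafety and early-adopter willingness are direct parents of vaccine
intention; demographics sit upstream and never receive edges from
non-demographic variables.  CPTs are fixed constants produced by a
deterministic softmax recipe over the hard-coded edge weights below, with
the social-responsibility effect on intention deliberately the largest.

This fixture is a synthetic test harness with known ground truth — it is not
a claim to reproduce any empirically learned survey network.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .bn import BayesianNetwork
from .data import VariableSchema
from .simulate import GroundTruthBN

_YN = ("No", "Yes")
_RISK3 = ("Almost zero or low", "Moderate", "High or almost certain")
_INFO3 = ("Disagree", "Agree", "Sometimes agree or disagree")

#: (name, levels, category) for all 45 variables.
VARIABLES: tuple[tuple[str, tuple[str, ...], str], ...] = (
    ("Expected chance of getting seriously ill from COVID-19", _RISK3, "outcome expectation"),
    ("Expected chance of getting COVID-19 with no vaccine", _RISK3, "outcome expectation"),
    ("Expected chance of dying from COVID-19 with no vaccine", _RISK3, "outcome expectation"),
    ("Expected chance of getting long-term side-effects from COVID-19 vaccine", _RISK3, "outcome expectation"),
    ("Worries about catching COVID-19", ("Not at all or not much", "Moderate", "A great deal"), "emotions"),
    ("Anticipated regret if I did not take COVID-19 vaccine", _YN, "emotions"),
    ("Believes COVID-19 vaccine is free", _YN, "beliefs and perceptions"),
    ("Believes COVID-19 vaccine is tested for safety and effectiveness in people of my race", ("Disagree", "Agree", "Neither agree or disagree"), "beliefs and perceptions"),
    ("Believes people of my race are fairly treated in a health-care setting", _YN, "beliefs and perceptions"),
    ("Trust in the vaccine development process", ("Disagree", "Agree"), "beliefs and perceptions"),
    ("Believes COVID-19 vaccine will be unsafe", _YN, "beliefs and perceptions"),
    ("Believes COVID-19 testing is too rushed", _YN, "beliefs and perceptions"),
    ("Believes in social responsibility to get vaccinated to protect others", _YN, "beliefs and perceptions"),
    ("Believes that a tracking chip is implanted through vaccine", _YN, "beliefs and perceptions"),
    ("Has control over getting COVID-19", _YN, "beliefs and perceptions"),
    ("COVID-19 is perceived to be dangerous to my community", _YN, "beliefs and perceptions"),
    ("Believes in COVID-19 information from Trump", _INFO3, "influencers/channels"),
    ("Believes in COVID-19 info from public health organisations", _INFO3, "influencers/channels"),
    ("Believes in COVID-19 information from my physician", _INFO3, "influencers/channels"),
    ("Believes in COVID-19 information from my local community", _INFO3, "influencers/channels"),
    ("Believes in COVID-19 information from my social media contacts", _INFO3, "influencers/channels"),
    ("Gets information on COVID-19 from left-wing media", _YN, "influencers/channels"),
    ("Gets information on COVID-19 from Fox News", _YN, "influencers/channels"),
    ("Gets information on COVID-19 from social media", _YN, "influencers/channels"),
    ("Gets information on COVID-19 from scientists", _YN, "influencers/channels"),
    ("Proportion of community that I think will take the COVID-19 vaccine", ("None or fewer than half", "More than half or all"), "social influence"),
    ("Reference community expects me to take COVID-19 vaccine", ("No", "Yes", "Not sure or no answer"), "social influence"),
    ("Reference community considers COVID-19 a serious threat", ("No", "Yes", "Not sure"), "social influence"),
    ("Has health insurance", _YN, "structural enablers/barriers"),
    ("Have primary care physician", _YN, "structural enablers/barriers"),
    ("Easy to get COVID-19 vaccine once it is available", _YN, "structural enablers/barriers"),
    ("Delayed medical care due to cost", _YN, "structural enablers/barriers"),
    ("Delayed medical care due to work schedule", _YN, "structural enablers/barriers"),
    ("Delayed medical care due to childcare", _YN, "structural enablers/barriers"),
    ("Gender", ("Man", "Woman"), "demographics"),
    ("Race", ("White", "Black", "Other minorities"), "demographics"),
    ("Political affiliation", ("Republican", "Democrat", "Independent or other"), "demographics"),
    ("Education", ("High school or less", "Some college or associates", "Bachelor's degree or more"), "demographics"),
    ("Age", ("18-34", "35-64", "65 or over"), "demographics"),
    ("Is essential worker", _YN, "demographics"),
    ("Urbanicity", ("Urban", "Rural"), "demographics"),
    ("Income", ("Less than $30,000", "$30,000 to under $100,000", "$100,000 or more"), "demographics"),
    ("Seek check-up if I have symptoms", _YN, "behaviours"),
    ("Willing to take the COVID-19 vaccine in the first three months", ("No", "Yes", "Unsure"), "intentions"),
    ("Vaccine intention", ("Low", "Moderate", "High"), "dependent variable"),
)

# Short aliases used only while wiring edges.
_SR = "Believes in social responsibility to get vaccinated to protect others"
_REGRET = "Anticipated regret if I did not take COVID-19 vaccine"
_UNSAFE = "Believes COVID-19 vaccine will be unsafe"
_EARLY = "Willing to take the COVID-19 vaccine in the first three months"
_INTENT = "Vaccine intention"
_WORRY = "Worries about catching COVID-19"
_DANGER = "COVID-19 is perceived to be dangerous to my community"
_CHANCE = "Expected chance of getting COVID-19 with no vaccine"
_TRUST = "Trust in the vaccine development process"
_PROPORTION = "Proportion of community that I think will take the COVID-19 vaccine"
_EXPECTS = "Reference community expects me to take COVID-19 vaccine"
_SCIENTISTS = "Gets information on COVID-19 from scientists"

#: Hand-encoded edge set with signed effect weights (logit scale).  A positive
#: weight pushes the child towards its higher levels as the parent's level
#: score rises.
EDGE_WEIGHTS: dict[tuple[str, str], float] = {
    # demographics upstream (only demographics point into demographics)
    ("Age", "Income"): 0.8,
    ("Education", "Income"): 1.0,
    ("Race", "Political affiliation"): 0.8,
    ("Political affiliation", "Believes in COVID-19 information from Trump"): -1.6,
    ("Political affiliation", "Gets information on COVID-19 from Fox News"): -1.4,
    ("Political affiliation", "Gets information on COVID-19 from left-wing media"): 1.4,
    ("Political affiliation", _WORRY): 0.8,
    ("Political affiliation", _DANGER): 0.9,
    ("Age", "Expected chance of getting seriously ill from COVID-19"): 1.2,
    ("Age", _WORRY): 0.7,
    ("Income", "Has health insurance"): 1.2,
    ("Income", "Delayed medical care due to cost"): -1.2,
    ("Urbanicity", "Easy to get COVID-19 vaccine once it is available"): -1.0,
    ("Education", _SCIENTISTS): 1.0,
    ("Is essential worker", _CHANCE): 0.9,
    ("Is essential worker", "Delayed medical care due to work schedule"): 1.0,
    ("Gender", "Delayed medical care due to childcare"): 0.9,
    ("Race", "Believes people of my race are fairly treated in a health-care setting"): -1.0,
    ("Race", "Believes COVID-19 vaccine is tested for safety and effectiveness in people of my race"): -0.8,
    # structural access chain
    ("Has health insurance", "Have primary care physician"): 1.4,
    ("Have primary care physician", "Seek check-up if I have symptoms"): 1.2,
    ("Have primary care physician", "Believes in COVID-19 information from my physician"): 1.0,
    ("Has health insurance", "Believes COVID-19 vaccine is free"): 0.8,
    # information channels shaping beliefs
    (_SCIENTISTS, _DANGER): 1.0,
    (_SCIENTISTS, "Believes that a tracking chip is implanted through vaccine"): -1.2,
    (_SCIENTISTS, "Has control over getting COVID-19"): 0.7,
    ("Believes in COVID-19 information from Trump", "Believes COVID-19 testing is too rushed"): 1.2,
    ("Gets information on COVID-19 from Fox News", "Believes COVID-19 testing is too rushed"): 0.8,
    ("Gets information on COVID-19 from social media", "Believes in COVID-19 information from my social media contacts"): 1.2,
    ("Believes in COVID-19 information from my social media contacts", "Believes that a tracking chip is implanted through vaccine"): 0.9,
    ("Believes in COVID-19 info from public health organisations", _TRUST): 1.2,
    ("Believes in COVID-19 information from my physician", _TRUST): 1.0,
    ("Believes COVID-19 vaccine is tested for safety and effectiveness in people of my race", _TRUST): 0.8,
    ("Believes in COVID-19 information from my local community", "Reference community considers COVID-19 a serious threat"): 1.0,
    # risk perception and emotions
    (_DANGER, _CHANCE): 1.2,
    ("Expected chance of getting seriously ill from COVID-19", "Expected chance of dying from COVID-19 with no vaccine"): 1.4,
    (_CHANCE, _WORRY): 1.2,
    (_DANGER, _WORRY): 0.9,
    ("Reference community considers COVID-19 a serious threat", _EXPECTS): 1.2,
    (_DANGER, _PROPORTION): 0.9,
    (_EXPECTS, _PROPORTION): 1.0,
    # drivers of the direct causes of intention
    (_CHANCE, _SR): 0.8,
    (_WORRY, _SR): 0.8,
    (_DANGER, _SR): 1.0,
    (_WORRY, _REGRET): 0.9,
    (_SR, _REGRET): 1.2,
    (_EXPECTS, _REGRET): 0.8,
    (_TRUST, _UNSAFE): -1.3,
    (_PROPORTION, _UNSAFE): -0.8,
    (_REGRET, _UNSAFE): -0.6,
    (_SR, _UNSAFE): -0.7,
    (_UNSAFE, "Expected chance of getting long-term side-effects from COVID-19 vaccine"): 1.4,
    ("Believes that a tracking chip is implanted through vaccine", "Expected chance of getting long-term side-effects from COVID-19 vaccine"): 0.9,
    (_SR, _EARLY): 1.3,
    (_UNSAFE, _EARLY): -1.1,
    ("Easy to get COVID-19 vaccine once it is available", _EARLY): 0.7,
    # direct causes of vaccine intention; social responsibility dominates
    (_SR, _INTENT): 2.6,
    (_REGRET, _INTENT): 0.9,
    (_UNSAFE, _INTENT): -1.1,
    (_EARLY, _INTENT): 1.1,
}

#: Marginal base logits (softmax scale) for selected nodes; zeros elsewhere.
BASE_LOGITS: dict[str, tuple[float, ...]] = {
    "Believes that a tracking chip is implanted through vaccine": (1.2, -1.2),
    "Has health insurance": (-1.0, 1.0),
    "Believes COVID-19 vaccine is free": (-0.5, 0.5),
    "Delayed medical care due to cost": (0.8, -0.8),
    "Delayed medical care due to work schedule": (0.8, -0.8),
    "Delayed medical care due to childcare": (1.0, -1.0),
    "Seek check-up if I have symptoms": (-0.5, 0.5),
    "Race": (1.0, -0.6, 0.0),
    "Age": (0.0, 0.6, -0.2),
    "Education": (0.0, 0.2, 0.0),
    "Urbanicity": (0.7, -0.7),
    "Income": (0.0, 0.4, -0.3),
    "Political affiliation": (0.0, 0.2, -0.2),
    "Is essential worker": (0.4, -0.4),
}

#: Level scores used by the softmax recipe.  Default: centred, equally spaced
#: (-0.5, +0.5) or (-0.5, 0, +0.5); variables whose third level means
#: "unsure/neither" get a neutral 0 for it instead.
_NEUTRAL_THIRD = {
    _EARLY,
    _EXPECTS,
    "Reference community considers COVID-19 a serious threat",
    "Believes COVID-19 vaccine is tested for safety and effectiveness in people of my race",
    "Believes in COVID-19 information from Trump",
    "Believes in COVID-19 info from public health organisations",
    "Believes in COVID-19 information from my physician",
    "Believes in COVID-19 information from my local community",
    "Believes in COVID-19 information from my social media contacts",
}


def _level_scores(name: str, card: int) -> np.ndarray:
    if card == 2:
        return np.array([-0.5, 0.5])
    if name in _NEUTRAL_THIRD:
        return np.array([-0.5, 0.5, 0.0])
    return np.array([-0.5, 0.0, 0.5])


def fixture_schemas() -> list[VariableSchema]:
    return [VariableSchema(n, lv, cat) for n, lv, cat in VARIABLES]


def fixture_dag() -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(n for n, _, _ in VARIABLES)
    g.add_edges_from(EDGE_WEIGHTS)
    return g


def vaccine_fixture() -> GroundTruthBN:
    """The full 45-variable ground-truth network with its constant CPTs."""
    schemas = fixture_schemas()
    card = {s.name: s.cardinality for s in schemas}
    dag = fixture_dag()
    cpts: dict[str, np.ndarray] = {}
    parents: dict[str, tuple[str, ...]] = {}
    for v in dag.nodes:
        pa = tuple(sorted(dag.predecessors(v)))
        parents[v] = pa
        base = np.array(BASE_LOGITS.get(v, (0.0,) * card[v]))
        t = _level_scores(v, card[v])
        pa_cards = [card[p] for p in pa]
        table = np.empty(pa_cards + [card[v]])
        for cfg in np.ndindex(*pa_cards) if pa else [()]:
            shift = sum(
                EDGE_WEIGHTS[(p, v)] * _level_scores(p, card[p])[lvl]
                for p, lvl in zip(pa, cfg)
            )
            logits = base + shift * t
            ex = np.exp(logits - logits.max())
            table[cfg] = ex / ex.sum()
        cpts[v] = table
    return BayesianNetwork(dag, schemas, cpts, parents)
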