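"""Guideline rules, CPT compilation, and the packaged larynx treatment model.

Clinical guidelines express treatment indications as conditions over
tumor staging ("for T1-T2 N0 M0 disease, primary surgery or definitive
radiotherapy") rather than as probability tables.  This module encodes
such statements as declarative :class:`GuidelineRule` records — a set
of matching TNM states plus a chemotherapy-tolerance condition, an
indication probability ``p_true`` and a priority — and compiles an
ordered rule set into full conditional probability tables for the
binary treatment nodes of a staging-driven decision network.

The packaged laryngeal-carcinoma model has nine variables: the TNM
staging triplet (T, N, M), chemotherapy tolerance as a therapy
prerequisite, and five binary treatment-recommendation targets
(larynx surgery, radiotherapy, radiochemotherapy, chemotherapy,
immunotherapy).  T, N and M feed every treatment node (15 edges);
tolerance feeds surgery, chemotherapy and radiochemotherapy (3 edges),
for 18 edges in total.  Two probabilities are fixed anchors of the
packaged rule set and are asserted at build time: with full evidence
T2/N2a/M0/tolerant the surgery node must answer 0.74, and with
T2/N2a/M1/tolerant it must answer 0.17.  All other rule probabilities
are a documented, guideline-flavored elicitation shipped in
``data/larynx_nccn_like.yaml`` — reconstructed, not transcribed from
any single guideline table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml

from .bn_core import CPT, Network, Variable, posterior, validate_network

logger = logging.getLogger("larynxbn")

# State spaces of the packaged model ---------------------------------------

T_STATES = ("TX", "T0", "TIS", "T1", "T1a", "T1b", "T2", "T3", "T4a", "T4b")
N_STATES = ("NX", "N0", "N1", "N2a", "N2b", "N2c", "N3a", "N3b")
M_STATES = ("MX", "M0", "M1")
TOLERANCE_STATES = ("tolerant", "intolerant")
#: Declared order matters: "false" first means argmax ties resolve to the
#: negative (no-treatment) recommendation.
TREATMENT_STATES = ("false", "true")

TREATMENTS = (
    "larynx_surgery",
    "radiotherapy",
    "radiochemotherapy",
    "chemotherapy",
    "immunotherapy",
)
#: Treatments whose CPT additionally conditions on chemotherapy tolerance.
TOLERANCE_CHILDREN = ("larynx_surgery", "radiochemotherapy", "chemotherapy")

#: Empirical T-stage marginal of the reference cohort (counts out of 97);
#: T0 is a declared state but was never observed.
T_PRIOR_COUNTS = {
    "TX": 1, "T0": 0, "TIS": 1, "T1": 5, "T1a": 19,
    "T1b": 8, "T2": 16, "T3": 22, "T4a": 23, "T4b": 2,
}

#: The two anchor probabilities every packaged build must reproduce.
ANCHORS = (
    (("T2", "N2a", "M0", "tolerant"), "larynx_surgery", 0.74),
    (("T2", "N2a", "M1", "tolerant"), "larynx_surgery", 0.17),
)

DEFAULT_RULESET_RESOURCE = "larynx_nccn_like.yaml"


# ---------------------------------------------------------------------------
# Rule types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GuidelineRule:
    """One declarative treatment-indication rule.

    ``t``/``n``/``m`` are the matched state subsets (``None`` = any);
    ``tolerance`` is ``"tolerant"``, ``"intolerant"`` or ``"any"``.
    ``p_true`` is the probability that the treatment is indicated for
    matching staging; ``priority`` resolves overlaps (higher wins;
    among equal priorities the rule listed last wins, with a warning
    if the probabilities disagree).
    """

    treatment: str
    p_true: float
    priority: int = 0
    t: frozenset[str] | None = None
    n: frozenset[str] | None = None
    m: frozenset[str] | None = None
    tolerance: str = "any"
    name: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_true <= 1.0:
            raise ValueError(f"rule {self.name!r}: p_true {self.p_true} not in [0,1]")
        if self.tolerance not in ("any", *TOLERANCE_STATES):
            raise ValueError(f"rule {self.name!r}: bad tolerance {self.tolerance!r}")
        for attr, valid in (("t", T_STATES), ("n", N_STATES), ("m", M_STATES)):
            states = getattr(self, attr)
            if states is not None:
                object.__setattr__(self, attr, frozenset(states))
                unknown = set(states) - set(valid)
                if unknown:
                    raise ValueError(
                        f"rule {self.name!r}: unknown {attr.upper()} states {sorted(unknown)}"
                    )

    def matches(self, t: str, n: str, m: str, tolerance: str | None) -> bool:
        if self.t is not None and t not in self.t:
            return False
        if self.n is not None and n not in self.n:
            return False
        if self.m is not None and m not in self.m:
            return False
        if self.tolerance != "any" and tolerance != self.tolerance:
            return False
        return True


@dataclass
class GuidelineRuleSet:
    """Ordered rules plus one fallback ``p_true`` per treatment."""

    rules: list[GuidelineRule]
    defaults: dict[str, float]

    def __post_init__(self) -> None:
        for tr, p in self.defaults.items():
            if tr not in TREATMENTS:
                raise ValueError(f"default for unknown treatment {tr!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"default p_true for {tr!r} not in [0,1]")
        missing = set(TREATMENTS) - set(self.defaults)
        if missing:
            raise ValueError(f"missing defaults for treatments: {sorted(missing)}")
        for rule in self.rules:
            if rule.treatment not in TREATMENTS:
                raise ValueError(
                    f"rule {rule.name!r}: unknown treatment {rule.treatment!r}"
                )
            if rule.treatment not in TOLERANCE_CHILDREN and rule.tolerance != "any":
                raise ValueError(
                    f"rule {rule.name!r}: {rule.treatment!r} has no tolerance parent; "
                    "tolerance condition must be 'any'"
                )


@dataclass(frozen=True)
class LarynxModelSpec:
    """State spaces and wiring of the larynx treatment network."""

    t_states: tuple[str, ...] = T_STATES
    n_states: tuple[str, ...] = N_STATES
    m_states: tuple[str, ...] = M_STATES
    tolerance_states: tuple[str, ...] = TOLERANCE_STATES
    treatments: tuple[str, ...] = TREATMENTS
    tolerance_children: tuple[str, ...] = TOLERANCE_CHILDREN

    def parents_of(self, treatment: str) -> tuple[str, ...]:
        base = ("T", "N", "M")
        if treatment in self.tolerance_children:
            return base + ("chemo_tolerance",)
        return base


LARYNX_SPEC = LarynxModelSpec()


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------


def _winning_p(
    rules: Sequence[GuidelineRule],
    default: float,
    t: str,
    n: str,
    m: str,
    tol: str | None,
) -> float:
    matching = [r for r in rules if r.matches(t, n, m, tol)]
    if not matching:
        return default
    top = max(r.priority for r in matching)
    finalists = [r for r in matching if r.priority == top]
    winner = finalists[-1]  # last listed wins among equal priorities
    if len({r.p_true for r in finalists}) > 1:
        logger.warning(
            "rule conflict at (%s,%s,%s,%s) for %s: equal priority %d, "
            "p_true %s; last-listed rule %r wins",
            t, n, m, tol, winner.treatment, top,
            sorted({r.p_true for r in finalists}), winner.name,
        )
    return winner.p_true


def compile_cpts(
    ruleset: GuidelineRuleSet, spec: LarynxModelSpec = LARYNX_SPEC
) -> list[CPT]:
    """Expand the rule set into one full CPT per treatment node.

    For every parent-state combination of every treatment the winning
    rule (highest priority; among equals, last listed; no match, the
    treatment default) sets ``P(true)`` and ``P(false) = 1 - P(true)``.
    """
    cpts: list[CPT] = []
    for treatment in spec.treatments:
        rules = [r for r in ruleset.rules if r.treatment == treatment]
        default = ruleset.defaults[treatment]
        parents = spec.parents_of(treatment)
        has_tol = "chemo_tolerance" in parents
        table: dict[tuple[str, ...], tuple[float, ...]] = {}
        for t in spec.t_states:
            for n in spec.n_states:
                for m in spec.m_states:
                    tols: tuple[str | None, ...] = (
                        spec.tolerance_states if has_tol else (None,)
                    )
                    for tol in tols:
                        p = _winning_p(rules, default, t, n, m, tol)
                        combo = (t, n, m) + ((tol,) if has_tol else ())
                        table[combo] = (1.0 - p, p)  # (false, true)
        cpts.append(CPT(child=treatment, parents=parents, table=table))
    return cpts


# ---------------------------------------------------------------------------
# Priors and model assembly
# ---------------------------------------------------------------------------


def default_priors() -> dict[str, dict[str, float]]:
    """Root priors: empirical T marginal; uniform N, M and tolerance.

    The reference cohort publishes only the T-stage marginal; N, M and
    tolerance priors default to uniform and are configurable.  Priors
    never affect full-evidence inference on the treatment nodes.
    """
    total = sum(T_PRIOR_COUNTS.values())
    return {
        "T": {s: T_PRIOR_COUNTS[s] / total for s in T_STATES},
        "N": {s: 1.0 / len(N_STATES) for s in N_STATES},
        "M": {s: 1.0 / len(M_STATES) for s in M_STATES},
        "chemo_tolerance": {s: 1.0 / len(TOLERANCE_STATES) for s in TOLERANCE_STATES},
    }


def _prior_cpt(name: str, states: tuple[str, ...], prior: Mapping[str, float]) -> CPT:
    missing = set(states) - set(prior)
    if missing:
        raise ValueError(f"prior for {name!r} missing states {sorted(missing)}")
    total = sum(prior[s] for s in states)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"prior for {name!r} sums to {total!r}")
    return CPT(child=name, parents=(), table={(): tuple(prior[s] for s in states)})


def build_larynx_model(
    ruleset: GuidelineRuleSet | None = None,
    priors: Mapping[str, Mapping[str, float]] | None = None,
    spec: LarynxModelSpec = LARYNX_SPEC,
    require_anchors: bool = True,
) -> Network:
    """Assemble the nine-node, eighteen-edge larynx treatment network.

    With ``require_anchors`` (the default, i.e. the packaged model) the
    build refuses rule sets in which either printed anchor probability
    is absent or overridden; custom models may disable the check.
    """
    if ruleset is None:
        ruleset = default_ruleset()
    merged = default_priors()
    if priors:
        for var, dist in priors.items():
            merged[var] = dict(dist)

    variables = [
        Variable("T", spec.t_states, "observable"),
        Variable("N", spec.n_states, "observable"),
        Variable("M", spec.m_states, "observable"),
        Variable("chemo_tolerance", spec.tolerance_states, "observable"),
    ] + [Variable(tr, TREATMENT_STATES, "target") for tr in spec.treatments]

    cpts = [
        _prior_cpt("T", spec.t_states, merged["T"]),
        _prior_cpt("N", spec.n_states, merged["N"]),
        _prior_cpt("M", spec.m_states, merged["M"]),
        _prior_cpt("chemo_tolerance", spec.tolerance_states, merged["chemo_tolerance"]),
    ] + compile_cpts(ruleset, spec)

    net = Network(variables, cpts)
    report = validate_network(net)
    if not report.ok:
        raise ValueError("larynx model failed validation:\n" + "\n".join(report.problems))

    if require_anchors:
        for (t, n, m, tol), treatment, expected in ANCHORS:
            got = net.cpts[treatment].column((t, n, m, tol))[
                TREATMENT_STATES.index("true")
            ]
            if abs(got - expected) > 1e-12:
                raise ValueError(
                    f"packaged model requires the anchor P({treatment}=true | "
                    f"T={t},N={n},M={m},tolerance={tol}) = {expected}, "
                    f"but the rule set compiles to {got}"
                )
    return net


def anchor_posteriors(net: Network) -> list[float]:
    """Full-evidence posterior P(true) at each anchor constellation."""
    out = []
    for (t, n, m, tol), treatment, _ in ANCHORS:
        dist = posterior(
            net, {"T": t, "N": n, "M": m, "chemo_tolerance": tol}, treatment
        )
        out.append(dist["true"])
    return out


# ---------------------------------------------------------------------------
# Ruleset (de)serialization
# ---------------------------------------------------------------------------


def _states_from_yaml(value) -> frozenset[str] | None:
    if value is None or value == "any":
        return None
    if isinstance(value, str):
        value = [value]
    return frozenset(str(v) for v in value)


def ruleset_from_dict(data: Mapping) -> GuidelineRuleSet:
    rules = [
        GuidelineRule(
            treatment=r["treatment"],
            p_true=float(r["p_true"]),
            priority=int(r.get("priority", 0)),
            t=_states_from_yaml(r.get("t", "any")),
            n=_states_from_yaml(r.get("n", "any")),
            m=_states_from_yaml(r.get("m", "any")),
            tolerance=str(r.get("tolerance", "any")),
            name=str(r.get("name", "")),
        )
        for r in data.get("rules", [])
    ]
    defaults = {k: float(v) for k, v in data["defaults"].items()}
    return GuidelineRuleSet(rules=rules, defaults=defaults)


def ruleset_to_dict(ruleset: GuidelineRuleSet) -> dict:
    def states(v: frozenset[str] | None, order: tuple[str, ...]):
        return "any" if v is None else [s for s in order if s in v]

    return {
        "defaults": dict(ruleset.defaults),
        "rules": [
            {
                "name": r.name,
                "treatment": r.treatment,
                "t": states(r.t, T_STATES),
                "n": states(r.n, N_STATES),
                "m": states(r.m, M_STATES),
                "tolerance": r.tolerance,
                "p_true": r.p_true,
                "priority": r.priority,
            }
            for r in ruleset.rules
        ],
    }


def load_ruleset(path) -> GuidelineRuleSet:
    with open(path, encoding="utf-8") as fh:
        return ruleset_from_dict(yaml.safe_load(fh))


def save_ruleset(ruleset: GuidelineRuleSet, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(ruleset_to_dict(ruleset), fh, sort_keys=False)


def default_ruleset() -> GuidelineRuleSet:
    """The packaged guideline-flavored rule set (``larynx_nccn_like.yaml``)."""
    ref = resources.files("larynxbn").joinpath("data", DEFAULT_RULESET_RESOURCE)
    with ref.open(encoding="utf-8") as fh:
        return ruleset_from_dict(yaml.safe_load(fh))
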