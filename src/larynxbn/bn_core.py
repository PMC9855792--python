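"""Discrete Bayesian networks with exact inference.

A Bayesian network (BN) is a directed acyclic graph of categorical
variables in which every variable carries one conditional probability
table (CPT): a probability distribution over its states for each
combination of its parents' states.  The joint distribution factorises
by the chain rule, ``P(x_1..x_n) = prod_i P(x_i | parents(x_i))``.

This module provides the network representation, structural validation,
exact posterior inference by variable elimination, a brute-force
full-joint enumeration oracle against which the elimination engine can
be verified, MAP state selection, ancestral (forward) sampling, and
serialization to a declarative YAML format plus a best-effort GeNIe
XDSL export.

Scope is deliberately narrow: finite categorical variables, exact
inference, no decision/utility nodes, no structure learning.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence
from xml.etree import ElementTree as ET

import networkx as nx
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("larynxbn")

#: Tolerance for treating a CPT column or posterior as normalized.
NORMALIZATION_TOL = 1e-9

VALID_ROLES = ("observable", "target")


class ImpossibleEvidenceError(ValueError):
    """Raised when the requested evidence has probability zero under the model."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Variable:
    """A categorical network variable.

    Parameters
    ----------
    name
        Unique identifier within a network.
    states
        Ordered tuple of at least two distinct state labels.  The order
        is meaningful: it defines CPT column layout and the MAP
        tie-break (first state wins).
    role
        ``"observable"`` for evidence-bearing input variables,
        ``"target"`` for inferred recommendation variables.
    """

    name: str
    states: tuple[str, ...]
    role: str = "observable"

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(str(s) for s in self.states))
        if len(self.states) < 2:
            raise ValueError(f"variable {self.name!r} needs >=2 states")
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"variable {self.name!r} has duplicate state labels")
        if self.role not in VALID_ROLES:
            raise ValueError(f"variable {self.name!r}: unknown role {self.role!r}")

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise ValueError(
                f"{state!r} is not a state of {self.name!r} (states: {self.states})"
            ) from None


@dataclass
class CPT:
    """Conditional probability table for one child variable.

    ``table`` maps every full combination of parent states (a tuple,
    ordered as ``parents``; the empty tuple for root variables) to a
    distribution over the child's states in declared state order.
    """

    child: str
    parents: tuple[str, ...]
    table: dict[tuple[str, ...], tuple[float, ...]]

    def __post_init__(self) -> None:
        self.parents = tuple(self.parents)
        self.table = {
            tuple(k): tuple(float(p) for p in v) for k, v in self.table.items()
        }

    def column(self, parent_states: Sequence[str]) -> tuple[float, ...]:
        return self.table[tuple(parent_states)]


class Network:
    """A Bayesian network: variables plus one CPT per variable.

    The constructor is deliberately permissive about deeper structural
    problems (cycles, unnormalized or incomplete CPTs) so that
    :func:`validate_network` can report them; inference assumes a
    network that validates cleanly.
    """

    def __init__(self, variables: Iterable[Variable], cpts: Iterable[CPT]):
        self.variables: tuple[Variable, ...] = tuple(variables)
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in network")
        self._vars: dict[str, Variable] = {v.name: v for v in self.variables}
        self.cpts: dict[str, CPT] = {}
        for cpt in cpts:
            if cpt.child in self.cpts:
                raise ValueError(f"duplicate CPT for {cpt.child!r}")
            self.cpts[cpt.child] = cpt

    # -- structure -----------------------------------------------------
    def variable(self, name: str) -> Variable:
        try:
            return self._vars[name]
        except KeyError:
            raise KeyError(f"unknown variable {name!r}") from None

    def parents(self, name: str) -> tuple[str, ...]:
        return self.cpts[name].parents

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Edge set derived from the CPT parent lists."""
        return {
            (p, cpt.child) for cpt in self.cpts.values() for p in cpt.parents
        }

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(v.name for v in self.variables)
        g.add_edges_from(self.edges)
        return g

    def topological_order(self) -> list[str]:
        g = self.graph()
        order = list(nx.topological_sort(g))
        decl = {v.name: i for i, v in enumerate(self.variables)}
        # lexicographic-by-declaration within topological freedom, for determinism
        return sorted(order, key=lambda n: (len(nx.ancestors(g, n)), decl[n]))

    def copy_with_cpts(self, cpts: Iterable[CPT]) -> "Network":
        return Network(self.variables, cpts)

    # -- probability ---------------------------------------------------
    def joint_probability(self, assignment: Mapping[str, str]) -> float:
        """Chain-rule probability of one full assignment."""
        missing = [v.name for v in self.variables if v.name not in assignment]
        if missing:
            raise ValueError(f"assignment missing variables: {missing}")
        p = 1.0
        for var in self.variables:
            cpt = self.cpts[var.name]
            combo = tuple(assignment[par] for par in cpt.parents)
            p *= cpt.column(combo)[var.index(assignment[var.name])]
        return p


@dataclass
class StructureReport:
    """Outcome of :func:`validate_network`: counts plus listed violations."""

    n_nodes: int
    n_edges: int
    acyclic: bool
    cpt_normalized: dict[str, bool]
    problems: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return self.acyclic and not self.problems and all(self.cpt_normalized.values())


def validate_network(net: Network) -> StructureReport:
    """Check every structural invariant; list violations, never raise.

    Verifies: one CPT per declared variable, CPT parents declared,
    CPT tables covering exactly the Cartesian product of parent state
    lists, nonnegative columns summing to one within ``1e-9``, and
    acyclicity of the derived edge set.
    """
    problems: list[str] = []
    normalized: dict[str, bool] = {}
    declared = {v.name for v in net.variables}

    for name in declared:
        if name not in net.cpts:
            problems.append(f"variable {name!r} has no CPT")
    for child in net.cpts:
        if child not in declared:
            problems.append(f"CPT child {child!r} is not a declared variable")

    for child, cpt in net.cpts.items():
        if child not in declared:
            continue
        ok = True
        undeclared = [p for p in cpt.parents if p not in declared]
        if undeclared:
            problems.append(f"CPT {child!r}: undeclared parents {undeclared}")
            normalized[child] = False
            continue
        var = net.variable(child)
        expected = set(
            itertools.product(*(net.variable(p).states for p in cpt.parents))
        )
        got = set(cpt.table)
        if got != expected:
            miss, extra = expected - got, got - expected
            if miss:
                problems.append(
                    f"CPT {child!r}: {len(miss)} parent combinations missing "
                    f"(e.g. {sorted(miss)[0]})"
                )
            if extra:
                problems.append(
                    f"CPT {child!r}: {len(extra)} unexpected combinations "
                    f"(e.g. {sorted(extra)[0]})"
                )
            ok = False
        for combo, dist in cpt.table.items():
            if len(dist) != len(var.states):
                problems.append(f"CPT {child!r} @ {combo}: wrong column length")
                ok = False
                continue
            if min(dist) < 0:
                problems.append(f"CPT {child!r} @ {combo}: negative probability")
                ok = False
            if abs(sum(dist) - 1.0) > NORMALIZATION_TOL:
                problems.append(
                    f"CPT {child!r} @ {combo}: column sums to {sum(dist)!r}"
                )
                ok = False
        normalized[child] = ok

    g = nx.DiGraph()
    g.add_nodes_from(declared)
    edges = {
        (p, c.child)
        for c in net.cpts.values()
        if c.child in declared
        for p in c.parents
        if p in declared
    }
    g.add_edges_from(edges)
    acyclic = nx.is_directed_acyclic_graph(g)
    if not acyclic:
        cycle = nx.find_cycle(g)
        problems.append(f"graph contains a cycle: {cycle}")

    return StructureReport(
        n_nodes=len(net.variables),
        n_edges=len(edges),
        acyclic=acyclic,
        cpt_normalized=normalized,
        problems=problems,
    )


# ---------------------------------------------------------------------------
# Evidence handling
# ---------------------------------------------------------------------------


def _check_evidence(net: Network, evidence: Mapping[str, str]) -> None:
    for name, state in evidence.items():
        net.variable(name).index(state)


# ---------------------------------------------------------------------------
# Brute-force oracle: full-joint enumeration
# ---------------------------------------------------------------------------


def enumerate_posterior(
    net: Network, evidence: Mapping[str, str], query: str
) -> dict[str, float]:
    """Posterior by exhaustive summation over the full joint distribution.

    Enumerates every completion of the evidence, accumulates
    :meth:`Network.joint_probability` per query state and normalizes.
    Exponential in the number of free variables; intended as the
    correctness oracle for :func:`posterior` on small networks.
    """
    _check_evidence(net, evidence)
    qvar = net.variable(query)
    axes = [
        (evidence[v.name],) if v.name in evidence else v.states
        for v in net.variables
    ]
    names = [v.name for v in net.variables]
    totals = dict.fromkeys(qvar.states, 0.0)
    for combo in itertools.product(*axes):
        assignment = dict(zip(names, combo))
        totals[assignment[query]] += net.joint_probability(assignment)
    z = sum(totals.values())
    if z <= 0.0:
        raise ImpossibleEvidenceError(f"evidence {dict(evidence)} has probability 0")
    return {s: totals[s] / z for s in qvar.states}


# ---------------------------------------------------------------------------
# Variable elimination
# ---------------------------------------------------------------------------


@dataclass
class Factor:
    """A nonnegative table over an ordered scope of variables."""

    scope: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.scope = tuple(self.scope)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != len(self.scope):
            raise ValueError("factor dimensions do not match scope")


def _broadcast(f: Factor, scope: tuple[str, ...], card: Mapping[str, int]) -> np.ndarray:
    """View of ``f.values`` aligned and broadcastable to ``scope``."""
    order = sorted(range(len(f.scope)), key=lambda i: scope.index(f.scope[i]))
    vals = np.transpose(f.values, order)
    shape = tuple(card[v] if v in f.scope else 1 for v in scope)
    return vals.reshape(shape)


def _product(factors: list[Factor], card: Mapping[str, int], var_rank: Mapping[str, int]) -> Factor:
    scope = tuple(sorted({v for f in factors for v in f.scope}, key=var_rank.__getitem__))
    out = np.ones(tuple(card[v] for v in scope))
    for f in factors:
        out = out * _broadcast(f, scope, card)
    return Factor(scope, out)


def _min_degree_order(scopes: list[tuple[str, ...]], hidden: list[str]) -> list[str]:
    """Greedy min-degree elimination ordering (a cost heuristic only)."""
    adj: dict[str, set[str]] = {v: set() for s in scopes for v in s}
    for s in scopes:
        for a, b in itertools.combinations(s, 2):
            adj[a].add(b)
            adj[b].add(a)
    rank = {v: i for i, v in enumerate(hidden)}  # declaration-order tie break
    remaining = [v for v in hidden if v in adj]
    order: list[str] = []
    while remaining:
        v = min(remaining, key=lambda x: (len(adj[x] & set(remaining)), rank[x]))
        neigh = adj[v] & set(remaining) - {v}
        for a, b in itertools.combinations(neigh, 2):
            adj[a].add(b)
            adj[b].add(a)
        remaining.remove(v)
        order.append(v)
    order.extend(v for v in hidden if v not in adj)
    return order


def _evidence_reduced_factors(
    net: Network, evidence: Mapping[str, str]
) -> tuple[list[Factor], dict[str, int]]:
    card = {v.name: len(v.states) for v in net.variables}
    factors: list[Factor] = []
    for var in net.variables:
        cpt = net.cpts[var.name]
        scope = cpt.parents + (var.name,)
        shape = tuple(card[s] for s in scope)
        arr = np.empty(shape)
        for combo, dist in cpt.table.items():
            idx = tuple(net.variable(p).index(s) for p, s in zip(cpt.parents, combo))
            arr[idx] = dist
        keep_scope = []
        indexer: list[object] = []
        for s in scope:
            if s in evidence:
                indexer.append(net.variable(s).index(evidence[s]))
            else:
                indexer.append(slice(None))
                keep_scope.append(s)
        factors.append(Factor(tuple(keep_scope), arr[tuple(indexer)]))
    return factors, card


def posterior(
    net: Network,
    evidence: Mapping[str, str],
    query: str,
    elimination_order: Sequence[str] | None = None,
) -> dict[str, float]:
    """Exact posterior over ``query`` given ``evidence``, by variable elimination.

    Agrees with :func:`enumerate_posterior` to within ``1e-9`` for every
    input and is independent of the elimination order; the default order
    is a min-degree heuristic (a cost choice only).  Evidence with zero
    probability raises :class:`ImpossibleEvidenceError`.
    """
    _check_evidence(net, evidence)
    qvar = net.variable(query)
    factors, card = _evidence_reduced_factors(net, evidence)
    var_rank = {v.name: i for i, v in enumerate(net.variables)}

    hidden = [
        v.name for v in net.variables if v.name not in evidence and v.name != query
    ]
    if elimination_order is not None:
        if sorted(elimination_order) != sorted(hidden):
            raise ValueError(
                "elimination_order must be a permutation of the hidden variables"
            )
        order = list(elimination_order)
    else:
        order = _min_degree_order([f.scope for f in factors], hidden)

    for v in order:
        touching = [f for f in factors if v in f.scope]
        if not touching:
            continue
        rest = [f for f in factors if v not in f.scope]
        prod = _product(touching, card, var_rank)
        summed = prod.values.sum(axis=prod.scope.index(v))
        scope = tuple(s for s in prod.scope if s != v)
        factors = rest + [Factor(scope, summed)]

    result = _product(factors, card, var_rank)
    z = float(result.values.sum())
    if z <= 0.0:
        raise ImpossibleEvidenceError(f"evidence {dict(evidence)} has probability 0")

    if query in evidence:  # degenerate but well-defined
        return {s: 1.0 if s == evidence[query] else 0.0 for s in qvar.states}
    vec = result.values.reshape(card[query])
    vec = vec / z
    return dict(zip(qvar.states, vec.tolist()))


def map_state(dist: Mapping[str, float], states: Sequence[str]) -> str:
    """Argmax state of a distribution; ties go to the first state in ``states``."""
    if not states:
        raise ValueError("empty state list")
    if not dist:
        raise ValueError("empty distribution")
    best, best_p = None, -np.inf
    for s in states:
        p = float(dist.get(s, 0.0))
        if p > best_p:
            best, best_p = s, p
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# Ancestral sampling
# ---------------------------------------------------------------------------


def forward_sample(net: Network, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Draw ``n`` complete cases from the network by ancestral sampling.

    Returns a DataFrame with one column of state labels per variable,
    in declaration order.
    """
    order = net.topological_order()
    idx_cols: dict[str, np.ndarray] = {}
    cols: dict[str, np.ndarray] = {}
    for name in order:
        var = net.variable(name)
        cpt = net.cpts[name]
        k = len(var.states)
        if not cpt.parents:
            p = np.asarray(cpt.table[()], dtype=float)
            idx = rng.choice(k, size=n, p=p / p.sum())
        else:
            parent_states = [net.variable(p).states for p in cpt.parents]
            combos = list(itertools.product(*parent_states))
            combo_rank = {c: i for i, c in enumerate(combos)}
            table = np.array([cpt.table[c] for c in combos], dtype=float)
            dims = [len(s) for s in parent_states]
            flat = np.zeros(n, dtype=int)
            for pname, d in zip(cpt.parents, dims):
                flat = flat * d + idx_cols[pname]
            # flat index must agree with itertools.product (row-major) order
            assert combo_rank[combos[0]] == 0
            probs = table[flat]
            u = rng.random(n)
            idx = np.minimum((u[:, None] > np.cumsum(probs, axis=1)).sum(axis=1), k - 1)
        idx_cols[name] = idx
        cols[name] = np.asarray(var.states, dtype=object)[idx]
    return pd.DataFrame({v.name: cols[v.name] for v in net.variables})


# ---------------------------------------------------------------------------
# Serialization: declarative YAML, lossless round trip
# ---------------------------------------------------------------------------


def network_to_dict(net: Network) -> dict:
    return {
        "variables": [
            {"name": v.name, "states": list(v.states), "role": v.role}
            for v in net.variables
        ],
        "cpts": [
            {
                "child": cpt.child,
                "parents": list(cpt.parents),
                "table": [
                    {"given": list(combo), "p": list(dist)}
                    for combo, dist in sorted(cpt.table.items())
                ],
            }
            for cpt in (net.cpts[v.name] for v in net.variables)
        ],
    }


def network_from_dict(data: Mapping) -> Network:
    variables = [
        Variable(d["name"], tuple(d["states"]), d.get("role", "observable"))
        for d in data["variables"]
    ]
    cpts = [
        CPT(
            child=d["child"],
            parents=tuple(d.get("parents", ())),
            table={tuple(row["given"]): tuple(row["p"]) for row in d["table"]},
        )
        for d in data["cpts"]
    ]
    net = Network(variables, cpts)
    report = validate_network(net)
    if not report.ok:
        raise ValueError("invalid network definition:\n" + "\n".join(report.problems))
    return net


def save_network(net: Network, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(network_to_dict(net), fh, sort_keys=False)


def load_network(path) -> Network:
    with open(path, encoding="utf-8") as fh:
        return network_from_dict(yaml.safe_load(fh))


def _xdsl_id(label: str) -> str:
    out = "".join(c if c.isalnum() or c == "_" else "_" for c in label)
    if not out or out[0].isdigit():
        out = "S_" + out
    return out


def export_xdsl(net: Network, path) -> None:
    """Write the network as a GeNIe/SMILE XDSL file (write-only, best effort).

    Probabilities are emitted in GeNIe's row-major layout: parent
    combinations iterate with the last parent fastest, the child state
    fastest of all.
    """
    smile = ET.Element("smile", version="1.0", id="larynxbn_export", numsamples="10000")
    nodes = ET.SubElement(smile, "nodes")
    for var in net.variables:
        cpt = net.cpts[var.name]
        el = ET.SubElement(nodes, "cpt", id=_xdsl_id(var.name))
        for s in var.states:
            ET.SubElement(el, "state", id=_xdsl_id(s))
        if cpt.parents:
            ET.SubElement(el, "parents").text = " ".join(
                _xdsl_id(p) for p in cpt.parents
            )
        parent_states = [net.variable(p).states for p in cpt.parents]
        probs: list[str] = []
        for combo in itertools.product(*parent_states):
            probs.extend(repr(p) for p in cpt.table[combo])
        ET.SubElement(el, "probabilities").text = " ".join(probs)
    ext = ET.SubElement(smile, "extensions")
    genie = ET.SubElement(
        ext, "genie", version="1.0", app="larynxbn", name="larynxbn export"
    )
    for var in net.variables:
        ET.SubElement(genie, "node", id=_xdsl_id(var.name)).append(
            _text_el("name", var.name)
        )
    tree = ET.ElementTree(smile)
    ET.indent(tree)
    tree.write(path, encoding="unicode", xml_declaration=True)


def _text_el(tag: str, text: str) -> ET.Element:
    el = ET.Element(tag)
    el.text = text
    return el
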