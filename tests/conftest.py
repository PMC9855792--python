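import numpy as np
import pytest

import larynxbn as lx


@pytest.fixture(scope="session")
def larynx_model():
    """The packaged nine-node larynx treatment network."""
    return lx.build_larynx_model()


@pytest.fixture(scope="session")
def two_node_net():
    """A -> B with hand-set tables, for chain-rule arithmetic."""
    a = lx.Variable("A", ("a1", "a2"))
    b = lx.Variable("B", ("b1", "b2", "b3"))
    cpt_a = lx.CPT("A", (), {(): (0.3, 0.7)})
    cpt_b = lx.CPT(
        "B",
        ("A",),
        {("a1",): (0.2, 0.5, 0.3), ("a2",): (0.6, 0.1, 0.3)},
    )
    return lx.Network([a, b], [cpt_a, cpt_b])


def random_network(rng: np.random.Generator, n_vars: int = 5, max_states: int = 3):
    """A random small DAG with Dirichlet CPTs (parents only among earlier vars)."""
    variables = []
    cpts = []
    for i in range(n_vars):
        k = int(rng.integers(2, max_states + 1))
        states = tuple(f"s{j}" for j in range(k))
        name = f"V{i}"
        variables.append(lx.Variable(name, states))
        n_parents = int(rng.integers(0, min(i, 2) + 1))
        parents = tuple(
            f"V{j}" for j in sorted(rng.choice(i, size=n_parents, replace=False))
        ) if n_parents else ()
        import itertools

        parent_states = [variables[int(p[1:])].states for p in parents]
        table = {}
        for combo in itertools.product(*parent_states):
            probs = rng.dirichlet(np.ones(k))
            table[combo] = tuple(probs / probs.sum())
        cpts.append(lx.CPT(name, parents, table))
    return lx.Network(variables, cpts)


def random_evidence_query(net, rng: np.random.Generator, p_obs: float = 0.5):
    """A random partial evidence assignment and a query variable."""
    evidence = {}
    for v in net.variables:
        if rng.random() < p_obs:
            evidence[v.name] = v.states[int(rng.integers(len(v.states)))]
    free = [v.name for v in net.variables if v.name not in evidence]
    if not free:
        name = net.variables[int(rng.integers(len(net.variables)))].name
        evidence.pop(name)
        free = [name]
    query = free[int(rng.integers(len(free)))]
    return evidence, query
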