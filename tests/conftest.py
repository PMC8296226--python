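import numpy as np
import pytest

from orflow.movement import Trajectory
from orflow.simulate import PhaseTemplate, RoleZone, SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def fast_sim_config():
    """Small simulation for fast tests: short phases, single cycle."""
    return SimulationConfig(
        phase_schedule=[
            PhaseTemplate("Preparation", 60.0),
            PhaseTemplate("Craniotomy", 70.0),
            PhaseTemplate("TR", 80.0),
            PhaseTemplate("MRI", 60.0),
            PhaseTemplate("Close", 60.0),
            PhaseTemplate("End", 50.0),
        ],
        extra_imaging_cycle_prob=0.0,
    )


def random_trajectory(rng, n, span=2000.0, case_id="c1", role="surgeon"):
    return Trajectory(
        case_id=case_id,
        role=role,
        t=np.arange(n, dtype=float),
        x=rng.uniform(0, span, n),
        y=rng.uniform(0, span, n),
    )


def lcss_bruteforce(a, b, eps, delta):
    """Exhaustive longest monotone matching: the independent LCSS oracle.

    Recursively explores match/skip decisions over both sequences; exact for
    short inputs.
    """
    eps2 = eps * eps
    dmax = delta if delta is not None else max(len(a), len(b))

    from functools import lru_cache

    ax, ay, bx, by = a.x, a.y, b.x, b.y

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == len(ax) or j == len(by):
            return 0
        best = max(rec(i + 1, j), rec(i, j + 1))
        dx, dy = ax[i] - bx[j], ay[i] - by[j]
        if abs(i - j) <= dmax and dx * dx + dy * dy <= eps2:
            best = max(best, 1 + rec(i + 1, j + 1))
        return best

    return rec(0, 0)


def random_bayesnet(rng, n_nodes=5, max_states=3, edge_prob=0.4):
    """Random DAG + Dirichlet CPTs, for inference-oracle tests."""
    from orflow.bayesnet import BayesNet, CPT, DAG, Variable

    names = [f"n{i}" for i in range(n_nodes)]
    order = list(rng.permutation(n_nodes))
    parents = {names[i]: () for i in range(n_nodes)}
    for pos, i in enumerate(order):
        ps = [names[j] for j in order[:pos] if rng.random() < edge_prob]
        parents[names[i]] = tuple(sorted(ps))
    variables = {
        n: Variable(n, tuple(f"s{k}" for k in range(int(rng.integers(2, max_states + 1)))))
        for n in names
    }
    dag = DAG(tuple(names), parents)
    cpts = {}
    for n in names:
        pnames = dag.parents[n]
        n_cfg = int(np.prod([variables[p].card for p in pnames])) if pnames else 1
        table = rng.dirichlet(np.ones(variables[n].card), size=n_cfg)
        cpts[n] = CPT(
            node=n,
            node_states=variables[n].states,
            parent_names=pnames,
            parent_states=tuple(variables[p].states for p in pnames),
            table=table,
        )
    return BayesNet(variables, dag, cpts)


def enumerate_posterior(bn, query, evidence):
    """Posterior by full joint enumeration (independent inference oracle)."""
    from itertools import product as iproduct

    names = list(bn.dag.nodes)
    free = [n for n in names if n not in evidence]
    states = {n: bn.variables[n].states for n in names}
    totals = {s: 0.0 for s in states[query]}
    for combo in iproduct(*[states[n] for n in free]):
        assignment = dict(zip(free, combo))
        assignment.update(evidence)
        p = 1.0
        for n in names:
            cpt = bn.cpts[n]
            idx = 0
            for pn, pstates in zip(cpt.parent_names, cpt.parent_states):
                idx = idx * len(pstates) + pstates.index(assignment[pn])
            p *= cpt.table[idx, states[n].index(assignment[n])]
        totals[assignment[query]] += p
    z = sum(totals.values())
    return {s: v / z for s, v in totals.items()}
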