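"""From-scratch discrete Bayesian network.

A Bayesian network over categorical variables is a DAG ``G`` plus one
conditional probability table (CPT) per node; the joint factorizes as

    P(X1, ..., Xn) = prod_i P(Xi | Parents(Xi)).

This module provides the pieces the workflow classifier needs, all authored
here: the joint, decomposable maximized log-likelihood and BIC structure
scores, greedy hill-climbing structure search over add/delete/reverse arc
moves, (smoothed) maximum-likelihood CPT estimation, exact posterior
inference by variable elimination, MAP classification of a target node, and
the naive-Bayes star structure as a baseline.

Pure maximum-likelihood scoring provably prefers the complete graph, so the
default structure score is BIC (log-likelihood minus (log N / 2) times the
free-parameter count); raw likelihood scoring is kept behind
``score="loglik"`` for comparison experiments.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_EPS_IMPROVE = 1e-9  # minimum score gain counted as a strict improvement


@dataclass(frozen=True)
class Variable:
    """A named categorical variable with an ordered, finite state set."""

    name: str
    states: tuple

    @property
    def card(self) -> int:
        return len(self.states)


class CycleError(ValueError):
    """Raised when an operation would create (or requires) a cyclic graph."""


@dataclass
class DAG:
    """Directed acyclic graph over named nodes.

    ``parents`` maps each node to a sorted tuple of its parent names.
    Acyclicity is checked on construction and on every mutation helper.
    """

    nodes: tuple
    parents: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        self.parents = {n: tuple(sorted(self.parents.get(n, ()))) for n in self.nodes}
        for n, ps in self.parents.items():
            for p in ps:
                if p not in self.nodes:
                    raise ValueError(f"parent {p!r} of {n!r} is not a node")
        if not self.is_acyclic():
            raise CycleError("graph contains a directed cycle")

    def edges(self) -> list[tuple[str, str]]:
        return sorted((p, c) for c in self.nodes for p in self.parents[c])

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges())
        return g

    def is_acyclic(self) -> bool:
        return nx.is_directed_acyclic_graph(self.to_networkx())

    def topological_order(self) -> list[str]:
        return list(nx.lexicographical_topological_sort(self.to_networkx()))

    def skeleton(self) -> set[frozenset]:
        return {frozenset(e) for e in self.edges()}

    def v_structures(self) -> set[tuple]:
        """Colliders a -> c <- b with a, b non-adjacent (equivalence-class marks)."""
        skel = self.skeleton()
        out = set()
        for c in self.nodes:
            ps = self.parents[c]
            for i, a in enumerate(ps):
                for b in ps[i + 1 :]:
                    if frozenset((a, b)) not in skel:
                        out.add((a, c, b))
        return out

    def with_edge(self, u: str, v: str) -> "DAG":
        new = dict(self.parents)
        new[v] = tuple(sorted(set(new[v]) | {u}))
        return DAG(self.nodes, new)

    def without_edge(self, u: str, v: str) -> "DAG":
        new = dict(self.parents)
        new[v] = tuple(p for p in new[v] if p != u)
        return DAG(self.nodes, new)


@dataclass
class CPT:
    """Conditional distribution of one node given each parent configuration.

    ``table`` has shape (prod of parent cardinalities, node cardinality);
    parent configurations are indexed in C order over the node's sorted
    parent tuple.  Every row sums to 1.
    """

    node: str
    node_states: tuple
    parent_names: tuple
    parent_states: tuple  # tuple of state tuples, matching parent_names
    table: np.ndarray

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=float)
        n_cfg = int(np.prod([len(s) for s in self.parent_states])) if self.parent_states else 1
        if self.table.shape != (n_cfg, len(self.node_states)):
            raise ValueError(
                f"CPT for {self.node!r} has shape {self.table.shape}, "
                f"expected {(n_cfg, len(self.node_states))}"
            )
        if np.any(self.table < 0):
            raise ValueError(f"negative probability in CPT for {self.node!r}")
        if not np.allclose(self.table.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"CPT rows for {self.node!r} do not sum to 1")


@dataclass
class Posterior:
    """Distribution over one node's states (sums to 1)."""

    node: str
    probs: dict

    def as_array(self, states=None) -> np.ndarray:
        states = states if states is not None else list(self.probs)
        return np.array([self.probs[s] for s in states])

    def argmax(self) -> str:
        # ties broken by the node's fixed state order (first max wins)
        best = max(self.probs.values())
        for s, p in self.probs.items():
            if p == best:
                return s
        raise RuntimeError("empty posterior")


@dataclass
class BayesNet:
    """A DAG plus one CPT per node."""

    variables: dict  # name -> Variable
    dag: DAG
    cpts: dict  # name -> CPT

    def __post_init__(self) -> None:
        for n in self.dag.nodes:
            if n not in self.cpts:
                raise ValueError(f"missing CPT for node {n!r}")
            if tuple(self.cpts[n].parent_names) != self.dag.parents[n]:
                raise ValueError(f"CPT parents for {n!r} do not match the DAG")

    # -- evaluation -----------------------------------------------------
    def joint_probability(self, assignment: dict) -> float:
        """P(full assignment) = product of CPT entries (Eq. of the chain rule)."""
        missing = [n for n in self.dag.nodes if n not in assignment]
        if missing:
            raise ValueError(f"assignment is missing nodes {missing}")
        p = 1.0
        for n in self.dag.nodes:
            cpt = self.cpts[n]
            row = _config_index(
                tuple(assignment[q] for q in cpt.parent_names), cpt.parent_states
            )
            var = self.variables[n]
            p *= cpt.table[row, var.states.index(assignment[n])]
        return p

    def joint_table(self) -> tuple[tuple, np.ndarray]:
        """Full joint as an ndarray with one axis per node (dag.nodes order)."""
        names = self.dag.nodes
        cards = [self.variables[n].card for n in names]
        out = np.ones(cards)
        for n in names:
            cpt = self.cpts[n]
            axes = tuple(cpt.parent_names) + (n,)
            shape = [len(s) for s in cpt.parent_states] + [self.variables[n].card]
            arr = cpt.table.reshape(shape)
            out = out * _broadcast_to(arr, axes, names, cards)
        return names, out

    def sample(self, n: int, rng) -> pd.DataFrame:
        """Ancestral sampling of ``n`` complete assignments."""
        order = self.dag.topological_order()
        cols: dict[str, np.ndarray] = {}
        for node in order:
            cpt = self.cpts[node]
            var = self.variables[node]
            if not cpt.parent_names:
                idx = rng.choice(var.card, size=n, p=cpt.table[0])
            else:
                cfg = np.zeros(n, dtype=np.int64)
                for p, states in zip(cpt.parent_names, cpt.parent_states):
                    cfg = cfg * len(states) + cols[p]
                idx = np.empty(n, dtype=np.int64)
                u = rng.random(n)
                cum = np.cumsum(cpt.table, axis=1)
                for i in range(n):
                    idx[i] = np.searchsorted(cum[cfg[i]], u[i], side="right")
                idx = np.minimum(idx, var.card - 1)
            cols[node] = idx
        return pd.DataFrame(
            {
                n: np.array(self.variables[n].states, dtype=object)[cols[n]]
                for n in self.dag.nodes
            }
        )

    # -- serialization --------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "nodes": [
                {"name": n, "states": list(self.variables[n].states)}
                for n in self.dag.nodes
            ],
            "edges": [list(e) for e in self.dag.edges()],
            "cpts": {n: self.cpts[n].table.tolist() for n in self.dag.nodes},
        }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "BayesNet":
        doc = json.loads(text)
        variables = {
            d["name"]: Variable(d["name"], tuple(d["states"])) for d in doc["nodes"]
        }
        nodes = tuple(d["name"] for d in doc["nodes"])
        parents: dict[str, list] = {n: [] for n in nodes}
        for p, c in doc["edges"]:
            parents[c].append(p)
        dag = DAG(nodes, {n: tuple(ps) for n, ps in parents.items()})
        cpts = {}
        for n in nodes:
            pnames = dag.parents[n]
            cpts[n] = CPT(
                node=n,
                node_states=variables[n].states,
                parent_names=pnames,
                parent_states=tuple(variables[p].states for p in pnames),
                table=np.asarray(doc["cpts"][n], dtype=float),
            )
        return cls(variables, dag, cpts)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def variables_from_frame(data: pd.DataFrame, state_space: dict | None = None) -> dict:
    """Infer Variables from a categorical DataFrame (states sorted), with
    optional explicit per-column state sets."""
    state_space = state_space or {}
    out = {}
    for col in data.columns:
        if col in state_space:
            states = tuple(state_space[col])
        else:
            states = tuple(sorted(data[col].dropna().unique()))
        if not states:
            raise ValueError(f"column {col!r} has no observed states")
        out[col] = Variable(col, states)
    return out


def _encode(data: pd.DataFrame, variables: dict) -> np.ndarray:
    cols = []
    for col in data.columns:
        states = variables[col].states
        lut = {s: i for i, s in enumerate(states)}
        mapped = data[col].map(lut)
        if mapped.isna().any():
            bad = sorted({str(v) for v in data[col][mapped.isna()].unique()})
            raise ValueError(f"column {col!r} contains unknown states {bad}")
        cols.append(mapped.to_numpy(dtype=np.int64))
    return np.column_stack(cols) if cols else np.empty((len(data), 0), dtype=np.int64)


def _config_index(values: tuple, state_sets: tuple) -> int:
    idx = 0
    for v, states in zip(values, state_sets):
        idx = idx * len(states) + states.index(v)
    return idx


def _broadcast_to(arr: np.ndarray, axes: tuple, names: tuple, cards) -> np.ndarray:
    """Reshape a factor with axis labels ``axes`` to broadcast over ``names``."""
    perm = [axes.index(n) for n in names if n in axes]
    arr = np.transpose(arr, perm)
    shape = [cards[names.index(n)] if n in axes else 1 for n in names]
    return arr.reshape(shape)


def _family_counts(arr: np.ndarray, child: int, parents: tuple, cards) -> tuple:
    """(child-given-config counts matrix, config counts) from encoded data."""
    n_cfg = 1
    cfg = np.zeros(arr.shape[0], dtype=np.int64)
    for p in parents:
        cfg = cfg * cards[p] + arr[:, p]
        n_cfg *= cards[p]
    joint = cfg * cards[child] + arr[:, child]
    counts = np.bincount(joint, minlength=n_cfg * cards[child]).reshape(
        n_cfg, cards[child]
    )
    return counts, counts.sum(axis=1)


def _family_ll(arr: np.ndarray, child: int, parents: tuple, cards) -> float:
    """Maximized log-likelihood contribution of one node's family:
    sum over configs a and states x of N(x, a) log(N(x, a) / N(a))."""
    counts, n_a = _family_counts(arr, child, parents, cards)
    c = counts[counts > 0]
    a = n_a[n_a > 0]
    return float(np.sum(c * np.log(c)) - np.sum(a * np.log(a)))


def _n_free_params(dag: DAG, cards: dict) -> int:
    return sum(
        (cards[n] - 1) * int(np.prod([cards[p] for p in dag.parents[n]]))
        for n in dag.nodes
    )


# ---------------------------------------------------------------------------
# scores
# ---------------------------------------------------------------------------

def log_likelihood(dag: DAG, data: pd.DataFrame, variables: dict | None = None) -> float:
    """Maximized log P(D | G): decomposable over node families."""
    variables = variables or variables_from_frame(data)
    missing = [n for n in dag.nodes if n not in data.columns]
    if missing:
        raise ValueError(f"data is missing columns for nodes {missing}")
    arr = _encode(data[list(dag.nodes)], variables)
    cards = [variables[n].card for n in dag.nodes]
    index = {n: i for i, n in enumerate(dag.nodes)}
    return sum(
        _family_ll(arr, index[n], tuple(index[p] for p in dag.parents[n]), cards)
        for n in dag.nodes
    )


def bic_score(dag: DAG, data: pd.DataFrame, variables: dict | None = None) -> float:
    """BIC = max log-likelihood − (log N / 2) · (number of free parameters)."""
    variables = variables or variables_from_frame(data)
    n = len(data)
    cards = {name: variables[name].card for name in dag.nodes}
    return log_likelihood(dag, data, variables) - 0.5 * math.log(n) * _n_free_params(
        dag, cards
    )


# ---------------------------------------------------------------------------
# structure search
# ---------------------------------------------------------------------------

def hill_climb(
    data: pd.DataFrame,
    score: str = "bic",
    forbidden=(),
    required=(),
    max_iter: int = 100,
    seed: int | None = None,
    variables: dict | None = None,
) -> DAG:
    """Greedy best-improvement structure search from the empty graph.

    At every step all legal single-arc moves (add, delete, reverse) are
    scored with the decomposable ``score`` ("bic" or "loglik") and the
    highest strictly improving one is applied; the search stops when no move
    improves or ``max_iter`` is reached.  Forbidden/required edge lists are
    honoured.  Tie-breaking is lexicographic over (move kind, edge), which
    makes the search fully deterministic; ``seed`` is accepted for interface
    stability but has no remaining role.
    """
    if score not in ("bic", "loglik"):
        raise ValueError("score must be 'bic' or 'loglik'")
    if len(data) < 1:
        raise ValueError("need at least one data row")
    variables = variables or variables_from_frame(data)
    names = tuple(data.columns)
    arr = _encode(data, variables)
    cards = [variables[n].card for n in names]
    n_rows = len(data)
    k = len(names)
    forbidden = {(u, v) for u, v in forbidden}
    required = {(u, v) for u, v in required}
    index = {n: i for i, n in enumerate(names)}

    cache: dict[tuple, float] = {}

    def fam(child: int, parents: tuple) -> float:
        key = (child, parents)
        if key not in cache:
            val = _family_ll(arr, child, parents, cards)
            if score == "bic":
                n_par = (cards[child] - 1) * int(
                    np.prod([cards[p] for p in parents])
                )
                val -= 0.5 * math.log(n_rows) * n_par
            cache[key] = val
        return cache[key]

    parents: dict[int, tuple] = {i: () for i in range(k)}

    def reachable(src: int, dst: int) -> bool:
        # is there a directed path src -> dst under current parents?
        children = {i: [] for i in range(k)}
        for c, ps in parents.items():
            for p in ps:
                children[p].append(c)
        stack, seen = [src], set()
        while stack:
            u = stack.pop()
            if u == dst:
                return True
            for w in children[u]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return False

    # seed the graph with required edges
    for u, v in sorted(required):
        iu, iv = index[u], index[v]
        if reachable(iv, iu):
            raise CycleError(f"required edges force a cycle at ({u}, {v})")
        parents[iv] = tuple(sorted(parents[iv] + (iu,)))

    for _ in range(max_iter):
        best = None  # (delta, kind_rank, u, v)
        for v in range(k):
            cur_v = fam(v, parents[v])
            for u in range(k):
                if u == v:
                    continue
                nu, nv = names[u], names[v]
                candidates = []
                if u not in parents[v]:
                    if (nu, nv) not in forbidden and not reachable(v, u):
                        delta = fam(v, tuple(sorted(parents[v] + (u,)))) - cur_v
                        candidates.append((delta, 0, u, v))
                else:
                    without_u = tuple(p for p in parents[v] if p != u)
                    if (nu, nv) not in required:
                        candidates.append((fam(v, without_u) - cur_v, 1, u, v))
                        # reverse u -> v into v -> u
                        if (nv, nu) not in forbidden:
                            saved = parents[v]
                            parents[v] = without_u
                            creates_cycle = reachable(u, v)
                            parents[v] = saved
                            if not creates_cycle:
                                delta = (
                                    fam(v, without_u)
                                    - cur_v
                                    + fam(u, tuple(sorted(parents[u] + (v,))))
                                    - fam(u, parents[u])
                                )
                                candidates.append((delta, 2, u, v))
                for cand in candidates:
                    if best is None or _better(cand, best):
                        best = cand
        if best is None or best[0] <= _EPS_IMPROVE:
            break
        _, kind, u, v = best
        if kind == 0:
            parents[v] = tuple(sorted(parents[v] + (u,)))
        elif kind == 1:
            parents[v] = tuple(p for p in parents[v] if p != u)
        else:
            parents[v] = tuple(p for p in parents[v] if p != u)
            parents[u] = tuple(sorted(parents[u] + (v,)))

    return DAG(
        names,
        {names[v]: tuple(names[p] for p in parents[v]) for v in range(k)},
    )


def _better(cand: tuple, best: tuple) -> bool:
    # higher delta wins; exact ties broken lexicographically by (kind, u, v)
    if cand[0] != best[0]:
        return cand[0] > best[0]
    return (cand[1], cand[2], cand[3]) < (best[1], best[2], best[3])


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def fit_cpts(
    dag: DAG,
    data: pd.DataFrame,
    alpha: float = 0.0,
    variables: dict | None = None,
) -> BayesNet:
    """Estimate CPTs: (N(x, a) + alpha) / (N(a) + alpha * |states|).

    ``alpha = 0`` is the pure maximum-likelihood estimate; parent
    configurations never observed then get a uniform row (with a warning).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    variables = variables or variables_from_frame(data)
    arr = _encode(data[list(dag.nodes)], variables)
    cards = [variables[n].card for n in dag.nodes]
    index = {n: i for i, n in enumerate(dag.nodes)}
    cpts = {}
    for n in dag.nodes:
        ps = dag.parents[n]
        counts, n_a = _family_counts(
            arr, index[n], tuple(index[p] for p in ps), cards
        )
        card = variables[n].card
        table = (counts + alpha) / np.maximum(n_a + alpha * card, 1e-300)[:, None]
        unseen = n_a + alpha * card == 0
        if np.any(unseen):
            logger.warning(
                "fit_cpts: %d unseen parent configuration(s) for %r set to uniform",
                int(unseen.sum()),
                n,
            )
            table[unseen] = 1.0 / card
        cpts[n] = CPT(
            node=n,
            node_states=variables[n].states,
            parent_names=ps,
            parent_states=tuple(variables[p].states for p in ps),
            table=table,
        )
    return BayesNet(variables, dag, cpts)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def posterior(bn: BayesNet, query: str, evidence: dict | None = None) -> Posterior:
    """Exact posterior of ``query`` given (possibly partial) evidence, by
    variable elimination.  Evidence inconsistent with the model (probability
    zero) raises; so does an unknown evidence state."""
    evidence = dict(evidence or {})
    if query not in bn.dag.nodes:
        raise ValueError(f"unknown query node {query!r}")
    if query in evidence:
        raise ValueError("query node cannot also be evidence")
    for node, state in evidence.items():
        if node not in bn.dag.nodes:
            raise ValueError(f"unknown evidence node {node!r}")
        if state not in bn.variables[node].states:
            raise ValueError(f"state {state!r} not in state set of {node!r}")

    # CPTs as factors with labelled axes, reduced by the evidence
    factors: list[tuple[tuple, np.ndarray]] = []
    for n in bn.dag.nodes:
        cpt = bn.cpts[n]
        axes = tuple(cpt.parent_names) + (n,)
        shape = [len(s) for s in cpt.parent_states] + [bn.variables[n].card]
        arr = cpt.table.reshape(shape)
        for ax_i, ax_name in reversed(list(enumerate(axes))):
            if ax_name in evidence:
                s_idx = bn.variables[ax_name].states.index(evidence[ax_name])
                arr = np.take(arr, s_idx, axis=ax_i)
        axes = tuple(a for a in axes if a not in evidence)
        factors.append((axes, arr))

    hidden = sorted(n for n in bn.dag.nodes if n != query and n not in evidence)
    for h in hidden:
        factors = _eliminate(factors, h)

    result = np.ones(bn.variables[query].card)
    scalar = 1.0
    for axes, arr in factors:
        if axes == (query,):
            result = result * arr
        elif axes == ():
            scalar *= float(arr)
        else:  # pragma: no cover - elimination leaves only query/scalar factors
            raise RuntimeError(f"unexpected residual factor over {axes}")
    result = result * scalar
    total = result.sum()
    if not total > 0:
        raise ValueError(f"evidence {evidence} has probability 0 under the model")
    probs = result / total
    return Posterior(query, dict(zip(bn.variables[query].states, probs.tolist())))


def _eliminate(factors: list, var: str) -> list:
    involved = [f for f in factors if var in f[0]]
    rest = [f for f in factors if var not in f[0]]
    union: list[str] = []
    for axes, _ in involved:
        for a in axes:
            if a not in union:
                union.append(a)
    letters = {v: chr(97 + i) for i, v in enumerate(union)}
    out_axes = tuple(v for v in union if v != var)
    spec = (
        ",".join("".join(letters[v] for v in axes) for axes, _ in involved)
        + "->"
        + "".join(letters[v] for v in out_axes)
    )
    arr = np.einsum(spec, *[a for _, a in involved])
    rest.append((out_axes, arr))
    return rest


def classify(bn: BayesNet, target: str, evidence: dict | None = None):
    """MAP state of the target node: ``(label, Posterior)``.

    Exact posterior ties are broken by the target's fixed state order.
    """
    post = posterior(bn, target, evidence)
    probs = list(post.probs.values())
    best = max(probs)
    if probs.count(best) > 1:
        logger.info("classify: posterior tie for %r broken by state order", target)
    return post.argmax(), post


# ---------------------------------------------------------------------------
# naive Bayes baseline
# ---------------------------------------------------------------------------

def naive_bayes(
    data: pd.DataFrame,
    target: str,
    alpha: float = 1.0,
    variables: dict | None = None,
) -> BayesNet:
    """Star-structured BN (target -> every attribute) with fitted CPTs."""
    if target not in data.columns:
        raise ValueError(f"target {target!r} not in data")
    nodes = tuple(data.columns)
    dag = DAG(nodes, {c: ((target,) if c != target else ()) for c in nodes})
    return fit_cpts(dag, data, alpha=alpha, variables=variables)
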