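import itertools
import json
import math

import numpy as np
import pandas as pd
import pytest

from conftest import enumerate_posterior, random_bayesnet
from orflow.bayesnet import (
    BayesNet,
    CPT,
    CycleError,
    DAG,
    Variable,
    bic_score,
    classify,
    fit_cpts,
    hill_climb,
    log_likelihood,
    naive_bayes,
    posterior,
    variables_from_frame,
)


def _two_binary_uniform():
    variables = {
        "A": Variable("A", ("f", "t")),
        "B": Variable("B", ("f", "t")),
    }
    dag = DAG(("A", "B"))
    cpts = {
        n: CPT(n, ("f", "t"), (), (), np.array([[0.5, 0.5]])) for n in ("A", "B")
    }
    return BayesNet(variables, dag, cpts)


class TestJointProbability:
    def test_independent_uniform_binary(self):
        bn = _two_binary_uniform()
        assert bn.joint_probability({"A": "f", "B": "t"}) == pytest.approx(0.25)

    def test_deterministic_chain(self):
        variables = {
            "X": Variable("X", ("a", "b")),
            "Y": Variable("Y", ("a", "b")),
        }
        dag = DAG(("X", "Y"), {"Y": ("X",)})
        cpts = {
            "X": CPT("X", ("a", "b"), (), (), np.array([[0.3, 0.7]])),
            "Y": CPT("Y", ("a", "b"), ("X",), (("a", "b"),),
                     np.array([[1.0, 0.0], [0.0, 1.0]])),
        }
        bn = BayesNet(variables, dag, cpts)
        assert bn.joint_probability({"X": "a", "Y": "a"}) == pytest.approx(0.3)
        assert bn.joint_probability({"X": "a", "Y": "b"}) == 0.0

    def test_incomplete_assignment_rejected(self):
        bn = _two_binary_uniform()
        with pytest.raises(ValueError, match="missing nodes"):
            bn.joint_probability({"A": "f"})

    def test_joint_sums_to_one_on_random_nets(self, rng):
        for _ in range(5):
            bn = random_bayesnet(rng, n_nodes=5)
            states = [bn.variables[n].states for n in bn.dag.nodes]
            total = sum(
                bn.joint_probability(dict(zip(bn.dag.nodes, combo)))
                for combo in itertools.product(*states)
            )
            assert total == pytest.approx(1.0, abs=1e-9)


class TestLogLikelihood:
    def test_hand_counted_two_node_table(self):
        # 6 rows, X -> Y; counts: X: 4a/2b; Y|X=a: 3p/1q; Y|X=b: 2q
        data = pd.DataFrame(
            {"X": ["a", "a", "a", "a", "b", "b"], "Y": ["p", "p", "p", "q", "q", "q"]}
        )
        dag = DAG(("X", "Y"), {"Y": ("X",)})
        expected = (
            4 * math.log(4 / 6) + 2 * math.log(2 / 6)
            + 3 * math.log(3 / 4) + 1 * math.log(1 / 4) + 2 * math.log(2 / 2)
        )
        assert log_likelihood(dag, data) == pytest.approx(expected)

    def test_empty_graph_is_sum_of_marginals(self, rng):
        data = pd.DataFrame(
            {
                "A": rng.choice(["x", "y", "z"], 50),
                "B": rng.choice(["u", "v"], 50),
            }
        )
        dag = DAG(("A", "B"))
        per_col = 0.0
        for col in data.columns:
            counts = data[col].value_counts()
            per_col += sum(c * math.log(c / len(data)) for c in counts)
        assert log_likelihood(dag, data) == pytest.approx(per_col)

    def test_edge_addition_never_decreases(self, rng):
        for _ in range(10):
            data = pd.DataFrame(
                {
                    "A": rng.choice(["x", "y"], 30),
                    "B": rng.choice(["u", "v", "w"], 30),
                    "C": rng.choice(["0", "1"], 30),
                }
            )
            base = DAG(("A", "B", "C"), {"B": ("A",)})
            more = base.with_edge("C", "B")
            assert log_likelihood(more, data) >= log_likelihood(base, data) - 1e-12

    def test_missing_column_rejected(self):
        data = pd.DataFrame({"A": ["x", "y"]})
        with pytest.raises(ValueError, match="missing columns"):
            log_likelihood(DAG(("A", "Z")), data)


class TestBICScore:
    def test_empty_graph_penalty_for_binary_nodes(self, rng):
        n_nodes, n_rows = 3, 64
        data = pd.DataFrame(
            {f"v{i}": rng.choice(["0", "1"], n_rows) for i in range(n_nodes)}
        )
        dag = DAG(tuple(data.columns))
        penalty = log_likelihood(dag, data) - bic_score(dag, data)
        assert penalty == pytest.approx(n_nodes * math.log(n_rows) / 2)

    def test_true_sparse_graph_beats_complete_graph(self, rng):
        # data simulated from A -> B with C independent
        truth = _chain_net(strength=0.9)
        data = truth.sample(500, rng)
        sparse = DAG(("A", "B", "C"), {"B": ("A",)})
        complete = DAG(
            ("A", "B", "C"), {"B": ("A",), "C": ("A", "B")}
        )
        assert bic_score(sparse, data) > bic_score(complete, data)

    def test_score_decomposes_over_families(self, rng):
        data = pd.DataFrame(
            {
                "A": rng.choice(["x", "y"], 40),
                "B": rng.choice(["u", "v"], 40),
                "C": rng.choice(["0", "1"], 40),
            }
        )
        variables = variables_from_frame(data)
        d0 = DAG(("A", "B", "C"))
        d1 = d0.with_edge("A", "B")
        # changing B's parents must change the total score by exactly the
        # difference in B's family contribution
        delta_total = bic_score(d1, data, variables) - bic_score(d0, data, variables)
        only_b0 = DAG(("A", "B"), {})
        only_b1 = DAG(("A", "B"), {"B": ("A",)})
        sub = data[["A", "B"]]
        delta_b = bic_score(only_b1, sub) - bic_score(only_b0, sub)
        # A's family term cancels in both differences
        assert delta_total == pytest.approx(delta_b)


def _chain_net(strength=0.9):
    s = strength
    variables = {n: Variable(n, ("0", "1")) for n in ("A", "B", "C")}
    dag = DAG(("A", "B", "C"), {"B": ("A",)})
    cpts = {
        "A": CPT("A", ("0", "1"), (), (), np.array([[0.5, 0.5]])),
        "B": CPT("B", ("0", "1"), ("A",), (("0", "1"),),
                 np.array([[s, 1 - s], [1 - s, s]])),
        "C": CPT("C", ("0", "1"), (), (), np.array([[0.5, 0.5]])),
    }
    return BayesNet(variables, dag, cpts)


def _all_three_node_dags():
    nodes = ("A", "B", "C")
    arcs = [(u, v) for u in nodes for v in nodes if u != v]
    for mask in itertools.product([0, 1], repeat=6):
        edges = [a for a, m in zip(arcs, mask) if m]
        parents = {n: tuple(p for p, c in edges if c == n) for n in nodes}
        try:
            yield DAG(nodes, parents)
        except CycleError:
            continue


class TestHillClimb:
    def test_independent_columns_give_empty_graph(self, rng):
        data = pd.DataFrame(
            {"A": rng.choice(["x", "y"], 200), "B": rng.choice(["u", "v"], 200)}
        )
        dag = hill_climb(data)
        assert dag.edges() == []

    def test_recovers_chain_equivalence_class(self, rng):
        truth = _three_node_chain_net(0.9)
        data = truth.sample(1000, rng)
        learned = hill_climb(data)
        # compare against exhaustive search over all 25 three-node DAGs
        best = max(_all_three_node_dags(), key=lambda d: bic_score(d, data))
        assert learned.skeleton() == best.skeleton()
        assert learned.v_structures() == best.v_structures()
        assert learned.skeleton() == {frozenset(("A", "B")), frozenset(("B", "C"))}

    def test_score_never_below_empty_graph(self, rng):
        for _ in range(5):
            data = pd.DataFrame(
                {
                    "A": rng.choice(["x", "y"], 30),
                    "B": rng.choice(["u", "v"], 30),
                    "C": rng.choice(["0", "1"], 30),
                }
            )
            learned = hill_climb(data)
            assert bic_score(learned, data) >= bic_score(DAG(tuple(data.columns)), data)

    def test_forbidden_edges_respected(self, rng):
        truth = _chain_net(0.95)
        data = truth.sample(500, rng)
        dag = hill_climb(data, forbidden=[("A", "B"), ("B", "A")])
        assert ("A", "B") not in dag.edges() and ("B", "A") not in dag.edges()

    def test_required_edges_present(self, rng):
        data = pd.DataFrame(
            {"A": rng.choice(["x", "y"], 50), "B": rng.choice(["u", "v"], 50)}
        )
        dag = hill_climb(data, required=[("A", "B")])
        assert ("A", "B") in dag.edges()

    def test_required_cycle_rejected(self, rng):
        data = pd.DataFrame(
            {"A": rng.choice(["x", "y"], 20), "B": rng.choice(["u", "v"], 20)}
        )
        with pytest.raises(CycleError):
            hill_climb(data, required=[("A", "B"), ("B", "A")])

    def test_deterministic(self, rng):
        data = pd.DataFrame(
            {
                "A": rng.choice(["x", "y"], 60),
                "B": rng.choice(["u", "v"], 60),
                "C": rng.choice(["0", "1"], 60),
            }
        )
        assert hill_climb(data).edges() == hill_climb(data).edges()


def _three_node_chain_net(strength=0.9):
    s = strength
    variables = {n: Variable(n, ("0", "1")) for n in ("A", "B", "C")}
    dag = DAG(("A", "B", "C"), {"B": ("A",), "C": ("B",)})
    flip = np.array([[s, 1 - s], [1 - s, s]])
    cpts = {
        "A": CPT("A", ("0", "1"), (), (), np.array([[0.5, 0.5]])),
        "B": CPT("B", ("0", "1"), ("A",), (("0", "1"),), flip),
        "C": CPT("C", ("0", "1"), ("B",), (("0", "1"),), flip),
    }
    return BayesNet(variables, dag, cpts)


class TestFitCPTs:
    def test_pure_mle_marginal(self):
        data = pd.DataFrame({"A": ["s", "s", "s", "t", "t", "t"]})
        bn = fit_cpts(DAG(("A",)), data, alpha=0.0)
        assert bn.cpts["A"].table[0, 0] == pytest.approx(0.5)

    def test_large_alpha_tends_to_uniform(self):
        data = pd.DataFrame({"A": ["s"] * 10})
        bn = fit_cpts(DAG(("A",)), data, alpha=1e9,
                      variables={"A": Variable("A", ("s", "t"))})
        np.testing.assert_allclose(bn.cpts["A"].table[0], [0.5, 0.5], atol=1e-6)

    def test_unseen_parent_config_gets_uniform_row(self, caplog):
        import logging

        data = pd.DataFrame({"A": ["x", "x"], "B": ["u", "v"]})
        variables = {
            "A": Variable("A", ("x", "y")),
            "B": Variable("B", ("u", "v")),
        }
        with caplog.at_level(logging.WARNING, logger="orflow.bayesnet"):
            bn = fit_cpts(DAG(("A", "B"), {"B": ("A",)}), data, alpha=0.0,
                          variables=variables)
        np.testing.assert_allclose(bn.cpts["B"].table[1], [0.5, 0.5])
        assert any("unseen" in r.message for r in caplog.records)

    def test_parameter_recovery_small(self, rng):
        truth = _three_node_chain_net(0.8)
        data = truth.sample(4000, rng)
        fitted = fit_cpts(truth.dag, data, alpha=1.0,
                          variables=truth.variables)
        for n in truth.dag.nodes:
            np.testing.assert_allclose(
                fitted.cpts[n].table, truth.cpts[n].table, atol=0.05
            )


class TestPosterior:
    def test_no_evidence_gives_prior_marginal(self):
        bn = _chain_net(0.9)
        post = posterior(bn, "A")
        assert post.probs["0"] == pytest.approx(0.5)

    def test_deterministic_child_concentrates_posterior(self):
        variables = {
            "X": Variable("X", ("a", "b")),
            "Y": Variable("Y", ("a", "b")),
        }
        dag = DAG(("X", "Y"), {"Y": ("X",)})
        cpts = {
            "X": CPT("X", ("a", "b"), (), (), np.array([[0.5, 0.5]])),
            "Y": CPT("Y", ("a", "b"), ("X",), (("a", "b"),), np.eye(2)),
        }
        bn = BayesNet(variables, dag, cpts)
        post = posterior(bn, "X", {"Y": "b"})
        assert post.probs["b"] == pytest.approx(1.0)

    def test_matches_enumeration_on_random_nets(self, rng):
        for _ in range(10):
            bn = random_bayesnet(rng, n_nodes=6, max_states=3)
            nodes = list(bn.dag.nodes)
            query = nodes[int(rng.integers(len(nodes)))]
            ev_nodes = [
                n for n in nodes
                if n != query and rng.random() < 0.5
            ]
            evidence = {
                n: bn.variables[n].states[int(rng.integers(bn.variables[n].card))]
                for n in ev_nodes
            }
            try:
                got = posterior(bn, query, evidence).probs
            except ValueError:
                continue  # zero-probability evidence draw
            want = enumerate_posterior(bn, query, evidence)
            for s in got:
                assert got[s] == pytest.approx(want[s], abs=1e-10)

    def test_unknown_evidence_state_rejected(self):
        bn = _chain_net()
        with pytest.raises(ValueError, match="state set"):
            posterior(bn, "A", {"B": "nope"})

    def test_zero_probability_evidence_reported(self):
        variables = {
            "X": Variable("X", ("a", "b")),
            "Y": Variable("Y", ("a", "b")),
        }
        dag = DAG(("X", "Y"), {"Y": ("X",)})
        cpts = {
            "X": CPT("X", ("a", "b"), (), (), np.array([[1.0, 0.0]])),
            "Y": CPT("Y", ("a", "b"), ("X",), (("a", "b"),), np.eye(2)),
        }
        bn = BayesNet(variables, dag, cpts)
        with pytest.raises(ValueError, match="probability 0"):
            posterior(bn, "X", {"Y": "b"})


class TestClassify:
    def test_deterministic_toy_net(self):
        variables = {
            "phase": Variable("phase", ("P1", "P2")),
            "A": Variable("A", ("lo", "hi")),
        }
        dag = DAG(("phase", "A"), {"A": ("phase",)})
        cpts = {
            "phase": CPT("phase", ("P1", "P2"), (), (), np.array([[0.5, 0.5]])),
            "A": CPT("A", ("lo", "hi"), ("phase",), (("P1", "P2"),), np.eye(2)),
        }
        bn = BayesNet(variables, dag, cpts)
        label, post = classify(bn, "phase", {"A": "hi"})
        assert label == "P2"
        assert post.probs["P2"] == pytest.approx(1.0)

    def test_empty_evidence_gives_prior_argmax(self):
        variables = {"phase": Variable("phase", ("P1", "P2", "P3"))}
        dag = DAG(("phase",))
        cpts = {
            "phase": CPT("phase", ("P1", "P2", "P3"), (), (),
                         np.array([[0.2, 0.5, 0.3]]))
        }
        bn = BayesNet(variables, dag, cpts)
        label, _ = classify(bn, "phase")
        assert label == "P2"

    def test_agrees_with_posterior_oracle_argmax(self, rng):
        for _ in range(20):
            bn = random_bayesnet(rng, n_nodes=4, max_states=3)
            query = bn.dag.nodes[0]
            evidence = {}
            for n in bn.dag.nodes[1:]:
                if rng.random() < 0.5:
                    evidence[n] = bn.variables[n].states[
                        int(rng.integers(bn.variables[n].card))
                    ]
            try:
                label, _ = classify(bn, query, evidence)
            except ValueError:
                continue
            want = enumerate_posterior(bn, query, evidence)
            best = max(want.values())
            assert want[label] == pytest.approx(best, abs=1e-12)


class TestNaiveBayes:
    def _data(self, rng, n=60):
        return pd.DataFrame(
            {
                "phase": rng.choice(["P1", "P2"], n),
                "a1": rng.choice(["L", "H"], n),
                "a2": rng.choice(["L", "M", "H"], n),
            }
        )

    def test_star_structure(self, rng):
        bn = naive_bayes(self._data(rng), target="phase")
        assert set(bn.dag.edges()) == {("phase", "a1"), ("phase", "a2")}

    def test_posterior_matches_product_formula(self, rng):
        bn = naive_bayes(self._data(rng), target="phase", alpha=1.0)
        evidence = {"a1": "L", "a2": "H"}
        post = posterior(bn, "phase", evidence).probs
        # direct P(T) * prod P(Ai | T), normalized
        raw = {}
        for k, t in enumerate(bn.variables["phase"].states):
            p = bn.cpts["phase"].table[0, k]
            for attr, val in evidence.items():
                p *= bn.cpts[attr].table[k, bn.variables[attr].states.index(val)]
            raw[t] = p
        z = sum(raw.values())
        for t in raw:
            assert post[t] == pytest.approx(raw[t] / z, abs=1e-12)


class TestSerialization:
    def test_roundtrip_exact(self, rng):
        bn = random_bayesnet(rng, n_nodes=5, max_states=3)
        text = bn.to_json()
        back = BayesNet.from_json(text)
        assert back.dag.edges() == bn.dag.edges()
        for n in bn.dag.nodes:
            np.testing.assert_array_equal(back.cpts[n].table, bn.cpts[n].table)
        assert back.to_json() == text

    def test_json_is_valid(self, rng):
        doc = json.loads(random_bayesnet(rng, 4).to_json())
        assert {"nodes", "edges", "cpts"} <= set(doc)
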