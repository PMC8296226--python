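"""Sklearn-style classifiers wrapping the discrete Bayesian network.

:class:`BayesNetClassifier` learns a structure over the interaction-level
attributes plus the phase target (hill climbing, BIC by default), fits
smoothed maximum-likelihood CPTs, and predicts the MAP phase given the
attribute evidence.  :class:`NaiveBayesClassifier` fixes the star structure
(target as sole parent of every attribute).  Both follow the sklearn
estimator contract (``fit`` / ``predict`` / ``predict_proba``,
``get_params`` / ``set_params``, trailing-underscore fitted attributes) and
compose with sklearn pipelines and model selection.

Missing attribute values (NaN/None — a role absent from the segment) are
treated as the "Low" interaction level during training and simply omitted
from the evidence at prediction time (marginalized over).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import bayesnet as bn
from .interaction import LEVELS

TARGET_NODE = "phase"


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X.copy()
    X = np.asarray(X, dtype=object)
    return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


class BayesNetClassifier(ClassifierMixin, BaseEstimator):
    """Discrete Bayesian-network classifier with learned structure.

    Parameters
    ----------
    score : "bic" (default) or "loglik" — structure-search score.
    alpha : Laplace smoothing for the CPTs (default 1; 0 is pure MLE).
        Smoothing keeps posteriors defined on held-out level combinations,
        which matters at the tiny sample sizes typical here.
    structure : None to learn by hill climbing, "naive" for the star
        baseline, or an explicit :class:`orflow.bayesnet.DAG`.
    feature_states : "auto" (default) infers each attribute's state set from
        the training data, widening to the full Low/Medium/High vocabulary
        whenever the observed values are a subset of it (so an interaction
        level unseen in a small training split is still legal evidence);
        alternatively a dict column -> state tuple.
    max_iter : hill-climbing move budget.
    random_state : accepted for sklearn compatibility; the search is
        deterministic (lexicographic tie-breaking) so it is unused.
    """

    def __init__(
        self,
        score: str = "bic",
        alpha: float = 1.0,
        structure=None,
        feature_states="auto",
        missing_fill: str = "Low",
        max_iter: int = 100,
        random_state=None,
    ):
        self.score = score
        self.alpha = alpha
        self.structure = structure
        self.feature_states = feature_states
        self.missing_fill = missing_fill
        self.max_iter = max_iter
        self.random_state = random_state

    # -- sklearn API ----------------------------------------------------
    def fit(self, X, y):
        X = _as_frame(X)
        y = pd.Series(np.asarray(y, dtype=object), index=X.index, name=TARGET_NODE)
        if len(X) == 0:
            raise ValueError("empty training set")
        if TARGET_NODE in X.columns:
            raise ValueError(f"feature column may not be named {TARGET_NODE!r}")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]

        X = X.where(pd.notna(X), other=None)
        X = X.map(lambda v: self.missing_fill if v is None else v)

        state_space = {}
        for col in X.columns:
            if isinstance(self.feature_states, dict) and col in self.feature_states:
                state_space[col] = tuple(self.feature_states[col])
            else:
                observed = set(X[col].unique())
                if observed <= set(LEVELS):
                    state_space[col] = LEVELS
        self.classes_ = np.array(sorted(y.unique()), dtype=object)
        state_space[TARGET_NODE] = tuple(self.classes_)

        frame = pd.concat([X, y], axis=1)
        variables = bn.variables_from_frame(frame, state_space)

        if self.structure is None:
            dag = bn.hill_climb(
                frame,
                score=self.score,
                max_iter=self.max_iter,
                variables=variables,
            )
        elif self.structure == "naive":
            nodes = tuple(frame.columns)
            dag = bn.DAG(
                nodes,
                {c: ((TARGET_NODE,) if c != TARGET_NODE else ()) for c in nodes},
            )
        else:
            dag = self.structure
        self.dag_ = dag
        self.network_ = bn.fit_cpts(dag, frame, alpha=self.alpha, variables=variables)

        # full-joint cache for fast repeated prediction (tiny state spaces)
        names, joint = self.network_.joint_table()
        self._joint_names = names
        self._joint = joint
        self._state_index = {
            n: {s: i for i, s in enumerate(self.network_.variables[n].states)}
            for n in names
        }
        self._posterior_cache: dict[tuple, np.ndarray] = {}
        return self

    def predict_proba(self, X):
        X = self._check_predict_input(X)
        out = np.empty((len(X), len(self.classes_)))
        for i, (_, row) in enumerate(X.iterrows()):
            out[i] = self._posterior_for_row(row)
        return out

    def predict(self, X):
        proba = self.predict_proba(X)
        # np.argmax takes the first maximum: ties resolve to the lower class
        return self.classes_[np.argmax(proba, axis=1)]

    # -- internals ------------------------------------------------------
    def _check_predict_input(self, X) -> pd.DataFrame:
        if not hasattr(self, "network_"):
            raise RuntimeError("classifier is not fitted")
        X = _as_frame(X)
        missing = [c for c in self.feature_names_in_ if c not in X.columns]
        if missing:
            raise ValueError(f"prediction input is missing columns {missing}")
        return X[list(self.feature_names_in_)]

    def _posterior_for_row(self, row) -> np.ndarray:
        key = tuple(
            (c, row[c]) for c in self.feature_names_in_ if pd.notna(row[c])
        )
        cached = self._posterior_cache.get(key)
        if cached is not None:
            return cached
        evidence = dict(key)
        target_ax = self._joint_names.index(TARGET_NODE)
        arr = self._joint
        for ax in reversed(range(len(self._joint_names))):
            name = self._joint_names[ax]
            if name == TARGET_NODE:
                continue
            if name in evidence:
                idx = self._state_index[name].get(evidence[name])
                if idx is None:
                    raise ValueError(
                        f"state {evidence[name]!r} not in state set of {name!r}"
                    )
                arr = np.take(arr, idx, axis=ax)
            else:
                arr = arr.sum(axis=ax)
            if ax < target_ax:
                target_ax -= 1
        total = arr.sum()
        if not total > 0:
            raise ValueError(f"evidence {evidence} has probability 0 under the model")
        post = arr / total
        # joint axis order is state order of the target == sorted classes_
        self._posterior_cache[key] = post
        return post

    def posterior(self, evidence: dict) -> bn.Posterior:
        """Exact posterior over phases for one evidence dict (library API)."""
        return bn.posterior(self.network_, TARGET_NODE, evidence)


class NaiveBayesClassifier(BayesNetClassifier):
    """Naive-Bayes baseline: fixed star structure, otherwise identical."""

    def __init__(
        self,
        alpha: float = 1.0,
        feature_states="auto",
        missing_fill: str = "Low",
        random_state=None,
    ):
        super().__init__(
            score="bic",
            alpha=alpha,
            structure="naive",
            feature_states=feature_states,
            missing_fill=missing_fill,
            random_state=random_state,
        )
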