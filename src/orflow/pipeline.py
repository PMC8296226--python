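"""End-to-end pipeline: simulate -> features -> learn -> evaluate.

Every run writes its resolved configuration next to the outputs and is a
pure function of that configuration (bit-identical artifacts on rerun).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os

import pandas as pd
import yaml

from .bayesnet import fit_cpts, hill_climb
from .estimators import TARGET_NODE, BayesNetClassifier, NaiveBayesClassifier
from .evaluation import compare_classifiers
from .interaction import (
    DEFAULT_PAIRS,
    LCSSParams,
    TertileDiscretizer,
    build_similarity_table,
)
from .simulate import SimulationConfig, generate_dataset, write_dataset
from sklearn.pipeline import Pipeline

logger = logging.getLogger(__name__)

_SIM_SCALAR_FIELDS = {
    f.name
    for f in dataclasses.fields(SimulationConfig)
    if f.name
    not in ("landmarks", "role_zones", "phase_schedule", "cooperation", "presence", "speed_scale")
}


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclasses.dataclass
class PipelineConfig:
    """Resolved configuration of a full run."""

    n_cases: int = 10
    seed: int = 7
    simulation: SimulationConfig = dataclasses.field(default_factory=SimulationConfig)
    lcss: LCSSParams = dataclasses.field(default_factory=LCSSParams)
    selected_pairs: tuple = DEFAULT_PAIRS
    score: str = "bic"
    alpha: float = 1.0
    n_train: int = 40
    n_reps: int = 1000
    out_dir: str = "orflow_run"

    def to_dict(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "seed": self.seed,
            "simulation": {
                k: v
                for k, v in dataclasses.asdict(self.simulation).items()
                if k in _SIM_SCALAR_FIELDS
            },
            "lcss": {"eps": self.lcss.eps, "delta": self.lcss.delta},
            "selected_pairs": [list(p) for p in self.selected_pairs],
            "score": self.score,
            "alpha": self.alpha,
            "n_train": self.n_train,
            "n_reps": self.n_reps,
            "out_dir": self.out_dir,
        }


def load_pipeline_config(path: str | None = None, **overrides) -> PipelineConfig:
    """Build a config from an optional YAML file plus keyword overrides.

    The YAML mirrors :class:`PipelineConfig`; ``simulation`` accepts the
    scalar simulator fields (noise_sd, sample_hz, rendezvous rates, ...) —
    zones, schedules and cooperation tables are set programmatically.
    CLI flags (passed here as ``overrides``) take precedence over the file.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})

    sim_kwargs = {
        k: v for k, v in (raw.get("simulation") or {}).items() if k in _SIM_SCALAR_FIELDS
    }
    lcss_kwargs = raw.get("lcss") or {}
    pairs = raw.get("selected_pairs")
    if pairs in (None, "default"):
        pairs = DEFAULT_PAIRS
    cfg = PipelineConfig(
        n_cases=int(raw.get("n_cases", 10)),
        seed=int(raw.get("seed", 7)),
        simulation=SimulationConfig(**sim_kwargs),
        lcss=LCSSParams(**lcss_kwargs),
        selected_pairs=tuple(tuple(p) for p in pairs),
        score=raw.get("score", "bic"),
        alpha=float(raw.get("alpha", 1.0)),
        n_train=int(raw.get("n_train", 40)),
        n_reps=int(raw.get("n_reps", 1000)),
        out_dir=raw.get("out_dir", "orflow_run"),
    )
    return cfg


def make_classifiers(config: PipelineConfig) -> dict:
    """The BN and naive-Bayes pipelines (tertile discretization + classifier)."""
    return {
        "bn": Pipeline(
            [
                ("discretize", TertileDiscretizer()),
                ("classify", BayesNetClassifier(score=config.score, alpha=config.alpha)),
            ]
        ),
        "naive_bayes": Pipeline(
            [
                ("discretize", TertileDiscretizer()),
                ("classify", NaiveBayesClassifier(alpha=config.alpha)),
            ]
        ),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a manifest of artifact paths."""
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    manifest: dict[str, str] = {}

    with open(os.path.join(out, "resolved_config.yaml"), "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    manifest["resolved_config"] = os.path.join(out, "resolved_config.yaml")

    # --- simulate ------------------------------------------------------
    try:
        cases = generate_dataset(config.simulation, config.n_cases, seed=config.seed)
        manifest.update(write_dataset(cases, out))
    except Exception as exc:
        raise PipelineError("simulate", str(exc)) from exc

    # --- features ------------------------------------------------------
    try:
        sim_table = build_similarity_table(cases, config.lcss, config.selected_pairs)
        sim_path = os.path.join(out, "features_similarity.csv")
        sim_table.to_csv(sim_path, index=False)
        manifest["features_similarity"] = sim_path

        feat_cols = [
            c for c in sim_table.columns if c not in ("case_id", "phase", "t_start")
        ]
        disc = TertileDiscretizer().fit(sim_table[feat_cols])
        levels = disc.transform(sim_table[feat_cols])
        table = pd.concat([sim_table[["case_id", "phase", "t_start"]], levels], axis=1)
        feat_path = os.path.join(out, "features_discrete.csv")
        table.to_csv(feat_path, index=False)
        manifest["features_discrete"] = feat_path
    except Exception as exc:
        raise PipelineError("features", str(exc)) from exc

    # --- learn ---------------------------------------------------------
    try:
        frame = levels.copy()
        frame[TARGET_NODE] = sim_table["phase"].to_numpy()
        frame = frame.fillna("Low")  # absent role -> lowest interaction level
        dag = hill_climb(frame, score=config.score)
        net = fit_cpts(dag, frame, alpha=config.alpha)
        net_path = os.path.join(out, "network.json")
        with open(net_path, "w") as fh:
            fh.write(net.to_json())
        manifest["network"] = net_path
    except Exception as exc:
        raise PipelineError("learn", str(exc)) from exc

    # --- evaluate ------------------------------------------------------
    try:
        comparison = compare_classifiers(
            sim_table[feat_cols],
            sim_table["phase"].to_numpy(),
            make_classifiers(config),
            n_train=config.n_train,
            n_reps=config.n_reps,
            seed=config.seed,
        )
        reports = comparison["reports"]
        doc = {
            name: {
                k: v for k, v in rep.to_dict().items() if k != "accuracies"
            }
            for name, rep in reports.items()
        }
        doc["mean_difference"] = {
            f"{a}-{b}": d for (a, b), d in comparison["mean_difference"].items()
        }
        eval_path = os.path.join(out, "evaluation.json")
        with open(eval_path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
        manifest["evaluation"] = eval_path

        acc_path = os.path.join(out, "accuracies.csv")
        pd.DataFrame(
            {name: rep.accuracies for name, rep in reports.items()}
        ).to_csv(acc_path, index_label="rep")
        manifest["accuracies"] = acc_path
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("evaluate", str(exc)) from exc

    logger.info("pipeline artifacts written to %s", out)
    return manifest
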