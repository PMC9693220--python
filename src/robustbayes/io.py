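"""Dataset and model-config I/O, and the end-to-end pipeline.

CSV dialect: comma separator (tab for ``.tsv``), "." decimal, UTF-8,
header mandatory; an empty field or "NA" in the label column means a
missing label.  Model configs are JSON or YAML mappings with one entry
per class: ``{label, mean, sd | cov, weight}``; they round-trip
exactly.  Every pipeline output embeds the configuration, the seed, ε
and the package version for provenance.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abc_analysis import evidence_threshold
from .assignment import class_centers, plausible_bayes, reasonable_bayes
from .components import BayesModel
from .evaluation import bootstrap_experiment
from .fitting import fit_from_labeled, fit_gmm_em
from .scenarios import SCENARIOS

__all__ = ["read_dataset", "write_dataset", "read_model_config",
           "write_model_config", "RunConfig", "PipelineResult", "run_pipeline"]

_MISSING_LABELS = {"", "NA", "NaN", "nan", None}


def read_dataset(path, label_column: str | None = None):
    """Read a case-by-feature table; returns ``(X, feature_names, labels)``.

    All feature columns must parse as finite numbers; a failing cell is
    reported with its (1-based) data row and column name.  The label
    column, if named, is returned as an object array with ``None`` for
    missing labels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")

    labels = None
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"{path}: no column named {label_column!r}")
        raw = df.pop(label_column)
        labels = np.array(
            [None if v in _MISSING_LABELS else v for v in raw], dtype=object
        )

    feature_names = list(df.columns)
    if not feature_names:
        raise ValueError(f"{path}: no feature columns")
    X = np.empty((df.shape[0], len(feature_names)))
    for j, col in enumerate(feature_names):
        for i, cell in enumerate(df[col]):
            try:
                v = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} in row {i + 1}, "
                    f"column {col!r}"
                ) from None
            if not np.isfinite(v):
                raise ValueError(
                    f"{path}: non-finite value in row {i + 1}, column {col!r}"
                )
            X[i, j] = v
    return X, feature_names, labels


def write_dataset(path, X, feature_names, labels=None) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.DataFrame(np.asarray(X), columns=feature_names)
    if labels is not None:
        df["label"] = [lab if lab is not None else "" for lab in labels]
    df.to_csv(path, sep=sep, index=False)


def read_model_config(path) -> BayesModel:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() in (".yaml", ".yml"):
        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    return BayesModel.from_dict(d)


def write_model_config(path, model: BayesModel) -> None:
    path = Path(path)
    d = model.to_dict()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False), encoding="utf-8")
    else:
        path.write_text(json.dumps(d, indent=2), encoding="utf-8")


_RUNCONFIG_KEYS = None  # filled after the dataclass definition


@dataclass
class RunConfig:
    """Validated configuration of an end-to-end run."""

    input: str | None = None            # dataset path, or None with scenario
    scenario: str | None = None         # alternative to input
    label_column: str | None = None
    model_config: str | None = None     # path to a model config file
    fit: str | None = None              # "labeled" | "em" (model from data)
    n_components: int | None = None     # for fit="em"
    prior_mode: str = "equal"
    mode: str = "plausible"             # "bayes" | "reasonable" | "plausible"
    epsilon_method: str = "abc"         # "abc" | "fraction"
    epsilon_fraction: float = 0.01
    epsilon_source: str = "grid"        # "grid" | "empirical"
    metric: str = "euclidean"           # "euclidean" | "zscore"
    seed: int | None = None
    bootstrap: int = 0                  # replicate count; 0 = no bootstrap
    output: str | None = None           # CSV of per-case results
    report: str | None = None           # JSON provenance/report path

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _RUNCONFIG_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if (self.input is None) == (self.scenario is None):
            raise ValueError("exactly one of 'input' and 'scenario' is required")
        if self.scenario is not None and self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        sources = (self.model_config is not None) + (self.fit is not None)
        if self.scenario is None and sources != 1:
            raise ValueError("need exactly one model source: model_config or fit")
        if self.fit == "em" and not self.n_components:
            raise ValueError("fit='em' needs n_components")
        for name, value, allowed in (
            ("mode", self.mode, ("bayes", "reasonable", "plausible")),
            ("epsilon_method", self.epsilon_method, ("abc", "fraction")),
            ("epsilon_source", self.epsilon_source, ("grid", "empirical")),
            ("metric", self.metric, ("euclidean", "zscore")),
            ("prior_mode", self.prior_mode, ("equal", "proportional")),
            ("fit", self.fit, (None, "labeled", "em")),
        ):
            if value not in allowed:
                raise ValueError(f"{name} must be one of {allowed}, got {value!r}")


_RUNCONFIG_KEYS = set(RunConfig.__dataclass_fields__)


@dataclass
class PipelineResult:
    """Per-case classification plus provenance (and an optional report)."""

    frame: pd.DataFrame
    provenance: dict
    bootstrap: object | None = None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """fit → threshold → classify (→ evaluate), with full provenance.

    Stages: model acquisition (config file, labeled fit or EM),
    ε computation, reasonable Bayes, plausible Bayes, and — when truth
    labels are present and ``bootstrap > 0`` — the bootstrap comparison.
    Deterministic under a fixed seed.
    """
    config.validate()

    # -- data -------------------------------------------------------------
    if config.scenario is not None:
        ds = SCENARIOS[config.scenario](seed=config.seed)
        X, feature_names, labels = ds.cases, ds.feature_names, ds.labels
        model = ds.model
    else:
        X, feature_names, labels = read_dataset(config.input, config.label_column)
        model = None

    # -- model ------------------------------------------------------------
    if model is None:
        try:
            if config.model_config is not None:
                model = read_model_config(config.model_config)
            elif config.fit == "labeled":
                if labels is None:
                    raise ValueError("fit='labeled' needs a label column")
                mask = np.array([lab is not None for lab in labels])
                model = fit_from_labeled(X[mask], labels[mask],
                                         prior_mode=config.prior_mode)
            else:
                model = fit_gmm_em(X, c=config.n_components, seed=config.seed)
        except Exception as exc:
            raise RuntimeError(f"model acquisition failed: {exc}") from exc

    # -- threshold + classification --------------------------------------
    provenance = {"config": asdict(config), "version": __version__}
    if config.mode == "bayes":
        res = reasonable_bayes(model, X, epsilon=0.0)
        frame = res.to_frame().drop(columns=["reasonable"])
    else:
        try:
            eps = evidence_threshold(
                model, data=X, method=config.epsilon_method,
                fraction=config.epsilon_fraction, source=config.epsilon_source,
            )
        except Exception as exc:
            raise RuntimeError(f"threshold computation failed: {exc}") from exc
        res = reasonable_bayes(model, X, eps)
        if config.mode == "plausible":
            res = plausible_bayes(res, class_centers(model, metric=config.metric))
        frame = res.to_frame()
        provenance["epsilon"] = float(eps)
        provenance["n_uncertain"] = int(res.uncertain.sum())
    provenance["n_cases"] = int(X.shape[0])
    provenance["class_labels"] = [str(lab) for lab in model.labels]

    # -- optional bootstrap evaluation ------------------------------------
    report = None
    if config.bootstrap > 0:
        if labels is None:
            raise ValueError("bootstrap evaluation needs truth labels")
        mask = np.array([lab is not None for lab in labels])
        spec = (
            {"kind": "em", "n_components": model.n_components}
            if config.fit == "em" or config.scenario == "cytometry"
            else {"kind": "labeled", "prior_mode": config.prior_mode}
        )
        report = bootstrap_experiment(
            X[mask], labels[mask], model_spec=spec, B=config.bootstrap,
            seed=config.seed, epsilon_method=config.epsilon_method,
            epsilon_fraction=config.epsilon_fraction,
            epsilon_source=config.epsilon_source, metric=config.metric,
        )
        provenance["bootstrap"] = report.to_dict()

    # -- outputs ----------------------------------------------------------
    if config.output is not None:
        frame.to_csv(config.output, index=False)
    if config.report is not None:
        Path(config.report).write_text(
            json.dumps(provenance, indent=2, default=_json_default), encoding="utf-8"
        )
    return PipelineResult(frame=frame, provenance=provenance, bootstrap=report)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
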