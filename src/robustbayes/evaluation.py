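"""Accuracy reporting and the 100-fold bootstrap comparison protocol.

The bootstrap experiment resamples the labeled data with replacement,
refits the model on each replicate (from the labels for supervised
scenarios, by EM for mixture scenarios), derives ε, applies the plain /
reasonable / plausible rules and scores them against the truth labels —
overall and on the *low-evidence subset*, the cases below the
replicate's own 10th percentile of evidence.  Replicate accuracies are
aggregated as mean ± SD with a nonparametric 95% CI (2.5th/97.5th
percentile of the replicate values, type-7 linear interpolation — the
numpy default).

EM component labels are arbitrary; each replicate's fitted components
are matched to the truth classes by maximising the contingency-table
agreement (Hungarian assignment).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .abc_analysis import evidence_threshold
from .assignment import UNCERTAIN, class_centers, plausible_bayes, reasonable_bayes
from .components import BayesModel
from .fitting import fit_from_labeled, fit_gmm_em

__all__ = ["AccuracyReport", "accuracy_report", "BootstrapReport",
           "bootstrap_experiment", "match_component_labels"]

METHODS = ("bayes", "reasonable", "plausible")


@dataclass
class AccuracyReport:
    """Accuracy with confusion counts; ``accuracy is None`` when undefined."""

    accuracy: float | None
    n_evaluated: int
    n_correct: int
    n_uncertain_dropped: int
    confusion: pd.DataFrame

    @property
    def defined(self) -> bool:
        return self.accuracy is not None


def accuracy_report(predicted, truth, exclude_uncertain: bool = False) -> AccuracyReport:
    """Fraction of correct labels, with UNCERTAIN handling.

    With ``exclude_uncertain`` the UNCERTAIN predictions are dropped
    from the denominator and counted separately; without it they simply
    count as wrong (the sentinel never equals a class label).  Cases
    with a missing truth label are always skipped.  If no cases remain,
    the accuracy is reported as explicitly undefined (``None``), not as
    a number.
    """
    predicted = np.asarray(predicted, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth labels differ in length")

    labeled = np.array([not _is_missing(t) for t in truth])
    predicted, truth = predicted[labeled], truth[labeled]
    is_unc = np.array([p == UNCERTAIN for p in predicted])
    n_dropped = 0
    if exclude_uncertain:
        n_dropped = int(is_unc.sum())
        predicted, truth = predicted[~is_unc], truth[~is_unc]

    n = predicted.size
    if n == 0:
        empty = pd.DataFrame()
        return AccuracyReport(None, 0, 0, n_dropped, empty)
    correct = int(np.sum(predicted == truth))
    confusion = pd.crosstab(
        pd.Series(truth, name="truth"), pd.Series(predicted, name="predicted")
    )
    return AccuracyReport(correct / n, n, correct, n_dropped, confusion)


@dataclass
class MethodSummary:
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    n_defined: int


@dataclass
class BootstrapReport:
    """Aggregated replicate accuracies for the three decision rules."""

    overall: dict = field(default_factory=dict)        # method -> MethodSummary
    low_evidence: dict = field(default_factory=dict)   # method -> MethodSummary
    replicates: pd.DataFrame | None = None
    n_replicates: int = 0
    seed: int | None = None
    epsilon_mean: float = np.nan
    uncertain_mean: float = np.nan
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def block(d):
            return {
                m: {
                    "mean": s.mean, "sd": s.sd,
                    "ci95": [s.ci_low, s.ci_high], "n_defined": s.n_defined,
                }
                for m, s in d.items()
            }
        return {
            "overall": block(self.overall),
            "low_evidence": block(self.low_evidence),
            "n_replicates": self.n_replicates,
            "seed": self.seed,
            "epsilon_mean": self.epsilon_mean,
            "uncertain_mean": self.uncertain_mean,
            "meta": self.meta,
        }

    def summary(self) -> str:
        lines = [f"Bootstrap report (B={self.n_replicates}, seed={self.seed})",
                 f"mean epsilon={self.epsilon_mean:.6g}, "
                 f"mean uncertain count={self.uncertain_mean:.1f}", ""]
        for name, blockd in (("overall", self.overall),
                             ("low-evidence decile", self.low_evidence)):
            lines.append(f"[{name}]")
            for m, s in blockd.items():
                lines.append(
                    f"  {m:10s} {100 * s.mean:6.2f}% ± {100 * s.sd:.2f}  "
                    f"CI95 [{100 * s.ci_low:.2f}, {100 * s.ci_high:.2f}]  "
                    f"(defined in {s.n_defined}/{self.n_replicates})"
                )
        return "\n".join(lines)


def match_component_labels(predicted, truth, class_labels) -> dict:
    """Map arbitrary component labels onto truth labels (Hungarian).

    Maximises the total contingency-table agreement between the
    predicted component labels and the truth classes.  Only meaningful
    when the numbers of components and truth classes coincide.
    """
    truth_classes = list(dict.fromkeys(truth))
    if len(truth_classes) != len(class_labels):
        raise ValueError("component and truth class counts differ")
    C = np.zeros((len(class_labels), len(truth_classes)))
    for i, cl in enumerate(class_labels):
        mask = predicted == cl
        for j, tc in enumerate(truth_classes):
            C[i, j] = np.sum(mask & (truth == tc))
    rows, cols = linear_sum_assignment(-C)
    return {class_labels[i]: truth_classes[j] for i, j in zip(rows, cols)}


def bootstrap_experiment(
    data,
    truth,
    model_spec: dict | None = None,
    B: int = 100,
    seed: int | None = None,
    epsilon_method: str = "abc",
    epsilon_fraction: float = 0.01,
    epsilon_source: str = "grid",
    low_evidence_quantile: float = 0.10,
    metric: str = "euclidean",
    keep_replicates: bool = True,
    max_redraws: int = 10,
) -> BootstrapReport:
    """B-fold bootstrap comparison of plain/reasonable/plausible Bayes.

    Parameters
    ----------
    data, truth : arrays
        Labeled cases; every case needs a truth label.
    model_spec : dict
        ``{"kind": "labeled", "prior_mode": "equal"}`` refits per-class
        Gaussians from the replicate labels (the default);
        ``{"kind": "em", "n_components": c, ...}`` refits an unlabeled
        mixture by EM with a replicate-specific seed and matches the
        component labels to the truth classes;
        ``{"kind": "fixed", "model": BayesModel}`` reuses one model.
    B, seed
        Replicate count and master seed; the report is bit-reproducible
        under a fixed seed.
    low_evidence_quantile
        The low-evidence subset of a replicate holds its cases below
        this within-replicate evidence quantile (default: lowest decile).

    A replicate that loses an entire class is redrawn (at most
    ``max_redraws`` times, then an error is raised).  The *reasonable*
    accuracy is computed on classified cases only (UNCERTAIN dropped
    from the denominator); where every case of a subset is UNCERTAIN
    the replicate contributes no value for that entry.
    """
    if B < 1:
        raise ValueError("need at least one bootstrap replicate")
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    y = np.asarray(truth, dtype=object)
    if any(_is_missing(t) for t in y):
        raise ValueError("bootstrap requires a truth label for every case")
    if model_spec is None:
        model_spec = {"kind": "labeled", "prior_mode": "equal"}
    classes = list(dict.fromkeys(y))
    n = X.shape[0]
    rng = np.random.default_rng(seed)

    rows = []
    for b in range(B):
        Xb, yb = _resample(X, y, classes, rng, model_spec["kind"], max_redraws)
        model, label_map = _fit_replicate(Xb, yb, model_spec, rng)

        eps = evidence_threshold(
            model, data=Xb, method=epsilon_method, fraction=epsilon_fraction,
            source=epsilon_source,
        )
        res = reasonable_bayes(model, Xb, eps)
        res = plausible_bayes(res, class_centers(model, metric=metric))

        bayes = _remap(res.bayes_label, label_map)
        reasonable = _remap(res.reasonable_label, label_map)
        plausible = _remap(res.plausible_label, label_map)

        thr = np.quantile(res.evidence, low_evidence_quantile)
        low = res.evidence < thr

        row = {"replicate": b, "epsilon": eps,
               "n_uncertain": int(res.uncertain.sum())}
        for name, pred in (("bayes", bayes), ("reasonable", reasonable),
                           ("plausible", plausible)):
            rep = accuracy_report(pred, yb, exclude_uncertain=(name == "reasonable"))
            row[f"{name}_acc"] = rep.accuracy
            rep_low = accuracy_report(
                pred[low], yb[low], exclude_uncertain=(name == "reasonable")
            )
            row[f"{name}_low_acc"] = rep_low.accuracy
        rows.append(row)

    reps = pd.DataFrame(rows)
    report = BootstrapReport(
        overall={m: _summarise(reps[f"{m}_acc"]) for m in METHODS},
        low_evidence={m: _summarise(reps[f"{m}_low_acc"]) for m in METHODS},
        replicates=reps if keep_replicates else None,
        n_replicates=B,
        seed=seed,
        epsilon_mean=float(reps["epsilon"].mean()),
        uncertain_mean=float(reps["n_uncertain"].mean()),
        meta={"model_spec": {k: v for k, v in model_spec.items() if k != "model"},
              "epsilon_method": epsilon_method, "epsilon_source": epsilon_source,
              "low_evidence_quantile": low_evidence_quantile, "metric": metric},
    )
    return report


def _resample(X, y, classes, rng, kind, max_redraws):
    n = X.shape[0]
    for _ in range(max_redraws + 1):
        idx = rng.integers(0, n, size=n)
        yb = y[idx]
        if kind != "labeled" or all(np.any(yb == c) for c in classes):
            return X[idx], yb
    raise RuntimeError(
        f"could not draw a replicate containing all classes in {max_redraws} tries"
    )


def _fit_replicate(Xb, yb, model_spec, rng):
    kind = model_spec["kind"]
    if kind == "labeled":
        model = fit_from_labeled(Xb, yb, prior_mode=model_spec.get("prior_mode", "equal"))
        return model, None
    if kind == "em":
        em_seed = int(rng.integers(2**31))
        model = fit_gmm_em(
            Xb,
            c=model_spec["n_components"],
            seed=em_seed,
            n_restarts=model_spec.get("n_restarts", 3),
            tol=model_spec.get("tol", 1e-6),
            max_iter=model_spec.get("max_iter", 500),
        )
        pred = np.asarray(
            [model.labels[k] for k in np.argmax(model.log_joint(Xb), axis=1)],
            dtype=object,
        )
        label_map = match_component_labels(pred, yb, model.labels)
        return model, label_map
    if kind == "fixed":
        return model_spec["model"], None
    raise ValueError(f"unknown model spec kind {kind!r}")


def _remap(labels, label_map):
    if label_map is None:
        return np.asarray(labels, dtype=object)
    return np.asarray(
        [label_map.get(lab, lab) if lab != UNCERTAIN else UNCERTAIN for lab in labels],
        dtype=object,
    )


def _summarise(series: pd.Series) -> MethodSummary:
    vals = series.dropna().astype(float).to_numpy()
    if vals.size == 0:
        return MethodSummary(np.nan, np.nan, np.nan, np.nan, 0)
    return MethodSummary(
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        ci_low=float(np.percentile(vals, 2.5)),
        ci_high=float(np.percentile(vals, 97.5)),
        n_defined=int(vals.size),
    )


def _is_missing(t) -> bool:
    return t is None or (isinstance(t, float) and np.isnan(t)) or t is pd.NA
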