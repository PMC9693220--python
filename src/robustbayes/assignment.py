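"""Reasonable and plausible Bayes: suspend, then relabel by nearest center.

*Reasonable Bayes* keeps the maximum-posterior label only where the
evidence is at least ε; below the threshold the decision is suspended
and the case is labeled with the :data:`UNCERTAIN` sentinel (serialised
as a missing value, mirroring SQL NULL / IEEE NaN).

*Plausible Bayes* resolves every suspended case by assigning the class
whose center (the component mean, i.e. the expected value of the class
distribution) is nearest: ``class(x) = argmin_k d(x, m_k)``.  For point
queries this is exactly membership in the Voronoi cell of the centers,
in any dimension, without constructing the tessellation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .boundaries import bayes_classify
from .components import BayesModel, _as_matrix

__all__ = ["UNCERTAIN", "ClassificationResult", "ClassCenters",
           "reasonable_bayes", "class_centers", "plausible_bayes"]

#: Sentinel for a suspended class decision.  Never a valid class label.
UNCERTAIN = "UNCERTAIN"


@dataclass
class ClassificationResult:
    """Per-case evidence, posteriors and the three label columns.

    Invariants: ``reasonable_label`` equals ``bayes_label`` exactly
    where ``evidence >= epsilon`` and is :data:`UNCERTAIN` elsewhere;
    ``plausible_label`` (once computed) never contains the sentinel and
    agrees with ``reasonable_label`` wherever that is not UNCERTAIN.
    """

    cases: np.ndarray            # (n, d)
    evidence: np.ndarray         # (n,)
    posteriors: np.ndarray       # (n, c)
    class_labels: list
    bayes_label: np.ndarray      # (n,) object
    reasonable_label: np.ndarray  # (n,) object, may contain UNCERTAIN
    plausible_label: np.ndarray | None = None
    epsilon: float = np.nan
    metadata: dict = field(default_factory=dict)

    @property
    def n_cases(self) -> int:
        return self.cases.shape[0]

    @property
    def uncertain(self) -> np.ndarray:
        return np.asarray([lab is UNCERTAIN or lab == UNCERTAIN
                           for lab in self.reasonable_label])

    def to_frame(self) -> pd.DataFrame:
        """Tabular view; the sentinel becomes a missing value (NA)."""
        out = {"evidence": self.evidence}
        for j, lab in enumerate(self.class_labels):
            out[f"posterior_{lab}"] = self.posteriors[:, j]
        out["bayes"] = self.bayes_label
        reasonable = self.reasonable_label.copy()
        reasonable[self.uncertain] = pd.NA
        out["reasonable"] = reasonable
        if self.plausible_label is not None:
            out["plausible"] = self.plausible_label
        return pd.DataFrame(out)


@dataclass
class ClassCenters:
    """Class centers (component means) for the Voronoi assignment."""

    centers: np.ndarray   # (c, d)
    labels: list
    metric: str = "euclidean"
    scale: np.ndarray | None = None  # per-feature scale for metric="zscore"

    def distances(self, X: np.ndarray) -> np.ndarray:
        """(n, c) distances from each case to each center."""
        if self.metric == "euclidean":
            Xs, Cs = X, self.centers
        elif self.metric == "zscore":
            Xs, Cs = X / self.scale, self.centers / self.scale
        else:
            raise ValueError(f"unknown metric {self.metric!r}")
        return np.linalg.norm(Xs[:, None, :] - Cs[None, :, :], axis=2)


def reasonable_bayes(model: BayesModel, X, epsilon: float) -> ClassificationResult:
    """Classify, but suspend every decision with ``evidence < epsilon``.

    The comparison is strict: a case whose evidence equals ε exactly is
    still classified.  With ε = 0 nothing is suspended, since evidence
    is strictly positive for finite input.
    """
    if not np.isfinite(epsilon) or epsilon < 0.0:
        raise ValueError(f"epsilon must be a nonnegative number, got {epsilon}")
    X = _as_matrix(np.asarray(X, dtype=float), model.dim)
    ev = model.evidence(X)
    post = model.posteriors(X)
    bayes = bayes_classify(model, X)
    reasonable = bayes.astype(object).copy()
    reasonable[ev < epsilon] = UNCERTAIN
    return ClassificationResult(
        cases=X,
        evidence=ev,
        posteriors=post,
        class_labels=model.labels,
        bayes_label=bayes.astype(object),
        reasonable_label=reasonable,
        epsilon=float(epsilon),
        metadata={"rule": "reasonable"},
    )


def class_centers(model: BayesModel, metric: str = "euclidean") -> ClassCenters:
    """Component means as Voronoi cell generators.

    Duplicate means are rejected (the cells would be ill-defined).  For
    ``metric="zscore"``, distances are computed on features divided by
    the prior-weighted root-mean-square component SD per feature.
    """
    centers = model.means
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            if np.linalg.norm(centers[i] - centers[j]) < 1e-12:
                raise ValueError(
                    f"classes {model.labels[i]!r} and {model.labels[j]!r} share "
                    "a center; Voronoi cells are ill-defined"
                )
    scale = None
    if metric == "zscore":
        variances = np.stack([np.diag(c.cov) for c in model.components])
        scale = np.sqrt(np.average(variances, weights=model.weights, axis=0))
    elif metric != "euclidean":
        raise ValueError(f"unknown metric {metric!r}")
    return ClassCenters(centers=centers, labels=model.labels, metric=metric,
                        scale=scale)


def plausible_bayes(
    result: ClassificationResult, centers: ClassCenters
) -> ClassificationResult:
    """Resolve UNCERTAIN cases by nearest class center.

    All other labels are unchanged.  An exact distance tie resolves to
    the lowest class index (argmin order), keeping the rule
    deterministic.  Applying the step twice is a no-op.
    """
    mask = result.uncertain
    plausible = result.reasonable_label.copy()
    if mask.any():
        d = centers.distances(result.cases[mask])
        labels = np.asarray(centers.labels, dtype=object)
        plausible[mask] = labels[np.argmin(d, axis=1)]
    out = replace(result, plausible_label=plausible)
    out.metadata = dict(result.metadata, rule="plausible", metric=centers.metric)
    return out
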