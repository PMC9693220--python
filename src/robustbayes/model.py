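"""Model/Results interface in the style of statistical modelling packages.

``RobustBayesClassifier`` holds the data; ``fit`` estimates the
Gaussian class models (from labels, or by EM) and returns a
``RobustBayesResults`` carrying the fitted components, the evidence
threshold ε, the per-case classification under all three rules, the
1-D decision boundaries and a ``summary()`` table.  Bootstrapping
hangs off the results object.

Example
-------
>>> from robustbayes import RobustBayesClassifier, generate_heights
>>> ds = generate_heights(seed=1)
>>> clf = RobustBayesClassifier(ds.cases, labels=ds.labels,
...                             feature_names=ds.feature_names)
>>> res = clf.fit(method="labeled")
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .abc_analysis import evidence_threshold
from .assignment import (ClassificationResult, class_centers, plausible_bayes,
                         reasonable_bayes)
from .boundaries import decision_boundaries_1d, default_search_range
from .components import BayesModel
from .evaluation import BootstrapReport, bootstrap_experiment
from .fitting import fit_from_labeled, fit_gmm_em

__all__ = ["RobustBayesClassifier", "RobustBayesResults"]


class RobustBayesClassifier:
    """Robust Bayes classification model built from a case table.

    Parameters
    ----------
    data : (n, d) array_like
        Case-by-feature table.
    labels : (n,) sequence, optional
        Truth/class labels; ``None`` entries mark unlabeled cases.
        Required for ``fit(method="labeled")`` and for bootstrapping.
    feature_names : list of str, optional
    """

    def __init__(self, data, labels=None, feature_names=None):
        X = np.asarray(data, dtype=float)
        if X.ndim == 1:
            X = X.reshape(-1, 1)
        if X.ndim != 2:
            raise ValueError("data must be a case-by-feature table")
        self.data = X
        self.nobs, self.dim = X.shape
        self.labels = None if labels is None else np.asarray(labels, dtype=object)
        if self.labels is not None and self.labels.shape[0] != self.nobs:
            raise ValueError("labels and data disagree on the number of cases")
        self.feature_names = (
            list(feature_names) if feature_names is not None
            else [f"x{i}" for i in range(self.dim)]
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str | None = None):
        df = df.copy()
        labels = None
        if label_column is not None:
            raw = df.pop(label_column)
            labels = np.array(
                [None if pd.isna(v) else v for v in raw], dtype=object
            )
        return cls(df.to_numpy(dtype=float), labels=labels,
                   feature_names=list(df.columns))

    @property
    def labeled_mask(self) -> np.ndarray:
        if self.labels is None:
            return np.zeros(self.nobs, dtype=bool)
        return np.array([lab is not None for lab in self.labels])

    def fit(
        self,
        method: str = "labeled",
        prior_mode: str = "equal",
        n_components: int | None = None,
        seed: int | None = None,
        epsilon_method: str = "abc",
        epsilon_fraction: float = 0.01,
        epsilon_source: str = "grid",
        metric: str = "euclidean",
        **em_kwargs,
    ) -> "RobustBayesResults":
        """Estimate the class models and derive the evidence threshold.

        method="labeled" fits per-class Gaussians from the labeled
        cases; method="em" fits an unlabeled ``n_components`` mixture.
        """
        if method == "labeled":
            if self.labels is None:
                raise ValueError("labeled fit requires labels")
            mask = self.labeled_mask
            model = fit_from_labeled(self.data[mask], self.labels[mask],
                                     prior_mode=prior_mode)
        elif method == "em":
            if not n_components:
                raise ValueError("EM fit requires n_components")
            model = fit_gmm_em(self.data, c=n_components, seed=seed, **em_kwargs)
        else:
            raise ValueError(f"unknown fit method {method!r}")

        eps = evidence_threshold(
            model, data=self.data, method=epsilon_method,
            fraction=epsilon_fraction, source=epsilon_source,
        )
        return RobustBayesResults(
            self, model, eps,
            fit_options={
                "method": method, "prior_mode": prior_mode, "seed": seed,
                "epsilon_method": epsilon_method,
                "epsilon_fraction": epsilon_fraction,
                "epsilon_source": epsilon_source, "metric": metric,
            },
        )


class RobustBayesResults:
    """Fitted class models, threshold ε and classification machinery."""

    def __init__(self, model_obj: RobustBayesClassifier, bayes_model: BayesModel,
                 epsilon: float, fit_options: dict):
        self.model = model_obj
        self.bayes_model = bayes_model
        self.epsilon = float(epsilon)
        self.fit_options = dict(fit_options)
        self._classification: ClassificationResult | None = None

    # -- classification ---------------------------------------------------
    def classify(self, data=None, mode: str = "plausible") -> ClassificationResult:
        """Plain / reasonable / plausible labels for ``data`` (default:
        the training cases)."""
        X = self.model.data if data is None else np.asarray(data, dtype=float)
        eps = 0.0 if mode == "bayes" else self.epsilon
        res = reasonable_bayes(self.bayes_model, X, eps)
        if mode == "plausible":
            centers = class_centers(self.bayes_model,
                                    metric=self.fit_options.get("metric", "euclidean"))
            res = plausible_bayes(res, centers)
        elif mode not in ("bayes", "reasonable"):
            raise ValueError(f"unknown mode {mode!r}")
        return res

    @property
    def classification(self) -> ClassificationResult:
        """Plausible-Bayes classification of the training data (cached)."""
        if self._classification is None:
            self._classification = self.classify()
        return self._classification

    # -- diagnostics ------------------------------------------------------
    def decision_boundaries(self, search_range=None):
        if search_range is None and self.bayes_model.dim == 1:
            search_range = default_search_range(self.bayes_model, self.model.data)
        return decision_boundaries_1d(self.bayes_model, search_range)

    def bootstrap(self, B: int = 100, seed: int | None = None,
                  **kwargs) -> BootstrapReport:
        """Bootstrap comparison of the three rules on the labeled cases."""
        if self.model.labels is None:
            raise ValueError("bootstrap requires labels")
        mask = self.model.labeled_mask
        if self.fit_options["method"] == "em":
            spec = {"kind": "em",
                    "n_components": self.bayes_model.n_components}
        else:
            spec = {"kind": "labeled",
                    "prior_mode": self.fit_options["prior_mode"]}
        return bootstrap_experiment(
            self.model.data[mask], self.model.labels[mask], model_spec=spec,
            B=B, seed=seed,
            epsilon_method=self.fit_options["epsilon_method"],
            epsilon_fraction=self.fit_options["epsilon_fraction"],
            epsilon_source=self.fit_options["epsilon_source"],
            metric=self.fit_options.get("metric", "euclidean"), **kwargs,
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        bm = self.bayes_model
        res = self.classification
        lines = [
            "Robust Bayes classification results",
            "=" * 51,
            f"cases: {self.model.nobs}   features: "
            + ", ".join(self.model.feature_names),
            f"fit method: {self.fit_options['method']}   "
            f"epsilon ({self.fit_options['epsilon_method']}, "
            f"{self.fit_options['epsilon_source']}): {self.epsilon:.6g}",
            "",
            f"{'class':>12} {'weight':>8} {'mean':>24} {'sd':>16}",
            "-" * 65,
        ]
        for c in bm.components:
            mean = ", ".join(f"{v:.4f}" for v in c.mean)
            sds = ", ".join(f"{v:.4f}" for v in c.sds)
            lines.append(f"{str(c.label):>12} {c.weight:8.4f} {mean:>24} {sds:>16}")
        lines.append("-" * 65)
        n_unc = int(res.uncertain.sum())
        lines.append(
            f"uncertain cases (evidence < epsilon): {n_unc} of {res.n_cases}"
        )
        if bm.dim == 1:
            bset = self.decision_boundaries()
            if len(bset):
                pretty = ", ".join(
                    f"{b:.2f} ({p[0]}|{p[1]})" for b, p in bset.to_rows()
                )
                lines.append(f"decision boundaries: {pretty}")
        return "\n".join(lines)

    def __repr__(self):
        return (f"<RobustBayesResults c={self.bayes_model.n_components} "
                f"d={self.bayes_model.dim} eps={self.epsilon:.4g}>")
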