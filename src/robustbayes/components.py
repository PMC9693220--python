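"""Gaussian class-conditional models and Bayes posterior computation.

A classifier here is a *closed world* of Gaussian components, one per
class.  Each component carries its mean ``m``, its dispersion (a standard
deviation ``s`` for univariate models, a covariance matrix for
multivariate ones) and a prior weight ``p(class)``.  The prior-weighted
sum of the class likelihoods at a point is the *evidence* — the overall
probability density of observing that value — and the posterior of a
class is ``p(class) * likelihood_class / evidence``.

All densities are evaluated in log space; the evidence is a
log-sum-exp, so posteriors stay well defined far into the tails.  The
evidence is reported as exactly zero only when every class log-density
underflows to ``-inf``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

__all__ = [
    "GaussianComponent",
    "BayesModel",
    "PosteriorTable",
    "gaussian_pdf",
    "evidence",
    "posteriors",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


class GaussianComponent:
    """One class of a Bayes model: label, mean, dispersion and prior weight.

    Parameters
    ----------
    label : str | int
        Class identifier; must be unique within a model and must not
        collide with the UNCERTAIN sentinel.
    mean : float or (d,) array_like
        Component mean, in the units of the measured feature.
    dispersion : float or (d, d) array_like
        Standard deviation ``s`` (> 0) for a univariate component, or a
        symmetric positive-definite covariance matrix for ``d > 1``.
        Univariate components store ``s`` itself, not the variance.
    weight : float
        Prior probability ``p(class)`` in ``(0, 1]``.
    """

    def __init__(self, label, mean, dispersion, weight):
        self.label = label
        mean = np.atleast_1d(np.asarray(mean, dtype=float))
        if mean.ndim != 1 or not np.all(np.isfinite(mean)):
            raise ValueError(f"component {label!r}: mean must be a finite vector")
        self.mean = mean
        self.dim = mean.size
        weight = float(weight)
        if not (0.0 < weight <= 1.0):
            raise ValueError(f"component {label!r}: weight {weight} outside (0, 1]")
        self.weight = weight

        disp = np.asarray(dispersion, dtype=float)
        if self.dim == 1 and disp.ndim == 0:
            s = float(disp)
            if not np.isfinite(s) or s <= 0.0:
                raise ValueError(f"component {label!r}: sd must be positive, got {s}")
            self.sd = s
            self.cov = np.array([[s * s]])
        else:
            cov = np.atleast_2d(disp)
            if cov.shape != (self.dim, self.dim):
                raise ValueError(
                    f"component {label!r}: covariance shape {cov.shape} does not "
                    f"match dimension {self.dim}"
                )
            if not np.allclose(cov, cov.T):
                raise ValueError(f"component {label!r}: covariance not symmetric")
            self.cov = cov
            self.sd = float(np.sqrt(cov[0, 0])) if self.dim == 1 else None
        # positive definiteness is checked once, here, via the Cholesky factor
        try:
            self._chol = np.linalg.cholesky(self.cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"component {label!r}: dispersion is not positive-definite"
            ) from exc
        self._log_det = 2.0 * float(np.sum(np.log(np.diag(self._chol))))

    @property
    def sds(self) -> np.ndarray:
        """Per-feature marginal standard deviations."""
        return np.sqrt(np.diag(self.cov))

    def log_density(self, X: np.ndarray) -> np.ndarray:
        """Multivariate normal log-density at the rows of ``X`` (n, d)."""
        X = _as_matrix(X, self.dim)
        diff = X - self.mean
        # solve L y = diff^T  =>  squared Mahalanobis distance = ||y||^2
        y = solve_triangular(self._chol, diff.T, lower=True)
        with np.errstate(over="ignore"):  # far tails: maha may reach inf
            maha = np.sum(y * y, axis=0)
        return -0.5 * (self.dim * _LOG_2PI + self._log_det + maha)

    def density(self, X: np.ndarray) -> np.ndarray:
        return np.exp(self.log_density(X))

    def to_dict(self) -> dict:
        d = {"label": self.label, "weight": self.weight}
        if self.dim == 1:
            d["mean"] = float(self.mean[0])
            d["sd"] = float(self.sd)
        else:
            d["mean"] = self.mean.tolist()
            d["cov"] = self.cov.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianComponent":
        disp = d["sd"] if "sd" in d else d["cov"]
        return cls(d["label"], d["mean"], disp, d["weight"])

    def __repr__(self):
        if self.dim == 1:
            return (
                f"GaussianComponent({self.label!r}, m={self.mean[0]:g}, "
                f"s={self.sd:g}, w={self.weight:g})"
            )
        return f"GaussianComponent({self.label!r}, d={self.dim}, w={self.weight:g})"


class BayesModel:
    """A closed-world set of Gaussian components.

    The component weights must sum to one (within 1e-9): the classes are
    assumed exhaustive, so the weighted likelihood sum is the full
    probability density of an observation (the evidence).
    """

    def __init__(self, components: Sequence[GaussianComponent]):
        components = list(components)
        if len(components) < 1:
            raise ValueError("model needs at least one component")
        dims = {c.dim for c in components}
        if len(dims) != 1:
            raise ValueError(f"components disagree on dimension: {sorted(dims)}")
        labels = [c.label for c in components]
        if len(set(labels)) != len(labels):
            raise ValueError(f"component labels not unique: {labels}")
        total = sum(c.weight for c in components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component weights sum to {total!r}, expected 1")
        self.components = components
        self.dim = components[0].dim
        self.fit_info = None  # optionally attached by fitting routines

    # -- basic accessors -------------------------------------------------
    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def labels(self) -> list:
        return [c.label for c in self.components]

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.stack([c.mean for c in self.components])

    # -- probability machinery -------------------------------------------
    def log_likelihoods(self, X) -> np.ndarray:
        """(n, c) class-conditional log-densities."""
        X = _as_matrix(X, self.dim)
        return np.stack([c.log_density(X) for c in self.components], axis=1)

    def likelihoods(self, X) -> np.ndarray:
        return np.exp(self.log_likelihoods(X))

    def log_joint(self, X) -> np.ndarray:
        """(n, c) log of weight_k * pdf_k."""
        return self.log_likelihoods(X) + np.log(self.weights)

    def log_evidence(self, X) -> np.ndarray:
        return logsumexp(self.log_joint(X), axis=1)

    def evidence(self, X) -> np.ndarray:
        return np.exp(self.log_evidence(X))

    def posteriors(self, X) -> np.ndarray:
        """(n, c) posterior probabilities p(class | x).

        Rows where every class log-density underflowed to ``-inf`` (no
        evidence at all) are returned as NaN; see :class:`PosteriorTable`
        for the explicit flag.
        """
        lj = self.log_joint(X)
        le = logsumexp(lj, axis=1)
        with np.errstate(invalid="ignore"):
            post = np.exp(lj - le[:, None])
        post[~np.isfinite(le)] = np.nan
        return post

    def posterior_table(self, X) -> "PosteriorTable":
        X = _as_matrix(X, self.dim)
        lj = self.log_joint(X)
        le = logsumexp(lj, axis=1)
        defined = np.isfinite(le)
        with np.errstate(invalid="ignore"):
            post = np.exp(lj - le[:, None])
        post[~defined] = np.nan
        return PosteriorTable(
            likelihoods=np.exp(lj - np.log(self.weights)),
            evidence=np.exp(le),
            posteriors=post,
            defined=defined,
            labels=self.labels,
        )

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict:
        return {"classes": [c.to_dict() for c in self.components]}

    @classmethod
    def from_dict(cls, d: dict) -> "BayesModel":
        return cls([GaussianComponent.from_dict(c) for c in d["classes"]])

    def __repr__(self):
        return f"BayesModel(c={self.n_components}, d={self.dim})"


@dataclass
class PosteriorTable:
    """Per-case likelihoods, evidence and posteriors.

    ``defined`` is False for cases whose evidence underflowed to zero —
    there the posteriors are NaN and any decision must be suspended.
    """

    likelihoods: np.ndarray  # (n, c) pdf values
    evidence: np.ndarray     # (n,)
    posteriors: np.ndarray   # (n, c)
    defined: np.ndarray      # (n,) bool
    labels: list = field(default_factory=list)


def gaussian_pdf(component: GaussianComponent, x) -> np.ndarray:
    """Normal density of one component at ``x`` (scalar, vector or matrix)."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0 or (x.ndim == 1 and component.dim > 1)
    out = component.density(x)
    return float(out[0]) if scalar else out


def evidence(model: BayesModel, x) -> np.ndarray:
    """Prior-weighted sum of class likelihoods at ``x``."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0 or (x.ndim == 1 and model.dim > 1)
    out = model.evidence(x)
    return float(out[0]) if scalar else out


def posteriors(model: BayesModel, x) -> np.ndarray:
    """Posterior probability vector(s) at ``x``; rows sum to one."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0 or (x.ndim == 1 and model.dim > 1)
    out = model.posteriors(x)
    return out[0] if scalar else out


def _as_matrix(X, dim: int) -> np.ndarray:
    """Coerce input to an (n, d) float matrix and validate finiteness."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 0:
        X = X.reshape(1, 1)
    elif X.ndim == 1:
        # a length-n series of univariate cases, or a single d-vector
        X = X.reshape(1, -1) if (dim > 1 and X.size == dim) else X.reshape(-1, 1)
    if X.ndim != 2 or X.shape[1] != dim:
        raise ValueError(f"expected cases with {dim} feature(s), got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("cases contain non-finite values")
    return X
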