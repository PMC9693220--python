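"""Model fitting: from labeled groups, or by EM for Gaussian mixtures.

``fit_from_labeled`` computes per-class sample moments.  ``fit_gmm_em``
is a standard expectation–maximisation fit of a Gaussian mixture with
k-means++ seeding, multiple restarts and a small covariance ridge on
singularity; it records the per-iteration log-likelihood trajectory of
the winning run (which must be nondecreasing) in the returned model's
``fit_info``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

from .components import BayesModel, GaussianComponent, _as_matrix

__all__ = ["fit_from_labeled", "fit_gmm_em", "EMFitInfo"]


def fit_from_labeled(data, labels, prior_mode: str = "equal") -> BayesModel:
    """Fit one Gaussian component per labeled group.

    Parameters
    ----------
    data : (n, d) array_like
        Case-by-feature table.
    labels : (n,) sequence
        Class label per case.  Missing labels (None/NaN) are rejected.
    prior_mode : {"equal", "proportional"}
        Component weights: all ``1/c``, or the observed class frequency.

    Each class needs at least two cases and nonzero variance in every
    feature.  Means and SDs/covariances are the ordinary sample moments
    (``ddof=1``).
    """
    if prior_mode not in ("equal", "proportional"):
        raise ValueError(f"unknown prior_mode {prior_mode!r}")
    labels = np.asarray(labels, dtype=object)
    data = np.asarray(data, dtype=float)
    X = _as_matrix(data, 1 if data.ndim == 1 else data.shape[1])
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels and data disagree on the number of cases")
    if any(lab is None or (isinstance(lab, float) and np.isnan(lab)) for lab in labels):
        raise ValueError("missing class label in training data")

    classes = list(dict.fromkeys(labels))  # first-appearance order
    n, d = X.shape
    comps = []
    for lab in classes:
        grp = X[labels == lab]
        if grp.shape[0] < 2:
            raise ValueError(f"class {lab!r} has fewer than 2 cases")
        mean = grp.mean(axis=0)
        if d == 1:
            s = grp[:, 0].std(ddof=1)
            if s <= 0.0:
                raise ValueError(f"class {lab!r} has zero variance")
            disp = s
        else:
            disp = np.cov(grp, rowvar=False, ddof=1)
            if np.any(np.diag(disp) <= 0.0):
                raise ValueError(f"class {lab!r} has zero variance in some feature")
        w = 1.0 / len(classes) if prior_mode == "equal" else grp.shape[0] / n
        comps.append(GaussianComponent(lab, mean, disp, w))
    return BayesModel(comps)


@dataclass
class EMFitInfo:
    """Diagnostics of an EM fit: winning-run trajectory and bookkeeping."""

    log_likelihood: float = np.nan          # final mean log-likelihood per case
    trajectory: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_iter: int = 0
    converged: bool = False
    n_restarts: int = 0
    seed: int | None = None
    ridge_used: bool = False


def fit_gmm_em(
    data,
    c: int,
    seed: int | None = None,
    n_restarts: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> BayesModel:
    """Fit a ``c``-component Gaussian mixture by expectation–maximisation.

    Restarts ``n_restarts`` times from k-means++ seedings and keeps the
    run with the best final log-likelihood.  Convergence is declared
    when the relative change of the mean log-likelihood per case falls
    below ``tol``.  A singular covariance update is regularised with a
    ridge of ``1e-6 * trace / d`` on the diagonal.

    Returns the fitted :class:`BayesModel`; the per-iteration
    log-likelihood trajectory of the winning run is attached as
    ``model.fit_info`` (an :class:`EMFitInfo`).
    """
    data = np.asarray(data, dtype=float)
    X = _as_matrix(data, 1 if data.ndim == 1 else data.shape[1])
    n, d = X.shape
    if c < 1:
        raise ValueError("need at least one component")
    if c > n:
        raise ValueError(f"more components ({c}) than cases ({n})")

    if c == 1:
        # closed form: a single M-step on uniform responsibilities
        mean = X.mean(axis=0)
        cov = _mle_cov(X, mean, d)
        comp = GaussianComponent(0, mean, cov if d > 1 else float(np.sqrt(cov)), 1.0)
        model = BayesModel([comp])
        ll = float(np.mean(model.log_evidence(X)))
        model.fit_info = EMFitInfo(
            log_likelihood=ll, trajectory=np.array([ll]), n_iter=1,
            converged=True, n_restarts=0, seed=seed,
        )
        return model

    rng = np.random.default_rng(seed)
    best = None
    for restart in range(max(1, n_restarts)):
        run_seed = int(rng.integers(2**31))
        run = _em_single_run(X, c, run_seed, tol, max_iter)
        if best is None or run["ll"] > best["ll"]:
            best = run

    order = np.argsort(best["means"][:, 0])  # stable label order along feature 0
    comps = []
    for new_label, k in enumerate(order):
        disp = best["covs"][k] if d > 1 else float(np.sqrt(best["covs"][k][0, 0]))
        comps.append(
            GaussianComponent(new_label, best["means"][k], disp, best["weights"][k])
        )
    # renormalise away accumulated rounding in the weights
    total = sum(cp.weight for cp in comps)
    for cp in comps:
        cp.weight /= total
    model = BayesModel(comps)
    model.fit_info = EMFitInfo(
        log_likelihood=best["ll"],
        trajectory=np.asarray(best["traj"]),
        n_iter=len(best["traj"]),
        converged=best["converged"],
        n_restarts=max(1, n_restarts),
        seed=seed,
        ridge_used=best["ridge_used"],
    )
    return model


def _em_single_run(X: np.ndarray, c: int, seed: int, tol: float, max_iter: int) -> dict:
    n, d = X.shape
    centers, _ = kmeans_plusplus(X, n_clusters=c, random_state=seed)
    # hard-assign to the nearest seed, then one M-step to initialise
    dist = np.linalg.norm(X[:, None, :] - centers[None, :, :], axis=2)
    resp = np.zeros((n, c))
    resp[np.arange(n), dist.argmin(axis=1)] = 1.0
    weights, means, covs, ridge_used = _m_step(X, resp, d)

    traj = []
    prev_ll = -np.inf
    converged = False
    for _ in range(max_iter):
        log_resp, ll = _e_step(X, weights, means, covs)
        traj.append(ll)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * abs(prev_ll):
            converged = True
            break
        prev_ll = ll
        w, m, cv, ridge = _m_step(X, np.exp(log_resp), d)
        weights, means, covs = w, m, cv
        ridge_used = ridge_used or ridge
    return {
        "ll": traj[-1], "traj": traj, "weights": weights, "means": means,
        "covs": covs, "converged": converged, "ridge_used": ridge_used,
    }


def _e_step(X, weights, means, covs):
    n, d = X.shape
    c = len(weights)
    log_joint = np.empty((n, c))
    for k in range(c):
        log_joint[:, k] = np.log(weights[k]) + _mvn_logpdf(X, means[k], covs[k])
    log_ev = logsumexp(log_joint, axis=1)
    return log_joint - log_ev[:, None], float(np.mean(log_ev))


def _m_step(X, resp, d):
    nk = resp.sum(axis=0) + 1e-300
    weights = nk / resp.shape[0]
    means = (resp.T @ X) / nk[:, None]
    covs = []
    ridge_used = False
    for k in range(len(nk)):
        diff = X - means[k]
        cov = (resp[:, k][:, None] * diff).T @ diff / nk[k]
        try:
            np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            cov = cov + np.eye(d) * (1e-6 * np.trace(cov) / d + 1e-12)
            ridge_used = True
        covs.append(cov)
    return weights, means, np.array(covs), ridge_used


def _mvn_logpdf(X, mean, cov):
    d = X.shape[1]
    chol = np.linalg.cholesky(cov)
    diff = X - mean
    y = np.linalg.solve(chol, diff.T)
    maha = np.sum(y * y, axis=0)
    log_det = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * np.log(2 * np.pi) + log_det + maha)


def _mle_cov(X, mean, d):
    diff = X - mean
    cov = diff.T @ diff / X.shape[0]
    if d == 1:
        return float(cov[0, 0])
    return cov
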