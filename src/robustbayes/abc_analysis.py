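"""Computed ABC analysis and the low-evidence threshold ε.

ABC analysis is a Pareto-type partition of a set of positive values
into the "important few" (set A, the largest values), a break-even set
B, and the "trivial many" (set C, the smallest values).  Applied to
evidence values, the value at the B–C boundary is the threshold ε below
which a Bayes decision is considered to rest on too little evidence.

Construction used here
----------------------
Values are sorted descending.  The *effort/yield* curve plots the
fraction of items against the cumulative share of the total.  The B–C
limit is the break-even point: the last item whose per-item slope
(value divided by the mean of all values) is still at least one — past
it, an item contributes less share than the effort of including it.
ε is the first value past break-even (the largest value in set C);
downstream comparison is strict, ``evidence < ε``.  The A–B limit is
the curve point closest to the ideal (0, 1); it is reported for
completeness but unused by the classifier.

For a normal distribution, ε computed from pdf values on a wide
equidistant grid captures roughly the central ±2 s; the alternative
"1% of the maximum evidence" rule captures ±3.035 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .components import BayesModel

__all__ = [
    "ABCCurve",
    "ABCLimits",
    "abc_curve",
    "abc_limits",
    "compute_epsilon",
    "evidence_grid",
    "evidence_threshold",
]


@dataclass
class ABCCurve:
    """Descending values with their effort/yield curve points."""

    values: np.ndarray  # sorted descending
    effort: np.ndarray  # i/n, i = 1..n
    yield_: np.ndarray  # cumulative value share

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class ABCLimits:
    """Set boundaries of an ABC partition and the threshold ε.

    ``ab_index`` and ``bc_index`` are item *counts*: set A is
    ``values[:ab_index]``, set B is ``values[ab_index:bc_index]`` and
    set C is ``values[bc_index:]`` on the descending-sorted values.
    """

    ab_index: int
    bc_index: int
    epsilon: float
    curve: ABCCurve

    @property
    def set_sizes(self) -> tuple[int, int, int]:
        n = self.curve.n
        return (self.ab_index, self.bc_index - self.ab_index, n - self.bc_index)


def abc_curve(values) -> ABCCurve:
    """Effort/yield curve of a set of positive values (order irrelevant)."""
    vals = np.asarray(values, dtype=float).ravel()
    if vals.size < 2:
        raise ValueError("ABC analysis needs at least two values")
    if not np.all(np.isfinite(vals)) or np.any(vals <= 0.0):
        raise ValueError("ABC analysis requires strictly positive finite values")
    svals = np.sort(vals)[::-1]
    n = svals.size
    effort = np.arange(1, n + 1) / n
    yield_ = np.cumsum(svals) / svals.sum()
    return ABCCurve(values=svals, effort=effort, yield_=yield_)


def abc_limits(curve: ABCCurve) -> ABCLimits:
    """Set boundaries from the curve.

    B|C: the last item with value >= the mean of all values (per-item
    slope of the piecewise-linear yield curve >= 1).  A|B: the curve
    point with minimal Euclidean distance to the ideal point (0, 1).
    With all values equal, set C is empty and ε is the common value, so
    a strict comparison downstream flags nothing.
    """
    svals = curve.values
    n = curve.n
    mean = svals.mean()
    at_least_break_even = np.nonzero(svals >= mean)[0]
    bc_index = int(at_least_break_even[-1]) + 1 if at_least_break_even.size else 0

    d2 = curve.effort**2 + (1.0 - curve.yield_) ** 2
    ab_index = int(np.argmin(d2)) + 1
    ab_index = min(ab_index, bc_index)  # keep A ⊆ A∪B even in degenerate data

    epsilon = float(svals[bc_index]) if bc_index < n else float(svals[-1])
    return ABCLimits(ab_index=ab_index, bc_index=bc_index, epsilon=epsilon, curve=curve)


def compute_epsilon(evidences, method: str = "abc", fraction: float = 0.01) -> float:
    """Low-evidence threshold from a set of positive evidence values.

    method="abc": ε is the B–C limit of the computed ABC analysis.
    method="fraction": ε = ``fraction`` · max(evidences) (default 1%).
    """
    vals = np.asarray(evidences, dtype=float).ravel()
    if vals.size == 0:
        raise ValueError("no evidence values given")
    if method == "abc":
        return abc_limits(abc_curve(vals)).epsilon
    if method == "fraction":
        if not (0.0 < fraction < 1.0):
            raise ValueError(f"fraction {fraction} outside (0, 1)")
        if not np.all(np.isfinite(vals)) or np.any(vals <= 0.0):
            raise ValueError("evidence values must be positive and finite")
        return float(fraction * vals.max())
    raise ValueError(f"unknown method {method!r}")


def evidence_grid(
    model: BayesModel,
    data=None,
    padding: float = 1.0,
    n_points: int | None = None,
) -> np.ndarray:
    """Model evidence at equidistant supporting points over the data range.

    The range of interest is the per-feature data range, padded by
    ``padding`` times the largest component SD in that feature (with no
    data, the range of the component means padded by five SDs).  In one
    dimension the grid has ``n_points`` (default 1000) points; in ``d``
    dimensions it is a mesh with roughly ``n_points`` points in total
    (default 128 per axis in 2-D).
    """
    d = model.dim
    smax = np.sqrt(np.stack([np.diag(c.cov) for c in model.components])).max(axis=0)
    if data is not None:
        arr = np.asarray(data, dtype=float)
        if arr.ndim == 1:
            arr = arr.reshape(-1, 1)
        lo = arr.min(axis=0) - padding * smax
        hi = arr.max(axis=0) + padding * smax
    else:
        means = model.means
        lo = means.min(axis=0) - 5.0 * smax
        hi = means.max(axis=0) + 5.0 * smax

    if d == 1:
        m = 1000 if n_points is None else int(n_points)
        grid = np.linspace(lo[0], hi[0], m).reshape(-1, 1)
    else:
        per_axis = (
            max(8, int(round((16384 if n_points is None else n_points) ** (1.0 / d))))
        )
        axes = [np.linspace(lo[k], hi[k], per_axis) for k in range(d)]
        grid = np.stack(np.meshgrid(*axes), axis=-1).reshape(-1, d)
    return model.evidence(grid)


def evidence_threshold(
    model: BayesModel,
    data=None,
    method: str = "abc",
    fraction: float = 0.01,
    source: str = "grid",
    padding: float = 1.0,
    n_points: int | None = None,
) -> float:
    """ε for a model, from grid evidence (default) or empirical evidence.

    ``source="grid"`` evaluates the evidence at equidistant supporting
    points over the padded data range; ``source="empirical"`` uses the
    evidence values of the cases themselves.
    """
    if source == "grid":
        vals = evidence_grid(model, data=data, padding=padding, n_points=n_points)
    elif source == "empirical":
        if data is None:
            raise ValueError("empirical evidence source needs data")
        vals = model.evidence(np.asarray(data, dtype=float))
    else:
        raise ValueError(f"unknown evidence source {source!r}")
    vals = vals[vals > 0.0]  # grid corners can underflow; ABC needs positives
    return compute_epsilon(vals, method=method, fraction=fraction)
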