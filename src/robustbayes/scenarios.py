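"""Seeded generators for the three worked example scenarios.

``generate_heights``   — two close univariate Gaussians (heights of
11-year-old girls and boys) plus 16 arbitrary grid heights between 140
and 170 cm; the textbook case where the class with the smaller mean has
the larger SD, so plain Bayes calls the far right tail "girls".

``generate_biomarker`` — serum concentrations of the ceramide C18Cer
for patients with multiple sclerosis versus healthy controls; same
pathology of means and SDs, with the paper's printed group sizes.
Negative concentrations are possible under the Gaussian model and are
deliberately not truncated.

``generate_cytometry`` — a 2-D three-component mixture mimicking a
CD45/CD13 flow-cytometry panel: one broad double-negative population
and two tighter CD45+ populations.  The parameters are documented
constants chosen to reproduce the qualitative geometry (the broad
class-1 component has a generalized variance 16 times that of the
other two, and a nonempty set of class-2/3 tail events attains higher
weighted likelihood under class 1 — the misassignment mechanism the
robust rules target).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .components import BayesModel, GaussianComponent

__all__ = ["ScenarioDataset", "generate_heights", "generate_biomarker",
           "generate_cytometry", "SCENARIOS"]

# printed population parameters: girls / boys, heights in cm
HEIGHTS_GIRLS = (149.8081, 0.5843)
HEIGHTS_BOYS = (151.0295, 0.5108)

# C18Cer serum concentration in ng/mL: patients / controls
C18CER_PATIENTS = (74.3881, 36.2643)
C18CER_CONTROLS = (86.8806, 29.8202)

# cytometry mixture constants (arbitrary marker units, CD45 then CD13)
CYTO_MEANS = ((0.0, 0.0), (8.0, 4.0), (8.0, 0.0))
CYTO_COVS = (
    ((4.0, 0.0), (0.0, 4.0)),   # class 1: CD45-/CD13-, broad
    ((1.0, 0.0), (0.0, 1.0)),   # class 2: CD45+/CD13+
    ((1.0, 0.0), (0.0, 1.0)),   # class 3: CD45+/CD13-
)
CYTO_WEIGHTS = (1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0)


@dataclass
class ScenarioDataset:
    """Synthetic cases with truth labels and the generating model."""

    name: str
    cases: np.ndarray            # (n, d)
    labels: np.ndarray           # (n,) object; None = no truth label
    model: BayesModel            # the generating model (also the classifier)
    seed: int | None
    feature_names: list

    @property
    def n_cases(self) -> int:
        return self.cases.shape[0]

    @property
    def labeled(self) -> np.ndarray:
        return np.array([lab is not None for lab in self.labels])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.cases, columns=self.feature_names)
        df["label"] = [lab if lab is not None else pd.NA for lab in self.labels]
        return df


def generate_heights(seed: int | None = None, n_per_sex: int = 100) -> ScenarioDataset:
    """Simulated heights: n draws per sex plus 16 arbitrary grid heights.

    Girls ~ N(149.8081, 0.5843), boys ~ N(151.0295, 0.5108); the grid
    holds the heights 140, 142, ..., 170 cm, which carry no truth label
    (they are observation points, not members of either group).
    """
    rng = np.random.default_rng(seed)
    girls = rng.normal(*HEIGHTS_GIRLS, size=n_per_sex)
    boys = rng.normal(*HEIGHTS_BOYS, size=n_per_sex)
    grid = np.arange(140.0, 171.0, 2.0)  # 16 values
    cases = np.concatenate([girls, boys, grid]).reshape(-1, 1)
    labels = np.array(
        ["girls"] * n_per_sex + ["boys"] * n_per_sex + [None] * grid.size,
        dtype=object,
    )
    model = BayesModel([
        GaussianComponent("girls", HEIGHTS_GIRLS[0], HEIGHTS_GIRLS[1], 0.5),
        GaussianComponent("boys", HEIGHTS_BOYS[0], HEIGHTS_BOYS[1], 0.5),
    ])
    return ScenarioDataset("heights", cases, labels, model, seed, ["height_cm"])


def generate_biomarker(
    seed: int | None = None, n_patients: int = 102, n_controls: int = 301
) -> ScenarioDataset:
    """C18Cer serum concentrations for patients and healthy controls."""
    rng = np.random.default_rng(seed)
    patients = rng.normal(*C18CER_PATIENTS, size=n_patients)
    controls = rng.normal(*C18CER_CONTROLS, size=n_controls)
    cases = np.concatenate([patients, controls]).reshape(-1, 1)
    labels = np.array(
        ["patients"] * n_patients + ["controls"] * n_controls, dtype=object
    )
    model = BayesModel([
        GaussianComponent("patients", C18CER_PATIENTS[0], C18CER_PATIENTS[1], 0.5),
        GaussianComponent("controls", C18CER_CONTROLS[0], C18CER_CONTROLS[1], 0.5),
    ])
    return ScenarioDataset("biomarker", cases, labels, model, seed,
                           ["c18cer_ng_ml"])


def generate_cytometry(seed: int | None = None, n: int = 20000) -> ScenarioDataset:
    """2-D three-population mixture mimicking a CD45/CD13 FACS panel.

    Class 1 (CD45−/CD13−) is broad; classes 2 (CD45+/CD13+) and 3
    (CD45+/CD13−) are tight.  Truth labels record the generating
    component of every event.
    """
    if n < 100:
        raise ValueError("cytometry scenario needs at least 100 events")
    rng = np.random.default_rng(seed)
    ks = rng.choice(3, size=n, p=np.asarray(CYTO_WEIGHTS))
    X = np.empty((n, 2))
    for k in range(3):
        mask = ks == k
        X[mask] = rng.multivariate_normal(
            np.asarray(CYTO_MEANS[k]), np.asarray(CYTO_COVS[k]), size=int(mask.sum())
        )
    labels = np.array([k + 1 for k in ks], dtype=object)
    model = BayesModel([
        GaussianComponent(k + 1, np.asarray(CYTO_MEANS[k]),
                          np.asarray(CYTO_COVS[k]), CYTO_WEIGHTS[k])
        for k in range(3)
    ])
    return ScenarioDataset("cytometry", X, labels, model, seed, ["CD45", "CD13"])


SCENARIOS = {
    "heights": generate_heights,
    "biomarker": generate_biomarker,
    "cytometry": generate_cytometry,
}
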