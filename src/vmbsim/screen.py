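"""Global probiotic strain screening and PLS-DA association analysis.

Candidate strains are Latin-Hypercube sampled over the same physiological
ranges as the virtual population's parameters -- with the single constraint
that the probiotic inhibits nAB (``a_P_to_nAB < 0``) -- and each is
evaluated across the whole virtual population under a regimen.  A strain's
*modal class* is the response type it elicits most frequently (ties resolve
toward nAB, the conservative failure call).  Partial least squares
discriminant analysis then relates the eight strain parameters to the modal
classes, and strains best matching clinically observed recurrence rates are
selected by absolute distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

from .classify import LABELS, CentroidSet
from .population import latin_hypercube
from .therapy import (
    DEFAULT_DOSE,
    ProbioticStrain,
    Regimen,
    STRAIN_PARAMS,
    evaluate_regimen,
    make_regimen,
)
from .population import VirtualPopulation

__all__ = [
    "ScreenResult",
    "LatentModel",
    "sample_strains",
    "screen_strains",
    "fit_plsda",
    "select_best_fit_strains",
    "CLINICAL_RECURRENCE",
]

#: Lactin-V phase 2b clinical BV recurrence rates (placebo-adjusted arm).
CLINICAL_RECURRENCE: dict[str, float] = {"12wk": 0.346, "24wk": 0.484}

#: LHS bounds for the 8 strain parameters, matching the population ranges;
#: a_P_to_nAB is constrained negative (a probiotic is selected to inhibit nAB).
STRAIN_BOUNDS: dict[str, tuple[float, float]] = {
    "k_grow": (0.1, 1.0),
    "alpha_self": (-0.04, -0.004),
    "a_nAB_to_P": (-0.04, 0.04),
    "a_Li_to_P": (-0.04, 0.04),
    "a_oLB_to_P": (-0.04, 0.04),
    "a_P_to_nAB": (-0.04, 0.0),
    "a_P_to_Li": (-0.04, 0.04),
    "a_P_to_oLB": (-0.04, 0.04),
}


def sample_strains(
    n_strains: int = 500, rng: np.random.Generator | int | None = None
) -> list[ProbioticStrain]:
    """LHS-sample candidate probiotic strains over the physiological bounds."""
    lower = np.array([STRAIN_BOUNDS[p][0] for p in STRAIN_PARAMS])
    upper = np.array([STRAIN_BOUNDS[p][1] for p in STRAIN_PARAMS])
    draws = latin_hypercube(lower, upper, n_strains, rng)
    return [
        ProbioticStrain(**dict(zip(STRAIN_PARAMS, map(float, row))), name=f"lhs_{i:04d}")
        for i, row in enumerate(draws)
    ]


@dataclass
class ScreenResult:
    """Per-strain response fractions and modal classes for one regimen."""

    strains: list[ProbioticStrain]
    regimen_name: str
    eval_times: np.ndarray
    labels: tuple[str, ...]
    fractions: np.ndarray  # (n_strains, n_times, n_labels)
    modal_classes: np.ndarray  # (n_strains,) object, from the last eval time
    n: int

    def parameter_matrix(self) -> pd.DataFrame:
        return pd.DataFrame(
            [s.as_array() for s in self.strains], columns=list(STRAIN_PARAMS)
        )

    def failure_rates(self, time: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.eval_times - time)))
        return self.fractions[:, i, self.labels.index("nAB")]

    def to_frame(self) -> pd.DataFrame:
        df = self.parameter_matrix()
        df.insert(0, "strain", [s.name for s in self.strains])
        i_last = len(self.eval_times) - 1
        for j, lab in enumerate(self.labels):
            df[f"frac_{lab}"] = self.fractions[:, i_last, j]
        df["modal_class"] = self.modal_classes
        return df


def modal_class(fractions: np.ndarray, labels: tuple[str, ...] = LABELS) -> str:
    """Most frequent response type; ties resolve by the nAB-first priority order."""
    return str(labels[int(np.argmax(fractions))])


def screen_strains(
    population: VirtualPopulation,
    regimen: Regimen | str = "short_term",
    n_strains: int = 500,
    rng: np.random.Generator | int | None = None,
    dose_amount: float = DEFAULT_DOSE,
    strains: list[ProbioticStrain] | None = None,
    centroids: CentroidSet | None = None,
    h: float = 0.01,
) -> ScreenResult:
    """Evaluate an LHS strain library across the population.

    The modal class of each strain is taken at the final evaluation
    timepoint of the regimen.
    """
    if isinstance(regimen, str):
        regimen = make_regimen(regimen, dose_amount=dose_amount)
    if strains is None:
        strains = sample_strains(n_strains, rng)
    fractions = []
    labels = LABELS
    for strain in strains:
        try:
            prof = evaluate_regimen(population, strain, regimen, centroids=centroids, h=h)
        except RuntimeError:
            # every patient diverged under this strain: a conservative failure
            fractions.append(
                np.tile(np.eye(len(labels))[0], (len(regimen.eval_times), 1))
            )
            continue
        fractions.append(prof.fractions)
        labels = prof.labels
    fractions = np.asarray(fractions)
    modal = np.array(
        [modal_class(fractions[i, -1], labels) for i in range(len(strains))],
        dtype=object,
    )
    return ScreenResult(
        list(strains),
        regimen.name,
        np.asarray(regimen.eval_times, dtype=float),
        tuple(labels),
        fractions,
        modal,
        len(population),
    )


@dataclass
class LatentModel:
    """PLS-DA latent space: loadings, scores and cross-validated accuracy."""

    classes: tuple[str, ...]
    feature_names: tuple[str, ...]
    loadings: pd.DataFrame  # features x LVs
    scores: np.ndarray  # (n, n_components)
    y_loadings: np.ndarray
    cv_accuracy: float
    n_components: int


def fit_plsda(
    X: np.ndarray | pd.DataFrame,
    classes,
    n_components: int = 2,
    n_folds: int = 10,
    rng_seed: int = 0,
) -> LatentModel:
    """Two-block PLS against one-hot class indicators (PLS-DA).

    Features are z-scored and the indicator block centered; scores/loadings
    come from the X block.  The cross-validated classification rate assigns
    each held-out strain to the class with the largest predicted indicator.
    """
    if isinstance(X, pd.DataFrame):
        feature_names = tuple(X.columns)
        X = X.to_numpy(float)
    else:
        X = np.asarray(X, float)
        feature_names = tuple(f"x{i}" for i in range(X.shape[1]))
    classes = np.asarray(classes, dtype=object)
    uniq = sorted(set(classes.tolist()), key=lambda c: LABELS.index(c) if c in LABELS else 99)
    if len(uniq) < 2:
        raise ValueError("PLS-DA requires at least two classes")
    Y = np.column_stack([(classes == c).astype(float) for c in uniq])

    n_components = min(n_components, X.shape[1])
    pls = PLSRegression(n_components=n_components, scale=True)
    pls.fit(X, Y)
    loadings = pd.DataFrame(
        pls.x_loadings_,
        index=list(feature_names),
        columns=[f"LV{i + 1}" for i in range(n_components)],
    )

    # stratified 10-fold CV classification rate
    counts = {c: int((classes == c).sum()) for c in uniq}
    folds = min(n_folds, min(counts.values()))
    if folds >= 2:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
        correct = 0
        for tr, te in skf.split(X, classes.astype(str)):
            m = PLSRegression(n_components=n_components, scale=True)
            m.fit(X[tr], Y[tr])
            pred = m.predict(X[te])
            correct += int((np.argmax(pred, axis=1) == np.argmax(Y[te], axis=1)).sum())
        cv_acc = correct / len(classes)
    else:
        cv_acc = float("nan")
    return LatentModel(
        tuple(uniq),
        feature_names,
        loadings,
        pls.x_scores_,
        pls.y_loadings_,
        cv_acc,
        n_components,
    )


def select_best_fit_strains(
    screen: ScreenResult,
    clinical_rates: dict[str, float] | None = None,
    k: int = 5,
) -> tuple[list[ProbioticStrain], np.ndarray]:
    """Strains whose predicted 12/24-week failure best matches the clinic.

    Distance is ``|pred_12 - obs_12| + |pred_24 - obs_24|``; returns the
    ``k`` closest strains and the full distance vector.
    """
    if clinical_rates is None:
        clinical_rates = CLINICAL_RECURRENCE
    if k > len(screen.strains):
        raise ValueError(f"k={k} exceeds the {len(screen.strains)} screened strains")
    if len(screen.eval_times) < 2:
        raise ValueError("screen must carry both 12- and 24-week evaluations")
    pred12 = screen.failure_rates(screen.eval_times[0])
    pred24 = screen.failure_rates(screen.eval_times[-1])
    dist = np.abs(pred12 - clinical_rates["12wk"]) + np.abs(pred24 - clinical_rates["24wk"])
    order = np.argsort(dist, kind="stable")
    return [screen.strains[i] for i in order[:k]], dist
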