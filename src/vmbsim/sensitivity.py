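"""Local one-at-a-time sensitivity analysis of probiotic strain parameters.

Each of the eight strain parameters is swept over its admissible range while
the others stay at the null reference strain; the population-level response
fractions at 12 months post-cessation quantify how much each parameter
matters.  Sensitivity is summarized with the normalized metric

    S = (dY / dP) * (P0 / Y0)

where Y is a response-type fraction, P the parameter value, and (P0, Y0) the
reference point.  For interspecies terms (null value 0) the reference is
P0 = +0.01 with Y0 the response there; for the growth rate and the
self-interaction the reference is the null strain's own value.  A
four-parameter full-factorial grid (3^4 = 81 combinations over the two
efficacy-driving and the two lactobacillus-steering interaction terms)
screens combinatorial designs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import LABELS, CentroidSet
from .population import VirtualPopulation
from .stats import bh_adjust, chi_square_frequency_test
from .therapy import (
    DEFAULT_DOSE,
    ProbioticStrain,
    Regimen,
    STRAIN_PARAMS,
    evaluate_regimen,
    make_regimen,
    make_strain,
)

__all__ = [
    "SensitivityResult",
    "normalized_sensitivity",
    "default_grid",
    "local_sweep_1d",
    "four_parameter_grid",
    "GRID4_PARAMETERS",
]

#: Default sweep bounds per parameter kind.
INTERSPECIES_RANGE = (-0.10, 0.10)
GROWTH_RANGE = (0.0, 1.0)
SELF_RANGE = (-0.04, -0.004)

#: Reference perturbation for interspecies terms (their null value is 0).
P0_INTERSPECIES = 0.01

_INTERSPECIES = tuple(p for p in STRAIN_PARAMS if p.startswith("a_") and p != "alpha_self")

GRID4_PARAMETERS: tuple[str, ...] = ("a_nAB_to_P", "a_P_to_nAB", "a_P_to_Li", "a_P_to_oLB")


def normalized_sensitivity(Y: float, Y0: float, P: float, P0: float) -> float:
    """Normalized local sensitivity ``((Y - Y0)/(P - P0)) * (P0/Y0)``.

    Returns ``nan`` when the reference response ``Y0`` is zero (the metric
    is undefined); raises for ``P == P0``.
    """
    if P == P0:
        raise ValueError("P must differ from the reference P0")
    if Y0 == 0:
        return float("nan")
    return (Y - Y0) / (P - P0) * (P0 / Y0)


def default_grid(parameter: str, n_points: int = 11) -> np.ndarray:
    if parameter == "k_grow":
        lo, hi = GROWTH_RANGE
    elif parameter == "alpha_self":
        lo, hi = SELF_RANGE
    elif parameter in _INTERSPECIES:
        lo, hi = INTERSPECIES_RANGE
    else:
        raise KeyError(f"unknown strain parameter {parameter!r}")
    return np.linspace(lo, hi, n_points)


@dataclass
class SensitivityResult:
    """1D sweep outcome: per-value response fractions and summary S per label."""

    parameter: str
    values: np.ndarray
    labels: tuple[str, ...]
    fractions: np.ndarray  # (n_values, n_labels)
    reference_value: float  # P0
    reference_fractions: np.ndarray  # Y0 per label
    sensitivity: dict[str, float]  # summary S per label (regression slope)
    pointwise: pd.DataFrame  # tidy: parameter, value, label, fraction, S

    def to_frame(self) -> pd.DataFrame:
        return self.pointwise.copy()


def _sweep_profiles(
    population: VirtualPopulation,
    base_strain: ProbioticStrain,
    parameter: str,
    values: np.ndarray,
    regimen: Regimen,
    eval_time: float,
    centroids: CentroidSet | None,
    h: float,
) -> np.ndarray:
    fracs = []
    for val in values:
        strain = replace(base_strain, **{parameter: float(val)})
        prof = evaluate_regimen(population, strain, regimen, centroids=centroids, h=h)
        i = int(np.argmin(np.abs(prof.eval_times - eval_time)))
        fracs.append(prof.fractions[i])
    return np.asarray(fracs)


def local_sweep_1d(
    population: VirtualPopulation,
    parameter: str,
    grid: Sequence[float] | None = None,
    base_strain: ProbioticStrain | None = None,
    regimen: Regimen | None = None,
    eval_time: float | None = None,
    dose_amount: float = DEFAULT_DOSE,
    centroids: CentroidSet | None = None,
    h: float = 0.01,
) -> SensitivityResult:
    """Sweep one strain parameter, others fixed at the null reference strain.

    The default evaluation point is 12 months post-cessation of the
    short-term regimen.  The summary S per response label is the
    least-squares slope of fraction vs parameter over the sweep, scaled by
    ``P0/Y0`` (robust to the exact grid spacing); per-value endpoint S
    values are reported alongside.
    """
    if base_strain is None:
        base_strain = make_strain("null")
    if regimen is None:
        regimen = make_regimen("short_term", dose_amount=dose_amount)
    if eval_time is None:
        eval_time = regimen.eval_times[-1]
    values = default_grid(parameter) if grid is None else np.asarray(grid, dtype=float)
    if parameter == "alpha_self" and np.any(values >= 0):
        raise ValueError("self-interaction sweep values must be negative")

    if parameter in _INTERSPECIES:
        p0 = P0_INTERSPECIES
    else:
        p0 = float(getattr(base_strain, parameter))
    sweep_vals = values.copy()
    if not np.any(np.isclose(sweep_vals, p0)):
        sweep_vals = np.sort(np.append(sweep_vals, p0))
    fracs = _sweep_profiles(
        population, base_strain, parameter, sweep_vals, regimen, eval_time, centroids, h
    )
    labels = LABELS if centroids is None else tuple(centroids.labels)
    i0 = int(np.argmin(np.abs(sweep_vals - p0)))
    y0 = fracs[i0]

    sens: dict[str, float] = {}
    rows = []
    dp = sweep_vals - float(np.mean(sweep_vals))
    for j, lab in enumerate(labels):
        slope = float(np.sum(dp * (fracs[:, j] - fracs[:, j].mean())) / np.sum(dp**2))
        sens[lab] = slope * p0 / y0[j] if y0[j] > 0 else float("nan")
        for val, f in zip(sweep_vals, fracs[:, j]):
            s_pt = (
                normalized_sensitivity(f, y0[j], val, p0)
                if not np.isclose(val, p0)
                else 0.0
            )
            rows.append(
                {"parameter": parameter, "value": val, "label": lab, "fraction": f, "S": s_pt}
            )
    return SensitivityResult(
        parameter,
        sweep_vals,
        tuple(labels),
        fracs,
        p0,
        y0,
        sens,
        pd.DataFrame(rows),
    )


def four_parameter_grid(
    population: VirtualPopulation,
    base_strain: ProbioticStrain | None = None,
    values: Sequence[float] = (-0.01, 0.0, +0.01),
    regimen: Regimen | None = None,
    eval_time: float | None = None,
    dose_amount: float = DEFAULT_DOSE,
    centroids: CentroidSet | None = None,
    h: float = 0.01,
) -> pd.DataFrame:
    """Full-factorial 3^4 grid over the four driving interaction terms.

    Returns one row per combination with the response fractions at the
    evaluation time, ordered from lowest to highest failure rate, plus a
    chi-square test (BH-adjusted) of each row's failure count against the
    all-zero (null-strain) row.
    """
    if base_strain is None:
        base_strain = make_strain("null")
    if regimen is None:
        regimen = make_regimen("short_term", dose_amount=dose_amount)
    if eval_time is None:
        eval_time = regimen.eval_times[-1]
    rows = []
    for combo in product(values, repeat=len(GRID4_PARAMETERS)):
        strain = replace(base_strain, **dict(zip(GRID4_PARAMETERS, map(float, combo))))
        prof = evaluate_regimen(population, strain, regimen, centroids=centroids, h=h)
        i = int(np.argmin(np.abs(prof.eval_times - eval_time)))
        row = dict(zip(GRID4_PARAMETERS, combo))
        for lab, f in zip(prof.labels, prof.fractions[i]):
            row[lab] = f
        row["n"] = prof.n
        rows.append(row)
    df = pd.DataFrame(rows)
    null_row = df.loc[(df[list(GRID4_PARAMETERS)] == 0).all(axis=1)].iloc[0]
    a_succ, a_n = int(round(null_row["nAB"] * null_row["n"])), int(null_row["n"])
    pvals = []
    for _, r in df.iterrows():
        b_succ, b_n = int(round(r["nAB"] * r["n"])), int(r["n"])
        if a_succ == b_succ and a_n == b_n:
            pvals.append(1.0)
        else:
            try:
                pvals.append(chi_square_frequency_test(a_succ, a_n, b_succ, b_n)[1])
            except ValueError:
                pvals.append(float("nan"))

    df["p_vs_null"] = pvals
    finite = np.isfinite(df["p_vs_null"].to_numpy())
    adj = np.full(len(df), np.nan)
    adj[finite] = bh_adjust(df.loc[finite, "p_vs_null"].to_numpy())
    df["p_adj"] = adj
    return df.sort_values("nAB", kind="stable").reset_index(drop=True)
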