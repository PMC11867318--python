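"""Probiotic strains, treatment regimens, and population-level evaluation.

A probiotic strain is the set of seven gLV parameters tied to the fourth
species P: its growth rate, self-interaction, and the six cross terms with
the resident groups.  A regimen is a dose schedule (instantaneous boluses of
P), optional antibiotic windows (first-order nAB kill), and evaluation
timepoints.  Evaluating a regimen across a virtual population yields a
response profile: the fraction of patients classified nAB-, Li-, oLB- or
P-dominant at each evaluation time.  The nAB-dominant fraction is the
treatment failure (BV recurrence) rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .classify import LABELS, CentroidSet, default_centroids
from .model import (
    NAB,
    PROB,
    AntibioticWindow,
    DoseEvent,
    GLVParameters,
    simulate_batch,
)
from .population import VirtualPopulation

logger = logging.getLogger(__name__)

__all__ = [
    "ProbioticStrain",
    "Regimen",
    "ResponseProfile",
    "STRAIN_LIBRARY",
    "make_strain",
    "make_regimen",
    "assemble_parameters",
    "evaluate_regimen",
    "calibrate_dose",
    "sweep_dose_frequency",
    "sweep_dose_amount",
    "DEFAULT_DOSE",
    "FREQUENCY_VARIANTS",
]

#: Default bolus size (density units).  Stand-in calibration: the null
#: strain's carrying capacity 0.5 / 0.022; use :func:`calibrate_dose` to set
#: the dose from a population instead.
DEFAULT_DOSE = 0.5 / 0.022

#: Moderate metronidazole kill rate for nAB (mean reported decay), d^-1.
K_KILL_MODERATE = -2.64
#: Strong kill rate (most sensitive G. vaginalis strain), d^-1.
K_KILL_STRONG = -3.82

STRAIN_PARAMS: tuple[str, ...] = (
    "k_grow",
    "alpha_self",
    "a_nAB_to_P",
    "a_Li_to_P",
    "a_oLB_to_P",
    "a_P_to_nAB",
    "a_P_to_Li",
    "a_P_to_oLB",
)


@dataclass(frozen=True)
class ProbioticStrain:
    """Seven gLV parameters describing a candidate probiotic strain.

    ``a_X_to_P`` terms are the effects of resident X on the probiotic and
    ``a_P_to_X`` the effects of the probiotic on resident X
    (density^-1 d^-1).
    """

    k_grow: float = 0.5
    alpha_self: float = -0.022
    a_nAB_to_P: float = 0.0
    a_Li_to_P: float = 0.0
    a_oLB_to_P: float = 0.0
    a_P_to_nAB: float = 0.0
    a_P_to_Li: float = 0.0
    a_P_to_oLB: float = 0.0
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.k_grow > 0 and self.alpha_self >= 0:
            raise ValueError("alpha_self must be negative when k_grow > 0")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, p) for p in STRAIN_PARAMS], dtype=float)


def _null(**kw) -> dict:
    base = dict(k_grow=0.5, alpha_self=-0.022)
    base.update(kw)
    return base


#: Named strains used throughout the study.  The "1p/2p/3p best" family
#: comes from the four-parameter sensitivity analysis; the oLB family boosts
#: endogenous optimal lactobacilli; the "lv_*" family benchmarks the
#: Lactin-V (L. crispatus CTV-05) phase 2b trial, with cross terms scaled to
#: the fixed -0.012 inhibition of nAB by the probiotic.
STRAIN_LIBRARY: dict[str, dict] = {
    "null": _null(),
    "traditional": _null(a_P_to_nAB=-0.01),
    "1p_best": _null(a_nAB_to_P=+0.01),
    "2p_best": _null(a_nAB_to_P=+0.01, a_P_to_nAB=-0.01),
    "3p_best": _null(a_nAB_to_P=+0.01, a_P_to_nAB=-0.01, k_grow=0.51),
    "2p_counter": _null(a_nAB_to_P=-0.01, a_P_to_nAB=-0.01),
    "1p_olb": _null(a_P_to_oLB=+0.05),
    "2p_olb": _null(a_P_to_oLB=+0.05, a_P_to_nAB=-0.05),
    "3p_olb": _null(a_P_to_oLB=+0.05, a_P_to_Li=-0.05, a_P_to_nAB=-0.05),
    "lv_traditional": _null(a_P_to_nAB=-0.012),
    "lv_null": _null(),
}


def _normalize(name: str) -> str:
    return (
        name.strip().lower().replace("-", "_").replace(":", "_").replace(" ", "").replace("__", "_")
    )


def make_strain(
    name: str | None = None,
    competition_reading: str = "p_to_nab",
    **overrides,
) -> ProbioticStrain:
    """Build a strain from the library and/or explicit parameter overrides.

    The Lactin-V "moderate"/"bad" strains carry strong competition with the
    endogenous lactobacilli at three times a reference strength.  Under the
    default reading (``competition_reading='p_to_nab'``) the reference is
    the fixed -0.012 inhibition of nAB by the probiotic, giving -0.036 on
    all four Li/oLB <-> P cross terms; the alternative reading
    (``'nab_to_p'``) scales the strain's own ``a_nAB_to_P`` instead.
    """
    params: dict = {}
    if name is not None:
        key = _normalize(name)
        if key in ("lv_moderate", "lv_bad"):
            if competition_reading == "p_to_nab":
                comp = -3 * 0.012
            elif competition_reading == "nab_to_p":
                comp = -3 * (0.006 if key == "lv_moderate" else 0.012)
            else:
                raise ValueError("competition_reading must be 'p_to_nab' or 'nab_to_p'")
            if key == "lv_moderate":
                params = _null(a_P_to_nAB=-0.012, a_nAB_to_P=-0.006)
            else:
                params = _null(a_P_to_nAB=-0.006, a_nAB_to_P=-0.012)
            params.update(
                a_P_to_Li=comp, a_P_to_oLB=comp, a_Li_to_P=comp, a_oLB_to_P=comp
            )
        elif key in STRAIN_LIBRARY:
            params = dict(STRAIN_LIBRARY[key])
        else:
            known = sorted(STRAIN_LIBRARY) + ["lv_moderate", "lv_bad"]
            raise KeyError(f"unknown strain {name!r}; library: {', '.join(known)}")
        params["name"] = key
    elif not overrides:
        raise ValueError("either a strain name or parameter overrides are required")
    params.update(overrides)
    params.setdefault("name", "custom")
    return ProbioticStrain(**params)


@dataclass(frozen=True)
class Regimen:
    """Dose schedule, antibiotic windows and evaluation timepoints (days)."""

    name: str
    dose_times: tuple[float, ...]
    dose_amount: float
    windows: tuple[AntibioticWindow, ...]
    eval_times: tuple[float, ...]  # absolute days from treatment start
    cessation: float  # end of all therapy, days from treatment start

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.eval_times):
            raise ValueError("evaluation timepoints must be >= 0")
        if self.dose_amount < 0:
            raise ValueError("dose amount must be >= 0")

    @property
    def doses(self) -> list[DoseEvent]:
        return [DoseEvent(t, self.dose_amount) for t in self.dose_times]

    @property
    def horizon(self) -> float:
        times = (self.cessation, *self.eval_times, *self.dose_times)
        return max(times)

    def with_dose_amount(self, amount: float) -> "Regimen":
        return replace(self, dose_amount=float(amount))


#: Intermittent-phase dosing intervals (days) for the Lactin-V variants.
FREQUENCY_VARIANTS: dict[str, float] = {
    "biweekly": 14.0,
    "weekly": 7.0,
    "twice_weekly": 3.5,
    "four_weekly": 1.75,
    "daily": 1.0,
}

_SHORT_TERM_OFFSETS = (0.0, 7.0, 30.0, 90.0, 180.0, 365.0)  # post-cessation


def make_regimen(
    name: str,
    dose_amount: float = DEFAULT_DOSE,
    k_kill: float = K_KILL_MODERATE,
    frequency: str = "twice_weekly",
    eval_offsets: Sequence[float] | None = None,
) -> Regimen:
    """Construct a named regimen.

    - ``short_term``: 7 once-daily probiotic doses (days 0-6), evaluated at
      cessation (day 7) and 1 wk, 1/3/6/12 months post-cessation.
    - ``abx_only``: 7-day antibiotic window, no probiotic.
    - ``abx_then_probiotic``: 7-day antibiotic window followed by 7 daily doses.
    - ``lactin_v``: 5-day antibiotic window, 4 once-daily doses, then 10
      weeks of intermittent dosing (default twice weekly), evaluated at
      weeks 12 and 24 of the trial clock (days 89 and 173; week 12 falls one
      week after therapy cessation on day 82).  ``frequency`` selects the
      intermittent-phase schedule.
    """
    key = _normalize(name)
    if key == "short_term":
        cess = 7.0
        offs = _SHORT_TERM_OFFSETS if eval_offsets is None else tuple(eval_offsets)
        return Regimen(
            key,
            tuple(float(t) for t in range(7)),
            dose_amount,
            (),
            tuple(cess + o for o in offs),
            cess,
        )
    if key == "abx_only":
        cess = 7.0
        offs = (0.0, 30.0, 90.0, 180.0, 365.0) if eval_offsets is None else tuple(eval_offsets)
        return Regimen(
            key, (), 0.0, (AntibioticWindow(0.0, 7.0, k_kill),), tuple(cess + o for o in offs), cess
        )
    if key == "abx_then_probiotic":
        cess = 14.0
        offs = (0.0, 30.0, 90.0, 180.0, 365.0) if eval_offsets is None else tuple(eval_offsets)
        return Regimen(
            key,
            tuple(7.0 + t for t in range(7)),
            dose_amount,
            (AntibioticWindow(0.0, 7.0, k_kill),),
            tuple(cess + o for o in offs),
            cess,
        )
    if key in ("lactin_v", "lactin_v_variant"):
        if frequency not in FREQUENCY_VARIANTS:
            raise ValueError(
                f"unknown dosing frequency {frequency!r}; options: {sorted(FREQUENCY_VARIANTS)}"
            )
        interval = FREQUENCY_VARIANTS[frequency]
        daily = tuple(5.0 + t for t in range(4))
        intermittent = tuple(12.0 + i * interval for i in range(int(round(70.0 / interval))))
        evals = (89.0, 173.0) if eval_offsets is None else tuple(eval_offsets)
        return Regimen(
            "lactin_v" if frequency == "twice_weekly" else f"lactin_v_{frequency}",
            daily + intermittent,
            dose_amount,
            (AntibioticWindow(0.0, 5.0, k_kill),),
            evals,
            82.0,
        )
    raise KeyError(
        f"unknown regimen {name!r}; options: short_term, abx_only, abx_then_probiotic, lactin_v"
    )


def assemble_parameters(
    population: VirtualPopulation, strain: ProbioticStrain
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Full 4-species parameter stack: resident block plus probiotic row/column.

    Returns ``(k_grow (n,4), alpha (n,4,4), x0 (n,4))`` with every patient
    started at its stable nAB-dominant fixed point and P absent.
    """
    n = len(population)
    k = np.zeros((n, 4))
    k[:, :3] = population.k_grow
    k[:, PROB] = strain.k_grow
    alpha = np.zeros((n, 4, 4))
    alpha[:, :3, :3] = population.alpha
    alpha[:, PROB, PROB] = strain.alpha_self
    alpha[:, PROB, NAB] = strain.a_nAB_to_P
    alpha[:, PROB, 1] = strain.a_Li_to_P
    alpha[:, PROB, 2] = strain.a_oLB_to_P
    alpha[:, NAB, PROB] = strain.a_P_to_nAB
    alpha[:, 1, PROB] = strain.a_P_to_Li
    alpha[:, 2, PROB] = strain.a_P_to_oLB
    x0 = np.zeros((n, 4))
    x0[:, :3] = population.initial
    if np.any(~np.isfinite(x0)):
        raise ValueError("population contains patients without a BV+ initial state")
    return k, alpha, x0


def patient_glv_parameters(patient_k, patient_alpha, strain: ProbioticStrain) -> GLVParameters:
    """Single-patient 4-species :class:`GLVParameters` (for trajectory work)."""
    k = np.zeros(4)
    k[:3] = patient_k
    k[PROB] = strain.k_grow
    a = np.zeros((4, 4))
    a[:3, :3] = patient_alpha
    a[PROB, PROB] = strain.alpha_self
    a[PROB, :3] = [strain.a_nAB_to_P, strain.a_Li_to_P, strain.a_oLB_to_P]
    a[:3, PROB] = [strain.a_P_to_nAB, strain.a_P_to_Li, strain.a_P_to_oLB]
    return GLVParameters(k, a)


@dataclass
class ResponseProfile:
    """Per-timepoint response-type frequencies over a virtual population."""

    eval_times: np.ndarray
    labels: tuple[str, ...]
    fractions: np.ndarray  # (n_times, n_labels); rows sum to 1
    n: int
    n_excluded: int = 0
    patient_labels: np.ndarray | None = None  # (n, n_times) object

    def fraction(self, label: str, time: float) -> float:
        i = int(np.argmin(np.abs(self.eval_times - time)))
        if abs(self.eval_times[i] - time) > 1e-6:
            raise KeyError(f"time {time} not evaluated")
        return float(self.fractions[i, self.labels.index(label)])

    def failure_rate(self, time: float | None = None) -> float:
        """nAB-dominant fraction at ``time`` (default: last evaluation point)."""
        t = self.eval_times[-1] if time is None else time
        return self.fraction("nAB", t)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.eval_times):
            for j, lab in enumerate(self.labels):
                rows.append({"timepoint": t, "label": lab, "fraction": self.fractions[i, j], "n": self.n})
        return pd.DataFrame(rows)


def evaluate_regimen(
    population: VirtualPopulation,
    strain: ProbioticStrain,
    regimen: Regimen,
    centroids: CentroidSet | None = None,
    h: float = 0.01,
) -> ResponseProfile:
    """Simulate a regimen for every patient and classify at each timepoint.

    Diverging patients (a rare event for strongly facilitative random
    parameter draws) are excluded from the frequencies and counted in
    ``n_excluded``.
    """
    if len(population) == 0:
        raise ValueError("population is empty")
    if centroids is None:
        centroids = default_centroids()
    k, alpha, x0 = assemble_parameters(population, strain)
    states, failed = simulate_batch(
        k, alpha, x0, regimen.doses, regimen.windows, regimen.eval_times, h=h
    )
    totals = states.sum(axis=2)
    dead = (totals <= 0) & ~np.isnan(totals)
    if dead.any():
        failed = failed | dead.any(axis=1)
    n_excl = int(failed.sum())
    if n_excl:
        logger.warning("%d/%d patients excluded (diverged or empty community)", n_excl, len(population))
    ok = ~failed
    n_ok = int(ok.sum())
    if n_ok == 0:
        raise RuntimeError("every patient simulation failed")
    labels = np.asarray(centroids.labels, dtype=object)
    m = len(regimen.eval_times)
    patient_labels = np.full((len(population), m), None, dtype=object)
    fractions = np.zeros((m, len(labels)))
    for i in range(m):
        rel = states[ok, i, :] / totals[ok, i][:, None]
        d2 = ((rel[:, None, :] - centroids.centroids[None, :, :]) ** 2).sum(axis=2)
        idx = np.argmin(d2, axis=1)
        patient_labels[ok, i] = labels[idx]
        fractions[i] = np.bincount(idx, minlength=len(labels)) / n_ok
    return ResponseProfile(
        np.asarray(regimen.eval_times, dtype=float),
        tuple(centroids.labels),
        fractions,
        n_ok,
        n_excl,
        patient_labels,
    )


def calibrate_dose(
    population: VirtualPopulation,
    strain: ProbioticStrain | None = None,
    target: float = 0.5,
    h: float = 0.01,
) -> float:
    """Dose amount at which the median probiotic relative abundance one day
    after a single dose equals ``target``.

    The original calibration anchored the dose to a clinically observed
    relative-abundance distribution that is not recoverable; this helper
    anchors it to a configurable target (default 0.5) using the null
    reference strain.
    """
    if strain is None:
        strain = make_strain("null")
    k, alpha, x0 = assemble_parameters(population, strain)

    def median_rel(dose: float) -> float:
        states, failed = simulate_batch(
            k, alpha, x0, [DoseEvent(0.0, dose)], (), [1.0], h=h
        )
        rel = states[~failed, 0, PROB] / states[~failed, 0, :].sum(axis=1)
        return float(np.median(rel))

    # upper bracket: P decays toward carrying capacity within a day anyway,
    # and the explicit step is only stable for |alpha_self| * dose * h < ~2
    lo, hi = 1e-6, min(1e6, 1.0 / (abs(strain.alpha_self) * h))
    f_lo, f_hi = median_rel(lo) - target, median_rel(hi) - target
    if f_lo * f_hi > 0:
        raise RuntimeError(
            "calibration target unreachable: the probiotic cannot reach the "
            f"requested relative abundance (attainable range ends at {f_hi + target:.3f})"
        )
    return float(brentq(lambda d: median_rel(d) - target, lo, hi, xtol=1e-3, rtol=1e-4))


def _failure_table(
    population: VirtualPopulation,
    strains: Sequence[ProbioticStrain],
    regimens: Mapping[str, Regimen],
    h: float,
    centroids: CentroidSet | None,
) -> pd.DataFrame:
    rows = []
    for strain in strains:
        for variant, reg in regimens.items():
            prof = evaluate_regimen(population, strain, reg, centroids=centroids, h=h)
            row = {"strain": strain.name, "variant": variant}
            for t in reg.eval_times:
                row[f"failure_{t:g}d"] = prof.failure_rate(t)
            rows.append(row)
    return pd.DataFrame(rows)


def sweep_dose_frequency(
    population: VirtualPopulation,
    strains: Sequence[ProbioticStrain],
    variants: Sequence[str] = tuple(FREQUENCY_VARIANTS),
    dose_amount: float = DEFAULT_DOSE,
    k_kill: float = K_KILL_MODERATE,
    h: float = 0.01,
    centroids: CentroidSet | None = None,
) -> pd.DataFrame:
    """Failure rates at weeks 12/24 for each strain x intermittent-phase frequency."""
    regs = {v: make_regimen("lactin_v", dose_amount, k_kill, frequency=v) for v in variants}
    return _failure_table(population, strains, regs, h, centroids)


def sweep_dose_amount(
    population: VirtualPopulation,
    strains: Sequence[ProbioticStrain],
    multipliers: Sequence[float] = (0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0),
    base_dose: float = DEFAULT_DOSE,
    k_kill: float = K_KILL_MODERATE,
    h: float = 0.01,
    centroids: CentroidSet | None = None,
) -> pd.DataFrame:
    """Failure rates at weeks 12/24 for each strain x dose multiplier."""
    regs = {
        f"x{m:g}": make_regimen("lactin_v", base_dose * m, k_kill) for m in multipliers
    }
    df = _failure_table(population, strains, regs, h, centroids)
    df["multiplier"] = df["variant"].str.lstrip("x").astype(float)
    return df


def summarize_sweep(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- sd of failure rates across strains, per variant."""
    cols = [c for c in table.columns if c.startswith("failure_")]
    return table.groupby("variant", sort=False)[cols].agg(["mean", "std"])
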