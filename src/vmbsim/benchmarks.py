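"""Headline treatment-study endpoints over a regenerated virtual population.

One call regenerates the full stated world -- 30,000-draw LHS pool,
HMP-matched resample of 2,000 BV+ patients, dose calibration -- and runs the
canonical strain/regimen experiments: the null and designed strains under
the 7-day short-term regimen, the antibiotic-only course, and the Lactin-V
regimen with its placebo and negative-control arms.  Returned fractions are
the raw population-level response frequencies used throughout the package.
"""

from __future__ import annotations

import numpy as np

from .experiments import stage_seeds
from .population import generate_population
from .therapy import calibrate_dose, evaluate_regimen, make_regimen, make_strain

__all__ = ["headline_results"]


def headline_results(
    seed: int,
    n_patients: int = 2_000,
    pool_size: int = 30_000,
    h: float = 0.01,
) -> dict[str, float]:
    """Compute the canonical endpoints; values are fractions in [0, 1].

    Keys
    ----
    - ``null_12mo``, ``traditional_1mo``, ``best_1p_12mo``, ``best_2p_12mo``,
      ``best_3p_12mo``, ``counter_2p_12mo``: nAB-dominant (failure) fraction
      under the short-term regimen at the named time post-cessation.
    - ``olb_3p_12mo_olb``: oLB-dominant fraction for the oLB-boosting
      3-parameter strain at 12 months.
    - ``abx_cessation``: failure at cessation of a 7-day antibiotic course.
    - ``lactin_v_placebo_12wk`` / ``24wk``: recurrence in the Lactin-V
      placebo arm (antibiotic only) at trial weeks 12 / 24.
    - ``lactin_v_bad_12wk``: recurrence for the negative-control strain
      under the full Lactin-V regimen at week 12.
    """
    pop_seed = stage_seeds(seed)[0]
    population = generate_population(pool_size=pool_size, n=n_patients, seed=pop_seed)
    dose = calibrate_dose(population, h=h)

    out: dict[str, float] = {}
    short = make_regimen("short_term", dose_amount=dose)

    def fail(profile, t):
        return float(profile.failure_rate(t))

    for key, strain, t in [
        ("null_12mo", "null", 372.0),
        ("traditional_1mo", "traditional", 37.0),
        ("best_1p_12mo", "1p_best", 372.0),
        ("best_2p_12mo", "2p_best", 372.0),
        ("best_3p_12mo", "3p_best", 372.0),
        ("counter_2p_12mo", "2p_counter", 372.0),
    ]:
        prof = evaluate_regimen(population, make_strain(strain), short, h=h)
        out[key] = fail(prof, t)

    prof = evaluate_regimen(population, make_strain("3p_olb"), short, h=h)
    out["olb_3p_12mo_olb"] = float(prof.fraction("oLB", 372.0))

    prof = evaluate_regimen(population, make_strain("null"), make_regimen("abx_only"), h=h)
    out["abx_cessation"] = fail(prof, 7.0)

    prof = evaluate_regimen(
        population, make_strain("null"), make_regimen("lactin_v", dose_amount=0.0), h=h
    )
    out["lactin_v_placebo_12wk"] = fail(prof, 89.0)
    out["lactin_v_placebo_24wk"] = fail(prof, 173.0)

    prof = evaluate_regimen(
        population, make_strain("lv_bad"), make_regimen("lactin_v", dose_amount=dose), h=h
    )
    out["lactin_v_bad_12wk"] = fail(prof, 89.0)

    out["n"] = n_patients
    out["dose"] = float(dose)
    return out
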