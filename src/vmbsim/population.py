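"""Virtual BV+ patient populations.

A virtual patient is a draw of resident-community gLV parameters (growth
rates and 3x3 interaction block for nAB, Li, oLB).  A large pool is produced
by Latin Hypercube Sampling of physiological parameter ranges; each draw is
characterized analytically by enumerating the fixed points of its 3-species
subsystem and testing their linear stability, and labelled by its "CST
equilibrium behavior" (mono-stable 1SS, bi-stable 2SS, ...).  The pool is
then resampled so the label frequencies match the clinically observed
distribution of BV-capable equilibrium behaviors in the Human Microbiome
Project cohort: 60% 1SS nAB, 31% 2SS nAB/Li, 9% 2SS nAB/oLB.

Each selected patient is BV positive: it admits a stable nAB-dominant state,
which (with the probiotic absent) is used as the initial condition for
treatment simulations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.stats import qmc

from .classify import CentroidSet, classify_compositions, default_centroids
from .model import NAB, LI, OLB, SPECIES

logger = logging.getLogger(__name__)

__all__ = [
    "RESIDENTS",
    "HMP_TARGET",
    "ParameterRanges",
    "default_ranges",
    "FixedPoint",
    "EquilibriumBehavior",
    "VirtualPatient",
    "VirtualPopulation",
    "latin_hypercube",
    "lhs_sample",
    "find_fixed_points",
    "classify_equilibrium_behavior",
    "generate_pool",
    "resample_population",
    "generate_population",
]

RESIDENTS: tuple[str, ...] = ("nAB", "Li", "oLB")
_N_RES = 3

#: Target distribution of BV-capable CST equilibrium behaviors (HMP cohort).
HMP_TARGET: dict[str, float] = {
    "1SS nAB": 0.60,
    "2SS nAB/Li": 0.31,
    "2SS nAB/oLB": 0.09,
}

#: Eigenvalue real parts must be below this for a point to count as stable.
STABILITY_TOL = -1e-9

#: Detection-limit seeding of subdominant residents in the initial state.
#: gLV extinction is absorbing, but clinically an nAB-dominant community
#: still harbours low-level lactobacilli (and vice versa); starting a
#: patient exactly on a boundary fixed point would freeze the species pool
#: and make multistable (2SS) patients unable to switch community state
#: under any therapy.  Residents below 1% of the community total are
#: therefore raised to that floor in the initial state.
SUBDOMINANT_FLOOR = 0.01


@dataclass
class ParameterRanges:
    """Sampling bounds for the 12 resident parameters.

    ``growth[i]`` bounds the intrinsic growth rate of resident ``i`` (d^-1);
    ``alpha[i, j]`` bounds the interaction coefficient alpha_{j->i}
    (density^-1 d^-1), diagonal entries being self-interactions.
    """

    growth: np.ndarray  # (3, 2) lower/upper
    alpha: np.ndarray  # (3, 3, 2) lower/upper

    def __post_init__(self) -> None:
        g = np.asarray(self.growth, dtype=float)
        a = np.asarray(self.alpha, dtype=float)
        if g.shape != (_N_RES, 2) or a.shape != (_N_RES, _N_RES, 2):
            raise ValueError("growth must be (3,2) and alpha (3,3,2)")
        if np.any(g[:, 0] > g[:, 1]) or np.any(a[..., 0] > a[..., 1]):
            raise ValueError("lower bounds must not exceed upper bounds")
        if np.any(np.diagonal(a[..., 1]) >= 0):
            raise ValueError("self-interaction upper bounds must be negative")
        self.growth, self.alpha = g, a

    @property
    def lower(self) -> np.ndarray:
        return np.concatenate([self.growth[:, 0], self.alpha[..., 0].ravel()])

    @property
    def upper(self) -> np.ndarray:
        return np.concatenate([self.growth[:, 1], self.alpha[..., 1].ravel()])

    @classmethod
    def from_yaml(cls, path) -> "ParameterRanges":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(np.asarray(data["growth"]), np.asarray(data["alpha"]))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"growth": self.growth.tolist(), "alpha": self.alpha.tolist()}, fh
            )


def default_ranges() -> ParameterRanges:
    """Physiological defaults for the resident community.

    Growth rates are uniform on [0.1, 1.0] d^-1 and self-interactions on
    [-0.04, -0.004] density^-1 d^-1 (in vitro-derived ranges scaled to in
    vivo rates).  Resident interspecies terms are sampled on the same
    in vivo-scaled envelope as the self-interactions, [-0.04, 0.04]:
    keeping cross terms on the intraspecific scale is what allows the
    clinically typical nAB-dominant *coexistence* states (subdominant
    lactobacilli persisting under BV) and keeps facilitative loops bounded
    -- cross terms much larger than every self term produce widespread
    competitive exclusion and finite-time blow-up of mutualistic pairs.
    The effects of the lactobacilli on nAB are restricted to be inhibitory
    (lactic acid / H2O2 / bacteriocin production), a directionality
    constraint applied at sampling; all other cross terms are free in sign.
    """
    growth = np.tile([0.1, 1.0], (_N_RES, 1))
    alpha = np.tile([-0.04, 0.04], (_N_RES, _N_RES, 1)).astype(float)
    for i in range(_N_RES):
        alpha[i, i] = [-0.04, -0.004]
    alpha[NAB, LI] = [-0.04, 0.0]  # Li -> nAB inhibitory
    alpha[NAB, OLB] = [-0.04, 0.0]  # oLB -> nAB inhibitory
    return ParameterRanges(growth, alpha)


def latin_hypercube(
    lower: np.ndarray,
    upper: np.ndarray,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Stratified uniform sample: one draw per equal-probability bin per margin.

    Degenerate dimensions (lower == upper) yield constant columns.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lower = np.atleast_1d(np.asarray(lower, dtype=float))
    upper = np.atleast_1d(np.asarray(upper, dtype=float))
    rng = np.random.default_rng(rng)
    sampler = qmc.LatinHypercube(d=lower.size, seed=rng)
    unit = sampler.random(n)
    return lower + unit * (upper - lower)


def lhs_sample(
    ranges: ParameterRanges, n: int, rng: np.random.Generator | int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` resident parameter sets; returns (growth (n,3), alpha (n,3,3))."""
    flat = latin_hypercube(ranges.lower, ranges.upper, n, rng)
    growth = flat[:, :_N_RES]
    alpha = flat[:, _N_RES:].reshape(n, _N_RES, _N_RES)
    return growth, alpha


@dataclass
class FixedPoint:
    """Equilibrium of the resident subsystem on a support of present species."""

    support: tuple[int, ...]
    abundances: np.ndarray
    stable: bool
    eigenvalues: np.ndarray | None = None


@dataclass
class EquilibriumBehavior:
    """CST equilibrium behavior label with the stable points behind it."""

    label: str
    stable_points: list[FixedPoint]


def _jacobian(k: np.ndarray, alpha: np.ndarray, x: np.ndarray) -> np.ndarray:
    f = k + alpha @ x
    return np.diag(f) + x[:, None] * alpha


def find_fixed_points(
    k: np.ndarray, alpha: np.ndarray, tol: float = 1e-9
) -> list[FixedPoint]:
    """Enumerate all non-negative equilibria of an m-species gLV system.

    For each support S the interior condition ``sum_{j in S} alpha[i, j] x_j
    = -k_i`` (i in S) is solved; solutions with strictly positive support
    abundances are kept, plus the extinction state.  Stability is linear:
    all Jacobian eigenvalues must have real part < -1e-9.
    """
    k = np.asarray(k, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    m = k.size
    points: list[FixedPoint] = []
    zero = np.zeros(m)
    ev0 = np.linalg.eigvals(_jacobian(k, alpha, zero))
    points.append(FixedPoint((), zero, bool(np.all(ev0.real < STABILITY_TOL)), ev0))
    for size in range(1, m + 1):
        for support in combinations(range(m), size):
            S = list(support)
            sub = alpha[np.ix_(S, S)]
            try:
                xs = np.linalg.solve(sub, -k[S])
            except np.linalg.LinAlgError:
                logger.info("singular interaction submatrix for support %s; skipped", support)
                continue
            if np.any(xs <= 0):
                continue
            x = np.zeros(m)
            x[S] = xs
            resid = np.abs(k[S] + (alpha @ x)[S])
            if np.any(resid > 1e-6 * max(1.0, np.abs(xs).max())):
                continue
            ev = np.linalg.eigvals(_jacobian(k, alpha, x))
            points.append(FixedPoint(support, x, bool(np.all(ev.real < STABILITY_TOL)), ev))
    return points


def _behavior_from_stable_points(
    stable_points: list[FixedPoint], centroids: CentroidSet
) -> EquilibriumBehavior:
    if not stable_points:
        logger.warning("no stable fixed point found; labelling 'other'")
        return EquilibriumBehavior("other", [])
    rel = []
    for fp in stable_points:
        x4 = np.zeros(4)
        x4[:_N_RES] = fp.abundances
        rel.append(x4 / x4.sum())
    labels = classify_compositions(np.asarray(rel), centroids)
    cats = sorted(set(labels), key=lambda s: RESIDENTS.index(s))
    if len(cats) == 1:
        label = f"1SS {cats[0]}"
    elif len(cats) == 2:
        label = f"2SS {cats[0]}/{cats[1]}"
    else:
        label = "other-multistable"
    return EquilibriumBehavior(label, stable_points)


def classify_equilibrium_behavior(
    k: np.ndarray, alpha: np.ndarray, centroids: CentroidSet | None = None
) -> EquilibriumBehavior:
    """Label a resident parameter set by the CSTs of its stable equilibria."""
    if centroids is None:
        centroids = default_centroids()
    pts = find_fixed_points(k, alpha)
    return _behavior_from_stable_points([p for p in pts if p.stable and p.support], centroids)


# ---------------------------------------------------------------------------
# Vectorized pool construction


def _fixed_point_analysis_batch(
    K: np.ndarray, A: np.ndarray, centroids: CentroidSet
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stable-point census for a stack of resident systems.

    Returns (labels (n,) object, bv_positive (n,) bool, initial (n,3)) where
    ``initial`` is the stable nAB-dominant point with the highest nAB
    abundance (nan rows where none exists).
    """
    n = K.shape[0]
    supports = [s for size in (1, 2, 3) for s in combinations(range(_N_RES), size)]
    cat_present = np.zeros((n, _N_RES), dtype=bool)
    n_stable = np.zeros(n, dtype=int)
    best_nab = np.full(n, -np.inf)
    initial = np.full((n, _N_RES), np.nan)
    for S in supports:
        S = list(S)
        sub = A[np.ix_(range(n), S, S)]
        det = np.linalg.det(sub)
        ok = np.abs(det) > 1e-12
        safe = np.where(ok[:, None, None], sub, np.eye(len(S)))
        xs = np.linalg.solve(safe, -K[:, S][..., None])[..., 0]
        feasible = ok & np.all(xs > 0, axis=1)
        if not feasible.any():
            continue
        x = np.zeros((n, _N_RES))
        x[:, S] = xs
        f = K + np.einsum("nij,nj->ni", A, x)
        J = np.zeros((n, _N_RES, _N_RES))
        J[:, np.arange(_N_RES), np.arange(_N_RES)] = f
        J += x[:, :, None] * A
        ev = np.linalg.eigvals(J[feasible])
        stable_f = np.all(ev.real < STABILITY_TOL, axis=1)
        stable = np.zeros(n, dtype=bool)
        stable[np.flatnonzero(feasible)[stable_f]] = True
        if not stable.any():
            continue
        idx = np.flatnonzero(stable)
        x4 = np.zeros((idx.size, 4))
        x4[:, :_N_RES] = x[idx]
        labels = classify_compositions(x4 / x4.sum(axis=1, keepdims=True), centroids)
        for c, name in enumerate(RESIDENTS):
            cat_present[idx[labels == name], c] = True
        n_stable[idx] += 1
        is_nab = labels == "nAB"
        nab_idx = idx[is_nab]
        better = x[nab_idx, NAB] > best_nab[nab_idx]
        upd = nab_idx[better]
        best_nab[upd] = x[upd, NAB]
        initial[upd] = x[upd]
    # seed subdominant residents at the detection-limit floor
    has_init = np.isfinite(initial[:, 0])
    totals = initial[has_init].sum(axis=1, keepdims=True)
    initial[has_init] = np.maximum(initial[has_init], SUBDOMINANT_FLOOR * totals)
    n_cats = cat_present.sum(axis=1)
    labels_out = np.empty(n, dtype=object)
    for i in range(n):
        if n_stable[i] == 0:
            labels_out[i] = "other"
        elif n_cats[i] == 1:
            labels_out[i] = f"1SS {RESIDENTS[int(np.flatnonzero(cat_present[i])[0])]}"
        elif n_cats[i] == 2:
            a, b = (RESIDENTS[j] for j in np.flatnonzero(cat_present[i]))
            labels_out[i] = f"2SS {a}/{b}"
        else:
            labels_out[i] = "other-multistable"
    return labels_out, cat_present[:, NAB], initial


@dataclass
class VirtualPatient:
    """Resident parameters plus equilibrium behavior and BV+ initial state."""

    id: int
    k_grow: np.ndarray  # (3,)
    alpha: np.ndarray  # (3, 3)
    behavior_label: str
    initial_state: np.ndarray  # (3,) stable nAB-dominant point, P absent

    @property
    def behavior(self) -> EquilibriumBehavior:
        return classify_equilibrium_behavior(self.k_grow, self.alpha)


@dataclass
class VirtualPopulation:
    """Column-oriented container for many virtual patients."""

    ids: np.ndarray
    k_grow: np.ndarray  # (n, 3)
    alpha: np.ndarray  # (n, 3, 3)
    labels: np.ndarray  # (n,) object
    initial: np.ndarray  # (n, 3)

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, i: int) -> VirtualPatient:
        return VirtualPatient(
            int(self.ids[i]),
            self.k_grow[i].copy(),
            self.alpha[i].copy(),
            str(self.labels[i]),
            self.initial[i].copy(),
        )

    def subset(self, idx) -> "VirtualPopulation":
        return VirtualPopulation(
            self.ids[idx], self.k_grow[idx], self.alpha[idx], self.labels[idx], self.initial[idx]
        )

    def label_frequencies(self) -> dict[str, float]:
        vals, counts = np.unique(self.labels.astype(str), return_counts=True)
        return {v: c / len(self) for v, c in zip(vals, counts)}

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, object] = {"id": self.ids}
        for i, sp in enumerate(RESIDENTS):
            cols[f"k_grow_{sp}"] = self.k_grow[:, i]
        for i, tgt in enumerate(RESIDENTS):
            for j, src in enumerate(RESIDENTS):
                cols[f"a_{src}_to_{tgt}"] = self.alpha[:, i, j]
        cols["behavior"] = self.labels.astype(str)
        for i, sp in enumerate(RESIDENTS):
            cols[f"x0_{sp}"] = self.initial[:, i]
        return pd.DataFrame(cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "VirtualPopulation":
        n = len(df)
        k = np.column_stack([df[f"k_grow_{sp}"] for sp in RESIDENTS])
        alpha = np.zeros((n, _N_RES, _N_RES))
        for i, tgt in enumerate(RESIDENTS):
            for j, src in enumerate(RESIDENTS):
                alpha[:, i, j] = df[f"a_{src}_to_{tgt}"]
        x0 = np.column_stack([df[f"x0_{sp}"] for sp in RESIDENTS])
        return cls(df["id"].to_numpy(), k, alpha, df["behavior"].to_numpy(object), x0)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "VirtualPopulation":
        return cls.from_frame(pd.read_csv(path))


#: Observation times (days) of the untreated-baseline screen: the standard
#: post-cessation readout grid of the regimens plus a one-year-plus endpoint.
BASELINE_SCREEN_TIMES: tuple[float, ...] = (7.0, 14.0, 37.0, 89.0, 97.0, 173.0, 187.0, 372.0, 400.0)


def _baseline_validity(
    K: np.ndarray,
    A: np.ndarray,
    initial: np.ndarray,
    centroids: CentroidSet,
    h: float = 0.01,
) -> np.ndarray:
    """Untreated-baseline screen for BV+ candidates.

    A virtual patient only counts as stably BV positive if, starting from
    its floored nAB-dominant state with no therapy, the community (a) stays
    bounded and (b) classifies nAB-dominant at every standard observation
    time over a year.  Random parameter draws can violate either:
    facilitative loops released by the detection-limit seeding may diverge,
    and a marginally stable nAB state may sit closer to the basin boundary
    than the floor perturbation.
    """
    from .model import simulate_batch  # deferred: avoids import cycle at module load

    idx = np.flatnonzero(np.isfinite(initial[:, 0]))
    ok = np.zeros(K.shape[0], dtype=bool)
    if idx.size == 0:
        return ok
    k4 = np.zeros((idx.size, 4))
    k4[:, :_N_RES] = K[idx]
    a4 = np.zeros((idx.size, 4, 4))
    a4[:, :_N_RES, :_N_RES] = A[idx]
    x0 = np.zeros((idx.size, 4))
    x0[:, :_N_RES] = initial[idx]
    states, failed = simulate_batch(
        k4, a4, x0, eval_times=BASELINE_SCREEN_TIMES, h=h
    )
    good = ~failed
    always_nab = good.copy()
    for j in range(len(BASELINE_SCREEN_TIMES)):
        totals = states[:, j, :].sum(axis=1)
        with np.errstate(invalid="ignore"):
            valid = good & np.isfinite(totals) & (totals > 0)
        labels = np.full(idx.size, "", dtype=object)
        labels[valid] = classify_compositions(
            states[valid, j, :] / totals[valid, None], centroids
        )
        always_nab &= labels == "nAB"
    ok[idx] = always_nab
    return ok


def generate_pool(
    ranges: ParameterRanges | None = None,
    n_pool: int = 30_000,
    rng: np.random.Generator | int | None = None,
    centroids: CentroidSet | None = None,
    validate_baseline: bool = True,
) -> VirtualPopulation:
    """LHS-sample a base pool and label every draw by equilibrium behavior.

    Draws with an nAB-dominant stable point additionally pass the untreated
    baseline screen (:func:`_baseline_validity`); the few that fail it are
    relabelled ``"other"`` and excluded from BV+ strata.
    """
    if ranges is None:
        ranges = default_ranges()
    if centroids is None:
        centroids = default_centroids()
    K, A = lhs_sample(ranges, n_pool, rng)
    labels, bv_pos, initial = _fixed_point_analysis_batch(K, A, centroids)
    if validate_baseline:
        valid = _baseline_validity(K, A, initial, centroids)
        bad = np.isfinite(initial[:, 0]) & ~valid
        if bad.any():
            logger.info(
                "%d/%d BV+ candidates failed the untreated-baseline screen",
                int(bad.sum()),
                int(np.isfinite(initial[:, 0]).sum()),
            )
            labels[bad] = "other"
            initial[bad] = np.nan
    return VirtualPopulation(np.arange(n_pool), K, A, labels, initial)


def resample_population(
    pool: VirtualPopulation,
    target_freqs: Mapping[str, float] | None = None,
    n: int = 2_000,
    rng: np.random.Generator | int | None = None,
) -> VirtualPopulation:
    """Stratified resample matching target label frequencies exactly.

    Per-label counts follow largest-remainder rounding of ``n * fraction``.
    Sampling is without replacement when the pool stratum suffices and with
    replacement otherwise (logged).
    """
    if target_freqs is None:
        target_freqs = HMP_TARGET
    rng = np.random.default_rng(rng)
    labels = list(target_freqs)
    fracs = np.array([target_freqs[l] for l in labels], dtype=float)
    fracs = fracs / fracs.sum()
    raw = n * fracs
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    picks = []
    for label, c in zip(labels, counts):
        stratum = np.flatnonzero(pool.labels.astype(str) == label)
        if stratum.size == 0:
            raise ValueError(f"pool contains no patients with label {label!r}")
        if stratum.size >= c:
            picks.append(rng.choice(stratum, size=c, replace=False))
        else:
            logger.warning(
                "stratum %r has %d candidates for %d slots; sampling with replacement",
                label, stratum.size, c,
            )
            picks.append(rng.choice(stratum, size=c, replace=True))
    idx = np.concatenate(picks)
    out = pool.subset(idx)
    out.ids = np.arange(n)
    return out


def generate_population(
    ranges: ParameterRanges | None = None,
    pool_size: int = 30_000,
    n: int = 2_000,
    target_freqs: Mapping[str, float] | None = None,
    seed: int | np.random.Generator | None = None,
    centroids: CentroidSet | None = None,
) -> VirtualPopulation:
    """Pool generation and HMP-matched resampling in one call (the default world)."""
    rng = np.random.default_rng(seed)
    pool = generate_pool(ranges, pool_size, rng, centroids)
    return resample_population(pool, target_freqs, n, rng)
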