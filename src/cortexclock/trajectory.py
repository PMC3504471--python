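"""Exponential maturation model of cerebral-cortical fractional anisotropy.

Cortical FA is maximal while pyramidal neurons are still migrating and then
decays exponentially as the neuropil differentiates:

    FA(age) = FA_max                                          for age <  t_init
    FA(age) = (FA_max - FA_min) * exp(-(age - t_init)/tau) + FA_min
                                                              for age >= t_init

with all ages in days post conception (dpc).  ``t_init`` marks the end of
pyramidal neurogenesis/migration and ``tau`` is the species' neuropil
maturation time constant.  The *decay fraction*

    f(age) = exp(-(age - t_init)/tau)        (1 on the plateau)

is the species-free currency used to compare developmental stages across
species: it depends only on the clock parameters (t_init, tau), never on the
absolute FA range.

This module houses the model, its inverse, and parameter estimation from
FA-versus-age observations.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "SpeciesFAParams",
    "FAObservation",
    "FAFitResult",
    "fa_at_age",
    "decay_fraction",
    "age_at_fraction",
    "fit_fa_params",
    "read_fa_csv",
]


@dataclass(frozen=True)
class SpeciesFAParams:
    """One species' cortical-FA maturation clock.

    Parameters
    ----------
    species_name:
        Label used in reports and registry lookups.
    gestation_days:
        Gestation length in days; used only to convert postnatal ages to
        days post conception at the I/O boundary.
    t_init:
        Age (dpc) at which cortical FA starts its exponential decline.
    tau:
        Exponential time constant of the decline, in days.
    fa_max, fa_min:
        Plateau and asymptotic FA values.  Cross-species predictions depend
        only on decay fractions, so the defaults (1, 0) are benign nominal
        bounds when absolute FA is not of interest.
    """

    species_name: str
    gestation_days: float
    t_init: float
    tau: float
    fa_max: float = 1.0
    fa_min: float = 0.0

    def __post_init__(self) -> None:
        if not self.gestation_days > 0:
            raise InvalidInputError("gestation_days must be > 0")
        if not self.t_init > 0:
            raise InvalidInputError("t_init must be > 0")
        if not self.tau > 0:
            raise InvalidInputError("tau must be > 0")
        if not (0.0 <= self.fa_min < self.fa_max <= 1.0):
            raise InvalidInputError("need 0 <= fa_min < fa_max <= 1")


@dataclass(frozen=True)
class FAObservation:
    """A single (age, FA) measurement; age in days post conception."""

    age_pc: float
    fa: float

    def __post_init__(self) -> None:
        if not self.age_pc > 0:
            raise InvalidInputError("age_pc must be > 0")
        if not (0.0 <= self.fa <= 1.0):
            raise InvalidInputError("fa must lie in [0, 1]")


@dataclass(frozen=True)
class FAFitResult:
    """Outcome of a trajectory fit."""

    params: SpeciesFAParams
    residual_sum_of_squares: float
    n_points: int
    converged: bool


def _check_ages(age_pc) -> np.ndarray:
    ages = np.asarray(age_pc, dtype=float)
    if not np.all(ages > 0):
        raise InvalidInputError("ages must be positive (days post conception)")
    return ages


def fa_at_age(params: SpeciesFAParams, age_pc):
    """Evaluate the FA trajectory at one or more ages (dpc).

    Returns ``fa_max`` on the pre-``t_init`` plateau and the exponential
    decay toward ``fa_min`` afterwards; continuous at ``t_init``.
    """
    ages = _check_ages(age_pc)
    f = np.where(
        ages < params.t_init,
        1.0,
        np.exp(-(np.maximum(ages, params.t_init) - params.t_init) / params.tau),
    )
    fa = (params.fa_max - params.fa_min) * f + params.fa_min
    return fa if np.ndim(age_pc) else float(fa)


def decay_fraction(params: SpeciesFAParams, age_pc):
    """Fraction of the FA range (FA_max - FA_min) remaining at ``age_pc``.

    Equals 1 up to ``t_init`` and ``exp(-(age - t_init)/tau)`` after; it is
    independent of ``fa_max``/``fa_min`` and is the species-free quantity
    used for cross-species developmental-stage matching.
    """
    ages = _check_ages(age_pc)
    f = np.where(
        ages <= params.t_init,
        1.0,
        np.exp(-(np.maximum(ages, params.t_init) - params.t_init) / params.tau),
    )
    return f if np.ndim(age_pc) else float(f)


def age_at_fraction(params: SpeciesFAParams, f):
    """Age (dpc) at which the decay fraction equals ``f`` in (0, 1].

    Exact inverse of :func:`decay_fraction` on ``age >= t_init``:
    ``t_init + tau * ln(1/f)``.
    """
    frac = np.asarray(f, dtype=float)
    if not np.all((frac > 0) & (frac <= 1)):
        raise InvalidInputError("fraction must lie in (0, 1]")
    age = params.t_init + params.tau * np.log(1.0 / frac)
    return age if np.ndim(f) else float(age)


# ---------------------------------------------------------------------------
# fitting


def _linear_amplitudes(
    g: np.ndarray,
    fa: np.ndarray,
    fixed: Mapping[str, float],
) -> tuple[float, float, float]:
    """Solve the linear layer of the model for amplitude A = fa_max - fa_min
    and offset B = fa_min given decay fractions ``g``; returns (A, B, rss).

    The model is fa = A*g + B.  Whichever of fa_max / fa_min is fixed turns
    this into a smaller (or empty) linear problem.  Estimates are clipped to
    the feasible box [0, 1]; clipping is rare away from degenerate data and
    the outer profile search simply sees the (worse) clipped RSS.
    """
    if "fa_max" in fixed and "fa_min" in fixed:
        A = fixed["fa_max"] - fixed["fa_min"]
        B = fixed["fa_min"]
    elif "fa_min" in fixed:
        B = fixed["fa_min"]
        denom = float(g @ g)
        A = float(g @ (fa - B)) / denom if denom > 0 else 0.0
    elif "fa_max" in fixed:
        # fa - M*g = B*(1-g), with M = fa_max
        M = fixed["fa_max"]
        h = 1.0 - g
        denom = float(h @ h)
        B = float(h @ (fa - M * g)) / denom if denom > 0 else 0.0
        A = M - B
    else:
        X = np.column_stack([g, np.ones_like(g)])
        (A, B), *_ = np.linalg.lstsq(X, fa, rcond=None)
    # clip to the feasible FA box
    B = float(np.clip(B, 0.0, 1.0 - 1e-9))
    A = float(np.clip(A, 1e-9, 1.0 - B))
    resid = fa - (A * g + B)
    return A, B, float(resid @ resid)


def _profile_rss(
    t_init: float,
    ages: np.ndarray,
    fa: np.ndarray,
    fixed: Mapping[str, float],
    tau_bounds: tuple[float, float],
) -> tuple[float, float, float, float, bool]:
    """Best (tau, A, B, rss) for a fixed breakpoint t_init."""

    def rss_of_tau(tau: float) -> float:
        g = np.exp(-np.maximum(ages - t_init, 0.0) / tau)
        return _linear_amplitudes(g, fa, fixed)[2]

    res = minimize_scalar(
        rss_of_tau,
        bounds=tau_bounds,
        method="bounded",
        options={"xatol": 1e-10},
    )
    tau = float(res.x)
    g = np.exp(-np.maximum(ages - t_init, 0.0) / tau)
    A, B, rss = _linear_amplitudes(g, fa, fixed)
    return tau, A, B, rss, bool(res.success)


def fit_fa_params(
    observations: Sequence[FAObservation],
    fixed: Mapping[str, float] | None = None,
    species_name: str = "fitted",
    gestation_days: float = 1.0,
    t_init_resolution: float = 0.1,
) -> FAFitResult:
    """Least-squares fit of the FA trajectory to (age, FA) observations.

    ``tau`` is always estimated; each of ``t_init``, ``fa_max``, ``fa_min``
    may be supplied in ``fixed`` to pin it.  The plateau breakpoint makes the
    model non-smooth in ``t_init``, so a free ``t_init`` is handled by a
    profile search on a grid (coarse 1-day pass, then refinement at
    ``t_init_resolution``); for each candidate the remaining parameters are
    obtained by a bounded scalar search over ``tau`` with the amplitude and
    offset solved linearly (the model is linear in ``fa_max - fa_min`` and
    ``fa_min`` once ``t_init`` and ``tau`` are known).

    Raises :class:`InsufficientDataError` unless there is at least one more
    observation than free parameters.
    """
    fixed = dict(fixed or {})
    unknown = set(fixed) - {"t_init", "fa_max", "fa_min"}
    if unknown:
        raise InvalidInputError(f"cannot fix unknown parameters: {sorted(unknown)}")

    obs = list(observations)
    n = len(obs)
    n_free = 1 + sum(p not in fixed for p in ("t_init", "fa_max", "fa_min"))
    if n < n_free + 1:
        raise InsufficientDataError(
            f"{n} observations cannot constrain {n_free} free parameters"
        )

    ages = np.array([o.age_pc for o in obs], dtype=float)
    fa = np.array([o.fa for o in obs], dtype=float)
    span = float(ages.max() - ages.min()) or 1.0
    tau_bounds = (1e-3, 20.0 * span)

    if "t_init" in fixed:
        candidates = [float(fixed["t_init"])]
    else:
        lo = max(1e-3, float(ages.min()) - 0.5 * span)
        hi = float(ages.max())
        candidates = list(np.arange(lo, hi + 1.0, 1.0))

    def best_over(cands: Iterable[float]):
        best = None
        for t0 in cands:
            tau, A, B, rss, ok = _profile_rss(t0, ages, fa, fixed, tau_bounds)
            if best is None or rss < best[4]:
                best = (t0, tau, A, B, rss, ok)
        return best

    t0, tau, A, B, rss, ok = best_over(candidates)
    if "t_init" not in fixed:
        fine = np.arange(t0 - 1.0, t0 + 1.0 + t_init_resolution / 2, t_init_resolution)
        fine = fine[fine > 0]
        t0, tau, A, B, rss, ok = best_over(fine)

    params = SpeciesFAParams(
        species_name=species_name,
        gestation_days=gestation_days,
        t_init=float(t0),
        tau=tau,
        fa_max=A + B,
        fa_min=B,
    )
    # tau pegged at a search bound means the optimiser did not localise it
    converged = ok and not math.isclose(tau, tau_bounds[1], rel_tol=1e-3)
    return FAFitResult(
        params=params,
        residual_sum_of_squares=rss,
        n_points=n,
        converged=converged,
    )


def read_fa_csv(path) -> list[FAObservation]:
    """Read FA observations from CSV.

    Expected columns: ``age_pc`` and ``fa``; alternatively ``age_postnatal``
    together with ``gestation_days`` (constant column or single value), which
    is converted to days post conception on read.
    """
    df = pd.read_csv(path)
    if "age_pc" in df.columns:
        ages = df["age_pc"].to_numpy(float)
    elif {"age_postnatal", "gestation_days"} <= set(df.columns):
        ages = df["age_postnatal"].to_numpy(float) + df["gestation_days"].to_numpy(float)
    else:
        raise InvalidInputError(
            "CSV needs 'age_pc' and 'fa', or 'age_postnatal' + 'gestation_days' + 'fa'"
        )
    if "fa" not in df.columns:
        raise InvalidInputError("CSV is missing the 'fa' column")
    return [FAObservation(a, f) for a, f in zip(ages, df["fa"].to_numpy(float))]


def with_fa_bounds(
    params: SpeciesFAParams, fa_max: float, fa_min: float
) -> SpeciesFAParams:
    """Return a copy of ``params`` with different absolute FA bounds."""
    return replace(params, fa_max=fa_max, fa_min=fa_min)
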