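"""Residue-resolved HDX rate fitting from peak-intensity time courses.

Each mainchain amide's H/D exchange is modelled as a pseudo-first-order
decay of its NMR peak intensity,

    I(t) = b + (I0 - b) * exp(-k t),        b >= 0,

with a fitted non-negative floor ``b`` absorbing residual protonated
solvent signal.  Fits are weighted least squares with fractional
(multiplicative) intensity errors; ``sigma_k`` comes from the curvature
of the objective at the optimum.  Residues that exchange too fast to
catch (first post-mixing point already low) or too slow to detect over
the sampled window are censored and reported as bounds, never as garbage
point estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constructs import Condition

__all__ = [
    "HDXTimeCourse",
    "RateFit",
    "RateTable",
    "fit_exchange_rate",
    "fit_rate_table",
    "protection_factor",
]

#: first post-mixing intensity below this -> exchange too fast to fit
FAST_EXCHANGE_THRESHOLD = 0.2

#: fitted decay smaller than this multiple of the intensity noise over the
#: sampled window -> exchange too slow to detect
SLOW_DETECTION_MULTIPLE = 3.0

#: default fractional intensity uncertainty when the data state none
DEFAULT_INTENSITY_SIGMA = 0.02

#: reporting threshold (min^-1) separating fast- from slow-exchanging amides
FAST_GROUP_THRESHOLD = 0.2

_RESTART_FACTORS = (1.0, 5.0, 0.2, 25.0, 0.04)


@dataclass
class HDXTimeCourse:
    """Normalized peak intensity versus exchange time for one amide."""

    construct_id: str
    condition: Condition
    residue: int
    times: np.ndarray        # minutes, strictly increasing
    intensities: np.ndarray  # unitless, normalized to the earliest usable point
    sigma: float = DEFAULT_INTENSITY_SIGMA  # fractional

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.size < 4:
            raise ValueError(
                f"residue {self.residue}: {self.times.size} time points; need >= 4 "
                "for a determined rate fit"
            )
        if self.times.shape != self.intensities.shape:
            raise ValueError(f"residue {self.residue}: times/intensities length mismatch")
        if (np.diff(self.times) <= 0).any():
            raise ValueError(f"residue {self.residue}: times must be strictly increasing")
        if (self.times < 0).any():
            raise ValueError(f"residue {self.residue}: negative times")
        if (self.intensities < 0).any():
            raise ValueError(f"residue {self.residue}: negative intensities")
        if self.sigma <= 0:
            raise ValueError(f"residue {self.residue}: sigma must be > 0")


@dataclass
class RateFit:
    """A fitted (or censored) exchange rate for one amide.

    ``status`` is ``ok`` for a converged fit, ``too_fast`` / ``too_slow``
    for censored residues (``k`` then holds the bound), ``failed`` when
    the optimizer never converged.
    """

    residue: int
    k: float                 # min^-1; bound value when censored
    sigma_k: float           # min^-1; NaN when censored/failed
    baseline: float = 0.0
    i0: float = 1.0
    status: str = "ok"
    residual_sd: float = np.nan   # weighted residual RMS
    n_points: int = 0
    diagnostics: dict = field(default_factory=dict)

    @property
    def censored(self) -> bool:
        return self.status in ("too_fast", "too_slow")

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def _model(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    i0, b, k = theta
    return b + (i0 - b) * np.exp(-k * t)


def _initial_rate_guess(t: np.ndarray, i: np.ndarray, b0: float) -> float:
    """Log-linear regression on early points above the floor (deterministic)."""
    y = i - b0
    mask = (y > 0.02) & (t >= 0)
    if mask.sum() >= 2:
        slope = np.polyfit(t[mask], np.log(y[mask]), 1)[0]
        if slope < 0:
            return float(-slope)
    return 1.0 / max(t[-1], 1e-9)


def fit_exchange_rate(
    tc: HDXTimeCourse,
    fast_threshold: float = FAST_EXCHANGE_THRESHOLD,
    slow_multiple: float = SLOW_DETECTION_MULTIPLE,
) -> RateFit:
    """Weighted least-squares exponential fit of one amide's decay.

    Censoring comes first: if the first post-mixing intensity is already
    below ``fast_threshold``, only a lower bound ``-ln(threshold)/t1`` is
    reported.  After fitting, a decay amplitude indistinguishable from the
    noise over the sampled window yields a ``too_slow`` upper bound.
    """
    t, i = tc.times, tc.intensities
    post = np.flatnonzero(t > 0)
    if post.size and i[post[0]] < fast_threshold:
        k_lb = -np.log(fast_threshold) / t[post[0]]
        return RateFit(
            residue=tc.residue, k=float(k_lb), sigma_k=np.nan, status="too_fast",
            n_points=t.size,
            diagnostics={"bound": "lower", "first_intensity": float(i[post[0]])},
        )

    scale = max(i.max(), 1e-12)
    sig = tc.sigma * np.maximum(i, 0.05 * scale)  # floor keeps zero-count points usable

    # fit in dimensionless time (window length = 1) so that rate estimates
    # are exactly covariant under a change of time units
    t_span = float(t[-1] - t[0])
    tau = (t - t[0]) / t_span

    def resid(theta):
        return (_model(theta, tau) - i) / sig

    b0 = max(float(i.min()) - 0.01 * scale, 0.0)
    i0_0 = float(i[0])
    k0 = _initial_rate_guess(tau, i, b0)

    best = None
    tried = 0
    for factor in _RESTART_FACTORS:
        tried += 1
        try:
            sol = least_squares(
                resid,
                x0=[i0_0, b0, k0 * factor],
                bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
                method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost - 1e-15):
            best = sol
        if best is not None and factor == 1.0 and best.cost < 1e-20:
            break
    if best is None:
        return RateFit(
            residue=tc.residue, k=np.nan, sigma_k=np.nan, status="failed",
            n_points=t.size, diagnostics={"restarts": tried},
        )

    i0_f, b_f, k_tau = best.x
    k_f = k_tau / t_span
    n, p = t.size, 3
    dof = max(n - p, 1)
    # residual scaling inflates errors when the data are noisier than the
    # stated sigma, but never shrinks them below the stated-noise level
    s2 = max(2.0 * best.cost / dof, 1.0)
    # curvature of the weighted objective at the optimum
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * s2
        sigma_k = float(np.sqrt(max(cov[2, 2], 0.0))) / t_span
    except np.linalg.LinAlgError:
        sigma_k = np.nan

    # too-slow censoring: decay amplitude over the window vs the noise
    decay = (i0_f - b_f) * (1.0 - np.exp(-k_tau))
    detectable = slow_multiple * tc.sigma * scale
    if decay < detectable:
        arg = min(slow_multiple * tc.sigma, 0.999)
        k_ub = -np.log(1.0 - arg) / max(t_span, 1e-9)
        return RateFit(
            residue=tc.residue, k=float(k_ub), sigma_k=np.nan, baseline=float(b_f),
            i0=float(i0_f), status="too_slow", n_points=n,
            diagnostics={"bound": "upper", "fitted_k": float(k_f)},
        )

    resid_sd = float(np.sqrt(np.mean(best.fun**2)))
    if not np.isfinite(sigma_k) or sigma_k <= 0:
        sigma_k = max(abs(k_f), 1e-12)  # uninformative but positive, flagged below
    return RateFit(
        residue=tc.residue, k=float(k_f), sigma_k=sigma_k, baseline=float(b_f),
        i0=float(i0_f), status="ok", residual_sd=resid_sd, n_points=n,
        diagnostics={"cost": float(best.cost), "restarts": tried},
    )


@dataclass
class RateTable:
    """Per-residue rate fits for one construct under one condition."""

    construct_id: str
    condition: Condition
    fits: dict[int, RateFit]
    fast_group_threshold: float = FAST_GROUP_THRESHOLD

    @property
    def frame(self) -> pd.DataFrame:
        rows = []
        for r in sorted(self.fits):
            f = self.fits[r]
            group = "fast" if (np.isfinite(f.k) and f.k > self.fast_group_threshold) else "slow"
            rows.append(
                {
                    "residue": r,
                    "k_hdx_per_min": f.k,
                    "sigma_k_per_min": f.sigma_k,
                    "baseline": f.baseline,
                    "status": f.status,
                    "group": group,
                    "residual_sd": f.residual_sd,
                    "n_points": f.n_points,
                }
            )
        return pd.DataFrame(rows)


def fit_rate_table(
    tcs: list[HDXTimeCourse],
    fast_group_threshold: float = FAST_GROUP_THRESHOLD,
    **fit_kwargs,
) -> RateTable:
    """Fit every residue of a shared (construct, condition) time-course set."""
    if not tcs:
        raise ValueError("no time courses to fit")
    cid = tcs[0].construct_id
    cond = tcs[0].condition
    for tc in tcs:
        if tc.construct_id != cid or tc.condition.label != cond.label:
            raise ValueError(
                f"time courses mix constructs/conditions: ({cid!r}, {cond.label!r}) "
                f"vs ({tc.construct_id!r}, {tc.condition.label!r})"
            )
    residues = [tc.residue for tc in tcs]
    dupes = {r for r in residues if residues.count(r) > 1}
    if dupes:
        raise ValueError(f"duplicate residue rows in time-course set: {sorted(dupes)}")
    fits = {tc.residue: fit_exchange_rate(tc, **fit_kwargs) for tc in tcs}
    return RateTable(cid, cond, fits, fast_group_threshold)


def protection_factor(
    fit: RateFit, k_int: float, sigma_kint: float = 0.0
) -> tuple[float, float]:
    """EX2 protection factor PF = k_int / k_obs with propagated error."""
    if k_int <= 0:
        raise ValueError("k_int must be > 0")
    if not fit.ok:
        raise ValueError(
            f"residue {fit.residue}: protection factor needs an ok fit, got "
            f"status {fit.status!r} (use the censored bound instead)"
        )
    if fit.k <= 0:
        raise ValueError(f"residue {fit.residue}: k_obs must be > 0")
    pf = k_int / fit.k
    sigma = pf * float(np.hypot(fit.sigma_k / fit.k, sigma_kint / k_int))
    return pf, sigma
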