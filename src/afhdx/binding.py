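"""Weak 1:1 binding-constant estimation from salt-titration shift series.

Observed amide shifts in fast exchange follow the standard 1:1 host-guest
isotherm,

    delta_obs = delta_free + delta_max * [HG] / H_tot,

with the complex concentration [HG] the exact physical root of the
binding quadratic in total concentrations

    Ka*[HG]^2 - (Ka*(G_tot + H_tot) + 1)*[HG] + Ka*G_tot*H_tot = 0.

The exact quadratic is used rather than the ligand-excess approximation,
even though salt is in vast excess — exactness is free.  Weak binding
(Ka * G_max well below 1) leaves the product Ka * delta_max identified
but not the factors; such fits are flagged ``weak_binding_degenerate``
from the shape of the Ka profile rather than reported with meaningless
errors.  Per-residue independent fits are the default; a global variant
(shared Ka, per-residue amplitude) is provided since every residue
reports the same weak binding event.
"""

from __future__ import annotations

from dataclasses import dataclass

import lmfit
import numpy as np
import pandas as pd

from .constructs import DEFAULT_SHIFT_SIGMA

__all__ = [
    "TitrationSeries",
    "BindingIsothermFit",
    "isotherm_1to1",
    "fit_binding",
    "fit_binding_global",
    "ka_matrix",
]

#: Ka * G_max below this -> binding too weak to separate Ka from delta_max
DEGENERACY_SATURATION_THRESHOLD = 0.1

#: chi-square must rise by more than this within a decade of Ka around the
#: optimum, else the profile is flat and the fit degenerate
PROFILE_FLATNESS_CHI2 = 1.0


@dataclass
class TitrationSeries:
    """One residue's referenced shifts across a ligand (salt) titration."""

    residue: int
    anion: str
    concentrations_M: np.ndarray  # ligand totals, strictly increasing from 0
    recipient_M: float            # peptide total
    delta_obs: np.ndarray         # ppm, reference-corrected
    sigma: float = DEFAULT_SHIFT_SIGMA  # ppm

    def __post_init__(self) -> None:
        self.concentrations_M = np.asarray(self.concentrations_M, dtype=float)
        self.delta_obs = np.asarray(self.delta_obs, dtype=float)
        if self.concentrations_M.size < 6:
            raise ValueError(
                f"residue {self.residue}: {self.concentrations_M.size} titration "
                "points; need >= 6"
            )
        if self.concentrations_M[0] != 0.0 or (np.diff(self.concentrations_M) <= 0).any():
            raise ValueError(
                f"residue {self.residue}: concentrations must increase strictly from 0"
            )
        if self.concentrations_M.shape != self.delta_obs.shape:
            raise ValueError(f"residue {self.residue}: concentration/shift length mismatch")
        if self.recipient_M <= 0 or self.sigma <= 0:
            raise ValueError(f"residue {self.residue}: recipient_M and sigma must be > 0")


@dataclass
class BindingIsothermFit:
    """Per-residue 1:1 fit: Ka, amplitude, free shift and identifiability."""

    residue: int
    anion: str
    Ka: float                # M^-1
    sigma_Ka: float
    delta_max: float         # ppm
    sigma_delta_max: float
    delta_free: float        # ppm
    identifiability: str     # well_determined | weak_binding_degenerate | failed
    chi2: float = np.nan
    profile: pd.DataFrame | None = None  # attached on degeneracy/failure

    @property
    def well_determined(self) -> bool:
        return self.identifiability == "well_determined"


def complex_concentration(Ka: float, G_total, H_total: float) -> np.ndarray:
    """Exact physical root of the 1:1 quadratic, 0 <= [HG] <= min(G, H)."""
    G = np.asarray(G_total, dtype=float)
    if Ka < 0:
        raise ValueError("Ka must be >= 0")
    if (G < 0).any() or H_total < 0:
        raise ValueError("concentrations must be >= 0")
    if Ka == 0:
        return np.zeros_like(G)
    b = G + H_total + 1.0 / Ka
    hg = (b - np.sqrt(b * b - 4.0 * G * H_total)) / 2.0
    return np.clip(hg, 0.0, np.minimum(G, H_total))


def isotherm_1to1(
    Ka: float, delta_free: float, delta_max: float, G_total, H_total: float
):
    """Fast-exchange observed shift (ppm) of the 1:1 model."""
    hg = complex_concentration(Ka, G_total, H_total)
    return delta_free + delta_max * hg / H_total


def _bound_fraction(Ka: float, G: np.ndarray, H: float) -> np.ndarray:
    return complex_concentration(Ka, G, H) / H


def _linear_subfit(fb: np.ndarray, delta: np.ndarray, w: float) -> tuple[float, float, float]:
    """For fixed Ka the model is linear in (delta_free, delta_max); solve exactly.

    Returns (delta_free, delta_max, chi2).
    """
    X = np.column_stack([np.ones_like(fb), fb])
    coef, *_ = np.linalg.lstsq(X, delta, rcond=None)
    resid = delta - X @ coef
    chi2 = float(np.sum((resid / w) ** 2))
    return float(coef[0]), float(coef[1]), chi2


def profile_Ka(series: TitrationSeries, ka_grid: np.ndarray) -> pd.DataFrame:
    """Chi-square profile in Ka with the amplitude terms solved exactly."""
    rows = []
    for ka in ka_grid:
        fb = _bound_fraction(float(ka), series.concentrations_M, series.recipient_M)
        dfree, dmax, chi2 = _linear_subfit(fb, series.delta_obs, series.sigma)
        rows.append({"Ka": float(ka), "delta_free": dfree, "delta_max": dmax, "chi2": chi2})
    return pd.DataFrame(rows)


def fit_binding(
    series: TitrationSeries,
    degeneracy_threshold: float = DEGENERACY_SATURATION_THRESHOLD,
) -> BindingIsothermFit:
    """Weighted least-squares 1:1 isotherm fit with identifiability check.

    A coarse deterministic Ka scan seeds an lmfit refinement of
    (Ka, delta_max, delta_free); errors come from the fit curvature.  The
    degeneracy flag fires when Ka*G_max falls below ``degeneracy_threshold``
    or the Ka profile is flat (chi2 rise < 1) within a decade of the
    optimum — the confidence region is then unbounded along the
    Ka*delta_max ridge.
    """
    G = series.concentrations_M
    d = series.delta_obs
    g_max = float(G[-1])

    scan = profile_Ka(series, np.logspace(-3, 3, 61))
    ka0 = float(scan.loc[scan["chi2"].idxmin(), "Ka"])

    params = lmfit.Parameters()
    params.add("Ka", value=ka0, min=0.0)
    params.add("delta_free", value=float(d[0]))
    params.add("delta_max", value=float(d[-1] - d[0]) or 0.01)

    def resid(p):
        return (
            isotherm_1to1(p["Ka"].value, p["delta_free"].value, p["delta_max"].value,
                          G, series.recipient_M)
            - d
        ) / series.sigma

    try:
        out = lmfit.minimize(resid, params, method="leastsq")
    except Exception:
        out = None

    if out is None or not out.success:
        prof = profile_Ka(series, np.logspace(-3, 3, 121))
        return BindingIsothermFit(
            series.residue, series.anion, np.nan, np.nan, np.nan, np.nan, np.nan,
            identifiability="failed", profile=prof,
        )

    ka = float(out.params["Ka"].value)
    dmax = float(out.params["delta_max"].value)
    dfree = float(out.params["delta_free"].value)
    ska = out.params["Ka"].stderr
    sdmax = out.params["delta_max"].stderr
    chi2 = float(out.chisqr)

    degenerate = ka * g_max < degeneracy_threshold
    profile = None
    if not degenerate:
        decade = np.logspace(np.log10(max(ka, 1e-6)) - 0.5, np.log10(max(ka, 1e-6)) + 0.5, 21)
        profile = profile_Ka(series, decade)
        if float(profile["chi2"].max() - profile["chi2"].min()) < PROFILE_FLATNESS_CHI2:
            degenerate = True
    if ska is None or not np.isfinite(ska):
        ska = np.nan
        degenerate = True
    if sdmax is None or not np.isfinite(sdmax):
        sdmax = np.nan

    return BindingIsothermFit(
        residue=series.residue,
        anion=series.anion,
        Ka=ka,
        sigma_Ka=float(ska) if ska == ska else np.nan,
        delta_max=dmax,
        sigma_delta_max=float(sdmax) if sdmax == sdmax else np.nan,
        delta_free=dfree,
        identifiability="weak_binding_degenerate" if degenerate else "well_determined",
        chi2=chi2,
        profile=profile if degenerate else None,
    )


def fit_binding_global(series_list: list[TitrationSeries]) -> dict:
    """Global fit: one shared Ka, per-residue (delta_free, delta_max).

    The per-residue amplitude terms are linear given Ka, so the global
    objective is profiled over Ka on a log grid and polished by golden
    section.  Returns the shared Ka with a curvature-based sigma and the
    per-residue amplitudes — labelled ``global`` to distinguish it from
    the default per-residue fits.
    """
    from scipy.optimize import minimize_scalar

    if not series_list:
        raise ValueError("no titration series")

    def total_chi2(log_ka: float) -> float:
        ka = 10.0**log_ka
        tot = 0.0
        for s in series_list:
            fb = _bound_fraction(ka, s.concentrations_M, s.recipient_M)
            tot += _linear_subfit(fb, s.delta_obs, s.sigma)[2]
        return tot

    grid = np.linspace(-3, 3, 61)
    chi = np.array([total_chi2(x) for x in grid])
    x0 = grid[int(np.argmin(chi))]
    res = minimize_scalar(total_chi2, bracket=(x0 - 0.2, x0, x0 + 0.2), method="brent")
    log_ka = float(res.x)
    ka = 10.0**log_ka
    # curvature of chi2 in Ka at the optimum -> sigma_Ka
    h = 0.01
    c0, cm, cp = total_chi2(log_ka), total_chi2(log_ka - h), total_chi2(log_ka + h)
    curv_log = (cp + cm - 2 * c0) / h**2  # d2chi2/dlogKa2
    ln10 = np.log(10.0)
    curv = curv_log / (ka * ln10) ** 2
    sigma_ka = float(np.sqrt(2.0 / curv)) if curv > 0 else np.nan

    amplitudes = []
    for s in series_list:
        fb = _bound_fraction(ka, s.concentrations_M, s.recipient_M)
        dfree, dmax, chi2 = _linear_subfit(fb, s.delta_obs, s.sigma)
        amplitudes.append(
            {"residue": s.residue, "anion": s.anion, "delta_free": dfree,
             "delta_max": dmax, "chi2": chi2}
        )
    return {
        "model": "global",
        "Ka": ka,
        "sigma_Ka": sigma_ka,
        "chi2": float(c0),
        "amplitudes": pd.DataFrame(amplitudes),
    }


def ka_matrix(fits: list[BindingIsothermFit]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the residue x anion affinity matrix and per-anion averages.

    Missing cells stay explicit (NaN).  Averages use well-determined cells
    only; the count of excluded degenerate cells is reported per anion.
    """
    seen = set()
    for f in fits:
        key = (f.residue, f.anion)
        if key in seen:
            raise ValueError(f"duplicate (residue, anion) cell {key}")
        seen.add(key)
    rows = [
        {
            "residue": f.residue,
            "anion": f.anion,
            "Ka": f.Ka,
            "sigma_Ka": f.sigma_Ka,
            "identifiability": f.identifiability,
        }
        for f in fits
    ]
    long = pd.DataFrame(rows)
    matrix = long.pivot(index="residue", columns="anion", values="Ka")
    summary = []
    for anion, grp in long.groupby("anion", sort=True):
        good = grp[grp["identifiability"] == "well_determined"]["Ka"]
        summary.append(
            {
                "anion": anion,
                "mean_Ka": float(good.mean()) if len(good) else np.nan,
                "n_used": int(len(good)),
                "n_excluded_degenerate": int((grp["identifiability"] != "well_determined").sum()),
                "min_Ka": float(good.min()) if len(good) else np.nan,
                "max_Ka": float(good.max()) if len(good) else np.nan,
            }
        )
    return matrix, pd.DataFrame(summary)
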