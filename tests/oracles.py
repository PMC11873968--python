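"""Independent oracles: brute-force grid searches and Monte-Carlo checks.

These deliberately re-derive every quantity from scratch (own formulas,
own weighting, exhaustive scans) so that agreement with the package's
optimizer-based fits is a real cross-check, not a tautology.
"""

import numpy as np


def fold_fraction_by_enumeration(K_fold: float, Ka: float, conc_M: float) -> float:
    """Fraction folded from explicit state enumeration (F, U, U*A)."""
    weights = {"F": K_fold, "U": 1.0, "UA": Ka * conc_M}
    z = sum(weights.values())
    return weights["F"] / z


def _parabolic_vertex(x, y):
    """Vertex of the parabola through three points (log-domain refinement)."""
    d1, d2 = y[1] - y[0], y[2] - y[1]
    denom = d1 - d2
    if denom == 0:
        return x[1]
    return x[1] + 0.5 * ((x[1] - x[0]) * d2 + (x[2] - x[1]) * d1) / denom


def grid_search_exp(t, intensities, sigma_frac, n_grid=10_000, k_lo=1e-5, k_hi=10.0):
    """Exhaustive 1-D scan over the decay rate with exact linear subfits.

    For each k the model I = I0*exp(-kt) + b*(1-exp(-kt)) is linear in
    (I0, b); b is clipped to 0 when the unconstrained solution goes
    negative.  Uses the same inverse-variance weighting convention as the
    package fit (fractional sigma with a 5%-of-max floor) so objective
    values are directly comparable.  Returns (best_chi2, best_k).
    """
    t = np.asarray(t, float)
    I = np.asarray(intensities, float)
    scale = max(I.max(), 1e-12)
    w = 1.0 / (sigma_frac * np.maximum(I, 0.05 * scale))
    y = I * w

    def chi2_at(k):
        e = np.exp(-k * t)
        A = np.column_stack([e * w, (1.0 - e) * w])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        if coef[1] < 0.0:
            a0 = A[:, 0]
            coef = np.array([(a0 @ y) / (a0 @ a0), 0.0])
        r = y - A @ coef
        return float(r @ r)

    ks = np.logspace(np.log10(k_lo), np.log10(k_hi), n_grid)
    chi2 = np.array([chi2_at(k) for k in ks])
    j = int(np.argmin(chi2))
    best_chi2, best_k = float(chi2[j]), float(ks[j])
    if 0 < j < n_grid - 1:
        # polish the discrete minimum: parabola through the three bracketing
        # grid points in log-k, then one extra objective evaluation
        logk = _parabolic_vertex(np.log(ks[j - 1 : j + 2]), chi2[j - 1 : j + 2])
        k_ref = float(np.exp(logk))
        c_ref = chi2_at(k_ref)
        if c_ref < best_chi2:
            best_chi2, best_k = c_ref, k_ref
    return best_chi2, best_k


def grid_search_binding(conc_M, delta_obs, recipient_M, sigma, n_grid=10_000,
                        ka_lo=1e-3, ka_hi=1e3):
    """Exhaustive 1-D scan over Ka with exact linear (delta_free, delta_max).

    The complex concentration uses its own quadratic-root evaluation.
    Returns (best_chi2, best_Ka).
    """
    G = np.asarray(conc_M, float)
    d = np.asarray(delta_obs, float)
    H = float(recipient_M)
    def chi2_at(ka):
        s = G + H + 1.0 / ka
        hg = (s - np.sqrt(s * s - 4.0 * G * H)) / 2.0
        fb = hg / H
        X = np.column_stack([np.ones_like(fb), fb])
        coef, *_ = np.linalg.lstsq(X, d, rcond=None)
        r = (d - X @ coef) / sigma
        return float(r @ r)

    kas = np.logspace(np.log10(ka_lo), np.log10(ka_hi), n_grid)
    chi2 = np.array([chi2_at(ka) for ka in kas])
    j = int(np.argmin(chi2))
    best_chi2, best_ka = float(chi2[j]), float(kas[j])
    if 0 < j < n_grid - 1:
        logka = _parabolic_vertex(np.log(kas[j - 1 : j + 2]), chi2[j - 1 : j + 2])
        ka_ref = float(np.exp(logka))
        c_ref = chi2_at(ka_ref)
        if c_ref < best_chi2:
            best_chi2, best_ka = c_ref, ka_ref
    return best_chi2, best_ka


def mc_percent_change_sigma(k0, s0, ks, ss, n=100_000, seed=0):
    """Monte-Carlo standard deviation of (ks - k0)/k0 * 100."""
    rng = np.random.default_rng(seed)
    d0 = rng.normal(k0, s0, n)
    ds = rng.normal(ks, ss, n)
    return float(np.std((ds - d0) / d0 * 100.0))
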