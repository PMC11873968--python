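"""AF-HDX maps: percentage exchange-rate changes between salt conditions.

The anion-facilitated HDX statistic compares residue-resolved exchange
rates without (k0) and with (k_salt) added salt:

    %dk = (k_salt - k0) / k0 * 100.

Errors are first-order propagation treating the two fits as independent
(the conditions are measured separately); significance uses a plain
z-style criterion |%dk| > m * sigma (default m = 2, strict inequality)
and is labelled as such in every report — no formal test is implied.  No
multiple-testing correction is applied by default (12 residues,
descriptive mapping); an optional Benjamini-Hochberg layer is available.

Region summaries mirror the bifurcation of a 12-mer hairpin into a
terminal half {1,2,3,10,11,12} and a turn half {4..9}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .kinetics import RateFit, RateTable

__all__ = [
    "AFHDXMap",
    "percent_rate_change",
    "significance_call",
    "build_map",
    "region_summary",
    "peak_residue",
    "DEFAULT_REGIONS",
]

DEFAULT_SIGNIFICANCE_MULTIPLE = 2.0

#: default region partition for a 12-mer hairpin
DEFAULT_REGIONS: dict[int, str] = {
    **{r: "terminal" for r in (1, 2, 3, 10, 11, 12)},
    **{r: "turn" for r in range(4, 10)},
}


def percent_rate_change(k0: RateFit, ksalt: RateFit) -> tuple[float, float]:
    """Percentage rate change and its first-order propagated error.

    Both fits must be uncensored; censored fits carry only bounds and are
    handled (flagged) at the map level, never pushed through this formula.
    """
    if not (k0.ok and ksalt.ok):
        raise ValueError(
            f"percent rate change needs two ok fits; got statuses "
            f"{k0.status!r} / {ksalt.status!r} for residue {k0.residue}"
        )
    if k0.k <= 0:
        raise ValueError(f"residue {k0.residue}: baseline rate must be > 0")
    pct = (ksalt.k - k0.k) / k0.k * 100.0
    # d/dks = 100/k0 ; d/dk0 = -100 * ks / k0^2
    sigma = 100.0 * float(
        np.hypot(ksalt.sigma_k / k0.k, ksalt.k * k0.sigma_k / k0.k**2)
    )
    return pct, sigma


def significance_call(
    pct: float, sigma_pct: float, criterion: float = DEFAULT_SIGNIFICANCE_MULTIPLE
) -> bool:
    """Propagated-error z-style significance: |%dk| strictly > criterion * sigma.

    The boundary case |%dk| == criterion * sigma is *not* significant.
    """
    if sigma_pct <= 0:
        raise ValueError("sigma of the percentage change must be > 0")
    return abs(pct) > criterion * sigma_pct


@dataclass
class AFHDXMap:
    """Residue-resolved percentage rate-change map for one condition pair.

    ``data`` columns: residue, pct_change, sigma_pct, direction
    (increase / attenuation / none), significant, censored, region.
    """

    data: pd.DataFrame
    baseline_label: str
    salt_label: str
    criterion: float = DEFAULT_SIGNIFICANCE_MULTIPLE
    regions: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    notes: str = (
        "significance = propagated-error criterion |%dk| > m*sigma (z-style), "
        "no multiple-testing correction applied"
    )


def build_map(
    baseline: RateTable,
    salted: RateTable,
    criterion: float = DEFAULT_SIGNIFICANCE_MULTIPLE,
    regions: dict[int, str] | None = None,
) -> AFHDXMap:
    """Assemble the AF-HDX map from baseline and salt rate tables.

    Censored fits (too fast / too slow) propagate as flagged bound rows:
    they never produce a significance call.
    """
    regions = dict(DEFAULT_REGIONS) if regions is None else dict(regions)
    rows = []
    for residue in sorted(set(baseline.fits) | set(salted.fits)):
        f0 = baseline.fits.get(residue)
        fs = salted.fits.get(residue)
        region = regions.get(residue)
        if f0 is None or fs is None or not (f0.ok and fs.ok):
            status = "missing" if (f0 is None or fs is None) else f"{f0.status}/{fs.status}"
            rows.append(
                {
                    "residue": residue,
                    "pct_change": np.nan,
                    "sigma_pct": np.nan,
                    "direction": "none",
                    "significant": False,
                    "censored": True,
                    "censor_detail": status,
                    "region": region,
                }
            )
            continue
        pct, sigma = percent_rate_change(f0, fs)
        sig = significance_call(pct, sigma, criterion)
        direction = "none"
        if pct > 0:
            direction = "increase"
        elif pct < 0:
            direction = "attenuation"
        rows.append(
            {
                "residue": residue,
                "pct_change": pct,
                "sigma_pct": sigma,
                "direction": direction,
                "significant": sig,
                "censored": False,
                "censor_detail": "",
                "region": region,
            }
        )
    return AFHDXMap(
        pd.DataFrame(rows),
        baseline_label=baseline.condition.label,
        salt_label=salted.condition.label,
        criterion=criterion,
        regions=regions,
    )


def region_summary(afmap: AFHDXMap) -> pd.DataFrame:
    """Per-region aggregates: mean |%dk|, significant count, dominant direction."""
    df = afmap.data
    unpartitioned = df.loc[df["region"].isna(), "residue"].tolist()
    if unpartitioned:
        raise ValueError(
            f"residues {unpartitioned} are not covered by the region partition"
        )
    out = []
    for region, grp in df.groupby("region", sort=True):
        usable = grp[~grp["censored"]]
        mean_abs = float(usable["pct_change"].abs().mean()) if len(usable) else np.nan
        mean_signed = float(usable["pct_change"].mean()) if len(usable) else np.nan
        n_sig = int(usable["significant"].sum())
        sig_rows = usable[usable["significant"]]
        counts = sig_rows["direction"].value_counts() if len(sig_rows) else usable["direction"].value_counts()
        dominant = counts.idxmax() if len(counts) else "none"
        out.append(
            {
                "region": region,
                "n_residues": int(len(grp)),
                "n_censored": int(grp["censored"].sum()),
                "mean_abs_pct": mean_abs,
                "mean_pct": mean_signed,
                "n_significant": n_sig,
                "dominant_direction": dominant,
            }
        )
    return pd.DataFrame(out)


def peak_residue(afmap: AFHDXMap) -> int:
    """The residue with the largest |%dk| among uncensored entries."""
    usable = afmap.data[~afmap.data["censored"]]
    if usable.empty:
        raise ValueError("map has no uncensored entries")
    idx = usable["pct_change"].abs().idxmax()
    return int(usable.loc[idx, "residue"])


def benjamini_hochberg(afmap: AFHDXMap, alpha: float = 0.05) -> AFHDXMap:
    """Optional FDR layer over the per-residue z-style calls (off by default).

    Two-sided normal p-values from pct/sigma are BH-adjusted; returns a new
    map whose ``significant`` column reflects the adjusted calls and whose
    notes record the correction.
    """
    df = afmap.data.copy()
    usable = ~df["censored"]
    z = (df.loc[usable, "pct_change"] / df.loc[usable, "sigma_pct"]).abs()
    pvals = 2.0 * norm.sf(z)
    reject, p_adj, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    df.loc[usable, "p_value"] = pvals
    df.loc[usable, "p_adjusted"] = p_adj
    df.loc[usable, "significant"] = reject
    out = AFHDXMap(
        df, afmap.baseline_label, afmap.salt_label, afmap.criterion, dict(afmap.regions)
    )
    out.notes = afmap.notes + f"; Benjamini-Hochberg FDR at alpha={alpha} applied"
    return out
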