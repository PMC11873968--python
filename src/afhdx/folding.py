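"""Two-state folding quantification and chemical-shift difference maps.

The fraction folded of a beta-hairpin is read off a single global
reporter: the splitting of the diastereotopic Gly CaH2 protons, linearly
interpolated between the fully unfolded reference (the corresponding
6-mer half peptide, splitting near zero) and the fully folded reference
(the cystine-bridged macrocycle),

    F = (delta_obs - delta_0) / (delta_100 - delta_0).

Salt-induced unfolding is reported in percentage points of fraction
folded.  Per-residue chemical-shift perturbation maps (Delta-delta) use
the ppm sign convention: downfield = larger delta = positive Delta-delta.
An N-terminal acetyl methyl serves as internal reference to remove bulk
ionic-strength drifts before conditions are compared.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constructs import (
    ATOM_NH,
    ATOM_REF_METHYL,
    Condition,
    PeptideConstruct,
    ShiftTable,
)

__all__ = [
    "FoldFraction",
    "DeltaShiftMap",
    "fraction_folded",
    "percent_unfolding",
    "reference_correct",
    "delta_shift_map",
]

#: references must be separated by at least this many combined sigmas
REFERENCE_SEPARATION_MULTIPLE = 3.0

#: internal-reference drifts larger than this (ppm) suggest mis-assignment
REFERENCE_DRIFT_WARN_PPM = 0.1

#: default multiple of propagated sigma for calling a shift significant
DEFAULT_SIGNIFICANCE_MULTIPLE = 2.0

#: fractions outside [0,1] by more than this are flagged as unphysical
FOLD_FRACTION_TOLERANCE = 0.05


@dataclass(frozen=True)
class FoldFraction:
    """A fraction-folded estimate with first-order propagated error."""

    value: float
    sigma: float
    construct_id: str = ""
    condition: Condition | None = None

    @property
    def percent(self) -> float:
        return 100.0 * self.value

    @property
    def flagged(self) -> bool:
        """True when the estimate falls outside [0, 1] beyond tolerance."""
        return not (-FOLD_FRACTION_TOLERANCE <= self.value <= 1.0 + FOLD_FRACTION_TOLERANCE)


def fraction_folded(
    delta_obs: float,
    delta_0: float,
    delta_100: float,
    sigma_obs: float = 0.005,
    sigma_0: float = 0.005,
    sigma_100: float = 0.005,
    construct_id: str = "",
    condition: Condition | None = None,
    reference_ids: tuple[str, str] = ("half_reference", "cyclic_reference"),
) -> FoldFraction:
    """Fraction folded from the global-reporter splitting (ppm).

    ``delta_0`` is the unfolded-reference splitting (half peptide),
    ``delta_100`` the folded-reference splitting (macrocycle).  The error
    is first-order propagation of the three input uncertainties.
    """
    den = delta_100 - delta_0
    sep = REFERENCE_SEPARATION_MULTIPLE * float(np.hypot(sigma_0, sigma_100))
    if abs(den) <= sep:
        raise ValueError(
            f"reference collapse: |delta_100 - delta_0| = {abs(den):.4g} ppm does not "
            f"exceed {REFERENCE_SEPARATION_MULTIPLE:g}x the combined reference error "
            f"({sep:.4g} ppm); references {reference_ids[1]!r} and {reference_ids[0]!r} "
            "are uninformative"
        )
    value = (delta_obs - delta_0) / den
    # partials: dF/d_obs = 1/den; dF/d_0 = (obs - 100)/den^2; dF/d_100 = -(obs - 0)/den^2
    d_obs = 1.0 / den
    d_0 = (delta_obs - delta_100) / den**2
    d_100 = -(delta_obs - delta_0) / den**2
    sigma = float(
        np.sqrt((d_obs * sigma_obs) ** 2 + (d_0 * sigma_0) ** 2 + (d_100 * sigma_100) ** 2)
    )
    return FoldFraction(float(value), sigma, construct_id, condition)


def percent_unfolding(
    baseline: FoldFraction, salted: FoldFraction
) -> tuple[float, float]:
    """Salt-induced unfolding in percentage points of fraction folded.

    Positive values mean the salt unfolded the hairpin.  Both fractions
    must come from the same hairpin (hence the same reference constructs).
    """
    if baseline.construct_id != salted.construct_id:
        raise ValueError(
            f"percent unfolding compares different constructs: "
            f"{baseline.construct_id!r} vs {salted.construct_id!r}"
        )
    points = (baseline.value - salted.value) * 100.0
    sigma = float(np.hypot(baseline.sigma, salted.sigma)) * 100.0
    return points, sigma


def reference_correct(
    table: ShiftTable, baseline_reference_ppm: float = None
) -> ShiftTable:
    """Remove the bulk ionic-strength drift using the internal reference.

    Every shift in the table is moved by (baseline reference position -
    this condition's reference position), so the internal-reference methyl
    lands exactly on its baseline value.  The reference row is kept in the
    corrected table for audit.  Correcting twice is a no-op.
    """
    ref_rows = table.data[table.data["atom"] == ATOM_REF_METHYL]
    if ref_rows.empty:
        raise ValueError(
            f"table ({table.construct_id!r}, {table.condition.label!r}) has no "
            "internal-reference methyl row; cannot reference-correct"
        )
    ref_here = float(ref_rows.iloc[0]["delta_ppm"])
    if baseline_reference_ppm is None:
        from .synthetic import ACETYL_REF_PPM

        baseline_reference_ppm = ACETYL_REF_PPM
    offset = baseline_reference_ppm - ref_here
    if abs(offset) > REFERENCE_DRIFT_WARN_PPM:
        warnings.warn(
            f"internal-reference correction of {offset:+.3f} ppm for "
            f"({table.construct_id!r}, {table.condition.label!r}) exceeds "
            f"{REFERENCE_DRIFT_WARN_PPM} ppm; check the reference assignment",
            stacklevel=2,
        )
    data = table.data.copy()
    data["delta_ppm"] = data["delta_ppm"] + offset
    return table.with_data(data)


@dataclass
class DeltaShiftMap:
    """Per-residue chemical-shift perturbations between two states.

    ``data`` has one row per parent-hairpin residue with columns
    ``residue``, ``delta_ppm`` (Delta-delta = delta_B - delta_A), ``sigma_ppm``,
    ``direction`` (downfield / upfield / insignificant / missing).
    """

    data: pd.DataFrame
    from_id: str
    to_id: str
    significance_multiple: float = DEFAULT_SIGNIFICANCE_MULTIPLE

    def negate(self) -> "DeltaShiftMap":
        out = self.data.copy()
        out["delta_ppm"] = -out["delta_ppm"]
        flip = {"downfield": "upfield", "upfield": "downfield"}
        out["direction"] = out["direction"].map(lambda d: flip.get(d, d))
        return DeltaShiftMap(out, self.to_id, self.from_id, self.significance_multiple)


def _classify(delta: float, sigma: float, multiple: float) -> str:
    if abs(delta) <= multiple * sigma:
        return "insignificant"
    return "downfield" if delta > 0 else "upfield"


def delta_shift_map(
    table_a: ShiftTable,
    table_b: ShiftTable,
    construct_a: PeptideConstruct | None = None,
    construct_b: PeptideConstruct | None = None,
    significance_multiple: float = DEFAULT_SIGNIFICANCE_MULTIPLE,
    atom: str = ATOM_NH,
) -> DeltaShiftMap:
    """Per-residue Delta-delta = delta_B - delta_A on the parent residue frame.

    Residues are matched through each construct's alignment onto the
    parent hairpin (identity when no construct is given).  A residue
    present in only one table appears in the map with direction
    ``"missing"`` and NaN shift — it is never silently dropped.
    Significance: |Delta-delta| must exceed ``significance_multiple`` times the
    root-sum-square of the two input errors.
    """

    def parent_frame(table: ShiftTable, construct: PeptideConstruct | None):
        rows = {}
        for r in table.residues(atom):
            parent = construct.to_parent(r) if construct is not None else r
            rows[parent] = table.get(r, atom)
        return rows

    a = parent_frame(table_a, construct_a)
    b = parent_frame(table_b, construct_b)
    out = []
    for residue in sorted(set(a) | set(b)):
        if residue in a and residue in b:
            da, sa = a[residue]
            db, sb = b[residue]
            delta = db - da
            sigma = float(np.hypot(sa, sb))
            out.append(
                {
                    "residue": residue,
                    "delta_ppm": delta,
                    "sigma_ppm": sigma,
                    "direction": _classify(delta, sigma, significance_multiple),
                }
            )
        else:
            out.append(
                {
                    "residue": residue,
                    "delta_ppm": np.nan,
                    "sigma_ppm": np.nan,
                    "direction": "missing",
                }
            )
    return DeltaShiftMap(
        pd.DataFrame(out),
        from_id=table_a.construct_id,
        to_id=table_b.construct_id,
        significance_multiple=significance_multiple,
    )
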