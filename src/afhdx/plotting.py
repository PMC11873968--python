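"""Per-residue bubble maps rendered on a schematic hairpin layout.

Residues 1..6 run along the top strand, 12..7 antiparallel along the
bottom, with the turn on the right.  Circle *area* is proportional to
the plotted magnitude; sign is encoded by colour (shift maps: downfield
blue / upfield red; rate-change maps: increase green / attenuation
yellow).  The area scale is exposed as a parameter so maps can share a
common scale across figures.  Output is vector SVG and is bit-stable for
fixed input (fixed hash salt, no embedded dates).
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["bubble_map", "save_delta_shift_map", "save_afhdx_map"]

plt.rcParams["svg.hashsalt"] = "afhdx"

SHIFT_COLOURS = {"positive": "#2c5aa0", "negative": "#c0392b"}   # downfield blue / upfield red
RATE_COLOURS = {"positive": "#27ae60", "negative": "#d4a017"}    # increase green / attenuation yellow


def _hairpin_layout(n: int) -> dict[int, tuple[float, float]]:
    half = n // 2
    layout = {}
    for i in range(1, half + 1):
        layout[i] = (float(i - 1), 1.0)
    for i in range(half + 1, n + 1):
        layout[i] = (float(n - i), 0.0)
    return layout


def bubble_map(
    residues,
    values,
    sigmas,
    sequence: str,
    colours: dict[str, str],
    path,
    scale: float | None = None,
    title: str = "",
    unit: str = "",
) -> None:
    """Render one bubble map to SVG.  ``scale`` is the magnitude mapped to
    the reference bubble area; default is the per-figure maximum."""
    residues = np.asarray(residues, dtype=int)
    values = np.asarray(values, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    layout = _hairpin_layout(len(sequence))
    finite = np.isfinite(values)
    vmax = scale if scale is not None else (np.abs(values[finite]).max() if finite.any() else 1.0)
    vmax = max(vmax, 1e-12)
    area_ref = 1200.0  # pt^2 for |value| == vmax

    fig, ax = plt.subplots(figsize=(7.0, 3.2))
    for r, v, s in zip(residues, values, sigmas):
        x, y = layout[int(r)]
        if not np.isfinite(v):
            ax.plot(x, y, marker="x", color="grey", markersize=6)
            continue
        colour = colours["positive"] if v > 0 else colours["negative"]
        ax.scatter([x], [y], s=area_ref * abs(v) / vmax, c=colour, alpha=0.75, zorder=3)
        if np.isfinite(s) and s > 0:
            half_w = 0.38 * min(s / vmax, 1.0)
            ax.plot([x - half_w, x + half_w], [y - 0.28, y - 0.28], color="#c0392b",
                    lw=1.2, zorder=2)
    for r, (x, y) in layout.items():
        ax.annotate(f"{sequence[r - 1]}{r}", (x, y), textcoords="offset points",
                    xytext=(0, 14), ha="center", fontsize=8)
    # reference bubble
    ax.scatter([len(sequence) / 2 - 0.5], [-0.6], s=area_ref, facecolors="none",
               edgecolors="black")
    ax.annotate(f"scale: {vmax:.3g} {unit}", (len(sequence) / 2 - 0.5, -0.6),
                textcoords="offset points", xytext=(24, -4), fontsize=8)
    ax.set_xlim(-0.8, len(sequence) / 2 + 0.5)
    ax.set_ylim(-1.1, 1.6)
    ax.set_axis_off()
    if title:
        ax.set_title(title, fontsize=10)
    fig.savefig(path, format="svg", metadata={"Date": None}, bbox_inches="tight")
    plt.close(fig)


def save_delta_shift_map(ddmap, sequence: str, path, scale: float | None = None) -> None:
    """Figure for a chemical-shift perturbation map (downfield blue, upfield red)."""
    df: pd.DataFrame = ddmap.data
    bubble_map(
        df["residue"], df["delta_ppm"], df["sigma_ppm"], sequence, SHIFT_COLOURS,
        path, scale=scale, title=f"Δδ: {ddmap.from_id} → {ddmap.to_id}",
        unit="ppm",
    )


def save_afhdx_map(afmap, sequence: str, path, scale: float | None = None) -> None:
    """Figure for an AF-HDX %-rate-change map (increase green, attenuation yellow)."""
    df: pd.DataFrame = afmap.data
    bubble_map(
        df["residue"], df["pct_change"], df["sigma_pct"], sequence, RATE_COLOURS,
        path, scale=scale,
        title=f"%Δk: {afmap.baseline_label} → {afmap.salt_label}",
        unit="%",
    )
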