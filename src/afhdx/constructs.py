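"""Peptide constructs, experimental conditions and shift-table containers.

The study design compares a 12-mer beta-hairpin against two kinds of
reference constructs: a disulfide-constrained macrocycle standing in for
the fully folded state (fraction folded = 1) and capped 6-mer half
peptides standing in for the fully unfolded state (fraction folded = 0).
Residue indexing is 1-based on the parent hairpin (R1 ... Q12); ornithine
is the non-standard one-letter code ``O``.  Capping groups (N-terminal
acetyl, C-terminal amide) are metadata, never residues.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ATOM_NH",
    "ATOM_REPORTER_SPLIT",
    "ATOM_REF_METHYL",
    "PeptideConstruct",
    "Condition",
    "ShiftTable",
    "default_constructs",
    "HAIRPIN_SEQUENCE",
]

#: atom-class labels used in every shift table
ATOM_NH = "NH"                      # mainchain amide N-H proton
ATOM_REPORTER_SPLIT = "CAH2_SPLIT"  # diastereotopic Gly CaH2 splitting (global reporter)
ATOM_REF_METHYL = "REF_METHYL"      # N-terminal acetyl methyl, internal reference

_VALID_ROLES = ("hairpin", "cyclic_reference", "half_reference")

#: parent hairpin sequence used throughout (Ac-RWVTVNGOKILQ-NH2); O = ornithine
HAIRPIN_SEQUENCE = "RWVTVNGOKILQ"

#: residue codes the package accepts (20 canonical + ornithine)
VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY") | {"O"}


@dataclass(frozen=True)
class PeptideConstruct:
    """A peptide construct and its alignment onto the parent hairpin.

    ``alignment`` maps this construct's own 1-based residue indices to the
    parent hairpin's 1-based indices.  For the hairpin itself and for the
    macrocycle the map is the identity over the shared sequence; half
    peptides cover either residues 1-6 or 7-12.  Alignments are stated
    explicitly in metadata, never inferred from sequence overlap.
    """

    id: str
    sequence: str
    role: str
    alignment: dict[int, int] = field(default_factory=dict)
    parent: str | None = None
    n_cap: str = "Ac"
    c_cap: str = "NH2"

    def __post_init__(self) -> None:
        if self.role not in _VALID_ROLES:
            raise ValueError(
                f"construct {self.id!r}: role {self.role!r} not one of {_VALID_ROLES}"
            )
        bad = [c for c in self.sequence if c not in VALID_RESIDUES]
        if bad:
            raise ValueError(f"construct {self.id!r}: unknown residue code(s) {bad}")
        if not self.alignment:
            object.__setattr__(
                self, "alignment", {i: i for i in range(1, len(self.sequence) + 1)}
            )
        targets = list(self.alignment.values())
        if len(set(targets)) != len(targets):
            raise ValueError(f"construct {self.id!r}: alignment is not injective")
        for src, dst in self.alignment.items():
            if not 1 <= src <= len(self.sequence):
                raise ValueError(
                    f"construct {self.id!r}: alignment source index {src} outside sequence"
                )
            if dst < 1:
                raise ValueError(
                    f"construct {self.id!r}: alignment target index {dst} must be >= 1"
                )

    def to_parent(self, residue: int) -> int:
        """Map this construct's residue index onto the parent hairpin."""
        try:
            return self.alignment[residue]
        except KeyError:
            raise KeyError(
                f"construct {self.id!r} has no alignment for residue {residue}"
            ) from None


@dataclass(frozen=True)
class Condition:
    """A solution condition: anion identity and concentration, pH, buffer.

    Concentration is in mM.  ``anion=None`` (or "none") denotes the
    salt-free baseline (50 mM phosphate buffer only).
    """

    anion: str | None = None
    concentration_mM: float = 0.0
    pH: float = 2.3
    buffer: str = "50 mM sodium phosphate"
    recipient_mM: float = 1.0  # total peptide ("host") concentration

    def __post_init__(self) -> None:
        if self.concentration_mM < 0:
            raise ValueError(
                f"condition {self.label!r}: negative anion concentration "
                f"({self.concentration_mM} mM)"
            )
        anion = self.anion
        if anion is not None and anion.lower() in ("none", ""):
            object.__setattr__(self, "anion", None)

    @property
    def concentration_M(self) -> float:
        return self.concentration_mM / 1000.0

    @property
    def is_baseline(self) -> bool:
        return self.anion is None or self.concentration_mM == 0.0

    @property
    def equivalents(self) -> float:
        """Anion equivalents relative to the recipient peptide."""
        if self.recipient_mM == 0:
            return float("nan")
        return self.concentration_mM / self.recipient_mM

    @property
    def label(self) -> str:
        if self.is_baseline:
            return "baseline"
        return f"{self.anion}_{self.concentration_mM:g}mM"


#: canonical shift-table columns
SHIFT_COLUMNS = ["residue", "atom", "delta_ppm", "sigma_ppm"]

#: default chemical-shift uncertainty (ppm), the typical peak-position error
DEFAULT_SHIFT_SIGMA = 0.005


@dataclass
class ShiftTable:
    """Residue-assigned chemical shifts for one construct under one condition.

    ``data`` holds one row per (residue, atom class) with columns
    ``residue`` (int; 0 for the cap-attached internal-reference methyl),
    ``atom`` (one of the ATOM_* labels), ``delta_ppm`` and ``sigma_ppm``.
    """

    construct_id: str
    condition: Condition
    data: pd.DataFrame
    seed: int | None = None

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        missing = [c for c in SHIFT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"shift table missing column(s) {missing}")
        df = df[SHIFT_COLUMNS].copy()
        df["residue"] = df["residue"].astype(int)
        dup = df.duplicated(subset=["residue", "atom"])
        if dup.any():
            rows = df.index[dup].tolist()
            raise ValueError(
                f"shift table for {self.construct_id!r}: duplicate (residue, atom) "
                f"at row(s) {rows}"
            )
        if (df["sigma_ppm"] <= 0).any():
            raise ValueError("shift table: sigma_ppm must be > 0 for every row")
        self.data = df.reset_index(drop=True)

    def get(self, residue: int, atom: str = ATOM_NH) -> tuple[float, float]:
        """Return (delta, sigma) in ppm for one (residue, atom) row."""
        sel = self.data[(self.data["residue"] == residue) & (self.data["atom"] == atom)]
        if sel.empty:
            raise KeyError(
                f"no {atom} row for residue {residue} in table "
                f"({self.construct_id!r}, {self.condition.label!r})"
            )
        row = sel.iloc[0]
        return float(row["delta_ppm"]), float(row["sigma_ppm"])

    def has(self, residue: int, atom: str = ATOM_NH) -> bool:
        return bool(
            ((self.data["residue"] == residue) & (self.data["atom"] == atom)).any()
        )

    def residues(self, atom: str = ATOM_NH) -> list[int]:
        return sorted(self.data.loc[self.data["atom"] == atom, "residue"].tolist())

    def with_data(self, data: pd.DataFrame) -> "ShiftTable":
        return ShiftTable(self.construct_id, self.condition, data, seed=self.seed)


def default_constructs(sequence: str = HAIRPIN_SEQUENCE) -> dict[str, PeptideConstruct]:
    """The standard construct registry for a 12-mer hairpin study.

    Returns the hairpin, its cystine-bridged macrocycle (fully folded
    reference) and the N-/C-terminal half peptides (unfolded references,
    aligned to residues 1-6 and 7-12 of the parent).
    """
    n = len(sequence)
    half = n // 2
    hairpin = PeptideConstruct("hairpin", sequence, "hairpin")
    cyclic = PeptideConstruct(
        "cyclic",
        sequence,
        "cyclic_reference",
        parent="hairpin",
    )
    n_half = PeptideConstruct(
        "half_N",
        sequence[:half],
        "half_reference",
        alignment={i: i for i in range(1, half + 1)},
        parent="hairpin",
    )
    c_half = PeptideConstruct(
        "half_C",
        sequence[half:],
        "half_reference",
        alignment={i: i + half for i in range(1, n - half + 1)},
        parent="hairpin",
    )
    return {c.id: c for c in (hairpin, cyclic, n_half, c_half)}


def merge_condition(cond: Condition, **changes) -> Condition:
    return replace(cond, **changes)
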