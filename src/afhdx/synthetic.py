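"""Forward-model generator for AF-HDX study data with known ground truth.

The generator emulates the observables of a salt-titration NMR study of a
12-mer beta-hairpin: per-residue mainchain amide N-H chemical shifts, the
diastereotopic Gly CaH2 splitting used as a global folding reporter,
internal-reference acetyl methyl shifts, and per-residue amide H/D
exchange decays.  Everything flows from a small thermodynamic model:

* Two-state folding with equilibrium constant ``K_fold = [F]/[U]`` at
  zero salt.
* Linkage: the anion binds the unfolded (open) state with a single-site
  association constant ``Ka_anion`` (M^-1), so added salt pulls the
  equilibrium toward the unfolded side,

      f_F([A]) = K_fold / (K_fold + (1 + Ka_anion * [A])**n_sites).

* Observed shifts are fast-exchange population averages of folded and
  unfolded state shifts plus additive Gaussian noise (peak positions).
* HDX follows the EX2 limit: exchange happens from open states at the
  intrinsic (unstructured) rate; folded-state amides are protected by a
  per-residue protection factor ``PF``; anion-bound open states exchange
  faster by a per-residue deprotection multiplier:

      k_obs = k_int * [ (1 - f_F) * ((1 - f_b) + f_b * deprotect)
                        + f_F / PF ],

  with ``f_b = Ka*[A]/(1 + Ka*[A])`` the bound fraction of the open
  population.  Intensities decay as ``exp(-k_obs t)`` with multiplicative
  Gaussian noise (peak heights).
* Intrinsic rates use a deliberately simple hydronium(acid)-catalysis
  law: log10(k_int) rises with slope 1 toward lower pH from a reference
  rate, scaled by a packaged per-residue side-chain context factor.

No spectral simulation is attempted: the generator produces peak-level
observables only.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .constructs import (
    ATOM_NH,
    ATOM_REF_METHYL,
    ATOM_REPORTER_SPLIT,
    DEFAULT_SHIFT_SIGMA,
    HAIRPIN_SEQUENCE,
    Condition,
    ShiftTable,
)

__all__ = [
    "KintParams",
    "ForwardModelParams",
    "SimulationOutput",
    "default_params",
    "scenario_params",
    "simulate_fold_fraction",
    "simulate_shift_table",
    "simulate_hdx_timecourse",
    "simulate_titration_series",
    "intrinsic_rate",
    "intrinsic_rates",
    "simulate_study",
    "write_truth",
    "read_truth",
]

# ---------------------------------------------------------------------------
# intrinsic-rate model
# ---------------------------------------------------------------------------

#: per-residue side-chain context factors for acid-catalysed amide exchange.
#: Deliberately coarse: beta-branched and bulky side chains slow exchange,
#: glycine speeds it.  Values are multiplicative relative to alanine.
CONTEXT_FACTORS: dict[str, float] = {
    "G": 1.35, "A": 1.00, "S": 1.05, "T": 0.80, "C": 1.10,
    "V": 0.60, "L": 0.75, "I": 0.60, "M": 0.90, "P": 0.75,
    "F": 0.85, "W": 0.85, "Y": 0.85, "H": 0.90, "K": 0.90,
    "R": 0.85, "D": 0.90, "E": 0.85, "N": 1.10, "Q": 0.95,
    "O": 0.95,  # ornithine
}

#: extra acceleration for the N-terminal-most amide (no preceding residue,
#: frayed terminus); applied in place of the left-neighbour factor.
N_TERMINAL_FACTOR = 2.0

_R_GAS = 8.314462618e-3  # kJ/(mol K)


@dataclass(frozen=True)
class KintParams:
    """Constants of the simplified acid-catalysis intrinsic-rate law."""

    k_ref: float = 0.5          # min^-1 for an alanine-context amide at pH_ref
    pH_ref: float = 2.3
    acid_slope: float = 1.0     # d log10(k) / d(-pH)
    activation_kJ: float = 17.0  # Arrhenius activation energy
    T_ref: float = 298.15       # K

    def __post_init__(self) -> None:
        if self.k_ref <= 0:
            raise ValueError("k_ref must be positive")


def intrinsic_rate(
    residue_context: str,
    pH: float,
    temperature: float = 298.15,
    kint_params: KintParams | None = None,
) -> float:
    """Intrinsic (unstructured) exchange rate of one amide, min^-1.

    ``residue_context`` is the amide's own residue label optionally
    preceded by its left neighbour's label (e.g. ``"RW"`` for the W2
    amide of R1-W2...); a single label means the N-terminal-most amide.
    Only the acid-catalysed branch is modelled, so ``pH`` must be < 7.
    """
    if not 0 < len(residue_context) <= 2:
        raise ValueError(
            f"residue context must be 1 or 2 labels, got {residue_context!r}"
        )
    if pH >= 7:
        raise ValueError("only the acid-catalysed branch is modelled (pH < 7)")
    p = kint_params or KintParams()
    own = residue_context[-1]
    for label in residue_context:
        if label not in CONTEXT_FACTORS:
            raise KeyError(f"unknown residue label {label!r}")
    if len(residue_context) == 2:
        left = CONTEXT_FACTORS[residue_context[0]]
    else:
        left = N_TERMINAL_FACTOR
    ctx = float(np.sqrt(left * CONTEXT_FACTORS[own]))
    acid = 10.0 ** (p.acid_slope * (p.pH_ref - pH))
    arrh = np.exp(-p.activation_kJ / _R_GAS * (1.0 / temperature - 1.0 / p.T_ref))
    return p.k_ref * ctx * acid * float(arrh)


def intrinsic_rates(
    sequence: str,
    pH: float,
    temperature: float = 298.15,
    kint_params: KintParams | None = None,
) -> np.ndarray:
    """Vector of intrinsic rates for every amide of ``sequence`` (1-based order)."""
    out = np.empty(len(sequence))
    for i, res in enumerate(sequence):
        ctx = res if i == 0 else sequence[i - 1] + res
        out[i] = intrinsic_rate(ctx, pH, temperature, kint_params)
    return out


# ---------------------------------------------------------------------------
# forward-model parameters
# ---------------------------------------------------------------------------

# plausible random-coil amide shifts (ppm) and folded-state offsets for the
# default hairpin; downfield (positive) offsets for hydrogen-bonded /
# sheet-like amides, upfield for R1 (frayed terminus), O8 (turn i+3) and
# L11 (indole ring current).
_DELTA_U_DEFAULT = np.array(
    [8.25, 8.15, 8.05, 8.20, 8.10, 8.45, 8.35, 8.30, 8.25, 8.10, 8.20, 8.15]
)
_FOLD_OFFSET_DEFAULT = np.array(
    [-0.10, 0.30, 0.45, 0.15, 0.40, 0.35, 0.20, -0.25, 0.25, 0.40, -0.15, 0.20]
)
# protection factors: strong in the cation-pi-hydrophobic core (V3, V5,
# I10, W2), weak at the frayed termini and the turn's exposed amides.
_PF_DEFAULT = np.array(
    [2.0, 60.0, 100.0, 12.0, 100.0, 2.5, 8.0, 6.0, 15.0, 100.0, 10.0, 5.0]
)

#: nominal acetyl-methyl internal reference position, ppm
ACETYL_REF_PPM = 2.05


@dataclass
class ForwardModelParams:
    """Ground-truth parameters of the linkage + EX2 forward model.

    Per-residue arrays (``delta_F``, ``delta_U``, ``PF``, ``deprotect``,
    ``bound_shift``) are indexed by the hairpin sequence, 1-based residue i
    at array position i-1.
    """

    sequence: str = HAIRPIN_SEQUENCE
    K_fold: float = 3.7619          # [F]/[U] at zero salt -> 79% folded
    Ka_anion: float = 1.5           # M^-1, single-site binding to the open state
    n_sites: int = 1                # multi-site linkage extension (default 1)
    delta_F: np.ndarray = field(default_factory=lambda: _DELTA_U_DEFAULT + _FOLD_OFFSET_DEFAULT)
    delta_U: np.ndarray = field(default_factory=lambda: _DELTA_U_DEFAULT.copy())
    reporter_split_F: float = 0.56  # ppm, Gly CaH2 splitting, folded
    reporter_split_U: float = 0.01  # ppm, half-peptide splitting (near zero)
    reporter_residue: int = 7
    PF: np.ndarray = field(default_factory=lambda: _PF_DEFAULT.copy())
    deprotect: np.ndarray = field(default_factory=lambda: np.ones(12))
    bound_shift: np.ndarray = field(default_factory=lambda: np.zeros(12))
    kint_params: KintParams = field(default_factory=KintParams)
    shift_noise_sd: float = 0.005       # ppm, additive on peak positions
    intensity_noise_sd: float = 0.02    # fractional, multiplicative on peak heights
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("delta_F", "delta_U", "PF", "deprotect", "bound_shift"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.sequence)
        for name in ("delta_F", "delta_U", "PF", "deprotect", "bound_shift"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(
                    f"{name} has shape {arr.shape}; expected ({n},) matching the "
                    f"residue set of {self.sequence!r}"
                )
        if self.K_fold <= 0:
            raise ValueError("K_fold must be > 0")
        if self.Ka_anion < 0:
            raise ValueError("Ka_anion must be >= 0")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if (self.PF < 1).any():
            raise ValueError("all protection factors must be >= 1")
        if (self.deprotect < 1).any():
            raise ValueError("all deprotection multipliers must be >= 1")
        if self.shift_noise_sd < 0 or self.intensity_noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    def residue_index(self, residue: int) -> int:
        if not 1 <= residue <= self.n_residues:
            raise IndexError(f"residue {residue} outside 1..{self.n_residues}")
        return residue - 1


def default_params(**overrides) -> ForwardModelParams:
    """The standard ground-truth preset: 79% folded baseline, weak binding."""
    return ForwardModelParams(**overrides)


def scenario_params(scenario: str, deprotect_factor: float = 8.0, **overrides) -> ForwardModelParams:
    """Mechanistic presets for where anion binding loosens the structure.

    ``"terminal_chelation"`` deprotects the terminal pincer residues
    {1, 12} (charge-dense anion chelated by the terminal N-H groups);
    ``"core_intercalation"`` deprotects residues {2, 9, 10, 11} around the
    cation-pi-hydrophobic core (charge-diffuse anion intercalation).
    """
    sites = {
        "terminal_chelation": (1, 12),
        "core_intercalation": (2, 9, 10, 11),
    }
    if scenario not in sites:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(sites)}")
    params = ForwardModelParams(**overrides)
    dep = np.ones(params.n_residues)
    for r in sites[scenario]:
        dep[r - 1] = deprotect_factor
    params.deprotect = dep
    return params


# ---------------------------------------------------------------------------
# deterministic model evaluation
# ---------------------------------------------------------------------------

def simulate_fold_fraction(params: ForwardModelParams, anion_conc: float) -> float:
    """Fraction folded under the linkage model at anion concentration (M).

    Deterministic and noise-free:
    ``f_F = K_fold / (K_fold + (1 + Ka*[A])**n_sites)``.
    """
    if anion_conc < 0:
        raise ValueError(
            f"negative anion concentration {anion_conc} M in fold-fraction evaluation"
        )
    open_weight = (1.0 + params.Ka_anion * anion_conc) ** params.n_sites
    return params.K_fold / (params.K_fold + open_weight)


def bound_fraction_open(params: ForwardModelParams, anion_conc: float) -> float:
    """Fraction of the open (unfolded) population that is anion-bound."""
    x = params.Ka_anion * anion_conc
    return x / (1.0 + x)


def true_exchange_rate(
    params: ForwardModelParams, condition: Condition
) -> np.ndarray:
    """Noise-free EX2 observed rates (min^-1) for every hairpin residue."""
    f_F = simulate_fold_fraction(params, condition.concentration_M)
    f_b = bound_fraction_open(params, condition.concentration_M)
    k_int = intrinsic_rates(params.sequence, condition.pH, kint_params=params.kint_params)
    open_term = (1.0 - f_F) * ((1.0 - f_b) + f_b * params.deprotect)
    return k_int * (open_term + f_F / params.PF)


# ---------------------------------------------------------------------------
# stochastic table generation
# ---------------------------------------------------------------------------

def _fold_fraction_for_role(params: ForwardModelParams, condition: Condition, role: str) -> float:
    # reference constructs are pinned: salt effects on them are negligible
    if role == "cyclic_reference":
        return 1.0
    if role == "half_reference":
        return 0.0
    return simulate_fold_fraction(params, condition.concentration_M)


def simulate_shift_table(
    params: ForwardModelParams,
    condition: Condition,
    seed: int,
    construct_id: str = "hairpin",
    role: str = "hairpin",
    residues: Sequence[int] | None = None,
    reference_offset: float = 0.0,
) -> ShiftTable:
    """One shift table: population-averaged shifts plus peak-position noise.

    ``reference_offset`` emulates a bulk ionic-strength drift applied
    uniformly to every signal of this condition, including the internal
    reference methyl — exactly what internal referencing removes.
    ``residues`` restricts the table to a subset (half peptides).
    """
    if condition.concentration_M > 1.0:
        raise ValueError(
            f"condition {condition.label!r}: concentration outside model validity (> 1 M)"
        )
    rng = np.random.default_rng(seed)
    f_F = _fold_fraction_for_role(params, condition, role)
    f_b = bound_fraction_open(params, condition.concentration_M)
    idx = (
        np.array([params.residue_index(r) for r in residues])
        if residues is not None
        else np.arange(params.n_residues)
    )
    d_open = params.delta_U[idx] + f_b * params.bound_shift[idx]
    delta = f_F * params.delta_F[idx] + (1.0 - f_F) * d_open
    delta = delta + reference_offset + rng.normal(0.0, params.shift_noise_sd, size=idx.size)

    rows = [
        {
            "residue": int(i + 1),
            "atom": ATOM_NH,
            "delta_ppm": float(d),
            "sigma_ppm": max(params.shift_noise_sd, DEFAULT_SHIFT_SIGMA),
        }
        for i, d in zip(idx, delta)
    ]
    # global reporter: Gly CaH2 splitting, interpolated the same way
    rep = params.reporter_residue
    if residues is None or rep in set(residues):
        split = f_F * params.reporter_split_F + (1.0 - f_F) * params.reporter_split_U
        split += rng.normal(0.0, params.shift_noise_sd)
        rows.append(
            {
                "residue": rep,
                "atom": ATOM_REPORTER_SPLIT,
                "delta_ppm": float(split),
                "sigma_ppm": max(params.shift_noise_sd, DEFAULT_SHIFT_SIGMA),
            }
        )
    # internal reference: acetyl methyl rides the bulk offset only
    ref = ACETYL_REF_PPM + reference_offset + rng.normal(0.0, params.shift_noise_sd)
    rows.append(
        {
            "residue": 0,
            "atom": ATOM_REF_METHYL,
            "delta_ppm": float(ref),
            "sigma_ppm": max(params.shift_noise_sd, DEFAULT_SHIFT_SIGMA),
        }
    )
    return ShiftTable(construct_id, condition, pd.DataFrame(rows), seed=seed)


def simulate_hdx_timecourse(
    params: ForwardModelParams,
    condition: Condition,
    times: Sequence[float],
    seed: int,
    construct_id: str = "hairpin",
    role: str = "hairpin",
):
    """Per-residue HDX intensity decays under EX2, with height noise.

    Returns ``(timecourses, truth_rates)`` where ``timecourses`` is a list
    of :class:`~afhdx.kinetics.HDXTimeCourse` (one per residue, all sharing
    ``times``) and ``truth_rates`` maps residue -> noise-free k_obs.
    """
    from .kinetics import HDXTimeCourse  # deferred: avoid import cycle

    times = np.asarray(times, dtype=float)
    if times.size < 4:
        raise ValueError("need >= 4 time points for a determined rate fit downstream")
    if times[0] != 0.0 or (np.diff(times) <= 0).any() or (times < 0).any():
        raise ValueError("times must be sorted, nonnegative and include 0")

    rng = np.random.default_rng(seed)
    if role == "hairpin":
        k_true = true_exchange_rate(params, condition)
    else:
        f_F = _fold_fraction_for_role(params, condition, role)
        f_b = bound_fraction_open(params, condition.concentration_M)
        k_int = intrinsic_rates(params.sequence, condition.pH, kint_params=params.kint_params)
        open_term = (1.0 - f_F) * ((1.0 - f_b) + f_b * params.deprotect)
        k_true = k_int * (open_term + f_F / params.PF)

    courses = []
    truth: dict[int, float] = {}
    for i in range(params.n_residues):
        clean = np.exp(-k_true[i] * times)
        noisy = clean * (1.0 + rng.normal(0.0, params.intensity_noise_sd, size=times.size))
        noisy = np.clip(noisy, 0.0, None)
        courses.append(
            HDXTimeCourse(
                construct_id=construct_id,
                condition=condition,
                residue=i + 1,
                times=times.copy(),
                intensities=noisy,
                sigma=max(params.intensity_noise_sd, 1e-6),
            )
        )
        truth[i + 1] = float(k_true[i])
    return courses, truth


def simulate_titration_series(
    Ka: float,
    delta_free: float,
    delta_max: float,
    concentrations_M: Sequence[float],
    recipient_M: float = 1e-3,
    noise_sd: float = 0.0,
    seed: int = 0,
    residue: int = 0,
    anion: str = "anion",
):
    """A referenced 1:1 fast-exchange titration series with known truth.

    The bound fraction is the exact physical root of the 1:1 binding
    quadratic in total concentrations (closed form, evaluated here
    independently of the analysis module).  Returns a
    :class:`~afhdx.binding.TitrationSeries`.
    """
    from .binding import TitrationSeries  # deferred: avoid import cycle

    G = np.asarray(concentrations_M, dtype=float)
    H = float(recipient_M)
    if Ka < 0:
        raise ValueError("Ka must be >= 0")
    if Ka == 0:
        hg = np.zeros_like(G)
    else:
        b = G + H + 1.0 / Ka
        hg = (b - np.sqrt(b * b - 4.0 * G * H)) / 2.0
    delta = delta_free + delta_max * hg / H
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        delta = delta + rng.normal(0.0, noise_sd, size=G.size)
    return TitrationSeries(
        residue=residue,
        anion=anion,
        concentrations_M=G,
        recipient_M=H,
        delta_obs=delta,
        sigma=max(noise_sd, DEFAULT_SHIFT_SIGMA),
    )


# ---------------------------------------------------------------------------
# whole-study bundle
# ---------------------------------------------------------------------------

#: default per-anion association constants (M^-1), spanning charge-dense
#: chloride to charge-diffuse perrhenate
DEFAULT_ANION_KA: dict[str, float] = {"Cl": 0.37, "ClO4": 1.5, "ReO4": 3.36}

#: default salt grid, mM (12-point titration from 0 to 650 mM)
DEFAULT_SALT_GRID_MM = (
    0.0, 25.0, 50.0, 75.0, 100.0, 150.0, 200.0, 230.0, 300.0, 400.0, 500.0, 650.0
)

#: default HDX sampling times, minutes
DEFAULT_HDX_TIMES = (0.0, 1.0, 2.0, 4.0, 8.0, 15.0, 30.0, 60.0, 120.0, 240.0, 480.0, 960.0)


@dataclass
class SimulationOutput:
    """Everything a full synthetic study emits, with its ground truth."""

    truth: ForwardModelParams
    anion_Ka: dict[str, float]
    shift_tables: list[ShiftTable]
    timecourses: dict[str, list]            # condition label -> HDXTimeCourse list
    truth_rates: dict[str, dict[int, float]]  # condition label -> residue -> k
    fold_fraction_truth: dict[str, float]     # condition label -> f_F
    titrations: list                          # TitrationSeries
    titration_truth: pd.DataFrame             # residue x anion truth Ka
    seed: int

    def __post_init__(self) -> None:
        for lbl, f in self.fold_fraction_truth.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fold fraction truth for {lbl!r} outside [0, 1]")


def _stage_seed(seed: int, stage: int) -> int:
    """Fan a study seed out into per-stage substream seeds (< 2**31)."""
    return int(np.random.default_rng([seed, stage]).integers(0, 2**31 - 1))


def simulate_study(
    params: ForwardModelParams | None = None,
    anion_Ka: Mapping[str, float] | None = None,
    salt_grid_mM: Sequence[float] = DEFAULT_SALT_GRID_MM,
    titration_grid_mM: Sequence[float] | None = None,
    hdx_times: Sequence[float] = DEFAULT_HDX_TIMES,
    hdx_salt_mM: float = 230.0,
    seed: int | None = None,
) -> SimulationOutput:
    """Generate a full synthetic AF-HDX study.

    Emits, for each anion: shift tables for the hairpin across the salt
    grid plus cyclic and half-peptide reference tables, HDX time courses
    at baseline and at ``hdx_salt_mM``, and per-residue titration series
    (truth Ka equal to the anion's association constant).  All randomness
    flows from a single seed fanned out per stage.
    """
    params = params or default_params()
    anions = dict(anion_Ka or DEFAULT_ANION_KA)
    if titration_grid_mM is None:
        titration_grid_mM = (
            salt_grid_mM if len(salt_grid_mM) >= 6 else DEFAULT_SALT_GRID_MM
        )
    seed = params.seed if seed is None else seed

    shift_tables: list[ShiftTable] = []
    timecourses: dict[str, list] = {}
    truth_rates: dict[str, dict[int, float]] = {}
    fold_truth: dict[str, float] = {}
    titrations = []
    ka_rows = []

    stage = 0
    baseline = Condition()
    n = params.n_residues
    half = n // 2

    # reference constructs at baseline (salt effects on them are negligible)
    for cid, role, residues in (
        ("cyclic", "cyclic_reference", None),
        ("half_N", "half_reference", tuple(range(1, half + 1))),
        ("half_C", "half_reference", tuple(range(half + 1, n + 1))),
    ):
        stage += 1
        shift_tables.append(
            simulate_shift_table(
                params, baseline, _stage_seed(seed, stage), cid, role, residues
            )
        )

    seen_shift_labels: set[str] = set()
    for anion, ka in sorted(anions.items()):
        p = dataclasses.replace(params, Ka_anion=ka)
        for conc in salt_grid_mM:
            cond = Condition(anion=anion if conc > 0 else None, concentration_mM=conc)
            if cond.label in seen_shift_labels:
                continue
            seen_shift_labels.add(cond.label)
            stage += 1
            shift_tables.append(
                simulate_shift_table(p, cond, _stage_seed(seed, stage), "hairpin", "hairpin")
            )
            fold_truth[cond.label] = simulate_fold_fraction(p, cond.concentration_M)
        for conc in (0.0, hdx_salt_mM):
            cond = Condition(anion=anion if conc > 0 else None, concentration_mM=conc)
            if cond.label in timecourses:
                continue
            stage += 1
            tcs, kt = simulate_hdx_timecourse(
                p, cond, hdx_times, _stage_seed(seed, stage)
            )
            timecourses[cond.label] = tcs
            truth_rates[cond.label] = kt
        # per-residue titrations: each residue reports the same weak binding
        # event; truth Ka is the anion's constant, the shift amplitude varies
        for r in range(1, n + 1):
            stage += 1
            dmax = -(params.delta_F[r - 1] - params.delta_U[r - 1]) * params.K_fold / (
                params.K_fold + 1.0
            )
            if abs(dmax) < 0.02:
                dmax = -0.05  # keep every residue's series informative
            titrations.append(
                simulate_titration_series(
                    Ka=ka,
                    delta_free=params.delta_U[r - 1],
                    delta_max=dmax,
                    concentrations_M=np.asarray(titration_grid_mM) / 1000.0,
                    recipient_M=baseline.recipient_mM / 1000.0,
                    noise_sd=params.shift_noise_sd,
                    seed=_stage_seed(seed, stage),
                    residue=r,
                    anion=anion,
                )
            )
            ka_rows.append({"residue": r, "anion": anion, "Ka_true": ka})

    return SimulationOutput(
        truth=params,
        anion_Ka=anions,
        shift_tables=shift_tables,
        timecourses=timecourses,
        truth_rates=truth_rates,
        fold_fraction_truth=fold_truth,
        titrations=titrations,
        titration_truth=pd.DataFrame(ka_rows),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# ground-truth sidecar
# ---------------------------------------------------------------------------

def write_truth(params: ForwardModelParams, path) -> None:
    """Write the full ground-truth parameter set as a JSON sidecar."""
    d = dataclasses.asdict(params)
    for k, v in d.items():
        if isinstance(v, np.ndarray):
            d[k] = v.tolist()
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> ForwardModelParams:
    with open(path) as fh:
        d = json.load(fh)
    d["kint_params"] = KintParams(**d["kint_params"])
    return ForwardModelParams(**d)
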