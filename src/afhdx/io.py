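"""Delimited text formats for shift tables, time courses and result tables.

Every file is plain CSV preceded by ``#``-prefixed metadata lines
(``# key: value``).  Units are documented in the header: chemical shifts
in ppm, concentrations in mM (M for titration ligand grids), times in
minutes, rates in min^-1.  Readers validate the schema and report
offending row numbers; writers round-trip exactly.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .constructs import ATOM_NH, ATOM_REF_METHYL, ATOM_REPORTER_SPLIT, Condition, ShiftTable
from .kinetics import HDXTimeCourse, RateFit, RateTable
from .binding import BindingIsothermFit, TitrationSeries

__all__ = [
    "read_shift_table",
    "write_shift_table",
    "read_timecourses",
    "write_timecourses",
    "read_rate_table",
    "write_rate_table",
    "read_titrations",
    "write_titrations",
]

_VALID_ATOMS = {ATOM_NH, ATOM_REPORTER_SPLIT, ATOM_REF_METHYL}


def _parse_header(path: Path) -> tuple[dict, str, int]:
    """Split ``# key: value`` metadata from the CSV body."""
    meta: dict[str, str] = {}
    body_lines = []
    n_meta = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                n_meta += 1
                stripped = line.lstrip("#").strip()
                if ":" in stripped:
                    key, _, val = stripped.partition(":")
                    meta[key.strip()] = val.strip()
            else:
                body_lines.append(line)
    return meta, "".join(body_lines), n_meta


def _condition_from_meta(meta: dict) -> Condition:
    anion = meta.get("anion", "none")
    return Condition(
        anion=None if anion in ("none", "") else anion,
        concentration_mM=float(meta.get("concentration_mM", 0.0)),
        pH=float(meta.get("pH", 2.3)),
        buffer=meta.get("buffer", "50 mM sodium phosphate"),
        recipient_mM=float(meta.get("recipient_mM", 1.0)),
    )


def _meta_lines(pairs: dict) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in pairs.items())


def _condition_meta(cond: Condition) -> dict:
    return {
        "anion": cond.anion or "none",
        "concentration_mM": f"{cond.concentration_mM:g}",
        "pH": f"{cond.pH:g}",
        "buffer": cond.buffer,
        "recipient_mM": f"{cond.recipient_mM:g}",
    }


def _read_body(body: str, columns: list[str], path, n_meta: int) -> pd.DataFrame:
    try:
        df = pd.read_csv(_io.StringIO(body))
    except Exception as exc:
        raise ValueError(f"{path}: cannot parse CSV body: {exc}") from exc
    unknown = [c for c in df.columns if c not in columns]
    if unknown:
        raise ValueError(f"{path}: unknown column(s) {unknown}; expected {columns}")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    # file row numbers (1-based, counting metadata and the header line)
    df.index = df.index + n_meta + 2
    df.index.name = "file_row"
    return df


def _require_numeric(df: pd.DataFrame, cols: list[str], path) -> None:
    for col in cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()].tolist()
        if bad or df[col].isna().any():
            bad = bad or df.index[df[col].isna()].tolist()
            raise ValueError(f"{path}: non-numeric {col!r} at file row(s) {bad}")
        df[col] = vals


# ---------------------------------------------------------------------------
# shift tables
# ---------------------------------------------------------------------------

SHIFT_FILE_COLUMNS = ["residue", "atom", "delta_ppm", "sigma_ppm"]


def write_shift_table(table: ShiftTable, path, extra_meta: dict | None = None) -> None:
    meta = {
        "format": "afhdx shift table v1",
        "construct": table.construct_id,
        **_condition_meta(table.condition),
        "seed": "" if table.seed is None else str(table.seed),
        "units": "delta_ppm=ppm sigma_ppm=ppm concentration=mM",
    }
    meta.update(extra_meta or {})
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        table.data.to_csv(fh, index=False, lineterminator="\n")


def read_shift_table(path) -> ShiftTable:
    """Read one construct/condition shift table, validating the schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta, body, n_meta = _parse_header(path)
    df = _read_body(body, SHIFT_FILE_COLUMNS, path, n_meta)
    _require_numeric(df, ["residue", "delta_ppm", "sigma_ppm"], path)
    bad_atom = df.index[~df["atom"].isin(_VALID_ATOMS)].tolist()
    if bad_atom:
        raise ValueError(
            f"{path}: unknown atom class at file row(s) {bad_atom}; "
            f"expected one of {sorted(_VALID_ATOMS)}"
        )
    dup = df.duplicated(subset=["residue", "atom"], keep=False)
    if dup.any():
        raise ValueError(
            f"{path}: duplicate (residue, atom) rows at file row(s) "
            f"{df.index[dup].tolist()}"
        )
    seed = meta.get("seed") or None
    return ShiftTable(
        construct_id=meta.get("construct", path.stem),
        condition=_condition_from_meta(meta),
        data=df.reset_index(drop=True),
        seed=int(seed) if seed else None,
    )


# ---------------------------------------------------------------------------
# HDX time courses
# ---------------------------------------------------------------------------

TIMECOURSE_COLUMNS = ["residue", "time_min", "intensity", "sigma"]


def write_timecourses(tcs: list[HDXTimeCourse], path, extra_meta: dict | None = None) -> None:
    if not tcs:
        raise ValueError("no time courses to write")
    meta = {
        "format": "afhdx hdx timecourse v1",
        "construct": tcs[0].construct_id,
        **_condition_meta(tcs[0].condition),
        "units": "time_min=min intensity=normalized sigma=fractional",
    }
    meta.update(extra_meta or {})
    rows = []
    for tc in tcs:
        for t, i in zip(tc.times, tc.intensities):
            rows.append(
                {"residue": tc.residue, "time_min": t, "intensity": i, "sigma": tc.sigma}
            )
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        pd.DataFrame(rows).to_csv(fh, index=False, lineterminator="\n")


def read_timecourses(path) -> list[HDXTimeCourse]:
    """Read per-residue time courses; unsorted times are rejected."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta, body, n_meta = _parse_header(path)
    df = _read_body(body, TIMECOURSE_COLUMNS, path, n_meta)
    _require_numeric(df, TIMECOURSE_COLUMNS, path)
    cond = _condition_from_meta(meta)
    cid = meta.get("construct", path.stem)
    out = []
    for residue, grp in df.groupby("residue", sort=True):
        t = grp["time_min"].to_numpy()
        if (np.diff(t) <= 0).any():
            raise ValueError(
                f"{path}: times for residue {int(residue)} are not strictly "
                f"increasing (file rows {grp.index.tolist()})"
            )
        out.append(
            HDXTimeCourse(
                construct_id=cid,
                condition=cond,
                residue=int(residue),
                times=t,
                intensities=grp["intensity"].to_numpy(),
                sigma=float(grp["sigma"].iloc[0]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# rate tables
# ---------------------------------------------------------------------------

RATE_COLUMNS = [
    "residue", "k_hdx_per_min", "sigma_k_per_min", "baseline",
    "status", "group", "residual_sd", "n_points",
]


def write_rate_table(table: RateTable, path, extra_meta: dict | None = None) -> None:
    meta = {
        "format": "afhdx rate table v1",
        "construct": table.construct_id,
        **_condition_meta(table.condition),
        "units": "k_hdx_per_min=min^-1 sigma_k_per_min=min^-1",
    }
    meta.update(extra_meta or {})
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        table.frame.to_csv(fh, index=False, lineterminator="\n")


def read_rate_table(path) -> RateTable:
    path = Path(path)
    meta, body, n_meta = _parse_header(path)
    df = _read_body(body, RATE_COLUMNS, path, n_meta)
    _require_numeric(df, ["residue", "k_hdx_per_min", "sigma_k_per_min"], path)
    fits = {}
    for _, row in df.iterrows():
        r = int(row["residue"])
        fits[r] = RateFit(
            residue=r,
            k=float(row["k_hdx_per_min"]),
            sigma_k=float(row["sigma_k_per_min"]),
            baseline=float(row["baseline"]),
            status=str(row["status"]),
            residual_sd=float(row["residual_sd"]),
            n_points=int(row["n_points"]),
        )
    return RateTable(
        construct_id=meta.get("construct", path.stem),
        condition=_condition_from_meta(meta),
        fits=fits,
    )


# ---------------------------------------------------------------------------
# titration series
# ---------------------------------------------------------------------------

TITRATION_COLUMNS = ["residue", "anion", "conc_M", "delta_ppm", "sigma_ppm"]


def write_titrations(series_list: list[TitrationSeries], path, extra_meta: dict | None = None) -> None:
    if not series_list:
        raise ValueError("no titration series to write")
    meta = {
        "format": "afhdx titration v1",
        "recipient_M": f"{series_list[0].recipient_M:g}",
        "units": "conc_M=M delta_ppm=ppm sigma_ppm=ppm",
    }
    meta.update(extra_meta or {})
    rows = []
    for s in series_list:
        for g, d in zip(s.concentrations_M, s.delta_obs):
            rows.append(
                {"residue": s.residue, "anion": s.anion, "conc_M": g,
                 "delta_ppm": d, "sigma_ppm": s.sigma}
            )
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        pd.DataFrame(rows).to_csv(fh, index=False, lineterminator="\n")


def read_titrations(path) -> list[TitrationSeries]:
    path = Path(path)
    meta, body, n_meta = _parse_header(path)
    df = _read_body(body, TITRATION_COLUMNS, path, n_meta)
    _require_numeric(df, ["residue", "conc_M", "delta_ppm", "sigma_ppm"], path)
    recipient = float(meta.get("recipient_M", 1e-3))
    out = []
    for (residue, anion), grp in df.groupby(["residue", "anion"], sort=True):
        out.append(
            TitrationSeries(
                residue=int(residue),
                anion=str(anion),
                concentrations_M=grp["conc_M"].to_numpy(),
                recipient_M=recipient,
                delta_obs=grp["delta_ppm"].to_numpy(),
                sigma=float(grp["sigma_ppm"].iloc[0]),
            )
        )
    return out


def write_ka_matrix(matrix: pd.DataFrame, summary: pd.DataFrame, path_matrix, path_summary,
                    extra_meta: dict | None = None) -> None:
    meta = {"format": "afhdx Ka matrix v1", "units": "Ka=M^-1"}
    meta.update(extra_meta or {})
    with open(path_matrix, "w") as fh:
        fh.write(_meta_lines(meta))
        matrix.to_csv(fh, lineterminator="\n")
    with open(path_summary, "w") as fh:
        fh.write(_meta_lines(meta))
        summary.to_csv(fh, index=False, lineterminator="\n")
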