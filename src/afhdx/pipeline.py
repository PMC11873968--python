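"""End-to-end orchestration: config, staging, reports and provenance.

A run chains the analysis stages on either simulated or file inputs:
fold fractions from the global reporter, percent-unfolding tables,
reference-corrected chemical-shift difference maps, residue-resolved HDX
rate fits, AF-HDX percentage-change maps with region summaries, and the
per-residue Ka matrix.  Runs are deterministic given config + seed; every
output table embeds the config hash (computed over everything except the
output directory), so two runs differing only in destination produce
identical content.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .constructs import ATOM_REPORTER_SPLIT, Condition, default_constructs
from .folding import delta_shift_map, fraction_folded, percent_unfolding, reference_correct
from .kinetics import fit_rate_table
from .ratemap import build_map, region_summary
from .binding import fit_binding, ka_matrix
from . import io as afio
from . import synthetic

__all__ = ["RunConfig", "PipelineError", "load_config", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage and the offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"{stage}: {message}")
        self.stage = stage


class NoiseConfig(BaseModel):
    shift_sd_ppm: float = 0.005
    intensity_sd_frac: float = 0.02


class SimulateConfig(BaseModel):
    """Generator settings; the defaults are the study conditions."""

    preset: str = "default"  # default | terminal_chelation | core_intercalation
    K_fold: float = 3.7619
    anion_Ka: dict[str, float] = Field(
        default_factory=lambda: dict(synthetic.DEFAULT_ANION_KA)
    )
    salt_grid_mM: list[float] = Field(
        default_factory=lambda: list(synthetic.DEFAULT_SALT_GRID_MM)
    )
    hdx_salt_mM: float = 230.0
    hdx_times_min: list[float] = Field(
        default_factory=lambda: list(synthetic.DEFAULT_HDX_TIMES)
    )
    deprotect_factor: float = 8.0
    noise: NoiseConfig = Field(default_factory=NoiseConfig)

    def build_params(self, seed: int) -> synthetic.ForwardModelParams:
        common = dict(
            K_fold=self.K_fold,
            shift_noise_sd=self.noise.shift_sd_ppm,
            intensity_noise_sd=self.noise.intensity_sd_frac,
            seed=seed,
        )
        if self.preset == "default":
            return synthetic.default_params(**common)
        return synthetic.scenario_params(
            self.preset, deprotect_factor=self.deprotect_factor, **common
        )


class InputPaths(BaseModel):
    shift_tables: list[str] = Field(default_factory=list)
    timecourses: list[str] = Field(default_factory=list)
    titrations: list[str] = Field(default_factory=list)


class AnalysisOptions(BaseModel):
    significance_multiple: float = 2.0
    fast_threshold: float = 0.2      # first-point intensity censoring
    slow_multiple: float = 3.0       # detectability multiple for too-slow censoring
    degeneracy_threshold: float = 0.1
    fast_group_threshold: float = 0.2  # min^-1, fast/slow reporting split


class RunConfig(BaseModel):
    seed: int = 0
    output_dir: str = "afhdx_out"
    simulate: SimulateConfig | None = Field(default_factory=SimulateConfig)
    inputs: InputPaths | None = None
    options: AnalysisOptions = Field(default_factory=AnalysisOptions)
    make_figures: bool = True

    def config_hash(self) -> str:
        payload = self.model_dump(mode="json")
        payload.pop("output_dir", None)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def _collect_inputs(config: RunConfig):
    """Return (shift_tables, timecourses by label, titrations, truth or None)."""
    if config.inputs is not None:
        tables = [afio.read_shift_table(p) for p in config.inputs.shift_tables]
        tcs: dict[str, list] = {}
        for p in config.inputs.timecourses:
            loaded = afio.read_timecourses(p)
            if loaded:
                tcs.setdefault(loaded[0].condition.label, []).extend(loaded)
        titr = []
        for p in config.inputs.titrations:
            titr.extend(afio.read_titrations(p))
        return tables, tcs, titr, None
    params = config.simulate.build_params(config.seed)
    study = synthetic.simulate_study(
        params,
        anion_Ka=config.simulate.anion_Ka,
        salt_grid_mM=config.simulate.salt_grid_mM,
        hdx_times=config.simulate.hdx_times_min,
        hdx_salt_mM=config.simulate.hdx_salt_mM,
        seed=config.seed,
    )
    return study.shift_tables, study.timecourses, study.titrations, study


def _fold_fraction_stage(tables, options, registry):
    by_id = {}
    for t in tables:
        by_id.setdefault(t.construct_id, []).append(t)
    for needed in ("hairpin", "cyclic"):
        if needed not in by_id:
            raise PipelineError(
                "folding_quant", f"missing reference construct {needed!r} in shift tables"
            )
    reporter = 7
    cyc = by_id["cyclic"][0]
    if not cyc.has(reporter, ATOM_REPORTER_SPLIT):
        raise PipelineError("folding_quant", "cyclic table lacks the reporter splitting row")
    d100, s100 = cyc.get(reporter, ATOM_REPORTER_SPLIT)
    half = next(
        (t for ts in by_id.items() if ts[0].startswith("half") for t in ts[1]
         if t.has(reporter, ATOM_REPORTER_SPLIT)),
        None,
    )
    if half is None:
        raise PipelineError(
            "folding_quant",
            "no half-peptide table carries the reporter splitting (residue "
            f"{reporter}); cannot set the unfolded reference",
        )
    d0, s0 = half.get(reporter, ATOM_REPORTER_SPLIT)

    fractions = {}
    rows = []
    for t in sorted(by_id["hairpin"], key=lambda t: (t.condition.anion or "", t.condition.concentration_mM)):
        dobs, sobs = t.get(reporter, ATOM_REPORTER_SPLIT)
        ff = fraction_folded(
            dobs, d0, d100, sobs, s0, s100,
            construct_id=t.construct_id, condition=t.condition,
            reference_ids=(half.construct_id, cyc.construct_id),
        )
        fractions[t.condition.label] = ff
        rows.append(
            {
                "condition": t.condition.label,
                "anion": t.condition.anion or "none",
                "concentration_mM": t.condition.concentration_mM,
                "fraction_folded": ff.value,
                "sigma": ff.sigma,
                "percent_folded": ff.percent,
                "flagged": ff.flagged,
            }
        )
    return fractions, pd.DataFrame(rows)


def _percent_unfolding_stage(fractions):
    if "baseline" not in fractions:
        raise PipelineError("folding_quant", "no baseline condition among fold fractions")
    base = fractions["baseline"]
    rows = []
    for label, ff in fractions.items():
        if label == "baseline":
            continue
        points, sigma = percent_unfolding(base, ff)
        rows.append(
            {
                "condition": label,
                "anion": ff.condition.anion,
                "concentration_mM": ff.condition.concentration_mM,
                "equivalents": ff.condition.equivalents,
                "unfolding_points": points,
                "sigma_points": sigma,
            }
        )
    return pd.DataFrame(rows).sort_values(["anion", "concentration_mM"]).reset_index(drop=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis chain; returns the report bundle.

    The bundle maps stage names to DataFrames plus a provenance record;
    everything is also written under ``config.output_dir``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    meta = {"config_hash": chash, "afhdx_version": __version__, "seed": str(config.seed)}
    registry = default_constructs()
    censored_log: list[dict] = []
    degenerate_log: list[dict] = []

    tables, tcs_by_label, titrations, study = _collect_inputs(config)

    # --- stage: fold fractions and percent unfolding -----------------------
    fractions, fold_frame = _fold_fraction_stage(tables, config.options, registry)
    unfold_frame = _percent_unfolding_stage(fractions)
    _write_frame(fold_frame, outdir / "fold_fractions.csv", meta,
                 "fraction folded from the reporter CaH2 splitting (unitless; percent)")
    _write_frame(unfold_frame, outdir / "percent_unfolding.csv", meta,
                 "salt-induced unfolding in percentage points of fraction folded")

    # --- stage: delta-shift maps -------------------------------------------
    hairpin_tables = {t.condition.label: t for t in tables if t.construct_id == "hairpin"}
    if "baseline" not in hairpin_tables:
        raise PipelineError("folding_quant", "no baseline hairpin shift table")
    base_ref = hairpin_tables["baseline"].get(0, "REF_METHYL")[0]
    corrected = {
        lbl: reference_correct(t, base_ref) for lbl, t in hairpin_tables.items()
    }
    ddmaps = {}
    for lbl, t in corrected.items():
        if lbl == "baseline":
            continue
        ddmaps[lbl] = delta_shift_map(
            corrected["baseline"], t,
            significance_multiple=config.options.significance_multiple,
        )
        _write_frame(ddmaps[lbl].data, outdir / f"ddmap_{lbl}.csv", meta,
                     "delta_ppm = delta(salt) - delta(baseline); downfield positive")

    # --- stage: HDX rate fits ----------------------------------------------
    rate_tables = {}
    for lbl, tcs in sorted(tcs_by_label.items()):
        rt = fit_rate_table(
            tcs,
            fast_group_threshold=config.options.fast_group_threshold,
            fast_threshold=config.options.fast_threshold,
            slow_multiple=config.options.slow_multiple,
        )
        rate_tables[lbl] = rt
        afio.write_rate_table(rt, outdir / f"rates_{lbl}.csv", extra_meta=meta)
        for r, f in rt.fits.items():
            if not f.ok:
                censored_log.append({"condition": lbl, "residue": r, "status": f.status})

    # --- stage: AF-HDX maps -------------------------------------------------
    af_maps = {}
    region_frames = {}
    if rate_tables and "baseline" in rate_tables:
        for lbl, rt in rate_tables.items():
            if lbl == "baseline":
                continue
            m = build_map(rate_tables["baseline"], rt,
                          criterion=config.options.significance_multiple)
            af_maps[lbl] = m
            region_frames[lbl] = region_summary(m)
            _write_frame(m.data, outdir / f"afhdx_{lbl}.csv", meta,
                         "pct_change = (k_salt - k_0)/k_0 * 100; " + m.notes)
            _write_frame(region_frames[lbl], outdir / f"afhdx_regions_{lbl}.csv", meta,
                         "per-region aggregates of the AF-HDX map")

    # --- stage: binding fits -------------------------------------------------
    binding_fits = []
    ka_mat = ka_sum = None
    if titrations:
        for s in titrations:
            f = fit_binding(s, degeneracy_threshold=config.options.degeneracy_threshold)
            binding_fits.append(f)
            if not f.well_determined:
                degenerate_log.append(
                    {"residue": f.residue, "anion": f.anion, "flag": f.identifiability}
                )
        ka_mat, ka_sum = ka_matrix(binding_fits)
        afio.write_ka_matrix(ka_mat, ka_sum, outdir / "ka_matrix.csv",
                             outdir / "ka_summary.csv", extra_meta=meta)

    # --- figures -------------------------------------------------------------
    if config.make_figures:
        from .plotting import save_afhdx_map, save_delta_shift_map

        seq = registry["hairpin"].sequence
        for lbl, m in ddmaps.items():
            save_delta_shift_map(m, seq, outdir / f"ddmap_{lbl}.svg")
        for lbl, m in af_maps.items():
            save_afhdx_map(m, seq, outdir / f"afhdx_{lbl}.svg")

    provenance = {
        "config_hash": chash,
        "afhdx_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "options": config.options.model_dump(),
        "censored_fits": censored_log,
        "degenerate_binding_fits": degenerate_log,
        "n_shift_tables": len(tables),
        "n_timecourse_sets": len(tcs_by_label),
        "n_titration_series": len(titrations),
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")

    report = {
        "fold_fractions": fold_frame,
        "percent_unfolding": unfold_frame,
        "ddmaps": ddmaps,
        "rate_tables": rate_tables,
        "afhdx_maps": af_maps,
        "region_summaries": region_frames,
        "binding_fits": binding_fits,
        "ka_matrix": ka_mat,
        "ka_summary": ka_sum,
        "provenance": provenance,
        "truth": study,
    }
    return report


def _write_frame(frame: pd.DataFrame, path, meta: dict, note: str) -> None:
    lines = "".join(f"# {k}: {v}\n" for k, v in meta.items())
    with open(path, "w") as fh:
        fh.write(lines)
        fh.write(f"# note: {note}\n")
        frame.to_csv(fh, index=False, lineterminator="\n")
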