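"""Batch drivers: sample sheet -> tidy parameters -> group comparison.

Three stages mirror the command-line interface:

* :func:`analyze_study` reads every sample, extracts cardinal points and
  all derived parameters per replicate (curves are never averaged before
  extraction), and writes the tidy table plus group-mean normalized curves
  and their difference kinetics against the control.
* :func:`compare_groups` runs ANOVA + protected LSD + percent change on a
  tidy table.
* :func:`jip_table` is the fluorescence-only subset used on its own.

Every stage logs sample_id, stage, and rejected rows; a manifest with the
config snapshot, input hashes and row counts makes reruns verifiable (and,
for seeded synthetic inputs, byte-identical).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as ojio
from .errors import OjipError, StatisticsError
from .jip import TABLE_PARAMETERS, jip_row
from .mr820 import analyze_mr820
from .normalization import WINDOWS, difference_kinetics, mean_curve, normalize, \
    relative_variable_fluorescence
from .pigments import PigmentRecord, pigment_concentrations
from .stats import summarize_groups
from .transient import extract_cardinals

logger = logging.getLogger("ojipkit")

GAS_PARAMETERS = ("Pn", "Gs", "Tr", "Ci")


def _load_samples(sheet: "ojio.SampleSheet", config: "ojio.RunConfig"):
    """Yield (row, transient, cardinals, rvf) for readable, QC-clean samples."""
    for row in sheet.rows():
        path = sheet.curve_path(row)
        try:
            transient = ojio.read_transient(path)
        except OjipError as exc:
            logger.warning("sample %s: unreadable curve (%s), excluded",
                           row.sample_id, exc)
            continue
        transient.sample_id = str(row.sample_id)
        transient.group = str(row.group)
        transient.replicate = int(row.replicate)
        try:
            cardinals = extract_cardinals(
                transient, config.cardinal_times_ms, config.fm_rule,
                config.median_filter)
        except OjipError as exc:
            logger.warning("sample %s: cardinal extraction failed (%s), excluded",
                           row.sample_id, exc)
            continue
        if cardinals.qc_flags:
            logger.warning("sample %s: QC flag(s) %s, excluded",
                           row.sample_id, list(cardinals.qc_flags))
            continue
        rvf = relative_variable_fluorescence(cardinals)
        yield row, transient, cardinals, rvf


def jip_table(sheet, config=None) -> pd.DataFrame:
    """Tidy fluorescence-parameter table, one row per sample x parameter.

    Parameters reported: V_L, V_K, V_J, Fv/Fm, PI_ABS, PI_total. Samples
    that fail reading or QC are excluded with a log entry; a group whose
    samples all fail is an error.
    """
    if not isinstance(sheet, ojio.SampleSheet):
        sheet = ojio.read_sample_sheet(sheet)
    config = config or ojio.RunConfig()
    rows = []
    for row, _, cardinals, rvf in _load_samples(sheet, config):
        for parameter, value in jip_row(cardinals, rvf).items():
            rows.append({"sample_id": row.sample_id, "group": row.group,
                         "replicate": int(row.replicate),
                         "parameter": parameter, "value": value})
    table = pd.DataFrame(rows)
    surviving = set(table["group"]) if len(table) else set()
    dead = [g for g in sheet.groups if g not in surviving]
    if dead:
        raise StatisticsError(f"group(s) {dead}: all samples QC-failed or unreadable")
    return table


def analyze_study(
    sheet,
    config=None,
    out_dir=None,
    pigments_path=None,
    gas_path=None,
    windows=tuple(WINDOWS),
) -> dict:
    """Full per-sample analysis of one study.

    Returns ``{"tidy": DataFrame, "curves": DataFrame, "paths": {...}}``;
    when ``out_dir`` is given, writes ``tidy_parameters.csv``,
    ``curves.csv``, ``run.log`` and ``manifest.json`` there. Pigment and
    gas-exchange record files are auto-discovered next to the sample sheet
    (``pigments.csv``, ``gas_exchange.csv``) unless given explicitly.
    """
    sheet_path = None
    if not isinstance(sheet, ojio.SampleSheet):
        sheet_path = Path(sheet)
        sheet = ojio.read_sample_sheet(sheet)
    config = config or ojio.RunConfig()
    log_handler = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        lg = ojio.setup_logging(out_dir / "run.log")
        log_handler = next(h for h in lg.handlers
                           if isinstance(h, logging.FileHandler))

    try:
        return _analyze_study_body(sheet, sheet_path, config, out_dir,
                                   pigments_path, gas_path, windows)
    finally:
        if log_handler is not None:  # scope the run log to this run
            log_handler.close()
            logger.removeHandler(log_handler)


def _analyze_study_body(sheet, sheet_path, config, out_dir,
                        pigments_path, gas_path, windows) -> dict:
    tidy_rows: list[dict] = []
    normalized: dict[str, dict[str, list]] = {w: {} for w in windows}
    n_samples = 0

    def add(row, parameter, value):
        tidy_rows.append({"sample_id": str(row.sample_id), "group": str(row.group),
                          "replicate": int(row.replicate),
                          "parameter": parameter, "value": float(value)})

    for row, transient, cardinals, rvf in _load_samples(sheet, config):
        n_samples += 1
        for parameter, value in jip_row(cardinals, rvf).items():
            add(row, parameter, value)
        for window in windows:
            curve = normalize(transient, cardinals, window, config.cardinal_times_ms)
            normalized[window].setdefault(str(row.group), []).append(curve)
        mr_path = sheet.mr820_path(row)
        if mr_path is None:
            logger.warning("sample %s: no MR820 path, fluorescence-only", row.sample_id)
        else:
            try:
                result = analyze_mr820(ojio.read_mr820(mr_path))
                add(row, "dI/Io", result.delta_i_over_io)
                add(row, "MR820_slope", result.initial_slope)
            except OjipError as exc:
                logger.warning("sample %s: MR820 analysis failed (%s), skipped",
                               row.sample_id, exc)
    if n_samples == 0:
        raise OjipError("all samples unreadable or QC-failed: nothing to analyze")

    base = sheet.base_dir
    pigments_path = pigments_path or (
        base / "pigments.csv" if (base / "pigments.csv").exists() else None)
    gas_path = gas_path or (
        base / "gas_exchange.csv" if (base / "gas_exchange.csv").exists() else None)
    if pigments_path:
        for rec in ojio.read_records(
                pigments_path,
                required=["sample_id", "group", "replicate", "a_663", "a_646"]
        ).itertuples(index=False):
            result = pigment_concentrations(PigmentRecord(
                a_663=rec.a_663, a_646=rec.a_646,
                dilution_factor=getattr(rec, "dilution_factor", 1.0),
                fresh_mass_g=getattr(rec, "fresh_mass_g", 0.1),
                extract_volume_ml=getattr(rec, "extract_volume_ml", 10.0),
                sample_id=str(rec.sample_id)))
            add(rec, "Chl_a", result.chl_a)
            add(rec, "Chl_b", result.chl_b)
            add(rec, "Chl_a+b", result.chl_ab_sum)
            if np.isfinite(result.chl_a_over_b):
                add(rec, "Chl_a/b", result.chl_a_over_b)
    if gas_path:
        for rec in ojio.read_records(
                gas_path, required=["sample_id", "group", "replicate",
                                    *GAS_PARAMETERS]).itertuples(index=False):
            for parameter in GAS_PARAMETERS:
                add(rec, parameter, getattr(rec, parameter))

    tidy = pd.DataFrame(tidy_rows)
    curves = _curve_table(normalized, config)
    result = {"tidy": tidy, "curves": curves, "paths": {}}
    if out_dir is not None:
        result["paths"]["tidy"] = ojio.write_tidy_table(tidy, out_dir / "tidy_parameters.csv")
        curves_path = out_dir / "curves.csv"
        curves.to_csv(curves_path, index=False, float_format=ojio.FLOAT_FORMAT)
        result["paths"]["curves"] = curves_path
        inputs = [p for p in [sheet_path, pigments_path, gas_path] if p]
        inputs += [sheet.curve_path(r) for r in sheet.rows()]
        inputs += [p for r in sheet.rows() if (p := sheet.mr820_path(r))]
        result["paths"]["manifest"] = write_manifest(
            out_dir / "manifest.json", config, inputs,
            {"samples_analyzed": n_samples, "tidy_rows": len(tidy),
             "samples_in_sheet": len(sheet)})
    return result


def _curve_table(normalized, config) -> pd.DataFrame:
    """Long table of group-mean V(t) and delta-V(t) vs the control."""
    rows = []
    for window, by_group in normalized.items():
        control = config.control if config.control in by_group else None
        for group, curves in by_group.items():
            mean = mean_curve(curves, config.points_per_decade)
            if control and group != control:
                dk = difference_kinetics(curves, by_group[control],
                                         config.points_per_decade)
                dv = np.interp(np.log10(mean.time_ms), np.log10(dk.time_ms),
                               dk.delta_v)
            else:
                dv = np.zeros_like(mean.time_ms)
            for t, v, d in zip(mean.time_ms, mean.v, dv):
                rows.append({"window": window, "group": group, "time_ms": t,
                             "v_mean": v, "delta_v_vs_control": d})
    return pd.DataFrame(rows)


def compare_groups(tidy, control: str = "CK", alpha: float = 0.05,
                   out_dir=None) -> pd.DataFrame:
    """ANOVA + protected LSD + percent change for every parameter."""
    if not isinstance(tidy, pd.DataFrame):
        tidy = ojio.read_tidy_table(tidy)
    groups = set(tidy["group"])
    if len(groups) < 2:
        raise StatisticsError("need at least two groups to compare")
    if control not in groups:
        raise StatisticsError(f"control group {control!r} missing from table")
    summary = summarize_groups(tidy, control=control, alpha=alpha)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out_dir / "group_summary.csv", index=False,
                       float_format=ojio.FLOAT_FORMAT)
        (out_dir / "group_report.txt").write_text(render_report(summary, control, alpha))
    return summary


def render_report(summary: pd.DataFrame, control: str, alpha: float) -> str:
    """Human-readable comparison report (means +- sd, letters, % change)."""
    lines = [f"Group comparison vs {control} (one-way ANOVA + LSD, alpha={alpha:g})", ""]
    for parameter, sub in summary.groupby("parameter", sort=True):
        f = sub["anova_F"].iloc[0]
        p = sub["anova_p"].iloc[0]
        lines.append(f"{parameter}:  F={f:.4g}  p={p:.4g}")
        for row in sub.itertuples(index=False):
            lines.append(
                f"  {row.group:>6}  {row.mean:12.5g} +- {row.sd:<10.4g}"
                f" n={row.n}  {row.letters:<4} {row.percent_change_vs_control:+8.2f}%")
        lines.append("")
    return "\n".join(lines)


def write_manifest(path, config, input_paths, counts: dict) -> Path:
    """Config snapshot + input hashes + row counts (no wall-clock time,
    so seeded reruns stay byte-identical)."""
    manifest = {
        "ojipkit_version": __version__,
        "config": config.to_mapping(),
        "counts": counts,
        "inputs": {
            str(Path(p).name): _sha256(p)
            for p in sorted(set(map(str, input_paths)))
        },
    }
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _sha256(path) -> str:
    digest = hashlib.sha256()
    digest.update(Path(path).read_bytes())
    return digest.hexdigest()
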