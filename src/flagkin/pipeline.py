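"""Batch orchestration: per-cell analysis, group comparison, and reporting.

``analyze_cell`` runs the full chain on one centerline series —
tangent angles → shape modes → POF → cycle segmentation → representative
beat cycle → amplitude envelope → RFT power → free-swimming projection —
and collects per-cell scalars into a summary row.  ``analyze_cells``
isolates per-cell failures: a cell that violates a precondition (e.g. no
oscillation) is logged and skipped without aborting the batch.
``compare_groups`` produces the within/between Procrustes table, regional
power table, and group mean ± SD summaries, export-ready for external
statistics tools.

All outputs are plain TSV/JSON/YAML with fixed numeric formatting, so a
rerun with the same inputs and configuration is byte-identical.
"""

from __future__ import annotations

import json
import os
import traceback
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .centerline import CenterlineSeries, tangent_angles, velocities
from .errors import FlagkinError
from .kinematics import (
    AmplitudeProfile,
    BeatCycleAverage,
    PofResult,
    average_beat_cycle,
    flagellar_amplitude,
    primary_oscillation_frequency,
    regional_summary,
    segment_beat_cycles,
)
from .pod import ShapeModeDecomposition, export_decomposition, pod_decompose, variance_explained
from .procrustes import group_comparison
from .rft import PowerFields, RFTParameters, power_fields
from .swimming import ProjectedTrajectory, project_free_swimming

__all__ = [
    "PipelineConfig",
    "CellResult",
    "analyze_cell",
    "analyze_cells",
    "summary_table",
    "compare_groups",
    "run_analyze",
    "run_compare",
]

_FLOAT_FMT = "%.9g"


@dataclass
class PipelineConfig:
    """Everything the pipeline needs beyond the data itself."""

    rft: RFTParameters = field(default_factory=RFTParameters)
    region_boundaries: tuple = (24.0, 104.0)  # μm; mid-piece | principal | end
    n_modes_report: int = 4
    phase_points: int = 64
    pof_band_hz: tuple = (0.5, None)
    procrustes_variant: str = "rms"
    n_points: int = 100  # resampling grid for raw polylines
    smoothing: float = 0.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["region_boundaries"] = list(self.region_boundaries)
        d["pof_band_hz"] = list(self.pof_band_hz)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "rft" in d and isinstance(d["rft"], dict):
            d["rft"] = RFTParameters(**d["rft"])
        for key in ("region_boundaries", "pof_band_hz"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_dict(yaml.safe_load(f) or {})

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=True)


@dataclass
class CellResult:
    """All per-cell products of the analysis chain."""

    cell_id: str
    decomposition: ShapeModeDecomposition
    pof: PofResult
    beat_average: BeatCycleAverage
    amplitude: AmplitudeProfile
    regional_amplitude: tuple
    power: PowerFields
    regional_power_w: tuple
    trajectory: ProjectedTrajectory
    group: str = ""

    def summary_row(self) -> dict:
        d = self.decomposition
        k2 = min(2, d.n_modes)
        k4 = min(4, d.n_modes)
        row = {
            "cell_id": self.cell_id,
            "group": self.group,
            "pof_hz": self.pof.pof_hz,
            "n_cycles": self.beat_average.n_cycles,
            "period_s": self.beat_average.period,
            "var_modes_1_2": variance_explained(d, range(1, k2 + 1)),
            "var_modes_1_4": variance_explained(d, range(1, k4 + 1)),
            "E_fW": self.power.E_fW,
            "P_mid_fW": self.regional_power_w[0] * 1e15,
            "P_principal_fW": self.regional_power_w[1] * 1e15,
            "P_end_fW": self.regional_power_w[2] * 1e15,
            "vsl_um_per_s": self.trajectory.vsl,
            "vsl_first_cycle_um_per_s": self.trajectory.vsl_first_cycle,
            "amp_mid": self.regional_amplitude[0],
            "amp_principal": self.regional_amplitude[1],
            "amp_end": self.regional_amplitude[2],
        }
        return row


def analyze_cell(
    series: CenterlineSeries,
    config: PipelineConfig | None = None,
    cell_id: str = "cell",
    group: str = "",
) -> CellResult:
    """Run the full analysis chain on one cell."""
    cfg = config or PipelineConfig()
    t = tangent_angles(series)
    decomp = pod_decompose(t)
    b1 = decomp.coeffs[:, 0]
    b2 = decomp.coeffs[:, 1] if decomp.n_modes > 1 else np.zeros_like(b1)
    pof = primary_oscillation_frequency(b1, series.fps, b2, band_hz=cfg.pof_band_hz)
    cycles = segment_beat_cycles(b1, b2, series.times)
    beat_avg = average_beat_cycle(series, cycles, phase_points=cfg.phase_points)
    amp = flagellar_amplitude(beat_avg)
    reg_amp = regional_summary(amp.arc_grid, amp.amplitude, cfg.region_boundaries)
    v = velocities(series)
    power = power_fields(v, cfg.rft)
    # regional INTEGRALS of the power density, in W (arc grid converted to m)
    reg_pow = regional_summary(
        power.arc_grid * 1e-6,
        power.p_bar,
        (cfg.region_boundaries[0] * 1e-6, cfg.region_boundaries[1] * 1e-6),
        integrate=True,
    )
    traj = project_free_swimming(series, cfg.rft, period=beat_avg.period, v=v)
    return CellResult(
        cell_id=cell_id,
        decomposition=decomp,
        pof=pof,
        beat_average=beat_avg,
        amplitude=amp,
        regional_amplitude=reg_amp,
        power=power,
        regional_power_w=reg_pow,
        trajectory=traj,
        group=group,
    )


def analyze_cells(
    cells: dict[str, CenterlineSeries],
    config: PipelineConfig | None = None,
    groups: dict[str, str] | None = None,
) -> tuple[dict[str, CellResult], dict[str, str]]:
    """Analyze many cells, isolating per-cell failures.

    Returns (results, failures); ``failures`` maps cell id to the reason the
    cell was skipped.
    """
    groups = groups or {}
    results: dict[str, CellResult] = {}
    failures: dict[str, str] = {}
    for cell_id, series in cells.items():
        try:
            results[cell_id] = analyze_cell(
                series, config, cell_id=cell_id, group=groups.get(cell_id, "")
            )
        except FlagkinError as exc:
            failures[cell_id] = f"{type(exc).__name__}: {exc}"
        except Exception as exc:  # unexpected: keep the batch alive, log fully
            failures[cell_id] = f"{type(exc).__name__}: {exc}\n{traceback.format_exc()}"
    return results, failures


def summary_table(results: dict[str, CellResult]) -> pd.DataFrame:
    """Consolidated per-cell summary table."""
    return pd.DataFrame([r.summary_row() for r in results.values()])


def compare_groups(
    results: dict[str, CellResult],
    config: PipelineConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Group-level tables: Procrustes within/between, group means ± SD, and
    regional power (in fW and 10⁻¹² J/s)."""
    cfg = config or PipelineConfig()
    by_group: dict[str, list] = {}
    for r in results.values():
        by_group.setdefault(r.group or "all", []).append(r)
    patterns = {g: [r.beat_average for r in rs] for g, rs in by_group.items()}
    proc_table, _ = group_comparison(patterns, cfg.procrustes_variant)

    summary = summary_table(results)
    agg = summary.groupby("group").agg(
        n_cells=("cell_id", "size"),
        pof_hz_mean=("pof_hz", "mean"),
        pof_hz_sd=("pof_hz", "std"),
        E_fW_mean=("E_fW", "mean"),
        E_fW_sd=("E_fW", "std"),
        vsl_mean=("vsl_um_per_s", "mean"),
        vsl_sd=("vsl_um_per_s", "std"),
    ).reset_index()

    regional = summary[
        ["cell_id", "group", "P_mid_fW", "P_principal_fW", "P_end_fW", "E_fW"]
    ].copy()
    for col in ("P_mid_fW", "P_principal_fW", "P_end_fW"):
        regional[col.replace("_fW", "_1e-12_J_per_s")] = regional[col] * 1e-3
    return {"procrustes": proc_table, "group_means": agg, "regional_power": regional}


# ---------------------------------------------------------------------------
# disk-level entry points (used by the CLI)
# ---------------------------------------------------------------------------


def run_analyze(
    inputs: list[str],
    out_dir: str | os.PathLike,
    config: PipelineConfig | None = None,
    groups: dict[str, str] | None = None,
) -> tuple[dict[str, CellResult], dict[str, str]]:
    """Read centerline TSV files, analyze each cell, write all exports.

    File-level read errors are isolated exactly like analysis failures.
    """
    cfg = config or PipelineConfig()
    os.makedirs(out_dir, exist_ok=True)
    cells: dict[str, CenterlineSeries] = {}
    failures: dict[str, str] = {}
    for path in sorted(inputs):
        cell_id = os.path.splitext(os.path.basename(path))[0]
        try:
            cells[cell_id] = fio.read_centerlines(
                path, n_points=cfg.n_points, smoothing=cfg.smoothing
            )
        except Exception as exc:
            failures[cell_id] = f"{type(exc).__name__}: {exc}"
    results, analysis_failures = analyze_cells(cells, cfg, groups)
    failures.update(analysis_failures)

    cfg.to_yaml(os.path.join(out_dir, "config.yaml"))
    summary = summary_table(results)
    summary.to_csv(
        os.path.join(out_dir, "summary.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT
    )
    for cell_id, r in results.items():
        prefix = os.path.join(out_dir, cell_id)
        export_decomposition(r.decomposition, prefix, k_max=cfg.n_modes_report)
        _export_cycle(r.beat_average, f"{prefix}_cycle.tsv")
        _export_power(r.power, f"{prefix}_power.tsv")
        _export_trajectory(r.trajectory, f"{prefix}_trajectory.tsv")
    with open(os.path.join(out_dir, "failures.json"), "w") as f:
        json.dump(failures, f, indent=1, sort_keys=True)
    return results, failures


def run_compare(
    results: dict[str, CellResult],
    out_dir: str | os.PathLike,
    config: PipelineConfig | None = None,
    make_plots: bool = False,
) -> dict[str, pd.DataFrame]:
    """Write the group-comparison tables (and optional figures)."""
    os.makedirs(out_dir, exist_ok=True)
    tables = compare_groups(results, config)
    for name, df in tables.items():
        df.to_csv(
            os.path.join(out_dir, f"{name}.tsv"), sep="\t", index=False, float_format=_FLOAT_FMT
        )
    if make_plots:
        from . import plots

        plots.comparison_figures(results, out_dir)
    return tables


def _export_cycle(b: BeatCycleAverage, path: str) -> None:
    P, M = b.mean_x.shape
    df = pd.DataFrame(
        {
            "phase": np.repeat(b.phase_grid, M),
            "s_um": np.tile(b.arc_grid, P),
            "mean_x": b.mean_x.ravel(),
            "mean_y": b.mean_y.ravel(),
            "sd_x": b.sd_x.ravel(),
            "sd_y": b.sd_y.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _export_power(p: PowerFields, path: str) -> None:
    pd.DataFrame({"s_um": p.arc_grid, "p_bar_W_per_m": p.p_bar}).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def _export_trajectory(t: ProjectedTrajectory, path: str) -> None:
    df = pd.DataFrame(
        {
            "time_s": t.times,
            "Ux_um_per_s": t.U[:, 0],
            "Uy_um_per_s": t.U[:, 1],
            "Rx_um": t.R[:, 0],
            "Ry_um": t.R[:, 1],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)
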