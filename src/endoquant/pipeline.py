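"""End-to-end orchestration: simulate/read -> segment -> quantify -> fit -> report.

Two pipelines mirror the two measurement modalities:

* the imaging pipeline takes two-channel fields (simulated or TIFF), splits
  every cell into membrane/interior compartments, computes per-cell
  internalization ratios, filters to comparable receptor expression,
  summarizes per ligand x time, compares ligands per timepoint and fits the
  sigmoid kinetics with k_max and half-time per ligand;
* the cytometry pipeline gates transfected events against an untransfected
  control, computes per-time QD geometric means and the M1 marker series
  normalized to time zero, plus quadrant statistics.

Both are deterministic for a fixed seed and account for every cell/event:
anything excluded is logged with a reason.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import cytometry as cyto
from . import internalization as internal
from . import kinetics
from . import segmentation as seg
from . import synthetic as syn
from .fov import FieldOfView

__all__ = [
    "RunConfig",
    "RunReport",
    "read_field",
    "write_field",
    "run_imaging_pipeline",
    "run_cytometry_pipeline",
]


@dataclass
class RunConfig:
    """Flat, file-round-trippable configuration for both pipelines."""

    # input: either a directory of TIFFs + manifest.csv, or simulation
    input_dir: str | None = None
    simulate: bool = True
    ligands: tuple = ("IGF-II", "insulin")
    times: tuple = (0.0, 10.0, 20.0, 150.0)
    fields_per_timepoint: int = 3
    cells_per_field: int = 5
    field_shape: tuple = (256, 256)
    # ligand kinetics for simulation: name -> (a1, a2, x0, p)
    kinetics_truth: dict = field(
        default_factory=lambda: {
            "IGF-II": (0.17, 0.96, 8.5, 1.4),
            "insulin": (0.06, 0.95, 22.0, 1.5),
        }
    )
    # segmentation / measurement
    background_method: str = "median"
    threshold_method: str = "otsu"
    min_area_px: int = 200
    exclude_border: bool = True
    grow_px: int = 2
    erosion_iterations: int = 8
    erosion_connectivity: str = "alternating"
    qd_k_sigma: float = 3.0
    # statistics
    expression_fold_window: float = 2.0
    t_test_method: str = "student_pooled"
    # kinetics fit
    fit_family: str = "logistic"
    fit_weights: str = "none"  # none | n | inv_sem2
    half_time_definition: str = "ln2_over_kmax"
    # cytometry
    gate_quantile: float = 0.995
    tail_fraction: float = 0.04
    zero_policy: str = "exclude"
    # bookkeeping
    make_plots: bool = False
    master_seed: int = 0
    outdir: str = "endoquant_out"

    def to_yaml(self, path):
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path):
        d = yaml.safe_load(Path(path).read_text())
        for key in ("ligands", "times", "field_shape"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        if "kinetics_truth" in d:
            d["kinetics_truth"] = {k: tuple(v) for k, v in d["kinetics_truth"].items()}
        return cls(**d)


@dataclass
class RunReport:
    """Per-stage accounting plus warnings; serializable to JSON."""

    software: str = "endoquant"
    config: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def to_json(self, path):
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, default=str))


# ---------------------------------------------------------------------------
# TIFF I/O (channel axis first, receptor page 0, QD page 1)

def write_field(path, fov: FieldOfView):
    """Write a field as a 2-page 16-bit TIFF (receptor first, then QD)."""
    stack = np.stack([fov.receptor, fov.qd]).clip(0, 65535).round().astype(np.uint16)
    tifffile.imwrite(path, stack, metadata={"axes": "CYX"})


def read_field(path, channel_map=("receptor", "qd"), metadata=None) -> FieldOfView:
    """Load a multi-page TIFF into a FieldOfView.

    ``channel_map`` names the pages in order; a file with fewer pages than
    named channels is rejected, naming the missing channel.
    """
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.shape[0] < len(channel_map):
        missing = channel_map[arr.shape[0]:]
        raise ValueError(f"{path}: missing channel(s) {missing}")
    chans = {name: arr[i].astype(float) for i, name in enumerate(channel_map)}
    return FieldOfView(receptor=chans["receptor"], qd=chans["qd"], metadata=dict(metadata or {}))


# ---------------------------------------------------------------------------
# imaging pipeline

def _measure_field(fov: FieldOfView, config: RunConfig):
    """Segment one field and measure every cell; returns (measurements, log)."""
    rec, bg_r = seg.subtract_background(fov.receptor, method=config.background_method)
    qd, bg_q = seg.subtract_background(fov.qd, method=config.background_method)
    labels, cells = seg.segment_cells(
        rec,
        min_area_px=config.min_area_px,
        threshold_method=config.threshold_method,
        exclude_border=config.exclude_border,
        grow_px=config.grow_px,
    )
    qd_mask = seg.compute_qd_mask(qd, k_sigma=config.qd_k_sigma)
    measurements, log = [], []
    meta = fov.metadata
    for i, cell in enumerate(cells):
        cell_id = f"{meta.get('field_id', 'field')}_cell{i:02d}"
        if cell["label"] == 0 or cell["border_touching"]:
            log.append({"stage": "segment", "item": cell_id, "action": "excluded",
                        "reason": "border-touching"})
            continue
        masks = seg.partition_cell(
            cell["mask"],
            erosion_iterations=config.erosion_iterations,
            qd_mask=qd_mask,
            connectivity=config.erosion_connectivity,
        )
        m = seg.measure_cell(
            masks, qd, rec,
            metadata={"field_id": meta.get("field_id", ""), "cell_id": cell_id,
                      "ligand": meta.get("ligand", ""), "time_min": meta.get("time_min", math.nan)},
        )
        measurements.append(m)
        if m.excluded:
            log.append({"stage": "measure", "item": cell_id, "action": "excluded",
                        "reason": m.exclusion_reason})
    return measurements, log


def _load_fields(config: RunConfig):
    """Either simulate the experiment or read TIFFs + manifest from disk."""
    if config.simulate:
        sim = syn.ImagingSimConfig(
            ligands={
                name: syn.KineticsSpec(*config.kinetics_truth[name]) for name in config.ligands
            },
            times=tuple(float(t) for t in config.times),
            fields_per_timepoint=config.fields_per_timepoint,
            cells_per_field=config.cells_per_field,
            field_shape=tuple(config.field_shape),
        )
        fields, manifest = syn.generate_image_dataset(sim, master_seed=config.master_seed)
        return [f for f, _ in fields], manifest
    indir = Path(config.input_dir)
    manifest = pd.read_csv(indir / "manifest.csv")
    fovs = []
    for field_id, g in manifest.groupby("field_id", sort=True):
        fov = read_field(indir / f"{field_id}.tif",
                         metadata={"field_id": field_id,
                                   "ligand": g["ligand"].iloc[0],
                                   "time_min": float(g["time_min"].iloc[0])})
        fovs.append(fov)
    return fovs, manifest


def run_imaging_pipeline(config: RunConfig, outdir=None):
    """Run the full imaging analysis; returns a dict of result tables.

    Writes (when ``outdir`` is set): cells.csv, exclusions.csv, summary.csv
    (ligand, time_min, mean, sem, n), comparisons.csv (per-time t-tests) and
    fits.csv (per-ligand sigmoid parameters, k_max, half-time), plus
    report.json.
    """
    fovs, manifest = _load_fields(config)
    report = RunReport(config=dataclasses.asdict(config))
    all_measurements, log_rows = [], []
    for fov in fovs:
        ms, log = _measure_field(fov, config)
        all_measurements.extend(ms)
        log_rows.extend(log)

    frame = internal.measurements_to_frame(all_measurements)
    retained, filter_log = internal.filter_by_expression(
        frame, fold_window=config.expression_fold_window
    )
    for _, row in filter_log.iterrows():
        reason = row["exclusion_reason"] or "expression outside fold window"
        log_rows.append({"stage": "expression_filter", "item": row["cell_id"],
                         "action": "excluded", "reason": reason})

    summary = internal.summarize_timepoints(retained)

    comparisons = []
    if len(config.ligands) >= 2:
        lig_a, lig_b = config.ligands[0], config.ligands[1]
        for t in sorted(retained["time_min"].unique()):
            a = retained.query("ligand == @lig_a and time_min == @t")["ratio"].dropna()
            b = retained.query("ligand == @lig_b and time_min == @t")["ratio"].dropna()
            if len(a) >= 2 and len(b) >= 2:
                res = internal.t_test_two_sample(a, b, method=config.t_test_method)
                comparisons.append({"time_min": t, "ligand_a": lig_a, "ligand_b": lig_b,
                                    "t": res.statistic, "df": res.df,
                                    "p_two_tailed": res.p_two_tailed, "method": res.method})
    comparisons = pd.DataFrame(comparisons)

    fits = []
    for ligand, g in summary.groupby("ligand"):
        g = g.sort_values("time_min")
        if len(g) < 4:
            report.warnings.append(f"{ligand}: fewer than 4 timepoints, no fit")
            continue
        weights = None
        if config.fit_weights == "n":
            weights = g["n"].to_numpy(float)
        elif config.fit_weights == "inv_sem2":
            weights = 1.0 / g["sem"].to_numpy(float) ** 2
        fit = kinetics.fit_logistic(
            g["time_min"].to_numpy(float), g["mean"].to_numpy(float),
            weights=weights, family=config.fit_family,
            half_time_definition=config.half_time_definition,
        )
        fits.append({"ligand": ligand, "a1": fit.a1, "a2": fit.a2, "x0": fit.x0,
                     "p": fit.p, "dx": fit.dx, "family": fit.family,
                     "k_max": fit.k_max, "t_at_kmax": fit.t_at_kmax,
                     "t_half": fit.t_half, "r_squared": fit.r_squared,
                     "converged": fit.converged})
    fits = pd.DataFrame(fits)

    exclusions = pd.DataFrame(log_rows)
    report.counts = {
        "fields": len(fovs),
        "cells_measured": len(frame),
        "cells_retained": len(retained),
        "cells_excluded": len(frame) - len(retained),
        "exclusion_log_rows": len(exclusions),
    }
    results = {"cells": frame, "retained": retained, "summary": summary,
               "comparisons": comparisons, "fits": fits,
               "exclusions": exclusions, "manifest": manifest, "report": report}
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "cells.csv", index=False)
        exclusions.to_csv(out / "exclusions.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
        comparisons.to_csv(out / "comparisons.csv", index=False)
        fits.to_csv(out / "fits.csv", index=False)
        report.to_json(out / "report.json")
        if config.make_plots and len(fits) and len(summary):
            from .plotting import plot_timecourse_fits

            plot_timecourse_fits(summary, fits, out / "timecourse_fits.png")
    return results


# ---------------------------------------------------------------------------
# cytometry pipeline

def run_cytometry_pipeline(
    config: RunConfig,
    tables_by_time=None,
    control=None,
    outdir=None,
):
    """Gate -> geometric means -> marker series -> quadrant statistics.

    When no event tables are passed in, a dataset is simulated from the
    default event model.  ``tables_by_time`` maps time (min) to event
    frames with ``syfp`` and ``qd`` columns; ``control`` is the
    untransfected reference used for gating.
    """
    if tables_by_time is None or control is None:
        sim = syn.EventSimConfig()
        tables_by_time, control, _truth = syn.generate_event_dataset(
            sim, seed=config.master_seed
        )
    tables_by_time = {float(t): tab for t, tab in tables_by_time.items()}
    if 0.0 not in tables_by_time:
        raise ValueError("missing required t=0 sample")

    report = RunReport(config=dataclasses.asdict(config))
    gate, _ = cyto.gate_positive(tables_by_time[0.0], control, channel="syfp",
                                 quantile=config.gate_quantile)
    gate.qd_threshold = float(np.quantile(control["qd"].to_numpy(float), config.gate_quantile))
    gated = {t: cyto.gate_positive(tab, control, channel="syfp",
                                   quantile=config.gate_quantile)[1]
             for t, tab in tables_by_time.items()}

    gm = cyto.geometric_mean_series(gated, channel="qd", zero_policy=config.zero_policy)
    m1 = cyto.place_marker(gated[0.0], tail_fraction=config.tail_fraction)
    marker = cyto.marker_series(gated, m1)
    quadrants = pd.DataFrame(
        [{"time_min": t, **cyto.quadrant_statistics(tab, gate)}
         for t, tab in sorted(tables_by_time.items())]
    )
    marker_df = pd.DataFrame(
        [{"time_min": t, "fraction_above_m1": marker.fractions[t],
          "marker_over_0min": marker.normalized[t]}
         for t in sorted(marker.fractions)]
    )
    report.counts = {
        "samples": len(tables_by_time),
        "events_total": int(sum(len(t) for t in tables_by_time.values())),
        "events_gated": int(sum(len(t) for t in gated.values())),
        "gate_syfp_threshold": gate.syfp_threshold,
        "m1_threshold": m1,
    }
    results = {"gate": gate, "geometric_means": gm, "marker": marker_df,
               "quadrants": quadrants, "report": report}
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        gm.to_csv(out / "geometric_means.csv", index=False)
        marker_df.to_csv(out / "marker_series.csv", index=False)
        quadrants.to_csv(out / "quadrants.csv", index=False)
        report.to_json(out / "cytometry_report.json")
        if config.make_plots:
            from .plotting import plot_qd_histogram_overlay

            plot_qd_histogram_overlay(gated, out / "qd_histograms.png")
    return results
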