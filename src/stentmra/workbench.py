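"""Fixtures, orchestration and reporting.

Two modes of operation:

``regrade_table``
    Re-derive scores, tallies and summaries from a published measurement
    table (the packaged 22-stent phantom study ships as
    ``measurements_table2.csv``).  This path is pure integer/decimal
    arithmetic — no imaging.

``simulate_full``
    For each selected stent, build the phantom, simulate the MRA
    acquisition, measure, and grade — the full in-silico replica of the
    bench experiment.

All output tables carry a provenance comment header (package version,
seed, config hash); read them back with ``pandas.read_csv(comment='#')``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .grading import (
    DEFAULT_THRESHOLDS,
    GradeReport,
    GradingThresholds,
    grade_table,
)
from .materials import get_material
from .metrics import MeasurementConfig, MeasurementResult, measure_phantom
from .phantom import StentSpec, TubeSpec, rasterize_phantom
from .simulate import AcquisitionParams, simulate_image

__all__ = [
    "RunConfig",
    "load_table1",
    "load_table2_measurements",
    "load_table3_scores",
    "stent_spec_from_row",
    "tube_for_stent",
    "simulate_stent",
    "run_pipeline",
    "summarize_results",
]

log = logging.getLogger("stentmra")

#: tube inner diameters available on the bench; a 6 mm stent goes into the
#: 5 mm tube (constrained expansion)
_TUBE_FOR_DIAMETER = {5: 5.0, 6: 5.0, 7: 7.0, 8: 8.0, 10: 10.0, 13: 13.0}

#: design heuristic by material: balloon-expandable 316L products are
#: laser-cut slotted tubes; the covered Wallstent keeps its braided mesh
_DESIGN_FOR_MATERIAL = {"316L": "slotted_tube", "PET+cobalt-superalloy": "covered"}


def _fixture(name: str) -> Path:
    return Path(str(resources.files("stentmra.data") / name))


def load_table1() -> pd.DataFrame:
    """The 22-stent catalogue: id, name, manufacturer, material, sizes."""
    return pd.read_csv(_fixture("stents_table1.csv"))


def load_table2_measurements() -> tuple[list[MeasurementResult], pd.DataFrame]:
    """Published measurement table with printed scores.

    Returns the measurements as :class:`MeasurementResult` (vis_max is not
    published; it is set equal to vis_min) plus the raw frame including the
    printed per-category scores.
    """
    df = pd.read_csv(_fixture("measurements_table2.csv"))
    ms = [
        MeasurementResult(
            stent_id=int(r.stent_id),
            name=str(r.name),
            si_percent=int(r.si_percent),
            vis_min_percent=int(r.vis_min_percent),
            vis_max_percent=int(r.vis_min_percent),
            sd_over_mean=float(r.sd_over_mean),
        )
        for r in df.itertuples(index=False)
    ]
    return ms, df


def load_table3_scores() -> pd.DataFrame:
    """Published per-category scores, overall scores and classes."""
    return pd.read_csv(_fixture("scores_table3.csv"))


def stent_spec_from_row(row: pd.Series | dict, **overrides) -> StentSpec:
    """Build a StentSpec from a catalogue row (material looked up by name)."""
    r = dict(row)
    kwargs = dict(
        id=int(r["stent_id"]),
        name=str(r["name"]),
        material=get_material(str(r["material"])),
        nominal_diameter=float(r["diameter_mm"]),
        length=float(r["length_mm"]),
        design=_DESIGN_FOR_MATERIAL.get(str(r["material"]), "mesh"),
    )
    kwargs.update(overrides)
    return StentSpec(**kwargs)


def tube_for_stent(
    stent: StentSpec, ref_segment: float = 12.0, **overrides
) -> TubeSpec:
    """Matching bench tube: nearest catalogue bore, thin wall for small
    tubes (~0.25 mm) and ~1 mm for the 10/13 mm tubes, with enough length
    for an unstented reference segment on both sides."""
    bore = _TUBE_FOR_DIAMETER.get(int(round(stent.nominal_diameter)))
    if bore is None:
        bore = min(_TUBE_FOR_DIAMETER.values(), key=lambda b: abs(b - stent.nominal_diameter))
    kwargs = dict(
        inner_diameter=bore,
        wall_thickness=0.25 if bore <= 8 else 1.0,
        length=stent.length + 2 * ref_segment,
    )
    kwargs.update(overrides)
    return TubeSpec(**kwargs)


def simulate_stent(
    stent: StentSpec,
    tube: TubeSpec | None = None,
    acq: AcquisitionParams | None = None,
    grid_voxel: float = 0.25,
    pad: float = 5.0,
):
    """Phantom -> image for one stent (convenience composition)."""
    tube = tube or tube_for_stent(stent)
    acq = acq or AcquisitionParams()
    labels = rasterize_phantom(tube, stent, grid_voxel=grid_voxel, pad=pad)
    return simulate_image(labels, stent, tube, acq)


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class RunConfig:
    mode: str = "regrade_table"  # or "simulate_full"
    stent_ids: list[int] | None = None  # None -> all
    outdir: str | Path = "results"
    seed: int = 0
    grid_voxel: float = 0.25
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    measurement: MeasurementConfig = field(default_factory=MeasurementConfig)
    thresholds: GradingThresholds = field(default_factory=GradingThresholds)
    write_images: bool = True
    write_mips: bool = False

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "mode": self.mode,
                "stent_ids": self.stent_ids,
                "seed": self.seed,
                "grid_voxel": self.grid_voxel,
                "acquisition": asdict(self.acquisition),
                "measurement": asdict(self.measurement),
                "thresholds": asdict(self.thresholds),
            },
            sort_keys=True,
        )
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def _provenance_header(config: RunConfig) -> str:
    return (
        f"# stentmra v{__version__} | mode={config.mode} | seed={config.seed} "
        f"| config={config.config_hash()}\n"
    )


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance_header(config))
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured pipeline and write the report bundle.

    Writes ``measurements.csv``, ``grades.csv``, ``counts.json`` and
    ``summary.md`` into the output directory (plus per-stent NIfTI images
    and optional longitudinal MIP PNGs in simulate_full mode).  Returns
    the in-memory results: measurements, reports, counts, summary.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    unknown: list[int] = []
    if config.mode == "regrade_table":
        measurements, _ = load_table2_measurements()
        if config.stent_ids is not None:
            known = {m.stent_id for m in measurements}
            unknown = sorted(set(config.stent_ids) - known)
            measurements = [m for m in measurements if m.stent_id in config.stent_ids]
    elif config.mode == "simulate_full":
        table1 = load_table1()
        if config.stent_ids is not None:
            known = set(table1.stent_id)
            unknown = sorted(set(config.stent_ids) - known)
            table1 = table1[table1.stent_id.isin(config.stent_ids)]
        measurements = []
        for _, row in table1.iterrows():
            stent = stent_spec_from_row(row)
            tube = tube_for_stent(stent)
            acq = AcquisitionParams(
                **{**asdict(config.acquisition), "seed": config.seed + stent.id}
            )
            t = time.time()
            img = simulate_stent(stent, tube, acq, grid_voxel=config.grid_voxel)
            m = measure_phantom(img, config.measurement)
            log.info("stent %2d %-24s simulated+measured in %.1fs",
                     stent.id, stent.name, time.time() - t)
            measurements.append(m)
            if config.write_images:
                img.to_nifti(outdir / f"stent_{stent.id:02d}.nii.gz")
            if config.write_mips:
                _write_mip(img, outdir / f"stent_{stent.id:02d}_mip.png")
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    for sid in unknown:
        log.warning("unknown stent id %s skipped", sid)

    reports, counts = grade_table(measurements, config.thresholds)
    summary = summarize_results(measurements, reports)

    mdf = pd.DataFrame(
        [
            {
                "stent_id": m.stent_id, "name": m.name,
                "si_percent": m.si_percent,
                "vis_min_percent": m.vis_min_percent,
                "vis_max_percent": m.vis_max_percent,
                "sd_over_mean": f"{m.sd_over_mean:.2f}",
            }
            for m in sorted(measurements, key=lambda m: m.stent_id)
        ]
    )
    gdf = pd.DataFrame([asdict_report(r) for r in reports])
    _write_csv(mdf, outdir / "measurements.csv", config)
    _write_csv(gdf, outdir / "grades.csv", config)
    with open(outdir / "counts.json", "w") as fh:
        json.dump(
            {"provenance": _provenance_header(config).strip("#\n "), "counts": counts},
            fh, indent=2,
        )
    _write_summary_md(outdir / "summary.md", config, counts, summary, gdf)
    log.info("pipeline (%s, %d stents) finished in %.1fs",
             config.mode, len(measurements), time.time() - t0)
    result = {
        "measurements": measurements,
        "reports": reports,
        "counts": counts,
        "summary": summary,
        "unknown_ids": unknown,
    }
    return result


def asdict_report(r: GradeReport) -> dict:
    return {
        "stent_id": r.stent_id, "name": r.name,
        "score_si": r.score_si, "score_vis": r.score_vis,
        "score_hom": r.score_hom, "overall_score": r.overall_score,
        "overall_class": r.overall_class,
    }


def summarize_results(
    measurements: list[MeasurementResult], reports: list[GradeReport]
) -> dict:
    """Headline numbers: SI extremes with stent names, truncation count.

    Truncation = a minimal visible lumen diameter of 0 (the signal of the
    whole lumen cross-section falls below the visibility threshold
    somewhere inside the stent).  Ties on the extremes break toward the
    lowest stent id.
    """
    if not measurements:
        raise ValueError("no measurements to summarize")
    ms = sorted(measurements, key=lambda m: m.stent_id)
    lo = min(ms, key=lambda m: m.si_percent)
    hi = max(ms, key=lambda m: m.si_percent)
    truncated = [m.stent_id for m in ms if m.vis_min_percent == 0]
    return {
        "min_si_percent": lo.si_percent,
        "min_si_stent": lo.name,
        "max_si_percent": hi.si_percent,
        "max_si_stent": hi.name,
        "truncation_count": len(truncated),
        "truncated_stent_ids": truncated,
        "n_stents": len(ms),
    }


def _write_summary_md(
    path: Path, config: RunConfig, counts: dict, summary: dict, gdf: pd.DataFrame
) -> None:
    lines = [
        "# Stent lumen visibility report",
        "",
        _provenance_header(config).strip(),
        "",
        f"- stents evaluated: {summary['n_stents']}",
        f"- relative signal intensity range: {summary['min_si_percent']}% "
        f"({summary['min_si_stent']}) to {summary['max_si_percent']}% "
        f"({summary['max_si_stent']})",
        f"- stents with signal truncation (visible lumen 0%): "
        f"{summary['truncation_count']}",
        "",
        "## Class counts (good / intermediate / poor)",
        "",
    ]
    for cat, label in [
        ("si", "signal intensity"), ("vis", "lumen narrowing"),
        ("hom", "homogeneity"), ("overall", "overall"),
    ]:
        c = counts[cat]
        lines.append(f"- {label}: {c['good']} / {c['intermediate']} / {c['poor']}")
    lines += ["", "## Grades", "", gdf.to_markdown(index=False), ""]
    path.write_text("\n".join(lines))


def _write_mip(image, path: Path) -> None:
    """Longitudinal maximum-intensity projection (demonstration output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mip = image.signal.max(axis=1)
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.imshow(mip, cmap="gray", aspect="equal", origin="lower")
    ax.set_axis_off()
    fig.tight_layout(pad=0)
    fig.savefig(path, dpi=150)
    plt.close(fig)
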