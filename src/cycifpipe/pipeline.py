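"""Config-driven end-to-end runner and the synthetic-bundle writer.

``run_pipeline`` chains preprocess -> register -> crop -> (AF subtract) ->
segment -> assemble -> gate -> spatial, persisting every intermediate as
plain TIFF/CSV so any stage can be inspected or re-run with standard tools,
and writes a machine-readable manifest (parameters, seed, versions,
per-stage wall time, stage counts).

``simulate`` writes a synthetic acquisition bundle (cycle TIFFs, trichrome
image, panel file, ground-truth CSVs) directly consumable by
``run_pipeline``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .errors import CycifError, PanelConfigError
from .io import (
    ChannelImage,
    PanelConfig,
    load_panel,
    read_cycle_images,
    write_cell_table,
)
from .phenotyping import apply_gates, population_summary
from .preprocess import (
    DEFAULT_BACKGROUND_RADIUS_PX,
    estimate_af_scale,
    extract_collagen,
    subtract_autofluorescence,
    subtract_background,
)
from .registration import AffineTransform, align_experiment, crop_common_region
from .segmentation import (
    DEFAULT_CELL_EXPAND_PX,
    DEFAULT_COVERAGE_MIN,
    DEFAULT_MIN_OBJECT_PX,
    DEFAULT_P_MIN,
    DEFAULT_SCALES,
    assemble_cells,
    auto_brush_labels,
    identify_nuclei,
    predict_mask,
    train_pixel_classifier,
)
from .spatial import define_regions, density_map, neighbor_count, region_composition
from .synthetic import (
    GroundTruth,
    SimulationConfig,
    default_panel,
    generate_ground_truth,
    render_cycles,
    render_trichrome,
)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "simulate"]

logger = logging.getLogger(__name__)

DEFAULT_PARAMS: dict = {
    "background_radius_px": DEFAULT_BACKGROUND_RADIUS_PX,
    "af_channel": "AF",
    "af_estimate_smooth_px": 3.0,
    "feature_scales": list(DEFAULT_SCALES),
    "p_min": DEFAULT_P_MIN,
    "min_object_px": DEFAULT_MIN_OBJECT_PX,
    "nucleus_size_range": [30, 1500],
    "nucleus_min_diameter_px": 7,
    "cell_expand_px": DEFAULT_CELL_EXPAND_PX,
    "coverage_min": DEFAULT_COVERAGE_MIN,
    "nuclear_markers": ["PCNA"],
    "proliferation_marker": "PCNA",
    "density_bandwidth_px": 20.0,
    "density_downsample": 4,
    # neighbor analysis: radius deliberately has NO default (reported
    # protocols use both 6 and 10 px) — set neighbor_radius_px to enable
    "neighbor_radius_px": None,
    "neighbor_reference_marker": "CK19",
    "neighbor_target_condition": "IBA1+",
    "region_closing_px": 10,
    "region_min_pcna_nuclei": 10,
    "region_min_px": 500,
}


@dataclass
class RunConfig:
    """Everything one pipeline run needs; ``params`` overrides module
    defaults (see ``DEFAULT_PARAMS`` for the available keys)."""

    cycle_paths: list[str]
    panel_path: str
    out_dir: str
    seed: int = 0
    trichrome_path: str | None = None
    do_background: bool = True
    do_af: bool = True
    do_registration: bool = True
    do_regions: bool = True  # needs a trichrome image to actually run
    do_density: bool = True
    params: dict = field(default_factory=dict)

    def param(self, key: str):
        if key in self.params:
            return self.params[key]
        if key not in DEFAULT_PARAMS:
            raise PanelConfigError(f"unknown pipeline parameter {key!r}")
        return DEFAULT_PARAMS[key]


@dataclass
class PipelineResult:
    cell_table: pd.DataFrame
    summary: pd.DataFrame
    transforms: list[AffineTransform]
    manifest: dict
    out_dir: Path


class _StageTimer:
    def __init__(self, manifest: dict):
        self.manifest = manifest
        self.manifest.setdefault("stages", {})

    def record(self, name: str, t0: float, **counts) -> None:
        entry = {"wall_time_s": round(time.perf_counter() - t0, 3)}
        entry.update(counts)
        self.manifest["stages"][name] = entry
        logger.info("stage %s done in %.2fs %s", name, entry["wall_time_s"], counts)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full analysis; see the module docstring for the stage chain.

    Raises the offending stage's error; artifacts of completed stages stay
    on disk under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "seed": int(config.seed),
        "config": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k != "params"
        },
        "params": {k: config.param(k) for k in DEFAULT_PARAMS} | dict(config.params),
    }
    timer = _StageTimer(manifest)
    panel = load_panel(config.panel_path)
    af_channel = str(config.param("af_channel"))

    # ---- load ---------------------------------------------------------
    t0 = time.perf_counter()
    cycles = read_cycle_images(config.cycle_paths, panel)
    timer.record("load", t0, n_cycles=len(cycles))

    # ---- background subtraction --------------------------------------
    t0 = time.perf_counter()
    if config.do_background:
        radius = int(config.param("background_radius_px"))
        cycles = [
            {m: subtract_background(img, radius) for m, img in cyc.items()}
            for cyc in cycles
        ]
    timer.record("background", t0, enabled=config.do_background)

    # ---- registration + crop -----------------------------------------
    t0 = time.perf_counter()
    if config.do_registration and len(cycles) > 1:
        alignment = align_experiment(cycles, panel)
        cycles = alignment.cycles
        transforms = alignment.transforms
        scores = [r.score for r in alignment.results]
        rect = crop_common_region(alignment.validity_masks)
    else:
        transforms = [AffineTransform.identity() for _ in cycles]
        scores = [1.0 for _ in cycles]
        rect = (0, 0, *next(iter(cycles[0].values())).pixels.shape)
    r0, c0, r1, c1 = rect
    cycles = [
        {m: img.with_pixels(img.pixels[r0:r1, c0:c1]) for m, img in cyc.items()}
        for cyc in cycles
    ]
    pd.DataFrame(
        [
            {"cycle": i, "score": s}
            | {f"a{j}": v for j, v in enumerate(t.to_row())}
            for i, (t, s) in enumerate(zip(transforms, scores))
        ]
    ).to_csv(out / "transforms.csv", index=False)
    manifest["crop"] = list(rect)
    timer.record(
        "register", t0, enabled=config.do_registration, crop=list(rect)
    )

    # flatten to one aligned image per marker (DAPI from cycle 0)
    aligned: dict[str, ChannelImage] = {}
    for cyc in cycles:
        for m, img in cyc.items():
            aligned.setdefault(m, img)
    for m, img in aligned.items():
        tifffile.imwrite(
            str(out / f"aligned_{m}.tif"), img.pixels.astype(np.float32)
        )

    # ---- autofluorescence subtraction --------------------------------
    t0 = time.perf_counter()
    af_scales: dict[str, float] = {}
    if config.do_af and af_channel in aligned:
        from scipy import ndimage as _ndi

        af_ref = aligned[af_channel].pixels
        # the slope is fitted on smoothed, median-centered copies: smoothing
        # averages out shot noise (whose presence in the AF reference would
        # attenuate the slope), centering removes the residual noise-floor
        # pedestal the top-hat leaves (which would inflate a through-origin
        # fit); subtraction then uses the above-pedestal AF structure
        smooth = float(config.param("af_estimate_smooth_px"))
        af_s = _ndi.gaussian_filter(af_ref, smooth)
        af_centered = af_s - float(np.median(af_s))
        af_positive = np.clip(af_ref - float(np.median(af_ref)), 0.0, None)
        for m in list(aligned):
            if m in (panel.nuclear_channel, af_channel):
                continue
            marker = _ndi.gaussian_filter(aligned[m].pixels, smooth)
            scale = estimate_af_scale(
                marker - float(np.median(marker)), af_centered
            )
            af_scales[m] = scale
            aligned[m] = subtract_autofluorescence(aligned[m], af_positive, scale)
    manifest["af_scales"] = af_scales
    timer.record("autofluorescence", t0, scales=af_scales)

    # ---- segmentation -------------------------------------------------
    t0 = time.perf_counter()
    nuclei = identify_nuclei(
        aligned[panel.nuclear_channel],
        size_range=tuple(config.param("nucleus_size_range")),
        split=True,
        min_diameter_px=int(config.param("nucleus_min_diameter_px")),
    )
    tifffile.imwrite(str(out / "nuclei_labels.tif"), nuclei)
    scales = tuple(float(s) for s in config.param("feature_scales"))
    marker_masks: dict[str, np.ndarray] = {}
    marker_images: dict[str, ChannelImage] = {}
    seg_markers = [
        m for m in aligned if m not in (panel.nuclear_channel, af_channel)
    ]
    for i, m in enumerate(sorted(seg_markers)):
        marker_seed = (int(config.seed) * 97 + i) % (2**31 - 1)
        labels = auto_brush_labels(aligned[m], seed=marker_seed)
        clf = train_pixel_classifier(
            aligned[m], labels, scales=scales, seed=marker_seed
        )
        mask = predict_mask(
            clf,
            aligned[m],
            p_min=float(config.param("p_min")),
            min_object_px=int(config.param("min_object_px")),
        )
        marker_masks[m] = mask
        marker_images[m] = aligned[m]
        tifffile.imwrite(str(out / f"mask_{m}.tif"), mask.astype(np.uint8))
    timer.record(
        "segment",
        t0,
        n_nuclei=int(nuclei.max()),
        markers=sorted(seg_markers),
    )

    # ---- cell assembly + gating ---------------------------------------
    t0 = time.perf_counter()
    table = assemble_cells(
        nuclei,
        marker_masks,
        marker_images,
        cell_expand_px=int(config.param("cell_expand_px")),
        coverage_min=float(config.param("coverage_min")),
        nuclear_markers=tuple(config.param("nuclear_markers")),
        marker_order=sorted(seg_markers),
    )
    table = apply_gates(table, panel.gating_rules)
    timer.record("assemble_gate", t0, n_cells=len(table))

    # ---- spatial -------------------------------------------------------
    t0 = time.perf_counter()
    shape = nuclei.shape
    if config.do_density and len(table):
        for pheno in sorted(table["phenotype"].unique()):
            pts = table.loc[
                table["phenotype"] == pheno, ["centroid_row", "centroid_col"]
            ].to_numpy()
            dm = density_map(
                pts,
                shape,
                bandwidth_px=float(config.param("density_bandwidth_px")),
                downsample=int(config.param("density_downsample")),
            )
            tifffile.imwrite(
                str(out / f"density_{pheno}.tif"), dm.grid.astype(np.float32)
            )
    neighbor_radius = config.param("neighbor_radius_px")
    if neighbor_radius is not None:
        ref_marker = str(config.param("neighbor_reference_marker"))
        if ref_marker in marker_masks:
            from skimage.measure import label as cc_label

            ref_labels = cc_label(marker_masks[ref_marker], connectivity=1)
            cond = str(config.param("neighbor_target_condition"))
            pos_col = f"pos_{cond[:-1]}"
            sel = table[pos_col].to_numpy(dtype=bool)
            if cond.endswith("-"):
                sel = ~sel
            counts = neighbor_count(
                ref_labels, table[sel], int(neighbor_radius)
            )
            pd.DataFrame(
                [
                    {"reference_object": k, "n_targets": v}
                    for k, v in sorted(counts.per_object.items())
                ]
            ).to_csv(out / "neighbor_counts.csv", index=False)
            manifest["neighbor_total_unique"] = counts.total_unique
            manifest["neighbor_per_area"] = counts.per_area
    else:
        logger.info("neighbor analysis skipped: neighbor_radius_px not set")

    region_table = None
    if config.do_regions and config.trichrome_path is not None:
        rgb = tifffile.imread(str(config.trichrome_path))
        collagen_full = extract_collagen(rgb)
        collagen = collagen_full[r0:r1, c0:c1]
        prolif = str(config.param("proliferation_marker"))
        pos_col = f"pos_{prolif}"
        if pos_col in table.columns:
            pos_ids = set(table.loc[table[pos_col], "cell_id"].astype(int))
            pcna_nuclei = np.where(np.isin(nuclei, list(pos_ids)), nuclei, 0)
        else:
            pcna_nuclei = np.zeros_like(nuclei)
        regions = define_regions(
            collagen,
            pcna_nuclei,
            closing_px=int(config.param("region_closing_px")),
            min_pcna_nuclei=int(config.param("region_min_pcna_nuclei")),
            min_region_px=int(config.param("region_min_px")),
        )
        tifffile.imwrite(str(out / "region_labels.tif"), regions.labels)
        pts = np.rint(
            table[["centroid_row", "centroid_col"]].to_numpy()
        ).astype(int)
        if len(pts):
            rid = regions.labels[pts[:, 0], pts[:, 1]]
            table["region"] = [
                regions.classes[int(v)]
                + (f"_{int(v)}" if regions.classes[int(v)] == "tumor" else "")
                for v in rid
            ]
        region_table = region_composition(regions, table)
        region_table.to_csv(out / "region_composition.csv", index=False)
        manifest["n_tumor_regions"] = regions.n_tumors
    timer.record("spatial", t0)

    # ---- outputs -------------------------------------------------------
    summary = population_summary(
        table, proliferation_marker=str(config.param("proliferation_marker"))
    )
    write_cell_table(table, out / "cell_table.csv")
    summary.to_csv(out / "summary.csv", index=False, float_format="%.6g")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return PipelineResult(
        cell_table=table,
        summary=summary,
        transforms=transforms,
        manifest=manifest,
        out_dir=out,
    )


# ---------------------------------------------------------------------------
# simulation bundles
# ---------------------------------------------------------------------------

def simulate(
    config: SimulationConfig,
    out_dir: str | Path,
    panel: PanelConfig | None = None,
) -> dict:
    """Render a synthetic acquisition bundle to ``out_dir``.

    Writes per-cycle multi-page TIFFs, a trichrome RGB TIFF, the panel YAML,
    ground-truth cell and transform CSVs and the true AF/collagen/region
    images; returns a dict of the written paths plus the ground truth.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    panel = panel or default_panel(config)
    if panel.n_cycles != len(config.cycle_transforms):
        config.cycle_transforms = (
            list(config.cycle_transforms)
            + [(0.0, 0.0, 0.0, 1.0)] * panel.n_cycles
        )[: panel.n_cycles]
    gt = generate_ground_truth(config)
    cycles = render_cycles(gt, config, panel)
    paths: dict = {"out_dir": str(out), "cycles": []}
    for i, cyc in enumerate(cycles):
        stack = np.stack(
            [cyc[m].pixels for m in panel.cycle_markers(i)]
        ).astype(np.float32)
        p = out / f"cycle_{i}.tif"
        tifffile.imwrite(str(p), stack)
        paths["cycles"].append(str(p))
    rgb = render_trichrome(gt, config)
    paths["trichrome"] = str(out / "trichrome.tif")
    tifffile.imwrite(paths["trichrome"], (rgb * 255).astype(np.uint8))
    paths["panel"] = str(out / "panel.yaml")
    panel.save(paths["panel"])

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(1, gt.n_cells + 1),
            "centroid_row": gt.centers[:, 0] if gt.n_cells else [],
            "centroid_col": gt.centers[:, 1] if gt.n_cells else [],
            "phenotype": gt.phenotypes,
        }
    )
    for marker, amp in gt.amplitudes.items():
        cells[f"amp_{marker}"] = amp
    paths["ground_truth_cells"] = str(out / "ground_truth_cells.csv")
    cells.to_csv(paths["ground_truth_cells"], index=False, float_format="%.6g")

    pd.DataFrame(
        [
            {"cycle": i} | {f"a{j}": v for j, v in enumerate(t.to_row())}
            for i, t in enumerate(gt.transforms)
        ]
    ).to_csv(out / "true_transforms.csv", index=False)
    paths["true_transforms"] = str(out / "true_transforms.csv")

    tifffile.imwrite(str(out / "af_true.tif"), gt.af_image.astype(np.float32))
    paths["af_true"] = str(out / "af_true.tif")
    if gt.collagen_mask is not None:
        tifffile.imwrite(
            str(out / "collagen_true.tif"), gt.collagen_mask.astype(np.uint8)
        )
        paths["collagen_true"] = str(out / "collagen_true.tif")
    if gt.region_mask is not None:
        tifffile.imwrite(
            str(out / "region_true.tif"), gt.region_mask.astype(np.int32)
        )
        paths["region_true"] = str(out / "region_true.tif")
    echo = dataclasses.asdict(config)
    with open(out / "simulation_config.json", "w") as fh:
        json.dump(echo, fh, indent=2, sort_keys=True, default=str)
    paths["config_echo"] = str(out / "simulation_config.json")
    paths["ground_truth"] = gt
    return paths
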