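"""Synthetic multiplex-tissue generator with full ground truth.

Renders what a cyclic immunofluorescence experiment on a liver section
produces — one nuclear-counterstain channel per staining cycle plus marker
channels, a trichrome-like RGB brightfield — from a known cell map, so every
downstream stage (preprocessing, registration, segmentation, gating, spatial
analysis) can be scored against ground truth instead of eyeballed.

The model is deliberately simple but covers the failure modes that matter:

* cells are placed by dart-throwing with a minimum center distance
  (nuclei of adherent tissue do not interpenetrate);
* phenotypes are i.i.d. draws from configurable frequencies; each phenotype
  expresses a configurable subset of markers with Gaussian amplitude
  variation truncated at zero;
* each cycle is observed through its own true affine transform (section
  re-mounting between staining rounds), applied before sensor noise;
* a smooth background plane, a shared smooth autofluorescence (AF) field
  mixed into marker channels, and shot-like noise (sd proportional to the
  square root of intensity) corrupt the rendered images;
* an optional tumor scenario adds collagen rings encapsulating disks where
  the proliferation-marker probability is raised.

Determinism: every stochastic element draws from a dedicated child stream of
``rng_seed`` (placement, phenotypes, amplitudes, AF field, tumor geometry,
per-cycle noise), so identical configs give bit-identical output and each
element can be re-drawn independently by tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage.color import hsv2rgb
from skimage.draw import disk as draw_disk

from .errors import CapacityError, InputError, ParameterError
from .io import ChannelImage, GatingRule, PanelConfig
from .registration import AffineTransform

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "default_panel",
    "generate_ground_truth",
    "render_cycles",
    "render_trichrome",
    "true_marker_mask",
    "true_phenotype_fractions",
]

# rng stream ids (children of rng_seed)
_STREAM_PLACEMENT = 1
_STREAM_PHENOTYPE = 2
_STREAM_AMPLITUDE = 3
_STREAM_AF = 4
_STREAM_TUMOR = 5
_STREAM_NOISE_BASE = 10  # + cycle index

#: spot width as a fraction of the object radius; the half-maximum contour
#: of a spot then sits at ~0.88 radius, so rendered objects fill most of
#: their nominal footprint.
SIGMA_PER_RADIUS = 0.75

DEFAULT_PHENOTYPE_FREQUENCIES = {
    "KC": 0.3,       # Kupffer cells, IBA1+ CLEC4F+
    "MoMF": 0.3,     # monocyte-derived macrophages, IBA1+ CLEC4F-
    "ductular": 0.1, # biliary/ductular cells, CK19+
    "other": 0.3,    # remaining parenchyma
}

#: per phenotype, the markers it expresses with (mean, sd) amplitude
DEFAULT_MARKER_MODEL = {
    "KC": {"IBA1": (180.0, 20.0), "CLEC4F": (160.0, 20.0)},
    "MoMF": {"IBA1": (180.0, 20.0)},
    "ductular": {"CK19": (170.0, 20.0)},
    "other": {},
}

DEFAULT_PROLIFERATION_PROBS = {
    "KC": 0.3,
    "MoMF": 0.3,
    "ductular": 0.05,
    "other": 0.05,
}

DEFAULT_CYCLE_TRANSFORMS = [
    (0.0, 0.0, 0.0, 1.0),
    (12.0, -7.0, 0.8, 1.0),
    (-15.0, 9.0, -2.0, 1.01),
    (6.0, 18.0, 3.0, 0.98),
    (-20.0, -11.0, 1.5, 1.02),
]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic experiment; defaults give a five-cycle
    liver-like section at desk scale.

    ``cycle_transforms`` are the *true* per-cycle transforms as
    ``(shift_row, shift_col, rotation_deg, scale)`` about the image center;
    cycle 0 must be the identity. ``af_mix`` maps marker name to the
    coefficient with which the shared AF field leaks into that channel.
    """

    image_shape: tuple[int, int] = (1024, 1024)
    n_cells: int = 300
    min_center_distance_px: float = 14.0
    margin_px: float = 48.0  # keeps every cell in the common field of view
    phenotype_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHENOTYPE_FREQUENCIES)
    )
    marker_model: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_MARKER_MODEL.items()
        }
    )
    nucleus_radius_px: float = 5.0
    cell_radius_px: float = 8.0
    dapi_amplitude: tuple[float, float] = (200.0, 20.0)
    proliferation_marker: str = "PCNA"
    proliferation_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROLIFERATION_PROBS)
    )
    proliferation_amplitude: tuple[float, float] = (150.0, 20.0)
    nuclear_markers: tuple[str, ...] = ("DAPI", "PCNA")
    cycle_transforms: list[tuple[float, float, float, float]] = field(
        default_factory=lambda: [tuple(t) for t in DEFAULT_CYCLE_TRANSFORMS]
    )
    background: tuple[float, float] = (20.0, 0.01)  # offset, diagonal slope
    af_channel_name: str = "AF"
    af_amplitude: float = 30.0
    af_mix: dict[str, float] = field(
        default_factory=lambda: {"IBA1": 0.2, "CLEC4F": 0.2, "CK19": 0.2}
    )
    # diet autofluorescence is granular (lipofuscin-like speckle), far
    # finer than the background-subtraction radius, so it survives the
    # top-hat and can be estimated from the AF reference channel
    af_smoothness_px: float = 8.0
    noise_sd: float = 1.0
    rng_seed: int = 0
    # tumor scenario -----------------------------------------------------
    tumor: bool = False
    n_tumors: int = 3
    tumor_radius_px: float = 70.0
    ring_thickness_px: float = 6.0
    # two capsule gaps of this arc per ring; at the default geometry the
    # gap chord (~7.5 px) stays below the region-closing radius, the
    # practical sealing limit for thin capsule walls
    ring_gap_deg: float = 6.0
    tumor_pcna_inside: float = 0.6
    tumor_pcna_outside: float = 0.05
    tumor_excluded_phenotype: str | None = None

    def validate(self) -> None:
        freq_sum = float(sum(self.phenotype_frequencies.values()))
        if abs(freq_sum - 1.0) > 1e-9:
            raise ParameterError(
                f"phenotype frequencies must sum to 1, got {freq_sum}"
            )
        if self.cell_radius_px < self.nucleus_radius_px:
            raise ParameterError("cell_radius_px must be >= nucleus_radius_px")
        if self.min_center_distance_px < 2 * self.nucleus_radius_px:
            raise ParameterError(
                "min_center_distance_px must be >= 2 * nucleus_radius_px"
            )
        if self.n_cells < 0:
            raise ParameterError("n_cells must be >= 0")
        for pheno in self.marker_model:
            if pheno not in self.phenotype_frequencies:
                raise ParameterError(
                    f"marker model lists unknown phenotype {pheno!r}"
                )

    def markers(self) -> list[str]:
        """Non-nuclear markers in deterministic order."""
        seen: list[str] = []
        for model in self.marker_model.values():
            for m in model:
                if m not in seen:
                    seen.append(m)
        if self.proliferation_marker not in seen:
            seen.append(self.proliferation_marker)
        return seen


@dataclass
class GroundTruth:
    """Everything the simulator knows and the pipeline must recover."""

    centers: np.ndarray  # (n, 2) float, (row, col)
    phenotypes: np.ndarray  # (n,) str
    amplitudes: dict[str, np.ndarray]  # marker -> (n,) true amplitude
    transforms: list[AffineTransform]  # per cycle, moving -> reference
    af_image: np.ndarray
    collagen_mask: np.ndarray | None = None
    region_mask: np.ndarray | None = None  # true tumor disks, labeled 1..K
    config: SimulationConfig | None = None

    @property
    def n_cells(self) -> int:
        return len(self.centers)

    def expressing(self, marker: str) -> np.ndarray:
        """Boolean per-cell ground-truth positivity for a marker."""
        return self.amplitudes[marker] > 0


def default_panel(config: SimulationConfig | None = None) -> PanelConfig:
    """Five-cycle panel matching the default simulation: DAPI every cycle,
    an AF reference channel in cycle 0 and one marker per later cycle."""
    config = config or SimulationConfig()
    cycles = [[("ch0", "DAPI"), ("ch1", config.af_channel_name)]]
    for marker in config.markers():
        cycles.append([("ch0", "DAPI"), ("ch1", marker)])
    rules = [
        GatingRule("KC", (("IBA1", "+"), ("CLEC4F", "+")), priority=0),
        GatingRule("MoMF", (("IBA1", "+"), ("CLEC4F", "-")), priority=1),
        GatingRule("ductular", (("CK19", "+"),), priority=2),
    ]
    return PanelConfig(cycles=cycles, nuclear_channel="DAPI", gating_rules=rules)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def _place_cells(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_cells
    if n == 0:
        return np.zeros((0, 2))
    lo = config.margin_px
    hi_r = config.image_shape[0] - 1 - config.margin_px
    hi_c = config.image_shape[1] - 1 - config.margin_px
    if hi_r <= lo or hi_c <= lo:
        raise CapacityError("margin leaves no room for cell placement")
    d2 = config.min_center_distance_px**2
    centers = np.empty((n, 2))
    placed = 0
    budget = max(2000, 200 * n)
    while placed < n and budget > 0:
        budget -= 1
        cand = np.array(
            [rng.uniform(lo, hi_r), rng.uniform(lo, hi_c)]
        )
        if placed:
            diff = centers[:placed] - cand
            if float(np.min(np.einsum("ij,ij->i", diff, diff))) < d2:
                continue
        centers[placed] = cand
        placed += 1
    if placed < n:
        raise CapacityError(
            f"placed only {placed}/{n} cells at min distance "
            f"{config.min_center_distance_px} within the retry budget"
        )
    return centers


def _tumor_geometry(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Collagen ring mask and labeled true tumor-disk mask."""
    shape = config.image_shape
    collagen = np.zeros(shape, dtype=bool)
    regions = np.zeros(shape, dtype=np.int32)
    r_out = config.tumor_radius_px + config.ring_thickness_px
    margin = r_out + 10
    centers = []
    tries = 0
    while len(centers) < config.n_tumors and tries < 10_000:
        tries += 1
        cand = np.array(
            [
                rng.uniform(margin, shape[0] - 1 - margin),
                rng.uniform(margin, shape[1] - 1 - margin),
            ]
        )
        if all(np.linalg.norm(cand - c) > 2.5 * r_out for c in centers):
            centers.append(cand)
    if len(centers) < config.n_tumors:
        raise CapacityError("cannot place the requested number of tumor rings")
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for k, (cy, cx) in enumerate(centers, start=1):
        dist = np.hypot(rr - cy, cc - cx)
        ring = (dist >= config.tumor_radius_px) & (dist < r_out)
        if config.ring_gap_deg > 0:
            ang = np.degrees(np.arctan2(rr - cy, cc - cx)) % 360.0
            gap_half = config.ring_gap_deg / 2.0
            for gap_center in (0.0, 180.0):
                d = np.abs((ang - gap_center + 180.0) % 360.0 - 180.0)
                ring &= ~(d < gap_half)
        collagen |= ring
        regions[dist < config.tumor_radius_px] = k
    return collagen, regions


def generate_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Sample the true cell map for one synthetic section.

    Placement uses dart-throwing with minimum-distance rejection and a
    bounded retry budget; phenotypes are i.i.d. multinomial; amplitudes are
    Gaussian per (phenotype, marker), truncated at zero.
    """
    config.validate()
    seed = int(config.rng_seed)
    rng_pos = np.random.default_rng([seed, _STREAM_PLACEMENT])
    rng_phe = np.random.default_rng([seed, _STREAM_PHENOTYPE])
    rng_amp = np.random.default_rng([seed, _STREAM_AMPLITUDE])
    rng_af = np.random.default_rng([seed, _STREAM_AF])
    rng_tum = np.random.default_rng([seed, _STREAM_TUMOR])

    collagen = region = None
    if config.tumor:
        collagen, region = _tumor_geometry(config, rng_tum)

    centers = _place_cells(config, rng_pos)
    labels = list(config.phenotype_frequencies)
    probs = np.array([config.phenotype_frequencies[k] for k in labels])
    phenotypes = rng_phe.choice(labels, size=config.n_cells, p=probs)

    in_tumor = np.zeros(config.n_cells, dtype=bool)
    if config.tumor and config.n_cells:
        idx = np.rint(centers).astype(int)
        in_tumor = region[idx[:, 0], idx[:, 1]] > 0
        if config.tumor_excluded_phenotype is not None:
            excl = config.tumor_excluded_phenotype
            others = [l for l in labels if l != excl]
            p_other = np.array([config.phenotype_frequencies[l] for l in others])
            p_other = p_other / p_other.sum()
            redo = in_tumor & (phenotypes == excl)
            if redo.any():
                phenotypes[redo] = rng_phe.choice(
                    others, size=int(redo.sum()), p=p_other
                )

    # amplitudes: deterministic marker order; draws taken for every cell,
    # then zeroed where the phenotype does not express the marker
    amplitudes: dict[str, np.ndarray] = {}
    mu, sd = config.dapi_amplitude
    amplitudes["DAPI"] = np.clip(
        rng_amp.normal(mu, sd, config.n_cells), 0.0, None
    )
    for marker in config.markers():
        if marker == config.proliferation_marker:
            continue
        amp = np.zeros(config.n_cells)
        for pheno, model in config.marker_model.items():
            if marker not in model:
                continue
            mu, sd = model[marker]
            sel = phenotypes == pheno
            draws = np.clip(rng_amp.normal(mu, sd, config.n_cells), 0.0, None)
            amp[sel] = draws[sel]
        amplitudes[marker] = amp

    # proliferation: Bernoulli per cell; tumor geometry overrides phenotype
    if config.tumor:
        p = np.where(in_tumor, config.tumor_pcna_inside, config.tumor_pcna_outside)
    else:
        p = np.array(
            [config.proliferation_probs.get(ph, 0.0) for ph in phenotypes]
        )
    proliferating = rng_amp.uniform(size=config.n_cells) < p
    mu, sd = config.proliferation_amplitude
    pcna = np.clip(rng_amp.normal(mu, sd, config.n_cells), 0.0, None)
    amplitudes[config.proliferation_marker] = np.where(proliferating, pcna, 0.0)

    # shared autofluorescence field: smooth random surface in [0, af_amplitude]
    rough = rng_af.normal(size=config.image_shape)
    smooth = ndimage.gaussian_filter(rough, config.af_smoothness_px)
    lo, hi = float(smooth.min()), float(smooth.max())
    af = (
        (smooth - lo) / (hi - lo) * config.af_amplitude
        if hi > lo
        else np.zeros(config.image_shape)
    )

    center = ((config.image_shape[0] - 1) / 2.0, (config.image_shape[1] - 1) / 2.0)
    transforms = [
        AffineTransform.from_params(
            translation=(t[0], t[1]), rotation_deg=t[2], scale=t[3], center=center
        )
        for t in config.cycle_transforms
    ]

    return GroundTruth(
        centers=centers,
        phenotypes=np.asarray(phenotypes, dtype=object),
        amplitudes=amplitudes,
        transforms=transforms,
        af_image=af,
        collagen_mask=collagen,
        region_mask=region,
        config=config,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _add_spots(
    canvas: np.ndarray,
    centers: np.ndarray,
    amplitudes: np.ndarray,
    sigma: float,
) -> None:
    """Accumulate isotropic Gaussian spots, truncated at 4 sigma."""
    if sigma <= 0:
        raise ParameterError("spot sigma must be positive")
    half = int(np.ceil(4.0 * sigma))
    size = 2 * half + 1
    ax = np.arange(size, dtype=float)
    nrows, ncols = canvas.shape
    for (cy, cx), amp in zip(centers, amplitudes):
        if amp <= 0:
            continue
        iy, ix = int(np.floor(cy)), int(np.floor(cx))
        y0, x0 = iy - half, ix - half
        gy = np.exp(-((ax + y0 - cy) ** 2) / (2 * sigma**2))
        gx = np.exp(-((ax + x0 - cx) ** 2) / (2 * sigma**2))
        sy0, sy1 = max(0, y0), min(nrows, y0 + size)
        sx0, sx1 = max(0, x0), min(ncols, x0 + size)
        if sy0 >= sy1 or sx0 >= sx1:
            continue
        patch = np.outer(gy[sy0 - y0 : sy1 - y0], gx[sx0 - x0 : sx1 - x0])
        canvas[sy0:sy1, sx0:sx1] += amp * patch


def _marker_sigma(config: SimulationConfig, marker: str) -> float:
    radius = (
        config.nucleus_radius_px
        if marker in config.nuclear_markers
        else config.cell_radius_px
    )
    return SIGMA_PER_RADIUS * radius


def _background_plane(config: SimulationConfig) -> np.ndarray:
    offset, slope = config.background
    rr, cc = np.mgrid[0 : config.image_shape[0], 0 : config.image_shape[1]]
    return offset + slope * (rr + cc) / 2.0


def render_scene(
    gt: GroundTruth, config: SimulationConfig, marker: str
) -> np.ndarray:
    """Noiseless signal image of one marker in the reference frame
    (spots only — no background, AF or noise)."""
    canvas = np.zeros(config.image_shape)
    if marker == config.af_channel_name:
        return canvas
    amp = gt.amplitudes.get(marker)
    if amp is None:
        raise InputError(f"marker {marker!r} not in ground truth")
    _add_spots(canvas, gt.centers, amp, _marker_sigma(config, marker))
    return canvas


def render_cycles(
    gt: GroundTruth, config: SimulationConfig, panel: PanelConfig
) -> list[dict[str, ChannelImage]]:
    """Render every cycle's channel set as acquired.

    Each channel is composed in the reference frame (spots + background
    plane + AF leakage), warped into the cycle's own frame by the true
    transform, and finally corrupted by shot-like sensor noise (applied
    after warping: noise belongs to the acquisition, not the tissue).
    """
    if panel.n_cycles != len(gt.transforms):
        raise InputError(
            f"panel has {panel.n_cycles} cycles but ground truth carries "
            f"{len(gt.transforms)} transforms"
        )
    bg = _background_plane(config)
    scenes: dict[str, np.ndarray] = {}
    for marker in set(panel.markers()):
        scene = render_scene(gt, config, marker)
        af_coeff = (
            1.0
            if marker == config.af_channel_name
            else float(config.af_mix.get(marker, 0.0))
        )
        scenes[marker] = scene + bg + af_coeff * gt.af_image
    seed = int(config.rng_seed)
    cycles: list[dict[str, ChannelImage]] = []
    for ci in range(panel.n_cycles):
        t = gt.transforms[ci]
        rng = np.random.default_rng([seed, _STREAM_NOISE_BASE + ci])
        channels: dict[str, ChannelImage] = {}
        for marker in panel.cycle_markers(ci):
            scene = scenes[marker]
            if np.allclose(t.matrix, AffineTransform.identity().matrix):
                observed = scene.copy()
            else:
                # observed moving-frame pixel x samples the scene at T(x)
                observed = ndimage.affine_transform(
                    scene,
                    t.linear,
                    offset=t.translation,
                    order=1,
                    mode="constant",
                    cval=0.0,
                )
            if config.noise_sd > 0:
                noise = rng.normal(size=observed.shape)
                observed = observed + noise * config.noise_sd * np.sqrt(
                    np.clip(observed, 0.0, None)
                )
            observed = np.clip(observed, 0.0, None)
            channels[marker] = ChannelImage(
                pixels=observed, cycle_index=ci, channel_name=marker
            )
        cycles.append(channels)
    return cycles


# trichrome hues (HSV): collagen blue, tissue pink, background near-white
_HSV_COLLAGEN = (0.60, 0.70, 0.65)
_HSV_TISSUE = (0.93, 0.40, 0.80)
_HSV_BACKGROUND = (0.00, 0.02, 0.97)


def render_trichrome(gt: GroundTruth, config: SimulationConfig) -> np.ndarray:
    """Masson's-trichrome-like RGB: collagen in a blue hue band, cellular
    tissue in pink, empty background near-white. Float RGB in [0, 1]."""
    shape = config.image_shape
    tissue = np.zeros(shape, dtype=bool)
    paint_r = int(round(2 * config.cell_radius_px))
    for cy, cx in gt.centers:
        rr, cc = draw_disk((cy, cx), paint_r, shape=shape)
        tissue[rr, cc] = True
    hsv = np.empty(shape + (3,))
    hsv[..., 0], hsv[..., 1], hsv[..., 2] = _HSV_BACKGROUND
    for ch in range(3):
        hsv[..., ch][tissue] = _HSV_TISSUE[ch]
    if gt.collagen_mask is not None and gt.collagen_mask.any():
        for ch in range(3):
            hsv[..., ch][gt.collagen_mask] = _HSV_COLLAGEN[ch]
    return hsv2rgb(hsv)


# ---------------------------------------------------------------------------
# ground-truth conveniences for scoring
# ---------------------------------------------------------------------------

def true_marker_mask(
    gt: GroundTruth,
    config: SimulationConfig,
    marker: str,
    level: float = 0.5,
) -> np.ndarray:
    """Ground-truth binary mask of a marker: pixels where the noiseless
    signal reaches ``level`` times the marker's model mean amplitude
    (default: the half-maximum support of a typical spot)."""
    scene = render_scene(gt, config, marker)
    if marker == config.proliferation_marker:
        ref_amp = config.proliferation_amplitude[0]
    elif marker == "DAPI":
        ref_amp = config.dapi_amplitude[0]
    else:
        means = [
            model[marker][0]
            for model in config.marker_model.values()
            if marker in model
        ]
        if not means:
            raise InputError(f"marker {marker!r} not in the marker model")
        ref_amp = float(np.mean(means))
    return scene >= level * ref_amp


def true_phenotype_fractions(gt: GroundTruth) -> dict[str, float]:
    labels, counts = np.unique(np.asarray(gt.phenotypes, dtype=str), return_counts=True)
    n = max(1, gt.n_cells)
    return {l: c / n for l, c in zip(labels, counts)}
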