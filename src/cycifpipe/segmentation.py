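"""Trainable pixel classification, nucleus identification and cell assembly.

The segmentation strategy mirrors interactive pixel-classification tools:
a small supervised ensemble (random forest) is trained on sparsely labeled
pixels over a standard feature bank (Gaussian-smoothed intensity, gradient
magnitude and Laplacian of Gaussian at several scales, plus the raw
intensity), then thresholded class probabilities become binary marker masks.

Because the original workflow labels pixels by hand in a GUI, this module
also ships an unattended auto-labeling fallback that brushes the brightest
and dimmest intensity quantiles — enough to bootstrap reproducible tests
and batch runs without interaction.

Nuclei are segmented from the nuclear counterstain with Otsu thresholding
(or a classifier probability map), hole filling, optional splitting of
touching nuclei by distance-transform peak seeding plus watershed growth,
and an area filter. Cell objects are then assembled by expanding each
nucleus outward a few pixels without crossing a neighbor's territory, and
marker positivity is called by the fraction of the footprint covered by the
marker's binary mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.segmentation import expand_labels, relabel_sequential, watershed
from sklearn.ensemble import RandomForestClassifier

from .errors import InputError, ParameterError
from .io import ChannelImage, cell_table_columns

__all__ = [
    "PixelClassifier",
    "compute_pixel_features",
    "auto_brush_labels",
    "train_pixel_classifier",
    "predict_mask",
    "identify_nuclei",
    "assemble_cells",
    "save_classifier",
    "load_classifier",
]

logger = logging.getLogger(__name__)

DEFAULT_SCALES = (1.0, 2.0, 4.0)
DEFAULT_P_MIN = 0.5
DEFAULT_MIN_OBJECT_PX = 20
DEFAULT_CELL_EXPAND_PX = 3
DEFAULT_COVERAGE_MIN = 0.3

_CLASSIFIER_FORMAT_VERSION = 1


def _pixels(img: ChannelImage | np.ndarray) -> np.ndarray:
    return img.pixels if isinstance(img, ChannelImage) else np.asarray(img, float)


def compute_pixel_features(
    img: ChannelImage | np.ndarray, scales: Sequence[float] = DEFAULT_SCALES
) -> np.ndarray:
    """Per-pixel feature stack: raw intensity plus, per scale, Gaussian
    smoothing, Gaussian gradient magnitude and Laplacian of Gaussian.

    Returns ``(rows, cols, 3 * len(scales) + 1)``.
    """
    scales = list(scales)
    if not scales:
        raise ParameterError("need at least one scale")
    if any(s <= 0 for s in scales):
        raise ParameterError("feature scales must be positive")
    pixels = _pixels(img)
    planes = [pixels]
    for s in scales:
        planes.append(ndimage.gaussian_filter(pixels, s))
        planes.append(ndimage.gaussian_gradient_magnitude(pixels, s))
        planes.append(ndimage.gaussian_laplace(pixels, s))
    return np.stack(planes, axis=-1)


@dataclass
class PixelClassifier:
    """Trained per-pixel classifier plus the feature spec to reproduce it."""

    model: RandomForestClassifier
    scales: tuple[float, ...]
    class_names: tuple[str, ...]
    training_accuracy: float = float("nan")

    def predict_proba_image(
        self, img: ChannelImage | np.ndarray
    ) -> dict[str, np.ndarray]:
        """Per-class probability maps; probabilities sum to 1 per pixel."""
        feats = compute_pixel_features(img, self.scales)
        flat = feats.reshape(-1, feats.shape[-1])
        proba = self.model.predict_proba(flat)
        shape = feats.shape[:2]
        out: dict[str, np.ndarray] = {}
        for k, cls in enumerate(self.model.classes_):
            name = self.class_names[int(cls) - 1]
            out[name] = proba[:, k].reshape(shape)
        return out


def auto_brush_labels(
    img: ChannelImage | np.ndarray,
    bg_quantile: float = 0.5,
    fg_quantile: float = 0.995,
    n_per_class: int = 4000,
    seed: int = 0,
) -> np.ndarray:
    """Unattended stand-in for hand-drawn brush strokes.

    Pixels below the ``bg_quantile`` intensity quantile are candidate
    background (class 1), pixels above ``fg_quantile`` candidate foreground
    (class 2); ``n_per_class`` of each are sampled reproducibly. Returns a
    sparse label image (0 = unlabeled).
    """
    pixels = _pixels(img)
    rng = np.random.default_rng(seed)
    labels = np.zeros(pixels.shape, dtype=np.uint8)
    flat = pixels.ravel()
    lo, hi = np.quantile(flat, [bg_quantile, fg_quantile])
    for cls, candidates in ((1, np.flatnonzero(flat <= lo)),
                            (2, np.flatnonzero(flat >= hi))):
        if candidates.size == 0:
            raise ParameterError("auto labeling found no candidate pixels")
        take = min(n_per_class, candidates.size)
        chosen = rng.choice(candidates, size=take, replace=False)
        labels.ravel()[chosen] = cls
    return labels


def train_pixel_classifier(
    images: ChannelImage | np.ndarray | Sequence[ChannelImage | np.ndarray],
    brush_labels: np.ndarray | Sequence[np.ndarray],
    scales: Sequence[float] = DEFAULT_SCALES,
    class_names: Sequence[str] = ("background", "foreground"),
    seed: int = 0,
    n_estimators: int = 50,
    max_depth: int | None = 12,
    min_labeled_per_class: int = 50,
) -> PixelClassifier:
    """Fit a random-forest pixel classifier on sparse brush labels.

    ``brush_labels`` uses 0 for unlabeled and k for class ``class_names[k-1]``.
    Deterministic for a fixed seed. Training accuracy on the labeled pixels
    is recorded on the returned classifier.
    """
    if isinstance(images, (ChannelImage, np.ndarray)) and (
        not isinstance(images, np.ndarray) or images.ndim == 2
    ):
        images = [images]
        brush_labels = [np.asarray(brush_labels)]
    xs, ys = [], []
    for img, lab in zip(images, brush_labels):
        lab = np.asarray(lab)
        feats = compute_pixel_features(img, scales)
        if lab.shape != feats.shape[:2]:
            raise InputError("brush label image shape differs from the image")
        sel = lab > 0
        xs.append(feats[sel])
        ys.append(lab[sel])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise InputError("training labels must contain at least two classes")
    thin = [int(c) for c, n in zip(classes, counts) if n < min_labeled_per_class]
    if thin:
        raise InputError(
            f"classes {thin} have fewer than {min_labeled_per_class} labeled pixels"
        )
    if max(classes) > len(class_names):
        raise InputError("label index exceeds the number of class names")
    model = RandomForestClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        random_state=int(seed),
        n_jobs=1,
    )
    model.fit(x, y)
    acc = float(model.score(x, y))
    logger.info(
        "pixel classifier trained: %d px, classes=%s, training accuracy=%.4f",
        len(y),
        list(classes),
        acc,
    )
    return PixelClassifier(
        model=model,
        scales=tuple(float(s) for s in scales),
        class_names=tuple(class_names),
        training_accuracy=acc,
    )


def save_classifier(clf: PixelClassifier, path) -> None:
    joblib.dump(
        {
            "format_version": _CLASSIFIER_FORMAT_VERSION,
            "model": clf.model,
            "scales": clf.scales,
            "class_names": clf.class_names,
            "training_accuracy": clf.training_accuracy,
        },
        path,
    )


def load_classifier(path) -> PixelClassifier:
    payload = joblib.load(path)
    if payload.get("format_version") != _CLASSIFIER_FORMAT_VERSION:
        raise InputError("unsupported classifier file version")
    return PixelClassifier(
        model=payload["model"],
        scales=tuple(payload["scales"]),
        class_names=tuple(payload["class_names"]),
        training_accuracy=payload["training_accuracy"],
    )


def predict_mask(
    clf: PixelClassifier,
    img: ChannelImage | np.ndarray,
    class_name: str = "foreground",
    p_min: float = DEFAULT_P_MIN,
    min_object_px: int = DEFAULT_MIN_OBJECT_PX,
) -> np.ndarray:
    """Binary mask: class probability >= ``p_min`` with small components
    (< ``min_object_px``, 4-connected) removed."""
    if class_name not in clf.class_names:
        raise ParameterError(
            f"unknown class {class_name!r}; classifier knows {clf.class_names}"
        )
    if not 0.0 < p_min <= 1.0:
        raise ParameterError("p_min must lie in (0, 1]")
    proba = clf.predict_proba_image(img)[class_name]
    mask = proba >= p_min
    if min_object_px > 1 and mask.any():
        lab, _ = ndimage.label(mask)  # default structure = 4-connectivity
        sizes = np.bincount(lab.ravel())
        keep = sizes >= min_object_px
        keep[0] = False
        mask = keep[lab]
    return mask


def identify_nuclei(
    dapi: ChannelImage | np.ndarray,
    threshold: float | None = None,
    prob_map: np.ndarray | None = None,
    size_range: tuple[int, int] = (30, 1500),
    split: bool = True,
    min_diameter_px: int = 7,
) -> np.ndarray:
    """Label individual nuclei in the counterstain channel.

    Foreground comes from ``prob_map >= 0.5`` when given, else from a global
    Otsu threshold (or an explicit ``threshold``). Holes are filled. With
    ``split=True``, touching nuclei are separated by seeding watershed-style
    region growth at distance-transform peaks (peaks closer than
    ``min_diameter_px`` merge into one seed). Objects outside ``size_range``
    are dropped and labels renumbered 1..K (4-connectivity throughout).
    """
    if size_range[0] >= size_range[1]:
        raise ParameterError("size_range must be (min, max) with min < max")
    pixels = _pixels(dapi)
    if prob_map is not None:
        fg = np.asarray(prob_map) >= 0.5
    else:
        if threshold is None:
            if float(pixels.max()) == float(pixels.min()):
                fg = np.zeros(pixels.shape, dtype=bool)
            else:
                threshold = float(threshold_otsu(pixels))
        if threshold is not None:
            fg = pixels > threshold
    fg = ndimage.binary_fill_holes(fg)
    if not fg.any():
        logger.warning("identify_nuclei: empty foreground, 0 objects")
        return np.zeros(pixels.shape, dtype=np.int32)
    if split:
        dist = ndimage.distance_transform_edt(fg)
        peaks = peak_local_max(
            dist,
            min_distance=max(1, int(min_diameter_px)),
            labels=fg,
            exclude_border=False,
        )
        seeds = np.zeros(pixels.shape, dtype=np.int32)
        for i, (r, c) in enumerate(peaks, start=1):
            seeds[r, c] = i
        if seeds.max() == 0:  # pragma: no cover - degenerate tiny foreground
            labels = cc_label(fg, connectivity=1)
        else:
            labels = watershed(-dist, seeds, mask=fg, connectivity=1)
    else:
        labels = cc_label(fg, connectivity=1)
    sizes = np.bincount(labels.ravel())
    bad = (sizes < size_range[0]) | (sizes > size_range[1])
    bad[0] = True
    labels = np.where(bad[labels], 0, labels)
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def assemble_cells(
    nuclei: np.ndarray,
    marker_masks: Mapping[str, np.ndarray],
    marker_images: Mapping[str, ChannelImage | np.ndarray],
    cell_expand_px: int = DEFAULT_CELL_EXPAND_PX,
    coverage_min: float = DEFAULT_COVERAGE_MIN,
    nuclear_markers: Sequence[str] = ("PCNA",),
    marker_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Build the per-cell table from labeled nuclei and marker masks/images.

    Each nucleus grows by at most ``cell_expand_px`` into unclaimed space
    (ties go to the nearest nucleus), giving the cell footprint. Per marker,
    the mean intensity over the footprint is recorded, and the cell is
    positive when the marker mask covers at least ``coverage_min`` of the
    footprint. Markers listed in ``nuclear_markers`` (nuclear stains such
    as proliferation markers) are scored over the nucleus footprint only.
    """
    nuclei = np.asarray(nuclei)
    if not 0.0 < coverage_min <= 1.0:
        raise ParameterError("coverage_min must lie in (0, 1]")
    for name, m in marker_masks.items():
        if np.asarray(m).shape != nuclei.shape:
            raise InputError(f"marker mask {name!r} frame differs from nuclei")
    for name, im in marker_images.items():
        if _pixels(im).shape != nuclei.shape:
            raise InputError(f"marker image {name!r} frame differs from nuclei")

    if marker_order is None:
        marker_order = sorted(set(marker_masks) | set(marker_images))
    cells = expand_labels(nuclei, distance=cell_expand_px)
    props = regionprops(nuclei)
    ids = np.array([p.label for p in props], dtype=int)
    table: dict[str, np.ndarray] = {
        "cell_id": ids,
        "centroid_row": np.array([p.centroid[0] for p in props]),
        "centroid_col": np.array([p.centroid[1] for p in props]),
        "area_px": np.array([p.area for p in props], dtype=int),
    }
    nuclear = set(nuclear_markers)
    for marker in marker_order:
        footprint = nuclei if marker in nuclear else cells
        if marker in marker_images:
            mean = ndimage.mean(
                _pixels(marker_images[marker]), labels=cells, index=ids
            )
        else:
            mean = np.full(len(ids), np.nan)
        if marker in marker_masks:
            coverage = ndimage.mean(
                np.asarray(marker_masks[marker], dtype=np.float64),
                labels=footprint,
                index=ids,
            )
            pos = coverage >= coverage_min
        else:
            pos = np.zeros(len(ids), dtype=bool)
        table[f"mean_{marker}"] = np.asarray(mean, dtype=float)
        table[f"pos_{marker}"] = pos
    df = pd.DataFrame(table)
    df["phenotype"] = ""
    df["region"] = ""
    return df[cell_table_columns(marker_order)]
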