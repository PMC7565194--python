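"""Cross-cycle affine registration anchored on the nuclear counterstain.

Every staining cycle re-images the same physical section after re-mounting,
so channels of one cycle share a single planar affine mapping to the
reference cycle (cycle 0 by convention). The nuclear channel (DAPI) is
imaged in every cycle and drives the estimation; the recovered transform is
then applied to all channels of the cycle.

Estimation is two-stage: a global translation from the phase-correlation
peak, then iterative refinement of the full 6-parameter affine by
maximizing normalized cross-correlation (NCC) on Gaussian-smoothed images,
coarse-to-fine over a multi-resolution pyramid. Accuracy is judged by
ground-truth landmark recovery, not by equivalence with any particular
interactive tool.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage, optimize
from skimage.registration import phase_cross_correlation
from skimage.transform import downscale_local_mean

from .errors import CroppingError, ParameterError, RegistrationError
from .io import ChannelImage

__all__ = [
    "AffineTransform",
    "RegistrationResult",
    "AlignmentResult",
    "LandmarkFit",
    "estimate_affine",
    "warp",
    "warp_array",
    "align_experiment",
    "crop_common_region",
    "align_brightfield",
]

logger = logging.getLogger(__name__)

#: sanity bounds on |det| of the linear part — microscopy re-mounting never
#: halves or doubles the field of view.
_DET_BOUNDS = (0.5, 2.0)


@dataclass(frozen=True)
class AffineTransform:
    """Planar affine map from a moving cycle's frame to the reference frame.

    ``matrix`` is 2x3; a moving-frame point ``(row, col)`` maps to
    ``matrix[:, :2] @ (row, col) + matrix[:, 2]`` in the reference frame.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (2, 3):
            raise ParameterError(f"affine matrix must be 2x3, got {m.shape}")
        det = abs(float(np.linalg.det(m[:, :2])))
        if det == 0.0:
            raise ParameterError("affine linear part is singular")
        if not (_DET_BOUNDS[0] <= det <= _DET_BOUNDS[1]):
            raise ParameterError(
                f"|det|={det:.3g} outside sanity bounds {_DET_BOUNDS}"
            )
        object.__setattr__(self, "matrix", m)

    # -- constructors --------------------------------------------------
    @staticmethod
    def identity() -> "AffineTransform":
        return AffineTransform(np.hstack([np.eye(2), np.zeros((2, 1))]))

    @staticmethod
    def from_params(
        translation: Sequence[float] = (0.0, 0.0),
        rotation_deg: float = 0.0,
        scale: float = 1.0,
        center: Sequence[float] = (0.0, 0.0),
    ) -> "AffineTransform":
        """Similarity transform rotating/scaling about ``center`` then shifting."""
        th = np.deg2rad(rotation_deg)
        lin = scale * np.array(
            [[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]
        )
        c = np.asarray(center, dtype=float)
        t = np.asarray(translation, dtype=float) + c - lin @ c
        return AffineTransform(np.column_stack([lin, t]))

    # -- accessors ------------------------------------------------------
    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    # -- algebra ---------------------------------------------------------
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map ``(n, 2)`` moving-frame points into the reference frame."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.linear.T + self.translation

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.linear)
        return AffineTransform(
            np.column_stack([inv, -inv @ self.translation])
        )

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """Transform equal to applying ``other`` first, then ``self``."""
        lin = self.linear @ other.linear
        t = self.linear @ other.translation + self.translation
        return AffineTransform(np.column_stack([lin, t]))

    def to_row(self) -> list[float]:
        """Six coefficients in row-major order (for CSV serialization)."""
        return [float(v) for v in self.matrix.ravel()]


@dataclass
class RegistrationResult:
    """Estimated transform plus the diagnostics of the estimation."""

    transform: AffineTransform
    score: float
    low_confidence: bool = False
    level_transforms: list[AffineTransform] = field(default_factory=list)


@dataclass
class LandmarkFit:
    transform: AffineTransform
    rms_residual: float


@dataclass
class AlignmentResult:
    """All cycles resampled into the reference frame."""

    cycles: list[dict[str, ChannelImage]]
    results: list[RegistrationResult]
    validity_masks: list[np.ndarray]

    @property
    def transforms(self) -> list[AffineTransform]:
        return [r.transform for r in self.results]


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def _ncc(a: np.ndarray, b: np.ndarray, valid: np.ndarray) -> float:
    """Normalized cross-correlation over the valid region."""
    a = a[valid]
    b = b[valid]
    if a.size < 16:
        return -1.0
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return -1.0
    return float((a * b).sum() / denom)


def _params_to_matrix(p: np.ndarray) -> np.ndarray:
    return np.array(
        [[1.0 + p[2], p[3], p[0]], [p[4], 1.0 + p[5], p[1]]]
    )


def _resample(moving: np.ndarray, matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resample the moving image into the reference frame of ``matrix``.

    ``matrix`` maps moving -> reference; the resampler needs the pre-image
    of each reference pixel, i.e. the inverse map.
    """
    lin = matrix[:, :2]
    inv = np.linalg.inv(lin)
    off = -inv @ matrix[:, 2]
    out = ndimage.affine_transform(
        moving, inv, offset=off, order=1, mode="constant", cval=0.0
    )
    valid = _validity_mask(moving.shape, inv, off)
    return out, valid


def _validity_mask(shape: tuple[int, int], inv: np.ndarray, off: np.ndarray) -> np.ndarray:
    """Pixels of the reference frame whose pre-image lies inside the moving frame."""
    rows = np.arange(shape[0], dtype=np.float64)
    cols = np.arange(shape[1], dtype=np.float64)
    # pre-image coordinates: inv @ (r, c) + off, separable in r and c
    pre_r = inv[0, 0] * rows[:, None] + inv[0, 1] * cols[None, :] + off[0]
    pre_c = inv[1, 0] * rows[:, None] + inv[1, 1] * cols[None, :] + off[1]
    eps = 1e-9
    return (
        (pre_r >= -eps)
        & (pre_r <= shape[0] - 1 + eps)
        & (pre_c >= -eps)
        & (pre_c <= shape[1] - 1 + eps)
    )


def _pyramid(img: np.ndarray, factors: Sequence[int]) -> dict[int, np.ndarray]:
    out = {}
    for f in factors:
        if f == 1:
            out[f] = ndimage.gaussian_filter(img, 1.0)
        else:
            out[f] = downscale_local_mean(
                ndimage.gaussian_filter(img, f / 2.0), (f, f)
            )
    return out


def estimate_affine(
    reference_dapi: ChannelImage | np.ndarray,
    moving_dapi: ChannelImage | np.ndarray,
    levels: Sequence[int] = (8, 4, 2, 1),
    score_floor: float = 0.2,
    maxiter: Mapping[int, int] | int | None = None,
) -> RegistrationResult:
    """Estimate the affine mapping the moving nuclear image onto the reference.

    Stage 1 finds a global translation from the phase-correlation peak at the
    coarsest pyramid level; stage 2 refines the full affine by Powell
    minimization of ``1 - NCC`` at each pyramid level, coarse to fine.

    Most of the optimization happens at the coarse levels where resampling
    is cheap; the finest levels only polish. ``maxiter`` may be one number
    for all levels or a ``{factor: iterations}`` map (default: 30 at the
    coarsest level, 4 at intermediate levels, 1 at full resolution).

    A result whose final NCC falls below ``score_floor`` is flagged
    ``low_confidence`` (and a warning emitted) but still returned — dropping
    cycles is the user's decision.
    """
    ref = reference_dapi.pixels if isinstance(reference_dapi, ChannelImage) else np.asarray(reference_dapi, float)
    mov = moving_dapi.pixels if isinstance(moving_dapi, ChannelImage) else np.asarray(moving_dapi, float)
    if ref.shape != mov.shape:
        raise RegistrationError("reference and moving images differ in shape")
    if float(ref.std()) == 0.0 or float(mov.std()) == 0.0:
        raise RegistrationError("cannot register constant images")

    factors = sorted(set(int(f) for f in levels), reverse=True)
    if maxiter is None:
        iters = {
            f: (30 if f == factors[0] else (1 if f == 1 else 4))
            for f in factors
        }
    elif isinstance(maxiter, Mapping):
        iters = {f: int(maxiter.get(f, 2)) for f in factors}
    else:
        iters = {f: int(maxiter) for f in factors}
    ref_pyr = _pyramid(ref, factors)
    mov_pyr = _pyramid(mov, factors)

    # stage 1: global translation at the coarsest level
    f0 = factors[0]
    shift, _, _ = phase_cross_correlation(
        ref_pyr[f0], mov_pyr[f0], upsample_factor=4, normalization=None
    )
    # phase correlation returns the shift that moves `mov` onto `ref`;
    # our convention maps moving coords -> reference coords, so the
    # translation component equals that shift (scaled back to full res).
    p = np.zeros(6)
    p[0], p[1] = float(shift[0]) * f0, float(shift[1]) * f0

    level_transforms: list[AffineTransform] = []
    score = -1.0
    for f in factors:
        ref_l, mov_l = ref_pyr[f], mov_pyr[f]

        def objective(q: np.ndarray, _f=f, _ref=ref_l, _mov=mov_l) -> float:
            m = _params_to_matrix(np.r_[q[:2] / _f, q[2:]])
            det = float(np.linalg.det(m[:, :2]))
            # keep the search inside the sanity bounds on |det|: a barrier
            # worse than any achievable 1 - NCC turns Powell around
            if not (_DET_BOUNDS[0] < abs(det) < _DET_BOUNDS[1]):
                return 3.0 + abs(abs(det) - 1.0)
            try:
                out, valid = _resample(_mov, m)
            except np.linalg.LinAlgError:  # pragma: no cover
                return 2.0
            return 1.0 - _ncc(_ref, out, valid)

        res = optimize.minimize(
            objective,
            p,
            method="Powell",
            options={"maxiter": iters[f], "xtol": 1e-3, "ftol": 1e-7},
        )
        p = res.x
        score = 1.0 - float(res.fun)
        level_transforms.append(
            AffineTransform(_params_to_matrix(np.r_[p[:2], p[2:]]))
        )

    transform = AffineTransform(_params_to_matrix(p))
    low = score < score_floor
    if low:
        warnings.warn(
            f"registration similarity {score:.3f} below floor {score_floor}; "
            "flagging low confidence",
            stacklevel=2,
        )
    logger.info("estimate_affine: score=%.4f low_confidence=%s", score, low)
    return RegistrationResult(
        transform=transform,
        score=score,
        low_confidence=low,
        level_transforms=level_transforms,
    )


# ---------------------------------------------------------------------------
# application
# ---------------------------------------------------------------------------

def warp_array(
    pixels: np.ndarray, t: AffineTransform, order: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Resample one array into the reference frame; returns (warped, validity).

    ``order=1`` (bilinear) for intensities; use ``order=0`` (nearest) for
    label or binary masks.
    """
    lin_inv = np.linalg.inv(t.linear)
    off = -lin_inv @ t.translation
    out = ndimage.affine_transform(
        np.asarray(pixels, np.float64),
        lin_inv,
        offset=off,
        order=order,
        mode="constant",
        cval=0.0,
    )
    if order > 0:
        out = np.clip(out, 0.0, None)
    return out, _validity_mask(pixels.shape, lin_inv, off)


def warp(
    channels: Mapping[str, ChannelImage], t: AffineTransform
) -> tuple[dict[str, ChannelImage], np.ndarray]:
    """Warp every channel of one cycle into the reference frame.

    All channels share the cycle's single transform and hence one validity
    mask (true where the pre-image of the pixel lies inside the moving frame).
    """
    out: dict[str, ChannelImage] = {}
    valid: np.ndarray | None = None
    for name, img in channels.items():
        pixels, valid = warp_array(img.pixels, t, order=1)
        out[name] = img.with_pixels(pixels)
    if valid is None:
        raise ParameterError("cannot warp an empty channel set")
    return out, valid


def align_experiment(
    cycles: Sequence[Mapping[str, ChannelImage]],
    panel,
    levels: Sequence[int] = (8, 4, 2, 1),
) -> AlignmentResult:
    """Register every cycle onto cycle 0 using the nuclear channel.

    Cycle 0 is the reference and keeps the identity transform; each later
    cycle's nuclear channel is registered against cycle 0's, then all its
    channels are warped with the recovered transform.
    """
    if not cycles:
        raise ParameterError("need at least one cycle")
    nuc = panel.nuclear_channel
    for i, cyc in enumerate(cycles):
        if nuc not in cyc:
            raise ParameterError(f"cycle {i} lacks the nuclear channel {nuc!r}")

    ref = cycles[0][nuc]
    shape = ref.pixels.shape
    aligned: list[dict[str, ChannelImage]] = [dict(cycles[0])]
    results = [
        RegistrationResult(transform=AffineTransform.identity(), score=1.0)
    ]
    masks = [np.ones(shape, dtype=bool)]
    for i, cyc in enumerate(cycles[1:], start=1):
        res = estimate_affine(ref, cyc[nuc], levels=levels)
        warped, valid = warp(cyc, res.transform)
        aligned.append(warped)
        results.append(res)
        masks.append(valid)
        logger.info(
            "cycle %d aligned: score=%.4f translation=(%.2f, %.2f)",
            i,
            res.score,
            *res.transform.translation,
        )
    return AlignmentResult(cycles=aligned, results=results, validity_masks=masks)


# ---------------------------------------------------------------------------
# cropping
# ---------------------------------------------------------------------------

def crop_common_region(
    validity_masks: Sequence[np.ndarray],
) -> tuple[int, int, int, int]:
    """Largest axis-aligned rectangle valid in every cycle.

    Returns ``(row0, col0, row1, col1)`` half-open. Uses the maximal-rectangle
    dynamic program over the intersection mask (exact, O(rows x cols)).
    """
    if not validity_masks:
        raise ParameterError("need at least one validity mask")
    inter = np.ones_like(np.asarray(validity_masks[0], bool))
    for m in validity_masks:
        m = np.asarray(m, bool)
        if m.shape != inter.shape:
            raise ParameterError("validity masks differ in shape")
        inter &= m
    if not inter.any():
        raise CroppingError("cycles share no common valid region")
    if inter.all():
        return (0, 0, inter.shape[0], inter.shape[1])

    best_area = 0
    best = (0, 0, 0, 0)
    heights = np.zeros(inter.shape[1], dtype=np.int64)
    for r in range(inter.shape[0]):
        row = inter[r]
        heights = np.where(row, heights + 1, 0)
        # largest rectangle in histogram `heights`
        stack: list[int] = []
        for c in range(len(heights) + 1):
            h = heights[c] if c < len(heights) else 0
            while stack and heights[stack[-1]] >= h:
                top = stack.pop()
                height = int(heights[top])
                left = stack[-1] + 1 if stack else 0
                area = height * (c - left)
                if area > best_area:
                    best_area = area
                    best = (r - height + 1, left, r + 1, c)
            stack.append(c)
    return best


# ---------------------------------------------------------------------------
# brightfield landmarks
# ---------------------------------------------------------------------------

def align_brightfield(
    src_points: np.ndarray, dst_points: np.ndarray
) -> LandmarkFit:
    """Least-squares affine from >= 3 landmark pairs (brightfield -> reference).

    The trichrome brightfield image lacks a nuclear channel, so its alignment
    relies on user-picked corresponding points instead of intensity matching.
    """
    src = np.atleast_2d(np.asarray(src_points, float))
    dst = np.atleast_2d(np.asarray(dst_points, float))
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ParameterError("landmark arrays must both be (n, 2)")
    if src.shape[0] < 3:
        raise ParameterError("need at least 3 landmark pairs")
    design = np.column_stack([src, np.ones(len(src))])
    if np.linalg.matrix_rank(design, tol=1e-9) < 3:
        raise ParameterError("landmarks are collinear; affine is underdetermined")
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    matrix = np.column_stack([coef[:2].T, coef[2]])
    residuals = design @ coef - dst
    rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return LandmarkFit(transform=AffineTransform(matrix), rms_residual=rms)
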