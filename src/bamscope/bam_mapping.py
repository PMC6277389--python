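"""From calcium movies to registered brain activity maps (BAMs).

The measurement chain: mesh each imaging plane into equal-area ROIs, detect
calcium transients on high-pass-filtered dF/F traces (threshold = mean +
2 SD), register the count maps to a common brain template using midline
symmetry, difference post- vs pre-treatment counts summed over z-planes
(the BAM), and summarise replicates as a per-ROI one-sample T statistic
(the T-score BAM).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sig
from scipy.ndimage import shift as nd_shift
from skimage.filters import threshold_otsu
from skimage.transform import rotate as sk_rotate

from .synthetic_data import CalciumMovie

logger = logging.getLogger("bamscope.bam_mapping")

__all__ = [
    "RoiTraceSet",
    "TransientCounts",
    "BrainTemplate",
    "RegistrationResult",
    "make_default_template",
    "mesh_rois",
    "highpass",
    "count_transients",
    "count_transients_epochs",
    "register_to_template",
    "apply_registration",
    "compute_bam",
    "compute_tscore_bam",
]

#: ROI area used throughout the screen, in square micrometres.
DEFAULT_ROI_AREA_UM2 = 15.21
#: High-pass cutoff removing illumination fluctuations, Hz.
DEFAULT_HIGHPASS_HZ = 0.2
#: Reference epoch duration for rate normalisation, seconds (10 min).
REFERENCE_DURATION_S = 600.0


@dataclass
class RoiTraceSet:
    """Per-ROI mean-fluorescence time series on a regular grid."""

    traces: np.ndarray  # (n_planes, grid_h, grid_w, T)
    fs: float
    roi_area_um2: float
    pre_frames: tuple[int, int]
    post_frames: tuple[int, int]


@dataclass
class TransientCounts:
    """Transient counts per ROI and z-plane for the pre and post epochs."""

    pre: np.ndarray  # (n_planes, grid_h, grid_w) non-negative ints
    post: np.ndarray
    pre_duration_s: float
    post_duration_s: float

    def __post_init__(self) -> None:
        if self.pre.shape != self.post.shape:
            raise ValueError("pre and post count grids must have the same shape")
        if np.any(self.pre < 0) or np.any(self.post < 0):
            raise ValueError("transient counts must be non-negative")


@dataclass
class BrainTemplate:
    """Binary brain mask with midline and eye-exclusion regions.

    The midline is the vertical axis between columns ``grid_w/2 - 1`` and
    ``grid_w/2``; mirroring is a left-right column flip. The eye mask is
    disjoint from the retained brain mask.
    """

    mask: np.ndarray  # bool (grid_h, grid_w)
    eye_mask: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.mask & self.eye_mask):
            raise ValueError("eye mask must be disjoint from the brain mask")
        if not np.array_equal(self.mask, self.mask[:, ::-1]):
            raise ValueError("brain mask must be mirror-consistent about the midline")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def midline_col(self) -> float:
        return (self.mask.shape[1] - 1) / 2.0


@dataclass
class RegistrationResult:
    """Similarity transform (rotation about the image centre, translation,
    isotropic scale) mapping an acquired map onto the template frame."""

    rotation_deg: float
    translation: tuple[float, float]  # (drow, dcol) applied after rotation
    scale: float
    score: float
    identity: bool = False


def make_default_template(grid_h: int = 60, grid_w: int = 40) -> BrainTemplate:
    """Elliptical brain mask with two anterior-lateral eye regions removed.

    Row 0 is anterior; the ellipse spans most of the grid and is exactly
    mirror-symmetric about the vertical midline.
    """
    rr, cc = np.mgrid[0:grid_h, 0:grid_w]
    r0, c0 = (grid_h - 1) / 2.0, (grid_w - 1) / 2.0
    a, b = 0.48 * grid_h, 0.45 * grid_w
    ellipse = ((rr - r0) / a) ** 2 + ((cc - c0) / b) ** 2 <= 1.0
    eye_r, eye_c = 0.15 * grid_h, 0.12 * grid_w
    er0 = 0.18 * grid_h
    ec0 = 0.12 * grid_w
    eyes = ((rr - er0) / eye_r) ** 2 + ((cc - ec0) / eye_c) ** 2 <= 1.0
    eyes |= ((rr - er0) / eye_r) ** 2 + ((cc - (grid_w - 1 - ec0)) / eye_c) ** 2 <= 1.0
    mask = ellipse & ~eyes
    mask = mask & mask[:, ::-1]
    eyes = eyes & ~mask
    eyes = eyes | eyes[:, ::-1]
    return BrainTemplate(mask=mask, eye_mask=eyes)


# ---------------------------------------------------------------------------
# ROI meshing and trace processing
# ---------------------------------------------------------------------------

def mesh_rois(movie: CalciumMovie, roi_area_um2: float = DEFAULT_ROI_AREA_UM2) -> RoiTraceSet:
    """Mesh each plane into square ROIs and average fluorescence per ROI.

    ``roi_area_um2`` must correspond to an integer-sided pixel block given
    the movie's pixel area; otherwise an error suggests the nearest valid
    area.
    """
    block_f = math.sqrt(roi_area_um2 / movie.pixel_area_um2)
    block = round(block_f)
    if block < 1 or abs(block_f - block) > 1e-6:
        near = max(1, block) ** 2 * movie.pixel_area_um2
        raise ValueError(
            f"roi_area {roi_area_um2} um^2 is {block_f:.3f} pixels per side; "
            f"nearest valid roi_area is {near:.4g} um^2"
        )
    n_t, n_planes, h_px, w_px = movie.data.shape
    if h_px % block or w_px % block:
        raise ValueError("ROI block does not tile the image")
    gh, gw = h_px // block, w_px // block
    r = movie.data.reshape(n_t, n_planes, gh, block, gw, block).mean(axis=(3, 5))
    traces = np.moveaxis(r, 0, -1)  # (planes, gh, gw, T)
    return RoiTraceSet(
        traces=traces,
        fs=movie.fs,
        roi_area_um2=block**2 * movie.pixel_area_um2,
        pre_frames=movie.pre_frames,
        post_frames=movie.post_frames,
    )


def highpass(trace: np.ndarray, cutoff_hz: float = DEFAULT_HIGHPASS_HZ, fs: float = 2.0) -> np.ndarray:
    """Zero-phase second-order Butterworth high-pass along the last axis.

    Removes DC and slow illumination fluctuations below ``cutoff_hz``.
    """
    if not (0 < cutoff_hz < fs / 2):
        raise ValueError("cutoff must satisfy 0 < cutoff < fs/2")
    order = 2
    min_len = int(3 * order * fs / cutoff_hz)
    if trace.shape[-1] < min_len:
        raise ValueError(
            f"trace too short for filter warm-up ({trace.shape[-1]} < {min_len} samples)"
        )
    sos = sig.butter(order, cutoff_hz, btype="highpass", fs=fs, output="sos")
    return sig.sosfiltfilt(sos, trace, axis=-1)


def count_transients(
    filtered_trace: np.ndarray,
    fs: float,
    f0: float | None = None,
    refractory_s: float = 1.0,
) -> int:
    """Count calcium transients on a high-pass-filtered fluorescence trace.

    The trace is converted to dF/F using the baseline ``f0`` (the epoch mean
    of the *unfiltered* trace; required to be positive). Events are upward
    crossings of the threshold mean + 2 SD of the dF/F curve, with
    successive events separated by at least ``refractory_s``.
    """
    trace = np.asarray(filtered_trace, dtype=float)
    if trace.size < 10:
        raise ValueError("trace must have at least 10 samples")
    if f0 is None:
        f0 = float(trace.mean())
    if f0 <= 0:
        raise ValueError("baseline fluorescence F0 must be positive")
    dff = trace / f0
    thr = dff.mean() + 2.0 * dff.std()
    above = dff > thr
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    if crossings.size == 0:
        return 0
    refractory = refractory_s * fs
    count, last = 1, crossings[0]
    for c in crossings[1:]:
        if c - last >= refractory:
            count += 1
            last = c
    return count


def count_transients_epochs(
    rois: RoiTraceSet,
    cutoff_hz: float = DEFAULT_HIGHPASS_HZ,
    refractory_s: float = 1.0,
) -> TransientCounts:
    """Per-ROI transient counts for the pre and post epochs.

    Each epoch's trace is baselined by its own mean (F0), high-pass
    filtered, and thresholded independently.
    """
    n_planes, gh, gw, _ = rois.traces.shape
    out = {}
    for name, (a, b) in (("pre", rois.pre_frames), ("post", rois.post_frames)):
        seg = rois.traces[..., a:b]
        f0 = seg.mean(axis=-1)
        filt = highpass(seg, cutoff_hz, rois.fs)
        counts = np.zeros((n_planes, gh, gw), dtype=np.int32)
        for p in range(n_planes):
            for i in range(gh):
                for j in range(gw):
                    counts[p, i, j] = count_transients(
                        filt[p, i, j], rois.fs, f0=float(f0[p, i, j]), refractory_s=refractory_s
                    )
        out[name] = counts
    return TransientCounts(
        pre=out["pre"],
        post=out["post"],
        pre_duration_s=(rois.pre_frames[1] - rois.pre_frames[0]) / rois.fs,
        post_duration_s=(rois.post_frames[1] - rois.post_frames[0]) / rois.fs,
    )


# ---------------------------------------------------------------------------
# Template registration
# ---------------------------------------------------------------------------

def _mirror_corr(img: np.ndarray, mask: np.ndarray) -> float:
    a = img[mask]
    b = img[:, ::-1][mask]
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _transform_image(
    img: np.ndarray, rotation_deg: float, translation: tuple[float, float], scale: float
) -> np.ndarray:
    out = sk_rotate(img, rotation_deg, resize=False, order=1, mode="constant", cval=0.0)
    if scale != 1.0:
        from skimage.transform import rescale

        h, w = img.shape
        scaled = rescale(out, scale, order=1, mode="constant", cval=0.0)
        canvas = np.zeros_like(img, dtype=float)
        sh, sw = scaled.shape
        r0 = (h - sh) // 2
        c0 = (w - sw) // 2
        rs, cs = max(r0, 0), max(c0, 0)
        re, ce = min(r0 + sh, h), min(c0 + sw, w)
        canvas[rs:re, cs:ce] = scaled[rs - r0 : re - r0, cs - c0 : ce - c0]
        out = canvas
    return nd_shift(out, translation, order=1, mode="constant", cval=0.0)


def register_to_template(
    mean_image: np.ndarray,
    template: BrainTemplate,
    rotation_range_deg: float = 20.0,
    fine_step_deg: float = 0.5,
    estimate_scale: bool = True,
) -> RegistrationResult:
    """Find the similarity transform aligning an acquired map to the template.

    Coarse-to-fine grid search over rotation (±``rotation_range_deg``, final
    step ``fine_step_deg``) and translation, scoring candidates by the sum
    of (a) foreground overlap with the template mask and (b) left-right
    mirror correlation about the template midline. Scale is estimated once
    from foreground areas.
    """
    img = np.asarray(mean_image, dtype=float)
    if np.ptp(img) == 0:
        raise ValueError("no foreground found: image is constant")
    thr = threshold_otsu(img)
    fg = img > thr
    if not fg.any():
        raise ValueError("no foreground found after background removal")

    scale = 1.0
    if estimate_scale:
        scale = float(np.sqrt(template.mask.sum() / fg.sum()))
        scale = float(np.clip(scale, 0.8, 1.25))

    def centroid(m: np.ndarray) -> np.ndarray:
        idx = np.argwhere(m)
        return idx.mean(axis=0)

    target = centroid(template.mask)

    def score(rot: float, extra: tuple[float, float]) -> tuple[float, tuple[float, float]]:
        warped0 = _transform_image(img, rot, (0.0, 0.0), scale)
        f = warped0 > thr
        if not f.any():
            return -np.inf, (0.0, 0.0)
        base_shift = target - centroid(f)
        trans = (base_shift[0] + extra[0], base_shift[1] + extra[1])
        warped = _transform_image(img, rot, trans, scale)
        f = warped > thr
        overlap = (f & template.mask).sum() / max(template.mask.sum(), 1)
        sym = _mirror_corr(warped, template.mask)
        return overlap + sym, trans

    offsets = [(dr, dc) for dr in (-2.0, 0.0, 2.0) for dc in (-2.0, 0.0, 2.0)]
    best = (-np.inf, 0.0, (0.0, 0.0))
    for rot in np.arange(-rotation_range_deg, rotation_range_deg + 1e-9, 2.0):
        s, trans = score(rot, (0.0, 0.0))
        if s > best[0]:
            best = (s, rot, trans)
    coarse_rot = best[1]
    for rot in np.arange(coarse_rot - 2.0, coarse_rot + 2.0 + 1e-9, fine_step_deg):
        for off in offsets:
            s, trans = score(rot, off)
            if s > best[0]:
                best = (s, rot, trans)

    base_sym = _mirror_corr(img, template.mask)
    base_overlap = (fg & template.mask).sum() / max(template.mask.sum(), 1)
    if best[0] <= base_sym + base_overlap - 1e-12 and (best[1] != 0.0 or best[2] != (0.0, 0.0)):
        logger.warning("registration found no improving transform; returning identity")
        return RegistrationResult(0.0, (0.0, 0.0), 1.0, base_sym + base_overlap, identity=True)
    return RegistrationResult(best[1], best[2], scale, best[0])


def apply_registration(
    count_map: np.ndarray,
    transform: RegistrationResult,
    template: BrainTemplate,
    integer_counts: bool = True,
) -> np.ndarray:
    """Warp a per-ROI map into the template frame and mask it.

    ROIs outside the brain mask (including the eye regions) are set to 0 and
    should be treated as absent downstream.
    """
    warped = _transform_image(
        np.asarray(count_map, dtype=float), transform.rotation_deg, transform.translation, transform.scale
    )
    if integer_counts:
        warped = np.rint(warped)
    warped[~template.mask] = 0
    if integer_counts:
        warped = np.clip(warped, 0, None).astype(np.int32)
    return warped


# ---------------------------------------------------------------------------
# BAM and T-score BAM
# ---------------------------------------------------------------------------

def compute_bam(
    counts: TransientCounts,
    normalize_rates: bool = True,
    reference_duration_s: float = REFERENCE_DURATION_S,
) -> np.ndarray:
    """Change in transient counts per ROI, summed across z-planes.

    With ``normalize_rates`` (default), each epoch's counts are first scaled
    to a common reference duration (10 min) and rounded, so that unequal
    pre/post recording lengths compare like with like; disable to difference
    raw counts.
    """
    pre = counts.pre.astype(np.int64)
    post = counts.post.astype(np.int64)
    if normalize_rates:
        pre = np.rint(pre * (reference_duration_s / counts.pre_duration_s)).astype(np.int64)
        post = np.rint(post * (reference_duration_s / counts.post_duration_s)).astype(np.int64)
    return (post - pre).sum(axis=0).astype(np.int32)


def compute_tscore_bam(bams: np.ndarray, sd_floor: float = 1.5) -> np.ndarray:
    """Per-ROI one-sample T statistic across replicate BAMs.

    ``t_ij = mean_ij / (SD_ij / sqrt(n))`` with the sample SD (ddof=1).
    The SD is floored at ``sd_floor`` (and an all-zero ROI keeps t = 0).

    The floor regularises a known pathology of few-replicate T maps: with
    n = 5 integer count differences, the sample SD is occasionally near
    zero by chance, yielding huge |t| spikes that would dominate every
    distance and PCA downstream. A BAM entry is a difference of transient
    counts and therefore carries irreducible Poisson counting noise of SD
    ~ sqrt(c0 + c1) >~ 1.4 whenever any transients occur, so sample SDs
    below ~1.5 counts are underestimates; flooring there keeps capped |t|
    on the scale of genuine T values. Set ``sd_floor=0`` for the raw
    statistic.
    """
    bams = np.asarray(bams, dtype=float)
    if bams.ndim != 3 or bams.shape[0] < 2:
        raise ValueError("need a stack of >= 2 replicate BAMs with identical grids")
    n = bams.shape[0]
    mean = bams.mean(axis=0)
    sd = bams.std(axis=0, ddof=1)
    if sd_floor > 0:
        sd_safe = np.maximum(sd, sd_floor)
    else:
        sd_safe = sd.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd_safe / np.sqrt(n))
    t[(sd == 0) & (mean == 0)] = 0.0
    if not np.all(np.isfinite(t)):
        raise FloatingPointError("non-finite T values; use a positive sd_floor")
    return t
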