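"""Projections, orientation, membrane masks, mask subtraction, background.

This module holds the shared image plumbing used by every quantification
stage: 8-µm-style sum/max projections, flips into the canonical orientation
(anterior at low x), a deterministic junction segmenter standing in for a
trainable classifier, exact mask subtraction, and background estimation from
an off-embryo region of interest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage import filters, morphology, measure

from .roi import Rect

__all__ = [
    "EmbryoImage",
    "MembraneMask",
    "MembraneSegParams",
    "sum_projection",
    "max_projection",
    "rotate_to_canonical",
    "segment_membrane",
    "subtract_mask",
    "estimate_background",
    "foreground_mask",
    "read_embryo_tiff",
]


@dataclass
class EmbryoImage:
    """A 4-D (channel, z, y, x) intensity stack with channel-role metadata."""

    data: np.ndarray
    channel_roles: dict[str, int]
    pixel_size_um: float
    z_step_um: float
    orientation: str = "unknown"  # "canonical" | "unknown"

    def __post_init__(self) -> None:
        if self.data.ndim != 4:
            raise ValueError("data must be (channel, z, y, x)")
        if (self.data < 0).any():
            raise ValueError("intensities must be >= 0")

    def channel(self, role: str) -> np.ndarray:
        return self.data[self.channel_roles[role]]


@dataclass
class MembraneMask:
    """Binary junctional-membrane mask aligned to a 2-D projection."""

    mask: np.ndarray
    source_channel: str = "junction"
    params: "MembraneSegParams | None" = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")


def _slices_for_depth(stack: np.ndarray, depth_um: float, z_step_um: float, z_origin: int) -> int:
    if depth_um <= 0:
        raise ValueError("depth_um must be > 0")
    if not 0 <= z_origin < stack.shape[0]:
        raise ValueError("z_origin outside stack")
    n = int(np.ceil(depth_um / z_step_um))
    available = stack.shape[0] - z_origin
    if n > available:
        raise ValueError(
            f"projection depth {depth_um} um needs {n} slices but only "
            f"{available} remain ({available * z_step_um} um available)"
        )
    return n


def sum_projection(
    stack: np.ndarray, depth_um: float, z_step_um: float, z_origin: int = 0
) -> np.ndarray:
    """Sum-intensity projection over ``ceil(depth_um / z_step_um)`` slices."""
    n = _slices_for_depth(stack, depth_um, z_step_um, z_origin)
    return stack[z_origin : z_origin + n].sum(axis=0)


def max_projection(
    stack: np.ndarray, depth_um: float, z_step_um: float, z_origin: int = 0
) -> np.ndarray:
    """Maximum-intensity projection over the same slice window."""
    n = _slices_for_depth(stack, depth_um, z_step_um, z_origin)
    return stack[z_origin : z_origin + n].max(axis=0)


def rotate_to_canonical(image: EmbryoImage, flip_ap: bool = False, flip_dv: bool = False) -> EmbryoImage:
    """Flip axes (no interpolation) so the anterior sits at low x; marks the
    result canonical.  Applying the same flips twice is the identity."""
    data = image.data
    if flip_ap:
        data = data[..., ::-1]
    if flip_dv:
        data = data[..., ::-1, :]
    return EmbryoImage(
        data=np.ascontiguousarray(data),
        channel_roles=dict(image.channel_roles),
        pixel_size_um=image.pixel_size_um,
        z_step_um=image.z_step_um,
        orientation="canonical",
    )


@dataclass(frozen=True)
class MembraneSegParams:
    """Deterministic junction-segmentation settings.

    Pipeline: Gaussian smooth -> Sato ridge filter -> hysteresis threshold
    -> morphological closing -> small-object removal -> optional dilation.
    The hysteresis thresholds are relative to the maximum ridge response;
    with the defaults the mask width tracks the PSF-spread support of the
    junction signal, which keeps the membrane/cytoplasm pool decomposition
    unbiased on simulated epithelia.
    """

    smooth_sigma: float = 1.0
    ridge_sigmas: tuple[float, ...] = (1.0, 1.5)
    low_rel: float = 0.05
    high_rel: float = 0.20
    min_object_px: int = 20
    closing_radius: int = 1
    dilation_radius: int = 0


def segment_membrane(
    junction_projection: np.ndarray, params: MembraneSegParams | None = None
) -> MembraneMask:
    """Segment junctional ridges from a junction-marker projection.

    Deterministic for fixed parameters.  A blank projection yields an empty
    mask with a warning rather than an error.
    """
    params = params or MembraneSegParams()
    img = np.asarray(junction_projection, dtype=float)
    if img.size == 0:
        raise ValueError("empty projection")
    if np.ptp(img) == 0:
        warnings.warn("blank junction projection; returning empty membrane mask")
        return MembraneMask(np.zeros_like(img, dtype=bool), params=params)
    smoothed = gaussian_filter(img, params.smooth_sigma)
    ridge = filters.sato(smoothed, sigmas=params.ridge_sigmas, black_ridges=False, mode="reflect")
    top = ridge.max()
    if top <= 0:
        warnings.warn("no ridge response; returning empty membrane mask")
        return MembraneMask(np.zeros_like(img, dtype=bool), params=params)
    mask = filters.apply_hysteresis_threshold(ridge, params.low_rel * top, params.high_rel * top)
    if params.closing_radius > 0:
        mask = morphology.closing(mask, morphology.disk(params.closing_radius))
    mask = _drop_small_components(mask, params.min_object_px)
    if params.dilation_radius > 0:
        mask = morphology.dilation(mask, morphology.disk(params.dilation_radius))
    return MembraneMask(mask, params=params)


def _drop_small_components(mask: np.ndarray, min_px: int) -> np.ndarray:
    labels = measure.label(mask)
    if labels.max() == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_px
    keep[0] = False
    return keep[labels]


def subtract_mask(image: np.ndarray, mask: MembraneMask | np.ndarray) -> np.ndarray:
    """Zero out masked pixels; ``sum(out) + sum(in * mask) == sum(in)`` exactly."""
    m = mask.mask if isinstance(mask, MembraneMask) else np.asarray(mask, dtype=bool)
    img = np.asarray(image)
    if img.shape != m.shape:
        raise ValueError(f"shape mismatch: image {img.shape} vs mask {m.shape}")
    out = img.copy()
    out[m] = 0
    return out


def estimate_background(
    image: np.ndarray, roi: Rect, foreground: np.ndarray | None = None
) -> float:
    """Mean intensity over an off-embryo ROI.

    If a foreground mask is supplied and the ROI overlaps it, a warning is
    emitted (the estimate is still returned).
    """
    if roi.w <= 0 or roi.h <= 0:
        raise ValueError("zero-area background ROI")
    roi.check_within(image.shape)
    if foreground is not None and foreground[roi.rows, roi.cols].any():
        warnings.warn("background ROI overlaps the embryo foreground")
    return float(image[roi.rows, roi.cols].mean())


def default_background_roi(image_shape: tuple[int, int], size: int = 30) -> Rect:
    """A ``size``-square ROI in the image corner (top-left)."""
    return Rect(x=0, y=0, w=size, h=size)


def foreground_mask(image: np.ndarray, smooth_sigma: float = 5.0) -> np.ndarray:
    """Otsu threshold on a smoothed image (or channel-summed image); keeps the
    largest connected component, holes filled.  Restricts percentile
    thresholding and box placement to in-embryo pixels."""
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:  # (channel, y, x)
        img = img.sum(axis=0)
    if np.ptp(img) == 0:
        return np.zeros_like(img, dtype=bool)
    smoothed = gaussian_filter(img, smooth_sigma)
    thr = filters.threshold_otsu(smoothed)
    mask = smoothed > thr
    labels = measure.label(mask)
    if labels.max() == 0:
        return np.zeros_like(img, dtype=bool)
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    from scipy.ndimage import binary_dilation, binary_fill_holes

    filled = binary_fill_holes(labels == largest)
    # compensate the edge erosion introduced by the pre-threshold smoothing
    return binary_dilation(filled, morphology.disk(int(round(smooth_sigma))))


def read_embryo_tiff(path, spec_yaml) -> EmbryoImage:
    """Load a simulator-written embryo TIFF plus its spec sidecar."""
    import tifffile
    import yaml

    data = np.asarray(tifffile.imread(path), dtype=float)
    with open(spec_yaml) as fh:
        meta = yaml.safe_load(fh)
    return EmbryoImage(
        data=data,
        channel_roles=meta["channel_roles"],
        pixel_size_um=meta["pixel_size_um"],
        z_step_um=meta["z_step_um"],
        orientation="canonical",
    )
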