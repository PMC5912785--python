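"""Quantification of Armadillo (beta-catenin) accumulation.

Three measurements on sum projections of the Arm channel:

* ``profile_across_segments`` — the graded cytoplasmic/nuclear Arm profile
  along the AP axis of a membrane-subtracted image, length-normalized and
  valley-zeroed;
* ``stripe_interstripe`` — background-subtracted mean Arm in boxes over Wg
  stripes versus interstripes, and their difference;
* ``pool_separation`` — exact decomposition of a region of interest into
  junctional (membrane) and cytoplasmic/nuclear pools using a membrane mask,
  tracking intensity and area of each pool separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .imgprep import MembraneMask
from .roi import Rect

__all__ = [
    "SegmentProfile",
    "StripeInterstripeResult",
    "PoolResult",
    "profile_across_segments",
    "place_stripe_boxes",
    "stripe_interstripe",
    "pool_separation",
]


@dataclass
class SegmentProfile:
    """Valley-zeroed, length-adjusted AP intensity profile over n segments."""

    position: np.ndarray  # normalized AP coordinate in [0, n_segments]
    intensity: np.ndarray
    roi: Rect
    n_segments_covered: int

    def n_peaks(self, min_prominence_frac: float = 0.2) -> int:
        """Count Arm stripes in the profile.

        The profile is smoothed over a tenth of a segment first so that the
        pixel-scale comb left by membrane-mask zeroing does not register as
        extra peaks.
        """
        from scipy.ndimage import gaussian_filter1d

        sigma = max(1.0, len(self.intensity) / (10.0 * self.n_segments_covered))
        y = gaussian_filter1d(self.intensity, sigma)
        prom = min_prominence_frac * (y.max() - y.min())
        if prom == 0:
            return 0
        # pad so peaks at the profile ends are counted
        padded = np.concatenate([[y.min()], y, [y.min()]])
        peaks, _ = find_peaks(padded, prominence=prom, distance=len(y) // (2 * self.n_segments_covered))
        return len(peaks)


@dataclass
class StripeInterstripeResult:
    stripe_mean: float
    interstripe_mean: float
    difference: float
    background: float
    stripe_boxes: list[Rect]
    interstripe_boxes: list[Rect]
    stripe_box_means: list[float] = field(default_factory=list)
    interstripe_box_means: list[float] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stripe_mean": self.stripe_mean,
                    "interstripe_mean": self.interstripe_mean,
                    "difference": self.difference,
                    "background": self.background,
                    "n_stripe_boxes": len(self.stripe_boxes),
                }
            ]
        )


@dataclass
class PoolResult:
    """Exact membrane/cytoplasmic decomposition of an ROI.

    ``membrane_intensity + cytoplasmic_intensity == total_intensity`` and
    ``membrane_area + cytoplasmic_area == roi_area`` hold exactly.
    """

    total_intensity: float
    membrane_intensity: float
    cytoplasmic_intensity: float
    roi_area: int
    membrane_area: int
    cytoplasmic_area: int

    @property
    def membrane_mean(self) -> float:
        return self.membrane_intensity / self.membrane_area if self.membrane_area else float("nan")

    @property
    def cytoplasmic_mean(self) -> float:
        return self.cytoplasmic_intensity / self.cytoplasmic_area

    @property
    def membrane_share(self) -> float:
        """Fraction of total ROI intensity assigned to the membrane pool."""
        return self.membrane_intensity / self.total_intensity

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "total_intensity": self.total_intensity,
                    "membrane_intensity": self.membrane_intensity,
                    "cytoplasmic_intensity": self.cytoplasmic_intensity,
                    "roi_area": self.roi_area,
                    "membrane_area": self.membrane_area,
                    "cytoplasmic_area": self.cytoplasmic_area,
                    "membrane_share": self.membrane_share,
                }
            ]
        )


def profile_across_segments(
    arm_masked: np.ndarray,
    roi: Rect,
    n_segments: int,
    points_per_segment: int = 100,
    mask: MembraneMask | np.ndarray | None = None,
) -> SegmentProfile:
    """Column-mean AP profile of a membrane-subtracted Arm projection.

    The raw per-column means are resampled to ``n_segments *
    points_per_segment`` points (the embryo-length adjustment; 300 points for
    the default three-segment ROI) and the global minimum is subtracted so
    valleys sit at zero.

    By default zeroed membrane pixels enter the column means (plot-profile
    semantics on the subtracted image).  Passing the membrane ``mask``
    averages only unmasked pixels instead, which removes the modulation that
    variable mask width would otherwise impose on the profile.
    """
    roi.check_within(arm_masked.shape)
    if n_segments < 1:
        raise ValueError("n_segments must be >= 1")
    sub = arm_masked[roi.rows, roi.cols]
    if mask is not None:
        m = mask.mask if isinstance(mask, MembraneMask) else np.asarray(mask, bool)
        keep = ~m[roi.rows, roi.cols]
        raw = (sub * keep).sum(axis=0) / np.maximum(keep.sum(axis=0), 1)
    else:
        raw = sub.mean(axis=0)
    n_out = n_segments * points_per_segment
    src = np.linspace(0.0, n_segments, num=raw.size)
    dst = np.linspace(0.0, n_segments, num=n_out)
    resampled = np.interp(dst, src, raw)
    resampled = resampled - resampled.min()
    return SegmentProfile(position=dst, intensity=resampled, roi=roi, n_segments_covered=n_segments)


def place_stripe_boxes(
    wg_projection: np.ndarray,
    box_shape: tuple[int, int] = (100, 30),
    n_stripes: int = 3,
    foreground: np.ndarray | None = None,
    skip_first: bool = True,
) -> tuple[list[Rect], list[Rect]]:
    """Center measurement boxes on detected Wg stripes.

    ``box_shape`` is (length along the stripe, width across it): the default
    100x30 box spans the Wg-expressing cell row and one neighbor on each
    side.  Stripes are found as peaks of the column-mean Wg profile; with
    ``skip_first`` the most anterior stripe is ignored so the boxes fall on
    the second through fourth stripes (the parasegment-2-to-4 analogs).
    Interstripe boxes sit midway between adjacent stripes.
    """
    wg = np.asarray(wg_projection, dtype=float)
    if foreground is not None:
        rows = np.flatnonzero(foreground.any(axis=1))
        cols_fg = np.flatnonzero(foreground.any(axis=0))
        profile = np.where(foreground, wg, 0.0).sum(axis=0)
        denom = np.clip(foreground.sum(axis=0), 1, None)
        profile = profile / denom
        y_center = (rows[0] + rows[-1]) / 2 if rows.size else wg.shape[0] / 2
    else:
        profile = wg.mean(axis=0)
        cols_fg = np.arange(wg.shape[1])
        y_center = wg.shape[0] / 2
    ptp = np.ptp(profile)
    if ptp == 0:
        raise ValueError("blank Wg channel: 0 stripes detected, need " f"{n_stripes}")
    from scipy.ndimage import gaussian_filter1d

    profile = gaussian_filter1d(profile, 3.0)  # suppress pixel noise on flat-topped stripes
    peaks, _ = find_peaks(profile, prominence=0.2 * np.ptp(profile), distance=10)
    need = n_stripes + (1 if skip_first else 0)
    if len(peaks) < need:
        raise ValueError(f"detected {len(peaks)} Wg stripes, need {need}")
    chosen = peaks[1 : 1 + n_stripes] if skip_first else peaks[:n_stripes]
    period = float(np.median(np.diff(peaks))) if len(peaks) > 1 else wg.shape[1] / 4
    length, width = box_shape
    stripe_boxes = [Rect.centered(cx, y_center, w=width, h=length) for cx in chosen]
    inter_boxes = []
    for i, cx in enumerate(chosen):
        nxt = peaks[np.searchsorted(peaks, cx) + 1] if np.searchsorted(peaks, cx) + 1 < len(peaks) else cx + period
        inter_boxes.append(Rect.centered((cx + nxt) / 2, y_center, w=width, h=length))
    return stripe_boxes, inter_boxes


def stripe_interstripe(
    arm_projection: np.ndarray,
    stripe_boxes: list[Rect],
    interstripe_boxes: list[Rect],
    background: float,
) -> StripeInterstripeResult:
    """Mean gray value per box; stripe and interstripe values are the box
    averages minus the off-embryo background, the difference their gap."""
    for b in stripe_boxes + interstripe_boxes:
        b.check_within(arm_projection.shape)
    s_means = [float(arm_projection[b.rows, b.cols].mean()) for b in stripe_boxes]
    i_means = [float(arm_projection[b.rows, b.cols].mean()) for b in interstripe_boxes]
    stripe_mean = float(np.mean(s_means)) - background
    inter_mean = float(np.mean(i_means)) - background
    return StripeInterstripeResult(
        stripe_mean=stripe_mean,
        interstripe_mean=inter_mean,
        difference=stripe_mean - inter_mean,
        background=background,
        stripe_boxes=list(stripe_boxes),
        interstripe_boxes=list(interstripe_boxes),
        stripe_box_means=s_means,
        interstripe_box_means=i_means,
    )


def pool_separation(
    arm_projection: np.ndarray,
    mask: MembraneMask | np.ndarray,
    roi: Rect = Rect(0, 0, 20, 160),
    background: float = 0.0,
) -> PoolResult:
    """Decompose ROI Arm intensity into membrane and cytoplasmic/nuclear
    pools using the membrane mask; areas are tracked per pool.

    The background (per-pixel, from an off-embryo region) is removed before
    the decomposition.  The caller is responsible for confining the ROI to
    one signaling regime (Wg-ON or Wg-OFF cells).
    """
    m = mask.mask if isinstance(mask, MembraneMask) else np.asarray(mask, dtype=bool)
    if m.shape != arm_projection.shape:
        raise ValueError("mask shape does not match projection")
    roi.check_within(arm_projection.shape)
    sub = arm_projection[roi.rows, roi.cols] - background
    msub = m[roi.rows, roi.cols]
    membrane_area = int(msub.sum())
    roi_area = roi.area
    if membrane_area == roi_area:
        raise ValueError("membrane mask covers the whole ROI; cytoplasmic pool undefined")
    total = float(sub.sum())
    membrane = float(sub[msub].sum())
    return PoolResult(
        total_intensity=total,
        membrane_intensity=membrane,
        cytoplasmic_intensity=total - membrane,
        roi_area=roi_area,
        membrane_area=membrane_area,
        cytoplasmic_area=roi_area - membrane_area,
    )
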