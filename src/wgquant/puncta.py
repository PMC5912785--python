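"""Punctum detection, intensity integration, and GFP molecule counting.

Destruction-complex puncta are detected as 3-D local maxima, integrated with
a nested-ROI background subtraction (15x15 px signal square inside a 21x21 px
square whose frame estimates the local background), and converted to GFP
molecule numbers by ratioing against fluorescence standards with known
molecules per structure (Ndc80-like ~306, Mif2-like ~58).  A count is
accepted only when the two standards agree to within ±15 molecules.
Saturated puncta (any inner-ROI pixel at the camera ceiling) are excluded,
mirroring the exclusion of structures outside the standards' linear range.

Percentile-threshold ranking reports, for a set of "brightest fraction"
cutoffs, how much of each ground-truth structure class exceeds each cutoff —
the brightest pixels concentrate in cytoplasmic Wg-OFF puncta, then
membrane-bound Wg-ON puncta, and only at permissive cutoffs the diffuse
Wg-ON cytoplasm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, distance_transform_edt
from skimage.feature import peak_local_max

from .imgprep import MembraneMask

__all__ = [
    "Punctum",
    "CalibrationStandard",
    "MoleculeCount",
    "DetectionParams",
    "detect_puncta",
    "integrated_intensity",
    "measure_standard",
    "count_molecules",
    "saturation_filter",
    "classify_punctum",
    "percentile_threshold_ranking",
    "puncta_to_table",
]

INNER_HALF = 7  # 15 x 15 px inner ROI
OUTER_HALF = 10  # 21 x 21 px outer ROI


@dataclass
class Punctum:
    """A detected spot with its nested integration ROIs."""

    centroid: tuple[int, int, int]  # (z, y, x)
    z_slices: tuple[int, ...] = ()
    peak_value: float = 0.0
    integrated_intensity: float = float("nan")
    max_inner_pixel: float = float("nan")
    distance_from_coverslip_um: float = float("nan")
    saturated: bool = False
    valid: bool = True  # False when the outer ROI is clipped by the image edge
    compartment: str = "unknown"  # "cytoplasmic" | "membrane" | "unknown"
    region: str = "unknown"  # "wg_on" | "wg_off" | "unknown"
    optics_id: str | None = None

    def __post_init__(self) -> None:
        if self.z_slices and list(self.z_slices) != list(
            range(self.z_slices[0], self.z_slices[-1] + 1)
        ):
            raise ValueError("z_slices must be contiguous")


@dataclass
class CalibrationStandard:
    """A measured fluorescence standard with known molecules per structure."""

    name: str
    molecules: float
    per_structure_intensity: float
    n_structures: int
    intensity_sd: float
    optics_id: str | None = None

    def __post_init__(self) -> None:
        if self.molecules <= 0:
            raise ValueError("molecules must be > 0")
        if self.per_structure_intensity <= 0:
            raise ValueError("per_structure_intensity must be > 0")

    @property
    def intensity_per_molecule(self) -> float:
        return self.per_structure_intensity / self.molecules


@dataclass
class MoleculeCount:
    punctum: Punctum
    count_by_standard: dict[str, float]
    accepted: bool
    accepted_count: float  # mean of the per-standard estimates when accepted
    tolerance: float


@dataclass(frozen=True)
class DetectionParams:
    """3-D local-maximum detection settings.

    Spots are found on a band-pass (difference-of-Gaussians) image; the
    threshold is ``k_sigma`` robust standard deviations of the band-pass
    response, which makes the prominence requirement insensitive to the
    diffuse cytoplasmic background.
    """

    smooth_sigma: float = 1.0
    background_sigma: float = 6.0
    k_sigma: float = 5.0
    min_separation_px: int = 4
    half_peak_fraction: float = 0.5
    z_border: int = 2  # spots this close to the stack faces cannot be depth-integrated


def detect_puncta(gfp_stack: np.ndarray, params: DetectionParams | None = None) -> list[Punctum]:
    """Detect puncta as 3-D local maxima; deterministic, sorted by
    descending band-pass peak value.

    Each punctum's ``z_slices`` are the contiguous slices whose inner-ROI
    integrated signal exceeds half the peak slice's value.
    """
    params = params or DetectionParams()
    stack = np.asarray(gfp_stack, dtype=float)
    if stack.size == 0:
        raise ValueError("empty stack")
    fine = gaussian_filter(stack, params.smooth_sigma)
    coarse = gaussian_filter(stack, params.background_sigma)
    dog = fine - coarse
    mad = np.median(np.abs(dog - np.median(dog)))
    sigma = 1.4826 * mad
    if sigma > 0:
        thr = params.k_sigma * sigma
    elif dog.max() > 0:
        thr = 0.1 * dog.max()  # noise-free image: any substantial peak counts
    else:
        return []
    coords = peak_local_max(
        dog,
        min_distance=params.min_separation_px,
        threshold_abs=thr,
        exclude_border=(params.z_border, 0, 0),
    )
    puncta = []
    for z, y, x in coords:
        p = Punctum(centroid=(int(z), int(y), int(x)), peak_value=float(dog[z, y, x]))
        p.z_slices = _half_peak_slices(dog, p.centroid, params.half_peak_fraction)
        puncta.append(p)
    puncta.sort(key=lambda p: -p.peak_value)
    return puncta


def _frame_background(
    outer: np.ndarray,
    inner_shape: tuple[int, int],
    method: str,
    occupied: np.ndarray | None = None,
) -> float:
    """Per-pixel background level from the outer-frame pixels.

    ``occupied`` marks pixels lying on *other* detected structures; those
    are excluded from the frame (a value-blind, hence unbiased, guard
    against a neighboring punctum inflating the background estimate).  The
    mean is the default; median and symmetric trimmed mean are offered for
    robustness at the price of a small shot-noise-skew bias.
    """
    mask = np.ones(outer.shape, dtype=bool)
    dy = (outer.shape[0] - inner_shape[0]) // 2
    dx = (outer.shape[1] - inner_shape[1]) // 2
    mask[dy : dy + inner_shape[0], dx : dx + inner_shape[1]] = False
    if occupied is not None:
        cleaned = mask & ~occupied
        if cleaned.sum() >= 20:  # keep a usable sample size
            mask = cleaned
    frame = outer[mask]
    if method == "mean":
        return float(frame.mean())
    if method == "median":
        return float(np.median(frame))
    if method == "trimmed_mean":
        from scipy.stats import trim_mean

        return float(trim_mean(frame, 0.25))
    raise ValueError(f"unknown background method '{method}'")


def _inner_slice_signal(
    stack: np.ndarray,
    z: int,
    y: int,
    x: int,
    bg_method: str = "mean",
    occupied_map: np.ndarray | None = None,
) -> float:
    """Background-subtracted inner-ROI signal of one slice (nested ROI)."""
    inner = stack[z, y - INNER_HALF : y + INNER_HALF + 1, x - INNER_HALF : x + INNER_HALF + 1]
    outer = stack[z, y - OUTER_HALF : y + OUTER_HALF + 1, x - OUTER_HALF : x + OUTER_HALF + 1]
    occ = None
    if occupied_map is not None:
        occ = occupied_map[y - OUTER_HALF : y + OUTER_HALF + 1, x - OUTER_HALF : x + OUTER_HALF + 1]
    return float(inner.sum() - inner.size * _frame_background(outer, inner.shape, bg_method, occ))


def occupied_pixel_map(
    shape: tuple[int, int], puncta: "list[Punctum]", radius: int = 4
) -> np.ndarray:
    """2-D map of pixels within ``radius`` of any detected punctum centroid
    (used to keep neighboring spots out of background frames)."""
    occ = np.zeros(shape, dtype=bool)
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    disk = yy**2 + xx**2 <= radius**2
    ny, nx = shape
    for p in puncta:
        _, y, x = p.centroid
        y0, y1 = max(y - radius, 0), min(y + radius + 1, ny)
        x0, x1 = max(x - radius, 0), min(x + radius + 1, nx)
        occ[y0:y1, x0:x1] |= disk[
            y0 - (y - radius) : y1 - (y - radius), x0 - (x - radius) : x1 - (x - radius)
        ]
    return occ


def _half_peak_slices(
    dog: np.ndarray, centroid: tuple[int, int, int], fraction: float
) -> tuple[int, ...]:
    """Contiguous slices whose in-slice spot signal exceeds ``fraction`` of
    the peak slice's (the spot's depth of field).

    The per-slice signal is the band-pass amplitude at the centroid, a
    low-noise proxy for the in-slice integrated intensity of a diffraction-
    limited spot; using the same rule for samples and standards makes the
    finite-depth capture fraction cancel in the calibration ratio.
    """
    z0, y, x = centroid
    nz = dog.shape[0]
    signals = dog[:, y, x]
    peak = signals[z0]
    if peak <= 0:
        return (z0,)
    # grow symmetric +/-k shells while their mean signal stays above the
    # half-peak cutoff; averaging the two shell slices halves the noise on
    # the inclusion decision for an axially symmetric PSF
    k = 0
    while True:
        lo, hi = z0 - (k + 1), z0 + (k + 1)
        shell = [signals[z] for z in (lo, hi) if 0 <= z < nz]
        if not shell or np.mean(shell) <= fraction * peak:
            break
        k += 1
    lo = max(z0 - k, 0)
    hi = min(z0 + k, nz - 1)
    return tuple(range(lo, hi + 1))


def integrated_intensity(
    punctum: Punctum,
    stack: np.ndarray,
    bg_method: str = "mean",
    occupied_map: np.ndarray | None = None,
) -> float:
    """Nested-ROI integrated intensity over the punctum's z slices.

    Per slice: (sum over the 15x15 inner ROI) minus (inner area x mean of
    the 21x21 outer frame), summed over ``z_slices``; negative totals are
    clipped to zero with a warning.  Raises if the outer ROI is clipped by
    the image edge (callers flag and exclude such puncta).
    """
    z0, y, x = punctum.centroid
    nz, ny, nx = stack.shape
    if not (OUTER_HALF <= y < ny - OUTER_HALF and OUTER_HALF <= x < nx - OUTER_HALF):
        raise ValueError("outer ROI clipped by the image edge")
    slices = punctum.z_slices or (z0,)
    total = sum(_inner_slice_signal(stack, z, y, x, bg_method, occupied_map) for z in slices)
    if total < 0:
        warnings.warn("negative integrated intensity clipped to 0")
        total = 0.0
    return float(total)


def measure_puncta(
    stack: np.ndarray,
    puncta: list[Punctum],
    z_step_um: float = 1.0,
    optics_id: str | None = None,
) -> list[Punctum]:
    """Fill integrated intensity, inner-ROI maximum, and coverslip distance
    for each punctum; puncta whose ROIs hit the image edge are marked
    invalid and skipped."""
    occupied = occupied_pixel_map(stack.shape[1:], puncta)
    out = []
    for p in puncta:
        z, y, x = p.centroid
        try:
            p.integrated_intensity = integrated_intensity(p, stack, occupied_map=occupied)
        except ValueError:
            p.valid = False
            out.append(p)
            continue
        inner = stack[
            min(p.z_slices) : max(p.z_slices) + 1,
            y - INNER_HALF : y + INNER_HALF + 1,
            x - INNER_HALF : x + INNER_HALF + 1,
        ]
        p.max_inner_pixel = float(inner.max())
        p.distance_from_coverslip_um = z * z_step_um
        p.optics_id = optics_id
        out.append(p)
    return out


def measure_standard(
    stacks: list[np.ndarray],
    known_molecules: float,
    name: str = "standard",
    params: DetectionParams | None = None,
    saturation_level: float = float("inf"),
    optics_id: str | None = None,
    min_structures: int = 10,
    min_intensity_frac: float = 0.25,
) -> CalibrationStandard:
    """Detect and integrate standard structures; the per-structure intensity
    is the mean nested-ROI integrated intensity over all usable structures.

    Standard structures all carry the same number of molecules, so
    detections dimmer than ``min_intensity_frac`` of the median structure
    intensity are spurious (noise maxima) and are dropped.  Fewer than
    ``min_structures`` usable structures is an error.
    """
    intensities: list[float] = []
    for stack in stacks:
        puncta = detect_puncta(stack, params)
        puncta = measure_puncta(stack, puncta, optics_id=optics_id)
        kept, _ = saturation_filter([p for p in puncta if p.valid], saturation_level)
        intensities.extend(p.integrated_intensity for p in kept)
    if intensities:
        med = float(np.median(intensities))
        intensities = [v for v in intensities if v >= min_intensity_frac * med]
    if len(intensities) < min_structures:
        raise ValueError(
            f"only {len(intensities)} structures measured; need >= {min_structures}"
        )
    arr = np.asarray(intensities)
    return CalibrationStandard(
        name=name,
        molecules=known_molecules,
        per_structure_intensity=float(arr.mean()),
        n_structures=len(arr),
        intensity_sd=float(arr.std(ddof=1)),
        optics_id=optics_id,
    )


def count_molecules(
    punctum: Punctum,
    standard_a: CalibrationStandard,
    standard_b: CalibrationStandard,
    tolerance: float = 15.0,
    attenuation_per_um: float = 0.0,
) -> MoleculeCount:
    """Dual-standard molecule count with the ±``tolerance``-molecule
    consistency rule.

    Per standard: ``count = I x depth_factor / (per-structure intensity /
    molecules)``.  The optional depth correction is ``exp(attenuation_per_um
    x distance_from_coverslip_um)`` (default: no correction).  The accepted
    count is the mean of the two estimates.
    """
    if punctum.saturated:
        raise ValueError("saturated punctum cannot be counted")
    if standard_a.optics_id != standard_b.optics_id or (
        punctum.optics_id is not None
        and standard_a.optics_id is not None
        and punctum.optics_id != standard_a.optics_id
    ):
        raise ValueError(
            "optics settings mismatch between punctum and standards; "
            "standards and samples must be imaged in the same session"
        )
    depth = punctum.distance_from_coverslip_um
    factor = 1.0
    if attenuation_per_um and np.isfinite(depth):
        factor = float(np.exp(attenuation_per_um * depth))
    counts = {
        s.name: punctum.integrated_intensity * factor / s.intensity_per_molecule
        for s in (standard_a, standard_b)
    }
    vals = list(counts.values())
    accepted = abs(vals[0] - vals[1]) <= tolerance
    return MoleculeCount(
        punctum=punctum,
        count_by_standard=counts,
        accepted=accepted,
        accepted_count=float(np.mean(vals)) if accepted else float("nan"),
        tolerance=tolerance,
    )


def saturation_filter(
    puncta: list[Punctum], saturation_level: float
) -> tuple[list[Punctum], list[Punctum]]:
    """Split puncta into (kept, excluded): excluded if any inner-ROI pixel
    reaches the camera ceiling (the brightest structures are outside the
    standards' linear range)."""
    kept, excluded = [], []
    for p in puncta:
        if np.isfinite(saturation_level) and p.max_inner_pixel >= saturation_level:
            p.saturated = True
            excluded.append(p)
        else:
            kept.append(p)
    return kept, excluded


def classify_punctum(
    punctum: Punctum,
    membrane_mask: MembraneMask | np.ndarray,
    wg_region_map: np.ndarray,
    d_mem: float = 2.0,
) -> Punctum:
    """Assign compartment (membrane if the centroid lies within ``d_mem`` px
    of the membrane mask, else cytoplasmic) and Wg region."""
    m = membrane_mask.mask if isinstance(membrane_mask, MembraneMask) else np.asarray(membrane_mask, bool)
    _, y, x = punctum.centroid
    if not m.any():
        punctum.compartment = "cytoplasmic"
    else:
        dist = distance_transform_edt(~m)
        punctum.compartment = "membrane" if dist[y, x] <= d_mem else "cytoplasmic"
    punctum.region = "wg_on" if wg_region_map[y, x] else "wg_off"
    return punctum


def classify_puncta(
    puncta: list[Punctum],
    membrane_mask: MembraneMask | np.ndarray,
    wg_region_map: np.ndarray,
    d_mem: float = 2.0,
) -> list[Punctum]:
    """Vectorized variant of :func:`classify_punctum` (one distance map)."""
    m = membrane_mask.mask if isinstance(membrane_mask, MembraneMask) else np.asarray(membrane_mask, bool)
    dist = distance_transform_edt(~m) if m.any() else None
    for p in puncta:
        _, y, x = p.centroid
        p.compartment = (
            "membrane" if dist is not None and dist[y, x] <= d_mem else "cytoplasmic"
        )
        p.region = "wg_on" if wg_region_map[y, x] else "wg_off"
    return puncta


def percentile_threshold_ranking(
    image: np.ndarray,
    foreground: np.ndarray,
    fractions: tuple[float, ...] = (0.001, 0.003, 0.01, 0.15),
    class_map: np.ndarray | None = None,
    class_names: dict[int, str] | None = None,
) -> tuple[pd.DataFrame, dict[float, np.ndarray]]:
    """Brightest-fraction thresholding restricted to in-embryo pixels.

    For each fraction f, the threshold is the (1-f) intensity quantile over
    foreground pixels; masks are nested (a larger fraction contains every
    smaller one).  When a ground-truth ``class_map`` is given, the table
    reports per-class pixel coverage at each fraction.
    """
    fr = list(fractions)
    if any(not 0 < f <= 1 for f in fr) or any(b <= a for a, b in zip(fr, fr[1:])):
        raise ValueError("fractions must be strictly increasing within (0, 1]")
    img = np.asarray(image, dtype=float)
    fg = np.asarray(foreground, dtype=bool)
    vals = img[fg]
    if vals.size == 0:
        raise ValueError("empty foreground")
    rows = []
    masks: dict[float, np.ndarray] = {}
    for f in fr:
        thr = -np.inf if f >= 1.0 else float(np.quantile(vals, 1.0 - f))
        mask = fg & (img >= thr)
        masks[f] = mask
        if class_map is None:
            rows.append({"fraction": f, "threshold": thr, "class": "all",
                         "n_class_pixels": int(fg.sum()), "n_covered": int(mask.sum()),
                         "coverage": float(mask.sum() / fg.sum())})
            continue
        for code in np.unique(class_map[fg]):
            cls_px = fg & (class_map == code)
            n_cls = int(cls_px.sum())
            n_cov = int((mask & cls_px).sum())
            label = (class_names or {}).get(int(code), str(int(code)))
            rows.append(
                {
                    "fraction": f,
                    "threshold": thr,
                    "class": label,
                    "n_class_pixels": n_cls,
                    "n_covered": n_cov,
                    "coverage": n_cov / n_cls if n_cls else float("nan"),
                }
            )
    return pd.DataFrame(rows), masks


def puncta_to_table(counts: list[MoleculeCount]) -> pd.DataFrame:
    """Tabulate dual-standard counting results, one row per punctum."""
    rows = []
    for i, c in enumerate(counts):
        p = c.punctum
        z, y, x = p.centroid
        row = {
            "id": i,
            "z": z,
            "y": y,
            "x": x,
            "n_slices": len(p.z_slices),
            "integrated_intensity": p.integrated_intensity,
            "accepted": c.accepted,
            "accepted_count": c.accepted_count,
            "compartment": p.compartment,
            "region": p.region,
        }
        for name, v in c.count_by_standard.items():
            row[f"count_{name}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
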