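"""Synthetic microscopy simulator for a segmented embryonic epidermis.

Renders multi-channel confocal-like Z-stacks of a ventral epidermis patch in
which stripes of Wingless (Wg)-expressing cells pattern each body segment:

* a junction channel (pTyr-like) marking the cell-cell membrane lattice,
* an Armadillo (Arm, fly beta-catenin) channel whose total intensity is split
  between a junctional pool (default 70% of the total) and a graded
  cytoplasmic/nuclear pool peaking at the Wg stripes,
* a Wg channel with single-cell-row expression stripes,
* a GFP channel carrying destruction-complex puncta: bright cytoplasmic
  puncta in Wg-OFF cells (mean ~260 molecules) and dimmer membrane-proximal
  puncta in Wg-ON cells (mean ~130 molecules), counts drawn log-normal and
  clipped to 46-931 molecules, over a diffuse cytoplasmic term that is
  elevated in Wg-ON cells.

It also renders yeast-style calibration standards (diffraction-limited spots
with a fixed number of GFP molecules per structure, Ndc80-like 306 or
Mif2-like 58) and an Engrailed (En) channel of countable cell blobs.

Every render returns full ground truth so downstream quantification can be
validated by parameter recovery.  Cells live on a rectangular lattice with
1-px membrane lines; images use 0-based (z, y, x) pixel coordinates with the
anterior-posterior (AP) axis along x, anterior at low x.

The camera model is Poisson shot noise on the optical signal (including the
background offset), additive Gaussian read noise, and a hard saturation
ceiling.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter

__all__ = [
    "EmbryoSpec",
    "StandardSpec",
    "TruePunctum",
    "GroundTruth",
    "render_embryo",
    "render_standard",
    "render_en_channel",
    "write_embryo_simulation",
    "write_standard_simulation",
    "CHANNEL_ROLES",
]

#: channel order of the stacks produced by :func:`render_embryo`
CHANNEL_ROLES = {"junction": 0, "arm": 1, "wg": 2, "gfp": 3}

# structure-class codes used by GroundTruth.structure_class_map
CLASS_BACKGROUND = 0
CLASS_OFF_CYTOPLASM = 1
CLASS_ON_CYTOPLASM = 2
CLASS_MEMBRANE = 3
CLASS_OFF_PUNCTUM = 4
CLASS_ON_PUNCTUM = 5

CLASS_NAMES = {
    CLASS_BACKGROUND: "background",
    CLASS_OFF_CYTOPLASM: "wg_off_cytoplasm",
    CLASS_ON_CYTOPLASM: "wg_on_cytoplasm",
    CLASS_MEMBRANE: "membrane",
    CLASS_OFF_PUNCTUM: "wg_off_punctum",
    CLASS_ON_PUNCTUM: "wg_on_punctum",
}


@dataclass(frozen=True)
class EmbryoSpec:
    """Generator parameters for one synthetic embryo field.

    Intensity units are camera counts; lengths are pixels unless suffixed
    ``_um``.  ``junctional_fraction`` is the fraction of total Arm placed on
    the membrane lattice (0.70 by default).  Per-punctum molecule counts are
    drawn log-normal with the configured regional mean and log-space
    dispersion, then clipped to ``puncta_count_range``.
    """

    n_segments: int = 5
    segment_period_px: int = 120
    cell_diameter_px: int = 20
    image_shape: tuple[int, int, int] = (10, 280, 680)
    pixel_size_um: float = 0.25
    z_step_um: float = 1.0
    junctional_fraction: float = 0.70
    arm_base_level: float = 60.0
    arm_stripe_amplitude: float = 40.0
    wg_stripe_width_cells: int = 1
    puncta_wgoff_count_mean: float = 260.0
    puncta_wgon_count_mean: float = 130.0
    puncta_count_range: tuple[float, float] = (46.0, 931.0)
    puncta_count_dispersion: float = 0.45
    brightness_per_molecule: float = 40.0
    psf_sigma_px: float = 1.0
    psf_sigma_z_px: float = 1.0
    read_noise_sd: float = 3.0
    background_offset: float = 100.0
    saturation_level: float = 4095.0
    attenuation_per_um: float = 0.0
    en_rows_per_segment: int = 2
    seed: int = 0
    noise: bool = True
    # secondary rendering knobs (not part of the study conditions)
    margin_px: int = 40
    junction_level: float = 400.0
    wg_level: float = 150.0
    en_level: float = 200.0
    diffuse_gfp_on: float = 12.0
    diffuse_gfp_off: float = 4.0
    puncta_per_cell: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.junctional_fraction <= 1.0:
            raise ValueError("junctional_fraction must lie in [0, 1]")
        for name in (
            "segment_period_px",
            "cell_diameter_px",
            "pixel_size_um",
            "z_step_um",
            "brightness_per_molecule",
            "saturation_level",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.arm_base_level < 0 or self.arm_stripe_amplitude < 0:
            raise ValueError("Arm levels must be >= 0")
        if self.puncta_count_range[0] < 1:
            raise ValueError("puncta_count_range minimum must be >= 1")
        if self.puncta_count_range[0] > self.puncta_count_range[1]:
            raise ValueError("puncta_count_range must be (min, max)")
        if self.segment_period_px % self.cell_diameter_px != 0:
            raise ValueError("segment_period_px must be a multiple of cell_diameter_px")
        if self.en_rows_per_segment > self.cells_per_segment:
            raise ValueError("en_rows_per_segment exceeds cells per segment")
        if self.wg_stripe_width_cells < 1:
            raise ValueError("wg_stripe_width_cells must be >= 1")
        nz, ny, nx = self.image_shape
        if nx < self.n_segments * self.segment_period_px + 2 * self.margin_px:
            raise ValueError(
                "image_shape x extent too small for "
                f"{self.n_segments} segments of {self.segment_period_px} px "
                f"plus margins of {self.margin_px} px"
            )
        if ny < self.cell_diameter_px + 2 * self.margin_px or nz < 3:
            raise ValueError("image_shape too small")

    # ---- derived geometry -------------------------------------------------
    @property
    def cells_per_segment(self) -> int:
        return self.segment_period_px // self.cell_diameter_px

    @property
    def x0(self) -> int:
        """Anterior edge of the embryo foreground."""
        return self.margin_px

    @property
    def x1(self) -> int:
        return self.x0 + self.n_segments * self.segment_period_px

    @property
    def n_cell_rows(self) -> int:
        ny = self.image_shape[1]
        return (ny - 2 * self.margin_px) // self.cell_diameter_px

    @property
    def y0(self) -> int:
        ny = self.image_shape[1]
        return (ny - self.n_cell_rows * self.cell_diameter_px) // 2

    @property
    def y1(self) -> int:
        return self.y0 + self.n_cell_rows * self.cell_diameter_px

    @property
    def n_cell_cols(self) -> int:
        return self.n_segments * self.cells_per_segment

    def stripe_centers_x(self) -> np.ndarray:
        """AP pixel coordinates of the Wg-stripe centers, one per segment."""
        half = self.wg_stripe_width_cells * self.cell_diameter_px / 2.0
        return self.x0 + np.arange(self.n_segments) * self.segment_period_px + half

    def interstripe_centers_x(self) -> np.ndarray:
        """Midpoints between consecutive Wg stripes (one per segment pair)."""
        c = self.stripe_centers_x()
        return (c[:-1] + c[1:]) / 2.0

    def replace(self, **kw) -> "EmbryoSpec":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class StandardSpec:
    """A fluorescence calibration standard: n diffraction-limited structures,
    each carrying a known number of GFP molecules (Ndc80-like default 306;
    use ``molecules_per_structure=58`` for a Mif2-like standard)."""

    name: str = "ndc80"
    molecules_per_structure: float = 306.0
    n_structures: int = 60
    brightness_per_molecule: float = 40.0
    psf_sigma_px: float = 1.0
    psf_sigma_z_px: float = 1.0
    read_noise_sd: float = 3.0
    background_offset: float = 100.0
    saturation_level: float = 4095.0
    image_shape: tuple[int, int, int] = (12, 384, 384)
    min_separation_px: int = 30
    margin_px: int = 16
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.molecules_per_structure < 1:
            raise ValueError("molecules_per_structure must be >= 1")
        if self.n_structures < 1:
            raise ValueError("n_structures must be >= 1")
        if self.brightness_per_molecule <= 0 or self.saturation_level <= 0:
            raise ValueError("intensities must be > 0")

    def replace(self, **kw) -> "StandardSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class TruePunctum:
    """Ground-truth record for one rendered punctum."""

    z: int
    y: int
    x: int
    compartment: str  # "cytoplasmic" | "membrane"
    region: str  # "wg_on" | "wg_off"
    molecules: float


@dataclass
class GroundTruth:
    """Everything the simulator knows about one rendered embryo field."""

    cell_map: np.ndarray  # (y, x) int cell id, 0 outside the embryo
    wg_expressing: np.ndarray  # (rows, cols) bool, True for Wg-producing cells
    wg_on: np.ndarray  # (rows, cols) bool, True for Wg-receiving (ON) cells
    membrane_truth: np.ndarray  # (y, x) bool membrane lattice
    arm_truth_junctional: np.ndarray  # (y, x) noiseless pre-PSF intensity
    arm_truth_cytoplasmic: np.ndarray  # (y, x) noiseless pre-PSF intensity
    puncta: list[TruePunctum]
    en_truth_rows: int
    spec: EmbryoSpec

    def foreground(self) -> np.ndarray:
        return self.cell_map > 0

    def wg_region_map(self) -> np.ndarray:
        """Per-pixel Wg-ON map (True inside ON cells, membrane included)."""
        s = self.spec
        on = np.zeros(s.image_shape[1:], dtype=bool)
        col_on = self.wg_on[0]  # identical across rows
        for col in np.flatnonzero(col_on):
            x_lo = s.x0 + col * s.cell_diameter_px
            on[s.y0 : s.y1 + 1, x_lo : x_lo + s.cell_diameter_px + 1] = True
        return on

    def structure_class_map(self, punctum_radius: int = 2) -> np.ndarray:
        """Per-pixel structure labels used by percentile-threshold ranking."""
        s = self.spec
        cls = np.full(s.image_shape[1:], CLASS_BACKGROUND, dtype=np.int8)
        fg = self.foreground()
        on = self.wg_region_map()
        cls[fg & on] = CLASS_ON_CYTOPLASM
        cls[fg & ~on] = CLASS_OFF_CYTOPLASM
        cls[self.membrane_truth] = CLASS_MEMBRANE
        yy, xx = np.mgrid[-punctum_radius : punctum_radius + 1, -punctum_radius : punctum_radius + 1]
        disk = yy**2 + xx**2 <= punctum_radius**2
        ny, nx = cls.shape
        for p in self.puncta:
            code = CLASS_ON_PUNCTUM if p.region == "wg_on" else CLASS_OFF_PUNCTUM
            y_sl = slice(max(p.y - punctum_radius, 0), min(p.y + punctum_radius + 1, ny))
            x_sl = slice(max(p.x - punctum_radius, 0), min(p.x + punctum_radius + 1, nx))
            d = disk[
                y_sl.start - (p.y - punctum_radius) : y_sl.stop - (p.y - punctum_radius),
                x_sl.start - (p.x - punctum_radius) : x_sl.stop - (p.x - punctum_radius),
            ]
            region = cls[y_sl, x_sl]
            region[d] = code
        return cls

    def puncta_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": np.arange(len(self.puncta)),
                "z": [p.z for p in self.puncta],
                "y": [p.y for p in self.puncta],
                "x": [p.x for p in self.puncta],
                "compartment": [p.compartment for p in self.puncta],
                "region": [p.region for p in self.puncta],
                "molecules": [p.molecules for p in self.puncta],
            }
        )


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------


def _lattice(spec: EmbryoSpec) -> tuple[np.ndarray, np.ndarray]:
    """Return (cell_map, membrane_truth) for the embryo rectangle.

    Membrane lines are 1 px wide and sit on the lattice coordinates that are
    multiples of the cell diameter (plus the far embryo edges).
    """
    nz, ny, nx = spec.image_shape
    cell_map = np.zeros((ny, nx), dtype=np.int32)
    membrane = np.zeros((ny, nx), dtype=bool)
    yy, xx = np.mgrid[0:ny, 0:nx]
    # every cell owns an identical 20x20-style block (its top/left membrane
    # lines included); the far-edge border lines are membrane without an
    # owning cell, keeping per-cell pixel counts uniform
    owned = (yy >= spec.y0) & (yy < spec.y1) & (xx >= spec.x0) & (xx < spec.x1)
    inside = (yy >= spec.y0) & (yy <= spec.y1) & (xx >= spec.x0) & (xx <= spec.x1)
    rel_y = yy - spec.y0
    rel_x = xx - spec.x0
    row = rel_y // spec.cell_diameter_px
    col = rel_x // spec.cell_diameter_px
    cell_map[owned] = (row * spec.n_cell_cols + col + 1)[owned]
    on_line = (rel_y % spec.cell_diameter_px == 0) | (rel_x % spec.cell_diameter_px == 0)
    on_line |= (yy == spec.y1) | (xx == spec.x1)
    membrane[inside & on_line] = True
    return cell_map, membrane


def _wg_state(spec: EmbryoSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell Wg expression and Wg-ON state, shape (rows, cols).

    The Wg-expressing column(s) sit at the start of each segment; ON cells
    are the expressing cells plus one neighboring column on each side
    (the cells contacted by secreted Wg), all other cells are OFF.
    """
    cps = spec.cells_per_segment
    col_in_seg = np.arange(spec.n_cell_cols) % cps
    expressing = col_in_seg < spec.wg_stripe_width_cells
    on = expressing.copy()
    on |= np.roll(expressing, 1)
    on |= np.roll(expressing, -1)
    wg_expressing = np.tile(expressing, (spec.n_cell_rows, 1))
    wg_on = np.tile(on, (spec.n_cell_rows, 1))
    return wg_expressing, wg_on


def _stripe_profile(spec: EmbryoSpec, x: np.ndarray) -> np.ndarray:
    """Smooth periodic AP modulation in [0, 1], peaking at Wg-stripe centers.

    A trapezoid with cosine shoulders: 1 within 1/8 period of a stripe
    center, 0 beyond 3/8 period, smooth in between.  The flat top and flat
    valley make the box-averaged stripe/interstripe difference recover the
    configured amplitude.
    """
    period = float(spec.segment_period_px)
    centers = spec.stripe_centers_x()
    d = np.min(np.abs(x[:, None] - centers[None, :]), axis=1)
    p1, p2 = period / 8.0, 3.0 * period / 8.0
    out = np.zeros_like(d, dtype=float)
    out[d <= p1] = 1.0
    ramp = (d > p1) & (d < p2)
    out[ramp] = 0.5 * (1.0 + np.cos(np.pi * (d[ramp] - p1) / (p2 - p1)))
    return out


def _arm_truth(
    spec: EmbryoSpec, cell_map: np.ndarray, membrane: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless pre-PSF junctional and cytoplasmic Arm images.

    Each cell's total Arm budget is the AP profile ``T(x)`` summed over all
    of its pixels; a ``junctional_fraction`` share is spread uniformly over
    the cell's membrane pixels and the remainder over its interior, so the
    membrane share of total Arm equals the configured fraction exactly, per
    cell and globally, and the mean intensity over a whole cell equals the
    local profile value.
    """
    ny, nx = cell_map.shape
    f = spec.junctional_fraction
    x = np.arange(nx, dtype=float)
    profile = spec.arm_base_level + spec.arm_stripe_amplitude * _stripe_profile(spec, x)
    total_field = np.where(cell_map > 0, np.broadcast_to(profile, (ny, nx)), 0.0)

    junc = np.zeros(ny * nx)
    cyto = np.zeros(ny * nx)
    order = np.argsort(cell_map, axis=None, kind="stable")
    flat_ids = cell_map.ravel()[order]
    starts = np.searchsorted(flat_ids, np.arange(1, cell_map.max() + 1))
    ends = np.searchsorted(flat_ids, np.arange(1, cell_map.max() + 1), side="right")
    mem_flat = membrane.ravel()
    tot_flat = total_field.ravel()
    for s0, s1 in zip(starts, ends):
        idx = order[s0:s1]
        mem_idx = idx[mem_flat[idx]]
        int_idx = idx[~mem_flat[idx]]
        budget = tot_flat[idx].sum()
        if mem_idx.size:
            junc[mem_idx] += f * budget / mem_idx.size
        if int_idx.size:
            cyto[int_idx] = (1.0 - f) * budget / int_idx.size
    return junc.reshape(ny, nx), cyto.reshape(ny, nx)


# ---------------------------------------------------------------------------
# optics + camera
# ---------------------------------------------------------------------------


def _apply_optics_2d(plane: np.ndarray, spec) -> np.ndarray:
    return gaussian_filter(plane, sigma=spec.psf_sigma_px, mode="nearest")


def _replicate_z(plane: np.ndarray, spec: EmbryoSpec) -> np.ndarray:
    nz = spec.image_shape[0]
    stack = np.repeat(plane[None], nz, axis=0)
    if spec.attenuation_per_um > 0:
        depth = np.arange(nz) * spec.z_step_um
        stack *= np.exp(-spec.attenuation_per_um * depth)[:, None, None]
    return stack


def _camera(stack: np.ndarray, spec, rng: np.random.Generator) -> np.ndarray:
    """Poisson shot noise on signal + offset, Gaussian read noise, hard clip."""
    signal = stack + spec.background_offset
    if spec.noise:
        noisy = rng.poisson(np.clip(signal, 0, None)).astype(float)
        noisy += rng.normal(0.0, spec.read_noise_sd, size=noisy.shape)
    else:
        noisy = signal
    return np.clip(noisy, 0.0, spec.saturation_level)


def _add_spot(
    stack: np.ndarray, z: int, y: int, x: int, photons: float
) -> None:
    """Deposit a point emitter (pre-PSF) at an integer voxel."""
    stack[z, y, x] += photons


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def render_embryo(spec: EmbryoSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render the 4-channel (junction, arm, wg, gfp) Z-stack plus ground truth.

    Identical ``spec`` (including ``seed``) gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.image_shape
    cell_map, membrane = _lattice(spec)
    wg_expressing, wg_on = _wg_state(spec)
    junc, cyto = _arm_truth(spec, cell_map, membrane)

    interior = (cell_map > 0) & ~membrane

    # junction channel: membrane lattice only
    junction_plane = np.where(membrane, spec.junction_level, 0.0)

    # Wg channel: cytoplasm of Wg-expressing cells
    row_col = _cell_row_col(spec, cell_map)
    expressing_px = np.zeros((ny, nx), dtype=bool)
    expressing_px[interior] = wg_expressing[row_col[0][interior], row_col[1][interior]]
    wg_plane = np.where(expressing_px, spec.wg_level, 0.0)

    # GFP channel: diffuse cytoplasmic term, elevated in Wg-ON cells
    on_px = np.zeros((ny, nx), dtype=bool)
    on_px[interior] = wg_on[row_col[0][interior], row_col[1][interior]]
    gfp_plane = np.zeros((ny, nx))
    gfp_plane[interior & on_px] = spec.diffuse_gfp_on
    gfp_plane[interior & ~on_px] = spec.diffuse_gfp_off

    gfp_stack = _replicate_z(gfp_plane, spec)
    puncta = _place_puncta(spec, cell_map, membrane, on_px, rng, gfp_stack)

    channels = np.empty((4, nz, ny, nx))
    for role, plane in (
        ("junction", junction_plane),
        ("arm", junc + cyto),
        ("wg", wg_plane),
    ):
        stack = _replicate_z(plane, spec)
        stack = gaussian_filter(
            stack, sigma=(spec.psf_sigma_z_px, spec.psf_sigma_px, spec.psf_sigma_px), mode="nearest"
        )
        channels[CHANNEL_ROLES[role]] = stack
    gfp_stack = gaussian_filter(
        gfp_stack, sigma=(spec.psf_sigma_z_px, spec.psf_sigma_px, spec.psf_sigma_px), mode="nearest"
    )
    channels[CHANNEL_ROLES["gfp"]] = gfp_stack

    image = np.empty_like(channels)
    for c in range(4):
        image[c] = _camera(channels[c], spec, rng)

    truth = GroundTruth(
        cell_map=cell_map,
        wg_expressing=wg_expressing,
        wg_on=wg_on,
        membrane_truth=membrane,
        arm_truth_junctional=junc,
        arm_truth_cytoplasmic=cyto,
        puncta=puncta,
        en_truth_rows=spec.en_rows_per_segment,
        spec=spec,
    )
    return image, truth


def _cell_row_col(spec: EmbryoSpec, cell_map: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ids = np.clip(cell_map - 1, 0, None)
    return ids // spec.n_cell_cols, ids % spec.n_cell_cols


def _punctum_molecules(spec: EmbryoSpec, mean: float, rng: np.random.Generator) -> float:
    s = spec.puncta_count_dispersion
    mu = np.log(mean) - 0.5 * s * s
    n = float(np.exp(rng.normal(mu, s)))
    lo, hi = spec.puncta_count_range
    return float(np.clip(n, lo, hi))


def _place_puncta(
    spec: EmbryoSpec,
    cell_map: np.ndarray,
    membrane: np.ndarray,
    on_px: np.ndarray,
    rng: np.random.Generator,
    gfp_stack: np.ndarray,
) -> list[TruePunctum]:
    """One punctum per cell by default: deep-cytoplasmic in Wg-OFF cells,
    within 2 px of the membrane in Wg-ON cells."""
    from scipy.ndimage import distance_transform_edt

    nz = spec.image_shape[0]
    d_mem = distance_transform_edt(~membrane)
    puncta: list[TruePunctum] = []
    n_cells = int(cell_map.max())
    interior = (cell_map > 0) & ~membrane
    for cid in range(1, n_cells + 1):
        cell_px = (cell_map == cid) & interior
        if not cell_px.any():
            continue
        is_on = bool(on_px[cell_px].any())
        if is_on:
            cand = cell_px & (d_mem >= 1) & (d_mem <= 2)
            compartment = "membrane"
            mean = spec.puncta_wgon_count_mean
        else:
            cand = cell_px & (d_mem >= 4)
            compartment = "cytoplasmic"
            mean = spec.puncta_wgoff_count_mean
        ys, xs = np.nonzero(cand)
        if ys.size == 0:
            continue
        for _ in range(spec.puncta_per_cell):
            k = int(rng.integers(ys.size))
            z = int(rng.integers(2, nz - 2))
            mol = _punctum_molecules(spec, mean, rng)
            _add_spot(gfp_stack, z, int(ys[k]), int(xs[k]), mol * spec.brightness_per_molecule)
            puncta.append(
                TruePunctum(
                    z=z,
                    y=int(ys[k]),
                    x=int(xs[k]),
                    compartment=compartment,
                    region="wg_on" if is_on else "wg_off",
                    molecules=mol,
                )
            )
    return puncta


def _render_spots(
    spec: StandardSpec, molecules: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    nz, ny, nx = spec.image_shape
    stack = np.zeros((nz, ny, nx))
    positions: list[tuple[int, int, int]] = []
    attempts = 0
    while len(positions) < len(molecules):
        attempts += 1
        if attempts > 10000 * len(molecules):
            raise RuntimeError("could not place structures with the requested separation")
        y = int(rng.integers(spec.margin_px, ny - spec.margin_px))
        x = int(rng.integers(spec.margin_px, nx - spec.margin_px))
        z = int(rng.integers(3, nz - 3))
        if any((y - py) ** 2 + (x - px) ** 2 < spec.min_separation_px**2 for _, py, px in positions):
            continue
        _add_spot(stack, z, y, x, molecules[len(positions)] * spec.brightness_per_molecule)
        positions.append((z, y, x))
    stack = gaussian_filter(
        stack, sigma=(spec.psf_sigma_z_px, spec.psf_sigma_px, spec.psf_sigma_px), mode="nearest"
    )
    return _camera(stack, spec, rng), positions


def render_standard(spec: StandardSpec) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Render a calibration-standard stack.

    Each structure is a diffraction-limited spot whose pre-noise integrated
    photon count is ``molecules_per_structure * brightness_per_molecule``.
    Returns the stack and the list of true (z, y, x) positions.
    """
    rng = np.random.default_rng(spec.seed)
    molecules = np.full(spec.n_structures, float(spec.molecules_per_structure))
    return _render_spots(spec, molecules, rng)


def render_spot_field(
    spec: StandardSpec, molecules
) -> tuple[np.ndarray, list[tuple[int, int, int]]]:
    """Render well-separated spots with per-spot molecule counts.

    Same optics and camera as :func:`render_standard`; used to validate the
    counting chain (calibration linearity) on isolated structures.
    """
    rng = np.random.default_rng(spec.seed)
    molecules = np.asarray(molecules, dtype=float)
    if (molecules < 1).any():
        raise ValueError("molecule counts must be >= 1")
    return _render_spots(spec, molecules, rng)


def render_en_channel(spec: EmbryoSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render the Engrailed channel: per segment, a band of En-positive cells
    ``en_rows_per_segment`` cell rows wide (the most posterior rows of each
    segment).  En is a nuclear signal, so each positive cell is drawn as a
    round nuclear blob at the cell center, leaving clear gaps between
    neighboring cells so they remain countable along a sampling line."""
    rng = np.random.default_rng(spec.seed + 1)
    nz, ny, nx = spec.image_shape
    cell_map, membrane = _lattice(spec)
    wg_expressing, wg_on = _wg_state(spec)
    junc, cyto = _arm_truth(spec, cell_map, membrane)

    cps = spec.cells_per_segment
    col_in_seg = np.arange(spec.n_cell_cols) % cps
    en_cols = np.flatnonzero(col_in_seg >= cps - spec.en_rows_per_segment)

    cell = spec.cell_diameter_px
    r_nuc = max(2, int(round(0.3 * cell)))
    dy, dx = np.mgrid[-r_nuc : r_nuc + 1, -r_nuc : r_nuc + 1]
    disk = dy**2 + dx**2 <= r_nuc**2
    en_px = np.zeros((ny, nx), dtype=bool)
    for col in en_cols:
        cx = spec.x0 + col * cell + cell // 2
        for row in range(spec.n_cell_rows):
            cy = spec.y0 + row * cell + cell // 2
            en_px[cy - r_nuc : cy + r_nuc + 1, cx - r_nuc : cx + r_nuc + 1] |= disk
    plane = np.where(en_px, spec.en_level, 0.0)
    stack = _replicate_z(plane, spec)
    stack = gaussian_filter(
        stack, sigma=(spec.psf_sigma_z_px, spec.psf_sigma_px, spec.psf_sigma_px), mode="nearest"
    )
    stack = _camera(stack, spec, rng)
    truth = GroundTruth(
        cell_map=cell_map,
        wg_expressing=wg_expressing,
        wg_on=wg_on,
        membrane_truth=membrane,
        arm_truth_junctional=junc,
        arm_truth_cytoplasmic=cyto,
        puncta=[],
        en_truth_rows=spec.en_rows_per_segment,
        spec=spec,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------


def write_embryo_simulation(image: np.ndarray, truth: GroundTruth, out_dir) -> None:
    """Write the stack as a multi-series TIFF plus ground-truth sidecars."""
    import tifffile
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "embryo.tif", image.astype(np.float32), metadata={"axes": "CZYX"})
    spec_dict = dataclasses.asdict(truth.spec)
    spec_dict["channel_roles"] = CHANNEL_ROLES
    with open(out / "spec.yaml", "w") as fh:
        yaml.safe_dump(_yamlable(spec_dict), fh)
    truth.puncta_table().to_csv(out / "puncta_truth.csv", index=False)
    tifffile.imwrite(out / "membrane_truth.tif", truth.membrane_truth.astype(np.uint8) * 255)


def write_standard_simulation(stack: np.ndarray, positions, spec: StandardSpec, out_dir) -> None:
    import tifffile
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / f"standard_{spec.name}.tif", stack.astype(np.float32), metadata={"axes": "ZYX"})
    pd.DataFrame(positions, columns=["z", "y", "x"]).to_csv(
        out / f"standard_{spec.name}_positions.csv", index=False
    )
    with open(out / f"standard_{spec.name}_spec.yaml", "w") as fh:
        yaml.safe_dump(_yamlable(dataclasses.asdict(spec)), fh)


def _yamlable(obj):
    if isinstance(obj, dict):
        return {k: _yamlable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yamlable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
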