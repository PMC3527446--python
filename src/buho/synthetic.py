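"""Synthetic two-channel micrographs with known ground truth.

The generator emulates the confocal regime the detector was designed for:
a DAPI-like nuclear channel with bright, compact nuclei on a dark
background, and a poly(A)-FISH-like foci channel with faintly stained
cytoplasm, an elevated nuclear signal (nuclear polyadenylated RNA), and
bright compact granules of varied size, shape and intensity pattern —
round, elliptical, uniform or brighter-cored — planted in the cytoplasm of
a known subset of "positive" cells.  Additive Gaussian noise is applied to
both channels.

Default intensities follow the post-clipping 16-bit training regime of the
original experiments: nuclear stain averaging ~200, foci-channel signal
staying below ~50, on a 0–255 working range.  Every field is
bit-reproducible from its spec and seed, and the ground truth records the
exact cell footprints, nucleus masks and granule parameters, so detection
precision/recall and size recovery can be scored without any manual
annotation.

The default prototype bank is extracted from a noiseless synthetic
reference rendering of the eight granule morphologies, with the
per-prototype similarity thresholds of the calibrated eight-template bank.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np

from .image_io import ChannelImage, ImageSet
from .foci_detection import FocusObject, Prototype, PrototypeBank

# ---------------------------------------------------------------------------
# Granule morphology library
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GranuleShape:
    """Parametric granule morphology: anisotropic Gaussian, optional core.

    ``sigma_major``/``sigma_minor`` are the Gaussian axes in pixels,
    ``theta_deg`` the major-axis orientation, and ``core_boost`` the
    relative amplitude of a half-width central core added on top (0 for a
    uniform-profile granule).
    """

    sigma_major: float
    sigma_minor: float
    theta_deg: float = 0.0
    core_boost: float = 0.0

    @property
    def isotropic(self) -> bool:
        return self.sigma_major == self.sigma_minor and self.core_boost >= 0


#: The eight default morphologies: small/medium/large round, two
#: perpendicular ellipses, an oblique ellipse, and brighter-cored round and
#: elliptical variants.  Mirrors the frequent granule patterns seen in
#: confocal data (round, elliptical, uniform, brighter core).
MORPHOLOGIES: tuple[GranuleShape, ...] = (
    GranuleShape(1.4, 1.4, 0.0, 0.0),      # I   small round
    GranuleShape(2.0, 2.0, 0.0, 0.0),      # II  medium round
    GranuleShape(2.8, 2.8, 0.0, 0.0),      # III large round
    GranuleShape(2.6, 1.5, 0.0, 0.0),      # IV  horizontal ellipse
    GranuleShape(2.6, 1.5, 90.0, 0.0),     # V   vertical ellipse
    GranuleShape(2.2, 1.3, 45.0, 0.0),     # VI  oblique ellipse
    GranuleShape(2.4, 2.4, 0.0, 0.8),      # VII round, brighter core
    GranuleShape(2.7, 1.7, 135.0, 0.6),    # VIII elliptical, brighter core
)

#: Calibrated per-prototype similarity thresholds for the default bank.
DEFAULT_STS: tuple[float, ...] = (0.89, 0.88, 0.80, 0.88, 0.86, 0.86, 0.92, 0.85)

PROTOTYPE_IDS: tuple[str, ...] = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")

#: Isotropic (round) morphology indices, for rotation-redundancy checks.
ISOTROPIC_MORPHOLOGIES: tuple[int, ...] = (0, 1, 2, 6)


def granule_profile(shape: GranuleShape, halfside: int) -> np.ndarray:
    """Unit-amplitude granule profile on a (2*halfside+1)^2 grid."""
    r = np.arange(-halfside, halfside + 1, dtype=np.float64)
    rr, cc = np.meshgrid(r, r, indexing="ij")
    t = math.radians(shape.theta_deg)
    # rotate coordinates into the granule frame (clockwise image convention)
    u = cc * math.cos(t) + rr * math.sin(t)
    v = -cc * math.sin(t) + rr * math.cos(t)
    q = (u / shape.sigma_major) ** 2 + (v / shape.sigma_minor) ** 2
    prof = np.exp(-0.5 * q)
    if shape.core_boost > 0:
        prof = prof + shape.core_boost * np.exp(-0.5 * q * 4.0)
    return prof / prof.max()


def granule_halfmax_area_px(shape: GranuleShape, jitter: float = 1.0) -> int:
    """Planted area in pixels: above-half-max footprint of the clean profile."""
    halfside = int(math.ceil(4.0 * shape.sigma_major * jitter)) + 1
    prof = granule_profile(
        replace(
            shape,
            sigma_major=shape.sigma_major * jitter,
            sigma_minor=shape.sigma_minor * jitter,
        ),
        halfside,
    )
    return int(np.count_nonzero(prof >= 0.5))


# ---------------------------------------------------------------------------
# Field specification and ground truth
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSpec:
    """Stated world for one synthetic field.

    Defaults emulate a 63x confocal field at 512x512 px: ~15 semi-adherent
    cells of ~100 um^2, nuclei ~1/3 of the cell radius, half the cells
    "positive" with 2–6 granules each, granule peak amplitudes 18–40
    intensity units over a cytoplasm of 12 on a 0–255 working range, and
    additive Gaussian noise of sigma 3 (worst-case granule SNR 6).
    """

    side: int = 512
    pixel_size_um: float = 0.2
    n_cells: int = 15
    cell_radius_px: tuple[float, float] = (26.0, 36.0)
    nucleus_radius_frac: tuple[float, float] = (0.22, 0.30)
    fraction_positive: float = 0.5
    granules_per_positive_cell: tuple[int, int] = (2, 6)
    morphologies: tuple[int, ...] = tuple(range(len(MORPHOLOGIES)))
    shape_jitter: tuple[float, float] = (0.9, 1.1)
    granule_amplitude: tuple[float, float] = (24.0, 45.0)
    granule_min_separation_px: float = 12.0
    granule_margin_px: float = 9.0
    granule_mode: str = "single"  # "compound" renders multi-lobed aggregates
    compound_target_area_px: tuple[float, float] = (18.0, 26.0)
    compound_lobe_sigma: float = 2.0
    background_nuclear: float = 5.0
    nucleus_intensity: float = 200.0
    background_foci: float = 2.0
    cytoplasm_intensity: float = 12.0
    nuclear_polya_intensity: float = 35.0
    noise_sigma: float = 2.0
    bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.fraction_positive <= 1):
            raise ValueError("fraction_positive must be in [0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        for lo, hi in (
            self.cell_radius_px,
            self.nucleus_radius_frac,
            self.shape_jitter,
            self.granule_amplitude,
        ):
            if not (0 < lo <= hi):
                raise ValueError("distribution bounds must be positive and ordered")


@dataclass
class TrueCell:
    cell_id: int
    center: tuple[float, float]
    cyto_axes: tuple[float, float]
    cyto_theta: float
    nucleus_center: tuple[float, float]
    nucleus_axes: tuple[float, float]
    positive: bool


@dataclass
class TrueGranule:
    center: tuple[int, int]
    cell_id: int
    morphology: int
    sigma_major: float
    sigma_minor: float
    theta_deg: float
    amplitude: float
    core_boost: float
    area_px: int


@dataclass
class GroundTruth:
    """Exact per-cell and per-granule parameters behind one rendered field."""

    cells: list[TrueCell]
    granules: list[TrueGranule]
    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    pixel_size_um: float
    seed: int

    @property
    def n_positive_cells(self) -> int:
        return sum(1 for c in self.cells if c.positive)

    def granule_area_um2(self, g: TrueGranule) -> float:
        return g.area_px * self.pixel_size_um**2


class OvercrowdedError(RuntimeError):
    """Cells could not be placed without overlap within the retry budget."""


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _ellipse_rho(
    shape_hw: tuple[int, int],
    center: tuple[float, float],
    axes: tuple[float, float],
    theta: float,
) -> np.ndarray:
    """Normalised elliptical radius over the full field (1 at the boundary)."""
    rr, cc = np.ogrid[: shape_hw[0], : shape_hw[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    u = dc * math.cos(theta) + dr * math.sin(theta)
    v = -dc * math.sin(theta) + dr * math.cos(theta)
    return np.sqrt((u / axes[0]) ** 2 + (v / axes[1]) ** 2)


def _soft_disc(rho: np.ndarray, edge_width: float) -> np.ndarray:
    """Flat-top disc with a sigmoid edge of the given normalised width."""
    return 1.0 / (1.0 + np.exp(np.clip((rho - 1.0) / edge_width, -60.0, 60.0)))


def _add_granule(
    canvas: np.ndarray,
    center: tuple[int, int],
    shape: GranuleShape,
    jitter: float,
    amplitude: float,
) -> int:
    """Render one granule additively; returns its above-half-max area (px)."""
    sig = replace(
        shape,
        sigma_major=shape.sigma_major * jitter,
        sigma_minor=shape.sigma_minor * jitter,
    )
    halfside = int(math.ceil(4.0 * sig.sigma_major)) + 1
    prof = granule_profile(sig, halfside)
    r, c = center
    h, w = canvas.shape
    r0, r1 = max(0, r - halfside), min(h, r + halfside + 1)
    c0, c1 = max(0, c - halfside), min(w, c + halfside + 1)
    pr0, pc0 = r0 - (r - halfside), c0 - (c - halfside)
    canvas[r0:r1, c0:c1] += amplitude * prof[
        pr0 : pr0 + (r1 - r0), pc0 : pc0 + (c1 - c0)
    ]
    return int(np.count_nonzero(prof >= 0.5))


def _add_compound_granule(
    canvas: np.ndarray,
    center: tuple[int, int],
    target_area_px: float,
    rng: np.random.Generator,
    amplitude: float,
    lobe_sigma: float = 2.0,
) -> int:
    """Render a multi-lobed aggregate of roughly ``target_area_px`` footprint.

    Large stress-induced foci are aggregates rather than scaled-up single
    blobs: they keep internal granular texture at the scale of a small
    focus.  Lobes (round Gaussians of ``lobe_sigma``) are max-composed at
    small mutual offsets until the above-half-max footprint reaches the
    target.  Returns the realised planted area in pixels.
    """
    halfside = int(math.ceil(4.0 * lobe_sigma + math.sqrt(target_area_px))) + 2
    size = 2 * halfside + 1
    prof = np.zeros((size, size))
    lobes: list[tuple[float, float]] = [(float(halfside), float(halfside))]
    r = np.arange(size, dtype=np.float64)
    rr, cc = np.meshgrid(r, r, indexing="ij")

    def lobe_at(lr: float, lc: float) -> np.ndarray:
        q = ((rr - lr) ** 2 + (cc - lc) ** 2) / lobe_sigma**2
        return np.exp(-0.5 * q)

    prof = lobe_at(*lobes[0])
    for _ in range(200):
        if int(np.count_nonzero(prof >= 0.5)) >= target_area_px:
            break
        base = lobes[int(rng.integers(0, len(lobes)))]
        ang = rng.uniform(0, 2 * math.pi)
        dist = rng.uniform(2.2, 3.8)
        lr = base[0] + dist * math.sin(ang)
        lc = base[1] + dist * math.cos(ang)
        if not (2 <= lr < size - 2 and 2 <= lc < size - 2):
            continue
        lobes.append((lr, lc))
        prof = np.maximum(prof, lobe_at(lr, lc))
    area = int(np.count_nonzero(prof >= 0.5))
    rg, c = center
    h, w = canvas.shape
    r0, r1 = max(0, rg - halfside), min(h, rg + halfside + 1)
    c0, c1 = max(0, c - halfside), min(w, c + halfside + 1)
    pr0, pc0 = r0 - (rg - halfside), c0 - (c - halfside)
    canvas[r0:r1, c0:c1] += amplitude * prof[
        pr0 : pr0 + (r1 - r0), pc0 : pc0 + (c1 - c0)
    ]
    return area


def generate_field(spec: SyntheticSpec) -> tuple[ImageSet, GroundTruth]:
    """Render one synthetic two-channel field with its ground truth.

    Cells are placed as non-overlapping soft-edged ellipses; each carries a
    smaller nuclear ellipse.  Granules are planted only in positive cells,
    inside the cytoplasmic annulus (clear of both the nucleus and the cell
    edge) with a minimum mutual separation, so each planted granule is an
    unambiguous detection target.

    Raises
    ------
    OvercrowdedError
        If cells cannot be placed without overlap after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    side = spec.side
    nuclear = np.full((side, side), spec.background_nuclear)
    foci = np.full((side, side), spec.background_foci)
    cell_labels = np.zeros((side, side), dtype=np.int32)
    nucleus_labels = np.zeros((side, side), dtype=np.int32)

    # -- place cells ---------------------------------------------------
    placed: list[tuple[float, float, float]] = []  # (r, c, radius)
    cells: list[TrueCell] = []
    for cid in range(1, spec.n_cells + 1):
        radius = rng.uniform(*spec.cell_radius_px)
        ok = False
        for _ in range(200):
            r = rng.uniform(radius + 2, side - radius - 2)
            c = rng.uniform(radius + 2, side - radius - 2)
            if all(
                (r - pr) ** 2 + (c - pc) ** 2 > (radius + prad + 2) ** 2
                for pr, pc, prad in placed
            ):
                ok = True
                break
        if not ok:
            raise OvercrowdedError(
                f"could not place cell {cid} of {spec.n_cells} in a {side}px field"
            )
        placed.append((r, c, radius))
        axis_ratio = rng.uniform(0.85, 1.0)
        theta = rng.uniform(0, math.pi)
        cyto_axes = (radius, radius * axis_ratio)
        nuc_frac = rng.uniform(*spec.nucleus_radius_frac)
        nuc_axes = (radius * nuc_frac, radius * nuc_frac * rng.uniform(0.85, 1.0))
        # nucleus sits near the cell centre
        off = radius * 0.1
        nuc_center = (r + rng.uniform(-off, off), c + rng.uniform(-off, off))
        cells.append(
            TrueCell(
                cell_id=cid,
                center=(r, c),
                cyto_axes=cyto_axes,
                cyto_theta=theta,
                nucleus_center=nuc_center,
                nucleus_axes=nuc_axes,
                positive=False,
            )
        )

    # -- render cell bodies and nuclei ---------------------------------
    for cell in cells:
        rho_cyto = _ellipse_rho(
            (side, side), cell.center, cell.cyto_axes, cell.cyto_theta
        )
        rho_nuc = _ellipse_rho(
            (side, side), cell.nucleus_center, cell.nucleus_axes, cell.cyto_theta
        )
        cyto = _soft_disc(rho_cyto, 0.04)
        nuc = _soft_disc(rho_nuc, 0.08)
        foci += spec.cytoplasm_intensity * cyto
        foci += (spec.nuclear_polya_intensity - spec.cytoplasm_intensity) * nuc
        nuclear += (spec.nucleus_intensity - spec.background_nuclear) * nuc
        cell_labels[rho_cyto <= 1.0] = cell.cell_id
        nucleus_labels[rho_nuc <= 1.0] = cell.cell_id

    # -- choose positive cells and plant granules ----------------------
    # stochastically rounded count: unbiased at any n_cells without the
    # full Bernoulli variance, so planted well fractions are tight
    target = spec.fraction_positive * len(cells)
    n_positive = int(math.floor(target))
    if rng.random() < target - n_positive:
        n_positive += 1
    positive_idx = rng.choice(len(cells), size=min(n_positive, len(cells)), replace=False)
    granules: list[TrueGranule] = []
    lo_n, hi_n = spec.granules_per_positive_cell
    for idx in sorted(int(i) for i in positive_idx):
        cell = cells[int(idx)]
        n_gran = int(rng.integers(lo_n, hi_n + 1))
        planted: list[tuple[int, int]] = []
        attempts = 0
        while len(planted) < n_gran and attempts < 400:
            attempts += 1
            ang = rng.uniform(0, 2 * math.pi)
            rad_frac = rng.uniform(0.0, 0.85)
            r = int(round(cell.center[0] + rad_frac * cell.cyto_axes[0] * math.sin(ang)))
            c = int(round(cell.center[1] + rad_frac * cell.cyto_axes[1] * math.cos(ang)))
            if not (0 <= r < side and 0 <= c < side):
                continue
            rho_c = _ellipse_rho(
                (1, 1), (cell.center[0] - r, cell.center[1] - c),
                cell.cyto_axes, cell.cyto_theta,
            )[0, 0]
            rho_n = _ellipse_rho(
                (1, 1),
                (cell.nucleus_center[0] - r, cell.nucleus_center[1] - c),
                cell.nucleus_axes,
                cell.cyto_theta,
            )[0, 0]
            # keep the full prototype window (granule + margin) clear of the
            # cytoplasm edge and of the bright nuclear poly(A) rim
            edge_gap_px = (1.0 - rho_c) * min(cell.cyto_axes)
            nuc_gap_px = (rho_n - 1.0) * min(cell.nucleus_axes)
            if edge_gap_px < spec.granule_margin_px or nuc_gap_px < spec.granule_margin_px:
                continue
            if any(
                (r - pr) ** 2 + (c - pc) ** 2 < spec.granule_min_separation_px**2
                for pr, pc in planted
            ):
                continue
            amplitude = rng.uniform(*spec.granule_amplitude)
            if spec.granule_mode == "compound":
                target = rng.uniform(*spec.compound_target_area_px)
                area_px = _add_compound_granule(
                    foci, (r, c), target, rng, amplitude, spec.compound_lobe_sigma
                )
                morph_idx = -1
                sig_major = sig_minor = spec.compound_lobe_sigma
                theta = 0.0
                core = 0.0
            else:
                morph_idx = int(rng.choice(spec.morphologies))
                shape = MORPHOLOGIES[morph_idx]
                jitter = rng.uniform(*spec.shape_jitter)
                area_px = _add_granule(foci, (r, c), shape, jitter, amplitude)
                sig_major = shape.sigma_major * jitter
                sig_minor = shape.sigma_minor * jitter
                theta = shape.theta_deg
                core = shape.core_boost
            planted.append((r, c))
            granules.append(
                TrueGranule(
                    center=(r, c),
                    cell_id=cell.cell_id,
                    morphology=morph_idx,
                    sigma_major=sig_major,
                    sigma_minor=sig_minor,
                    theta_deg=theta,
                    amplitude=amplitude,
                    core_boost=core,
                    area_px=area_px,
                )
            )
        # the truth reflects the realised field: a cell is positive only if
        # at least two granules actually fitted into its cytoplasm
        cell.positive = len(planted) >= 2

    # -- noise and quantisation ----------------------------------------
    cap = float(2**spec.bit_depth - 1)
    if spec.noise_sigma > 0:
        nuclear = nuclear + rng.normal(0.0, spec.noise_sigma, nuclear.shape)
        foci = foci + rng.normal(0.0, spec.noise_sigma, foci.shape)
    nuclear = np.clip(np.rint(nuclear), 0, cap)
    foci = np.clip(np.rint(foci), 0, cap)

    image_set = ImageSet(
        nuclear=ChannelImage(nuclear, spec.bit_depth, spec.pixel_size_um, "nuclear"),
        foci=ChannelImage(foci, spec.bit_depth, spec.pixel_size_um, "foci"),
        field_id=f"synthetic-{spec.seed}",
    )
    truth = GroundTruth(
        cells=cells,
        granules=granules,
        cell_labels=cell_labels,
        nucleus_labels=nucleus_labels,
        pixel_size_um=spec.pixel_size_um,
        seed=spec.seed,
    )
    return image_set, truth


# ---------------------------------------------------------------------------
# Default prototype bank
# ---------------------------------------------------------------------------


def render_reference_patch(
    shape: GranuleShape,
    margin: int = 2,
    amplitude: float = 30.0,
    cytoplasm: float = 12.0,
) -> np.ndarray:
    """Noiseless rendering of one granule on cytoplasm, with margin."""
    half_box = int(math.ceil(2.2 * shape.sigma_major))
    halfside = half_box + margin
    prof = granule_profile(shape, halfside)
    return cytoplasm + amplitude * prof


def default_bank(margin: int = 2) -> PrototypeBank:
    """The calibrated eight-prototype bank (ids I–VIII).

    Patches are extracted from noiseless synthetic reference renderings of
    the eight default morphologies, each with a margin of plain cytoplasm,
    and paired with the calibrated per-prototype similarity thresholds.
    """
    prototypes = [
        Prototype(
            patch=render_reference_patch(shape, margin=margin),
            id=pid,
            similarity_threshold=st,
        )
        for shape, pid, st in zip(MORPHOLOGIES, PROTOTYPE_IDS, DEFAULT_STS)
    ]
    return PrototypeBank(prototypes=prototypes, source="synthetic-reference")


# ---------------------------------------------------------------------------
# Plate generation
# ---------------------------------------------------------------------------


@dataclass
class WellLayout:
    """One well of a plate layout."""

    well_id: str
    treatment: str
    is_control: bool = False


@dataclass
class WellTruth:
    well_id: str
    treatment: str
    is_control: bool
    expected_pct_positive: float
    planted_pct_positive: float
    n_fields: int


def generate_plate(
    base_spec: SyntheticSpec,
    layout: Sequence[WellLayout],
    treatment_fraction_scale: Optional[dict[str, float]] = None,
    fields_per_well: int = 7,
    seed: int = 0,
) -> Iterator[tuple[WellTruth, list[tuple[ImageSet, GroundTruth]]]]:
    """Yield per-well synthetic fields for a screening plate.

    Each well's fields are drawn from ``base_spec`` with the positive-cell
    fraction scaled by the well treatment's factor (1.0 when absent), so a
    "knockdown" at factor 0.6 should score 0.6 against untreated controls.
    Wells are yielded one at a time to keep memory bounded.
    """
    if not layout:
        raise ValueError("layout must contain at least one well")
    scales = treatment_fraction_scale or {}
    seq = np.random.SeedSequence(seed)
    well_seeds = seq.spawn(len(layout))
    for well, wseed in zip(layout, well_seeds):
        scale = scales.get(well.treatment, 1.0)
        frac = min(1.0, base_spec.fraction_positive * scale)
        field_seed_rng = np.random.default_rng(wseed)
        fields = []
        n_cells_total = 0
        n_pos_total = 0
        for _ in range(fields_per_well):
            fseed = int(field_seed_rng.integers(0, 2**31 - 1))
            spec = replace(base_spec, fraction_positive=frac, seed=fseed)
            imgs, truth = generate_field(spec)
            imgs = replace(imgs, well_id=well.well_id)
            fields.append((imgs, truth))
            n_cells_total += len(truth.cells)
            n_pos_total += truth.n_positive_cells
        yield (
            WellTruth(
                well_id=well.well_id,
                treatment=well.treatment,
                is_control=well.is_control,
                expected_pct_positive=100.0 * frac,
                planted_pct_positive=(
                    100.0 * n_pos_total / n_cells_total if n_cells_total else 0.0
                ),
                n_fields=fields_per_well,
            ),
            fields,
        )


# ---------------------------------------------------------------------------
# Detection scoring
# ---------------------------------------------------------------------------


@dataclass
class DetectionReport:
    """Greedy one-to-one matching of detections to planted granules."""

    n_detections: int
    n_granules: int
    n_matched: int
    precision: float
    recall: float
    precision_defined: bool
    matches: list[tuple[int, int]] = field(default_factory=list)  # (det, granule)
    size_errors_px: list[int] = field(default_factory=list)


def evaluate_detection(
    foci: Sequence[FocusObject],
    truth: GroundTruth,
    match_radius_um: float = 1.0,
) -> DetectionReport:
    """Score detections against planted granules.

    Detection/granule pairs within ``match_radius_um`` are matched greedily
    by increasing distance, one-to-one.  Precision is matched/detections
    (reported as 1 with a flag when there are no detections) and recall
    matched/granules (1 when nothing was planted).
    """
    if not match_radius_um > 0:
        raise ValueError("match_radius_um must be > 0")
    n_det, n_gran = len(foci), len(truth.granules)
    if n_det == 0 or n_gran == 0:
        return DetectionReport(
            n_detections=n_det,
            n_granules=n_gran,
            n_matched=0,
            precision=1.0,
            recall=1.0 if n_gran == 0 else 0.0,
            precision_defined=n_det > 0,
        )
    det_pts = np.array([o.point for o in foci], dtype=float)
    gran_pts = np.array([g.center for g in truth.granules], dtype=float)
    d = np.sqrt(
        ((det_pts[:, None, :] - gran_pts[None, :, :]) ** 2).sum(axis=2)
    ) * truth.pixel_size_um
    pairs = [
        (d[i, j], i, j)
        for i in range(n_det)
        for j in range(n_gran)
        if d[i, j] <= match_radius_um
    ]
    pairs.sort()
    used_det: set[int] = set()
    used_gran: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _dist, i, j in pairs:
        if i in used_det or j in used_gran:
            continue
        used_det.add(i)
        used_gran.add(j)
        matches.append((i, j))
    size_errors = [
        int(foci[i].pixel_count - truth.granules[j].area_px) for i, j in matches
    ]
    n_matched = len(matches)
    return DetectionReport(
        n_detections=n_det,
        n_granules=n_gran,
        n_matched=n_matched,
        precision=n_matched / n_det,
        recall=n_matched / n_gran,
        precision_defined=True,
        matches=matches,
        size_errors_px=size_errors,
    )
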