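"""Foci detection by normalized cross-correlation against prototype granules.

Rather than fitting a parametric spot model, detection works by similarity:
a small bank of example granules ("prototypes"), each cut from a reference
image together with a margin of surrounding cytoplasm, is slid over the
foci channel and a Pearson correlation is computed at every position.
Positions whose correlation exceeds the prototype's empirically calibrated
similarity threshold (ST) become seed pixels.  Strict STs kill false
positives at the cost of per-prototype sensitivity; the union over several
prototypes of different size, shape and intensity pattern restores recall.

Seeds inside the nucleus (abundant nuclear polyadenylated RNA correlates
with any bright template) and in extracellular territory are removed.  The
surviving seeds — typically several per granule, from redundant prototype
hits — are merged into one counted object per granule by dilating each
seed to a 3x3 square and taking connected components.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import match_template

from .cell_segmentation import BinaryMask
from .image_io import ChannelImage, unsharp_filter

logger = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class Prototype:
    """An example-granule patch used as a matching template.

    The patch covers the granule plus a margin of cytoplasm — the margin
    anchors the local contrast and markedly improves specificity.  Each
    prototype carries its own similarity threshold, calibrated so that it
    alone produces no false positives.
    """

    patch: np.ndarray
    id: str
    similarity_threshold: float
    rotation_deg: int = 0

    def __post_init__(self) -> None:
        patch = np.asarray(self.patch, dtype=np.float64)
        object.__setattr__(self, "patch", patch)
        if patch.ndim != 2 or min(patch.shape) < 3:
            raise ValueError("prototype patch must be 2-D with side >= 3")
        if float(patch.std()) == 0.0:
            raise ValueError("prototype patch has zero variance")
        if not (0 < self.similarity_threshold < 1):
            raise ValueError("similarity_threshold must be in (0, 1)")
        if self.rotation_deg not in (0, 90, 180, 270):
            raise ValueError("rotation_deg must be one of 0, 90, 180, 270")

    @property
    def key(self) -> tuple[str, int]:
        return (self.id, self.rotation_deg)


@dataclass
class PrototypeBank:
    """Ordered collection of prototypes with unique (id, rotation) keys."""

    prototypes: list[Prototype]
    source: str = ""

    def __post_init__(self) -> None:
        keys = [p.key for p in self.prototypes]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (id, rotation) keys in prototype bank")

    def __len__(self) -> int:
        return len(self.prototypes)

    def __iter__(self):
        return iter(self.prototypes)

    def with_rotations(self) -> "PrototypeBank":
        """Bank extended with the 90/180/270-degree clockwise rotations."""
        extended = list(self.prototypes)
        for p in self.prototypes:
            for q in (1, 2, 3):
                extended.append(rotate_prototype(p, q))
        return PrototypeBank(prototypes=extended, source=self.source)

    def with_thresholds(self, st: float | Sequence[float]) -> "PrototypeBank":
        """Bank with overridden similarity thresholds (scalar or per-prototype)."""
        if np.isscalar(st):
            sts = [float(st)] * len(self.prototypes)
        else:
            sts = [float(s) for s in st]  # type: ignore[union-attr]
            if len(sts) != len(self.prototypes):
                raise ValueError("one threshold per prototype required")
        return PrototypeBank(
            prototypes=[
                replace(p, similarity_threshold=s)
                for p, s in zip(self.prototypes, sts)
            ],
            source=self.source,
        )


@dataclass
class CorrelationMap:
    """Per-pixel correlation of one prototype with the image.

    ``values[r, c]`` is the Pearson correlation of the prototype centred at
    (r, c); positions where the patch does not fit inside the image are NaN
    and marked invalid in ``valid``.
    """

    values: np.ndarray
    valid: np.ndarray
    prototype_id: str
    rotation_deg: int = 0


@dataclass
class SeedMap:
    """Binary seed positions plus per-pixel prototype provenance."""

    pixels: np.ndarray
    provenance: dict[tuple[int, int], set[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)

    @property
    def n_seeds(self) -> int:
        return int(self.pixels.sum())


@dataclass
class FocusObject:
    """One detected focus: merged seed cluster reduced to a counted point."""

    focus_id: int
    point: tuple[int, int]
    pixel_set: np.ndarray  # (n, 2) array of (row, col)
    pixel_count: int
    area_um2: float
    size_reliable: bool = False
    cell_id: int = 0
    prototype_hits: set[str] = field(default_factory=set)


def extract_prototype(
    img: ChannelImage,
    center: tuple[int, int],
    granule_box: int,
    margin: int,
    id: str = "P",
    similarity_threshold: float = 0.85,
) -> Prototype:
    """Cut a square prototype patch (granule + cytoplasm margin) from an image.

    The patch side is ``granule_box + 2 * margin`` centred on ``center``;
    raw intensities are preserved.  Patches with zero variance are rejected.
    """
    side = granule_box + 2 * margin
    half = side // 2
    r, c = center
    r0, c0 = r - half, c - half
    h, w = img.shape
    if r0 < 0 or c0 < 0 or r0 + side > h or c0 + side > w:
        raise ValueError(f"{side}x{side} patch at {center} does not fit in image {img.shape}")
    patch = img.pixels[r0 : r0 + side, c0 : c0 + side].copy()
    return Prototype(patch=patch, id=id, similarity_threshold=similarity_threshold)


def rotate_prototype(p: Prototype, quarter_turns: int) -> Prototype:
    """Rotate a prototype clockwise by 90-degree steps.

    The similarity threshold is inherited from the unrotated prototype.
    """
    if quarter_turns not in (1, 2, 3):
        raise ValueError("quarter_turns must be 1, 2 or 3")
    # np.rot90 rotates counter-clockwise; negative k gives clockwise turns.
    patch = np.rot90(p.patch, k=-quarter_turns)
    return replace(p, patch=patch.copy(), rotation_deg=(p.rotation_deg + 90 * quarter_turns) % 360)


def normxcorr(img: ChannelImage, p: Prototype) -> CorrelationMap:
    """Normalized 2-D cross-correlation of a prototype over the image.

    At each valid centre the value is the Pearson correlation between the
    (mean-centred, SD-normalised) patch and the co-located image window, so
    the map is invariant to local affine intensity changes.  Windows with
    zero variance give 0.  Border positions where the patch does not fit
    are invalid (no padding: padded correlations are biased and generate
    rim artifacts).
    """
    patch = p.patch
    ph, pw = patch.shape
    h, w = img.shape
    if ph > h or pw > w:
        raise ValueError("prototype larger than image")
    # FFT-based sliding Pearson correlation; result indexed by patch top-left.
    raw = match_template(img.pixels, patch, pad_input=False)
    raw = np.clip(np.nan_to_num(raw, nan=0.0, posinf=0.0, neginf=0.0), -1.0, 1.0)
    values = np.full((h, w), np.nan)
    valid = np.zeros((h, w), dtype=bool)
    r_off, c_off = ph // 2, pw // 2
    values[r_off : r_off + raw.shape[0], c_off : c_off + raw.shape[1]] = raw
    valid[r_off : r_off + raw.shape[0], c_off : c_off + raw.shape[1]] = True
    return CorrelationMap(
        values=values, valid=valid, prototype_id=p.id, rotation_deg=p.rotation_deg
    )


def threshold_seeds(c: CorrelationMap, st: float, pass_name: str = "raw") -> SeedMap:
    """Keep positions whose correlation strictly exceeds the ST as seeds."""
    if not (0 < st < 1):
        raise ValueError(f"similarity threshold must be in (0, 1), got {st}")
    with np.errstate(invalid="ignore"):
        seeds = np.where(c.valid, c.values > st, False)
    prov_tag = (
        c.prototype_id if c.rotation_deg == 0 else f"{c.prototype_id}@{c.rotation_deg}"
    )
    provenance = {
        (int(r), int(cc)): {(prov_tag, pass_name)}
        for r, cc in zip(*np.nonzero(seeds))
    }
    return SeedMap(pixels=seeds, provenance=provenance)


def _union_seeds(maps: Iterable[SeedMap], shape: tuple[int, int]) -> SeedMap:
    pixels = np.zeros(shape, dtype=bool)
    provenance: dict[tuple[int, int], set[tuple[str, str]]] = {}
    for m in maps:
        pixels |= m.pixels
        for pos, tags in m.provenance.items():
            provenance.setdefault(pos, set()).update(tags)
    return SeedMap(pixels=pixels, provenance=provenance)


def detect_seeds(
    img: ChannelImage,
    bank: PrototypeBank,
    use_sharpened_pass: bool = True,
    unsharp_alpha: float = 0.2,
) -> SeedMap:
    """Union of supra-threshold seeds over all prototypes (and both passes).

    With the sharpened pass enabled the correlation battery runs twice —
    on the raw channel and on its unsharp-filtered version — doubling the
    number of correlations (e.g. 8 prototypes -> 16 maps).  The second pass
    recovers the small fraction of weakly stained, blurry foci whose raw
    correlation falls just below threshold; its seeds are added to those
    from the unfiltered image.
    """
    if len(bank) == 0:
        raise ValueError("prototype bank is empty")
    maps: list[SeedMap] = []
    for p in bank:
        maps.append(
            threshold_seeds(normxcorr(img, p), p.similarity_threshold, "raw")
        )
    if use_sharpened_pass:
        sharp = unsharp_filter(img, alpha=unsharp_alpha)
        for p in bank:
            maps.append(
                threshold_seeds(normxcorr(sharp, p), p.similarity_threshold, "sharpened")
            )
    return _union_seeds(maps, img.shape)


def mask_seeds(
    seeds: SeedMap, nuc_mask: BinaryMask, foreground: BinaryMask
) -> SeedMap:
    """Remove nuclear and extracellular seeds: seeds & ~nucleus & foreground."""
    if seeds.pixels.shape != nuc_mask.shape or seeds.pixels.shape != foreground.shape:
        raise ValueError("seed map and mask shapes differ")
    keep = seeds.pixels & ~nuc_mask.pixels & foreground.pixels
    provenance = {pos: tags for pos, tags in seeds.provenance.items() if keep[pos]}
    return SeedMap(pixels=keep, provenance=provenance)


def merge_seeds(seeds: SeedMap, pixel_size_um: float) -> list[FocusObject]:
    """Merge redundant seeds into one counted object per focus.

    Each seed is dilated to a centred 3x3 square — the size of a small
    granule at 63x / 512-px resolution — so the squares of seeds belonging
    to the same focus overlap and become a single 8-connected component,
    while nearby but distinct foci stay separate.  Every component is
    reduced to one representative point (the centroid, snapped to the
    nearest in-object pixel); counting the points counts the foci, and the
    component pixel count estimates the focus size.
    """
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be > 0")
    dilated = ndimage.binary_dilation(seeds.pixels, structure=_STRUCT8)
    labeled, n_obj = ndimage.label(dilated, structure=_STRUCT8)
    if n_obj == 0:
        return []
    objects: list[FocusObject] = []
    hits_by_obj: dict[int, set[str]] = {}
    for pos, tags in seeds.provenance.items():
        oid = int(labeled[pos])
        hits_by_obj.setdefault(oid, set()).update(tag for tag, _pass in tags)
    px_area = pixel_size_um**2
    slices = ndimage.find_objects(labeled)
    for obj_id in range(1, n_obj + 1):
        sl = slices[obj_id - 1]
        local = labeled[sl] == obj_id
        rows, cols = np.nonzero(local)
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        pixel_set = np.column_stack([rows, cols])
        centroid = pixel_set.mean(axis=0)
        d2 = ((pixel_set - centroid) ** 2).sum(axis=1)
        point = tuple(int(v) for v in pixel_set[int(np.argmin(d2))])
        hits = hits_by_obj.get(obj_id, set())
        objects.append(
            FocusObject(
                focus_id=obj_id,
                point=point,  # type: ignore[arg-type]
                pixel_set=pixel_set,
                pixel_count=int(len(pixel_set)),
                area_um2=float(len(pixel_set)) * px_area,
                prototype_hits=hits,
            )
        )
    for obj in objects:
        obj.size_reliable = size_reliability(obj)
    return objects


def size_reliability(obj: FocusObject, min_width_px: int = 6) -> bool:
    """Flag objects wide enough for their pixel count to estimate size.

    Below ~6 px width the measured object size is dominated by the seed
    dilation and the optics rather than the focus itself.
    """
    if min_width_px < 1:
        raise ValueError("min_width_px must be >= 1")
    rows = obj.pixel_set[:, 0]
    cols = obj.pixel_set[:, 1]
    width = max(int(rows.max() - rows.min() + 1), int(cols.max() - cols.min() + 1))
    return width > min_width_px


def refine_focus_sizes(
    img: ChannelImage,
    objects: Sequence[FocusObject],
    halfmax_frac: float = 0.5,
    pad: int = 6,
    min_width_px: int = 6,
) -> list[FocusObject]:
    """Re-measure focus footprints by local above-half-max thresholding.

    The merged-seed pixel count locates and counts foci well but its extent
    reflects the correlation footprint of the template bank, not the focus
    itself, so it compresses true size changes.  For size studies each
    detected focus is therefore re-segmented from the intensity image: the
    local background is the median of the window border ring, the peak the
    brightest pixel of the detected object, and the footprint the connected
    component above background + ``halfmax_frac`` * (peak - background)
    that contains the peak (FWHM-style sizing).  Counting semantics are
    unchanged; only pixel_set/area/reliability are replaced.
    """
    if not (0 < halfmax_frac < 1):
        raise ValueError("halfmax_frac must be in (0, 1)")
    h, w = img.shape
    px_area = img.pixel_size_um**2
    refined: list[FocusObject] = []
    for obj in objects:
        rows, cols = obj.pixel_set[:, 0], obj.pixel_set[:, 1]
        # window must clear the focus flanks so the border ring samples
        # true background; scale the padding with the detected extent
        extent = max(int(rows.max() - rows.min()), int(cols.max() - cols.min())) + 1
        wpad = max(pad, 2 * extent)
        r0 = max(0, int(rows.min()) - wpad)
        r1 = min(h, int(rows.max()) + wpad + 1)
        c0 = max(0, int(cols.min()) - wpad)
        c1 = min(w, int(cols.max()) + wpad + 1)
        sub = img.pixels[r0:r1, c0:c1]
        # 3x3 box-smoothed peak: robust to noise spikes; its attenuation of
        # a curved peak is undone below from a provisional width estimate
        sub_smooth = ndimage.uniform_filter(sub, size=3, mode="nearest")
        obj_rc = (rows - r0, cols - c0)
        peak_idx = int(np.argmax(sub_smooth[obj_rc]))
        peak_rc = (int(rows[peak_idx]) - r0, int(cols[peak_idx]) - c0)
        peak_sm = float(sub_smooth[peak_rc])
        ring = np.concatenate([sub[0, :], sub[-1, :], sub[:, 0], sub[:, -1]])
        background = float(np.median(ring))
        if peak_sm <= background:
            refined.append(obj)
            continue

        def _component(thr: float) -> tuple[np.ndarray, np.ndarray] | None:
            comp_labels, _ = ndimage.label(sub >= thr, structure=_STRUCT8)
            comp_id = comp_labels[peak_rc]
            if comp_id == 0:
                return None
            return np.nonzero(comp_labels == comp_id)  # type: ignore[return-value]

        # pass 1: provisional footprint at the smoothed-peak half level
        first = _component(background + halfmax_frac * (peak_sm - background))
        if first is None:
            refined.append(obj)
            continue
        # undo box attenuation (a 3x3 mean lowers a Gaussian peak of width
        # sigma by sigma^2/(sigma^2 + 2/3) per axis), then re-threshold
        sigma_sq = max(len(first[0]) / math.pi, 1.0) / (2.0 * math.log(2.0))
        atten = (sigma_sq / (sigma_sq + 2.0 / 3.0))
        peak = background + (peak_sm - background) / atten
        final = _component(background + halfmax_frac * (peak - background))
        if final is None:
            final = first
        rr, cc = final
        pixel_set = np.column_stack([rr + r0, cc + c0])
        d2 = ((pixel_set - np.array(obj.point)) ** 2).sum(axis=1)
        point = tuple(int(v) for v in pixel_set[int(np.argmin(d2))])
        new = FocusObject(
            focus_id=obj.focus_id,
            point=point,  # type: ignore[arg-type]
            pixel_set=pixel_set,
            pixel_count=int(len(pixel_set)),
            area_um2=float(len(pixel_set)) * px_area,
            cell_id=obj.cell_id,
            prototype_hits=set(obj.prototype_hits),
        )
        new.size_reliable = size_reliability(new, min_width_px)
        refined.append(new)
    return refined


def filter_small_foci(
    objects: list[FocusObject], min_area_um2: float
) -> list[FocusObject]:
    """Drop foci below a physical area floor (e.g. 0.2 um^2 for S-foci)."""
    return [o for o in objects if o.area_um2 >= min_area_um2]


def save_bank(bank: PrototypeBank, directory) -> None:
    """Write a bank as TIFF patches plus a YAML manifest."""
    from pathlib import Path

    import tifffile
    import yaml

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for p in bank:
        fname = f"prototype_{p.id}_{p.rotation_deg}.tif"
        tifffile.imwrite(directory / fname, p.patch.astype(np.float32))
        manifest.append(
            {
                "id": p.id,
                "file": fname,
                "similarity_threshold": float(p.similarity_threshold),
                "rotation_deg": int(p.rotation_deg),
            }
        )
    (directory / "manifest.yaml").write_text(
        yaml.safe_dump({"source": bank.source, "prototypes": manifest}, sort_keys=False)
    )


def load_bank(directory) -> PrototypeBank:
    """Read a bank written by :func:`save_bank`."""
    from pathlib import Path

    import tifffile
    import yaml

    directory = Path(directory)
    manifest = yaml.safe_load((directory / "manifest.yaml").read_text())
    prototypes = [
        Prototype(
            patch=tifffile.imread(directory / entry["file"]).astype(np.float64),
            id=str(entry["id"]),
            similarity_threshold=float(entry["similarity_threshold"]),
            rotation_deg=int(entry.get("rotation_deg", 0)),
        )
        for entry in manifest["prototypes"]
    ]
    return PrototypeBank(prototypes=prototypes, source=str(manifest.get("source", "")))


def prototype_redundancy(
    objects: Sequence[FocusObject], bank: PrototypeBank
) -> np.ndarray:
    """Lower-triangular percentage matrix of (joint) prototype recognition.

    Entry (i, i) is the percentage of objects hit by prototype i; entry
    (i, j), i > j, the percentage hit by both i and j.  Quantifies how
    redundantly the bank recognises each focus.
    """
    ids = [p.id for p in bank]
    n = len(ids)
    mat = np.zeros((n, n))
    total = len(objects)
    if total == 0:
        return mat
    for i, pi in enumerate(ids):
        for j, pj in enumerate(ids[: i + 1]):
            count = sum(
                1 for o in objects if pi in o.prototype_hits and pj in o.prototype_hits
            )
            mat[i, j] = 100.0 * count / total
    return mat
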