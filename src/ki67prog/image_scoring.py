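"""Automated KI67 scoring of TMA core images.

The scoring protocol mirrors a shape-and-colour automated IHC workflow:

1. per-pixel optical densities, ``OD = -log10((I + eps)/255)``;
2. colour deconvolution against an H-DAB stain basis to obtain
   haematoxylin and DAB concentration maps;
3. nuclear segmentation on the combined nuclear signal (Otsu-initialised
   threshold, distance-transform watershed to split touching nuclei);
4. per-nucleus shape features in microns -- spot width (equivalent
   diameter), width (ellipse minor axis), roundness ``4*pi*A/P**2``,
   compactness ``P**2/(4*pi*A)`` and axis ratio;
5. classification: a nucleus is malignant iff every shape feature lies
   within its protocol range, and a malignant nucleus is KI67-positive
   iff the positivity rule fires (by default mean deconvolved DAB
   density above a cut; an HSI colour-box rule is available).

A computer-assisted visual (CAV) counting emulator tiles the core into
250 um grid squares and accumulates counts tile by tile, assigning each
nucleus to exactly one tile by its centroid under a half-open tile
convention, so no nucleus is double counted.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

from ._types import CoreImage, CoreScore, StainVectors

__all__ = [
    "CoreImage",
    "CoreScore",
    "NucleusRecord",
    "ScoringProtocol",
    "CavResult",
    "od_transform",
    "deconvolve",
    "segment_nuclei",
    "compute_shape_features",
    "classify_nuclei",
    "score_core",
    "analyse_core",
    "cav_grid_count",
    "calibrate_protocol",
]

_OD_EPS = 1e-6

FEATURE_NAMES = ("spot_width_um", "width_um", "roundness", "compactness", "axis_ratio")


@dataclass
class NucleusRecord:
    """Features of one segmented nuclear region.

    ``spot_width_um`` is the equivalent-circle diameter, ``width_um`` the
    ellipse minor-axis length from second-order moments (both microns).
    ``roundness`` and ``compactness`` are reciprocal by construction;
    digitisation of the perimeter can push roundness slightly above 1.
    """

    label: int
    centroid_xy: tuple[float, float]     # pixel coordinates (x, y)
    area_px: float
    spot_width_um: float
    width_um: float
    roundness: float
    compactness: float
    axis_ratio: float
    mean_od_hem: float
    mean_od_dab: float
    mean_hsi: tuple[float, float, float] | None = None
    flagged: bool = False
    malignant: bool | None = None
    positive: bool | None = None

    def feature(self, name: str) -> float:
        return getattr(self, name)


@dataclass
class ScoringProtocol:
    """Everything needed to score a core reproducibly.

    ``shape_ranges`` maps each shape feature to its (min, max) malignant
    window; the defaults were fitted on labelled synthetic training
    cores.  ``nuclear_od_threshold`` of None means Otsu initialisation
    per core.  Positivity is decided by ``dab_od_cut`` on the mean
    deconvolved DAB density, or by an HSI box when ``positivity_rule``
    is ``"hsi"``.
    """

    stains: StainVectors = field(default_factory=StainVectors)
    nuclear_od_threshold: float | None = None
    min_nucleus_area_um2: float = 8.0
    watershed_min_distance_um: float = 4.0
    shape_ranges: dict = field(
        default_factory=lambda: {
            "spot_width_um": (6.3, 12.5),
            "width_um": (5.6, 11.8),
            "roundness": (0.95, 1.30),
            "compactness": (0.77, 1.06),
            "axis_ratio": (0.74, 1.0),
        }
    )
    positivity_rule: str = "dab_od"       # "dab_od" | "hsi"
    dab_od_cut: float = 0.15
    hsi_box: dict = field(
        default_factory=lambda: {"hue": (0.02, 0.18), "saturation": (0.15, 1.0),
                                 "intensity": (0.0, 0.75)}
    )

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.shape_ranges.items():
            if name not in FEATURE_NAMES:
                raise ValueError(f"unknown shape feature {name!r}")
            if not lo < hi:
                raise ValueError(f"degenerate range for {name}: ({lo}, {hi})")
        if self.positivity_rule not in ("dab_od", "hsi"):
            raise ValueError("positivity_rule must be 'dab_od' or 'hsi'")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stains"] = {
            "hematoxylin_od": list(self.stains.hematoxylin_od),
            "dab_od": list(self.stains.dab_od),
            "residual_od": list(self.stains.residual_od) if self.stains.residual_od else None,
        }
        d["shape_ranges"] = {k: list(v) for k, v in self.shape_ranges.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScoringProtocol":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        stains = d.pop("stains", None)
        if stains:
            stains = StainVectors(
                hematoxylin_od=tuple(stains["hematoxylin_od"]),
                dab_od=tuple(stains["dab_od"]),
                residual_od=tuple(stains["residual_od"]) if stains.get("residual_od") else None,
            )
            d["stains"] = stains
        if "shape_ranges" in d:
            d["shape_ranges"] = {k: tuple(v) for k, v in d["shape_ranges"].items()}
        if "hsi_box" in d:
            d["hsi_box"] = {k: tuple(v) for k, v in d["hsi_box"].items()}
        return cls(**d)


# --------------------------------------------------------------------------
# colour deconvolution
# --------------------------------------------------------------------------

def od_transform(image: CoreImage | np.ndarray) -> np.ndarray:
    """Per-pixel optical density map, ``OD = -log10((I + eps)/255)``."""
    pixels = image.pixels if isinstance(image, CoreImage) else np.asarray(image)
    if pixels.ndim != 3 or pixels.shape[2] != 3:
        raise ValueError("od_transform expects an HxWx3 RGB image")
    od = -np.log10((pixels.astype(float) + _OD_EPS) / 255.0)
    return np.maximum(od, 0.0)


def deconvolve(od_map: np.ndarray, stains: StainVectors) -> np.ndarray:
    """Invert the stain basis per pixel; concentrations clamped at zero.

    Returns an H x W x 3 array of (haematoxylin, DAB, residual)
    concentrations.  Raises if the stain matrix is singular, naming the
    condition number.
    """
    inv = stains.inverse()
    conc = od_map @ inv.T
    return np.maximum(conc, 0.0)


# --------------------------------------------------------------------------
# segmentation and features
# --------------------------------------------------------------------------

def compute_shape_features(mask: np.ndarray, mpp: float) -> dict:
    """The five shape features of a single region mask, in microns.

    Single-pixel (and other degenerate) regions get a perimeter floor of
    one pixel boundary (4 px) and are flagged.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty region mask")
    props = regionprops(mask.astype(np.uint8))[0]
    area_px = props.area
    perimeter_px = props.perimeter
    flagged = False
    if perimeter_px < 4.0:
        perimeter_px = 4.0
        flagged = True
    area_um2 = area_px * mpp * mpp
    perimeter_um = perimeter_px * mpp
    spot_width = 2.0 * np.sqrt(area_um2 / np.pi)
    minor = props.axis_minor_length * mpp
    major = props.axis_major_length * mpp
    if major <= 0:                      # degenerate moments (single pixel)
        major = minor = spot_width
        flagged = True
    roundness = 4.0 * np.pi * area_um2 / perimeter_um**2
    return {
        "area_px": float(area_px),
        "spot_width_um": float(spot_width),
        "width_um": float(minor),
        "roundness": float(roundness),
        "compactness": float(1.0 / roundness),
        "axis_ratio": float(min(minor / major, 1.0)) if major > 0 else 1.0,
        "flagged": flagged,
        "centroid_xy": (float(props.centroid[1]), float(props.centroid[0])),
    }


def segment_nuclei(
    concentration_maps: np.ndarray,
    protocol: ScoringProtocol,
    mpp: float,
    rgb: np.ndarray | None = None,
) -> list[NucleusRecord]:
    """Segment nuclear regions from deconvolved concentration maps.

    The nuclear signal is haematoxylin + DAB.  Foreground is thresholded
    (protocol threshold, else Otsu), touching nuclei are split by a
    watershed on the distance transform, and regions below the minimum
    area are discarded.  Classes are left unset.
    """
    nuclear = concentration_maps[..., 0] + concentration_maps[..., 1]
    thr = protocol.nuclear_od_threshold
    if thr is None:
        if nuclear.max() <= 0:
            return []
        thr = threshold_otsu(nuclear)
    fg = nuclear > thr
    if not fg.any():
        return []
    min_area_px = max(int(round(protocol.min_nucleus_area_um2 / (mpp * mpp))), 1)
    distance = ndimage.distance_transform_edt(fg)
    min_dist_px = max(int(round(protocol.watershed_min_distance_um / mpp)), 1)
    peaks = peak_local_max(
        distance, min_distance=min_dist_px, labels=fg, exclude_border=False
    )
    markers = np.zeros_like(fg, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    markers, _ = ndimage.label(markers > 0)
    labels = watershed(-distance, markers, mask=fg)

    mean_hem = ndimage.labeled_comprehension(
        concentration_maps[..., 0], labels, np.arange(1, labels.max() + 1), np.mean, float, 0.0
    ) if labels.max() else np.array([])
    mean_dab = ndimage.labeled_comprehension(
        concentration_maps[..., 1], labels, np.arange(1, labels.max() + 1), np.mean, float, 0.0
    ) if labels.max() else np.array([])

    records: list[NucleusRecord] = []
    for props in regionprops(labels):
        if props.area < min_area_px:
            continue
        sl = props.slice
        feats = compute_shape_features(labels[sl] == props.label, mpp)
        # centroid from the full-image frame, not the crop
        cy, cx = props.centroid
        hsi = None
        if rgb is not None:
            region_rgb = rgb[sl][labels[sl] == props.label].astype(float) / 255.0
            hsi = _mean_hsi(region_rgb)
        records.append(
            NucleusRecord(
                label=props.label,
                centroid_xy=(float(cx), float(cy)),
                area_px=feats["area_px"],
                spot_width_um=feats["spot_width_um"],
                width_um=feats["width_um"],
                roundness=feats["roundness"],
                compactness=feats["compactness"],
                axis_ratio=feats["axis_ratio"],
                mean_od_hem=float(mean_hem[props.label - 1]),
                mean_od_dab=float(mean_dab[props.label - 1]),
                mean_hsi=hsi,
                flagged=feats["flagged"],
            )
        )
    return records


def _mean_hsi(rgb: np.ndarray) -> tuple[float, float, float]:
    """Mean hue/saturation/intensity of a set of RGB pixels in [0, 1]."""
    r, g, b = rgb[:, 0], rgb[:, 1], rgb[:, 2]
    mx, mn = rgb.max(axis=1), rgb.min(axis=1)
    delta = mx - mn
    hue = np.zeros_like(mx)
    nz = delta > 0
    rmax = nz & (mx == r)
    gmax = nz & (mx == g) & ~rmax
    bmax = nz & ~rmax & ~gmax
    hue[rmax] = ((g[rmax] - b[rmax]) / delta[rmax]) % 6
    hue[gmax] = (b[gmax] - r[gmax]) / delta[gmax] + 2
    hue[bmax] = (r[bmax] - g[bmax]) / delta[bmax] + 4
    hue /= 6.0
    sat = np.where(mx > 0, delta / np.maximum(mx, 1e-12), 0.0)
    intensity = rgb.mean(axis=1)
    return (float(hue.mean()), float(sat.mean()), float(intensity.mean()))


# --------------------------------------------------------------------------
# classification and scoring
# --------------------------------------------------------------------------

def classify_nuclei(
    records: list[NucleusRecord], protocol: ScoringProtocol
) -> list[NucleusRecord]:
    """Set ``malignant`` and ``positive`` on each record in place.

    A record is malignant iff *every* shape feature lies inside its
    protocol range; positivity is evaluated only for malignant records.
    """
    lo = {k: v[0] for k, v in protocol.shape_ranges.items()}
    hi = {k: v[1] for k, v in protocol.shape_ranges.items()}
    any_malignant_possible = all(lo[k] < hi[k] for k in protocol.shape_ranges)
    if not any_malignant_possible:  # pragma: no cover - guarded in __post_init__
        warnings.warn("protocol defines an empty malignant region", stacklevel=2)
    for rec in records:
        rec.malignant = all(
            lo[name] <= rec.feature(name) <= hi[name] for name in protocol.shape_ranges
        )
        if not rec.malignant:
            rec.positive = False
            continue
        if protocol.positivity_rule == "dab_od":
            rec.positive = rec.mean_od_dab > protocol.dab_od_cut
        else:
            if rec.mean_hsi is None:
                raise ValueError("HSI positivity rule requires records segmented with rgb")
            h, s, i = rec.mean_hsi
            box = protocol.hsi_box
            rec.positive = (
                box["hue"][0] <= h <= box["hue"][1]
                and box["saturation"][0] <= s <= box["saturation"][1]
                and box["intensity"][0] <= i <= box["intensity"][1]
            )
    return records


def analyse_core(
    image: CoreImage, protocol: ScoringProtocol | None = None
) -> tuple[list[NucleusRecord], CoreScore]:
    """Full per-core analysis: classified nucleus records plus the score."""
    protocol = protocol or ScoringProtocol()
    od = od_transform(image)
    conc = deconvolve(od, protocol.stains)
    rgb = image.pixels if protocol.positivity_rule == "hsi" else None
    records = segment_nuclei(conc, protocol, image.mpp, rgb=rgb)
    classify_nuclei(records, protocol)
    n_mal = sum(bool(r.malignant) for r in records)
    n_pos = sum(bool(r.positive) for r in records)
    score = CoreScore(
        core_id=image.core_id,
        patient_id=image.patient_id,
        study_id=image.study_id,
        n_total_malignant=n_mal,
        n_positive=n_pos,
    )
    return records, score


def score_core(image: CoreImage, protocol: ScoringProtocol | None = None) -> CoreScore:
    """Score one core: % KI67-positive among malignant nuclei.

    With zero malignant nuclei the score is undefined (``ki67_pct`` is
    NaN) and ``n_total_malignant = 0`` is recorded for QC to reject.
    """
    _, score = analyse_core(image, protocol)
    return score


# --------------------------------------------------------------------------
# CAV grid counting
# --------------------------------------------------------------------------

@dataclass
class CavResult:
    """Computer-assisted-visual grid counts for one core."""

    tiles: pd.DataFrame            # tile_ix, tile_iy, n_negative, n_positive
    n_counted: int                 # malignant nuclei counted over all tiles
    n_positive: int
    reached_target: bool           # >= target_cells counted
    satisfactory: bool             # > 500 cells counted
    ki67_pct: float
    cumulative: pd.DataFrame       # raster-order running totals


def cav_grid_count(
    image_or_records,
    protocol: ScoringProtocol | None = None,
    grid_side_um: float = 250.0,
    target_cells: int = 1000,
    satisfactory_cells: int = 500,
    mpp: float | None = None,
) -> CavResult:
    """Emulate CAV counting on a 250 um grid.

    Tiles the core into ``grid_side_um`` squares (half-open
    ``[x, x + side)`` in microns, so each nucleus falls in exactly one
    tile by its centroid) and accumulates negative/positive malignant
    counts tile by tile in raster order.  Reports whether at least
    ``target_cells`` were counted and whether the core exceeds the
    ``satisfactory_cells`` quality bar.

    Accepts either a :class:`CoreImage` (scored with ``protocol``) or a
    pre-classified record list (then ``mpp`` is required).
    """
    if isinstance(image_or_records, CoreImage):
        records, _ = analyse_core(image_or_records, protocol)
        mpp = image_or_records.mpp
        extent = (image_or_records.pixels.shape[1], image_or_records.pixels.shape[0])
    else:
        records = image_or_records
        if mpp is None:
            raise ValueError("mpp is required when passing records directly")
        if records:
            extent = (
                max(r.centroid_xy[0] for r in records) + 1,
                max(r.centroid_xy[1] for r in records) + 1,
            )
        else:
            extent = (1, 1)

    side_px = grid_side_um / mpp
    nx = max(int(np.ceil(extent[0] / side_px)), 1)
    ny = max(int(np.ceil(extent[1] / side_px)), 1)

    counts = {}
    for rec in records:
        if not rec.malignant:
            continue
        ix = min(int(rec.centroid_xy[0] // side_px), nx - 1)
        iy = min(int(rec.centroid_xy[1] // side_px), ny - 1)
        neg, pos = counts.get((ix, iy), (0, 0))
        if rec.positive:
            counts[(ix, iy)] = (neg, pos + 1)
        else:
            counts[(ix, iy)] = (neg + 1, pos)

    rows, cum_rows = [], []
    tot_neg = tot_pos = 0
    for iy in range(ny):                     # fixed raster order
        for ix in range(nx):
            neg, pos = counts.get((ix, iy), (0, 0))
            rows.append({"tile_ix": ix, "tile_iy": iy, "n_negative": neg, "n_positive": pos})
            tot_neg += neg
            tot_pos += pos
            cum_rows.append(
                {"tile_ix": ix, "tile_iy": iy, "cum_counted": tot_neg + tot_pos,
                 "cum_positive": tot_pos}
            )
    n_counted = tot_neg + tot_pos
    return CavResult(
        tiles=pd.DataFrame(rows),
        n_counted=n_counted,
        n_positive=tot_pos,
        reached_target=n_counted >= target_cells,
        satisfactory=n_counted > satisfactory_cells,
        ki67_pct=100.0 * tot_pos / n_counted if n_counted else float("nan"),
        cumulative=pd.DataFrame(cum_rows),
    )


# --------------------------------------------------------------------------
# protocol calibration
# --------------------------------------------------------------------------

def calibrate_protocol(
    records: list[NucleusRecord],
    truth_malignant: np.ndarray,
    base: ScoringProtocol | None = None,
    quantile_grid: tuple[float, ...] = (0.001, 0.005, 0.01, 0.02, 0.05),
) -> ScoringProtocol:
    """Fit malignant shape ranges on a labelled training set.

    For each candidate tail quantile ``q`` the malignant window of every
    feature is set to the (q, 1-q) quantiles of the malignant training
    class; the grid search keeps the ``q`` maximising training-class
    accuracy.  This mirrors protocol training on a labelled subset of
    cores before scoring the full collection.
    """
    truth_malignant = np.asarray(truth_malignant, dtype=bool)
    if len(records) != len(truth_malignant):
        raise ValueError("records and labels must align")
    if truth_malignant.sum() < 5:
        raise ValueError("need at least 5 malignant training nuclei")
    feats = {
        name: np.array([r.feature(name) for r in records]) for name in FEATURE_NAMES
    }
    base = base or ScoringProtocol()
    best_q, best_acc, best_ranges = None, -1.0, None
    for q in quantile_grid:
        ranges = {}
        for name in FEATURE_NAMES:
            vals = feats[name][truth_malignant]
            lo, hi = np.quantile(vals, [q, 1 - q])
            pad = 0.02 * max(hi - lo, 1e-6)
            ranges[name] = (float(lo - pad), float(hi + pad))
        pred = np.ones(len(records), dtype=bool)
        for name, (lo, hi) in ranges.items():
            pred &= (feats[name] >= lo) & (feats[name] <= hi)
        acc = float(np.mean(pred == truth_malignant))
        if acc > best_acc:
            best_q, best_acc, best_ranges = q, acc, ranges
    return dataclasses.replace(base, shape_ranges=best_ranges)


def scores_to_frame(scores: list[CoreScore]) -> pd.DataFrame:
    """Per-core score table with the documented CSV columns."""
    return pd.DataFrame(
        {
            "core_id": [s.core_id for s in scores],
            "patient_id": [s.patient_id for s in scores],
            "study_id": [s.study_id for s in scores],
            "n_total": [s.n_total_malignant for s in scores],
            "n_positive": [s.n_positive for s in scores],
            "ki67_pct": [s.ki67_pct for s in scores],
            "counted_cells_flag": [
                "satisfactory" if s.n_total_malignant > 500 else "low_count"
                for s in scores
            ],
        }
    )
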