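"""Plan-complexity metrics and their encoding into the model feature vector.

The metrics quantify how "difficult" an MLC-modulated beam is to deliver and
measure: aperture area and perimeter of the complete irradiated area outline
(CIAO), the prevalence of small leaf gaps, how much of the fluence sits at low
levels, how irregular and off-axis the apertures are, how much area is exposed
only through penumbra, and the duty cycle (MU per cGy).  Continuous metrics
are combined with the categorical context (QA device, energy, machine, MLC
model) and one-hot binned families into a single feature vector whose first
element is the intercept (always 1).  The default encoding has 91 entries.

Geometry is computed on a binary aperture raster at the isocenter plane
(default 1 mm pixels).  A pixel is open when its center lies strictly between
the two leaves of its pair and inside the jaw rectangle.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage import measure

from .plans import (
    ENERGIES,
    MACHINE_TYPES,
    MLC_MODELS,
    QA_DEVICES,
    Beam,
    ControlPoint,
    Plan,
)

__all__ = [
    "ApertureMask",
    "FluenceGrid",
    "FeatureVector",
    "FeatureConfig",
    "DEFAULT_CONFIG",
    "rasterize_aperture",
    "accumulate_fluence",
    "ciao",
    "small_aperture_score",
    "fluence_level_fractions",
    "radius_fractions",
    "shape_irregularity",
    "penumbra_fraction",
    "mask_area_cm2",
    "mask_perimeter_cm",
    "duty_cycle",
    "bin_encode",
    "bin_labels",
    "beam_metrics",
    "assemble_feature_vector",
    "extract_features",
    "FeatureError",
    "DegenerateFluenceError",
]


class FeatureError(ValueError):
    """A metric could not be computed (empty mask, bad input)."""


class DegenerateFluenceError(FeatureError):
    """The beam never opens: the fluence grid is identically zero."""


# ---------------------------------------------------------------------------
# Grids and masks
# ---------------------------------------------------------------------------

@dataclass
class ApertureMask:
    """Binary occupancy of the open aperture on a pixel grid (mm units).

    ``origin`` is the (x, y) coordinate of the center of pixel [0, 0];
    ``values`` is indexed [iy, ix].
    """

    origin: tuple[float, float]
    spacing: float
    values: np.ndarray

    @property
    def open_pixels(self) -> int:
        return int(self.values.sum())

    def pixel_centers(self):
        ny, nx = self.values.shape
        xs = self.origin[0] + np.arange(nx) * self.spacing
        ys = self.origin[1] + np.arange(ny) * self.spacing
        return xs, ys


@dataclass
class FluenceGrid:
    """MU-weighted aperture accumulation, normalised to max 1 when nonzero."""

    origin: tuple[float, float]
    spacing: float
    values: np.ndarray
    degenerate: bool = False


@dataclass
class FeatureVector:
    """Named, ordered feature values; element 0 is the intercept (=1)."""

    names: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != len(self.values):
            raise ValueError("names and values length mismatch")
        if self.names[0] != "intercept" or self.values[0] != 1.0:
            raise ValueError("feature vector must start with intercept = 1")

    def __len__(self) -> int:
        return len(self.values)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def _beam_bbox(beam: Beam) -> tuple[float, float, float, float]:
    """Bounding box (xmin, xmax, ymin, ymax) covering every jaw rectangle,
    clipped in y to the MLC leaf-boundary extent."""
    x1 = min(cp.jaw_x1 for cp in beam.control_points)
    x2 = max(cp.jaw_x2 for cp in beam.control_points)
    y1 = max(min(cp.jaw_y1 for cp in beam.control_points),
             beam.leaf_boundaries[0])
    y2 = min(max(cp.jaw_y2 for cp in beam.control_points),
             beam.leaf_boundaries[-1])
    return x1, x2, y1, y2


def _make_grid(bbox, spacing):
    x1, x2, y1, y2 = bbox
    nx = max(int(np.ceil((x2 - x1) / spacing)), 1)
    ny = max(int(np.ceil((y2 - y1) / spacing)), 1)
    origin = (x1 + spacing / 2.0, y1 + spacing / 2.0)
    return origin, nx, ny


def rasterize_aperture(cp: ControlPoint, leaf_boundaries, spacing: float = 1.0,
                       bbox: tuple | None = None) -> ApertureMask:
    """Rasterize one control point's open aperture.

    A pixel is open iff its center is strictly between bank_a and bank_b of
    the leaf pair covering its y coordinate and inside the jaw rectangle.
    An all-closed aperture yields an empty (all-False) mask, not an error.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    leaf_boundaries = np.asarray(leaf_boundaries, dtype=float)
    if bbox is None:
        bbox = (cp.jaw_x1, cp.jaw_x2,
                max(cp.jaw_y1, leaf_boundaries[0]),
                min(cp.jaw_y2, leaf_boundaries[-1]))
    origin, nx, ny = _make_grid(bbox, spacing)
    xs = origin[0] + np.arange(nx) * spacing
    ys = origin[1] + np.arange(ny) * spacing

    pair = np.searchsorted(leaf_boundaries, ys, side="right") - 1
    valid = (pair >= 0) & (pair < len(leaf_boundaries) - 1)
    pair_c = np.clip(pair, 0, len(leaf_boundaries) - 2)
    a = cp.leaf_positions_bank_a[pair_c][:, None]
    b = cp.leaf_positions_bank_b[pair_c][:, None]
    X = xs[None, :]
    open_ = (X > a) & (X < b)
    open_ &= valid[:, None]
    open_ &= (X >= cp.jaw_x1) & (X <= cp.jaw_x2)
    open_ &= ((ys >= cp.jaw_y1) & (ys <= cp.jaw_y2))[:, None]
    return ApertureMask(origin=origin, spacing=spacing, values=open_)


def mask_area_cm2(mask: ApertureMask) -> float:
    return mask.open_pixels * mask.spacing ** 2 / 100.0


_PERIMETER_SIGMA_PX = 1.5


def _contour_length_px(img: np.ndarray) -> float:
    total = 0.0
    for contour in measure.find_contours(img, 0.5):
        total += np.sum(np.hypot(*np.diff(contour, axis=0).T))
    return total


def mask_perimeter_cm(mask: ApertureMask) -> float:
    """Boundary length of the open region via sub-pixel contouring.

    Contours are taken at the 0.5 level of the lightly Gaussian-smoothed
    indicator (marching squares): smoothing recovers sub-pixel boundary
    positions, so the estimate converges at O(spacing) for both polygonal
    and curved shapes, and is additive over well-separated components.
    Apertures thinner than about two pixels can vanish under smoothing;
    the raw binary contour is used as a fallback there (a slight
    staircase-induced overestimate on curved boundaries).
    """
    if mask.open_pixels == 0:
        raise FeatureError("perimeter of an empty mask is undefined")
    pad = int(4 * _PERIMETER_SIGMA_PX) + 2
    padded = np.pad(mask.values.astype(float), pad)
    smoothed = ndimage.gaussian_filter(padded, _PERIMETER_SIGMA_PX)
    total = _contour_length_px(smoothed)
    if total == 0.0:  # thin aperture erased by smoothing
        total = _contour_length_px(np.pad(mask.values.astype(float), 1))
    return total * mask.spacing / 10.0


def accumulate_fluence(beam: Beam, spacing: float = 1.0,
                       mode: str = "start") -> FluenceGrid:
    """MU-fraction-weighted accumulation of apertures over a beam.

    ``mode='start'`` (step-and-shoot convention) exposes each interval through
    the aperture of its starting control point; ``mode='mid'`` averages the
    interval's endpoint apertures (sliding-window delivery).  The result is
    normalised so its maximum is 1; a beam that never opens is returned as a
    zero grid flagged degenerate.
    """
    if len(beam.control_points) < 2:
        raise FeatureError("fluence needs >= 2 control points")
    if mode not in ("start", "mid"):
        raise ValueError(f"unknown fluence mode {mode!r}")
    bbox = _beam_bbox(beam)
    origin, nx, ny = _make_grid(bbox, spacing)
    masks = [rasterize_aperture(cp, beam.leaf_boundaries, spacing, bbox)
             for cp in beam.control_points]
    total = np.zeros((ny, nx))
    dmu = beam.interval_weights()
    for k, d in enumerate(dmu):
        if d <= 0:
            continue
        if mode == "start":
            contrib = masks[k].values.astype(float)
        else:
            contrib = 0.5 * (masks[k].values + masks[k + 1].values)
        total += d * contrib
    peak = total.max()
    if peak <= 0:
        return FluenceGrid(origin, spacing, total, degenerate=True)
    return FluenceGrid(origin, spacing, total / peak)


def ciao(beam: Beam, spacing: float = 1.0) -> ApertureMask:
    """Complete irradiated area outline: union of all jaw-clipped apertures."""
    bbox = _beam_bbox(beam)
    origin, nx, ny = _make_grid(bbox, spacing)
    union = np.zeros((ny, nx), dtype=bool)
    for cp in beam.control_points:
        union |= rasterize_aperture(cp, beam.leaf_boundaries, spacing, bbox).values
    return ApertureMask(origin=origin, spacing=spacing, values=union)


# ---------------------------------------------------------------------------
# Leaf-gap metrics
# ---------------------------------------------------------------------------

def _counted_gaps(cp: ControlPoint, leaf_boundaries, min_gap_mm: float):
    """Gaps of leaf pairs that are genuinely part of the aperture: gap above
    the park threshold and pair midline inside the jaw y-opening."""
    centers = 0.5 * (leaf_boundaries[:-1] + leaf_boundaries[1:])
    gaps = cp.gaps
    counted = (gaps > min_gap_mm) & (centers >= cp.jaw_y1) & (centers <= cp.jaw_y2)
    return gaps[counted]


def small_aperture_score(beam: Beam, gap_thresholds: Sequence[float],
                         min_gap_mm: float = 0.5):
    """ΔMU-weighted fraction of counted leaf gaps below each threshold.

    Control points with no counted gaps are excluded (weights renormalised);
    returns None per threshold when no control point has a counted gap.
    """
    if any(t <= 0 for t in gap_thresholds):
        raise ValueError("gap thresholds must be positive")
    w = beam.control_point_weights()
    fracs = np.zeros((len(beam.control_points), len(gap_thresholds)))
    has = np.zeros(len(beam.control_points), dtype=bool)
    for k, cp in enumerate(beam.control_points):
        g = _counted_gaps(cp, beam.leaf_boundaries, min_gap_mm)
        if g.size:
            has[k] = True
            fracs[k] = [np.mean(g < t) for t in gap_thresholds]
    if not has.any() or w[has].sum() <= 0:
        return [None] * len(gap_thresholds)
    wn = w[has] / w[has].sum()
    out = wn @ fracs[has]
    return [float(v) for v in out]


def gap_statistics(beam: Beam, min_gap_mm: float = 0.5):
    """ΔMU-weighted mean and standard deviation of counted leaf gaps (mm).

    Each counted gap at a control point shares that control point's ΔMU
    weight equally.  Returns (nan, nan) if no gaps are ever counted.
    """
    w = beam.control_point_weights()
    vals, wts = [], []
    for k, cp in enumerate(beam.control_points):
        g = _counted_gaps(cp, beam.leaf_boundaries, min_gap_mm)
        if g.size and w[k] > 0:
            vals.append(g)
            wts.append(np.full(g.size, w[k] / g.size))
    if not vals:
        return float("nan"), float("nan")
    v = np.concatenate(vals)
    ww = np.concatenate(wts)
    ww = ww / ww.sum()
    mean = float(ww @ v)
    var = float(ww @ (v - mean) ** 2)
    return mean, float(np.sqrt(var))


# ---------------------------------------------------------------------------
# Fluence / shape metrics
# ---------------------------------------------------------------------------

def fluence_level_fractions(fluence: FluenceGrid,
                            levels: Sequence[float]) -> list[float]:
    """Fraction of the evaluated area at or above each fluence level.

    Levels are percent of the peak; the denominator is the area at or above
    the 10% measurement threshold, mirroring how QA analyses exclude
    low-signal pixels.
    """
    if fluence.degenerate:
        raise DegenerateFluenceError("fluence grid is identically zero")
    denom = np.count_nonzero(fluence.values >= 0.10)
    if denom == 0:
        raise DegenerateFluenceError("no pixels at or above the 10% level")
    return [float(np.count_nonzero(fluence.values >= lv / 100.0) / denom)
            for lv in levels]


def radius_fractions(mask: ApertureMask, radii_cm: Sequence[float],
                     center: tuple[float, float] = (0.0, 0.0)) -> list[float]:
    """Fraction of open area farther than each radius from the central axis."""
    if mask.open_pixels == 0:
        raise FeatureError("radius fractions of an empty mask are undefined")
    xs, ys = mask.pixel_centers()
    dist = np.hypot(xs[None, :] - center[0], ys[:, None] - center[1])
    open_ = mask.values
    n = open_.sum()
    return [float(np.count_nonzero(open_ & (dist > r * 10.0)) / n)
            for r in radii_cm]


def shape_irregularity(mask: ApertureMask) -> float:
    """Isoperimetric quotient P^2 / (4 pi A): 1 for a disc, larger for
    elongated or ragged apertures."""
    area = mask_area_cm2(mask)
    if area <= 0:
        raise FeatureError("shape irregularity of an empty mask is undefined")
    per = mask_perimeter_cm(mask)
    return per ** 2 / (4.0 * np.pi * area)


def penumbra_fraction(beam: Beam, margin_mm: float = 5.0,
                      spacing: float = 1.0) -> float:
    """ΔMU-weighted fraction of aperture area within ``margin_mm`` of the
    aperture edge (the inner morphological band that only sees penumbra)."""
    if margin_mm < 0:
        raise ValueError("margin must be >= 0")
    bbox = _beam_bbox(beam)
    w = beam.control_point_weights()
    fracs, wts = [], []
    for k, cp in enumerate(beam.control_points):
        m = rasterize_aperture(cp, beam.leaf_boundaries, spacing, bbox)
        if m.open_pixels == 0 or w[k] <= 0:
            continue
        dist = ndimage.distance_transform_edt(
            np.pad(m.values, 1)) * spacing
        band = (dist[1:-1, 1:-1] <= margin_mm) & m.values
        fracs.append(band.sum() / m.open_pixels)
        wts.append(w[k])
    if not fracs:
        raise FeatureError("beam has no open apertures")
    wts = np.asarray(wts) / np.sum(wts)
    return float(wts @ np.asarray(fracs))


def aperture_statistics(beam: Beam, spacing: float = 1.0):
    """ΔMU-weighted mean/std of per-control-point aperture area (cm^2) and
    mean aperture perimeter (cm); shape irregularity weighted mean."""
    bbox = _beam_bbox(beam)
    w = beam.control_point_weights()
    areas, pers, irr, wts = [], [], [], []
    for k, cp in enumerate(beam.control_points):
        m = rasterize_aperture(cp, beam.leaf_boundaries, spacing, bbox)
        if m.open_pixels == 0 or w[k] <= 0:
            continue
        areas.append(mask_area_cm2(m))
        pers.append(mask_perimeter_cm(m))
        irr.append(shape_irregularity(m))
        wts.append(w[k])
    if not areas:
        raise FeatureError("beam has no open apertures")
    wts = np.asarray(wts) / np.sum(wts)
    areas = np.asarray(areas)
    mean_area = float(wts @ areas)
    std_area = float(np.sqrt(wts @ (areas - mean_area) ** 2))
    return {
        "mean_aperture_area_cm2": mean_area,
        "std_aperture_area_cm2": std_area,
        "mean_aperture_perimeter_cm": float(wts @ np.asarray(pers)),
        "shape_irregularity": float(wts @ np.asarray(irr)),
    }


def duty_cycle(total_mu: float, dose_per_fraction: float) -> float:
    """Monitor units delivered per cGy of prescribed dose."""
    if dose_per_fraction <= 0:
        raise ValueError("dose_per_fraction must be > 0")
    return total_mu / dose_per_fraction


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def bin_labels(prefix: str, edges: Sequence[float]) -> list[str]:
    def f(e):
        return format(e, "g").replace(".", "p").replace("-", "m")
    labels = [f"{prefix}_lt_{f(edges[0])}"]
    labels += [f"{prefix}_{f(a)}_{f(b)}" for a, b in zip(edges[:-1], edges[1:])]
    labels.append(f"{prefix}_ge_{f(edges[-1])}")
    return labels


def bin_encode(value: float, edges: Sequence[float]) -> np.ndarray:
    """One-hot encode into len(edges)+1 left-closed right-open intervals
    (-inf, e0), [e0, e1), ..., [e_last, inf)."""
    if not np.isfinite(value):
        raise ValueError(f"cannot bin non-finite value {value}")
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    out = np.zeros(len(edges) + 1)
    out[int(np.searchsorted(edges, value, side="right"))] = 1.0
    return out


def _onehot(value: str, levels: Sequence[str], what: str) -> np.ndarray:
    if value not in levels:
        raise FeatureError(f"unknown {what} {value!r} (levels: {list(levels)})")
    out = np.zeros(len(levels))
    out[list(levels).index(value)] = 1.0
    return out


@dataclass(frozen=True)
class FeatureConfig:
    """Everything that fixes the feature encoding.

    Bin edges follow the clinical binning conventions for each family; the
    duty-cycle family uses contiguous edges at 2, 3, 4, 5, 6 MU/cGy.  Two
    configs with equal ``hash()`` produce identical feature vectors for the
    same plan.
    """

    grid_spacing_mm: float = 1.0
    ciao_area_edges_cm2: tuple = (5, 10, 15, 20, 25, 30)
    jaw_opening_edges_cm: tuple = (5, 10, 15, 20, 25)
    perimeter_edges_cm: tuple = (10, 30, 50, 70, 90, 110)
    duty_cycle_edges: tuple = (2, 3, 4, 5, 6)
    gap_thresholds_mm: tuple = (2, 5, 10, 20)
    min_counted_gap_mm: float = 0.5
    fluence_levels_pct: tuple = (10, 20, 30, 40, 50)
    irregularity_radii_cm: tuple = (5, 10, 20)
    penumbra_margin_mm: float = 5.0
    fluence_mode: str = "start"
    modulation_edges: tuple = (3.0, 5.0)   # duty-cycle cuts for levels 1/2/3
    fraction_bin_edges: tuple = (1 / 3, 2 / 3)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    # -- canonical layout -------------------------------------------------

    def feature_names(self) -> list[str]:
        names = ["intercept"]
        names += [f"qa_device_{v}" for v in QA_DEVICES]
        names += [f"energy_{v}" for v in ENERGIES]
        names += [f"machine_{v}" for v in MACHINE_TYPES]
        names += [f"mlc_{v}" for v in MLC_MODELS]
        names += [f"modulation_{k}" for k in (1, 2, 3)]
        names += ["collimator_angle_mean_deg"]
        names += bin_labels("ciao_area", self.ciao_area_edges_cm2)
        names += ["ciao_area_cm2"]
        names += bin_labels("jaw_opening", self.jaw_opening_edges_cm)
        names += ["jaw_x_opening_cm", "jaw_y_opening_cm"]
        names += bin_labels("perimeter", self.perimeter_edges_cm)
        names += ["perimeter_cm"]
        names += bin_labels("duty_cycle", self.duty_cycle_edges)
        names += ["duty_cycle_mu_per_cgy", "total_mu"]
        names += [f"small_aperture_lt_{t}mm" for t in self.gap_thresholds_mm]
        names += ["mean_gap_mm", "std_gap_mm"]
        names += [f"fluence_ge_{lv}pct" for lv in self.fluence_levels_pct]
        names += [f"fluence_lt_{lv}pct" for lv in self.fluence_levels_pct[1:]]
        names += [f"irregularity_outside_{r}cm"
                  for r in self.irregularity_radii_cm]
        names += ["shape_irregularity", "penumbra_fraction"]
        names += ["mean_aperture_area_cm2", "std_aperture_area_cm2",
                  "mean_aperture_perimeter_cm"]
        for m in self._binned_fraction_metrics():
            names += [f"{m}_bin_low", f"{m}_bin_mid", f"{m}_bin_high"]
        names += ["small_aperture_undefined"]
        return names

    def _binned_fraction_metrics(self) -> list[str]:
        top = self.fluence_levels_pct[-1]
        return ([f"small_aperture_lt_{t}mm" for t in self.gap_thresholds_mm]
                + [f"fluence_lt_{top}pct", "penumbra_fraction"])

    def one_hot_groups(self) -> list[list[str]]:
        """Groups of indicator features, each of which sums to exactly 1."""
        groups = [
            [f"qa_device_{v}" for v in QA_DEVICES],
            [f"energy_{v}" for v in ENERGIES],
            [f"machine_{v}" for v in MACHINE_TYPES],
            [f"mlc_{v}" for v in MLC_MODELS],
            [f"modulation_{k}" for k in (1, 2, 3)],
            bin_labels("ciao_area", self.ciao_area_edges_cm2),
            bin_labels("jaw_opening", self.jaw_opening_edges_cm),
            bin_labels("perimeter", self.perimeter_edges_cm),
            bin_labels("duty_cycle", self.duty_cycle_edges),
        ]
        for m in self._binned_fraction_metrics():
            groups.append([f"{m}_bin_low", f"{m}_bin_mid", f"{m}_bin_high"])
        return groups

    def fraction_feature_names(self) -> list[str]:
        """Continuous features guaranteed to lie in [0, 1]."""
        names = [f"small_aperture_lt_{t}mm" for t in self.gap_thresholds_mm]
        names += [f"fluence_ge_{lv}pct" for lv in self.fluence_levels_pct]
        names += [f"fluence_lt_{lv}pct" for lv in self.fluence_levels_pct[1:]]
        names += [f"irregularity_outside_{r}cm"
                  for r in self.irregularity_radii_cm]
        names += ["penumbra_fraction", "small_aperture_undefined"]
        return names


DEFAULT_CONFIG = FeatureConfig()


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def beam_metrics(beam: Beam, config: FeatureConfig = DEFAULT_CONFIG) -> dict:
    """All continuous complexity metrics for one beam (pre-encoding)."""
    s = config.grid_spacing_mm
    ciao_mask = ciao(beam, s)
    if ciao_mask.open_pixels == 0:
        raise FeatureError(f"beam {beam.beam_id}: no open aperture anywhere")
    fl = accumulate_fluence(beam, s, config.fluence_mode)
    fge = fluence_level_fractions(fl, config.fluence_levels_pct)
    scores = small_aperture_score(beam, config.gap_thresholds_mm,
                                  config.min_counted_gap_mm)
    undefined = scores[0] is None
    mean_gap, std_gap = gap_statistics(beam, config.min_counted_gap_mm)
    ap = aperture_statistics(beam, s)
    cw = beam.control_point_weights()
    angles = np.array([cp.collimator_angle for cp in beam.control_points])
    jaw_x = max(cp.jaw_x2 - cp.jaw_x1 for cp in beam.control_points) / 10.0
    jaw_y = max(cp.jaw_y2 - cp.jaw_y1 for cp in beam.control_points) / 10.0

    m = {
        "collimator_angle_mean_deg": float(cw @ angles),
        "ciao_area_cm2": mask_area_cm2(ciao_mask),
        "perimeter_cm": mask_perimeter_cm(ciao_mask),
        "jaw_x_opening_cm": jaw_x,
        "jaw_y_opening_cm": jaw_y,
        "total_mu": beam.total_mu,
        "mean_gap_mm": 0.0 if undefined else mean_gap,
        "std_gap_mm": 0.0 if undefined else std_gap,
        "penumbra_fraction": penumbra_fraction(
            beam, config.penumbra_margin_mm, s),
        "small_aperture_undefined": 1.0 if undefined else 0.0,
    }
    for t, v in zip(config.gap_thresholds_mm, scores):
        m[f"small_aperture_lt_{t}mm"] = 0.0 if v is None else v
    for lv, v in zip(config.fluence_levels_pct, fge):
        m[f"fluence_ge_{lv}pct"] = v
    for lv, v in zip(config.fluence_levels_pct[1:], fge[1:]):
        m[f"fluence_lt_{lv}pct"] = 1.0 - v
    for r, v in zip(config.irregularity_radii_cm,
                    radius_fractions(ciao_mask, config.irregularity_radii_cm)):
        m[f"irregularity_outside_{r}cm"] = v
    m.update(ap)
    return m


def _aggregate_plan_metrics(plan: Plan, config: FeatureConfig) -> dict:
    """MU-weighted aggregation of per-beam continuous metrics (before any
    binning), as composite-plan QA measures the whole delivery at once."""
    mus = np.array([b.total_mu for b in plan.beams], dtype=float)
    w = mus / mus.sum()
    per_beam = [beam_metrics(b, config) for b in plan.beams]
    agg: dict[str, float] = {}
    for key in per_beam[0]:
        agg[key] = float(w @ np.array([m[key] for m in per_beam]))
    # flags/extensive quantities are not averages
    agg["total_mu"] = plan.total_mu
    agg["small_aperture_undefined"] = float(
        all(m["small_aperture_undefined"] == 1.0 for m in per_beam))
    return agg


def _encode(metrics: dict, *, qa_device: str, energy: str, machine: str,
            mlc_model: str, duty: float, config: FeatureConfig,
            modulation_override: int | None = None) -> FeatureVector:
    if modulation_override is not None:
        mod = int(modulation_override)
    else:
        mod = 1 + int(np.searchsorted(
            np.asarray(config.modulation_edges, dtype=float), duty,
            side="right"))
    if mod not in (1, 2, 3):
        raise FeatureError(f"modulation level {mod} outside 1..3")

    parts = [np.array([1.0]),
             _onehot(qa_device, QA_DEVICES, "QA device"),
             _onehot(energy, ENERGIES, "energy"),
             _onehot(machine, MACHINE_TYPES, "machine type"),
             _onehot(mlc_model, MLC_MODELS, "MLC model"),
             _onehot(str(mod), ("1", "2", "3"), "modulation level"),
             np.array([metrics["collimator_angle_mean_deg"]]),
             bin_encode(metrics["ciao_area_cm2"], config.ciao_area_edges_cm2),
             np.array([metrics["ciao_area_cm2"]]),
             bin_encode(max(metrics["jaw_x_opening_cm"],
                            metrics["jaw_y_opening_cm"]),
                        config.jaw_opening_edges_cm),
             np.array([metrics["jaw_x_opening_cm"],
                       metrics["jaw_y_opening_cm"]]),
             bin_encode(metrics["perimeter_cm"], config.perimeter_edges_cm),
             np.array([metrics["perimeter_cm"]]),
             bin_encode(duty, config.duty_cycle_edges),
             np.array([duty, metrics["total_mu"]]),
             np.array([metrics[f"small_aperture_lt_{t}mm"]
                       for t in config.gap_thresholds_mm]),
             np.array([metrics["mean_gap_mm"], metrics["std_gap_mm"]]),
             np.array([metrics[f"fluence_ge_{lv}pct"]
                       for lv in config.fluence_levels_pct]),
             np.array([metrics[f"fluence_lt_{lv}pct"]
                       for lv in config.fluence_levels_pct[1:]]),
             np.array([metrics[f"irregularity_outside_{r}cm"]
                       for r in config.irregularity_radii_cm]),
             np.array([metrics["shape_irregularity"],
                       metrics["penumbra_fraction"],
                       metrics["mean_aperture_area_cm2"],
                       metrics["std_aperture_area_cm2"],
                       metrics["mean_aperture_perimeter_cm"]])]
    for name in config._binned_fraction_metrics():
        parts.append(bin_encode(metrics[name], config.fraction_bin_edges))
    parts.append(np.array([metrics["small_aperture_undefined"]]))
    values = np.concatenate(parts)
    names = config.feature_names()
    if len(values) != len(names):
        raise AssertionError(
            f"encoded {len(values)} values for {len(names)} names")
    return FeatureVector(names=names, values=values)


def assemble_feature_vector(obj, config: FeatureConfig = DEFAULT_CONFIG,
                            plan: Plan | None = None,
                            modulation_override: int | None = None
                            ) -> FeatureVector:
    """Build the model feature vector for a Plan, or for one Beam of a plan.

    Pass a :class:`Plan` for composite-plan units (continuous metrics are
    MU-weighted across beams before binning) or a :class:`Beam` together with
    its owning ``plan`` (QA device and prescription context) for per-beam
    units.  Pure function of (input, config).
    """
    try:
        if isinstance(obj, Plan):
            metrics = _aggregate_plan_metrics(obj, config)
            duty = duty_cycle(obj.total_mu, obj.dose_per_fraction)
            first = obj.beams[0]
            return _encode(metrics, qa_device=obj.qa_device,
                           energy=first.energy, machine=first.machine_type,
                           mlc_model=first.mlc_model, duty=duty, config=config,
                           modulation_override=modulation_override)
        if isinstance(obj, Beam):
            if plan is None:
                raise ValueError(
                    "beam-level assembly needs the owning plan for context")
            metrics = beam_metrics(obj, config)
            duty = duty_cycle(obj.total_mu, plan.dose_per_fraction)
            return _encode(metrics, qa_device=plan.qa_device,
                           energy=obj.energy, machine=obj.machine_type,
                           mlc_model=obj.mlc_model, duty=duty, config=config,
                           modulation_override=modulation_override)
    except FeatureError:
        raise
    except ValueError as exc:
        raise FeatureError(str(exc)) from exc
    raise TypeError(f"expected Plan or Beam, got {type(obj).__name__}")


def extract_features(plans: Sequence[Plan],
                     config: FeatureConfig = DEFAULT_CONFIG,
                     granularity: str = "plan"):
    """Feature table for a batch of plans.

    granularity='plan' yields one row per plan (unit_id = plan_id);
    granularity='beam' yields one row per beam (unit_id = plan_id/beam_id).
    Returns (DataFrame, failures) where failures maps unit_id -> error text.
    """
    import pandas as pd

    rows, ids, failures = [], [], {}
    for plan in plans:
        if granularity == "plan":
            units = [(plan.plan_id, plan, None)]
        elif granularity == "beam":
            units = [(f"{plan.plan_id}/{b.beam_id}", b, plan)
                     for b in plan.beams]
        else:
            raise ValueError(f"unknown granularity {granularity!r}")
        for unit_id, obj, ctx in units:
            try:
                fv = assemble_feature_vector(obj, config, plan=ctx)
            except (FeatureError, ValueError) as exc:
                failures[unit_id] = str(exc)
                continue
            rows.append(fv.values)
            ids.append(unit_id)
    df = pd.DataFrame(rows, columns=config.feature_names())
    df.insert(0, "unit_id", ids)
    return df, failures
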