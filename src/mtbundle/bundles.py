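"""Filament axis models, bundled-pair detection and bundle statistics.

Works in the math-convention micrograph frame, in nm.  A filament's axis is
a total-least-squares line through its segment coordinates (first principal
component); two filaments in the same micrograph form a candidate bundled
pair when their axes run close together (small edge gap) over a substantial
mutual overlap.  Pairs are classified parallel/antiparallel from the angle
between the two consensus plus-end directions, and the inter-filament
spacing is reported both center-to-center and as the wall-to-wall edge gap
(center distance minus the microtubule outer diameter, 25 nm by default —
the reported minimum gaps of a few nm are only meaningful wall-to-wall).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULT_CONFIG, RunConfig
from .polarity import PolarityResult
from .star_io import FilamentTrace


class BundleError(ValueError):
    pass


@dataclass
class AxisModel:
    """Total-least-squares line model of one filament axis (nm, math frame)."""

    centroid: np.ndarray          # (2,)
    direction: np.ndarray         # unit (2,)
    t_min: float                  # param range of the data along the axis
    t_max: float
    residual_nm: float            # rms perpendicular residual
    points: np.ndarray = field(repr=False, default=None)  # ordered polyline
    filament_id: tuple[str, int] | None = None

    @property
    def arclength_nm(self) -> float:
        return self.t_max - self.t_min

    def point_at(self, t: float) -> np.ndarray:
        return self.centroid + t * self.direction

    def perp_distance(self, pts: np.ndarray) -> np.ndarray:
        """Unsigned perpendicular distance of points to the infinite line."""
        d = np.atleast_2d(pts) - self.centroid
        n = np.array([-self.direction[1], self.direction[0]])
        return np.abs(d @ n)


@dataclass
class BundlePair:
    """Two bundled filaments with orientation class and spacing."""

    id_a: tuple[str, int]
    id_b: tuple[str, int]
    orientation_class: str            # parallel | antiparallel | ambiguous
    angle_between_deg: float          # in [0, 180]
    center_distance_nm: float
    edge_gap_nm: float
    overlap_fraction: float
    overlapping_walls: bool = False   # edge gap < 0


@dataclass
class BundleSummary:
    n_total: int
    n_parallel: int
    n_antiparallel: int
    n_ambiguous: int
    fraction_parallel: float
    binomial_p: float
    gap_min_nm: float
    gap_max_nm: float
    gap_mean_nm: float
    gap_sd_nm: float
    hist_edges_nm: np.ndarray
    hist_counts: np.ndarray

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()
             if k not in ("hist_edges_nm", "hist_counts")}
        d["hist_edges_nm"] = [float(x) for x in self.hist_edges_nm]
        d["hist_counts"] = [int(x) for x in self.hist_counts]
        return d


@dataclass(frozen=True)
class LatticeComparison:
    """Axial dimer-rise comparison between a reference and an observed lattice."""

    rise_ref_A: float
    rise_obs_A: float
    delta_A: float
    delta_display: str


def fit_axis(points_nm: np.ndarray,
             filament_id: tuple[str, int] | None = None) -> AxisModel:
    """Fit a total-least-squares line through 2-D points (nm).

    The direction is the first principal component of the centered cloud;
    the residual is the rms perpendicular distance.  Orthogonal regression
    treats x and y symmetrically, which matters for filaments at arbitrary
    orientation in the micrograph.
    """
    pts = np.asarray(points_nm, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise BundleError("fit_axis needs >=2 2-D points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if np.allclose(centered, 0.0):
        raise BundleError("all points coincident: axis undefined")
    _u, s, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    if direction[0] < 0 or (direction[0] == 0 and direction[1] < 0):
        direction = -direction
    t = centered @ direction
    order = np.argsort(t, kind="stable")
    perp = centered @ np.array([-direction[1], direction[0]])
    residual = float(np.sqrt(np.mean(perp**2)))
    return AxisModel(centroid=centroid, direction=direction,
                     t_min=float(t.min()), t_max=float(t.max()),
                     residual_nm=residual, points=pts[order],
                     filament_id=filament_id)


def axis_from_trace(trace: FilamentTrace) -> AxisModel:
    model = fit_axis(trace.coords_nm(), filament_id=(trace.micrograph_id, trace.tube_id))
    trace.axis = model
    return model


def _mutual_overlap(a: AxisModel, b: AxisModel) -> tuple[float, float, float]:
    """Overlap interval of b's extent projected onto a's axis.

    Returns (t_lo, t_hi, overlap_fraction) in a's axis parameter, where the
    fraction is the overlap length relative to the shorter filament.
    """
    tb = (np.vstack([b.point_at(b.t_min), b.point_at(b.t_max)]) - a.centroid) @ a.direction
    lo = max(a.t_min, float(tb.min()))
    hi = min(a.t_max, float(tb.max()))
    shorter = min(a.arclength_nm, b.arclength_nm)
    if shorter <= 0 or hi <= lo:
        return lo, hi, 0.0
    return lo, hi, (hi - lo) / shorter


def gap_distance(a1: AxisModel, a2: AxisModel,
                 outer_diameter_nm: float = DEFAULT_CONFIG.mt_outer_diameter_nm,
                 n_samples: int = 64) -> tuple[float, float]:
    """Center-to-center and edge-to-edge spacing of two overlapping axes.

    The center distance is the mean perpendicular distance from points
    sampled along the shorter axis's part of the mutual overlap to the
    other axis's line; the edge gap subtracts the outer diameter.  The
    measure is symmetric in its arguments up to sampling tolerance.
    A negative edge gap (walls overlapping) is allowed but flagged by the
    caller via :class:`BundlePair`.
    """
    short, long_ = (a1, a2) if a1.arclength_nm <= a2.arclength_nm else (a2, a1)
    lo, hi, frac = _mutual_overlap(short, long_)
    if frac <= 0:
        raise BundleError("axes do not overlap: gap undefined")
    ts = np.linspace(lo, hi, n_samples)
    pts = short.centroid + ts[:, None] * short.direction
    center = float(np.mean(long_.perp_distance(pts)))
    return center, center - outer_diameter_nm


def find_pairs(axes: list[AxisModel],
               polarities: dict[tuple[str, int], PolarityResult] | None = None,
               config: RunConfig = DEFAULT_CONFIG) -> list[BundlePair]:
    """Detect and classify bundled pairs among one micrograph's axes.

    Every unordered pair is tested once: it qualifies when the mutual
    overlap fraction reaches ``min_overlap_frac`` and the edge gap is at
    most ``max_edge_gap_nm``.  When polarities are supplied, qualifying
    pairs with both polarities confident are classified; pairs with a
    non-confident polarity are dropped (they cannot be oriented).
    """
    pairs: list[BundlePair] = []
    for i in range(len(axes)):
        for j in range(i + 1, len(axes)):
            a, b = axes[i], axes[j]
            short, long_ = (a, b) if a.arclength_nm <= b.arclength_nm else (b, a)
            _lo, _hi, frac = _mutual_overlap(short, long_)
            if frac < config.min_overlap_frac:
                continue
            center, gap = gap_distance(a, b, config.mt_outer_diameter_nm)
            if gap > config.max_edge_gap_nm:
                continue
            ida = a.filament_id or ("", i)
            idb = b.filament_id or ("", j)
            if idb < ida:
                ida, idb = idb, ida
            cls, angle = "unclassified", math.nan
            if polarities is not None:
                pa = polarities.get(a.filament_id)
                pb = polarities.get(b.filament_id)
                if pa is None or pb is None or not (pa.confident and pb.confident):
                    continue
                cls, angle = classify_pair(pa, pb, config.ambiguous_angle_tol_deg)
            pairs.append(BundlePair(
                id_a=ida, id_b=idb, orientation_class=cls,
                angle_between_deg=angle, center_distance_nm=center,
                edge_gap_nm=gap, overlap_fraction=frac,
                overlapping_walls=gap < 0))
    return pairs


def classify_pair(p1: PolarityResult, p2: PolarityResult,
                  ambiguous_tol_deg: float = DEFAULT_CONFIG.ambiguous_angle_tol_deg,
                  ) -> tuple[str, float]:
    """Parallel/antiparallel call from two consensus plus-end directions.

    The angle between the unit vectors lies in [0, 180]; below 90 deg the
    pair is parallel, above antiparallel, and within the tie tolerance of
    90 deg it is flagged ambiguous.  Symmetric in its arguments.
    """
    dot = float(np.clip(np.dot(p1.u, p2.u), -1.0, 1.0))
    angle = float(np.degrees(np.arccos(dot)))
    if abs(angle - 90.0) <= ambiguous_tol_deg:
        cls = "ambiguous"
    elif angle < 90.0:
        cls = "parallel"
    else:
        cls = "antiparallel"
    return cls, angle


def bundle_summary(pairs: list[BundlePair],
                   hist_bin_nm: float = 1.0) -> BundleSummary:
    """Orientation counts, parallel fraction with exact binomial test, and
    edge-gap statistics over a set of classified pairs.

    The parallel fraction and its two-sided exact binomial test against
    0.5 exclude ambiguous pairs; gap statistics pool all pairs.
    """
    if not pairs:
        raise BundleError("no pairs to summarise")
    n_par = sum(p.orientation_class == "parallel" for p in pairs)
    n_anti = sum(p.orientation_class == "antiparallel" for p in pairs)
    n_amb = sum(p.orientation_class == "ambiguous" for p in pairs)
    n_cls = n_par + n_anti
    frac = n_par / n_cls if n_cls else math.nan
    p_val = stats.binomtest(n_par, n_cls, 0.5).pvalue if n_cls else math.nan
    gaps = np.array([p.edge_gap_nm for p in pairs])
    lo = math.floor(gaps.min() / hist_bin_nm) * hist_bin_nm
    hi = math.ceil(gaps.max() / hist_bin_nm) * hist_bin_nm
    nbins = max(int(round((hi - lo) / hist_bin_nm)), 1)
    counts, edges = np.histogram(gaps, bins=nbins, range=(lo, lo + nbins * hist_bin_nm))
    return BundleSummary(
        n_total=len(pairs), n_parallel=n_par, n_antiparallel=n_anti,
        n_ambiguous=n_amb, fraction_parallel=frac, binomial_p=float(p_val),
        gap_min_nm=float(gaps.min()), gap_max_nm=float(gaps.max()),
        gap_mean_nm=float(gaps.mean()),
        gap_sd_nm=float(gaps.std(ddof=1)) if len(gaps) > 1 else math.nan,
        hist_edges_nm=edges, hist_counts=counts)


def dimer_rise_delta(rise_ref_A: float, rise_obs_A: float) -> LatticeComparison:
    """Axial dimer-rise change between a reference and an observed lattice.

    A positive delta means lattice compaction (the observed rise is smaller
    than the reference).  Reported at 0.01-A precision with a 1-decimal
    display value.
    """
    if rise_ref_A <= 0 or rise_obs_A <= 0:
        raise BundleError("dimer rises must be positive")
    delta = round(rise_ref_A - rise_obs_A, 2)
    return LatticeComparison(rise_ref_A=rise_ref_A, rise_obs_A=rise_obs_A,
                             delta_A=delta, delta_display=f"{delta:.1f}")


def analyze_particles(table, config: RunConfig = DEFAULT_CONFIG,
                      ) -> tuple[list[FilamentTrace], list[BundlePair], BundleSummary]:
    """End-to-end bundle analysis of a particle table.

    Groups particles into filaments, attaches consensus polarities, fits
    axes, detects and classifies bundled pairs per micrograph, and
    summarises.  Returns (traces, pairs, summary).
    """
    from .polarity import annotate_polarity
    from .star_io import group_filaments, usable_traces

    traces = annotate_polarity(group_filaments(table, config.pixel_size_A), config)
    pairs: list[BundlePair] = []
    by_mic: dict[str, list[FilamentTrace]] = {}
    for t in usable_traces(traces):
        by_mic.setdefault(t.micrograph_id, []).append(t)
    for mic, mic_traces in sorted(by_mic.items()):
        axes = [axis_from_trace(t) for t in mic_traces]
        pols = {(t.micrograph_id, t.tube_id): t.polarity
                for t in mic_traces if t.polarity is not None}
        pairs.extend(find_pairs(axes, pols, config))
    summary = bundle_summary(pairs) if pairs else None
    return traces, pairs, summary


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def pairs_to_frame(pairs: list[BundlePair]) -> pd.DataFrame:
    return pd.DataFrame([{
        "micrograph_id": p.id_a[0], "tube_a": p.id_a[1], "tube_b": p.id_b[1],
        "orientation_class": p.orientation_class,
        "angle_between_deg": p.angle_between_deg,
        "center_distance_nm": p.center_distance_nm,
        "edge_gap_nm": p.edge_gap_nm,
        "overlap_fraction": p.overlap_fraction,
        "overlapping_walls": p.overlapping_walls,
    } for p in pairs])


def write_summary(summary: BundleSummary, pairs: list[BundlePair],
                  out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pairs_to_frame(pairs).to_csv(out / "pairs.tsv", sep="\t", index=False)
    (out / "bundle_summary.json").write_text(json.dumps(summary.to_dict(), indent=2))
    hist = pd.DataFrame({"bin_left_nm": summary.hist_edges_nm[:-1],
                         "bin_right_nm": summary.hist_edges_nm[1:],
                         "count": summary.hist_counts})
    hist.to_csv(out / "gap_histogram.csv", index=False)
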