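"""Per-particle polarity vectors and per-filament consensus polarity.

A helical segment's Euler triplet (rot, tilt, psi; RELION/XMIPP ZYZ
convention, rotation matrix ``A = Rz(psi) Ry(tilt) Rz(rot)``) maps the
reference filament axis +z into the micrograph plane.  The in-plane image of
+z is

    A . z = (sin(tilt) cos(psi), sin(tilt) sin(psi), cos(tilt)),

so the projected plus-end direction is ``u = (cos psi, sin psi)`` — it does
not depend on rot — and ``sin(tilt)`` measures how much of the axis lies in
the plane, which we use as a reliability weight.  Segments viewed nearly
end-on (sin tilt below a cutoff) carry no usable in-plane direction and are
excluded.

Per filament, segment directions are combined by a weighted circular mean
with a two-orientation (axial) disambiguation: each segment vector may be
flipped by 180 deg if that brings it onto the majority orientation, and the
assignment maximising the weighted mean resultant length wins.  The mean
resultant length of the final assignment ("coherence", in [0, 1]) gauges how
internally consistent the filament's polarity evidence is.

All directions here live in the math-convention frame (y up); the single
y flip back to image pixels happens only in :func:`export_arrows`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, RunConfig
from .star_io import FilamentTrace


@dataclass(frozen=True)
class PlaneDirection:
    """In-plane plus-end direction of one segment with reliability weight."""

    u: tuple[float, float]
    weight: float
    defined: bool = True


@dataclass(frozen=True)
class PolarityResult:
    """Consensus polarity of one filament.

    angle_deg is the consensus plus-end direction in [-180, 180) (math
    frame); coherence is the weighted mean resultant length of the final
    orientation assignment; n_flipped counts segments assigned against
    their raw orientation (minority side).
    """

    angle_deg: float
    coherence: float
    n_used: int
    n_flipped: int
    confident: bool
    tie_broken: bool = False

    @property
    def u(self) -> np.ndarray:
        a = np.deg2rad(self.angle_deg)
        return np.array([np.cos(a), np.sin(a)])


class PolarityError(ValueError):
    pass


def plane_direction(rot_deg: float, tilt_deg: float, psi_deg: float,
                    near_polar_sin_tilt: float = DEFAULT_CONFIG.near_polar_sin_tilt,
                    ) -> PlaneDirection:
    """In-plane plus-end direction for one segment's Euler triplet.

    Returns a unit vector ``(cos psi, sin psi)`` with weight ``sin(tilt)``.
    ``rot`` is accepted for interface symmetry but cannot affect the result.
    Segments with ``sin(tilt)`` below the near-polar cutoff are flagged
    undefined (end-on view: the in-plane direction is ill-conditioned).
    """
    if not 0.0 <= tilt_deg <= 180.0:
        raise PolarityError(f"tilt_deg={tilt_deg} outside [0, 180]")
    t = np.deg2rad(tilt_deg)
    p = np.deg2rad(psi_deg)
    w = float(np.sin(t))
    if w < near_polar_sin_tilt:
        return PlaneDirection(u=(np.nan, np.nan), weight=0.0, defined=False)
    return PlaneDirection(u=(float(np.cos(p)), float(np.sin(p))),
                          weight=min(max(w, 0.0), 1.0))


def _weighted_mean_angle(theta: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted circular mean angle and mean resultant length."""
    c = float(np.sum(w * np.cos(theta)))
    s = float(np.sum(w * np.sin(theta)))
    wsum = float(np.sum(w))
    r = np.hypot(c, s) / wsum if wsum > 0 else 0.0
    return float(np.arctan2(s, c)), float(r)


def _refine_assignment(theta: np.ndarray, w: np.ndarray,
                       mean0: float, max_iter: int = 10) -> tuple[np.ndarray, float, float]:
    """Iteratively flip vectors toward the running mean until stable.

    Each pass assigns every vector to whichever of {theta, theta+pi} lies
    within 90 deg of the current mean, then recomputes the mean; converges
    in a couple of passes and makes the result invariant to pre-flipping
    any individual vector.
    """
    flips = np.zeros(len(theta), dtype=bool)
    mean = mean0
    for _ in range(max_iter):
        d = np.angle(np.exp(1j * (theta - mean)))
        new_flips = np.abs(d) > np.pi / 2
        if np.array_equal(new_flips, flips) and _ > 0:
            break
        flips = new_flips
        mean, _r = _weighted_mean_angle(theta + np.pi * flips, w)
    mean, r = _weighted_mean_angle(theta + np.pi * flips, w)
    return flips, mean, r


def consensus_polarity(trace_or_dirs,
                       config: RunConfig = DEFAULT_CONFIG) -> PolarityResult:
    """Weighted circular consensus of segment directions with majority flip.

    Accepts a :class:`FilamentTrace` (directions derived from its Euler
    columns) or an iterable of :class:`PlaneDirection`.  Two candidate
    global orientations are evaluated — the mean of the raw angles and the
    axial (doubled-angle) mean — each refined by flip-toward-mean passes;
    the assignment with the larger weighted mean resultant length wins.
    The winning orientation's global sign is chosen so that flipped
    segments are the (weighted) minority; an exact tie is broken toward
    the representative whose angle lies in [0, 180) and flagged.
    """
    if isinstance(trace_or_dirs, FilamentTrace):
        df = trace_or_dirs.particles
        dirs = [plane_direction(r, t, p, config.near_polar_sin_tilt)
                for r, t, p in zip(df["rot_deg"], df["tilt_deg"], df["psi_deg"])]
    else:
        dirs = list(trace_or_dirs)

    used = [d for d in dirs if d.defined]
    if len(used) < 2:
        raise PolarityError("no usable directions (need >=2 defined segments)")

    theta = np.array([np.arctan2(d.u[1], d.u[0]) for d in used])
    w = np.array([d.weight for d in used])

    # Candidate A: refine from the raw weighted mean.
    mean_raw, _ = _weighted_mean_angle(theta, w)
    flips_a, mean_a, r_a = _refine_assignment(theta, w, mean_raw)
    # Candidate B: refine from the axial (doubled-angle) mean.
    mean2, _ = _weighted_mean_angle(2.0 * theta, w)
    flips_b, mean_b, r_b = _refine_assignment(theta, w, mean2 / 2.0)

    if r_b > r_a:
        flips, mean, r = flips_b, mean_b, r_b
    else:
        flips, mean, r = flips_a, mean_a, r_a

    # Global sign: flipped mass must be the minority.
    w_flipped = float(np.sum(w[flips]))
    w_total = float(np.sum(w))
    tie = False
    if w_flipped > w_total / 2:
        flips = ~flips
        mean = np.angle(np.exp(1j * (mean + np.pi)))
    elif w_flipped == w_total / 2:
        tie = True
        if not (0.0 <= np.rad2deg(mean) < 180.0):
            flips = ~flips
            mean = np.angle(np.exp(1j * (mean + np.pi)))

    angle_deg = float(np.rad2deg(np.angle(np.exp(1j * mean))))
    if angle_deg >= 180.0:  # guard the half-open interval
        angle_deg -= 360.0
    return PolarityResult(
        angle_deg=angle_deg,
        coherence=float(r),
        n_used=len(used),
        n_flipped=int(np.count_nonzero(flips)),
        confident=bool(r >= config.coherence_threshold),
        tie_broken=tie,
    )


def annotate_polarity(traces: list[FilamentTrace],
                      config: RunConfig = DEFAULT_CONFIG) -> list[FilamentTrace]:
    """Attach a PolarityResult to every traceable filament in place."""
    for t in traces:
        if t.untraceable:
            continue
        try:
            t.polarity = consensus_polarity(t, config)
        except PolarityError:
            t.polarity = None
    return traces


# ---------------------------------------------------------------------------
# Arrow overlays (minus -> plus), image-convention output
# ---------------------------------------------------------------------------

ARROW_COLUMNS = ["micrograph_id", "tube_id", "anchor_x", "anchor_y",
                 "tip_x", "tip_y", "coherence", "confident"]


def export_arrows(traces: list[FilamentTrace], arrow_len_px: float = 50.0,
                  csv_path: str | Path | None = None,
                  svg_path: str | Path | None = None) -> pd.DataFrame:
    """Arrow overlay records (one minus->plus arrow per filament).

    The anchor is the filament's coordinate midpoint in image-convention
    pixels; the tip is ``anchor + arrow_len * (u_x, -u_y)`` — the single
    y flip converting the math-frame polarity vector back to image pixels.
    Filaments whose polarity is not confident are kept with
    ``confident=False`` (drawn dashed in the SVG).
    """
    rows = []
    for t in traces:
        if t.untraceable or t.polarity is None:
            continue
        pol: PolarityResult = t.polarity
        xy = t.particles[["x_px", "y_px"]].to_numpy(float)
        anchor = xy.mean(axis=0)
        u = pol.u
        tip = anchor + arrow_len_px * np.array([u[0], -u[1]])
        rows.append((t.micrograph_id, t.tube_id, anchor[0], anchor[1],
                     tip[0], tip[1], pol.coherence, bool(pol.confident)))
    out = pd.DataFrame(rows, columns=ARROW_COLUMNS)
    if csv_path is not None:
        out.to_csv(csv_path, index=False)
    if svg_path is not None:
        Path(svg_path).write_text(_arrows_svg(out))
    return out


def _arrows_svg(arrows: pd.DataFrame) -> str:
    if len(arrows):
        w = float(arrows[["anchor_x", "tip_x"]].to_numpy().max()) + 60
        h = float(arrows[["anchor_y", "tip_y"]].to_numpy().max()) + 60
    else:
        w = h = 100.0
    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{w:.0f}" height="{h:.0f}">']
    for _, r in arrows.iterrows():
        dash = '' if r["confident"] else ' stroke-dasharray="6,4"'
        parts.append(
            f'<line x1="{r.anchor_x:.1f}" y1="{r.anchor_y:.1f}" '
            f'x2="{r.tip_x:.1f}" y2="{r.tip_y:.1f}" stroke="cyan" '
            f'stroke-width="3" marker-end="url(#tip)"{dash}/>')
    parts.insert(1, '<defs><marker id="tip" markerWidth="8" markerHeight="8" '
                    'refX="6" refY="3" orient="auto">'
                    '<path d="M0,0 L6,3 L0,6 z" fill="cyan"/></marker></defs>')
    parts.append('</svg>')
    return "\n".join(parts)
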