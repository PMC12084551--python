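"""Dynamic-instability analysis of filament length-vs-time traces.

A trace is segmented into growth / pause / shrinkage phases and the phase
sequence is reduced to the standard dynamic-instability statistics: mean
growth velocity, catastrophe frequency (events per unit time spent growing
or paused), rescue frequency (events per unit time spent shrinking) and
pause durations.

Segmentation
------------
The trace is modelled as piecewise linear with additive Gaussian noise.
Changepoints come from exact penalised optimal partitioning (dynamic
programming over least-squares line segments) with a BIC-like penalty of
``penalty_factor * sigma^2 * ln n`` per segment, the noise level sigma
estimated robustly from successive length differences.  Segments are then
classified by their fitted slope against a symmetric pause band
(|v| <= band is pause), with a significance guard — the slope must clear
the band by ``z_guard`` standard errors to be called growth or shrinkage —
and same-kind neighbours are merged.  Phases shorter than the minimum
duration are absorbed into a neighbour only when the merge is itself
statistically cheap under the same penalty, so noise flickers vanish while
genuine brief excursions (a fast depolymerisation spike) survive.  A
rescue pass re-examines each phase at a reduced penalty for a split whose
two halves classify as *different* kinds: this recovers short growth|pause
kinks that fall just under the free-changepoint penalty without letting
noise fragment uniform phases.

Least-squares slopes over whole phases are precise even when short-window
velocity estimates are not (the slope standard error falls as
span^{-3/2}), which is what makes slow growth distinguishable from pause
at realistic noise levels.  Reported phase velocities are re-fitted on a
boundary-trimmed interior (changepoint localisation error is of order
sigma/|dv| samples and always leaks the neighbour's velocity into an
untrimmed fit); phases too short to trim are flagged
``velocity_reliable=False`` and excluded from velocity aggregates.
:func:`window_velocity` exposes the sliding-window velocity profile for
inspection and band-level sanity checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, RunConfig

GROWTH, PAUSE, SHRINKAGE = "growth", "pause", "shrinkage"


class DynamicsError(ValueError):
    pass


@dataclass
class DynamicsTrace:
    """Length-vs-time record of one filament."""

    time_s: np.ndarray
    length_nm: np.ndarray
    condition: str = ""
    trace_id: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.length_nm = np.asarray(self.length_nm, dtype=float)
        if len(self.time_s) != len(self.length_nm):
            raise DynamicsError("time and length arrays differ in length")
        if len(self.time_s) < 10:
            raise DynamicsError("trace too short (need >=10 samples)")
        if np.any(np.diff(self.time_s) <= 0):
            raise DynamicsError("time must be strictly increasing")
        if np.any(self.length_nm < 0):
            raise DynamicsError("negative filament length")


@dataclass(frozen=True)
class Phase:
    kind: str
    start_s: float
    end_s: float
    velocity_nm_s: float
    #: False when the phase is too short to trim its interior clear of the
    #: changepoint-localisation uncertainty; such velocities are excluded
    #: from velocity aggregates (the phase still counts for durations and
    #: event transitions).
    velocity_reliable: bool = True

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class DynamicsSummary:
    n_traces: int
    growth_rate_nm_s: float          # robust mean over reliable growth phases
    growth_rate_sem: float
    n_growth_phases: int             # all growth phases, before screening
    f_cat_per_s: float               # catastrophes / (growth+pause time)
    f_res_per_s: float | None        # rescues / shrinkage time; None if no shrinkage
    f_res_defined: bool
    n_catastrophes: int
    n_rescues: int
    pause_mean_s: float
    pause_sem_s: float
    n_pauses: int
    total_growth_pause_s: float
    total_shrinkage_s: float


# ---------------------------------------------------------------------------
# Segment statistics (O(1) line fits from cumulative sums)
# ---------------------------------------------------------------------------

class _SegStats:
    """Prefix sums enabling O(1) least-squares line fits on any index range."""

    def __init__(self, t: np.ndarray, y: np.ndarray):
        z = np.zeros(1)
        self.n = len(t)
        self.ct = np.concatenate([z, np.cumsum(t)])
        self.ct2 = np.concatenate([z, np.cumsum(t * t)])
        self.cy = np.concatenate([z, np.cumsum(y)])
        self.cy2 = np.concatenate([z, np.cumsum(y * y)])
        self.cty = np.concatenate([z, np.cumsum(t * y)])

    def fit(self, i: int, j: int) -> tuple[float, float]:
        """(slope, rss) of the LS line over samples i..j inclusive."""
        n = j - i + 1
        st = self.ct[j + 1] - self.ct[i]
        st2 = self.ct2[j + 1] - self.ct2[i]
        sy = self.cy[j + 1] - self.cy[i]
        sy2 = self.cy2[j + 1] - self.cy2[i]
        sty = self.cty[j + 1] - self.cty[i]
        if n < 2:
            return 0.0, 0.0
        sxx = st2 - st * st / n
        sxy = sty - st * sy / n
        syy = sy2 - sy * sy / n
        if sxx <= 0:
            return 0.0, max(syy, 0.0)
        slope = sxy / sxx
        return slope, max(syy - sxy * sxy / sxx, 0.0)


def window_velocity(trace: DynamicsTrace, window: int) -> np.ndarray:
    """Centered sliding-window least-squares slope at every sample.

    Near the trace ends the window is truncated to the available samples.
    """
    t, y = trace.time_s, trace.length_nm
    n = len(t)
    if n < window:
        raise DynamicsError(f"trace shorter than one window ({n} < {window})")
    stats = _SegStats(t, y)
    h = window // 2
    v = np.empty(n)
    for i in range(n):
        lo = max(0, i - h)
        hi = min(n - 1, i + h)
        if hi - lo + 1 < 2:
            lo, hi = max(0, i - 1), min(n - 1, i + 1)
        v[i], _ = stats.fit(lo, hi)
    return v


def _robust_noise_var(y: np.ndarray) -> float:
    """Noise variance estimate from successive differences (robust to the
    piecewise-linear signal: the median absolute deviation of the
    differences around their median ignores slope and rare jumps)."""
    d = np.diff(y)
    mad = np.median(np.abs(d - np.median(d)))
    return (1.4826 * mad) ** 2 / 2.0


def _optimal_partition(stats: _SegStats, n: int, penalty: float,
                       min_seg: int = 2) -> list[tuple[int, int]]:
    """Exact penalized optimal partitioning into least-squares line segments.

    Minimises sum(RSS of each segment) + penalty * (number of segments) by
    dynamic programming; the inner minimisation over segment starts is
    vectorised on the prefix sums.  Splitting a segment in two is accepted
    exactly when it reduces the residual by more than ``penalty``.  Ties
    resolve toward fewer segments.
    """
    ct, ct2, cy, cy2, cty = stats.ct, stats.ct2, stats.cy, stats.cy2, stats.cty
    F = np.full(n + 1, np.inf)
    F[0] = 0.0
    prev = np.zeros(n + 1, dtype=int)
    for j in range(min_seg - 1, n):
        iv = np.arange(0, j - min_seg + 2)
        ni = j - iv + 1.0
        st = ct[j + 1] - ct[iv]
        st2 = ct2[j + 1] - ct2[iv]
        sy = cy[j + 1] - cy[iv]
        sy2 = cy2[j + 1] - cy2[iv]
        sty = cty[j + 1] - cty[iv]
        sxx = st2 - st * st / ni
        sxy = sty - st * sy / ni
        syy = sy2 - sy * sy / ni
        rss = np.maximum(syy - np.where(sxx > 0, sxy * sxy / np.maximum(sxx, 1e-300), 0.0), 0.0)
        tot = F[iv] + rss + penalty
        k = int(np.argmin(tot))
        F[j + 1] = tot[k]
        prev[j + 1] = iv[k]
    segs: list[tuple[int, int]] = []
    j = n
    while j > 0:
        i = int(prev[j])
        segs.append((i, j - 1))
        j = i
    segs.reverse()
    return segs


def _kind_of(slope: float, band: float) -> int:
    return 0 if slope > band else (2 if slope < -band else 1)  # 0 g, 1 p, 2 s


def _classify_and_merge(segs: list[tuple[int, int]], stats: _SegStats,
                        band: float) -> list[tuple[int, int, int]]:
    """Attach a kind (by fitted slope vs band) and merge same-kind runs."""
    out: list[tuple[int, int, int]] = []
    for i, j in segs:
        slope, _ = stats.fit(i, j)
        kind = _kind_of(slope, band)
        if out and out[-1][2] == kind:
            out[-1] = (out[-1][0], j, kind)
        else:
            out.append((i, j, kind))
    return out


def segment_trace(trace: DynamicsTrace,
                  pause_band_nm_s: float = DEFAULT_CONFIG.pause_band_nm_s,
                  min_phase_s: float = DEFAULT_CONFIG.min_phase_s,
                  window: int = DEFAULT_CONFIG.velocity_window,
                  penalty_factor: float = 3.0,
                  z_guard: float = 2.0) -> list[Phase]:
    """Segment a length-vs-time trace into growth/pause/shrinkage phases.

    See the module docstring for the procedure.  ``window`` is the
    sliding-window length of the companion velocity profile; here it only
    bounds the minimum analysable trace length.  The returned phases tile
    the trace exactly: phase k ends where phase k+1 starts, the first
    starts at the first sample and the last ends at the last sample.
    """
    t, y = trace.time_s, trace.length_nm
    n = len(t)
    if n < window:
        raise DynamicsError(f"trace shorter than one window ({n} < {window})")
    stats = _SegStats(t, y)

    sigma2 = _robust_noise_var(y)
    penalty = penalty_factor * sigma2 * math.log(n)
    segs = _optimal_partition(stats, n, penalty)

    kinds = _classify_and_merge(segs, stats, pause_band_nm_s)

    # Absorb sub-minimum phases into a neighbour, but only when the merge
    # is statistically cheap (same changepoint penalty): noise flickers
    # merge away, genuine brief excursions (e.g. fast depolymerisation
    # spikes) are retained even if short.
    def dur(s):
        return t[s[1]] - t[s[0]]

    while len(kinds) > 1:
        candidates = []
        for k, seg in enumerate(kinds):
            if dur(seg) >= min_phase_s:
                continue
            for tgt in (k - 1, k + 1):
                if 0 <= tgt < len(kinds):
                    lo = min(seg[0], kinds[tgt][0])
                    hi = max(seg[1], kinds[tgt][1])
                    cost = (stats.fit(lo, hi)[1] - stats.fit(*seg[:2])[1]
                            - stats.fit(*kinds[tgt][:2])[1])
                    candidates.append((cost, k, tgt, lo, hi))
        if not candidates:
            break
        cost, k, tgt, lo, hi = min(candidates)
        if cost > penalty + 1e-9:
            break
        kinds[min(k, tgt):max(k, tgt) + 1] = [
            (lo, hi, _kind_of(stats.fit(lo, hi)[0], pause_band_nm_s))]
        merged: list[tuple[int, int, int]] = []
        for seg in kinds:
            if merged and merged[-1][2] == seg[2]:
                merged[-1] = (merged[-1][0], seg[1], seg[2])
            else:
                merged.append(seg)
        kinds = merged

    # Phase velocities from boundary-trimmed interiors.  The LS changepoint
    # location carries an uncertainty of roughly sigma / |dv| samples; that
    # much of the neighbouring phase can leak across the boundary and bias
    # the slope (always toward the neighbour's velocity).  Trimming twice
    # that margin from each shared boundary before fitting removes the
    # leakage at negligible cost in precision; the margin is capped at a
    # quarter of the phase so short phases keep a fittable interior.  The
    # final phase kind comes from the trimmed slope (re-merging same-kind
    # neighbours until stable).
    dt_med = float(np.median(np.diff(t))) if n > 1 else 1.0
    sigma = math.sqrt(sigma2)

    def trimmed_slopes(segments: list[tuple[int, int, int]]
                       ) -> tuple[list[float], list[bool]]:
        raw = [stats.fit(i, j)[0] for i, j, _k in segments]
        out, reliable = [], []
        for k, (i, j, _kind) in enumerate(segments):
            span = j - i + 1
            m_left = m_right = 0
            if k > 0:
                dv = abs(raw[k] - raw[k - 1])
                m_left = int(math.ceil(2.0 * sigma / (max(dv, 1e-9) * dt_med)))
            if k < len(segments) - 1:
                dv = abs(raw[k] - raw[k + 1])
                m_right = int(math.ceil(2.0 * sigma / (max(dv, 1e-9) * dt_med)))
            lo = i + m_left
            hi = j - m_right
            ok = hi - lo + 1 >= 5
            if not ok:
                # interior cannot be cleared of boundary uncertainty;
                # fall back to a quarter-span trim and flag the velocity
                cap = span // 4
                lo = i + min(m_left, cap)
                hi = j - min(m_right, cap)
                if hi - lo + 1 < 2:
                    lo, hi = i, j
            out.append(stats.fit(lo, hi)[0])
            reliable.append(ok)
        return out, reliable

    def slope_se(i: int, j: int) -> float:
        m = j - i + 1
        span = max(t[j] - t[i], dt_med)
        return sigma * math.sqrt(12.0 * (m - 1) / (m * (m + 1))) / span

    def classify(i: int, j: int, slope: float) -> int:
        # A phase is only called growth/shrinkage when its slope clears the
        # pause band by z_guard standard errors of the slope estimate; a
        # velocity indistinguishable from the band edge is a pause.
        guard = z_guard * slope_se(i, j)
        return _kind_of(slope, pause_band_nm_s + guard)

    def relabel_and_merge(segments: list[tuple[int, int, int]],
                          ) -> list[tuple[int, int, int]]:
        # classification uses the full-segment slope: trimming is only for
        # the reported velocity (a heavily trimmed short segment would be
        # classified on a handful of samples and could cascade into wrong
        # merges)
        for _ in range(3):
            relabelled = [(i, j, classify(i, j, stats.fit(i, j)[0]))
                          for (i, j, _k) in segments]
            merged: list[tuple[int, int, int]] = []
            for seg in relabelled:
                if merged and merged[-1][2] == seg[2]:
                    merged[-1] = (merged[-1][0], seg[1], seg[2])
                else:
                    merged.append(seg)
            if merged == segments:
                return merged
            segments = merged
        return segments

    kinds = relabel_and_merge(kinds)

    # Rescue pass for kinks just below the free-changepoint penalty: a
    # two-run mixture (e.g. short growth followed by pause) fits a single
    # line whose slope lies between the state velocities.  Re-splitting is
    # allowed at a reduced penalty, but only when the two halves receive
    # different kinds and each is long enough (>=10 samples) to classify —
    # a far stronger requirement than a free split, so pure phases are not
    # fragmented by noise.
    rescue_penalty = max(penalty / 3.0, sigma2 * math.log(n))
    for _pass in range(2):
        rescued: list[tuple[int, int, int]] = []
        for i, j, kind in kinds:
            best = None
            if j - i + 1 >= 20:
                base = stats.fit(i, j)[1]
                for s in range(i + 9, j - 9):
                    gain = base - stats.fit(i, s)[1] - stats.fit(s + 1, j)[1]
                    if gain > rescue_penalty and (best is None or gain > best[1]):
                        kl = _kind_of(stats.fit(i, s)[0], pause_band_nm_s)
                        kr = _kind_of(stats.fit(s + 1, j)[0], pause_band_nm_s)
                        if kl != kr:
                            best = (s, gain, kl, kr)
            if best is None:
                rescued.append((i, j, kind))
            else:
                s, _gain, kl, kr = best
                rescued.append((i, s, kl))
                rescued.append((s + 1, j, kr))
        if rescued == kinds:
            break
        kinds = relabel_and_merge(rescued)

    slopes, reliable = trimmed_slopes(kinds)

    names = {0: GROWTH, 1: PAUSE, 2: SHRINKAGE}
    phases: list[Phase] = []
    for k, (i, j, kind) in enumerate(kinds):
        start = t[0] if k == 0 else t[kinds[k][0]]
        end = t[-1] if k == len(kinds) - 1 else t[kinds[k + 1][0]]
        phases.append(Phase(kind=names[kind], start_s=float(start),
                            end_s=float(end), velocity_nm_s=float(slopes[k]),
                            velocity_reliable=bool(reliable[k])))
    return phases


def event_statistics(segmented: list[list[Phase]]) -> DynamicsSummary:
    """Dynamic-instability statistics over segmented traces.

    A catastrophe is a (growth|pause) -> shrinkage transition, a rescue is
    shrinkage -> (growth|pause).  Catastrophe frequency is normalised by
    the total time in growth and pause; rescue frequency by the total time
    in shrinkage (reported undefined, not zero, when no shrinkage time was
    observed).  The growth rate is the mean of growth-phase velocities with
    its SEM across phases, over phases whose velocity is reliable (interior
    clear of boundary uncertainty) and consistent with the population: a
    phase more than 3 scaled-MAD from the median growth velocity is
    rejected as an unresolved mixture (slow growth interrupted by pauses
    below the changepoint detection limit fits a single line whose slope
    lies between the true levels; such phases form a one-sided tail that
    would otherwise bias the mean).  Pause durations are pooled.
    """
    if not segmented:
        raise DynamicsError("no segmented traces")
    n_cat = n_res = 0
    t_gp = t_s = 0.0
    growth_v: list[float] = []
    pause_d: list[float] = []
    for phases in segmented:
        for a, b in zip(phases[:-1], phases[1:]):
            if a.kind in (GROWTH, PAUSE) and b.kind == SHRINKAGE:
                n_cat += 1
            if a.kind == SHRINKAGE and b.kind in (GROWTH, PAUSE):
                n_res += 1
        for p in phases:
            if p.kind == SHRINKAGE:
                t_s += p.duration_s
            else:
                t_gp += p.duration_s
            if p.kind == GROWTH and p.velocity_reliable:
                growth_v.append(p.velocity_nm_s)
            elif p.kind == PAUSE:
                pause_d.append(p.duration_s)

    gv = np.array(growth_v)
    n_growth_total = len(gv)
    if len(gv) >= 3:
        med = np.median(gv)
        mad = 1.4826 * np.median(np.abs(gv - med))
        if mad > 0:
            gv = gv[np.abs(gv - med) <= 3.0 * mad]
    pd_ = np.array(pause_d)
    res_defined = t_s > 0
    return DynamicsSummary(
        n_traces=len(segmented),
        growth_rate_nm_s=float(gv.mean()) if len(gv) else math.nan,
        growth_rate_sem=float(gv.std(ddof=1) / math.sqrt(len(gv))) if len(gv) > 1 else math.nan,
        n_growth_phases=n_growth_total,
        f_cat_per_s=n_cat / t_gp if t_gp > 0 else math.nan,
        f_res_per_s=(n_res / t_s) if res_defined else None,
        f_res_defined=res_defined,
        n_catastrophes=n_cat, n_rescues=n_res,
        pause_mean_s=float(pd_.mean()) if len(pd_) else math.nan,
        pause_sem_s=float(pd_.std(ddof=1) / math.sqrt(len(pd_))) if len(pd_) > 1 else math.nan,
        n_pauses=len(pd_),
        total_growth_pause_s=t_gp, total_shrinkage_s=t_s)


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

TRACE_COLUMNS = ["trace_id", "condition", "time_s", "length_nm"]


def traces_from_frame(df: pd.DataFrame) -> list[DynamicsTrace]:
    """Build traces from the long-format CSV layout
    (trace_id, condition, time_s, length_nm)."""
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise DynamicsError(f"missing trace columns: {missing}")
    traces = []
    for tid, grp in df.groupby("trace_id", sort=True):
        grp = grp.sort_values("time_s")
        traces.append(DynamicsTrace(
            time_s=grp["time_s"].to_numpy(float),
            length_nm=grp["length_nm"].to_numpy(float),
            condition=str(grp["condition"].iloc[0]), trace_id=str(tid)))
    return traces


def phases_to_frame(segmented: list[list[Phase]],
                    trace_ids: list[str] | None = None) -> pd.DataFrame:
    rows = []
    for k, phases in enumerate(segmented):
        tid = trace_ids[k] if trace_ids else str(k)
        for p in phases:
            rows.append({"trace_id": tid, "kind": p.kind, "start_s": p.start_s,
                         "end_s": p.end_s, "duration_s": p.duration_s,
                         "velocity_nm_s": p.velocity_nm_s})
    return pd.DataFrame(rows)
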