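"""Co-sedimentation quantification, binding-isotherm fits and SEC oligomer
state inference.

Densitometry rows (pellet / supernatant band intensities per lane) are
reduced to a fraction pelleted; titration series are fitted with a
single-site binding isotherm

    f([L]) = Bmax * [L] / (Kd + [L]),

by nonlinear least squares, once per replicate (reported as mean +/- SD
across replicates, the usual triplicate presentation) and once pooled.  The
hyperbolic form assumes the probe is sub-stoichiometric relative to polymer
binding sites (no ligand depletion); a quadratic tight-binding variant is
available via ``model="quadratic"`` for cases where the probe concentration
is comparable to Kd.

SEC apparent molecular weights come from a linear calibration of log10(MW)
against elution volume (standard practice for Superdex-type columns); the
oligomeric state is the nearest integer ratio of apparent to theoretical
monomer weight.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


class BiochemError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Densitometry
# ---------------------------------------------------------------------------

def band_fraction(pellet: float, supernatant: float,
                  pellet_background: float = 0.0,
                  supernatant_background: float = 0.0) -> float:
    """Fraction of probe in the pellet, ``P / (P + S)``.

    Optional background intensities from matched no-partner control lanes
    are subtracted first (clipped at zero).  Scale-invariant: multiplying
    both intensities by a common factor leaves the fraction unchanged.
    """
    if pellet < 0 or supernatant < 0:
        raise BiochemError("band intensities must be non-negative")
    p = max(pellet - pellet_background, 0.0)
    s = max(supernatant - supernatant_background, 0.0)
    if p + s == 0:
        raise BiochemError("pellet and supernatant intensities both zero")
    return p / (p + s)


@dataclass
class BindingSeries:
    """Titration: fraction bound vs ligand concentration, per replicate.

    ``fraction_bound`` has shape (n_replicates, n_concentrations).
    """

    concentrations_uM: np.ndarray
    fraction_bound: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations_uM = np.asarray(self.concentrations_uM, dtype=float)
        self.fraction_bound = np.atleast_2d(np.asarray(self.fraction_bound, dtype=float))
        if np.any(np.diff(self.concentrations_uM) <= 0):
            raise BiochemError("concentrations must be strictly increasing")
        if self.fraction_bound.shape[1] != len(self.concentrations_uM):
            raise BiochemError("fraction_bound shape does not match concentrations")

    @property
    def n_replicates(self) -> int:
        return self.fraction_bound.shape[0]


def hyperbolic(L, kd, bmax):
    """Single-site isotherm without ligand depletion."""
    return bmax * L / (kd + L)


def quadratic_binding(L, kd, bmax, probe_uM):
    """Single-site isotherm with ligand depletion (tight binding).

    Fraction of probe bound when probe at ``probe_uM`` competes for free
    ligand: the exact root of the binding quadratic.
    """
    b = probe_uM + L + kd
    return bmax * (b - np.sqrt(b * b - 4.0 * probe_uM * L)) / (2.0 * probe_uM)


@dataclass
class IsothermFit:
    kd_uM: float                    # mean across replicates
    kd_sd_uM: float
    bmax: float                     # mean across replicates
    bmax_sd: float
    kd_per_replicate: np.ndarray
    bmax_per_replicate: np.ndarray
    pooled_kd_uM: float
    pooled_bmax: float
    pooled_rss: float
    warnings: list[str] = field(default_factory=list)


def _fit_one(conc: np.ndarray, frac: np.ndarray, model: str,
             probe_uM: float | None) -> tuple[float, float, float]:
    bmax0 = max(float(frac.max()), 1e-3)
    half = bmax0 / 2.0
    kd0 = float(conc[np.argmin(np.abs(frac - half))])
    kd0 = max(kd0, 1e-6)
    if model == "hyperbolic":
        fun = hyperbolic
    elif model == "quadratic":
        if probe_uM is None or probe_uM <= 0:
            raise BiochemError("quadratic model requires probe_uM > 0")
        def fun(L, kd, bmax):
            return quadratic_binding(L, kd, bmax, probe_uM)
    else:
        raise BiochemError(f"unknown binding model {model!r}")
    try:
        popt, _ = optimize.curve_fit(
            fun, conc, frac, p0=[kd0, min(bmax0, 1.05)],
            bounds=([1e-9, 1e-9], [np.inf, 1.05]), maxfev=20000)
    except RuntimeError as exc:
        raise BiochemError(f"isotherm fit failed to converge: {exc}") from exc
    resid = frac - fun(conc, *popt)
    return float(popt[0]), float(popt[1]), float(np.sum(resid**2))


def fit_isotherm(series: BindingSeries, model: str = "hyperbolic",
                 probe_uM: float | None = None) -> IsothermFit:
    """Fit the binding isotherm per replicate and pooled.

    Initialisation: Kd0 = concentration nearest half-maximal binding,
    Bmax0 = maximal observed fraction.  Kd is reported as the mean +/- SD
    of per-replicate estimates; the pooled fit uses all points at once.
    Warnings (not errors): a titration spanning less than one order of
    magnitude, and a fitted Kd exceeding 5x the top concentration
    ("poorly constrained").
    """
    conc = series.concentrations_uM
    if len(conc) < 3:
        raise BiochemError("need at least 3 distinct concentrations to fit")
    warns: list[str] = []
    if conc.max() / conc.min() < 10.0:
        warns.append("concentration span below one order of magnitude")
        warnings.warn(warns[-1], stacklevel=2)

    kds, bmaxs = [], []
    for rep in series.fraction_bound:
        kd, bm, _ = _fit_one(conc, rep, model, probe_uM)
        kds.append(kd)
        bmaxs.append(bm)
    kds = np.array(kds)
    bmaxs = np.array(bmaxs)

    pooled_conc = np.tile(conc, series.n_replicates)
    pooled_frac = series.fraction_bound.ravel()
    pkd, pbm, prss = _fit_one(pooled_conc, pooled_frac, model, probe_uM)

    if pkd > 5.0 * conc.max():
        warns.append("poorly constrained: fitted Kd exceeds 5x top concentration")
        warnings.warn(warns[-1], stacklevel=2)
    if np.ptp(pooled_frac) < 1e-3:
        warns.append("no curvature: Kd unconstrained (constant response)")
        warnings.warn(warns[-1], stacklevel=2)

    return IsothermFit(
        kd_uM=float(kds.mean()), kd_sd_uM=float(kds.std(ddof=1)) if len(kds) > 1 else math.nan,
        bmax=float(bmaxs.mean()), bmax_sd=float(bmaxs.std(ddof=1)) if len(bmaxs) > 1 else math.nan,
        kd_per_replicate=kds, bmax_per_replicate=bmaxs,
        pooled_kd_uM=pkd, pooled_bmax=pbm, pooled_rss=prss,
        warnings=warns)


def binding_series_from_rows(rows: pd.DataFrame,
                             condition: str | None = None) -> BindingSeries:
    """Reduce densitometry rows to a BindingSeries (fractions per replicate).

    ``rows`` uses the densitometry CSV layout; when ``condition`` is given,
    rows are filtered to it first.  Every replicate must cover the same
    concentration grid.
    """
    if condition is not None:
        rows = rows[rows["condition"] == condition]
    if rows.empty:
        raise BiochemError("no densitometry rows for the requested condition")
    conc = np.array(sorted(rows["concentration_uM"].unique()))
    reps = sorted(rows["replicate"].unique())
    frac = np.empty((len(reps), len(conc)))
    for i, rep in enumerate(reps):
        sub = rows[rows["replicate"] == rep].set_index("concentration_uM")
        for j, c in enumerate(conc):
            r = sub.loc[c]
            frac[i, j] = band_fraction(float(r["pellet"]), float(r["supernatant"]))
    return BindingSeries(conc, frac)


# ---------------------------------------------------------------------------
# Dose-response summaries (bundling assays)
# ---------------------------------------------------------------------------

DENSITOMETRY_COLUMNS = ["condition", "concentration_uM", "replicate",
                        "pellet", "supernatant"]


def dose_response_summary(rows: pd.DataFrame) -> pd.DataFrame:
    """Per-condition, per-concentration mean +/- SD of the pellet fraction.

    ``rows`` follows the densitometry CSV layout (condition,
    concentration_uM, replicate, pellet, supernatant).  No curve is fitted:
    bundling dose curves are reported as summary points.  A group with a
    single replicate gets SD = NaN and ``sd_defined = False``.
    """
    missing = [c for c in DENSITOMETRY_COLUMNS if c not in rows.columns]
    if missing:
        raise BiochemError(f"missing densitometry columns: {missing}")
    frac = np.array([band_fraction(p, s) for p, s in
                     zip(rows["pellet"], rows["supernatant"])])
    work = rows[["condition", "concentration_uM"]].copy()
    work["fraction"] = frac
    out = []
    for (cond, conc), grp in work.groupby(["condition", "concentration_uM"], sort=True):
        f = grp["fraction"].to_numpy()
        out.append({
            "condition": cond, "concentration_uM": conc,
            "n": len(f), "mean_fraction": float(f.mean()),
            "sd_fraction": float(f.std(ddof=1)) if len(f) > 1 else math.nan,
            "sd_defined": len(f) > 1,
        })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Size-exclusion chromatography
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SecResult:
    slope: float                  # d log10(MW) / d elution volume (negative)
    intercept: float
    apparent_mw_kDa: float
    theoretical_mw_kDa: float
    ratio: float
    oligomer_state: int
    extrapolated: bool


def sec_oligomer(standards: list[tuple[float, float]], sample_elution: float,
                 theoretical_mw_kDa: float) -> SecResult:
    """Apparent MW and oligomeric state from an SEC calibration.

    ``standards`` is a list of (MW in kDa, elution volume) for at least
    three calibrants; elution volume must decrease strictly with log10(MW)
    (larger species elute earlier).  The calibration is a least-squares
    line of log10(MW) on elution volume; the sample's apparent MW is read
    off by inversion, and the oligomeric state is the nearest positive
    integer of apparent/theoretical monomer MW.
    """
    if len(standards) < 3:
        raise BiochemError("need at least 3 SEC standards")
    if theoretical_mw_kDa <= 0:
        raise BiochemError("theoretical MW must be positive")
    mw = np.array([s[0] for s in standards], dtype=float)
    vol = np.array([s[1] for s in standards], dtype=float)
    order = np.argsort(mw)
    if not np.all(np.diff(vol[order]) < 0):
        raise BiochemError("standards not strictly monotonic: elution volume "
                           "must decrease with molecular weight")
    res = stats.linregress(vol, np.log10(mw))
    apparent = float(10.0 ** (res.slope * sample_elution + res.intercept))
    extrapolated = not (vol.min() <= sample_elution <= vol.max())
    if extrapolated:
        warnings.warn("sample elution volume outside calibration range "
                      "(extrapolated apparent MW)", stacklevel=2)
    ratio = apparent / theoretical_mw_kDa
    state = max(int(round(ratio)), 1)
    return SecResult(slope=float(res.slope), intercept=float(res.intercept),
                     apparent_mw_kDa=apparent,
                     theoretical_mw_kDa=theoretical_mw_kDa,
                     ratio=float(ratio), oligomer_state=state,
                     extrapolated=extrapolated)
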