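"""RELION particle STAR input/output and per-filament grouping.

Reads the particle metadata of helical-segment picks — coordinates, ZYZ Euler
angles (rot, tilt, psi) and helical tube IDs — from RELION 3.0 (flat) or 3.1
(``data_optics`` + ``data_particles``) STAR files, normalises angle ranges,
and groups segments into per-filament traces ordered along the filament axis.

Parsing and serialisation are delegated to :mod:`gemmi`, which handles STAR
syntax (quoting, comments, multi-block documents); this module owns the
RELION column conventions and the image-to-math coordinate contract.

Coordinate conventions
----------------------
STAR coordinates are 0-based pixels in image convention: origin top-left,
y increasing downward.  All geometry downstream works in a math-convention
frame (y increasing upward).  The conversion is a single documented flip,
``(x_math, y_math) = (x_px, -y_px)`` (scaled to nm) — see
:meth:`FilamentTrace.coords_nm`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column name -> required RELION tag.
REQUIRED_COLUMNS: dict[str, str] = {
    "micrograph_id": "_rlnMicrographName",
    "x_px": "_rlnCoordinateX",
    "y_px": "_rlnCoordinateY",
    "rot_deg": "_rlnAngleRot",
    "tilt_deg": "_rlnAngleTilt",
    "psi_deg": "_rlnAnglePsi",
    "tube_id": "_rlnHelicalTubeID",
}

PIXEL_SIZE_TAG = "_rlnImagePixelSize"

_NUMERIC = ("x_px", "y_px", "rot_deg", "tilt_deg", "psi_deg")


class StarError(ValueError):
    """Structured STAR parsing/validation failure."""


class MissingColumnError(StarError):
    def __init__(self, column: str, block: str = "particles"):
        self.column = column
        super().__init__(f"missing column {column!r} in {block} table")


def wrap_angle_deg(a):
    """Reduce an angle (deg) to the half-open interval [-180, 180)."""
    return (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass
class ParticleTable:
    """Particle metadata table.

    ``df`` holds the canonical columns (:data:`REQUIRED_COLUMNS` keys, plus
    ``pixel_size_A`` when known); ``extra`` preserves any further STAR
    columns verbatim (same row order) so that a read -> write round trip
    loses nothing.
    """

    df: pd.DataFrame
    extra: pd.DataFrame = field(default_factory=pd.DataFrame)
    pixel_size_A: float | None = None

    def __len__(self) -> int:
        return len(self.df)

    def validate(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise MissingColumnError(REQUIRED_COLUMNS[missing[0]])
        tilt = self.df["tilt_deg"].to_numpy(float)
        if np.any((tilt < 0) | (tilt > 180)):
            raise StarError("tilt_deg outside [0, 180]")
        if self.pixel_size_A is not None and self.pixel_size_A <= 0:
            raise StarError("pixel_size_A must be positive")
        key = self.df[["micrograph_id", "tube_id", "x_px", "y_px"]]
        if key.duplicated().any():
            raise StarError("duplicate (micrograph, tube, x, y) particle keys")


@dataclass
class FilamentTrace:
    """Ordered segments of one filament within one micrograph.

    Particles are sorted by their projection onto the group's principal
    axis.  Traces with fewer than two particles cannot define a direction
    and are flagged ``untraceable``.  ``axis`` and ``polarity`` are attached
    by downstream stages.
    """

    micrograph_id: str
    tube_id: int
    particles: pd.DataFrame
    pixel_size_A: float
    axis: object | None = None
    polarity: object | None = None

    @property
    def n_particles(self) -> int:
        return len(self.particles)

    @property
    def untraceable(self) -> bool:
        return self.n_particles < 2

    def coords_nm(self) -> np.ndarray:
        """Particle coordinates in the math-convention frame, in nm.

        The image->math conversion is the single y flip of the module
        contract: ``(x, y)_math = (x_px, -y_px) * pixel_size / 10``.
        """
        xy = self.particles[["x_px", "y_px"]].to_numpy(float).copy()
        xy[:, 1] *= -1.0
        return xy * (self.pixel_size_A / 10.0)


def _loop_dataframe(block: gemmi.cif.Block) -> pd.DataFrame | None:
    """First loop of a block as a string DataFrame, or None."""
    for item in block:
        if item.loop is not None:
            loop = item.loop
            n, w = loop.length(), loop.width()
            vals = np.array([gemmi.cif.as_string(v) for v in loop.values],
                            dtype=object).reshape(n, w)
            return pd.DataFrame(vals, columns=list(loop.tags))
    return None


def _to_float(series: pd.Series, tag: str) -> np.ndarray:
    out = np.empty(len(series), dtype=float)
    for i, v in enumerate(series.to_numpy()):
        try:
            out[i] = float(v)
        except (TypeError, ValueError):
            raise StarError(f"malformed numeric value {v!r} for {tag} at row {i}")
    return out


def read_particles(source: str | Path) -> ParticleTable:
    """Read a RELION particle STAR file (3.0 flat or 3.1 optics dialect).

    Parameters
    ----------
    source:
        Path to a STAR file, or the STAR text itself (recognised by the
        presence of a ``loop_`` keyword and absence of such a file on disk).

    Returns
    -------
    ParticleTable
        Canonical columns normalised: ``rot_deg``/``psi_deg`` wrapped to
        [-180, 180), ``tilt_deg`` validated against [0, 180]; unknown STAR
        columns preserved in ``extra``; pixel size taken from the optics
        table (or a per-particle ``_rlnImagePixelSize`` column) when present.
    """
    if isinstance(source, str) and "\n" in source:
        text = source
    else:
        text = Path(source).read_text()
    doc = gemmi.cif.read_string(text)

    particles_block = None
    optics_block = None
    for block in doc:
        if block.name == "particles" or block.name.endswith("particles"):
            particles_block = block
        elif block.name == "optics" or block.name.endswith("optics"):
            optics_block = block
    if particles_block is None:
        # RELION 3.0 flat dialect: single block, whatever its name.
        loops = [b for b in doc if _loop_dataframe(b) is not None]
        if not loops:
            raise StarError("no loop_ block found in STAR source")
        particles_block = loops[0]

    raw = _loop_dataframe(particles_block)
    if raw is None:
        # header-only block (e.g. an empty written table): gemmi drops the
        # loop when it has no rows, so reconstruct an empty frame from any
        # bare tags present, else from the required columns
        tags = [item.pair[0] for item in particles_block
                if item.pair is not None and item.pair[0].startswith("_")]
        raw = pd.DataFrame(columns=tags or list(REQUIRED_COLUMNS.values()))

    for canon, tag in REQUIRED_COLUMNS.items():
        if tag not in raw.columns:
            raise MissingColumnError(tag)

    df = pd.DataFrame()
    df["micrograph_id"] = raw[REQUIRED_COLUMNS["micrograph_id"]].astype(str)
    for canon in _NUMERIC:
        df[canon] = _to_float(raw[REQUIRED_COLUMNS[canon]], REQUIRED_COLUMNS[canon])
    tube = _to_float(raw[REQUIRED_COLUMNS["tube_id"]], REQUIRED_COLUMNS["tube_id"])
    df["tube_id"] = tube.astype(int)
    df["rot_deg"] = wrap_angle_deg(df["rot_deg"])
    df["psi_deg"] = wrap_angle_deg(df["psi_deg"])

    pixel_size = None
    if PIXEL_SIZE_TAG in raw.columns:
        ps = _to_float(raw[PIXEL_SIZE_TAG], PIXEL_SIZE_TAG)
        pixel_size = float(ps[0])
    elif optics_block is not None:
        opt = _loop_dataframe(optics_block)
        if opt is not None and PIXEL_SIZE_TAG in opt.columns:
            pixel_size = float(opt[PIXEL_SIZE_TAG].iloc[0])
        elif optics_block.find_value(PIXEL_SIZE_TAG) is not None:
            pixel_size = float(optics_block.find_value(PIXEL_SIZE_TAG))

    known_tags = set(REQUIRED_COLUMNS.values())
    extra = raw[[c for c in raw.columns if c not in known_tags]].copy()

    table = ParticleTable(df=df, extra=extra, pixel_size_A=pixel_size)
    table.validate()
    return table


def write_particles(table: ParticleTable, path: str | Path | None = None) -> str:
    """Serialise a ParticleTable to RELION 3.1 STAR text.

    Emits a ``data_optics`` block when the table carries a pixel size, then
    a ``data_particles`` loop with the canonical columns followed by any
    preserved extra columns verbatim.  ``read_particles(write_particles(t))``
    is value-identical to ``t`` on the required columns.
    """
    doc = gemmi.cif.Document()
    if table.pixel_size_A is not None:
        optics = doc.add_new_block("optics")
        loop = optics.init_loop("", ["_rlnOpticsGroup", PIXEL_SIZE_TAG])
        loop.add_row(["1", _fmt(table.pixel_size_A)])

    particles = doc.add_new_block("particles")
    tags = list(REQUIRED_COLUMNS.values()) + [c for c in table.extra.columns]
    loop = particles.init_loop("", tags)
    extra_vals = table.extra.to_numpy(dtype=object) if len(table.extra.columns) else None
    df = table.df
    for i in range(len(df)):
        row = [
            str(df["micrograph_id"].iat[i]),
            _fmt(df["x_px"].iat[i]),
            _fmt(df["y_px"].iat[i]),
            _fmt(df["rot_deg"].iat[i]),
            _fmt(df["tilt_deg"].iat[i]),
            _fmt(df["psi_deg"].iat[i]),
            str(int(df["tube_id"].iat[i])),
        ]
        if extra_vals is not None:
            row += [str(v) for v in extra_vals[i]]
        loop.add_row([gemmi.cif.quote(v) for v in row])

    text = doc.as_string()
    if path is not None:
        Path(path).write_text(text)
    return text


def _fmt(x: float) -> str:
    return f"{float(x):.6f}".rstrip("0").rstrip(".") or "0"


def group_filaments(table: ParticleTable,
                    pixel_size_A: float | None = None) -> list[FilamentTrace]:
    """Group particles into per-filament traces.

    One group per ``(micrograph_id, tube_id)``.  Within a group, particles
    are ordered by their projection onto the group's principal axis (first
    principal component of the coordinates), making the ordering invariant
    to input row order.  Single-particle groups are returned flagged
    ``untraceable`` and logged; downstream geometry skips them.
    """
    table.validate()
    if len(table) == 0:
        raise StarError("empty particle table")
    ps = table.pixel_size_A if table.pixel_size_A is not None else pixel_size_A
    if ps is None:
        raise StarError("pixel size unknown: not in STAR file and not supplied")

    traces: list[FilamentTrace] = []
    for (mic, tube), grp in sorted(table.df.groupby(["micrograph_id", "tube_id"], sort=True),
                                   key=lambda kv: (kv[0][0], kv[0][1])):
        grp = grp.reset_index(drop=True)
        if len(grp) >= 2:
            xy = grp[["x_px", "y_px"]].to_numpy(float)
            centered = xy - xy.mean(axis=0)
            _, _, vt = np.linalg.svd(centered, full_matrices=False)
            axis = vt[0]
            # Deterministic sign: principal axis points toward +x (then +y).
            if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
                axis = -axis
            proj = centered @ axis
            order = np.argsort(proj, kind="stable")
            grp = grp.iloc[order].reset_index(drop=True)
        trace = FilamentTrace(micrograph_id=str(mic), tube_id=int(tube),
                              particles=grp, pixel_size_A=float(ps))
        if trace.untraceable:
            logger.warning("tube %s in %s has %d particle(s): untraceable",
                           tube, mic, len(grp))
        traces.append(trace)
    return traces


def usable_traces(traces: list[FilamentTrace]) -> list[FilamentTrace]:
    """Traces with at least two particles (geometry-capable)."""
    return [t for t in traces if not t.untraceable]
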