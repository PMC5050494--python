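"""Data model, readers/writers and filtering for single-molecule localization tables.

A localization table is a list of single-fluorophore detection events, each
reduced to an x/y position (nanometers), the camera frame it was detected in,
and optional per-event metadata (photon count, PSF width, background,
localization precision, color channel).  Tables are the universal currency of
this package: every analysis operation consumes one.

Internal conventions
--------------------
* Coordinates are always nanometers, origin at the top-left of the field,
  x rightward, y downward.
* Frames are 0-based internally.  ThunderSTORM counts frames from 1; the
  reader shifts them.
* Unknown columns are carried through untouched and never interpreted.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from shapely import intersects_xy

from .exceptions import FormatError, ParseError, SchemaError

#: internal column names, in canonical output order
CANONICAL_COLUMNS = (
    "x", "y", "frame", "photons", "psf_sigma", "background", "precision", "channel",
)

MANDATORY = ("x", "y", "frame")

#: column headers of the internal TSV dialect, aligned with CANONICAL_COLUMNS
_INTERNAL_HEADER = (
    "x_nm", "y_nm", "frame", "photons", "psf_sigma_nm", "background",
    "precision_nm", "channel",
)


@dataclass
class ReaderConfig:
    """Parameters needed to interpret a localization file.

    pixel_size_nm
        Camera pixel size; used to convert pixel-unit coordinates to nm and
        consumed by the photon-statistics precision formulas.
    column_map
        Optional explicit mapping from file column name to internal role
        (one of :data:`CANONICAL_COLUMNS`); overrides the dialect's
        automatic header recognition.
    unit_of_xy
        ``"nm"`` or ``"pixel"``; pixel coordinates are multiplied by
        ``pixel_size_nm``.
    frame_base
        First frame index used by the file (0 or 1).  ``None`` selects the
        dialect default (rapidSTORM 0, ThunderSTORM 1, internal 0).
    dialect
        ``"rapidstorm"``, ``"thunderstorm"``, ``"lama_internal"`` or ``None``
        for sniffing.
    """

    pixel_size_nm: float = 100.0
    column_map: dict[str, str] | None = None
    unit_of_xy: str = "nm"
    frame_base: int | None = None
    dialect: str | None = None

    def __post_init__(self):
        if not self.pixel_size_nm > 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.unit_of_xy not in ("nm", "pixel"):
            raise ValueError("unit_of_xy must be 'nm' or 'pixel'")


class LocalizationTable:
    """An ordered collection of localizations plus its spatial region.

    Parameters
    ----------
    data
        DataFrame with at least columns ``x``, ``y`` (nm) and ``frame``
        (0-based int).  Optional recognized columns: ``photons``,
        ``psf_sigma``, ``background``, ``precision``, ``channel``.  Any other
        columns are preserved as opaque extras.
    region
        ``(x0, y0, x1, y1)`` axis-aligned bounding rectangle in nm.  Derived
        as the tight bounding box of the data when omitted.  Analyses that
        assume the observation window (e.g. Ripley edge correction) read it
        from here, so widen it explicitly when the data under-fill the field.
    pixel_size
        nm per camera pixel (metadata; used for unit conversion on write).
    source_format
        Provenance tag: ``rapidstorm``, ``thunderstorm`` or ``lama_internal``.
    """

    def __init__(self, data: pd.DataFrame, region=None, pixel_size: float = 100.0,
                 source_format: str = "lama_internal"):
        data = data.reset_index(drop=True)
        for col in MANDATORY:
            if col not in data.columns:
                raise SchemaError(f"mandatory column {col!r} missing")
        data = data.copy()
        data["x"] = data["x"].astype(float)
        data["y"] = data["y"].astype(float)
        data["frame"] = data["frame"].astype(np.int64)
        self._validate(data)
        self.data = data
        self.pixel_size = float(pixel_size)
        self.source_format = source_format
        if region is None:
            region = self._derive_region(data)
        else:
            region = tuple(float(v) for v in region)
            if len(region) != 4:
                raise ValueError("region must be (x0, y0, x1, y1)")
        self.region = region

    @staticmethod
    def _validate(data: pd.DataFrame) -> None:
        if len(data):
            if not (np.isfinite(data["x"]).all() and np.isfinite(data["y"]).all()):
                raise ValueError("x and y must be finite")
            if (data["frame"] < 0).any():
                raise ValueError("frame indices must be >= 0")
            if "photons" in data and (data["photons"].dropna() < 0).any():
                raise ValueError("photon counts must be >= 0")
            if "psf_sigma" in data and (data["psf_sigma"].dropna() <= 0).any():
                raise ValueError("psf_sigma must be > 0")

    @staticmethod
    def _derive_region(data: pd.DataFrame):
        if not len(data):
            return (0.0, 0.0, 0.0, 0.0)
        return (float(data["x"].min()), float(data["y"].min()),
                float(data["x"].max()), float(data["y"].max()))

    # -- convenience ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def coordinates(self) -> np.ndarray:
        """(n, 2) float array of x/y positions in nm."""
        return self.data[["x", "y"]].to_numpy(dtype=float)

    @property
    def frames(self) -> np.ndarray:
        return self.data["frame"].to_numpy()

    @property
    def region_size(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.region
        return (x1 - x0, y1 - y0)

    @property
    def region_area(self) -> float:
        w, h = self.region_size
        return w * h

    def with_data(self, data: pd.DataFrame, region=None) -> "LocalizationTable":
        """New table with replaced records, inheriting metadata."""
        return LocalizationTable(data, region=region if region is not None else self.region,
                                 pixel_size=self.pixel_size,
                                 source_format=self.source_format)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"LocalizationTable(n={len(self)}, region={self.region}, "
                f"source={self.source_format!r})")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

# ThunderSTORM header name -> role; units in brackets are parsed separately
_THUNDERSTORM_ROLES = {
    "x": "x", "y": "y", "frame": "frame",
    "intensity": "photons", "sigma": "psf_sigma", "bkgstd": "background",
    "offset": None,  # camera offset, kept as extra
    "uncertainty": "precision", "uncertainty_xy": "precision",
    "channel": "channel",
}

# rapidSTORM field identifier prefix -> role
_RAPIDSTORM_ROLES = {
    "Position-0": "x",
    "Position-1": "y",
    "ImageNumber": "frame",
    "Amplitude": "photons",
    "PSFWidth-0": "psf_sigma",
    "LocalizationPrecision": "precision",
    "FluorophoreType": "channel",
}


def _sniff_dialect(first_line: str) -> str:
    if first_line.lstrip().startswith("#") and "<" in first_line:
        return "rapidstorm"
    stripped = [h.strip() for h in first_line.rstrip("\n").split("\t")]
    if stripped[:3] == list(_INTERNAL_HEADER[:3]):
        return "lama_internal"
    if "," in first_line or first_line.strip().startswith('"'):
        return "thunderstorm"
    raise FormatError("could not recognize localization-table dialect from header")


def read_localizations(path, config: ReaderConfig | None = None) -> LocalizationTable:
    """Read a localization file in any supported dialect.

    Coordinates are converted to nm and frames to 0-based indices.  Row order
    is preserved.  Raises :class:`FormatError` for an unknown dialect,
    :class:`SchemaError` when x/y/frame cannot be found and
    :class:`ParseError` (with the offending row) for non-numeric cells.
    """
    config = config or ReaderConfig()
    with open(path, "r", newline="") as fh:
        text = fh.read()
    # normalize line endings so output is OS-independent
    text = text.replace("\r\n", "\n").replace("\r", "\n")
    if not text.strip():
        raise FormatError(f"{path}: empty file")
    first_line = text.split("\n", 1)[0]
    dialect = config.dialect or _sniff_dialect(first_line)
    if dialect == "rapidstorm":
        return _read_rapidstorm(text, config)
    if dialect == "thunderstorm":
        return _read_thunderstorm(text, config)
    if dialect == "lama_internal":
        return _read_internal(text, config)
    raise FormatError(f"unknown dialect {dialect!r}")


def _finalize(df: pd.DataFrame, roles: dict[str, str], units: dict[str, str],
              config: ReaderConfig, source_format: str,
              default_frame_base: int) -> LocalizationTable:
    """Map raw columns to roles, convert units and frame base."""
    if config.column_map:
        roles = {**roles, **config.column_map}
    rename = {}
    seen = set()
    for col, role in roles.items():
        if role and role in CANONICAL_COLUMNS and role not in seen and col in df.columns:
            rename[col] = role
            seen.add(role)
    df = df.rename(columns=rename)
    missing = [c for c in MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column role(s): {', '.join(missing)}")

    for col in df.columns:
        if col == "frame" or col not in CANONICAL_COLUMNS:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"non-numeric value {df[col].iloc[row]!r} in column {col!r} at data row {row}",
                row=row)
        df[col] = coerced
    frame_raw = pd.to_numeric(df["frame"], errors="coerce")
    if frame_raw.isna().any():
        row = int(np.flatnonzero(frame_raw.isna().to_numpy())[0])
        raise ParseError(f"non-numeric frame at data row {row}", row=row)

    for axis in ("x", "y"):
        # a unit declared in the file header wins over the config default
        unit = units.get(axis) or config.unit_of_xy
        factor = config.pixel_size_nm if unit == "pixel" else 1.0
        df[axis] = df[axis].astype(float) * factor

    base = config.frame_base if config.frame_base is not None else default_frame_base
    df["frame"] = frame_raw.astype(np.int64) - base
    return LocalizationTable(df, pixel_size=config.pixel_size_nm,
                             source_format=source_format)


def _read_thunderstorm(text: str, config: ReaderConfig) -> LocalizationTable:
    df = pd.read_csv(io.StringIO(text), dtype=str, skipinitialspace=True)
    roles, units = {}, {}
    for col in df.columns:
        m = re.match(r'^\s*"?([A-Za-z_]+)"?\s*(?:\[(\w+)\])?\s*$', col)
        if not m:
            continue
        name, unit = m.group(1).lower(), m.group(2)
        role = _THUNDERSTORM_ROLES.get(name)
        if role:
            roles[col] = role
            if unit:
                units[role] = {"nm": "nm", "px": "pixel", "pixel": "pixel"}.get(unit.lower())
    return _finalize(df, roles, units, config, "thunderstorm", default_frame_base=1)


def _read_rapidstorm(text: str, config: ReaderConfig) -> LocalizationTable:
    lines = text.split("\n")
    header = lines[0]
    fields = re.findall(r'<field\s+([^>]*?)/?>', header)
    roles, units, names = {}, {}, []
    for i, attrs in enumerate(fields):
        ident = re.search(r'identifier="([^"]+)"', attrs)
        unit = re.search(r'unit="([^"]+)"', attrs)
        name = ident.group(1) if ident else f"field_{i}"
        names.append(name)
        for prefix, role in _RAPIDSTORM_ROLES.items():
            if name.startswith(prefix):
                roles[name] = role
                if unit and role in ("x", "y"):
                    units[role] = {"nanometer": "nm", "nm": "nm",
                                   "pixel": "pixel", "px": "pixel"}.get(unit.group(1))
                break
    if not names:
        raise FormatError("rapidSTORM header contains no <field> declarations")
    body = "\n".join(ln for ln in lines[1:] if ln.strip())
    df = pd.read_csv(io.StringIO(body), sep=r"\s+", header=None, dtype=str,
                     names=names) if body else pd.DataFrame(columns=names)
    return _finalize(df, roles, units, config, "rapidstorm", default_frame_base=0)


def _read_internal(text: str, config: ReaderConfig) -> LocalizationTable:
    df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str)
    roles = dict(zip(_INTERNAL_HEADER, CANONICAL_COLUMNS))
    units = {"x": "nm", "y": "nm"}
    df = df.dropna(axis=1, how="all")
    return _finalize(df, roles, units, config, "lama_internal", default_frame_base=0)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_localizations(table: LocalizationTable, path, dialect: str = "thunderstorm") -> None:
    """Write a table as ThunderSTORM-style CSV or the internal TSV.

    The round trip write → read reproduces x, y, frame and photons to within
    1e-6 nm.
    """
    if dialect == "thunderstorm":
        _write_thunderstorm(table, path)
    elif dialect == "lama_internal":
        _write_internal(table, path)
    else:
        raise FormatError(f"unsupported output dialect {dialect!r}")


_TS_HEADERS = {
    "x": "x [nm]", "y": "y [nm]", "frame": "frame", "photons": "intensity [photon]",
    "psf_sigma": "sigma [nm]", "background": "bkgstd [photon]",
    "precision": "uncertainty [nm]", "channel": "channel",
}


def _ordered_present(table: LocalizationTable):
    return [c for c in CANONICAL_COLUMNS if c in table.data.columns]


def _write_thunderstorm(table: LocalizationTable, path) -> None:
    cols = _ordered_present(table)
    out = table.data[cols].copy()
    out["frame"] = out["frame"] + 1  # ThunderSTORM counts frames from 1
    out = out.rename(columns={c: _TS_HEADERS[c] for c in cols})
    out.to_csv(path, index=False, float_format="%.6f",
               quoting=2, lineterminator="\n")  # QUOTE_NONNUMERIC


def _write_internal(table: LocalizationTable, path) -> None:
    cols = _ordered_present(table)
    out = table.data[cols].rename(
        columns=dict(zip(CANONICAL_COLUMNS, _INTERNAL_HEADER)))
    out.to_csv(path, sep="\t", index=False, float_format="%.6f", lineterminator="\n")


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_localizations(table: LocalizationTable, roi=None, frame_range=None,
                         min_photons=None) -> LocalizationTable:
    """Subset a table by region of interest, frame window and photon count.

    Parameters
    ----------
    roi
        ``(x0, y0, x1, y1)`` rectangle in nm with half-open containment
        ``[x0, x1) × [y0, y1)`` (so adjacent tiles partition points uniquely),
        or a simple :class:`shapely.geometry.Polygon` (boundary-inclusive),
        or ``None``.
    frame_range
        Inclusive ``(lo, hi)`` 0-based frame window, or ``None``.
    min_photons
        Keep records with ``photons >= min_photons``; requires the photons
        column.

    Record order is preserved; the region shrinks to the ROI bounding box
    when an ROI is given.  Filtering is idempotent.
    """
    data = table.data
    mask = np.ones(len(data), dtype=bool)
    region = table.region

    if roi is not None:
        x = data["x"].to_numpy(dtype=float)
        y = data["y"].to_numpy(dtype=float)
        if isinstance(roi, Polygon):
            if not roi.is_simple or not roi.is_valid:
                raise ValueError("polygon ROI must be simple and valid")
            mask &= intersects_xy(roi, x, y)
            region = tuple(roi.bounds)
        else:
            x0, y0, x1, y1 = (float(v) for v in roi)
            mask &= (x >= x0) & (x < x1) & (y >= y0) & (y < y1)
            region = (x0, y0, x1, y1)

    if frame_range is not None:
        lo, hi = frame_range
        if lo > hi:
            raise ValueError(f"inverted frame_range ({lo}, {hi})")
        f = data["frame"].to_numpy()
        mask &= (f >= lo) & (f <= hi)

    if min_photons is not None:
        if "photons" not in data.columns:
            raise SchemaError("min_photons filter requires a photons column")
        mask &= data["photons"].to_numpy(dtype=float) >= min_photons

    return table.with_data(data.loc[mask], region=region)
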