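"""Localization-table I/O, pipeline configuration and run logging.

Localization tables are plain :class:`pandas.DataFrame` objects with one row
per single-molecule localization and columns

``frame``
    0-based acquisition frame index.
``x, y``
    position in nm (origin at the lower-left corner of the field of view,
    y increasing upward).
``precision``
    per-localization precision sigma in nm (isotropic; when a source stores
    separate x/y precisions their mean is used).
``photons``
    optional photon count (NaN when unknown).
``channel``
    barcode identifier, an integer in ``0..n_channels-1``.  String labels
    ``R1..R6`` in input files are mapped to ``0..5``.

Two on-disk dialects are supported: CSV (one file per channel, header line
``frame,x,y,precision,photons,channel``) and HDF5 (one file holding groups
``/channel_<i>/`` with one 1-D dataset per column and a root attribute
``units='nm'``).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ResiGlycoError",
    "SchemaError",
    "ValidationError",
    "ConfigError",
    "AlignmentError",
    "DataError",
    "LOC_COLUMNS",
    "REQUIRED_COLUMNS",
    "empty_localizations",
    "make_localizations",
    "validate_localizations",
    "read_localizations",
    "write_localizations",
    "ClusteringConfig",
    "TraceFilterConfig",
    "DbscanConfig",
    "AreasConfig",
    "NndConfig",
    "CsrConfig",
    "KineticsConfig",
    "NoiseConfig",
    "SimulateConfig",
    "PipelineConfig",
    "load_config",
    "resolve_config",
    "config_to_dict",
    "get_logger",
    "setup_logging",
]


# --------------------------------------------------------------------------
# errors and logging
# --------------------------------------------------------------------------

class ResiGlycoError(Exception):
    """Base class for all package errors."""


class SchemaError(ResiGlycoError):
    """An input file does not have the expected columns/layout."""


class ValidationError(ResiGlycoError):
    """Data or parameters violate an invariant."""


class ConfigError(ResiGlycoError):
    """Malformed or inconsistent pipeline configuration."""


class AlignmentError(ResiGlycoError):
    """Channel alignment failed (e.g. no mutual fiducial matches)."""


class DataError(ResiGlycoError):
    """A pipeline stage input is missing or unreadable."""


_LOGGER_NAME = "resiglyco"


def get_logger(name: str | None = None) -> logging.Logger:
    return logging.getLogger(_LOGGER_NAME if name is None else f"{_LOGGER_NAME}.{name}")


def setup_logging(level: int = logging.INFO, logfile: str | Path | None = None) -> logging.Logger:
    """Configure the package logger; optionally tee to ``logfile``."""
    logger = logging.getLogger(_LOGGER_NAME)
    logger.setLevel(level)
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s: %(message)s")
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(fmt)
        logger.addHandler(sh)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(fmt)
        logger.addHandler(fh)
    return logger


# --------------------------------------------------------------------------
# localization tables
# --------------------------------------------------------------------------

LOC_COLUMNS = ("frame", "x", "y", "precision", "photons", "channel")
REQUIRED_COLUMNS = ("frame", "x", "y", "precision")

_DTYPES = {
    "frame": np.int64,
    "x": np.float64,
    "y": np.float64,
    "precision": np.float64,
    "photons": np.float64,
    "channel": np.int64,
}


def empty_localizations() -> pd.DataFrame:
    """Return an empty localization table with the canonical columns."""
    return pd.DataFrame({c: pd.Series(dtype=_DTYPES[c]) for c in LOC_COLUMNS})


def make_localizations(
    frame: Iterable[int],
    x: Iterable[float],
    y: Iterable[float],
    precision: Iterable[float],
    photons: Iterable[float] | None = None,
    channel: Iterable[int] | int = 0,
) -> pd.DataFrame:
    """Assemble a localization table from column arrays."""
    frame = np.asarray(frame, dtype=np.int64)
    n = frame.size
    if photons is None:
        photons = np.full(n, np.nan)
    if np.isscalar(channel):
        channel = np.full(n, int(channel), dtype=np.int64)
    df = pd.DataFrame(
        {
            "frame": frame,
            "x": np.asarray(x, dtype=np.float64),
            "y": np.asarray(y, dtype=np.float64),
            "precision": np.asarray(precision, dtype=np.float64),
            "photons": np.asarray(photons, dtype=np.float64),
            "channel": np.asarray(channel, dtype=np.int64),
        }
    )
    return df


def _parse_channel_values(values: np.ndarray) -> np.ndarray:
    """Map channel labels to integers: 'R1'..'R6' -> 0..5, ints pass through."""
    if values.dtype.kind in "iu":
        return values.astype(np.int64)
    if values.dtype.kind == "f":
        return values.astype(np.int64)
    out = np.empty(values.size, dtype=np.int64)
    for i, v in enumerate(values):
        s = str(v).strip()
        if s.upper().startswith("R") and s[1:].isdigit():
            out[i] = int(s[1:]) - 1
        else:
            try:
                out[i] = int(s)
            except ValueError as exc:
                raise ValidationError(f"unparseable channel label {v!r} at record {i}") from exc
    return out


def validate_localizations(
    df: pd.DataFrame,
    n_frames: int | None = None,
    fov: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Validate a localization table against its invariants.

    Checks column presence, finiteness of coordinates, strictly positive
    precisions, frame bounds (when ``n_frames`` is given) and FOV bounds
    (when ``fov=(width, height)`` is given).  Returns the table with
    canonical dtypes and column order.
    """
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"localization table is missing required column '{col}'")
    df = df.copy()
    if "photons" not in df.columns:
        df["photons"] = np.nan
    if "channel" not in df.columns:
        df["channel"] = 0
    df["channel"] = _parse_channel_values(df["channel"].to_numpy())
    for col, dt in _DTYPES.items():
        df[col] = df[col].astype(dt)
    df = df[list(LOC_COLUMNS)]

    xy = df[["x", "y"]].to_numpy()
    bad = ~np.isfinite(xy).all(axis=1)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise ValidationError(f"non-finite coordinate at record {idx}")
    if not np.isfinite(df["precision"].to_numpy()).all() or (df["precision"].to_numpy() <= 0).any():
        idx = int(np.flatnonzero(~(df["precision"].to_numpy() > 0))[0])
        raise ValidationError(f"non-positive precision at record {idx}")
    frames = df["frame"].to_numpy()
    if (frames < 0).any():
        raise ValidationError("negative frame index")
    if n_frames is not None and frames.size and frames.max() >= n_frames:
        raise ValidationError(f"frame index {frames.max()} >= n_frames={n_frames}")
    if fov is not None and len(df):
        w, h = fov
        if xy[:, 0].min() < 0 or xy[:, 0].max() > w or xy[:, 1].min() < 0 or xy[:, 1].max() > h:
            idx = int(
                np.flatnonzero(
                    (xy[:, 0] < 0) | (xy[:, 0] > w) | (xy[:, 1] < 0) | (xy[:, 1] > h)
                )[0]
            )
            raise ValidationError(f"coordinate outside FOV at record {idx}")
    return df


def read_localizations(
    path: str | Path,
    dialect: str = "csv",
    units: str = "nm",
    pixel_size: float | None = None,
    channel: int | None = None,
) -> pd.DataFrame:
    """Read a localization table from disk.

    Parameters
    ----------
    path:
        File to read.
    dialect:
        ``'csv'`` (one channel per file) or ``'hdf5'`` (all channels, one
        group per channel).
    units:
        ``'nm'`` or ``'px'``; pixel-unit coordinates and precisions are
        multiplied by ``pixel_size``.
    pixel_size:
        Camera pixel size in nm; required for ``units='px'``.
    channel:
        Channel id assigned to all records when the file has no channel
        column (CSV only).
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"localization file not found: {path}")
    if units not in ("nm", "px"):
        raise ConfigError(f"unknown units {units!r}; expected 'nm' or 'px'")
    if units == "px" and pixel_size is None:
        raise ConfigError("pixel_size is required when units='px'")

    if dialect == "csv":
        df = pd.read_csv(path)
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"{path}: missing required column '{col}'")
        if "channel" not in df.columns:
            if channel is None:
                raise SchemaError(
                    f"{path}: no 'channel' column and no per-file channel argument given"
                )
            df["channel"] = channel
    elif dialect == "hdf5":
        parts = []
        with h5py.File(path, "r") as f:
            groups = sorted(
                (name for name in f if name.startswith("channel_")),
                key=lambda s: int(s.split("_")[1]),
            )
            for name in groups:
                g = f[name]
                for col in REQUIRED_COLUMNS:
                    if col not in g:
                        raise SchemaError(f"{path}:/{name}: missing dataset '{col}'")
                part = pd.DataFrame({col: g[col][()] for col in g})
                part["channel"] = int(name.split("_")[1])
                parts.append(part)
        df = pd.concat(parts, ignore_index=True) if parts else empty_localizations()
    else:
        raise ConfigError(f"unknown dialect {dialect!r}; expected 'csv' or 'hdf5'")

    if units == "px":
        for col in ("x", "y", "precision"):
            df[col] = df[col].astype(np.float64) * float(pixel_size)
    return validate_localizations(df)


def write_localizations(table: pd.DataFrame, path: str | Path, dialect: str = "csv") -> None:
    """Write a localization table; inverse of :func:`read_localizations`."""
    table = validate_localizations(table)
    path = Path(path)
    if dialect == "csv":
        table.to_csv(path, index=False)
    elif dialect == "hdf5":
        with h5py.File(path, "w") as f:
            f.attrs["units"] = "nm"
            for ch, part in table.groupby("channel"):
                g = f.create_group(f"channel_{int(ch)}")
                for col in ("frame", "x", "y", "precision", "photons"):
                    g.create_dataset(col, data=part[col].to_numpy())
    else:
        raise ConfigError(f"unknown dialect {dialect!r}; expected 'csv' or 'hdf5'")


# --------------------------------------------------------------------------
# pipeline configuration
# --------------------------------------------------------------------------

@dataclass
class ClusteringConfig:
    """Per-channel RESI clustering parameters.

    ``r`` is the cluster radius in nm, ~2.35x the localization precision;
    ``n_min`` the minimum number of localizations a cluster must collect
    over the acquisition to count as a genuine binding site.
    """

    r: float = 7.15
    n_min: int = 10
    radius_factor: float = 2.35


@dataclass
class TraceFilterConfig:
    """Time-trace filter: binding-event structure a genuine site must show."""

    gap_frames: int = 5
    min_events: int = 3
    min_span_fraction: float = 0.1


@dataclass
class DbscanConfig:
    """DBSCAN parameters for site-level cluster analysis (nm / count)."""

    epsilon: float = 10.0
    min_pts: int = 2


@dataclass
class AreasConfig:
    """Selection of homogeneous analysis areas (0.5 um^2 squares by default)."""

    n_areas: int = 40
    area_side: float = 707.1
    density_band: tuple[float, float] = (0.5, 1.5)


@dataclass
class NndConfig:
    k_max: int = 4
    bin_width: float = 0.5


@dataclass
class CsrConfig:
    n_reps: int = 100
    toroidal: bool = True


@dataclass
class KineticsConfig:
    """DNA-PAINT binding kinetics of the simulator."""

    mean_events_per_site: float = 20.0
    mean_event_frames: float = 5.0


@dataclass
class NoiseConfig:
    """Localization noise and nonspecific binding of the simulator."""

    sigma_smlm: float = 3.0
    nonspecific_event_density: float = 500.0
    nonspecific_locs_min: int = 1
    nonspecific_locs_max: int = 3


@dataclass
class SimulateConfig:
    """Scene generation for the simulate stage."""

    mode: str = "csr"  # 'csr' or 'glycan'
    density: float = 1100.0  # sugar sites per um^2 (csr mode)
    protein_density: float = 220.0  # proteins per um^2 (glycan mode)
    glycans_per_protein: int = 1
    protein_jitter: float = 2.0
    templates: str = "default"
    dialect: str = "csv"
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)


@dataclass
class PipelineConfig:
    """Fully resolved pipeline configuration.

    Defaults carry the standard analysis parameters: clustering radius
    r = 7.15 nm with n_min = 10 localizations, DBSCAN epsilon = 10 nm with
    minPts = 2, N = 40 areas of 0.5 um^2, nearest neighbours up to K = 4,
    an acquisition of 40,000 frames over 6 barcode channels, and a camera
    pixel size of 130 nm for pixel-unit input tables.
    """

    fov_width: float = 4950.0
    fov_height: float = 4950.0
    n_frames: int = 40000
    n_channels: int = 6
    pixel_size: float = 130.0
    seed: int = 1
    clustering: ClusteringConfig = field(default_factory=ClusteringConfig)
    trace_filter: TraceFilterConfig = field(default_factory=TraceFilterConfig)
    dbscan: DbscanConfig = field(default_factory=DbscanConfig)
    areas: AreasConfig = field(default_factory=AreasConfig)
    nnd: NndConfig = field(default_factory=NndConfig)
    csr: CsrConfig = field(default_factory=CsrConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)

    def validate(self) -> "PipelineConfig":
        c = self
        if c.fov_width <= 0 or c.fov_height <= 0:
            raise ValidationError("FOV dimensions must be positive")
        if c.n_frames <= 0 or c.pixel_size <= 0:
            raise ValidationError("n_frames and pixel_size must be positive")
        if c.n_channels < 1:
            raise ValidationError("n_channels must be >= 1")
        if c.clustering.r <= 0:
            raise ValidationError("clustering.r must be positive")
        if c.clustering.n_min < 1:
            raise ValidationError("clustering.n_min must be >= 1")
        if c.trace_filter.gap_frames < 0 or c.trace_filter.min_events < 0:
            raise ValidationError("trace_filter parameters must be >= 0")
        if not 0.0 <= c.trace_filter.min_span_fraction <= 1.0:
            raise ValidationError("trace_filter.min_span_fraction must be in [0, 1]")
        if c.dbscan.epsilon <= 0:
            raise ValidationError("dbscan.epsilon must be positive")
        if c.dbscan.min_pts < 2:
            raise ValidationError("dbscan.min_pts must be >= 2")
        if c.areas.n_areas < 1 or c.areas.area_side <= 0:
            raise ValidationError("areas parameters must be positive")
        if c.areas.area_side**2 > c.fov_width * c.fov_height:
            raise ValidationError("areas.area_side^2 exceeds the FOV area")
        if c.nnd.k_max < 1 or c.nnd.bin_width <= 0:
            raise ValidationError("nnd parameters must be positive")
        if c.csr.n_reps < 2:
            raise ValidationError("csr.n_reps must be >= 2")
        if c.simulate.mode not in ("csr", "glycan"):
            raise ValidationError(f"unknown simulate.mode {c.simulate.mode!r}")
        if c.simulate.density < 0 or c.simulate.protein_density < 0:
            raise ValidationError("densities must be >= 0")
        if c.simulate.noise.sigma_smlm <= 0:
            raise ValidationError("noise.sigma_smlm must be positive")
        return c


def _update_dataclass(obj: Any, data: Mapping[str, Any], prefix: str = "") -> Any:
    """Recursively overlay a mapping onto a dataclass, failing on unknown keys."""
    fields = {f.name: f for f in dataclasses.fields(obj)}
    for key, value in data.items():
        if key not in fields:
            raise ConfigError(f"unknown configuration key '{prefix}{key}'")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current):
            if not isinstance(value, Mapping):
                raise ConfigError(f"configuration key '{prefix}{key}' must be a mapping")
            _update_dataclass(current, value, prefix=f"{prefix}{key}.")
        else:
            if key == "density_band":
                value = tuple(float(v) for v in value)
            setattr(obj, key, value)
    return obj


def resolve_config(data: Mapping[str, Any] | None) -> PipelineConfig:
    """Overlay a (possibly partial) mapping onto the defaults and validate."""
    cfg = PipelineConfig()
    if data:
        _update_dataclass(cfg, data)
    return cfg.validate()


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML configuration file; unknown keys are errors (fail closed)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    with open(path) as f:
        data = yaml.safe_load(f)
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    cfg = resolve_config(data)
    get_logger("config").info("resolved configuration: %s", config_to_dict(cfg))
    return cfg


def config_to_dict(cfg: PipelineConfig) -> dict[str, Any]:
    d = dataclasses.asdict(cfg)
    d["areas"]["density_band"] = list(d["areas"]["density_band"])
    return d


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(config_to_dict(cfg), f, sort_keys=False)
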