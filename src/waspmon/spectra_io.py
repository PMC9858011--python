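"""Spectral data container and CSV I/O.

A :class:`SpectraSet` bundles an absorbance matrix (rows = individual scans,
columns = wavelength channels) with per-row sample metadata and the
wavelength grid of the instrument.  It is the common currency passed
between every stage of the pipeline.

Metadata follows the cold-storage study design: each scan belongs to a
lettuce head (``specimen_id``), a storage day, a leaf zone (``inner`` or
``outer``), a measurement position within the zone and a consecutive-scan
index.  Replicate averaging marks collapsed fields with the sentinel 0 so
the metadata schema never changes shape downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "META_COLUMNS",
    "ZONES",
    "SpectrumGrid",
    "SpectraSet",
    "read_spectra_csv",
    "write_spectra_csv",
    "trim_range",
    "average_scans",
]

META_COLUMNS = ("specimen_id", "day", "zone", "position", "scan")
ZONES = ("inner", "outer")

#: Maximum allowed ratio between the largest and smallest adjacent channel
#: spacing for a grid to count as (approximately) uniform.
_MAX_SPACING_RATIO = 1.01
_MIN_CHANNELS = 8


@dataclass(frozen=True)
class SpectrumGrid:
    """Strictly increasing, near-uniform wavelength grid in nanometres."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        if wl.ndim != 1 or wl.size < _MIN_CHANNELS:
            raise ValueError(f"grid needs >= {_MIN_CHANNELS} channels, got {wl.size}")
        d = np.diff(wl)
        if np.any(d <= 0):
            raise ValueError("grid wavelengths must be strictly increasing")
        if d.max() / d.min() > _MAX_SPACING_RATIO:
            raise ValueError(
                "grid spacing not approximately uniform "
                f"(max/min adjacent spacing ratio {d.max() / d.min():.4f} > {_MAX_SPACING_RATIO})"
            )

    def __len__(self) -> int:
        return self.wavelengths.size

    @property
    def spacing(self) -> float:
        """Mean channel spacing in nm."""
        return float(np.mean(np.diff(self.wavelengths)))

    def nearest_channel(self, wavelength: float) -> int:
        """Index of the grid channel closest to ``wavelength``; ties go low."""
        wl = self.wavelengths
        i = int(np.searchsorted(wl, wavelength))
        if i == 0:
            return 0
        if i == wl.size:
            return wl.size - 1
        # tie (equidistant) resolves to the lower wavelength
        return i - 1 if wavelength - wl[i - 1] <= wl[i] - wavelength else i

    def snap(self, wavelength: float) -> float:
        return float(self.wavelengths[self.nearest_channel(wavelength)])


def default_grid(start: float = 908.0, stop: float = 1670.0, n_channels: int = 125) -> SpectrumGrid:
    """125-channel 908-1670 nm grid of the handheld NIR instrument (~6.1 nm pitch)."""
    return SpectrumGrid(np.linspace(start, stop, n_channels))


def _validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required column(s): {missing}")
    meta = meta.loc[:, list(META_COLUMNS)].copy()
    meta["specimen_id"] = meta["specimen_id"].astype(str)
    for col in ("day", "position", "scan"):
        meta[col] = meta[col].astype(int)
    meta["zone"] = meta["zone"].astype(str)
    bad_zone = set(meta["zone"].unique()) - set(ZONES)
    if bad_zone:
        raise ValueError(f"unknown zone label(s) {sorted(bad_zone)}; expected {ZONES}")
    if (meta["day"] < 1).any():
        raise ValueError("storage day must be >= 1")
    dup = meta.duplicated()
    if dup.any():
        first = meta.loc[dup].iloc[0]
        raise ValueError(f"duplicate sample metadata tuple: {tuple(first)}")
    return meta


@dataclass
class SpectraSet:
    """Absorbance spectra plus sample metadata on a common wavelength grid."""

    grid: SpectrumGrid
    absorbance: np.ndarray
    meta: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        x = np.asarray(self.absorbance, dtype=float)
        if x.ndim != 2:
            raise ValueError("absorbance must be a 2-D matrix")
        if not np.all(np.isfinite(x)):
            raise ValueError("absorbance contains non-finite values")
        meta = _validate_meta(self.meta)
        if len(meta) != x.shape[0]:
            raise ValueError(
                f"metadata rows ({len(meta)}) != absorbance rows ({x.shape[0]})"
            )
        if x.shape[1] != len(self.grid):
            raise ValueError(
                f"absorbance columns ({x.shape[1]}) != grid channels ({len(self.grid)})"
            )
        self.absorbance = x
        self.meta = meta.reset_index(drop=True)

    @property
    def n(self) -> int:
        return self.absorbance.shape[0]

    @property
    def p(self) -> int:
        return self.absorbance.shape[1]

    def sorted(self) -> "SpectraSet":
        """Rows sorted by the metadata tuple, the canonical on-disk order."""
        order = self.meta.sort_values(list(META_COLUMNS), kind="mergesort").index
        return SpectraSet(
            self.grid,
            self.absorbance[np.asarray(order)],
            self.meta.loc[order].reset_index(drop=True),
            list(self.provenance),
        )

    def select(self, mask: np.ndarray) -> "SpectraSet":
        """Row subset by boolean mask or integer index array."""
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return SpectraSet(
            self.grid,
            self.absorbance[idx],
            self.meta.iloc[idx].reset_index(drop=True),
            list(self.provenance),
        )

    def zone(self, zone: str) -> "SpectraSet":
        if zone not in ZONES:
            raise ValueError(f"unknown zone {zone!r}")
        return self.select((self.meta["zone"] == zone).to_numpy())

    def with_absorbance(self, x: np.ndarray, step: str | None = None) -> "SpectraSet":
        prov = list(self.provenance) + ([step] if step else [])
        return SpectraSet(self.grid, x, self.meta, prov)


def read_spectra_csv(path, dialect: str = "wide") -> SpectraSet:
    """Read a :class:`SpectraSet` from CSV.

    ``wide``: one row per scan, metadata columns followed by one numeric
    column per wavelength (header = nm value).  ``long``: tidy records with
    columns ``(*META_COLUMNS, wavelength, absorbance)``.
    """
    if dialect == "wide":
        df = pd.read_csv(path)
        meta_cols = [c for c in df.columns if c in META_COLUMNS]
        if len(meta_cols) != len(META_COLUMNS):
            raise ValueError(
                f"wide CSV must contain metadata columns {META_COLUMNS}; found {meta_cols}"
            )
        chan_cols = [c for c in df.columns if c not in META_COLUMNS]
        try:
            wl = np.array([float(c) for c in chan_cols])
        except ValueError as exc:
            raise ValueError(f"non-numeric wavelength column header: {exc}") from exc
        x = df[chan_cols].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            bad = int(np.flatnonzero(~np.isfinite(x).all(axis=1))[0])
            raise ValueError(f"non-numeric/non-finite absorbance in data row {bad}")
        return SpectraSet(SpectrumGrid(wl), x, df[list(META_COLUMNS)]).sorted()
    if dialect == "long":
        df = pd.read_csv(path)
        required = list(META_COLUMNS) + ["wavelength", "absorbance"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"long CSV missing column(s): {missing}")
        wide = df.pivot_table(
            index=list(META_COLUMNS), columns="wavelength", values="absorbance"
        )
        if wide.isna().any().any():
            raise ValueError("long CSV has missing (row, wavelength) combinations")
        wl = wide.columns.to_numpy(dtype=float)
        meta = wide.index.to_frame(index=False)
        return SpectraSet(SpectrumGrid(wl), wide.to_numpy(dtype=float), meta).sorted()
    raise ValueError(f"unknown dialect {dialect!r}; use 'wide' or 'long'")


def write_spectra_csv(data: SpectraSet, path, dialect: str = "wide"):
    """Write a :class:`SpectraSet`; output is re-readable by :func:`read_spectra_csv`."""
    if data.n == 0:
        raise ValueError("refusing to write an empty SpectraSet")
    data = data.sorted()
    if dialect == "wide":
        chans = pd.DataFrame(
            data.absorbance,
            columns=[repr(float(wl)) for wl in data.grid.wavelengths],
        )
        pd.concat([data.meta, chans], axis=1).to_csv(path, index=False)
        return path
    if dialect == "long":
        n, p = data.absorbance.shape
        meta_rep = data.meta.loc[data.meta.index.repeat(p)].reset_index(drop=True)
        meta_rep["wavelength"] = np.tile(data.grid.wavelengths, n)
        meta_rep["absorbance"] = data.absorbance.ravel()
        meta_rep.to_csv(path, index=False)
        return path
    raise ValueError(f"unknown dialect {dialect!r}; use 'wide' or 'long'")


def trim_range(data: SpectraSet, lo: float, hi: float) -> SpectraSet:
    """Restrict the grid to channels with ``lo <= wavelength <= hi``.

    The study evaluates the first overtone of water at 1300-1600 nm; this
    is the trimming used ahead of every multivariate stage.
    """
    if lo >= hi:
        raise ValueError(f"invalid range: lo ({lo}) must be < hi ({hi})")
    keep = (data.grid.wavelengths >= lo) & (data.grid.wavelengths <= hi)
    if keep.sum() < _MIN_CHANNELS:
        raise ValueError(
            f"only {int(keep.sum())} channels inside [{lo}, {hi}]; need >= {_MIN_CHANNELS}"
        )
    return SpectraSet(
        SpectrumGrid(data.grid.wavelengths[keep]),
        data.absorbance[:, keep],
        data.meta,
        list(data.provenance) + [f"trim({lo:g},{hi:g})"],
    )


def average_scans(data: SpectraSet, over=("scan",)) -> SpectraSet:
    """Average replicate spectra over the given metadata fields.

    ``over`` may contain ``scan`` and/or ``position``.  Rows agreeing on all
    remaining metadata fields are replaced by their arithmetic mean
    spectrum; averaged-out fields are set to the sentinel value 0.
    """
    over = set(over)
    if not over <= {"scan", "position"}:
        raise ValueError(f"can only average over scan/position, got {sorted(over)}")
    if data.n == 0:
        raise ValueError("cannot average an empty SpectraSet")
    keys = [c for c in META_COLUMNS if c not in over]
    df = data.meta.copy()
    df["_row"] = np.arange(data.n)
    groups = df.groupby(keys, sort=True)["_row"].agg(list)
    meta_rows = []
    x_rows = []
    for key, rows in groups.items():
        key = key if isinstance(key, tuple) else (key,)
        rec = dict(zip(keys, key))
        for f_ in over:
            rec[f_] = 0
        meta_rows.append(rec)
        x_rows.append(data.absorbance[rows].mean(axis=0))
    meta = pd.DataFrame(meta_rows)
    return SpectraSet(
        data.grid,
        np.vstack(x_rows),
        meta,
        list(data.provenance) + [f"average({','.join(sorted(over))})"],
    ).sorted()
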