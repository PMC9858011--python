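"""Day-versus-reference difference spectra and peak extraction.

The first look at storage dynamics: spectra of one leaf zone are smoothed
(Savitzky-Golay, 2nd order, 11 points) and SNV-transformed, averaged per
storage day, and the day-1 average is subtracted from every later day's
average.  Regions gaining absorbance with storage show positive lobes,
regions losing absorbance negative lobes; their extrema locate candidate
water absorbance bands.

Peak tables produced here (and by the PCA / LDA / PLS stages, which reuse
:func:`pick_peaks`) share one schema so the consensus band-selection stage
can pool them: columns ``wavelength, sign, magnitude, source, context``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import apply_recipe
from .spectra_io import SpectraSet, SpectrumGrid

__all__ = [
    "PEAK_COLUMNS",
    "DifferenceSpectrum",
    "empty_peak_table",
    "difference_spectra",
    "pick_peaks",
]

PEAK_COLUMNS = ("wavelength", "sign", "magnitude", "source", "context")
PEAK_SOURCES = ("diff", "pca_loading", "lda_contrib", "pls_vector")

DEFAULT_DIFF_PRETREAT = ("savgol(11,2)", "snv")


@dataclass
class DifferenceSpectrum:
    grid: SpectrumGrid
    values: np.ndarray
    zone: str
    day: int
    reference_day: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.day == self.reference_day:
            raise ValueError("difference day must differ from reference day")
        if self.values.shape != (len(self.grid),):
            raise ValueError("difference values must match grid length")


def empty_peak_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "wavelength": pd.Series(dtype=float),
            "sign": pd.Series(dtype=int),
            "magnitude": pd.Series(dtype=float),
            "source": pd.Series(dtype=str),
            "context": pd.Series(dtype=str),
        }
    )


def difference_spectra(
    data: SpectraSet,
    zone: str,
    reference_day: int = 1,
    pretreat=DEFAULT_DIFF_PRETREAT,
) -> list[DifferenceSpectrum]:
    """Per-day mean difference spectra against the reference storage day.

    All rows of the zone are pooled with equal weight within each day (the
    scan/position hierarchy collapses into one trace per day).  Returns one
    spectrum per non-reference day, in day order.
    """
    sub = data.zone(zone)
    if sub.n == 0:
        raise ValueError(f"no spectra for zone {zone!r}")
    sub = apply_recipe(sub, pretreat)
    days = sorted(sub.meta["day"].unique())
    if reference_day not in days:
        raise ValueError(f"reference day {reference_day} absent from data (days: {days})")
    day_mean = {
        d: sub.absorbance[(sub.meta["day"] == d).to_numpy()].mean(axis=0) for d in days
    }
    return [
        DifferenceSpectrum(
            sub.grid, day_mean[d] - day_mean[reference_day], zone, d, reference_day
        )
        for d in days
        if d != reference_day
    ]


def pick_peaks(
    values: np.ndarray,
    grid: SpectrumGrid,
    min_rel_magnitude: float = 0.10,
    source: str = "diff",
    context: str = "",
) -> pd.DataFrame:
    """Signed local extrema of ``|values|`` above a relative threshold.

    An interior channel is a peak when its absolute value exceeds both
    neighbours and reaches ``min_rel_magnitude`` times the global maximum
    of ``|values|``; edge channels are never peaks (an extremum running
    into the grid boundary is not a resolved band).  Plateau ties resolve
    to the lowest wavelength.  The rule is scale invariant, so peak sets
    survive any positive rescaling of the input.
    """
    if not 0 < min_rel_magnitude <= 1:
        raise ValueError("min_rel_magnitude must lie in (0, 1]")
    if source not in PEAK_SOURCES:
        raise ValueError(f"unknown peak source {source!r}; allowed {PEAK_SOURCES}")
    v = np.asarray(values, dtype=float)
    if v.shape != (len(grid),):
        raise ValueError("values length must match grid")
    a = np.abs(v)
    vmax = a.max()
    if vmax == 0:
        return empty_peak_table()
    floor = min_rel_magnitude * vmax
    rows = []
    p = a.size
    for i in range(1, p - 1):
        # strict against the left neighbour, >= against the right:
        # a flat plateau yields exactly its lowest-wavelength channel
        if a[i] > a[i - 1] and a[i] >= a[i + 1] and a[i] >= floor:
            rows.append(
                dict(
                    wavelength=float(grid.wavelengths[i]),
                    sign=int(np.sign(v[i])),
                    magnitude=float(a[i]),
                    source=source,
                    context=context,
                )
            )
    if not rows:
        return empty_peak_table()
    return pd.DataFrame(rows, columns=list(PEAK_COLUMNS)).sort_values(
        "wavelength", ignore_index=True
    )
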