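"""Small statistics for reference measurements.

The study compares pigment-band absorbances (VIS region: 454 nm
beta-carotene, 479 nm chlorophyll b, 678 nm chlorophyll a) between the
first and last storage day with a paired t-test, and summarises weight /
water-activity measurements as group mean +/- SD.  These helpers provide
exactly that plumbing; they make no physiological inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .spectra_io import SpectraSet

__all__ = ["PairedTestResult", "band_values", "paired_t_test", "group_summary"]

PIGMENT_BANDS = (454.0, 479.0, 678.0)


@dataclass
class PairedTestResult:
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    df: int
    p: float
    n_pairs: int


def band_values(data: SpectraSet, band: float) -> np.ndarray:
    """Absorbance at the grid channel nearest ``band``, one value per row.

    ``band`` must lie within the grid range; an exact midpoint between two
    channels resolves to the lower wavelength.
    """
    wl = data.grid.wavelengths
    if not wl[0] <= band <= wl[-1]:
        raise ValueError(f"band {band} nm outside grid range [{wl[0]}, {wl[-1]}]")
    return data.absorbance[:, data.grid.nearest_channel(band)]


def paired_t_test(a, b) -> PairedTestResult:
    """Two-tailed paired-samples t-test: t = mean(d) / (sd(d)/sqrt(n)), d = a - b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D vectors of equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd_d = d.std(ddof=1)
    if sd_d == 0:
        raise ValueError("paired differences have zero variance; t-test degenerate")
    t = d.mean() / (sd_d / np.sqrt(n))
    p = 2 * stats.t.sf(abs(t), n - 1)
    return PairedTestResult(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        t=float(t),
        df=n - 1,
        p=float(p),
        n_pairs=n,
    )


def group_summary(values, groups) -> pd.DataFrame:
    """Per-group mean, (n-1)-denominator SD and SEM.

    Single-element groups get sd = sem = 0 with ``sd_defined = False``
    rather than NaN, so downstream tabulation stays numeric.
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": groups})
    if df.empty:
        raise ValueError("no values to summarise")
    rows = []
    for g, sub in df.groupby("group", sort=True):
        n = len(sub)
        sd = float(sub["value"].std(ddof=1)) if n > 1 else 0.0
        rows.append(
            dict(
                group=g,
                n=n,
                mean=float(sub["value"].mean()),
                sd=sd,
                sem=sd / np.sqrt(n),
                sd_defined=n > 1,
            )
        )
    return pd.DataFrame(rows, columns=["group", "n", "mean", "sd", "sem", "sd_defined"])
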