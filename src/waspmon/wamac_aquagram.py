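"""Consensus WAMAC selection and aquagram (water spectral pattern) computation.

The pipeline's four evidence streams — difference-spectrum peaks, PCA
loading peaks, LDA wavelength contributions and PLS regression-vector
peaks — each nominate influential wavelengths per leaf zone.  A wavelength
becomes a water matrix coordinate (WAMAC) when it repeats consistently
across streams: with the frozen default rule it must be nominated by at
least two distinct source categories in at least one zone and appear in
both zones.  Applied to the published prominent-wavelength tables of the
lettuce study, this rule reproduces its 19 selected WAMACs exactly.

An aquagram standardises absorbance per channel over all spectra in scope
((A - mu)/sigma), averages per group (storage day) at the WAMAC channels,
and subtracts the reference group's vector; the resulting per-day vectors
are the water spectral patterns (WASPs) usually drawn on a radar plot.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .preprocess import apply_recipe
from .spectra_io import SpectraSet

__all__ = [
    "EVIDENCE_COLUMNS",
    "WamacSet",
    "Aquagram",
    "load_reference_tables",
    "reference_evidence",
    "build_evidence",
    "select_wamacs",
    "compute_aquagram",
    "wamac_annotation",
    "plot_aquagram",
]

EVIDENCE_COLUMNS = ("source", "context", "wavelength")
DEFAULT_AQUAGRAM_PRETREAT = ("savgol(17,2)", "snv")


def load_reference_tables() -> dict:
    """Bundled published reference tables (WAMAC classes, confusion matrices,
    prominent-wavelength evidence) for the cold-storage lettuce study."""
    with resources.files("waspmon").joinpath("data/reference_tables.json").open() as fh:
        return json.load(fh)


def reference_evidence(zone: str, consistent_only: bool = True) -> pd.DataFrame:
    """Published prominent-wavelength table of one zone as an evidence table."""
    tab = load_reference_tables()["prominent_wavelengths"][zone]
    df = pd.DataFrame(tab)
    if consistent_only:
        df = df[df["consistent"]]
    return df.loc[:, list(EVIDENCE_COLUMNS)].reset_index(drop=True)


@dataclass
class WamacSet:
    """Consensus-selected wavelengths with per-zone, per-source support counts."""

    wavelengths: list[float]
    support: dict  # zone -> {wavelength -> {source -> count}}

    def __post_init__(self) -> None:
        wl = sorted(set(float(w) for w in self.wavelengths))
        if len(wl) != len(self.wavelengths):
            raise ValueError("WAMAC wavelengths must be unique")
        self.wavelengths = wl

    def __len__(self) -> int:
        return len(self.wavelengths)


@dataclass
class Aquagram:
    wamacs: WamacSet
    groups: list
    values: pd.DataFrame  # groups x wamac wavelengths, reference-subtracted
    reference_group: object
    pretreat: tuple


def build_evidence(peak_tables, zone: str, grid=None) -> pd.DataFrame:
    """Pool peak tables from all analysis stages into one evidence table.

    Wavelengths are snapped to the nearest grid channel when ``grid`` is
    given (warning beyond half a channel spacing) and deduplicated per
    (source, context, wavelength).
    """
    frames = [t for t in peak_tables if t is not None and len(t)]
    if not frames:
        return pd.DataFrame(columns=list(EVIDENCE_COLUMNS))
    df = pd.concat(frames, ignore_index=True).loc[:, list(EVIDENCE_COLUMNS)].copy()
    if grid is not None:
        half = grid.spacing / 2
        snapped = []
        for wl in df["wavelength"]:
            s = grid.snap(wl)
            if abs(s - wl) > half * (1 + 1e-9):
                warnings.warn(
                    f"wavelength {wl:.1f} nm is {abs(s - wl):.2f} nm from the nearest "
                    f"grid channel {s:.1f} nm (> half spacing)"
                )
            snapped.append(s)
        df["wavelength"] = snapped
    df["zone"] = zone
    return df.drop_duplicates(list(EVIDENCE_COLUMNS), ignore_index=True)


def _support(evidence: pd.DataFrame) -> dict:
    """wavelength -> {source -> number of distinct contexts nominating it}."""
    out: dict[float, dict[str, int]] = {}
    if evidence is None or not len(evidence):
        return out
    for (wl, src), sub in evidence.groupby(["wavelength", "source"]):
        out.setdefault(float(wl), {})[str(src)] = sub["context"].nunique()
    return out


def select_wamacs(
    evidence_inner: pd.DataFrame,
    evidence_outer: pd.DataFrame,
    min_sources: int = 2,
    require_both_zones: bool = True,
) -> WamacSet:
    """Consensus rule for promoting repeatedly nominated wavelengths to WAMACs.

    A wavelength is selected iff it is nominated by at least ``min_sources``
    distinct source categories (contexts pooled) in at least one zone and,
    when ``require_both_zones``, appears at least once in both zones.  The
    rule is monotone: adding evidence can only add selections.
    """
    if min_sources < 1:
        raise ValueError("min_sources must be >= 1")
    sup = {"inner": _support(evidence_inner), "outer": _support(evidence_outer)}
    selected = []
    for wl in sorted(set(sup["inner"]) | set(sup["outer"])):
        n_src = max(len(sup[z].get(wl, {})) for z in ("inner", "outer"))
        both = wl in sup["inner"] and wl in sup["outer"]
        if n_src >= min_sources and (both or not require_both_zones):
            selected.append(wl)
    support = {
        z: {wl: sup[z][wl] for wl in selected if wl in sup[z]} for z in ("inner", "outer")
    }
    return WamacSet(selected, support)


def compute_aquagram(
    data: SpectraSet,
    wamacs: WamacSet,
    group_by: str = "day",
    reference_group=1,
    pretreat=DEFAULT_AQUAGRAM_PRETREAT,
) -> Aquagram:
    """Reference-subtracted standardised group absorbances at the WAMACs.

    Pre-treats all spectra in scope (default Savitzky-Golay 17-point
    2nd-order smoothing + SNV), standardises each channel over the pooled
    scope — (A - mu)/sigma, making day-to-day values comparable on one
    radar overlay — averages per group at the WAMAC channels and subtracts
    the reference group's vector (its row is identically zero).
    """
    if data.n == 0:
        raise ValueError("empty SpectraSet")
    pre = apply_recipe(data, pretreat)
    groups = sorted(pre.meta[group_by].unique().tolist())
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not among {groups}")
    channels = [pre.grid.nearest_channel(wl) for wl in wamacs.wavelengths]
    x = pre.absorbance[:, channels]
    mu = x.mean(axis=0)
    sigma = x.std(axis=0, ddof=1)
    if np.any(sigma == 0):
        bad = wamacs.wavelengths[int(np.flatnonzero(sigma == 0)[0])]
        raise ValueError(f"zero variance at WAMAC channel {bad:g} nm")
    z = (x - mu) / sigma
    rows = {
        g: z[(pre.meta[group_by] == g).to_numpy()].mean(axis=0) for g in groups
    }
    values = pd.DataFrame.from_dict(rows, orient="index", columns=wamacs.wavelengths)
    values = values - values.loc[reference_group]
    return Aquagram(
        wamacs=wamacs,
        groups=groups,
        values=values,
        reference_group=reference_group,
        pretreat=tuple(str(s) for s in pretreat),
    )


def wamac_annotation(wamacs: WamacSet) -> pd.DataFrame:
    """Annotate WAMACs with their conventional C-class and a band assignment.

    Classes follow the C1-C12 water matrix coordinate ranges of the first
    overtone region; wavelengths inside a range without a C-label, or
    outside every tabulated range, are labelled ``unclassified``.
    """
    ref = load_reference_tables()
    classes = ref["wamac_classes"]
    assignments = ref["assignments"]
    rows = []
    for wl in wamacs.wavelengths:
        label = "unclassified"
        for c in classes:
            if c["lo"] <= wl <= c["hi"]:
                label = c["label"] or "unclassified"
                break
        rows.append(
            dict(
                wavelength=wl,
                wamac_class=label,
                assignment=assignments.get(str(int(round(wl))), ""),
            )
        )
    return pd.DataFrame(rows, columns=["wavelength", "wamac_class", "assignment"])


def plot_aquagram(aquagram: Aquagram, path, title: str = "Aquagram"):
    """Radar-plot rendering of the WASPs, one trace per group; saves to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wl = aquagram.values.columns.to_numpy(dtype=float)
    theta = np.linspace(0, 2 * np.pi, len(wl), endpoint=False)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    for g in aquagram.groups:
        vals = aquagram.values.loc[g].to_numpy()
        ax.plot(np.r_[theta, theta[0]], np.r_[vals, vals[0]], label=f"day {g}")
    ax.set_xticks(theta)
    ax.set_xticklabels([f"{w:.0f}" for w in wl], fontsize=7)
    ax.set_title(title)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
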