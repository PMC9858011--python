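"""Row-wise spectral pre-treatments: Savitzky-Golay smoothing, SNV, detrend.

All transforms operate independently on each spectrum (no information flows
across samples), preserve the matrix shape and metadata, and append their
name to the set's provenance list.  Recipes are declared as ordered lists
of specs, e.g. ``[savgol(11,2), snv]`` — the pre-treatment used for the
difference spectra — or ``[savgol(17,2), snv]`` used for aquagrams.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .spectra_io import SpectraSet

__all__ = [
    "TransformSpec",
    "savgol_smooth",
    "snv",
    "detrend",
    "apply_recipe",
    "parse_recipe",
]


@dataclass(frozen=True)
class TransformSpec:
    """Named pre-treatment with parameters; ``apply`` dispatches to the op."""

    name: str
    params: dict = field(default_factory=dict)

    _ALLOWED = ("raw", "savgol", "snv", "detrend")

    def __post_init__(self) -> None:
        if self.name not in self._ALLOWED:
            raise ValueError(f"unknown transform {self.name!r}; allowed: {self._ALLOWED}")
        if self.name == "savgol":
            w, k = self.params.get("window", 11), self.params.get("polyorder", 2)
            if w % 2 == 0 or w < 5:
                raise ValueError(f"savgol window must be odd and >= 5, got {w}")
            if not 1 <= k < w:
                raise ValueError(f"savgol polyorder must satisfy 1 <= polyorder < window")
        if self.name == "detrend" and self.params.get("degree", 2) not in (1, 2):
            raise ValueError("detrend degree must be 1 or 2")

    def apply(self, data: SpectraSet) -> SpectraSet:
        if self.name == "raw":
            return data
        if self.name == "savgol":
            return savgol_smooth(
                data, self.params.get("window", 11), self.params.get("polyorder", 2)
            )
        if self.name == "snv":
            return snv(data)
        return detrend(data, self.params.get("degree", 2))

    def __str__(self) -> str:
        if self.name == "savgol":
            return f"savgol({self.params.get('window', 11)},{self.params.get('polyorder', 2)})"
        if self.name == "detrend":
            return f"detrend({self.params.get('degree', 2)})"
        return self.name


_RECIPE_RE = re.compile(r"^(?P<name>[a-z]+)(?:\((?P<args>[^)]*)\))?$")


def parse_recipe(recipe) -> list[TransformSpec]:
    """Parse ``['savgol(11,2)', 'snv']``-style recipes into TransformSpecs."""
    if recipe is None:
        return []
    specs = []
    for item in recipe:
        if isinstance(item, TransformSpec):
            specs.append(item)
            continue
        m = _RECIPE_RE.match(str(item).strip())
        if not m:
            raise ValueError(f"cannot parse transform spec {item!r}")
        name = m.group("name")
        args = [int(a) for a in m.group("args").split(",")] if m.group("args") else []
        if name == "savgol":
            params = dict(zip(("window", "polyorder"), args)) if args else {}
        elif name == "detrend":
            params = {"degree": args[0]} if args else {}
        else:
            params = {}
        specs.append(TransformSpec(name, params))
    return specs


def apply_recipe(data: SpectraSet, recipe) -> SpectraSet:
    for spec in parse_recipe(recipe):
        data = spec.apply(data)
    return data


def savgol_smooth(data: SpectraSet, window: int = 11, polyorder: int = 2) -> SpectraSet:
    """Savitzky-Golay least-squares polynomial smoothing along wavelength.

    The study smooths with a second-order polynomial over 11 points before
    difference spectra and over 17 points before aquagrams (0th derivative
    in both cases).  Edges are handled by evaluating the polynomial fitted
    to the terminal window at the edge channels rather than padding with
    fabricated data, which matters where water-band tails reach the ends
    of the grid.
    """
    TransformSpec("savgol", {"window": window, "polyorder": polyorder})  # validates
    if window > data.p:
        raise ValueError(f"savgol window {window} exceeds channel count {data.p}")
    x = savgol_filter(data.absorbance, window, polyorder, axis=1, mode="interp")
    return data.with_absorbance(x, f"savgol({window},{polyorder})")


def snv(data: SpectraSet) -> SpectraSet:
    """Standard normal variate: per spectrum, centre and scale to unit sd.

    Removes additive offsets and multiplicative scatter differences between
    spectra; after SNV every row has mean 0 and (n-1)-denominator sd 1.
    """
    x = data.absorbance
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        raise ValueError(f"SNV undefined: spectrum row {int(zero[0])} has zero variance")
    return data.with_absorbance((x - mu) / sd, "snv")


def detrend(data: SpectraSet, degree: int = 2) -> SpectraSet:
    """Subtract each spectrum's least-squares polynomial baseline in wavelength.

    Degree 2 is the convention coupled with SNV in the scatter-correction
    literature and the default here; the residual is orthogonal to the
    polynomial basis {1, lambda, ..., lambda^degree}.
    """
    TransformSpec("detrend", {"degree": degree})  # validates
    if data.p <= degree + 1:
        raise ValueError(f"need more than degree+1={degree + 1} channels, got {data.p}")
    wl = data.grid.wavelengths
    # scale wavelength to [-1, 1] for a well-conditioned Vandermonde basis
    t = 2 * (wl - wl[0]) / (wl[-1] - wl[0]) - 1
    basis = np.vander(t, degree + 1, increasing=True)  # p x (degree+1)
    coef, *_ = np.linalg.lstsq(basis, data.absorbance.T, rcond=None)
    x = data.absorbance - (basis @ coef).T
    return data.with_absorbance(x, f"detrend({degree})")
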