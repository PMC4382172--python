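"""Reading, validating, averaging, regridding and smoothing spectral curves.

A :class:`Spectrum` holds one curve on a wavelength grid: eggshell
reflectance, photoreceptor spectral sensitivity, or ambient irradiance.
Reflectance files produced by portable spectrometers come either *wide*
(a wavelength column plus one column per measurement) or *long* (one row
per id/wavelength/value); both dialects are supported.  Measurement
metadata (egg id, clutch id, probe position, replicate index) is parsed
from column headers of the form ``egg_clutch_position_replicate``.

Typical preprocessing, in order: read raw replicate spectra, average the
replicates of each egg, interpolate onto a common 1-nm working grid
(300-700 nm by default), and apply a triangular smoothing kernel to
attenuate spectrometer noise before visual modeling.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "WavelengthGrid",
    "SpectrumError",
    "read_spectra",
    "write_spectra",
    "average_replicates",
    "regrid",
    "pad_sensitivity",
    "triangular_smooth",
]

KINDS = ("reflectance", "sensitivity", "irradiance")

#: Wavelength bounds (nm) outside which no avian-vision curve is meaningful.
WL_MIN, WL_MAX = 250.0, 800.0

#: Maximum value above which reflectance is assumed to be in percent.
PERCENT_THRESHOLD = 2.0


class SpectrumError(ValueError):
    """Raised on malformed spectral input (parse or validation failure)."""


@dataclass(frozen=True)
class WavelengthGrid:
    """A uniform wavelength grid in nanometers.

    The default, 300-700 nm at 1-nm steps, is the working grid of the
    visual model: sensitivity data are required over this full range,
    with the 300-330 nm region zero-padded when the source curves start
    at 330 nm (see :func:`pad_sensitivity`).
    """

    start: float = 300.0
    stop: float = 700.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise SpectrumError(f"grid start {self.start} must be < stop {self.stop}")
        if self.step <= 0:
            raise SpectrumError(f"grid step must be positive, got {self.step}")

    @property
    def wavelengths(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)


@dataclass(frozen=True)
class Spectrum:
    """One spectral curve with provenance metadata.

    Parameters
    ----------
    wavelengths
        Strictly increasing wavelengths in nm, within [250, 800].
    values
        Curve values: reflectance as a proportion in [0, 1] scale
        (percent inputs are rescaled on read), sensitivity or irradiance
        in arbitrary non-negative units.
    kind
        One of ``"reflectance"``, ``"sensitivity"``, ``"irradiance"``.
    meta
        Free-form labels: ``egg_id``, ``clutch_id``, ``position``
        (blunt/middle/sharp), ``replicate``, ``n_averaged`` ...
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "reflectance"
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)
        if self.kind not in KINDS:
            raise SpectrumError(f"unknown spectrum kind {self.kind!r}")
        if wl.ndim != 1 or v.ndim != 1 or wl.size != v.size:
            raise SpectrumError("wavelengths and values must be 1-d and equal length")
        if wl.size < 2:
            raise SpectrumError("a spectrum needs at least two samples")
        if not np.all(np.diff(wl) > 0):
            raise SpectrumError("wavelengths must be strictly increasing")
        if wl[0] < WL_MIN or wl[-1] > WL_MAX:
            raise SpectrumError(
                f"wavelengths must lie within [{WL_MIN:g}, {WL_MAX:g}] nm, "
                f"got [{wl[0]:g}, {wl[-1]:g}]"
            )
        if not np.all(np.isfinite(v)):
            raise SpectrumError("values must be finite")
        if self.kind == "reflectance" and np.any(v < 0):
            raise SpectrumError("reflectance values must be non-negative")

    @property
    def grid_step(self) -> float:
        steps = np.diff(self.wavelengths)
        if not np.allclose(steps, steps[0]):
            raise SpectrumError("spectrum is not on a uniform grid")
        return float(steps[0])

    def with_values(self, values: np.ndarray, **meta: object) -> "Spectrum":
        return replace(self, values=np.asarray(values, dtype=float),
                       meta={**self.meta, **meta})


def _parse_header(name: str) -> dict:
    """Parse ``egg_clutch_position_replicate`` column headers.

    Shorter headers are kept as a bare ``egg_id``; the full four-field
    convention is what the synthetic generator writes.
    """
    parts = name.strip().split("_")
    meta: dict[str, object] = {"egg_id": name.strip()}
    if len(parts) >= 4:
        meta = {
            "egg_id": parts[0],
            "clutch_id": parts[1],
            "position": parts[2],
            "replicate": parts[3],
        }
    elif len(parts) == 2:
        meta = {"egg_id": parts[0], "clutch_id": parts[1]}
    return meta


def _normalize_units(values: np.ndarray, kind: str, percent: bool | None) -> np.ndarray:
    """Percent reflectance (any value > 2) is rescaled to proportions."""
    if kind != "reflectance":
        return values
    if percent is None:
        percent = bool(np.nanmax(values) > PERCENT_THRESHOLD)
    return values / 100.0 if percent else values


def read_spectra(
    path: str | Path | io.TextIOBase,
    dialect: str = "wide",
    kind: str = "reflectance",
    percent: bool | None = None,
) -> list[Spectrum]:
    """Read spectra from delimited text (tab or comma separated).

    Parameters
    ----------
    path
        File path or open text handle.
    dialect
        ``"wide"``: first column is wavelength (nm), every other column
        one measurement, metadata in the header.  ``"long"``: columns
        ``id``, ``wavelength``, ``value`` (header required).
    kind
        Spectrum kind assigned to every curve in the file.
    percent
        Force percent (True) or proportion (False) units for
        reflectance; ``None`` auto-detects (max value > 2 means percent).

    Returns
    -------
    list of Spectrum, one per measurement.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise SpectrumError(f"could not parse {path}: {exc}") from exc

    for col in df.columns:
        bad = pd.to_numeric(df[col] if dialect == "wide" or col != "id" else [],
                            errors="coerce")
        if dialect == "wide" and pd.isna(bad).any():
            row = int(np.argmax(pd.isna(bad).to_numpy()))
            raise SpectrumError(f"non-numeric cell in column {col!r}, row {row}")

    spectra: list[Spectrum] = []
    if dialect == "wide":
        wl = df.iloc[:, 0].to_numpy(dtype=float)
        if not np.all(np.diff(wl) > 0):
            raise SpectrumError("wavelength column must be strictly increasing")
        for col in df.columns[1:]:
            vals = _normalize_units(df[col].to_numpy(dtype=float), kind, percent)
            spectra.append(Spectrum(wl, vals, kind=kind, meta=_parse_header(str(col))))
    elif dialect == "long":
        required = {"id", "wavelength", "value"}
        if not required.issubset(df.columns):
            raise SpectrumError(f"long dialect requires columns {sorted(required)}")
        for sid, grp in df.groupby("id", sort=False):
            wl = grp["wavelength"].to_numpy(dtype=float)
            if not np.all(np.diff(wl) > 0):
                raise SpectrumError(f"wavelengths for id {sid!r} not strictly increasing")
            vals = pd.to_numeric(grp["value"], errors="coerce").to_numpy()
            if np.isnan(vals).any():
                row = int(np.argmax(np.isnan(vals)))
                raise SpectrumError(f"non-numeric value for id {sid!r}, row {row}")
            vals = _normalize_units(vals, kind, percent)
            spectra.append(Spectrum(wl, vals, kind=kind, meta=_parse_header(str(sid))))
    else:
        raise SpectrumError(f"unknown dialect {dialect!r}")
    return spectra


def write_spectra(spectra: Sequence[Spectrum], path: str | Path, sep: str = "\t") -> None:
    """Write spectra sharing one grid as a wide delimited-text table."""
    if not spectra:
        raise SpectrumError("no spectra to write")
    wl = spectra[0].wavelengths
    cols = {"wavelength": wl}
    for s in spectra:
        if not np.array_equal(s.wavelengths, wl):
            raise SpectrumError("all spectra must share one grid to write wide")
        parts = [str(s.meta.get(k)) for k in ("egg_id", "clutch_id", "position", "replicate")
                 if s.meta.get(k) is not None]
        cols["_".join(parts) or f"s{len(cols)}"] = s.values
    pd.DataFrame(cols).to_csv(path, sep=sep, index=False)


def average_replicates(
    spectra: Iterable[Spectrum],
    group_by: Sequence[str] = ("egg_id", "clutch_id"),
) -> list[Spectrum]:
    """Average replicate measurements pointwise, one output per group.

    The nine probe readings per egg (three each at the blunt pole,
    middle and sharp pole) collapse to a single mean spectrum; the flat
    mean over all replicates equals the mean of per-position means for
    balanced designs.  Position/replicate labels are dropped and the
    replicate count is recorded as ``n_averaged``.
    """
    groups: dict[tuple, list[Spectrum]] = {}
    for s in spectra:
        key = tuple(s.meta.get(k) for k in group_by)
        groups.setdefault(key, []).append(s)

    out: list[Spectrum] = []
    for key, members in groups.items():
        wl = members[0].wavelengths
        for m in members[1:]:
            if not np.array_equal(m.wavelengths, wl):
                raise SpectrumError(
                    f"group {key} mixes wavelength grids; regrid before averaging"
                )
        mean = np.mean([m.values for m in members], axis=0)
        meta = dict(zip(group_by, key))
        meta["n_averaged"] = len(members)
        out.append(Spectrum(wl, mean, kind=members[0].kind, meta=meta))
    return out


def regrid(s: Spectrum, grid: WavelengthGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto a target grid (no extrapolation)."""
    target = grid.wavelengths
    lo, hi = s.wavelengths[0], s.wavelengths[-1]
    if target[0] < lo - 1e-9 or target[-1] > hi + 1e-9:
        raise SpectrumError(
            f"target grid [{target[0]:g}, {target[-1]:g}] outside data range "
            f"[{lo:g}, {hi:g}]; pad first if intended"
        )
    vals = np.interp(target, s.wavelengths, s.values)
    return Spectrum(target, vals, kind=s.kind, meta=dict(s.meta))


def pad_sensitivity(
    s: Spectrum,
    region: tuple[float, float] = (300.0, 330.0),
    value: float = 0.0,
    overwrite: bool = False,
) -> Spectrum:
    """Extend a sensitivity curve over ``region`` with a constant value.

    Digitized cone sensitivities often start at 330 nm while the visual
    model integrates from 300 nm; the convention is to set absorbance to
    zero over the missing ultraviolet region.
    """
    if s.kind != "sensitivity":
        raise SpectrumError("pad_sensitivity applies to sensitivity curves only")
    lo, hi = region
    if lo >= hi:
        raise SpectrumError("empty pad region")
    overlaps = (lo < s.wavelengths[-1]) and (hi > s.wavelengths[0])
    if overlaps and not overwrite:
        raise SpectrumError(
            f"pad region [{lo:g}, {hi:g}] overlaps existing support "
            f"[{s.wavelengths[0]:g}, {s.wavelengths[-1]:g}]; pass overwrite=True"
        )
    if overlaps:
        inside = (s.wavelengths >= lo) & (s.wavelengths <= hi)
        vals = s.values.copy()
        vals[inside] = value
        new_wl, new_vals = s.wavelengths, vals
    else:
        step = s.grid_step
        if hi <= s.wavelengths[0]:
            pad_wl = np.arange(lo, s.wavelengths[0] - step / 2, step)
            new_wl = np.concatenate([pad_wl, s.wavelengths])
            new_vals = np.concatenate([np.full(pad_wl.size, value), s.values])
        else:
            pad_wl = np.arange(s.wavelengths[-1] + step, hi + step / 2, step)
            new_wl = np.concatenate([s.wavelengths, pad_wl])
            new_vals = np.concatenate([s.values, np.full(pad_wl.size, value)])
    return Spectrum(new_wl, new_vals, kind=s.kind, meta=dict(s.meta))


def triangular_smooth(s: Spectrum, width: float = 30.0) -> Spectrum:
    """Smooth with a symmetric triangular kernel of total base ``width`` nm.

    Kernel weights are maximal at the center and decay linearly to zero
    at +-width/2.  Near the boundaries the kernel is renormalized to
    unit mass, so a constant spectrum passes through unchanged and the
    integral of an interior-supported spectrum is conserved.  A width
    smaller than two grid steps cannot smooth anything: a warning is
    issued and the input returned unchanged.
    """
    if width <= 0:
        raise SpectrumError("smoothing width must be positive")
    step = s.grid_step
    if width < 2 * step:
        warnings.warn(
            f"smoothing width {width:g} nm < 2 grid steps ({step:g} nm); "
            "returning input unchanged",
            stacklevel=2,
        )
        return s
    half = width / 2.0
    k = int(np.floor(half / step))
    offsets = np.arange(-k, k + 1) * step
    kernel = np.clip(1.0 - np.abs(offsets) / half, 0.0, None)
    kernel /= kernel.sum()
    # Boundary renormalization: divide by the local kernel mass.  Slice
    # the centered part of the full convolution (mode="same" would
    # return the wrong length when the kernel is longer than the data).
    n = s.values.size
    num = np.convolve(s.values, kernel, mode="full")[k:k + n]
    den = np.convolve(np.ones(n), kernel, mode="full")[k:k + n]
    return s.with_values(num / den, smoothed_nm=width)
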