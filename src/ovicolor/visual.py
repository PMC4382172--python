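"""Receptor-noise-limited tetrachromatic visual model.

Quantum catches are photon counts per single-cone class i,

    Q_i = sum_lambda R(lambda) * I(lambda) * S_i(lambda) * dlambda,

a rectangular sum over the 300-700 nm working grid, where R is egg
reflectance, I ambient irradiance and S_i the cone sensitivity.  The
achromatic channel uses the summed MWS + LWS sensitivity, a stand-in
for the double-cone/rod luminance pathway.

Chromatic discriminability between two spectra is the receptor-noise
distance Delta-S in just-noticeable-difference (JND) units: log catch
contrasts Delta-f_i = ln(Q_i^a / Q_i^b) weighted by per-channel noise
omega_i.  Noise follows the Weber fraction w of the reference cone and
scales inversely with the square root of relative cone density:
omega_i = w * sqrt(eta_ref / eta_i).  Delta-S > 1 JND is conventionally
discriminable.

Because both spectra share one illuminant, per-receptor multiplicative
(von Kries) adaptation cancels in every Delta-f_i and is not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .spectra import Spectrum, SpectrumError

__all__ = [
    "RECEPTOR_ORDER",
    "DEFAULT_DENSITIES",
    "ReceptorSet",
    "Illuminant",
    "QuantumCatches",
    "NoiseVector",
    "quantum_catch",
    "receptor_noise",
    "chromatic_jnd",
    "achromatic_jnd",
]

#: Single-cone classes of the tetrachromatic avian retina, short to long.
RECEPTOR_ORDER = ("UVS", "SWS", "MWS", "LWS")

#: Relative cone densities for a UVS-type turdid retina.
DEFAULT_DENSITIES = {"UVS": 1.0, "SWS": 1.78, "MWS": 2.21, "LWS": 1.96}


@dataclass(frozen=True)
class ReceptorSet:
    """Four cone sensitivities plus the noise parameterization.

    ``weber_fraction`` anchors the noise of ``reference_receptor``
    (default LWS, the most abundant cone in the default densities and
    the dominant convention in the receptor-noise literature); all other
    channels inherit noise via the density scaling.  ``achromatic_weber``
    is the Weber fraction of the luminance channel.
    """

    sensitivities: Mapping[str, Spectrum]
    densities: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DENSITIES))
    weber_fraction: float = 0.1
    reference_receptor: str = "LWS"
    achromatic_weber: float = 0.1

    def __post_init__(self) -> None:
        missing = [r for r in RECEPTOR_ORDER if r not in self.sensitivities]
        if missing:
            raise ValueError(f"missing sensitivity curves for {missing}")
        grids = [self.sensitivities[r].wavelengths for r in RECEPTOR_ORDER]
        for g in grids[1:]:
            if not np.array_equal(g, grids[0]):
                raise ValueError("sensitivity curves must share one wavelength grid")
        for r in RECEPTOR_ORDER:
            if np.any(self.sensitivities[r].values < 0):
                raise ValueError(f"{r} sensitivity has negative values")
            if self.densities.get(r, 0.0) <= 0:
                raise ValueError(f"density for {r} must be positive")
        if self.weber_fraction <= 0 or self.achromatic_weber <= 0:
            raise ValueError("Weber fractions must be positive")
        if self.reference_receptor not in RECEPTOR_ORDER:
            raise ValueError(f"unknown reference receptor {self.reference_receptor!r}")

    @property
    def wavelengths(self) -> np.ndarray:
        return self.sensitivities[RECEPTOR_ORDER[0]].wavelengths

    def sensitivity_matrix(self) -> np.ndarray:
        """(4, n_wavelengths) array in UVS, SWS, MWS, LWS order."""
        return np.vstack([self.sensitivities[r].values for r in RECEPTOR_ORDER])


@dataclass(frozen=True)
class Illuminant:
    """An ambient-irradiance spectrum under which catches are computed."""

    spectrum: Spectrum
    name: str = "illuminant"

    def __post_init__(self) -> None:
        if self.spectrum.kind != "irradiance":
            raise ValueError("illuminant spectrum must have kind='irradiance'")
        if np.any(self.spectrum.values < 0):
            raise ValueError("irradiance must be non-negative")

    @classmethod
    def flat(cls, wavelengths: np.ndarray, name: str = "ideal-white") -> "Illuminant":
        """Spectrally flat ('ideal white') irradiance of unit photon flux."""
        return cls(Spectrum(wavelengths, np.ones_like(wavelengths, dtype=float),
                            kind="irradiance"), name=name)


@dataclass(frozen=True)
class QuantumCatches:
    """Per-receptor catches Q_i and achromatic catch Q_A for one egg."""

    Q: np.ndarray  # (4,) in RECEPTOR_ORDER
    Q_A: float
    egg_id: str | None = None
    clutch_id: str | None = None

    def __post_init__(self) -> None:
        q = np.asarray(self.Q, dtype=float)
        object.__setattr__(self, "Q", q)
        if q.shape != (4,):
            raise ValueError("Q must hold four catches (UVS, SWS, MWS, LWS)")
        if np.any(q < 0) or self.Q_A < 0:
            raise ValueError("quantum catches must be non-negative")


@dataclass(frozen=True)
class NoiseVector:
    """Per-channel noise standard deviations omega_i (UVS, SWS, MWS, LWS)."""

    omega: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.omega, dtype=float)
        object.__setattr__(self, "omega", w)
        if w.shape != (4,) or np.any(w <= 0):
            raise ValueError("omega must hold four positive noise values")


def quantum_catch(egg: Spectrum, receptors: ReceptorSet, light: Illuminant) -> QuantumCatches:
    """Integrate reflectance x irradiance x sensitivity per cone class."""
    if egg.kind != "reflectance":
        raise SpectrumError("quantum_catch expects a reflectance spectrum")
    wl = receptors.wavelengths
    if not (np.array_equal(egg.wavelengths, wl)
            and np.array_equal(light.spectrum.wavelengths, wl)):
        raise SpectrumError("egg, receptors and illuminant must share one grid")
    if np.any(egg.values < 0):
        raise SpectrumError("negative reflectance")
    step = egg.grid_step
    radiance = egg.values * light.spectrum.values
    S = receptors.sensitivity_matrix()
    Q = S @ radiance * step
    achro = S[2] + S[3]  # MWS + LWS luminance channel
    Q_A = float(achro @ radiance * step)
    if np.all(Q == 0):
        import warnings

        warnings.warn("all-zero quantum catches; log contrasts are undefined downstream",
                      stacklevel=2)
    return QuantumCatches(Q=Q, Q_A=Q_A,
                          egg_id=egg.meta.get("egg_id"),
                          clutch_id=egg.meta.get("clutch_id"))


def receptor_noise(receptors: ReceptorSet) -> NoiseVector:
    """Noise per channel: omega_i = w * sqrt(eta_ref / eta_i)."""
    eta = np.array([receptors.densities[r] for r in RECEPTOR_ORDER])
    eta_ref = receptors.densities[receptors.reference_receptor]
    omega = receptors.weber_fraction * np.sqrt(eta_ref / eta)
    return NoiseVector(omega=omega)


def _log_contrasts(a: QuantumCatches, b: QuantumCatches) -> np.ndarray:
    for qc, label in ((a, "first"), (b, "second")):
        if np.any(qc.Q <= 0):
            bad = RECEPTOR_ORDER[int(np.argmax(qc.Q <= 0))]
            raise ValueError(
                f"non-positive {bad} catch for {label} egg "
                f"({qc.egg_id!r}); log contrast undefined"
            )
    return np.log(a.Q / b.Q)


def chromatic_jnd(a: QuantumCatches, b: QuantumCatches, noise: NoiseVector) -> float:
    """Tetrachromatic receptor-noise chromatic distance in JND units.

    With log contrasts df_i and noises e_i (i = 1..4 for UVS, SWS, MWS,
    LWS):

        DS^2 = [ (e1 e2)^2 (df4-df3)^2 + (e1 e3)^2 (df4-df2)^2
               + (e1 e4)^2 (df3-df2)^2 + (e2 e3)^2 (df4-df1)^2
               + (e2 e4)^2 (df3-df1)^2 + (e3 e4)^2 (df2-df1)^2 ]
               / [ (e1 e2 e3)^2 + (e1 e2 e4)^2 + (e1 e3 e4)^2 + (e2 e3 e4)^2 ]

    Uniform intensity scaling of either spectrum shifts every df_i by
    the same constant, which cancels in the pairwise differences, so
    Delta-S depends on chromaticity only.
    """
    df = _log_contrasts(a, b)
    e1, e2, e3, e4 = noise.omega
    f1, f2, f3, f4 = df
    num = ((e1 * e2) ** 2 * (f4 - f3) ** 2
           + (e1 * e3) ** 2 * (f4 - f2) ** 2
           + (e1 * e4) ** 2 * (f3 - f2) ** 2
           + (e2 * e3) ** 2 * (f4 - f1) ** 2
           + (e2 * e4) ** 2 * (f3 - f1) ** 2
           + (e3 * e4) ** 2 * (f2 - f1) ** 2)
    den = ((e1 * e2 * e3) ** 2 + (e1 * e2 * e4) ** 2
           + (e1 * e3 * e4) ** 2 + (e2 * e3 * e4) ** 2)
    return float(np.sqrt(num / den))


def chromatic_jnd_matrix(Q: np.ndarray, noise: NoiseVector) -> np.ndarray:
    """All pairwise chromatic JNDs for an (n, 4) array of positive catches.

    Vectorized equivalent of :func:`chromatic_jnd` over every unordered
    pair; returns a symmetric (n, n) matrix with zero diagonal.
    """
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[1] != 4:
        raise ValueError("Q must be (n, 4)")
    if np.any(Q <= 0):
        raise ValueError("all catches must be positive for log contrasts")
    logQ = np.log(Q)
    df = logQ[:, None, :] - logQ[None, :, :]  # (n, n, 4)
    e = noise.omega
    pairs = [(0, 1, 3, 2), (0, 2, 3, 1), (0, 3, 2, 1),
             (1, 2, 3, 0), (1, 3, 2, 0), (2, 3, 1, 0)]
    num = np.zeros(df.shape[:2])
    for i, j, k, l in pairs:
        num += (e[i] * e[j]) ** 2 * (df[..., k] - df[..., l]) ** 2
    den = sum((np.prod(np.delete(e, i))) ** 2 for i in range(4))
    return np.sqrt(num / den)


def achromatic_jnd(a: QuantumCatches, b: QuantumCatches, achromatic_weber: float = 0.1) -> float:
    """Luminance-channel contrast: |ln(Q_A^a / Q_A^b)| / Weber fraction."""
    if a.Q_A <= 0 or b.Q_A <= 0:
        raise ValueError("achromatic catches must be positive")
    if achromatic_weber <= 0:
        raise ValueError("achromatic Weber fraction must be positive")
    return float(abs(np.log(a.Q_A / b.Q_A)) / achromatic_weber)
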