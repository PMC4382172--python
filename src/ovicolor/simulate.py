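"""Synthetic inputs with the statistical structure the analysis assumes.

Every stage of the pipeline is testable offline: clutch-structured
blue-green egg reflectance spectra with separately controllable
between-clutch and within-clutch hue variance plus replicate
measurement noise; template photoreceptor sensitivities (Gaussian or
the standard A1 visual-pigment nomogram) at user-supplied peak
wavelengths; and three-arm rejection-outcome tables with per-arm
rejection probabilities and covariates.

Egg reflectance is modeled as a baseline plus one Gaussian peak whose
center is the egg's hue: per clutch j the center c_j is drawn around
the population mean with between-clutch spread sigma_B, per egg k the
center c_jk around c_j with within-clutch spread sigma_W.  Hue is the
varied parameter because hue (wavelength at peak reflectance) is what
distinguishes blue-green eggshell colors.  Real eggshell spectra also
carry a UV shoulder that this single-peak model omits; one peak is
enough to exercise every pipeline stage.

All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rejection import OutcomeRecord, TREATMENTS
from .spectra import Spectrum, WavelengthGrid
from .visual import RECEPTOR_ORDER, ReceptorSet, DEFAULT_DENSITIES

__all__ = [
    "SpectraSimConfig",
    "OutcomeSimConfig",
    "DEFAULT_LAMBDA_MAX",
    "simulate_egg_spectra",
    "simulate_sensitivities",
    "simulate_outcomes",
]

#: Cone peak wavelengths (nm) for a UVS-type turdid retina, short to long.
DEFAULT_LAMBDA_MAX = (373.0, 454.0, 504.0, 557.0)


@dataclass(frozen=True)
class SpectraSimConfig:
    """Clutch-structured egg-spectrum generator settings.

    Defaults mirror the field study's design: 23 clutches of 3 eggs,
    each egg measured 9 times.  Hue parameters put the reflectance peak
    near 500 nm (blue-green), with clutch identity explaining most hue
    variance (sigma_B = 6 nm between clutches vs sigma_W = 2 nm within)
    and 1% additive replicate measurement noise.
    """

    n_clutches: int = 23
    eggs_per_clutch: int = 3
    replicates_per_egg: int = 9
    grid: WavelengthGrid = field(default_factory=WavelengthGrid)
    baseline: float = 0.10
    peak_center_mean: float = 500.0
    between_clutch_sd: float = 6.0
    within_clutch_sd: float = 2.0
    peak_width: float = 60.0
    peak_height: float = 0.45
    measurement_noise_sd: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_clutches, self.eggs_per_clutch, self.replicates_per_egg) < 1:
            raise ValueError("counts must be positive")
        if min(self.between_clutch_sd, self.within_clutch_sd,
               self.measurement_noise_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        if not (0 <= self.baseline and self.baseline + self.peak_height <= 1):
            raise ValueError("baseline + peak height must stay within [0, 1]")
        if self.peak_width <= 0:
            raise ValueError("peak width must be positive")


@dataclass(frozen=True)
class OutcomeSimConfig:
    """Three-arm rejection-experiment generator settings.

    Default arm sizes give a study of 57 nests (IV 13, DV 14, UNM 30)
    and a common rejection probability of 0.58 per arm — the blue model
    egg's known rejection rate — i.e. no treatment effect, the study
    system's expected regime.  Covariates: Julian date uniform over the
    May-July breeding window, laying vs incubation stage, clutch sizes
    2-4, three year labels.
    """

    n_per_group: tuple[int, int, int] = (13, 14, 30)
    p_reject: tuple[float, float, float] = (0.58, 0.58, 0.58)
    julian_range: tuple[int, int] = (130, 200)
    p_laying: float = 0.5
    clutch_sizes: tuple[int, ...] = (2, 3, 4)
    years: tuple[str, ...] = ("2010", "2011", "2012")
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_group):
            raise ValueError("group sizes must be non-negative")
        if any(not 0 <= p <= 1 for p in self.p_reject):
            raise ValueError("rejection probabilities must be in [0, 1]")
        if not 0 <= self.p_laying <= 1:
            raise ValueError("p_laying must be in [0, 1]")


def simulate_egg_spectra(cfg: SpectraSimConfig) -> list[Spectrum]:
    """Generate raw replicate reflectance spectra with clutch structure.

    Returns n_clutches * eggs_per_clutch * replicates_per_egg spectra
    carrying egg/clutch/position/replicate metadata, ready for
    :func:`ovicolor.spectra.average_replicates`.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    wl = cfg.grid.wavelengths
    positions = ("blunt", "middle", "sharp")
    out: list[Spectrum] = []
    for j in range(cfg.n_clutches):
        c_j = rng.normal(cfg.peak_center_mean, cfg.between_clutch_sd)
        for k in range(cfg.eggs_per_clutch):
            c_jk = rng.normal(c_j, cfg.within_clutch_sd)
            clean = cfg.baseline + cfg.peak_height * np.exp(
                -((wl - c_jk) ** 2) / (2 * cfg.peak_width**2))
            clean = np.clip(clean, 0.0, 1.0)
            for rep in range(cfg.replicates_per_egg):
                noisy = clean + rng.normal(0.0, cfg.measurement_noise_sd, wl.size)
                noisy = np.clip(noisy, 0.0, None)
                out.append(Spectrum(
                    wl, noisy, kind="reflectance",
                    meta={
                        "egg_id": f"e{j + 1:02d}{chr(ord('a') + k)}",
                        "clutch_id": f"c{j + 1:02d}",
                        "position": positions[rep % 3],
                        "replicate": str(rep + 1),
                    },
                ))
    return out


def _a1_template(wl: np.ndarray, lmax: float) -> np.ndarray:
    """Standard A1 visual-pigment absorbance template (alpha + beta bands)."""
    x = lmax / wl
    a = 0.8795 + 0.0459 * np.exp(-((lmax - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (np.exp(69.7 * (a - x)) + np.exp(28.0 * (0.922 - x))
                   + np.exp(-14.9 * (1.104 - x)) + 0.674)
    lmb = 189.0 + 0.315 * lmax
    bb = -40.5 + 0.195 * lmax
    beta = 0.26 * np.exp(-(((wl - lmb) / bb) ** 2))
    return alpha + beta


def simulate_sensitivities(
    lambda_max: tuple[float, float, float, float] = DEFAULT_LAMBDA_MAX,
    shape: str = "a1_template",
    grid: WavelengthGrid | None = None,
    gaussian_width: float = 40.0,
    emulate_padding: bool = False,
    densities: dict | None = None,
    weber_fraction: float = 0.1,
    reference_receptor: str = "LWS",
    achromatic_weber: float = 0.1,
) -> ReceptorSet:
    """Build a four-cone ReceptorSet from peak wavelengths.

    ``shape="a1_template"`` uses the standard visual-pigment nomogram
    (unimodal alpha band plus UV beta band); ``"gaussian"`` a fixed
    width normal shape.  Curves are normalized to unit peak.  With
    ``emulate_padding`` the 300-330 nm region is forced to zero, as
    done when digitized sensitivity data start at 330 nm.

    These template curves are a synthetic stand-in: to reproduce
    published results, substitute digitized sensitivity files for the
    species of interest.
    """
    grid = grid or WavelengthGrid()
    wl = grid.wavelengths
    if len(lambda_max) != 4:
        raise ValueError("need four peak wavelengths (UVS, SWS, MWS, LWS)")
    sens = {}
    for name, lmax in zip(RECEPTOR_ORDER, lambda_max):
        if not wl[0] <= lmax <= wl[-1]:
            raise ValueError(f"{name} lambda_max {lmax} nm outside grid "
                             f"[{wl[0]:g}, {wl[-1]:g}]")
        if shape == "gaussian":
            curve = np.exp(-((wl - lmax) ** 2) / (2 * gaussian_width**2))
        elif shape == "a1_template":
            curve = _a1_template(wl, lmax)
        else:
            raise ValueError(f"unknown shape {shape!r}")
        curve = curve / curve.max()
        if emulate_padding:
            curve = curve.copy()
            curve[(wl >= 300.0) & (wl < 330.0)] = 0.0
        sens[name] = Spectrum(wl, curve, kind="sensitivity",
                              meta={"receptor": name, "lambda_max": lmax})
    return ReceptorSet(
        sensitivities=sens,
        densities=densities or dict(DEFAULT_DENSITIES),
        weber_fraction=weber_fraction,
        reference_receptor=reference_receptor,
        achromatic_weber=achromatic_weber,
    )


def simulate_outcomes(cfg: OutcomeSimConfig) -> list[OutcomeRecord]:
    """Generate independent Bernoulli rejection outcomes with covariates."""
    rng = np.random.default_rng(cfg.rng_seed)
    records: list[OutcomeRecord] = []
    nest = 0
    for g, (treatment, n, p) in enumerate(zip(TREATMENTS, cfg.n_per_group, cfg.p_reject)):
        for _ in range(n):
            nest += 1
            records.append(OutcomeRecord(
                nest_id=f"n{nest:03d}",
                treatment=treatment,
                outcome="reject" if rng.random() < p else "accept",
                julian_date=int(rng.integers(cfg.julian_range[0], cfg.julian_range[1] + 1)),
                stage="laying" if rng.random() < cfg.p_laying else "incubation",
                clutch_size=int(rng.choice(cfg.clutch_sizes)),
                year=str(rng.choice(cfg.years)),
            ))
    return records
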