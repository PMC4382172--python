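"""End-to-end orchestration: config, pipelines, report artifacts.

Two pipelines mirror the two halves of the analysis.  The color
pipeline runs read -> average replicates -> regrid -> smooth -> quantum
catches -> proportional catches -> pairwise JNDs -> disjoint random
pairing -> Welch tests, and writes a variation report, per-egg catches
and the full JND matrix.  The rejection pipeline runs tabulate ->
Fisher exact (+ Monte Carlo) on the 3x2 table and the IV-vs-DV 2x2 ->
Cramér's V -> power at the observed N -> required N at the target
power -> binomial logistic GLM, and writes contingency, coefficient
and power reports.  Every run writes a provenance block (config hash,
seed, package version) next to its reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clutch import clutch_variation_report
from .rejection import (
    DEFAULT_TERMS,
    cramers_v,
    chisq_power,
    fisher_exact,
    fisher_mc,
    fit_binomial_glm,
    read_outcomes,
    records_to_frame,
    required_n,
    tabulate,
)
from .spectra import (
    Spectrum,
    WavelengthGrid,
    average_replicates,
    pad_sensitivity,
    read_spectra,
    regrid,
    triangular_smooth,
)
from .visual import (
    DEFAULT_DENSITIES,
    Illuminant,
    ReceptorSet,
    chromatic_jnd_matrix,
    quantum_catch,
    receptor_noise,
    RECEPTOR_ORDER,
)

__all__ = ["RunConfig", "run_color_pipeline", "run_rejection_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Flat run configuration, loadable from a YAML mapping."""

    # paths
    spectra: str | None = None
    sensitivities: str | None = None
    illuminant: str | None = None
    outcomes: str | None = None
    outdir: str = "ovicolor_out"
    # visual-model parameters
    densities: dict = field(default_factory=lambda: dict(DEFAULT_DENSITIES))
    weber_fraction: float = 0.1
    achromatic_weber: float = 0.1
    reference_receptor: str = "LWS"
    smoothing_nm: float = 30.0
    grid_start: float = 300.0
    grid_stop: float = 700.0
    grid_step: float = 1.0
    # analysis parameters
    rng_seed: int = 0
    mc_replicates: int = 2000
    alpha: float = 0.05
    target_power: float = 0.8
    # flags
    pad_sensitivities: bool = True
    percent_reflectance: bool | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @property
    def grid(self) -> WavelengthGrid:
        return WavelengthGrid(self.grid_start, self.grid_stop, self.grid_step)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_provenance(cfg: RunConfig, outdir: Path, stage: str) -> None:
    block = {
        "stage": stage,
        "package": "ovicolor",
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "rng_seed": cfg.rng_seed,
        "config": asdict(cfg),
    }
    with open(outdir / f"{stage}_run.json", "w") as fh:
        json.dump(block, fh, indent=2, sort_keys=True, default=str)


def _load_receptors(cfg: RunConfig) -> ReceptorSet:
    if cfg.sensitivities is None:
        raise FileNotFoundError("no sensitivity file configured")
    curves = read_spectra(cfg.sensitivities, dialect="wide", kind="sensitivity")
    sens = {}
    for s in curves:
        label = str(s.meta.get("egg_id", "")).upper()
        if label in RECEPTOR_ORDER:
            if cfg.pad_sensitivities and s.wavelengths[0] > cfg.grid_start:
                s = pad_sensitivity(s, (cfg.grid_start, s.wavelengths[0]), 0.0)
            sens[label] = regrid(s, cfg.grid)
    missing = [r for r in RECEPTOR_ORDER if r not in sens]
    if missing:
        raise ValueError(f"sensitivity file lacks curves for {missing}")
    return ReceptorSet(sensitivities=sens, densities=cfg.densities,
                       weber_fraction=cfg.weber_fraction,
                       reference_receptor=cfg.reference_receptor,
                       achromatic_weber=cfg.achromatic_weber)


def _load_illuminant(cfg: RunConfig) -> Illuminant:
    if cfg.illuminant is None:
        return Illuminant.flat(cfg.grid.wavelengths)
    curves = read_spectra(cfg.illuminant, dialect="wide", kind="irradiance")
    return Illuminant(regrid(curves[0], cfg.grid),
                      name=str(curves[0].meta.get("egg_id", "file")))


def run_color_pipeline(
    cfg: RunConfig,
    spectra: list[Spectrum] | None = None,
    receptors: ReceptorSet | None = None,
    light: Illuminant | None = None,
) -> dict[str, Path]:
    """Run the perceptual clutch-variation analysis; return artifact paths.

    Inputs may be passed in memory (as the simulators produce them) or
    read from the configured files.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        if spectra is None:
            if cfg.spectra is None:
                raise FileNotFoundError("no spectra file configured")
            spectra = read_spectra(cfg.spectra, dialect="wide", kind="reflectance",
                                   percent=cfg.percent_reflectance)
        receptors = receptors or _load_receptors(cfg)
        light = light or _load_illuminant(cfg)

        eggs = average_replicates(spectra)
        eggs = [triangular_smooth(regrid(e, cfg.grid), cfg.smoothing_nm) for e in eggs]

        report = clutch_variation_report(eggs, receptors, light, rng_seed=cfg.rng_seed)

        catches = [quantum_catch(e, receptors, light) for e in eggs]
        catch_df = pd.DataFrame(
            [{"egg_id": c.egg_id, "clutch_id": c.clutch_id,
              **dict(zip(RECEPTOR_ORDER, c.Q)), "Achrom": c.Q_A}
             for c in catches])
        Q = np.array([c.Q for c in catches])
        jnd = chromatic_jnd_matrix(Q, receptor_noise(receptors))
        jnd_df = pd.DataFrame(jnd, index=catch_df["egg_id"], columns=catch_df["egg_id"])

        manifest = pd.DataFrame(
            [{"egg_id": e.meta.get("egg_id"), "clutch_id": e.meta.get("clutch_id"),
              "n_averaged": e.meta.get("n_averaged", 1)} for e in eggs])
    except Exception as exc:
        raise RuntimeError(f"color pipeline failed at stage: {exc}") from exc

    paths = {
        "variation_report": outdir / "variation_report.tsv",
        "egg_catches": outdir / "egg_catches.tsv",
        "jnd_matrix": outdir / "jnd_matrix.tsv",
        "egg_manifest": outdir / "egg_manifest.tsv",
    }
    report.to_csv(paths["variation_report"], sep="\t", index=False, float_format="%.6g")
    catch_df.to_csv(paths["egg_catches"], sep="\t", index=False, float_format="%.6g")
    jnd_df.to_csv(paths["jnd_matrix"], sep="\t", float_format="%.6g")
    manifest.to_csv(paths["egg_manifest"], sep="\t", index=False)
    _write_provenance(cfg, outdir, "color")
    return paths


def run_rejection_pipeline(cfg: RunConfig, records=None) -> dict[str, Path]:
    """Run the rejection-experiment statistics; return artifact paths."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        if records is None:
            if cfg.outcomes is None:
                raise FileNotFoundError("no outcome file configured")
            records = read_outcomes(cfg.outcomes)
        frame = records_to_frame(records)
        present = frame["treatment"].unique()
        missing = [t for t in ("IV", "DV", "UNM") if t not in present]
        if missing:
            raise ValueError(f"outcome data lack treatment level(s): {missing}")

        table = tabulate(records)
        p_exact = fisher_exact(table)
        p_mc = fisher_mc(table, cfg.mc_replicates, cfg.rng_seed)
        sub = table.counts[:2]  # IV vs DV only
        p_exact_ivdv = fisher_exact(sub)
        p_mc_ivdv = fisher_mc(sub, cfg.mc_replicates, cfg.rng_seed)

        eff = cramers_v(table)
        power = chisq_power(eff.w, eff.N, eff.df, cfg.alpha)
        n_cont, n_up = required_n(eff.w, cfg.target_power, eff.df, cfg.alpha)

        fit = fit_binomial_glm(frame, DEFAULT_TERMS)
    except Exception as exc:
        raise RuntimeError(f"rejection pipeline failed at stage: {exc}") from exc

    paths = {
        "contingency": outdir / "contingency.tsv",
        "fisher": outdir / "fisher.tsv",
        "power_report": outdir / "power_report.tsv",
        "glm_coefficients": outdir / "glm_coefficients.tsv",
    }
    table.to_frame().to_csv(paths["contingency"], sep="\t")
    pd.DataFrame([
        {"comparison": "IV/DV/UNM", "p_exact": p_exact, "p_mc": p_mc,
         "replicates": cfg.mc_replicates, "rng_seed": cfg.rng_seed},
        {"comparison": "IV/DV", "p_exact": p_exact_ivdv, "p_mc": p_mc_ivdv,
         "replicates": cfg.mc_replicates, "rng_seed": cfg.rng_seed},
    ]).to_csv(paths["fisher"], sep="\t", index=False, float_format="%.6g")
    pd.DataFrame([{
        "chi2": eff.chi2, "cramers_v": eff.V, "w": eff.w, "df": eff.df,
        "N": eff.N, "alpha": cfg.alpha, "power": power,
        "required_n_continuous": n_cont, "required_n": n_up,
        "target_power": cfg.target_power,
    }]).to_csv(paths["power_report"], sep="\t", index=False, float_format="%.6g")
    out = fit.params.copy()
    out.insert(0, "term", out.index)
    out["converged"] = fit.converged
    out.to_csv(paths["glm_coefficients"], sep="\t", index=False, float_format="%.6g")
    _write_provenance(cfg, outdir, "rejection")
    return paths
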