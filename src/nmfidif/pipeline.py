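"""End-to-end orchestration: phantom -> IDIFs -> plasma correction -> 2TCM.

`run_compare` renders a phantom, extracts both the threshold-IDIF and the
NMF-IDIF, and scores each against the known left-ventricle curve (pointwise
percent difference, Pearson correlation, 0-60 min activity integral, and
Bland-Altman bias +/- SD).  `run_end_to_end` continues into kinetic
modeling: brain-like region TACs are synthesized from the true LV plasma
curve with known micro-parameters, then fitted with the true plasma, the
NMF-IDIF and the threshold-IDIF inputs, so both V_T recovery and the
input-function-induced bias ordering are quantified for the whole chain.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .blood import CorrectionModel, correct_input_function
from .components import extract_nmf_idif
from .io import SphericalVoi, Tac, write_tac
from .kinetics import TcmParams, fit_2tcm, simulate_2tcm, vt
from .phantom import HEART_CENTER_MM, default_phantom_spec, render_dynamic_image
from .threshold import extract_threshold_idif
from .unmix import build_voxel_matrix
from .io import voi_mask

__all__ = ["RunConfig", "compare_tacs", "run_compare", "run_end_to_end", "DEFAULT_BRAIN_REGIONS"]

#: synthetic brain regions with reversible kinetics; V_T spans the range a
#: high-binding tracer shows across gray-matter structures
DEFAULT_BRAIN_REGIONS = {
    "CTX": TcmParams(K1=0.60, k2=0.25, k3=0.10, k4=0.015),
    "TH": TcmParams(K1=0.70, k2=0.22, k3=0.09, k4=0.012),
    "CB": TcmParams(K1=0.55, k2=0.30, k3=0.08, k4=0.018),
}


@dataclass
class RunConfig:
    """Configuration of a reproducible end-to-end run."""

    seed: int = 0
    out_dir: str | None = None
    regions: tuple = ("RV", "LV", "MYO")
    psf_fwhm_mm: float = 1.2
    noise_scale: float = 0.7
    voi_center_mm: tuple = HEART_CENTER_MM
    voi_radius_mm: float = 3.5
    n_components: int | None = None  # None -> automatic selection
    activity_threshold: float = 0.5
    r_threshold: float = 0.9
    corr_threshold: float = 0.7
    correction_model: str | None = None  # JSON path; None -> identity
    brain_regions: dict = field(default_factory=lambda: dict(DEFAULT_BRAIN_REGIONS))
    tissue_noise_frac: float = 0.02

    def __post_init__(self) -> None:
        for name in ("activity_threshold", "r_threshold", "corr_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        self.seed = int(self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "brain_regions" in raw:
            raw["brain_regions"] = {
                k: TcmParams(**v) for k, v in raw["brain_regions"].items()
            }
        if "regions" in raw:
            raw["regions"] = tuple(raw["regions"])
        if "voi_center_mm" in raw:
            raw["voi_center_mm"] = tuple(raw["voi_center_mm"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["brain_regions"] = {
            k: dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v
            for k, v in self.brain_regions.items()
        }
        d["regions"] = list(self.regions)
        d["voi_center_mm"] = list(self.voi_center_mm)
        return d


def compare_tacs(candidate: Tac, reference: Tac, t_max_s: float = 3600.0) -> dict:
    """Score a candidate input function against a reference curve.

    Both curves must share framing.  Percent differences are signed,
    relative to the reference; integrals use the trapezoidal rule on frame
    mid-times up to ``t_max_s``; the Bland-Altman summary is the mean and
    SD of the pointwise percent differences.
    """
    if len(candidate) != len(reference) or not np.allclose(
        candidate.times_s, reference.times_s
    ):
        raise ValueError("candidate and reference must share framing")
    keep = reference.times_s <= t_max_s
    t_min = candidate.times_s[keep] / 60.0
    c = candidate.values[keep]
    r = reference.values[keep]
    nz = r != 0
    pct = np.full(len(c), np.nan)
    pct[nz] = 100.0 * (c[nz] - r[nz]) / r[nz]
    corr = float(np.corrcoef(c, r)[0, 1])
    return {
        "percent_diff": pct,
        "pearson_r": corr,
        "integral_candidate": float(np.trapezoid(c, t_min)),
        "integral_reference": float(np.trapezoid(r, t_min)),
        "bias_pct": float(np.nanmean(pct)),
        "bias_sd_pct": float(np.nanstd(pct)),
    }


def _extract_idifs(config: RunConfig):
    spec = default_phantom_spec(
        regions=config.regions,
        psf_fwhm_mm=config.psf_fwhm_mm,
        noise_scale=config.noise_scale,
        seed=config.seed,
    )
    image, truth = render_dynamic_image(spec)
    voi = SphericalVoi(config.voi_center_mm, config.voi_radius_mm)
    thr = extract_threshold_idif(image, voi, config.activity_threshold)
    Zmat = build_voxel_matrix(image, voi_mask(image, voi))
    nmf_tac, cset = extract_nmf_idif(
        Zmat,
        n_components=config.n_components,
        seed=config.seed,
        r_threshold=config.r_threshold,
        corr_threshold=config.corr_threshold,
    )
    return image, truth, thr, nmf_tac, cset


def run_compare(config: RunConfig) -> dict:
    """Phantom comparison of threshold-IDIF and NMF-IDIF against true LV."""
    image, truth, thr, nmf_tac, cset = _extract_idifs(config)
    reference = truth.region_tacs["LV"]
    report = {
        "seed": config.seed,
        "n_components": cset.n,
        "labels": list(cset.labels),
        "threshold_idif": compare_tacs(thr.tac, reference),
        "nmf_idif": compare_tacs(nmf_tac, reference),
    }
    for key in ("threshold_idif", "nmf_idif"):
        report[key]["abs_integral_error"] = abs(
            report[key]["integral_candidate"] - report[key]["integral_reference"]
        )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_tac(thr.tac, out / "threshold_idif.csv")
        write_tac(nmf_tac, out / "nmf_idif.csv")
        write_tac(reference, out / "true_lv.csv")
        serializable = json.loads(json.dumps(report, default=lambda o: np.asarray(o).tolist()))
        (out / "compare_report.json").write_text(json.dumps(serializable, indent=2))
    return report


def run_end_to_end(config: RunConfig) -> pd.DataFrame:
    """Full chain through 2TCM; returns a per-region fit table.

    Synthetic brain TACs are generated from the *true* LV plasma curve with
    the configured micro-parameters plus proportional Gaussian noise, then
    fitted three times: with that true plasma curve (validating the kinetic
    stage itself), with the NMF-IDIF-derived plasma, and with the
    threshold-IDIF-derived plasma.  The table carries, per region, the true
    V_T and the fitted V_T / wsMAPE for each input function, so the
    characteristic ordering — threshold-IDIF underestimates V_T more than
    the unmixed input function — can be read off directly.  A provenance
    log (config hash, versions, seed) is written when ``out_dir`` is set.
    """
    image, truth, thr, nmf_tac, cset = _extract_idifs(config)
    model = (
        CorrectionModel.from_json(config.correction_model)
        if config.correction_model
        else CorrectionModel.identity()
    )
    inputs = {
        "true_plasma": correct_input_function(truth.region_tacs["LV"], model),
        "nmf_idif": correct_input_function(nmf_tac, model),
        "threshold_idif": correct_input_function(thr.tac, model),
    }
    true_plasma = inputs["true_plasma"]

    rng = np.random.default_rng(config.seed + 1)
    rows = []
    for name, params in config.brain_regions.items():
        clean = simulate_2tcm(true_plasma, params, true_plasma.times_s)
        noisy = clean + rng.standard_normal(len(clean)) * config.tissue_noise_frac * clean.max()
        tissue = true_plasma.with_values(np.clip(noisy, 0.0, None))
        row = {"region": name, "V_T_true": vt(params)}
        for key, plasma in inputs.items():
            fit = fit_2tcm(tissue, plasma, seed=config.seed)
            row[f"V_T_{key}"] = fit.V_T
            row[f"wsmape_pct_{key}"] = fit.wsmape_pct
            row[f"converged_{key}"] = fit.converged
        rows.append(row)
    table = pd.DataFrame(rows)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "tcm_fits.csv", index=False)
        cfg = config.to_dict()
        cfg_json = json.dumps(cfg, sort_keys=True, default=str)
        provenance = {
            "config": cfg,
            "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": config.seed,
            "nmfidif_version": __version__,
            "numpy_version": np.__version__,
        }
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return table
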