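"""Pipeline configuration, table writers and the end-to-end runner.

A single YAML config (validated against a pydantic schema; unknown keys
are rejected) selects the stages to run — ``synth`` (generate inputs),
``metrics`` (image/contour analysis), ``theory`` (stability scan and
residual-stiffness fit) and ``fem`` (growth simulation) — all fed from one
root seed.  Outputs are CSV tables with units in the headers plus a JSON +
Markdown report recording versions, seed and the config hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .fem import FemConfig, run_growth
from .mechanics import LayerStack
from .metrics import (
    blister_metrics, contour_metrics, count_ring_features, expansion_fit,
    fit_wavelength, local_kinematics, extract_contour, normalize_and_segment,
)
from .synthetic import (
    SyntheticScene, gen_blister_series, gen_colony_series,
    gen_radial_pattern_image, gen_stiffness_dataset,
)
from .theory import fit_residual_stiffness, scan_and_slope

SCHEMA_VERSION = 1

_FORBID = ConfigDict(extra="forbid")


class TheoryBlock(BaseModel):
    model_config = _FORBID
    gr_over_gf: float = 0.1
    hr_over_hf: float = 0.3
    ratio_start: float = 0.05
    ratio_stop: float = 1000.0
    ratio_num: int = 40
    slope_window: tuple[float, float] = (10.0, 1000.0)
    fit_bracket: tuple[float, float] = (1e-3, 1.0)


class SynthBlock(BaseModel):
    model_config = _FORBID
    lambda_mm: float = 1.0
    colony_radius_mm: float = 6.0
    noise_sigma: float = 0.02
    petal_count: int = 6
    t_c_hr: float = 40.0
    hf_mm: float = 0.1
    gr_true: float = 0.1
    stiffness_noise_sigma: float = 0.05


class MetricsBlock(BaseModel):
    model_config = _FORBID
    edge_radius_frac: float = 0.9
    min_prominence: float = 0.02
    ring_samples: int = 1024


class FemBlock(BaseModel):
    model_config = _FORBID
    gf_over_gs: float = 10.0
    gr_over_gf: float = 1.0      # bilayer-like demo default
    hr_over_hf: float = 0.3
    dg: float = 0.002
    g_max: float = 0.4
    wavelengths: float = 10.0
    elements_per_hf: int = 4
    elements_per_wavelength: int = 12


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = _FORBID
    stages: list[Literal["synth", "metrics", "theory", "fem"]] = \
        Field(default_factory=lambda: ["synth", "metrics", "theory"])
    seed: int = 0
    units: Literal["Pa", "kPa"] = "Pa"
    log_level: str = "INFO"
    theory: TheoryBlock = Field(default_factory=TheoryBlock)
    synth: SynthBlock = Field(default_factory=SynthBlock)
    metrics: MetricsBlock = Field(default_factory=MetricsBlock)
    fem: FemBlock = Field(default_factory=FemBlock)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()).hexdigest()[:12]


def _fmt(x) -> str:
    return f"{x:.6g}" if isinstance(x, (float, np.floating)) else str(x)


def write_table(df: pd.DataFrame, path: Path) -> None:
    """CSV with fixed column order and floats at 6 significant digits."""
    path.parent.mkdir(parents=True, exist_ok=True)
    out = df.copy()
    for col in out.columns:
        out[col] = out[col].map(_fmt)
    out.to_csv(path, index=False)


def write_json(obj: dict, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {"schema_version": SCHEMA_VERSION, **obj}
    path.write_text(json.dumps(payload, indent=2, default=float) + "\n")


def _pressure_cols(df: pd.DataFrame, units: str) -> pd.DataFrame:
    """Apply the kPa unit preference: scale *_Pa columns, rename headers."""
    if units != "kPa":
        return df
    out = df.copy()
    for col in list(out.columns):
        if col.endswith("_Pa"):
            out[col.removesuffix("_Pa") + "_kPa"] = out[col] / 1e3
            out = out.drop(columns=col)
    return out


def _stage_seed(root_seed: int, stage: str) -> int:
    """Derive a per-stage seed from the root seed (single-knob runs)."""
    digest = hashlib.sha256(f"{root_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the configured stages and write all tables and the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    scene = SyntheticScene(
        seed=_stage_seed(config.seed, "synth"),
        lambda_mm=config.synth.lambda_mm,
        colony_radius_mm=config.synth.colony_radius_mm,
        noise_sigma=config.synth.noise_sigma,
        petal_count=config.synth.petal_count,
        t_c_hr=config.synth.t_c_hr,
    )

    artifacts: dict = {}
    if "synth" in config.stages:
        img, img_truth = gen_radial_pattern_image(scene)
        masks, colony_truth = gen_colony_series(scene)
        blisters, blister_truth = gen_blister_series(
            hf=config.synth.hf_mm, seed=scene.seed)
        template = LayerStack.from_ratios(
            1.0, gr_over_gf=config.synth.gr_true,
            hr_over_hf=config.theory.hr_over_hf)
        ratios = np.geomspace(0.02, 10.0, 8)
        scan_data, scan_truth = gen_stiffness_dataset(
            template, config.synth.gr_true, ratios,
            noise_sigma=config.synth.stiffness_noise_sigma, seed=scene.seed)
        artifacts = {"image": img, "masks": masks, "blisters": blisters,
                     "scan_data": scan_data, "template": template}
        import tifffile
        tifffile.imwrite(out / "radial_pattern.tif", img.astype(np.float32))
        write_json({"radial_pattern": img_truth, "colony_series": colony_truth,
                    "blisters": blister_truth, "stiffness_data": scan_truth},
                   out / "truth.json")
        report["stages"]["synth"] = {"seed": scene.seed,
                                     "n_colony_frames": len(masks)}

    if "metrics" in config.stages:
        if not artifacts:
            raise RuntimeError("metrics stage requires the synth stage in this pipeline")
        img, masks, blisters = artifacts["image"], artifacts["masks"], artifacts["blisters"]
        from .metrics import NormalizedImage, ColonyMask
        nimg, cmask = normalize_and_segment(img, pixel_size=scene.pixel_size_mm)
        rows = []
        radii = np.arange(scene.pattern_inner_mm + 0.5,
                          scene.colony_radius_mm - 0.5, 0.5)
        for r_mm in radii:
            N, flagged = count_ring_features(
                nimg, cmask.center, r_mm / scene.pixel_size_mm,
                n_samples=config.metrics.ring_samples)
            rows.append({"r_mm": r_mm, "t_hr": 0.0, "N": N, "flagged": flagged})
        wl_df = pd.DataFrame(rows)
        good = wl_df[~wl_df.flagged & (wl_df.N > 0)]
        fit = fit_wavelength(good[["r_mm", "t_hr", "N"]].to_numpy())
        write_table(wl_df, out / "wavelength.csv")

        times = np.asarray(scene.times_hr)
        crows, rf = [], []
        for t, m in zip(times, masks):
            cm = ColonyMask(mask=m, center=scene_center(scene), pixel_size=scene.pixel_size_mm)
            P, A, alpha, r_mean = contour_metrics(cm)
            crows.append({"t_hr": t, "P_mm": P, "A_mm2": A, "alpha": alpha,
                          "Rf_mm": r_mean})
            rf.append(r_mean)
        write_table(pd.DataFrame(crows), out / "contour_metrics.csv")
        t_c, v1, v2 = expansion_fit(times, np.array(rf))

        kin = local_kinematics(extract_contour(masks[-2]), extract_contour(masks[-1]),
                               dt=float(times[-1] - times[-2]))
        px = scene.pixel_size_mm
        kin_df = pd.DataFrame({
            "t_hr": times[-2], "point_id": np.arange(len(kin.points)),
            "x_mm": kin.points[:, 0] * px, "y_mm": kin.points[:, 1] * px,
            "kappa_per_mm": kin.curvature / px,
            "vf_mm_per_hr": kin.velocity * px,
        })
        write_table(kin_df, out / "kinematics.csv")

        brows = []
        for i, prof in enumerate(blisters):
            H, W = blister_metrics(prof)
            brows.append({"id": i, "H_um": H * 1e3, "W_um": W * 1e3})
        write_table(pd.DataFrame(brows), out / "blister.csv")
        report["stages"]["metrics"] = {
            "wavelength_mm": fit.wavelength, "t_c_hr": t_c,
            "v_before_mm_hr": v1, "v_after_mm_hr": v2,
            "final_W_over_hf": brows[-1]["W_um"] / (config.synth.hf_mm * 1e3),
        }

    if "theory" in config.stages:
        template = LayerStack.from_ratios(
            1.0, gr_over_gf=config.theory.gr_over_gf,
            hr_over_hf=config.theory.hr_over_hf)
        ratios = np.geomspace(config.theory.ratio_start, config.theory.ratio_stop,
                              config.theory.ratio_num)
        scan, slope = scan_and_slope(template, ratios, config.theory.slope_window)
        scan_df = pd.DataFrame({
            "gf_over_gs": scan.ratios,
            "lambda_over_hf": scan.normalized_wavelengths,
            "eps_cr": scan.eps_cr,
            "S_cr_over_Gf": scan.S_cr_over_Gf,
        })
        write_table(scan_df, out / "scan.csv")
        fit_payload = {"slope": slope, "slope_window": list(config.theory.slope_window)}
        if "scan_data" in artifacts:
            fit = fit_residual_stiffness(artifacts["scan_data"], artifacts["template"],
                                         bracket=config.theory.fit_bracket)
            fit_payload["residual_fit"] = asdict(fit)
        write_json(fit_payload, out / "fit.json")
        report["stages"]["theory"] = {"slope": slope}

    if "fem" in config.stages:
        stack = LayerStack.from_ratios(
            config.fem.gf_over_gs, gr_over_gf=config.fem.gr_over_gf,
            hr_over_hf=config.fem.hr_over_hf, nu=0.45)
        fem_cfg = FemConfig.for_stack(
            stack, wavelengths=config.fem.wavelengths, dg=config.fem.dg,
            g_max=config.fem.g_max, seed=_stage_seed(config.seed, "fem"),
            elements_per_hf=config.fem.elements_per_hf,
            elements_per_wavelength=config.fem.elements_per_wavelength)
        result = run_growth(fem_cfg)
        traj = pd.DataFrame({
            "g": result.g_series,
            "epsilon": result.g_series / (1 + result.g_series),
            "max_deflection_m": result.deflection_series,
            "Pi_J_per_m": result.energy_series,
        })
        write_table(traj, out / "trajectory.csv")
        write_table(pd.DataFrame({"X1_m": result.surface_x,
                                  "u2_m": result.surface_u2}),
                    out / "final_surface.csv")
        state = result.final_state()
        cent = result.mesh.coords[result.mesh.triangles].mean(axis=1)
        strain_df = pd.DataFrame({
            "x_m": cent[:, 0], "y_m": cent[:, 1],
            "e11": state.green_lagrange[:, 0, 0],
            "e22": state.green_lagrange[:, 1, 1],
            "e12": state.green_lagrange[:, 0, 1],
            "evm": state.von_mises,
        })
        write_table(strain_df, out / "strain.csv")
        report["stages"]["fem"] = {
            "onset_g": result.onset_g, "onset_strain": result.onset_strain,
            "measured_wavelength": result.measured_wavelength,
        }

    write_json(report, out / "report.json")
    lines = [f"# biofilm-mech pipeline report",
             f"- version: {__version__}",
             f"- seed: {config.seed}",
             f"- config hash: {report['config_hash']}", ""]
    for stage, info in report["stages"].items():
        lines.append(f"## {stage}")
        for k, v in info.items():
            lines.append(f"- {k}: {_fmt(v) if v is not None else 'n/a'}")
        lines.append("")
    (out / "report.md").write_text("\n".join(lines))
    return report


def scene_center(scene: SyntheticScene) -> tuple[float, float]:
    ny, nx = scene.image_shape
    return ((nx - 1) / 2.0, (ny - 1) / 2.0)
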