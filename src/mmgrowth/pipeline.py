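"""End-to-end run: simulate → measure → summarize → fit → transport report.

Every run writes its artifacts plus the fully-resolved configuration and a
log into one run directory, and is bit-reproducible from (config, seed): all
random streams are spawned from the single pipeline seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import growthlaw, measure, mechanics, synthetic, transport
from .config import PipelineConfig, dataclass_to_mapping, save_config

__all__ = ["PipelineError", "run_pipeline"]

log = logging.getLogger("mmgrowth")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _round_floats(obj, sig: int = 9):
    """Round every float to ``sig`` significant digits for stable serialization."""
    if isinstance(obj, float):
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(f"{float(obj):.{sig}g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _write_json(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(_round_floats(payload), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.9g")


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            log.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as err:
                raise PipelineError(f"stage '{name}' failed: {err}") from err
        return wrapper
    return deco


@_stage("simulate")
def _simulate(config: PipelineConfig, outdir: Path) -> list[tuple[str, Path, Path]]:
    sc = config.scene
    chan_len = None
    out = []
    for rep in range(1, sc.n_replicates + 1):
        spec = synthetic.typical_scene(
            rng_seed=config.rng_seed * 1000 + rep,
            n_cells=sc.n_cells,
            mean_length=sc.mean_length,
            mean_width=sc.mean_width,
            length_sd=sc.length_sd,
            width_sd=sc.width_sd,
            gap_um=sc.gap_um,
            pixel_size=sc.pixel_size,
            psf_sigma=sc.psf_sigma,
            background_level=sc.background_level,
            peak_signal=sc.peak_signal,
            read_noise_sd=sc.read_noise_sd,
        )
        img, truth = synthetic.render_scene(spec)
        tiff = outdir / f"scene_rep{rep}.tiff"
        truth_csv = outdir / f"truth_rep{rep}.csv"
        synthetic.write_scene(spec, img, tiff, truth_csv)
        out.append((str(rep), tiff, truth_csv))
        chan_len = spec.channel.length
    log.info("rendered %d replicate scenes (channel length %.1f μm)", len(out), chan_len)
    return out


@_stage("measure")
def _measure(config: PipelineConfig, scenes, outdir: Path) -> pd.DataFrame:
    sc = config.scene
    mcfg = dataclasses.replace(
        config.measurement,
        diffraction_offset=measure.calibrate_diffraction_offset(
            sc.mean_width, config.measurement, sc.pixel_size, sc.psf_sigma, sc.mean_length
        ),
    )
    log.info("calibrated diffraction offset: %.4f μm", mcfg.diffraction_offset)
    tables = {}
    for rep, tiff, _truth in scenes:
        img = tifffile.imread(tiff).astype(float)
        tables[rep] = measure.measure_scene(img, mcfg, sc.pixel_size)
    table = synthetic.generate_measurement_table(tables)
    _write_csv(table, outdir / "measurements.csv")
    return table


@_stage("summarize")
def _summarize(table: pd.DataFrame, outdir: Path) -> pd.DataFrame:
    ok = table[table["flag"] == ""] if "flag" in table else table
    tidy = ok.melt(
        id_vars=["replicate"],
        value_vars=["length_um", "width_outer_um", "volume_um3"],
        var_name="group",
        value_name="value",
    ).dropna()
    summaries = growthlaw.replicate_statistics(tidy)
    df = pd.DataFrame(
        [
            {
                "group": s.group,
                "grand_mean": s.grand_mean,
                "sem": s.sem,
                "n_replicates": s.n_replicates,
            }
            for s in summaries
        ]
    )
    _write_csv(df, outdir / "replicate_summary.csv")
    return df


@_stage("fit")
def _fit(config: PipelineConfig, outdir: Path) -> growthlaw.GrowthLawFit:
    g = config.growth_law
    samples = synthetic.generate_growth_law_dataset(
        g.v_i, g.cd_period, g.n_samples, (g.td_min, g.td_max), g.noise_cv,
        rng_seed=config.rng_seed * 1000 + 777,
    )
    frame = synthetic.samples_to_frame(samples)
    _write_csv(frame, outdir / "growth_law_samples.csv")
    fit = growthlaw.fit_growth_law(frame["v_b_um3"], frame["t_d_min"])
    _write_json(outdir / "growth_law_fit.json", dataclasses.asdict(fit))
    td_grid = np.linspace(g.td_min, g.td_max, 50)
    curve = pd.DataFrame(
        {"t_d_min": td_grid, "v_b_um3": [growthlaw.predict_birth_volume(fit, t) for t in td_grid]}
    )
    _write_csv(curve, outdir / "growth_law_curve.csv")
    return fit


@_stage("transport")
def _transport(config: PipelineConfig, outdir: Path) -> dict:
    t = config.transport
    geom = transport.ChannelGeometry(
        config.scene.channel_width, config.scene.channel_height, t.channel_length
    )
    x = np.linspace(0.0, geom.length, t.n_profile_points)

    absorb = transport.AbsorbingColonyParams(t.cell_radius, t.diffusion_nutrient, t.k_abs)
    kin = transport.GrowthKinetics(t.td_min_minutes, t.td_liquid_minutes)
    nut = transport.nutrient_profile(geom, absorb, x)
    td_prof = transport.doubling_time_profile(geom, absorb, kin, x)

    perm = transport.PermeationParams(t.water_flux, t.diffusion_bsa, t.water_density)
    acc = transport.accumulation_profile(geom, perm, x)

    profiles = pd.DataFrame(
        {
            "x_um": x,
            "nutrient_c_over_c0": nut.values,
            "doubling_time_min": td_prof.values,
            "bsa_c_over_c0": acc.values,
        }
    )
    _write_csv(profiles, outdir / "transport_profiles.csv")

    uptake = transport.KineticUptakeParams(t.imax, t.mean_cell_length, t.diffusion_nutrient, t.c0_mM)
    depl = transport.kinetic_depletion(geom, uptake, t.cell_radius)

    report = {
        "screening_length_um": nut.characteristic_length,
        "mother_cell_doubling_time_min": transport.mother_cell_doubling_time(geom, absorb, kin),
        "accumulation_length_um": acc.characteristic_length,
        "bsa_fold_increase": {
            str(L): float(np.exp(L**2 / (2 * acc.characteristic_length**2)))
            for L in (50.0, 100.0, 200.0)
        },
        "kinetic_depletion_mM": depl.delta_c_mM,
        "kinetic_depletion_valid": depl.valid,
        "inputs": dataclass_to_mapping(t),
    }
    _write_json(outdir / "transport_report.json", report)
    return report


@_stage("mechanics")
def _mechanics(config: PipelineConfig, outdir: Path) -> dict:
    m = config.mechanics
    forces = {
        key: mechanics.stall_force(
            mechanics.ShellMechanics(
                E, m.envelope_thickness_nm, m.cell_diameter_um, m.axial_strain
            )
        )
        for key, E in (
            ("low_uN", m.youngs_modulus_MPa_low),
            ("high_uN", m.youngs_modulus_MPa_high),
        )
    }
    report = {"stall_force": forces, "inputs": dataclass_to_mapping(m)}
    _write_json(outdir / "mechanics_report.json", report)
    return report


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute all stages into ``outdir``; returns the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)
    try:
        save_config(config, outdir / "resolved_config.yaml")
        scenes = _simulate(config, outdir)
        table = _measure(config, scenes, outdir)
        _summarize(table, outdir)
        _fit(config, outdir)
        _transport(config, outdir)
        _mechanics(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()
    return outdir
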