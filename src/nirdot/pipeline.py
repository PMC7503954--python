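"""End-to-end pipeline: simulate -> preprocess -> reconstruct -> stats.

A :class:`PipelineConfig` fully determines a run; the config hash is
stamped into every artifact so intermediates from different configurations
cannot be mixed.  Stages: synthetic recording (or SNIRF input), optical
density + motion correction + band-pass + decimation, Jacobian (cached by
geometry hash), Tikhonov inversion + spectral unmixing, then the GLM
(block designs) or window-variance (unstructured tasks) statistic,
thresholded at |t| > 1.65 inside the sensitivity mask.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import preprocess, protocol, stats, synth, tomo
from .constants import DEFAULT_SAMPLING_RATE, TISSUE_GRAY
from .forward import Jacobian, compute_jacobian, sensitivity_mask
from .headmodel import HeadModel, build_layered_head
from .probe import default_prefrontal_layout, fit_layout_to_head

__all__ = ["PipelineConfig", "run_pipeline", "default_activation_center"]


@dataclass
class PipelineConfig:
    """Serializable description of one pipeline run."""

    task: str = "SWG"  # SWG | SS | DS_backward
    task_duration: float = 120.0  # unstructured tasks only
    geometry: str = "hemisphere"
    grid_shape: tuple = (36, 36, 20)
    voxel_size: float = 4.0
    layer_thicknesses: tuple = (10.0, 2.0, 6.0, None)
    dome_radius: float | None = None
    sd_range: tuple = (10.0, 45.0)
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    band: tuple = (0.01, 0.3)
    filter_order: int = 4
    decimation: int = 8
    alpha: float = 0.01
    attenuation_factor: float = 1000.0
    window_length: float = 10.0
    threshold: float = stats.DEFAULT_THRESHOLD
    seed: int = 0
    activation_radius: float = 10.0
    activation_peak_o2hb: float = 1.0
    activation_hhb_ratio: float = 2.5
    noise: str = "default"  # default | zero
    snirf_input: str | None = None  # reconstruct a measured file instead
    property_table: str = "pinned-literature-compilation"

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("grid_shape", "layer_thicknesses", "sd_range", "band"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def default_activation_center(head: HeadModel) -> np.ndarray:
    """Gray-matter voxel center nearest the top of the head's central axis."""
    flat = np.flatnonzero((head.tissue_label == TISSUE_GRAY).ravel())
    if flat.size == 0:
        raise ValueError("head model contains no gray matter")
    pos = (np.array(np.unravel_index(flat, head.grid_shape)).T + 0.5) * head.voxel_size
    nx, ny, _ = head.grid_shape
    cx, cy = nx * head.voxel_size / 2.0, ny * head.voxel_size / 2.0
    lateral = np.hypot(pos[:, 0] - cx, pos[:, 1] - cy)
    near = lateral <= lateral.min() + head.voxel_size
    cand = pos[near]
    return cand[np.argmax(cand[:, 2])]


def build_task_design(cfg: PipelineConfig) -> protocol.TaskDesign:
    if cfg.task == "SWG":
        return protocol.build_swg()
    return protocol.build_unstructured(cfg.task, cfg.task_duration)


def run_pipeline(cfg: PipelineConfig, outdir, jacobian: Jacobian | None = None) -> dict:
    """Execute the full chain and write artifacts under `outdir`.

    Returns a dict with the in-memory results (head, layout, recording,
    movie, fits, stat map) and the paths written.  Passing a precomputed
    `jacobian` skips the forward solves (it is checked against the
    geometry hash).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    log: list = []

    def stage(name, fn):
        t0 = time.perf_counter()
        out = fn()
        log.append({"stage": name, "seconds": round(time.perf_counter() - t0, 3)})
        return out

    head = stage("head", lambda: build_layered_head(
        cfg.grid_shape, cfg.voxel_size, cfg.layer_thicknesses,
        geometry=cfg.geometry, dome_radius=cfg.dome_radius,
    ))
    layout = stage("layout", lambda: fit_layout_to_head(
        default_prefrontal_layout(cfg.sd_range), head
    ))
    design = build_task_design(cfg)

    ghash = head.geometry_hash()
    jac_path = outdir / f"jacobian_{ghash[:12]}.h5"
    if jacobian is None:
        if jac_path.exists():
            jacobian = Jacobian.load_hdf5(jac_path)
        else:
            jacobian = stage("jacobian", lambda: compute_jacobian(head, layout))
            jacobian.save_hdf5(jac_path)
    if jacobian.geometry_hash != ghash:
        raise ValueError("jacobian/head geometry hash mismatch — refusing to mix artifacts")
    mask = sensitivity_mask(jacobian, cfg.attenuation_factor)

    if cfg.snirf_input:
        from .snirf_io import read_snirf

        rec = stage("read", lambda: read_snirf(cfg.snirf_input))
        truth = None
    else:
        noise = synth.NoiseSpec.zero() if cfg.noise == "zero" else synth.NoiseSpec()
        act = synth.ActivationSpec(
            center=tuple(default_activation_center(head)),
            radius=cfg.activation_radius,
            peak_o2hb=cfg.activation_peak_o2hb,
            hhb_ratio=cfg.activation_hhb_ratio,
        )
        sim = stage("simulate", lambda: synth.simulate_recording(
            head, layout, design, act, noise, seed=cfg.seed,
            jacobian=jacobian, sampling_rate=cfg.sampling_rate,
        ))
        rec, truth = sim.recording, sim.truth

    od = stage("preprocess", lambda: preprocess.bandpass(
        preprocess.motion_correct(preprocess.to_optical_density(rec)),
        *cfg.band, order=cfg.filter_order,
    ).decimated(cfg.decimation))

    movie = stage("reconstruct", lambda: tomo.unmix(
        tomo.invert(jacobian, od, cfg.alpha, mask=mask)
    ))

    if cfg.task == "SWG":
        fits = stage("stats", lambda: stats.glm_tscores(movie, design, band=cfg.band))
        tmaps = {k: f.t_score for k, f in fits.items()}
        method, two_sided = "GLM", True
    else:
        fits = stage("stats", lambda: stats.variance_tscores(
            movie, design, cfg.window_length
        ))
        tmaps = {k: f.t_score for k, f in fits.items()}
        method, two_sided = "variance", False
    smap = stats.threshold_map(
        tmaps, mask, movie, cfg.threshold, two_sided=two_sided, method=method
    )

    paths = {}
    for chrom in ("o2hb", "hhb"):
        p = outdir / f"tmap_{chrom}_{chash}.nii.gz"
        smap.to_nifti(chrom, cfg.voxel_size).to_filename(p)
        paths[f"tmap_{chrom}"] = str(p)
        tab = outdir / f"suprathreshold_{chrom}_{chash}.csv"
        smap.suprathreshold_table(chrom, cfg.voxel_size).to_csv(tab, index=False)
        paths[f"table_{chrom}"] = str(tab)
    sidecar = {
        "config_hash": chash,
        "config": json.loads(json.dumps(asdict(cfg), default=str)),
        "method": method,
        "threshold": cfg.threshold,
        "two_sided": two_sided,
        "geometry_hash": ghash,
        "n_mask_voxels": int(mask.n_voxels),
        "bad_channels": od.bad_channels,
        "dof": getattr(next(iter(fits.values())), "dof", None),
        "anticorrelation": stats.anticorrelation_summary(
            smap.t_scores["o2hb"], smap.t_scores["hhb"], mask.mask
        ),
        "stages": log,
    }
    sidecar_path = outdir / f"statmap_{chash}.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=1))
    paths["sidecar"] = str(sidecar_path)

    return {
        "config": cfg, "head": head, "layout": layout, "design": design,
        "jacobian": jacobian, "mask": mask, "recording": rec, "truth": truth,
        "od": od, "movie": movie, "fits": fits, "statmap": smap,
        "paths": paths, "log": log,
    }
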