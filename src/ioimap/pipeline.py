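"""End-to-end runner: configuration, execution, artifacts, manifest.

A pipeline run goes simulate-or-ingest → (motion compensation) →
(detrending) → activity map → segmentation → comparison, writing every
intermediate with a manifest of relative paths and SHA-256 checksums.
Identical configuration and seed reproduce byte-identical ratio maps and
reports.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from . import io as ioi_io
from .compare import ComparisonReport, dice_triplet, region_statistics
from .preprocess import (ReflectanceSequence, StimulusParadigm,
                         compensate_motion, detrend_pixelwise,
                         extract_green_channel)
from .segment import RegionMaskSet, segment_activation
from .simulate import SimulationConfig, simulate_sequence
from .spectral import compute_activity_map

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ParadigmBlock(_Block):
    rest_duration: float = 30.0
    stim_duration: float = 30.0
    cycles: int = 9
    frame_rate: float = 2.0

    def build(self) -> StimulusParadigm:
        return StimulusParadigm(**self.model_dump())


class SimulationBlock(_Block):
    grid_rows: int = 128
    grid_cols: int = 128
    baseline_level: float = 128.0
    activation_amplitude: float = -0.02
    response_delay: float = 2.0
    response_tau: float = 5.0
    vasomotion_components: list[tuple[float, float, float]] = [
        (0.008, 0.005, 0.0),
        (0.015, 0.005, 1.1),
        (0.030, 0.005, 2.3),
    ]
    noise_sd: float = 0.005
    drift_slope: float = 0.002
    motion_max_shift: int = 0
    activation_offset: float = 0.0

    def build(self, paradigm: StimulusParadigm, seed: int) -> SimulationConfig:
        return SimulationConfig(
            paradigm=paradigm,
            frame_rate=paradigm.frame_rate,
            seed=seed,
            vasomotion_components=tuple(
                tuple(c) for c in self.vasomotion_components
            ),
            **self.model_dump(exclude={"vasomotion_components"}),
        )


class InputBlock(_Block):
    stack: str
    trepanation_mask: str
    psc_mask: Optional[str] = None
    reference_mask: Optional[str] = None
    channel: Literal["gray", "rgb_green"] = "gray"


class SpectralBlock(_Block):
    vlf_max: float = 0.04
    exclude_stim_bin_from_vlf: bool = True
    stim_guard_bins: int = 1
    mode: Literal["power", "amplitude"] = "power"


class SegmentationBlock(_Block):
    min_size: int = 10
    k: int = 3
    k_sd: float = 1.0
    connectivity: Literal[4, 8] = 8


class PipelineConfig(_Block):
    """Validated configuration of a full run.

    Exactly one of ``simulation`` and ``input`` must be present; the
    paradigm block is always required. Unknown keys anywhere are
    rejected.
    """

    paradigm: ParadigmBlock = ParadigmBlock()
    simulation: Optional[SimulationBlock] = None
    input: Optional[InputBlock] = None
    spectral: SpectralBlock = SpectralBlock()
    segmentation: SegmentationBlock = SegmentationBlock()
    register_motion: bool = False
    detrend: bool = True
    seed: int = 0

    @model_validator(mode="after")
    def _exactly_one_source(self) -> "PipelineConfig":
        if (self.simulation is None) == (self.input is None):
            raise ValueError(
                "exactly one of 'simulation' and 'input' must be configured"
            )
        return self

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML (or JSON — YAML is a superset) pipeline config."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    cfg = PipelineConfig.model_validate(data)
    if cfg.input is not None:
        for key in ("stack", "trepanation_mask", "psc_mask", "reference_mask"):
            value = getattr(cfg.input, key)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"input.{key}: {value} does not exist")
    return cfg


def _log(message: str, verbose: bool) -> None:
    if verbose:
        print(f"[ioimap] {message}", file=sys.stderr)


def _ingest(config: PipelineConfig, verbose: bool):
    paradigm = config.paradigm.build()
    if config.simulation is not None:
        sim_cfg = config.simulation.build(paradigm, config.seed)
        _log(f"simulating {sim_cfg.grid_rows}x{sim_cfg.grid_cols} "
             f"x{paradigm.total_frames} frames (seed {sim_cfg.seed})", verbose)
        seq, truth = simulate_sequence(sim_cfg)
        masks = RegionMaskSet(
            trepanation=truth.trepanation_mask,
            psc=truth.psc_mask,
            reference_activation=truth.activation_mask,
        )
        return seq, masks, truth
    inp = config.input
    assert inp is not None
    _log(f"reading stack {inp.stack}", verbose)
    if inp.channel == "rgb_green":
        rgb = ioi_io.read_rgb_stack(inp.stack)
        seq = extract_green_channel(rgb, frame_interval=paradigm.frame_interval)
    else:
        seq = ioi_io.read_stack(inp.stack, frame_interval=paradigm.frame_interval)
    shape = seq.shape
    masks = RegionMaskSet(
        trepanation=ioi_io.read_mask(inp.trepanation_mask, shape),
        psc=(ioi_io.read_mask(inp.psc_mask, shape)
             if inp.psc_mask else None),
        reference_activation=(ioi_io.read_mask(inp.reference_mask, shape)
                              if inp.reference_mask else None),
    )
    return seq, masks, None


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    verbose: bool = True,
) -> ComparisonReport:
    """Execute the full chain and write all artifacts under ``out_dir``.

    Writes truth/input masks, the activity-map bundle, every
    segmentation stage, the comparison report and a manifest listing
    each artifact with its SHA-256 checksum (paths relative to
    ``out_dir``, so the manifest itself is location-independent).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paradigm = config.paradigm.build()

    seq, masks, _truth = _ingest(config, verbose)
    if config.register_motion:
        _log("compensating motion", verbose)
        seq = compensate_motion(seq)
    if config.detrend:
        _log("detrending pixelwise", verbose)
        seq = detrend_pixelwise(seq)

    _log("computing activity map", verbose)
    amap = compute_activity_map(
        seq, paradigm,
        vlf_max=config.spectral.vlf_max,
        exclude_stim_bin_from_vlf=config.spectral.exclude_stim_bin_from_vlf,
        stim_guard_bins=config.spectral.stim_guard_bins,
        mode=config.spectral.mode,
    )
    _log("segmenting activation", verbose)
    seg = segment_activation(
        amap, masks.trepanation,
        min_size=config.segmentation.min_size,
        k=config.segmentation.k,
        k_sd=config.segmentation.k_sd,
        connectivity=config.segmentation.connectivity,
    )

    artifacts: dict[str, Path] = {}
    artifacts.update(
        {f"activity_{k}": v
         for k, v in ioi_io.write_activity_map(out_dir, amap).items()}
    )
    for name, mask in [
        ("trepanation", masks.trepanation),
        ("psc", masks.psc),
        ("reference_activation", masks.reference_activation),
        ("thresholded", seg.thresholded_map),
        ("opened", seg.opened_map),
        ("activation", seg.activation),
        ("hull", seg.hull),
    ]:
        if mask is not None:
            artifacts[f"mask_{name}"] = ioi_io.write_mask(
                out_dir / f"{name}.png", mask
            )

    if masks.reference_activation is not None:
        d_act, d_hull, d_full = dice_triplet(
            seg, masks.reference_activation, masks.trepanation
        )
    else:
        d_act = d_hull = d_full = float("nan")
    if masks.psc is not None and masks.reference_activation is not None:
        stats = region_statistics(amap, masks)
    else:
        stats = {}
    report = ComparisonReport(
        dice_activation=d_act, dice_hull=d_hull, dice_full=d_full,
        region_stats=stats, z_thresh=seg.z_thresh,
    )

    seg_summary = {
        "z_thresh": seg.z_thresh,
        "k_sd": seg.k_sd,
        "min_size": seg.min_size,
        "k": seg.k,
        "connectivity": seg.connectivity,
        "components": [
            {"label": lab, "pixels": n, "centroid": list(cen)}
            for lab, n, cen in seg.components
        ],
    }
    artifacts["segmentation"] = ioi_io.write_report(
        out_dir / "segmentation.json", seg_summary
    )
    artifacts["report"] = ioi_io.write_report(
        out_dir / "report.json", report.to_dict()
    )
    (out_dir / "config.yaml").write_text(config.to_yaml())
    artifacts["config"] = out_dir / "config.yaml"

    manifest = {
        "seed": config.seed,
        "paradigm": config.paradigm.model_dump(),
        "n_frames": paradigm.total_frames,
        "preprocessing_log": seq.preprocessing_log,
        "artifacts": {
            name: {
                "path": str(path.relative_to(out_dir)),
                "sha256": ioi_io.sha256_of(path),
            }
            for name, path in sorted(artifacts.items())
        },
    }
    ioi_io.write_report(out_dir / "manifest.json", manifest)
    _log(f"wrote {len(artifacts) + 1} artifacts to {out_dir}", verbose)
    return report


def verify_manifest(out_dir: str | Path) -> bool:
    """Re-hash every artifact listed in the manifest; True if all match."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    return all(
        ioi_io.sha256_of(out_dir / entry["path"]) == entry["sha256"]
        for entry in manifest["artifacts"].values()
    )
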