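"""End-to-end orchestration: simulate → segment → classify → coloc →
calcium → ephys → stats, with a run manifest for provenance.

Configuration is a YAML document validated against :class:`RunConfig`; every
stage seed is derived deterministically from the master seed, and every
output file is listed in ``manifest.json``.
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
from .calcium import (StimulusProtocol, assign_roi_classes, background_subtract_timeseries,
                      compare_roi_groups, compute_dF_image, dFmax_over_F0, roi_trace)
from .coloc import build_cell_geometry, costes_test, peripheral_ratio
from .ephys import extract_iv, fit_activation, qc_filter
from .image import write_ome_tiff
from .spots import (DetectionParams, classify_by_proximity, detect_spots, filter_spots,
                    spots_to_frame, summarize_spots)
from .synthetic import (GroundTruthTransient, NoiseModel, SimConfig, generate_cell_stack,
                        generate_iv_recording, generate_timeseries, random_syribbon_spots,
                        write_ground_truth)

__all__ = ["RunConfig", "run_pipeline", "make_figure_panels", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the master seed (< 2**31)."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    out_dir: str = "run_output"
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "segment", "classify", "coloc", "calcium", "ephys"]
    )
    n_pairs: int = 10
    pair_threshold_um: float = 0.06       # RIBEYE–Bassoon colocalization class
    syribbon_threshold_um: float = 0.045  # Ca_V + SyRibbon class
    costes_repetitions: int = 100
    detection: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    sim: dict = field(default_factory=dict)
    input_stack: str | None = None        # skip simulation, read this OME-TIFF

    KNOWN_STAGES = ("simulate", "segment", "classify", "coloc", "calcium", "ephys")

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in self.KNOWN_STAGES]
        if bad:
            raise ValueError(f"unknown stage(s) {bad}; valid: {self.KNOWN_STAGES}")
        if self.input_stack is not None and not Path(self.input_stack).exists():
            raise ValueError(f"input_stack path does not exist: {self.input_stack}")
        if self.costes_repetitions <= 0:
            raise ValueError("costes_repetitions must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "outputs": {},
    }

    def record(stage, name, path):
        manifest["outputs"].setdefault(stage, {})[name] = str(path)

    sim_kwargs = dict(config.sim)
    noise = sim_kwargs.pop("noise", None)
    if noise is not None:
        sim_kwargs["noise"] = NoiseModel(**noise)
    sim_cfg = SimConfig(seed=stage_seed(config.seed, "simulate"), **sim_kwargs)

    stack = gt = None
    if "simulate" in config.stages:
        rng = np.random.default_rng(stage_seed(config.seed, "spots"))
        spots_gt = random_syribbon_spots(sim_cfg, n_pairs=config.n_pairs, rng=rng)
        stack, gt = generate_cell_stack(sim_cfg, spots_gt)
        write_ome_tiff(out / "stack.ome.tif", stack)
        write_ground_truth(out, gt, sim_cfg)
        record("simulate", "stack", out / "stack.ome.tif")
        record("simulate", "ground_truth", out / "ground_truth.csv")
    elif config.input_stack:
        from .image import read_ome_tiff

        stack = read_ome_tiff(config.input_stack)

    detected = {}
    if "segment" in config.stages:
        if stack is None:
            raise RuntimeError("segment stage requires a simulated or provided stack")
        params = DetectionParams(**config.detection) if config.detection else DetectionParams()
        for ch in stack.channels[1:]:
            spots = detect_spots(stack, ch, params)
            kept, _ = filter_spots(spots, params.volume_bounds)
            detected[ch] = kept
            frame = spots_to_frame(kept)
            frame.to_csv(out / f"spots_{ch}.csv", index=False)
            record("segment", f"spots_{ch}", out / f"spots_{ch}.csv")
        summary = pd.DataFrame(
            {ch: summarize_spots(sp) for ch, sp in detected.items()}
        ).T
        summary.to_csv(out / "spot_summary.csv")
        record("segment", "summary", out / "spot_summary.csv")

    if "classify" in config.stages and len(detected) >= 2:
        channels = list(detected)
        query, ref = detected[channels[0]], detected[channels[1]]
        result = classify_by_proximity(query, ref, config.pair_threshold_um)
        pd.DataFrame(result.paired, columns=["query_id", "reference_id", "distance_um"]).to_csv(
            out / "pairs.csv", index=False
        )
        record("classify", "pairs", out / "pairs.csv")
        manifest["n_paired"] = result.n_paired

    if "coloc" in config.stages:
        if stack is None:
            raise RuntimeError("coloc stage requires a stack")
        geom = build_cell_geometry(stack, membrane_channel=0)
        rows = []
        for ch in stack.channels[1:]:
            rows.append({"channel": ch, "peripheral_ratio": peripheral_ratio(stack, ch, geom)})
        if len(stack.channels) >= 3:
            a = stack.channel(1)
            b = stack.channel(2)
            res = costes_test(
                a, b, geom.ring_mask, n=config.costes_repetitions,
                rng=stage_seed(config.seed, "costes"),
            )
            rows.append({
                "channel": f"{stack.channels[1]}~{stack.channels[2]}",
                "pearson_r": res.pearson_r, "m1": res.m1, "m2": res.m2,
                "costes_p": res.costes_p,
            })
        pd.DataFrame(rows).to_csv(out / "coloc.csv", index=False)
        record("coloc", "coloc", out / "coloc.csv")

    if "calcium" in config.stages:
        protocol = StimulusProtocol(**config.protocol) if config.protocol else StimulusProtocol()
        ts_cfg = SimConfig(
            seed=stage_seed(config.seed, "calcium"),
            noise=NoiseModel(offset=10.0),
            **{k: v for k, v in sim_kwargs.items() if k != "noise"},
        )
        cx, cy, _ = ts_cfg.cell_center
        ax_, ay_, _ = ts_cfg.cell_semi_axes
        hotspots = [
            GroundTruthTransient(roi_center=(cx + 0.9 * ax_, cy), onset_frame=protocol.onset_frame,
                                 duration_frames=protocol.duration_frames),
            GroundTruthTransient(roi_center=(cx - 0.9 * ax_, cy), onset_frame=protocol.onset_frame,
                                 duration_frames=protocol.duration_frames),
        ]
        ts, ts_gt = generate_timeseries(ts_cfg, hotspots,
                                        n_frames=protocol.onset_frame + protocol.duration_frames + 10)
        ts_bg = background_subtract_timeseries(ts, background_roi=(slice(0, 8), slice(0, 8)))
        df_img = compute_dF_image(ts_bg, protocol)
        np.save(out / "dF_image.npy", df_img)
        centers = [tuple(c) for c in ts_gt[["roi_x_um", "roi_y_um"]].to_numpy()]
        centers.append((cx, cy + 0.5 * ay_))  # control site without a ribbon
        structural = np.zeros(ts.data.shape[1:], bool)
        traces = []
        for i, c in enumerate(centers):
            tr = roi_trace(ts_bg, c, protocol, roi_id=i)
            if tr.valid:
                traces.append(dFmax_over_F0(tr, protocol))
        pd.DataFrame(
            [{"roi_id": t.roi_id, "x_um": t.roi_center[0], "y_um": t.roi_center[1],
              "f0": t.f0, "dfmax_over_f0": t.dfmax_over_f0} for t in traces]
        ).to_csv(out / "roi_traces.csv", index=False)
        record("calcium", "roi_traces", out / "roi_traces.csv")

    if "ephys" in config.stages:
        rec = generate_iv_recording(noise_sd=2.0, seed=stage_seed(config.seed, "ephys"))
        iv = fit_activation(extract_iv(rec, leak_correct=True))
        verdict = qc_filter(rec, iv)
        iv.to_frame().to_csv(out / "iv_curve.csv", index=False)
        pd.DataFrame([{"passed": verdict.passed, "reasons": ";".join(verdict.reasons),
                       "v_half": iv.v_half, "slope_k": iv.slope_k}]).to_csv(
            out / "iv_qc.csv", index=False)
        record("ephys", "iv_curve", out / "iv_curve.csv")
        record("ephys", "qc", out / "iv_qc.csv")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def make_figure_panels(manifest: dict, out_dir=None) -> dict:
    """Assemble summary figures from a finished run's outputs.

    Returns the glyph data per panel (positions of box-plot percentiles
    etc.), so reruns can be compared on figure *data* rather than pixels.
    """
    import matplotlib.pyplot as plt

    from .plotting import box_panel, volume_histogram

    out = Path(out_dir or Path(next(iter(manifest["outputs"].get(
        "segment", {"_": manifest["config"]["out_dir"]}).values()))).parent)
    panels = {}
    seg = manifest["outputs"].get("segment", {})
    groups = {}
    for name, path in seg.items():
        if name.startswith("spots_"):
            df = pd.read_csv(path)
            if len(df):
                groups[name.removeprefix("spots_")] = df["volume_um3"].to_numpy()
    if groups:
        fig, axes = plt.subplots(1, 2, figsize=(8, 3))
        _, glyphs = box_panel(groups, ax=axes[0], ylabel="volume (µm³)")
        _, hist = volume_histogram(np.concatenate(list(groups.values())), ax=axes[1])
        fig.tight_layout()
        fig.savefig(out / "volumes.png", dpi=120)
        plt.close(fig)
        panels["volumes"] = {"box": glyphs, "hist_counts": hist[0].tolist()}
    return panels
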