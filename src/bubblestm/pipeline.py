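"""End-to-end pipeline: simulate demo neurons, run every analysis stage and
write a report bundle (HDF5 arrays, CSV tables, JSON scalars, PNG renders).

The pipeline is a library orchestrator: ``run_pipeline(config, outdir)``
executes simulate -> spatial RF / SRF -> spike-triggered masks -> linear
prediction -> invariance -> statistical report, deterministically for a
given seed, and records provenance (config hash, seed, package version)
with every run.  ``make_fixtures`` emits a tiny plain-text session bundle
for regression tests.
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

from . import invariance, io, linear_model, receptive_field, session as sess, stm
from . import stimuli, synthetic
from .exceptions import InsufficientDataError, InvalidConfigurationError


@dataclass
class RunConfig:
    """All pipeline knobs; defaults follow the reference protocol:
    20 bubble windows of sigma 7 px on 128 px rasters at 4.25 Hz, 10 Hz
    gratings, a 50-150 ms response window, alpha = 0.01 shuffle test and
    four gaze bins."""

    seed: int = 0
    size_px: int = 128
    deg_per_px: float = stimuli.DEFAULT_DEG_PER_PX
    n_windows: int = 20
    sigma_px: float = 7.0
    frame_rate_hz: float = 4.25
    grating_rate_hz: float = 10.0
    latency_ms: float = 50.0
    window_ms: float = 100.0
    alpha: float = 0.01
    n_shuffles: int = 500
    n_bins: int = 4
    min_frames_per_bin: int = 100
    srf_min_count: int = 5
    percentile_q: float = 90.0
    n_bubble_frames: int = 2000
    n_grating_frames: int = 3000
    n_image_frames: int = 200

    def __post_init__(self):
        if not 0.0 < self.alpha <= 1.0:
            raise InvalidConfigurationError("alpha must lie in (0, 1]")
        if self.sigma_px <= 0 or self.n_windows < 0:
            raise InvalidConfigurationError("invalid bubble parameters")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def demo_neurons(config: RunConfig, image: stimuli.BaseImage):
    """Three synthetic neurons spanning the mechanism classes: quasi-linear,
    feature conjunction with tuned suppression, and head-centered template."""
    c = config.size_px // 2
    off = config.size_px // 5
    linear = synthetic.linear_neuron(
        "linear", 45.0, 1.5, deg_per_px=config.deg_per_px
    )
    conj = synthetic.feature_neuron(
        "conjunction-suppression",
        image,
        (c - off, c),
        suppressive_center_px=(c + off, c),
        patch_radius_px=max(config.size_px // 13, 4),
        position_coding=0.0,
    )
    headc = synthetic.feature_neuron(
        "head-centered",
        image,
        (c, c),
        patch_radius_px=max(config.size_px // 13, 4),
        position_coding=1.0,
    )
    return [linear, conj, headc]


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Run the full demo pipeline; returns the report dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    report: dict = {
        "provenance": {
            "seed": config.seed,
            "config_hash": config.config_hash,
            "version": __import__("bubblestm").__version__,
        }
    }
    config.to_yaml(outdir / "config.yaml")

    image = stimuli.generate_base_image(
        config.size_px, 1.0, rng, deg_per_px=config.deg_per_px, image_id="img0"
    )
    io.save_base_image(image, outdir / "base_image.png")
    neurons = demo_neurons(config, image)

    og, fg, pg = synthetic.default_grating_grids()
    grating_frames = sess.grating_frame_stream(
        config.n_grating_frames,
        rng,
        orientations_deg=og,
        sfs_cpd=fg,
        phases_deg=pg,
        size=config.size_px,
        deg_per_px=config.deg_per_px,
        rate_hz=config.grating_rate_hz,
        compute_amps=True,
    )
    bubble_frames = sess.bubble_frame_stream(
        [image],
        config.n_bubble_frames,
        rng,
        n_windows=config.n_windows,
        sigma=config.sigma_px,
        rate_hz=config.frame_rate_hz,
        compute_amps=True,
    )
    eye = synthetic.gen_eye_trace(
        config.n_bubble_frames, 0.3, rng, frame_duration_ms=1000.0 / config.frame_rate_hz
    )

    slope_rows = []
    scores = []
    for neuron in neurons:
        ndir = outdir / neuron.neuron_id
        ndir.mkdir(exist_ok=True)
        io.neuron_to_json(neuron, ndir / "ground_truth.json")

        bubble_session = synthetic.simulate_session(
            neuron, bubble_frames, eye, np.random.default_rng(rng.integers(2**31))
        )
        io.save_session(bubble_session, ndir / "bubble_session.h5")
        io.export_frames_csv(bubble_session, ndir / "bubble_frames.csv")

        masks = stm.stms_from_session(
            bubble_session,
            window_ms=(config.latency_ms, config.latency_ms + config.window_ms),
            n_shuffles=config.n_shuffles,
            alpha=config.alpha,
            rng=np.random.default_rng(rng.integers(2**31)),
        )
        neuron_report = {"valid_masks": sum(s.valid for s in masks.values())}
        for img_id, s in masks.items():
            io.save_stm(s, ndir / f"stm_{img_id}.h5")
            io.render_stm_png(s, ndir / f"stm_{img_id}.png", image)

        srf = None
        if neuron.srf_gain is not None:
            grating_session = synthetic.simulate_session(
                neuron, grating_frames, None, np.random.default_rng(rng.integers(2**31))
            )
            srf = receptive_field.estimate_srf(
                grating_session,
                config.latency_ms,
                config.window_ms,
                min_count=config.srf_min_count,
            )
            io.save_srf(srf, ndir / "srf.h5")
            curve = receptive_field.orientation_tuning(srf)
            try:
                neuron_report["osi"] = receptive_field.osi(curve[0], curve[1])
            except InsufficientDataError:
                neuron_report["osi"] = None

        measured = masks.get(image.id)
        if srf is not None and measured is not None and measured.excitatory.any():
            pred = linear_model.predict_masks(
                image, srf, int(measured.excitatory.sum()), base_image_id=image.id
            )
            sc = linear_model.score_prediction(pred, measured)
            sc["neuron_id"] = neuron.neuron_id
            scores.append(sc)

        if measured is not None and measured.valid:
            try:
                part = invariance.bin_by_gaze(
                    bubble_session, config.n_bins, config.min_frames_per_bin
                )
                binned = invariance.conditional_stms(
                    bubble_session,
                    part,
                    image.id,
                    n_shuffles=config.n_shuffles,
                    alpha=config.alpha,
                    rng=np.random.default_rng(rng.integers(2**31)),
                    min_frames=config.min_frames_per_bin,
                )
                sl = invariance.invariance_slope(
                    binned, config.deg_per_px, config.size_px
                )
                slope_rows.append(
                    {
                        "neuron_id": neuron.neuron_id,
                        "base_image_id": image.id,
                        "slope": sl.slope,
                        "n_bins": sl.n_points,
                        "valid": sl.valid,
                    }
                )
            except InvalidConfigurationError:
                pass
        report[neuron.neuron_id] = neuron_report

    if scores:
        pd.DataFrame(scores).to_csv(outdir / "prediction_scores.csv", index=False)
    if slope_rows:
        slopes = pd.DataFrame(slope_rows)
        slopes.to_csv(outdir / "slopes.csv", index=False)
        report["invariance"] = invariance.population_tests(
            slopes.rename(columns={"neuron_id": "neuron_id"}), min_slopes=2
        )
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report


def make_fixtures(outdir, seed: int = 0) -> dict:
    """Write a tiny plain-text session bundle (64 px rasters, 500 frames).

    Regeneration with the same seed reproduces the committed bytes; the
    returned manifest maps file names to SHA-256 hashes for corruption
    checks.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    image = stimuli.generate_base_image(64, 1.0, rng, image_id="fix0")
    neuron = synthetic.feature_neuron(
        "fixture-linear", image, (32, 32), patch_radius_px=6
    )
    frames = sess.bubble_frame_stream(
        [image], 500, rng, n_windows=8, sigma=4.0
    )
    log = synthetic.simulate_session(neuron, frames, None, np.random.default_rng(seed + 1))

    fmt = "%.6g"
    log.frames.to_csv(outdir / "frames.csv", index=False, float_format=fmt)
    pd.DataFrame({"spike_ms": log.spikes}).to_csv(
        outdir / "spikes.csv", index=False, float_format=fmt
    )
    log.masks.to_csv(outdir / "masks.csv", index=False, float_format=fmt)
    io.neuron_to_json(neuron, outdir / "neuron.json")
    (outdir / "meta.json").write_text(json.dumps(log.meta, sort_keys=True))

    manifest = {}
    for name in ["frames.csv", "spikes.csv", "masks.csv", "neuron.json", "meta.json"]:
        manifest[name] = hashlib.sha256((outdir / name).read_bytes()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def verify_fixtures(outdir) -> bool:
    """Check the fixture bundle against its manifest hashes."""
    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    for name, digest in manifest.items():
        if hashlib.sha256((outdir / name).read_bytes()).hexdigest() != digest:
            return False
    return True
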