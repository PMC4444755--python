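"""Serialization: HDF5 for arrays and sessions, CSV/JSON sidecars, PNG renders.

Bubble masks are stored as window centers only (plus sigma in the session
metadata); transparency fields are recomputed on load, bit-exactly, from
the stated combination rule.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from PIL import Image

from .receptive_field import SRF, SpatialRF
from .session import FRAME_COLUMNS, SessionLog
from .stimuli import BaseImage
from .stm import SpikeTriggeredMask
from .synthetic import FeaturePatch, ModelNeuron

# -- base images (8-bit grayscale PNG + JSON sidecar) -----------------------


def save_base_image(image: BaseImage, path) -> None:
    path = Path(path)
    arr = np.clip(np.round(image.pixels * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"id": image.id, "deg_per_px": image.deg_per_px})
    )


def load_base_image(path) -> BaseImage:
    path = Path(path)
    arr = np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return BaseImage(id=meta["id"], pixels=arr, deg_per_px=meta["deg_per_px"])


# -- sessions (HDF5; CSV export of the frames table) ------------------------


def save_session(session: SessionLog, path) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("frames")
        for col in FRAME_COLUMNS:
            data = session.frames[col].to_numpy()
            if data.dtype == object:
                data = np.array(
                    ["" if v is None else str(v) for v in data], dtype="S64"
                )
            grp.create_dataset(col, data=data)
        f.create_dataset("spikes", data=session.spikes)
        if session.masks is not None:
            m = f.create_group("masks")
            for col in session.masks.columns:
                m.create_dataset(col, data=session.masks[col].to_numpy())
        meta = f.create_group("meta")
        for k, v in session.meta.items():
            meta.attrs[k] = v


def load_session(path) -> SessionLog:
    with h5py.File(path, "r") as f:
        cols = {}
        for col in FRAME_COLUMNS:
            data = f["frames"][col][()]
            if data.dtype.kind == "S":
                data = np.array(
                    [None if not s else s.decode() for s in data], dtype=object
                )
            cols[col] = data
        frames = pd.DataFrame(cols)
        spikes = f["spikes"][()]
        masks = None
        if "masks" in f:
            masks = pd.DataFrame({c: f["masks"][c][()] for c in f["masks"]})
        meta = dict(f["meta"].attrs)
    return SessionLog(frames=frames, spikes=spikes, masks=masks, meta=meta)


def export_frames_csv(session: SessionLog, path) -> None:
    session.frames.to_csv(path, index=False)


def masks_to_csv(masks: pd.DataFrame, path) -> None:
    masks.to_csv(path, index=False)


def masks_from_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


# -- SRFs and spatial RFs ---------------------------------------------------


def save_srf(srf: SRF, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("grids")
        g.create_dataset("orientations_deg", data=srf.orientations_deg)
        g.create_dataset("spatial_freqs_cpd", data=srf.spatial_freqs_cpd)
        g.create_dataset("phases_deg", data=srf.phases_deg)
        f.create_dataset("R", data=srf.response)
        f.create_dataset("per_phase", data=srf.per_phase)
        f.create_dataset("counts", data=srf.counts)


def load_srf(path) -> SRF:
    with h5py.File(path, "r") as f:
        return SRF(
            orientations_deg=f["grids/orientations_deg"][()],
            spatial_freqs_cpd=f["grids/spatial_freqs_cpd"][()],
            phases_deg=f["grids/phases_deg"][()],
            response=f["R"][()],
            per_phase=f["per_phase"][()],
            counts=f["counts"][()],
        )


def save_spatial_rf(rf: SpatialRF, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "center_deg": list(rf.center_deg),
                "radius_deg": rf.radius_deg,
                "grid_x_deg": rf.grid_x_deg.tolist(),
                "grid_y_deg": rf.grid_y_deg.tolist(),
                "response_map": rf.response_map.tolist(),
            }
        )
    )


def load_spatial_rf(path) -> SpatialRF:
    d = json.loads(Path(path).read_text())
    return SpatialRF(
        response_map=np.asarray(d["response_map"]),
        grid_x_deg=np.asarray(d["grid_x_deg"]),
        grid_y_deg=np.asarray(d["grid_y_deg"]),
        center_deg=tuple(d["center_deg"]),
        radius_deg=d["radius_deg"],
    )


# -- spike-triggered masks --------------------------------------------------


def save_stm(stm: SpikeTriggeredMask, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=stm.weights)
        f.create_dataset("labels", data=stm.labels)
        meta = f.create_group("meta")
        meta.attrs["base_image_id"] = stm.base_image_id or ""
        meta.attrs["n_frames"] = stm.n_frames
        meta.attrs["alpha"] = stm.alpha
        meta.attrs["n_shuffles"] = stm.n_shuffles
        meta.attrs["null_mean_subtracted"] = True


def load_stm(path) -> SpikeTriggeredMask:
    with h5py.File(path, "r") as f:
        meta = f["meta"].attrs
        return SpikeTriggeredMask(
            base_image_id=meta["base_image_id"] or None,
            weights=f["weights"][()],
            labels=f["labels"][()],
            n_frames=int(meta["n_frames"]),
            alpha=float(meta["alpha"]),
            n_shuffles=int(meta["n_shuffles"]),
        )


def render_stm_png(
    stm: SpikeTriggeredMask, path, base_image: BaseImage | None = None
) -> None:
    """Overlay render: red = excitatory, blue = suppressive pixels."""
    size = stm.labels.shape[0]
    if base_image is not None:
        gray = base_image.pixels
    else:
        gray = np.full((size, size), 0.5)
    rgb = np.repeat(gray[..., None], 3, axis=2)
    exc = stm.excitatory
    sup = stm.suppressive
    rgb[exc] = 0.5 * rgb[exc] + 0.5 * np.array([1.0, 0.0, 0.0])
    rgb[sup] = 0.5 * rgb[sup] + 0.5 * np.array([0.0, 0.0, 1.0])
    arr = np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="RGB").save(path)


# -- model neurons (ground truth) ------------------------------------------


def neuron_to_json(neuron: ModelNeuron, path) -> None:
    def patch_dict(p: FeaturePatch) -> dict:
        return {
            "center_px": list(p.center_px),
            "template": p.template.tolist(),
            "weight": p.weight,
        }

    d = {
        "neuron_id": neuron.neuron_id,
        "orientations_deg": None
        if neuron.orientations_deg is None
        else np.asarray(neuron.orientations_deg).tolist(),
        "spatial_freqs_cpd": None
        if neuron.spatial_freqs_cpd is None
        else np.asarray(neuron.spatial_freqs_cpd).tolist(),
        "srf_gain": None if neuron.srf_gain is None else neuron.srf_gain.tolist(),
        "features": {
            img: [patch_dict(p) for p in patches]
            for img, patches in neuron.features.items()
        },
        "position_coding": neuron.position_coding,
        "threshold": neuron.threshold,
        "gain": neuron.gain,
        "baseline": neuron.baseline,
        "latency_ms": neuron.latency_ms,
        "latency_jitter_ms": neuron.latency_jitter_ms,
        "deg_per_px": neuron.deg_per_px,
    }
    Path(path).write_text(json.dumps(d))


def neuron_from_json(path) -> ModelNeuron:
    d = json.loads(Path(path).read_text())
    features = {
        img: [
            FeaturePatch(
                tuple(p["center_px"]), np.asarray(p["template"]), p["weight"]
            )
            for p in patches
        ]
        for img, patches in d["features"].items()
    }
    return ModelNeuron(
        neuron_id=d["neuron_id"],
        orientations_deg=None
        if d["orientations_deg"] is None
        else np.asarray(d["orientations_deg"]),
        spatial_freqs_cpd=None
        if d["spatial_freqs_cpd"] is None
        else np.asarray(d["spatial_freqs_cpd"]),
        srf_gain=None if d["srf_gain"] is None else np.asarray(d["srf_gain"]),
        features=features,
        position_coding=d["position_coding"],
        threshold=d["threshold"],
        gain=d["gain"],
        baseline=d["baseline"],
        latency_ms=d["latency_ms"],
        latency_jitter_ms=d["latency_jitter_ms"],
        deg_per_px=d["deg_per_px"],
    )
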