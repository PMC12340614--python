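"""HDF5 / CSV plumbing for raw records, flow programs and result series.

Raw detector records live in one HDF5 bundle per run:

    /dcs/counts          (n_channels, n_bins)   attrs: dt
    /idws/frames         (n_pixels, n_time)     attrs: dt, reference_level, spatial_hwhm
    /idws/reference      (n_pixels, n_time)     same attrs
    /scos/frames         (n_frames, H, W)       attrs: t_exp, frame_rate, gain,
                                                       read_sigma, dark_offset,
                                                       speckle_pixel_ratio
    /scos/dark           (n_frames, H, W)       same attrs

Root attributes carry the master seed and free-form run parameters. Flow
programs round-trip through CSV (time_s, bfi_cm2s, segment); per-modality
results are written as the CSV tables each pipeline documents.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import pandas as pd

from .synthetic import FlowProgram, FrameStack, LineScanRecord, PhotonCountSeries


def write_raw_bundle(
    path: str | Path,
    dcs: PhotonCountSeries | None = None,
    idws: LineScanRecord | None = None,
    idws_reference: LineScanRecord | None = None,
    scos: FrameStack | None = None,
    scos_dark: FrameStack | None = None,
    seed: int | None = None,
    params: dict | None = None,
) -> Path:
    """Write the per-run raw-record bundle."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        if seed is not None:
            f.attrs["seed"] = int(seed)
        if params:
            f.attrs["params_json"] = json.dumps(params)
        if dcs is not None:
            d = f.create_dataset("dcs/counts", data=dcs.counts)
            d.attrs["dt"] = dcs.dt
        for name, rec in (("idws/frames", idws), ("idws/reference", idws_reference)):
            if rec is None:
                continue
            # chunk as n_pixels x 3334 "images", the line camera's frame layout
            chunk = (rec.counts.shape[0], min(3334, rec.counts.shape[1]))
            d = f.create_dataset(name, data=rec.counts, chunks=chunk)
            d.attrs["dt"] = rec.dt
            d.attrs["reference_level"] = rec.reference_level
            d.attrs["spatial_hwhm"] = rec.spatial_hwhm
        for name, stack in (("scos/frames", scos), ("scos/dark", scos_dark)):
            if stack is None:
                continue
            d = f.create_dataset(name, data=stack.frames)
            for key in ("t_exp", "frame_rate", "gain", "read_sigma",
                        "dark_offset", "speckle_pixel_ratio"):
                d.attrs[key] = getattr(stack, key)
    return path


def read_dcs(path: str | Path) -> PhotonCountSeries:
    with h5py.File(path, "r") as f:
        d = f["dcs/counts"]
        return PhotonCountSeries(counts=d[...], dt=float(d.attrs["dt"]))


def _read_linescan(d: h5py.Dataset) -> LineScanRecord:
    return LineScanRecord(
        counts=d[...],
        dt=float(d.attrs["dt"]),
        reference_level=float(d.attrs["reference_level"]),
        spatial_hwhm=float(d.attrs["spatial_hwhm"]),
    )


def read_idws(path: str | Path) -> tuple[LineScanRecord, LineScanRecord | None]:
    """Read the iDWS record and, when present, its reference-only run."""
    with h5py.File(path, "r") as f:
        record = _read_linescan(f["idws/frames"])
        reference = _read_linescan(f["idws/reference"]) if "idws/reference" in f else None
    return record, reference


def _read_stack(d: h5py.Dataset) -> FrameStack:
    return FrameStack(
        frames=d[...],
        t_exp=float(d.attrs["t_exp"]),
        frame_rate=float(d.attrs["frame_rate"]),
        gain=float(d.attrs["gain"]),
        read_sigma=float(d.attrs["read_sigma"]),
        dark_offset=float(d.attrs["dark_offset"]),
        speckle_pixel_ratio=float(d.attrs["speckle_pixel_ratio"]),
    )


def read_scos(path: str | Path) -> tuple[FrameStack, FrameStack | None]:
    """Read the SCOS frame stack and, when present, the dark stack."""
    with h5py.File(path, "r") as f:
        stack = _read_stack(f["scos/frames"])
        dark = _read_stack(f["scos/dark"]) if "scos/dark" in f else None
    return stack, dark


def read_scos_tiff(path: str | Path, **stack_attrs) -> FrameStack:
    """Read a multi-page TIFF as a SCOS frame stack.

    Camera attributes (t_exp, gain, ...) are not stored in plain TIFF and
    must be supplied as keyword arguments.
    """
    import tifffile

    frames = tifffile.imread(str(path))
    if frames.ndim == 2:
        frames = frames[None]
    defaults = dict(t_exp=1e-3, frame_rate=120.0, gain=9.64, read_sigma=0.0,
                    dark_offset=0.0, speckle_pixel_ratio=2.3)
    defaults.update(stack_attrs)
    return FrameStack(frames=frames, **defaults)


def write_flow_program(program: FlowProgram, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {"time_s": program.time, "bfi_cm2s": program.bfi, "segment": program.segment}
    )
    if program.temperature_k is not None:
        df["temperature_k"] = program.temperature_k
    df.to_csv(path, index=False)
    return path


def read_flow_program(path: str | Path) -> FlowProgram:
    df = pd.read_csv(path)
    return FlowProgram(
        time=df["time_s"].to_numpy(),
        bfi=df["bfi_cm2s"].to_numpy(),
        segment=df["segment"].to_numpy(dtype=str),
        temperature_k=df["temperature_k"].to_numpy() if "temperature_k" in df else None,
    )


def write_series_csv(path: str | Path, **columns) -> Path:
    """Write a simple named-column CSV (time series of any pipeline)."""
    path = Path(path)
    pd.DataFrame(columns).to_csv(path, index=False)
    return path


def read_series_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
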