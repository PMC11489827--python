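"""Container and table I/O plus run manifests.

HDF5 layout (one file may hold several modalities):

- ``/calcium/F`` (cells x frames), ``/calcium/frame_times``, ``/calcium/mask``
- ``/ephys/sweeps/sweep_000/{data,command}`` with per-sweep attributes
- ``/lfp/{signal,reference}`` and ``/lfp/mask`` (n x 2 interval array)

Every array carries ``units`` and, where applicable, ``sampling_rate_hz``
attributes. Times are seconds, sample indexing 0-based, intervals half-open.
CSV/TSV mirrors exist for the event and summary tables.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .types import (CaTRaster, GDPEvent, LFPRecording, FluorescenceTraceSet,
                    Sweep, SweepSet, SyntheticGroundTruth)

__all__ = ["save_calcium", "load_calcium", "save_sweeps", "load_sweeps",
           "save_lfp", "load_lfp", "write_ground_truth", "write_raster",
           "write_gdps", "write_manifest"]


def save_calcium(path, traces: FluorescenceTraceSet) -> None:
    with h5py.File(path, "a") as f:
        grp = f.require_group("calcium")
        for name in ("F", "frame_times", "mask"):
            if name in grp:
                del grp[name]
        d = grp.create_dataset("F", data=traces.F)
        d.attrs["units"] = "a.u."
        t = grp.create_dataset("frame_times", data=traces.frame_times)
        t.attrs["units"] = "s"
        grp.create_dataset("mask", data=traces.missing_mask)


def load_calcium(path) -> FluorescenceTraceSet:
    with h5py.File(path, "r") as f:
        grp = f["calcium"]
        return FluorescenceTraceSet(F=grp["F"][()],
                                    frame_times=grp["frame_times"][()],
                                    missing_mask=grp["mask"][()].astype(bool))


def load_calcium_csv(path, mask_path=None) -> FluorescenceTraceSet:
    """Wide CSV mirror: frame_time_s, cell_0 ... cell_N; optional mask TSV of
    (start_s, end_s) intervals."""
    table = pd.read_csv(path)
    frame_times = table["frame_time_s"].to_numpy()
    cells = [c for c in table.columns if c.startswith("cell_")]
    F = table[cells].to_numpy().T
    mask = np.zeros(frame_times.size, dtype=bool)
    if mask_path is not None:
        intervals = pd.read_csv(mask_path, sep="\t", header=None).to_numpy()
        for t0, t1 in intervals:
            mask |= (frame_times >= t0) & (frame_times < t1)
    return FluorescenceTraceSet(F=F, frame_times=frame_times, missing_mask=mask)


def save_sweeps(path, sweeps: SweepSet) -> None:
    with h5py.File(path, "a") as f:
        if "ephys" in f:
            del f["ephys"]
        grp = f.create_group("ephys/sweeps")
        grp.attrs["protocol"] = sweeps.protocol
        grp.attrs["sampling_rate_hz"] = sweeps.sampling_rate
        if sweeps.stim_times is not None:
            grp.attrs["stim_times_s"] = sweeps.stim_times
        if sweeps.condition is not None:
            grp.attrs["condition"] = sweeps.condition
        for i, sweep in enumerate(sweeps.sweeps):
            sg = grp.create_group(f"sweep_{i:03d}")
            d = sg.create_dataset("data", data=sweep.data)
            d.attrs["units"] = "mV" if sweeps.protocol in (
                "zero_current_test_pulse", "step_series") else "pA"
            c = sg.create_dataset("command", data=sweep.command)
            c.attrs["units"] = "pA"
            sg.attrs["series_index"] = sweep.series_index
            if sweep.step_amplitude_pa is not None:
                sg.attrs["step_amplitude_pa"] = sweep.step_amplitude_pa


def load_sweeps(path) -> SweepSet:
    with h5py.File(path, "r") as f:
        grp = f["ephys/sweeps"]
        rate = float(grp.attrs["sampling_rate_hz"])
        sweeps = []
        for name in sorted(k for k in grp if k.startswith("sweep_")):
            sg = grp[name]
            sweeps.append(Sweep(
                data=sg["data"][()], command=sg["command"][()],
                sampling_rate=rate,
                step_amplitude_pa=float(sg.attrs["step_amplitude_pa"])
                if "step_amplitude_pa" in sg.attrs else None,
                series_index=int(sg.attrs.get("series_index", 0))))
        amps = sorted({s.step_amplitude_pa for s in sweeps
                       if s.step_amplitude_pa is not None})
        return SweepSet(
            sweeps=sweeps, sampling_rate=rate,
            protocol=str(grp.attrs["protocol"]),
            step_amplitudes=list(amps) or None,
            stim_times=list(grp.attrs["stim_times_s"])
            if "stim_times_s" in grp.attrs else None,
            condition=str(grp.attrs["condition"])
            if "condition" in grp.attrs else None)


def save_lfp(path, rec: LFPRecording) -> None:
    with h5py.File(path, "a") as f:
        if "lfp" in f:
            del f["lfp"]
        grp = f.create_group("lfp")
        for name, data in (("signal", rec.signal), ("reference", rec.noise_reference)):
            d = grp.create_dataset(name, data=data)
            d.attrs["units"] = "mV"
            d.attrs["sampling_rate_hz"] = rec.sampling_rate
        grp.create_dataset("mask", data=np.asarray(rec.artifact_mask,
                                                   dtype=float).reshape(-1, 2))
        if rec.injection_time is not None:
            grp.attrs["injection_time_s"] = rec.injection_time


def load_lfp(path) -> LFPRecording:
    with h5py.File(path, "r") as f:
        grp = f["lfp"]
        mask = [tuple(row) for row in grp["mask"][()]]
        return LFPRecording(
            signal=grp["signal"][()], noise_reference=grp["reference"][()],
            sampling_rate=float(grp["signal"].attrs["sampling_rate_hz"]),
            artifact_mask=mask,
            injection_time=float(grp.attrs["injection_time_s"])
            if "injection_time_s" in grp.attrs else None)


def write_ground_truth(path, truth: SyntheticGroundTruth) -> None:
    truth.to_frame().to_csv(path, sep="\t", index=False)


def write_raster(path, raster: CaTRaster) -> None:
    times, cells = raster.all_onsets()
    pd.DataFrame({"cell": cells, "onset_s": times}).to_csv(path, sep="\t",
                                                           index=False)


def write_gdps(path, gdps: list[GDPEvent]) -> None:
    pd.DataFrame(
        [(g.start, g.end, g.n_members, g.peak_participation) for g in gdps],
        columns=["start_s", "end_s", "n_members", "participation"],
    ).to_csv(path, sep="\t", index=False)


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True,
                                     default=str).encode()).hexdigest()[:16]


def write_manifest(out_dir, config: dict, seed: int, outputs: list[str]) -> Path:
    """Traceability record: config hash, seed, versions, output checksums."""
    import neosync
    out_dir = Path(out_dir)
    entries = {}
    for name in outputs:
        p = out_dir / name
        if p.exists():
            entries[name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    manifest = {
        "config_hash": config_hash(config),
        "config": config,
        "seed": seed,
        "neosync_version": neosync.__version__,
        "numpy_version": np.__version__,
        "python": platform.python_version(),
        "outputs": entries,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str))
    return path
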