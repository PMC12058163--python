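"""Readers and writers for the plain-text interchange formats.

* ECG: two-column delimited text (time_s, voltage_mV) with a
  ``# sampling_rate_hz:`` header line (plus optional ``# lead:`` and
  ``# species:``).
* Beat series: one or two columns (qt_ms[, hr_bpm]), ``#`` comments allowed.
* Voltage-clamp bundles: a directory with ``protocol.json`` (protocol name,
  holding potential, capacitance, per-sweep pulse timings and metadata) and
  one two-column trace file per sweep.
* Mask sets: one single-channel image per channel plus a ``channels.json``
  sidecar mapping channel names to filenames and carrying the pixel size.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .clamp import Sweep, SweepSet
from .ecg import ECGRecord
from .histo import MaskSet

__all__ = [
    "read_ecg",
    "write_ecg",
    "read_series",
    "write_series",
    "read_sweep_bundle",
    "write_sweep_bundle",
    "read_maskset",
    "write_maskset",
]


def read_ecg(path: str | Path) -> ECGRecord:
    path = Path(path)
    fs = None
    lead, species = "II", "mouse"
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(":")
            key = key.strip().lower()
            if key == "sampling_rate_hz":
                fs = float(val)
            elif key == "lead":
                lead = val.strip()
            elif key == "species":
                species = val.strip()
    if fs is None:
        raise ValueError(f"{path}: missing '# sampling_rate_hz:' header")
    data = np.loadtxt(path, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time_s, voltage_mV)")
    return ECGRecord(samples=data[:, 1], sampling_rate=fs, lead_label=lead,
                     species_hint=species)  # type: ignore[arg-type]


def write_ecg(record: ECGRecord, path: str | Path) -> None:
    path = Path(path)
    t = np.arange(record.n) / record.sampling_rate
    header = (
        f"sampling_rate_hz: {record.sampling_rate}\n"
        f"lead: {record.lead_label}\nspecies: {record.species_hint}"
    )
    np.savetxt(path, np.column_stack([t, record.samples]), header=header,
               fmt="%.6f", delimiter="\t")


def read_series(path: str | Path) -> np.ndarray:
    """Beat series as an (n,) or (n, 2) array: qt_ms[, hr_bpm]."""
    data = np.loadtxt(Path(path), comments="#", ndmin=1)
    return data


def write_series(qt_ms: np.ndarray, path: str | Path, hr_bpm: np.ndarray | None = None) -> None:
    cols = [np.asarray(qt_ms, dtype=float)]
    header = "qt_ms"
    if hr_bpm is not None:
        cols.append(np.asarray(hr_bpm, dtype=float))
        header += "\thr_bpm"
    np.savetxt(Path(path), np.column_stack(cols), header=header, fmt="%.6f", delimiter="\t")


def write_sweep_bundle(sweep_set: SweepSet, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {
        "protocol": sweep_set.protocol,
        "capacitance_pF": sweep_set.cell_capacitance_pF,
        "sweeps": [],
    }
    for k, s in enumerate(sweep_set.sweeps):
        fname = f"sweep_{k:03d}.tsv"
        np.savetxt(d / fname, np.column_stack([s.time_ms, s.current_pA]),
                   header="time_ms\tcurrent_pA", fmt="%.6f", delimiter="\t")
        manifest["sweeps"].append(
            {
                "file": fname,
                "test_potential_mV": s.test_potential_mV,
                "holding_potential_mV": s.holding_potential_mV,
                "pulse_start_ms": s.pulse_start_ms,
                "pulse_duration_ms": s.pulse_duration_ms,
                "meta": s.meta,
            }
        )
    (d / "protocol.json").write_text(json.dumps(manifest, indent=2))


def read_sweep_bundle(directory: str | Path) -> SweepSet:
    d = Path(directory)
    manifest = json.loads((d / "protocol.json").read_text())
    sweeps = []
    for entry in manifest["sweeps"]:
        data = np.loadtxt(d / entry["file"], comments="#")
        sweeps.append(
            Sweep(
                time_ms=data[:, 0],
                current_pA=data[:, 1],
                test_potential_mV=float(entry["test_potential_mV"]),
                holding_potential_mV=float(entry["holding_potential_mV"]),
                pulse_start_ms=float(entry["pulse_start_ms"]),
                pulse_duration_ms=float(entry["pulse_duration_ms"]),
                meta=entry.get("meta", {}),
            )
        )
    return SweepSet(sweeps=tuple(sweeps), protocol=manifest["protocol"],
                    cell_capacitance_pF=float(manifest["capacitance_pF"]))


def write_maskset(maskset: MaskSet, directory: str | Path) -> None:
    import imageio.v3 as iio

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    sidecar = {"pixel_size_um": maskset.pixel_size_um, "channels": {}}
    for channel, mask in maskset.masks.items():
        fname = f"{channel}.png"
        iio.imwrite(d / fname, (mask.astype(np.uint8) * 255))
        sidecar["channels"][channel] = fname
    (d / "channels.json").write_text(json.dumps(sidecar, indent=2))


def read_maskset(directory: str | Path) -> MaskSet:
    import imageio.v3 as iio

    d = Path(directory)
    sidecar = json.loads((d / "channels.json").read_text())
    masks = {
        channel: iio.imread(d / fname) > 0
        for channel, fname in sidecar["channels"].items()
    }
    return MaskSet(masks=masks, pixel_size_um=float(sidecar.get("pixel_size_um", 1.0)))
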