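"""Plain-text and TIFF I/O for sweep sets, probe tables and image pairs.

Sweep sets are stored as one tab-separated text file per cell — one block per
sweep, each introduced by a ``# sweep`` header line — with a JSON sidecar
(same stem, ``.json``) holding the protocol, identifiers and any generator
ground truth.  Image pairs are two-page TIFFs (page 1 = 458-nm excitation
channel, page 2 = 514-nm channel) with seed points in a companion text file
of 0-based ``row<TAB>col<TAB>kind`` lines.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import RatioImageSet
from .traces import Sweep, SweepSet, VoltageProtocol

__all__ = [
    "write_sweepset",
    "read_sweepset",
    "write_ratio_images",
    "read_ratio_images",
    "read_probe_table",
]


def write_sweepset(sweepset: SweepSet, path) -> Path:
    """Write one cell's sweeps as a block-structured TSV plus JSON sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# cell_id={sweepset.cell_id}\ttreatment={sweepset.treatment_label}"
                 f"\tday={sweepset.day_id}\n")
        for s in sweepset.sweeps:
            fh.write(f"# sweep\ttest_potential_mV={s.test_potential:g}\n")
            fh.write("time_ms\tvoltage_mV\tcurrent_uA\tfluorescence_au\n")
            v_cmd = sweepset.protocol.voltage_trace(s.test_potential)
            block = np.column_stack([s.time_ms, v_cmd, s.current_ua, s.fluorescence_au])
            np.savetxt(fh, block, fmt="%.10g", delimiter="\t")
    sidecar = {
        "cell_id": sweepset.cell_id,
        "treatment_label": sweepset.treatment_label,
        "day_id": sweepset.day_id,
        "protocol": dataclasses.asdict(sweepset.protocol),
        "metadata": sweepset.metadata,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path


def read_sweepset(path) -> SweepSet:
    """Read a sweep set written by :func:`write_sweepset`."""
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    protocol = VoltageProtocol(**sidecar["protocol"])
    sweeps = []
    current_v = None
    rows: list[list[float]] = []

    def flush():
        if current_v is None:
            return
        block = np.asarray(rows, dtype=float)
        sweeps.append(
            Sweep(
                test_potential=current_v,
                time_ms=block[:, 0],
                current_ua=block[:, 2],
                fluorescence_au=block[:, 3],
            )
        )

    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# sweep"):
                flush()
                rows = []
                current_v = float(line.split("test_potential_mV=")[1])
            elif line.startswith("#") or line.startswith("time_ms") or not line:
                continue
            else:
                rows.append([float(x) for x in line.split("\t")])
        flush()
    return SweepSet(
        cell_id=sidecar["cell_id"],
        treatment_label=sidecar["treatment_label"],
        day_id=sidecar["day_id"],
        protocol=protocol,
        sweeps=sweeps,
        metadata=sidecar.get("metadata", {}),
    )


def write_ratio_images(image_set: RatioImageSet, tiff_path, seeds_path=None) -> Path:
    """Write an image pair as a two-page TIFF plus a seed-point text file."""
    tiff_path = Path(tiff_path)
    stack = np.stack(
        [
            np.asarray(image_set.channel_blue, dtype=np.float32),
            np.asarray(image_set.channel_red, dtype=np.float32),
        ]
    )
    tifffile.imwrite(tiff_path, stack)
    seeds_path = Path(seeds_path) if seeds_path else tiff_path.with_suffix(".seeds.txt")
    with open(seeds_path, "w") as fh:
        fh.write("# row\tcol\tkind (0-based pixel coordinates)\n")
        for r, c, kind in image_set.seeds:
            fh.write(f"{r}\t{c}\t{kind}\n")
    return tiff_path


def read_ratio_images(tiff_path, seeds_path=None) -> RatioImageSet:
    """Read an image pair and its seed file back into a :class:`RatioImageSet`."""
    tiff_path = Path(tiff_path)
    stack = tifffile.imread(tiff_path)
    seeds_path = Path(seeds_path) if seeds_path else tiff_path.with_suffix(".seeds.txt")
    seeds = []
    with open(seeds_path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            r, c, kind = line.split()
            seeds.append((int(r), int(c), kind))
    return RatioImageSet(
        channel_blue=np.asarray(stack[0], dtype=float),
        channel_red=np.asarray(stack[1], dtype=float),
        seeds=seeds,
    )


def read_probe_table(path) -> pd.DataFrame:
    """Read a delimited probe-intensity table (one sample per row)."""
    return pd.read_csv(path, sep="\t")
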