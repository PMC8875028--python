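"""Trajectory, measurement-table and manifest output.

Coordinates are written in reduced units (length unit: the maximum bond
extension); no unit conversion happens anywhere.  The trajectory dialect
is plain XYZ so any molecular viewer renders snapshots: bead count,
comment line ``mcs=<value>``, then one ``V x y 0.0`` line per vesicle
bead followed by one ``P x y 0.0`` line per polymer bead, in fixed bead
order, z identically 0.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator, Sequence, TextIO

import numpy as np
import pandas as pd

from .model import Conformation
from .observables import MeasurementRecord


def write_trajectory_frame(conf: Conformation, mcs: int, sink: TextIO) -> None:
    """Append one XYZ frame (2(N+1) beads, 9 significant digits)."""
    n = conf.n_beads
    sink.write(f"{2 * n}\n")
    sink.write(f"mcs={mcs}\n")
    for tag, xy in (("V", conf.vesicle_xy), ("P", conf.polymer_xy)):
        for x, y in xy:
            sink.write(f"{tag} {x:.9g} {y:.9g} 0.0\n")


def read_trajectory(path: str | Path) -> Iterator[tuple[int, Conformation]]:
    """Yield (mcs, conformation) for every frame of an XYZ trajectory."""
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        count = int(lines[i])
        comment = lines[i + 1]
        mcs = int(comment.split("mcs=", 1)[1]) if "mcs=" in comment else -1
        ves, pol = [], []
        for row in lines[i + 2: i + 2 + count]:
            tag, x, y, _ = row.split()
            (ves if tag == "V" else pol).append((float(x), float(y)))
        yield mcs, Conformation(np.array(ves), np.array(pol))
        i += 2 + count


def measurements_frame(
    records: Sequence[MeasurementRecord], run: int = 0, seed: int = 0
) -> pd.DataFrame:
    """Per-sample measurement table (one row per record)."""
    return pd.DataFrame(
        {
            "run": run,
            "seed": seed,
            "mcs": [r.mcs for r in records],
            "u_vl": [r.u_vl for r in records],
            "r_ee": [r.r_ee for r in records],
            "asphericity": [r.asphericity_vesicle for r in records],
            "shape_label": [r.shape_label for r in records],
        }
    )


def write_measurements(path: str | Path, frames: Sequence[pd.DataFrame]) -> None:
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def write_correlation(path: str | Path, c_mean: np.ndarray, c_stderr: np.ndarray) -> None:
    """Correlation curve as delimited text: columns s, C_mean, C_stderr."""
    pd.DataFrame(
        {"s": np.arange(c_mean.size), "C_mean": c_mean, "C_stderr": c_stderr}
    ).to_csv(path, sep="\t", index=False)


def read_correlation(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_manifest(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
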