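"""Tabular population traces and structured ensemble output.

Population traces go to diff-able tab-separated text with a provenance
header (``# key: value`` lines recording seed, units and code version);
trajectory-resolved ensembles go to HDF5.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .dynamics import EnsembleResult, HopEvent

__all__ = ["write_traces", "read_traces", "save_ensemble", "load_ensemble"]


def write_traces(path, t_fs: np.ndarray, populations: np.ndarray,
                 labels: list[str] | None = None,
                 meta: dict | None = None) -> None:
    """Write a time/population table with a commented provenance header."""
    n = populations.shape[1]
    labels = labels or [f"state{i}" for i in range(n)]
    header = ["# lvcdyn population traces", "# time unit: fs",
              "# populations: dimensionless fractions"]
    for k, v in (meta or {}).items():
        header.append(f"# {k}: {v}")
    df = pd.DataFrame({"t_fs": t_fs})
    for i, lbl in enumerate(labels):
        df[lbl] = populations[:, i]
    with open(path, "w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_traces(path) -> tuple[np.ndarray, np.ndarray, list[str], dict]:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if ":" in line:
                k, _, v = line.lstrip("# ").partition(":")
                meta[k.strip()] = v.strip()
        else:
            body_start = i
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])), sep="\t")
    labels = [c for c in df.columns if c != "t_fs"]
    return df["t_fs"].to_numpy(), df[labels].to_numpy(), labels, meta


def save_ensemble(path, ens: EnsembleResult, meta: dict | None = None) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["format"] = "lvcdyn-ensemble"
        for k, v in (meta or {}).items():
            fh.attrs[k] = v
        fh.create_dataset("t_fs", data=ens.t_fs)
        fh.create_dataset("active", data=ens.active)
        fh.create_dataset("c", data=ens.c)
        fh.create_dataset("U", data=ens.U)
        fh.create_dataset("energy", data=ens.energy)
        fh.create_dataset("max_drift", data=ens.max_drift)
        fh.create_dataset("seeds", data=np.array([list(s) for s in ens.seeds],
                                                 dtype=np.int64))
        fh.attrs["state_labels"] = list(ens.state_labels)
        hop_rows = []
        for i, traj in enumerate(ens.hops):
            for h in traj:
                hop_rows.append([i, h.t_fs, h.source, h.target,
                                 int(h.accepted), int(h.frustrated),
                                 int(h.reflected), h.delta_v])
        fh.create_dataset("hops", data=np.array(hop_rows, dtype=float)
                          if hop_rows else np.zeros((0, 8)))


def load_ensemble(path) -> EnsembleResult:
    with h5py.File(path, "r") as fh:
        hops_raw = fh["hops"][...]
        n_traj = fh["active"].shape[0]
        hops: list[list[HopEvent]] = [[] for _ in range(n_traj)]
        for row in hops_raw:
            hops[int(row[0])].append(HopEvent(
                t_fs=row[1], source=int(row[2]), target=int(row[3]),
                accepted=bool(row[4]), frustrated=bool(row[5]),
                reflected=bool(row[6]), delta_v=row[7]))
        return EnsembleResult(
            t_fs=fh["t_fs"][...],
            active=fh["active"][...],
            c=fh["c"][...],
            U=fh["U"][...],
            energy=fh["energy"][...],
            seeds=[tuple(int(x) for x in row) for row in fh["seeds"][...]],
            hops=hops,
            max_drift=fh["max_drift"][...],
            state_labels=tuple(fh.attrs.get("state_labels", ())),
        )
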