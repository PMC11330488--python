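"""Reading and writing the delimited tables the pipeline exchanges.

Formats:

* plate-reader table: first column time (``time_h`` or ``time_s``,
  auto-detected from the header), one column per well; conditions per
  well come from a config mapping.
* fibril length table: ``t_h, length`` (one row per fibril) or
  ``t_h, mean_length, n``.
* oligomer table: ``time_h, S_rel, sem, n_rep, condition``.
* photon table: ``bin_index, counts``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .bulk import KineticTrace
from .bursts import PhotonTrace
from .lengths import LengthSample
from .oligomers import OligomerSeries

__all__ = [
    "read_plate_table",
    "write_traces",
    "read_length_table",
    "write_length_samples",
    "read_oligomer_table",
    "write_oligomer_series",
    "read_photon_table",
    "write_photon_trace",
    "load_config",
]


def load_config(path) -> dict:
    """Load a YAML config (well map, generator or fit parameters)."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def read_plate_table(path, condition_map: dict, sep: str = ",") -> list[KineticTrace]:
    """Read a plate-reader table into kinetic traces.

    `condition_map` maps well (column) names to dicts with keys
    ``m_total_uM``, ``seed_pct`` and optionally ``direction``.  The time
    column must be named ``time_h`` or ``time_s`` (seconds are converted
    to hours).
    """
    df = pd.read_csv(path, sep=sep)
    cols = list(df.columns)
    if cols[0] == "time_h":
        times = df[cols[0]].to_numpy(dtype=float)
    elif cols[0] == "time_s":
        times = df[cols[0]].to_numpy(dtype=float) / 3600.0
    else:
        raise ValueError(
            f"first column must be 'time_h' or 'time_s', got {cols[0]!r}"
        )
    traces = []
    for well, cond in condition_map.items():
        if well not in df.columns:
            raise KeyError(f"well {well!r} not found in table")
        m_total = float(cond["m_total_uM"])
        seed_mass = float(cond.get("seed_pct", 0.0)) / 100.0 * m_total
        traces.append(
            KineticTrace(
                times=times,
                signal=df[well].to_numpy(dtype=float),
                m_total=m_total,
                seed_mass=seed_mass,
                direction=cond.get("direction", "increase"),
            )
        )
    return traces


def write_traces(traces: list[KineticTrace], path, sep: str = ",") -> None:
    """Write kinetic traces as a plate-reader-style table (well_0, well_1, ...)."""
    data = {"time_h": traces[0].times}
    for i, tr in enumerate(traces):
        if not np.array_equal(tr.times, traces[0].times):
            raise ValueError("all traces must share one time grid for a plate table")
        data[f"well_{i}"] = tr.signal
    pd.DataFrame(data).to_csv(path, sep=sep, index=False)


def read_length_table(path, sep: str = ",") -> list[LengthSample]:
    """Read fibril lengths (t_h, length per row, or t_h, mean_length, n)."""
    df = pd.read_csv(path, sep=sep)
    if {"t_h", "length"} <= set(df.columns):
        return [
            LengthSample(t=float(t), lengths=grp["length"].to_numpy(dtype=float))
            for t, grp in df.groupby("t_h", sort=True)
        ]
    if {"t_h", "mean_length", "n"} <= set(df.columns):
        return [
            LengthSample(t=float(r.t_h), mean_length=float(r.mean_length),
                         n_measured=int(r.n))
            for r in df.itertuples()
        ]
    raise ValueError("length table needs columns (t_h, length) or (t_h, mean_length, n)")


def write_length_samples(samples: list[LengthSample], path, sep: str = ",") -> None:
    rows = []
    for s in samples:
        if s.lengths is not None:
            rows.append(pd.DataFrame({"t_h": s.t, "length": s.lengths}))
        else:
            rows.append(pd.DataFrame({"t_h": [s.t], "mean_length": [s.mean_length],
                                      "n": [s.n_measured]}))
    pd.concat(rows, ignore_index=True).to_csv(path, sep=sep, index=False)


def read_oligomer_table(path, sep: str = ",") -> dict[str, OligomerSeries]:
    """Read oligomer series keyed by condition label."""
    df = pd.read_csv(path, sep=sep)
    required = {"time_h", "S_rel", "condition"}
    if not required <= set(df.columns):
        raise ValueError(f"oligomer table needs columns {sorted(required)}")
    out = {}
    for cond, grp in df.groupby("condition"):
        grp = grp.sort_values("time_h")
        out[str(cond)] = OligomerSeries(
            times=grp["time_h"].to_numpy(dtype=float),
            S=grp["S_rel"].to_numpy(dtype=float),
            sem=grp["sem"].to_numpy(dtype=float) if "sem" in grp else None,
            n_replicates=grp["n_rep"].to_numpy(dtype=int) if "n_rep" in grp else None,
            condition=str(cond),
        )
    return out


def write_oligomer_series(series: dict[str, OligomerSeries], path, sep: str = ",") -> None:
    frames = []
    for label, s in series.items():
        frames.append(pd.DataFrame({
            "time_h": s.times,
            "S_rel": s.S,
            "sem": s.sem if s.sem is not None else np.nan,
            "n_rep": s.n_replicates if s.n_replicates is not None else 1,
            "condition": label,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def read_photon_table(path, bin_width_ms: float, sep: str = ",") -> PhotonTrace:
    df = pd.read_csv(path, sep=sep)
    if not {"bin_index", "counts"} <= set(df.columns):
        raise ValueError("photon table needs columns (bin_index, counts)")
    df = df.sort_values("bin_index")
    return PhotonTrace(bin_width_ms=bin_width_ms,
                       counts=df["counts"].to_numpy(dtype=np.int64))


def write_photon_trace(trace: PhotonTrace, path, sep: str = ",") -> None:
    pd.DataFrame({"bin_index": np.arange(trace.counts.size),
                  "counts": trace.counts}).to_csv(path, sep=sep, index=False)
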