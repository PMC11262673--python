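"""Flat config files, CSV serialization, and trace export.

Configs are flat human-editable ``key: value`` YAML files; orders
round-trip through CSV with their defining parameters in ``# key=value``
header comments; curve tables and traces go through pandas CSV plus a
JSON summary.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .acquisition import SetupParameters
from .engine import ProtocolTrace, resolution_summary
from .orders import AcquisitionOrder, make_angle_grid
from .recon_cost import GPUParameters

__all__ = [
    "load_config",
    "setup_from_config",
    "gpu_from_config",
    "write_order_csv",
    "read_order_csv",
    "write_trace",
]


def load_config(path: str | Path) -> dict:
    """Load a flat key/value config file (YAML syntax)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping):
        raise ValueError(f"{path}: expected a flat key/value mapping")
    return dict(cfg)


def setup_from_config(path: str | Path) -> SetupParameters:
    """Build instrument parameters from a flat config file."""
    cfg = load_config(path)
    cfg.setdefault("name", Path(path).stem)
    return SetupParameters(**cfg)


def gpu_from_config(path: str | Path) -> GPUParameters:
    """Build GPU parameters from a flat config file."""
    cfg = load_config(path)
    cfg.setdefault("name", Path(path).stem)
    return GPUParameters(**cfg)


def write_order_csv(order: AcquisitionOrder, path: str | Path) -> None:
    """Write an order as ``i, order_i, angle_deg`` with a lossless header."""
    grid = order.grid
    header = {
        "kind": order.kind,
        "a_min": grid.a_min,
        "a_max": grid.a_max,
        "n_proj": grid.n_proj,
    }
    if order.n_prescan is not None:
        header["n_prescan"] = order.n_prescan
    if order.seed is not None:
        header["seed"] = order.seed
    angles = order.angles()
    with open(path, "w") as fh:
        for key, value in header.items():
            fh.write(f"# {key}={value}\n")
        fh.write("i,order_i,angle_deg\n")
        for i, (idx, ang) in enumerate(zip(order.order, angles)):
            fh.write(f"{i},{idx},{ang!r}\n")


def read_order_csv(path: str | Path) -> AcquisitionOrder:
    """Read an order written by :func:`write_order_csv` (lossless)."""
    meta: dict[str, str] = {}
    rows: list[int] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition("=")
                meta[key.strip()] = value.strip()
            elif line and not line.startswith("i,"):
                rows.append(int(line.split(",")[1]))
    grid = make_angle_grid(
        float(meta["a_min"]), float(meta["a_max"]), int(meta["n_proj"])
    )
    return AcquisitionOrder(
        grid=grid,
        order=np.asarray(rows),
        kind=meta.get("kind", "consecutive"),
        n_prescan=int(meta["n_prescan"]) if "n_prescan" in meta else None,
        seed=int(meta["seed"]) if "seed" in meta else None,
    )


def trace_frames(
    trace: ProtocolTrace,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Events, cycles, and decisions of a trace as DataFrames."""
    events = pd.DataFrame(
        {
            "index": [e.index for e in trace.events],
            "angle_deg": [e.angle for e in trace.events],
            "t_available_s": [e.t_available for e in trace.events],
        }
    )
    cycles = pd.DataFrame(
        {
            "t_start_s": [c.t_start for c in trace.cycles],
            "t_end_s": [c.t_end for c in trace.cycles],
            "batch_size": [len(c.batch) for c in trace.cycles],
            "n_after": [c.n_after for c in trace.cycles],
        }
    )
    decisions = pd.DataFrame(
        {
            "cycle_index": [d.cycle_index for d in trace.decisions],
            "quality_value": [d.quality_value for d in trace.decisions],
            "decision": [d.decision for d in trace.decisions],
        }
    )
    return events, cycles, decisions


def write_trace(trace: ProtocolTrace, out_dir: str | Path, stem: str = "trace") -> None:
    """Export a trace as three CSVs plus a JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    events, cycles, decisions = trace_frames(trace)
    events.to_csv(out / f"{stem}_events.csv", index=False)
    cycles.to_csv(out / f"{stem}_cycles.csv", index=False)
    decisions.to_csv(out / f"{stem}_decisions.csv", index=False)
    with open(out / f"{stem}_summary.json", "w") as fh:
        json.dump(resolution_summary(trace), fh, indent=2)
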