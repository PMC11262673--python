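"""GPU reconstruction-time model and real-time feasibility accounting.

The cost of one reconstruction is decomposed into host-to-device
loading, device memory traffic, projection preprocessing, and the
reconstruction kernel itself:

    proj_size = N_x * N_z * N_a          (projection pixels)
    vol_size  = N_x * N_x * N_z          (volume voxels)
    T_load    = proj_size * bytes_per_pixel / s_load   (one-time)
    T_memory  = proj_size * bytes_per_pixel / s_memory
    T_prep    = proj_size * P_pixel / s_rec
    T_rec     = it_count * vol_size * N_a * P_voxel / s_rec

For the incremental partial variant (``fbp_partial``) ``N_a`` counts
only the NEW projections folded into the running volume (typically 1),
which makes the per-cycle cost independent of how many projections were
already acquired.  SIRT multiplies the kernel term by an additional
per-iteration operations factor (forward + back projection + update
passes; default 3).

The headline feasibility number is how many reconstruction cycles fit
into one full acquisition: ``floor(T_acq / cycle_time)``.  Values below
one mean real-time reconstruction is impossible on that instrument.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .acquisition import SetupParameters, total_time_dose
from .orders import consecutive_order
from .presets import GPU_PRESETS

__all__ = [
    "GPUParameters",
    "ReconJob",
    "ReconCostBreakdown",
    "recon_time",
    "reconstructions_per_acquisition",
    "cost_table",
    "load_gpu_preset",
    "ALGORITHMS",
]

ALGORITHMS = ("fbp_fdk", "sirt", "fbp_partial")


@dataclass(frozen=True)
class GPUParameters:
    """Compute-unit parameters (flop/s, B/s, ops per data element)."""

    name: str
    s_rec: float
    s_load: float
    s_memory: float
    p_voxel: float
    p_pixel: float
    ram_bytes: float

    def __post_init__(self) -> None:
        for attr in ("s_rec", "s_load", "s_memory", "p_voxel", "p_pixel", "ram_bytes"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be strictly positive")


@dataclass(frozen=True)
class ReconJob:
    """One reconstruction task: geometry, algorithm, iteration count.

    For ``fbp_partial``, ``n_a`` is the number of NEW projections in the
    incremental update (usually 1), while the volume term still covers
    the full reconstruction grid.
    """

    n_x: int
    n_z: int
    n_a: int
    algorithm: str = "fbp_fdk"
    it_count: int = 1
    bytes_per_pixel: int = 4
    iteration_ops_multiplier: float = 3.0
    include_load: bool = False

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_z < 1 or self.n_a < 0:
            raise ValueError("detector/projection dimensions must be positive")
        if self.it_count < 1:
            raise ValueError("it_count must be >= 1")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}")

    @property
    def proj_size(self) -> int:
        return self.n_x * self.n_z * self.n_a

    @property
    def vol_size(self) -> int:
        return self.n_x * self.n_x * self.n_z


@dataclass(frozen=True)
class ReconCostBreakdown:
    """Load/memory/preprocess/reconstruct time split, seconds."""

    t_load: float
    t_memory: float
    t_prep: float
    t_rec: float

    @property
    def t_total(self) -> float:
        return self.t_load + self.t_memory + self.t_prep + self.t_rec


def recon_time(gpu: GPUParameters, job: ReconJob) -> ReconCostBreakdown:
    """Evaluate the cost model for one reconstruction job.

    ``T_load`` is charged only when ``job.include_load`` is set: in a
    monitored run the projection data are shipped to the device once and
    the per-cycle cost excludes it.  A warning is emitted when volume
    plus projections exceed device memory (the model assumes both stay
    resident).
    """
    ops_multiplier = (
        job.iteration_ops_multiplier if job.algorithm == "sirt" else 1.0
    )
    proj_bytes = job.proj_size * job.bytes_per_pixel
    t_load = proj_bytes / gpu.s_load if job.include_load else 0.0
    t_memory = proj_bytes / gpu.s_memory
    t_prep = job.proj_size * gpu.p_pixel / gpu.s_rec
    t_rec = (
        job.it_count * job.vol_size * job.n_a * gpu.p_voxel / gpu.s_rec
    ) * ops_multiplier
    needed = (job.vol_size + job.proj_size) * job.bytes_per_pixel
    if needed > gpu.ram_bytes:
        warnings.warn(
            f"volume+projections need {needed / 1e9:.1f} GB but device has "
            f"{gpu.ram_bytes / 1e9:.1f} GB; model assumes resident data",
            stacklevel=2,
        )
    return ReconCostBreakdown(t_load, t_memory, t_prep, t_rec)


def reconstructions_per_acquisition(
    t_acq: float, cycle_time: float
) -> tuple[int, bool]:
    """How many reconstruction cycles fit in one acquisition.

    Returns ``(count, feasible)`` with ``count = floor(t_acq / cycle)``;
    ``feasible`` is False when not even one cycle completes in time
    (real-time reconstruction impossible).
    """
    if cycle_time <= 0:
        raise ValueError("cycle_time must be positive")
    count = math.floor(t_acq / cycle_time)
    return count, count >= 1


def load_gpu_preset(name: str) -> GPUParameters:
    """Look up a named GPU preset (``rtx4090``, ``rtx3080ti``)."""
    key = str(name).lower()
    if key in GPU_PRESETS:
        return GPUParameters(**GPU_PRESETS[key])
    raise KeyError(
        f"unknown GPU preset {name!r}; known presets: {sorted(GPU_PRESETS)}"
    )


def cost_table(
    gpu: GPUParameters,
    setups: Iterable[SetupParameters],
    sirt_iterations: int = 50,
) -> pd.DataFrame:
    """Algorithms-by-instruments grid of cycle times and feasibility.

    For every setup, evaluates batch FBP/FDK over all projections, SIRT
    with ``sirt_iterations`` iterations, and the single-projection
    incremental update; divides the modeled consecutive-order total
    acquisition time by each cycle time.  Columns: ``setup``,
    ``algorithm``, ``cycle_time_s``, ``t_acq_s``, ``n_per_acquisition``,
    ``per_n_p``, ``feasible``.
    """
    rows = []
    for setup in setups:
        t_acq = total_time_dose(setup, consecutive_order(setup.angle_grid())).t_total
        jobs = {
            "fbp_fdk": ReconJob(setup.n_x, setup.n_z, setup.n_proj, "fbp_fdk"),
            "sirt": ReconJob(
                setup.n_x, setup.n_z, setup.n_proj, "sirt", it_count=sirt_iterations
            ),
            "fbp_partial": ReconJob(setup.n_x, setup.n_z, 1, "fbp_partial"),
        }
        for algo, job in jobs.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cycle = recon_time(gpu, job).t_total
            count, feasible = reconstructions_per_acquisition(t_acq, cycle)
            rows.append(
                {
                    "setup": setup.name,
                    "algorithm": algo,
                    "cycle_time_s": cycle,
                    "t_acq_s": t_acq,
                    "n_per_acquisition": count,
                    "per_n_p": count / setup.n_proj,
                    "feasible": feasible,
                }
            )
    return pd.DataFrame(rows)
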