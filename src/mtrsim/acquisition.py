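"""Per-projection scan time and dose model.

Each acquired projection ``i`` costs

- exposure        ``T_exp_i  = T_frame + C_det``
- stage movement  ``T_move_i = C_move + dist_i / s_rot``
- gating          ``T_gate_i = gate * C_gate_move``

where ``dist_i`` is the angular travel to projection ``i`` and ``s_rot``
the rotation speed (``360 deg / time_per_rotation``).  Dose is tracked
as *object-exposition time*: the object always absorbs the exposure
time; it absorbs the movement time only when no gating blocks the beam,
and gating itself may add a fixed dose overhead per projection:

- ``D_exp_i  = T_exp_i``
- ``D_move_i = (1 - gate) * T_move_i``
- ``D_gate_i = gate * C_gate_dose``

Totals over the first ``n`` acquired projections follow two regimes.
Quasi-stationary instruments (stage stops for every frame) simply sum
all terms.  Continuous-movement instruments (medical/cargo gantries)
expose while rotating, so each projection costs
``max(T_exp_i + T_gate_i, T_move_i)`` in time while the dose keeps only
the exposure and gating terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .orders import AcquisitionOrder, AngleGrid, make_angle_grid, order_metrics
from .presets import SETUP_PRESETS

__all__ = [
    "SetupParameters",
    "PerProjectionCosts",
    "TimingDoseResult",
    "per_projection_costs",
    "total_time_dose",
    "dose_time_curves",
    "load_setup_preset",
]

#: Stage-travel convention used by the time model when none is given.
#: Consecutive and logarithmic orders are executed as forward rotation
#: programs (wrap allowed, matching the closed-form logarithmic travel);
#: arbitrary (random) orders move the stage directly between absolute
#: positions without crossing the range ends.
_AUTO_TRAVEL = {
    "consecutive": "unidirectional",
    "logarithmic": "unidirectional",
    "random": "bounded",
}


@dataclass(frozen=True)
class SetupParameters:
    """One instrument's acquisition constants (times s, angles deg)."""

    name: str
    n_proj: int
    angle_range: float
    t_frame: float
    time_per_rotation: float
    c_det: float = 0.0
    c_move: float = 0.0
    gate: int = 0
    c_gate_move: float = 0.0
    c_gate_dose: float = 0.0
    continuous: bool = False
    n_x: int = 1
    n_z: int = 1

    def __post_init__(self) -> None:
        if self.n_proj < 1:
            raise ValueError("n_proj must be >= 1")
        if not 0.0 < self.angle_range <= 360.0:
            raise ValueError("angle_range must lie in (0, 360]")
        for attr in (
            "t_frame",
            "time_per_rotation",
            "c_det",
            "c_move",
            "c_gate_move",
            "c_gate_dose",
        ):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")
        if self.gate not in (0, 1):
            raise ValueError("gate must be 0 or 1")

    def angle_grid(self) -> AngleGrid:
        """The instrument's angle grid, ``[0, angle_range)``."""
        return make_angle_grid(0.0, self.angle_range, self.n_proj)


@dataclass(frozen=True)
class PerProjectionCosts:
    """Eq-style time/dose decomposition, one entry per acquired projection."""

    t_exp: np.ndarray
    t_move: np.ndarray
    t_gate: np.ndarray
    d_exp: np.ndarray
    d_move: np.ndarray
    d_gate: np.ndarray

    def __len__(self) -> int:
        return len(self.t_exp)


@dataclass(frozen=True)
class TimingDoseResult:
    """Totals and per-n partial-sum curves for one setup and order."""

    t_total: float
    d_total: float
    n_used: int
    t_curve: np.ndarray
    d_curve: np.ndarray
    order_kind: str = ""


def per_projection_costs(
    setup: SetupParameters,
    order: AcquisitionOrder,
    rotation_mode: str = "auto",
) -> PerProjectionCosts:
    """Evaluate the per-projection time/dose terms for an order.

    ``rotation_mode`` selects the stage-travel convention (see
    :data:`mtrsim.orders.ROTATION_MODES`); ``"auto"`` picks per order
    kind.  One movement term is charged per acquired projection; the
    initial positioning move has zero angular distance.
    """
    if len(order) != setup.n_proj:
        raise ValueError(
            f"order length {len(order)} != setup n_proj {setup.n_proj}"
        )
    if rotation_mode == "auto":
        rotation_mode = _AUTO_TRAVEL.get(order.kind, "bounded")
    dist = order_metrics(order, rotation_mode).per_step_distance

    t_exp = np.full(setup.n_proj, setup.t_frame + setup.c_det)
    t_move = setup.c_move + dist * setup.time_per_rotation / 360.0
    t_gate = np.full(setup.n_proj, setup.gate * setup.c_gate_move)
    d_exp = t_exp.copy()
    # Gating blocks the beam while the stage moves: movement dose is
    # charged only on ungated instruments.
    d_move = (1 - setup.gate) * t_move
    d_gate = np.full(setup.n_proj, setup.gate * setup.c_gate_dose)
    return PerProjectionCosts(t_exp, t_move, t_gate, d_exp, d_move, d_gate)


def _step_series(
    setup: SetupParameters, costs: PerProjectionCosts
) -> tuple[np.ndarray, np.ndarray]:
    if setup.continuous:
        t_step = np.maximum(costs.t_exp + costs.t_gate, costs.t_move)
        d_step = costs.d_exp + costs.d_gate
    else:
        t_step = costs.t_exp + costs.t_move + costs.t_gate
        d_step = costs.d_exp + costs.d_move + costs.d_gate
    return t_step, d_step


def total_time_dose(
    setup: SetupParameters,
    order: AcquisitionOrder,
    n: int | None = None,
    rotation_mode: str = "auto",
) -> TimingDoseResult:
    """Total time and dose after the first ``n`` acquired projections.

    ``n`` defaults to the full scan.  The returned curves are the
    partial sums for every prefix 1..N_p of the *acquisition sequence*
    (not sorted angles), i.e. the monitored-protocol time/dose-vs-n
    trajectories.
    """
    if n is None:
        n = setup.n_proj
    if not 1 <= n <= setup.n_proj:
        raise ValueError(f"n must be in [1, {setup.n_proj}], got {n}")
    costs = per_projection_costs(setup, order, rotation_mode)
    t_step, d_step = _step_series(setup, costs)
    t_curve = np.cumsum(t_step)
    d_curve = np.cumsum(d_step)
    return TimingDoseResult(
        t_total=float(t_curve[n - 1]),
        d_total=float(d_curve[n - 1]),
        n_used=n,
        t_curve=t_curve,
        d_curve=d_curve,
        order_kind=order.kind,
    )


def dose_time_curves(
    setup: SetupParameters,
    orders: Iterable[AcquisitionOrder],
    rotation_mode: str = "auto",
) -> pd.DataFrame:
    """Tidy table of T_total(n) and D_total(n) for each order.

    Columns: ``n``, ``order_kind``, ``t_total_s``, ``d_total_s``.
    """
    frames = []
    for order in orders:
        res = total_time_dose(setup, order, rotation_mode=rotation_mode)
        frames.append(
            pd.DataFrame(
                {
                    "n": np.arange(1, setup.n_proj + 1),
                    "order_kind": res.order_kind,
                    "t_total_s": res.t_curve,
                    "d_total_s": res.d_curve,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def load_setup_preset(name: str | Path) -> SetupParameters:
    """Look up a named instrument preset, or load one from a config file.

    Known names: ``micro``, ``nano``, ``medical``, ``cargo``, ``ebct``.
    Anything else is treated as a path to a flat key/value config file
    (see :func:`mtrsim.io.load_config`).
    """
    key = str(name).lower()
    if key in SETUP_PRESETS:
        return SetupParameters(**SETUP_PRESETS[key])
    path = Path(name)
    if path.exists():
        from .io import setup_from_config

        return setup_from_config(path)
    raise KeyError(
        f"unknown setup preset {name!r}; known presets: "
        f"{sorted(SETUP_PRESETS)} (or pass a config file path)"
    )
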