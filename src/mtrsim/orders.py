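"""Projection acquisition orders over an angle grid.

A tomographic scan acquires ``N_p`` projections at angles laid out on a
regular grid over ``[a_min, a_max)``.  The *acquisition order* is the
permutation mapping acquisition-sequence position ``i`` to angle-grid
index ``order(i)``.  Three orders are provided:

``consecutive``
    The standard protocol, ``order(i) = i``.  The rotation stage sweeps
    the range once, total angular travel ~= the angular range.
``random``
    A uniformly random permutation.  Partial data are spread over the
    whole range from the start, but the stage travels a long way between
    consecutive angles (mean shortest-arc step -> 90 deg).
``logarithmic``
    A prescan rotation of ``N_prescan`` equidistant angles followed by
    refinement rotations that insert midpoints, doubling the number of
    acquired angles per rotation.  After every completed rotation the
    acquired set is again equidistant, so classical filtered back
    projection stays artifact-free on the partial data, while the total
    travel grows only logarithmically in ``N_p``:
    ``d_total = 360 * (1 + log2(N_p / N_prescan))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "AngleGrid",
    "AcquisitionOrder",
    "OrderMetrics",
    "make_angle_grid",
    "consecutive_order",
    "random_order",
    "logarithmic_order",
    "order_metrics",
    "logarithmic_total_distance",
    "ROTATION_MODES",
]

#: Supported stage-travel conventions for per-step angular distances.
#:
#: - ``unidirectional``: forward arc only; the stage always rotates the
#:   same way and may wrap through 0/360.
#: - ``bidirectional``: shortest arc on the circle (wrap allowed).
#: - ``bounded``: straight travel between absolute angles, no wrap —
#:   a stage whose cabling or hard stops forbid crossing the range ends.
ROTATION_MODES = ("unidirectional", "bidirectional", "bounded")


@dataclass(frozen=True)
class AngleGrid:
    """Regular angle grid: ``angle(j) = a_min + j/n_proj * (a_max - a_min)``.

    The grid is half-open: ``a_max`` itself is never generated (for a
    full-circle scan the 360 deg position duplicates 0 deg).
    """

    a_min: float
    a_max: float
    n_proj: int

    def __post_init__(self) -> None:
        if self.n_proj < 1:
            raise ValueError(f"n_proj must be >= 1, got {self.n_proj}")
        if not self.a_max > self.a_min:
            raise ValueError(
                f"need a_max > a_min, got [{self.a_min}, {self.a_max}]"
            )

    @property
    def span(self) -> float:
        """Angular range in degrees."""
        return self.a_max - self.a_min

    @property
    def spacing(self) -> float:
        """Grid step in degrees."""
        return self.span / self.n_proj

    def angles(self) -> np.ndarray:
        """All grid angles in degrees, index order."""
        j = np.arange(self.n_proj, dtype=float)
        return self.a_min + j / self.n_proj * self.span


@dataclass(frozen=True)
class AcquisitionOrder:
    """A permutation of grid indices together with the grid it indexes."""

    grid: AngleGrid
    order: np.ndarray
    kind: str
    n_prescan: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        order = np.asarray(self.order, dtype=np.int64)
        object.__setattr__(self, "order", order)
        if order.shape != (self.grid.n_proj,) or not np.array_equal(
            np.sort(order), np.arange(self.grid.n_proj)
        ):
            raise ValueError("order must be a permutation of 0..n_proj-1")

    def __len__(self) -> int:
        return self.grid.n_proj

    def angles(self) -> np.ndarray:
        """Acquired angles in acquisition sequence (degrees)."""
        return self.grid.angles()[self.order]


@dataclass(frozen=True)
class OrderMetrics:
    """Angular travel cost of an order under a stage-travel convention."""

    per_step_distance: np.ndarray
    rotation_mode: str
    d_total: float = field(init=False)

    def __post_init__(self) -> None:
        dist = np.asarray(self.per_step_distance, dtype=float)
        if np.any(dist < 0):
            raise ValueError("per-step distances must be non-negative")
        object.__setattr__(self, "per_step_distance", dist)
        object.__setattr__(self, "d_total", float(dist.sum()))

    @property
    def mean_step(self) -> float:
        """Mean per-step distance over actual moves (degrees)."""
        if len(self.per_step_distance) <= 1:
            return 0.0
        return float(self.per_step_distance[1:].mean())


def make_angle_grid(a_min: float, a_max: float, n_proj: int) -> AngleGrid:
    """Build the half-open regular angle grid over ``[a_min, a_max)``."""
    return AngleGrid(a_min=a_min, a_max=a_max, n_proj=int(n_proj))


def consecutive_order(grid: AngleGrid) -> AcquisitionOrder:
    """Standard incremental order, ``order(i) = i``."""
    return AcquisitionOrder(
        grid=grid, order=np.arange(grid.n_proj), kind="consecutive"
    )


def random_order(grid: AngleGrid, seed: int) -> AcquisitionOrder:
    """Uniformly random permutation, reproducible from ``seed``."""
    rng = np.random.default_rng(seed)
    return AcquisitionOrder(
        grid=grid,
        order=rng.permutation(grid.n_proj),
        kind="random",
        seed=int(seed),
    )


def logarithmic_order(grid: AngleGrid, n_prescan: int) -> AcquisitionOrder:
    """Prescan plus midpoint-refinement rotations.

    Rotation 0 acquires ``n_prescan`` equidistant indices
    ``{0, N_p/n_prescan, 2*N_p/n_prescan, ...}``; every later rotation
    acquires the midpoints of the already-acquired set in ascending
    angle, doubling the count, until all ``N_p`` indices are taken.
    ``N_p / n_prescan`` must be a power of two so that each refinement
    exactly halves the spacing.
    """
    n_prescan = int(n_prescan)
    n_p = grid.n_proj
    if n_prescan < 1:
        raise ValueError(f"n_prescan must be >= 1, got {n_prescan}")
    ratio, rem = divmod(n_p, n_prescan)
    if rem != 0 or ratio & (ratio - 1) != 0:
        raise ValueError(
            f"N_p / n_prescan must be a power of two; got "
            f"N_p={n_p}, n_prescan={n_prescan}"
        )
    chunks = [np.arange(0, n_p, ratio)]
    step = ratio
    while step > 1:
        chunks.append(np.arange(step // 2, n_p, step))
        step //= 2
    return AcquisitionOrder(
        grid=grid,
        order=np.concatenate(chunks),
        kind="logarithmic",
        n_prescan=n_prescan,
    )


def logarithmic_rotation_checkpoints(n_p: int, n_prescan: int) -> list[int]:
    """Cumulative acquired counts at which each rotation completes."""
    counts = [n_prescan]
    while counts[-1] < n_p:
        counts.append(min(2 * counts[-1], n_p))
    return counts


def logarithmic_total_distance(n_p: int, n_prescan: int) -> float:
    """Closed-form total angular travel of the logarithmic order (degrees).

    One full rotation for the prescan plus one per refinement level:
    ``360 * (1 + log2(N_p / n_prescan))``.
    """
    ratio = n_p / n_prescan
    return 360.0 * (1.0 + np.log2(ratio))


def _step_distances(angles: np.ndarray, rotation_mode: str) -> np.ndarray:
    """Per-step travel, including a zero-length initial positioning move."""
    if rotation_mode not in ROTATION_MODES:
        raise ValueError(
            f"rotation_mode must be one of {ROTATION_MODES}, got {rotation_mode!r}"
        )
    steps = np.diff(angles)
    if rotation_mode == "unidirectional":
        dist = np.mod(steps, 360.0)
    elif rotation_mode == "bidirectional":
        fwd = np.mod(np.abs(steps), 360.0)
        dist = np.minimum(fwd, 360.0 - fwd)
    else:  # bounded
        dist = np.abs(steps)
    return np.concatenate([[0.0], dist])


def order_metrics(
    order: AcquisitionOrder, rotation_mode: str = "bidirectional"
) -> OrderMetrics:
    """Angular travel of ``order`` under the given stage convention.

    The first entry of ``per_step_distance`` is the initial positioning
    move and is charged zero distance (its fixed overhead is still
    counted by the time model), so ``d_total`` sums ``N_p - 1`` moves.
    """
    return OrderMetrics(
        per_step_distance=_step_distances(order.angles(), rotation_mode),
        rotation_mode=rotation_mode,
    )
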