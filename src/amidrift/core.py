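"""Per-cell stochastic machinery of macronuclear amitosis.

Ciliate macronuclei divide without a mitotic spindle: before each fission
every gene-size chromosome is replicated, and the doubled pool is
partitioned at random between the two daughter cells.  For a cell carrying
``n`` copies of a chromosome, one daughter therefore receives a
``Binomial(2n, 1/2)`` draw and the other the complement, so copy number
performs an unbiased random walk whose one-division variance is ``n/2``.

Stabilizing selection on copy number is modelled with a Gaussian fitness
surface: a cell at copy number ``x`` survives a division round with
probability ``W(z) = exp(-z^2 / (2 * omega_sq))`` where ``z = (x - theta) /
theta`` is the relative deviation from the optimum ``theta``.  Smaller
``omega_sq`` means a narrower surface and stronger selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CellState",
    "SelectionParams",
    "Culture",
    "NonviableCellError",
    "divide_cell",
    "fitness",
    "apply_selection",
    "grow_culture",
]


class NonviableCellError(ValueError):
    """Raised when a zero-copy (dead) cell is asked to divide or seed."""


@dataclass(frozen=True)
class CellState:
    """Copy number of one macronuclear chromosome in one cell."""

    copies: int

    def __post_init__(self) -> None:
        if self.copies < 0:
            raise ValueError(f"copies must be >= 0, got {self.copies}")

    @property
    def viable(self) -> bool:
        """A cell that has lost every copy never divides or seeds."""
        return self.copies >= 1


@dataclass(frozen=True)
class SelectionParams:
    """Gaussian stabilizing-selection surface on chromosome copy number.

    Parameters
    ----------
    theta
        Optimal copy number; by convention the starting copy number of the
        experiment.
    omega_sq
        Width of the selection surface.  Smaller values mean stronger
        selection; the sweeps here use 0.02-0.80.
    enabled
        ``False`` disables selection entirely (neutral drift).
    mode
        ``"relative"`` (default) measures deviation as ``(x - theta)/theta``;
        ``"absolute"`` uses ``x - theta``, kept for sensitivity checks.
    """

    theta: int
    omega_sq: float
    enabled: bool = True
    mode: str = "relative"

    def __post_init__(self) -> None:
        if self.enabled and not self.omega_sq > 0:
            raise ValueError(f"omega_sq must be > 0, got {self.omega_sq}")
        if self.theta < 1:
            raise ValueError(f"theta must be >= 1, got {self.theta}")
        if self.mode not in ("relative", "absolute"):
            raise ValueError(f"unknown deviation mode {self.mode!r}")

    @classmethod
    def none(cls) -> "SelectionParams":
        """A disabled (neutral) parameter set."""
        return cls(theta=1, omega_sq=1.0, enabled=False)


@dataclass
class Culture:
    """A clonal culture: the copy numbers of its viable cells.

    ``cells`` holds one entry per viable cell (all >= 1); ``generation``
    counts synchronous division rounds since the founder within the current
    transfer cycle.  Absent selection and absent zero-copy daughters the
    culture holds ``2**generation`` cells.
    """

    cells: np.ndarray
    generation: int = 0

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int64)
        if self.cells.ndim != 1:
            raise ValueError("cells must be a 1-D array of copy counts")
        if np.any(self.cells < 1):
            raise ValueError("a Culture contains only viable cells (copies >= 1)")

    def __len__(self) -> int:
        return self.cells.size

    @property
    def is_extinct(self) -> bool:
        return self.cells.size == 0

    def mean_copies(self) -> float:
        """Mean copy number over the viable cells (nan if extinct)."""
        if self.is_extinct:
            return float("nan")
        return float(self.cells.mean())


def divide_cell(parent: CellState, rng: np.random.Generator) -> tuple[CellState, CellState]:
    """Amitotically divide one cell: double, then segregate binomially.

    Returns the two daughters; their copies always sum to ``2 * parent.copies``.
    Either daughter may receive 0 copies (it is returned but nonviable).
    """
    if parent.copies < 1:
        raise NonviableCellError("a cell with 0 copies cannot divide")
    a = int(rng.binomial(2 * parent.copies, 0.5))
    return CellState(a), CellState(2 * parent.copies - a)


def fitness(x, params: SelectionParams):
    """Survival probability W(z) under Gaussian stabilizing selection.

    ``x`` may be a scalar or array of copy numbers.  ``W`` equals 1 at the
    optimum and decays as ``exp(-z^2 / (2 * omega_sq))`` with deviation
    ``z = (x - theta)/theta`` (or ``x - theta`` in absolute mode).
    """
    if not params.enabled:
        raise ValueError("fitness() requires an enabled SelectionParams")
    x = np.asarray(x, dtype=np.float64)
    z = x - params.theta
    if params.mode == "relative":
        z = z / params.theta
    w = np.exp(-(z * z) / (2.0 * params.omega_sq))
    return w if w.ndim else float(w)


def apply_selection(culture: Culture, params: SelectionParams, rng: np.random.Generator) -> Culture:
    """Independently kill each cell with probability ``1 - W(copies)``."""
    if culture.is_extinct:
        return culture
    w = fitness(culture.cells, params)
    keep = rng.random(culture.cells.size) < w
    return Culture(culture.cells[keep], generation=culture.generation)


def _segregate_all(cells: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Divide every cell in ``cells`` once; daughters of cell i land at 2i, 2i+1.

    Zero-copy daughters are retained; callers filter viability.  Batched
    binomial sampling across the whole culture keeps 4096-cell populations
    cheap.
    """
    a = rng.binomial(2 * cells, 0.5)
    daughters = np.empty(2 * cells.size, dtype=np.int64)
    daughters[0::2] = a
    daughters[1::2] = 2 * cells - a
    return daughters


def grow_culture(
    founder: CellState,
    generations: int,
    params: SelectionParams | None,
    rng: np.random.Generator,
) -> Culture:
    """Grow a culture from one founder through synchronous division rounds.

    Every viable cell divides each generation; zero-copy daughters are
    discarded as dead, and when selection is enabled the Gaussian viability
    filter is applied after every round (including the last).  The returned
    culture may be empty, i.e. extinct.  A nonviable founder yields an empty
    culture rather than raising.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    if not founder.viable:
        return Culture(np.empty(0, dtype=np.int64), generation=0)
    cells = np.array([founder.copies], dtype=np.int64)
    for g in range(generations):
        cells = _segregate_all(cells, rng)
        cells = cells[cells > 0]
        if params is not None and params.enabled:
            w = fitness(cells, params)
            cells = cells[rng.random(cells.size) < w]
        if cells.size == 0:
            return Culture(cells, generation=g + 1)
    return Culture(cells, generation=generations)
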