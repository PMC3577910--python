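"""The two headline in-silico experiments.

1. Among-line variance: 6 replicate lines, founders drawn from the copy
   number distribution measured at the start of the experiment, run through
   the full serial-transfer protocol; the quantity of interest is the change
   in among-line variance of mean copy number from initial to final.
   Neutral amitotic drift inflates that variance; stabilizing selection
   compresses it.

2. Mortality sweep: 60 lines started at the lowest-copy chromosome's count
   (66), run under a grid of selection strengths omega_sq; mortality is the
   fraction of lines extinct after the full protocol.

A single-cell "regulatory model" oracle is included for comparison: copy
number snaps back to the parental state after every division, so the only
way to change is to lose the chromosome outright.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SelectionParams
from .transfer import GENS_PER_TRANSFER, N_TRANSFERS, run_lineages

__all__ = [
    "VarianceExperimentResult",
    "MortalityCurve",
    "RegulatoryLossResult",
    "draw_start_copies",
    "run_variance_experiment",
    "run_mortality_sweep",
    "regulatory_model_oracle",
    "delta_variance_frame",
    "DEFAULT_OMEGA_GRID",
]

# 0.02 .. 0.80 in steps of 0.02 (40 points)
DEFAULT_OMEGA_GRID = tuple(np.round(np.arange(1, 41) * 0.02, 2))

# lineage batches are chunked to bound the flat cell array (~2 * 4096 cells
# per line at peak)
_CHUNK_LINES = 1024


@dataclass(frozen=True)
class VarianceExperimentResult:
    """One replicate of the 6-line variance experiment.

    ``delta_variance`` is the sample variance of the surviving lines' final
    mean copy numbers minus the sample variance of those same lines'
    starting copy numbers; NaN (``flagged``) when fewer than two lines
    survived.
    """

    replicate_id: int
    delta_variance: float
    n_surviving: int
    flagged: bool


@dataclass(frozen=True)
class MortalityCurve:
    """Mortality fraction per selection strength over a sweep grid."""

    omega_sq_grid: np.ndarray
    mortality: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"omega_sq": self.omega_sq_grid, "mortality": self.mortality})


@dataclass(frozen=True)
class RegulatoryLossResult:
    """Loss-time summary for the copy-number-resetting oracle."""

    mean_loss_generations: float  # NaN when no losses were observed
    n_lost: int
    n_censored: int


def draw_start_copies(
    mean: float, var: float, n_lines: int, rng: np.random.Generator
) -> np.ndarray:
    """Starting copy numbers: Normal(mean, var) rounded, truncated below at 1."""
    draws = rng.normal(mean, np.sqrt(var), size=n_lines)
    return np.maximum(np.rint(draws), 1).astype(np.int64)


def _run_lineage_chunks(
    starts: np.ndarray,
    n_transfers: int,
    gens_per_transfer: int,
    params: SelectionParams | None,
    rng: np.random.Generator,
):
    """Run a flat batch of lineages in memory-bounded chunks."""
    finals = np.empty(starts.size)
    extinct = np.empty(starts.size, dtype=bool)
    for lo in range(0, starts.size, _CHUNK_LINES):
        hi = min(lo + _CHUNK_LINES, starts.size)
        res = run_lineages(starts[lo:hi], n_transfers, gens_per_transfer, params, rng)
        finals[lo:hi] = res.final_means
        extinct[lo:hi] = res.extinct
    return finals, extinct


def run_variance_experiment(
    chromosome_mean: float,
    chromosome_var: float,
    params: SelectionParams | None = None,
    n_lines: int = 6,
    n_reps: int = 1000,
    n_transfers: int = N_TRANSFERS,
    gens_per_transfer: int = GENS_PER_TRANSFER,
    transform=None,
    rng: np.random.Generator | None = None,
) -> list[VarianceExperimentResult]:
    """Replicate the 6-line change-in-variance experiment.

    Per replicate, ``n_lines`` founders are drawn from the measured initial
    copy-number distribution and run through the full protocol; the change
    in among-line variance uses surviving lines only (mirroring the qPCR
    analysis, which could only measure lines that were still alive).
    Replicates with fewer than two survivors carry ``flagged=True`` and a
    NaN delta.

    ``transform`` (e.g. ``numpy.log``) is applied to line-level values
    before taking variances, for comparison against variance components
    estimated on a transformed scale; ``None`` keeps the raw copy scale.
    """
    if chromosome_mean <= 0:
        raise ValueError("chromosome_mean must be positive")
    if chromosome_var < 0:
        raise ValueError("chromosome_var must be non-negative")
    if rng is None:
        rng = np.random.default_rng()

    starts = np.stack(
        [draw_start_copies(chromosome_mean, chromosome_var, n_lines, rng) for _ in range(n_reps)]
    )
    finals, extinct = _run_lineage_chunks(
        starts.ravel(), n_transfers, gens_per_transfer, params, rng
    )
    finals = finals.reshape(n_reps, n_lines)
    surviving = ~extinct.reshape(n_reps, n_lines)

    results = []
    for rep in range(n_reps):
        mask = surviving[rep]
        n_surv = int(mask.sum())
        if n_surv < 2:
            results.append(VarianceExperimentResult(rep, float("nan"), n_surv, True))
            continue
        fin = finals[rep, mask]
        ini = starts[rep, mask].astype(float)
        if transform is not None:
            fin, ini = transform(fin), transform(ini)
        delta = float(np.var(fin, ddof=1) - np.var(ini, ddof=1))
        results.append(VarianceExperimentResult(rep, delta, n_surv, False))
    return results


def delta_variance_frame(results: list[VarianceExperimentResult]) -> pd.DataFrame:
    """Per-replicate deltas with the change in variance under column ``x``."""
    return pd.DataFrame(
        {
            "replicate": [r.replicate_id for r in results],
            "x": [r.delta_variance for r in results],
            "n_surviving": [r.n_surviving for r in results],
            "flagged": [r.flagged for r in results],
        }
    )


def run_mortality_sweep(
    start_copies: int = 66,
    n_lines: int = 60,
    n_reps: int = 1000,
    omega_grid=DEFAULT_OMEGA_GRID,
    n_transfers: int = N_TRANSFERS,
    gens_per_transfer: int = GENS_PER_TRANSFER,
    rng: np.random.Generator | None = None,
) -> MortalityCurve:
    """Mortality of 60-line experiments across selection strengths.

    The optimum theta equals the starting copy number, so selection acts
    purely against drift away from the initial state.  Mortality at each
    grid point is the extinct fraction over ``n_lines * n_reps`` lines.
    """
    grid = np.asarray(omega_grid, dtype=float)
    if np.any(grid <= 0):
        raise ValueError("omega_sq values must be > 0")
    if rng is None:
        rng = np.random.default_rng()
    starts = np.full(n_lines * n_reps, start_copies, dtype=np.int64)
    mortality = np.empty(grid.size)
    for i, omega_sq in enumerate(grid):
        params = SelectionParams(theta=start_copies, omega_sq=float(omega_sq))
        _, extinct = _run_lineage_chunks(starts, n_transfers, gens_per_transfer, params, rng)
        mortality[i] = extinct.mean()
    return MortalityCurve(omega_sq_grid=grid, mortality=mortality)


def regulatory_model_oracle(
    start_copies: int,
    max_generations: int,
    n_reps: int,
    rng: np.random.Generator | None = None,
) -> RegulatoryLossResult:
    """Mean generations to chromosome loss under copy-number regulation.

    One cell is tracked per replicate: each generation it doubles to ``2n``
    and one daughter draws ``Binomial(2n, 1/2)``; a zero draw is permanent
    loss, any other outcome is reset to the parental copy number
    (regulation).  Loss is therefore geometric with per-generation
    probability ``0.5 ** (2 * start_copies)`` — negligible beyond a handful
    of copies, which is the oracle's point of contrast with unregulated
    drift.  Replicates without a loss by ``max_generations`` are censored.
    """
    if start_copies < 1:
        raise ValueError("start_copies must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    loss_time = np.zeros(n_reps, dtype=np.int64)  # 0 = censored
    active = np.arange(n_reps)
    for gen in range(1, max_generations + 1):
        if active.size == 0:
            break
        draws = rng.binomial(2 * start_copies, 0.5, size=active.size)
        lost_now = draws == 0
        loss_time[active[lost_now]] = gen
        active = active[~lost_now]
    lost = loss_time > 0
    mean_t = float(loss_time[lost].mean()) if lost.any() else float("nan")
    return RegulatoryLossResult(mean_t, int(lost.sum()), int(n_reps - lost.sum()))
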