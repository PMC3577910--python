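"""Synthetic qPCR copy-number data for four macronuclear chromosomes.

Emulates the measurement design of the serial-transfer experiment: 6 clonal
cell lines assayed at the initial and final timepoints, with 3 independent
DNA extracts per line per timepoint, for four gene-size chromosomes (SSU
rRNA, two alpha-tubulin paralogs, EF1-alpha) whose true per-cell copy
numbers span roughly 60 to 10,000.  Line effects and extract-level
measurement error are both multiplicative lognormal: qPCR error acts on the
fold-change scale and copy numbers must stay positive.

The comparative quantification helper converts a ddCt fold change into
copies per cell against a reference sample carrying ~1345 copies of
alpha-tubulin paralog 1.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ChromosomeSpec",
    "DEFAULT_CHROMOSOMES",
    "GENES",
    "DATASET_COLUMNS",
    "generate_dataset",
    "ddct_copies",
    "ddct_from_copies",
    "estimate_start_params",
    "write_dataset",
    "read_dataset",
    "specs_from_config",
    "load_config",
]

GENES = ("SSU", "a-tubP1", "EF1a", "a-tubP2")
DATASET_COLUMNS = ("Cell.line", "Time", "DNA.extract", "Gene", "CNPC")
REFERENCE_ATUBP1_COPIES = 1345.0


@dataclass(frozen=True)
class ChromosomeSpec:
    """Generative parameters for one chromosome's copy-number data.

    ``true_mean`` is the population-mean copies per cell; ``among_line_cv``
    the relative SD of the lognormal line effects; ``measurement_cv`` the
    relative SD of extract-level noise; ``final_shift`` multiplies each
    line's true value at the final timepoint (1.0 = no change over the
    experiment).
    """

    gene: str
    true_mean: float
    among_line_cv: float = 0.15
    measurement_cv: float = 0.05
    final_shift: float = 1.0

    def __post_init__(self) -> None:
        if self.true_mean <= 0:
            raise ValueError("true_mean must be positive")
        if self.among_line_cv < 0 or self.measurement_cv < 0:
            raise ValueError("CVs must be non-negative")
        if self.final_shift <= 0:
            raise ValueError("final_shift must be positive")


# SSU most abundant; a-tubP1 anchored at the 1345-copy reference; EF1a at an
# intermediate level; a-tubP2 the lowest-copy chromosome at 66.  SSU's final
# shift emulates the observed increase in rRNA-chromosome copy number.
DEFAULT_CHROMOSOMES = (
    ChromosomeSpec("SSU", 10_000.0, final_shift=1.2),
    ChromosomeSpec("a-tubP1", REFERENCE_ATUBP1_COPIES),
    ChromosomeSpec("EF1a", 500.0),
    ChromosomeSpec("a-tubP2", 66.0),
)


def _lognormal(mean: float, cv: float, size, rng: np.random.Generator) -> np.ndarray:
    """Lognormal draws with exact arithmetic mean ``mean`` and relative SD ``cv``."""
    if cv == 0:
        return np.full(size, mean)
    sigma_sq = np.log1p(cv * cv)
    mu = np.log(mean) - sigma_sq / 2
    return rng.lognormal(mu, np.sqrt(sigma_sq), size=size)


def generate_dataset(
    specs=DEFAULT_CHROMOSOMES,
    n_lines: int = 6,
    n_extracts: int = 3,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate a copies-per-cell table over lines x timepoints x extracts.

    Per gene, each line gets a lognormal true copy number around
    ``true_mean``; the final timepoint multiplies that truth by
    ``final_shift``; each extract observes the truth with multiplicative
    lognormal noise.  Row count is ``n_lines * 2 * n_extracts * len(specs)``.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for spec in specs:
        line_truth = _lognormal(spec.true_mean, spec.among_line_cv, n_lines, rng)
        for li in range(n_lines):
            for time, shift in (("initial", 1.0), ("final", spec.final_shift)):
                noise = _lognormal(1.0, spec.measurement_cv, n_extracts, rng)
                for ei in range(n_extracts):
                    rows.append(
                        (f"L{li + 1}", time, ei + 1, spec.gene, line_truth[li] * shift * noise[ei])
                    )
    return pd.DataFrame(rows, columns=list(DATASET_COLUMNS))


def ddct_copies(delta_delta_ct: float, reference_copies: float = REFERENCE_ATUBP1_COPIES) -> float:
    """Copies per cell from a comparative ddCt: reference * 2**(-ddCt).

    Assumes 100% amplification efficiency (one doubling per cycle); the
    reference default is the ~1345-copy alpha-tubulin P1 calibrator.
    """
    if reference_copies <= 0:
        raise ValueError("reference_copies must be positive")
    return reference_copies * 2.0 ** (-delta_delta_ct)


def ddct_from_copies(copies: float, reference_copies: float = REFERENCE_ATUBP1_COPIES) -> float:
    """Inverse of :func:`ddct_copies`."""
    if copies <= 0 or reference_copies <= 0:
        raise ValueError("copy numbers must be positive")
    return -float(np.log2(copies / reference_copies))


def per_line_means(table: pd.DataFrame, gene: str, time: str) -> pd.Series:
    """Mean copies per cell per line (over extracts) at one timepoint."""
    sub = table[(table["Gene"] == gene) & (table["Time"] == time)]
    if sub.empty:
        raise KeyError(f"no records for gene {gene!r} at time {time!r}")
    return sub.groupby("Cell.line")["CNPC"].mean()


def estimate_start_params(table: pd.DataFrame, gene: str) -> tuple[float, float]:
    """Mean and sample variance of initial copy number across lines.

    Extract replicates are averaged within line first; the line-level
    means then give the (mean, variance) pair that seeds the simulated
    founder distribution.
    """
    means = per_line_means(table, gene, "initial")
    return float(means.mean()), float(means.var(ddof=1))


def write_dataset(table: pd.DataFrame, path) -> None:
    """Write the copies-per-cell table as CSV with the canonical header."""
    missing = set(DATASET_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"table is missing columns {sorted(missing)}")
    table.loc[:, list(DATASET_COLUMNS)].to_csv(path, index=False)


def read_dataset(path) -> pd.DataFrame:
    """Read a copies-per-cell CSV, validating schema and positivity."""
    table = pd.read_csv(path)
    missing = set(DATASET_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if (table["CNPC"] <= 0).any():
        bad = table.index[table["CNPC"] <= 0][:5]
        raise ValueError(f"{path}: nonpositive CNPC at rows {list(bad)}")
    return table


def load_config(path) -> dict:
    """Load a key-value (YAML) configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def specs_from_config(cfg: dict) -> tuple[ChromosomeSpec, ...]:
    """Build chromosome specs from a config mapping.

    Expects ``chromosomes:`` as a list of mappings with a ``gene`` key and
    any subset of the ChromosomeSpec fields; omitted fields fall back to
    the package defaults for that gene (or the dataclass defaults for a
    novel gene, in which case ``true_mean`` is required).
    """
    entries = cfg.get("chromosomes")
    if not entries:
        return DEFAULT_CHROMOSOMES
    defaults = {s.gene: s for s in DEFAULT_CHROMOSOMES}
    specs = []
    for entry in entries:
        gene = entry["gene"]
        fields = {k: v for k, v in entry.items() if k != "gene"}
        if gene in defaults:
            specs.append(replace(defaults[gene], **fields))
        else:
            specs.append(ChromosomeSpec(gene=gene, **fields))
    return tuple(specs)
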