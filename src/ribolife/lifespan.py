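"""Replicative-lifespan summaries and strain comparisons.

A replicative-lifespan assay records, per mother cell, the number of
daughter cells produced before senescence. Strains are summarized by
the mean division count and compared with the Wilcoxon rank-sum
(Mann-Whitney U) test; integer division counts routinely tie, so the
midrank normal approximation is the default at typical assay sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .stats import mann_whitney_u


@dataclass(frozen=True)
class LifespanAssay:
    strain: str
    divisions: Tuple[int, ...]

    def __init__(self, strain: str, divisions: Sequence[int]):
        divisions = tuple(int(d) for d in divisions)
        if not divisions:
            raise ValueError("assay needs at least one cell")
        if any(d < 0 for d in divisions):
            raise ValueError("division counts must be non-negative")
        object.__setattr__(self, "strain", strain)
        object.__setattr__(self, "divisions", divisions)

    @property
    def n(self) -> int:
        return len(self.divisions)


def read_lifespan_tsv(path: str | Path) -> Dict[str, LifespanAssay]:
    """Read a (strain, cell_id, divisions) TSV into per-strain assays."""
    df = pd.read_csv(path, sep="\t")
    for col in ("strain", "divisions"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    return {
        strain: LifespanAssay(strain, sub["divisions"].tolist())
        for strain, sub in df.groupby("strain")
    }


def mean_lifespan(assay: LifespanAssay) -> float:
    return float(np.mean(assay.divisions))


def percent_increase(mean_test: float, mean_ref: float) -> float:
    """Percent change of a test mean over a reference mean (directional)."""
    if mean_ref <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * (mean_test - mean_ref) / mean_ref


def lifespan_test(a: LifespanAssay, b: LifespanAssay) -> Tuple[float, float]:
    """Two-sided rank-sum comparison of two strains' division counts."""
    return mann_whitney_u(a.divisions, b.divisions, alternative="two-sided")


def survival_curve(assay: LifespanAssay) -> pd.DataFrame:
    """Fraction of mother cells still dividing as a function of divisions."""
    divs = np.asarray(assay.divisions)
    grid = np.arange(0, divs.max() + 2)
    alive = (divs[None, :] >= grid[:, None]).mean(axis=1)
    return pd.DataFrame({"divisions": grid, "fraction_alive": alive})
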