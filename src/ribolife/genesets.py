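"""Gene-set aggregation of fold-changes and category-shift tests.

"Mean fold-change" of a set is the arithmetic mean of member log2
fold-changes (the geometric mean of linear fold-changes); sets with
fewer than ``min_size`` measured members are rejected. Category shifts
(e.g. ribosomal proteins vs all other genes) are tested with a
two-sided Mann-Whitney U of member vs non-member log2 fold-changes.
Gene sets come from GMT files; no live database retrieval.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .stats import mann_whitney_u

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: Tuple[str, ...]

    def __init__(self, set_id: str, name: str, members: Iterable[str]):
        uniq = tuple(dict.fromkeys(members))  # preserve order, drop duplicates
        object.__setattr__(self, "set_id", set_id)
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members", uniq)

    @property
    def size(self) -> int:
        return len(self.members)


def read_gmt(path: str | Path) -> List[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(parts[0], parts[1], parts[2:]))
    if not sets:
        raise ValueError(f"no gene sets in {path}")
    return sets


def write_gmt(sets: Sequence[GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.name, *s.members]) + "\n")


def mean_set_foldchange(
    fc: pd.DataFrame, gene_set: GeneSet, min_size: int = 10, linear: bool = False
) -> Optional[float]:
    """Mean log2 fold-change over measured members, or None if rejected.

    ``linear=True`` averages linear fold-changes instead (arithmetic
    mean of 2**log2fc).
    """
    present = [g for g in gene_set.members if g in fc.index]
    if len(present) < min_size:
        logger.info(
            "set %s rejected: %d measured members < %d",
            gene_set.set_id, len(present), min_size,
        )
        return None
    vals = fc.loc[present, "log2fc"].to_numpy()
    if linear:
        return float(np.mean(np.power(2.0, vals)))
    return float(np.mean(vals))


def set_vs_rest_test(fc: pd.DataFrame, gene_set: GeneSet) -> Tuple[float, float]:
    """Two-sided Mann-Whitney U of member vs non-member log2 fold-changes."""
    members = set(gene_set.members)
    in_set = fc.index.isin(members)
    a = fc.loc[in_set, "log2fc"].to_numpy()
    b = fc.loc[~in_set, "log2fc"].to_numpy()
    if a.size == 0 or b.size == 0:
        raise ValueError("both member and non-member groups must be non-empty")
    return mann_whitney_u(a, b, alternative="two-sided")


def heatmap_matrix(
    fc_by_strain: Dict[str, pd.DataFrame],
    sets: Sequence[GeneSet],
    min_size: int = 10,
) -> pd.DataFrame:
    """Set x strain matrix of mean log2 fold-changes.

    Sets rejected (too few measured members) in any strain are dropped
    with a log entry.
    """
    rows: Dict[str, Dict[str, float]] = {}
    for s in sets:
        entry = {}
        for strain, fc in fc_by_strain.items():
            m = mean_set_foldchange(fc, s, min_size=min_size)
            if m is None:
                entry = None
                break
            entry[strain] = m
        if entry is None:
            logger.info("dropping set %s from heatmap", s.set_id)
            continue
        rows[s.set_id] = entry
    out = pd.DataFrame.from_dict(rows, orient="index", columns=list(fc_by_strain))
    out.index.name = "set_id"
    return out
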