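"""5'UTR-to-CDS (and uORF-to-CDS) ribosome occupancy ratios.

Reduced 5'UTR occupancy relative to the CDS — uORF skipping — is
quantified per gene as the ratio of aggregated, library-normalized
5'UTR (or uORF-union) footprint counts to CDS counts. Genes qualify
only when the raw aggregated counts exceed ``min_reads`` in both the
numerator region and the CDS in BOTH strains being compared; the
resulting paired ratio vectors are compared with a two-sided
Mann-Whitney U test, with the median paired log2 ratio shift as the
effect direction.
"""

from __future__ import annotations

import logging
from typing import Tuple

import numpy as np
import pandas as pd

from .stats import mann_whitney_u

logger = logging.getLogger(__name__)


def utr_cds_ratio(
    agg_a: pd.DataFrame,
    agg_b: pd.DataFrame,
    strain_a: str,
    strain_b: str,
    min_reads: int = 50,
    numerator_kind: str = "utr5",
) -> pd.DataFrame:
    """Paired per-gene occupancy ratios for two strains.

    ``agg_a``/``agg_b`` are aggregated region-count tables (one row per
    gene, raw and normalized columns) from
    :func:`ribolife.ribo.aggregate_replicates`. The inclusion filter is
    strict (> ``min_reads``) and operates on raw counts; ratios are
    computed on normalized counts.
    """
    if numerator_kind not in ("utr5", "uorf"):
        raise ValueError(f"bad numerator_kind {numerator_kind!r}")
    num_raw, num_norm = f"{numerator_kind}_raw", f"{numerator_kind}_norm"
    common = agg_a.index.intersection(agg_b.index)
    a = agg_a.loc[common]
    b = agg_b.loc[common]
    keep = (
        (a[num_raw] > min_reads) & (a["cds_raw"] > min_reads)
        & (b[num_raw] > min_reads) & (b["cds_raw"] > min_reads)
    )
    if not keep.any():
        logger.warning("no gene passes the >%d-read filter", min_reads)
    a, b = a[keep], b[keep]
    out = pd.DataFrame(
        {
            "strain_a": strain_a,
            "strain_b": strain_b,
            "numerator_kind": numerator_kind,
            f"ratio_{strain_a}": a[num_norm] / a["cds_norm"],
            f"ratio_{strain_b}": b[num_norm] / b["cds_norm"],
        },
        index=a.index,
    )
    out["log2_shift"] = np.log2(out[f"ratio_{strain_a}"] / out[f"ratio_{strain_b}"])
    return out


def compare_ratio_distributions(pairs: pd.DataFrame, min_genes: int = 10) -> Tuple[float, float, float]:
    """(U, two-sided p, median log2 shift) between the two strains' ratios."""
    if len(pairs) < min_genes:
        raise ValueError(f"only {len(pairs)} genes included (need >= {min_genes})")
    strain_a = pairs["strain_a"].iloc[0]
    strain_b = pairs["strain_b"].iloc[0]
    ra = pairs[f"ratio_{strain_a}"].to_numpy()
    rb = pairs[f"ratio_{strain_b}"].to_numpy()
    u, p = mann_whitney_u(ra, rb, alternative="two-sided")
    shift = float(np.median(pairs["log2_shift"]))
    return u, p, shift


def rank_extreme_genes(pairs: pd.DataFrame) -> pd.DataFrame:
    """Genes ordered by |log2 ratio shift|, largest change first.

    Exact ties break lexicographically by gene id.
    """
    out = pairs.copy()
    out["abs_log2_shift"] = out["log2_shift"].abs()
    # stable two-key sort: ascending gene id first, then descending |shift|
    out = out.sort_index(kind="mergesort").sort_values(
        "abs_log2_shift", ascending=False, kind="mergesort"
    )
    return out
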