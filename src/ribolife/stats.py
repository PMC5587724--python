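"""Expression statistics shared across the pipeline.

Count normalization uses the median-of-ratios size factor (a geometric-
mean reference, as in standard RNA-seq differential-expression tools);
fold-changes are pseudocounted log2 ratios of normalized condition
means, tested with a Welch t-test on log-transformed replicate values
and gated by Benjamini-Hochberg FDR. The module also provides the
Mann-Whitney U test (exact by enumeration for small tie-free samples,
otherwise normal approximation with midranks, tie correction and
continuity correction) which every distribution comparison in the
package delegates to.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

STATUS_UP = "up"
STATUS_DOWN = "down"
STATUS_UNCHANGED = "unchanged"
STATUS_LOW_DATA = "low_data"


@dataclass
class CountMatrix:
    """Gene x sample integer counts with a sample->condition mapping."""

    counts: pd.DataFrame  # index: gene ids, columns: sample ids
    conditions: Dict[str, str]  # sample id -> condition label

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        missing = set(self.counts.columns) - set(self.conditions)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    def samples_of(self, condition: str) -> List[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]

    def to_tsv(self, path) -> None:
        df = self.counts.copy()
        df.columns = [f"{s}|{self.conditions[s]}" for s in df.columns]
        df.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        samples, conds = [], {}
        for col in df.columns:
            sample, _, cond = col.partition("|")
            samples.append(sample)
            conds[sample] = cond
        df.columns = samples
        return cls(df, conds)


def size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios per-sample scaling factors.

    The reference is the per-gene geometric mean over samples, computed
    on rows with no zero count; each sample's factor is the median ratio
    of its counts to the reference. Falls back to total-count scaling
    (geometric mean normalized to 1) when no all-nonzero row exists.
    """
    counts = m.counts.to_numpy(dtype=float)
    nonzero = (counts > 0).all(axis=1)
    if not nonzero.any():
        logger.warning("no gene with nonzero counts in all samples; "
                       "falling back to total-count scaling")
        totals = counts.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("sample with zero total count")
        factors = totals / math.exp(np.mean(np.log(totals)))
    else:
        sub = counts[nonzero]
        ref = np.exp(np.mean(np.log(sub), axis=1))
        factors = np.median(sub / ref[:, None], axis=0)
    return pd.Series(factors, index=m.counts.columns, name="size_factor")


def normalized_counts(m: CountMatrix) -> pd.DataFrame:
    return m.counts / size_factors(m)


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    if n == 0:
        return np.array([])
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify_regulation(
    log2fc: float, q_value: float, fc_threshold: float = 2.0, fdr_threshold: float = 0.01
) -> str:
    """Strict >fc_threshold-fold and FDR<fdr_threshold significance gate."""
    lthr = math.log2(fc_threshold)
    if np.isnan(q_value):
        return STATUS_UNCHANGED
    if log2fc > lthr and q_value < fdr_threshold:
        return STATUS_UP
    if log2fc < -lthr and q_value < fdr_threshold:
        return STATUS_DOWN
    return STATUS_UNCHANGED


def fold_changes(
    m: CountMatrix,
    cond_a: str,
    cond_b: str,
    pseudocount: float = 0.5,
    min_total: int = 10,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.01,
) -> pd.DataFrame:
    """Per-gene log2 fold-change (B vs A), Welch p-value and BH q-value.

    Genes with total raw count below ``min_total`` are excluded from
    testing (``status == low_data``, p = q = 1). With a single replicate
    per condition only the fold-change is reported (p = q = NaN).
    """
    samples_a, samples_b = m.samples_of(cond_a), m.samples_of(cond_b)
    if not samples_a or not samples_b:
        raise ValueError(f"conditions {cond_a!r}/{cond_b!r} not both present")
    norm = normalized_counts(m)
    na = norm[samples_a].to_numpy()
    nb = norm[samples_b].to_numpy()
    mean_a, mean_b = na.mean(axis=1), nb.mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    total_raw = m.counts.to_numpy().sum(axis=1)
    low = total_raw < min_total

    n_rep = min(len(samples_a), len(samples_b))
    p = np.full(len(norm), np.nan)
    if n_rep >= 2:
        la, lb = np.log2(na + pseudocount), np.log2(nb + pseudocount)
        with np.errstate(invalid="ignore", divide="ignore"):
            res = sps.ttest_ind(lb, la, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
        # zero-variance groups: identical -> no evidence, different -> certain
        degenerate = np.isnan(p)
        p[degenerate & np.isclose(la.mean(axis=1), lb.mean(axis=1))] = 1.0
        p[degenerate & ~np.isclose(la.mean(axis=1), lb.mean(axis=1))] = 0.0
        p[low] = 1.0
        q = np.full(len(norm), 1.0)
        tested = ~low
        q[tested] = bh_fdr(p[tested])
    else:
        q = np.full(len(norm), np.nan)

    status = [
        STATUS_LOW_DATA if lo else classify_regulation(fc, qq, fc_threshold, fdr_threshold)
        for fc, qq, lo in zip(log2fc, q, low)
    ]
    return pd.DataFrame(
        {
            "gene_id": m.counts.index,
            "log2fc": log2fc,
            f"mean_{cond_a}": mean_a,
            f"mean_{cond_b}": mean_b,
            "p_value": p,
            "q_value": q,
            "status": status,
        }
    ).set_index("gene_id")


def translation_efficiency(ribo: pd.DataFrame, mrna: pd.DataFrame) -> pd.DataFrame:
    """TE fold-change: footprint fold-change divided by mRNA fold-change.

    On the log2 scale ``te_log2fc = ribo.log2fc - mrna.log2fc``. Genes
    present in only one table are dropped (logged).
    """
    common = ribo.index.intersection(mrna.index)
    dropped = len(ribo.index.symmetric_difference(mrna.index))
    if dropped:
        logger.info("translation_efficiency: %d genes present in only one assay", dropped)
    te = pd.DataFrame(
        {
            "ribo_log2fc": ribo.loc[common, "log2fc"],
            "mrna_log2fc": mrna.loc[common, "log2fc"],
        },
        index=common,
    )
    te["te_log2fc"] = te["ribo_log2fc"] - te["mrna_log2fc"]
    te.index.name = "gene_id"
    return te


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _rank_midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two-sided",
    exact_limit: int = 12,
) -> Tuple[float, float]:
    """Mann-Whitney U test (a.k.a. Wilcoxon rank-sum).

    Returns ``(U_a, p)`` where ``U_a`` counts (a > b) pairs plus half the
    ties. Exact p by enumeration of all labelings when
    ``len(a) + len(b) <= exact_limit`` and there are no ties; otherwise
    normal approximation with midranks, tie correction and a 0.5
    continuity correction. ``alternative`` is two-sided, 'greater'
    (a tends larger) or 'less'.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"bad alternative {alternative!r}")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = _rank_midranks(pooled)
    u_a = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(pooled)) < len(pooled)

    if not has_ties and n1 + n2 <= exact_limit:
        p = _exact_mwu_p(ranks, n1, u_a, alternative)
        return u_a, p

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u_a, 1.0
    sd = math.sqrt(var)
    if alternative == "two-sided":
        z = (abs(u_a - mu) - 0.5) / sd
        p = 2 * sps.norm.sf(max(z, 0.0))
    elif alternative == "greater":
        z = (u_a - mu - 0.5) / sd
        p = sps.norm.sf(z)
    else:
        z = (u_a - mu + 0.5) / sd
        p = sps.norm.cdf(z)
    return u_a, min(float(p), 1.0)


def _exact_mwu_p(ranks: np.ndarray, n1: int, u_obs: float, alternative: str) -> float:
    """Exact null distribution of U by enumerating all rank labelings."""
    n = len(ranks)
    base = n1 * (n1 + 1) / 2.0
    us = [sum(combo) - base for combo in itertools.combinations(ranks, n1)]
    total = len(us)
    n_le = sum(1 for u in us if u <= u_obs + 1e-9)
    n_ge = sum(1 for u in us if u >= u_obs - 1e-9)
    if alternative == "greater":
        return n_ge / total
    if alternative == "less":
        return n_le / total
    return min(1.0, 2.0 * min(n_le, n_ge) / total)
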