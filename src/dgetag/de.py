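"""Differential expression between two tag libraries via the Audic-Claverie exact test.

DGE tag sequencing yields a single count per gene per library, so
replicate-based dispersion models do not apply.  The classical SAGE/DGE
statistic conditions on the count ``x`` observed in library A (clean size
``N1``) and asks how surprising the count ``y`` in library B (size ``N2``)
is under equal relative abundance.  The conditional kernel is

    P(y | x) = (N2/N1)**y * (x+y)! / (x! * y! * (1 + N2/N1)**(x+y+1))

which is a negative binomial with ``x+1`` successes and success
probability ``N1/(N1+N2)``.  Both tails are summed directly in log space
and the two-sided p-value is ``min(1, 2*min(lower, upper))``.

To make the statistic exactly symmetric under exchanging the two
libraries, the tails are always evaluated in the canonical orientation in
which the higher-rate library plays the role of ``y``; the observed count
is included in both tails, so ``p(x=0, y=20, N1=N2) = 2**-19``.

Genes are called differentially expressed when the Benjamini-Hochberg
FDR falls below ``alpha`` (default 0.001) and the absolute log2 TPM ratio
exceeds ``lfc_min`` (default 1), mirroring standard DGE screening
practice.  Each pairwise screen yields a "subtractive library": the set
of significant genes with their direction of change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "CALL_UP_A",
    "CALL_UP_B",
    "CALL_NS",
    "SubtractiveLibrary",
    "ac_pvalue",
    "log2_ratio",
    "bh_adjust",
    "compare_libraries",
]

CALL_UP_A = "up_in_A"
CALL_UP_B = "up_in_B"
CALL_NS = "not_significant"

#: smallest positive double; p-values are clamped into (0, 1]
_TINY = 5e-324


def _log_kernel(x: int, log_r: float, log1p_r: float, ys: np.ndarray) -> np.ndarray:
    """Log of P(ys | x) for ratio r = N2/N1 given as (log r, log(1+r))."""
    return (
        ys * log_r
        + gammaln(x + ys + 1.0)
        - gammaln(x + 1.0)
        - gammaln(ys + 1.0)
        - (x + ys + 1.0) * log1p_r
    )


def _tails(x: int, y: int, r: float) -> tuple[float, float]:
    """(P(Y <= y | x), P(Y >= y | x)) by direct log-space summation."""
    log_r = math.log(r)
    log1p_r = math.log1p(r)
    lower_ys = np.arange(0, y + 1, dtype=np.float64)
    lower = float(np.exp(logsumexp(_log_kernel(x, log_r, log1p_r, lower_ys))))
    # upper tail summed from y to a bound past which the remainder is
    # negligible: the kernel is NB with mean (x+1) r and variance
    # (x+1) r (1+r), and beyond the bulk the terms decay geometrically
    # with ratio r/(1+r), so 60/log1p(1/r) extra terms cover > 25 decades
    mean = (x + 1.0) * r
    sd = math.sqrt((x + 1.0) * r * (1.0 + r))
    hi = int(max(mean + 8.0 * sd, y) + 60.0 / math.log1p(1.0 / r) + 20.0)
    upper_ys = np.arange(y, hi + 1, dtype=np.float64)
    upper = float(np.exp(logsumexp(_log_kernel(x, log_r, log1p_r, upper_ys))))
    return min(lower, 1.0), min(upper, 1.0)


def ac_pvalue(x: int, n1: float, y: int, n2: float) -> float:
    """Two-sided exact p-value for tag counts ``x``/``N1`` vs ``y``/``N2``.

    Parameters
    ----------
    x, y
        Non-negative integer tag counts of one gene in the two libraries.
    n1, n2
        Positive clean-library sizes the counts were drawn from.

    Returns
    -------
    float
        p in (0, 1], invariant under swapping ``(x, n1)`` with ``(y, n2)``.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError(f"library sizes must be positive, got N1={n1}, N2={n2}")
    if x < 0 or y < 0:
        raise ValueError(f"counts must be non-negative, got x={x}, y={y}")
    x = int(x)
    y = int(y)
    # canonical orientation: the library with the higher per-tag rate is
    # the query side, which makes the statistic exchange-symmetric
    if (y * n1 < x * n2) or (y * n1 == x * n2 and y < x):
        x, y = y, x
        n1, n2 = n2, n1
    lower, upper = _tails(x, y, n2 / n1)
    p = 2.0 * min(lower, upper)
    return float(min(max(p, _TINY), 1.0))


def log2_ratio(x: int, n1: float, y: int, n2: float, zero_floor: int = 1) -> float:
    """log2 of the TPM ratio of library B over library A.

    Zero counts are floored at ``zero_floor`` (>= 1) so presence/absence
    genes still receive a finite, callable ratio.
    """
    if zero_floor < 1:
        raise ValueError(f"zero_floor must be >= 1, got {zero_floor}")
    if n1 <= 0 or n2 <= 0:
        raise ValueError(f"library sizes must be positive, got N1={n1}, N2={n2}")
    if x < 0 or y < 0:
        raise ValueError(f"counts must be non-negative, got x={x}, y={y}")
    return float(math.log2((max(y, zero_floor) / n2) / (max(x, zero_floor) / n1)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} p_(j) * m / j on the sorted p-values, capped at 1.
    Tied p-values receive identical q-values.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=np.float64)
    q[order] = q_sorted
    return q


@dataclass
class SubtractiveLibrary:
    """Significant genes of one ordered pairwise comparison.

    ``pair`` is (baseline condition A, other condition B); ``records``
    holds only the significant genes, ``table`` every tested gene.
    """

    pair: tuple[str, str]
    records: pd.DataFrame
    table: pd.DataFrame = field(repr=False, default=None)

    @property
    def genes(self) -> set[str]:
        return set(self.records["gene_id"])

    def genes_with_call(self, call: str) -> set[str]:
        return set(self.records.loc[self.records["call"] == call, "gene_id"])

    def direction_of(self, gene_id: str) -> str:
        row = self.records.loc[self.records["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(gene_id)
        return str(row["call"].iloc[0])


_RECORD_COLUMNS = [
    "gene_id", "x", "y", "n1", "n2", "log2_ratio", "p_value", "fdr", "call",
]


def compare_libraries(
    table,
    cond_a: str,
    cond_b: str,
    alpha: float = 0.001,
    lfc_min: float = 1.0,
    zero_floor: int = 1,
) -> SubtractiveLibrary:
    """Screen ``cond_b`` against baseline ``cond_a`` of a GeneCountTable.

    Genes with zero counts in both libraries are excluded before the
    FDR adjustment; calls require both ``fdr < alpha`` and
    ``|log2_ratio| > lfc_min``.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    for cond in (cond_a, cond_b):
        if cond not in table.conditions:
            raise KeyError(f"unknown condition {cond!r}; have {table.conditions}")
    n1 = float(table.library_sizes[cond_a])
    n2 = float(table.library_sizes[cond_b])
    counts = table.counts
    xs = counts[cond_a].to_numpy()
    ys = counts[cond_b].to_numpy()
    tested = (xs + ys) >= 1
    gene_ids = counts.index.to_numpy()[tested]
    xs = xs[tested]
    ys = ys[tested]

    pvals = np.array([ac_pvalue(int(x), n1, int(y), n2) for x, y in zip(xs, ys)])
    lfcs = np.array(
        [log2_ratio(int(x), n1, int(y), n2, zero_floor) for x, y in zip(xs, ys)]
    )
    fdr = bh_adjust(pvals) if pvals.size else np.array([])

    calls = np.full(len(gene_ids), CALL_NS, dtype=object)
    sig = fdr < alpha
    calls[sig & (lfcs > lfc_min)] = CALL_UP_B
    calls[sig & (lfcs < -lfc_min)] = CALL_UP_A

    full = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "x": xs.astype(int),
            "y": ys.astype(int),
            "n1": n1,
            "n2": n2,
            "log2_ratio": lfcs,
            "p_value": pvals,
            "fdr": fdr,
            "call": calls,
        },
        columns=_RECORD_COLUMNS,
    )
    records = full[full["call"] != CALL_NS].reset_index(drop=True)
    return SubtractiveLibrary(pair=(cond_a, cond_b), records=records, table=full)
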