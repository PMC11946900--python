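"""FEST-style expanded-TCR-clone calling.

The functional expansion of specific T cells (FEST/MANAFEST) assay detects
antigen-reactive T cells as CDR3B clonotypes that expand in a
peptide-stimulated culture relative to a cytokine-only control from the
matched timepoint.  The caller works on the 3,000 most abundant clones of
each sample (with a whole-tie-group rule at the rank-3,000 boundary), tests
each clone's 2x2 count table by Fisher's exact test, corrects across clones
by Benjamini-Hochberg, and calls a clone significantly expanded when the
odds ratio exceeds 10, Q < 0.01, the test count reaches 500 copies and the
enrichment is in the test direction.  Expansion from absence (zero control
copies) is the assay's canonical positive and yields an infinite odds
ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class RepertoireSample:
    """One TCR-seq sample: CDR3B -> template count."""

    sample_id: str
    condition: str
    timepoint: float
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.counts.values()):
            raise ValueError(f"{self.sample_id}: stored clone counts must be >= 1")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class ExpansionCall:
    """Per-clone test-vs-control statistics and the significance verdict."""

    cdr3b: str
    test_count: int
    control_count: int
    test_total: int
    control_total: int
    odds_ratio: float
    p_value: float
    q_value: float
    significant: bool


def select_top_clones(sample: RepertoireSample, n: int = 3000) -> RepertoireSample:
    """Keep the ``n`` most abundant clones, handling ties at the boundary.

    Where several clones share the count at rank ``n``, the whole tie group
    is kept or dropped together, whichever leaves a clone number closer to
    ``n`` (ties broken toward keeping more).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(sample.counts) <= n:
        return sample
    ordered = sorted(sample.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    boundary = ordered[n - 1][1]
    n_ge = sum(1 for _, c in ordered if c >= boundary)
    n_gt = sum(1 for _, c in ordered if c > boundary)
    keep = n_ge if abs(n_ge - n) <= abs(n_gt - n) else n_gt
    kept = dict(ordered[:keep])
    return RepertoireSample(sample.sample_id, sample.condition, sample.timepoint, kept)


def call_expansions(
    test: RepertoireSample,
    control: RepertoireSample,
    or_threshold: float = 10.0,
    q_threshold: float = 0.01,
    min_copies: int = 500,
    min_count: int = 0,
) -> list[ExpansionCall]:
    """Call significantly expanded clones in ``test`` versus ``control``.

    Each clone in the union of the two (pre-selected) repertoires gets a
    2x2 table (clone count vs remaining reads, test vs control), a sample
    odds ratio (infinite when the control count is zero), a two-sided
    Fisher exact P, and a BH Q over all tested clones.  Significance
    requires OR > ``or_threshold``, Q < ``q_threshold``, a test count of at
    least ``min_copies`` and enrichment in the test direction.

    ``min_count`` optionally drops clones below that count in both samples
    before testing.  Calls are sorted by (Q, -test_count, cdr3b).
    """
    if not test.counts or not control.counts:
        raise ValueError("empty repertoire")
    if test.timepoint != control.timepoint:
        warnings.warn(
            f"test timepoint {test.timepoint} != control timepoint "
            f"{control.timepoint}; FEST controls should be timepoint-matched",
            stacklevel=2)

    t_total, c_total = test.total, control.total
    clones = sorted(set(test.counts) | set(control.counts))
    if min_count > 0:
        clones = [cl for cl in clones
                  if max(test.counts.get(cl, 0), control.counts.get(cl, 0)) >= min_count]

    records = []
    for cl in clones:
        a = test.counts.get(cl, 0)
        c = control.counts.get(cl, 0)
        table = [[a, t_total - a], [c, c_total - c]]
        p = float(scipy.stats.fisher_exact(table, alternative="two-sided").pvalue)
        if c == 0:
            odds = float("inf") if a > 0 else float("nan")
        else:
            odds = (a * (c_total - c)) / ((t_total - a) * c)
        records.append((cl, a, c, odds, p))

    pvals = np.array([r[4] for r in records])
    qvals = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else np.array([])

    calls = []
    for (cl, a, c, odds, p), q in zip(records, qvals):
        enriched = a / t_total > c / c_total
        significant = (odds > or_threshold and q < q_threshold
                       and a >= min_copies and enriched)
        calls.append(ExpansionCall(cl, a, c, t_total, c_total, odds,
                                   p, float(q), bool(significant)))
    calls.sort(key=lambda e: (e.q_value, -e.test_count, e.cdr3b))
    return calls


def fold_change_detected(n_post: int, n_pre: int) -> float:
    """Fold change in detected clone numbers with the zero-baseline
    convention: an undetected baseline counts as 1, so (22, 0) -> 22."""
    if n_post < 0 or n_pre < 0:
        raise ValueError("counts must be >= 0")
    return n_post / max(n_pre, 1)


def threshold_sweep(
    test: RepertoireSample,
    control: RepertoireSample,
    min_copies_grid: Sequence[int],
    or_threshold: float = 10.0,
    q_threshold: float = 0.01,
) -> pd.DataFrame:
    """Significant-clone counts across a sliding min-copies threshold.

    OR and Q thresholds stay fixed; since P and Q do not depend on the
    copy filter, the count is monotone non-increasing in ``min_copies``.
    """
    if not min_copies_grid:
        raise ValueError("empty threshold grid")
    calls = call_expansions(test, control, or_threshold, q_threshold, min_copies=0)
    rows = []
    for g in min_copies_grid:
        n = sum(1 for c in calls if c.significant and c.test_count >= g)
        rows.append((g, n))
    return pd.DataFrame(rows, columns=["min_copies", "n_significant"])
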