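"""Cohort-style clonality and persistence analyses.

Single biopsies can suffer an "illusion of clonality": a regional selective
sweep makes a subclonal mutation look clonal locally.  Because genome
doubling is typically an early truncal event, mutations timed pre-WGD from a
single region are enriched for true tumor-wide clonality and, sitting on
multiple DNA copies, are harder to lose in metastatic transition.  The
functions here quantify both effects on timed variant sets: per-region
proportions of pre-WGD mutations that are tumor-clonal (with cohort
median/IQR), pre- vs post-WGD persistence in metastases, clonal-driver
timing tallies, and the two-sided Fisher exact tests used for the
associated contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .timing import RegionProfile, proportion_ci


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 count table; rows are groups, columns outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class MutationAnnotation:
    """Tumor-level annotation of one variant for cohort analyses."""

    variant_id: str
    timing: str  # pre | post | unclear | non_wgd
    clonality: str  # clonal | subclonal
    present_in_regions: set[str] = field(default_factory=set)
    present_in_metastases: set[str] = field(default_factory=set)


def fisher_exact_two_sided(table: ContingencyTable2x2) -> tuple[float, float]:
    """Two-sided Fisher exact P and odds ratio for a 2x2 table.

    P is the exact hypergeometric two-sided value: the sum over tables with
    the observed margins whose point probability does not exceed the
    observed table's.  The conditional (maximum-likelihood) odds ratio is
    returned, infinite when a zero cell forces it.
    """
    if table.total == 0:
        raise ValueError("empty table")
    res = scipy.stats.fisher_exact(
        [[table.a, table.b], [table.c, table.d]], alternative="two-sided")
    odds = scipy.stats.contingency.odds_ratio(
        [[table.a, table.b], [table.c, table.d]], kind="conditional")
    return float(res.pvalue), float(odds.statistic)


def infer_clonality_simple(
    variant_tables: Mapping[str, pd.DataFrame],
    timing_calls: Mapping[str, pd.DataFrame],
    regions: Mapping[str, RegionProfile],
    segments_total_cn: Mapping[str, Mapping[str, int]],
    ccf_threshold: float = 0.9,
    min_alt: int = 2,
    confidence: float = 0.95,
) -> dict[str, str]:
    """Simplified tumor-level clonality from multi-region presence and CCF.

    A variant is called clonal iff it is present (``alt_count >= min_alt``)
    in every region and, in each region, the upper confidence bound of its
    cancer-cell fraction reaches ``ccf_threshold``.  The CCF transform is
    ``vaf * (purity * CN_total + 2(1 - purity)) / (purity * multiplicity)``
    with the point-estimate integer copy-number state as multiplicity; the
    upper bound propagates the Wilson upper VAF limit through the same
    transform.  This is a stand-in for full phylogenetic clonality and needs
    at least two regions.

    ``segments_total_cn`` maps region_id -> variant_id -> local total copy
    number.  Returns variant_id -> "clonal" | "subclonal".
    """
    if len(regions) < 2:
        raise ValueError("clonality inference needs at least 2 regions")

    cn_point: dict[str, dict[str, int]] = {}
    for rid, calls in timing_calls.items():
        cn_point[rid] = dict(zip(calls["variant_id"], calls["cn_var_point"]))

    presence: dict[str, set[str]] = {}
    ccf_ok: dict[str, bool] = {}
    for rid, table in variant_tables.items():
        prof = regions[rid]
        for rec in table.itertuples(index=False):
            vid = str(rec.variant_id)
            if rec.alt_count >= min_alt:
                presence.setdefault(vid, set()).add(rid)
            total_cn = segments_total_cn[rid].get(vid, 2)
            mult = max(cn_point.get(rid, {}).get(vid, 1), 1)
            _, vaf_high = proportion_ci(int(rec.alt_count), int(rec.depth), confidence)
            ccf_high = vaf_high * (prof.purity * total_cn + 2 * (1 - prof.purity)) \
                / (prof.purity * mult)
            ok = ccf_high >= ccf_threshold
            ccf_ok[vid] = ccf_ok.get(vid, True) and ok

    all_regions = set(regions)
    out = {}
    for vid in set().union(*(set(t["variant_id"].astype(str)) for t in variant_tables.values())):
        ubiquitous = presence.get(vid, set()) == all_regions
        out[vid] = "clonal" if (ubiquitous and ccf_ok.get(vid, False)) else "subclonal"
    return out


def annotations_from_calls(
    timing_calls: Mapping[str, pd.DataFrame],
    variant_tables: Mapping[str, pd.DataFrame],
    regions: Mapping[str, RegionProfile],
    clonality: Mapping[str, str],
    met_presence: Mapping[str, set[str]] | None = None,
    min_alt: int = 2,
) -> dict[str, MutationAnnotation]:
    """Tumor-level MutationAnnotations from per-region timing calls.

    Timing aggregates across regions with the same conservative precedence
    as multi-region driver timing: presence in an undoubled region of a
    subclonal-WGD tumor forces pre; otherwise any-pre > all-post > unclear
    over the regions where the variant is present.  Presence means
    ``alt_count >= min_alt``.
    """
    presence: dict[str, set[str]] = {}
    for rid, table in variant_tables.items():
        for rec in table.itertuples(index=False):
            if rec.alt_count >= min_alt:
                presence.setdefault(str(rec.variant_id), set()).add(rid)

    wgd_rids = {rid for rid, r in regions.items() if r.n_wgd >= 1}
    non_wgd_rids = set(regions) - wgd_rids
    subclonal_wgd = bool(wgd_rids) and bool(non_wgd_rids)

    timing_by_variant: dict[str, dict[str, str]] = {}
    for rid, calls in timing_calls.items():
        for rec in calls.itertuples(index=False):
            timing_by_variant.setdefault(str(rec.variant_id), {})[rid] = rec.timing

    out = {}
    for vid, per_region in timing_by_variant.items():
        pres = presence.get(vid, set())
        votes = [t for rid, t in per_region.items()
                 if rid in pres and t in ("pre", "post", "unclear")]
        if subclonal_wgd and pres & non_wgd_rids:
            agg = "pre"
        elif not wgd_rids:
            agg = "non_wgd"
        elif not votes:
            agg = "unclear"
        elif "pre" in votes:
            agg = "pre"
        elif all(v == "post" for v in votes):
            agg = "post"
        else:
            agg = "unclear"
        out[vid] = MutationAnnotation(
            vid, agg, clonality.get(vid, "subclonal"), pres,
            set(met_presence.get(vid, set())) if met_presence else set())
    return out


def region_level_preWGD_clonality(
    annotations: Mapping[str, MutationAnnotation],
    timing_calls: Mapping[str, pd.DataFrame],
) -> tuple[pd.DataFrame, float, tuple[float, float], int]:
    """Per-region proportion of pre-WGD-classified mutations that are
    tumor-level clonal, with the cohort median and IQR.

    Regions with no pre-WGD calls are excluded from the summary and counted.
    Returns ``(per_region_table, median, (q1, q3), n_excluded_regions)``.
    """
    rows = []
    n_excluded = 0
    for rid, calls in timing_calls.items():
        pre = calls[calls["timing"] == "pre"]
        if len(pre) == 0:
            n_excluded += 1
            continue
        clonal = sum(annotations[v].clonality == "clonal" for v in pre["variant_id"])
        rows.append((rid, len(pre), clonal / len(pre)))
    if not rows:
        raise ValueError("no region has any pre-WGD call")
    table = pd.DataFrame(rows, columns=["region_id", "n_pre_wgd", "proportion_clonal"])
    props = table["proportion_clonal"].to_numpy()
    q1, med, q3 = np.percentile(props, [25, 50, 75])
    return table, float(med), (float(q1), float(q3)), n_excluded


def metastasis_persistence(
    annotations: Mapping[str, MutationAnnotation],
    all_metastases: set[str],
    all_primary_regions: set[str],
) -> dict:
    """Pre- vs post-WGD persistence of primary-ubiquitous variants in
    metastases.

    Restricted to variants present in every primary region; a variant
    persists if it is present in ALL metastases.  Returns the per-class
    fractions, the 2x2 table (pre/post x retained/not) and its Fisher P.
    Unclear- and non-WGD-timed variants are excluded.
    """
    if not all_metastases:
        raise ValueError("no metastases")
    counts = {"pre": [0, 0], "post": [0, 0]}  # [retained, lost]
    for ann in annotations.values():
        if ann.timing not in counts:
            continue
        if ann.present_in_regions != all_primary_regions:
            continue
        retained = all_metastases <= ann.present_in_metastases
        counts[ann.timing][0 if retained else 1] += 1
    table = ContingencyTable2x2(counts["pre"][0], counts["pre"][1],
                                counts["post"][0], counts["post"][1])
    fractions = {
        t: (c[0] / (c[0] + c[1]) if c[0] + c[1] else float("nan"))
        for t, c in counts.items()}
    p = fisher_exact_two_sided(table)[0] if table.total > 0 else float("nan")
    return {"table": table, "fractions": fractions, "fisher_p": p}


def driver_timing_tally(driver_timings: Sequence[str]) -> pd.DataFrame:
    """Counts and percentages of pre/post/unclear among clonal driver calls."""
    if not driver_timings:
        raise ValueError("no driver calls")
    categories = ["pre", "post", "unclear"]
    timed = [t for t in driver_timings if t in categories]
    rows = []
    for cat in categories:
        n = sum(t == cat for t in timed)
        rows.append((cat, n, 100.0 * n / len(timed) if timed else 0.0))
    return pd.DataFrame(rows, columns=["timing", "n", "percent"])
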