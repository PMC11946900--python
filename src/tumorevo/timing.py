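"""Timing somatic mutations relative to whole-genome doubling (WGD).

A mutation that arises before a genome doubling is carried on every copy of
the duplicated allele (multiplicity >= 2 in a once-doubled lineage), while a
mutation arising afterwards sits on a single copy.  Given a variant's read
counts, the local allele-specific copy number and the sample purity, the
functions here recover the integer copy-number state of the variant, decide
which parental allele it tracks, and classify it as ``pre``, ``post`` or
``unclear`` relative to the first WGD event.  Classification is made
deliberately conservative by running it at both ends of a binomial
confidence interval on the VAF: if the two ends disagree, the call is
``unclear``.

Single-region calls use both interval ends; multi-region driver timing uses
the upper end only (to avoid falsely calling an event post-WGD) together
with a subclonal-WGD override: a variant present in a region that never
doubled must predate the doubling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

Timing = Literal["pre", "post", "unclear", "non_wgd"]
Allele = Literal["major", "minor", "undetermined"]

# reason codes carried on every TimingCall
NO_WGD_REGION = "NO_WGD_REGION"
LOH_MAJOR_TRACK = "LOH_MAJOR_TRACK"
SINGLE_COPY_ALLELE = "SINGLE_COPY_ALLELE"
SINGLE_COPY_VARIANT = "SINGLE_COPY_VARIANT"
MULTI_COPY_VARIANT = "MULTI_COPY_VARIANT"
AMBIGUOUS_SECOND_WGD = "AMBIGUOUS_SECOND_WGD"
BOUND_DISAGREEMENT = "BOUND_DISAGREEMENT"
NO_SEGMENT = "NO_SEGMENT"
ZERO_COPY_SEGMENT = "ZERO_COPY_SEGMENT"
NON_WGD_REGION_PRESENCE = "NON_WGD_REGION_PRESENCE"


@dataclass(frozen=True)
class VariantObservation:
    """Read evidence for one somatic variant in one sample."""

    variant_id: str
    chrom: str
    pos: int  # 1-based
    alt_count: int
    depth: int

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError(f"{self.variant_id}: depth must be > 0")
        if not 0 <= self.alt_count <= self.depth:
            raise ValueError(f"{self.variant_id}: need 0 <= alt_count <= depth")

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth


@dataclass(frozen=True)
class CopyNumberSegment:
    """Allele-specific integer copy number over a 0-based half-open interval."""

    chrom: str
    start: int
    end: int
    major_cn: int
    minor_cn: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"segment {self.chrom}:{self.start}-{self.end}: end <= start")
        if self.minor_cn < 0 or self.major_cn < self.minor_cn:
            raise ValueError(
                f"segment {self.chrom}:{self.start}-{self.end}: need major_cn >= minor_cn >= 0"
            )

    @property
    def total_cn(self) -> int:
        return self.major_cn + self.minor_cn

    def contains(self, chrom: str, pos: int) -> bool:
        """True if the 1-based position falls inside this segment."""
        return chrom == self.chrom and self.start < pos <= self.end


@dataclass(frozen=True)
class RegionProfile:
    """Purity and genome-doubling annotation for one tumor region."""

    region_id: str
    purity: float
    n_wgd: int

    def __post_init__(self) -> None:
        if not 0 < self.purity <= 1:
            raise ValueError(f"{self.region_id}: purity must be in (0, 1]")
        if self.n_wgd not in (0, 1, 2):
            raise ValueError(f"{self.region_id}: n_wgd must be 0, 1 or 2")


@dataclass(frozen=True)
class TimingCall:
    """Pre/post/unclear-WGD classification of one variant in one region."""

    variant_id: str
    region_id: str
    tracked_allele: Allele
    cn_var_point: int
    cn_var_low: int
    cn_var_high: int
    timing: Timing
    reason: str


def proportion_ci(alt_count: int, depth: int, confidence: float = 0.95) -> tuple[float, float]:
    """Two-sided Wilson score interval with continuity correction for a VAF.

    This is the confidence interval reported by the standard two-sided
    one-sample proportion test (R ``prop.test`` with its default continuity
    correction).  Bounds are clamped to [0, 1]; zero successes give a lower
    bound of exactly 0 and ``alt_count == depth`` an upper bound of exactly 1.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not 0 <= alt_count <= depth:
        raise ValueError("need 0 <= alt_count <= depth")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")

    n = depth
    p = alt_count / n
    z = norm.ppf(1 - (1 - confidence) / 2)
    z2 = z * z
    denom = 2 * (n + z2)

    if alt_count == 0:
        low = 0.0
    else:
        rad = z2 - 2 - 1 / n + 4 * p * (n * (1 - p) + 1)
        low = (2 * n * p + z2 - 1 - z * math.sqrt(max(rad, 0.0))) / denom
    if alt_count == n:
        high = 1.0
    else:
        rad = z2 + 2 - 1 / n + 4 * p * (n * (1 - p) - 1)
        high = (2 * n * p + z2 + 1 + z * math.sqrt(max(rad, 0.0))) / denom

    return max(0.0, min(low, p)), min(1.0, max(high, p))


def variant_copy_number(vaf: float, purity: float, total_cn: int) -> float:
    """Real-valued copies per cancer cell implied by a VAF.

    Inverts the admixture relation for a diploid normal contaminant:
    ``vaf = m * purity / (purity * total_cn + 2 * (1 - purity))``, solving for
    the mutant-copy load ``m`` (multiplicity times cancer-cell fraction).
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    if total_cn < 1:
        raise ValueError("total_cn must be >= 1")
    return vaf * (purity * total_cn + 2.0 * (1.0 - purity)) / purity


def integer_cn_state(cn_real: float, total_cn: int) -> int:
    """Nearest-integer copy-number state, clamped to [1, total_cn].

    A called variant occupies at least one copy in the cells that carry it;
    rounding is half-away-from-zero to avoid directional bias.
    """
    if cn_real < 0:
        raise ValueError("cn_real must be >= 0")
    state = int(math.floor(cn_real + 0.5))
    return max(1, min(state, total_cn))


def classify_timing_point(
    cn_var: int,
    major_cn: int,
    minor_cn: int,
    n_wgd: int,
    single_copy_rule: str = "tracked",
) -> tuple[Timing, Allele, str]:
    """Classify an integer variant copy-number state against the local
    allele-specific copy number, relative to the FIRST genome doubling.

    Allele tracking: with LOH (minor_cn == 0) the variant must sit on the
    major allele, as it must when its copy number exceeds the minor count;
    otherwise it is assumed to track the minor allele.  A variant on an
    allele with a single copy cannot be timed.  In a once-doubled region a
    state >= 2 is pre-WGD and a state of 1 post-WGD; with two doublings only
    a state >= 4 is confidently pre (relative to the first event) and states
    2-3 are unclear.

    ``single_copy_rule`` selects the untimeable condition: ``"tracked"``
    (default) requires only the tracked allele to have >= 2 copies;
    ``"either"`` additionally refuses to time any variant on a segment
    retaining a single-copy allele (minor_cn == 1), the strictly more
    conservative reading.
    """
    if n_wgd < 1:
        raise ValueError("classify_timing_point requires n_wgd >= 1")
    if cn_var < 1:
        raise ValueError("cn_var must be >= 1")
    if cn_var > major_cn + minor_cn:
        raise ValueError("cn_var exceeds total copy number")
    if single_copy_rule not in ("tracked", "either"):
        raise ValueError("single_copy_rule must be 'tracked' or 'either'")

    loh = minor_cn == 0
    if loh or cn_var > minor_cn:
        allele: Allele = "major"
        allele_copies = major_cn
    else:
        allele = "minor"
        allele_copies = minor_cn

    if allele_copies <= 1:
        return "unclear", allele, SINGLE_COPY_ALLELE
    if single_copy_rule == "either" and not loh and (major_cn <= 1 or minor_cn <= 1):
        return "unclear", allele, SINGLE_COPY_ALLELE

    if n_wgd == 1:
        if cn_var >= 2:
            return "pre", allele, LOH_MAJOR_TRACK if loh else MULTI_COPY_VARIANT
        return "post", allele, SINGLE_COPY_VARIANT
    # two doublings: timed relative to the first event
    if cn_var >= 4:
        return "pre", allele, LOH_MAJOR_TRACK if loh else MULTI_COPY_VARIANT
    if cn_var == 1:
        return "post", allele, SINGLE_COPY_VARIANT
    return "unclear", allele, AMBIGUOUS_SECOND_WGD


def time_variant_single_region(
    obs: VariantObservation,
    seg: CopyNumberSegment | None,
    region: RegionProfile,
    confidence: float = 0.95,
    single_copy_rule: str = "tracked",
) -> TimingCall:
    """Single-biopsy timing call for one variant.

    The VAF's Wilson lower limit guards against false pre-WGD calls (it
    yields the minimum copy-number state) and the upper limit against false
    post-WGD calls (maximum state); if the two limits classify differently
    the call is ``unclear``.  Regions without genome doubling return
    ``non_wgd``; variants outside any segment, or on segments with no tumor
    copies, are reported ``unclear`` with a reason code rather than dropped.
    """
    if region.n_wgd == 0:
        return TimingCall(obs.variant_id, region.region_id, "undetermined", 1, 1, 1,
                          "non_wgd", NO_WGD_REGION)
    if seg is None or not seg.contains(obs.chrom, obs.pos):
        return TimingCall(obs.variant_id, region.region_id, "undetermined", 1, 1, 1,
                          "unclear", NO_SEGMENT)
    if seg.total_cn < 1 or seg.major_cn < 1:
        return TimingCall(obs.variant_id, region.region_id, "undetermined", 1, 1, 1,
                          "unclear", ZERO_COPY_SEGMENT)

    vaf_low, vaf_high = proportion_ci(obs.alt_count, obs.depth, confidence)
    states = {}
    for name, vaf in (("point", obs.vaf), ("low", vaf_low), ("high", vaf_high)):
        cn = integer_cn_state(variant_copy_number(vaf, region.purity, seg.total_cn), seg.total_cn)
        states[name] = (cn, *classify_timing_point(cn, seg.major_cn, seg.minor_cn,
                                                   region.n_wgd, single_copy_rule))

    cn_point, _, allele_point, _ = states["point"]
    cn_low, timing_low, allele_low, reason_low = states["low"]
    cn_high, timing_high, allele_high, reason_high = states["high"]

    allele: Allele = allele_low if allele_low == allele_high else "undetermined"
    if timing_low == timing_high:
        timing, reason = timing_low, reason_low
        if allele == "undetermined":
            allele = allele_point
    else:
        timing, reason = "unclear", BOUND_DISAGREEMENT
    return TimingCall(obs.variant_id, region.region_id, allele,
                      cn_point, cn_low, cn_high, timing, reason)


def _segment_for(segments: Sequence[CopyNumberSegment], chrom: str, pos: int):
    for seg in segments:
        if seg.contains(chrom, pos):
            return seg
    return None


def time_variants_table(
    variants: pd.DataFrame,
    segments: Sequence[CopyNumberSegment],
    region: RegionProfile,
    confidence: float = 0.95,
    single_copy_rule: str = "tracked",
) -> pd.DataFrame:
    """Vectorised-enough wrapper: one TimingCall row per variant table row.

    ``variants`` needs columns variant_id, chrom, pos, alt_count, depth.
    """
    seg_by_chrom: dict[str, list[CopyNumberSegment]] = {}
    for seg in segments:
        seg_by_chrom.setdefault(seg.chrom, []).append(seg)
    rows = []
    for rec in variants.itertuples(index=False):
        obs = VariantObservation(str(rec.variant_id), str(rec.chrom), int(rec.pos),
                                 int(rec.alt_count), int(rec.depth))
        seg = _segment_for(seg_by_chrom.get(obs.chrom, ()), obs.chrom, obs.pos)
        call = time_variant_single_region(obs, seg, region, confidence, single_copy_rule)
        rows.append(call)
    return pd.DataFrame([c.__dict__ for c in rows])


def time_driver_multi_region(
    observations: Mapping[str, VariantObservation | None],
    segments: Mapping[str, Sequence[CopyNumberSegment]],
    regions: Sequence[RegionProfile],
    confidence: float = 0.95,
    min_alt: int = 1,
    single_copy_rule: str = "tracked",
) -> tuple[Timing, str]:
    """Tumor-level driver timing from all regions.

    Uses only the upper VAF confidence limit (maximum copy-number state) so
    that an event is not falsely called post-WGD.  When the tumor's WGD is
    subclonal (a mix of doubled and undoubled regions), presence of the
    variant in an undoubled region forces a pre-WGD call: the mutation must
    predate a doubling it never experienced.  Otherwise, per-region upper
    bound calls aggregate as any-pre > all-post > unclear.

    ``observations`` maps region_id -> VariantObservation (None when the
    variant was not assayed in that region).
    """
    if not regions:
        raise ValueError("need at least one region")
    by_id = {r.region_id: r for r in regions}
    unknown = set(observations) - set(by_id)
    if unknown:
        raise ValueError(f"observations for unknown regions: {sorted(unknown)}")

    wgd_regions = [r for r in regions if r.n_wgd >= 1]
    non_wgd_regions = [r for r in regions if r.n_wgd == 0]

    if not wgd_regions:
        return "non_wgd", NO_WGD_REGION

    if non_wgd_regions:  # subclonal WGD at the tumor level
        for r in non_wgd_regions:
            obs = observations.get(r.region_id)
            if obs is not None and obs.alt_count >= min_alt:
                return "pre", NON_WGD_REGION_PRESENCE

    votes: list[Timing] = []
    for r in wgd_regions:
        obs = observations.get(r.region_id)
        if obs is None or obs.alt_count < min_alt:
            continue
        seg = _segment_for(segments.get(r.region_id, ()), obs.chrom, obs.pos)
        if seg is None or seg.major_cn < 1:
            votes.append("unclear")
            continue
        _, vaf_high = proportion_ci(obs.alt_count, obs.depth, confidence)
        cn_high = integer_cn_state(
            variant_copy_number(vaf_high, r.purity, seg.total_cn), seg.total_cn)
        timing, _, _ = classify_timing_point(cn_high, seg.major_cn, seg.minor_cn,
                                             r.n_wgd, single_copy_rule)
        votes.append(timing)

    if not votes:
        return "unclear", NO_SEGMENT
    if "pre" in votes:
        return "pre", MULTI_COPY_VARIANT
    if all(v == "post" for v in votes):
        return "post", SINGLE_COPY_VARIANT
    return "unclear", BOUND_DISAGREEMENT
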