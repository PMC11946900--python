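"""Synthetic multi-region tumors, plasma time courses and TCR repertoires.

Every downstream stage in this package is exercised against data with known
ground truth.  The generator here emulates the sampling design of a
multi-region sequencing study: a clone tree with a truncal root, per-region
clone mixtures (including regional selective sweeps that create an
"illusion of clonality"), clonal or subclonal whole-genome doubling,
arm-level allele-specific copy number with optional pre-WGD LOH, metastases
founded by single sampled clones, and binomial read sampling at configurable
depth and purity.  It is fixture engineering, deliberately separated from
the inference code it tests: no sequence-level reads, no mutational
signatures, no phasing.

Distributional choices (documented in docs/methods.md): Poisson depth with
floor 1; one copy-number segment per chromosome arm; geometric-like
power-law background clone sizes for repertoires.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .timing import CopyNumberSegment, RegionProfile

# one segment per autosomal chromosome arm; acrocentric p-arms omitted
_ARMS = [f"chr{c}{a}" for c in range(1, 23) for a in ("p", "q")
         if not (a == "p" and c in (13, 14, 15, 21, 22))]
_ARM_LENGTH = 100_000_000


class SimulationConfig(BaseModel):
    """Study conditions for one simulated tumor.

    Defaults reflect a multi-region NSCLC-like design: four regions at
    exome-like 400x depth, WGD in ~three quarters of tumors with 19% of the
    doubled tumors carrying a subclonal (rather than truncal) doubling.
    """

    model_config = ConfigDict(extra="forbid")

    n_regions: int = 4
    n_mutations: int = 500
    purity_range: tuple[float, float] = (0.4, 0.8)
    mean_depth: float = 400.0
    wgd_probability: float = 0.76
    subclonal_wgd_probability: float = 0.19
    second_wgd_probability: float = 0.14
    fraction_pre_wgd: float = 0.55
    n_subclones: int = 3
    n_metastases: int = 2
    loh_rate: float = 0.2
    truncal_fraction: float = 0.6
    met_segment_loss_rate: float = 0.3
    met_full_loss_rate: float = 0.02
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        lo, hi = self.purity_range
        if not (0 < lo <= hi <= 1):
            raise ValueError("purity_range must satisfy 0 < low <= high <= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        for name in ("wgd_probability", "subclonal_wgd_probability",
                     "second_wgd_probability", "fraction_pre_wgd", "loh_rate",
                     "truncal_fraction", "met_segment_loss_rate",
                     "met_full_loss_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.fraction_pre_wgd > 0 and self.wgd_probability == 0:
            raise ValueError("fraction_pre_wgd > 0 requires wgd_probability > 0")
        return self


@dataclass(frozen=True)
class MutationTruth:
    """Ground truth for one simulated mutation."""

    branch: int  # clone id whose branch carries the mutation
    true_timing: str  # pre | post | non_wgd
    true_clonality: str  # clonal | subclonal
    allele: str  # major | minor
    arm: str
    multiplicity_by_region: dict[str, int] = field(default_factory=dict)


@dataclass
class TumorTruth:
    """Everything needed to score downstream calls on one simulated tumor."""

    clone_tree: dict[int, int | None]  # clone -> parent (root maps to None)
    clone_ccf_by_region: dict[int, dict[str, float]]
    mutation_truth: dict[str, MutationTruth]
    region_wgd: dict[str, int]
    metastasis_membership: dict[str, int]
    mutation_in_metastases: dict[str, set[str]]
    wgd_clone: int | None  # clone at whose birth the (first) WGD happened

    def ancestors(self, clone: int) -> list[int]:
        """Path from clone up to the root, inclusive."""
        path = [clone]
        while (p := self.clone_tree[path[-1]]) is not None:
            path.append(p)
        return path

    def carriers(self, branch: int) -> set[int]:
        """Clones whose genome contains mutations on ``branch``."""
        return {c for c in self.clone_tree if branch in self.ancestors(c)}

    def to_json(self) -> str:
        payload = {
            "clone_tree": {str(k): v for k, v in self.clone_tree.items()},
            "clone_ccf_by_region": {str(k): v for k, v in self.clone_ccf_by_region.items()},
            "mutation_truth": {
                m: {"branch": t.branch, "true_timing": t.true_timing,
                    "true_clonality": t.true_clonality, "allele": t.allele,
                    "arm": t.arm, "multiplicity_by_region": t.multiplicity_by_region}
                for m, t in self.mutation_truth.items()},
            "region_wgd": self.region_wgd,
            "metastasis_membership": self.metastasis_membership,
            "mutation_in_metastases": {m: sorted(s) for m, s in self.mutation_in_metastases.items()},
            "wgd_clone": self.wgd_clone,
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def expected_vaf(multiplicity: int, ccf: float, purity: float, total_cn: int) -> float:
    """Mean VAF of a variant with the given multiplicity and cancer-cell
    fraction in a sample of the given purity and local total copy number."""
    if total_cn < 1:
        return 0.0
    return multiplicity * ccf * purity / (purity * total_cn + 2.0 * (1.0 - purity))


def _build_clone_tree(n_subclones: int, rng: np.random.Generator) -> dict[int, int | None]:
    tree: dict[int, int | None] = {0: None}
    for c in range(1, n_subclones + 1):
        tree[c] = int(rng.integers(0, c))
    return tree


def _clone_ccfs(tree: Mapping[int, int | None], regions: Sequence[str],
                rng: np.random.Generator) -> dict[int, dict[str, float]]:
    """Per-region CCFs respecting child <= parent; mixture of absence,
    regional sweeps (CCF equal to the parent's) and intermediate fractions."""
    ccf: dict[int, dict[str, float]] = {0: {r: 1.0 for r in regions}}
    for clone in sorted(tree):
        if clone == 0:
            continue
        parent = tree[clone]
        ccf[clone] = {}
        for r in regions:
            u = rng.random()
            if u < 0.35:
                frac = 0.0
            elif u < 0.55:
                frac = 1.0  # regional selective sweep of the parent lineage
            else:
                frac = rng.uniform(0.1, 0.9)
            ccf[clone][r] = frac * ccf[parent][r]

    # sibling CCFs cannot jointly exceed their parent's (disjoint cell
    # populations); rescale offending subtrees top-down
    children: dict[int, list[int]] = {c: [] for c in tree}
    for c, p in tree.items():
        if p is not None:
            children[p].append(c)

    def scale_subtree(clone: int, region: str, factor: float) -> None:
        ccf[clone][region] *= factor
        for ch in children[clone]:
            scale_subtree(ch, region, factor)

    for r in regions:
        for parent in sorted(tree):
            s = sum(ccf[ch][r] for ch in children[parent])
            if s > ccf[parent][r] and s > 0:
                f = ccf[parent][r] / s
                for ch in children[parent]:
                    scale_subtree(ch, r, f)
    return ccf


def simulate_tumor(config: SimulationConfig):
    """Simulate one multi-region tumor.

    Returns ``(truth, variant_tables, segment_tables, region_profiles)``
    where ``variant_tables`` maps region_id -> DataFrame with columns
    (sample, chrom, pos, ref, alt, alt_count, depth), ``segment_tables``
    maps region_id -> list of CopyNumberSegment, and ``region_profiles``
    maps region_id -> RegionProfile.  Identical config (including seed)
    gives byte-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    regions = [f"R{i + 1}" for i in range(config.n_regions)]

    tree = _build_clone_tree(config.n_subclones, rng)
    has_wgd = rng.random() < config.wgd_probability
    subclonal_wgd = False
    wgd_clone: int | None = None
    n_wgd_events = 0
    if has_wgd:
        n_wgd_events = 1
        subclonal_wgd = config.n_subclones > 0 and config.n_regions > 1 \
            and rng.random() < config.subclonal_wgd_probability
        if subclonal_wgd:
            wgd_clone = int(rng.integers(1, config.n_subclones + 1))
        else:
            wgd_clone = 0
            if rng.random() < config.second_wgd_probability:
                n_wgd_events = 2

    ccf = _clone_ccfs(tree, regions, rng)

    if has_wgd and subclonal_wgd:
        # force the carrier to sweep a proper nonempty subset of regions;
        # those regions are annotated as doubled, the rest stay undoubled
        k = int(rng.integers(1, config.n_regions))
        swept = set(rng.choice(config.n_regions, size=k, replace=False).tolist())
        path = _path_to_root(tree, wgd_clone)
        lineage = {c for c in tree
                   if wgd_clone in _path_to_root(tree, c)} | set(path)
        for i, r in enumerate(regions):
            if i in swept:
                # the doubled lineage sweeps the region: every cancer cell
                # there is a descendant of the carrier clone
                for c in reversed(path):
                    ccf[c][r] = 1.0
                for c in tree:
                    if c not in lineage:
                        ccf[c][r] = 0.0
            else:
                for c in tree:
                    if wgd_clone in _path_to_root(tree, c):
                        ccf[c][r] = 0.0
        region_wgd = {r: (1 if i in swept else 0) for i, r in enumerate(regions)}
    else:
        region_wgd = {r: n_wgd_events if has_wgd else 0 for r in regions}

    doubled_clones: set[int] = set()
    if has_wgd:
        doubled_clones = {c for c in tree if wgd_clone in _path_to_root(tree, c)}

    # arm-level copy number per region
    loh_arms = {arm for arm in _ARMS if rng.random() < config.loh_rate}
    segment_tables: dict[str, list[CopyNumberSegment]] = {}
    arm_cn: dict[tuple[str, str], tuple[int, int]] = {}
    for r in regions:
        k = region_wgd[r]
        segs = []
        for i, arm in enumerate(_ARMS):
            major = 2 ** k
            minor = 0 if arm in loh_arms else 2 ** k
            arm_cn[(r, arm)] = (major, minor)
            segs.append(CopyNumberSegment(arm, 0, _ARM_LENGTH, major, minor))
        segment_tables[r] = segs

    # mutation placement
    n_truncal = int(round(config.truncal_fraction * config.n_mutations)) \
        if config.n_subclones > 0 else config.n_mutations
    branches = [0] * n_truncal + [
        int(rng.integers(1, config.n_subclones + 1))
        for _ in range(config.n_mutations - n_truncal)]

    mutation_truth: dict[str, MutationTruth] = {}
    for i, branch in enumerate(branches):
        mid = f"mut{i:05d}"
        arm = _ARMS[int(rng.integers(0, len(_ARMS)))]
        allele = "major" if (arm in loh_arms or rng.random() < 0.5) else "minor"
        if not has_wgd:
            timing = "non_wgd"
        elif subclonal_wgd:
            path = _path_to_root(tree, wgd_clone)
            if branch in path and branch != wgd_clone:
                timing = "pre"  # strictly ancestral to the doubling
            elif branch == wgd_clone:
                timing = "pre" if rng.random() < config.fraction_pre_wgd else "post"
            elif branch in doubled_clones:
                timing = "post"
            else:
                timing = "non_wgd"
        else:
            if branch == 0:
                timing = "pre" if rng.random() < config.fraction_pre_wgd else "post"
            else:
                timing = "post"
        clonality = "clonal" if branch == 0 else "subclonal"

        mult_by_region: dict[str, int] = {}
        for r in regions:
            major, minor = arm_cn[(r, arm)]
            k = region_wgd[r]
            if ccf[branch][r] <= 0:
                mult_by_region[r] = 0
                continue
            allele_cn = major if allele == "major" else minor
            if allele_cn == 0:
                mult_by_region[r] = 0  # carried on an allele lost pre-WGD
            elif timing == "pre" and k >= 1:
                mult_by_region[r] = allele_cn  # doubled along with its allele
            else:
                mult_by_region[r] = 1
        mutation_truth[mid] = MutationTruth(branch, timing, clonality, allele, arm,
                                            mult_by_region)

    # metastases: each founded by one sampled clone; post-WGD single-copy
    # variants can be lost to further segment losses, multi-copy pre-WGD
    # variants only through (rare) full-allele loss
    met_membership: dict[str, int] = {}
    mut_in_mets: dict[str, set[str]] = {m: set() for m in mutation_truth}
    for j in range(config.n_metastases):
        met = f"M{j + 1}"
        founder = int(rng.integers(0, config.n_subclones + 1))
        met_membership[met] = founder
        founder_path = set(_path_to_root(tree, founder))
        # chromosomal instability in the metastasis: some arms lose one copy
        # of one parental allele; rarely an entire allele is lost
        lost_one = {arm: ("major" if rng.random() < 0.5 else "minor")
                    for arm in _ARMS if rng.random() < config.met_segment_loss_rate}
        lost_all = {arm: ("major" if rng.random() < 0.5 else "minor")
                    for arm in _ARMS if rng.random() < config.met_full_loss_rate}
        for mid, mt in mutation_truth.items():
            if mt.branch not in founder_path:
                continue  # private to a non-ancestral branch: absent
            base_mult = max(mt.multiplicity_by_region.values(), default=0)
            if base_mult == 0:
                continue  # carried on an allele already lost pre-WGD
            if lost_all.get(mt.arm) == mt.allele:
                continue  # whole allele lost: gone whatever the multiplicity
            if lost_one.get(mt.arm) == mt.allele and base_mult == 1 \
                    and rng.random() < 0.5:
                continue  # the single mutant copy was the one lost
            mut_in_mets[mid].add(met)

    truth = TumorTruth(tree, ccf, mutation_truth, region_wgd, met_membership,
                       mut_in_mets, wgd_clone if has_wgd else None)

    # read sampling
    purities = rng.uniform(config.purity_range[0], config.purity_range[1],
                           size=config.n_regions)
    region_profiles = {
        r: RegionProfile(r, float(purities[i]), region_wgd[r])
        for i, r in enumerate(regions)}

    arm_pos: dict[str, int] = {}
    positions: dict[str, tuple[str, int]] = {}
    for mid, mt in mutation_truth.items():
        arm_pos[mt.arm] = arm_pos.get(mt.arm, 0) + 1000
        positions[mid] = (mt.arm, arm_pos[mt.arm])

    variant_tables: dict[str, pd.DataFrame] = {}
    mids = sorted(mutation_truth)
    for r in regions:
        prof = region_profiles[r]
        depth = np.maximum(rng.poisson(config.mean_depth, size=len(mids)), 1)
        evs = np.empty(len(mids))
        for i, mid in enumerate(mids):
            mt = mutation_truth[mid]
            major, minor = arm_cn[(r, mt.arm)]
            evs[i] = expected_vaf(mt.multiplicity_by_region[r], ccf[mt.branch][r],
                                  prof.purity, major + minor)
        alt = rng.binomial(depth, np.clip(evs, 0.0, 1.0))
        variant_tables[r] = pd.DataFrame({
            "sample": r,
            "variant_id": mids,
            "chrom": [positions[m][0] for m in mids],
            "pos": [positions[m][1] for m in mids],
            "ref": "A",
            "alt": "T",
            "alt_count": alt,
            "depth": depth,
        })
    return truth, variant_tables, segment_tables, region_profiles


def _path_to_root(tree: Mapping[int, int | None], clone: int) -> list[int]:
    path = [clone]
    while tree[path[-1]] is not None:
        path.append(tree[path[-1]])
    return path


def simulate_plasma_timecourse(
    truth: TumorTruth,
    timepoints: Sequence[float],
    shedding: Mapping[int, Sequence[float]],
    plasma_depth: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Longitudinal plasma VAFs for every simulated mutation.

    ``shedding[clone][t]`` is the fraction of plasma DNA contributed by that
    clone at timepoint index ``t``.  A variant's expected plasma AF is the
    sum over clones carrying it of shedding x multiplicity / 2 (diploid
    genome-equivalent accounting); reads are binomial at ``plasma_depth``.
    Output columns: variant_id, cluster_id, timepoint, alt_count, depth, af.
    """
    unknown = set(shedding) - set(truth.clone_tree)
    if unknown:
        raise ValueError(f"unknown clone identifiers: {sorted(unknown)}")
    for clone, series in shedding.items():
        if len(series) != len(timepoints):
            raise ValueError(f"clone {clone}: need one shedding value per timepoint")
        if any(s < 0 for s in series):
            raise ValueError("shedding fractions must be >= 0")

    rng = np.random.default_rng(seed)
    rows = []
    for mid in sorted(truth.mutation_truth):
        mt = truth.mutation_truth[mid]
        carriers = truth.carriers(mt.branch)
        base_mult = max(mt.multiplicity_by_region.values(), default=0)
        for ti, tp in enumerate(timepoints):
            af = sum(shedding.get(c, [0.0] * len(timepoints))[ti] * base_mult / 2.0
                     for c in carriers)
            af = min(af, 0.999)
            alt = int(rng.binomial(plasma_depth, af))
            rows.append((mid, f"cluster{mt.branch}", float(tp), alt, plasma_depth,
                         alt / plasma_depth))
    return pd.DataFrame(rows, columns=["variant_id", "cluster_id", "timepoint",
                                       "alt_count", "depth", "af"])


_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _random_cdr3(rng: np.random.Generator) -> str:
    middle = "".join(rng.choice(_AA, size=int(rng.integers(6, 12))))
    return f"CASS{middle}F"


def simulate_repertoire(
    n_clones: int,
    total_reads: int,
    spiked_expansions: Sequence[tuple[str, int, int]] = (),
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired test/control CDR3B count tables with optional spiked expansions.

    Background clone frequencies follow a geometric-like power law (Zipf
    rank-abundance), identical for test and control; both tables are then
    multinomial draws of ``total_reads``.  Each spiked clone's counts are
    overwritten with the requested (test_count, control_count).
    Returns ``(test, control)`` DataFrames with columns (cdr3b, count),
    zero-count clones dropped.
    """
    spike_ids = [s[0] for s in spiked_expansions]
    if len(set(spike_ids)) != len(spike_ids):
        raise ValueError("duplicate clone identifiers in spiked_expansions")
    for cid, t, c in spiked_expansions:
        if t > total_reads or c > total_reads:
            raise ValueError(f"{cid}: spiked counts must be <= total_reads")

    rng = np.random.default_rng(seed)
    names = []
    seen = set()
    while len(names) < n_clones:
        c = _random_cdr3(rng)
        if c not in seen:
            seen.add(c)
            names.append(c)
    ranks = np.arange(1, n_clones + 1, dtype=float)
    probs = 1.0 / ranks ** 1.5
    probs /= probs.sum()

    tables = {}
    for label in ("test", "control"):
        counts = rng.multinomial(total_reads, probs)
        tables[label] = dict(zip(names, counts))
    for cid, t, c in spiked_expansions:
        tables["test"][cid] = t
        tables["control"][cid] = c

    out = []
    for label in ("test", "control"):
        items = [(k, int(v)) for k, v in tables[label].items() if v > 0]
        df = pd.DataFrame(items, columns=["cdr3b", "count"])
        df = df.sort_values(["count", "cdr3b"], ascending=[False, True],
                            ignore_index=True)
        out.append(df)
    return out[0], out[1]
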