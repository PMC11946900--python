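"""Phylogenetic-cluster ctDNA trajectories.

Plasma variants are grouped by the tumor-tree branch (cluster) they were
assigned to, and each cluster is summarised per timepoint by the arithmetic
mean mutant allele frequency over its tracked variants.  Variants assayed
but yielding zero reads count as AF 0 (tracked and not found); variants not
assayed at a timepoint are excluded from that mean.  A cluster is called
detected when enough of its variants show enough mutant reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PlasmaObservation:
    """One tracked variant's plasma read counts at one timepoint."""

    variant_id: str
    cluster_id: str
    timepoint: float
    alt_count: int
    depth: int

    def __post_init__(self) -> None:
        if not 0 <= self.alt_count <= self.depth:
            raise ValueError(f"{self.variant_id}: need 0 <= alt_count <= depth")

    @property
    def af(self) -> float:
        return self.alt_count / self.depth if self.depth > 0 else 0.0


@dataclass(frozen=True)
class ClusterTrack:
    """Mean mutant AF of one phylogenetic cluster at one timepoint."""

    cluster_id: str
    timepoint: float
    mean_af: float
    n_variants: int
    n_detected_variants: int
    detected: bool


def cluster_mean_af(
    observations: Iterable[PlasmaObservation],
    min_variants_detected: int = 2,
    min_alt: int = 2,
    weight_by_depth: bool = False,
) -> list[ClusterTrack]:
    """Mean mutant allele frequency per (cluster, timepoint).

    The unweighted arithmetic mean over the cluster's assayed variants is
    the default; ``weight_by_depth`` switches to a depth-weighted mean
    (pooled-read estimate).  Each (variant, timepoint) may appear at most
    once and a variant may belong to only one cluster.
    """
    obs = list(observations)
    cluster_of: dict[str, str] = {}
    seen: set[tuple[str, float]] = set()
    for o in obs:
        if cluster_of.setdefault(o.variant_id, o.cluster_id) != o.cluster_id:
            raise ValueError(f"{o.variant_id} mapped to two clusters")
        key = (o.variant_id, o.timepoint)
        if key in seen:
            raise ValueError(f"duplicate observation for {key}")
        seen.add(key)

    groups: dict[tuple[str, float], list[PlasmaObservation]] = {}
    for o in obs:
        groups.setdefault((o.cluster_id, o.timepoint), []).append(o)

    tracks = []
    for (cid, tp) in sorted(groups):
        members = groups[(cid, tp)]
        if weight_by_depth:
            depth = sum(o.depth for o in members)
            mean = sum(o.alt_count for o in members) / depth if depth else 0.0
        else:
            mean = float(np.mean([o.af for o in members]))
        n_det = sum(o.alt_count >= min_alt for o in members)
        track = ClusterTrack(cid, tp, mean, len(members), n_det,
                             n_det >= min_variants_detected)
        tracks.append(track)
    return tracks


def cluster_detection(track: ClusterTrack, min_variants_detected: int = 2,
                      min_alt: int = 2) -> bool:
    """Detection call for a cluster at one timepoint: at least
    ``min_variants_detected`` of its variants carry >= ``min_alt`` mutant
    reads.  ``track.n_detected_variants`` must have been computed with the
    same ``min_alt``."""
    if min_variants_detected < 1 or min_alt < 1:
        raise ValueError("thresholds must be >= 1")
    return track.n_detected_variants >= min_variants_detected


def tracks_from_table(plasma: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Long-format cluster tracks from a plasma variant table with columns
    (variant_id, cluster_id, timepoint, alt_count, depth)."""
    obs = [PlasmaObservation(str(r.variant_id), str(r.cluster_id),
                             float(r.timepoint), int(r.alt_count), int(r.depth))
           for r in plasma.itertuples(index=False)]
    tracks = cluster_mean_af(obs, **kwargs)
    return pd.DataFrame([t.__dict__ for t in tracks])
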