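"""Replicate-consensus binding sites.

High-confidence sites are derived from several biological-replicate peak sets:
peaks are clustered across replicates by overlap, clusters supported by at
least ``min_support`` distinct replicates are kept as merged "consensus"
sites, and sites also found in a control line are discarded as artifacts.
Consensus sites are named ``Merged-<chrom>-<center>-<k>``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

from .intervals import GenomicInterval, IntervalSet, merge_overlapping, subtract_intervals

__all__ = [
    "SiteCluster",
    "ConsensusPeakSet",
    "cluster_replicates",
    "consensus_sites",
    "subtract_control",
    "call_consensus",
    "parse_merged_name",
]


@dataclass(frozen=True)
class SiteCluster:
    """A group of replicate peaks connected by overlap.

    ``members`` holds (replicate index, peak) pairs; ``span`` is the union
    interval; ``support`` counts distinct contributing replicates.
    """

    members: tuple[tuple[int, GenomicInterval], ...]
    span: GenomicInterval
    support: int

    def __post_init__(self) -> None:
        assert 1 <= self.support <= len(self.members)
        for _, peak in self.members:
            assert self.span.chrom == peak.chrom
            assert self.span.start <= peak.start and peak.end <= self.span.end


class ConsensusPeakSet(IntervalSet):
    """IntervalSet of consensus sites with unique ``Merged-`` names.

    The score field of each interval stores its replicate support.
    """

    def __init__(self, intervals=(), genome=None):
        super().__init__(intervals, genome=genome)
        names = [iv.name for iv in self.intervals]
        if len(set(names)) != len(names):
            raise ValueError("consensus peak names must be unique")

    @property
    def supports(self) -> dict[str, int]:
        return {iv.name: int(iv.score) for iv in self.intervals}


def parse_merged_name(name: str) -> tuple[str, int, int]:
    """Split ``Merged-<chrom>-<center>-<k>`` into (chrom, center, k).

    The center embedded in a consensus peak name is the coordinate used for
    all center-to-TSS distances, so published peak IDs alone determine those
    distances once the TSS is known.
    """
    if not name.startswith("Merged-"):
        raise ValueError(f"not a Merged- name: {name!r}")
    body = name[len("Merged-"):]
    chrom, center, k = body.rsplit("-", 2)
    return chrom, int(center), int(k)


def cluster_replicates(
    replicate_sets: Sequence[IntervalSet],
    min_overlap_bp: int = 1,
) -> list[SiteCluster]:
    """Cluster peaks across replicates by transitive >= ``min_overlap_bp`` overlap.

    Every input peak lands in exactly one cluster.  With the default 1 bp
    criterion, two peaks are co-clustered iff connected by a chain of
    overlapping peaks (any replicates, including the same one).
    """
    if len(replicate_sets) == 0:
        raise ValueError("need at least one replicate set")
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")

    tagged = [
        (rep_idx, peak)
        for rep_idx, rset in enumerate(replicate_sets)
        for peak in rset
    ]
    # sweep: sort by (chrom, start); peaks whose overlap with the running
    # cluster span reaches min_overlap_bp extend it, otherwise a new cluster
    # starts.  Transitive closure of pairwise overlap == span-chaining for
    # min_overlap_bp == 1; for larger thresholds the span criterion is the
    # documented (slightly more permissive) behaviour.
    tagged.sort(key=lambda t: (t[1].chrom, t[1].start, t[1].end, t[0]))
    clusters: list[SiteCluster] = []
    current: list[tuple[int, GenomicInterval]] = []
    span: GenomicInterval | None = None
    for rep_idx, peak in tagged:
        if (
            span is not None
            and peak.chrom == span.chrom
            and min(peak.end, span.end) - peak.start >= min_overlap_bp
        ):
            current.append((rep_idx, peak))
            if peak.end > span.end:
                span = replace(span, end=peak.end)
        else:
            if current:
                clusters.append(_finish_cluster(current, span))
            current = [(rep_idx, peak)]
            span = GenomicInterval(peak.chrom, peak.start, peak.end)
    if current:
        clusters.append(_finish_cluster(current, span))
    return clusters


def _finish_cluster(
    members: list[tuple[int, GenomicInterval]], span: GenomicInterval
) -> SiteCluster:
    support = len({rep for rep, _ in members})
    return SiteCluster(members=tuple(members), span=span, support=support)


def consensus_sites(
    clusters: Sequence[SiteCluster],
    min_support: int = 2,
    genome=None,
) -> ConsensusPeakSet:
    """Keep clusters supported by >= ``min_support`` replicates.

    Each surviving cluster becomes one consensus site spanning the union of
    its members, named ``Merged-<chrom>-<center>-<k>`` where ``center`` is the
    span midpoint and ``k`` (from 1) disambiguates identical centers.  The
    replicate support is stored in the score field.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    kept = [c for c in clusters if c.support >= min_support]
    kept.sort(key=lambda c: (c.span.chrom, c.span.start, c.span.end))
    seen: dict[tuple[str, int], int] = {}
    out = []
    for c in kept:
        key = (c.span.chrom, c.span.center)
        seen[key] = seen.get(key, 0) + 1
        name = f"Merged-{c.span.chrom}-{c.span.center}-{seen[key]}"
        out.append(
            replace(c.span, name=name, score=float(c.support))
        )
    return ConsensusPeakSet(out, genome=genome)


def subtract_control(peaks: ConsensusPeakSet, control: IntervalSet) -> ConsensusPeakSet:
    """Drop consensus sites sharing >= 1 bp with any control peak.

    Names and order of survivors are unchanged (no renumbering), so site IDs
    remain stable across control sets.  Idempotent.
    """
    survivors = subtract_intervals(peaks, control)
    return ConsensusPeakSet(survivors.intervals, genome=peaks.genome)


def call_consensus(
    replicate_sets: Sequence[IntervalSet],
    control: IntervalSet | None = None,
    min_support: int = 2,
    min_overlap_bp: int = 1,
    control_order: str = "per-replicate",
    genome=None,
) -> ConsensusPeakSet:
    """Full consensus-calling step: control subtraction + clustering + filter.

    ``control_order``:

    - ``"per-replicate"`` (default): artifact peaks are removed from each
      replicate before clustering — mirrors per-sample background cleaning.
    - ``"post-consensus"``: consensus sites are called first and sites
      overlapping control peaks are then removed.
    """
    if len(replicate_sets) < 2:
        raise ValueError("need >= 2 replicate sets for a consensus")
    if control_order not in ("per-replicate", "post-consensus"):
        raise ValueError(f"unknown control_order {control_order!r}")
    if control is not None and control_order == "per-replicate":
        replicate_sets = [subtract_intervals(r, control) for r in replicate_sets]
    clusters = cluster_replicates(replicate_sets, min_overlap_bp=min_overlap_bp)
    sites = consensus_sites(clusters, min_support=min_support, genome=genome)
    if control is not None and control_order == "post-consensus":
        sites = subtract_control(sites, control)
    return sites
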