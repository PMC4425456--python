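"""Gene annotation, genomic-context classification and peak-to-gene assignment.

Each peak is classified by the position of its CENTER with precedence
promoter > exonic > intronic > intergenic.  The promoter window is
strand-oriented: [TSS-1000, TSS+300] on "+", [TSS-300, TSS+1000] on "-".
Promoter/exonic peaks are assigned to the single host gene; intronic and
intergenic peaks are assigned to the closest gene by TSS on each side of the
center (bidirectional nearest-TSS rule), with unsigned center-to-TSS
distances.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .intervals import GenomicInterval, IntervalSet

logger = logging.getLogger(__name__)

__all__ = [
    "Transcript",
    "Gene",
    "GeneAnnotation",
    "GeneAssignment",
    "PROMOTER_UPSTREAM_BP",
    "PROMOTER_DOWNSTREAM_BP",
    "classify_context",
    "assign_target_genes",
    "tss_distance_summary",
    "read_gtf",
    "write_gtf",
]

# Promoter = -1 kb / +300 bp around the TSS, oriented by gene strand.
PROMOTER_UPSTREAM_BP = 1000
PROMOTER_DOWNSTREAM_BP = 300


@dataclass(frozen=True)
class Transcript:
    transcript_id: str
    chrom: str
    start: int  # 0-based half-open span
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...]

    @property
    def tss(self) -> int:
        """Transcription start site: span start on "+", span end - 1 on "-"."""
        return self.start if self.strand == "+" else self.end - 1

    def promoter_window(
        self,
        upstream_bp: int = PROMOTER_UPSTREAM_BP,
        downstream_bp: int = PROMOTER_DOWNSTREAM_BP,
    ) -> tuple[int, int]:
        """Closed genomic interval [lo, hi] containing promoter positions."""
        if self.strand == "+":
            return self.tss - upstream_bp, self.tss + downstream_bp
        return self.tss - downstream_bp, self.tss + upstream_bp


@dataclass(frozen=True)
class Gene:
    symbol: str
    chrom: str
    strand: str
    transcripts: tuple[Transcript, ...]

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def tss_positions(self) -> tuple[int, ...]:
        return tuple(t.tss for t in self.transcripts)

    def closest_tss(self, position: int) -> tuple[int, int]:
        """(tss, distance) of the transcript TSS closest to ``position``."""
        best = min(self.tss_positions, key=lambda t: (abs(t - position), t))
        return best, abs(best - position)


class GeneAnnotation:
    """Genes -> transcripts -> TSS/exons, indexed for point queries."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes: list[Gene] = sorted(genes, key=lambda g: (g.chrom, g.start, g.symbol))
        self._by_symbol = {g.symbol: g for g in self.genes}
        if len(self._by_symbol) != len(self.genes):
            raise ValueError("gene symbols must be unique")
        # per-chromosome sorted TSS list [(tss, symbol)] for nearest queries
        self._tss: dict[str, list[tuple[int, str]]] = {}
        for g in self.genes:
            lst = self._tss.setdefault(g.chrom, [])
            for t in g.tss_positions:
                lst.append((t, g.symbol))
        for lst in self._tss.values():
            lst.sort()

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def gene(self, symbol: str) -> Gene:
        return self._by_symbol[symbol]

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._tss)

    def promoter_intervals(
        self,
        upstream_bp: int = PROMOTER_UPSTREAM_BP,
        downstream_bp: int = PROMOTER_DOWNSTREAM_BP,
        genome: Mapping[str, int] | None = None,
    ) -> IntervalSet:
        """One half-open interval per transcript promoter window, named by gene."""
        out = []
        for g in self.genes:
            for t in g.transcripts:
                lo, hi = t.promoter_window(upstream_bp, downstream_bp)
                out.append(
                    GenomicInterval(g.chrom, max(0, lo), hi + 1, name=g.symbol, strand=g.strand)
                )
        return IntervalSet(out, genome=genome)

    def tss_intervals(self, genome: Mapping[str, int] | None = None) -> IntervalSet:
        return IntervalSet(
            [
                GenomicInterval(g.chrom, t.tss, t.tss + 1, name=g.symbol, strand=g.strand)
                for g in self.genes
                for t in g.transcripts
            ],
            genome=genome,
        )


@dataclass(frozen=True)
class GeneAssignment:
    """One candidate target gene for one peak (a row of the peak->gene map)."""

    peak: str
    gene: str
    distance: int  # |peak center - closest TSS|, bp, unsigned
    side: str  # "upstream" (gene TSS left of center), "downstream", or "within"
    context: str
    tied: bool = False  # equidistant flanking gene kept rather than dropped

    def __post_init__(self) -> None:
        assert self.distance >= 0
        assert self.side in ("upstream", "downstream", "within")
        assert self.context in ("promoter", "exonic", "intronic", "intergenic")


def _center_of(peak: GenomicInterval | int) -> int:
    return peak if isinstance(peak, int) else peak.center


def classify_context(
    peak: GenomicInterval,
    ann: GeneAnnotation,
    upstream_bp: int = PROMOTER_UPSTREAM_BP,
    downstream_bp: int = PROMOTER_DOWNSTREAM_BP,
) -> str:
    """Genomic context of the peak center.

    Precedence: promoter > exonic > intronic > intergenic.  A center inside
    both an exon and some promoter window is "promoter" (the promoter pie
    category is disjoint from exonic).
    """
    ctx, _ = _classify_with_host(peak, ann, upstream_bp, downstream_bp)
    return ctx


def _classify_with_host(
    peak: GenomicInterval,
    ann: GeneAnnotation,
    upstream_bp: int = PROMOTER_UPSTREAM_BP,
    downstream_bp: int = PROMOTER_DOWNSTREAM_BP,
) -> tuple[str, str | None]:
    """(context, host gene symbol or None).

    The host gene of a promoter peak is the gene owning the promoter window;
    of an exonic (or intronic) peak, the gene whose exon (gene span) contains
    the center.  Overlapping candidates are broken by closest TSS, then
    symbol, so the host is deterministic.
    """
    c = peak.center
    promoter_hosts: list[tuple[int, str]] = []
    exonic_hosts: list[tuple[int, str]] = []
    intronic_hosts: list[tuple[int, str]] = []
    for g in ann.genes:
        if g.chrom != peak.chrom:
            continue
        in_promoter = False
        for t in g.transcripts:
            lo, hi = t.promoter_window(upstream_bp, downstream_bp)
            if lo <= c <= hi:
                in_promoter = True
                break
        _, dist = g.closest_tss(c)
        if in_promoter:
            promoter_hosts.append((dist, g.symbol))
            continue
        if g.start <= c < g.end:
            in_exon = any(
                s <= c < e for t in g.transcripts for (s, e) in t.exons
            )
            (exonic_hosts if in_exon else intronic_hosts).append((dist, g.symbol))
    for hosts, label in (
        (promoter_hosts, "promoter"),
        (exonic_hosts, "exonic"),
        (intronic_hosts, "intronic"),
    ):
        if hosts:
            return label, min(hosts)[1]
    return "intergenic", None


def assign_target_genes(
    peak: GenomicInterval,
    ann: GeneAnnotation,
    upstream_bp: int = PROMOTER_UPSTREAM_BP,
    downstream_bp: int = PROMOTER_DOWNSTREAM_BP,
) -> list[GeneAssignment]:
    """Candidate target gene(s) of one peak.

    Promoter/exonic peaks get exactly the host gene.  Intronic/intergenic
    peaks get the closest gene by TSS on each side of the center (genomic
    left/right), at most two assignments; equidistant genes on one side are
    all kept and flagged ``tied``.  Distances are to the closest transcript
    TSS of the assigned gene.
    """
    name = peak.name or f"{peak.chrom}:{peak.start}-{peak.end}"
    context, host = _classify_with_host(peak, ann, upstream_bp, downstream_bp)
    c = peak.center
    if context in ("promoter", "exonic"):
        _, dist = ann.gene(host).closest_tss(c)
        return [GeneAssignment(name, host, dist, "within", context)]

    tss_list = ann._tss.get(peak.chrom, [])
    if not tss_list:
        logger.warning("peak %s on chromosome %s with no annotated genes", name, peak.chrom)
        return []

    out: list[GeneAssignment] = []
    for side in ("upstream", "downstream"):
        if side == "upstream":
            # closest TSS at position <= center
            idx = bisect.bisect_right(tss_list, (c, "￿")) - 1
            if idx < 0:
                continue
            best_dist = c - tss_list[idx][0]
        else:
            idx = bisect.bisect_left(tss_list, (c + 1, ""))
            if idx >= len(tss_list):
                continue
            best_dist = tss_list[idx][0] - c
        genes = sorted(
            {sym for t, sym in tss_list if abs(t - c) == best_dist
             and ((t <= c) if side == "upstream" else (t > c))}
        )
        tied = len(genes) > 1
        for sym in genes:
            # report the gene's closest TSS overall (may be nearer than the
            # side-defining one only in degenerate multi-TSS layouts)
            _, dist = ann.gene(sym).closest_tss(c)
            out.append(GeneAssignment(name, sym, dist, side, context, tied=tied))
    # a gene flanking on both sides with the same distance appears once
    dedup: dict[tuple[str, str], GeneAssignment] = {}
    for a in out:
        dedup.setdefault((a.peak, a.gene), a)
    return list(dedup.values())


def tss_distance_summary(
    peaks: IntervalSet,
    ann: GeneAnnotation,
    threshold_bp: int = 100_000,
    bins: Sequence[int] | None = None,
) -> dict:
    """Per-peak minimum center-to-TSS distance, histogram and fraction <= threshold.

    Peaks on chromosomes without genes have no finite distance and count
    against the fraction.
    """
    distances: list[int] = []
    n_no_gene = 0
    for peak in peaks:
        tss_list = ann._tss.get(peak.chrom)
        if not tss_list:
            n_no_gene += 1
            continue
        c = peak.center
        idx = bisect.bisect_left(tss_list, (c, ""))
        cands = []
        if idx > 0:
            cands.append(abs(c - tss_list[idx - 1][0]))
        if idx < len(tss_list):
            cands.append(abs(tss_list[idx][0] - c))
        distances.append(min(cands))
    n = len(peaks)
    frac = (sum(d <= threshold_bp for d in distances) / n) if n else float("nan")
    if bins is None:
        bins = [0, 1_000, 5_000, 10_000, 25_000, 50_000, 100_000, 250_000, 10**9]
    ser = pd.cut(pd.Series(distances, dtype=float), bins=list(bins), right=True,
                 include_lowest=True).value_counts().sort_index() if distances else pd.Series(dtype=int)
    return {
        "distances": distances,
        "n_peaks": n,
        "n_without_gene": n_no_gene,
        "fraction_within_threshold": frac,
        "threshold_bp": threshold_bp,
        "histogram": ser,
    }


def annotate_peaks(
    peaks: IntervalSet,
    ann: GeneAnnotation,
    upstream_bp: int = PROMOTER_UPSTREAM_BP,
    downstream_bp: int = PROMOTER_DOWNSTREAM_BP,
) -> pd.DataFrame:
    """Assignment table for a whole peak set: peak, gene, distance, side, context."""
    rows = []
    for peak in peaks:
        assignments = assign_target_genes(peak, ann, upstream_bp, downstream_bp)
        if not assignments:
            ctx = classify_context(peak, ann, upstream_bp, downstream_bp)
            rows.append({"peak": peak.name, "gene": None, "distance": pd.NA,
                         "side": None, "context": ctx, "tied": False})
        for a in assignments:
            rows.append({"peak": a.peak, "gene": a.gene, "distance": a.distance,
                         "side": a.side, "context": a.context, "tied": a.tied})
    return pd.DataFrame(rows, columns=["peak", "gene", "distance", "side", "context", "tied"])


# ---------------------------------------------------------------------------
# GTF I/O


def read_gtf(path: str | Path) -> GeneAnnotation:
    """Load gene/transcript/exon features from a GTF file.

    Requires explicit ``gene`` and ``transcript`` features with ``gene_id``
    / ``transcript_id`` attributes (the dialect :func:`write_gtf` emits and
    Ensembl-style GTFs provide).
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = []
    for g in db.features_of_type("gene"):
        transcripts = []
        for t in db.children(g, featuretype="transcript", order_by="start"):
            exons = tuple(
                (e.start - 1, e.end)  # GTF is 1-based closed; convert to half-open
                for e in db.children(t, featuretype="exon", order_by="start")
            )
            transcripts.append(
                Transcript(
                    transcript_id=t.id,
                    chrom=t.seqid,
                    start=t.start - 1,
                    end=t.end,
                    strand=t.strand,
                    exons=exons,
                )
            )
        symbol = g.attributes.get("gene_name", [g.id])[0]
        genes.append(Gene(symbol=symbol, chrom=g.seqid, strand=g.strand,
                          transcripts=tuple(transcripts)))
    return GeneAnnotation(genes)


def write_gtf(ann: GeneAnnotation, path: str | Path, source: str = "regcoloc") -> None:
    """Write gene/transcript/exon features as GTF (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for g in ann.genes:
            attrs_g = f'gene_id "{g.symbol}"; gene_name "{g.symbol}";'
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs_g}\n"
            )
            for t in g.transcripts:
                attrs_t = f'gene_id "{g.symbol}"; transcript_id "{t.transcript_id}"; gene_name "{g.symbol}";'
                fh.write(
                    f"{t.chrom}\t{source}\ttranscript\t{t.start + 1}\t{t.end}\t.\t{t.strand}\t.\t{attrs_t}\n"
                )
                for s, e in t.exons:
                    fh.write(
                        f"{t.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs_t}\n"
                    )
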