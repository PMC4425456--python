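"""ChIA-PET anchor-to-promoter mapping and direct-target calling.

Paired-anchor chromatin interactions (BEDPE) are intersected with consensus
binding sites on one anchor and annotated gene promoters on the other; linked
genes that are differentially expressed (FDR below threshold) become direct
targets.  Intra-chromosomal links carry the peak-center-to-TSS distance;
inter-chromosomal links carry the label ``Inter (<geneChrom>-<peakChrom>)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import GeneAnnotation, PROMOTER_DOWNSTREAM_BP, PROMOTER_UPSTREAM_BP
from .consensus import ConsensusPeakSet
from .intervals import GenomicInterval, IntervalSet, window_hits

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionPair",
    "MappedLink",
    "TargetRecord",
    "read_interactions",
    "write_interactions",
    "map_interactions",
    "classify_interaction",
    "direct_target_table",
    "intra_distance_summary",
]


@dataclass(frozen=True)
class InteractionPair:
    """An unordered pair of interacting anchors, with optional tag support."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    name: str | None = None
    support: int | None = None


@dataclass(frozen=True)
class MappedLink:
    """One (peak, gene) link backed by one interaction."""

    peak: GenomicInterval
    gene: str
    pair: InteractionPair
    kind: str  # "intra" or "inter"
    distance: int | None  # peak center to gene TSS, bp; None for inter
    label: str  # formatted distance or "Inter (geneChrom-peakChrom)"


@dataclass(frozen=True)
class TargetRecord:
    """A direct-target table row: DE gene physically linked to a binding site."""

    gene: str
    log_fc: float
    fdr: float
    peak: str
    linkage: str  # "41,644" style distance or "Inter (chr2-chr18)"
    distance: int | None = None

    def __post_init__(self) -> None:
        assert 0.0 <= self.fdr <= 1.0
        if self.distance is not None:
            assert self.distance >= 0


def read_interactions(path: str | Path) -> list[InteractionPair]:
    """Read BEDPE (>= 6 columns; optional name, score).  Order preserved."""
    pairs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise ValueError(f"line {lineno}: BEDPE needs >= 6 columns")
            try:
                a = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                b = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
            name = fields[6] if len(fields) > 6 and fields[6] != "." else None
            support = int(float(fields[7])) if len(fields) > 7 and fields[7] != "." else None
            pairs.append(InteractionPair(a, b, name=name, support=support))
    return pairs


def write_interactions(pairs: Iterable[InteractionPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            a, b = p.anchor_a, p.anchor_b
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t"
                f"{p.name or '.'}\t{p.support if p.support is not None else '.'}\n"
            )


def classify_interaction(
    gene_chrom: str,
    gene_tss: int | None,
    peak: GenomicInterval,
) -> tuple[str, int | None, str]:
    """(kind, distance, label) of a mapped (gene, peak) link.

    Same chromosome -> ("intra", |peak center - TSS|, "12,320"-style label);
    different chromosomes -> ("inter", None, "Inter (<geneChrom>-<peakChrom>)")
    with the gene's chromosome printed first.
    """
    if gene_chrom == peak.chrom:
        if gene_tss is None:
            raise ValueError("intra-chromosomal link needs a TSS position")
        d = abs(peak.center - gene_tss)
        return "intra", d, f"{d:,}"
    return "inter", None, f"Inter ({gene_chrom}-{peak.chrom})"


def map_interactions(
    pairs: Sequence[InteractionPair],
    peaks: ConsensusPeakSet,
    ann: GeneAnnotation,
    promoter_filter: IntervalSet | None = None,
    anchor_window_bp: int = 0,
    upstream_bp: int = PROMOTER_UPSTREAM_BP,
    downstream_bp: int = PROMOTER_DOWNSTREAM_BP,
) -> list[MappedLink]:
    """Map interactions to (peak, gene) links.

    An interaction is mapped iff one anchor overlaps (within
    ``anchor_window_bp``) >= 1 consensus peak and the other anchor overlaps
    >= 1 gene promoter window; both anchor orientations are tried.  When
    ``promoter_filter`` is given (e.g. RNAPII-occupied regions), only
    promoters overlapping it qualify.  Each distinct (peak, gene) pair is
    reported once per interaction.
    """
    promoters = ann.promoter_intervals(upstream_bp, downstream_bp)
    if promoter_filter is not None:
        keep = {q for q, _ in window_hits(promoters, promoter_filter, 0)}
        promoters = IntervalSet([iv for iv in promoters if iv in keep])

    links: list[MappedLink] = []
    for pair in pairs:
        found: set[tuple[str, str]] = set()
        for peak_anchor, prom_anchor in ((pair.anchor_a, pair.anchor_b),
                                         (pair.anchor_b, pair.anchor_a)):
            pa = peak_anchor.expanded(anchor_window_bp)
            hit_peaks = peaks.overlapping(pa.chrom, pa.start, pa.end)
            if not hit_peaks:
                continue
            qa = prom_anchor.expanded(anchor_window_bp)
            hit_genes = {iv.name for iv in promoters.overlapping(qa.chrom, qa.start, qa.end)}
            for peak in hit_peaks:
                for gene_symbol in sorted(hit_genes):
                    if (peak.name, gene_symbol) in found:
                        continue
                    found.add((peak.name, gene_symbol))
                    gene = ann.gene(gene_symbol)
                    tss, _ = gene.closest_tss(peak.center) if gene.chrom == peak.chrom else (None, None)
                    kind, distance, label = classify_interaction(gene.chrom, tss, peak)
                    links.append(MappedLink(peak, gene_symbol, pair, kind, distance, label))
    return links


def intra_distance_summary(links: Sequence[MappedLink], threshold_bp: int = 100_000) -> dict:
    """Counts of intra/inter links and the fraction of intra links < threshold."""
    n_intra = sum(1 for l in links if l.kind == "intra")
    n_inter = sum(1 for l in links if l.kind == "inter")
    n_short = sum(1 for l in links if l.kind == "intra" and l.distance < threshold_bp)
    return {
        "n_links": len(links),
        "n_intra": n_intra,
        "n_inter": n_inter,
        "fraction_intra_below_threshold": (n_short / n_intra) if n_intra else float("nan"),
        "threshold_bp": threshold_bp,
    }


def direct_target_table(
    links: Sequence[MappedLink] | pd.DataFrame,
    de_table: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Direct-target table: DE genes linked to binding sites.

    ``de_table`` needs columns ``gene``, ``log_fc``, ``fdr`` with unique gene
    keys.  One row per (gene, peak) link whose gene passes
    ``fdr < fdr_threshold``; genes linked to several peaks appear on several
    rows.  Sorted by gene symbol, then peak name.  Linked genes absent from
    the DE table are excluded (counted in a logged warning).
    """
    if de_table["gene"].duplicated().any():
        raise ValueError("de_table gene keys must be unique")
    de = de_table.set_index("gene")

    if isinstance(links, pd.DataFrame):
        link_rows = links[["gene", "peak", "linkage", "distance"]].to_dict("records")
    else:
        link_rows = [
            {"gene": l.gene, "peak": l.peak.name, "linkage": l.label, "distance": l.distance}
            for l in links
        ]

    missing = sorted({r["gene"] for r in link_rows} - set(de.index))
    if missing:
        logger.warning("%d linked genes absent from the DE table", len(missing))

    records = []
    seen: set[tuple[str, str]] = set()
    for r in link_rows:
        g = r["gene"]
        if g not in de.index:
            continue
        if not (de.at[g, "fdr"] < fdr_threshold):
            continue
        key = (g, r["peak"])
        if key in seen:
            continue
        seen.add(key)
        records.append(
            {
                "gene": g,
                "log_fc": float(de.at[g, "log_fc"]),
                "fdr": float(de.at[g, "fdr"]),
                "peak": r["peak"],
                "linkage": r["linkage"],
                "distance": r["distance"],
            }
        )
    df = pd.DataFrame(records, columns=["gene", "log_fc", "fdr", "peak", "linkage", "distance"])
    return df.sort_values(["gene", "peak"], kind="stable").reset_index(drop=True)
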