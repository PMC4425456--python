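"""Synthetic data with known ground truth for every pipeline stage.

The generator emits everything the pipeline consumes — a genome table, a gene
annotation (GTF), three replicate ChIP peak sets of unequal sensitivity plus
a control-line peak set, co-factor peak sets with tunable planted
co-localization, promoter-anchored interaction pairs (BEDPE), a count matrix
with planted differential expression concentrated on interacting genes, and a
differential-expression table — together with a ground-truth JSON naming the
true sites, their replicate membership, control contamination, planted
co-factor sites, loops, and differentially expressed genes.

Defaults emulate the statistical structure of a SIM2-style ChIP experiment in
mouse ES cells at roughly 1/10 scale: three replicates with detection
probabilities 0.9/0.85/0.4 (a strong/strong/weak sensitivity spread),
peak contexts drawn ~57% intergenic / 37% intronic, co-factor co-localization
fractions 0.82/0.462/0.4475, ~28% inter-chromosomal loops with 63% of
intra-chromosomal loops under 100 kb, and negative-binomial expression
(dispersion 0.1) with +1 log2-unit shifts planted on loop target genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import (
    Gene,
    GeneAnnotation,
    Transcript,
    classify_context,
    write_gtf,
)
from .intervals import GenomicInterval, IntervalSet, write_genome, write_intervals
from .chiapet import InteractionPair, write_interactions

__all__ = ["SimulationConfig", "GroundTruth", "Simulator", "simulate_all"]


@dataclass
class SimulationConfig:
    """All knobs of the generator.  Probabilities in [0, 1]; counts >= 0."""

    seed: int = 0

    # genome & annotation
    n_chromosomes: int = 5
    chromosome_length: int = 2_000_000
    n_genes: int = 1500
    gene_length_range: tuple[int, int] = (600, 3000)
    exon_count_range: tuple[int, int] = (1, 5)

    # true binding sites
    n_true_sites: int = 120
    site_length_mean: float = 400.0
    site_length_sd: float = 80.0
    site_length_min: int = 150
    min_site_spacing: int = 5_000
    context_fractions: dict = field(
        default_factory=lambda: {
            "intergenic": 0.57,
            "intronic": 0.37,
            "promoter": 0.026,
            "exonic": 0.024,
        }
    )

    # replicates & control
    detection_probs: tuple[float, ...] = (0.9, 0.85, 0.4)
    replicate_noise_peaks: tuple[int, ...] = (130, 110, 15)
    replicate_jitter_sd: float = 20.0
    control_artifact_fraction: float = 0.1
    control_noise_peaks: int = 40

    # co-factors
    cofactor_rho: dict = field(
        default_factory=lambda: {"NANOG": 0.82, "OCT4": 0.462, "SOX2": 0.4475}
    )
    cofactor_total_peaks: int = 200
    cofactor_jitter_sd: float = 30.0

    # interactions
    n_interactions: int = 40
    inter_chromosomal_fraction: float = 0.278
    short_range_fraction: float = 0.63  # of intra-chromosomal loops, < 100 kb
    short_range_bp: int = 100_000
    anchor_jitter_sd: float = 0.0

    # expression
    n_samples_per_group: int = 3
    nb_dispersion: float = 0.1
    log_mean_expression: float = 5.0
    log_sd_expression: float = 1.0
    effect_size_log2: float = 1.0
    de_fraction_of_looped: float = 1.0
    n_extra_up: int = 12
    n_extra_down: int = 23
    de_fdr_threshold: float = 0.05

    def validate(self) -> None:
        if not 0 < sum(self.context_fractions.values()) <= 1.0 + 1e-9:
            raise ValueError("context fractions must sum to (0, 1]")
        for p in (*self.detection_probs, self.control_artifact_fraction,
                  self.inter_chromosomal_fraction, self.short_range_fraction,
                  self.de_fraction_of_looped, *self.cofactor_rho.values()):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if len(self.detection_probs) != len(self.replicate_noise_peaks):
            raise ValueError("need one noise count per replicate")
        if min(self.gene_length_range) < 10:
            raise ValueError("genes shorter than 10 bp are not supported")

    @property
    def genome(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chromosome_length for i in range(self.n_chromosomes)}

    def expected_consensus_sensitivity(self, min_support: int = 2) -> float:
        """Exact P(site detected in >= min_support replicates)."""
        probs = self.detection_probs
        n = len(probs)
        total = 0.0
        for mask in range(2 ** n):
            k = bin(mask).count("1")
            if k < min_support:
                continue
            pr = 1.0
            for i in range(n):
                pr *= probs[i] if (mask >> i) & 1 else 1 - probs[i]
            total += pr
        return total


@dataclass
class GroundTruth:
    """Truth labels consistent with the emitted files."""

    sites: list  # [{id, chrom, start, end, center, context}]
    replicate_membership: dict  # site id -> [0/1 per replicate]
    control_contaminated: list  # site ids planted in the control set
    cofactor_sites: dict  # factor -> [site ids with a planted co-factor peak]
    loops: list  # [{site, gene, kind, distance}]
    de_genes: dict  # gene -> planted log2 effect
    direct_target_genes: list  # looped genes called DE at the threshold
    expected_consensus_sensitivity: float

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


class Simulator:
    """Deterministic generator: one root seed, named substreams per stage."""

    def __init__(self, config: SimulationConfig | None = None):
        self.config = config or SimulationConfig()
        self.config.validate()
        ss = np.random.SeedSequence(self.config.seed)
        kids = ss.spawn(6)
        self._rng = {
            name: np.random.default_rng(k)
            for name, k in zip(
                ["annotation", "sites", "replicates", "cofactors",
                 "interactions", "expression"],
                kids,
            )
        }

    # -- genome & annotation ------------------------------------------------

    def simulate_genome_and_annotation(self) -> tuple[dict[str, int], GeneAnnotation]:
        """Non-overlapping genes with strand and 1-5 exons, deterministic from seed."""
        cfg = self.config
        rng = self._rng["annotation"]
        genome = cfg.genome
        chroms = list(genome)
        genes = []
        per_chrom = np.full(len(chroms), cfg.n_genes // len(chroms))
        per_chrom[: cfg.n_genes % len(chroms)] += 1
        lo_len, hi_len = cfg.gene_length_range
        for chrom, n_here in zip(chroms, per_chrom):
            # sequential placement with random gaps keeps genes non-overlapping
            lengths = rng.integers(lo_len, hi_len + 1, size=n_here)
            clen = genome[chrom]
            slack = clen - int(lengths.sum())
            if slack <= n_here:
                raise ValueError(
                    f"{n_here} genes of mean length {lengths.mean():.0f} cannot fit "
                    f"on a {clen} bp chromosome"
                )
            gaps = rng.multinomial(slack - n_here, np.full(n_here + 1, 1 / (n_here + 1))) + 1
            pos = 0
            for gi in range(n_here):
                pos += int(gaps[gi])
                start, end = pos, pos + int(lengths[gi])
                pos = end
                strand = "+" if rng.random() < 0.5 else "-"
                symbol = f"Gene{chrom[3:]}_{gi + 1:04d}"
                exons = self._make_exons(rng, start, end)
                tr = Transcript(f"{symbol}.t1", chrom, start, end, strand, exons)
                genes.append(Gene(symbol, chrom, strand, (tr,)))
        return genome, GeneAnnotation(genes)

    @staticmethod
    def _make_exons(rng, start: int, end: int) -> tuple[tuple[int, int], ...]:
        length = end - start
        max_exons = max(1, min(5, length // 200))
        n_exons = int(rng.integers(1, max_exons + 1))
        if n_exons == 1:
            return ((start, end),)
        cuts = np.sort(rng.choice(np.arange(1, length), size=2 * (n_exons - 1), replace=False))
        bounds = [0, *cuts.tolist(), length]
        return tuple(
            (start + bounds[i], start + bounds[i + 1]) for i in range(0, len(bounds) - 1, 2)
        )

    # -- true sites ---------------------------------------------------------

    def simulate_true_sites(self, ann: GeneAnnotation) -> list[dict]:
        """True binding sites with planted genomic contexts.

        Contexts are drawn from ``context_fractions`` and realised by
        rejection sampling: a candidate center is proposed inside a region of
        the desired kind and accepted iff the real classifier agrees, so
        truth labels are self-consistent with the pipeline's definitions.
        """
        cfg = self.config
        rng = self._rng["sites"]
        genome = cfg.genome
        chroms = list(genome)
        ctx_names = list(cfg.context_fractions)
        ctx_probs = np.array([cfg.context_fractions[c] for c in ctx_names], dtype=float)
        ctx_probs /= ctx_probs.sum()

        centers: dict[str, list[int]] = {c: [] for c in chroms}
        sites = []
        for i in range(cfg.n_true_sites):
            want = ctx_names[int(rng.choice(len(ctx_names), p=ctx_probs))]
            length = max(cfg.site_length_min,
                         int(round(rng.normal(cfg.site_length_mean, cfg.site_length_sd))))
            for _attempt in range(200):
                chrom, center = self._propose_center(rng, ann, genome, want)
                start, end = center - length // 2, center - length // 2 + length
                if start < 0 or end > genome[chrom]:
                    continue
                if any(abs(center - c) < cfg.min_site_spacing for c in centers[chrom]):
                    continue
                iv = GenomicInterval(chrom, start, end)
                if classify_context(iv, ann) != want:
                    continue
                centers[chrom].append(center)
                sites.append({
                    "id": f"site-{i + 1:03d}",
                    "chrom": chrom, "start": start, "end": end,
                    "center": iv.center, "context": want,
                })
                break
            else:
                raise RuntimeError(f"could not place a {want} site after 200 attempts")
        return sites

    def _propose_center(self, rng, ann: GeneAnnotation, genome, want: str) -> tuple[str, int]:
        chroms = list(genome)
        if want == "intergenic":
            chrom = chroms[int(rng.integers(len(chroms)))]
            return chrom, int(rng.integers(0, genome[chrom]))
        gene = ann.genes[int(rng.integers(len(ann.genes)))]
        t = gene.transcripts[0]
        if want == "promoter":
            lo, hi = t.promoter_window()
            return gene.chrom, int(rng.integers(max(0, lo), hi + 1))
        if want == "exonic":
            s, e = t.exons[int(rng.integers(len(t.exons)))]
            return gene.chrom, int(rng.integers(s, e))
        # intronic: need a gene with >= 2 exons
        if len(t.exons) < 2:
            return gene.chrom, -1  # rejected by caller (start < 0)
        j = int(rng.integers(len(t.exons) - 1))
        intron = (t.exons[j][1], t.exons[j + 1][0])
        if intron[1] <= intron[0]:
            return gene.chrom, -1
        return gene.chrom, int(rng.integers(intron[0], intron[1]))

    # -- replicate & control peaks -------------------------------------------

    def simulate_replicate_peaks(
        self, sites: list[dict]
    ) -> tuple[list[IntervalSet], IntervalSet, dict, list]:
        """Replicate peak sets, control set, membership table, contaminated IDs.

        Each true site appears in replicate r with probability
        ``detection_probs[r]``, shifted by N(0, jitter) bp; each replicate
        gets its own uniform noise peaks.  A fraction of sites is also planted
        into the control set (artifact sites), on top of control noise peaks.
        """
        cfg = self.config
        rng = self._rng["replicates"]
        genome = cfg.genome
        membership = {s["id"]: [0] * len(cfg.detection_probs) for s in sites}

        replicate_sets = []
        for r, (p_det, n_noise) in enumerate(zip(cfg.detection_probs, cfg.replicate_noise_peaks)):
            peaks = []
            for s in sites:
                if rng.random() < p_det:
                    membership[s["id"]][r] = 1
                    shift = int(round(rng.normal(0, cfg.replicate_jitter_sd)))
                    start = min(max(0, s["start"] + shift), genome[s["chrom"]] - (s["end"] - s["start"]))
                    peaks.append(GenomicInterval(
                        s["chrom"], start, start + (s["end"] - s["start"]),
                        name=f"rep{r + 1}-{s['id']}",
                    ))
            peaks.extend(self._noise_peaks(rng, n_noise, prefix=f"rep{r + 1}-noise"))
            peaks.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
            replicate_sets.append(IntervalSet(peaks, genome=genome))

        n_cont = int(round(cfg.control_artifact_fraction * len(sites)))
        cont_idx = sorted(rng.choice(len(sites), size=n_cont, replace=False).tolist()) if n_cont else []
        contaminated = [sites[i]["id"] for i in cont_idx]
        control_peaks = [
            GenomicInterval(sites[i]["chrom"], sites[i]["start"], sites[i]["end"],
                            name=f"control-{sites[i]['id']}")
            for i in cont_idx
        ]
        control_peaks.extend(self._noise_peaks(rng, cfg.control_noise_peaks, prefix="control-noise"))
        control_peaks.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
        return replicate_sets, IntervalSet(control_peaks, genome=genome), membership, contaminated

    def _noise_peaks(self, rng, n: int, prefix: str) -> list[GenomicInterval]:
        cfg = self.config
        genome = cfg.genome
        chroms = list(genome)
        out = []
        for i in range(n):
            length = max(cfg.site_length_min,
                         int(round(rng.normal(cfg.site_length_mean, cfg.site_length_sd))))
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, genome[chrom] - length))
            out.append(GenomicInterval(chrom, start, start + length, name=f"{prefix}-{i + 1}"))
        return out

    # -- co-factors ---------------------------------------------------------

    def simulate_cofactor_peaks(self, sites: list[dict], factor: str) -> tuple[IntervalSet, list]:
        """One co-factor peak set: fraction rho of true sites get a peak at
        their center (+- jitter); the rest of the configured total is uniform
        background.  Returns (peaks, planted site ids)."""
        cfg = self.config
        rho = cfg.cofactor_rho[factor]
        rng = self._rng["cofactors"]
        genome = cfg.genome
        n_plant = int(round(rho * len(sites)))
        idx = sorted(rng.choice(len(sites), size=n_plant, replace=False).tolist()) if n_plant else []
        peaks = []
        for k, i in enumerate(idx):
            s = sites[i]
            length = max(cfg.site_length_min,
                         int(round(rng.normal(cfg.site_length_mean, cfg.site_length_sd))))
            shift = int(round(rng.normal(0, cfg.cofactor_jitter_sd)))
            center = s["center"] + shift
            start = min(max(0, center - length // 2), genome[s["chrom"]] - length)
            peaks.append(GenomicInterval(s["chrom"], start, start + length,
                                         name=f"{factor}-site-{k + 1}"))
        n_bg = max(0, cfg.cofactor_total_peaks - n_plant)
        peaks.extend(self._noise_peaks(rng, n_bg, prefix=f"{factor}-bg"))
        peaks.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
        return IntervalSet(peaks, genome=genome), [sites[i]["id"] for i in idx]

    # -- interactions -------------------------------------------------------

    def simulate_interactions(
        self, sites: list[dict], ann: GeneAnnotation, exclude_sites: set[str] = frozenset()
    ) -> tuple[list[InteractionPair], list[dict]]:
        """Promoter-anchored loops from true sites to gene promoters.

        One anchor is the binding site, the other the target gene's promoter
        window.  Configured fractions of loops are inter-chromosomal and,
        among intra-chromosomal ones, short-range (< ``short_range_bp``).
        ``exclude_sites`` removes sites that would not survive consensus
        calling (artifact or under-replicated sites), mirroring a study
        design where loops are read off the consensus site list.
        Returns (pairs, loop truth records).
        """
        cfg = self.config
        rng = self._rng["interactions"]
        eligible = [s for s in sites if s["id"] not in exclude_sites]
        if cfg.n_interactions > len(eligible):
            raise ValueError("more interactions requested than eligible sites")
        order = rng.permutation(len(eligible))[: cfg.n_interactions]
        by_chrom: dict[str, list[Gene]] = {}
        for g in ann.genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        used_genes: set[str] = set()
        pairs, loops = [], []
        for n, si in enumerate(order):
            site = eligible[int(si)]
            inter = rng.random() < cfg.inter_chromosomal_fraction
            if inter:
                cands = [g for c, gl in by_chrom.items() if c != site["chrom"] for g in gl]
            else:
                short = rng.random() < cfg.short_range_fraction
                gl = by_chrom.get(site["chrom"], [])
                dists = [(abs(g.closest_tss(site["center"])[0] - site["center"]), g) for g in gl]
                if short:
                    cands = [g for d, g in dists if 0 < d < cfg.short_range_bp]
                else:
                    cands = [g for d, g in dists if d >= cfg.short_range_bp]
            cands = [g for g in cands if g.symbol not in used_genes]
            if not cands:
                raise RuntimeError("no eligible target gene for a planted loop")
            gene = cands[int(rng.integers(len(cands)))]
            used_genes.add(gene.symbol)
            t = gene.transcripts[0]
            lo, hi = t.promoter_window()
            prom = GenomicInterval(gene.chrom, max(0, lo), hi + 1)
            site_iv = GenomicInterval(site["chrom"], site["start"], site["end"])
            if cfg.anchor_jitter_sd > 0:
                site_iv = self._jitter(rng, site_iv)
                prom = self._jitter(rng, prom)
            pairs.append(InteractionPair(site_iv, prom, name=f"loop-{n + 1}",
                                         support=int(rng.integers(2, 20))))
            tss, dist = gene.closest_tss(site["center"]) if gene.chrom == site["chrom"] else (None, None)
            loops.append({
                "site": site["id"], "gene": gene.symbol,
                "kind": "inter" if gene.chrom != site["chrom"] else "intra",
                "distance": dist,
            })
        return pairs, loops

    def _jitter(self, rng, iv: GenomicInterval) -> GenomicInterval:
        shift = int(round(rng.normal(0, self.config.anchor_jitter_sd)))
        start = max(0, iv.start + shift)
        return GenomicInterval(iv.chrom, start, start + iv.length, name=iv.name, strand=iv.strand)

    # -- expression ---------------------------------------------------------

    def simulate_expression(
        self, ann: GeneAnnotation, loops: list[dict]
    ) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame, dict]:
        """Counts, gene lengths, DE table and planted-effect labels.

        Negative-binomial counts (dispersion ``nb_dispersion``) for two groups
        of ``n_samples_per_group`` samples.  A fraction of loop target genes
        gets a planted +``effect_size_log2`` shift; additional non-looped
        genes get +/- shifts.  The DE table holds observed log2 fold changes
        and BH-adjusted p-values from a per-gene Wald test on the log ratio of
        group count sums, using the generator's known dispersion — a
        lightweight calibrated caller for synthetic data, standing where an
        external differential-expression table would enter the pipeline.
        """
        cfg = self.config
        rng = self._rng["expression"]
        genes = [g.symbol for g in ann.genes]
        lengths = pd.Series(
            {g.symbol: sum(e - s for t in g.transcripts for s, e in t.exons) for g in ann.genes},
            name="length",
        )

        looped_genes = [l["gene"] for l in loops]
        n_de_loop = int(round(cfg.de_fraction_of_looped * len(looped_genes)))
        de_loop = sorted(
            np.array(looped_genes)[
                np.sort(rng.choice(len(looped_genes), size=n_de_loop, replace=False))
            ].tolist()
        ) if n_de_loop else []
        non_looped = [g for g in genes if g not in set(looped_genes)]
        extra = rng.choice(len(non_looped), size=cfg.n_extra_up + cfg.n_extra_down, replace=False)
        extra_up = [non_looped[i] for i in extra[: cfg.n_extra_up]]
        extra_down = [non_looped[i] for i in extra[cfg.n_extra_up:]]

        effects = {g: cfg.effect_size_log2 for g in de_loop}
        effects.update({g: cfg.effect_size_log2 for g in extra_up})
        effects.update({g: -cfg.effect_size_log2 for g in extra_down})

        base_mu = np.exp(rng.normal(cfg.log_mean_expression, cfg.log_sd_expression, size=len(genes)))
        mu = pd.Series(base_mu, index=genes)
        k = cfg.n_samples_per_group
        samples_a = [f"sim2_{i + 1}" for i in range(k)]
        samples_b = [f"ctrl_{i + 1}" for i in range(k)]
        counts = {}
        phi = cfg.nb_dispersion
        for sample_list, is_a in ((samples_a, True), (samples_b, False)):
            for s in sample_list:
                m = mu.to_numpy().copy()
                if is_a:
                    for g, eff in effects.items():
                        m[genes.index(g)] *= 2.0 ** eff
                n_param = 1.0 / phi
                p_param = n_param / (n_param + m)
                counts[s] = rng.negative_binomial(n_param, p_param)
        counts_df = pd.DataFrame(counts, index=genes)

        de_table = self._de_test(counts_df, lengths, samples_a, samples_b, phi)
        return counts_df, lengths, de_table, effects

    @staticmethod
    def _de_test(counts, lengths, samples_a, samples_b, dispersion) -> pd.DataFrame:
        """Wald test on the log ratio of group count sums.

        With n i.i.d. NB(m, phi) samples per group, Var(log(sum)) is
        approximately (1 + phi*m) / (n*m); the common mean m is estimated
        from the pooled counts.  The known dispersion does the moderation an
        empirical-Bayes DE model would otherwise supply.
        """
        from statsmodels.stats.multitest import multipletests
        from .expression import rpkm as _rpkm

        n = len(samples_a)
        sa = counts[samples_a].sum(axis=1).to_numpy(dtype=float)
        sb = counts[samples_b].sum(axis=1).to_numpy(dtype=float)
        m_hat = np.maximum((sa + sb) / (2 * n), 0.5)
        var_log_ratio = 2 * (1 + dispersion * m_hat) / (n * m_hat)
        z = np.log((sa + 0.5) / (sb + 0.5)) / np.sqrt(var_log_ratio)
        p = 2 * sps.norm.sf(np.abs(z))
        r = _rpkm(counts, lengths)
        log_fc = np.log2((r[samples_a].mean(axis=1) + 0.1) / (r[samples_b].mean(axis=1) + 0.1))
        fdr = multipletests(p, method="fdr_bh")[1]
        return pd.DataFrame({"gene": counts.index, "log_fc": log_fc.to_numpy(), "fdr": fdr})


def simulate_all(config: SimulationConfig | None = None, out_dir: str | Path | None = None):
    """Run every generator stage; optionally write all files to ``out_dir``.

    Returns a dict with in-memory objects (genome, annotation, replicate and
    control peak sets, cofactor sets, interaction pairs, counts, DE table)
    plus the :class:`GroundTruth`.  Identical config+seed produce
    byte-identical files.
    """
    sim = Simulator(config)
    cfg = sim.config
    genome, ann = sim.simulate_genome_and_annotation()
    sites = sim.simulate_true_sites(ann)
    replicates, control, membership, contaminated = sim.simulate_replicate_peaks(sites)
    cofactors, cofactor_truth = {}, {}
    for factor in cfg.cofactor_rho:
        cofactors[factor], cofactor_truth[factor] = sim.simulate_cofactor_peaks(sites, factor)
    # loops attach to sites that survive consensus calling: detected in >= 2
    # replicates and not planted in the control set
    undetectable = {sid for sid, m in membership.items() if sum(m) < 2}
    pairs, loops = sim.simulate_interactions(
        sites, ann, exclude_sites=set(contaminated) | undetectable
    )
    counts, lengths, de_table, effects = sim.simulate_expression(ann, loops)

    called = set(de_table.loc[de_table["fdr"] < cfg.de_fdr_threshold, "gene"])
    direct_targets = sorted({l["gene"] for l in loops} & called)
    truth = GroundTruth(
        sites=sites,
        replicate_membership=membership,
        control_contaminated=contaminated,
        cofactor_sites=cofactor_truth,
        loops=loops,
        de_genes={g: float(e) for g, e in sorted(effects.items())},
        direct_target_genes=direct_targets,
        expected_consensus_sensitivity=cfg.expected_consensus_sensitivity(),
    )

    result = {
        "config": cfg,
        "genome": genome,
        "annotation": ann,
        "replicates": replicates,
        "control": control,
        "cofactors": cofactors,
        "interactions": pairs,
        "counts": counts,
        "gene_lengths": lengths,
        "de_table": de_table,
        "truth": truth,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_genome(genome, out / "genome.tsv")
        write_gtf(ann, out / "genes.gtf")
        for r, rset in enumerate(replicates):
            write_intervals(rset, out / f"replicate_{r + 1}.bed")
        write_intervals(control, out / "control.bed")
        for factor, cset in cofactors.items():
            write_intervals(cset, out / f"cofactor_{factor}.bed")
        write_interactions(pairs, out / "interactions.bedpe")
        counts_out = counts.copy()
        counts_out.insert(0, "length", lengths)
        counts_out.to_csv(out / "counts.tsv", sep="\t", index_label="gene")
        de_table.to_csv(out / "de_table.tsv", sep="\t", index=False, float_format="%.6g")
        truth.to_json(out / "truth.json")
    return result
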