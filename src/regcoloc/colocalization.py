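"""Co-occupancy statistics between a reference peak set and other features.

The core quantities:

- a co-occupancy profile: frequency of feature midpoints in distance bins
  around reference peak centers (default 40 kb window), with fold-enrichment
  over the genome-average feature density;
- the windowed overlap fraction: share of reference peaks with >= 1 feature
  within a window (default 100 bp), the ``bedtools window`` criterion;
- a matched random-interval null: n intervals with lengths resampled from the
  reference set, placed uniformly on the genome;
- Fisher's exact test comparing observed vs random overlap counts;
- the F-score: harmonic mean of precision (features near a reference peak)
  and recall (reference peaks near a feature); 1 = perfect match.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, IntervalSet, window_hits

__all__ = [
    "CoOccupancyProfile",
    "OverlapTestResult",
    "cooccupancy_profile",
    "sample_random_intervals",
    "overlap_stats",
    "fisher_overlap_test",
    "f_score",
    "coloc_panel",
    "format_p",
]


@dataclass(frozen=True)
class CoOccupancyProfile:
    """Binned feature frequency around reference centers.

    ``bin_centers[i]`` is the signed offset (bp) of bin i's midpoint;
    ``counts[i]`` the number of (reference, feature-midpoint) pairs whose
    offset falls in bin i; ``fold_enrichment`` the per-bin density divided by
    the genome-average feature-midpoint density.
    """

    bin_centers: np.ndarray
    counts: np.ndarray
    fold_enrichment: np.ndarray
    n_reference: int
    bin_size: int
    half_window: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "offset": self.bin_centers,
                "count": self.counts,
                "fold_enrichment": self.fold_enrichment,
            }
        )


@dataclass(frozen=True)
class OverlapTestResult:
    """One feature set tested against the reference peaks (one panel row)."""

    feature: str
    n_ref: int
    n_overlap: int
    fraction: float
    n_random: int
    n_random_overlap: int
    odds_ratio: float
    p_value: float
    f_score: float
    error: str | None = None


def cooccupancy_profile(
    ref: IntervalSet,
    features: IntervalSet,
    genome: dict[str, int] | None = None,
    half_window: int = 20_000,
    bin_size: int = 500,
) -> CoOccupancyProfile:
    """Histogram of feature midpoints around reference peak centers.

    For every feature midpoint within ``half_window`` of a reference center
    (same chromosome), the bin of its signed offset (feature - reference) is
    incremented.  Offsets are binned over ``[-half_window, half_window)``.
    Fold-enrichment in bin b is::

        (count_b / (n_ref * bin_size)) / (total feature midpoints / genome bp)

    so a feature set scattered uniformly over the genome gives ~1 everywhere.
    """
    if bin_size <= 0 or (2 * half_window) % bin_size != 0:
        raise ValueError("bin_size must be positive and divide 2*half_window")
    genome = genome if genome is not None else (ref.genome or features.genome)
    if not genome:
        raise ValueError("a genome table is required for fold-enrichment")
    genome_bp = sum(genome.values())
    if genome_bp <= 0:
        raise ValueError("genome has zero total length")

    n_bins = (2 * half_window) // bin_size
    counts = np.zeros(n_bins, dtype=np.int64)

    mids: dict[str, np.ndarray] = {}
    for chrom in features.chromosomes:
        mids[chrom] = np.sort(
            np.array([iv.center for iv in features if iv.chrom == chrom], dtype=np.int64)
        )
    for peak in ref:
        m = mids.get(peak.chrom)
        if m is None or len(m) == 0:
            continue
        c = peak.center
        lo = np.searchsorted(m, c - half_window, side="left")
        hi = np.searchsorted(m, c + half_window, side="left")
        offsets = m[lo:hi] - c
        np.add.at(counts, (offsets + half_window) // bin_size, 1)

    density = len(features) / genome_bp
    n_ref = len(ref)
    with np.errstate(divide="ignore", invalid="ignore"):
        fe = (counts / (max(n_ref, 1) * bin_size)) / density if density > 0 else np.full(n_bins, np.nan)
    centers = np.arange(n_bins) * bin_size - half_window + bin_size // 2
    return CoOccupancyProfile(
        bin_centers=centers,
        counts=counts,
        fold_enrichment=np.asarray(fe, dtype=float),
        n_reference=n_ref,
        bin_size=bin_size,
        half_window=half_window,
    )


def sample_random_intervals(
    n: int,
    genome: dict[str, int],
    lengths: list[int] | np.ndarray,
    seed: int | np.random.Generator = 0,
) -> IntervalSet:
    """n random intervals, length-matched to a reference length multiset.

    Each interval draws a length (with replacement) from ``lengths``, a
    chromosome with probability proportional to chromosome length among
    chromosomes long enough to hold it, and a start uniform in
    ``[0, chrom_len - L]``.  Fully reproducible from ``seed``.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    lengths = np.asarray(lengths, dtype=np.int64)
    if n > 0 and len(lengths) == 0:
        raise ValueError("need a non-empty length multiset")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = list(genome)
    chrom_lens = np.array([genome[c] for c in chroms], dtype=np.int64)
    if n > 0 and lengths.max() > chrom_lens.max():
        raise ValueError("a sampled length exceeds every chromosome length")
    out = []
    for i in range(n):
        L = int(rng.choice(lengths))
        ok = chrom_lens >= L
        probs = np.where(ok, chrom_lens, 0).astype(float)
        probs /= probs.sum()
        ci = int(rng.choice(len(chroms), p=probs))
        start = int(rng.integers(0, chrom_lens[ci] - L + 1))
        out.append(GenomicInterval(chroms[ci], start, start + L, name=f"random-{i + 1}"))
    return IntervalSet(out, genome=genome)


def overlap_stats(
    ref: IntervalSet,
    features: IntervalSet,
    window_bp: int = 100,
) -> tuple[int, float]:
    """(n_overlap, fraction): reference peaks with >= 1 feature within the window."""
    if len(ref) == 0:
        raise ValueError("reference set is empty")
    hit_refs = {q for q, _ in window_hits(ref, features, window_bp)}
    n_overlap = len(hit_refs)
    return n_overlap, n_overlap / len(ref)


def fisher_overlap_test(
    obs: tuple[int, int],
    rand: tuple[int, int],
) -> tuple[float, float]:
    """Two-sided Fisher's exact test of observed vs random overlap counts.

    ``obs = (n_overlap, n_ref)`` and ``rand = (n_overlap_random, n_random)``
    form the 2x2 table ``[[a, n_ref-a], [b, n_random-b]]``.  Returns
    (odds_ratio, p).  The odds ratio is the sample ratio ``ad/bc`` with a
    Haldane 0.5 correction applied only when some cell is zero; the p-value is
    reported unmodified.
    """
    a, n_ref = obs
    b, n_rand = rand
    if n_ref <= 0 or n_rand <= 0:
        raise ValueError("both totals must be positive")
    if not (0 <= a <= n_ref and 0 <= b <= n_rand):
        raise ValueError("overlap counts must lie within totals")
    table = np.array([[a, n_ref - a], [b, n_rand - b]], dtype=np.int64)
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if (table == 0).any():
        t = table + 0.5
    else:
        t = table.astype(float)
    odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return float(odds), float(p)


def f_score(
    ref: IntervalSet,
    features: IntervalSet,
    window_bp: int = 100,
    return_components: bool = False,
):
    """F-score of the interval-overlap agreement between two peak sets.

    precision = fraction of FEATURE intervals with >= 1 reference peak within
    the window; recall = fraction of REFERENCE peaks with >= 1 feature within
    the window; F = 2PR/(P+R), defined as 0 when P + R = 0.  Identical sets
    give F = 1 (perfect match).
    """
    if len(ref) == 0 or len(features) == 0:
        raise ValueError("both sets must be non-empty")
    pairs = window_hits(ref, features, window_bp)
    recall = len({q for q, _ in pairs}) / len(ref)
    precision = len({s for _, s in pairs}) / len(features)
    f = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    if return_components:
        return f, precision, recall
    return f


def coloc_panel(
    ref: IntervalSet,
    feature_panel: dict[str, IntervalSet],
    genome: dict[str, int] | None = None,
    window_bp: int = 100,
    n_random: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Overlap/Fisher/F-score panel: one row per feature set.

    Every feature set is tested against the SAME seeded random interval set
    (length-matched to the reference, ``n_random`` defaults to ``len(ref)``).
    Per-feature failures are reported as flagged rows, not raised.  A
    Benjamini–Hochberg adjusted p column is appended across the panel.
    """
    if not feature_panel:
        raise ValueError("feature panel is empty")
    if len(ref) == 0:
        raise ValueError("reference set is empty")
    genome = genome if genome is not None else ref.genome
    if not genome:
        raise ValueError("a genome table is required for the random null")
    n_random = n_random if n_random is not None else len(ref)
    lengths = [iv.length for iv in ref]
    random_set = sample_random_intervals(n_random, genome, lengths, seed=seed)

    rows: list[OverlapTestResult] = []
    for name, features in feature_panel.items():
        try:
            n_overlap, fraction = overlap_stats(ref, features, window_bp)
            n_rand_overlap, _ = overlap_stats(random_set, features, window_bp)
            odds, p = fisher_overlap_test((n_overlap, len(ref)), (n_rand_overlap, n_random))
            f = f_score(ref, features, window_bp)
            rows.append(
                OverlapTestResult(name, len(ref), n_overlap, fraction, n_random,
                                  n_rand_overlap, odds, p, f)
            )
        except Exception as exc:  # error isolation: flag the row, keep going
            rows.append(
                OverlapTestResult(name, len(ref), 0, float("nan"), n_random, 0,
                                  float("nan"), float("nan"), float("nan"), error=str(exc))
            )
    df = pd.DataFrame([r.__dict__ for r in rows])
    ok = df["p_value"].notna()
    df["p_adj_bh"] = np.nan
    if ok.any():
        df.loc[ok, "p_adj_bh"] = multipletests(df.loc[ok, "p_value"], method="fdr_bh")[1]
    return df


def format_p(p: float, floor: float = 2.2e-16) -> str:
    """Printed-style p-value: values below the double-precision reporting
    floor are shown as "< 2.2e-16"."""
    if np.isnan(p):
        return "NA"
    if p < floor:
        return f"< {floor:g}"
    return f"{p:.3g}"
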