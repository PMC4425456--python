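import numpy as np
import pytest

from regcoloc.annotation import Gene, GeneAnnotation, Transcript
from regcoloc.intervals import GenomicInterval, IntervalSet
from regcoloc.simulate import SimulationConfig, simulate_all


def make_gene(symbol, chrom, strand, start, end, exons=None, tid=None):
    exons = tuple(exons) if exons is not None else ((start, end),)
    tr = Transcript(tid or f"{symbol}.t1", chrom, start, end, strand, exons)
    return Gene(symbol, chrom, strand, (tr,))


@pytest.fixture(scope="session")
def sim_default():
    """One default synthetic dataset shared across tests (fixed seed)."""
    return simulate_all(SimulationConfig(seed=1234))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_interval_set(rng, n, chroms=("chr1", "chr2"), span=20_000, max_len=400, genome=None):
    """n random intervals for oracle comparisons (collision-prone coordinates)."""
    out = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length, name=f"iv{i}"))
    return IntervalSet(out, genome=genome)


def brute_force_window_pairs(query, subject, window_bp):
    """O(n^2) oracle for window_hits: explicit gap check on every pair."""
    pairs = set()
    for q in query:
        for s in subject:
            if q.chrom != s.chrom:
                continue
            if max(0, q.start - window_bp) < s.end and s.start < q.end + window_bp:
                pairs.add((q, s))
    return pairs


def brute_force_merge(iset):
    """Union-find oracle for merge_overlapping."""
    ivs = list(iset)
    parent = list(range(len(ivs)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(ivs)):
        for j in range(i + 1, len(ivs)):
            if ivs[i].overlaps(ivs[j]):
                parent[find(i)] = find(j)
    groups = {}
    for i, iv in enumerate(ivs):
        groups.setdefault(find(i), []).append(iv)
    return sorted(
        (g[0].chrom, min(iv.start for iv in g), max(iv.end for iv in g))
        for g in groups.values()
    )


def exact_fisher_two_sided(a, b, c, d):
    """Exact-rational two-sided Fisher p for table [[a, b], [c, d]].

    Sums hypergeometric probabilities over all tables with the same margins
    whose probability does not exceed the observed one (with the standard
    1 + 1e-7 relative tolerance for ties).
    """
    from fractions import Fraction
    from math import comb

    row1, col1, n = a + b, a + c, a + b + c + d
    denom = comb(n, col1)
    lo, hi = max(0, col1 - (n - row1)), min(row1, col1)
    pmf = {
        k: Fraction(comb(row1, k) * comb(n - row1, col1 - k), denom)
        for k in range(lo, hi + 1)
    }
    cutoff = pmf[a] * Fraction(10_000_001, 10_000_000)
    return sum(p for p in pmf.values() if p <= cutoff)


def unweighted_es_oracle(hit_flags):
    """Brute-force running-sum ES for weight exponent 0."""
    n = len(hit_flags)
    k = sum(hit_flags)
    rs, best = 0.0, 0.0
    for h in hit_flags:
        rs += 1.0 / k if h else -1.0 / (n - k)
        if abs(rs) > abs(best):
            best = rs
    return best
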