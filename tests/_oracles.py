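"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (dictionaries, quadratic scans,
enumeration) and shares no code with the implementation paths it checks.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from scipy.stats import hypergeom

_COMP = str.maketrans("ACGT", "TGCA")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def canonical_kmer_counts(contigs: dict[str, str], k: int) -> Counter:
    """Exhaustive dictionary enumeration of canonical k-mer counts."""
    counts: Counter = Counter()
    for seq in contigs.values():
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if set(w) - set("ACGT"):
                continue
            counts[min(w, rc(w))] += 1
    return counts


def single_copy_intervals(contigs: dict[str, str], k: int) -> dict[str, list[tuple[int, int]]]:
    """Positions whose canonical k-mer occurs exactly once, per contig."""
    counts = canonical_kmer_counts(contigs, k)
    out: dict[str, list[tuple[int, int]]] = {}
    for name, seq in contigs.items():
        ivs = []
        for i in range(len(seq) - k + 1):
            w = seq[i : i + k]
            if set(w) - set("ACGT"):
                continue
            if counts[min(w, rc(w))] == 1:
                ivs.append((i, i + k))
        out[name] = ivs
    return out


def probe_hit_count(probe: str, contigs: dict[str, str], max_mismatch: int) -> dict[str, int]:
    """Per-position Hamming-distance scan of a probe over both strands."""
    out = {}
    for name, seq in contigs.items():
        n = 0
        for query in (probe, rc(probe)):
            m = len(query)
            for i in range(len(seq) - m + 1):
                window = seq[i : i + m]
                mm = sum(1 for x, y in zip(window, query) if x != y or x not in "ACGT" or y not in "ACGT")
                if mm <= max_mismatch:
                    n += 1
        out[name] = n
    return out


def overlap_counts(records: list[tuple[str, int, int]], intervals: list[tuple[str, int, int]],
                   min_overlap: int = 1) -> list[int]:
    """Quadratic all-pairs overlap counting."""
    out = []
    for c, s, e in intervals:
        n = 0
        for rc_, rs, re in records:
            if rc_ == c and min(e, re) - max(s, rs) >= min_overlap:
                n += 1
        out.append(n)
    return out


def containment_retained(aln: tuple[str, int, int], track: dict[str, list[tuple[int, int]]]) -> bool:
    """Whole-k-mer containment rule, checked interval by interval."""
    c, s, e = aln
    return any(s <= ts and te <= e for ts, te in track.get(c, ()))


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration over fixed margins."""
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, r1, c1)
    p_obs = hypergeom.pmf(a, n, r1, c1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


def permutation_ttest_p(a: np.ndarray, b: np.ndarray, n_perm: int, seed: int) -> float:
    """Two-sided permutation p for the difference of means (label shuffling)."""
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    na = len(a)
    obs = abs(a.mean() - b.mean())
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(perm[:na].mean() - perm[na:].mean()) >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)
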