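"""Single-copy k-mer tracks and whole-k-mer containment filtering.

A k-mer is *single-copy* when its canonical form — the lexicographic minimum
of the k-mer and its reverse complement — occurs exactly once among all
k-length windows of the assembly (strand-collapsed counting, matching
standard k-mer-counter defaults). Windows containing N contribute nothing.

The containment filter retains a read alignment iff its reference span fully
contains at least one single-copy k-mer interval: full containment of a
unique k-mer certifies that the aligned locus is the only place in the
assembly the read's evidence is consistent with. Partial overlap (even k-1
of k bases) is not enough.

Windows are scanned with numpy: each k-mer is packed into base-4 integer
"parts" of at most 31 bases (so any k <= 64 fits in a row of int64 parts),
and global counts come from one ``np.unique`` over all window rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome import GenomeAssembly, encode_seq, revcomp

_MAX_PART = 31  # bases per int64 part; 4**31 < 2**62

K_PROSEQ = 21  # library insert is short for nuclear run-on data
K_RNASEQ = 51


def _part_sizes(k: int) -> list[int]:
    nparts = -(-k // _MAX_PART)
    base = k // nparts
    sizes = [base + (1 if i < k % nparts else 0) for i in range(nparts)]
    return sizes


def _window_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Pack every k-window of an encoded contig into rows of base-4 int64 parts."""
    n = len(arr)
    nwin = n - k + 1
    sizes = _part_sizes(k)
    codes = np.empty((nwin, len(sizes)), dtype=np.int64)
    a64 = arr.astype(np.int64)
    offset = 0
    for p, size in enumerate(sizes):
        c = np.zeros(nwin, dtype=np.int64)
        for j in range(offset, offset + size):
            c = c * 4 + a64[j : j + nwin]
        codes[:, p] = c
        offset += size
    return codes


def _canonical_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(valid_mask, canonical part-codes) for all k-windows of one contig."""
    n = len(arr)
    if n < k:
        return np.zeros(0, dtype=bool), np.zeros((0, len(_part_sizes(k))), dtype=np.int64)
    nwin = n - k + 1
    is_n = (arr >= 4).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(is_n)])
    valid = (cs[k:] - cs[:-k]) == 0  # no N anywhere in the window

    fwd = _window_codes(arr, k)
    rc_arr = np.where(arr >= 4, 4, 3 - arr)[::-1].copy()
    rev = _window_codes(rc_arr, k)[::-1]  # row i = revcomp of forward window i

    take_rev = np.zeros(nwin, dtype=bool)
    decided = np.zeros(nwin, dtype=bool)
    for p in range(fwd.shape[1]):
        less = rev[:, p] < fwd[:, p]
        greater = rev[:, p] > fwd[:, p]
        take_rev |= less & ~decided
        decided |= less | greater
    canon = np.where(take_rev[:, None], rev, fwd)
    return valid, canon


def _decode(row: np.ndarray, k: int) -> str:
    out = []
    for code, size in zip(row, _part_sizes(k)):
        part = []
        c = int(code)
        for _ in range(size):
            part.append("ACGT"[c % 4])
            c //= 4
        out.append("".join(reversed(part)))
    return "".join(out)


def _scan(assembly: GenomeAssembly, k: int):
    """Per-contig valid window positions and canonical codes, plus global counts."""
    if not 1 <= k <= 64:
        raise ValueError(f"k must be in [1, 64], got {k}")
    per_contig = []
    blocks = []
    for name, seq in assembly.contigs.items():
        valid, canon = _canonical_codes(encode_seq(seq), k)
        pos = np.nonzero(valid)[0]
        rows = canon[valid]
        per_contig.append((name, pos, rows))
        blocks.append(rows)
    allrows = (
        np.concatenate(blocks, axis=0) if blocks else np.zeros((0, len(_part_sizes(k))), dtype=np.int64)
    )
    if len(allrows):
        uniq, inverse, counts = np.unique(allrows, axis=0, return_inverse=True, return_counts=True)
    else:
        uniq = allrows
        inverse = np.zeros(0, dtype=np.int64)
        counts = np.zeros(0, dtype=np.int64)
    return per_contig, uniq, inverse.ravel(), counts


def count_kmers(assembly: GenomeAssembly, k: int) -> dict[str, int]:
    """Canonical k-mer multiset of the assembly as ``{k-mer: count}``.

    Every A/C/G/T-only window contributes 1 to its canonical k-mer's count.
    """
    _, uniq, _, counts = _scan(assembly, k)
    return {_decode(row, k): int(c) for row, c in zip(uniq, counts)}


@dataclass
class SingleCopyKmerTrack:
    """Per-contig sorted start positions of k-length windows whose canonical
    k-mer occurs exactly once in the assembly. Adjacent unique k-mers overlap
    by k-1, so intervals may overlap."""

    k: int
    starts: dict[str, np.ndarray] = field(default_factory=dict)
    source_assembly_id: str = ""

    @property
    def n_intervals(self) -> int:
        return sum(len(v) for v in self.starts.values())

    def intervals(self, contig: str) -> list[tuple[int, int]]:
        return [(int(s), int(s) + self.k) for s in self.starts.get(contig, ())]

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# single-copy k-mer track k={self.k} assembly={self.source_assembly_id}\n")
            for contig, starts in self.starts.items():
                for s in starts:
                    fh.write(f"{contig}\t{int(s)}\t{int(s) + self.k}\n")

    @classmethod
    def from_bed(cls, path: str | Path) -> "SingleCopyKmerTrack":
        k = None
        checksum = ""
        acc: dict[str, list[int]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    for tok in line.lstrip("# ").split():
                        if tok.startswith("k="):
                            k = int(tok[2:])
                        elif tok.startswith("assembly="):
                            checksum = tok[len("assembly=") :]
                    continue
                if not line:
                    continue
                contig, s, e = line.split("\t")[:3]
                acc.setdefault(contig, []).append(int(s))
                if k is None:
                    k = int(e) - int(s)
        if k is None:
            raise ValueError(f"{path}: no k found in header and no intervals")
        starts = {c: np.asarray(sorted(v), dtype=np.int64) for c, v in acc.items()}
        return cls(k=k, starts=starts, source_assembly_id=checksum)


def single_copy_kmer_track(assembly: GenomeAssembly, k: int) -> SingleCopyKmerTrack:
    """Build the single-copy (unique) k-mer track of an assembly.

    One interval per window whose canonical k-mer has global count exactly 1;
    deterministic given assembly and k.
    """
    per_contig, _, inverse, counts = _scan(assembly, k)
    is_single = counts == 1
    starts: dict[str, np.ndarray] = {}
    off = 0
    for name, pos, rows in per_contig:
        m = len(pos)
        sel = is_single[inverse[off : off + m]]
        starts[name] = pos[sel].astype(np.int64)
        off += m
    return SingleCopyKmerTrack(k=k, starts=starts, source_assembly_id=assembly.checksum())


def filter_alignments_by_containment(aset, track: SingleCopyKmerTrack):
    """Retain alignments whose reference span fully contains a single-copy k-mer.

    An alignment (contig, s, e) is kept iff some track interval [t, t+k)
    satisfies s <= t and t+k <= e. Retained alignments are unchanged; a read
    may retain multiple alignments. The alignment set and the track must come
    from the same assembly (checksum match is a hard error otherwise).
    Returns a new AlignmentSet with mode="k100_filtered".
    """
    from .profiles import AlignmentSet  # local import to avoid a cycle

    if aset.assembly_checksum and track.source_assembly_id and aset.assembly_checksum != track.source_assembly_id:
        raise ValueError(
            "alignment set and k-mer track refer to different assemblies "
            f"({aset.assembly_checksum} != {track.source_assembly_id})"
        )
    k = track.k
    kept = []
    for aln in aset.alignments:
        starts = track.starts.get(aln.contig)
        if starts is None or len(starts) == 0 or aln.end - aln.start < k:
            continue
        lo = np.searchsorted(starts, aln.start, side="left")
        hi = np.searchsorted(starts, aln.end - k, side="right")
        if hi > lo:
            kept.append(aln)
    return AlignmentSet(
        mode="k100_filtered",
        alignments=kept,
        assembly_checksum=aset.assembly_checksum,
        library=aset.library,
        orientation=aset.orientation,
    )


def kmer_coverage_per_interval(track: SingleCopyKmerTrack, intervals: Iterable) -> "pd.DataFrame":
    """Unique-k-mer content of query intervals.

    ``count`` = number of track intervals fully inside the query;
    ``fraction`` = query positions covered by >= 1 single-copy k-mer (any
    overlap) divided by query length.
    Accepts (contig, start, end[, name]) tuples or objects with
    .contig/.start/.end/.element_id attributes.
    """
    import pandas as pd

    k = track.k
    rows = []
    for iv in intervals:
        if hasattr(iv, "contig"):
            contig, s, e = iv.contig, iv.start, iv.end
            name = getattr(iv, "element_id", None) or f"{contig}:{s}-{e}"
        else:
            contig, s, e = iv[0], iv[1], iv[2]
            name = iv[3] if len(iv) > 3 else f"{contig}:{s}-{e}"
        starts = track.starts.get(contig, np.zeros(0, dtype=np.int64))
        lo = np.searchsorted(starts, s, side="left")
        hi = np.searchsorted(starts, e - k, side="right")
        count = max(0, int(hi - lo))
        # any-overlap set for base coverage
        lo2 = np.searchsorted(starts, s - k, side="right")
        hi2 = np.searchsorted(starts, e, side="left")
        sel = starts[lo2:hi2]
        if len(sel):
            a = np.maximum(sel, s)
            b = np.minimum(sel + k, e)
            gaps = np.maximum(0, a[1:] - b[:-1]).sum() if len(sel) > 1 else 0
            covered = int(b[-1] - a[0] - gaps)
        else:
            covered = 0
        rows.append(
            {
                "name": name,
                "contig": contig,
                "start": s,
                "end": e,
                "count": count,
                "covered_bp": covered,
                "fraction": covered / (e - s) if e > s else 0.0,
            }
        )
    return pd.DataFrame(rows)
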