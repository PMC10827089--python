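"""Alignment reporting modes, PRO-seq 3'-end signal, counting and density matrices.

Three alignment-reporting modes bound locus-level transcription of multi-copy
repeats:

* ``best_match`` — one placement per read (lower-bound style profile);
* ``k100``       — up to 100 placements per read (over-fit upper bound);
* ``k100_filtered`` — a k100 set restricted to alignments that fully contain
  a single-copy k-mer (intermediate bound; see :mod:`centrotx.kmers`).

For PRO-seq, each read's 3' end marks the position of an engaged RNA
polymerase: a +-strand alignment [s, e) contributes position e-1 on +, a
--strand alignment contributes position s on -. When the library was
prepared with read 1 reverse-complemented before alignment
(``orientation="read1_revcomp"``), the mapped strand is flipped to recover
the transcript strand before applying the same rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeAssembly, RepeatElement

MODES = ("best_match", "k100", "k100_filtered")
LIBRARIES = ("proseq", "rnaseq")
ORIENTATIONS = ("reads_are_sense", "read1_revcomp")
K100_CAP = 100  # reporting cap: up to 100 mapped loci per read


@dataclass
class ReadAlignment:
    read_id: str
    contig: str
    start: int
    end: int
    strand: str
    mismatches: int = 0
    mate_span: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.read_id}: start must be < end")
        if self.mismatches < 0:
            raise ValueError(f"{self.read_id}: negative mismatch count")
        if self.strand not in "+-":
            raise ValueError(f"{self.read_id}: strand must be '+' or '-'")


@dataclass
class AlignmentSet:
    """Read placements under one reporting mode."""

    mode: str
    alignments: list[ReadAlignment] = field(default_factory=list)
    assembly_checksum: str = ""
    library: str = "proseq"
    orientation: str = "reads_are_sense"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.library not in LIBRARIES:
            raise ValueError(f"unknown library {self.library!r}")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"unknown orientation {self.orientation!r}")
        self.validate()

    def validate(self) -> None:
        """Enforce the per-read reporting caps of the mode."""
        per_read: dict[str, int] = {}
        for aln in self.alignments:
            per_read[aln.read_id] = per_read.get(aln.read_id, 0) + 1
        if self.mode == "best_match":
            bad = sorted(r for r, n in per_read.items() if n > 1)
            if bad:
                raise ValueError(
                    f"best_match mode allows one alignment per read; offending read_ids: {bad[:10]}"
                )
        else:
            bad = sorted(r for r, n in per_read.items() if n > K100_CAP)
            if bad:
                raise ValueError(
                    f"k100 modes allow at most {K100_CAP} alignments per read; "
                    f"offending read_ids: {bad[:10]}"
                )

    @property
    def n_reads(self) -> int:
        return len({a.read_id for a in self.alignments})

    def sorted_alignments(self, assembly: GenomeAssembly | None = None) -> list[ReadAlignment]:
        """Deterministic order: (contig order in assembly, start, read_id)."""
        if assembly is not None:
            order = {c: i for i, c in enumerate(assembly.contig_order)}
            key = lambda a: (order.get(a.contig, len(order)), a.contig, a.start, a.read_id, a.strand)
        else:
            key = lambda a: (a.contig, a.start, a.read_id, a.strand)
        return sorted(self.alignments, key=key)


@dataclass
class ThreePrimeSignal:
    """Single-base RNA-polymerase occupancy records, one per alignment."""

    records: list[tuple[str, int, str]] = field(default_factory=list)  # (contig, position, strand)

    def __len__(self) -> int:
        return len(self.records)

    def per_contig(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """contig -> (positions int64 array, strand '+'-mask) for vectorized counting."""
        acc: dict[str, list[tuple[int, bool]]] = {}
        for contig, pos, strand in self.records:
            acc.setdefault(contig, []).append((pos, strand == "+"))
        out = {}
        for contig, items in acc.items():
            pos = np.asarray([p for p, _ in items], dtype=np.int64)
            plus = np.asarray([s for _, s in items], dtype=bool)
            out[contig] = (pos, plus)
        return out


def load_alignments(
    path: str | Path,
    mode: str,
    library: str = "proseq",
    orientation: str = "reads_are_sense",
    assembly_checksum: str = "",
) -> AlignmentSet:
    """Read the 7-column alignment table.

    Columns: contig, start, end, read_id, mismatches, strand,
    mate_span as ``start:end`` or ``.``. Mode invariants are enforced on
    load — violations are hard errors, never silent truncation.
    """
    alignments: list[ReadAlignment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 7:
                raise ValueError(f"{path}:{lineno}: expected 7 columns, got {len(fields)}")
            contig, start, end, read_id, mm, strand, mate = fields[:7]
            mate_span = None
            if mate != ".":
                ms, me = mate.split(":")
                mate_span = (int(ms), int(me))
            alignments.append(
                ReadAlignment(
                    read_id=read_id,
                    contig=contig,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    mismatches=int(mm),
                    mate_span=mate_span,
                )
            )
    return AlignmentSet(
        mode=mode,
        alignments=alignments,
        assembly_checksum=assembly_checksum,
        library=library,
        orientation=orientation,
    )


def write_alignments(aset: AlignmentSet, path: str | Path, assembly: GenomeAssembly | None = None) -> None:
    """Serialize in the 7-column dialect, deterministically ordered."""
    with open(path, "w") as fh:
        for a in aset.sorted_alignments(assembly):
            mate = f"{a.mate_span[0]}:{a.mate_span[1]}" if a.mate_span else "."
            fh.write(f"{a.contig}\t{a.start}\t{a.end}\t{a.read_id}\t{a.mismatches}\t{a.strand}\t{mate}\n")


def extract_three_prime_ends(aset: AlignmentSet) -> ThreePrimeSignal:
    """PRO-seq 3'-end (polymerase occupancy) positions, one record per alignment.

    Raises for RNA-seq sets: 3'-end extraction is PRO-seq-specific.
    """
    if aset.library != "proseq":
        raise ValueError("3'-end extraction is defined for PRO-seq libraries only")
    flip = aset.orientation == "read1_revcomp"
    records: list[tuple[str, int, str]] = []
    for a in aset.alignments:
        strand = a.strand
        if flip:
            strand = "-" if strand == "+" else "+"
        if strand == "+":
            records.append((a.contig, a.end - 1, "+"))
        else:
            records.append((a.contig, a.start, "-"))
    return ThreePrimeSignal(records=records)


def _as_interval(iv) -> tuple[str, int, int, str]:
    if hasattr(iv, "contig"):
        name = getattr(iv, "element_id", None) or getattr(iv, "domain_id", None)
        return iv.contig, iv.start, iv.end, name or f"{iv.contig}:{iv.start}-{iv.end}"
    contig, s, e = iv[0], iv[1], iv[2]
    name = iv[3] if len(iv) > 3 else f"{contig}:{s}-{e}"
    return contig, s, e, name


def count_over_intervals(
    data: AlignmentSet | ThreePrimeSignal,
    intervals: Iterable,
    min_overlap_bp: int = 1,
    strand: str | None = None,
) -> pd.Series:
    """Per-interval record counts under the >= ``min_overlap_bp`` overlap rule.

    Alignments count toward an interval iff their reference span overlaps it
    by at least ``min_overlap_bp``; 3'-end records iff the single base lies in
    the interval. One record may count toward several overlapping intervals.
    Strand is ignored unless ``strand`` ('+' or '-') is given (sense /
    antisense reporting).
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    ivs = [_as_interval(iv) for iv in intervals]
    counts = np.zeros(len(ivs), dtype=np.int64)

    if isinstance(data, ThreePrimeSignal):
        per_contig = data.per_contig()
        for i, (contig, s, e, _) in enumerate(ivs):
            got = per_contig.get(contig)
            if got is None:
                continue
            pos, plus = got
            sel = (pos >= s) & (pos < e)
            if strand is not None:
                sel &= plus if strand == "+" else ~plus
            counts[i] = int(np.count_nonzero(sel))
    else:
        acc: dict[str, list[tuple[int, int, bool]]] = {}
        for a in data.alignments:
            acc.setdefault(a.contig, []).append((a.start, a.end, a.strand == "+"))
        arrs = {
            c: (
                np.asarray([s for s, _, _ in v], dtype=np.int64),
                np.asarray([e for _, e, _ in v], dtype=np.int64),
                np.asarray([p for _, _, p in v], dtype=bool),
            )
            for c, v in acc.items()
        }
        for i, (contig, s, e, _) in enumerate(ivs):
            got = arrs.get(contig)
            if got is None:
                continue
            starts, ends, plus = got
            overlap = np.minimum(ends, e) - np.maximum(starts, s)
            sel = overlap >= min_overlap_bp
            if strand is not None:
                sel &= plus if strand == "+" else ~plus
            counts[i] = int(np.count_nonzero(sel))
    return pd.Series(counts, index=[name for _, _, _, name in ivs], name="count")


@dataclass
class RepeatCountMatrix:
    """Per-family x per-contig counts, densities and copy numbers.

    density(family, contig) = reads overlapping any copy of the family on the
    contig, divided by total reads mapping to that contig. Contigs with zero
    mapped reads have NA densities.
    """

    counts: pd.DataFrame
    density: pd.DataFrame
    copy_number: pd.DataFrame
    contig_totals: pd.Series

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for label, df in (("counts", self.counts), ("density", self.density), ("copy_number", self.copy_number)):
                fh.write(f"# {label}\n")
                df.to_csv(fh, sep="\t", float_format="%.6g")
            fh.write("# contig_totals\n")
            self.contig_totals.to_frame("total").T.to_csv(fh, sep="\t")


def repeat_density_matrix(
    data: AlignmentSet | ThreePrimeSignal,
    elements: Sequence[RepeatElement],
    assembly: GenomeAssembly,
) -> RepeatCountMatrix:
    """The per-repeat / per-contig normalized density matrix.

    A record overlapping two copies of the same family on one contig counts
    once toward that cell (prevents double counting in nested clusters).
    """
    families = sorted({el.family for el in elements})
    contigs = assembly.contig_order
    fam_idx = {f: i for i, f in enumerate(families)}
    ctg_idx = {c: i for i, c in enumerate(contigs)}

    counts = np.zeros((len(families), len(contigs)), dtype=np.int64)
    copy_number = np.zeros_like(counts)
    for el in elements:
        copy_number[fam_idx[el.family], ctg_idx[el.contig]] += 1

    by_contig_elements: dict[str, list[RepeatElement]] = {}
    for el in elements:
        by_contig_elements.setdefault(el.contig, []).append(el)

    totals = np.zeros(len(contigs), dtype=np.int64)
    if isinstance(data, ThreePrimeSignal):
        per_contig = data.per_contig()
        for contig, (pos, _) in per_contig.items():
            if contig not in ctg_idx:
                continue
            totals[ctg_idx[contig]] = len(pos)
            for fam in families:
                els = [el for el in by_contig_elements.get(contig, []) if el.family == fam]
                if not els:
                    continue
                hit = np.zeros(len(pos), dtype=bool)
                for el in els:
                    hit |= (pos >= el.start) & (pos < el.end)
                counts[fam_idx[fam], ctg_idx[contig]] = int(np.count_nonzero(hit))
    else:
        acc: dict[str, list[tuple[int, int]]] = {}
        for a in data.alignments:
            acc.setdefault(a.contig, []).append((a.start, a.end))
        for contig, spans in acc.items():
            if contig not in ctg_idx:
                continue
            starts = np.asarray([s for s, _ in spans], dtype=np.int64)
            ends = np.asarray([e for _, e in spans], dtype=np.int64)
            totals[ctg_idx[contig]] = len(starts)
            for fam in families:
                els = [el for el in by_contig_elements.get(contig, []) if el.family == fam]
                if not els:
                    continue
                hit = np.zeros(len(starts), dtype=bool)
                for el in els:
                    hit |= (np.minimum(ends, el.end) - np.maximum(starts, el.start)) >= 1
                counts[fam_idx[fam], ctg_idx[contig]] = int(np.count_nonzero(hit))

    counts_df = pd.DataFrame(counts, index=families, columns=contigs)
    copy_df = pd.DataFrame(copy_number, index=families, columns=contigs)
    totals_s = pd.Series(totals, index=contigs, name="total")
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = counts / totals[np.newaxis, :]
    dens[:, totals == 0] = np.nan  # zero mapped reads: density undefined, flagged NA
    density_df = pd.DataFrame(dens, index=families, columns=contigs)
    counts_df.index.name = density_df.index.name = copy_df.index.name = "family"
    return RepeatCountMatrix(counts=counts_df, density=density_df, copy_number=copy_df, contig_totals=totals_s)


def per_element_counts(
    data: AlignmentSet | ThreePrimeSignal,
    elements: Sequence[RepeatElement],
    min_overlap_bp: int = 1,
) -> pd.DataFrame:
    """Per-copy read counts plus counts-per-kb (length-normalized density)."""
    counts = count_over_intervals(data, elements, min_overlap_bp=min_overlap_bp)
    df = pd.DataFrame(
        {
            "element_id": [el.element_id for el in elements],
            "contig": [el.contig for el in elements],
            "length": [el.length for el in elements],
            "count": counts.to_numpy(),
        }
    )
    df["count_per_kb"] = df["count"] / (df["length"] / 1000.0)
    return df.set_index("element_id")


def write_coverage(
    data: AlignmentSet | ThreePrimeSignal,
    path: str | Path,
    stranded: bool = False,
    assembly: GenomeAssembly | None = None,
) -> list[Path]:
    """Write bedGraph coverage.

    3'-end signal is written at base resolution; alignment sets as span
    coverage. With ``stranded=True`` two files are written with ``.plus`` /
    ``.minus`` inserted before the extension. The sum of emitted values
    equals the number of records (conservation).
    """
    path = Path(path)

    def _write(records: list[tuple[str, int, int, int]], out: Path, label: str) -> None:
        order = {c: i for i, c in enumerate(assembly.contig_order)} if assembly else None
        records.sort(key=lambda r: (order.get(r[0], 0) if order else 0, r[0], r[1]))
        with open(out, "w") as fh:
            fh.write(f'track type=bedGraph name="{label}"\n')
            for contig, s, e, v in records:
                fh.write(f"{contig}\t{s}\t{e}\t{v}\n")

    def _signal_records(sig: ThreePrimeSignal, strand: str | None) -> list[tuple[str, int, int, int]]:
        acc: dict[tuple[str, int], int] = {}
        for contig, pos, st in sig.records:
            if strand is not None and st != strand:
                continue
            acc[(contig, pos)] = acc.get((contig, pos), 0) + 1
        return [(c, p, p + 1, v) for (c, p), v in acc.items()]

    def _span_records(aset: AlignmentSet, strand: str | None) -> list[tuple[str, int, int, int]]:
        # piecewise-constant coverage from span starts/ends
        acc: dict[str, list[tuple[int, int]]] = {}
        for a in aset.alignments:
            if strand is not None and a.strand != strand:
                continue
            acc.setdefault(a.contig, []).append((a.start, a.end))
        out: list[tuple[str, int, int, int]] = []
        for contig, spans in acc.items():
            edges = sorted({x for s, e in spans for x in (s, e)})
            starts = np.asarray([s for s, _ in spans])
            ends = np.asarray([e for _, e in spans])
            for a, b in zip(edges[:-1], edges[1:]):
                cov = int(np.count_nonzero((starts <= a) & (ends >= b)))
                if cov > 0:
                    out.append((contig, a, b, cov))
        return out

    maker = _signal_records if isinstance(data, ThreePrimeSignal) else _span_records
    written: list[Path] = []
    if stranded:
        for strand, tag in (("+", "plus"), ("-", "minus")):
            out = path.with_name(f"{path.stem}.{tag}{path.suffix or '.bedGraph'}")
            _write(maker(data, strand), out, f"{path.stem}.{tag}")
            written.append(out)
    else:
        _write(maker(data, None), path, path.stem)
        written.append(path)
    return written
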