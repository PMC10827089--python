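"""Genome assembly and repeat-annotation handling.

Coordinates are 0-based half-open (BED convention) throughout the package;
any 1-based external representation is converted at the I/O boundary.

A repeat copy is *full-length* iff its consensus interval fully contains the
family's ORF2 interval; otherwise it is *truncated*. Completeness is decided
purely from consensus coverage, never from element length.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# byte-level encoding used by the numpy scanners: A,C,G,T -> 0..3, anything else 4
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode_seq(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0,C=1,G=2,T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class GenomeAssembly:
    """Named contigs plus a set of contig ids flagged as centromeric.

    ``contigs`` preserves file order (dicts are insertion-ordered).
    ``softmask`` keeps the lowercase (soft-masked) positions of the source
    FASTA as boolean arrays; it is carried along but ignored by every
    downstream operation.
    """

    contigs: dict[str, str]
    centromeric_ids: frozenset[str] = frozenset()
    softmask: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        missing = set(self.centromeric_ids) - set(self.contigs)
        if missing:
            raise ValueError(f"centromeric ids not present in assembly: {sorted(missing)}")
        self.centromeric_ids = frozenset(self.centromeric_ids)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    @property
    def contig_order(self) -> list[str]:
        return list(self.contigs)

    def checksum(self) -> str:
        """MD5 over contig ids and uppercase sequences; identifies the assembly."""
        h = hashlib.md5()
        for name, seq in self.contigs.items():
            h.update(f">{name}\n".encode())
            h.update(seq.encode())
        return h.hexdigest()

    def encoded(self) -> dict[str, np.ndarray]:
        return {name: encode_seq(seq) for name, seq in self.contigs.items()}


@dataclass
class FamilyModel:
    """Consensus model of a repeat family with its ORF2 interval (bp on consensus)."""

    family: str
    consensus_length: int
    orf2_start: int
    orf2_end: int

    def __post_init__(self) -> None:
        if not (0 <= self.orf2_start < self.orf2_end <= self.consensus_length):
            raise ValueError(
                f"invalid ORF2 interval [{self.orf2_start},{self.orf2_end}) "
                f"for consensus of length {self.consensus_length}"
            )


@dataclass
class RepeatElement:
    """One annotated repeat copy, with the consensus interval it covers."""

    element_id: str
    contig: str
    start: int
    end: int
    strand: str
    family: str
    consensus_start: int
    consensus_end: int
    completeness: str | None = None  # "full_length" | "truncated", set by classify_elements

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.element_id}: invalid interval [{self.start},{self.end})")
        if self.consensus_start >= self.consensus_end:
            raise ValueError(
                f"{self.element_id}: invalid consensus interval "
                f"[{self.consensus_start},{self.consensus_end})"
            )
        if self.strand not in "+-":
            raise ValueError(f"{self.element_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start


def load_assembly(path: str | Path, centromeric_ids: Sequence[str] = ()) -> GenomeAssembly:
    """Load a FASTA assembly, flagging ``centromeric_ids`` as centromere contigs.

    Sequences are uppercased; the soft-mask (lowercase) pattern is preserved as
    a boolean attribute but ignored downstream. Contig order = file order.
    Duplicate headers, missing centromeric ids and empty files are hard errors.
    """
    contigs: dict[str, str] = {}
    softmask: dict[str, np.ndarray] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate FASTA header: {rec.id!r}")
        raw = str(rec.seq)
        contigs[rec.id] = raw.upper()
        mask = np.frombuffer(raw.encode("ascii"), dtype=np.uint8)
        softmask[rec.id] = (mask >= ord("a")) & (mask <= ord("z"))
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    missing = set(centromeric_ids) - set(contigs)
    if missing:
        raise ValueError(f"centromeric ids absent from {path}: {sorted(missing)}")
    return GenomeAssembly(contigs=contigs, centromeric_ids=frozenset(centromeric_ids), softmask=softmask)


def write_assembly(assembly: GenomeAssembly, path: str | Path) -> None:
    """Write the assembly as FASTA, line-wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in assembly.contigs.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


def load_repeat_annotation(path: str | Path, assembly: GenomeAssembly) -> list[RepeatElement]:
    """Read the BED6+2 repeat annotation dialect.

    Columns: contig, start, end, element_id, score (ignored), strand,
    family, consensus interval as ``start:end``. Intervals are validated
    against contig bounds; completeness is left unset until
    :func:`classify_elements`.
    """
    elements: list[RepeatElement] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(f"{path}:{lineno}: expected 8 columns (BED6+2), got {len(fields)}")
            contig, start_s, end_s, element_id, _score, strand, family, cons = fields[:8]
            try:
                start, end = int(start_s), int(end_s)
                cons_start_s, cons_end_s = cons.split(":")
                cons_start, cons_end = int(cons_start_s), int(cons_end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed columns: {exc}") from None
            if contig not in assembly.contigs:
                raise ValueError(f"{path}:{lineno}: unknown contig {contig!r}")
            if not (0 <= start < end <= len(assembly.contigs[contig])):
                raise ValueError(
                    f"{path}:{lineno}: interval [{start},{end}) out of bounds for "
                    f"{contig} (length {len(assembly.contigs[contig])})"
                )
            elements.append(
                RepeatElement(
                    element_id=element_id,
                    contig=contig,
                    start=start,
                    end=end,
                    strand=strand,
                    family=family,
                    consensus_start=cons_start,
                    consensus_end=cons_end,
                )
            )
    return elements


def write_repeat_annotation(elements: Iterable[RepeatElement], path: str | Path) -> None:
    """Serialize elements in the BED6+2 dialect read by :func:`load_repeat_annotation`."""
    with open(path, "w") as fh:
        for el in elements:
            fh.write(
                f"{el.contig}\t{el.start}\t{el.end}\t{el.element_id}\t0\t{el.strand}\t"
                f"{el.family}\t{el.consensus_start}:{el.consensus_end}\n"
            )


def classify_elements(
    elements: Iterable[RepeatElement],
    models: FamilyModel | Mapping[str, FamilyModel],
) -> list[RepeatElement]:
    """Set completeness on each element from its consensus coverage.

    full_length iff consensus_start <= orf2_start and consensus_end >= orf2_end
    (the copy contains the family's entire ORF2). Families without a model are
    labeled truncated with a warning. Idempotent; genomic coordinates are
    never consulted.
    """
    if isinstance(models, FamilyModel):
        models = {models.family: models}
    out: list[RepeatElement] = []
    warned: set[str] = set()
    for el in elements:
        model = models.get(el.family)
        if model is None:
            if el.family not in warned:
                warned.add(el.family)
                logger.warning("no family model for %r; labeling its copies truncated", el.family)
                warnings.warn(f"no family model for {el.family!r}; labeling truncated", stacklevel=2)
            out.append(replace(el, completeness="truncated"))
            continue
        full = el.consensus_start <= model.orf2_start and el.consensus_end >= model.orf2_end
        out.append(replace(el, completeness="full_length" if full else "truncated"))
    return out


def load_family_models(path: str | Path) -> dict[str, FamilyModel]:
    """Read family models from TSV (family, consensus_length, orf2_start, orf2_end)."""
    df = pd.read_csv(path, sep="\t")
    required = {"family", "consensus_length", "orf2_start", "orf2_end"}
    if not required.issubset(df.columns):
        raise ValueError(f"family model table must have columns {sorted(required)}")
    return {
        row.family: FamilyModel(row.family, int(row.consensus_length), int(row.orf2_start), int(row.orf2_end))
        for row in df.itertuples()
    }


def _probe_hits_on_contig(probe_arr: np.ndarray, contig_arr: np.ndarray, max_mismatch: int) -> int:
    """Number of offsets where the probe matches with <= max_mismatch substitutions.

    N (or any non-ACGT base) never matches, on either side.
    """
    m, n = len(probe_arr), len(contig_arr)
    if n < m:
        return 0
    nwin = n - m + 1
    mm = np.zeros(nwin, dtype=np.int32)
    probe_is_n = probe_arr >= 4
    for j in range(m):
        col = contig_arr[j : j + nwin]
        mm += ((col != probe_arr[j]) | (col >= 4) | probe_is_n[j]).astype(np.int32)
    return int(np.count_nonzero(mm <= max_mismatch))


def probe_target_census(
    probes: Mapping[str, str] | str | Path,
    assembly: GenomeAssembly,
    max_mismatch: int = 0,
) -> pd.DataFrame:
    """Census probe oligos against every contig, both strands.

    A hit is any position on either strand where the probe matches with
    <= ``max_mismatch`` substitutions (brute-force scan; probes are short).
    Returns a DataFrame with one row per probe: per-contig hit counts, a
    ``total`` column and an ``any_hit`` boolean. Probes containing non-ACGT
    characters are skipped with a warning.
    """
    if not isinstance(probes, Mapping):
        probes = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(probes), "fasta")}
    if max_mismatch < 0 or max_mismatch > 3:
        raise ValueError("max_mismatch must be in [0, 3]")
    enc = assembly.encoded()
    rows = []
    index = []
    for name, seq in probes.items():
        seq = seq.upper()
        if len(seq) > 60:
            raise ValueError(f"probe {name!r} longer than 60 nt")
        if set(seq) - set("ACGT"):
            logger.warning("probe %r contains non-ACGT characters; skipped", name)
            warnings.warn(f"probe {name!r} contains non-ACGT characters; skipped", stacklevel=2)
            continue
        fwd = encode_seq(seq)
        rev = encode_seq(revcomp(seq))
        counts = {}
        for contig, arr in enc.items():
            counts[contig] = _probe_hits_on_contig(fwd, arr, max_mismatch) + _probe_hits_on_contig(
                rev, arr, max_mismatch
            )
        index.append(name)
        rows.append(counts)
    df = pd.DataFrame(rows, index=index, columns=assembly.contig_order).fillna(0).astype(int)
    df.index.name = "probe"
    df["total"] = df.sum(axis=1)
    df["any_hit"] = df["total"] > 0
    return df
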