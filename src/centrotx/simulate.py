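"""Ground-truthed synthetic genomes, nascent reads, alignments and peak calls.

The generator emulates the structures the pipeline is built for:

* centromere contigs carrying an *island* of retroelement copies embedded in
  simple-satellite arrays, plus arm contigs carrying copies in random
  background sequence;
* one retroelement family with full-length copies (whole consensus) and
  5'-truncated copies (3'-anchored consensus suffixes, the non-LTR
  truncation mode), each copy independently diverged by point substitutions;
* nascent (PRO-seq-style) reads emitted from a designated active subset of
  copies, with uniform 3'-end positions on the copy's sense strand;
* multi-mapping ambiguity, resolved by an exact brute-force multi-mapper
  that reports either a single best placement or up to 100 placements;
* peak calls covering designated CENP-A regions.

The default configuration mirrors the copy census of the system the package
models: 329 copies of one Jockey-like family over five centromere contigs
(2/11/21/21/147 copies; nine full-length copies all on the Y centromere) and
two arm contigs (127 copies, 14 full-length).

Every stage draws from its own RNG stream seeded as (seed, stage tag), so
stages are independently reproducible and byte-identical under a fixed seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .genome import FamilyModel, GenomeAssembly, RepeatElement, encode_seq, revcomp
from .profiles import AlignmentSet, K100_CAP, ReadAlignment

logger = logging.getLogger(__name__)

_TAG_GENOME, _TAG_READS, _TAG_MAPPER, _TAG_PEAKS = 11, 22, 33, 44
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions for the synthetic genome.

    Copy counts default to the modeled system's census (five centromere
    contigs with 2/11/21/21/147 copies, two arms with 64+63; full-length
    copies: 9 on cenY, 7 per arm). Divergence defaults to 5% substitutions
    per bp — enough for most copies to carry unique 21-mers. Truncated
    copies retain a uniform 10-70% 3' suffix of the consensus, so no
    truncated copy contains the full ORF2.
    """

    seed: int = 0
    centromeric_contigs: tuple[str, ...] = ("cen2", "cen3", "cen4", "cenX", "cenY")
    arm_contigs: tuple[str, ...] = ("arm2", "arm3")
    copies_per_contig: dict[str, int] = field(
        default_factory=lambda: {
            "cen2": 2, "cen3": 11, "cen4": 21, "cenX": 21, "cenY": 147,
            "arm2": 64, "arm3": 63,
        }
    )
    fl_per_contig: dict[str, int] = field(default_factory=lambda: {"cenY": 9, "arm2": 7, "arm3": 7})
    family: str = "jockey3"
    consensus_length: int = 4500
    orf2: tuple[int, int] = (1300, 4200)
    truncation_frac: tuple[float, float] = (0.1, 0.7)  # retained 3' suffix, fraction of consensus
    divergence: float = 0.05  # substitutions per bp, per copy
    satellite_unit: str = "AATAT"
    satellite_flank_len: int = 3000
    island_slack_frac: float = 0.5  # background sequence inside islands, as fraction of copy bp
    island_length: int | None = None  # explicit island size; error if copies do not fit
    arm_flank_len: int = 5000
    cenpa_noncen_copy_fraction: float = 0.15  # arm copies designated CENP-A-associated
    # reads
    library: str = "proseq"
    read_length: int = 100
    depth: int = 10  # reads per active copy
    seq_error_rate: float = 0.0
    active_policy: str = "fl_cenpa"  # "fl_cenpa" | "fl" | "fraction" | "explicit"
    active_fraction: float = 0.3
    active_copies: tuple[str, ...] | None = None
    antisense: bool = False
    read1_revcomp: bool = False
    # mapping / filtering
    max_mismatch: int = 1
    k_proseq: int = 21
    k_rnaseq: int = 51

    @property
    def k(self) -> int:
        return self.k_proseq if self.library == "proseq" else self.k_rnaseq

    def family_model(self) -> FamilyModel:
        return FamilyModel(self.family, self.consensus_length, *self.orf2)

    def validate(self) -> None:
        for name, rate in (
            ("divergence", self.divergence),
            ("seq_error_rate", self.seq_error_rate),
            ("cenpa_noncen_copy_fraction", self.cenpa_noncen_copy_fraction),
            ("active_fraction", self.active_fraction),
        ):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")
        lo, hi = self.truncation_frac
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError("truncation_frac must satisfy 0 < lo <= hi <= 1")
        if self.read_length < self.k:
            warnings.warn(
                f"read_length {self.read_length} < k {self.k}: containment filtering will retain nothing",
                stacklevel=2,
            )


def small_config(seed: int = 0, **overrides) -> SimConfig:
    """Desk-scale configuration (two centromere contigs, one arm, ~40 copies)."""
    cfg = SimConfig(
        seed=seed,
        centromeric_contigs=("cenA", "cenB"),
        arm_contigs=("arm1",),
        copies_per_contig={"cenA": 8, "cenB": 16, "arm1": 14},
        fl_per_contig={"cenB": 4, "arm1": 3},
        satellite_flank_len=1500,
        arm_flank_len=2000,
    )
    return replace(cfg, **overrides)


def twin_config(seed: int = 0, depth: int = 500, **overrides) -> SimConfig:
    """Two identical (divergence-0) full-length copies on one centromere contig.

    The classic ambiguity stress case: no interior k-mer is single-copy, so
    containment filtering retains nothing inside the twins, the report-all
    mode doubles the true count, and best-match splits reads ~50/50.
    """
    cfg = SimConfig(
        seed=seed,
        centromeric_contigs=("cenT",),
        arm_contigs=(),
        copies_per_contig={"cenT": 2},
        fl_per_contig={"cenT": 2},
        divergence=0.0,
        depth=depth,
        active_policy="fl",
        satellite_flank_len=1500,
    )
    return replace(cfg, **overrides)


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset."""

    elements: list[RepeatElement]
    active_ids: list[str]
    cenpa_regions: list[tuple[str, int, int, str]]  # (contig, start, end, klass intent)
    reads: list[dict] = field(default_factory=list)  # per-read source records

    def element(self, element_id: str) -> RepeatElement:
        for el in self.elements:
            if el.element_id == element_id:
                return el
        raise KeyError(element_id)


@dataclass
class SimRead:
    read_id: str
    seq: str
    copy_id: str
    contig: str
    start: int  # genomic span of the true placement
    end: int
    strand: str  # transcript strand
    three_prime_pos: int


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.int8).astype(np.uint8)


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, arr: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return arr.copy()
    out = arr.copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hits):
        out[hits] = (out[hits] + rng.integers(1, 4, size=len(hits))) % 4
    return out


def simulate_repeat_genome(cfg: SimConfig) -> tuple[GenomeAssembly, list[RepeatElement], SimTruth]:
    """Build the synthetic assembly, its repeat annotation and the ground truth.

    Full-length copies carry the whole consensus; truncated copies carry a
    3'-anchored suffix (5' truncation). Copies are placed at random
    non-overlapping positions inside the island (centromere contigs) or the
    arm body, separated by random background sequence; islands are flanked
    by satellite arrays. Fully deterministic under ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, _TAG_GENOME])
    consensus = _random_seq(rng, cfg.consensus_length)
    sat = (cfg.satellite_unit * (cfg.satellite_flank_len // len(cfg.satellite_unit) + 1))[
        : cfg.satellite_flank_len
    ]

    contigs: dict[str, str] = {}
    elements: list[RepeatElement] = []
    cenpa_regions: list[tuple[str, int, int, str]] = []
    all_contigs = tuple(cfg.centromeric_contigs) + tuple(cfg.arm_contigs)
    counter = 0

    for contig in all_contigs:
        is_cen = contig in cfg.centromeric_contigs
        n = cfg.copies_per_contig.get(contig, 0)
        n_fl = cfg.fl_per_contig.get(contig, 0)
        if n_fl > n:
            raise ValueError(f"{contig}: more full-length copies than copies ({n_fl} > {n})")
        # copy templates: consensus interval + strand + mutated sequence
        specs = []
        for i in range(n):
            full = i < n_fl
            if full:
                cs, ce = 0, cfg.consensus_length
            else:
                frac = rng.uniform(*cfg.truncation_frac)
                length = max(1, int(round(frac * cfg.consensus_length)))
                cs, ce = cfg.consensus_length - length, cfg.consensus_length
            strand = "+" if rng.random() < 0.5 else "-"
            seq = _mutate(rng, consensus[cs:ce], cfg.divergence)
            if strand == "-":
                seq = np.asarray(encode_seq(revcomp(_decode(seq))))
            specs.append((cs, ce, strand, seq))
        order = rng.permutation(n)
        specs = [specs[i] for i in order]

        total_copy_len = sum(len(s[3]) for s in specs)
        region_len = cfg.island_length if (is_cen and cfg.island_length) else None
        if region_len is None:
            region_len = int(total_copy_len * (1 + cfg.island_slack_frac)) + 2000
        if region_len < total_copy_len + n + 1:
            raise ValueError(
                f"{contig}: requested copies do not fit in island of {region_len} bp "
                f"(need > {total_copy_len + n + 1}); increase island_length"
            )
        slack = region_len - total_copy_len
        gaps = rng.multinomial(slack, [1.0 / (n + 1)] * (n + 1)) if n else np.array([slack])

        parts: list[np.ndarray] = []
        flank_left = encode_seq(sat) if is_cen else _random_seq(rng, cfg.arm_flank_len)
        offset = len(flank_left)
        parts.append(flank_left)
        region_start = offset
        for i, (cs, ce, strand, seq) in enumerate(specs):
            gap = _random_seq(rng, int(gaps[i]))
            parts.append(gap)
            offset += len(gap)
            counter += 1
            el = RepeatElement(
                element_id=f"{cfg.family}_{counter:04d}",
                contig=contig,
                start=offset,
                end=offset + len(seq),
                strand=strand,
                family=cfg.family,
                consensus_start=cs,
                consensus_end=ce,
            )
            elements.append(el)
            parts.append(seq)
            offset += len(seq)
        if n:
            tail = _random_seq(rng, int(gaps[n]))
            parts.append(tail)
            offset += len(tail)
        region_end = offset
        flank_right = encode_seq(sat) if is_cen else _random_seq(rng, cfg.arm_flank_len)
        parts.append(flank_right)
        contigs[contig] = _decode(np.concatenate(parts))
        if is_cen and n:
            cenpa_regions.append((contig, region_start, region_end, "CEN"))

    assembly = GenomeAssembly(contigs=contigs, centromeric_ids=frozenset(cfg.centromeric_contigs))

    # designate CENP-A-associated arm copies
    arm_elements = [el for el in elements if el.contig in cfg.arm_contigs]
    n_pick = int(round(cfg.cenpa_noncen_copy_fraction * len(arm_elements)))
    if n_pick and arm_elements:
        picked = rng.choice(len(arm_elements), size=n_pick, replace=False)
        for i in sorted(picked):
            el = arm_elements[i]
            cenpa_regions.append((el.contig, el.start, el.end, "nonCEN"))

    truth = SimTruth(elements=list(elements), active_ids=[], cenpa_regions=cenpa_regions)
    truth.active_ids = _choose_active(cfg, truth, rng)
    return assembly, elements, truth


def _choose_active(cfg: SimConfig, truth: SimTruth, rng: np.random.Generator) -> list[str]:
    """Active (transcribed) copy set per the configured policy."""
    model = cfg.family_model()
    long_enough = [el for el in truth.elements if el.length >= cfg.read_length]

    def is_fl(el: RepeatElement) -> bool:
        return el.consensus_start <= model.orf2_start and el.consensus_end >= model.orf2_end

    if cfg.active_policy == "explicit":
        if cfg.active_copies is None:
            raise ValueError("active_policy='explicit' requires active_copies")
        return list(cfg.active_copies)
    if cfg.active_policy == "fl":
        return [el.element_id for el in long_enough if is_fl(el)]
    if cfg.active_policy == "fl_cenpa":
        out = []
        for el in long_enough:
            if not is_fl(el):
                continue
            touches = any(
                c == el.contig and min(el.end, e) - max(el.start, s) >= 1
                for c, s, e, _ in truth.cenpa_regions
            )
            if touches:
                out.append(el.element_id)
        return out
    if cfg.active_policy == "fraction":
        n = int(round(cfg.active_fraction * len(long_enough)))
        if n == 0:
            return []
        picked = rng.choice(len(long_enough), size=n, replace=False)
        return [long_enough[i].element_id for i in sorted(picked)]
    raise ValueError(f"unknown active_policy {cfg.active_policy!r}")


def simulate_nascent_reads(
    assembly: GenomeAssembly, truth: SimTruth, cfg: SimConfig
) -> list[SimRead]:
    """Emit ``cfg.depth`` reads per active copy with uniform 3'-end positions.

    PRO-seq semantics: the read is the ``read_length`` transcript-sense bases
    ending at the sampled 3' position, kept entirely inside the copy so every
    read's source is within an annotated element. Copies shorter than the
    read length are skipped with a warning. ``cfg.antisense`` flips all
    transcript strands.
    """
    rng = np.random.default_rng([cfg.seed, _TAG_READS])
    reads: list[SimRead] = []
    L = cfg.read_length
    idx = 0
    for copy_id in truth.active_ids:
        el = truth.element(copy_id)
        if el.length < L:
            warnings.warn(f"{copy_id}: shorter than read_length; skipped", stacklevel=2)
            continue
        seq = assembly.contigs[el.contig]
        sense = el.strand if not cfg.antisense else ("-" if el.strand == "+" else "+")
        for _ in range(cfg.depth):
            if sense == "+":
                p = int(rng.integers(el.start + L - 1, el.end))  # 3' end position
                s, e = p - L + 1, p + 1
                read_seq = seq[s:e]
                tpp = p
            else:
                q = int(rng.integers(el.start, el.end - L + 1))
                s, e = q, q + L
                read_seq = revcomp(seq[s:e])
                tpp = q
            if cfg.seq_error_rate > 0:
                arr = _mutate(rng, encode_seq(read_seq), cfg.seq_error_rate)
                read_seq = _decode(arr)
            reads.append(
                SimRead(
                    read_id=f"r{idx:06d}",
                    seq=read_seq,
                    copy_id=copy_id,
                    contig=el.contig,
                    start=s,
                    end=e,
                    strand=sense,
                    three_prime_pos=tpp,
                )
            )
            idx += 1
    truth.reads = [r.__dict__.copy() for r in reads]
    return reads


class MultiMapper:
    """Exact brute-force mapper: all placements with <= max_mismatch substitutions.

    Candidates come from a pigeonhole substring index (any placement with at
    most m mismatches matches at least one of m+1 disjoint read chunks
    exactly); every candidate is then verified base-by-base, so the
    enumeration is exhaustive for substitution-only alignment (no indels).
    N never matches any base.
    """

    def __init__(self, assembly: GenomeAssembly, max_mismatch: int = 1):
        self.max_mismatch = max_mismatch
        self.contig_names = assembly.contig_order
        arrs = [encode_seq(assembly.contigs[c]) for c in self.contig_names]
        self.offsets = np.zeros(len(arrs) + 1, dtype=np.int64)
        np.cumsum([len(a) for a in arrs], out=self.offsets[1:])
        self.genome = np.concatenate(arrs) if arrs else np.zeros(0, dtype=np.uint8)
        self._hash_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    @staticmethod
    def _rolling_hashes(arr: np.ndarray, width: int) -> np.ndarray:
        B = np.uint64(1099511628211)
        n = len(arr)
        if n < width:
            return np.zeros(0, dtype=np.uint64)
        nwin = n - width + 1
        h = np.zeros(nwin, dtype=np.uint64)
        a = arr.astype(np.uint64)
        with np.errstate(over="ignore"):
            for j in range(width):
                h = h * B + a[j : j + nwin] + np.uint64(1)
        return h

    def _index(self, width: int) -> tuple[np.ndarray, np.ndarray]:
        cached = self._hash_cache.get(width)
        if cached is not None:
            return cached
        hashes = self._rolling_hashes(self.genome, width)
        order = np.argsort(hashes, kind="stable")
        built = (hashes[order], order.astype(np.int64))
        self._hash_cache[width] = built
        return built

    def _contig_of(self, pos: int) -> int:
        return int(np.searchsorted(self.offsets, pos, side="right") - 1)

    def placements(self, seq: str) -> list[tuple[str, int, str, int]]:
        """All (contig, start, strand, mismatches) placements of the read."""
        L = len(seq)
        m = self.max_mismatch
        width = L // (m + 1)
        if width < 1:
            raise ValueError(f"read of length {L} too short for max_mismatch={m}")
        sorted_hashes, pos_by_hash = self._index(width)
        found: dict[tuple[int, str], int] = {}
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            arr = encode_seq(s)
            read_hashes = self._rolling_hashes(arr, width)
            for ci in range(m + 1):
                off = ci * width
                h = read_hashes[off]
                lo = np.searchsorted(sorted_hashes, h, side="left")
                hi = np.searchsorted(sorted_hashes, h, side="right")
                for gpos in pos_by_hash[lo:hi]:
                    start = int(gpos) - off
                    if start < 0 or start + L > len(self.genome):
                        continue
                    key = (start, strand)
                    if key in found:
                        continue
                    ctg = self._contig_of(start)
                    if start + L > self.offsets[ctg + 1]:
                        continue  # placement would cross a contig boundary
                    g = self.genome[start : start + L]
                    mm = int(np.count_nonzero((g != arr) | (g >= 4) | (arr >= 4)))
                    if mm <= m:
                        found[key] = mm
        out = []
        for (start, strand), mm in found.items():
            ctg = self._contig_of(start)
            out.append((self.contig_names[ctg], start - int(self.offsets[ctg]), strand, mm))
        return out


def toy_multimapper(
    reads: Sequence[SimRead],
    assembly: GenomeAssembly,
    cfg: SimConfig,
) -> tuple[AlignmentSet, AlignmentSet]:
    """Map reads under the two reporting modes.

    Returns (best_match set, k100 set). The k100 set keeps up to 100
    placements per read preferring fewer mismatches (a seeded random
    subsample fills the last stratum if more than 100 exist); best_match
    keeps one minimal-mismatch placement, ties broken by a seeded uniform
    choice. Unmapped reads are dropped and counted on the returned sets as
    ``n_unmapped``.
    """
    if not reads:
        raise ValueError("no reads to map")
    rng = np.random.default_rng([cfg.seed, _TAG_MAPPER])
    mapper = MultiMapper(assembly, max_mismatch=cfg.max_mismatch)
    orientation = "read1_revcomp" if cfg.read1_revcomp else "reads_are_sense"
    order = {c: i for i, c in enumerate(assembly.contig_order)}

    best_alns: list[ReadAlignment] = []
    k100_alns: list[ReadAlignment] = []
    n_unmapped = 0
    for read in reads:
        seq = revcomp(read.seq) if cfg.read1_revcomp else read.seq
        places = mapper.placements(seq)
        if not places:
            n_unmapped += 1
            continue
        L = len(seq)
        places.sort(key=lambda p: (p[3], order[p[0]], p[1], p[2]))
        # k100: fill whole mismatch strata while they fit; subsample the last
        chosen: list[tuple[str, int, str, int]] = []
        i = 0
        while i < len(places) and len(chosen) < K100_CAP:
            mm = places[i][3]
            stratum = [p for p in places[i:] if p[3] == mm]
            room = K100_CAP - len(chosen)
            if len(stratum) <= room:
                chosen.extend(stratum)
            else:
                pick = rng.choice(len(stratum), size=room, replace=False)
                chosen.extend(stratum[j] for j in sorted(pick))
            i += len(stratum)
        for contig, start, strand, mm in chosen:
            k100_alns.append(
                ReadAlignment(read.read_id, contig, start, start + L, strand, mismatches=mm)
            )
        best_mm = places[0][3]
        ties = [p for p in places if p[3] == best_mm]
        contig, start, strand, mm = ties[int(rng.integers(0, len(ties)))] if len(ties) > 1 else ties[0]
        best_alns.append(ReadAlignment(read.read_id, contig, start, start + L, strand, mismatches=mm))

    checksum = assembly.checksum()
    best = AlignmentSet(
        mode="best_match", alignments=best_alns, assembly_checksum=checksum,
        library=cfg.library, orientation=orientation,
    )
    k100 = AlignmentSet(
        mode="k100", alignments=k100_alns, assembly_checksum=checksum,
        library=cfg.library, orientation=orientation,
    )
    best.n_unmapped = k100.n_unmapped = n_unmapped  # type: ignore[attr-defined]
    return best, k100


def simulate_peaks(truth: SimTruth, cfg: SimConfig, peaks_per_island: int = 3,
                   cen_signal: tuple[float, float] = (20.0, 4.0),
                   noncen_signal: tuple[float, float] = (2.0, 0.5),
                   boundary_jitter_sd: float = 50.0):
    """Peak calls covering the designated CENP-A regions.

    Each centromeric island yields ``peaks_per_island`` peaks tiling its
    span (first starts at the island start, last ends at the island end, so
    the first-to-last domain reconstructs the island); each designated
    non-centromeric copy yields one peak with jittered boundaries. Signals
    are drawn from per-class normal distributions (CEN mean ~10x nonCEN by
    default). Deterministic under ``cfg.seed``.
    """
    from .domains import PeakCall

    rng = np.random.default_rng([cfg.seed, _TAG_PEAKS])
    peaks: list[PeakCall] = []
    i = 0
    for contig, start, end, klass in truth.cenpa_regions:
        if klass == "CEN":
            edges = np.linspace(start, end, peaks_per_island + 1).astype(int)
            for j in range(peaks_per_island):
                s, e = int(edges[j]), int(edges[j + 1])
                if j > 0:
                    s = min(e - 50, max(start, s + int(rng.normal(0, boundary_jitter_sd))))
                if j < peaks_per_island - 1:
                    e = max(s + 50, min(end, e + int(rng.normal(0, boundary_jitter_sd))))
                i += 1
                sig = max(0.1, float(rng.normal(*cen_signal)))
                peaks.append(PeakCall(contig, s, e, signal=sig, name=f"peak_{i:04d}",
                                      summit_offset=(e - s) // 2))
        else:
            s = max(0, start + int(rng.normal(0, boundary_jitter_sd)))
            e = max(s + 50, end + int(rng.normal(0, boundary_jitter_sd)))
            i += 1
            sig = max(0.1, float(rng.normal(*noncen_signal)))
            peaks.append(PeakCall(contig, s, e, signal=sig, name=f"peak_{i:04d}",
                                  summit_offset=(e - s) // 2))
    return peaks
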