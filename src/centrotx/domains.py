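"""CENP-A domain construction from peak calls and repeat-copy labeling.

The centromeric (CEN) domain of each centromere contig spans from the first
to the last peak on that contig. Non-centromeric (nonCEN) domains are built
from peaks alone: every peak not absorbed by a CEN domain becomes a domain,
with overlapping or book-ended peaks merged (merge distance 0 by default —
the most conservative reading of "peaks alone").

Repeat copies are labeled by >= 1 bp overlap: CENPA_CEN if they touch a CEN
domain, else CENPA_nonCEN if they touch a nonCEN domain, else nonCENPA
(CEN takes precedence when a copy touches both). A copy is *expressed* when
at least ``expression_threshold`` (default 2) reads overlap it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeAssembly, RepeatElement

logger = logging.getLogger(__name__)

ASSOCIATIONS = ("CENPA_CEN", "CENPA_nonCEN", "nonCENPA")
DEFAULT_EXPRESSION_THRESHOLD = 2  # reads; ">= 2 overlapping reads" expression call


@dataclass
class PeakCall:
    contig: str
    start: int
    end: int
    signal: float
    name: str = "."
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.name}: start must be < end")
        if self.signal < 0:
            raise ValueError(f"peak {self.name}: negative signal")


@dataclass
class CenpaDomain:
    domain_id: str
    contig: str
    start: int
    end: int
    klass: str  # "CEN" | "nonCEN" | "random_control"
    n_peaks: int = 0
    mean_signal: float | None = None

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class ElementLabel:
    element_id: str
    association: str
    expressed: bool
    read_count: int


def load_narrowpeak(path: str | Path) -> list[PeakCall]:
    """Read a narrowPeak (BED6+4) file; ``signalValue`` (col 7) is the signal."""
    peaks: list[PeakCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ValueError(f"{path}:{lineno}: narrowPeak needs 10 columns, got {len(f)}")
            summit = int(f[9])
            peaks.append(
                PeakCall(
                    contig=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    name=f[3],
                    signal=float(f[6]),
                    summit_offset=summit if summit >= 0 else None,
                )
            )
    return peaks


def write_narrowpeak(peaks: Iterable[PeakCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            summit = p.summit_offset if p.summit_offset is not None else -1
            score = int(min(1000, round(10 * p.signal)))
            fh.write(
                f"{p.contig}\t{p.start}\t{p.end}\t{p.name}\t{score}\t.\t{p.signal:.4f}\t-1\t-1\t{summit}\n"
            )


def build_cen_domains(peaks: Sequence[PeakCall], centromeric_ids: Iterable[str]) -> list[CenpaDomain]:
    """One CEN domain per centromeric contig with >= 1 peak: first-to-last span.

    Centromeric contigs without a peak emit nothing (warning logged).
    """
    centromeric_ids = list(centromeric_ids)
    by_contig: dict[str, list[PeakCall]] = {}
    for p in peaks:
        by_contig.setdefault(p.contig, []).append(p)
    domains: list[CenpaDomain] = []
    for contig in centromeric_ids:
        ps = by_contig.get(contig, [])
        if not ps:
            logger.warning("centromeric contig %s has no peaks; no CEN domain emitted", contig)
            continue
        start = min(p.start for p in ps)
        end = max(p.end for p in ps)
        domains.append(
            CenpaDomain(
                domain_id=f"CEN_{contig}",
                contig=contig,
                start=start,
                end=end,
                klass="CEN",
                n_peaks=len(ps),
                mean_signal=float(np.mean([p.signal for p in ps])),
            )
        )
    return domains


def build_noncen_domains(
    peaks: Sequence[PeakCall],
    cen_domains: Sequence[CenpaDomain],
    merge_distance: int = 0,
) -> list[CenpaDomain]:
    """nonCEN domains from peaks alone.

    Every peak outside the CEN domains (peaks on centromeric contigs that do
    not overlap the CEN span included — flagged here as ordinary nonCEN
    domains) is merged with neighbours closer than ``merge_distance``
    (0 = only overlapping/book-ended peaks merge) into one domain whose span
    is the union hull and whose mean_signal averages the member peaks.
    """
    cen_by_contig = {d.contig: d for d in cen_domains}
    eligible: list[PeakCall] = []
    for p in peaks:
        cen = cen_by_contig.get(p.contig)
        if cen is not None and min(p.end, cen.end) - max(p.start, cen.start) >= 1:
            continue  # absorbed into the CEN span
        eligible.append(p)
    eligible.sort(key=lambda p: (p.contig, p.start, p.end))
    domains: list[CenpaDomain] = []
    cluster: list[PeakCall] = []

    def _flush() -> None:
        if not cluster:
            return
        start = min(p.start for p in cluster)
        end = max(p.end for p in cluster)
        domains.append(
            CenpaDomain(
                domain_id=f"nonCEN_{len(domains) + 1:04d}",
                contig=cluster[0].contig,
                start=start,
                end=end,
                klass="nonCEN",
                n_peaks=len(cluster),
                mean_signal=float(np.mean([p.signal for p in cluster])),
            )
        )

    for p in eligible:
        if cluster and p.contig == cluster[-1].contig and p.start <= max(q.end for q in cluster) + merge_distance:
            cluster.append(p)
        else:
            _flush()
            cluster = [p]
    _flush()
    return domains


def domain_stats(domains: Sequence[CenpaDomain]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-domain (id, klass, size, mean_signal) plus per-class mean/SD summary."""
    per_domain = pd.DataFrame(
        {
            "domain_id": [d.domain_id for d in domains],
            "contig": [d.contig for d in domains],
            "start": [d.start for d in domains],
            "end": [d.end for d in domains],
            "klass": [d.klass for d in domains],
            "size": [d.size for d in domains],
            "n_peaks": [d.n_peaks for d in domains],
            "mean_signal": [d.mean_signal for d in domains],
        }
    )
    summary = (
        per_domain.groupby("klass")
        .agg(
            n=("domain_id", "size"),
            mean_size=("size", "mean"),
            sd_size=("size", "std"),
            mean_signal=("mean_signal", "mean"),
            sd_signal=("mean_signal", "std"),
        )
        .reset_index()
    )
    return per_domain, summary


def label_elements(
    elements: Sequence[RepeatElement],
    domains: Sequence[CenpaDomain],
    counts: Mapping[str, int] | pd.Series,
    expression_threshold: int = DEFAULT_EXPRESSION_THRESHOLD,
) -> list[ElementLabel]:
    """Label each repeat copy by CENP-A association and expression.

    Association uses >= 1 bp overlap; copies touching both a CEN and a nonCEN
    domain take CENPA_CEN (documented precedence). ``counts`` maps element_id
    to its read count (e.g. from :func:`centrotx.profiles.count_over_intervals`).
    """
    cen = [(d.contig, d.start, d.end) for d in domains if d.klass == "CEN"]
    noncen = [(d.contig, d.start, d.end) for d in domains if d.klass == "nonCEN"]

    def _touches(el: RepeatElement, ivs: list[tuple[str, int, int]]) -> bool:
        return any(c == el.contig and min(el.end, e) - max(el.start, s) >= 1 for c, s, e in ivs)

    labels: list[ElementLabel] = []
    for el in elements:
        if _touches(el, cen):
            assoc = "CENPA_CEN"
        elif _touches(el, noncen):
            assoc = "CENPA_nonCEN"
        else:
            assoc = "nonCENPA"
        rc = int(counts.get(el.element_id, 0) if hasattr(counts, "get") else counts[el.element_id])
        labels.append(
            ElementLabel(
                element_id=el.element_id,
                association=assoc,
                expressed=rc >= expression_threshold,
                read_count=rc,
            )
        )
    return labels


def random_control_intervals(
    assembly: GenomeAssembly,
    length: int,
    n: int,
    seed: int,
    exclude: Sequence[tuple[str, int, int]] = (),
    exclude_contigs: Iterable[str] | None = None,
    max_tries_per_interval: int = 1000,
) -> list[CenpaDomain]:
    """Matched random control intervals (klass=random_control).

    ``n`` intervals of exactly ``length`` bp placed uniformly over all
    positions where they fit, sampling contigs with probability proportional
    to their eligible-position counts. Intervals overlapping ``exclude`` (by
    >= 1 bp) or falling on ``exclude_contigs`` (default: the centromeric
    contigs) are rejected and resampled. Deterministic under ``seed``;
    exhausting the retry cap is a hard error.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if exclude_contigs is None:
        exclude_contigs = assembly.centromeric_ids
    exclude_contigs = set(exclude_contigs)
    eligible = [
        (name, len(seq) - length + 1)
        for name, seq in assembly.contigs.items()
        if name not in exclude_contigs and len(seq) >= length
    ]
    if not eligible:
        raise ValueError(f"no contig can host an interval of length {length}")
    names = [name for name, _ in eligible]
    weights = np.asarray([w for _, w in eligible], dtype=float)
    probs = weights / weights.sum()
    excl_by_contig: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in exclude:
        excl_by_contig.setdefault(c, []).append((s, e))

    rng = np.random.default_rng(seed)
    out: list[CenpaDomain] = []
    for i in range(n):
        for _ in range(max_tries_per_interval):
            ci = rng.choice(len(names), p=probs)
            contig = names[ci]
            start = int(rng.integers(0, weights[ci]))
            end = start + length
            if any(min(end, e) - max(start, s) >= 1 for s, e in excl_by_contig.get(contig, ())):
                continue
            out.append(
                CenpaDomain(
                    domain_id=f"random_{i + 1:04d}",
                    contig=contig,
                    start=start,
                    end=end,
                    klass="random_control",
                )
            )
            break
        else:
            raise RuntimeError(
                f"could not place random interval {i + 1}/{n} of length {length} "
                f"after {max_tries_per_interval} tries; exclusion set too dense"
            )
    return out


def write_domains_bed(domains: Iterable[CenpaDomain], path: str | Path) -> None:
    """BED6 with klass in the name field and mean_signal in the score column."""
    with open(path, "w") as fh:
        for d in domains:
            score = f"{d.mean_signal:.4f}" if d.mean_signal is not None else "0"
            fh.write(f"{d.contig}\t{d.start}\t{d.end}\t{d.klass}:{d.domain_id}\t{score}\t.\n")


def load_domains_bed(path: str | Path) -> list[CenpaDomain]:
    domains: list[CenpaDomain] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            klass, _, domain_id = f[3].partition(":")
            domains.append(
                CenpaDomain(
                    domain_id=domain_id or f[3],
                    contig=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    klass=klass,
                    mean_signal=float(f[4]) if len(f) > 4 and f[4] not in (".", "") else None,
                )
            )
    return domains
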