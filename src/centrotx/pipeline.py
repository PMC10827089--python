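"""End-to-end orchestration: simulate -> map -> filter -> profile -> domains -> labels.

``run_pipeline`` executes every stage in memory and returns the intermediate
objects; ``write_fixture_set`` additionally serializes the complete fixture
set (FASTA, BED6+2 annotation, alignment tables for all three modes, k-mer
track, narrowPeak, domain BED, per-element labels, group summary, density
matrix, truth tables and the run config) into one directory, ready for
:func:`centrotx.report.build_report`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from . import domains as dom
from . import kmers, profiles, stats
from .genome import classify_elements, write_assembly, write_repeat_annotation
from .simulate import SimConfig, simulate_nascent_reads, simulate_peaks, simulate_repeat_genome, toy_multimapper


def run_pipeline(cfg: SimConfig, expression_mode: str = "best_match") -> dict:
    """Run the full analysis on one simulated dataset.

    ``expression_mode`` picks the alignment set used for expression calling
    (the grouping is mode-sensitive, so all three modes are computed and the
    per-mode counts are reported side by side).
    """
    assembly, elements, truth = simulate_repeat_genome(cfg)
    elements = classify_elements(elements, cfg.family_model())
    truth.elements = elements
    reads = simulate_nascent_reads(assembly, truth, cfg)
    best, k100 = toy_multimapper(reads, assembly, cfg)
    track = kmers.single_copy_kmer_track(assembly, cfg.k)
    filtered = kmers.filter_alignments_by_containment(k100, track)

    asets = {"best_match": best, "k100": k100, "k100_filtered": filtered}
    signals = {}
    counts = {}
    for mode, aset in asets.items():
        if cfg.library == "proseq":
            sig = profiles.extract_three_prime_ends(aset)
            signals[mode] = sig
            counts[mode] = profiles.count_over_intervals(sig, elements)
        else:
            counts[mode] = profiles.count_over_intervals(aset, elements)

    data_for_matrix = signals.get(expression_mode, asets[expression_mode])
    matrix = profiles.repeat_density_matrix(data_for_matrix, elements, assembly)

    peaks = simulate_peaks(truth, cfg)
    cen_domains = dom.build_cen_domains(peaks, assembly.centromeric_ids)
    noncen_domains = dom.build_noncen_domains(peaks, cen_domains)
    all_domains = cen_domains + noncen_domains
    labels = dom.label_elements(elements, all_domains, counts[expression_mode])
    groups = stats.group_proportions(labels, elements)

    return {
        "cfg": cfg,
        "assembly": assembly,
        "elements": elements,
        "truth": truth,
        "reads": reads,
        "alignment_sets": asets,
        "signals": signals,
        "counts": counts,
        "track": track,
        "matrix": matrix,
        "peaks": peaks,
        "domains": all_domains,
        "labels": labels,
        "groups": groups,
        "expression_mode": expression_mode,
    }


def elements_table(elements) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "element_id": [e.element_id for e in elements],
            "contig": [e.contig for e in elements],
            "start": [e.start for e in elements],
            "end": [e.end for e in elements],
            "strand": [e.strand for e in elements],
            "family": [e.family for e in elements],
            "consensus_start": [e.consensus_start for e in elements],
            "consensus_end": [e.consensus_end for e in elements],
            "completeness": [e.completeness for e in elements],
        }
    )


def labels_table(labels, counts_by_mode: dict[str, pd.Series] | None = None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "element_id": [l.element_id for l in labels],
            "association": [l.association for l in labels],
            "expressed": [l.expressed for l in labels],
            "read_count": [l.read_count for l in labels],
        }
    )
    if counts_by_mode:
        for mode, counts in counts_by_mode.items():
            df[f"count_{mode}"] = counts.reindex(df["element_id"]).to_numpy()
    return df


def write_fixture_set(cfg: SimConfig, outdir: str | Path, expression_mode: str = "best_match") -> dict:
    """Run the pipeline and serialize the complete fixture set into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = run_pipeline(cfg, expression_mode=expression_mode)

    write_assembly(res["assembly"], outdir / "genome.fa")
    write_repeat_annotation(res["elements"], outdir / "repeats.bed")
    elements_table(res["elements"]).to_csv(outdir / "elements.tsv", sep="\t", index=False)
    for mode, aset in res["alignment_sets"].items():
        profiles.write_alignments(aset, outdir / f"aln_{mode}.tsv", res["assembly"])
    res["track"].to_bed(outdir / f"unique{cfg.k}.bed")
    res["matrix"].to_tsv(outdir / "density_matrix.tsv")
    dom.write_narrowpeak(res["peaks"], outdir / "peaks.narrowPeak")
    dom.write_domains_bed(res["domains"], outdir / "domains.bed")
    labels_table(res["labels"], res["counts"]).to_csv(outdir / "labels.tsv", sep="\t", index=False)
    res["groups"].to_csv(outdir / "group_summary.tsv", sep="\t", index=False)
    if res["signals"]:
        sig = res["signals"][expression_mode]
        profiles.write_coverage(sig, outdir / "signal.bedGraph", stranded=True, assembly=res["assembly"])

    truth = res["truth"]
    pd.DataFrame({"active_id": truth.active_ids}).to_csv(outdir / "truth_active.tsv", sep="\t", index=False)
    pd.DataFrame(truth.reads).drop(columns=["seq"], errors="ignore").to_csv(
        outdir / "truth_reads.tsv", sep="\t", index=False
    )
    cfg_dict = dataclasses.asdict(cfg)
    (outdir / "run_config.yaml").write_text(yaml.safe_dump(cfg_dict, sort_keys=True))
    return res
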