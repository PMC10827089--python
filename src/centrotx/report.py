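"""Collate per-stage outputs into one report bundle.

``build_report`` reads the TSV/BED files the pipeline stages wrote into a
fixture directory, cross-checks that derived numbers agree across files (no
recomputation drift) and writes a markdown summary with the run seed
recorded for provenance.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

STAGE_FILES = {
    "config": "run_config.yaml",
    "elements": "elements.tsv",
    "density": "density_matrix.tsv",
    "domains": "domains.bed",
    "labels": "labels.tsv",
    "groups": "group_summary.tsv",
}


class MissingStageError(FileNotFoundError):
    def __init__(self, stage: str, path: Path):
        self.stage = stage
        super().__init__(f"missing output for stage '{stage}': {path}")


def build_report(fixture_dir: str | Path, out_path: str | Path | None = None) -> dict:
    """Assemble the final report from a fixture directory.

    Raises :class:`MissingStageError` naming the first absent stage. Returns
    the collated tables plus the markdown text; writes ``report.md`` into the
    fixture directory (or ``out_path``).
    """
    fixture_dir = Path(fixture_dir)
    paths = {}
    for stage, fname in STAGE_FILES.items():
        p = fixture_dir / fname
        if not p.exists():
            raise MissingStageError(stage, p)
        paths[stage] = p

    config = yaml.safe_load(paths["config"].read_text())
    elements = pd.read_csv(paths["elements"], sep="\t")
    labels = pd.read_csv(paths["labels"], sep="\t")
    groups = pd.read_csv(paths["groups"], sep="\t")
    domains = pd.read_csv(
        paths["domains"], sep="\t", header=None, comment="#",
        names=["contig", "start", "end", "name", "score", "strand"],
    )

    # cross-file consistency: group totals must equal the label partition
    n_labeled = len(labels)
    base = groups[(groups["completeness"] == "all") & (~groups["collapsed"].astype(bool))]
    if int(base["n"].sum()) != n_labeled:
        raise ValueError(
            f"group summary n ({int(base['n'].sum())}) does not match label count ({n_labeled})"
        )
    n_expressed = int(labels["expressed"].sum())
    if int(base["n_expressed"].sum()) != n_expressed:
        raise ValueError("group summary n_expressed does not match labels")

    domains["klass"] = domains["name"].str.split(":").str[0]
    n_cen = int((domains["klass"] == "CEN").sum())
    n_noncen = int((domains["klass"] == "nonCEN").sum())

    lines = [
        "# centrotx run report",
        "",
        f"- seed: {config.get('seed')}",
        f"- elements annotated: {len(elements)}",
        f"- full-length: {int((elements['completeness'] == 'full_length').sum())}",
        f"- CEN domains: {n_cen}; nonCEN domains: {n_noncen}",
        f"- elements expressed (>= threshold reads): {n_expressed} / {n_labeled}",
        "",
        "## Expression by group",
        "",
        groups.to_markdown(index=False),
        "",
    ]
    text = "\n".join(lines)
    out_path = Path(out_path) if out_path else fixture_dir / "report.md"
    out_path.write_text(text)
    return {
        "config": config,
        "elements": elements,
        "labels": labels,
        "groups": groups,
        "domains": domains,
        "markdown": text,
        "path": out_path,
    }
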