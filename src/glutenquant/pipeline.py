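"""End-to-end orchestration: digestion -> mapping -> grouping ->
normalization -> group quantitation -> epitope mapping -> enrichment.

``run_pipeline`` consumes file inputs (protein FASTA, transition
peak-area table, epitope list, optional group overrides and term
annotations) and writes every intermediate table plus a reproducible
plain-text report. ``run_scenario`` first materializes a synthetic
scenario to disk and then runs the same file-based pipeline over it, so
simulated runs exercise the identical code path as real exports.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import digestion, enrichment, epitopes, grouping, quantitation
from .quantitation import PipelineConfig

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunReport:
    config_echo: dict = field(default_factory=dict)
    input_checksums: dict = field(default_factory=dict)
    stage_counts: dict = field(default_factory=dict)
    group_summary: pd.DataFrame | None = None
    net_gluten_percent: float = float("nan")
    category_table: pd.DataFrame | None = None
    warnings: list = field(default_factory=list)

    def body(self) -> str:
        lines = ["# glutenquant run report", "", "## configuration"]
        for k, v in sorted(self.config_echo.items()):
            lines.append(f"{k}: {v}")
        lines += ["", "## input checksums (sha256)"]
        for k, v in sorted(self.input_checksums.items()):
            lines.append(f"{k}: {v}")
        lines += ["", "## stage row counts"]
        for k, v in self.stage_counts.items():
            lines.append(f"{k}: {v}")
        lines += ["", "## group summary"]
        if self.group_summary is not None:
            lines.append(self.group_summary.to_csv(sep="\t", float_format="%.6g").rstrip())
        lines += ["", f"net_gluten_percent: {self.net_gluten_percent:.4f}", ""]
        lines += ["## epitope categories"]
        if self.category_table is not None:
            lines.append(self.category_table.to_csv(sep="\t", float_format="%.6g").rstrip())
        lines += ["", "## warnings"]
        lines += [f"- {w}" for w in self.warnings] or ["(none)"]
        return "\n".join(lines) + "\n"


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def protein_fold_changes(
    normalized: quantitation.NormalizedMatrix,
    peptide_records: list[digestion.PeptideRecord],
) -> dict[str, float]:
    """Protein-level log2(GW/MW) from the summed normalized abundance of
    each protein's unique peptides; proteins with no unique quantified
    peptide are omitted."""
    by_protein: dict[str, list[str]] = {}
    for rec in peptide_records:
        if rec.is_unique and rec.sequence in normalized.values.index:
            by_protein.setdefault(next(iter(rec.parent_ids)), []).append(rec.sequence)
    out: dict[str, float] = {}
    for pid, peps in by_protein.items():
        block = normalized.values.loc[peps]
        gw = block[normalized.replicates("GW")].sum(axis=0).mean()
        mw = block[normalized.replicates("MW")].sum(axis=0).mean()
        if gw > 0 and mw > 0:
            out[pid] = float(np.log2(gw / mw))
    return out


def run_pipeline(
    fasta: str | Path,
    quant: str | Path,
    epitope_list: str | Path | None = None,
    overrides: str | Path | None = None,
    annotations: str | Path | None = None,
    config: PipelineConfig | None = None,
    outdir: str | Path = "glutenquant_out",
) -> RunReport:
    """Run every stage over file inputs and write outputs to ``outdir``."""
    if config is None:
        config = PipelineConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_echo={k: getattr(config, k) for k in config.__dataclass_fields__})

    inputs = {"fasta": fasta, "quant": quant}
    if epitope_list:
        inputs["epitopes"] = epitope_list
    if overrides:
        inputs["overrides"] = overrides
    if annotations:
        inputs["annotations"] = annotations
    for name, path in inputs.items():
        if not Path(path).exists():
            raise StageError(f"digestion_io: file not found: {path}")
        report.input_checksums[name] = _sha256(path)

    t0 = time.perf_counter()
    try:
        proteins = digestion.read_fasta(fasta)
    except Exception as exc:
        raise StageError(f"digestion_io: {exc}") from exc
    report.stage_counts["proteins"] = len(proteins)
    log.info("digestion_io: %d proteins (%.2fs)", len(proteins), time.perf_counter() - t0)

    try:
        table = quantitation.load_quant_table(quant)
    except Exception as exc:
        raise StageError(f"quantitation: {exc}") from exc
    report.stage_counts["quant_rows"] = len(table)

    peptide_seqs = list(dict.fromkeys(table["peptide"]))
    protease_of = table.drop_duplicates("peptide").set_index("peptide")["protease"].to_dict()
    records = digestion.map_peptides(peptide_seqs, proteins)
    for rec in records:
        rec.protease = protease_of.get(rec.sequence, rec.protease)
    orphans = [r.sequence for r in records if not r.parent_ids]
    if orphans:
        report.warnings.append(f"{len(orphans)} orphan peptide(s) matched no protein")
        records = [r for r in records if r.parent_ids]
    report.stage_counts["mapped_peptides"] = len(records)
    digestion.write_peptides_tsv(records, out / "peptides.tsv")

    try:
        override_map = grouping.load_overrides(overrides) if overrides else None
        protein_groups = {
            p.id: grouping.classify_protein(p, override=override_map) for p in proteins
        }
        allocations = grouping.allocate_all(records, protein_groups)
    except Exception as exc:
        raise StageError(f"grouping: {exc}") from exc
    grouping.write_allocations(
        [grouping.allocate_peptide_group(r, protein_groups) for r in records],
        out / "allocations.tsv",
    )

    try:
        areas = quantitation.peptide_area(table)
        areas.values = areas.values.loc[[p for p in areas.values.index if p in allocations]]
        normalized = quantitation.normalize(areas)
        normalized.values.to_csv(out / "normalized.tsv", sep="\t", float_format="%.6g")
        volcano = quantitation.differential(normalized, config)
        volcano["group"] = [allocations[p] for p in volcano.index]
        volcano.to_csv(out / "volcano.tsv", sep="\t", float_format="%.6g")
        groups = quantitation.group_abundance(normalized, allocations)
        groups.to_csv(out / "group_summary.tsv", sep="\t", float_format="%.6g")
        net = quantitation.net_gluten_ratio(groups)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"quantitation: {exc}") from exc
    report.stage_counts["quantified_peptides"] = len(normalized.values)
    report.group_summary = groups
    report.net_gluten_percent = net
    with open(out / "net_gluten.txt", "w") as fh:
        fh.write(f"net_gluten_percent\t{net:.4f}\n")

    if epitope_list:
        try:
            epis = epitopes.load_epitopes(epitope_list)
            matches = epitopes.find_epitopes(
                list(normalized.values.index), epis, mode=config.epitope_mode
            )
            epitopes.write_matches(matches, out / "epitope_matches.tsv")
            cats = epitopes.category_abundance(
                matches, normalized,
                categories=tuple(sorted({e.category for e in epis})),
            )
            cats.to_csv(out / "epitope_categories.tsv", sep="\t", float_format="%.6g")
        except Exception as exc:
            raise StageError(f"epitope_mapping: {exc}") from exc
        report.stage_counts["epitope_matches"] = len(matches)
        report.category_table = cats

    if annotations:
        try:
            ann = enrichment.AnnotationTable.from_tsv(annotations)
            fcs = protein_fold_changes(normalized, records)
            selected = enrichment.select_proteins(
                "fold_change", fold_changes=fcs,
                fc_threshold=config.fc_threshold, direction="both",
            )
            background = set(fcs)
            result = enrichment.hypergeom_enrich(selected, background, ann)
            result.to_csv(out / "enrichment.tsv", sep="\t", float_format="%.6g")
            report.stage_counts["enriched_terms_tested"] = len(result)
        except Exception as exc:
            raise StageError(f"enrichment: {exc}") from exc

    with open(out / "report.txt", "w") as fh:
        fh.write(report.body())
    return report


def run_scenario(
    scenario_name: str = "paper",
    seed: int = 2021,
    outdir: str | Path = "glutenquant_out",
    config: PipelineConfig | None = None,
):
    """Simulate a scenario, write its inputs, and run the file pipeline."""
    from . import simulate

    if scenario_name != "paper":
        raise ValueError(f"unknown scenario {scenario_name!r}")
    run = simulate.generate_scenario(simulate.paper_scenario(seed))
    out = Path(outdir)
    inputs = out / "inputs"
    run.write(inputs)
    report = run_pipeline(
        fasta=inputs / "proteome.fasta",
        quant=inputs / "quant.csv",
        epitope_list=inputs / "epitopes.tsv",
        overrides=inputs / "overrides.tsv",
        config=config,
        outdir=out,
    )
    return run, report
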