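"""Protein-family classification and peptide group allocation.

Proteins are assigned to prolamin/allergen families (alpha-, gamma-,
omega-gliadin, LMW-GS, HMW-GS, ALP, ATI) from header keywords and
sequence motifs that proxy the diagnostic Pfam domains (gliadin
PF13016, HMW glutenin PF03157, cereal alpha-amylase/trypsin inhibitor
PF00234), with an explicit per-identifier override table standing in
for manual curation. A peptide inherits the group of its parents when
they agree and is labelled ``multiple`` otherwise.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import yaml

from .digestion import GROUPS, PeptideRecord, ProteinRecord

QUANT_GROUPS = tuple(g for g in GROUPS if g not in ("mixed", "unassigned")) + ("multiple",)


@dataclass
class GroupRule:
    group: str
    header_patterns: list[str] = field(default_factory=list)
    sequence_motifs: list[str] = field(default_factory=list)
    priority: int = 0

    def __post_init__(self) -> None:
        if not self.header_patterns and not self.sequence_motifs:
            raise ValueError(f"rule for {self.group} has no patterns or motifs")
        self._compiled = [re.compile(p, re.IGNORECASE) for p in self.header_patterns]

    def matches(self, record: ProteinRecord) -> bool:
        if any(rx.search(record.description) for rx in self._compiled):
            return True
        return any(m.upper() in record.sequence for m in self.sequence_motifs)


@dataclass
class GroupAllocation:
    peptide: str
    group: str
    evidence: tuple[str, ...]  # distinct parent groups observed


def default_rules() -> list[GroupRule]:
    """Keyword/motif rules for the seven quantified wheat families."""
    return [
        GroupRule("alpha_gliadin", [r"alpha[- /]?gliadin", r"alpha[- ]?beta[- ]?gliadin"]),
        GroupRule("gamma_gliadin", [r"gamma[- /]?gliadin"]),
        GroupRule("omega_gliadin", [r"omega[- /]?gliadin"]),
        GroupRule("lmw_gs", [r"low[- ]molecular[- ]weight glutenin", r"\bLMW\b.*glutenin", r"glutenin.*\bLMW\b"]),
        # PF03157-style HMW repeat motifs back up the header match
        GroupRule("hmw_gs", [r"high[- ]molecular[- ]weight glutenin", r"\bHMW\b.*glutenin", r"glutenin.*\bHMW\b"],
                  ["GYYPTSPQQ", "GQQPGQGQQ"]),
        GroupRule("alp", [r"avenin[- ]?like"]),
        GroupRule("ati", [r"amylase[ /-]*(?:and|/)?[ ]*trypsin inhibitor",
                          r"alpha[- ]?amylase inhibitor", r"\bATI\b"]),
    ]


def classify_protein(
    record: ProteinRecord,
    rules: list[GroupRule] | None = None,
    override: dict[str, str] | None = None,
) -> str:
    """Assign a protein to one family.

    An override entry wins outright; otherwise the rule set is applied
    and a protein firing rules of two or more distinct families is
    ``mixed``; one of no family is ``non_gluten``.
    """
    if override and record.id in override:
        group = override[record.id]
        if group not in GROUPS:
            raise ValueError(f"override for {record.id} names unknown group {group!r}")
        return group
    if rules is None:
        rules = default_rules()
    if not rules:
        raise ValueError("rule list is empty")
    hits = {r.group for r in rules if r.matches(record)}
    if len(hits) == 1:
        return hits.pop()
    if len(hits) >= 2:
        return "mixed"
    return "non_gluten"


def allocate_peptide_group(
    peptide: PeptideRecord, protein_groups: dict[str, str]
) -> GroupAllocation:
    """Allocate a quantified peptide to a single family or ``multiple``.

    Unanimous parent family -> that family. Parents spanning two or more
    families -> ``multiple``; parents that are themselves ``mixed``
    proteins cannot be attributed and also yield ``multiple``.
    """
    missing = sorted(p for p in peptide.parent_ids if p not in protein_groups)
    if missing:
        raise KeyError(f"parent ids missing from group mapping: {missing}")
    parent_groups = tuple(sorted({protein_groups[p] for p in peptide.parent_ids}))
    if len(parent_groups) == 1 and parent_groups[0] != "mixed":
        group = parent_groups[0]
    else:
        group = "multiple"
    return GroupAllocation(peptide.sequence, group, parent_groups)


def allocate_all(
    peptides: list[PeptideRecord], protein_groups: dict[str, str]
) -> dict[str, str]:
    """Peptide sequence -> group label for a whole peptide list."""
    return {
        p.sequence: allocate_peptide_group(p, protein_groups).group for p in peptides
    }


def load_rules(path) -> list[GroupRule]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [
        GroupRule(
            entry["group"],
            entry.get("header_patterns", []),
            entry.get("sequence_motifs", []),
            entry.get("priority", 0),
        )
        for entry in raw
    ]


def load_overrides(path) -> dict[str, str]:
    """Two-column TSV (protein_id, group), '#' comments allowed."""
    overrides: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("protein_id\t"):
                continue
            pid, group = line.split("\t")[:2]
            overrides[pid] = group
    return overrides


def write_allocations(allocations: list[GroupAllocation], path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide\tgroup\tparent_groups\n")
        for a in allocations:
            fh.write(f"{a.peptide}\t{a.group}\t{';'.join(a.evidence)}\n")
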