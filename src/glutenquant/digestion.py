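"""In-silico protease digestion and peptide-to-protein mapping.

Enumerates fully specific cleavage products of trypsin or chymotrypsin
digests of seed-storage (prolamin) protein databases, applies the
candidate length window used for MRM assay building (6-30 residues by
default), and maps observed peptides back onto the database by exact
substring identity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO

log = logging.getLogger(__name__)

#: The ten recognised protein-family labels.
GROUPS = (
    "alpha_gliadin",
    "gamma_gliadin",
    "omega_gliadin",
    "lmw_gs",
    "hmw_gs",
    "alp",
    "ati",
    "mixed",
    "non_gluten",
    "unassigned",
)

#: Families whose summed abundance defines the canonical gluten content
#: (gliadins plus glutenins; ALP and ATI are quantified but excluded).
CANONICAL_GLUTEN_GROUPS = (
    "alpha_gliadin",
    "gamma_gliadin",
    "omega_gliadin",
    "lmw_gs",
    "hmw_gs",
)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
ALLOWED_LETTERS = AMINO_ACIDS | {"X"}


class FastaParseError(ValueError):
    """Raised for malformed or inconsistent protein database entries."""


@dataclass
class ProteinRecord:
    """One database sequence with its assigned prolamin/allergen family."""

    id: str
    description: str
    sequence: str
    group: str = "unassigned"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise FastaParseError(f"empty sequence for entry {self.id!r}")
        bad = set(self.sequence) - ALLOWED_LETTERS
        if bad:
            raise FastaParseError(
                f"entry {self.id!r} contains invalid letters {sorted(bad)}"
            )
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


@dataclass
class DigestionRules:
    """Cleavage specificity for one protease.

    ``cleave_after`` residues trigger cleavage C-terminal to themselves
    unless the following residue is in ``suppress_before`` (the classical
    proline suppression rule).
    """

    protease: str
    cleave_after: frozenset[str]
    suppress_before: frozenset[str] = frozenset("P")
    max_missed: int = 0

    def __post_init__(self) -> None:
        if not self.cleave_after:
            raise ValueError("cleave_after must be non-empty")
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")

    @classmethod
    def trypsin(cls, max_missed: int = 0) -> "DigestionRules":
        return cls("trypsin", frozenset("KR"), frozenset("P"), max_missed)

    @classmethod
    def chymotrypsin(cls, max_missed: int = 0) -> "DigestionRules":
        return cls("chymotrypsin", frozenset("FWYL"), frozenset("P"), max_missed)


@dataclass
class PeptideRecord:
    """A digestion product with its parent proteins and uniqueness."""

    sequence: str
    protease: str = "trypsin"
    missed_cleavages: int = 0
    parent_ids: set[str] = field(default_factory=set)
    positions: list[tuple[str, int]] = field(default_factory=list)

    @property
    def is_unique(self) -> bool:
        return len(self.parent_ids) == 1


def read_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA into :class:`ProteinRecord` objects.

    Sequences are uppercased and ``*`` stop characters stripped; the
    family label starts out as ``unassigned``. Duplicate identifiers and
    empty sequences raise :class:`FastaParseError`.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if not entry.id:
            raise FastaParseError("entry with empty identifier")
        if entry.id in seen:
            raise FastaParseError(f"duplicate identifier {entry.id!r}")
        seen.add(entry.id)
        seq = str(entry.seq).upper().replace("*", "")
        if not seq:
            raise FastaParseError(f"empty sequence for entry {entry.id!r}")
        records.append(ProteinRecord(entry.id, entry.description, seq))
    if not records:
        warnings.warn(f"no FASTA entries found in {path}", stacklevel=2)
    return records


def cleavage_sites(sequence: str, rules: DigestionRules) -> list[int]:
    """0-based positions *after* which the protease cleaves."""
    n = len(sequence)
    sites = []
    for i, aa in enumerate(sequence[:-1]):
        if aa in rules.cleave_after and sequence[i + 1] not in rules.suppress_before:
            sites.append(i)
    # a C-terminal cleavable residue coincides with the protein end
    if n and sequence[-1] in rules.cleave_after:
        pass  # protein end already terminates the last fragment
    return sites


def digest(sequence: str, rules: DigestionRules) -> list[tuple[str, int, int]]:
    """Fully specific digestion of ``sequence``.

    Returns ``(peptide, start, missed)`` triples with 1-based start
    positions; every peptide with at most ``rules.max_missed`` retained
    internal sites is enumerated. The zero-missed products concatenate,
    in order, to the input.
    """
    sequence = sequence.upper()
    if not sequence:
        return []
    bounds = [0] + [s + 1 for s in cleavage_sites(sequence, rules)] + [len(sequence)]
    out: list[tuple[str, int, int]] = []
    nfrag = len(bounds) - 1
    for i in range(nfrag):
        for m in range(rules.max_missed + 1):
            j = i + m + 1
            if j > nfrag:
                break
            start, end = bounds[i], bounds[j]
            out.append((sequence[start:end], start + 1, m))
    return out


def filter_candidates(
    peptides: list[str], min_len: int = 6, max_len: int = 30, exclude_x: bool = True
) -> list[str]:
    """Length-filter and deduplicate candidate peptides.

    Keeps the first occurrence order; peptides containing the ambiguous
    residue X are dropped by default because neither mass nor exact
    matching is defined for them.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    seen: set[str] = set()
    out: list[str] = []
    for pep in peptides:
        pep = pep.upper()
        if not (min_len <= len(pep) <= max_len):
            continue
        if exclude_x and "X" in pep:
            continue
        if pep not in seen:
            seen.add(pep)
            out.append(pep)
    return out


def _occurrences(needle: str, haystack: str) -> list[int]:
    """All (overlapping) 0-based start offsets of needle in haystack."""
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def map_peptides(
    peptides: list[str],
    proteins: list[ProteinRecord],
    protease: str = "trypsin",
    missed_cleavages: int = 0,
) -> list[PeptideRecord]:
    """Map peptides onto proteins by 100% sequence identity.

    Overlapping occurrences within one protein count once toward the
    parent set but every 1-based start position is recorded. Peptides
    matching no protein are retained as flagged orphans (empty parent
    set) with a warning rather than silently dropped.
    """
    if not proteins:
        raise ValueError("protein database is empty")
    records = []
    for pep in peptides:
        pep = pep.upper()
        rec = PeptideRecord(pep, protease, missed_cleavages)
        for prot in proteins:
            for off in _occurrences(pep, prot.sequence):
                rec.parent_ids.add(prot.id)
                rec.positions.append((prot.id, off + 1))
        if not rec.parent_ids:
            warnings.warn(f"peptide {pep} matches no protein (orphan)", stacklevel=2)
        records.append(rec)
    return records


def write_peptides_tsv(records: list[PeptideRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tprotease\tmissed_cleavages\tparent_count\tparent_ids\tunique\n")
        for r in records:
            fh.write(
                f"{r.sequence}\t{r.protease}\t{r.missed_cleavages}\t"
                f"{len(r.parent_ids)}\t{';'.join(sorted(r.parent_ids))}\t"
                f"{int(r.is_unique)}\n"
            )
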