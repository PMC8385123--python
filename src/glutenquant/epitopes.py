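"""Immune-epitope containment search and per-category quantitation.

Monitored peptides are screened for full-length containment of known
immune-reactive sequences: coeliac HLA-DQ T-cell epitopes, baker's
asthma (BA) and wheat allergy (WA) IgE epitopes, the wheat-dependent
exercise-induced anaphylaxis (WDEIA) epitope, and the R5/G12 ELISA
antibody motifs. Matching is exact (100% identity) by default; I/L and
Q/E equivalence modes are available because mass spectrometry cannot
distinguish isoleucine from leucine and coeliac epitopes are defined on
deamidated (Q->E) sequences, but both are off unless requested.

Category abundance sums, per sample, the mean normalized abundance of
the distinct peptides containing at least one epitope of the category;
a peptide with several epitopes of one category counts once, and the
combined allergy total (BA + WA + WDEIA) deduplicates peptides across
categories as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .digestion import AMINO_ACIDS, _occurrences
from .quantitation import NormalizedMatrix

CATEGORIES = ("CD_HLA_DQ", "BA", "WA", "WDEIA", "R5", "G12")
ALLERGY_CATEGORIES = ("BA", "WA", "WDEIA")
ALLERGY_TOTAL = "ALLERGY_TOTAL"
MODES = ("strict", "il_equivalent", "qe_equivalent", "both")


@dataclass(frozen=True)
class Epitope:
    sequence: str
    category: str
    source_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if len(self.sequence) < 4:
            raise ValueError(f"epitope {self.sequence!r} shorter than 4 residues")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValueError(f"epitope {self.sequence!r} has non-amino-acid letters {sorted(bad)}")
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; allowed: {list(CATEGORIES)}"
            )


@dataclass(frozen=True)
class EpitopeMatch:
    peptide: str
    epitope: Epitope
    start: int  # 1-based position in the peptide
    mode: str = "strict"


def load_epitopes(path=None) -> list[Epitope]:
    """Read an epitope TSV (sequence, category, source_id).

    Lines starting with '#' are comments; duplicates on (sequence,
    category) collapse to one entry. Without a path the packaged
    example list is loaded.
    """
    if path is None:
        ref = resources.files("glutenquant.data") / "epitopes_example.tsv"
        lines = ref.read_text().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    epitopes: list[Epitope] = []
    seen: set[tuple[str, str]] = set()
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("sequence\t"):
            continue
        parts = line.split("\t")
        seq, cat = parts[0].upper(), parts[1]
        src = parts[2] if len(parts) > 2 else ""
        if (seq, cat) in seen:
            continue
        seen.add((seq, cat))
        epitopes.append(Epitope(seq, cat, src))
    return epitopes


def _canonical(seq: str, mode: str) -> str:
    if mode in ("il_equivalent", "both"):
        seq = seq.replace("I", "L")
    if mode in ("qe_equivalent", "both"):
        seq = seq.replace("E", "Q")
    return seq


def find_epitopes(
    peptides: list[str], epitopes: list[Epitope], mode: str = "strict"
) -> list[EpitopeMatch]:
    """All full-length epitope occurrences inside the peptides.

    Overlapping occurrences are all reported; ``mode`` selects the
    residue equivalence applied to both sides before matching.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; allowed: {list(MODES)}")
    matches: list[EpitopeMatch] = []
    for pep in peptides:
        hay = _canonical(pep.upper(), mode)
        for epi in epitopes:
            needle = _canonical(epi.sequence, mode)
            for off in _occurrences(needle, hay):
                matches.append(EpitopeMatch(pep.upper(), epi, off + 1, mode))
    return matches


def category_abundance(
    matches: list[EpitopeMatch],
    normalized: NormalizedMatrix,
    categories: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Per-category GW/MW relative abundance of epitope-bearing peptides.

    For each category the contributing peptides (distinct, regardless
    of how many epitopes they contain) are summed: per replicate the
    category value is the sum of their normalized abundances, means and
    SEM over each sample's replicates, ratio = 100 * GW/MW. A combined
    ``ALLERGY_TOTAL`` row pools BA, WA and WDEIA peptides with
    cross-category deduplication. Matched peptides absent from the
    normalized matrix are reported and skipped; a category whose MW
    total is zero gets a NaN ratio and an ``undefined-ratio`` flag.
    """
    by_cat: dict[str, set[str]] = {}
    for m in matches:
        by_cat.setdefault(m.epitope.category, set()).add(m.peptide)
    if categories is None:
        categories = tuple(c for c in CATEGORIES if c in by_cat)

    quantified = set(normalized.values.index)
    gw_cols = normalized.replicates("GW")
    mw_cols = normalized.replicates("MW")

    def _row(label: str, peptides: set[str]) -> dict:
        absent = sorted(peptides - quantified)
        if absent:
            warnings.warn(
                f"{label}: {len(absent)} matched peptide(s) not quantified, skipped: "
                f"{absent[:3]}",
                stacklevel=3,
            )
        peps = sorted(peptides & quantified)
        if not peps:
            return {
                "category": label, "n_peptides": 0, "gw": 0.0, "mw": 0.0,
                "ratio_percent": np.nan, "sem_gw": 0.0, "sem_mw": 0.0,
                "flag": "no quantified peptides",
            }
        block = normalized.values.loc[peps]
        gw_sums = block[gw_cols].sum(axis=0, skipna=True).to_numpy(float)
        mw_sums = block[mw_cols].sum(axis=0, skipna=True).to_numpy(float)
        gw, mw = gw_sums.mean(), mw_sums.mean()
        flag = "" if mw > 0 else "undefined-ratio"
        return {
            "category": label,
            "n_peptides": len(peps),
            "gw": gw,
            "mw": mw,
            "ratio_percent": 100.0 * gw / mw if mw > 0 else np.nan,
            "sem_gw": stats.sem(gw_sums) if len(gw_sums) > 1 else 0.0,
            "sem_mw": stats.sem(mw_sums) if len(mw_sums) > 1 else 0.0,
            "flag": flag,
        }

    rows = [_row(cat, by_cat.get(cat, set())) for cat in categories]
    allergy_peps: set[str] = set()
    for cat in ALLERGY_CATEGORIES:
        allergy_peps |= by_cat.get(cat, set())
    rows.append(_row(ALLERGY_TOTAL, allergy_peps))
    return pd.DataFrame.from_records(rows).set_index("category")


def write_matches(matches: list[EpitopeMatch], path) -> None:
    with open(path, "w") as fh:
        fh.write("peptide\tepitope\tcategory\tstart\tmode\n")
        for m in matches:
            fh.write(
                f"{m.peptide}\t{m.epitope.sequence}\t{m.epitope.category}\t{m.start}\t{m.mode}\n"
            )
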