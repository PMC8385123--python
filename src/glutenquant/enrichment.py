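"""Hypergeometric overrepresentation analysis of annotation terms.

A selected protein set (proteins unique to one sample, or proteins past
a fold-change cutoff) is tested term by term against a background using
the upper-tail hypergeometric distribution, with Benjamini-Hochberg
adjustment across terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class AnnotationTable:
    """protein id -> set of term ids, plus term id -> readable name."""

    terms_of: dict[str, set[str]]
    term_names: dict[str, str]

    @classmethod
    def from_tsv(cls, path) -> "AnnotationTable":
        terms_of: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("protein_id\t"):
                    continue
                parts = line.split("\t")
                pid, term = parts[0], parts[1]
                terms_of.setdefault(pid, set()).add(term)
                if len(parts) > 2:
                    names[term] = parts[2]
        return cls(terms_of, names)


def select_proteins(
    mode: str,
    *,
    sample_sets: dict[str, set[str]] | None = None,
    sample: str | None = None,
    fold_changes: dict[str, float] | None = None,
    fc_threshold: float = 2.0,
    direction: str = "up",
) -> set[str]:
    """Select the protein set to test.

    ``unique_to_sample``: proteins detected only in ``sample``.
    ``fold_change``: proteins whose log2 fold change passes
    ``log2(fc_threshold)`` in ``direction`` ('up', 'down' or 'both').
    """
    if mode == "unique_to_sample":
        if not sample_sets or sample not in sample_sets:
            raise ValueError("unique_to_sample needs sample_sets and a sample label")
        others: set[str] = set()
        for label, ids in sample_sets.items():
            if label != sample:
                others |= ids
        selected = sample_sets[sample] - others
    elif mode == "fold_change":
        if fold_changes is None:
            raise ValueError("fold_change mode needs fold_changes")
        cut = np.log2(fc_threshold)
        if direction == "up":
            selected = {p for p, fc in fold_changes.items() if fc >= cut}
        elif direction == "down":
            selected = {p for p, fc in fold_changes.items() if fc <= -cut}
        elif direction == "both":
            selected = {p for p, fc in fold_changes.items() if abs(fc) >= cut}
        else:
            raise ValueError(f"unknown direction {direction!r}")
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    if not selected:
        warnings.warn("protein selection is empty", stacklevel=2)
    return selected


def hypergeom_enrich(
    selected: set[str], background: set[str], annotations: AnnotationTable
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of every annotated term.

    p = P(X >= k) for k selected-and-annotated proteins among n selected,
    K background-annotated, N background; q by Benjamini-Hochberg.
    Results sort by (q, p, term).
    """
    offenders = sorted(selected - background)
    if offenders:
        raise ValueError(f"selected proteins not in background: {offenders[:5]}")
    N, n = len(background), len(selected)
    members: dict[str, set[str]] = {}
    for pid in background:
        for term in annotations.terms_of.get(pid, ()):
            members.setdefault(term, set()).add(pid)
    records = []
    for term, ids in sorted(members.items()):
        K = len(ids)
        k = len(ids & selected)
        p = float(hypergeom.sf(k - 1, N, K, n))  # P(X >= k)
        records.append(
            {
                "term": term,
                "name": annotations.term_names.get(term, term),
                "k": k, "K": K, "n": n, "N": N,
                "p_value": min(p, 1.0),
            }
        )
    df = pd.DataFrame.from_records(records)
    if df.empty:
        return df
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df.sort_values(["q_value", "p_value", "term"]).set_index("term")
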