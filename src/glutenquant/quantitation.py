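"""Peak-area normalization, differential abundance and group quantitation.

The quantitative unit is the peptide: its peak area in one replicate is
the sum of the areas of its monitored transitions. Each peptide is then
normalized to the average area seen across all replicates of both
samples, so group-level comparisons are relative-abundance comparisons
in which every peptide carries equal weight. Group abundance per
replicate is the sum of the normalized values of its allocated
peptides; the net canonical gluten content is the GW/MW ratio of the
five gliadin/glutenin families' summed means, reported as a percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .digestion import CANONICAL_GLUTEN_GROUPS

SAMPLES = ("GW", "MW")
REQUIRED_COLUMNS = ("peptide", "protease", "replicate", "sample", "transition", "area")


@dataclass
class PipelineConfig:
    """All tunable thresholds of the quantitation pipeline."""

    min_len: int = 6
    max_len: int = 30
    fc_threshold: float = 2.0
    p_threshold: float = 0.01
    n_replicates: int = 4
    log_transform: bool = True
    max_missed: int = 0
    epitope_mode: str = "strict"
    precursor_charges: tuple[int, ...] = (2, 3)

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len > max_len")
        if self.fc_threshold <= 0 or self.p_threshold <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        if "precursor_charges" in known:
            known["precursor_charges"] = tuple(known["precursor_charges"])
        return cls(**known)


@dataclass
class NormalizedMatrix:
    """Peptide x replicate normalized abundances.

    ``values`` has peptide sequences as index and replicate ids as
    columns; ``sample_of`` maps each replicate id to its sample label.
    NaN marks a missing peptide/replicate observation.
    """

    values: pd.DataFrame
    sample_of: dict[str, str]

    def replicates(self, sample: str) -> list[str]:
        return [r for r in self.values.columns if self.sample_of[r] == sample]

    def sample_means(self, sample: str) -> pd.Series:
        return self.values[self.replicates(sample)].mean(axis=1)


def load_quant_table(path) -> pd.DataFrame:
    """Load and validate a transition peak-area table (CSV or TSV)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype={"replicate": str})
    return validate_quant_table(df)


def validate_quant_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"quant table missing required columns: {missing}")
    bad_samples = sorted(set(df["sample"]) - set(SAMPLES))
    if bad_samples:
        raise ValueError(f"unknown sample labels {bad_samples}; allowed: {list(SAMPLES)}")
    if (df["area"] < 0).any():
        rows = df.index[df["area"] < 0].tolist()[:5]
        raise ValueError(f"negative peak areas at rows {rows}")
    dup = df.duplicated(subset=["peptide", "replicate", "transition"])
    if dup.any():
        raise ValueError(
            f"duplicate (peptide, replicate, transition) rows: {df.index[dup].tolist()[:5]}"
        )
    for sample in SAMPLES:
        if not (df["sample"] == sample).any():
            raise ValueError(f"no replicates for sample {sample}")
    ambiguous = df.groupby("replicate")["sample"].nunique()
    ambiguous = ambiguous[ambiguous > 1]
    if len(ambiguous):
        raise ValueError(
            f"replicate id(s) used by both samples: {ambiguous.index.tolist()}"
        )
    return df


def peptide_area(table: pd.DataFrame) -> NormalizedMatrix:
    """Sum transition areas to a peptide x replicate matrix.

    Returns an (unnormalized) matrix whose missing cells are NaN where a
    peptide was not observed in a replicate.
    """
    sample_of = (
        table.drop_duplicates("replicate").set_index("replicate")["sample"].to_dict()
    )
    mat = table.pivot_table(
        index="peptide", columns="replicate", values="area", aggfunc="sum"
    )
    # stable column order: GW replicates then MW, each sorted
    cols = sorted(mat.columns, key=lambda r: (sample_of[r], str(r)))
    return NormalizedMatrix(mat[cols], sample_of)


def normalize(matrix: NormalizedMatrix) -> NormalizedMatrix:
    """Normalize each peptide to its mean across all observed replicates."""
    values = matrix.values.astype(float)
    means = values.mean(axis=1, skipna=True)
    zero = means <= 0
    if zero.any():
        warnings.warn(
            f"dropping {int(zero.sum())} all-zero peptide(s): "
            f"{values.index[zero].tolist()[:5]}",
            stacklevel=2,
        )
        values = values.loc[~zero]
        means = means.loc[~zero]
    return NormalizedMatrix(values.div(means, axis=0), dict(matrix.sample_of))


@dataclass
class DifferentialResult:
    peptide: str
    log2_fold_change: float
    p_value: float
    q_value: float = float("nan")
    significant: bool = False
    flag: str = ""


def welch_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Welch unequal-variance t-test p-value."""
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.pvalue)


def differential(
    normalized: NormalizedMatrix, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Per-peptide GW/MW volcano statistics.

    log2FC is log2(mean GW / mean MW) of normalized values; the p-value
    comes from a two-sided Welch test on log2-transformed values (raw
    scale if ``config.log_transform`` is off). Peptides observed in only
    one sample are flagged ``one-sided presence``; zero within-group
    variance yields a NaN p flagged ``degenerate-variance``; both are
    excluded from significance calls. BH-adjusted q-values are added for
    transparency although significance uses the raw p threshold.
    """
    if config is None:
        config = PipelineConfig()
    rows = []
    gw_cols = normalized.replicates("GW")
    mw_cols = normalized.replicates("MW")
    for pep, row in normalized.values.iterrows():
        gw = row[gw_cols].dropna().to_numpy(float)
        mw = row[mw_cols].dropna().to_numpy(float)
        if len(gw) == 0 or len(mw) == 0:
            rows.append(DifferentialResult(pep, np.nan, np.nan, flag="one-sided presence"))
            continue
        log2fc = float(np.log2(gw.mean() / mw.mean()))
        a, b = (np.log2(gw), np.log2(mw)) if config.log_transform else (gw, mw)
        if len(a) < 2 or len(b) < 2:
            rows.append(DifferentialResult(pep, log2fc, np.nan, flag="insufficient replicates"))
            continue
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            rows.append(DifferentialResult(pep, log2fc, np.nan, flag="degenerate-variance"))
            continue
        rows.append(DifferentialResult(pep, log2fc, welch_test(a, b)))

    df = pd.DataFrame(
        {
            "peptide": [r.peptide for r in rows],
            "log2_fold_change": [r.log2_fold_change for r in rows],
            "p_value": [r.p_value for r in rows],
            "flag": [r.flag for r in rows],
        }
    ).set_index("peptide")
    ok = df["p_value"].notna()
    df["q_value"] = np.nan
    if ok.any():
        df.loc[ok, "q_value"] = multipletests(df.loc[ok, "p_value"], method="fdr_bh")[1]
    df["significant"] = (
        ok
        & (df["log2_fold_change"].abs() >= np.log2(config.fc_threshold))
        & (df["p_value"] < config.p_threshold)
    )
    return df


def group_abundance(
    normalized: NormalizedMatrix, allocations: dict[str, str]
) -> pd.DataFrame:
    """Summed normalized abundance per family, with GW/MW ratio and Welch p.

    Per replicate the group value is the sum of normalized values of the
    peptides allocated to the group; means and SEM are taken over each
    sample's replicates.
    """
    missing = sorted(set(normalized.values.index) - set(allocations))
    if missing:
        raise KeyError(f"peptides without group allocation: {missing[:5]}")
    groups = sorted({allocations[p] for p in normalized.values.index})
    gw_cols = normalized.replicates("GW")
    mw_cols = normalized.replicates("MW")
    records = []
    for group in groups:
        peps = [p for p in normalized.values.index if allocations[p] == group]
        if not peps:
            warnings.warn(f"group {group} has no peptides; omitted", stacklevel=2)
            continue
        block = normalized.values.loc[peps]
        gw_sums = block[gw_cols].sum(axis=0, skipna=True).to_numpy(float)
        mw_sums = block[mw_cols].sum(axis=0, skipna=True).to_numpy(float)
        mean_gw, mean_mw = gw_sums.mean(), mw_sums.mean()
        p = (
            welch_test(gw_sums, mw_sums)
            if np.ptp(gw_sums) > 0 or np.ptp(mw_sums) > 0
            else np.nan
        )
        records.append(
            {
                "group": group,
                "n_peptides": len(peps),
                "mean_gw": mean_gw,
                "mean_mw": mean_mw,
                "sem_gw": stats.sem(gw_sums) if len(gw_sums) > 1 else 0.0,
                "sem_mw": stats.sem(mw_sums) if len(mw_sums) > 1 else 0.0,
                "ratio_gw_mw": mean_gw / mean_mw if mean_mw > 0 else np.inf,
                "p_value": p,
            }
        )
    return pd.DataFrame.from_records(records).set_index("group")


def net_gluten_ratio(group_results: pd.DataFrame) -> float:
    """Net gliadin+glutenin GW/MW content in percent.

    Sums the mean group abundances of the five canonical families
    (alpha-, gamma-, omega-gliadin, LMW-GS, HMW-GS); ALP, ATI, multiple
    and non-gluten groups are excluded.
    """
    gw = mw = 0.0
    for group in CANONICAL_GLUTEN_GROUPS:
        if group not in group_results.index:
            warnings.warn(f"canonical group {group} absent; contributes 0", stacklevel=2)
            continue
        gw += group_results.loc[group, "mean_gw"]
        mw += group_results.loc[group, "mean_mw"]
    if mw == 0:
        raise ZeroDivisionError("MW canonical gluten abundance is zero")
    return 100.0 * gw / mw
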