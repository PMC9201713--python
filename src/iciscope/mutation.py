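"""MAF parsing, tumor mutation burden (TMB) and its link to ICI scores.

TMB is the count of non-silent somatic mutations per megabase of captured
exome. The default denominator is 38 Mb, a common whole-exome convention;
it is configurable because reported TMB values depend on it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ["Hugo_Symbol", "Variant_Classification",
                    "Tumor_Sample_Barcode", "Chromosome", "Start_Position"]

#: Variant classes counted as non-silent (protein-affecting).
NONSILENT_CLASSES = frozenset({
    "Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del",
    "Frame_Shift_Ins", "In_Frame_Del", "In_Frame_Ins", "Splice_Site",
    "Translation_Start_Site", "Nonstop_Mutation",
})

DEFAULT_EXOME_MB = 38.0


def read_maf(path: str | Path) -> pd.DataFrame:
    """Read a MAF file (tab-separated, '#' comment lines skipped).

    Header matching is case-insensitive; the required columns are renamed
    to their canonical capitalization and extra columns pass through
    untouched. A missing required column raises with its name.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    lower = {c.lower(): c for c in df.columns}
    rename = {}
    for col in REQUIRED_COLUMNS:
        if col.lower() not in lower:
            raise ValueError(f"MAF is missing required column {col!r}")
        rename[lower[col.lower()]] = col
    df = df.rename(columns=rename)
    df["Start_Position"] = df["Start_Position"].astype(int)
    if (df["Start_Position"] <= 0).any():
        raise ValueError("Start_Position must be a positive integer")
    return df


def write_maf(maf: pd.DataFrame, path: str | Path) -> None:
    maf.to_csv(path, sep="\t", index=False)


def compute_tmb(maf: pd.DataFrame,
                exome_mb: float = DEFAULT_EXOME_MB,
                nonsilent_classes: frozenset = NONSILENT_CLASSES,
                sample_roster: list[str] | None = None) -> pd.DataFrame:
    """Per-sample TMB table (n_nonsilent, tmb = n_nonsilent / exome_mb).

    Samples listed in ``sample_roster`` but absent from the MAF receive a
    TMB of zero (a sequenced sample with no reported mutations).
    """
    if exome_mb <= 0:
        raise ValueError("exome_mb must be positive")
    ns = maf[maf["Variant_Classification"].isin(nonsilent_classes)]
    counts = ns.groupby("Tumor_Sample_Barcode").size()
    if sample_roster is not None:
        counts = counts.reindex(sample_roster, fill_value=0)
    out = pd.DataFrame({"n_nonsilent": counts.astype(int)})
    out["tmb"] = out["n_nonsilent"] / exome_mb
    out.index.name = "sample"
    return out


def compare_tmb_by_group(tmb: pd.DataFrame, groups: pd.Series
                         ) -> dict:
    """Compare TMB across ICI score groups.

    Two groups get a two-sided Wilcoxon rank-sum test, more get
    Kruskal-Wallis; per-group medians are reported alongside.
    """
    from iciscope.downstream import kruskal_wallis, rank_stats

    groups = groups.reindex(tmb.index)
    if groups.isna().any():
        raise ValueError("every sample needs a group label")
    levels = sorted(groups.unique().tolist())
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    by_group = [tmb.loc[groups == g, "tmb"].to_numpy() for g in levels]
    if len(levels) == 2:
        stat, p = rank_stats(by_group[0], by_group[1])
        test = "wilcoxon-rank-sum"
    else:
        stat, _, p = kruskal_wallis(by_group)
        test = "kruskal-wallis"
    medians = {g: float(np.median(v)) for g, v in zip(levels, by_group)}
    return {"test": test, "statistic": stat, "p": p, "medians": medians}


def tmb_score_correlation(tmb: pd.DataFrame, score: pd.Series
                          ) -> tuple[float, float]:
    """Pearson correlation between TMB and a per-sample score, with the
    t-distribution p-value."""
    score = score.reindex(tmb.index)
    paired = pd.DataFrame({"tmb": tmb["tmb"], "score": score}).dropna()
    if len(paired) < 3:
        raise ValueError("need at least 3 paired observations")
    r, p = stats.pearsonr(paired["tmb"], paired["score"])
    return float(r), float(p)
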