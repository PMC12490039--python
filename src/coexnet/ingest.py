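"""Expression input, gene-level filtering, and the two-group differential ranking.

Mirrors the preprocessing applied to normalized log-scale microarray data:
collapse duplicate transcripts to the highest-expressed one, discard genes
below the first quartile of median absolute deviation, and rank genes by
log2 fold change between the two conditions with Welch t p-values and
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

__all__ = [
    "read_expression",
    "collapse_transcripts",
    "mad_filter",
    "differential_ranking",
]


def read_expression(path: str | Path, condition_path: str | Path) -> ExpressionMatrix:
    """Load a genes-by-samples TSV plus a (sample, condition) TSV.

    The first column of the expression file holds gene symbols; duplicate
    symbols are allowed (collapse them with :func:`collapse_transcripts`).
    Non-numeric cells and samples missing from the condition file are
    rejected.
    """
    path, condition_path = Path(path), Path(condition_path)
    header = path.read_text().splitlines()[0].rstrip("\n").split("\t")
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ValueError(f"duplicate sample ids in {path.name}: {dupes}")

    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    values = raw.apply(pd.to_numeric, errors="coerce")
    if values.isna().any().any():
        bad = np.argwhere(values.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric cell at gene {values.index[bad[0]]!r}, "
            f"sample {values.columns[bad[1]]!r} "
            f"(value {raw.iat[bad[0], bad[1]]!r})"
        )

    cond_df = pd.read_csv(condition_path, sep="\t", dtype=str)
    if cond_df.shape[1] < 2:
        raise ValueError("condition file needs (sample, condition) columns")
    condition = pd.Series(
        cond_df.iloc[:, 1].to_numpy(), index=cond_df.iloc[:, 0].to_numpy()
    )
    missing = [s for s in values.columns if s not in condition.index]
    if missing:
        raise ValueError(f"condition file missing samples: {missing}")
    return ExpressionMatrix(values.astype(float), condition)


def collapse_transcripts(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Keep, per gene symbol, the transcript row with the highest mean.

    Ties are broken toward the earlier row in the input so the result is
    stable under re-application.
    """
    values = matrix.values
    if values.index.is_unique:
        return matrix.copy()
    means = values.mean(axis=1).to_numpy()
    frame = pd.DataFrame(
        {"gene": values.index, "mean": means, "pos": np.arange(len(values))}
    )
    # highest mean wins; on an exact tie the smaller original index wins
    frame = frame.sort_values(["gene", "mean", "pos"], ascending=[True, False, True])
    keep = frame.drop_duplicates("gene", keep="first").sort_values("pos")["pos"]
    collapsed = values.iloc[list(keep)]
    return ExpressionMatrix(collapsed, matrix.condition)


def gene_mad(values: pd.DataFrame, center: str = "median") -> pd.Series:
    """Per-gene absolute deviation score about the row median (or mean)."""
    if center == "median":
        dev = values.sub(values.median(axis=1), axis=0)
        return dev.abs().median(axis=1)
    if center == "mean":
        dev = values.sub(values.mean(axis=1), axis=0)
        return dev.abs().mean(axis=1)
    raise ValueError("center must be 'median' or 'mean'")


def mad_filter(matrix: ExpressionMatrix, center: str = "median") -> ExpressionMatrix:
    """Drop genes whose MAD falls strictly below the first quartile of MADs.

    The quartile uses linear interpolation. For a continuous MAD
    distribution over G genes this retains ceil(0.75 * G) genes.
    """
    if len(matrix.values) < 4:
        raise ValueError("mad_filter needs at least 4 genes")
    mads = gene_mad(matrix.values, center=center)
    if float(mads.max()) == float(mads.min()):
        warnings.warn("all genes have identical MAD; nothing removed", stacklevel=2)
        return matrix.copy()
    q1 = float(np.quantile(mads.to_numpy(), 0.25))
    kept = matrix.values.loc[mads >= q1]
    return ExpressionMatrix(kept, matrix.condition)


def differential_ranking(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Two-group differential table sorted by log2 fold change, descending.

    Data are assumed log2-scale, so log2fc is the difference of group means
    (B minus A). P-values come from Welch's t-test and are BH-adjusted.
    Ties in log2fc are broken by gene symbol so the ranking is total.
    """
    a_cols = matrix.samples_in("A")
    b_cols = matrix.samples_in("B")
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each condition needs >= 2 samples for the t-test")
    a = matrix.values[a_cols].to_numpy()
    b = matrix.values[b_cols].to_numpy()
    log2fc = b.mean(axis=1) - a.mean(axis=1)
    t_stat, p_value = stats.ttest_ind(b, a, axis=1, equal_var=False)
    p_value = np.nan_to_num(p_value, nan=1.0)
    _, adj_p, _, _ = multipletests(p_value, method="fdr_bh")
    out = pd.DataFrame(
        {
            "gene": matrix.genes,
            "log2fc": log2fc,
            "t": t_stat,
            "p": p_value,
            "adj_p": adj_p,
        }
    )
    out = out.sort_values(["log2fc", "gene"], ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)
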