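"""Connectivity-score drug repurposing.

A query signature (up- and down-regulated gene sets) is scored against a
library of drug-induced gene rankings with the weighted connectivity score
(WTCS): separate weighted running-sum enrichments of the up and down sets
are combined as ``(ES_up - ES_down) / 2`` when their signs differ and 0
otherwise. Scores are normalized per sign onto [-1, 1] across the library
and candidates are drugs whose normalized score falls below a reversal
threshold (default -0.7).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import DrugSignatureLibrary

__all__ = [
    "QuerySignature",
    "signature_es",
    "wtcs",
    "score_library",
    "normalize_scores",
    "screen_drugs",
]


@dataclass
class QuerySignature:
    """Disjoint up/down gene sets; at least one must be non-empty."""

    up_genes: list[str]
    down_genes: list[str]

    def __post_init__(self) -> None:
        up, down = set(self.up_genes), set(self.down_genes)
        if up & down:
            raise ValueError("up and down sets must be disjoint")
        if not up and not down:
            raise ValueError("query signature is empty")
        self.up_genes = sorted(up)
        self.down_genes = sorted(down)


def signature_es(profile: pd.Series, gene_set: list[str]) -> float:
    """Weighted running-sum enrichment of a gene set in a ranked profile.

    ``profile`` maps genes to signed differential scores and is sorted
    descending internally. Hit increments are proportional to |score|;
    misses decrement uniformly. Returns the maximum deviation from zero,
    in [-1, 1].
    """
    ordered = profile.sort_values(ascending=False, kind="mergesort")
    genes = np.array(ordered.index)
    hits = np.isin(genes, list(gene_set))
    if not hits.any():
        missing = sorted(set(gene_set) - set(genes))
        raise ValueError(f"gene set absent from profile: {missing[:10]}")
    n = genes.size
    n_hits = int(hits.sum())
    if n_hits == n:
        raise ValueError("gene set covers the whole profile")
    w = np.abs(ordered.to_numpy(dtype=float))
    hit_total = w[hits].sum()
    if hit_total == 0:
        steps = np.where(hits, 1.0 / n_hits, -1.0 / (n - n_hits))
    else:
        steps = np.where(hits, w / hit_total, -1.0 / (n - n_hits))
        steps[~hits] = -1.0 / (n - n_hits)
    path = np.cumsum(steps)
    return float(path[np.argmax(np.abs(path))])


def wtcs(profile: pd.Series, query: QuerySignature) -> dict:
    """Weighted connectivity score of a query signature in one profile.

    With both sets present, ``wtcs = (es_up - es_down)/2`` when the two
    enrichments have opposite signs and 0 otherwise. One-sided queries use
    the single enrichment (down-only queries are negated so reversal stays
    negative).
    """
    es_up = signature_es(profile, query.up_genes) if query.up_genes else np.nan
    es_down = signature_es(profile, query.down_genes) if query.down_genes else np.nan
    if query.up_genes and query.down_genes:
        if np.sign(es_up) == np.sign(es_down):
            score = 0.0
        else:
            score = (es_up - es_down) / 2.0
    elif query.up_genes:
        score = es_up
    else:
        score = -es_down
    return {"es_up": es_up, "es_down": es_down, "wtcs": float(score)}


def score_library(
    library: DrugSignatureLibrary | pd.DataFrame, query: QuerySignature
) -> pd.DataFrame:
    """WTCS of every drug in a library, plus normalized scores.

    Query genes missing from the library universe are dropped with a log
    message (landmark-style partial profiles).
    """
    scores = library.scores if isinstance(library, DrugSignatureLibrary) else library
    universe = set(scores.index)
    up = [g for g in query.up_genes if g in universe]
    down = [g for g in query.down_genes if g in universe]
    dropped = (set(query.up_genes) | set(query.down_genes)) - universe
    if dropped:
        warnings.warn(
            f"{len(dropped)} query gene(s) absent from the library universe; dropped",
            stacklevel=2,
        )
    if not up and not down:
        raise ValueError("no query gene present in the library universe")
    trimmed = QuerySignature(up_genes=up, down_genes=down)
    rows = []
    for drug in scores.columns:
        res = wtcs(scores[drug], trimmed)
        rows.append({"drug": drug, **res})
    out = pd.DataFrame(rows)
    return normalize_scores(out)


def normalize_scores(results: pd.DataFrame) -> pd.DataFrame:
    """Scale connectivity scores onto [-1, 1] per sign.

    Positive scores are divided by the library's maximum positive score,
    negative scores by the magnitude of its minimum; zeros are unchanged.
    The map is order-preserving within each sign and idempotent.
    """
    if len(results) == 0:
        raise ValueError("no results to normalize")
    s = results["wtcs"].to_numpy(dtype=float)
    out = results.copy()
    norm = s.copy()
    pos_max = s[s > 0].max() if (s > 0).any() else 0.0
    neg_min = s[s < 0].min() if (s < 0).any() else 0.0
    if pos_max == 0 and neg_min == 0:
        warnings.warn("all connectivity scores are zero; nothing to normalize",
                      stacklevel=2)
    if pos_max > 0:
        norm[s > 0] = s[s > 0] / pos_max
    if neg_min < 0:
        norm[s < 0] = s[s < 0] / abs(neg_min)
    out["normalized_score"] = norm
    return out


def screen_drugs(results: pd.DataFrame, threshold: float = -0.7) -> pd.DataFrame:
    """Drugs whose normalized connectivity score reverses the query.

    Returns rows with ``normalized_score < threshold`` sorted ascending,
    keeping ``es_up``/``es_down`` for audit.
    """
    if "normalized_score" not in results.columns:
        raise ValueError("normalize scores before screening")
    hits = results[results["normalized_score"] < threshold]
    return hits.sort_values("normalized_score").reset_index(drop=True)
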