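"""Marker-panel construction by Jaccard similarity over GO annotation sets.

Starting from seed marker genes (fast: Myh1/Myh2/Myh4, slow: Myh7), every
other annotated gene is scored by its Jaccard similarity to the seeds'
GO-term sets and the top candidates join the factor-analysis panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["jaccard", "rank_similar_genes", "select_feature_panel",
           "SimilarityRanking"]


def jaccard(set_a: set, set_b: set) -> float:
    """|A∩B| / |A∪B| for two non-empty annotation sets."""
    a, b = set(set_a), set(set_b)
    if not a or not b:
        raise ValueError("Jaccard index requires non-empty sets")
    return len(a & b) / len(a | b)


@dataclass
class SimilarityRanking:
    """Non-seed genes sorted by descending score, ties lexicographic."""

    frame: pd.DataFrame  # columns: gene, score
    seeds: tuple[str, ...]

    def top(self, k: int) -> list[str]:
        return self.frame["gene"].head(k).tolist()


def rank_similar_genes(seeds: list[str], table: dict[str, set[str]],
                       aggregate: str = "max") -> SimilarityRanking:
    """Score every non-seed gene by aggregated Jaccard against the seeds.

    ``aggregate="max"`` treats a gene similar to any single seed as a
    candidate (the myosin relatives each resemble one seed);
    ``"mean"`` averages over all seeds.
    """
    if aggregate not in ("max", "mean"):
        raise ValueError(f"unknown aggregate {aggregate!r}")
    missing = [s for s in seeds if s not in table]
    if missing:
        raise KeyError(f"seed gene(s) not annotated: {missing}")
    seed_sets = [table[s] for s in seeds]
    rows = []
    for gene in table:
        if gene in seeds:
            continue
        scores = [jaccard(table[gene], s) for s in seed_sets]
        agg = max(scores) if aggregate == "max" else sum(scores) / len(scores)
        rows.append((gene, agg))
    frame = pd.DataFrame(rows, columns=["gene", "score"])
    frame = frame.sort_values(["score", "gene"], ascending=[False, True],
                              ignore_index=True)
    return SimilarityRanking(frame=frame, seeds=tuple(seeds))


def select_feature_panel(seeds: list[str], ranking: SimilarityRanking,
                         top_k: int | None = None,
                         min_score: float | None = None) -> list[str]:
    """Panel = seeds plus selected similar genes, seeds first."""
    if (top_k is None) == (min_score is None):
        raise ValueError("give exactly one of top_k / min_score")
    if top_k is not None:
        if top_k < 0:
            raise ValueError("top_k must be >= 0")
        if top_k > len(ranking.frame):
            logger.warning("top_k=%d exceeds %d available genes; truncating",
                           top_k, len(ranking.frame))
            top_k = len(ranking.frame)
        selected = ranking.top(top_k)
    else:
        selected = ranking.frame.loc[ranking.frame["score"] >= min_score,
                                     "gene"].tolist()
    panel: list[str] = []
    for g in list(seeds) + selected:
        if g not in panel:
            panel.append(g)
    return panel


def panel_table(seeds: list[str], ranking: SimilarityRanking,
                panel: list[str]) -> pd.DataFrame:
    """panel.tsv content: gene, score, origin in {seed, similar}."""
    score = ranking.frame.set_index("gene")["score"]
    return pd.DataFrame({
        "gene": panel,
        "score": [1.0 if g in seeds else float(score.get(g, float("nan")))
                  for g in panel],
        "origin": ["seed" if g in seeds else "similar" for g in panel],
    })
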