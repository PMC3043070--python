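"""Pivot-miRNA integration: ranking schemes feeding mHG enrichment.

Three ways of ranking the mRNA universe are supported: (A) by
differential-expression score, (B) by Spearman correlation to a pivot
miRNA across the cohort, and (C) by predicted-targeting (context)
score. Scheme-B rankings in both orientations drive the signed
miRNA x gene-set association matrix and the concordance analysis
between differential expression and process enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import ExpressionMatrix, GeneSetCollection, TargetScoreTable
from .mhg import EnrichmentResult, build_label_vector, mhg_test

logger = logging.getLogger(__name__)

__all__ = [
    "RankedList",
    "AssociationMatrix",
    "ConcordanceResult",
    "spearman_correlations",
    "spearman_rank_genes",
    "rank_by_differential",
    "rank_by_target_score",
    "target_anticorrelation_enrichment",
    "signed_association_score",
    "association_matrix",
    "de_enrichment_concordance",
]

DIRECTIONS = (
    "descending_correlation",
    "ascending_correlation",
    "ascending_target_score",
    "descending_de_score",
)


@dataclass
class RankedList:
    """Ordered gene ids with their ranking scores and a direction tag."""

    genes: list[str]
    scores: np.ndarray
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids in ranking")
        self.scores = np.asarray(self.scores, dtype=float)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ConcordanceResult:
    set_name: str
    r: float
    n_mirnas: int


AssociationMatrix = pd.DataFrame  # rows: pivot miRNAs, cols: gene sets


def spearman_correlations(pivot: np.ndarray, mrna: ExpressionMatrix) -> np.ndarray:
    """Spearman rho of every gene against the pivot vector (average ranks
    for ties); genes with zero rank variance get rho = 0."""
    pivot = np.asarray(pivot, dtype=float)
    if pivot.size != mrna.n_samples:
        raise ValueError("pivot vector and mRNA matrix sample counts differ")
    pr = rankdata(pivot)
    pr = pr - pr.mean()
    pnorm = np.sqrt((pr**2).sum())
    gr = np.apply_along_axis(rankdata, 1, mrna.values)
    gr = gr - gr.mean(axis=1, keepdims=True)
    gnorm = np.sqrt((gr**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (gr @ pr) / (gnorm * pnorm)
    rho[(gnorm == 0) | (pnorm == 0)] = 0.0
    return rho


def spearman_rank_genes(
    pivot: np.ndarray,
    mrna: ExpressionMatrix,
    direction: str = "descending_correlation",
) -> RankedList:
    """Rank all genes by Spearman correlation to the pivot expression.

    ``descending_correlation`` puts the strongest positive correlatees
    first (ties by gene id); ``ascending_correlation`` is its exact
    reverse, so the two orientations of one pivot are mirror rankings.
    """
    if direction not in ("descending_correlation", "ascending_correlation"):
        raise ValueError(f"direction must be a correlation direction, got {direction!r}")
    rho = spearman_correlations(pivot, mrna)
    order = sorted(range(len(rho)), key=lambda i: (-rho[i], mrna.feature_ids[i]))
    if direction == "ascending_correlation":
        order = order[::-1]
    return RankedList(
        [mrna.feature_ids[i] for i in order], rho[order], direction
    )


def rank_by_differential(results: pd.DataFrame) -> RankedList:
    """Rank features by signed differential-expression score
    (-log10 p for 'up', +log10 p for 'down'); most up-regulated first,
    ties broken by feature id."""
    if results.empty:
        raise ValueError("empty differential result table")
    sign = np.where(results["direction"].to_numpy() == "up", -1.0, 1.0)
    score = sign * np.log10(results["tnom_p"].to_numpy())
    df = pd.DataFrame({"feature_id": results["feature_id"], "score": score})
    df = df.sort_values(
        ["score", "feature_id"], ascending=[False, True], kind="mergesort"
    )
    return RankedList(
        df["feature_id"].tolist(), df["score"].to_numpy(), "descending_de_score"
    )


def rank_by_target_score(
    pivot_id: str,
    targets: TargetScoreTable,
    universe: Sequence[str],
) -> RankedList:
    """Rank the universe genes predicted to be targets of the pivot,
    ascending by context score (more negative = stronger predicted
    targeting); genes absent from the table are excluded."""
    sub = targets.targets_of(pivot_id)  # raises KeyError naming the pivot
    universe_set = set(universe)
    sub = sub[sub["gene"].isin(universe_set)]
    return RankedList(
        sub["gene"].tolist(), sub["score"].to_numpy(), "ascending_target_score"
    )


def top_targets(
    pivot_id: str, targets: TargetScoreTable, top_n: int = 2000
) -> list[str]:
    """The top_n strongest-scoring (most negative) predicted targets of a
    pivot; all of them when fewer exist."""
    sub = targets.targets_of(pivot_id)
    if len(sub) < top_n:
        logger.info(
            "pivot %s has only %d predicted targets (< %d); using all",
            pivot_id, len(sub), top_n,
        )
    return sub["gene"].head(top_n).tolist()


def target_anticorrelation_enrichment(
    pivot_id: str,
    pivot_expr: np.ndarray,
    mrna: ExpressionMatrix,
    targets: TargetScoreTable,
    top_n: int = 2000,
) -> EnrichmentResult:
    """Enrichment of the pivot's top predicted targets among its top
    anti-correlated genes: H = top ``top_n`` targets by context score,
    ranking = genes ascending by Spearman rho to the pivot. A small
    p-value indicates the pivot's targets are anti-correlated with it."""
    h = set(top_targets(pivot_id, targets, top_n))
    ranking = spearman_rank_genes(pivot_expr, mrna, "ascending_correlation")
    v = build_label_vector(ranking.genes, h & set(ranking.genes))
    s, n_star, b_star, p = mhg_test(v)
    return EnrichmentResult(
        set_name=f"targets:{pivot_id}",
        s=s,
        n_star=n_star,
        b_star=b_star,
        p_exact=p,
        q=p,
        direction="anti-correlated",
    )


def signed_association_score(p_pos: float, p_neg: float) -> float:
    """Signed association: +(-log10 p_pos) when the set is better
    supported among positively correlated genes, -(-log10 p_neg)
    otherwise (the smaller p wins the sign)."""
    if p_pos <= p_neg:
        return -np.log10(p_pos)
    return np.log10(p_neg)


def association_matrix(
    pivots: ExpressionMatrix,
    mrna: ExpressionMatrix,
    sets: GeneSetCollection,
) -> AssociationMatrix:
    """Signed mHG association of every pivot miRNA with every gene set.

    For each pivot both correlation orientations are tested; the cell is
    the signed score (positive when the set is enriched among the genes
    positively correlated to the pivot). Row/column order follows the
    input pivots and set collection.
    """
    if pivots.sample_ids != mrna.sample_ids:
        raise ValueError("pivot and mRNA matrices must share samples in order")
    if len(sets) == 0 or pivots.n_features == 0:
        raise ValueError("need at least one pivot and one gene set")
    universe = set(mrna.feature_ids)
    member_lists = {
        name: [g for g in sets.members(name) if g in universe] for name in sets.names()
    }
    scores = np.zeros((pivots.n_features, len(sets)))
    for i in range(pivots.n_features):
        ranking = spearman_rank_genes(
            pivots.values[i], mrna, "descending_correlation"
        )
        rev = ranking.genes[::-1]
        for j, name in enumerate(sets.names()):
            members = member_lists[name]
            if not members:
                scores[i, j] = np.nan
                continue
            *_, p_pos = mhg_test(build_label_vector(ranking.genes, members))
            *_, p_neg = mhg_test(build_label_vector(rev, members))
            scores[i, j] = signed_association_score(p_pos, p_neg)
    return pd.DataFrame(scores, index=pivots.feature_ids, columns=sets.names())


def de_enrichment_concordance(
    de_scores: pd.Series,
    assoc: AssociationMatrix,
    set_name: str,
) -> ConcordanceResult:
    """Pearson correlation between per-miRNA signed differential-
    expression scores and signed enrichment scores for one gene set,
    over the miRNAs shared by both inputs."""
    if set_name not in assoc.columns:
        raise KeyError(f"gene set {set_name!r} not in association matrix")
    shared = [m for m in de_scores.index if m in assoc.index]
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared miRNAs")
    x = de_scores.loc[shared].to_numpy(dtype=float)
    y = assoc.loc[shared, set_name].to_numpy(dtype=float)
    r = float(np.corrcoef(x, y)[0, 1])
    return ConcordanceResult(set_name=set_name, r=r, n_mirnas=len(shared))


def signed_de_scores(results: pd.DataFrame) -> pd.Series:
    """Per-feature signed DE score (-log10 p if up, +log10 p if down),
    indexed by feature id."""
    sign = np.where(results["direction"].to_numpy() == "up", -1.0, 1.0)
    return pd.Series(
        sign * np.log10(results["tnom_p"].to_numpy()),
        index=results["feature_id"].to_numpy(),
    )
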