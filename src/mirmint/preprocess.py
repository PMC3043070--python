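"""Raw-matrix preprocessing: replicate averaging, detection OR-rule,
75th-percentile scaling, log2 transform, detection filtering and
top-variance feature selection.

The pipeline order is: average replicates (linear scale) ->
percentile-normalize (linear) -> log2-transform. Multiplicative
per-sample scaling is only meaningful on the linear scale, which fixes
the order even though textual protocol descriptions often list the log
transform first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .io import ExpressionMatrix

__all__ = [
    "NormalizationReport",
    "average_replicates",
    "percentile_normalize",
    "log2_transform",
    "detection_filter",
    "top_variance_select",
    "collapse_probes",
]


@dataclass
class NormalizationReport:
    """Per-sample scale factors c_i and the global constant c such that
    after scaling each sample's target percentile equals c."""

    sample_ids: list[str]
    scale_factors: np.ndarray
    constant: float
    percentile: float = 75.0


def average_replicates(
    m: ExpressionMatrix, groups: Mapping[str, str]
) -> ExpressionMatrix:
    """Average replicate hybridizations of the same sample.

    ``groups`` maps each sample id to its replicate-group name. Output
    has one column per group (ordered by first appearance among the
    matrix's samples); values are arithmetic means of member columns on
    the linear scale and a feature is called present in a group if it
    was detected on at least one member array (OR-rule).
    """
    if m.scale != "linear":
        raise ValueError("replicate averaging requires a linear-scale matrix")
    missing = [s for s in m.sample_ids if s not in groups]
    if missing:
        raise ValueError(f"samples without a replicate group: {missing}")
    order: list[str] = []
    members: dict[str, list[int]] = {}
    for j, s in enumerate(m.sample_ids):
        g = groups[s]
        if g not in members:
            members[g] = []
            order.append(g)
        members[g].append(j)
    for g in set(groups.values()) - set(order):
        raise ValueError(f"replicate group {g!r} has no member samples")
    values = np.column_stack([m.values[:, members[g]].mean(axis=1) for g in order])
    detection = None
    if m.detection is not None:
        detection = np.column_stack(
            [m.detection[:, members[g]].any(axis=1) for g in order]
        )
    return ExpressionMatrix(m.feature_ids, order, values, "linear", detection)


def percentile_normalize(
    m: ExpressionMatrix,
    c: Optional[float] = None,
    percentile: float = 75.0,
) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Scale each sample so its 75th percentile equals a constant c.

    Each sample i is multiplied by c_i = c / p75(sample i). When ``c``
    is omitted it defaults to the dataset-wide location of the sample
    percentiles - their median - so a cohort of identically distributed
    samples gets unit scale factors. Percentiles use linear
    interpolation between order statistics.
    """
    if m.scale != "linear":
        raise ValueError("percentile normalization requires a linear-scale matrix")
    if np.any(m.values < 0):
        raise ValueError("negative intensities; normalize before any log transform")
    p = np.percentile(m.values, percentile, axis=0)
    zero = np.nonzero(p <= 0)[0]
    if zero.size:
        raise ValueError(
            f"sample {m.sample_ids[zero[0]]!r} has non-positive "
            f"{percentile:g}th percentile"
        )
    if c is None:
        c = float(np.median(p))
    elif c <= 0:
        raise ValueError("normalization constant must be positive")
    factors = c / p
    out = ExpressionMatrix(
        m.feature_ids, m.sample_ids, m.values * factors, "linear", m.detection
    )
    report = NormalizationReport(list(m.sample_ids), factors, float(c), percentile)
    return out, report


def log2_transform(m: ExpressionMatrix, floor: float = 1.0) -> ExpressionMatrix:
    """log2 with a positive intensity floor (values below ``floor`` are
    clipped up before the log; the default floor of 1.0 intensity unit
    treats sub-unit intensities as noise-floor)."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    if m.scale != "linear":
        raise ValueError("matrix is already on the log2 scale")
    return ExpressionMatrix(
        m.feature_ids,
        m.sample_ids,
        np.log2(np.maximum(m.values, floor)),
        "log2",
        m.detection,
    )


def detection_filter(m: ExpressionMatrix, min_fraction: float = 0.10) -> ExpressionMatrix:
    """Drop features detected in less than ``min_fraction`` of samples
    (a feature detected in exactly that fraction is retained)."""
    if m.detection is None:
        raise ValueError("matrix carries no detection flags")
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    frac = m.detection.mean(axis=1)
    keep = np.nonzero(frac >= min_fraction)[0]
    return m.select_features(keep)


def top_variance_select(m: ExpressionMatrix, k: int) -> ExpressionMatrix:
    """Keep the k features of largest across-sample variance (unbiased,
    n-1 denominator), preserving input row order; ties at the cutoff are
    broken by lexicographic feature id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= m.n_features:
        return m
    var = m.values.var(axis=1, ddof=1)
    ranked = sorted(range(m.n_features), key=lambda i: (-var[i], m.feature_ids[i]))
    keep = sorted(ranked[:k])
    return m.select_features(keep)


def preprocess_mirna(
    m: ExpressionMatrix,
    groups: Optional[Mapping[str, str]] = None,
    min_detect_fraction: float = 0.10,
    c: Optional[float] = None,
    floor: float = 1.0,
) -> ExpressionMatrix:
    """The standard miRNA chain: average replicates (when ``groups``
    given), drop features detected in under ``min_detect_fraction`` of
    samples (when flags are present), scale samples to a common 75th
    percentile, then log2-transform."""
    if groups is not None:
        m = average_replicates(m, groups)
    if m.detection is not None:
        m = detection_filter(m, min_detect_fraction)
    m, _ = percentile_normalize(m, c)
    return log2_transform(m, floor)


def collapse_probes(
    m: ExpressionMatrix, feature_to_gene: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene id, keeping the
    probe with the largest across-sample variance. Features absent from
    the mapping keep their own id."""
    gene_of = [feature_to_gene.get(f, f) for f in m.feature_ids]
    var = m.values.var(axis=1, ddof=1) if m.n_samples > 1 else np.zeros(m.n_features)
    best: dict[str, int] = {}
    for i, g in enumerate(gene_of):
        if g not in best or var[i] > var[best[g]]:
            best[g] = i
    keep = sorted(best.values())
    out = m.select_features(keep)
    out.feature_ids = [gene_of[i] for i in keep]
    return out
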