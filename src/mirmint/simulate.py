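"""Synthetic paired miRNA/mRNA cohorts with planted structure.

The generator emulates the statistical shape of a breast-tumor
microarray cohort: ~100 samples with intrinsic-subtype labels,
replicate hybridizations, detection dropout that increases as intensity
falls, several hundred miRNAs and several thousand mRNAs. On top of a
Gaussian log2 baseline it can plant (i) subtype- or
proliferation-differential miRNAs, (ii) co-expression modules driven by
a per-sample latent factor to which designated pivot miRNAs are coupled
with signed loadings, and (iii) miRNA->target anti-correlation at a
configured strength. A ground-truth manifest records every planted
effect so recovery can be scored.

Intensities are linear scale: 2^(baseline + effects + noise); replicate
arrays share the sample-level signal and differ by independent
replicate noise. A single seed drives all draws through deterministic
sub-streams, so identical configs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import (
    ExpressionMatrix,
    GeneSetCollection,
    SampleAnnotation,
    TargetScoreTable,
    ki67_category,
    mitotic_category,
)

__all__ = [
    "PlantedDE",
    "ModuleSpec",
    "TargetSpec",
    "CohortConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_gene_sets",
    "generate_target_table",
    "truth_report",
    "read_truth_report",
]

SUBTYPE_DEFAULTS = {
    "basal-like": 0.15,
    "luminal-A": 0.40,
    "luminal-B": 0.15,
    "ERBB2-enriched": 0.11,
    "normal-like": 0.07,
    "unclassified": 0.12,
}

# P(ER negative | subtype), P(TP53 mutant | subtype)
_ER_NEG = {"basal-like": 0.9, "luminal-A": 0.1, "luminal-B": 0.2,
           "ERBB2-enriched": 0.5, "normal-like": 0.3, "unclassified": 0.4}
_TP53_MUT = {"basal-like": 0.8, "luminal-A": 0.15, "luminal-B": 0.4,
             "ERBB2-enriched": 0.7, "normal-like": 0.2, "unclassified": 0.4}


@dataclass
class PlantedDE:
    """Differential miRNAs: ``n_features`` features shifted by
    ``effect_sd`` noise-SD units in samples of ``contrast`` level A
    ('up') or level B ('down')."""

    n_features: int
    effect_sd: float
    direction: str  # 'up' = higher in level_a
    contrast: tuple[str, str, str]  # (annotation column, level_a, level_b)


@dataclass
class ModuleSpec:
    """A co-expression module: ``n_genes`` mRNAs loading on one latent
    factor; ``pivot_couplings`` maps miRNA index -> signed coupling of
    that pivot onto the same factor. ``group_shift`` optionally shifts
    the factor mean by +/- delta in two annotation levels, tying the
    module (and its pivots) to a sample contrast."""

    name: str
    n_genes: int
    loading: float
    pivot_couplings: dict[int, float] = field(default_factory=dict)
    group_shift: Optional[tuple[str, str, str, float]] = None  # (col, hi, lo, delta)


@dataclass
class TargetSpec:
    """Planted direct regulation: ``n_targets`` mRNAs anti-correlated
    with pivot miRNA ``pivot`` at Spearman-scale strength ``rho``
    (negative)."""

    pivot: int
    n_targets: int
    rho: float = -0.5


@dataclass
class CohortConfig:
    n_samples: int = 100
    n_mirna: int = 300
    n_mrna: int = 3000
    subtype_proportions: dict[str, float] = field(
        default_factory=lambda: dict(SUBTYPE_DEFAULTS)
    )
    replicates: int = 2
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    noise_sd: float = 1.0
    replicate_noise_sd: float = 0.5
    dropout_midpoint: float = 4.0
    dropout_slope: float = 1.0
    prolif_proportions: tuple[float, float, float] = (0.25, 0.35, 0.40)  # HP, LP, mid
    planted_de: list[PlantedDE] = field(default_factory=list)
    modules: list[ModuleSpec] = field(default_factory=list)
    target_spec: Optional[TargetSpec] = None
    seed: int = 0

    def validate(self) -> None:
        problems = []
        for name, v in (("n_samples", self.n_samples), ("n_mirna", self.n_mirna),
                        ("n_mrna", self.n_mrna), ("replicates", self.replicates)):
            if v < 1:
                problems.append(f"{name} must be >= 1 (got {v})")
        if abs(sum(self.subtype_proportions.values()) - 1) > 1e-9:
            problems.append("subtype proportions must sum to 1")
        if abs(sum(self.prolif_proportions) - 1) > 1e-9:
            problems.append("proliferation proportions must sum to 1")
        if self.noise_sd <= 0:
            problems.append("noise_sd must be positive")
        for spec in self.planted_de:
            if spec.n_features < 1 or spec.effect_sd < 0:
                problems.append(f"invalid planted DE spec {spec}")
            if spec.direction not in ("up", "down"):
                problems.append(f"unknown DE direction {spec.direction!r}")
        for mod in self.modules:
            if mod.n_genes < 1:
                problems.append(f"module {mod.name!r} needs genes")
            for idx in mod.pivot_couplings:
                if not 0 <= idx < self.n_mirna:
                    problems.append(f"module {mod.name!r} pivot index {idx} out of range")
        if self.target_spec is not None:
            t = self.target_spec
            if not 0 <= t.pivot < self.n_mirna:
                problems.append("target pivot index out of range")
            if not -1 < t.rho < 0:
                problems.append("target rho must be in (-1, 0)")
            if t.n_targets < 1 or t.n_targets > self.n_mrna:
                problems.append("invalid target count")
        if problems:
            raise ValueError("invalid cohort config: " + "; ".join(problems))


@dataclass
class SyntheticTruth:
    mirna_ids: list[str]
    mrna_ids: list[str]
    de_features: list[tuple[str, str, str, str, str, float]]
    # (feature_id, column, level_a, level_b, direction, effect_sd)
    modules: dict[str, list[str]]
    pivot_couplings: list[tuple[str, str, float]]  # (module, mirna_id, coupling)
    target_pairs: list[tuple[str, str, float]]  # (pivot_id, gene_id, rho)

    def validate(self) -> None:
        mirna, mrna = set(self.mirna_ids), set(self.mrna_ids)
        for f, *_ in self.de_features:
            assert f in mirna, f
        for genes in self.modules.values():
            assert set(genes) <= mrna
        for mod, m, _ in self.pivot_couplings:
            assert mod in self.modules and m in mirna
        for p, g, _ in self.target_pairs:
            assert p in mirna and g in mrna


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng((seed, stream))


def _group_indicator(ann: pd.DataFrame, column: str, level: str) -> np.ndarray:
    if column not in ann.columns:
        raise ValueError(f"unknown annotation column {column!r}")
    return (ann[column] == level).to_numpy()


def _sample_annotations(config: CohortConfig) -> pd.DataFrame:
    rng = _rng(config.seed, 1)
    n = config.n_samples
    subtypes = rng.choice(
        list(config.subtype_proportions),
        size=n,
        p=list(config.subtype_proportions.values()),
    )
    er = np.where(
        rng.random(n) < [_ER_NEG.get(s, 0.4) for s in subtypes], "negative", "positive"
    )
    tp53 = np.where(
        rng.random(n) < [_TP53_MUT.get(s, 0.4) for s in subtypes], "mutant", "WT"
    )
    ecm = rng.choice(["ECM1", "ECM2", "ECM3", "ECM4"], size=n)
    prolif = rng.choice(["HP", "LP", "mid"], size=n, p=list(config.prolif_proportions))
    ki67_pct = np.empty(n)
    mitoses = np.empty(n, dtype=int)
    for i, p in enumerate(prolif):
        if p == "HP":
            ki67_pct[i] = rng.uniform(11, 45)
            mitoses[i] = rng.integers(12, 30)
        elif p == "LP":
            ki67_pct[i] = rng.uniform(0, 1)
            mitoses[i] = rng.integers(0, 6)
        else:
            ki67_pct[i] = rng.uniform(1.5, 10)
            mitoses[i] = rng.integers(6, 12)
    df = pd.DataFrame(
        {
            "sample_id": [f"S{i+1:03d}" for i in range(n)],
            "subtype": subtypes,
            "er_status": er,
            "tp53_status": tp53,
            "ecm_class": ecm,
            "ki67_percent": np.round(ki67_pct, 2),
            "mitoses": mitoses,
        }
    )
    df["ki67_category"] = [ki67_category(x) for x in df["ki67_percent"]]
    df["mitotic_category"] = [mitotic_category(x) for x in df["mitoses"]]
    # derived HP/LP call (matches phenotype.proliferation_class by design)
    from .phenotype import proliferation_class

    df["proliferation"] = [
        proliferation_class(k, m)
        for k, m in zip(df["ki67_category"], df["mitotic_category"])
    ]
    return df.set_index("sample_id", drop=False)


def generate_cohort(
    config: CohortConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, list[SampleAnnotation], SyntheticTruth]:
    """Generate the paired cohort: (miRNA matrix with replicate arrays
    and detection flags, mRNA matrix, sample annotations, truth).

    The miRNA matrix has ``replicates`` columns per sample named
    ``<sample>_r<j>``; the annotation ``replicate_group`` maps arrays
    back to samples. Both matrices are linear scale.
    """
    config.validate()
    ann = _sample_annotations(config)
    n, n_mi, n_mr = config.n_samples, config.n_mirna, config.n_mrna
    mirna_ids = [f"miR-{i+1:04d}" for i in range(n_mi)]
    mrna_ids = [f"GENE{i+1:05d}" for i in range(n_mr)]

    rng_f = _rng(config.seed, 2)  # factors + loadings + assignments
    rng_mi = _rng(config.seed, 3)  # miRNA noise
    rng_mr = _rng(config.seed, 4)  # mRNA noise
    rng_det = _rng(config.seed, 5)  # detection dropout

    # latent factors per module
    factors = {}
    for mod in config.modules:
        f = rng_f.normal(size=n)
        if mod.group_shift is not None:
            col, hi, lo, delta = mod.group_shift
            f = f + delta * _group_indicator(ann, col, hi)
            f = f - delta * _group_indicator(ann, col, lo)
        factors[mod.name] = f

    # miRNA sample-level log2 signal
    base_mi = rng_f.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_mi)
    sig_mi = base_mi[:, None] + rng_mi.normal(0, config.noise_sd, (n_mi, n))

    pivot_indices: set[int] = set()
    pivot_couplings = []
    for mod in config.modules:
        for idx, coupling in mod.pivot_couplings.items():
            sig_mi[idx] += coupling * factors[mod.name]
            pivot_indices.add(idx)
            pivot_couplings.append((mod.name, mirna_ids[idx], float(coupling)))
    if config.target_spec is not None:
        pivot_indices.add(config.target_spec.pivot)

    de_features = []
    free = [i for i in range(n_mi) if i not in pivot_indices]
    for spec in config.planted_de:
        if spec.n_features > len(free):
            raise ValueError("not enough non-pivot miRNAs for planted DE")
        chosen = list(rng_f.choice(free, size=spec.n_features, replace=False))
        free = [i for i in free if i not in set(chosen)]
        col, la, lb = spec.contrast
        shift = spec.effect_sd * config.noise_sd
        target_level = la if spec.direction == "up" else lb
        mask = _group_indicator(ann, col, target_level)
        for i in chosen:
            sig_mi[i, mask] += shift
            de_features.append(
                (mirna_ids[i], col, la, lb, spec.direction, float(spec.effect_sd))
            )

    # mRNA log2 signal
    base_mr = rng_f.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_mr)
    sig_mr = base_mr[:, None] + rng_mr.normal(0, config.noise_sd, (n_mr, n))

    modules: dict[str, list[str]] = {}
    used_genes: set[int] = set()
    gene_pool = list(range(n_mr))
    for mod in config.modules:
        avail = [g for g in gene_pool if g not in used_genes]
        chosen = list(rng_f.choice(avail, size=mod.n_genes, replace=False))
        used_genes.update(chosen)
        loadings = mod.loading * rng_f.uniform(0.8, 1.2, size=mod.n_genes)
        for g, w in zip(chosen, loadings):
            sig_mr[g] += w * factors[mod.name]
        modules[mod.name] = [mrna_ids[g] for g in chosen]

    target_pairs = []
    if config.target_spec is not None:
        t = config.target_spec
        pivot_z = sig_mi[t.pivot] - sig_mi[t.pivot].mean()
        pivot_z = pivot_z / pivot_z.std()
        gamma = config.noise_sd * abs(t.rho) / np.sqrt(1 - t.rho**2)
        avail = [g for g in gene_pool if g not in used_genes]
        chosen = list(rng_f.choice(avail, size=t.n_targets, replace=False))
        used_genes.update(chosen)
        for g in chosen:
            sig_mr[g] -= gamma * pivot_z
            target_pairs.append((mirna_ids[t.pivot], mrna_ids[g], float(t.rho)))

    # replicate arrays + detection dropout for the miRNA matrix
    r = config.replicates
    array_ids = []
    cols = []
    det_cols = []
    for j in range(r):
        arr = sig_mi + rng_mi.normal(0, config.replicate_noise_sd, (n_mi, n))
        cols.append(arr)
        # P(absent) rises as log2 intensity falls below the midpoint
        p_absent = 1.0 / (
            1.0 + np.exp((arr - config.dropout_midpoint) / config.dropout_slope)
        )
        det_cols.append(rng_det.random((n_mi, n)) >= p_absent)
    values = np.empty((n_mi, n * r))
    detection = np.empty((n_mi, n * r), dtype=bool)
    for i_s, sid in enumerate(ann["sample_id"]):
        for j in range(r):
            array_ids.append(f"{sid}_r{j+1}" if r > 1 else sid)
            values[:, i_s * r + j] = cols[j][:, i_s]
            detection[:, i_s * r + j] = det_cols[j][:, i_s]
    mirna = ExpressionMatrix(
        mirna_ids, array_ids, np.power(2.0, values), "linear", detection
    )
    mrna = ExpressionMatrix(
        mrna_ids, list(ann["sample_id"]), np.power(2.0, sig_mr), "linear"
    )

    annotations = [
        SampleAnnotation(
            sample_id=row["sample_id"],
            subtype=row["subtype"],
            er_status=row["er_status"],
            tp53_status=row["tp53_status"],
            ecm_class=row["ecm_class"],
            ki67_category=row["ki67_category"],
            mitotic_category=row["mitotic_category"],
        )
        for _, row in ann.iterrows()
    ]
    truth = SyntheticTruth(
        mirna_ids=mirna_ids,
        mrna_ids=mrna_ids,
        de_features=de_features,
        modules=modules,
        pivot_couplings=pivot_couplings,
        target_pairs=target_pairs,
    )
    truth.validate()
    return mirna, mrna, annotations, truth


def replicate_groups(mirna: ExpressionMatrix) -> dict[str, str]:
    """Array id -> sample id mapping implied by the ``_r<j>`` naming."""
    return {a: a.rsplit("_r", 1)[0] if "_r" in a else a for a in mirna.sample_ids}


def generate_gene_sets(
    truth: SyntheticTruth,
    n_decoys: int,
    decoy_size_range: tuple[int, int] = (20, 200),
    seed: int = 0,
) -> GeneSetCollection:
    """One set per planted module plus random decoy sets drawn from the
    genes outside every module."""
    rng = _rng(seed, 6)
    module_genes = {g for genes in truth.modules.values() for g in genes}
    background = [g for g in truth.mrna_ids if g not in module_genes]
    lo, hi = decoy_size_range
    if hi > len(background):
        raise ValueError("decoy size exceeds available background universe")
    sets = {name: ("planted module", list(genes)) for name, genes in truth.modules.items()}
    for d in range(n_decoys):
        size = int(rng.integers(lo, hi + 1))
        genes = list(rng.choice(background, size=size, replace=False))
        sets[f"decoy{d+1:03d}"] = ("random decoy set", genes)
    return GeneSetCollection(sets)


def generate_target_table(
    truth: SyntheticTruth,
    n_background_pairs: int = 5000,
    planted_score: tuple[float, float] = (-0.55, 0.05),
    background_score: tuple[float, float] = (-0.15, 0.08),
    seed: int = 0,
) -> TargetScoreTable:
    """Context-score table: planted (pivot, target) pairs offset toward
    strongly negative scores; background pairs drawn at random."""
    if not truth.target_pairs:
        raise ValueError("truth contains no planted target pairs")
    rng = _rng(seed, 7)
    rows = []
    for pivot, gene, _ in truth.target_pairs:
        rows.append((pivot, gene, min(rng.normal(*planted_score), -1e-3)))
    planted = {(p, g) for p, g, _ in truth.target_pairs}
    seen = set(planted)
    while len(rows) < len(planted) + n_background_pairs:
        m = truth.mirna_ids[rng.integers(len(truth.mirna_ids))]
        g = truth.mrna_ids[rng.integers(len(truth.mrna_ids))]
        if (m, g) in seen:
            continue
        seen.add((m, g))
        rows.append((m, g, min(rng.normal(*background_score), -1e-3)))
    return TargetScoreTable(pd.DataFrame(rows, columns=["mirna", "gene", "score"]))


def truth_report(truth: SyntheticTruth, path) -> None:
    """Write the planted-structure manifest as a long-format TSV
    (kind, name, item, detail, value)."""
    rows = []
    for fid, col, la, lb, direction, eff in truth.de_features:
        rows.append(("de", f"{col}:{la}-vs-{lb}", fid, direction, eff))
    for name, genes in truth.modules.items():
        for g in genes:
            rows.append(("module", name, g, "", np.nan))
    for mod, m, c in truth.pivot_couplings:
        rows.append(("pivot", mod, m, "", c))
    for p, g, rho in truth.target_pairs:
        rows.append(("target", p, g, "", rho))
    pd.DataFrame(
        rows, columns=["kind", "name", "item", "detail", "value"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_truth_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
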