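"""Tabular I/O and the validated in-memory containers of the pipeline.

File dialect throughout: UTF-8, tab-separated, '.' decimal point, no
quoting. Expression matrices are features-in-rows with a sample header;
gene sets use the GMT convention (name TAB description TAB genes...);
target-prediction scores are three-column TSV (mirna, gene, score).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "SampleAnnotation",
    "GeneSetCollection",
    "TargetScoreTable",
    "read_expression_tsv",
    "read_gmt",
    "read_target_scores",
    "read_sample_annotations",
    "write_table",
    "ki67_category",
    "mitotic_category",
]

SUBTYPES = (
    "basal-like",
    "luminal-A",
    "luminal-B",
    "ERBB2-enriched",
    "normal-like",
    "unclassified",
)
ER_STATUS = ("positive", "negative", "unknown")
TP53_STATUS = ("WT", "mutant", "unknown")
ECM_CLASSES = ("ECM1", "ECM2", "ECM3", "ECM4", "unknown")
KI67_CATEGORIES = ("negative", "moderate", "high", "missing")
MITOTIC_CATEGORIES = ("low", "moderate", "high", "missing")


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what}: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """A feature x sample matrix of finite real intensities.

    Parameters
    ----------
    feature_ids, sample_ids
        Unique row / column identifiers.
    values
        Array of shape (F, S); every entry finite. The pipeline never
        carries missing values past I/O.
    scale
        ``"linear"`` or ``"log2"``; transformations check and update it.
    detection
        Optional boolean present/absent calls, same shape as ``values``.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    scale: str = "linear"
    detection: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.feature_ids = list(self.feature_ids)
        self.sample_ids = list(self.sample_ids)
        _check_unique(self.feature_ids, "feature id")
        _check_unique(self.sample_ids, "sample id")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if self.scale not in ("linear", "log2"):
            raise FormatError(f"unknown scale {self.scale!r}")
        if self.detection is not None:
            self.detection = np.asarray(self.detection, dtype=bool)
            if self.detection.shape != self.values.shape:
                raise FormatError("detection shape does not match values")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    def feature_vector(self, feature_id: str) -> np.ndarray:
        return self.values[self.feature_ids.index(feature_id)]

    def select_features(self, keep: Sequence[int]) -> "ExpressionMatrix":
        keep = list(keep)
        return ExpressionMatrix(
            [self.feature_ids[i] for i in keep],
            self.sample_ids,
            self.values[keep],
            self.scale,
            None if self.detection is None else self.detection[keep],
        )

    def select_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            self.feature_ids,
            [self.sample_ids[i] for i in idx],
            self.values[:, idx],
            self.scale,
            None if self.detection is None else self.detection[:, idx],
        )


def ki67_category(percent: float) -> str:
    """Map a Ki67 percent-stained value to negative/moderate/high.

    Negative iff <=1% stained cells, moderate iff in (1, 10],
    high iff >10%. NaN maps to ``missing``.
    """
    if percent is None or (isinstance(percent, float) and math.isnan(percent)):
        return "missing"
    if percent <= 1:
        return "negative"
    if percent <= 10:
        return "moderate"
    return "high"


def mitotic_category(count: float) -> str:
    """Map a mitosis count (per 10 high-power fields) to low/moderate/high.

    Low iff 0-5 mitoses, moderate iff 6-11, high iff >11.
    """
    if count is None or (isinstance(count, float) and math.isnan(count)):
        return "missing"
    if count <= 5:
        return "low"
    if count <= 11:
        return "moderate"
    return "high"


@dataclass
class SampleAnnotation:
    sample_id: str
    subtype: str = "unclassified"
    er_status: str = "unknown"
    tp53_status: str = "unknown"
    ecm_class: str = "unknown"
    ki67_category: str = "missing"
    mitotic_category: str = "missing"
    replicate_group: str = ""

    def __post_init__(self) -> None:
        if not self.replicate_group:
            self.replicate_group = self.sample_id
        for value, allowed in (
            (self.subtype, SUBTYPES),
            (self.er_status, ER_STATUS),
            (self.tp53_status, TP53_STATUS),
            (self.ecm_class, ECM_CLASSES),
            (self.ki67_category, KI67_CATEGORIES),
            (self.mitotic_category, MITOTIC_CATEGORIES),
        ):
            if value not in allowed:
                raise FormatError(f"invalid category {value!r}")


@dataclass
class GeneSetCollection:
    """Named gene sets: set name -> (description, member gene ids)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, genes) in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
            _check_unique(genes, f"gene in set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]


@dataclass
class TargetScoreTable:
    """Predicted (miRNA, gene) targeting scores; more negative = stronger."""

    records: pd.DataFrame  # columns: mirna, gene, score

    def __post_init__(self) -> None:
        need = {"mirna", "gene", "score"}
        missing = need - set(self.records.columns)
        if missing:
            raise FormatError(f"missing column(s): {sorted(missing)}")
        if self.records.duplicated(["mirna", "gene"]).any():
            raise FormatError("duplicate (mirna, gene) pair")

    def __len__(self) -> int:
        return len(self.records)

    def targets_of(self, mirna_id: str) -> pd.DataFrame:
        """Records for one miRNA, ascending by score (strongest first),
        ties broken by gene id."""
        sub = self.records[self.records["mirna"] == mirna_id]
        if sub.empty:
            raise KeyError(f"miRNA {mirna_id!r} not present in target table")
        return sub.sort_values(["score", "gene"], kind="mergesort").reset_index(
            drop=True
        )


def read_expression_tsv(path, scale: str = "linear") -> ExpressionMatrix:
    """Read a feature x sample TSV (first row samples, first column ids).

    Row and column order are preserved. Duplicate feature ids and
    non-numeric cells raise :class:`FormatError` naming the offender.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    ids = [str(i) for i in df.index]
    _check_unique(ids, "feature id")
    values = np.empty(df.shape, dtype=float)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            try:
                v = float(raw[i, j])
            except (TypeError, ValueError):
                v = math.nan
            if math.isnan(v):
                raise FormatError(
                    f"non-numeric cell {raw[i, j]!r} at feature {ids[i]!r}, "
                    f"sample {df.columns[j]!r}"
                )
            values[i, j] = v
    return ExpressionMatrix(ids, [str(c) for c in df.columns], values, scale)


def read_detection_tsv(path) -> np.ndarray:
    """Read a detection-call matrix of 0/1 (or true/false) flags."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy().astype(bool)


def read_gmt(path) -> GeneSetCollection:
    """Read gene sets in GMT format (name TAB description TAB genes...).

    Duplicate genes within a line are dropped keeping first occurrence.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: expected >=3 tab-separated fields")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"line {lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise FormatError(f"line {lineno}: set {name!r} has no genes")
            sets[name] = (desc, genes)
    return GeneSetCollection(sets)


def write_gmt(sets: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, (desc, genes) in sets.sets.items():
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_target_scores(path) -> TargetScoreTable:
    """Read a (mirna, gene, score) TSV of predicted targeting scores.

    Duplicate (mirna, gene) rows collapse to the most negative
    (strongest predicted) score.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("mirna", "gene", "score"):
        if col not in df.columns:
            raise FormatError(f"missing column {col!r}")
    df = (
        df.groupby(["mirna", "gene"], as_index=False, sort=False)["score"]
        .min()
        .astype({"score": float})
    )
    return TargetScoreTable(df[["mirna", "gene", "score"]])


def _max_category(values: Iterable[str], order: Sequence[str]) -> str:
    """Highest category among values, ignoring 'missing'; TMA cores with
    discrepant scores resolve to the highest."""
    best = -1
    for v in values:
        if v == "missing":
            continue
        best = max(best, order.index(v))
    return order[best] if best >= 0 else "missing"


def read_sample_annotations(path) -> list[SampleAnnotation]:
    """Read a sample annotation TSV.

    Required column ``sample_id``; any subset of: subtype, er_status,
    tp53_status, ecm_class, ki67_percent (or ki67_category),
    mitoses (or mitotic_category), replicate_group. Raw Ki67 percents
    and mitosis counts are binned per the scoring rules; when a cell
    holds several semicolon-separated core measurements the highest
    resulting category is used. Unrecognized subtype strings map to
    ``unclassified``; empty/NA categorical cells map to the unknown value.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample_id" not in df.columns:
        raise FormatError("missing column 'sample_id'")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise FormatError(f"duplicate sample_id: {dup!r}")

    def cell(row, col):
        if col not in df.columns:
            return None
        v = row[col]
        if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
            return None
        return v

    out = []
    for _, row in df.iterrows():
        subtype = cell(row, "subtype") or "unclassified"
        if subtype not in SUBTYPES:
            subtype = "unclassified"
        er = cell(row, "er_status") or "unknown"
        if er not in ER_STATUS:
            er = "unknown"
        tp53 = cell(row, "tp53_status") or "unknown"
        if tp53 not in TP53_STATUS:
            tp53 = "unknown"
        ecm = cell(row, "ecm_class") or "unknown"
        if ecm not in ECM_CLASSES:
            ecm = "unknown"

        ki = cell(row, "ki67_category")
        raw = cell(row, "ki67_percent")
        if raw is not None:
            cats = [ki67_category(float(x)) for x in str(raw).split(";")]
            ki = _max_category(cats, KI67_CATEGORIES[:3])
        if ki not in KI67_CATEGORIES or ki is None:
            ki = "missing"

        mi = cell(row, "mitotic_category")
        raw = cell(row, "mitoses")
        if raw is not None:
            cats = [mitotic_category(float(x)) for x in str(raw).split(";")]
            mi = _max_category(cats, MITOTIC_CATEGORIES[:3])
        if mi not in MITOTIC_CATEGORIES or mi is None:
            mi = "missing"

        out.append(
            SampleAnnotation(
                sample_id=row["sample_id"],
                subtype=subtype,
                er_status=er,
                tp53_status=tp53,
                ecm_class=ecm,
                ki67_category=ki,
                mitotic_category=mi,
                replicate_group=cell(row, "replicate_group") or row["sample_id"],
            )
        )
    return out


def annotations_to_frame(annotations: Sequence[SampleAnnotation]) -> pd.DataFrame:
    return pd.DataFrame([vars(a) for a in annotations]).set_index("sample_id")


def write_table(rows, path, float_format: str = "%.6g") -> None:
    """Write a result table as TSV with header, floats at 6 significant
    digits; row order is preserved from the caller (result builders sort
    deterministically before writing)."""
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        rows = list(rows)
        df = pd.DataFrame([vars(r) if hasattr(r, "__dict__") else r for r in rows])
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def write_expression_tsv(m: ExpressionMatrix, path, float_format: str = "%.10g") -> None:
    m.to_frame().to_csv(path, sep="\t", index_label="feature_id",
                        float_format=float_format)


def write_detection_tsv(m: ExpressionMatrix, path) -> None:
    if m.detection is None:
        raise ValueError("matrix carries no detection flags")
    pd.DataFrame(
        m.detection.astype(int), index=m.feature_ids, columns=m.sample_ids
    ).to_csv(path, sep="\t", index_label="feature_id")
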