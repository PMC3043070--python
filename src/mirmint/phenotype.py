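"""Derived sample phenotypes and transfection-screen calls.

HP/LP proliferation classes combine the Ki67 immunohistochemistry
category with the mitotic-index category; lysate-microarray (LMA)
screen readouts are normalized to negative-control z-scores and called
as proliferation hits; hits are compared against the tumor
differential-expression direction for concordance labeling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import SampleAnnotation

__all__ = [
    "ProliferationCall",
    "LmaRecord",
    "proliferation_class",
    "proliferation_calls",
    "lma_zscores",
    "lma_hit_call",
    "concordance_with_tumor_de",
]

# highly proliferative: high on both markers, or high paired with moderate
_HP_PAIRS = {("high", "high"), ("high", "moderate"), ("moderate", "high")}
# weakly proliferative: low/negative on both, or low/negative with moderate
_LP_PAIRS = {("negative", "low"), ("negative", "moderate"), ("moderate", "low")}


@dataclass
class ProliferationCall:
    sample_id: str
    cls: str  # 'HP' | 'LP' | 'unassigned'


@dataclass
class LmaRecord:
    mirna_id: str
    cell_line: str
    z48: float
    z72: float
    hit: bool
    effect_direction: str  # 'increase' | 'decrease' | 'none'


def proliferation_class(ki67: str, mi: str) -> str:
    """HP/LP/unassigned from (Ki67 category, mitotic-index category).

    HP for (high, high), (high, moderate), (moderate, high); LP for
    (negative, low), (negative, moderate), (moderate, low). All other
    combinations - including (moderate, moderate) and any missing
    marker - are unassigned.
    """
    pair = (ki67, mi)
    if pair in _HP_PAIRS:
        return "HP"
    if pair in _LP_PAIRS:
        return "LP"
    return "unassigned"


def proliferation_calls(
    annotations: Sequence[SampleAnnotation],
) -> list[ProliferationCall]:
    return [
        ProliferationCall(a.sample_id, proliferation_class(a.ki67_category, a.mitotic_category))
        for a in annotations
    ]


def lma_zscores(signals, negative_controls) -> np.ndarray:
    """Normalize screen readouts to negative-control z-scores:
    z = (signal - mean(controls)) / sd(controls), per time point and
    cell line. Requires >= 2 control replicates with nonzero spread."""
    controls = np.asarray(negative_controls, dtype=float)
    if controls.size < 2:
        raise ValueError("need at least two negative-control replicates")
    sd = controls.std(ddof=1)
    if sd == 0:
        raise ValueError("negative controls have zero spread")
    return (np.asarray(signals, dtype=float) - controls.mean()) / sd


def lma_hit_call(z48: float, z72: float) -> tuple[bool, str]:
    """Proliferation-effect call from 48 h and 72 h z-scores.

    Hit iff at least one |z| > 2, both |z| > 1, and the two time points
    agree in sign; the effect direction is the shared sign. Mixed-sign
    pairs are never called, avoiding contradictory effects.
    """
    same_sign = np.sign(z48) == np.sign(z72) and z48 != 0 and z72 != 0
    hit = (
        same_sign
        and max(abs(z48), abs(z72)) > 2
        and min(abs(z48), abs(z72)) > 1
    )
    if not hit:
        return False, "none"
    return True, "increase" if z48 > 0 else "decrease"


def make_lma_record(mirna_id: str, cell_line: str, z48: float, z72: float) -> LmaRecord:
    hit, direction = lma_hit_call(z48, z72)
    return LmaRecord(mirna_id, cell_line, float(z48), float(z72), hit, direction)


def concordance_with_tumor_de(tumor_direction: str, screen: LmaRecord) -> str:
    """Compare a miRNA's tumor HP-vs-LP direction with its screen effect:
    'matching' when an HP-up miRNA increases Ki67 (or HP-down decreases),
    'opposite' for a hit with the reverse pairing, 'none' for no hit."""
    if tumor_direction not in ("up_in_HP", "down_in_HP"):
        raise ValueError(f"unknown tumor direction {tumor_direction!r}")
    if not screen.hit:
        return "none"
    expected = "increase" if tumor_direction == "up_in_HP" else "decrease"
    return "matching" if screen.effect_direction == expected else "opposite"
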