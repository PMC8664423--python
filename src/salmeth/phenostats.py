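"""Phenotype derivations and the family-controlled group comparison.

Fulton's condition factor K = 100 * W / L^3 (W in grams, L in cm)
summarizes body condition. Group differences in juvenile traits are
tested while controlling for among-family variance by a family-means
one-way ANOVA: per-family trait means are computed first and the two
groups of family means are compared (df 1 and n_families - 2), the
analysis identified by the printed F degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["PhenotypeRecord", "AnovaResult", "condition_factor", "family_anova"]


@dataclass
class PhenotypeRecord:
    sample_id: str
    family: str
    group: str
    length_mm: float
    weight_g: float

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.weight_g <= 0:
            raise ValueError(f"{self.sample_id}: length and weight must be positive")

    @property
    def condition_k(self) -> float:
        return condition_factor(self.weight_g, self.length_mm)


def condition_factor(weight_g, length_mm):
    """Fulton's K = 100 * weight(g) / length(cm)^3 (length given in mm)."""
    weight_g = np.asarray(weight_g, dtype=float)
    length_mm = np.asarray(length_mm, dtype=float)
    if np.any(weight_g <= 0) or np.any(length_mm <= 0):
        raise ValueError("weight and length must be positive")
    k = 100.0 * weight_g / (length_mm / 10.0) ** 3
    return float(k) if k.ndim == 0 else k


@dataclass
class AnovaResult:
    f_stat: float
    df1: int
    df2: int
    p: float


def family_anova(records: Sequence[PhenotypeRecord], trait: str) -> AnovaResult:
    """Family-means ANOVA of a trait between two groups.

    ``trait`` is one of length_mm, weight_g, condition_k. Each family
    must belong to exactly one group and each group must contribute at
    least two families.
    """
    fam_group: dict[str, str] = {}
    fam_vals: dict[str, list[float]] = {}
    for r in records:
        g = fam_group.setdefault(r.family, r.group)
        if g != r.group:
            raise ValueError(f"family {r.family} spans both groups")
        fam_vals.setdefault(r.family, []).append(float(getattr(r, trait)))
    groups = sorted(set(fam_group.values()))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    means = {g: [np.mean(fam_vals[f]) for f in fam_vals if fam_group[f] == g]
             for g in groups}
    if any(len(v) < 2 for v in means.values()):
        raise ValueError("need at least two families per group")
    f, p = stats.f_oneway(means[groups[0]], means[groups[1]])
    n_fam = sum(len(v) for v in means.values())
    if not np.isfinite(f):  # all family means identical
        f, p = 0.0, 1.0
    return AnovaResult(float(f), 1, n_fam - 2, float(p))
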