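"""Lifestyle-associated gene (LAG) classification by prevalence thresholds.

A gene family's prevalence within a lifestyle is the exact fraction of that
lifestyle's genomes carrying it (kept as a rational number, so printed
boundaries like 60/100 vs 59/100 classify without floating-point leakage).
Families at or above the restrictive threshold (default 60%) are
restrictive LAGs for that lifestyle; families in [lax, restrictive)
(default 40%–59%) are lax; families meeting a threshold in two or more
lifestyles are shared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import pandas as pd


@dataclass
class LagThresholds:
    restrictive_min: Fraction = Fraction(60, 100)
    lax_min: Fraction = Fraction(40, 100)

    def __post_init__(self) -> None:
        self.restrictive_min = Fraction(self.restrictive_min).limit_denominator(10**9)
        self.lax_min = Fraction(self.lax_min).limit_denominator(10**9)
        if not (0 < self.lax_min < self.restrictive_min <= 1):
            raise ValueError("need 0 < lax_min < restrictive_min <= 1")


@dataclass
class LagTable:
    """Per family x lifestyle: exact prevalence, class, and shared flag."""

    prevalence: dict[str, dict[str, Fraction]]  # family -> lifestyle -> fraction
    classes: dict[str, dict[str, str]]  # family -> lifestyle -> class
    shared: dict[str, bool]  # family -> shared flag
    thresholds: LagThresholds = field(default_factory=LagThresholds)

    @property
    def families(self) -> list[str]:
        return sorted(self.prevalence)

    @property
    def lifestyles(self) -> list[str]:
        first = next(iter(self.prevalence.values()), {})
        return sorted(first)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fam in self.families:
            for ls in self.lifestyles:
                rows.append(
                    {
                        "family": fam,
                        "lifestyle": ls,
                        "prevalence": float(self.prevalence[fam][ls]),
                        "class": self.classes[fam][ls],
                        "shared": self.shared[fam],
                    }
                )
        return pd.DataFrame(rows)


def prevalence(
    matrix: pd.DataFrame, labels: dict[str, str] | pd.Series
) -> dict[str, dict[str, Fraction]]:
    """Exact per-family per-lifestyle presence fractions.

    ``matrix`` is a binary genomes x families table; ``labels`` maps every
    genome id to its lifestyle.
    """
    if isinstance(labels, pd.Series):
        labels = labels.to_dict()
    missing = [g for g in matrix.index if g not in labels]
    if missing:
        raise ValueError(f"genomes without lifestyle label: {missing}")
    values = matrix.to_numpy()
    if not ((values == 0) | (values == 1)).all():
        raise ValueError("presence-absence matrix must be binary")
    lifestyles = sorted(set(labels[g] for g in matrix.index))
    members = {
        ls: [g for g in matrix.index if labels[g] == ls] for ls in lifestyles
    }
    out: dict[str, dict[str, Fraction]] = {}
    for fam in matrix.columns:
        col = matrix[fam]
        out[str(fam)] = {
            ls: Fraction(int(col.loc[members[ls]].sum()), len(members[ls]))
            for ls in lifestyles
        }
    return out


def classify_lags(
    prev: dict[str, dict[str, Fraction]],
    thresholds: LagThresholds | None = None,
) -> LagTable:
    """Classify each family per lifestyle as restrictive / lax / none.

    restrictive iff prevalence >= restrictive_min; lax iff
    lax_min <= prevalence < restrictive_min; shared iff the family reaches a
    class in two or more lifestyles.  Comparisons are exact rationals.
    """
    thresholds = thresholds or LagThresholds()
    classes: dict[str, dict[str, str]] = {}
    shared: dict[str, bool] = {}
    for fam, by_ls in prev.items():
        classes[fam] = {}
        hits = 0
        for ls, p in by_ls.items():
            if p >= thresholds.restrictive_min:
                cls = "restrictive"
            elif thresholds.lax_min <= p < thresholds.restrictive_min:
                cls = "lax"
            else:
                cls = "none"
            classes[fam][ls] = cls
            hits += cls != "none"
        shared[fam] = hits >= 2
    return LagTable(
        prevalence=prev, classes=classes, shared=shared, thresholds=thresholds
    )


def lag_summary(
    table: LagTable, matrix: pd.DataFrame, focal_genome: str
) -> dict:
    """Counts per lifestyle x class plus the focal genome's coverage.

    Reports both views of shared families: included in each lifestyle's
    count, and the shared count separately.
    """
    if focal_genome not in matrix.index:
        raise KeyError(focal_genome)
    counts: dict[str, dict[str, int]] = {}
    focal_fraction: dict[str, dict[str, float]] = {}
    for ls in table.lifestyles:
        counts[ls] = {"restrictive": 0, "lax": 0}
        present = {"restrictive": 0, "lax": 0}
        for fam in table.families:
            cls = table.classes[fam][ls]
            if cls in counts[ls]:
                counts[ls][cls] += 1
                present[cls] += int(matrix.loc[focal_genome, fam])
        focal_fraction[ls] = {
            cls: (present[cls] / counts[ls][cls]) if counts[ls][cls] else 0.0
            for cls in ("restrictive", "lax")
        }
    return {
        "counts": counts,
        "n_shared": sum(table.shared.values()),
        "focal_genome": focal_genome,
        "focal_fraction": focal_fraction,
        "total_restrictive": sum(c["restrictive"] for c in counts.values()),
        "total_lax": sum(c["lax"] for c in counts.values()),
    }
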