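"""Cohort-level statistics and the three-group comparison report.

Categorical variables are compared by the two-sided Fisher exact test in
the minimum-likelihood convention (the two-sided p-value is the sum of the
probabilities of all same-margin tables no more likely than the observed
one). Continuous variables use the Mann-Whitney U test with midranks,
tie correction, and continuity correction on the normal approximation; the
exact null distribution is used for small untied samples. No
multiple-testing adjustment is applied anywhere — the analyses are
exploratory and every p-value is reported raw.

Expression handling follows the microarray convention: raw intensities are
log2-transformed and normalized to each sample's 75th percentile, and the
per-patient fold change is the tumor minus normal difference of normalized
values (a ratio on the raw scale).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from poleclass.classify import (
    COMMON_HYPERMUTATOR,
    LABELS,
    NONHYPERMUTATOR,
    POLE_CATEGORY,
    TumorProfile,
)
from poleclass.io_formats import ClinicalRecord


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = category levels and columns = groups."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be nonnegative")
        if self.total == 0:
            raise ValueError("empty table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value (minimum-likelihood convention).

    Invariant to transposing the table and to swapping both rows and
    columns; exact and deterministic.
    """
    _, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    return float(min(p, 1.0))


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U (for ``x``) and the two-sided p-value.

    For min(n, m) <= 8 without ties the exact null distribution is used;
    otherwise the normal approximation with midranks, tie correction and
    continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    small = min(x.size, y.size) <= 8
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def normalize_expression(raw_intensities: Sequence[float]) -> np.ndarray:
    """Log2-transform one sample and center on its 75th percentile.

    Every value maps to ``log2(value) - q75(log2 values)``, so each
    sample's normalized 75th percentile is exactly 0 and a global scale
    factor between samples cancels.
    """
    raw = np.asarray(raw_intensities, dtype=float)
    if raw.size == 0:
        raise ValueError("empty sample")
    if np.any(raw <= 0):
        raise ValueError("raw intensities must be positive")
    logv = np.log2(raw)
    return logv - np.percentile(logv, 75)


@dataclass(slots=True)
class ExpressionRecord:
    """Normalized expression of one gene in one patient's tumor/normal pair."""

    tumor_id: str
    gene: str
    tumor_value: float
    normal_value: float

    @property
    def fold_change(self) -> float:
        """Tumor minus normal on the log scale (ratio on the raw scale)."""
        return self.tumor_value - self.normal_value


PAIRWISE = (
    (NONHYPERMUTATOR, COMMON_HYPERMUTATOR),
    (NONHYPERMUTATOR, POLE_CATEGORY),
    (COMMON_HYPERMUTATOR, POLE_CATEGORY),
)

_SHORT = {NONHYPERMUTATOR: "NH", COMMON_HYPERMUTATOR: "CH", POLE_CATEGORY: "PC"}


def compare_expression_by_group(
    records: Sequence[ExpressionRecord],
    labels: Mapping[str, str],
    gene: str,
) -> dict[str, float]:
    """Pairwise Mann-Whitney p-values of one gene's fold changes across groups.

    Returns ``{"NH_vs_CH": p, "NH_vs_PC": p, "CH_vs_PC": p}``. Raises if the
    gene is absent or any group is empty.
    """
    by_group: dict[str, list[float]] = {g: [] for g in LABELS}
    seen = False
    for r in records:
        if r.gene != gene:
            continue
        seen = True
        if r.tumor_id not in labels:
            raise ValueError(f"tumor {r.tumor_id!r} has no label")
        by_group[labels[r.tumor_id]].append(r.fold_change)
    if not seen:
        raise ValueError(f"gene {gene!r} not present in expression records")
    for g, values in by_group.items():
        if not values:
            raise ValueError(f"group {g!r} has no expression values for {gene!r}")
    out = {}
    for ga, gb in PAIRWISE:
        _, p = mann_whitney_u(by_group[ga], by_group[gb])
        out[f"{_SHORT[ga]}_vs_{_SHORT[gb]}"] = p
    return out


def expression_records_from_frame(df: pd.DataFrame) -> list[ExpressionRecord]:
    """Build records from a table with tumor_id, gene, tumor_value, normal_value."""
    required = {"tumor_id", "gene", "tumor_value", "normal_value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing columns {sorted(missing)}")
    return [
        ExpressionRecord(
            tumor_id=str(r.tumor_id), gene=str(r.gene),
            tumor_value=float(r.tumor_value), normal_value=float(r.normal_value),
        )
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# three-group clinicopathological comparison report

_CATEGORICAL = [
    # variable, attribute, (level-1 name, predicate), (level-2 name)
    ("sex", "sex", ("man", lambda r: r.sex == "man"), "woman"),
    ("location", "location", ("right", lambda r: r.location == "right"), "left"),
    ("histology", "histology",
     ("well_or_mod", lambda r: r.histology == "well_or_mod"), "por_or_muc"),
    ("pT_stage", "pT", ("Tis-T2", lambda r: r.pT in ("Tis", "T1", "T2")), "T3-T4"),
    ("pStage", "pStage", ("0-II", lambda r: r.pStage in ("0", "I", "II")), "III-IV"),
    ("lymphatic_invasion", "lymphatic_invasion",
     ("yes", lambda r: r.lymphatic_invasion), "no"),
    ("vessel_invasion", "vessel_invasion",
     ("yes", lambda r: r.vessel_invasion), "no"),
]

_CONTINUOUS = [("age_years", "age"), ("tumor_size_mm", "tumor_size_mm")]


def _fmt_count(n: int, total: int) -> str:
    pct = 100.0 * n / total if total else float("nan")
    return f"{n} ({pct:.1f})"


def _fmt_median_range(values: Sequence[float]) -> str:
    v = np.asarray(values, dtype=float)
    return f"{np.median(v):g} ({v.min():g}-{v.max():g})"


def build_group_comparison(
    profiles: Sequence[TumorProfile],
    clinical: Sequence[ClinicalRecord],
) -> pd.DataFrame:
    """Three-group clinicopathological comparison table.

    One row per variable level, with per-group ``count (percent)`` or
    ``median (range)`` summaries and, where both groups are populated,
    Fisher p-values (categorical, dichotomized as Tis-T2 vs T3-T4 and
    0-II vs III-IV) or Mann-Whitney p-values (age, size) for
    nonhypermutators-vs-POLE and common-hypermutators-vs-POLE. Comparisons
    with an empty group are left as NaN (not computable).
    """
    clin_by_id = {c.tumor_id: c for c in clinical}
    missing = [p.tumor_id for p in profiles if p.tumor_id not in clin_by_id]
    if missing:
        raise ValueError(f"no clinical record for tumor ids: {missing[:10]}")
    groups: dict[str, list[ClinicalRecord]] = {g: [] for g in LABELS}
    for p in profiles:
        groups[p.label].append(clin_by_id[p.tumor_id])

    comparisons = ((NONHYPERMUTATOR, POLE_CATEGORY), (COMMON_HYPERMUTATOR, POLE_CATEGORY))

    def fisher_p(pred, ga, gb) -> float:
        if not groups[ga] or not groups[gb]:
            return float("nan")
        a = sum(pred(r) for r in groups[ga])
        b = sum(pred(r) for r in groups[gb])
        c = len(groups[ga]) - a
        d = len(groups[gb]) - b
        return fisher_exact_2x2(ContingencyTable2x2(a, b, c, d))

    def mw_p(attr, ga, gb) -> float:
        if not groups[ga] or not groups[gb]:
            return float("nan")
        _, p = mann_whitney_u(
            [getattr(r, attr) for r in groups[ga]],
            [getattr(r, attr) for r in groups[gb]],
        )
        return p

    rows = []
    for variable, attr in _CONTINUOUS:
        row = {"variable": variable, "level": "median (range)"}
        for g in LABELS:
            vals = [getattr(r, attr) for r in groups[g]]
            row[_SHORT[g]] = _fmt_median_range(vals) if vals else ""
        for ga, gb in comparisons:
            row[f"p_{_SHORT[ga]}_vs_{_SHORT[gb]}"] = round(mw_p(attr, ga, gb), 3)
        rows.append(row)
    for variable, attr, (level1, pred), level2 in _CATEGORICAL:
        p_values = {
            f"p_{_SHORT[ga]}_vs_{_SHORT[gb]}": round(fisher_p(pred, ga, gb), 3)
            for ga, gb in comparisons
        }
        row1 = {"variable": variable, "level": level1}
        row2 = {"variable": variable, "level": level2}
        for g in LABELS:
            n = len(groups[g])
            k = sum(pred(r) for r in groups[g])
            row1[_SHORT[g]] = _fmt_count(k, n) if n else ""
            row2[_SHORT[g]] = _fmt_count(n - k, n) if n else ""
        row1.update(p_values)
        row2.update({k: float("nan") for k in p_values})
        rows.append(row1)
        rows.append(row2)
    columns = ["variable", "level", "NH", "CH", "PC", "p_NH_vs_PC", "p_CH_vs_PC"]
    return pd.DataFrame(rows, columns=columns)
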