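"""False-positive removal for somatic variant calls.

A call is discarded when it meets at least one of six criteria:

1. caller quality score below 60,
2. depth of coverage below 20,
3. variant reads observed on one strand only,
4. average clipped read length below 100,
5. variant sitting at a read end (average position-in-read fraction < 0.05),
6. site present on a user-supplied false-positive blacklist.

All numeric comparisons are strict, so a value exactly at a threshold
passes (quality 60 passes, position fraction 0.05 passes). Criterion 3
also fails a degenerate call with zero variant reads on both strands.
Verdicts depend only on the variant itself plus the blacklist, so
filtering is order-independent and idempotent.

Missing QC metrics: by default a criterion that cannot be evaluated is
treated as passing, with a logged warning; with ``strict_missing=True``
the variant fails that criterion instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from poleclass.io_formats import FormatError, VariantCall

logger = logging.getLogger(__name__)

CRITERIA = (1, 2, 3, 4, 5, 6)


@dataclass(frozen=True)
class FilterThresholds:
    """Numeric cutoffs for criteria (1), (2), (4), (5); strict comparisons."""

    min_quality: float = 60.0
    min_depth: int = 20
    min_clipped_length: float = 100.0
    min_pos_fraction: float = 0.05


@dataclass(frozen=True)
class Blacklist:
    """Known false-positive sites keyed by (chrom, pos, ref, alt)."""

    entries: frozenset[tuple[str, int, str, str]] = frozenset()

    @classmethod
    def from_iterable(cls, items: Iterable[tuple[str, int, str, str]]) -> "Blacklist":
        return cls(frozenset((str(c), int(p), r.upper(), a.upper()) for c, p, r, a in items))

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return key in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def read_blacklist(path: str | Path) -> Blacklist:
    """Read a blacklist as tab-separated chrom, pos, ref, alt (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 4:
        raise FormatError(f"{path}: expected 4 columns (chrom, pos, ref, alt)")
    return Blacklist.from_iterable(
        (row[0], int(row[1]), row[2], row[3]) for row in df.itertuples(index=False)
    )


def write_blacklist(blacklist: Blacklist, path: str | Path) -> None:
    rows = sorted(blacklist.entries)
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


@dataclass(slots=True)
class FilterVerdict:
    variant: VariantCall
    kept: bool
    failed_criteria: frozenset[int]

    def __post_init__(self) -> None:
        if self.kept != (len(self.failed_criteria) == 0):
            raise ValueError("kept must be equivalent to an empty failed set")


def _evaluate(
    v: VariantCall,
    blacklist: Blacklist,
    thresholds: FilterThresholds,
    strict_missing: bool,
) -> frozenset[int]:
    failed: set[int] = set()

    def check(criterion: int, value, fails) -> None:
        if value is None:
            if strict_missing:
                failed.add(criterion)
            else:
                logger.warning(
                    "variant %s:%d missing metric for criterion %d; passing",
                    v.chrom, v.pos, criterion,
                )
            return
        if fails(value):
            failed.add(criterion)

    check(1, v.quality, lambda q: q < thresholds.min_quality)
    check(2, v.depth, lambda d: d < thresholds.min_depth)
    if v.var_reads_fwd is None or v.var_reads_rev is None:
        if strict_missing:
            failed.add(3)
        else:
            logger.warning(
                "variant %s:%d missing strand counts for criterion 3; passing",
                v.chrom, v.pos,
            )
    else:
        fwd, rev = v.var_reads_fwd, v.var_reads_rev
        # one-strand-only, including the degenerate zero-read call
        if fwd == 0 or rev == 0:
            failed.add(3)
    check(4, v.avg_clipped_length, lambda c: c < thresholds.min_clipped_length)
    check(5, v.avg_pos_as_fraction, lambda f: f < thresholds.min_pos_fraction)
    if v.key in blacklist:
        failed.add(6)
    return frozenset(failed)


def apply_fp_filters(
    variants: Sequence[VariantCall],
    blacklist: Blacklist | None = None,
    thresholds: FilterThresholds = FilterThresholds(),
    strict_missing: bool = False,
) -> list[FilterVerdict]:
    """Apply the six false-positive criteria; verdicts come back in input order."""
    blacklist = blacklist or Blacklist()
    verdicts = []
    for v in variants:
        failed = _evaluate(v, blacklist, thresholds, strict_missing)
        verdicts.append(FilterVerdict(variant=v, kept=not failed, failed_criteria=failed))
    return verdicts


def kept_variants(verdicts: Iterable[FilterVerdict]) -> list[VariantCall]:
    return [vd.variant for vd in verdicts if vd.kept]


@dataclass(slots=True)
class FilterSummary:
    total: int
    kept: int
    discarded: int
    per_criterion: dict[int, int]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"criterion": c, "n_failed": self.per_criterion[c]} for c in CRITERIA]
        return pd.DataFrame(rows)


def filter_summary(verdicts: Sequence[FilterVerdict]) -> FilterSummary:
    """Tally kept/discarded totals and failure counts per criterion.

    A variant failing several criteria counts once per criterion, so the
    per-criterion sum may exceed the number of discarded variants.
    """
    per = {c: 0 for c in CRITERIA}
    kept = 0
    for vd in verdicts:
        if vd.kept:
            kept += 1
        for c in vd.failed_criteria:
            per[c] += 1
    return FilterSummary(
        total=len(verdicts), kept=kept, discarded=len(verdicts) - kept, per_criterion=per
    )
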