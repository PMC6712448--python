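"""Per-tumor mutation statistics and the three-way tumor classification.

Tumors are stratified by nonsynonymous SNV count and substitution spectrum:
a tumor exceeding 500 nonsynonymous SNVs is a hypermutator; a hypermutator
whose pyrimidine-normalized spectrum shows more than 20% C>A and less than
3% C>G transversions falls in the POLE category (the ultramutated phenotype
of proofreading-deficient DNA polymerase epsilon), the rest are
common-hypermutators (typically mismatch-repair deficient, C>T-rich).
All three comparisons are strict: a count of exactly 500, a C>A fraction of
exactly 0.20, or a C>G fraction of exactly 0.03 does not qualify.

POLE protein changes are annotated for membership in the exonuclease
(proofreading) domain, residues 86-427, and for the recurrent pathogenic
hotspots at residues 286, 297, 367, and 411 (P286R, S297Y, F367C, V411L).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from poleclass.io_formats import (
    BASES,
    COMPLEMENT,
    SUBSTITUTION_CLASSES,
    VariantCall,
)

NONHYPERMUTATOR = "nonhypermutator"
COMMON_HYPERMUTATOR = "common_hypermutator"
POLE_CATEGORY = "pole_category"
LABELS = (NONHYPERMUTATOR, COMMON_HYPERMUTATOR, POLE_CATEGORY)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_PROTEIN_CHANGE_RE = re.compile(
    rf"^(?:p\.)?([{AMINO_ACIDS}])(\d+)([{AMINO_ACIDS}*])$"
)


@dataclass(frozen=True)
class ClassifyThresholds:
    """Classification cutoffs; defaults are the conventional published values."""

    hypermutator_count: int = 500
    c_to_a_min: float = 0.20
    c_to_g_max: float = 0.03
    exo_domain: tuple[int, int] = (86, 427)
    hotspots: frozenset[int] = frozenset({286, 297, 367, 411})

    def __post_init__(self) -> None:
        lo, hi = self.exo_domain
        if not (0 < lo <= hi):
            raise ValueError(f"exonuclease domain bounds must be ordered, got {self.exo_domain}")
        if self.hypermutator_count <= 0:
            raise ValueError("hypermutator_count must be positive")


def substitution_class(ref: str, alt: str) -> str:
    """Collapse a single-base substitution onto the six pyrimidine classes.

    Purine-reference substitutions are complemented onto the pyrimidine
    strand, e.g. G>T maps to C>A and A>G maps to T>C.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"bases must be one of {BASES!r}, got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref in "AG":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}>{alt}"


@dataclass
class MutationSpectrum:
    """Counts (and fractions) of SNVs over the six substitution classes."""

    counts: dict[str, int]
    n_ignored: int = 0  # non-SNV records skipped when building the spectrum

    def __post_init__(self) -> None:
        full = {cls: int(self.counts.get(cls, 0)) for cls in SUBSTITUTION_CLASSES}
        if any(c < 0 for c in full.values()):
            raise ValueError("spectrum counts must be nonnegative")
        unknown = set(self.counts) - set(SUBSTITUTION_CLASSES)
        if unknown:
            raise ValueError(f"unknown substitution classes {sorted(unknown)}")
        self.counts = full

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def fractions(self) -> dict[str, float] | None:
        """Per-class fractions; ``None`` when the spectrum is empty."""
        t = self.total
        if t == 0:
            return None
        return {cls: c / t for cls, c in self.counts.items()}

    def fraction(self, cls: str) -> float:
        fr = self.fractions
        if fr is None:
            raise ValueError("spectrum is empty; fractions undefined")
        return fr[cls]


def compute_spectrum(variants: Iterable[VariantCall]) -> MutationSpectrum:
    """Tally the six-class substitution spectrum over the SNVs in a call set.

    Non-SNV records (indels, MNVs) are ignored and counted in
    ``n_ignored``. An empty SNV set yields all-zero counts with undefined
    fractions.
    """
    counts = {cls: 0 for cls in SUBSTITUTION_CLASSES}
    ignored = 0
    for v in variants:
        if not v.is_snv:
            ignored += 1
            continue
        counts[substitution_class(v.ref, v.alt)] += 1
    return MutationSpectrum(counts=counts, n_ignored=ignored)


def classify_tumor(
    nonsyn_snv_count: int,
    spectrum: MutationSpectrum,
    thresholds: ClassifyThresholds = ClassifyThresholds(),
) -> str:
    """Assign the three-way label from nonsynonymous SNV count and spectrum.

    A count of at most ``hypermutator_count`` (default 500) gives
    ``nonhypermutator``. Above it, the tumor is ``pole_category`` iff
    C>A fraction > 0.20 and C>G fraction < 0.03 (both strict), else
    ``common_hypermutator``. A hypermutator with an empty spectrum (no
    usable SNVs) cannot satisfy the spectrum rule and is a
    common-hypermutator.
    """
    if nonsyn_snv_count < 0:
        raise ValueError(f"nonsyn_snv_count must be nonnegative, got {nonsyn_snv_count}")
    if nonsyn_snv_count <= thresholds.hypermutator_count:
        return NONHYPERMUTATOR
    fr = spectrum.fractions
    if fr is None:
        return COMMON_HYPERMUTATOR
    if fr["C>A"] > thresholds.c_to_a_min and fr["C>G"] < thresholds.c_to_g_max:
        return POLE_CATEGORY
    return COMMON_HYPERMUTATOR


def mutations_per_mb(total_mutation_count: int, footprint_mb: float) -> float:
    """Tumor mutational burden: mutations per megabase of interrogated sequence.

    The callable footprint is mandatory configuration — no default is baked
    in, since it depends on the capture design.
    """
    if footprint_mb <= 0:
        raise ValueError(f"footprint_mb must be positive, got {footprint_mb}")
    if total_mutation_count < 0:
        raise ValueError("total_mutation_count must be nonnegative")
    return total_mutation_count / footprint_mb


@dataclass(slots=True)
class PoleMutation:
    """One POLE protein change with domain and hotspot annotation."""

    protein_change: str
    residue: int
    ref_aa: str
    alt_aa: str
    mutation_type: str  # missense | nonsense
    in_exonuclease_domain: bool
    is_hotspot: bool


def parse_protein_change(text: str) -> tuple[str, int, str, str]:
    """Parse a protein change like ``P286R`` or ``p.Q196*``.

    Returns ``(ref_aa, residue, alt_aa, mutation_type)``; an asterisk
    alternate means nonsense. Compound entries must be split by the caller
    (see :func:`annotate_pole`).
    """
    m = _PROTEIN_CHANGE_RE.match(text.strip())
    if not m:
        raise ValueError(
            f"cannot parse protein change {text!r}; expected "
            "[p.]<ref aa><residue><alt aa or *>, e.g. P286R, p.V411L, Q196*"
        )
    ref_aa, residue, alt_aa = m.group(1), int(m.group(2)), m.group(3)
    mutation_type = "nonsense" if alt_aa == "*" else "missense"
    return ref_aa, residue, alt_aa, mutation_type


def annotate_pole(
    protein_changes: Sequence[str],
    thresholds: ClassifyThresholds = ClassifyThresholds(),
) -> list[PoleMutation]:
    """Annotate POLE protein changes for exonuclease-domain and hotspot status.

    Compound strings ("P1207S, V1218I") are split on commas and each change
    annotated independently.
    """
    lo, hi = thresholds.exo_domain
    out: list[PoleMutation] = []
    for entry in protein_changes:
        for text in str(entry).split(","):
            text = text.strip()
            if not text:
                continue
            ref_aa, residue, alt_aa, mutation_type = parse_protein_change(text)
            out.append(
                PoleMutation(
                    protein_change=text.removeprefix("p."),
                    residue=residue,
                    ref_aa=ref_aa,
                    alt_aa=alt_aa,
                    mutation_type=mutation_type,
                    in_exonuclease_domain=lo <= residue <= hi,
                    is_hotspot=residue in thresholds.hotspots,
                )
            )
    return out


@dataclass
class TumorProfile:
    """Per-tumor aggregate statistics and classification."""

    tumor_id: str
    nonsyn_snv_count: int
    total_snv_count: int
    spectrum: MutationSpectrum
    label: str
    mutations_per_mb: float | None = None
    pole_mutations: list[PoleMutation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label {self.label!r} not in {LABELS}")


def build_profile(
    tumor_id: str,
    variants: Sequence[VariantCall],
    footprint_mb: float | None = None,
    spectrum_set: str = "all",
    pole_gene: str = "POLE",
    thresholds: ClassifyThresholds = ClassifyThresholds(),
) -> TumorProfile:
    """Aggregate filtered variants of one tumor into a :class:`TumorProfile`.

    ``spectrum_set`` selects whether the 20%/3% spectrum rule is evaluated
    over all SNVs (default; maximizes counts) or nonsynonymous SNVs only.
    TMB is computed from all retained mutations when ``footprint_mb`` is
    given.
    """
    if spectrum_set not in ("all", "nonsynonymous"):
        raise ValueError(f"spectrum_set must be 'all' or 'nonsynonymous', got {spectrum_set!r}")
    snvs = [v for v in variants if v.is_snv]
    nonsyn = [v for v in snvs if v.consequence == "nonsynonymous_SNV"]
    spectrum_variants = snvs if spectrum_set == "all" else nonsyn
    spectrum = compute_spectrum(spectrum_variants)
    label = classify_tumor(len(nonsyn), spectrum, thresholds)
    tmb = None
    if footprint_mb is not None:
        tmb = mutations_per_mb(len(variants), footprint_mb)
    changes = [
        v.protein_change
        for v in variants
        if v.gene == pole_gene and v.protein_change
    ]
    return TumorProfile(
        tumor_id=tumor_id,
        nonsyn_snv_count=len(nonsyn),
        total_snv_count=len(snvs),
        spectrum=spectrum,
        label=label,
        mutations_per_mb=tmb,
        pole_mutations=annotate_pole(changes, thresholds),
    )


def profiles_to_frame(profiles: Sequence[TumorProfile]):
    """Tabulate profiles (one row per tumor) for reporting."""
    import pandas as pd

    rows = []
    for p in profiles:
        fr = p.spectrum.fractions or {cls: float("nan") for cls in SUBSTITUTION_CLASSES}
        row = {
            "tumor_id": p.tumor_id,
            "nonsyn_snv_count": p.nonsyn_snv_count,
            "total_snv_count": p.total_snv_count,
            **{f"frac_{cls.replace('>', '_')}": fr[cls] for cls in SUBSTITUTION_CLASSES},
            "mutations_per_mb": p.mutations_per_mb,
            "label": p.label,
            "pole_domain_mutations": ";".join(
                m.protein_change for m in p.pole_mutations if m.in_exonuclease_domain
            ),
            "pole_hotspots": ";".join(
                m.protein_change for m in p.pole_mutations if m.is_hotspot
            ),
        }
        rows.append(row)
    return pd.DataFrame(rows)
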