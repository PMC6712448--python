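"""Readers and writers for the formats the pipeline touches.

Somatic variants come in as VCF v4.2 (via :mod:`pysam`) or tab-separated
variant tables; clinical covariates, expression values, and reference
signature matrices are tab-separated tables with a header row (UTF-8).
Everything is parsed into the validated domain types defined here:
:class:`VariantCall`, :class:`ClinicalRecord`, :class:`SignatureMatrix`.

Coordinates are 1-based and fully closed, matching VCF. Multi-allelic VCF
records are split into one :class:`VariantCall` per alternate allele, since
filtering and the substitution spectrum operate per substitution.

Per-variant QC metrics (caller quality, depth, per-strand variant read
counts, average clipped read length, average position-in-read fraction) are
read from configurable INFO keys — the defaults ``DP``/``SAF``/``SAR``/
``ACL``/``APF`` plus the record QUAL column — because upstream callers name
them differently. A metric absent from a record is carried as an explicit
``None`` (missing marker), never silently defaulted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: The six pyrimidine-normalized single-base substitution classes.
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Canonical order of the 96 trinucleotide substitution contexts:
#: six substitution blocks, each spanning the 16 flanking-base combinations
#: in lexicographic order (the conventional COSMIC ordering).
CANONICAL_CONTEXTS = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTION_CLASSES
    for five in BASES
    for three in BASES
)

CONTEXT_INDEX = {ctx: i for i, ctx in enumerate(CANONICAL_CONTEXTS)}

CONSEQUENCES = ("nonsynonymous_SNV", "synonymous_SNV", "nonsense", "other")

#: Aliases seen in the wild for the consequence vocabulary.
_CONSEQUENCE_ALIASES = {
    "nonsynonymous_snv": "nonsynonymous_SNV",
    "missense": "nonsynonymous_SNV",
    "missense_variant": "nonsynonymous_SNV",
    "synonymous_snv": "synonymous_SNV",
    "synonymous_variant": "synonymous_SNV",
    "nonsense": "nonsense",
    "stopgain": "nonsense",
    "stop_gained": "nonsense",
    "other": "other",
}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def normalize_consequence(value: str | None) -> str:
    """Map a free-text consequence annotation onto the closed vocabulary.

    Unknown strings map to ``"other"`` with a logged warning; ``None``
    (unannotated) also maps to ``"other"``, silently.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return "other"
    key = str(value).strip().lower()
    if key in _CONSEQUENCE_ALIASES:
        return _CONSEQUENCE_ALIASES[key]
    logger.warning("unknown consequence %r mapped to 'other'", value)
    return "other"


@dataclass(slots=True)
class VariantCall:
    """One somatic SNV/indel call with QC annotations and consequence.

    QC metrics left as ``None`` are explicitly missing; downstream filtering
    decides how to treat them (pass-with-warning by default, fail in strict
    mode).
    """

    tumor_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    quality: float | None = None
    depth: int | None = None
    var_reads_fwd: int | None = None
    var_reads_rev: int | None = None
    avg_clipped_length: float | None = None
    avg_pos_as_fraction: float | None = None
    consequence: str = "other"
    gene: str | None = None
    protein_change: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"consequence {self.consequence!r} not in {CONSEQUENCES}")
        for name in ("quality", "depth", "var_reads_fwd", "var_reads_rev",
                     "avg_clipped_length"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative, got {v}")
        if self.avg_pos_as_fraction is not None and not (
            0.0 <= self.avg_pos_as_fraction <= 1.0
        ):
            raise ValueError(
                f"avg_pos_as_fraction must be in [0,1], got {self.avg_pos_as_fraction}"
            )
        if (
            self.depth is not None
            and self.var_reads_fwd is not None
            and self.var_reads_rev is not None
            and self.var_reads_fwd + self.var_reads_rev > self.depth
        ):
            raise ValueError(
                f"variant reads exceed depth at {self.chrom}:{self.pos} "
                f"({self.var_reads_fwd}+{self.var_reads_rev} > {self.depth})"
            )

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and \
            self.ref in BASES and self.alt in BASES

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


SEX_VALUES = ("man", "woman")
LOCATION_VALUES = ("right", "left")
HISTOLOGY_VALUES = ("well_or_mod", "por_or_muc")
PT_VALUES = ("Tis", "T1", "T2", "T3", "T4")
PSTAGE_VALUES = ("0", "I", "II", "III", "IV")
MMR_VALUES = ("MMR_P", "MMR_D", "unknown")


@dataclass(slots=True)
class ClinicalRecord:
    """Clinicopathological covariates for one patient.

    Right-sided tumors arise from the cecum, ascending, or transverse colon;
    left-sided from the descending colon, sigmoid, or rectum. Mismatch-repair
    status comes from immunohistochemistry and is usually ``unknown`` (it is
    measured only when clinically indicated).
    """

    tumor_id: str
    age: int
    sex: str
    location: str
    histology: str
    tumor_size_mm: int
    pT: str
    pStage: str
    lymphatic_invasion: bool
    vessel_invasion: bool
    mmr_status: str = "unknown"

    def __post_init__(self) -> None:
        if not (0 <= self.age <= 120):
            raise ValueError(f"age {self.age} outside [0, 120]")
        if self.tumor_size_mm <= 0:
            raise ValueError(f"tumor_size_mm must be positive, got {self.tumor_size_mm}")
        for name, vocab in (
            ("sex", SEX_VALUES),
            ("location", LOCATION_VALUES),
            ("histology", HISTOLOGY_VALUES),
            ("pT", PT_VALUES),
            ("pStage", PSTAGE_VALUES),
            ("mmr_status", MMR_VALUES),
        ):
            if getattr(self, name) not in vocab:
                raise ValueError(f"{name} value {getattr(self, name)!r} not in {vocab}")


@dataclass
class SignatureMatrix:
    """Reference mutational signatures over the 96 trinucleotide contexts.

    ``weights`` is a 96 x K array; each column is a probability distribution
    over contexts (sums to 1). Rows follow :data:`CANONICAL_CONTEXTS`.
    """

    names: tuple[str, ...]
    weights: np.ndarray
    contexts: tuple[str, ...] = CANONICAL_CONTEXTS

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != 96:
            raise ValueError(f"weights must be 96 x K, got {self.weights.shape}")
        if self.weights.shape[1] != len(self.names):
            raise ValueError("number of names does not match number of columns")
        if len(set(self.names)) != len(self.names):
            raise ValueError("signature names must be unique")
        if np.any(self.weights < 0):
            raise ValueError("signature weights must be nonnegative")
        sums = self.weights.sum(axis=0)
        bad = np.where(np.abs(sums - 1.0) > 1e-6)[0]
        if bad.size:
            raise ValueError(
                f"signature {self.names[bad[0]]!r} column sums to {sums[bad[0]]:.6g}, not 1"
            )
        if tuple(self.contexts) != CANONICAL_CONTEXTS:
            raise ValueError("contexts must be in canonical order")

    @property
    def k(self) -> int:
        return self.weights.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.weights[:, self.names.index(name)]

    def subset(self, names: Sequence[str]) -> "SignatureMatrix":
        idx = [self.names.index(n) for n in names]
        return SignatureMatrix(names=tuple(names), weights=self.weights[:, idx])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights, index=pd.Index(self.contexts, name="Context"),
            columns=list(self.names),
        )


# ---------------------------------------------------------------------------
# variant I/O

@dataclass(frozen=True)
class QcFieldMap:
    """INFO-key names under which per-variant QC metrics are stored."""

    depth: str = "DP"
    var_reads_fwd: str = "SAF"
    var_reads_rev: str = "SAR"
    avg_clipped_length: str = "ACL"
    avg_pos_as_fraction: str = "APF"
    consequence: str = "CONSEQ"
    gene: str = "GENE"
    protein_change: str = "AAC"


_VARIANT_COLUMNS = [f.name for f in fields(VariantCall)]

_INT_FIELDS = {"pos", "depth", "var_reads_fwd", "var_reads_rev"}
_FLOAT_FIELDS = {"quality", "avg_clipped_length", "avg_pos_as_fraction"}


def _pick_allele_value(value, alt_index: int):
    """INFO values may be scalar or per-alt tuples (Number=A)."""
    if isinstance(value, (tuple, list)):
        return value[alt_index] if alt_index < len(value) else None
    return value


def _from_f32(value: float) -> float:
    """Shortest decimal faithful to float32 storage.

    htslib keeps QUAL and Float INFO fields as single precision; recovering
    the shortest round-tripping decimal makes write-then-read exact for
    values that were written with float32-representable precision.
    """
    return float(np.format_float_positional(np.float32(value), unique=True))


def _variants_from_vcf(path: Path, tumor_id: str, qc: QcFieldMap) -> list[VariantCall]:
    out: list[VariantCall] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"{path}: not a readable VCF: {exc}") from exc
    with vcf:
        for rec in vcf:
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                def info(key):
                    try:
                        value = rec.info.get(key)
                    except (KeyError, ValueError):
                        # key not declared in this file's header: missing
                        return None
                    return _pick_allele_value(value, i)

                def as_int(key):
                    v = info(key)
                    return None if v is None else int(v)

                def as_float(key):
                    v = info(key)
                    return None if v is None else _from_f32(v)

                raw_gene = info(qc.gene)
                raw_pchg = info(qc.protein_change)
                out.append(
                    VariantCall(
                        tumor_id=tumor_id,
                        chrom=rec.chrom,
                        pos=rec.pos,  # pysam exposes 1-based .pos
                        ref=rec.ref,
                        alt=alt,
                        quality=None if rec.qual is None else _from_f32(rec.qual),
                        depth=as_int(qc.depth),
                        var_reads_fwd=as_int(qc.var_reads_fwd),
                        var_reads_rev=as_int(qc.var_reads_rev),
                        avg_clipped_length=as_float(qc.avg_clipped_length),
                        avg_pos_as_fraction=as_float(qc.avg_pos_as_fraction),
                        consequence=normalize_consequence(info(qc.consequence)),
                        gene=None if raw_gene is None else str(raw_gene),
                        protein_change=None if raw_pchg is None else str(raw_pchg),
                    )
                )
    return out


def _variants_from_tsv(path: Path, tumor_id: str | None) -> list[VariantCall]:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    required = {"chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required columns {sorted(missing)}")
    out: list[VariantCall] = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        kwargs: dict = {}
        row_d = dict(zip(df.columns, row))
        for name in _VARIANT_COLUMNS:
            raw = row_d.get(name)
            if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
                continue
            if name in _INT_FIELDS:
                kwargs[name] = int(float(raw))
            elif name in _FLOAT_FIELDS:
                kwargs[name] = float(raw)
            else:
                kwargs[name] = str(raw)
        if "consequence" in kwargs:
            kwargs["consequence"] = normalize_consequence(kwargs["consequence"])
        kwargs.setdefault("tumor_id", tumor_id or Path(path).stem)
        if tumor_id is not None:
            kwargs["tumor_id"] = kwargs.get("tumor_id", tumor_id)
        try:
            out.append(VariantCall(**kwargs))
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path}: line {line_no}: {exc}") from exc
    return out


def read_variants(
    path: str | Path,
    format: str = "vcf",
    tumor_id: str | None = None,
    qc_fields: QcFieldMap = QcFieldMap(),
) -> list[VariantCall]:
    """Read somatic variant calls from a VCF or tab-separated table.

    Parameters
    ----------
    path
        Input file. Must exist.
    format
        ``"vcf"`` (default) or ``"tsv"``.
    tumor_id
        Sample identifier attached to every record; defaults to the file
        stem (for TSV input, a ``tumor_id`` column takes precedence).
    qc_fields
        INFO-key mapping for the QC metrics (VCF input only).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _variants_from_vcf(path, tumor_id or path.stem, qc_fields)
    if format == "tsv":
        return _variants_from_tsv(path, tumor_id)
    raise ValueError(f"format must be 'vcf' or 'tsv', got {format!r}")


def _vcf_header(variants: Sequence[VariantCall], qc: QcFieldMap) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(v.chrom for v in variants):
        header.contigs.add(chrom)
    header.info.add(qc.depth, 1, "Integer", "Depth of coverage at site")
    header.info.add(qc.var_reads_fwd, 1, "Integer", "Variant reads on forward strand")
    header.info.add(qc.var_reads_rev, 1, "Integer", "Variant reads on reverse strand")
    header.info.add(qc.avg_clipped_length, 1, "Float", "Average clipped read length")
    header.info.add(qc.avg_pos_as_fraction, 1, "Float",
                    "Average variant position in read as fraction")
    header.info.add(qc.consequence, 1, "String", "Coding consequence")
    header.info.add(qc.gene, 1, "String", "Gene symbol")
    header.info.add(qc.protein_change, 1, "String", "Protein change")
    return header


def write_variants(
    variants: Sequence[VariantCall],
    path: str | Path,
    format: str = "vcf",
    qc_fields: QcFieldMap = QcFieldMap(),
) -> None:
    """Write variant calls as uncompressed VCF v4.2 or a tab-separated table."""
    path = Path(path)
    if format == "tsv":
        rows = []
        for v in variants:
            rows.append({name: getattr(v, name) for name in _VARIANT_COLUMNS})
        pd.DataFrame(rows, columns=_VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)
        return
    if format != "vcf":
        raise ValueError(f"format must be 'vcf' or 'tsv', got {format!r}")
    header = _vcf_header(variants, qc_fields)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            rec.qual = v.quality
            info_map = {
                qc_fields.depth: v.depth,
                qc_fields.var_reads_fwd: v.var_reads_fwd,
                qc_fields.var_reads_rev: v.var_reads_rev,
                qc_fields.avg_clipped_length: v.avg_clipped_length,
                qc_fields.avg_pos_as_fraction: v.avg_pos_as_fraction,
                qc_fields.consequence: v.consequence,
                qc_fields.gene: v.gene,
                qc_fields.protein_change: v.protein_change,
            }
            for key, value in info_map.items():
                if value is not None:
                    rec.info[key] = value
            out.write(rec)


# ---------------------------------------------------------------------------
# clinical table I/O

_CLINICAL_COLUMNS = [f.name for f in fields(ClinicalRecord)]
_BOOL_MAP = {"yes": True, "no": False, "true": True, "false": False, "1": True, "0": False}


def read_clinical_table(path: str | Path) -> list[ClinicalRecord]:
    """Read per-patient clinicopathological covariates.

    A missing ``mmr_status`` column yields ``unknown`` for every record.
    Out-of-vocabulary values raise :class:`FormatError` naming the row and
    column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = set(_CLINICAL_COLUMNS) - {"mmr_status"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out: list[ClinicalRecord] = []
    for i, row in df.iterrows():
        kwargs = {}
        for col in _CLINICAL_COLUMNS:
            if col == "mmr_status" and col not in df.columns:
                continue
            raw = row[col]
            try:
                if col in ("age", "tumor_size_mm"):
                    kwargs[col] = int(raw)
                elif col in ("lymphatic_invasion", "vessel_invasion"):
                    kwargs[col] = _BOOL_MAP[str(raw).strip().lower()]
                else:
                    kwargs[col] = str(raw).strip()
            except (KeyError, ValueError, TypeError) as exc:
                raise FormatError(
                    f"{path}: row {i + 2}, column {col!r}: bad value {raw!r}"
                ) from exc
        try:
            out.append(ClinicalRecord(**kwargs))
        except ValueError as exc:
            raise FormatError(f"{path}: row {i + 2}: {exc}") from exc
    return out


def write_clinical_table(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {name: getattr(r, name) for name in _CLINICAL_COLUMNS}
        row["lymphatic_invasion"] = "yes" if r.lymphatic_invasion else "no"
        row["vessel_invasion"] = "yes" if r.vessel_invasion else "no"
        rows.append(row)
    pd.DataFrame(rows, columns=_CLINICAL_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# signature matrix I/O

def read_signature_matrix(path: str | Path) -> SignatureMatrix:
    """Read a 96-context x K reference signature matrix.

    The first column ("Context") holds labels like ``A[C>A]A``; the header
    row names the signatures. Rows are reordered into canonical context
    order, so a shuffled file reads identically to a sorted one. Columns must
    each sum to 1 within 1e-3 (then renormalized exactly).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != 96:
        raise FormatError(f"{path}: expected 96 contexts, got {df.shape[0]}")
    unknown = set(df.index) - set(CANONICAL_CONTEXTS)
    if unknown:
        raise FormatError(f"{path}: unknown context labels {sorted(unknown)[:3]}")
    if len(set(df.index)) != 96:
        raise FormatError(f"{path}: duplicate context labels")
    df = df.reindex(list(CANONICAL_CONTEXTS))
    weights = df.to_numpy(dtype=float)
    sums = weights.sum(axis=0)
    for j, name in enumerate(df.columns):
        if abs(sums[j] - 1.0) > 1e-3:
            raise FormatError(
                f"{path}: signature {name!r} column sums to {sums[j]:.6g}, not 1"
            )
    weights = weights / sums  # exact renormalization
    return SignatureMatrix(names=tuple(str(c) for c in df.columns), weights=weights)


def write_signature_matrix(matrix: SignatureMatrix, path: str | Path) -> None:
    matrix.to_dataframe().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# catalog table I/O (tumor x 96 counts)

def read_catalog_table(path: str | Path) -> pd.DataFrame:
    """Read a tumors x 96-contexts count table (first column ``tumor_id``)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.columns) != list(CANONICAL_CONTEXTS):
        missing = set(CANONICAL_CONTEXTS) - set(df.columns)
        if missing:
            raise FormatError(f"{path}: missing context columns (e.g. {sorted(missing)[:3]})")
        df = df[list(CANONICAL_CONTEXTS)]
    return df.astype(int)


def write_catalog_table(catalogs: pd.DataFrame, path: str | Path) -> None:
    catalogs.to_csv(path, sep="\t", index_label="tumor_id")
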