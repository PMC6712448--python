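"""End-to-end orchestration: filter -> classify -> signatures -> compare.

A run is a pure function of (inputs, config, seed). All classification
thresholds live in the config with their conventional published defaults
rather than being hard-coded in operations — the hypermutator definition
itself is debated in the field, so it must be overridable. The run
manifest records a hash of the configuration, checksums of the inputs and
outputs, and library versions, so identical runs are verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from poleclass.classify import (
    ClassifyThresholds,
    build_profile,
    profiles_to_frame,
)
from poleclass.cohort_stats import (
    build_group_comparison,
    compare_expression_by_group,
    expression_records_from_frame,
)
from poleclass.io_formats import (
    read_clinical_table,
    read_signature_matrix,
    read_variants,
)
from poleclass.qc_filter import (
    Blacklist,
    FilterThresholds,
    apply_fp_filters,
    filter_summary,
    kept_variants,
    read_blacklist,
)
from poleclass.signature_refit import ReferenceContext, build_catalog, refit_exposures

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """Wraps a stage failure with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths, thresholds, and options of one pipeline run."""

    variants_dir: str | None = None
    clinical: str | None = None
    expression: str | None = None
    signatures: str | None = None
    reference_fasta: str | None = None
    blacklist: str | None = None
    footprint_mb: float | None = None
    spectrum_set: str = "all"
    strict_missing: bool = False
    signature_cutoff: float = 0.06
    signature_min_total: int = 50
    genes: tuple = ("PD-L1", "PD-1", "CTLA-4", "CD8A")
    classify_thresholds: ClassifyThresholds = field(default_factory=ClassifyThresholds)
    filter_thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load a flat ``key = value`` configuration file ('#' comments)."""
        values: dict = {}
        for line_no, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}: line {line_no}: expected 'key = value'")
            key, raw = (s.strip() for s in line.split("=", 1))
            if key not in {f.name for f in dataclasses.fields(cls)}:
                raise ValueError(f"{path}: line {line_no}: unknown key {key!r}")
            if key in ("footprint_mb", "signature_cutoff"):
                values[key] = float(raw)
            elif key in ("seed", "signature_min_total"):
                values[key] = int(raw)
            elif key == "strict_missing":
                values[key] = raw.lower() in ("1", "true", "yes")
            elif key == "genes":
                values[key] = tuple(g.strip() for g in raw.split(","))
            else:
                values[key] = raw
        return cls(**values)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["classify_thresholds"]["hotspots"] = sorted(
            self.classify_thresholds.hotspots
        )
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_variant_files(directory: Path):
    files = sorted(directory.glob("*.vcf")) + sorted(directory.glob("*.tsv"))
    if not files:
        raise FileNotFoundError(f"no .vcf or .tsv variant files in {directory}")
    for path in files:
        fmt = "vcf" if path.suffix == ".vcf" else "tsv"
        yield path.stem, read_variants(path, format=fmt, tumor_id=path.stem)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run filter -> classify -> signatures -> compare and write the bundle.

    Writes ``profiles.tsv``, ``filter_report.tsv``, and — when the
    corresponding inputs are configured — ``exposures.tsv``, ``table4.tsv``,
    ``expression_comparison.tsv``, plus ``manifest.json``. Returns the
    manifest. Stages whose inputs are not configured are skipped with a
    logged notice; stage errors propagate wrapped with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.variants_dir is None:
        raise ValueError("variants_dir is required")

    inputs = {}
    for key in ("clinical", "expression", "signatures", "reference_fasta", "blacklist"):
        value = getattr(config, key)
        if value is not None:
            inputs[key] = _sha256(Path(value))

    # --- filter + classify ------------------------------------------------
    try:
        blacklist = (
            read_blacklist(config.blacklist) if config.blacklist else Blacklist()
        )
        kept: dict[str, list] = {}
        summary_rows = []
        profiles = []
        for tumor_id, variants in _load_variant_files(Path(config.variants_dir)):
            verdicts = apply_fp_filters(
                variants, blacklist, config.filter_thresholds, config.strict_missing
            )
            summary = filter_summary(verdicts)
            summary_rows.append({
                "tumor_id": tumor_id, "total": summary.total, "kept": summary.kept,
                "discarded": summary.discarded,
                **{f"criterion_{c}": n for c, n in summary.per_criterion.items()},
            })
            kept[tumor_id] = kept_variants(verdicts)
            profiles.append(
                build_profile(
                    tumor_id, kept[tumor_id],
                    footprint_mb=config.footprint_mb,
                    spectrum_set=config.spectrum_set,
                    thresholds=config.classify_thresholds,
                )
            )
    except Exception as exc:  # noqa: BLE001 - rewrap with stage name
        raise PipelineStageError("filter+classify", exc) from exc

    profiles_df = profiles_to_frame(profiles)
    profiles_df.to_csv(outdir / "profiles.tsv", sep="\t", index=False)
    pd.DataFrame(summary_rows).to_csv(outdir / "filter_report.tsv", sep="\t", index=False)

    # --- signatures -------------------------------------------------------
    if config.signatures and config.reference_fasta:
        try:
            matrix = read_signature_matrix(config.signatures)
            context = ReferenceContext.from_fasta(config.reference_fasta)
            rows = []
            for p in profiles:
                catalog = build_catalog(kept[p.tumor_id], context, p.tumor_id)
                if catalog.total < config.signature_min_total:
                    continue
                exposure = refit_exposures(
                    catalog, matrix, cutoff=config.signature_cutoff,
                    min_total=config.signature_min_total,
                )
                row = {"tumor_id": p.tumor_id, "label": p.label,
                       "reconstruction_error": exposure.reconstruction_error}
                row.update({name: exposure.get(name) for name in matrix.names})
                rows.append(row)
            pd.DataFrame(rows).to_csv(outdir / "exposures.tsv", sep="\t", index=False)
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("signatures", exc) from exc
    else:
        logger.info("signatures stage skipped (no signature matrix or reference)")

    # --- compare ----------------------------------------------------------
    if config.clinical:
        try:
            clinical = read_clinical_table(config.clinical)
            table4 = build_group_comparison(profiles, clinical)
            table4.to_csv(outdir / "table4.tsv", sep="\t", index=False)
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("compare:clinical", exc) from exc
    else:
        logger.info("clinical comparison skipped (no clinical table)")
    if config.expression:
        try:
            records = expression_records_from_frame(
                pd.read_csv(config.expression, sep="\t")
            )
            labels = {p.tumor_id: p.label for p in profiles}
            present = {r.tumor_id for r in records}
            labels = {t: l for t, l in labels.items() if t in present}
            records = [r for r in records if r.tumor_id in labels]
            rows = []
            for gene in config.genes:
                try:
                    pvals = compare_expression_by_group(records, labels, gene)
                except ValueError as exc:
                    # e.g. a label group with no members in this cohort
                    logger.info("expression comparison for %s not computable: %s",
                                gene, exc)
                    pvals = {k: float("nan") for k in
                             ("NH_vs_CH", "NH_vs_PC", "CH_vs_PC")}
                rows.append({"gene": gene, **pvals})
            pd.DataFrame(rows).to_csv(
                outdir / "expression_comparison.tsv", sep="\t", index=False
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineStageError("compare:expression", exc) from exc
    else:
        logger.info("expression comparison skipped (no expression table)")

    # --- manifest ---------------------------------------------------------
    import numpy
    import scipy

    from poleclass import __version__

    config_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    outputs = {
        p.name: _sha256(p) for p in sorted(outdir.glob("*.tsv"))
    }
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "inputs_sha256": inputs,
        "outputs_sha256": outputs,
        "versions": {
            "poleclass": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
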