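"""Synthetic colorectal-tumor cohorts with the structure the analysis assumes.

The generator emulates three somatic mutational processes:

* a background process (nonhypermutators, ~93% of tumors) with a median of
  71 nonsynonymous SNVs and a C>T-dominated spectrum;
* a mismatch-repair-deficiency-like process (common-hypermutators, ~6%)
  with >500 nonsynonymous SNVs and an even more C>T-rich spectrum;
* a proofreading-deficiency-like process (POLE category, ~1%) with
  1,700-9,500 nonsynonymous SNVs, a C>A-heavy / C>G-poor spectrum, and a
  hotspot POLE exonuclease-domain protein change (P286R most often).

Around the variant calls it draws class-conditional clinical covariates
(younger, predominantly male POLE patients; right-sided MMR-deficient
common-hypermutators), immune-gene expression fold changes (PD-L1/PD-1
upshifted in both hypermutator classes, CD8A in the POLE class, CTLA-4
flat), per-variant QC metrics with a configurable fraction failing each
false-positive criterion, and a small random reference genome so that
trinucleotide contexts exist for signature analysis.

Everything is reproducible from the seed; truth labels are emitted
alongside the data so recovery can be scored without peeking elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from poleclass.classify import (
    AMINO_ACIDS,
    COMMON_HYPERMUTATOR,
    LABELS,
    NONHYPERMUTATOR,
    POLE_CATEGORY,
)
from poleclass.io_formats import (
    BASES,
    COMPLEMENT,
    SUBSTITUTION_CLASSES,
    ClinicalRecord,
    VariantCall,
    write_clinical_table,
    write_variants,
)
from poleclass.qc_filter import Blacklist, write_blacklist

IMMUNE_GENES = ("PD-L1", "PD-1", "CTLA-4", "CD8A")

PT_LEVELS = ("Tis", "T1", "T2", "T3", "T4")
PSTAGE_LEVELS = ("0", "I", "II", "III", "IV")


def _d(**kwargs):
    return field(default_factory=lambda: dict(kwargs))


@dataclass
class CohortSpec:
    """Parameters of a simulated cohort; defaults encode the study conditions.

    ``prevalence`` defaults to 92.6% / 6.3% / 1.1%; ``group_sizes`` (a map
    label -> count) overrides the random class draw with fixed group sizes.
    SNV counts refer to the nonsynonymous target per tumor; the total SNV
    count is that divided by ``nonsyn_ratio``.
    """

    n_tumors: int = 1000
    prevalence: dict = _d(nonhypermutator=0.926, common_hypermutator=0.063,
                          pole_category=0.011)
    group_sizes: dict | None = None
    nonsyn_ratio: float = 0.7
    # nonsynonymous SNV count distributions per class
    nh_count: dict = _d(median=71.0, sigma=0.7, max=450)
    ch_count: dict = _d(offset=650.0, median=550.0, sigma=0.6)
    pc_count: dict = _d(low=1700, high=9500)
    # six-class substitution spectra per class (PC's C>A is drawn per tumor)
    nh_spectrum: dict = _d(**{"C>A": 0.08, "C>G": 0.06, "C>T": 0.45,
                              "T>A": 0.07, "T>C": 0.27, "T>G": 0.07})
    ch_spectrum: dict = _d(**{"C>A": 0.08, "C>G": 0.06, "C>T": 0.55,
                              "T>A": 0.05, "T>C": 0.21, "T>G": 0.05})
    pc_c_to_a: tuple = (0.28, 0.45)
    pc_c_to_g: float = 0.01
    pc_rest: dict = _d(**{"C>T": 0.55, "T>A": 0.15, "T>C": 0.22, "T>G": 0.08})
    # clinical covariates per class
    clinical: dict = field(default_factory=lambda: {
        NONHYPERMUTATOR: dict(age_mean=66, age_sd=12, male=0.586, right=0.291,
                              poor=0.045, size_median=45, size_sigma=0.35,
                              pt=(0.005, 0.04, 0.18, 0.47, 0.305),
                              pstage=(0.005, 0.165, 0.295, 0.39, 0.145),
                              lvi=0.512, vi=0.663, mmr_tested=0.058, mmr_d=0.04),
        COMMON_HYPERMUTATOR: dict(age_mean=68, age_sd=12, male=0.509, right=0.719,
                                  poor=0.281, size_median=55, size_sigma=0.35,
                                  pt=(0.004, 0.04, 0.184, 0.47, 0.302),
                                  pstage=(0.0, 0.25, 0.417, 0.25, 0.083),
                                  lvi=0.614, vi=0.491, mmr_tested=0.368, mmr_d=1.0),
        POLE_CATEGORY: dict(age_mean=45, age_sd=12, male=0.90, right=0.40,
                            poor=0.20, size_median=60, size_sigma=0.35,
                            pt=(0.0, 0.04, 0.16, 0.5, 0.3),
                            pstage=(0.0, 0.3, 0.5, 0.18, 0.02),
                            lvi=0.40, vi=0.50, mmr_tested=0.60, mmr_d=0.0),
    })
    # immune-gene expression: log2 fold-change shifts by class, noise sd
    expression_shifts: dict = field(default_factory=lambda: {
        "PD-L1": {COMMON_HYPERMUTATOR: 2.5, POLE_CATEGORY: 2.5},
        "PD-1": {COMMON_HYPERMUTATOR: 2.5, POLE_CATEGORY: 2.5},
        "CTLA-4": {},
        "CD8A": {POLE_CATEGORY: 2.5},
    })
    expression_base: dict = _d(**{"PD-L1": 1.0, "PD-1": 0.5, "CTLA-4": 0.8,
                                  "CD8A": 2.0})
    fold_change_sd: float = 1.0
    normal_value_sd: float = 0.5
    gep_missing_rate: float = 0.02
    # POLE protein-change spec
    pole: dict = _d(p286r_prob=0.7, other_hotspots=("S297Y", "F367C", "V411L"),
                    passenger_rate={NONHYPERMUTATOR: 0.012, COMMON_HYPERMUTATOR: 0.16,
                                    POLE_CATEGORY: 0.0},
                    nonsense_frac=0.1, protein_length=2286, domain=(86, 427))
    # per-criterion fraction of variants carrying failing QC metrics
    qc_noise: dict = _d(**{"q1": 0.01, "q2": 0.01, "q3": 0.01, "q4": 0.01,
                           "q5": 0.01, "blacklist": 0.0})
    genome_contigs: int = 2
    contig_length: int = 60000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumors <= 0:
            raise ValueError("n_tumors must be positive")
        if abs(sum(self.prevalence.values()) - 1.0) > 1e-9:
            raise ValueError("prevalences must sum to 1")
        for name, spec in (("nh_spectrum", self.nh_spectrum),
                           ("ch_spectrum", self.ch_spectrum)):
            if set(spec) != set(SUBSTITUTION_CLASSES):
                raise ValueError(f"{name} must cover the six substitution classes")
            if abs(sum(spec.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} fractions must sum to 1")
            # background spectra must violate the POLE-category rule
            if spec["C>A"] > 0.20 and spec["C>G"] < 0.03:
                raise ValueError(f"{name} satisfies the POLE spectrum rule")
        lo, hi = self.pc_c_to_a
        if not (0.20 < lo <= hi < 1.0) or not (0.0 <= self.pc_c_to_g < 0.03):
            raise ValueError("POLE spectrum parameters must satisfy the "
                             "classification rule by construction")
        if not (0.0 < self.nonsyn_ratio <= 1.0):
            raise ValueError("nonsyn_ratio must be in (0, 1]")


def _pc_spectrum(spec: CohortSpec, rng: np.random.Generator) -> dict[str, float]:
    """Per-tumor POLE-like spectrum: C>A uniform in its band, C>G fixed low."""
    ca = float(rng.uniform(*spec.pc_c_to_a))
    cg = spec.pc_c_to_g
    rest = 1.0 - ca - cg
    rest_norm = sum(spec.pc_rest.values())
    out = {"C>A": ca, "C>G": cg}
    for cls, w in spec.pc_rest.items():
        out[cls] = rest * w / rest_norm
    return out


def _class_spectrum(spec: CohortSpec, label: str, rng: np.random.Generator) -> dict:
    if label == POLE_CATEGORY:
        return _pc_spectrum(spec, rng)
    return dict(spec.nh_spectrum if label == NONHYPERMUTATOR else spec.ch_spectrum)


def _draw_nonsyn_count(spec: CohortSpec, label: str, rng: np.random.Generator) -> int:
    if label == NONHYPERMUTATOR:
        p = spec.nh_count
        while True:
            c = rng.lognormal(np.log(p["median"]), p["sigma"])
            if c <= p["max"]:
                return max(1, int(round(c)))
    if label == COMMON_HYPERMUTATOR:
        p = spec.ch_count
        return int(round(p["offset"] + rng.lognormal(np.log(p["median"]), p["sigma"])))
    p = spec.pc_count
    return int(round(np.exp(rng.uniform(np.log(p["low"]), np.log(p["high"])))))


class _GenomeIndex:
    """Random reference genome with precomputed site lists by base family."""

    def __init__(self, genome: dict[str, str]):
        self.genome = genome
        self.contigs = list(genome)
        chrom_idx, pos, base = [], [], []
        for ci, (chrom, seq) in enumerate(genome.items()):
            arr = np.frombuffer(seq.encode(), dtype="S1")
            # interior positions only, so flanking bases always exist
            interior = np.arange(2, len(seq))  # 1-based pos in [2, L-1]
            chrom_idx.append(np.full(interior.size, ci))
            pos.append(interior)
            base.append(arr[interior - 1])
        chrom_idx = np.concatenate(chrom_idx)
        pos = np.concatenate(pos)
        base = np.concatenate(base)
        is_cg = (base == b"C") | (base == b"G")
        self.cg = (chrom_idx[is_cg], pos[is_cg], base[is_cg])
        self.at = (chrom_idx[~is_cg], pos[~is_cg], base[~is_cg])


def simulate_genome(rng: np.random.Generator, n_contigs: int = 2,
                    length: int = 60000) -> dict[str, str]:
    """Uniform-random reference contigs (synthetic; no genomic realism)."""
    return {
        f"chr{i + 1}": "".join(rng.choice(list(BASES), size=length))
        for i in range(n_contigs)
    }


def simulate_tumor_variants(
    tumor_id: str,
    label: str,
    n_snv: int,
    spectrum: Mapping[str, float],
    rng: np.random.Generator,
    genome_index: _GenomeIndex,
    spec: CohortSpec,
    blacklist_sink: set | None = None,
) -> list[VariantCall]:
    """Draw exactly ``n_snv`` SNV calls for one tumor.

    Substitution classes are multinomial at the class spectrum, positions
    uniform over genome sites of the matching base family (both strands
    represented), consequences ~70% nonsynonymous, and QC metrics sampled
    so that the configured noise fraction fails each filter criterion.
    """
    if n_snv == 0:
        return []
    probs = np.array([spectrum[c] for c in SUBSTITUTION_CLASSES])
    if abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
        raise ValueError("spectrum fractions must be nonnegative and sum to 1")
    classes = rng.choice(6, size=n_snv, p=probs)
    is_c_class = classes < 3

    chroms = np.empty(n_snv, dtype=object)
    positions = np.empty(n_snv, dtype=int)
    refs = np.empty(n_snv, dtype="U1")
    for family, mask in ((genome_index.cg, is_c_class), (genome_index.at, ~is_c_class)):
        k = int(mask.sum())
        if k == 0:
            continue
        idx = rng.integers(0, family[0].size, size=k)
        chroms[mask] = np.array(genome_index.contigs, dtype=object)[family[0][idx]]
        positions[mask] = family[1][idx]
        refs[mask] = family[2][idx].astype("U1")

    qc = spec.qc_noise
    fail = {c: rng.random(n_snv) < qc[f"q{c}"] for c in (1, 2, 3, 4, 5)}
    quality = 60.0 + rng.exponential(120.0, n_snv)
    quality[fail[1]] = rng.uniform(0.0, 59.9, int(fail[1].sum()))
    fwd = 1 + rng.poisson(10, n_snv)
    rev = 1 + rng.poisson(10, n_snv)
    depth = fwd + rev + 20 + rng.poisson(60, n_snv)
    k2 = int(fail[2].sum())
    if k2:
        d2 = rng.integers(2, 20, k2)
        depth[fail[2]] = d2
        fwd[fail[2]] = 1
        rev[fail[2]] = rng.integers(1, d2)
    rev[fail[3]] = 0
    acl = rng.uniform(100.0, 220.0, n_snv)
    acl[fail[4]] = rng.uniform(10.0, 99.9, int(fail[4].sum()))
    apf = rng.uniform(0.05, 0.95, n_snv)
    apf[fail[5]] = rng.uniform(0.0, 0.0499, int(fail[5].sum()))
    nonsyn = rng.random(n_snv) < spec.nonsyn_ratio
    blacklisted = rng.random(n_snv) < qc.get("blacklist", 0.0)

    variants = []
    for i in range(n_snv):
        cls = SUBSTITUTION_CLASSES[classes[i]]
        pyr_ref, pyr_alt = cls[0], cls[2]
        ref = refs[i]
        alt = pyr_alt if ref == pyr_ref else COMPLEMENT[pyr_alt]
        v = VariantCall(
            tumor_id=tumor_id,
            chrom=chroms[i],
            pos=int(positions[i]),
            ref=ref,
            alt=alt,
            quality=round(float(quality[i]), 2),
            depth=int(depth[i]),
            var_reads_fwd=int(fwd[i]),
            var_reads_rev=int(rev[i]),
            avg_clipped_length=round(float(acl[i]), 2),
            avg_pos_as_fraction=round(float(apf[i]), 4),
            consequence="nonsynonymous_SNV" if nonsyn[i] else "synonymous_SNV",
        )
        if blacklisted[i] and blacklist_sink is not None:
            blacklist_sink.add(v.key)
        variants.append(v)
    return variants


def _draw_pole_change(spec: CohortSpec, label: str, rng: np.random.Generator) -> str | None:
    p = spec.pole
    lo, hi = p["domain"]
    if label == POLE_CATEGORY:
        if rng.random() < p["p286r_prob"]:
            return "P286R"
        return str(rng.choice(list(p["other_hotspots"])))
    if rng.random() >= p["passenger_rate"][label]:
        return None
    # passenger change outside the exonuclease domain
    while True:
        residue = int(rng.integers(1, p["protein_length"] + 1))
        if not (lo <= residue <= hi):
            break
    ref_aa = str(rng.choice(list(AMINO_ACIDS)))
    if rng.random() < p["nonsense_frac"]:
        alt_aa = "*"
    else:
        alt_aa = ref_aa
        while alt_aa == ref_aa:
            alt_aa = str(rng.choice(list(AMINO_ACIDS)))
    return f"{ref_aa}{residue}{alt_aa}"


def _attach_pole_change(variants: list[VariantCall], change: str) -> None:
    for v in variants:
        if v.consequence == "nonsynonymous_SNV":
            v.gene = "POLE"
            v.protein_change = change
            if change.endswith("*"):
                v.consequence = "nonsense"
            return
    if variants:  # tumor with no nonsynonymous call; tag the first record
        variants[0].gene = "POLE"
        variants[0].protein_change = change


def _draw_clinical(spec: CohortSpec, tumor_id: str, label: str,
                   rng: np.random.Generator) -> ClinicalRecord:
    p = spec.clinical[label]
    age = int(np.clip(round(rng.normal(p["age_mean"], p["age_sd"])), 20, 93))
    size = int(np.clip(round(rng.lognormal(np.log(p["size_median"]), p["size_sigma"])),
                       14, 158))
    if rng.random() < p["mmr_tested"]:
        mmr = "MMR_D" if rng.random() < p["mmr_d"] else "MMR_P"
    else:
        mmr = "unknown"
    return ClinicalRecord(
        tumor_id=tumor_id,
        age=age,
        sex="man" if rng.random() < p["male"] else "woman",
        location="right" if rng.random() < p["right"] else "left",
        histology="por_or_muc" if rng.random() < p["poor"] else "well_or_mod",
        tumor_size_mm=size,
        pT=str(rng.choice(PT_LEVELS, p=np.array(p["pt"]) / sum(p["pt"]))),
        pStage=str(rng.choice(PSTAGE_LEVELS, p=np.array(p["pstage"]) / sum(p["pstage"]))),
        lymphatic_invasion=bool(rng.random() < p["lvi"]),
        vessel_invasion=bool(rng.random() < p["vi"]),
        mmr_status=mmr,
    )


def simulate_expression(
    labels: Mapping[str, str],
    spec: CohortSpec,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Immune-gene expression table for labeled tumors.

    Normalized log2 values for tumor and patient-matched normal tissue;
    the fold change is their difference, shifted by the class effect for
    the affected genes. A small fraction of tumors has no expression data
    (profiling occasionally fails on real cohorts).
    """
    rows = []
    for tumor_id, label in labels.items():
        if rng.random() < spec.gep_missing_rate:
            continue
        for gene in IMMUNE_GENES:
            shift = spec.expression_shifts[gene].get(label, 0.0)
            normal = rng.normal(spec.expression_base[gene], spec.normal_value_sd)
            fold = shift + rng.normal(0.0, spec.fold_change_sd)
            rows.append({
                "tumor_id": tumor_id, "gene": gene,
                "tumor_value": round(normal + fold, 4),
                "normal_value": round(normal, 4),
                "fold_change": round(fold, 4),
            })
    return pd.DataFrame(rows, columns=["tumor_id", "gene", "tumor_value",
                                       "normal_value", "fold_change"])


@dataclass
class SimulatedCohort:
    """Full simulated cohort plus the latent truth behind it."""

    spec: CohortSpec
    genome: dict[str, str]
    variants: dict[str, list[VariantCall]]
    blacklist: Blacklist
    clinical: list[ClinicalRecord]
    expression: pd.DataFrame
    truth: pd.DataFrame

    def truth_labels(self) -> dict[str, str]:
        return dict(zip(self.truth["tumor_id"], self.truth["label"]))

    def write(self, outdir: str | Path) -> None:
        """Write VCFs, clinical/expression/truth tables, genome, blacklist."""
        outdir = Path(outdir)
        (outdir / "variants").mkdir(parents=True, exist_ok=True)
        with open(outdir / "genome.fa", "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        for tumor_id, calls in self.variants.items():
            write_variants(calls, outdir / "variants" / f"{tumor_id}.vcf")
        write_clinical_table(self.clinical, outdir / "clinical.tsv")
        self.expression.to_csv(outdir / "expression.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        write_blacklist(self.blacklist, outdir / "blacklist.tsv")


def simulate_cohort(spec: CohortSpec) -> SimulatedCohort:
    """Generate a cohort: variants, clinical, expression, and truth labels.

    Fully reproducible from ``spec.seed``. Class assignments come from the
    prevalence draw (or fixed ``group_sizes``); per tumor, the
    nonsynonymous SNV target, spectrum, variants with QC metrics, clinical
    covariates, POLE protein changes and expression values are drawn from
    class-conditional distributions.
    """
    rng = np.random.default_rng(spec.seed)
    genome = simulate_genome(rng, spec.genome_contigs, spec.contig_length)
    index = _GenomeIndex(genome)

    if spec.group_sizes is not None:
        labels_list = [g for g, k in spec.group_sizes.items() for _ in range(k)]
        if len(labels_list) != spec.n_tumors:
            raise ValueError("group_sizes must sum to n_tumors")
        rng.shuffle(labels_list)
    else:
        labels_list = [
            str(g) for g in rng.choice(LABELS, size=spec.n_tumors,
                                       p=[spec.prevalence[g] for g in LABELS])
        ]

    variants: dict[str, list[VariantCall]] = {}
    clinical: list[ClinicalRecord] = []
    truth_rows = []
    blacklist_sink: set = set()
    label_map: dict[str, str] = {}
    for i, label in enumerate(labels_list):
        tumor_id = f"T{i + 1:04d}"
        label_map[tumor_id] = label
        target_nonsyn = _draw_nonsyn_count(spec, label, rng)
        n_total = max(1, int(round(target_nonsyn / spec.nonsyn_ratio)))
        spectrum = _class_spectrum(spec, label, rng)
        calls = simulate_tumor_variants(
            tumor_id, label, n_total, spectrum, rng, index, spec, blacklist_sink
        )
        change = _draw_pole_change(spec, label, rng)
        if change:
            _attach_pole_change(calls, change)
        variants[tumor_id] = calls
        clinical.append(_draw_clinical(spec, tumor_id, label, rng))
        truth_rows.append({
            "tumor_id": tumor_id,
            "label": label,
            "target_nonsyn_count": target_nonsyn,
            "n_snv_total": n_total,
            "c_to_a": round(spectrum["C>A"], 4),
            "c_to_g": round(spectrum["C>G"], 4),
            "pole_change": change or "",
        })
    expression = simulate_expression(label_map, spec, rng)
    return SimulatedCohort(
        spec=spec,
        genome=genome,
        variants=variants,
        blacklist=Blacklist.from_iterable(sorted(blacklist_sink)),
        clinical=clinical,
        expression=expression,
        truth=pd.DataFrame(truth_rows),
    )
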