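"""Mutational-signature refitting over the 96 trinucleotide contexts.

A tumor's mutation catalog (counts per pyrimidine-centered trinucleotide
substitution context) is expressed as a nonnegative convex combination of
fixed reference signatures. The estimator mirrors the widely used
refitting scheme of forward signature selection with a small-weight
cutoff:

1. normalize the catalog to a 96-fraction vector ``f``;
2. starting from the empty signature set, repeatedly add the signature
   whose inclusion most reduces the sum-of-squares reconstruction error
   of ``f`` under nonnegative weights summing to one (each candidate set
   is fitted by nonnegative least squares followed by simplex
   normalization);
3. stop when the relative error improvement drops below ``rel_tol``
   (default 1e-3);
4. discard signatures with weight below ``cutoff`` (default 0.06) and
   renormalize the remaining weights.

The procedure is deterministic given its inputs and invariant to scaling
the catalog counts. :func:`exhaustive_refit` fits every signature subset
up to a size bound with the same per-subset fit and serves as an
independent selection oracle for small signature banks.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import nnls

from poleclass.classify import COMMON_HYPERMUTATOR, POLE_CATEGORY
from poleclass.io_formats import (
    BASES,
    CANONICAL_CONTEXTS,
    COMPLEMENT,
    CONTEXT_INDEX,
    SignatureMatrix,
    VariantCall,
)

logger = logging.getLogger(__name__)


@dataclass
class Catalog96:
    """Mutation counts of one tumor over the 96 canonical contexts."""

    tumor_id: str
    counts: np.ndarray
    n_skipped: int = 0  # variants without usable context (edges, non-SNVs)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (96,):
            raise ValueError(f"counts must have length 96, got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("catalog counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def fractions(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("empty catalog has no fractions")
        return self.counts / self.total


class ReferenceContext:
    """Flanking-base lookup for (chrom, 1-based pos) against a reference.

    Construct from an in-memory mapping of contig name to sequence, or from
    a FASTA file (indexed lazily through :mod:`pyfaidx`).
    """

    def __init__(self, fetch: Callable[[str, int], str | None]):
        self._fetch = fetch

    @classmethod
    def from_dict(cls, sequences: Mapping[str, str]) -> "ReferenceContext":
        upper = {c: s.upper() for c, s in sequences.items()}

        def fetch(chrom: str, pos: int) -> str | None:
            seq = upper.get(chrom)
            if seq is None or not (1 <= pos <= len(seq)):
                return None
            return seq[pos - 1]

        return cls(fetch)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceContext":
        import pyfaidx

        fasta = pyfaidx.Fasta(str(path), rebuild=True)

        def fetch(chrom: str, pos: int) -> str | None:
            if chrom not in fasta:
                return None
            if not (1 <= pos <= len(fasta[chrom])):
                return None
            return str(fasta[chrom][pos - 1]).upper()

        return cls(fetch)

    def flanks(self, chrom: str, pos: int) -> tuple[str, str] | None:
        """The bases immediately 5' and 3' of ``pos``, or None at an edge."""
        left = self._fetch(chrom, pos - 1)
        right = self._fetch(chrom, pos + 1)
        if left is None or right is None or left not in BASES or right not in BASES:
            return None
        return left, right


def context_label(ref: str, alt: str, left: str, right: str) -> str:
    """Canonical pyrimidine-strand context label for one substitution.

    Purine-reference substitutions are reverse-complemented together with
    their flanks, so a G>T with 5' T and 3' G becomes ``C[C>A]A``.
    """
    ref, alt = ref.upper(), alt.upper()
    left, right = left.upper(), right.upper()
    if ref in "AG":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        left, right = COMPLEMENT[right], COMPLEMENT[left]
    return f"{left}[{ref}>{alt}]{right}"


def build_catalog(
    variants: Sequence[VariantCall],
    context_source: ReferenceContext,
    tumor_id: str | None = None,
) -> Catalog96:
    """Build the 96-context catalog of a tumor's SNVs.

    Non-SNV records and SNVs whose flanking bases are unavailable (contig
    edge, unknown contig, ambiguous base) are skipped with a warning count.
    """
    counts = np.zeros(96, dtype=int)
    skipped = 0
    tid = tumor_id
    for v in variants:
        if tid is None:
            tid = v.tumor_id
        if not v.is_snv:
            skipped += 1
            continue
        flanks = context_source.flanks(v.chrom, v.pos)
        if flanks is None:
            logger.warning("no flanking context for %s:%d; variant skipped", v.chrom, v.pos)
            skipped += 1
            continue
        counts[CONTEXT_INDEX[context_label(v.ref, v.alt, *flanks)]] += 1
    return Catalog96(tumor_id=tid or "", counts=counts, n_skipped=skipped)


@dataclass
class ExposureVector:
    """Estimated signature exposures of one catalog.

    ``weights`` maps kept signature names to weights in [0, 1] summing to 1;
    ``reconstruction_error`` is the sum of squared differences between the
    catalog's fraction vector and its reconstruction.
    """

    weights: dict[str, float]
    reconstruction_error: float

    def get(self, name: str) -> float:
        return self.weights.get(name, 0.0)


def _fit_subset(f: np.ndarray, columns: np.ndarray) -> tuple[np.ndarray, float]:
    """Nonnegative least squares on the subset, normalized onto the simplex."""
    w, _ = nnls(columns, f)
    s = w.sum()
    if s <= 0:
        # degenerate: fall back to uniform weights on the subset
        w = np.full(columns.shape[1], 1.0 / columns.shape[1])
    else:
        w = w / s
    resid = f - columns @ w
    return w, float(resid @ resid)


def refit_exposures(
    catalog: Catalog96,
    signatures: SignatureMatrix,
    cutoff: float = 0.06,
    rel_tol: float = 1e-3,
    min_total: int = 50,
) -> ExposureVector:
    """Estimate signature exposures by forward selection with a weight cutoff.

    Parameters
    ----------
    catalog
        Mutation catalog; must contain at least ``min_total`` mutations
        (refitting is unstable on sparse catalogs — only hypermutated
        tumors are usually refit).
    signatures
        Reference signature matrix (unique names, convex columns).
    cutoff
        Signatures with final weight below this are discarded and the rest
        renormalized. Default 0.06, the conventional refitting default.
    rel_tol
        Forward selection stops when the relative reduction of the
        reconstruction error falls below this.
    """
    if not (0.0 <= cutoff < 1.0):
        raise ValueError(f"cutoff must be in [0, 1), got {cutoff}")
    if catalog.total == 0:
        raise ValueError("cannot refit an empty catalog")
    if catalog.total < min_total:
        raise ValueError(
            f"catalog has {catalog.total} mutations, fewer than min_total={min_total}; "
            "pass min_total explicitly to override"
        )
    f = catalog.fractions()
    W = signatures.weights
    chosen: list[int] = []
    remaining = list(range(signatures.k))
    err = float(f @ f)  # error of the empty reconstruction
    weights = np.zeros(0)
    while remaining:
        best = None
        for j in remaining:
            cols = W[:, chosen + [j]]
            w, e = _fit_subset(f, cols)
            if best is None or e < best[1]:
                best = (j, e, w)
        j, new_err, w = best
        # the first signature is always accepted; later ones only if they
        # still improve the reconstruction meaningfully
        improvement = (err - new_err) / err if err > 0 else 0.0
        if chosen and improvement < rel_tol:
            break
        chosen.append(j)
        remaining.remove(j)
        weights = w
        err = new_err
        if err <= 1e-15:
            break
    keep = [(j, wj) for j, wj in zip(chosen, weights) if wj >= cutoff]
    if not keep:  # everything fell under the cutoff; keep the largest
        jmax = int(np.argmax(weights))
        keep = [(chosen[jmax], weights[jmax])]
    idx = [j for j, _ in keep]
    kept_w = np.array([wj for _, wj in keep])
    kept_w = kept_w / kept_w.sum()
    resid = f - W[:, idx] @ kept_w
    return ExposureVector(
        weights={signatures.names[j]: float(w) for j, w in zip(idx, kept_w)},
        reconstruction_error=float(resid @ resid),
    )


def exhaustive_refit(
    catalog: Catalog96,
    signatures: SignatureMatrix,
    cutoff: float = 0.06,
    max_subset: int = 3,
    min_total: int = 50,
) -> ExposureVector:
    """Fit every signature subset up to ``max_subset`` and keep the best.

    Uses the same per-subset constrained fit as :func:`refit_exposures`;
    intended as a selection oracle for small signature banks, exponential
    in the bank size.
    """
    if catalog.total == 0:
        raise ValueError("cannot refit an empty catalog")
    if catalog.total < min_total:
        raise ValueError(f"catalog has {catalog.total} mutations, fewer than {min_total}")
    f = catalog.fractions()
    W = signatures.weights
    best: tuple[float, tuple[int, ...], np.ndarray] | None = None
    for size in range(1, max_subset + 1):
        for subset in itertools.combinations(range(signatures.k), size):
            w, e = _fit_subset(f, W[:, subset])
            if best is None or e < best[0] - 1e-12:
                best = (e, subset, w)
    e, subset, w = best
    keep = [(j, wj) for j, wj in zip(subset, w) if wj >= cutoff]
    if not keep:
        jmax = int(np.argmax(w))
        keep = [(subset[jmax], w[jmax])]
    idx = [j for j, _ in keep]
    kept_w = np.array([wj for _, wj in keep])
    kept_w = kept_w / kept_w.sum()
    resid = f - W[:, idx] @ kept_w
    return ExposureVector(
        weights={signatures.names[j]: float(wj) for j, wj in zip(idx, kept_w)},
        reconstruction_error=float(resid @ resid),
    )


@dataclass
class SignatureGroupComparison:
    """Per-group exposure scores of one signature plus a rank test."""

    signature: str
    groups: tuple[str, str]
    scores: dict[str, list[float]]
    u_statistic: float
    p_value: float


def signature_score_by_group(
    exposures: Sequence[tuple[str, ExposureVector]],
    labels: Mapping[str, str],
    signature: str,
    groups: tuple[str, str] = (COMMON_HYPERMUTATOR, POLE_CATEGORY),
) -> SignatureGroupComparison:
    """Compare one signature's exposure between two tumor groups.

    Tumors whose label is not one of ``groups`` are ignored; a tumor with
    no label at all is an error, as is an empty group. The two-sided
    p-value comes from the Mann-Whitney U test.
    """
    from poleclass.cohort_stats import mann_whitney_u

    scores: dict[str, list[float]] = {g: [] for g in groups}
    for tumor_id, exposure in exposures:
        if tumor_id not in labels:
            raise ValueError(f"tumor {tumor_id!r} has no label")
        label = labels[tumor_id]
        if label in scores:
            scores[label].append(exposure.get(signature))
    for g in groups:
        if not scores[g]:
            raise ValueError(f"group {g!r} has no members")
    u, p = mann_whitney_u(scores[groups[0]], scores[groups[1]])
    return SignatureGroupComparison(
        signature=signature, groups=groups, scores=scores, u_statistic=u, p_value=p
    )
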