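"""Packaged reference data and synthetic fixtures.

Two small tables from a published 910-tumor colorectal whole-exome cohort
ship with the package:

* the 27 POLE-mutant cases (protein change, mutation type,
  exonuclease-domain membership, nonsynonymous SNV count, classification),
  used to validate the domain annotation and the hypermutator rule against
  independently reported calls;
* per-group clinicopathological counts for the three tumor classes
  (843 nonhypermutators / 57 common-hypermutators / 10 POLE category),
  from which the 2x2 contingency tables for exact Fisher testing are
  assembled.

:func:`synthetic_signature_bank` builds a deterministic random reference
signature matrix for refitting tests — it is synthetic and carries no
relation to real mutational processes.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from poleclass.cohort_stats import ContingencyTable2x2
from poleclass.io_formats import SignatureMatrix


def _read_packaged(name: str) -> pd.DataFrame:
    with resources.files("poleclass.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def load_pole_case_table() -> pd.DataFrame:
    """The 27 reported POLE-mutant cases of the reference cohort."""
    df = _read_packaged("pole_case_table.tsv")
    df["exonuclease_domain"] = df["exonuclease_domain"].map({"yes": True, "no": False})
    return df


def load_cohort_group_counts() -> pd.DataFrame:
    """Per-group clinicopathological counts of the reference cohort."""
    return _read_packaged("cohort_group_counts.tsv")


def cohort_comparison_tables() -> dict[str, dict[str, ContingencyTable2x2]]:
    """2x2 tables per variable for the NH-vs-PC and CH-vs-PC comparisons.

    Rows are the two category levels, columns the two groups being
    compared (nonhypermutators or common-hypermutators vs POLE category).
    """
    counts = load_cohort_group_counts()
    out: dict[str, dict[str, ContingencyTable2x2]] = {}
    for variable, sub in counts.groupby("variable", sort=False):
        sub = sub.reset_index(drop=True)
        if len(sub) != 2:
            raise ValueError(f"variable {variable!r} must have exactly two levels")
        out[variable] = {
            "NH_vs_PC": ContingencyTable2x2(
                int(sub.loc[0, "nonhypermutator"]), int(sub.loc[0, "pole_category"]),
                int(sub.loc[1, "nonhypermutator"]), int(sub.loc[1, "pole_category"]),
            ),
            "CH_vs_PC": ContingencyTable2x2(
                int(sub.loc[0, "common_hypermutator"]), int(sub.loc[0, "pole_category"]),
                int(sub.loc[1, "common_hypermutator"]), int(sub.loc[1, "pole_category"]),
            ),
        }
    return out


def synthetic_signature_bank(k: int = 4, seed: int = 12345,
                             concentration: float = 0.3) -> SignatureMatrix:
    """Deterministic synthetic 96 x k signature matrix (Dirichlet columns).

    A low ``concentration`` makes columns sparse and mutually distinct, so
    mixtures of them are identifiable in refitting tests.
    """
    rng = np.random.default_rng(seed)
    weights = rng.dirichlet(np.full(96, concentration), size=k).T
    names = tuple(f"SynthSig{i + 1}" for i in range(k))
    return SignatureMatrix(names=names, weights=weights)
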