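"""Trio-shared / proband-unique gene-set logic and the cross-model
direction-consistent input-gene-set construction.

"Trio-shared" genes are DEGs in both the proband-vs-HC and parent-vs-HC
contrasts; "proband-unique" genes are DEGs only in the proband contrast.
The input-gene-set construction intersects the coding DEGs of two
proband-vs-HC contrasts from different cellular models, narrows to genes
also differentially expressed in a parent-vs-HC contrast, and finally keeps
only genes whose fold-change direction agrees between the two models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ValidationError

logger = logging.getLogger("triomics")

CODING_LOCUS_TYPES = ("coding", "multiple_complex")


def _deg_set(de: pd.DataFrame) -> set:
    return set(de.loc[de["is_deg"], "gene_id"])


def _directions(de: pd.DataFrame) -> pd.Series:
    return de.set_index("gene_id")["direction"]


@dataclass
class DEGSetFamily:
    """Partition of two contrasts' DEG sets with per-gene directions."""

    shared: set
    a_unique: set
    b_unique: set
    directions_a: pd.Series
    directions_b: pd.Series

    @property
    def counts(self) -> dict:
        return {"shared": len(self.shared), "a_unique": len(self.a_unique),
                "b_unique": len(self.b_unique)}


def venn_partition(deA: pd.DataFrame, deB: pd.DataFrame) -> DEGSetFamily:
    """Partition DEGs of two results on the same gene universe."""
    ua, ub = set(deA["gene_id"]), set(deB["gene_id"])
    if ua != ub:
        raise ValidationError(
            f"gene universes differ: only-A={sorted(ua - ub)[:5]}, "
            f"only-B={sorted(ub - ua)[:5]}")
    a, b = _deg_set(deA), _deg_set(deB)
    fam = DEGSetFamily(a & b, a - b, b - a, _directions(deA), _directions(deB))
    logger.info("venn partition: shared=%d, A-unique=%d, B-unique=%d",
                *fam.counts.values())
    return fam


def build_input_gene_set(de_model1_proband: pd.DataFrame,
                         de_model2_proband: pd.DataFrame,
                         de_parent: pd.DataFrame,
                         coding_only: bool = True,
                         locus_type: pd.Series | None = None,
                         ) -> tuple[pd.DataFrame, tuple[int, int, int]]:
    """Direction-consistent cross-model gene set.

    Step 1: intersect the (coding) DEGs of the two proband contrasts;
    step 2: intersect with the parent-contrast DEGs;
    step 3: keep genes whose direction agrees between the two models.

    Returns the final table (gene_id, direction, log2fc in both models) and
    the three intermediate counts.
    """
    d1, d2, dp = _deg_set(de_model1_proband), _deg_set(de_model2_proband), \
        _deg_set(de_parent)
    if coding_only:
        if locus_type is None:
            raise ValidationError("coding_only=True requires locus_type")
        coding = set(locus_type.index[locus_type.isin(CODING_LOCUS_TYPES)])
        d1, d2 = d1 & coding, d2 & coding
    step1 = d1 & d2
    step2 = step1 & dp
    dir1 = _directions(de_model1_proband)
    dir2 = _directions(de_model2_proband)
    step3 = {g for g in step2 if dir1[g] == dir2[g]}
    counts = (len(step1), len(step2), len(step3))
    if not step3:
        logger.warning("input gene set is empty (intermediates %s)", counts)
    else:
        logger.info("input gene set: intermediates %s", counts)
    fc1 = de_model1_proband.set_index("gene_id")["log2fc"]
    fc2 = de_model2_proband.set_index("gene_id")["log2fc"]
    genes = sorted(step3)
    table = pd.DataFrame({"gene_id": genes,
                          "direction": [dir1[g] for g in genes],
                          "log2fc_model1": [fc1[g] for g in genes],
                          "log2fc_model2": [fc2[g] for g in genes]})
    return table, counts


def overlap_with_annotated(setA: pd.DataFrame, annotated: pd.DataFrame,
                           flip_sign_a: bool = False
                           ) -> tuple[pd.DataFrame, float, float]:
    """Overlap two gene sets carrying log2 fold changes; correlate the pair.

    Both inputs are tables with columns ``gene_id`` and ``log2fc``.  Gene IDs
    are matched case-insensitively.  ``flip_sign_a`` negates set A's fold
    changes (the reversed-for-display convention).  Returns the overlap table
    and the Pearson (r, p) of the paired fold changes; with fewer than 3
    overlapping genes r and p are NaN.
    """
    if len(setA) == 0 or len(annotated) == 0:
        raise ValidationError("both gene sets must be nonempty")
    a = setA.assign(_key=setA["gene_id"].str.upper())
    b = annotated.assign(_key=annotated["gene_id"].str.upper())
    merged = a.merge(b, on="_key", suffixes=("_a", "_b"))
    fc_a = merged["log2fc_a"].to_numpy(dtype=float)
    if flip_sign_a:
        fc_a = -fc_a
    table = pd.DataFrame({"gene_id": merged["gene_id_a"],
                          "log2fc_a": fc_a,
                          "log2fc_b": merged["log2fc_b"].to_numpy(dtype=float)})
    if len(table) < 3:
        return table, float("nan"), float("nan")
    r, p = stats.pearsonr(table["log2fc_a"], table["log2fc_b"])
    return table, float(r), float(p)
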