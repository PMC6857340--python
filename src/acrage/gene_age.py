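"""Evolutionary ages of protein-coding genes and expression-by-age summaries.

Gene ages come from a homolog presence/absence matrix (gene x species:
whether a similar sequence exists in that species' genome).  A gene's age is
the MRCA category of all species carrying a homolog, exactly as for ACRs;
genes whose presence pattern implies secondary loss can be excluded.  The
per-stage percentage of summed expression per age category is the gene-level
counterpart of the relative accessibility table and serves as the negative
control: repeated re-deployment of old genes at late stages obscures any
recapitulative ordering at the gene level.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .phylo import STRICT, PhyloTree
from .evo_age import classify_conservation
from .recap import RelativeTable, _percentages


def gene_ages(
    presence: pd.DataFrame,
    tree: PhyloTree,
    exclude_secondary_loss: bool = True,
) -> pd.DataFrame:
    """Age category per gene from the homolog presence/absence matrix.

    ``presence`` is indexed by gene id with one boolean (or 0/1) column per
    non-reference species; a reference column, if present, is ignored (the
    reference trivially carries each of its own genes).  With
    ``exclude_secondary_loss``, genes whose presence set is not exactly the
    clade of its MRCA are flagged ``excluded``.
    """
    species = [c for c in presence.columns if c != tree.reference]
    unknown = set(species) - set(tree.nonreference_leaves)
    if unknown:
        raise ValueError(f"presence matrix has species not in the tree: {sorted(unknown)}")
    mat = presence[species].astype(bool)
    rows = []
    for gene, row in mat.iterrows():
        present = frozenset(sp for sp in species if row[sp])
        cat = tree.mrca_category(present)
        status = classify_conservation(present, tree)
        rows.append(
            {
                "gene_id": gene,
                "category": cat.node_id,
                "rank": cat.rank,
                "age_my": cat.age,
                "status": status,
                "excluded": bool(exclude_secondary_loss and status != STRICT),
            }
        )
    return pd.DataFrame(rows)


def expressed_gene_counts(
    expression: pd.DataFrame,
    ages: pd.DataFrame,
    fpkm_threshold: float = 1.0,
) -> pd.DataFrame:
    """Counts of expressed genes (FPKM strictly above threshold) per stage/category.

    ``expression`` is a long table (gene_id, stage[, replicate], fpkm); with
    replicates present, the replicate-mean FPKM per gene and stage is
    compared against the threshold.
    """
    expr = expression.copy()
    if "replicate" in expr.columns:
        expr = expr.groupby(["gene_id", "stage"], sort=True)["fpkm"].mean().reset_index()
    use = ages[~ages["excluded"]][["gene_id", "category", "rank"]]
    merged = expr.merge(use, on="gene_id", how="inner")
    merged = merged[merged["fpkm"] > fpkm_threshold]
    out = (
        merged.groupby(["stage", "category", "rank"], sort=True)
        .size()
        .reset_index(name="n_expressed")
    )
    return out


def relative_expression_table(
    expression: pd.DataFrame,
    ages: pd.DataFrame,
    stages: Sequence[str],
    expressed_only: bool = False,
    fpkm_threshold: float = 1.0,
) -> RelativeTable:
    """Percentage of summed FPKM per age category, per stage and replicate.

    All genes contribute by default; ``expressed_only`` restricts the sums to
    genes above the FPKM threshold in the given stage/replicate.  Excluded
    (secondary-loss) genes never contribute.
    """
    expr = expression.copy()
    if "replicate" not in expr.columns:
        expr["replicate"] = "pooled"
    use = ages[~ages["excluded"]][["gene_id", "category", "rank"]]
    merged = expr.merge(use, on="gene_id", how="inner")
    if expressed_only:
        merged = merged[merged["fpkm"] > fpkm_threshold]
    sums = (
        merged.groupby(["stage", "replicate", "category", "rank"], sort=True)["fpkm"]
        .sum()
        .reset_index()
        .rename(columns={"fpkm": "value"})
    )
    return RelativeTable(
        _percentages(sums, stages, "expression").data, "expression", tuple(stages)
    )
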