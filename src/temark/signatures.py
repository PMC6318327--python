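"""2C-like gene-expression program analysis.

Builds the top-N (default 200) 2C-vs-ESC fold-change gene signature,
scores knockdown expression against it (Mann-Whitney vs background
genes), runs the reverse direction (knockdown-upregulated genes measured
across reference stages), and annotates genes with MERVL proximity and
strand orientation — the hallmark of the totipotent 2-cell-like state
where MERVL elements splice into nearby same-strand genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import TETypeCatalog

__all__ = [
    "GeneSignature",
    "build_signature",
    "score_signature",
    "reverse_signature",
    "annotate_mervl_proximal_genes",
]

MERVL_TYPES = ("MERVL-int", "MT2_Mm")


@dataclass
class GeneSignature:
    """Ordered gene list with reference fold-changes (descending)."""

    genes: list[str]
    fold_changes: pd.Series  # indexed by gene, sorted descending
    provenance: str = ""

    def __post_init__(self) -> None:
        fc = self.fold_changes
        if list(fc.index) != self.genes:
            raise ValueError("fold_changes must be indexed by the signature genes, in order")
        if not fc.is_monotonic_decreasing:
            raise ValueError("signature fold-changes must be sorted descending")

    def __len__(self) -> int:
        return len(self.genes)

    def to_tsv(self, path: str) -> None:
        self.fold_changes.rename("fold_change").rename_axis("gene_id").to_csv(path, sep="\t")


def build_signature(
    expr_table: pd.DataFrame,
    reference: str = "twoC",
    baseline: str = "esc",
    n: int = 200,
    pseudocount: float = 1.0,
) -> GeneSignature:
    """Top-``n`` genes by reference-over-baseline fold-change.

    Only upregulated genes (fold > 1) qualify; ties at the boundary are
    broken deterministically by gene id (ascending).  If fewer than ``n``
    genes are upregulated, all of them are returned with a warning.
    """
    for col in (reference, baseline):
        if col not in expr_table.columns:
            raise KeyError(f"expression table lacks column {col!r}")
    fold = (expr_table[reference] + pseudocount) / (expr_table[baseline] + pseudocount)
    up = fold[fold > 1.0]
    # sort by fold descending, gene id ascending for ties
    ordered = up.to_frame("fold").rename_axis("gene").reset_index()
    ordered = ordered.sort_values(["fold", "gene"], ascending=[False, True], kind="stable")
    if len(ordered) < n:
        warnings.warn(f"only {len(ordered)} upregulated genes available (requested {n})")
    top = ordered.head(n)
    fc = pd.Series(top["fold"].values, index=top["gene"].values)
    return GeneSignature(genes=list(fc.index), fold_changes=fc, provenance=f"{reference}_vs_{baseline}_top{n}")


@dataclass
class SignatureScore:
    median_log2fc: float
    mean_log2fc: float
    p: float  # one-sided Mann-Whitney, signature > background
    n_signature: int
    n_background: int
    coverage: float  # fraction of the signature present in the expression table
    log2fc: pd.Series = field(repr=False, default=None)


def score_signature(
    sig: GeneSignature,
    knockdown_expr: pd.Series,
    control_expr: pd.Series,
    pseudocount: float = 1.0,
) -> SignatureScore:
    """Score a knockdown against the signature.

    Computes log2 fold (knockdown vs control) for every gene, then
    compares the signature genes' folds with the non-signature background
    by a one-sided Mann-Whitney U test (signature > background).  Reports
    the median (and mean) signature log2 fold.
    """
    common = knockdown_expr.index.intersection(control_expr.index)
    log2fc = np.log2((knockdown_expr[common] + pseudocount) / (control_expr[common] + pseudocount))
    in_sig = log2fc.index.isin(sig.genes)
    coverage = float(in_sig.sum()) / len(sig) if len(sig) else 0.0
    if in_sig.sum() == 0:
        raise ValueError("no signature gene present in the expression tables")
    if coverage < 0.5:
        warnings.warn(f"only {coverage:.0%} of the signature overlaps the expression table")
    sig_fc = log2fc[in_sig]
    bg_fc = log2fc[~in_sig]
    if len(bg_fc) == 0:
        p = np.nan
    else:
        p = float(stats.mannwhitneyu(sig_fc, bg_fc, alternative="greater").pvalue)
    return SignatureScore(
        median_log2fc=float(sig_fc.median()),
        mean_log2fc=float(sig_fc.mean()),
        p=p,
        n_signature=int(in_sig.sum()),
        n_background=int(len(bg_fc)),
        coverage=coverage,
        log2fc=log2fc,
    )


def reverse_signature(
    up_genes: list[str],
    reference_expr: pd.DataFrame,
    baseline: str = "esc",
    n: int = 200,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Measure a knockdown's upregulated gene set across reference stages.

    ``up_genes`` is the knockdown's upregulated list (already ranked; only
    the first ``n`` are used).  For every stage column of
    ``reference_expr`` (other than ``baseline``), the up-set genes' log2
    expression ratios over baseline are compared with all other genes by
    one-sided Mann-Whitney (up-set higher).  An empty up-set yields an
    all-NA row with a warning.
    """
    stages = [c for c in reference_expr.columns if c != baseline]
    subset = [g for g in up_genes[:n] if g in reference_expr.index]
    rows = []
    if not subset:
        warnings.warn("empty upregulated gene set; reverse signature undefined")
        return pd.DataFrame(
            [(s, np.nan, np.nan, 0) for s in stages],
            columns=["stage", "median_log2fc", "p", "n_genes"],
        ).set_index("stage")
    in_set = reference_expr.index.isin(subset)
    for stage in stages:
        log2fc = np.log2(
            (reference_expr[stage] + pseudocount) / (reference_expr[baseline] + pseudocount)
        )
        p = float(stats.mannwhitneyu(log2fc[in_set], log2fc[~in_set], alternative="greater").pvalue)
        rows.append((stage, float(log2fc[in_set].median()), p, int(in_set.sum())))
    return pd.DataFrame(rows, columns=["stage", "median_log2fc", "p", "n_genes"]).set_index("stage")


def annotate_mervl_proximal_genes(
    genes: pd.DataFrame,
    catalog: TETypeCatalog,
    te_names: tuple[str, ...] = MERVL_TYPES,
    window: int = 10000,
) -> pd.Series:
    """Label each gene ``none`` / ``same_ori`` / ``opposite_ori`` by MERVL proximity.

    A gene qualifies when any copy of the named TE types lies within
    ``window`` bp of the gene body (edge to edge; overlap counts as
    distance 0).  ``same_ori`` wins when both same- and opposite-strand
    copies qualify (the biologically meaningful case is the presence of a
    same-strand element).  Strandless records are an error.
    """
    from intervaltree import IntervalTree

    copies = catalog.copies[catalog.copies["type_name"].isin(te_names)]
    trees: dict[str, IntervalTree] = {}
    for row in copies.itertuples(index=False):
        if row.strand not in ("+", "-"):
            raise ValueError(f"TE copy without strand: {row.type_name} {row.chrom}:{row.start}")
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.strand)
    labels = {}
    for g in genes.itertuples(index=False):
        if g.strand not in ("+", "-"):
            raise ValueError(f"gene without strand: {g.gene_id}")
        # +1: half-open overlap would otherwise miss a copy starting exactly
        # `window` bp downstream; the gap test below keeps the bound exact
        hits = trees.get(g.chrom, IntervalTree()).overlap(
            max(0, g.start - window), g.end + window + 1
        )
        strands = set()
        for iv in hits:
            gap = max(iv.begin - g.end, g.start - iv.end, 0)
            if gap <= window:
                strands.add(iv.data)
        if not strands:
            labels[g.gene_id] = "none"
        elif g.strand in strands:
            labels[g.gene_id] = "same_ori"
        else:
            labels[g.gene_id] = "opposite_ori"
    return pd.Series(labels, name="mervl_orientation")
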