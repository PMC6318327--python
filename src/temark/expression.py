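"""Gene and TE-type expression: counting, normalization, differential calls.

TE reads are counted at the level of the TE type (metagene), not the
individual copy, following the random-best-alignment convention for
multimappers: each alignment is counted once at its reported position.
Differential expression uses a negative-binomial Wald test with
method-of-moments dispersion; the engine is deliberately simple and
pluggable — the substance here is the thresholds (BH-adjusted P < 0.05,
|fold| > 2) and the TE-level summaries layered on top.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import TETypeCatalog

__all__ = [
    "CountMatrix",
    "count_features",
    "compute_te_read_fraction",
    "normalize_counts",
    "bh_adjust",
    "test_differential",
    "summarize_deregulated_tes",
]

UNASSIGNED_CONTIG_RE = re.compile(r"(chrUn|_random$|_alt$|chrM$|^MT$)")


@dataclass
class CountMatrix:
    """Feature (genes + TE types) x sample counts.

    ``feature_kind`` flags each row as ``gene`` or ``te``;
    ``normalization`` records the state (``raw`` counts are integers).
    """

    counts: pd.DataFrame
    feature_kind: pd.Series
    normalization: str = "raw"
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("feature ids must be unique")
        if self.normalization == "raw":
            vals = self.counts.to_numpy()
            if (vals < 0).any():
                raise ValueError("raw counts must be >= 0")
        self.feature_kind = self.feature_kind.reindex(self.counts.index)
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def te_features(self) -> list[str]:
        return list(self.feature_kind.index[self.feature_kind == "te"])


def _load_gene_exons(gene_gtf: str):
    """Exon intervals per chromosome -> gene_id, via gffutils (in-memory db)."""
    import gffutils
    from intervaltree import IntervalTree

    db = gffutils.create_db(
        gene_gtf, dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", disable_infer_genes=True, disable_infer_transcripts=True,
    )
    trees: dict[str, IntervalTree] = {}
    for exon in db.features_of_type("exon"):
        gene_id = exon.attributes.get("gene_id", ["unknown"])[0]
        trees.setdefault(exon.seqid, IntervalTree()).addi(exon.start - 1, exon.end, gene_id)
    return trees


def _te_trees(catalog: TETypeCatalog):
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for row in catalog.copies.itertuples(index=False):
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end, row.type_name)
    return trees


def count_features(
    bam_path: str,
    gene_gtf: str,
    te_catalog: TETypeCatalog,
    gene_precedence: bool = True,
) -> tuple[pd.Series, pd.Series, dict]:
    """Count alignments into genes and TE types from a coordinate-sorted BAM/SAM.

    Each primary alignment is counted once at its reported position
    (multimappers having been resolved upstream to one random best hit).
    Reads overlapping both a gene exon and a TE copy go to the gene by
    default (``gene_precedence=False`` inverts this); reads on
    mitochondrial or unassigned contigs are discarded.

    Returns ``(counts, feature_kind, stats)`` where stats reports totals
    so that assigned + unassigned + discarded = alignments considered.
    """
    import pysam

    gene_trees = _load_gene_exons(gene_gtf)
    te_trees = _te_trees(te_catalog)
    gene_counts: dict[str, int] = {}
    te_counts = {t: 0 for t in te_catalog.type_names}
    n_total = n_assigned = n_unassigned = n_discarded = 0

    with pysam.AlignmentFile(bam_path) as bam:
        so = (bam.header.to_dict().get("HD") or {}).get("SO")
        if so != "coordinate":
            raise ValueError(f"{bam_path}: alignments must be coordinate-sorted (SO={so})")
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            n_total += 1
            chrom = aln.reference_name
            if UNASSIGNED_CONTIG_RE.search(chrom):
                n_discarded += 1
                continue
            s, e = aln.reference_start, aln.reference_end
            genes = {iv.data for iv in gene_trees[chrom].overlap(s, e)} if chrom in gene_trees else set()
            tes = {iv.data for iv in te_trees[chrom].overlap(s, e)} if chrom in te_trees else set()
            target = None
            if genes and (gene_precedence or not tes):
                target = ("gene", sorted(genes)[0])
            elif tes:
                target = ("te", sorted(tes)[0])
            elif genes:
                target = ("gene", sorted(genes)[0])
            if target is None:
                n_unassigned += 1
                continue
            n_assigned += 1
            kind, name = target
            if kind == "gene":
                gene_counts[name] = gene_counts.get(name, 0) + 1
            else:
                te_counts[name] += 1

    all_genes = sorted({iv.data for tree in gene_trees.values() for iv in tree})
    counts = pd.Series(
        {g: gene_counts.get(g, 0) for g in all_genes} | te_counts, dtype=int
    )
    kind = pd.Series(
        {g: "gene" for g in all_genes} | {t: "te" for t in te_counts}
    ).reindex(counts.index)
    stats_d = dict(total=n_total, assigned=n_assigned, unassigned=n_unassigned, discarded=n_discarded)
    return counts, kind, stats_d


def compute_te_read_fraction(matrix: CountMatrix) -> pd.Series:
    """Fraction of counted reads assigned to TE features, per sample."""
    te = matrix.counts.loc[matrix.feature_kind == "te"].sum(axis=0)
    total = matrix.counts.sum(axis=0)
    frac = te / total
    if (total == 0).any():
        warnings.warn("sample(s) with zero total counts: TE fraction undefined")
    return frac


def normalize_counts(matrix: CountMatrix, method: str = "full_quantile", gc: pd.Series | None = None) -> CountMatrix:
    """Normalize counts across samples.

    ``full_quantile`` forces every sample's sorted value distribution onto
    the cross-sample mean distribution.  Ties are assigned consecutive
    quantile values in stable input order — deterministic, and it makes
    the transform exactly idempotent (each column's value multiset equals
    the target, so a second pass is a no-op).  An optional GC step first
    removes a lowess trend of log counts on per-feature GC.  Genes and TE
    metafeatures are normalized together in one matrix.
    """
    if method != "full_quantile":
        raise ValueError(f"unknown normalization method: {method!r}")
    data = matrix.counts.to_numpy(dtype=float)
    state = "full_quantile"
    if gc is not None:
        from statsmodels.nonparametric.smoothers_lowess import lowess

        gcv = gc.reindex(matrix.counts.index).to_numpy(dtype=float)
        for j in range(data.shape[1]):
            logc = np.log2(data[:, j] + 0.5)
            fit = lowess(logc, gcv, frac=0.5, return_sorted=False)
            data[:, j] = 2.0 ** (logc - fit + np.mean(logc)) - 0.5
            np.maximum(data[:, j], 0.0, out=data[:, j])
        state = "gc_adjusted"
    if data.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    order = np.argsort(data, axis=0, kind="stable")
    sorted_vals = np.take_along_axis(data, order, axis=0)
    target = sorted_vals.mean(axis=1)
    out = np.empty_like(data)
    for j in range(data.shape[1]):
        out[order[:, j], j] = target
    norm = pd.DataFrame(out, index=matrix.counts.index, columns=matrix.counts.columns)
    return CountMatrix(
        counts=norm, feature_kind=matrix.feature_kind,
        normalization=state, library_sizes=matrix.counts.sum(axis=0),
    )


def bh_adjust(p: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min_{j >= i} p_(j) * n / j over the sorted p-values, capped
    at 1 (vectorized via a reversed running minimum).
    """
    arr = np.asarray(p, dtype=float)
    n = len(arr)
    order = np.argsort(arr, kind="stable")
    scaled = arr[order] * n / np.arange(1, n + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adj = np.empty(n)
    adj[order] = adj_sorted
    return adj


@dataclass
class DEResult:
    """Per-feature differential-expression table and the thresholds used."""

    table: pd.DataFrame  # base_mean, log2fc, p, adj_p, call, feature_kind
    alpha: float
    fc_min: float
    excluded: list[str] = field(default_factory=list)

    def upregulated(self, kind: str | None = None) -> pd.DataFrame:
        t = self.table[self.table["call"] == "up"]
        return t if kind is None else t[t["feature_kind"] == kind]

    def significant_tes(self) -> pd.DataFrame:
        t = self.table
        return t[(t["feature_kind"] == "te") & (t["call"] != "ns")]


def _mom_dispersion(y: np.ndarray, mu: float, df: int) -> float:
    """Method-of-moments NB dispersion from residual variance around mu."""
    if mu <= 0 or df <= 0:
        return 0.0
    var = float(np.sum((y - np.mean(y)) ** 2)) / df
    return max(0.0, (var - mu) / (mu * mu))


def test_differential(
    matrix: CountMatrix,
    control: list[str],
    treatment: list[str],
    alpha: float = 0.05,
    fc_min: float = 2.0,
    pseudocount: float = 1.0,
    prior_df: float = 20.0,
    normalize: bool = True,
) -> DEResult:
    """Negative-binomial Wald test of treatment vs control per feature.

    Raw counts are full-quantile normalized first by default; pass
    ``normalize=False`` when the samples are already on a common scale
    (equal library sizes), since rank-based normalization of a small
    feature space with many changed features distorts the null.
    Dispersion is
    method-of-moments per feature, shrunk toward the across-feature
    common (median) value with ``prior_df`` pseudo-degrees of freedom —
    at typical replicate numbers the per-feature estimate is very noisy
    and the common value dominates; the Wald statistic is the log fold
    over its delta-method standard error.
    Genes and TEs are tested and BH-corrected jointly; ``up`` requires
    adjusted P < ``alpha`` and linear fold > ``fc_min`` (``down``
    symmetric).  Features with zero counts everywhere are excluded and
    reported.
    """
    if normalize and matrix.normalization == "raw":
        matrix = normalize_counts(matrix)
    missing = [s for s in control + treatment if s not in matrix.samples]
    if missing:
        raise KeyError(f"unknown samples: {missing}")
    if len(control) < 2 or len(treatment) < 2:
        warnings.warn("fewer than 2 replicates per group: dispersion pooled across features")

    data = matrix.counts
    c = data[control].to_numpy(dtype=float)
    t = data[treatment].to_numpy(dtype=float)
    nonzero = (c.sum(axis=1) + t.sum(axis=1)) > 0
    excluded = list(data.index[~nonzero])

    mu_c, mu_t = c.mean(axis=1), t.mean(axis=1)
    n_c, n_t = c.shape[1], t.shape[1]
    resid_df = (n_c - 1) + (n_t - 1)
    disp = np.zeros(len(data))
    if resid_df > 0:
        rv = np.sum((c - mu_c[:, None]) ** 2, axis=1) + np.sum((t - mu_t[:, None]) ** 2, axis=1)
        resid_var = rv / resid_df
        mu_bar = (n_c * mu_c + n_t * mu_t) / (n_c + n_t)
        with np.errstate(divide="ignore", invalid="ignore"):
            raw_disp = np.where(mu_bar > 0, (resid_var - mu_bar) / (mu_bar * mu_bar), 0.0)
        disp = np.clip(raw_disp, 0.0, None)
    positive = disp[nonzero & (disp > 0)]
    common = float(np.median(positive)) if len(positive) else 0.01
    # moderate the noisy per-feature estimate toward the common value
    disp = (resid_df * disp + prior_df * common) / (resid_df + prior_df)

    fold = (mu_t + pseudocount) / (mu_c + pseudocount)
    log2fc = np.log2(fold)
    mu_c_s, mu_t_s = mu_c + pseudocount, mu_t + pseudocount
    var_log = (1.0 / (n_c * mu_c_s) + disp / n_c) + (1.0 / (n_t * mu_t_s) + disp / n_t)
    se = np.sqrt(var_log)  # natural-log scale
    z = np.log(fold) / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(nonzero, p, np.nan)

    adj = np.full(len(data), np.nan)
    adj[nonzero] = bh_adjust(p[nonzero])
    call = np.full(len(data), "ns", dtype=object)
    call[(adj < alpha) & (fold > fc_min) & nonzero] = "up"
    call[(adj < alpha) & (fold < 1.0 / fc_min) & nonzero] = "down"

    table = pd.DataFrame(
        {
            "base_mean": (mu_c + mu_t) / 2.0,
            "log2fc": log2fc,
            "p": p,
            "adj_p": adj,
            "call": call,
            "feature_kind": matrix.feature_kind.values,
        },
        index=data.index,
    )
    return DEResult(table=table, alpha=alpha, fc_min=fc_min, excluded=excluded)


def summarize_deregulated_tes(de_by_knockdown: dict[str, DEResult], high_fold: float = 4.0) -> dict:
    """Per-knockdown deregulated-TE counts, cross-knockdown overlap, and the
    strongly upregulated (linear fold strictly > ``high_fold``) list."""
    per_kd = {}
    sig_sets: dict[str, set[str]] = {}
    high_rows = []
    for kd, de in de_by_knockdown.items():
        tes = de.significant_tes()
        per_kd[kd] = {
            "n_up": int((tes["call"] == "up").sum()),
            "n_down": int((tes["call"] == "down").sum()),
        }
        sig_sets[kd] = set(tes.index)
        up = tes[tes["call"] == "up"]
        for te, row in up.iterrows():
            if 2.0 ** row["log2fc"] > high_fold:
                high_rows.append((kd, te, float(row["log2fc"])))
    multiplicity: dict[str, int] = {}
    for s in sig_sets.values():
        for te in s:
            multiplicity[te] = multiplicity.get(te, 0) + 1
    shared = sorted(t for t, m in multiplicity.items() if m >= 2)
    unique = sorted(t for t, m in multiplicity.items() if m == 1)
    return {
        "per_knockdown": pd.DataFrame(per_kd).T,
        "shared_tes": shared,
        "unique_tes": unique,
        "high_fold_upregulated": pd.DataFrame(high_rows, columns=["knockdown", "te_type", "log2fc"]),
    }
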