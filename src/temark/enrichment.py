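"""Metagene enrichment of chromatin marks at TE types.

The central statistic: each TE type is treated as a metagene.  Every copy
is cut into consecutive 500-bp bins anchored at its 5' end (strand-aware),
the per-bin values are averaged across copies, and the maximum bin is the
*observed* signal.  The *expected* signal is the same statistic over
size-matched random genomic regions (one per copy).  Enrichment is
log2((observed + pc) / (expected + pc)).

Bin sums use ``np.sum`` over contiguous slices throughout; results are
therefore reproducible to the bit for a given track and catalog.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr, spearmanr

from .annotation import TETypeCatalog
from .coverage import CoverageTrack

__all__ = [
    "BinnedProfile",
    "EnrichmentMatrix",
    "bin_te_type",
    "sample_background_regions",
    "compute_te_enrichment",
    "compute_enrichment_matrix",
    "call_enriched_marks",
    "partition_high_low",
    "cluster_enrichment_matrix",
    "correlate_age_enrichment",
    "compute_metagene_profile",
    "qc_replicates",
]

DEFAULT_BIN_BP = 500
DEFAULT_PSEUDOCOUNT = 0.01


@dataclass
class BinnedProfile:
    """Metagene bin vector for one TE type (or background set)."""

    values: np.ndarray  # mean bin value across copies having that bin
    n_copies_per_bin: np.ndarray
    bin_bp: int

    @property
    def max_bin(self) -> float:
        return float(np.max(self.values)) if len(self.values) else float("nan")


@dataclass
class EnrichmentMatrix:
    """Observed/expected max-bin RPKM per (mark, TE type) and log2 folds.

    ``log2fold`` is always derived from the stored ``obs``/``exp`` and the
    pseudocount, so the three never drift apart.
    """

    obs: pd.DataFrame  # rows = marks/modifiers, cols = TE types
    exp: pd.DataFrame
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    background_seed: int | None = None
    low_information: pd.DataFrame | None = None

    @property
    def log2fold(self) -> pd.DataFrame:
        return np.log2((self.obs + self.pseudocount) / (self.exp + self.pseudocount))

    @property
    def fold(self) -> pd.DataFrame:
        return (self.obs + self.pseudocount) / (self.exp + self.pseudocount)

    @property
    def marks(self) -> list[str]:
        return list(self.obs.index)

    @property
    def te_types(self) -> list[str]:
        return list(self.obs.columns)

    @classmethod
    def from_log2fold(cls, log2fold: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> "EnrichmentMatrix":
        """Build a matrix with the requested folds (obs = fold, exp = 1), for
        assembling fixtures or importing external fold tables."""
        fold = 2.0 ** log2fold.astype(float)
        obs = fold * (1.0 + pseudocount) - pseudocount
        exp = pd.DataFrame(1.0, index=log2fold.index, columns=log2fold.columns)
        return cls(obs=obs, exp=exp, pseudocount=pseudocount)

    def to_tsv(self, path: str) -> None:
        long = (
            self.log2fold.stack().rename("log2fold").to_frame()
            .join(self.obs.stack().rename("obs"))
            .join(self.exp.stack().rename("exp"))
            .reset_index(names=["mark", "te_type"])
        )
        for c in ("obs", "exp", "log2fold"):
            long[c] = long[c].map(lambda v: float(f"{v:.6g}"))
        long.to_csv(path, sep="\t", index=False)


def _copy_bin_means(vals: np.ndarray, bin_bp: int) -> np.ndarray:
    """Per-bin means for one copy; final partial bin kept; >=1 bin always."""
    n = len(vals)
    n_bins = max(1, -(-n // bin_bp))
    out = np.empty(n_bins)
    for b in range(n_bins):
        seg = vals[b * bin_bp:min(n, (b + 1) * bin_bp)]
        out[b] = np.sum(seg) / len(seg)
    return out


def bin_te_type(track: CoverageTrack, copies: pd.DataFrame, bin_bp: int = DEFAULT_BIN_BP) -> BinnedProfile:
    """Metagene bin profile over one TE type's copies.

    Bin 0 is the 5'-most bin of each copy (the signal of minus-strand
    copies is reversed before binning); the metagene value of bin *b* is
    the mean over all copies long enough to have bin *b*.
    """
    if len(copies) == 0:
        raise ValueError("bin_te_type requires at least one copy")
    per_copy: list[np.ndarray] = []
    for row in copies.itertuples(index=False):
        vals = track.values[row.chrom][row.start:row.end]
        if row.strand == "-":
            vals = vals[::-1]
        per_copy.append(_copy_bin_means(vals, bin_bp))
    n_bins = max(len(v) for v in per_copy)
    values = np.empty(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        col = np.array([v[b] for v in per_copy if len(v) > b])
        counts[b] = len(col)
        values[b] = np.sum(col) / len(col)
    return BinnedProfile(values=values, n_copies_per_bin=counts, bin_bp=bin_bp)


def _background_rng(seed, te_type: str | None = None) -> np.random.Generator:
    """Independent stream per (seed, TE type): the type name enters the seed
    entropy so different types never replay one another's draws (nor the
    synthetic placement stream that may share the integer seed)."""
    if isinstance(seed, np.random.Generator):
        return seed
    entropy = [seed, int.from_bytes(b"temark-bg", "big")]
    if te_type is not None:
        entropy.append(int.from_bytes(te_type.encode(), "big"))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def sample_background_regions(
    type_copies: pd.DataFrame,
    chrom_sizes: dict[str, int],
    seed: int | np.random.Generator = 0,
    exclude: dict[str, IntervalTree] | None = None,
    max_retries: int = 1000,
    te_type: str | None = None,
) -> pd.DataFrame:
    """Size-matched random background: one region per copy, same length.

    Chromosomes are drawn proportional to length (among those long enough
    for the copy), starts uniformly; regions falling in ``exclude`` are
    rejected.  Deterministic for a fixed seed; ``te_type`` (when given)
    salts the stream so each type draws an independent null.
    """
    rng = _background_rng(seed, te_type)
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    rows = []
    for row in type_copies.itertuples(index=False):
        length = row.end - row.start
        eligible = [k for k, c in enumerate(chroms) if chrom_sizes[c] >= length]
        if not eligible:
            raise ValueError(f"no chromosome can hold a {length}-bp background region")
        w = sizes[eligible] / sizes[eligible].sum()
        for attempt in range(max_retries):
            k = eligible[int(rng.choice(len(eligible), p=w))]
            chrom = chroms[k]
            start = int(rng.integers(0, chrom_sizes[chrom] - length + 1))
            if exclude and chrom in exclude and exclude[chrom].overlap(start, start + length):
                continue
            rows.append((chrom, start, start + length, "+"))
            break
        else:
            raise ValueError(f"could not place a {length}-bp background region after {max_retries} retries")
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])


def compute_te_enrichment(
    track: CoverageTrack,
    catalog: TETypeCatalog,
    bin_bp: int = DEFAULT_BIN_BP,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    seed: int = 0,
    backgrounds: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """One mark's enrichment row: per TE type, observed and expected max-bin
    RPKM and log2 fold.

    ``backgrounds`` maps TE type to a pre-drawn background region set so a
    run can share one null across marks; when absent, backgrounds are
    drawn here from ``seed``.
    """
    chrom_sizes = track.chrom_sizes
    rows = []
    for te_type in catalog.type_names:
        copies = catalog.copies_of(te_type)
        obs = bin_te_type(track, copies, bin_bp).max_bin
        if backgrounds is not None and te_type in backgrounds:
            bg = backgrounds[te_type]
        else:
            bg = sample_background_regions(copies, chrom_sizes, seed=seed, te_type=te_type)
        exp = bin_te_type(track, bg, bin_bp).max_bin
        low_info = obs == 0.0 and exp == 0.0
        rows.append((te_type, obs, exp, low_info))
    df = pd.DataFrame(rows, columns=["te_type", "obs", "exp", "low_information"]).set_index("te_type")
    df["log2fold"] = np.log2((df["obs"] + pseudocount) / (df["exp"] + pseudocount))
    return df


def compute_enrichment_matrix(
    tracks: dict[str, CoverageTrack],
    catalog: TETypeCatalog,
    bin_bp: int = DEFAULT_BIN_BP,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    seed: int = 0,
) -> EnrichmentMatrix:
    """Enrichment for several marks, sharing one background draw per TE type
    so the marks are compared against the same null."""
    if not tracks:
        raise ValueError("no tracks given")
    chrom_sizes = next(iter(tracks.values())).chrom_sizes
    backgrounds = {
        t: sample_background_regions(catalog.copies_of(t), chrom_sizes, seed=seed, te_type=t)
        for t in catalog.type_names
    }
    obs_rows, exp_rows, li_rows = {}, {}, {}
    for mark in sorted(tracks):
        row = compute_te_enrichment(
            tracks[mark], catalog, bin_bp=bin_bp, pseudocount=pseudocount, backgrounds=backgrounds
        )
        obs_rows[mark] = row["obs"]
        exp_rows[mark] = row["exp"]
        li_rows[mark] = row["low_information"]
    return EnrichmentMatrix(
        obs=pd.DataFrame(obs_rows).T,
        exp=pd.DataFrame(exp_rows).T,
        pseudocount=pseudocount,
        background_seed=seed,
        low_information=pd.DataFrame(li_rows).T,
    )


@dataclass
class MarkCalls:
    """Boolean enrichment calls plus the tallies behind 'N marks per TE'."""

    calls: pd.DataFrame  # marks x TE types, bool
    relaxed_calls: pd.DataFrame
    per_te: pd.DataFrame  # n_marks_enriched, n_marks_relaxed per TE type
    per_mark: pd.DataFrame  # n_te_enriched, n_te_relaxed per mark
    threshold: float
    relaxed: float


def call_enriched_marks(
    matrix: EnrichmentMatrix,
    threshold: float = 2.0,
    relaxed: float = 1.5,
    strict: bool = True,
) -> MarkCalls:
    """Threshold the fold matrix into enrichment calls.

    A mark is enriched at a TE type when its linear fold exceeds
    ``threshold`` (strictly by default, ``>=`` with ``strict=False``);
    ``relaxed`` gives the secondary permissive call set.
    """
    fold = matrix.fold
    op = fold.gt if strict else fold.ge
    calls = op(threshold)
    relaxed_calls = op(relaxed)
    per_te = pd.DataFrame(
        {"n_marks_enriched": calls.sum(axis=0), "n_marks_relaxed": relaxed_calls.sum(axis=0)}
    )
    per_mark = pd.DataFrame(
        {"n_te_enriched": calls.sum(axis=1), "n_te_relaxed": relaxed_calls.sum(axis=1)}
    )
    return MarkCalls(calls, relaxed_calls, per_te, per_mark, threshold, relaxed)


def partition_high_low(
    matrix: EnrichmentMatrix, mark: str, threshold: float = 2.0
) -> tuple[list[str], list[str]]:
    """High = TE types with fold > threshold for ``mark``; Low = equally many
    types from the bottom of the fold ranking.  The sets must not overlap."""
    fold = matrix.fold.loc[mark]
    high = sorted(fold.index[fold > threshold])
    if len(high) > len(fold) / 2:
        raise ValueError(
            f"High set ({len(high)}) exceeds half the TE types ({len(fold)}); Low would overlap"
        )
    order = fold.sort_values(kind="stable").index  # ascending
    low = sorted(order[: len(high)])
    return high, low


def _correlation_distance(data: np.ndarray) -> np.ndarray:
    """1 - Pearson distance matrix; constant rows get distance 1 to everything."""
    n = data.shape[0]
    sd = data.std(axis=1)
    dist = np.ones((n, n))
    np.fill_diagonal(dist, 0.0)
    ok = sd > 0
    if ok.sum() >= 2:
        corr = np.corrcoef(data[ok])
        idx = np.flatnonzero(ok)
        for a, ia in enumerate(idx):
            for b, ib in enumerate(idx):
                dist[ia, ib] = 1.0 - corr[a, b]
    np.fill_diagonal(dist, 0.0)
    return np.clip(dist, 0.0, 2.0)


@dataclass
class ClusterResult:
    labels: list[str]
    leaf_order: list[str]
    linkage_matrix: np.ndarray

    def cut(self, k: int) -> dict[str, int]:
        from scipy.cluster.hierarchy import fcluster

        assign = fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.labels, assign.tolist()))


def cluster_enrichment_matrix(
    matrix: EnrichmentMatrix | pd.DataFrame, axis: str = "rows", method: str = "average"
) -> ClusterResult:
    """Hierarchical clustering (average linkage, 1 - Pearson) of the fold
    matrix along marks (``rows``) or TE types (``cols``)."""
    df = matrix.log2fold if isinstance(matrix, EnrichmentMatrix) else matrix
    if axis == "cols":
        df = df.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'cols'")
    if len(df) < 2:
        raise ValueError("need >= 2 items to cluster")
    dist = _correlation_distance(df.to_numpy(dtype=float))
    Z = linkage(squareform(dist, checks=False), method=method)
    order = leaves_list(Z)
    labels = list(df.index)
    return ClusterResult(labels=labels, leaf_order=[labels[i] for i in order], linkage_matrix=Z)


def correlate_age_enrichment(matrix: EnrichmentMatrix, ages: pd.Series) -> pd.DataFrame:
    """Spearman correlation of TE age vs log2 fold, per mark (ties mid-ranked).

    Types with undefined age are ignored; a mark needs >= 3 aged types for
    a defined rho.
    """
    lf = matrix.log2fold
    common = [t for t in lf.columns if t in ages.index and np.isfinite(ages[t])]
    rows = []
    for mark in lf.index:
        x = ages[common].to_numpy(float)
        y = lf.loc[mark, common].to_numpy(float)
        if len(common) < 3:
            rows.append((mark, np.nan, np.nan, False))
            continue
        if np.std(y) == 0 or np.std(x) == 0:
            warnings.warn(f"{mark}: constant vector, Spearman rho undefined")
            rows.append((mark, np.nan, np.nan, False))
            continue
        rho, p = spearmanr(x, y)
        rows.append((mark, float(rho), float(p), True))
    return pd.DataFrame(rows, columns=["mark", "rho", "p", "defined"]).set_index("mark")


def compute_metagene_profile(
    track: CoverageTrack,
    copies: pd.DataFrame,
    flank_bp: int = 5000,
    n_body_bins: int = 50,
    flank_bin_bp: int = 500,
) -> np.ndarray:
    """Scaled pileup: body rescaled to ``n_body_bins`` equal fractions with
    fixed-width flank bins either side, 5'->3' orientation, mean across
    copies.  For inspection/figures; the enrichment statistic uses
    :func:`bin_te_type` on the body only.
    """
    if n_body_bins < 1:
        raise ValueError("n_body_bins must be >= 1")
    n_flank = flank_bp // flank_bin_bp
    width = 2 * n_flank + n_body_bins
    acc = np.zeros(width)
    cnt = np.zeros(width, dtype=int)
    for row in copies.itertuples(index=False):
        size = len(track.values[row.chrom])
        s, e = row.start, row.end
        up = track.values[row.chrom][max(0, s - flank_bp):s]
        body = track.values[row.chrom][s:e]
        down = track.values[row.chrom][e:min(size, e + flank_bp)]
        if row.strand == "-":
            up, down = down[::-1], up[::-1]
            body = body[::-1]
        bins = []
        for i in range(n_flank):
            seg = up[i * flank_bin_bp:(i + 1) * flank_bin_bp]
            bins.append(np.sum(seg) / len(seg) if len(seg) else np.nan)
        edges = np.linspace(0, len(body), n_body_bins + 1).round().astype(int)
        for i in range(n_body_bins):
            seg = body[edges[i]:max(edges[i] + 1, edges[i + 1])]
            bins.append(np.sum(seg) / len(seg))
        for i in range(n_flank):
            seg = down[i * flank_bin_bp:(i + 1) * flank_bin_bp]
            bins.append(np.sum(seg) / len(seg) if len(seg) else np.nan)
        vals = np.array(bins)
        good = np.isfinite(vals)
        acc[good] += vals[good]
        cnt[good] += 1
    with np.errstate(invalid="ignore"):
        return acc / np.where(cnt > 0, cnt, np.nan)


def _per_copy_rpkm_vector(track: CoverageTrack, catalog: TETypeCatalog) -> np.ndarray:
    """Mean per-base RPKM for every TE copy, in catalog order."""
    out = np.empty(len(catalog))
    for i, row in enumerate(catalog.copies.itertuples(index=False)):
        seg = track.values[row.chrom][row.start:row.end]
        out[i] = np.sum(seg) / len(seg)
    return out


@dataclass
class ReplicateQC:
    kept: list[str]
    dropped: list[str]
    merged: CoverageTrack
    correlations: pd.DataFrame


def qc_replicates(
    tracks: dict[str, CoverageTrack],
    catalog: TETypeCatalog,
    min_r: float = 0.6,
) -> ReplicateQC:
    """Replicate QC on per-TE RPKM vectors.

    Pearson correlation is computed between the replicates' per-copy RPKM
    vectors over all TEs; a replicate is kept when it correlates > ``min_r``
    with at least one other replicate.  Kept replicates are merged by
    mean (preserving the RPKM scale).  A single track is kept as-is; if
    all replicates are mutually discordant the highest-coverage one is
    kept with a warning.
    """
    names = sorted(tracks)
    if not names:
        raise ValueError("no replicate tracks given")
    vectors = {n: _per_copy_rpkm_vector(tracks[n], catalog) for n in names}
    corr = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.std(vectors[a]) == 0 or np.std(vectors[b]) == 0:
                r = 0.0
            else:
                r = float(pearsonr(vectors[a], vectors[b])[0])
            corr.loc[a, b] = corr.loc[b, a] = r
    if len(names) == 1:
        kept = list(names)
    else:
        kept = [a for a in names if any(corr.loc[a, b] > min_r for b in names if b != a)]
        if not kept:
            best = max(names, key=lambda n: float(np.mean(vectors[n])))
            warnings.warn(
                f"all replicates mutually discordant (r <= {min_r}); keeping highest-coverage {best!r}"
            )
            kept = [best]
    dropped = [n for n in names if n not in kept]
    merged_vals = {
        c: np.mean([tracks[n].values[c] for n in kept], axis=0)
        for c in tracks[names[0]].values
    }
    merged = CoverageTrack(merged_vals, label="+".join(kept))
    return ReplicateQC(kept=kept, dropped=dropped, merged=merged, correlations=corr)
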