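"""Self-contained synthetic fixtures with planted, known ground truth.

Generates a coordinates-only toy genome (no sequence) carrying TE copies
with realistic copy numbers, lengths and milliDiv values; RPKM-like
coverage tracks with planted fold-enrichments (optionally 5'-biased);
negative-binomial count matrices with planted expression changes; a
two-condition expression table with a planted top-upregulated gene set;
and toy genes placed near MERVL-like copies in both orientations.  Every
generator is deterministic for a fixed seed and each planted effect is
recoverable by direct measurement on the emitted files.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import CATALOG_COLUMNS, TETypeCatalog
from .coverage import CoverageTrack

__all__ = [
    "TETypeSpec",
    "SyntheticGenomeSpec",
    "PlantedEffect",
    "CapacityError",
    "generate_te_annotation",
    "generate_coverage_track",
    "generate_count_matrix",
    "generate_signature_dataset",
    "generate_gene_annotation",
    "write_fixture_bundle",
]

MILLIDIV_SD = 30.0  # per-copy spread around the type mean, clipped to [0, 1000]


class CapacityError(RuntimeError):
    """Raised when TE copies cannot be placed in the genome without overlap."""


@dataclass
class TETypeSpec:
    """Blueprint for one TE type's copies."""

    name: str
    te_class: str  # LINE, SINE, LTR or DNA
    n_copies: int
    length_range: tuple[int, int]
    millidiv_mean: float
    strand_balance: float = 0.5
    te_family: str = ""

    def __post_init__(self) -> None:
        if self.n_copies < 0:
            raise ValueError(f"{self.name}: n_copies must be >= 0")
        if not (0 <= self.millidiv_mean <= 1000):
            raise ValueError(f"{self.name}: millidiv_mean outside [0, 1000]")
        if not self.te_family:
            self.te_family = self.te_class


@dataclass
class SyntheticGenomeSpec:
    """Toy genome layout: chromosome sizes, TE types and the master seed."""

    chrom_sizes: dict[str, int]
    te_types: list[TETypeSpec]
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.chrom_sizes.values()):
            raise ValueError("chromosome lengths must be > 0")


@dataclass
class PlantedEffect:
    """A known effect to plant: mark enrichment, expression or accessibility fold."""

    target: str  # TE type name or gene id
    kind: str  # mark_enrichment | expression_fold | accessibility_fold
    magnitude: float  # linear fold vs background/control
    profile_bias: str | None = None  # None/"uniform" or "5prime"

    def __post_init__(self) -> None:
        if self.magnitude <= 0:
            raise ValueError("magnitude must be > 0")
        if self.kind not in {"mark_enrichment", "expression_fold", "accessibility_fold"}:
            raise ValueError(f"unknown effect kind: {self.kind!r}")


def generate_te_annotation(spec: SyntheticGenomeSpec, max_retries: int = 1000) -> TETypeCatalog:
    """Place TE copies by rejection sampling; no copy overlaps another.

    Chromosomes are chosen proportional to length, starts uniformly within
    bounds; a copy that cannot be placed after ``max_retries`` draws
    raises :class:`CapacityError`.  Per-copy milliDiv is Normal(mean, 30)
    clipped to [0, 1000].
    """
    rng = np.random.default_rng(spec.seed)
    chroms = sorted(spec.chrom_sizes)
    sizes = np.array([spec.chrom_sizes[c] for c in chroms], dtype=float)
    occupied = {c: IntervalTree() for c in chroms}
    rows = []
    for ts in spec.te_types:
        lo, hi = ts.length_range
        for i in range(ts.n_copies):
            length = int(rng.integers(lo, hi + 1))
            eligible = [k for k, c in enumerate(chroms) if spec.chrom_sizes[c] >= length]
            if not eligible:
                raise CapacityError(f"{ts.name}: no chromosome can hold a {length}-bp copy")
            w = sizes[eligible] / sizes[eligible].sum()
            placed = False
            for _ in range(max_retries):
                k = eligible[int(rng.choice(len(eligible), p=w))]
                chrom = chroms[k]
                start = int(rng.integers(0, spec.chrom_sizes[chrom] - length + 1))
                if not occupied[chrom].overlap(start, start + length):
                    occupied[chrom].addi(start, start + length)
                    placed = True
                    break
            if not placed:
                raise CapacityError(
                    f"{ts.name}: could not place copy {i} after {max_retries} retries; genome too small"
                )
            millidiv = float(np.clip(rng.normal(ts.millidiv_mean, MILLIDIV_SD), 0.0, 1000.0))
            strand = "+" if rng.random() < ts.strand_balance else "-"
            rows.append((chrom, start, start + length, strand, ts.name, ts.te_class, ts.te_family, millidiv))
    df = pd.DataFrame(rows, columns=CATALOG_COLUMNS)
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    return TETypeCatalog(df)


def generate_coverage_track(
    catalog: TETypeCatalog,
    chrom_sizes: dict[str, int],
    effects: list[PlantedEffect],
    mark: str,
    noise_sd: float = 0.0,
    seed: int = 0,
    background: float = 1.0,
    noise_step_bp: int = 25,
    bias_bp: int = 500,
) -> CoverageTrack:
    """Background ~``background`` RPKM plus truncated-Gaussian noise, with
    each planted type's copies multiplied by the effect magnitude.

    Noise is drawn once per ``noise_step_bp`` window (keeps emitted
    bedGraphs compact) and truncated at 0.  A ``5prime`` profile bias
    restricts the fold to the 5'-most ``bias_bp`` of each copy,
    strand-aware.
    """
    known = set(catalog.copies["type_name"])
    for eff in effects:
        if eff.target not in known:
            raise KeyError(f"planted effect references unknown TE type: {eff.target!r}")
    rng = np.random.default_rng(seed)
    values: dict[str, np.ndarray] = {}
    for chrom in sorted(chrom_sizes):
        n = chrom_sizes[chrom]
        arr = np.full(n, float(background))
        if noise_sd > 0:
            n_steps = int(np.ceil(n / noise_step_bp))
            noise = rng.normal(0.0, noise_sd, size=n_steps)
            arr += np.repeat(noise, noise_step_bp)[:n]
            np.maximum(arr, 0.0, out=arr)
        values[chrom] = arr
    for eff in effects:
        fivep = eff.profile_bias in ("5prime", "5'", "five_prime")
        for row in catalog.copies_of(eff.target).itertuples(index=False):
            if fivep:
                if row.strand == "+":
                    s, e = row.start, min(row.end, row.start + bias_bp)
                else:
                    s, e = max(row.start, row.end - bias_bp), row.end
            else:
                s, e = row.start, row.end
            values[row.chrom][s:e] *= eff.magnitude
    return CoverageTrack(values, label=mark)


def generate_count_matrix(
    features: list[tuple[str, str]],
    design: dict,
    planted: list[PlantedEffect],
    nb_dispersion: float = 0.1,
    seed: int = 0,
    base_mean: float | dict[str, float] = 100.0,
):
    """Negative-binomial counts with planted fold-changes in non-reference groups.

    ``features`` is a list of ``(name, kind)`` with kind ``gene`` or
    ``te``; ``design`` is ``{"groups": [ref, treat, ...], "n_reps": r}``.
    Planted ``expression_fold`` effects multiply the mean of the target
    feature in every non-reference group.  ``nb_dispersion`` is the NB
    dispersion alpha (variance = mu + alpha mu^2); 0 degrades to Poisson.
    """
    from .expression import CountMatrix

    if nb_dispersion < 0:
        raise ValueError("nb_dispersion must be >= 0")
    groups = design["groups"]
    n_reps = int(design["n_reps"])
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    names = [f for f, _ in features]
    kinds = pd.Series([k for _, k in features], index=names, name="feature_kind")
    if isinstance(base_mean, dict):
        mu0 = np.array([base_mean[f] for f in names], dtype=float)
    else:
        mu0 = np.full(len(names), float(base_mean))
    if (mu0 < 0).any():
        raise ValueError("feature means must be non-negative")
    fold = pd.Series(1.0, index=names)
    for eff in planted:
        if eff.kind != "expression_fold":
            continue
        if eff.target not in fold.index:
            raise KeyError(f"planted effect references unknown feature: {eff.target!r}")
        fold[eff.target] = eff.magnitude

    rng = np.random.default_rng(seed)
    cols = {}
    for gi, group in enumerate(groups):
        mu = mu0 if gi == 0 else mu0 * fold.values
        for rep in range(1, n_reps + 1):
            if nb_dispersion == 0:
                col = rng.poisson(mu)
            else:
                n_param = 1.0 / nb_dispersion
                p_param = n_param / (n_param + mu)
                col = rng.negative_binomial(n_param, p_param)
            cols[f"{group}_{rep}"] = col
    counts = pd.DataFrame(cols, index=names)
    return CountMatrix(counts=counts, feature_kind=kinds)


def generate_signature_dataset(
    n_genes: int,
    n_top: int,
    fold_top: float,
    seed: int = 0,
    base_mean: float = 200.0,
):
    """Two-condition (2C-like vs ESC) expression table with a planted top set.

    Exactly ``n_top`` genes carry fold ``fold_top`` (2C over ESC); the
    rest get folds in [0.5, 2], so the planted set is recoverable by
    sorting fold-changes.  Returns ``(table, planted_gene_list)`` where
    the table has columns ``esc`` and ``twoC`` indexed by gene id.
    """
    if n_top > n_genes:
        raise ValueError("n_top must be <= n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    esc = base_mean * rng.lognormal(0.0, 0.5, size=n_genes)
    folds = rng.uniform(0.5, 2.0, size=n_genes)
    planted_idx = rng.choice(n_genes, size=n_top, replace=False)
    folds[planted_idx] = fold_top
    table = pd.DataFrame({"esc": esc, "twoC": esc * folds}, index=pd.Index(genes, name="gene_id"))
    planted = sorted(genes[i] for i in planted_idx)
    return table, planted


def generate_gene_annotation(
    catalog: TETypeCatalog,
    chrom_sizes: dict[str, int],
    n_genes: int = 60,
    gene_length: int = 2000,
    mervl_types: tuple[str, ...] = ("MERVL-int", "MT2_Mm"),
    proximity_bp: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Toy genes on both strands, some placed near MERVL-like copies.

    For each MERVL copy (up to ``n_genes // 2``), a gene is planted
    ``proximity_bp`` downstream, alternating same/opposite orientation so
    both labels occur; remaining genes are scattered uniformly.  Returns
    a DataFrame ``(gene_id, chrom, start, end, strand)``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    mervl = catalog.copies[catalog.copies["type_name"].isin(mervl_types)]
    gid = 0
    for j, row in enumerate(mervl.itertuples(index=False)):
        if gid >= n_genes // 2:
            break
        start = row.end + proximity_bp
        end = start + gene_length
        if end > chrom_sizes[row.chrom]:
            continue
        strand = row.strand if j % 2 == 0 else ("-" if row.strand == "+" else "+")
        rows.append((f"toygene{gid:04d}", row.chrom, start, end, strand))
        gid += 1
    chroms = sorted(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    while gid < n_genes:
        k = int(rng.choice(len(chroms), p=sizes / sizes.sum()))
        chrom = chroms[k]
        if chrom_sizes[chrom] <= gene_length:
            continue
        start = int(rng.integers(0, chrom_sizes[chrom] - gene_length))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((f"toygene{gid:04d}", chrom, start, start + gene_length, strand))
        gid += 1
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def write_gtf(genes: pd.DataFrame, path: str) -> None:
    """Write gene + exon records (one exon per gene) as GTF2.2 (1-based)."""
    with open(path, "w") as fh:
        for row in genes.itertuples(index=False):
            attrs = f'gene_id "{row.gene_id}"; transcript_id "{row.gene_id}.t1";'
            for feat in ("gene", "exon"):
                fh.write(
                    f"{row.chrom}\ttemark\t{feat}\t{row.start + 1}\t{row.end}\t.\t{row.strand}\t.\t{attrs}\n"
                )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_fixture_bundle(
    spec: SyntheticGenomeSpec,
    mark_effects: dict[str, list[PlantedEffect]],
    outdir: str,
    noise_sd: float = 0.2,
    expression_effects: dict[str, list[PlantedEffect]] | None = None,
    atac_effects: dict[str, list[PlantedEffect]] | None = None,
    n_genes: int = 60,
    n_reps: int = 3,
    nb_dispersion: float = 0.1,
    signature: tuple[int, int, float] = (1000, 200, 10.0),
    signature_responders: dict[str, float] | None = None,
) -> dict:
    """Emit the full fixture bundle and a checksum manifest.

    Writes chrom.sizes, an rmsk-style TE table, BED, GTF toy genes, one
    bedGraph per mark (and per ATAC sample), count tables, the
    2C-vs-ESC signature table, ground-truth JSON, and ``manifest.json``.
    Returns the manifest dict.
    """
    os.makedirs(outdir, exist_ok=True)
    rng_seed = spec.seed
    catalog = generate_te_annotation(spec)
    files: dict[str, str] = {}

    def emit(name: str) -> str:
        files[name] = os.path.join(outdir, name)
        return files[name]

    with open(emit("chrom.sizes"), "w") as fh:
        for chrom in sorted(spec.chrom_sizes):
            fh.write(f"{chrom}\t{spec.chrom_sizes[chrom]}\n")
    catalog.to_rmsk_tsv(emit("te_rmsk.tsv"))
    catalog.to_bed(emit("te.bed"))

    genes = generate_gene_annotation(catalog, spec.chrom_sizes, n_genes=n_genes, seed=rng_seed + 1)
    write_gtf(genes, emit("genes.gtf"))

    os.makedirs(os.path.join(outdir, "tracks"), exist_ok=True)
    for i, (mark, effects) in enumerate(sorted(mark_effects.items())):
        track = generate_coverage_track(
            catalog, spec.chrom_sizes, effects, mark, noise_sd=noise_sd, seed=rng_seed + 100 + i
        )
        track.write_bedgraph(emit(os.path.join("tracks", f"{mark}.bedGraph")))

    if atac_effects:
        for i, (sample, effects) in enumerate(sorted(atac_effects.items())):
            track = generate_coverage_track(
                catalog, spec.chrom_sizes, effects, f"ATAC_{sample}",
                noise_sd=noise_sd, seed=rng_seed + 500 + i,
            )
            track.write_bedgraph(emit(os.path.join("tracks", f"ATAC_{sample}.bedGraph")))

    truth: dict = {
        "seed": rng_seed,
        "n_copies_per_type": {t: int(n) for t, n in catalog.copies["type_name"].value_counts().items()},
        "mark_effects": {
            m: [vars(e) for e in effs] for m, effs in (mark_effects or {}).items()
        },
        "atac_effects": {
            s: [vars(e) for e in effs] for s, effs in (atac_effects or {}).items()
        },
    }

    if expression_effects:
        features = [(g, "gene") for g in genes["gene_id"]] + [
            (t, "te") for t in catalog.type_names
        ]
        # heterogeneous baselines (lognormal around 100) so rank-based
        # full-quantile normalization has a realistic distribution to work
        # with; TE metafeatures aggregate counts over all copies of the
        # type, so they sit an order of magnitude higher than single genes
        mean_rng = np.random.default_rng(rng_seed + 800)
        base_means = {}
        for name, kind in features:
            if kind == "te":
                base_means[name] = float(max(100.0, 500.0 * mean_rng.lognormal(0.0, 0.5)))
            else:
                base_means[name] = float(max(30.0, 100.0 * mean_rng.lognormal(0.0, 1.5)))
        truth["expression_effects"] = {}
        for i, (kd, effects) in enumerate(sorted(expression_effects.items())):
            cm = generate_count_matrix(
                features, {"groups": ["control", kd], "n_reps": n_reps},
                effects, nb_dispersion=nb_dispersion, seed=rng_seed + 900 + i,
                base_mean=base_means,
            )
            cm.counts.rename_axis("feature").reset_index().assign(
                kind=cm.feature_kind.values
            ).to_csv(emit(f"counts_{kd}.tsv"), sep="\t", index=False)
            truth["expression_effects"][kd] = [vars(e) for e in effects]

    n_genes_sig, n_top, fold_top = signature
    sig_table, planted_sig = generate_signature_dataset(
        int(n_genes_sig), int(n_top), float(fold_top), seed=rng_seed + 2000
    )
    sig_table.to_csv(emit("expr_2c.tsv"), sep="\t")
    truth["signature_planted_genes"] = planted_sig

    if signature_responders:
        # knockdown expression over the signature gene space: responders
        # upregulate the planted 2C genes by the given fold
        rng = np.random.default_rng(rng_seed + 2500)
        base = sig_table["esc"]
        kd_expr = pd.DataFrame(index=sig_table.index)
        kd_expr["control"] = base * rng.lognormal(0.0, 0.05, len(base))
        planted_mask = sig_table.index.isin(planted_sig)
        for kd in sorted(signature_responders):
            fold = signature_responders[kd]
            col = base * rng.lognormal(0.0, 0.05, len(base))
            col = col.where(~planted_mask, col * fold)
            kd_expr[kd] = col
        kd_expr.to_csv(emit("expr_knockdowns.tsv"), sep="\t")
        truth["signature_responders"] = dict(signature_responders)

    with open(emit("ground_truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)

    manifest = {
        "seed": rng_seed,
        "files": {name: _sha256(path) for name, path in sorted(files.items())},
    }
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
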