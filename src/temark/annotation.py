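"""TE catalog ingestion, filtering, length splits, age estimation, GC content.

The catalog treats every genomic copy of a named repeat (RepeatMasker
``repName``, e.g. ``L1Md_Gf``) as one record, and a *TE type* as the set of
all copies sharing that name.  Downstream modules aggregate signal over a
type's copies as a single metagene.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TETypeCatalog",
    "read_repeatmasker",
    "filter_te_catalog",
    "split_lines_by_length",
    "merge_split_types",
    "estimate_te_age",
    "compute_gc_content",
    "JC_SUBSTITUTION_RATE",
]

#: default neutral substitution rate (per base per year) used for repeat ages
JC_SUBSTITUTION_RATE = 4.5e-9

CATALOG_COLUMNS = [
    "chrom",
    "start",
    "end",
    "strand",
    "type_name",
    "te_class",
    "te_family",
    "millidiv",
]

TE_CLASSES = {"LINE", "SINE", "LTR", "DNA", "other"}


class CatalogError(ValueError):
    """Raised for malformed or inconsistent TE annotation."""


@dataclass
class TETypeCatalog:
    """All genomic copies of each TE type.

    Parameters
    ----------
    copies
        DataFrame with columns ``chrom, start, end, strand, type_name,
        te_class, te_family, millidiv``.  Coordinates are 0-based
        half-open; ``millidiv`` is RepeatMasker per-mille divergence from
        the family consensus (0–1000).
    """

    copies: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=CATALOG_COLUMNS))

    def __post_init__(self) -> None:
        df = self.copies
        missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
        if missing:
            raise CatalogError(f"catalog missing columns: {missing}")
        df = df[CATALOG_COLUMNS].reset_index(drop=True)
        if len(df):
            if (df["end"] <= df["start"]).any():
                bad = df.index[df["end"] <= df["start"]][0]
                raise CatalogError(f"copy {bad}: end <= start")
            if ((df["millidiv"] < 0) | (df["millidiv"] > 1000)).any():
                raise CatalogError("millidiv outside [0, 1000]")
            if (~df["strand"].isin(["+", "-"])).any():
                raise CatalogError("strand must be '+' or '-'")
        self.copies = df

    # -- basic views ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.copies)

    @property
    def type_names(self) -> list[str]:
        return sorted(self.copies["type_name"].unique())

    def copies_of(self, type_name: str) -> pd.DataFrame:
        out = self.copies[self.copies["type_name"] == type_name]
        if out.empty and type_name not in set(self.copies["type_name"]):
            raise KeyError(f"unknown TE type: {type_name}")
        return out

    def lengths(self) -> pd.Series:
        return self.copies["end"] - self.copies["start"]

    def summary(self, age_rate: float | None = None) -> pd.DataFrame:
        """Per-type summary table (copy number, median length, divergence).

        When ``age_rate`` is given an ``age_years`` column is added via
        :func:`estimate_te_age`.
        """
        df = self.copies.assign(length=self.lengths())
        grouped = df.groupby("type_name")
        out = pd.DataFrame(
            {
                "te_class": grouped["te_class"].first(),
                "te_family": grouped["te_family"].first(),
                "n_copies": grouped.size(),
                "median_length": grouped["length"].median(),
                "mean_millidiv": grouped["millidiv"].mean(),
            }
        )
        if age_rate is not None:
            ages = estimate_te_age(self, rate=age_rate)
            out = out.join(ages[["age_years"]])
        return out.sort_index()

    # -- writers ----------------------------------------------------------
    def to_bed(self, path: str) -> None:
        """Write BED6+2 (columns 7/8 carry class/family and milliDiv)."""
        df = self.copies
        with open(path, "w") as fh:
            for row in df.itertuples(index=False):
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t{row.type_name}\t0\t"
                    f"{row.strand}\t{row.te_class}/{row.te_family}\t{row.millidiv:g}\n"
                )

    def to_rmsk_tsv(self, path: str) -> None:
        """Write a UCSC rmsk-style TSV (0-based half-open starts)."""
        df = self.copies.rename(
            columns={
                "chrom": "genoName",
                "start": "genoStart",
                "end": "genoEnd",
                "type_name": "repName",
                "te_class": "repClass",
                "te_family": "repFamily",
                "millidiv": "milliDiv",
            }
        )
        cols = ["genoName", "genoStart", "genoEnd", "strand", "repName", "repClass", "repFamily", "milliDiv"]
        df[cols].to_csv(path, sep="\t", index=False)


def _parse_bed_line(parts: list[str]) -> dict:
    chrom, start, end = parts[0], int(parts[1]), int(parts[2])
    name = parts[3] if len(parts) > 3 else "unknown"
    strand = parts[5] if len(parts) > 5 else "+"
    te_class, te_family, millidiv = "other", "", 0.0
    if len(parts) > 6 and parts[6]:
        cf = parts[6].split("/")
        te_class = cf[0]
        te_family = cf[1] if len(cf) > 1 else ""
    if len(parts) > 7:
        millidiv = float(parts[7])
    return dict(
        chrom=chrom, start=start, end=end, strand=strand, type_name=name,
        te_class=te_class, te_family=te_family, millidiv=millidiv,
    )


def read_repeatmasker(path: str, dialect: str = "ucsc_rmsk", skip_malformed: bool = False) -> TETypeCatalog:
    """Read a TE annotation into a :class:`TETypeCatalog`.

    Parameters
    ----------
    dialect
        ``ucsc_rmsk`` — tab-separated with a header naming at least
        ``genoName, genoStart, genoEnd, strand, repName, repClass,
        repFamily, milliDiv`` (0-based half-open, as in the UCSC table).
        ``rmsk_out`` — native RepeatMasker ``.out`` (1-based inclusive,
        ``C`` for minus strand, divergence in percent).
        ``bed`` — BED6, optionally with class/family in column 7 and
        milliDiv in column 8.
    skip_malformed
        Skip unparseable lines with a warning instead of failing.
    """
    records: list[dict] = []

    def handle(lineno: int, exc: Exception) -> None:
        msg = f"{path}:{lineno}: {exc}"
        if skip_malformed:
            warnings.warn(f"skipping malformed line {msg}")
        else:
            raise CatalogError(msg) from exc

    if dialect == "ucsc_rmsk":
        df = pd.read_csv(path, sep="\t")
        required = ["genoName", "genoStart", "genoEnd", "strand", "repName", "repClass", "repFamily", "milliDiv"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise CatalogError(f"{path}: missing rmsk columns {missing}")
        records = [
            dict(
                chrom=r.genoName, start=int(r.genoStart), end=int(r.genoEnd),
                strand="-" if r.strand in ("-", "C") else "+",
                type_name=r.repName, te_class=str(r.repClass),
                te_family=str(r.repFamily), millidiv=float(r.milliDiv),
            )
            for r in df.itertuples(index=False)
        ]
    elif dialect == "rmsk_out":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                stripped = line.strip()
                if not stripped or stripped.startswith(("SW", "score", "There were no")):
                    continue
                parts = stripped.split()
                try:
                    if len(parts) < 11:
                        raise ValueError(f"expected >= 11 fields, got {len(parts)}")
                    div_pct = float(parts[1])
                    chrom = parts[4]
                    start = int(parts[5]) - 1  # 1-based inclusive -> 0-based half-open
                    end = int(parts[6])
                    strand = "-" if parts[8] == "C" else "+"
                    name = parts[9]
                    cf = parts[10].split("/")
                    records.append(
                        dict(
                            chrom=chrom, start=start, end=end, strand=strand,
                            type_name=name, te_class=cf[0],
                            te_family=cf[1] if len(cf) > 1 else "",
                            millidiv=min(1000.0, div_pct * 10.0),
                        )
                    )
                except (ValueError, IndexError) as exc:
                    handle(lineno, exc)
    elif dialect == "bed":
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                stripped = line.rstrip("\n")
                if not stripped or stripped.startswith(("track", "browser", "#")):
                    continue
                try:
                    records.append(_parse_bed_line(stripped.split("\t")))
                except (ValueError, IndexError) as exc:
                    handle(lineno, exc)
    else:
        raise CatalogError(f"unknown dialect: {dialect!r}")

    df = pd.DataFrame(records, columns=CATALOG_COLUMNS)
    return TETypeCatalog(df)


def filter_te_catalog(catalog: TETypeCatalog, min_len: int = 300, min_copies: int = 50) -> TETypeCatalog:
    """Apply the copy-length then copy-number filter.

    Copies shorter than ``min_len`` are removed first; TE types whose
    *remaining* copy count falls below ``min_copies`` are then dropped
    entirely.  The order matters (a type can lose enough short copies to
    fall under the copy threshold) and is fixed: length first.
    """
    if min_len < 0 or min_copies < 0:
        raise ValueError("thresholds must be >= 0")
    df = catalog.copies
    df = df[(df["end"] - df["start"]) >= min_len]
    counts = df.groupby("type_name")["chrom"].transform("size")
    df = df[counts >= min_copies]
    return TETypeCatalog(df.reset_index(drop=True))


def split_lines_by_length(
    catalog: TETypeCatalog, cutoff: int = 5000, te_classes: tuple[str, ...] = ("LINE",)
) -> TETypeCatalog:
    """Split each LINE type into long/short pseudo-types at ``cutoff`` bp.

    Copies strictly longer than ``cutoff`` become ``<type>__long``; all
    others (including copies exactly at the cutoff) become
    ``<type>__short``.  Non-LINE classes pass through unchanged.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be > 0")
    df = catalog.copies.copy()
    in_class = df["te_class"].isin(te_classes)
    lengths = df["end"] - df["start"]
    suffix = np.where(lengths > cutoff, "__long", "__short")
    df.loc[in_class, "type_name"] = df.loc[in_class, "type_name"] + pd.Series(suffix, index=df.index)[in_class]
    return TETypeCatalog(df)


def merge_split_types(catalog: TETypeCatalog) -> TETypeCatalog:
    """Undo :func:`split_lines_by_length` by stripping the pseudo-type suffix."""
    df = catalog.copies.copy()
    df["type_name"] = df["type_name"].str.replace(r"__(long|short)$", "", regex=True)
    return TETypeCatalog(df)


def estimate_te_age(
    catalog: TETypeCatalog,
    rate: float = JC_SUBSTITUTION_RATE,
    doubled_rate: bool = False,
    length_weighted: bool = False,
) -> pd.DataFrame:
    """Estimate per-type age from mean milliDiv via the Jukes-Cantor distance.

    The per-type proportion of divergent sites ``p = mean(milliDiv)/1000``
    is corrected for multiple hits, ``d = -(3/4) ln(1 - (4/3) p)``, and
    converted to years as ``T = d / rate`` (single-lineage convention:
    milliDiv measures divergence of a copy from its consensus, taken as
    the ancestral state).  ``doubled_rate=True`` uses ``d / (2 rate)``
    instead, the pairwise-divergence convention.  Types whose ``p``
    reaches the JC domain boundary (3/4) are flagged with undefined age
    rather than dropped.

    Returns a DataFrame indexed by type with columns ``p``, ``jc_distance``,
    ``age_years``, ``jc_defined``.
    """
    df = catalog.copies.assign(length=catalog.lengths())
    if length_weighted:
        def _p(g: pd.DataFrame) -> float:
            return float(np.average(g["millidiv"], weights=g["length"])) / 1000.0
        p = df.groupby("type_name").apply(_p, include_groups=False)
    else:
        p = df.groupby("type_name")["millidiv"].mean() / 1000.0
    defined = p < 0.75
    d = pd.Series(np.nan, index=p.index)
    d[defined] = -0.75 * np.log1p(-(4.0 / 3.0) * p[defined])
    divisor = 2.0 * rate if doubled_rate else rate
    out = pd.DataFrame(
        {"p": p, "jc_distance": d, "age_years": d / divisor, "jc_defined": defined}
    )
    if (~defined).any():
        warnings.warn(
            f"{(~defined).sum()} TE type(s) exceed the Jukes-Cantor domain (p >= 0.75); age undefined"
        )
    return out.sort_index()


def jukes_cantor_age(millidiv: float, rate: float = JC_SUBSTITUTION_RATE, doubled_rate: bool = False) -> float:
    """Scalar Jukes-Cantor age (years) for a milliDiv value; NaN outside the domain."""
    p = millidiv / 1000.0
    if p >= 0.75:
        return math.nan
    d = -0.75 * math.log1p(-(4.0 / 3.0) * p)
    return d / (2.0 * rate if doubled_rate else rate)


def compute_gc_content(catalog: TETypeCatalog, genome_fasta: str) -> pd.DataFrame:
    """Per-type mean GC fraction over copy intervals.

    GC is computed per copy over ``[start, end)`` with ``N`` bases
    excluded from the denominator, then averaged (unweighted) per type.
    """
    from pyfaidx import Fasta

    fasta = Fasta(genome_fasta)
    per_copy = []
    for row in catalog.copies.itertuples(index=False):
        if row.chrom not in fasta:
            raise CatalogError(f"chromosome {row.chrom!r} not present in {genome_fasta}")
        seq = str(fasta[row.chrom][row.start:row.end]).upper()
        acgt = sum(seq.count(b) for b in "ACGT")
        gc = (seq.count("G") + seq.count("C")) / acgt if acgt else math.nan
        per_copy.append((row.type_name, gc))
    df = pd.DataFrame(per_copy, columns=["type_name", "gc"])
    return df.groupby("type_name")["gc"].mean().to_frame("gc_fraction")
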