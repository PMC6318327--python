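"""ATAC-seq accessibility at TE types: the 20% open/close rule, peak-gene
linkage, and mark enrichment among opened types.

Accessibility of a TE type is the length-weighted mean per-base RPKM over
all of its copies (an overall-accessibility measure, unlike the max-bin
enrichment statistic; a max-bin variant is available via ``statistic``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import TETypeCatalog
from .coverage import CoverageTrack
from .enrichment import bin_te_type

__all__ = [
    "quantify_te_accessibility",
    "call_accessibility_changes",
    "summarize_opened_tes",
    "link_peaks_to_genes",
    "test_mark_enrichment_of_opened",
]


def quantify_te_accessibility(
    tracks: dict[str, CoverageTrack],
    catalog: TETypeCatalog,
    statistic: str = "mean",
    bin_bp: int = 500,
) -> pd.DataFrame:
    """TE type x sample accessibility table.

    ``mean`` (default): total signal over all the type's copies divided by
    total copy bases (length-weighted).  ``max_bin``: the metagene
    max-bin statistic instead.
    """
    rows = {}
    for sample in sorted(tracks):
        track = tracks[sample]
        col = {}
        for te_type in catalog.type_names:
            copies = catalog.copies_of(te_type)
            if statistic == "mean":
                total = 0.0
                bases = 0
                for row in copies.itertuples(index=False):
                    seg = track.values[row.chrom][row.start:row.end]
                    total += float(np.sum(seg))
                    bases += len(seg)
                col[te_type] = total / bases if bases else np.nan
            elif statistic == "max_bin":
                col[te_type] = bin_te_type(track, copies, bin_bp).max_bin
            else:
                raise ValueError(f"unknown statistic: {statistic!r}")
        rows[sample] = col
        if all(v == 0 for v in col.values()):
            warnings.warn(f"sample {sample!r} has zero coverage at every TE type")
    return pd.DataFrame(rows)


@dataclass
class AccessibilityCalls:
    """Fold vs control and the opened/closed/unchanged state per (type, sample)."""

    fold: pd.DataFrame  # TE type x non-control samples
    state: pd.DataFrame  # same shape, values in {opened, closed, unchanged}
    control: str
    up: float
    down: float


def call_accessibility_changes(
    table: pd.DataFrame,
    control_sample: str,
    up: float = 1.2,
    down: float = 0.8,
    pseudocount: float = 0.01,
) -> AccessibilityCalls:
    """Apply the 20%-more / 20%-less rule vs the control sample.

    ``opened`` when fold >= ``up`` (1.2 = 20% more open), ``closed`` when
    fold <= ``down`` (0.8), otherwise ``unchanged``; the pseudocount is
    added to both sides before the ratio.
    """
    if control_sample not in table.columns:
        raise KeyError(f"control sample {control_sample!r} not in table")
    others = [c for c in table.columns if c != control_sample]
    fold = (table[others] + pseudocount).div(table[control_sample] + pseudocount, axis=0)
    state = pd.DataFrame("unchanged", index=fold.index, columns=fold.columns)
    state = state.mask(fold >= up, "opened").mask(fold <= down, "closed")
    return AccessibilityCalls(fold=fold, state=state, control=control_sample, up=up, down=down)


def summarize_opened_tes(states: pd.DataFrame) -> dict:
    """Partition opened TE types by knockdown multiplicity.

    ``unique`` = types opened in exactly one knockdown, ``shared`` = in
    more than one; with a single knockdown column, shared is 0 by
    definition.
    """
    opened_by_kd = {kd: set(states.index[states[kd] == "opened"]) for kd in states.columns}
    multiplicity: dict[str, int] = {}
    for s in opened_by_kd.values():
        for te in s:
            multiplicity[te] = multiplicity.get(te, 0) + 1
    unique = sorted(t for t, m in multiplicity.items() if m == 1)
    shared = sorted(t for t, m in multiplicity.items() if m >= 2)
    return {
        "opened_by_knockdown": opened_by_kd,
        "unique": unique,
        "shared": shared,
        "n_unique": len(unique),
        "n_shared": len(shared),
    }


def _interval_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap between two half-open intervals; 0 when they overlap or touch."""
    if a_end <= b_start:
        return b_start - a_end
    if b_end <= a_start:
        return a_start - b_end
    return 0


def link_peaks_to_genes(peaks: pd.DataFrame, genes: pd.DataFrame, window: int = 10000) -> pd.DataFrame:
    """Link each peak to every gene whose gene body lies within ``window`` bp.

    ``peaks`` needs columns ``chrom, start, end`` (and optionally
    ``peak_id``); ``genes`` needs ``gene_id, chrom, start, end``.
    Overlapping pairs get distance 0.  Returns (peak_id, gene_id,
    distance) rows.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for g in genes.itertuples(index=False):
        # +1 so a peak starting exactly `window` bp away still overlaps the
        # half-open query interval; the distance filter below stays exact
        trees.setdefault(g.chrom, IntervalTree()).addi(
            max(0, g.start - window), g.end + window + 1, (g.gene_id, g.start, g.end)
        )
    rows = []
    for i, p in enumerate(peaks.itertuples(index=False)):
        pid = getattr(p, "peak_id", None) or f"peak{i}"
        for iv in trees.get(p.chrom, IntervalTree()).overlap(p.start, p.end):
            gene_id, gs, ge = iv.data
            d = _interval_distance(p.start, p.end, gs, ge)
            if d <= window:
                rows.append((pid, gene_id, d))
    return pd.DataFrame(sorted(rows), columns=["peak_id", "gene_id", "distance"])


def test_mark_enrichment_of_opened(
    states: pd.DataFrame,
    mark_calls: pd.DataFrame,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Fisher exact test: are mark-enriched TE types over-represented among
    the types that open after a knockdown?

    ``mark_calls`` is the boolean marks x TE-types call table.  The TE
    universe is the intersection of both inputs.  One two-sided Fisher
    exact test per (knockdown, mark); significance at P < ``alpha``;
    a 2x2 table with an empty margin yields NA.
    """
    universe = [t for t in states.index if t in set(mark_calls.columns)]
    if not universe:
        raise ValueError("no shared TE types between states and mark calls")
    rows = []
    for kd in states.columns:
        opened = states.loc[universe, kd] == "opened"
        for mark in mark_calls.index:
            enriched = mark_calls.loc[mark, universe].astype(bool)
            a = int((opened & enriched.values).sum())
            b = int((opened & ~enriched.values).sum())
            c = int((~opened & enriched.values).sum())
            d = int((~opened & ~enriched.values).sum())
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                rows.append((kd, mark, a, b, c, d, np.nan, np.nan, None))
                continue
            odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            rows.append((kd, mark, a, b, c, d, float(odds), float(p), bool(p < alpha)))
    return pd.DataFrame(
        rows,
        columns=["knockdown", "mark", "opened_enriched", "opened_other",
                 "closed_enriched", "closed_other", "odds_ratio", "p", "significant"],
    )
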