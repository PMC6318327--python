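"""Genome coverage tracks: dense per-base signal plus bedGraph/bigWig I/O.

Tracks hold RPKM-normalized coverage as one float64 array per chromosome.
This is the internal representation behind every enrichment and
accessibility computation; file format (bedGraph or bigWig) is erased on
read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CoverageTrack",
    "read_chrom_sizes",
    "read_coverage",
    "write_bigwig",
    "bam_to_rpkm_track",
]


class CoverageError(ValueError):
    pass


@dataclass
class CoverageTrack:
    """Per-base signal over a genome.

    ``values`` maps chromosome name to a float64 array of length equal to
    the chromosome size; values are RPKM-like and non-negative.
    """

    values: dict[str, np.ndarray]
    label: str = ""

    def __post_init__(self) -> None:
        self.values = {c: np.asarray(v, dtype=np.float64) for c, v in self.values.items()}

    @classmethod
    def zeros(cls, chrom_sizes: dict[str, int], label: str = "") -> "CoverageTrack":
        return cls({c: np.zeros(n, dtype=np.float64) for c, n in chrom_sizes.items()}, label=label)

    @classmethod
    def constant(cls, chrom_sizes: dict[str, int], value: float, label: str = "") -> "CoverageTrack":
        return cls({c: np.full(n, float(value)) for c, n in chrom_sizes.items()}, label=label)

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.values.items()}

    def mean(self, chrom: str, start: int, end: int) -> float:
        seg = self.values[chrom][start:end]
        if len(seg) == 0:
            return float("nan")
        return float(np.sum(seg) / len(seg))

    def genome_mean(self) -> float:
        total = sum(float(np.sum(v)) for v in self.values.values())
        n = sum(len(v) for v in self.values.values())
        return total / n if n else float("nan")

    def write_bedgraph(self, path: str) -> None:
        """Write run-length-encoded bedGraph (6 significant digits)."""
        with open(path, "w") as fh:
            for chrom in sorted(self.values):
                arr = self.values[chrom]
                if len(arr) == 0:
                    continue
                breaks = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], breaks))
                ends = np.concatenate((breaks, [len(arr)]))
                for s, e in zip(starts, ends):
                    fh.write(f"{chrom}\t{s}\t{e}\t{arr[s]:.6g}\n")


def read_chrom_sizes(path: str) -> dict[str, int]:
    """Read a two-column ``name<TAB>length`` chrom.sizes file."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, size = line.split()[:2]
            out[name] = int(size)
    return out


def read_coverage(path: str, chrom_sizes: dict[str, int], format: str | None = None, label: str = "") -> CoverageTrack:
    """Read bedGraph or bigWig into a :class:`CoverageTrack`.

    Overlapping input intervals are an error (the signal would be
    ambiguous); intervals extending past the chromosome end are clipped
    with a warning.  ``format`` is inferred from the extension when None.
    """
    if format is None:
        lower = path.lower()
        format = "bigwig" if lower.endswith((".bw", ".bigwig")) else "bedgraph"
    track = CoverageTrack.zeros(chrom_sizes, label=label or path)
    if format == "bedgraph":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": np.float64},
        ) if _nonempty(path) else pd.DataFrame(columns=["chrom", "start", "end", "value"])
        for chrom, sub in df.groupby("chrom", sort=False):
            if chrom not in chrom_sizes:
                warnings.warn(f"{path}: skipping unknown chromosome {chrom}")
                continue
            sub = sub.sort_values("start")
            if (sub["end"].values[:-1] > sub["start"].values[1:]).any():
                raise CoverageError(f"{path}: overlapping intervals on {chrom}")
            size = chrom_sizes[chrom]
            if (sub["end"] > size).any():
                warnings.warn(f"{path}: clipping intervals past end of {chrom}")
            arr = track.values[chrom]
            for s, e, v in zip(sub["start"].values, sub["end"].values, sub["value"].values):
                arr[max(0, s):min(e, size)] = v
    elif format == "bigwig":
        import pyBigWig

        bw = pyBigWig.open(path)
        try:
            for chrom in chrom_sizes:
                if chrom not in bw.chroms():
                    continue
                size = min(chrom_sizes[chrom], bw.chroms(chrom))
                vals = np.nan_to_num(np.asarray(bw.values(chrom, 0, size), dtype=np.float64))
                track.values[chrom][:size] = vals
        finally:
            bw.close()
    else:
        raise CoverageError(f"unknown coverage format: {format!r}")
    return track


def _nonempty(path: str) -> bool:
    import os

    return os.path.getsize(path) > 0


def write_bigwig(track: CoverageTrack, path: str) -> None:
    """Write the track as bigWig (run-length encoded intervals)."""
    import pyBigWig

    bw = pyBigWig.open(path, "w")
    sizes = track.chrom_sizes
    header = [(c, sizes[c]) for c in sorted(sizes)]
    bw.addHeader(header)
    for chrom, _ in header:
        arr = track.values[chrom]
        if len(arr) == 0:
            continue
        breaks = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate(([0], breaks)).astype(np.int64)
        ends = np.concatenate((breaks, [len(arr)])).astype(np.int64)
        bw.addEntries(
            [chrom] * len(starts), starts.tolist(), ends=ends.tolist(),
            values=arr[starts].astype(np.float64).tolist(),
        )
    bw.close()


def bam_to_rpkm_track(
    bam_path: str,
    chrom_sizes: dict[str, int],
    bin_bp: int = 50,
    exclude_contigs: tuple[str, ...] = ("chrM", "MT"),
) -> CoverageTrack:
    """Plumbing helper: binned RPKM coverage from a coordinate-sorted BAM.

    RPKM per bin = reads overlapping the bin / (bin length in kb x mapped
    reads in millions), painted per base.  Upstream pipelines normally
    supply pre-normalized tracks; this exists so toy BAMs can enter the
    pipeline without external tools.
    """
    import pysam

    counts = {c: np.zeros(int(np.ceil(n / bin_bp))) for c, n in chrom_sizes.items()}
    total = 0
    with pysam.AlignmentFile(bam_path) as bam:
        for aln in bam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            chrom = aln.reference_name
            if chrom in exclude_contigs or chrom not in counts:
                continue
            total += 1
            b0 = aln.reference_start // bin_bp
            b1 = (aln.reference_end - 1) // bin_bp
            counts[chrom][b0:b1 + 1] += 1
    track = CoverageTrack.zeros(chrom_sizes, label=bam_path)
    if total == 0:
        return track
    scale = 1.0 / ((bin_bp / 1000.0) * (total / 1e6))
    for chrom, size in chrom_sizes.items():
        per_bin = counts[chrom] * scale
        track.values[chrom][:] = np.repeat(per_bin, bin_bp)[:size]
    return track
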