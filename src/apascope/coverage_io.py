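"""Per-base coverage loading, orientation, normalization, and merging.

Coverage comes in as bedGraph (UCSC dialect, 0-based half-open intervals).
Each gene's track is extracted over its extended 3'UTR region and oriented
transcript 5'->3': index 0 is the first base after the stop codon
regardless of genomic strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from apascope.annotation_io import UTR3Region
from apascope.errors import CoverageError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CoverageTrack:
    """Transcript-oriented per-base coverage over an extended 3'UTR.

    ``scale`` records the depth-normalization factor applied to the raw
    counts (1.0 when raw).
    """

    sample_id: str
    gene_id: str
    values: np.ndarray
    lib_size: int
    scale: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise CoverageError("coverage must be a 1-D array")
        if np.any(self.values < 0):
            raise CoverageError("coverage values must be non-negative")


def read_bedgraph(path) -> pd.DataFrame:
    """Load a bedGraph file as a (chrom, start, end, value) frame."""
    df = pd.read_csv(
        path,
        sep=r"\s+",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        usecols=[0, 1, 2, 3],
        dtype={"chrom": str},
        engine="python",
    )
    df = df[~df["chrom"].isin(["track", "browser"])].reset_index(drop=True)
    df[["start", "end"]] = df[["start", "end"]].astype(int)
    df["value"] = df["value"].astype(float)
    return df


def read_coverage(
    track_path,
    region: UTR3Region,
    sample_id: str,
    lib_size: int,
) -> CoverageTrack:
    """Extract raw per-base coverage for one region from a bedGraph file.

    Positions absent from the bedGraph are zero. Minus-strand regions are
    reversed so the array always runs transcript 5'->3'. Overlapping
    intervals on the region's chromosome are an error; a chromosome that
    is absent altogether yields an all-zero track with a logged warning.
    """
    df = read_bedgraph(track_path)
    sub = df[df["chrom"] == region.chrom].sort_values(["start", "end"])
    length = region.utr_end3 - region.utr_start3
    values = np.zeros(length, dtype=float)
    if sub.empty:
        logger.warning(
            "%s: chromosome %s absent from %s; zero coverage",
            region.gene_id, region.chrom, track_path,
        )
        return CoverageTrack(sample_id, region.gene_id, values, lib_size)
    starts = sub["start"].to_numpy()
    ends = sub["end"].to_numpy()
    if np.any(starts[1:] < ends[:-1]):
        i = int(np.argmax(starts[1:] < ends[:-1])) + 1
        raise CoverageError(
            f"{track_path}: overlapping bedGraph intervals on {region.chrom}: "
            f"[{starts[i - 1]},{ends[i - 1]}) and [{starts[i]},{ends[i]})"
        )
    for s, e, v in zip(starts, ends, sub["value"].to_numpy()):
        lo = max(s, region.utr_start3) - region.utr_start3
        hi = min(e, region.utr_end3) - region.utr_start3
        if hi > lo:
            values[lo:hi] = v
    if region.strand == "-":
        values = values[::-1].copy()
    return CoverageTrack(sample_id, region.gene_id, values, lib_size)


def normalize_depth(track: CoverageTrack, per_million: bool = True) -> CoverageTrack:
    """Scale coverage to per-million-mapped-fragments depth.

    Re-normalizing an already scaled track is rejected so the factor is
    applied exactly once.
    """
    if track.lib_size <= 0:
        raise CoverageError(f"{track.sample_id}: lib_size must be positive")
    if not per_million:
        return replace(track, values=track.values.copy(), scale=1.0)
    if track.scale != 1.0:
        raise CoverageError(f"{track.sample_id}: track already normalized (scale={track.scale})")
    factor = 1e6 / track.lib_size
    return replace(track, values=track.values * factor, scale=factor)


def merge_tracks(tracks: list[CoverageTrack]) -> CoverageTrack:
    """Element-wise sum of same-gene tracks (the combined coverage used to
    define the distal polyA site)."""
    if not tracks:
        raise CoverageError("no tracks to merge")
    first = tracks[0]
    for t in tracks[1:]:
        if t.gene_id != first.gene_id:
            raise CoverageError("cannot merge tracks from different genes")
        if len(t.values) != len(first.values):
            raise CoverageError(
                f"length mismatch merging {t.sample_id} ({len(t.values)}) "
                f"with {first.sample_id} ({len(first.values)})"
            )
    total = np.sum([t.values for t in tracks], axis=0)
    return CoverageTrack(
        sample_id="merged",
        gene_id=first.gene_id,
        values=total,
        lib_size=sum(t.lib_size for t in tracks),
    )


class BedGraphIndex:
    """One-pass bedGraph load with fast per-region extraction.

    Validates interval sortedness/non-overlap per chromosome once, then
    serves per-gene extraction via binary search — the pipeline extracts
    hundreds of regions per sample file.
    """

    def __init__(self, path):
        self.path = str(path)
        df = read_bedgraph(path)
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            sub = sub.sort_values(["start", "end"])
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if np.any(starts[1:] < ends[:-1]):
                i = int(np.argmax(starts[1:] < ends[:-1])) + 1
                raise CoverageError(
                    f"{path}: overlapping bedGraph intervals on {chrom}: "
                    f"[{starts[i - 1]},{ends[i - 1]}) and [{starts[i]},{ends[i]})"
                )
            self._chroms[chrom] = (starts, ends, sub["value"].to_numpy(dtype=float))

    def extract(self, region: UTR3Region, sample_id: str, lib_size: int) -> CoverageTrack:
        length = region.utr_end3 - region.utr_start3
        values = np.zeros(length, dtype=float)
        entry = self._chroms.get(region.chrom)
        if entry is None:
            logger.warning(
                "%s: chromosome %s absent from %s; zero coverage",
                region.gene_id, region.chrom, self.path,
            )
        else:
            starts, ends, vals = entry
            lo = int(np.searchsorted(ends, region.utr_start3, side="right"))
            hi = int(np.searchsorted(starts, region.utr_end3, side="left"))
            for s, e, v in zip(starts[lo:hi], ends[lo:hi], vals[lo:hi]):
                a = max(s, region.utr_start3) - region.utr_start3
                b = min(e, region.utr_end3) - region.utr_start3
                if b > a:
                    values[a:b] = v
        if region.strand == "-":
            values = values[::-1].copy()
        return CoverageTrack(sample_id, region.gene_id, values, lib_size)


def read_sample_sheet(path) -> pd.DataFrame:
    """Sample sheet TSV: sample_id, group, compartment, path, lib_size."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    required = {"sample_id", "group", "compartment", "path", "lib_size"}
    missing = required - set(df.columns)
    if missing:
        raise CoverageError(f"sample sheet missing columns: {sorted(missing)}")
    return df
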