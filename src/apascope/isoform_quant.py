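"""Isoform-level abundance: FPKM, long/short 3'UTR decomposition, ddCT.

The decomposition follows the distal-exon logic: per-base read density
over the distal-most exon, normalized to density over the domain common
to the long and short 3'UTR isoforms, estimates the fraction of
transcripts carrying the long 3'UTR; total FPKM splits accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from apascope.coverage_io import CoverageTrack
from apascope.errors import ApascopeError


@dataclass(frozen=True)
class IsoformAbundance:
    gene_id: str
    fpkm_total: float
    f_long: float
    fpkm_long: float
    fpkm_short: float


def fpkm(fragments: float, length_bp: int, total_fragments: int) -> float:
    """Fragments per kilobase of exon per million mapped fragments."""
    if length_bp <= 0:
        raise ValueError("length_bp must be positive")
    if total_fragments <= 0:
        raise ValueError("total_fragments must be positive")
    return fragments * 1e9 / (length_bp * total_fragments)


def split_by_distal_exon(
    common_density: float,
    distal_density: float,
    fpkm_total: float,
    gene_id: str = "",
) -> IsoformAbundance:
    """Decompose total FPKM into long/short 3'UTR isoform shares.

    f_long = min(1, distal_density / common_density): over-unity ratios
    from sampling noise clip to 1 rather than erroring.
    """
    if common_density <= 0:
        if distal_density > 0:
            raise ApascopeError(
                f"{gene_id or 'gene'}: distal coverage without common-domain coverage; "
                "f_long undefined"
            )
        f_long = 0.0
    else:
        f_long = min(1.0, distal_density / common_density)
    fpkm_long = fpkm_total * f_long
    return IsoformAbundance(
        gene_id=gene_id,
        fpkm_total=fpkm_total,
        f_long=f_long,
        fpkm_long=fpkm_long,
        fpkm_short=fpkm_total - fpkm_long,
    )


def segment_density(track: CoverageTrack, start: int, end: int) -> float:
    """Per-base mean coverage over a transcript-relative segment [start, end)."""
    if not (0 <= start < end <= len(track.values)):
        raise ValueError(f"segment [{start},{end}) outside track of length {len(track.values)}")
    return float(track.values[start:end].mean())


def ddct_fold(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Comparative-CT fold change 2^-ddCT."""
    cts = (ct_target_test, ct_ref_test, ct_target_ctrl, ct_ref_ctrl)
    if not all(np.isfinite(cts)):
        raise ValueError("all CT values must be finite")
    ddct = (ct_target_test - ct_ref_test) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
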