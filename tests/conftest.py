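import numpy as np
import pytest

from apascope.annotation_io import GeneModel, UTR3Region
from apascope.coverage_io import CoverageTrack


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


def make_gene(
    gene_id="g1",
    chrom="chr1",
    strand="+",
    tx_start=100,
    tx_end=1000,
    cds_end3=600,
    exons=None,
    transcript_id=None,
):
    return GeneModel(
        gene_id=gene_id,
        transcript_id=transcript_id or gene_id,
        chrom=chrom,
        strand=strand,
        tx_start=tx_start,
        tx_end=tx_end,
        cds_end3=cds_end3,
        exons=exons or ((tx_start, tx_end),),
    )


def make_region(gene_id="g1", strand="+", start=0, length=200, annotated=None):
    return UTR3Region(
        gene_id=gene_id,
        chrom="chr1",
        strand=strand,
        utr_start3=start,
        utr_end3=start + length,
        annotated_len=annotated if annotated is not None else length,
        extended_len=length,
        extension_cap_hit="none",
    )


def make_track(values, sample_id="s1", gene_id="g1", lib_size=1_000_000):
    return CoverageTrack(sample_id, gene_id, np.asarray(values, dtype=float), lib_size)


# --- independent oracles --------------------------------------------------

def brute_force_breakpoint(value_arrays, min_flank=50):
    """Exhaustive enumeration of the joint two-isoform least-squares fit.

    Loops every candidate breakpoint and recomputes per-sample weights
    and residuals with plain numpy means — independent of the prefix-sum
    implementation it checks.
    """
    D = len(value_arrays[0])
    best = None
    for P in range(min_flank, D - min_flank):
        rss = 0.0
        weights = []
        for v in value_arrays:
            wl = float(np.mean(v[P + 1:]))
            ws = max(0.0, float(np.mean(v[: P + 1])) - wl)
            pred = np.where(np.arange(D) <= P, wl + ws, wl)
            rss += float(np.sum((v - pred) ** 2))
            weights.append((wl, ws))
        if best is None or rss < best[1] - 1e-12:
            best = (P, rss, weights)
    return best


def brute_force_distal_end(values, anchor_len=100, frac=0.05, min_abs=1.0, gap_tol=50):
    """Literal run/gap scan of the distal-end definition."""
    anchor = values[: min(anchor_len, len(values))]
    if len(anchor) == 0 or anchor.mean() <= 0:
        return None
    thr = max(min_abs, frac * anchor.mean())
    last, gap = -1, 0
    for i, v in enumerate(values):
        if v >= thr:
            last, gap = i, 0
        else:
            gap += 1
            if gap > gap_tol:
                break
    return last + 1 if last >= 0 else None


def fisher_two_sided_enumeration(table):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    from math import comb

    (a, b), (c, d) = table
    row1, col1, n = a + b, a + c, a + b + c + d
    denom = comb(n, row1)
    p_obs = comb(col1, a) * comb(n - col1, row1 - a) / denom
    p = 0.0
    for x in range(max(0, row1 - (n - col1)), min(row1, col1) + 1):
        px = comb(col1, x) * comb(n - col1, row1 - x) / denom
        if px <= p_obs * (1 + 1e-9):
            p += px
    return p
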