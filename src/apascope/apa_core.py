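"""Two-isoform breakpoint regression and PDUI/DPDUI statistics.

The model: a gene expresses a long 3'UTR isoform reaching the distal
polyA site D and a short isoform ending at a proximal breakpoint P.
Expected per-base coverage for sample s is

    mu_s(i) = w_long_s + w_short_s   for i <= P
    mu_s(i) = w_long_s               for i >  P

with w_long_s the distal-isoform per-base density and w_short_s >= 0 the
extra density contributed by the short isoform over [0, P]. A single
breakpoint is fitted jointly across all samples (per-sample weights, one
shared P) by least squares over every candidate P; PDUI_s =
w_long_s / (w_long_s + w_short_s) is the fraction of transcripts using
the distal site.

Group comparison converts the fitted densities to read-equivalents
(density x segment length / fragment length), pools them per group into a
2x2 long/short table, and tests with Fisher's exact test; q-values come
from Benjamini-Hochberg across genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from apascope.coverage_io import CoverageTrack
from apascope.errors import CoverageError

logger = logging.getLogger(__name__)

#: default mean library insert (fragment) length in nt
DEFAULT_FRAG_LEN = 350


@dataclass
class APAFit:
    """Joint breakpoint fit for one gene.

    ``distal_end`` is the transcript-relative exclusive offset D of the
    distal polyA site; ``breakpoint`` is the last base covered by the
    short isoform (0-based inclusive), or None when untestable.
    """

    gene_id: str
    distal_end: int
    breakpoint: int | None
    w_long: dict[str, float] = field(default_factory=dict)
    w_short: dict[str, float] = field(default_factory=dict)
    pdui: dict[str, float | None] = field(default_factory=dict)
    rss: float = math.nan
    testable: bool = True
    degenerate: bool = False


@dataclass
class APAComparison:
    """Group-level DPDUI with significance and classification."""

    gene_id: str
    pdui_mean_a: float
    pdui_mean_b: float
    dpdui: float
    p_value: float
    counts_2x2: tuple[tuple[int, int], tuple[int, int]]
    q_value: float = math.nan
    label: str = "unchanged"


def detect_distal_end(
    merged: CoverageTrack,
    anchor_len: int = 100,
    frac: float = 0.05,
    min_abs: float = 1.0,
    gap_tol: int = 50,
) -> int | None:
    """Locate the distal polyA site D on the merged coverage track.

    D is one past the last base reachable from the 3'UTR start through
    runs of coverage >= max(min_abs, frac * anchor mean) without crossing
    a zero/low gap longer than ``gap_tol``. Returns None (untestable)
    when the anchor region has no coverage.
    """
    v = merged.values
    anchor = v[: min(anchor_len, len(v))]
    anchor_mean = float(anchor.mean()) if len(anchor) else 0.0
    if anchor_mean <= 0:
        return None
    thr = max(min_abs, frac * anchor_mean)
    idx = np.flatnonzero(v >= thr)
    if idx.size == 0 or idx[0] > gap_tol:
        return None
    gaps = np.diff(idx) - 1
    over = np.flatnonzero(gaps > gap_tol)
    last = int(idx[over[0]]) if over.size else int(idx[-1])
    return last + 1


def fit_breakpoint(
    tracks: Sequence[CoverageTrack],
    min_flank: int = 50,
) -> APAFit:
    """Fit the shared proximal breakpoint by exhaustive least squares.

    Every candidate P in [min_flank, D - min_flank) is scored: per sample
    w_long = mean coverage over (P, D), w_short = max(0, mean over [0, P]
    - w_long), and the total squared residual is summed over all samples.
    Ties break toward the smallest P (the most proximal site). Runs in
    O(D) per sample via prefix sums.
    """
    if not tracks:
        raise CoverageError("fit_breakpoint requires at least one track")
    D = len(tracks[0].values)
    gene_id = tracks[0].gene_id
    if any(len(t.values) != D for t in tracks):
        raise CoverageError("all tracks must share the truncated length D")
    if D < 2 * min_flank:
        return APAFit(gene_id=gene_id, distal_end=D, breakpoint=None, testable=False)

    cand = np.arange(min_flank, D - min_flank)  # candidate P values
    n_pre = cand + 1.0
    n_post = D - cand - 1.0
    total_rss = np.zeros(len(cand))
    per_sample = []
    for t in tracks:
        v = t.values
        s1 = np.concatenate(([0.0], np.cumsum(v)))
        s2 = np.concatenate(([0.0], np.cumsum(v * v)))
        sum_pre = s1[cand + 1]
        sum2_pre = s2[cand + 1]
        sum_post = s1[D] - sum_pre
        sum2_post = s2[D] - sum2_pre
        wl = sum_post / n_post
        ws = np.maximum(0.0, sum_pre / n_pre - wl)
        mu_pre = wl + ws
        rss = (
            sum2_pre - 2 * mu_pre * sum_pre + n_pre * mu_pre**2
            + sum2_post - 2 * wl * sum_post + n_post * wl**2
        )
        total_rss += rss
        per_sample.append((t.sample_id, wl, ws))

    best = int(np.argmin(total_rss))  # argmin returns the first (smallest P) tie
    p_star = int(cand[best])
    fit = APAFit(
        gene_id=gene_id,
        distal_end=D,
        breakpoint=p_star,
        rss=float(total_rss[best]),
    )
    for sample_id, wl, ws in per_sample:
        wl_i, ws_i = float(wl[best]), float(ws[best])
        fit.w_long[sample_id] = wl_i
        fit.w_short[sample_id] = ws_i
        fit.pdui[sample_id] = wl_i / (wl_i + ws_i) if wl_i + ws_i > 0 else None
    defined_ws = [ws for sid, ws in fit.w_short.items() if fit.pdui[sid] is not None]
    fit.degenerate = bool(defined_ws) and all(ws == 0.0 for ws in defined_ws)
    return fit


def correct_bias(track: CoverageTrack, mode: str = "none") -> CoverageTrack:
    """Optionally remove a smooth 5'->3' coverage trend before fitting.

    ``linear_detrend`` fits a least-squares line to log1p(coverage) over
    the distal half of the region (where, under a proximal breakpoint,
    coverage comes from the long isoform alone so the step does not
    contaminate the slope), re-expands the line across the full region,
    floors the linear-scale trend at 0.25x its mean, divides it out, and
    rescales so the output mean equals the input mean.
    """
    if mode == "none":
        return replace(track, values=track.values.copy())
    if mode != "linear_detrend":
        raise ValueError(f"unknown bias-correction mode {mode!r}")
    v = track.values
    L = len(v)
    if L < 100:
        logger.warning("%s: track shorter than 100 nt; detrend skipped", track.gene_id)
        return replace(track, values=v.copy())
    x = np.arange(L, dtype=float)
    half = L // 2
    slope, intercept = np.polyfit(x[half:], np.log1p(v[half:]), 1)
    trend = np.expm1(intercept + slope * x)
    trend = np.maximum(trend, 0.0)
    mean_t = trend.mean()
    if mean_t <= 0:
        return replace(track, values=v.copy())
    trend = np.maximum(trend, 0.25 * mean_t)
    corrected = v / trend
    mean_c = corrected.mean()
    if mean_c > 0:
        corrected *= v.mean() / mean_c
    return replace(track, values=corrected)


def _read_equivalents(fit: APAFit, sample_id: str, frag_len: int) -> tuple[int, int]:
    P, D = fit.breakpoint, fit.distal_end
    long_n = int(round(fit.w_long[sample_id] * D / frag_len))
    short_n = int(round(fit.w_short[sample_id] * (P + 1) / frag_len))
    return long_n, short_n


def compare_groups(
    fit: APAFit,
    group_a: Sequence[str],
    group_b: Sequence[str],
    frag_len: int = DEFAULT_FRAG_LEN,
) -> APAComparison:
    """DPDUI between two sample groups with a pooled Fisher exact test.

    Fitted densities are converted to read-equivalents (density x segment
    length / fragment length), pooled within group into a 2x2 long/short
    table, and tested two-sided. A table with an all-zero margin gets
    p = 1. Raises when a group has no defined PDUI (gene untestable).
    """
    pdui_a = [fit.pdui[s] for s in group_a if fit.pdui.get(s) is not None]
    pdui_b = [fit.pdui[s] for s in group_b if fit.pdui.get(s) is not None]
    if not pdui_a or not pdui_b or fit.breakpoint is None:
        raise CoverageError(f"{fit.gene_id}: no defined PDUI in a compared group")
    mean_a = float(np.mean(pdui_a))
    mean_b = float(np.mean(pdui_b))
    pooled = []
    for group in (group_a, group_b):
        long_n = short_n = 0
        for s in group:
            if fit.pdui.get(s) is None:
                continue
            l, sh = _read_equivalents(fit, s, frag_len)
            long_n += l
            short_n += sh
        pooled.append((long_n, short_n))
    table = np.array(pooled)
    if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
        p = 1.0
    else:
        _, p = stats.fisher_exact(table, alternative="two-sided")
    return APAComparison(
        gene_id=fit.gene_id,
        pdui_mean_a=mean_a,
        pdui_mean_b=mean_b,
        dpdui=mean_a - mean_b,
        p_value=float(p),
        counts_2x2=(tuple(pooled[0]), tuple(pooled[1])),
    )


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_apa(
    comparison: APAComparison,
    alpha: float = 0.05,
    min_dpdui: float = 0.2,
) -> str:
    """Label a comparison as lengthened / shortened / unchanged.

    Lengthened means group A uses the distal site more (3'UTRs longer in
    A); requires q < alpha and |DPDUI| >= min_dpdui.
    """
    if math.isnan(comparison.q_value):
        raise ValueError(f"{comparison.gene_id}: q_value not set; run adjust_bh first")
    if comparison.q_value < alpha and comparison.dpdui >= min_dpdui:
        return "lengthened"
    if comparison.q_value < alpha and comparison.dpdui <= -min_dpdui:
        return "shortened"
    return "unchanged"
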