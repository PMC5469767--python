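"""PolyA-signal and PWM motif scanning on 3'UTR sequences.

Sequences are given 5'->3' as transcribed; only the sense strand is
scanned. U is treated as T, and N scores as background (log-odds 0).
PWM windows are scored as sum_j log2(matrix[base_j, j] / background_j)
after pseudocount regularization; a hit is reported when the relative
score — the fraction of the span between the minimal and maximal
attainable window scores — reaches the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from apascope.errors import ApascopeError, DegeneratePWMError

ALPHABET = "ACGT"
CANONICAL_POLYA = ("AATAAA",)
#: common variant signal, available via config
POLYA_VARIANTS = ("AATAAA", "ATTAAA")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}


@dataclass(frozen=True)
class PWMModel:
    """Column-stochastic position probability matrix over A,C,G,T."""

    pwm_id: str
    matrix: np.ndarray  # shape (4, width)
    pseudocount: float = 0.01
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4 or m.shape[1] < 1:
            raise ValueError("PWM matrix must be 4 x width with width >= 1")
        if np.any(m < 0):
            raise ValueError("PWM probabilities must be non-negative")
        object.__setattr__(self, "matrix", m)

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def log_odds(self) -> np.ndarray:
        """Pseudocount-regularized log2-odds lookup, with a zero row for N."""
        reg = self.matrix + self.pseudocount
        reg = reg / reg.sum(axis=0, keepdims=True)
        bg = np.asarray(self.background, dtype=float).reshape(4, 1)
        lo = np.log2(reg / bg)
        return np.vstack([lo, np.zeros((1, self.width))])


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    offset: int
    motif_id: str
    score: float
    rel_score: float


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper()
    try:
        return np.array([_BASE_INDEX[c] for c in seq], dtype=np.int8)
    except KeyError as exc:
        raise ApascopeError(f"non-IUPAC character in sequence: {exc.args[0]!r}") from None


def scan_polya_signal(
    seq: str,
    motifs: Iterable[str] = CANONICAL_POLYA,
    seq_id: str = "",
) -> list[MotifHit]:
    """Report every exact (overlapping) occurrence of each hexamer signal."""
    _encode(seq)  # alphabet validation
    s = seq.upper().replace("U", "T")
    hits = []
    for motif in motifs:
        m = motif.upper().replace("U", "T")
        start = s.find(m)
        while start != -1:
            hits.append(MotifHit(seq_id=seq_id, offset=start, motif_id=m,
                                 score=0.0, rel_score=1.0))
            start = s.find(m, start + 1)
    hits.sort(key=lambda h: (h.offset, h.motif_id))
    return hits


def scan_pwm(
    pwm: PWMModel,
    seq: str,
    min_rel_score: float = 0.8,
    seq_id: str = "",
) -> list[MotifHit]:
    """Score every window of the sequence against the PWM.

    Returns hits with rel_score >= min_rel_score, offsets strictly
    increasing. Raises DegeneratePWMError for a PWM whose maximal and
    minimal attainable scores coincide (e.g. the uniform matrix), since
    the relative score is then undefined.
    """
    W = pwm.width
    if len(seq) < W:
        raise ApascopeError(f"sequence shorter than PWM width {W}")
    lut = pwm.log_odds()
    max_attain = float(lut[:4].max(axis=0).sum())
    min_attain = float(lut[:4].min(axis=0).sum())
    if max_attain <= min_attain:
        raise DegeneratePWMError(
            f"{pwm.pwm_id}: max and min attainable scores coincide; relative score undefined"
        )
    enc = _encode(seq)
    n_win = len(seq) - W + 1
    scores = np.zeros(n_win)
    for j in range(W):
        scores += lut[enc[j : j + n_win], j]
    rel = (scores - min_attain) / (max_attain - min_attain)
    return [
        MotifHit(seq_id=seq_id, offset=int(i), motif_id=pwm.pwm_id,
                 score=float(scores[i]), rel_score=float(rel[i]))
        for i in np.flatnonzero(rel >= min_rel_score)
    ]


def compare_site_counts(
    short_utr: str,
    long_utr: str,
    pwms: Sequence[PWMModel],
    min_rel_score: float = 0.8,
) -> pd.DataFrame:
    """Per-PWM hit counts and per-kb rates in the short vs long 3'UTR.

    ``long_only`` flags motifs found exclusively in the long variant —
    candidate regulators gained by 3'UTR lengthening.
    """
    if not short_utr or not long_utr:
        raise ApascopeError("both sequences must be nonempty")
    rows = []
    for pwm in pwms:
        n_short = len(scan_pwm(pwm, short_utr, min_rel_score)) if len(short_utr) >= pwm.width else 0
        n_long = len(scan_pwm(pwm, long_utr, min_rel_score)) if len(long_utr) >= pwm.width else 0
        rows.append({
            "pwm_id": pwm.pwm_id,
            "count_short": n_short,
            "count_long": n_long,
            "per_kb_short": 1000.0 * n_short / len(short_utr),
            "per_kb_long": 1000.0 * n_long / len(long_utr),
            "delta": n_long - n_short,
            "long_only": n_long > 0 and n_short == 0,
        })
    return pd.DataFrame(rows)


def load_pwms_tsv(path) -> list[PWMModel]:
    """Read PWMs from a simple 4-row TSV block format.

    Blocks are ``>pwm_id`` followed by four whitespace-separated rows of
    probabilities in A, C, G, T order.
    """
    pwms = []
    name, rows = None, []
    def _flush():
        if name is not None:
            if len(rows) != 4:
                raise ApascopeError(f"PWM {name}: expected 4 rows, got {len(rows)}")
            pwms.append(PWMModel(pwm_id=name, matrix=np.array(rows)))
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name, rows = line[1:].strip(), []
            else:
                rows.append([float(x) for x in line.split()])
    _flush()
    return pwms


def write_hits(hits: Iterable[MotifHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tmotif_id\toffset\tscore\trel_score\n")
        for h in hits:
            fh.write(f"{h.seq_id}\t{h.motif_id}\t{h.offset}\t{h.score:.4f}\t{h.rel_score:.4f}\n")
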