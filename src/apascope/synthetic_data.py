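"""Synthetic APA datasets with known ground truth.

Emulates the compartmentalized nerve-injury study design: two
compartments (axon, cell body) x two sides (ipsi = injury-conditioned,
contra = control) x 3 replicates. Each gene carries a short and a long
3'UTR isoform mixed at a group-specific distal-usage fraction pi; per-base
coverage is Poisson around the two-step mean profile, optionally decaying
linearly 5'->3' to mimic library bias. A configurable fraction of genes
has its annotated transcript end upstream of the true distal site, so the
long-isoform coverage surfaces as a distal read cluster inside the
extension — the pattern that flags unannotated 3'UTRs.

Outputs are the exact dialects the analysis consumes: BED12 annotation,
per-sample bedGraph coverage, FASTA 3'UTR sequences with AATAAA hexamers
planted at the cleavage sites, a sample sheet, and a ground-truth table.
All output is byte-deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

DEFAULT_GROUPS: dict[str, int] = {
    "ipsi_axon": 3, "contra_axon": 3, "ipsi_body": 3, "contra_body": 3,
}
# distal-usage fraction pi per gene class and group; lengthened/shortened
# are relative to axon-vs-body comparisons on the ipsi side
DEFAULT_PDUI_BY_GROUP: dict[str, dict[str, float]] = {
    "lengthened": {"ipsi_axon": 0.8, "contra_axon": 0.5, "ipsi_body": 0.3, "contra_body": 0.3},
    "shortened": {"ipsi_axon": 0.2, "contra_axon": 0.4, "ipsi_body": 0.6, "contra_body": 0.6},
    "stable": {"ipsi_axon": 0.5, "contra_axon": 0.5, "ipsi_body": 0.5, "contra_body": 0.5},
}
DEFAULT_CLASS_FRACTIONS: dict[str, float] = {
    "lengthened": 0.25, "shortened": 0.15, "stable": 0.6,
}

_BASES = np.array(list("ACGT"))
_GENE_SLOT = 30_000  # genomic spacing between simulated genes
_CDS_LEN = 300


@dataclass
class SimConfig:
    """Generator settings; defaults reproduce the emulated study design."""

    n_genes: int = 60
    groups: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    utr_len_range: tuple[int, int] = (500, 2000)
    breakpoint_rule: float = 0.4  # P_true as a fraction of the true distal end
    pdui_by_group: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PDUI_BY_GROUP.items()}
    )
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    depth: float = 50.0  # mean per-base coverage on the common segment
    bias_beta: float = 0.0  # slope of linear 5'->3' decay, in [0, 1)
    frag_len: int = 350
    distal_cluster_frac: float = 0.3  # genes with true distal end beyond annotation
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not (0 <= self.bias_beta < 1):
            raise ValueError("bias_beta must lie in [0, 1)")
        if not (0 < self.breakpoint_rule < 1):
            raise ValueError("breakpoint_rule must lie in (0, 1)")
        if any(n < 1 for n in self.groups.values()):
            raise ValueError("replicate counts must be >= 1")
        for cls, by_group in self.pdui_by_group.items():
            for g, pi in by_group.items():
                if not (0 <= pi <= 1):
                    raise ValueError(f"pi out of [0,1] for class {cls}, group {g}")


def simulate_coverage(
    L: int,
    p_true: int,
    pi: float,
    depth: float,
    bias_beta: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Poisson per-base coverage under the two-isoform mixture.

    lambda(i) = depth * (1 - bias_beta * i / L) * (pi + (1 - pi) * [i <= p_true]).
    """
    if not (0 < p_true < L):
        raise ValueError("p_true must satisfy 0 < p_true < L")
    if not (0 <= pi <= 1):
        raise ValueError("pi must lie in [0, 1]")
    if depth <= 0 or not (0 <= bias_beta < 1):
        raise ValueError("invalid depth or bias_beta")
    i = np.arange(L)
    bias = 1.0 - bias_beta * i / L
    mix = pi + (1.0 - pi) * (i <= p_true)
    return rng.poisson(depth * bias * mix).astype(float)


def _random_seq(length: int, rng: np.random.Generator) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _runs(values: np.ndarray) -> list[tuple[int, int, float]]:
    """Run-length encode, skipping zero runs (bedGraph omits them)."""
    if len(values) == 0:
        return []
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(values)]))
    return [(int(s), int(e), float(values[s]))
            for s, e in zip(starts, ends) if values[s] != 0]


def simulate_dataset(config: SimConfig, out_dir) -> dict[str, Path]:
    """Write a complete synthetic dataset; returns the emitted file paths.

    Identical seeds yield byte-identical output. The sample sheet's
    coverage paths are relative to the sheet's own directory.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    chrom = "chrS1"

    samples = []  # (sample_id, group, compartment)
    for group, n_rep in config.groups.items():
        compartment = "axon" if group.endswith("axon") else "body"
        for r in range(1, n_rep + 1):
            samples.append((f"{group}_r{r}", group, compartment))

    classes = list(config.class_fractions)
    probs = np.array([config.class_fractions[c] for c in classes], dtype=float)
    probs /= probs.sum()

    lo, hi = config.utr_len_range
    bed_lines, fasta_chunks, truth_lines = [], [], []
    per_sample_cov: dict[str, list[tuple[int, int, float]]] = {s[0]: [] for s in samples}

    for g in range(config.n_genes):
        gene_id = f"gene{g + 1:04d}"
        slot = g * _GENE_SLOT
        strand = "+" if g % 2 == 0 else "-"
        L = int(rng.integers(lo, hi + 1))  # true distal end, transcript-relative
        p_true = int(round(config.breakpoint_rule * L))
        gene_class = classes[int(rng.choice(len(classes), p=probs))]
        has_cluster = bool(rng.random() < config.distal_cluster_frac)
        ann_len = max(p_true + 50, int(0.6 * L)) if has_cluster else L
        ann_len = min(ann_len, L)

        if strand == "+":
            tx_start = slot + 1000
            cds_end3 = tx_start + _CDS_LEN
            tx_end = cds_end3 + ann_len
            thick_start, thick_end = tx_start, cds_end3
        else:
            utr_low = slot + 12_000
            cds_end3 = utr_low + ann_len
            tx_start, tx_end = utr_low, cds_end3 + _CDS_LEN
            thick_start, thick_end = cds_end3, tx_end
        bed_lines.append(
            f"{chrom}\t{tx_start}\t{tx_end}\t{gene_id}\t0\t{strand}\t"
            f"{thick_start}\t{thick_end}\t0\t1\t{tx_end - tx_start},\t0,\n"
        )

        seq = _random_seq(L, rng)
        seq[p_true : p_true + 6] = list("AATAAA")
        seq[L - 6 : L] = list("AATAAA")
        fasta_chunks.append(f">{gene_id}\n")
        s = "".join(seq)
        fasta_chunks.extend(s[k : k + 60] + "\n" for k in range(0, L, 60))

        pi_by_group = config.pdui_by_group[gene_class]
        for sample_id, group, _comp in samples:
            pi = float(pi_by_group[group])
            arr = simulate_coverage(L, p_true, pi, config.depth, config.bias_beta, rng)
            if strand == "+":
                genomic = arr
                offset0 = cds_end3
            else:
                genomic = arr[::-1]
                offset0 = cds_end3 - L
            for s0, e0, v in _runs(genomic):
                per_sample_cov[sample_id].append((offset0 + s0, offset0 + e0, v))
            truth_lines.append(
                f"{gene_id}\t{sample_id}\t{pi:.4f}\t{p_true}\t{L}\t{arr.mean():.4f}\n"
            )

    paths: dict[str, Path] = {}
    paths["annotation"] = out_dir / "annotation.bed"
    with open(paths["annotation"], "w") as fh:
        fh.writelines(bed_lines)
    paths["fasta"] = out_dir / "utr_sequences.fa"
    with open(paths["fasta"], "w") as fh:
        fh.writelines(fasta_chunks)
    paths["truth"] = out_dir / "truth.tsv"
    with open(paths["truth"], "w") as fh:
        fh.write("gene_id\tsample_id\tpi_true\tp_true\td_true\tdepth_realized\n")
        fh.writelines(truth_lines)

    sheet_rows = []
    for sample_id, group, compartment in samples:
        fname = f"{sample_id}.bedgraph"
        with open(out_dir / fname, "w") as fh:
            for start, end, v in sorted(per_sample_cov[sample_id]):
                val = int(v) if float(v).is_integer() else v
                fh.write(f"{chrom}\t{start}\t{end}\t{val}\n")
        lib_size = int(1e6 * (0.8 + 0.4 * rng.random()))
        sheet_rows.append(f"{sample_id}\t{group}\t{compartment}\t{fname}\t{lib_size}\n")
    paths["sample_sheet"] = out_dir / "samples.tsv"
    with open(paths["sample_sheet"], "w") as fh:
        fh.write("sample_id\tgroup\tcompartment\tpath\tlib_size\n")
        fh.writelines(sheet_rows)
    return paths
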