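"""End-to-end orchestration: annotation -> coverage -> APA -> quant -> scan -> crosstab.

Stage order and bookkeeping: genes loaded from the annotation are gated
for testability (anchor coverage in every compared sample), fitted
jointly, compared between the two named sample groups, BH-adjusted across
tested genes, and classified. Quantification and motif scanning run on
the same regions; an externally produced differential-expression table
can be joined to cross-tabulate APA status against expression change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from apascope import annotation_io, apa_core, coverage_io, isoform_quant, motif_scan
from apascope.coverage_io import CoverageTrack
from apascope.errors import CoverageError, PipelineError, SchemaError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    annotation: str = ""
    sample_sheet: str = ""
    out_dir: str = "apascope_out"
    fasta: str | None = None
    de_table: str | None = None
    pwms: str | None = None
    annotation_format: str | None = None  # inferred from extension when None
    group_a: str = "ipsi_axon"
    group_b: str = "ipsi_body"
    alpha: float = 0.05
    min_dpdui: float = 0.2
    frag_len: int = 350
    anchor_len: int = 100
    frac: float = 0.05
    min_abs: float = 1.0
    gap_tol: int = 50
    min_flank: int = 50
    bias_mode: str = "none"
    coverage_gate: float = 20.0
    per_million: bool = False
    max_extension: int = 10_000
    common_len: int = 400  # common-domain length for isoform decomposition
    polya_motifs: tuple[str, ...] = ("AATAAA",)
    min_rel_score: float = 0.8
    min_log2fc: float = 1.0
    max_de_q: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        if "polya_motifs" in raw:
            raw["polya_motifs"] = tuple(raw["polya_motifs"])
        return cls(**raw)

    def validate(self) -> None:
        for name in ("annotation", "sample_sheet"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise PipelineError("validate", f"{name} file not found: {p!r}")
        for name in ("fasta", "de_table", "pwms"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise PipelineError("validate", f"{name} file not found: {p!r}")


def filter_enriched(
    de_table: pd.DataFrame,
    min_log2fc: float = 1.0,
    max_q: float = 0.05,
) -> dict[str, set[str]]:
    """Split a DE table into enriched (up) and depleted (down) gene sets.

    Enrichment is at least a two-fold change (|log2FC| > min_log2fc) at
    FDR q < max_q.
    """
    required = {"gene", "log2fc", "q"}
    missing = required - set(de_table.columns)
    if missing:
        raise SchemaError(f"DE table missing columns: {sorted(missing)}")
    sig = de_table[de_table["q"] < max_q]
    return {
        "up": set(sig.loc[sig["log2fc"] > min_log2fc, "gene"]),
        "down": set(sig.loc[sig["log2fc"] < -min_log2fc, "gene"]),
    }


def crosstab_apa_de(
    apa_labels: Mapping[str, str],
    de_sets: Mapping[str, set[str]],
) -> pd.DataFrame:
    """Cross-tabulate APA classification against DE status.

    Rows are APA labels, columns up/down/ns; genes absent from the DE
    table count as ns. Row percentages are over genes with that APA label.
    """
    rows = ["lengthened", "shortened", "unchanged"]
    up, down = de_sets.get("up", set()), de_sets.get("down", set())
    counts = {r: {"up": 0, "down": 0, "ns": 0} for r in rows}
    for gene, label in apa_labels.items():
        if label not in counts:
            continue
        if gene in up:
            counts[label]["up"] += 1
        elif gene in down:
            counts[label]["down"] += 1
        else:
            counts[label]["ns"] += 1
    if apa_labels and not (set(apa_labels) & (up | down)):
        logger.warning("no overlap between APA genes and DE gene sets; all counted as ns")
    out = []
    for r in rows:
        n = sum(counts[r].values())
        row = {"apa_label": r, **counts[r], "n": n}
        for c in ("up", "down", "ns"):
            row[f"pct_{c}"] = 100.0 * counts[r][c] / n if n else 0.0
        out.append(row)
    return pd.DataFrame(out)


def _fmt(x, nd=4) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    if isinstance(x, float):
        return f"{x:.{nd}g}" if abs(x) < 1e-3 and x != 0 else f"{x:.{nd}f}"
    return str(x)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write the result bundle into config.out_dir."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines = [f"apascope run: group_a={config.group_a} group_b={config.group_b} "
                 f"alpha={config.alpha} min_dpdui={config.min_dpdui} seed={config.seed}"]

    # --- annotation ---
    fmt = config.annotation_format or (
        "gtf" if str(config.annotation).endswith((".gtf", ".gff")) else "bed12"
    )
    try:
        transcripts = annotation_io.load_annotation(config.annotation, fmt)
    except Exception as exc:
        raise PipelineError("annotate", str(exc)) from exc
    genes = annotation_io.representative_transcripts(transcripts)
    regions = {}
    for g in genes:
        try:
            regions[g.gene_id] = annotation_io.extract_utr3(
                g, genes, max_extension=config.max_extension
            )
        except annotation_io.NoUTRError:
            logger.warning("%s: no annotated 3'UTR; skipped", g.gene_id)
    log_lines.append(f"annotate: {len(genes)} genes, {len(regions)} with 3'UTR regions")

    # --- coverage ---
    sheet = coverage_io.read_sample_sheet(config.sample_sheet)
    sheet_dir = Path(config.sample_sheet).parent
    wanted = sheet[sheet["group"].isin([config.group_a, config.group_b])]
    if wanted.empty:
        raise PipelineError("coverage", f"no samples in groups {config.group_a}/{config.group_b}")
    indexes: dict[str, coverage_io.BedGraphIndex] = {}
    lib_sizes: dict[str, int] = {}
    sample_groups: dict[str, str] = {}
    for _, row in wanted.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = sheet_dir / p
        try:
            indexes[row["sample_id"]] = coverage_io.BedGraphIndex(p)
        except Exception as exc:
            raise PipelineError("coverage", str(exc)) from exc
        lib_sizes[row["sample_id"]] = int(row["lib_size"])
        sample_groups[row["sample_id"]] = row["group"]
    group_a_samples = sorted(s for s, g in sample_groups.items() if g == config.group_a)
    group_b_samples = sorted(s for s, g in sample_groups.items() if g == config.group_b)

    # --- fit & compare per gene ---
    results, comparisons, fits = [], [], {}
    n_testable = 0
    raw_tracks_by_gene: dict[str, dict[str, CoverageTrack]] = {}
    for gene_id in sorted(regions):
        region = regions[gene_id]
        tracks = {
            s: indexes[s].extract(region, sample_id=s, lib_size=lib_sizes[s])
            for s in sorted(indexes)
        }
        raw_tracks_by_gene[gene_id] = tracks
        anchor = slice(0, config.anchor_len)
        gated = all(
            t.values[anchor].mean() >= config.coverage_gate for t in tracks.values()
        )
        if not gated:
            results.append({"gene_id": gene_id, "label": "untestable"})
            continue
        work = tracks
        if config.per_million:
            work = {s: coverage_io.normalize_depth(t) for s, t in tracks.items()}
        merged = coverage_io.merge_tracks(list(work.values()))
        D = apa_core.detect_distal_end(
            merged, anchor_len=config.anchor_len, frac=config.frac,
            min_abs=config.min_abs, gap_tol=config.gap_tol,
        )
        if D is None or D < 2 * config.min_flank:
            results.append({"gene_id": gene_id, "label": "untestable"})
            continue
        truncated = [
            apa_core.correct_bias(
                CoverageTrack(t.sample_id, t.gene_id, t.values[:D], t.lib_size, t.scale),
                mode=config.bias_mode,
            )
            for _, t in sorted(work.items())
        ]
        fit = apa_core.fit_breakpoint(truncated, min_flank=config.min_flank)
        if not fit.testable:
            results.append({"gene_id": gene_id, "label": "untestable"})
            continue
        try:
            comp = apa_core.compare_groups(
                fit, group_a_samples, group_b_samples, frag_len=config.frag_len
            )
        except CoverageError:
            results.append({"gene_id": gene_id, "label": "untestable"})
            continue
        n_testable += 1
        fits[gene_id] = fit
        comparisons.append(comp)

    if comparisons:
        qs = apa_core.adjust_bh([c.p_value for c in comparisons])
        for c, q in zip(comparisons, qs):
            c.q_value = float(q)
            c.label = apa_core.classify_apa(c, alpha=config.alpha, min_dpdui=config.min_dpdui)
    n_sig = sum(c.label in ("lengthened", "shortened") for c in comparisons)
    log_lines.append(
        f"apa: loaded={len(regions)} testable={n_testable} "
        f"untestable={len(regions) - n_testable} significant={n_sig}"
    )

    # --- write apa_results.tsv ---
    all_samples = group_a_samples + group_b_samples
    comp_by_gene = {c.gene_id: c for c in comparisons}
    paths: dict[str, Path] = {}
    paths["apa_results"] = out_dir / "apa_results.tsv"
    with open(paths["apa_results"], "w") as fh:
        pdui_cols = "\t".join(f"pdui_{s}" for s in all_samples)
        fh.write(f"gene_id\tD\tP\t{pdui_cols}\tpdui_mean_a\tpdui_mean_b\tdpdui\tp\tq\tlabel\n")
        for gene_id in sorted(regions):
            if gene_id in comp_by_gene:
                fit, comp = fits[gene_id], comp_by_gene[gene_id]
                pduis = "\t".join(_fmt(fit.pdui.get(s)) for s in all_samples)
                fh.write(
                    f"{gene_id}\t{fit.distal_end}\t{fit.breakpoint}\t{pduis}\t"
                    f"{_fmt(comp.pdui_mean_a)}\t{_fmt(comp.pdui_mean_b)}\t{_fmt(comp.dpdui)}\t"
                    f"{_fmt(comp.p_value, 6)}\t{_fmt(comp.q_value, 6)}\t{comp.label}\n"
                )
            else:
                na = "\t".join("NA" for _ in all_samples)
                fh.write(f"{gene_id}\tNA\tNA\t{na}\tNA\tNA\tNA\tNA\tNA\tuntestable\n")

    # --- quantify ---
    paths["quant"] = out_dir / "quant.tsv"
    with open(paths["quant"], "w") as fh:
        fh.write("gene_id\tsample_id\tfpkm_total\tf_long\tfpkm_long\tfpkm_short\n")
        for gene_id in sorted(fits):
            fit = fits[gene_id]
            P, D = fit.breakpoint, fit.distal_end
            common_end = min(config.common_len, P + 1)
            for s in all_samples:
                t = raw_tracks_by_gene[gene_id][s]
                fragments = float(t.values[:D].sum()) / config.frag_len
                total = isoform_quant.fpkm(fragments, D, lib_sizes[s])
                common = isoform_quant.segment_density(t, 0, common_end)
                distal = isoform_quant.segment_density(t, P + 1, D)
                ab = isoform_quant.split_by_distal_exon(common, distal, total, gene_id)
                fh.write(
                    f"{gene_id}\t{s}\t{_fmt(ab.fpkm_total)}\t{_fmt(ab.f_long)}\t"
                    f"{_fmt(ab.fpkm_long)}\t{_fmt(ab.fpkm_short)}\n"
                )
    log_lines.append(f"quantify: {len(fits)} genes x {len(all_samples)} samples")

    # --- motif scan ---
    if config.fasta:
        from Bio import SeqIO

        hits = []
        pwms = motif_scan.load_pwms_tsv(config.pwms) if config.pwms else []
        for rec in SeqIO.parse(config.fasta, "fasta"):
            seq = str(rec.seq)
            hits.extend(motif_scan.scan_polya_signal(seq, config.polya_motifs, seq_id=rec.id))
            for pwm in pwms:
                if len(seq) >= pwm.width:
                    hits.extend(motif_scan.scan_pwm(pwm, seq, config.min_rel_score, seq_id=rec.id))
        paths["hits"] = out_dir / "hits.tsv"
        motif_scan.write_hits(hits, paths["hits"])
        log_lines.append(f"scan: {len(hits)} motif hits")

    # --- crosstab against DE ---
    if config.de_table:
        de = pd.read_csv(config.de_table, sep="\t")
        de_sets = filter_enriched(de, config.min_log2fc, config.max_de_q)
        apa_labels = {c.gene_id: c.label for c in comparisons}
        ct = crosstab_apa_de(apa_labels, de_sets)
        paths["crosstab"] = out_dir / "crosstab.tsv"
        ct.to_csv(paths["crosstab"], sep="\t", index=False, float_format="%.2f")
        log_lines.append("crosstab: written")

    paths["log"] = out_dir / "run.log"
    with open(paths["log"], "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    for line in log_lines:
        logger.info(line)
    return paths
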