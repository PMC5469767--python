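"""Gene annotation parsing and 3'UTR search-space construction.

Transcript models are read from BED12 or GTF and normalized to 0-based
half-open genomic coordinates. The APA search space for a gene is its
genomically contiguous terminal-exon 3'UTR, extended downstream
(strand-aware) by up to ``max_extension`` nucleotides or until the nearest
annotated neighboring transcript boundary on either strand, whichever
comes first. Distal cleavage sites beyond the annotated transcript end
surface as read clusters inside this extension.

Transcript-relative offsets count from the first base after the stop
codon (offset 0), increasing 5'->3' along the transcript.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from apascope.errors import AnnotationParseError, NoUTRError

logger = logging.getLogger(__name__)

MAX_EXTENSION_NT = 10_000

_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


@dataclass(frozen=True)
class GeneModel:
    """A transcript with its CDS 3' boundary, in 0-based half-open coordinates.

    ``cds_end3`` is the genomic boundary of the stop codon's 3' edge in
    transcription direction: on '+' it equals BED12 thickEnd, on '-' it
    equals thickStart.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_end3: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.tx_start < self.tx_end):
            raise ValueError(f"invalid transcript bounds [{self.tx_start}, {self.tx_end})")
        prev_end = self.tx_start - 1
        for s, e in self.exons:
            if s >= e or s < self.tx_start or e > self.tx_end:
                raise ValueError(f"exon [{s},{e}) outside transcript bounds")
            if s < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e
        if not any(s <= self.cds_end3 <= e for s, e in self.exons):
            raise ValueError(f"cds_end3 {self.cds_end3} does not lie within an exon")

    @property
    def annotated_utr3_len(self) -> int:
        """Length of the terminal-exon 3'UTR implied by the annotation."""
        if self.strand == "+":
            return self.tx_end - self.cds_end3
        return self.cds_end3 - self.tx_start


@dataclass(frozen=True)
class UTR3Region:
    """Genomic span of the extended 3'UTR used as the APA search space."""

    gene_id: str
    chrom: str
    strand: str
    utr_start3: int
    utr_end3: int
    annotated_len: int
    extended_len: int
    extension_cap_hit: str  # "neighbor", "max_extension", or "none"

    def __post_init__(self):
        if self.extended_len < self.annotated_len:
            raise ValueError("extended_len must be >= annotated_len")
        if self.extended_len - self.annotated_len > MAX_EXTENSION_NT:
            raise ValueError("extension exceeds the 10 kb cap")
        if self.utr_end3 - self.utr_start3 != self.extended_len:
            raise ValueError("genomic span inconsistent with extended_len")


def _bed12_to_gene(fields: Sequence[str], path, lineno) -> GeneModel | None:
    try:
        chrom = fields[0]
        start, end = int(fields[1]), int(fields[2])
        name = fields[3]
        strand = fields[5]
        thick_start, thick_end = int(fields[6]), int(fields[7])
        n_blocks = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
    except (IndexError, ValueError) as exc:
        raise AnnotationParseError(path, lineno, f"malformed BED12 record: {exc}") from None
    if len(sizes) != n_blocks or len(offsets) != n_blocks:
        raise AnnotationParseError(path, lineno, "blockCount does not match block lists")
    if thick_start == thick_end:
        logger.warning("%s:%d: transcript %s lacks a CDS; skipped", path, lineno, name)
        return None
    exons = tuple((start + o, start + o + sz) for o, sz in zip(offsets, sizes))
    # BED names are often "transcript" only; gene_id falls back to the name.
    gene_id, _, tx_id = name.partition("|")
    cds_end3 = thick_end if strand == "+" else thick_start
    try:
        return GeneModel(
            gene_id=gene_id,
            transcript_id=tx_id or name,
            chrom=chrom,
            strand=strand,
            tx_start=start,
            tx_end=end,
            cds_end3=cds_end3,
            exons=exons,
        )
    except ValueError as exc:
        raise AnnotationParseError(path, lineno, str(exc)) from None


def _parse_gtf_attrs(raw: str) -> dict[str, str]:
    return dict(_GTF_ATTR_RE.findall(raw))


def _load_gtf(path) -> list[GeneModel]:
    # GTF is 1-based closed; convert to 0-based half-open on read.
    per_tx: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationParseError(path, lineno, "GTF record has fewer than 9 fields")
            feature = fields[2]
            if feature not in ("exon", "CDS"):
                continue
            try:
                start = int(fields[3]) - 1
                end = int(fields[4])
            except ValueError:
                raise AnnotationParseError(path, lineno, "non-integer coordinates") from None
            strand = fields[6]
            attrs = _parse_gtf_attrs(fields[8])
            tx_id = attrs.get("transcript_id")
            if tx_id is None:
                raise AnnotationParseError(path, lineno, "missing transcript_id attribute")
            rec = per_tx.setdefault(
                tx_id,
                {"gene_id": attrs.get("gene_id", tx_id), "chrom": fields[0],
                 "strand": strand, "exons": [], "cds": []},
            )
            rec["exons" if feature == "exon" else "cds"].append((start, end))
    genes = []
    for tx_id, rec in per_tx.items():
        if not rec["cds"]:
            logger.warning("%s: transcript %s lacks a CDS; skipped", path, tx_id)
            continue
        exons = tuple(sorted(rec["exons"]))
        if rec["strand"] == "+":
            cds_end3 = max(e for _, e in rec["cds"])
        else:
            cds_end3 = min(s for s, _ in rec["cds"])
        genes.append(
            GeneModel(
                gene_id=rec["gene_id"],
                transcript_id=tx_id,
                chrom=rec["chrom"],
                strand=rec["strand"],
                tx_start=exons[0][0],
                tx_end=exons[-1][1],
                cds_end3=cds_end3,
                exons=exons,
            )
        )
    return genes


def load_annotation(path, format: str = "bed12") -> list[GeneModel]:
    """Parse an annotation file into GeneModels, one per CDS-bearing transcript.

    Output is deterministically ordered by (chrom, tx_start, transcript_id).
    Transcripts without a CDS are skipped with a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "bed12":
        genes = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                gene = _bed12_to_gene(line.rstrip("\n").split("\t"), path, lineno)
                if gene is not None:
                    genes.append(gene)
    elif format == "gtf":
        genes = _load_gtf(path)
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    genes.sort(key=lambda g: (g.chrom, g.tx_start, g.transcript_id))
    return genes


def write_bed12(genes: Iterable[GeneModel], path) -> None:
    """Write GeneModels as BED12 (round-trips through load_annotation)."""
    with open(path, "w") as fh:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - g.tx_start) for s, e in g.exons)
            if g.strand == "+":
                thick_start, thick_end = g.tx_start, g.cds_end3
            else:
                thick_start, thick_end = g.cds_end3, g.tx_end
            name = g.gene_id if g.gene_id == g.transcript_id else f"{g.gene_id}|{g.transcript_id}"
            fh.write(
                f"{g.chrom}\t{g.tx_start}\t{g.tx_end}\t{name}\t0\t{g.strand}\t"
                f"{thick_start}\t{thick_end}\t0\t{len(g.exons)}\t{sizes},\t{offsets},\n"
            )


def _terminal_exon(gene: GeneModel) -> tuple[int, int]:
    return gene.exons[-1] if gene.strand == "+" else gene.exons[0]


def extract_utr3(
    gene: GeneModel,
    neighbors: Sequence[GeneModel],
    max_extension: int = MAX_EXTENSION_NT,
) -> UTR3Region:
    """Build the extended 3'UTR region for one gene.

    The region runs from the stop codon's 3' edge to the annotated
    transcript end, then extends downstream by
    ``min(max_extension, distance to the nearest neighbor boundary)``.
    Neighbors on either strand block the extension.

    Raises ``NoUTRError`` when the annotated 3'UTR has zero length.
    """
    term_s, term_e = _terminal_exon(gene)
    annotated_len = gene.annotated_utr3_len
    if annotated_len <= 0:
        raise NoUTRError(f"{gene.gene_id}: zero-length annotated 3'UTR")
    if not (term_s < gene.cds_end3 < term_e):
        raise NoUTRError(
            f"{gene.gene_id}: stop codon boundary not strictly inside the terminal exon"
        )

    others = [n for n in neighbors
              if n.chrom == gene.chrom and n.transcript_id != gene.transcript_id]
    if gene.strand == "+":
        ann_end = gene.tx_end
        dist = float("inf")
        for n in others:
            if n.tx_start < ann_end < n.tx_end:
                dist = 0
                break
            for b in (n.tx_start, n.tx_end):
                if b >= ann_end:
                    dist = min(dist, b - ann_end)
        ext = int(min(max_extension, dist))
        start, end = gene.cds_end3, ann_end + ext
    else:
        ann_end = gene.tx_start
        dist = float("inf")
        for n in others:
            if n.tx_start < ann_end < n.tx_end:
                dist = 0
                break
            for b in (n.tx_start, n.tx_end):
                if b <= ann_end:
                    dist = min(dist, ann_end - b)
        ext = int(min(max_extension, dist))
        start, end = ann_end - ext, gene.cds_end3
    cap = "neighbor" if dist < max_extension else "max_extension"
    return UTR3Region(
        gene_id=gene.gene_id,
        chrom=gene.chrom,
        strand=gene.strand,
        utr_start3=start,
        utr_end3=end,
        annotated_len=annotated_len,
        extended_len=annotated_len + ext,
        extension_cap_hit=cap,
    )


def representative_transcripts(genes: Sequence[GeneModel]) -> list[GeneModel]:
    """One transcript per gene: the one with the longest annotated 3'UTR.

    Ties break toward the lexicographically smallest transcript_id so the
    choice is deterministic.
    """
    best: dict[str, GeneModel] = {}
    for g in genes:
        cur = best.get(g.gene_id)
        if cur is None or (g.annotated_utr3_len, cur.transcript_id) > (
            cur.annotated_utr3_len, g.transcript_id
        ):
            best[g.gene_id] = g
    return sorted(best.values(), key=lambda g: (g.chrom, g.tx_start, g.transcript_id))


def write_region_table(regions: Iterable[UTR3Region], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\tutr_start3\tutr_end3\t"
                 "annotated_len\textended_len\textension_cap_hit\n")
        for r in regions:
            fh.write(
                f"{r.gene_id}\t{r.chrom}\t{r.strand}\t{r.utr_start3}\t{r.utr_end3}\t"
                f"{r.annotated_len}\t{r.extended_len}\t{r.extension_cap_hit}\n"
            )
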