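"""Gene models: loading, filtering, and promoter/body region definition.

Transcript records are read from refFlat, BED12 or GTF into a common
:class:`GeneModel` with 0-based half-open genomic coordinates. Filtering
follows the standard protein-coding pipeline: keep NM-tagged transcripts,
drop genes shorter than 2 kb, and keep only the longest transcript within
each cluster of overlapping genes. Regions are strand-aware: the promoter
spans −100/+500 around the TSS and the gene body runs from +1 kb
downstream of the TSS to the transcription termination site.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .config import PipelineConfig

FORWARD = "+"
REVERSE = "-"

_TAG_RE = re.compile(r"^(NM|NR)_")


class ParseError(ValueError):
    """A malformed record in an annotation file; carries the line number."""

    def __init__(self, path: str | Path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


@dataclass(frozen=True)
class GeneModel:
    """One transcript with 0-based half-open genomic extent."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    tx_start: int
    tx_end: int
    tag: str = "other"  # 'NM', 'NR' or 'other'

    def __post_init__(self) -> None:
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.tx_start < self.tx_end:
            raise ValueError(
                f"{self.gene_id}: tx_start must be < tx_end ({self.tx_start} >= {self.tx_end})"
            )

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start

    @property
    def tss(self) -> int:
        """TSS as a 0-based position: tx_start for '+', tx_end for '-'.

        On the reverse strand the TSS is the half-open end coordinate;
        interval arithmetic downstream treats it as the anchor point.
        """
        return self.tx_start if self.strand == FORWARD else self.tx_end


@dataclass(frozen=True)
class GeneRegions:
    """Promoter and body intervals of one gene (half-open, genome coords)."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    promoter_start: int
    promoter_end: int
    body_start: int
    body_end: int
    clipped: bool = False

    @property
    def promoter_length(self) -> int:
        return self.promoter_end - self.promoter_start

    @property
    def body_length(self) -> int:
        return self.body_end - self.body_start

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == FORWARD else self.tx_end


def _infer_tag(name: str) -> str:
    m = _TAG_RE.match(name)
    return m.group(1) if m else "other"


def _parse_refflat_line(path, lineno, fields) -> GeneModel:
    # refFlat: geneName name chrom strand txStart txEnd cdsStart cdsEnd
    #          exonCount exonStarts exonEnds   (UCSC, 0-based half-open)
    if len(fields) < 6:
        raise ParseError(path, lineno, f"refFlat needs >=6 columns, got {len(fields)}")
    name = fields[1]
    try:
        tx_start, tx_end = int(fields[4]), int(fields[5])
    except ValueError as e:
        raise ParseError(path, lineno, f"bad coordinate: {e}") from None
    if tx_start >= tx_end:
        raise ParseError(path, lineno, f"txStart >= txEnd ({tx_start} >= {tx_end})")
    if fields[3] not in (FORWARD, REVERSE):
        raise ParseError(path, lineno, f"bad strand {fields[3]!r}")
    return GeneModel(name, fields[2], fields[3], tx_start, tx_end, _infer_tag(name))


def _parse_bed12_line(path, lineno, fields) -> GeneModel:
    if len(fields) < 6:
        raise ParseError(path, lineno, f"BED needs >=6 columns, got {len(fields)}")
    name = fields[3]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError as e:
        raise ParseError(path, lineno, f"bad coordinate: {e}") from None
    if start >= end:
        raise ParseError(path, lineno, f"start >= end ({start} >= {end})")
    if fields[5] not in (FORWARD, REVERSE):
        raise ParseError(path, lineno, f"bad strand {fields[5]!r}")
    return GeneModel(name, fields[0], fields[5], start, end, _infer_tag(name))


_GTF_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_gtf_transcript(path, lineno, fields) -> GeneModel | None:
    if len(fields) < 9:
        raise ParseError(path, lineno, f"GTF needs 9 columns, got {len(fields)}")
    if fields[2] != "transcript":
        return None
    try:
        start1, end = int(fields[3]), int(fields[4])  # GTF is 1-based closed
    except ValueError as e:
        raise ParseError(path, lineno, f"bad coordinate: {e}") from None
    start = start1 - 1
    if start >= end:
        raise ParseError(path, lineno, f"start >= end after conversion ({start} >= {end})")
    if fields[6] not in (FORWARD, REVERSE):
        raise ParseError(path, lineno, f"bad strand {fields[6]!r}")
    attrs = dict(_GTF_ATTR_RE.findall(fields[8]))
    name = attrs.get("transcript_id") or attrs.get("gene_id")
    if not name:
        raise ParseError(path, lineno, "transcript record lacks transcript_id/gene_id")
    tag = attrs.get("tag")
    if tag not in ("NM", "NR"):
        tag = _infer_tag(name)
    return GeneModel(name, fields[0], fields[6], start, end, tag)


def load_gene_models(path: str | Path, format: str = "refflat") -> list[GeneModel]:
    """Read transcript records from ``path`` in the named dialect.

    ``format`` is one of ``refflat``, ``bed12``, ``gtf``. Coordinates are
    normalized to 0-based half-open; the NM/NR tag is inferred from the
    transcript-name prefix (or, for GTF, a ``tag`` attribute).
    """
    if format not in ("refflat", "bed12", "gtf"):
        raise ValueError(f"unknown gene-model format {format!r}")
    models: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if format == "refflat":
                models.append(_parse_refflat_line(path, lineno, fields))
            elif format == "bed12":
                models.append(_parse_bed12_line(path, lineno, fields))
            else:
                m = _parse_gtf_transcript(path, lineno, fields)
                if m is not None:
                    models.append(m)
    return models


def filter_genes(
    models: Sequence[GeneModel], config: PipelineConfig | None = None
) -> list[GeneModel]:
    """Apply the protein-coding filtering rules.

    Keeps NM-tagged transcripts of genomic extent >= ``min_gene_length``;
    within each cluster of transcripts with overlapping extents on the
    same chromosome (strand ignored), keeps only the longest, breaking
    length ties by the lexicographically smallest gene_id. Idempotent.
    Output sorted by (chrom, tx_start).
    """
    config = config or PipelineConfig()
    kept = [m for m in models if m.tag == "NM" and m.length >= config.min_gene_length]
    kept.sort(key=lambda m: (m.chrom, m.tx_start, m.tx_end, m.gene_id))

    out: list[GeneModel] = []
    cluster: list[GeneModel] = []
    cluster_end = -1
    cluster_chrom = None

    def flush() -> None:
        if cluster:
            best = min(cluster, key=lambda m: (-m.length, m.gene_id))
            out.append(best)

    for m in kept:
        if cluster_chrom == m.chrom and m.tx_start < cluster_end:
            cluster.append(m)
            cluster_end = max(cluster_end, m.tx_end)
        else:
            flush()
            cluster = [m]
            cluster_chrom = m.chrom
            cluster_end = m.tx_end
    flush()
    out.sort(key=lambda m: (m.chrom, m.tx_start))
    return out


def define_regions(gene: GeneModel, config: PipelineConfig | None = None) -> GeneRegions:
    """Promoter and body intervals for one filtered gene.

    Forward strand (TSS = tx_start): promoter ``[TSS-up, TSS+down)``,
    body ``[TSS+body_offset, tx_end)``. Reverse strand mirrors both.
    Promoters extending past position 0 are clipped and flagged.
    """
    config = config or PipelineConfig()
    if gene.length < config.body_offset + 1:
        raise ValueError(
            f"{gene.gene_id}: gene length {gene.length} leaves an empty body "
            f"(body_offset={config.body_offset}); filter genes first"
        )
    up, down = config.promoter_upstream, config.promoter_downstream
    if gene.strand == FORWARD:
        tss = gene.tx_start
        prom = (tss - up, tss + down)
        body = (tss + config.body_offset, gene.tx_end)
    else:
        tss = gene.tx_end
        prom = (tss - down, tss + up)
        body = (gene.tx_start, tss - config.body_offset)
    clipped = prom[0] < 0
    prom = (max(prom[0], 0), prom[1])
    return GeneRegions(
        gene.gene_id,
        gene.chrom,
        gene.strand,
        gene.tx_start,
        gene.tx_end,
        prom[0],
        prom[1],
        body[0],
        body[1],
        clipped,
    )


REGIONS_COLUMNS = [
    "gene_id",
    "chrom",
    "strand",
    "tx_start",
    "tx_end",
    "promoter_start",
    "promoter_end",
    "body_start",
    "body_end",
    "clipped",
]


def regions_to_frame(regions: Iterable[GeneRegions]) -> pd.DataFrame:
    rows = [
        (
            r.gene_id,
            r.chrom,
            r.strand,
            r.tx_start,
            r.tx_end,
            r.promoter_start,
            r.promoter_end,
            r.body_start,
            r.body_end,
            r.clipped,
        )
        for r in regions
    ]
    return pd.DataFrame(rows, columns=REGIONS_COLUMNS)


def frame_to_regions(df: pd.DataFrame) -> list[GeneRegions]:
    return [
        GeneRegions(
            str(row.gene_id),
            str(row.chrom),
            str(row.strand),
            int(row.tx_start),
            int(row.tx_end),
            int(row.promoter_start),
            int(row.promoter_end),
            int(row.body_start),
            int(row.body_end),
            bool(row.clipped),
        )
        for row in df.itertuples(index=False)
    ]


def write_regions(regions: Iterable[GeneRegions], path: str | Path) -> None:
    """Write the filtered gene/region table as TSV (coordinates in bp)."""
    regions_to_frame(regions).to_csv(path, sep="\t", index=False)


def read_regions(path: str | Path) -> list[GeneRegions]:
    return frame_to_regions(pd.read_csv(path, sep="\t"))
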