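"""G-quadruplex motif scanning and TSS-window enrichment statistics.

A putative G4 motif (QuadParser-style) is four maximal runs of at least
``g4_min_run`` guanines whose inter-run gaps ("loops") each span
``g4_loop_min``..``g4_loop_max`` nucleotides. Both strands are searched
(C-run motifs on the forward sequence are reverse-strand hits) and
overlapping motif intervals are merged per strand into maximal regions.
Merged hits are then assigned to transcription-direction-aware windows
around each gene's TSS (default 3 kb upstream, 500 bp downstream) and
resolved into template vs non-template strand. Per-gene motif counts
between gene groups are compared with a two-sided Mann-Whitney test and
summarized by median and (unscaled) median absolute deviation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import FORWARD, REVERSE, GeneModel
from .config import PipelineConfig

_VALID_RE = re.compile(r"^[ACGTN]*$")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class QuadruplexHit:
    """One merged G4 motif region (half-open, forward-genome coords)."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"hit start must be < end ({self.start} >= {self.end})")
        if self.strand not in (FORWARD, REVERSE):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching-by-overlap half-open intervals.

    Intervals that merely abut (end == next start) stay separate; only
    genuine overlap (>= 1 shared base) merges. Idempotent and
    order-independent.
    """
    ivs = sorted(intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s < out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def scan_g4(sequence: str, config: PipelineConfig | None = None) -> list[tuple[int, int]]:
    """Forward-strand G4 motif regions in ``sequence``, merged.

    Enumerates maximal G-runs of length >= ``g4_min_run``, slides a
    window of ``g4_n_runs`` consecutive runs, keeps windows whose gaps
    all lie in [``g4_loop_min``, ``g4_loop_max``], and merges the
    resulting intervals. N never matches a run but may sit in a loop.
    Returns half-open (start, end) pairs.
    """
    config = config or PipelineConfig()
    sequence = sequence.upper()
    if not _VALID_RE.match(sequence):
        bad = sorted(set(sequence) - set("ACGTN"))
        raise ValueError(f"sequence contains invalid characters: {bad}")
    run_re = re.compile("G{%d,}" % config.g4_min_run)
    starts: list[int] = []
    ends: list[int] = []
    for m in run_re.finditer(sequence):
        starts.append(m.start())
        ends.append(m.end())
    k = config.g4_n_runs
    if len(starts) < k:
        return []
    s = np.asarray(starts)
    e = np.asarray(ends)
    gaps = s[1:] - e[:-1]  # nucleotides strictly between consecutive runs
    ok = (gaps >= config.g4_loop_min) & (gaps <= config.g4_loop_max)
    hits = []
    for i in range(len(s) - k + 1):
        if ok[i : i + k - 1].all():
            hits.append((int(s[i]), int(e[i + k - 1])))
    return merge_intervals(hits)


def scan_g4_both_strands(
    sequence: str,
    config: PipelineConfig | None = None,
    chrom: str = "chr1",
    offset: int = 0,
) -> list[QuadruplexHit]:
    """G4 motif regions on both strands, merged per strand.

    Reverse-strand hits come from scanning the reverse complement and
    mapping coordinates back to the forward genome. ``offset`` shifts
    all reported coordinates (for scanning genomic slices).
    """
    config = config or PipelineConfig()
    fwd = scan_g4(sequence, config)
    L = len(sequence)
    rev_rc = scan_g4(reverse_complement(sequence), config)
    rev = merge_intervals((L - e, L - s) for s, e in rev_rc)
    hits = [QuadruplexHit(chrom, s + offset, e + offset, FORWARD) for s, e in fwd]
    hits += [QuadruplexHit(chrom, s + offset, e + offset, REVERSE) for s, e in rev]
    hits.sort(key=lambda h: (h.start, h.end, h.strand))
    return hits


def _window_bounds(gene: GeneModel, config: PipelineConfig) -> tuple[tuple[int, int], tuple[int, int]]:
    """(upstream, downstream) windows in genome coords, direction-aware."""
    up, down = config.g4_upstream_window, config.g4_downstream_window
    tss = gene.tss
    if gene.strand == FORWARD:
        return (max(tss - up, 0), tss), (tss, tss + down)
    return (tss, tss + up), (max(tss - down, 0), tss)


def _overlaps(iv: tuple[int, int], s: int, e: int) -> bool:
    return s < iv[1] and iv[0] < e


G4_COUNT_COLUMNS = [
    "gene_id",
    "upstream_total",
    "downstream_total",
    "upstream_template",
    "upstream_nontemplate",
    "downstream_template",
    "downstream_nontemplate",
]


def assign_windows(
    hits: Sequence[QuadruplexHit], gene: GeneModel, config: PipelineConfig | None = None
) -> dict:
    """Count G4 hits in the upstream/downstream TSS windows of one gene.

    A hit counts in a window if it overlaps it by >= 1 bp (a hit may
    count in both windows). Hits on the gene's own strand are
    non-template, opposite-strand hits template. Totals use the
    cross-strand union of hit intervals (re-merged), strand-resolved
    counts the per-strand merged hits as given.
    """
    config = config or PipelineConfig()
    upstream, downstream = _window_bounds(gene, config)
    counts = {c: 0 for c in G4_COUNT_COLUMNS[1:]}
    counts["gene_id"] = gene.gene_id

    same = [h for h in hits if h.chrom == gene.chrom]
    for h in same:
        kind = "nontemplate" if h.strand == gene.strand else "template"
        if _overlaps(upstream, h.start, h.end):
            counts[f"upstream_{kind}"] += 1
        if _overlaps(downstream, h.start, h.end):
            counts[f"downstream_{kind}"] += 1
    union = merge_intervals((h.start, h.end) for h in same)
    counts["upstream_total"] = sum(1 for s, e in union if _overlaps(upstream, s, e))
    counts["downstream_total"] = sum(1 for s, e in union if _overlaps(downstream, s, e))
    return counts


def count_g4_per_gene(
    hits: Sequence[QuadruplexHit],
    genes: Sequence[GeneModel],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Window-resolved G4 counts for every gene (one row per gene)."""
    config = config or PipelineConfig()
    by_chrom: dict[str, list[QuadruplexHit]] = {}
    for h in hits:
        by_chrom.setdefault(h.chrom, []).append(h)
    rows = []
    for g in genes:
        chrom_hits = by_chrom.get(g.chrom, [])
        lo = min(_window_bounds(g, config)[0][0], _window_bounds(g, config)[1][0])
        hi = max(_window_bounds(g, config)[0][1], _window_bounds(g, config)[1][1])
        near = [h for h in chrom_hits if h.start < hi and lo < h.end]
        rows.append(assign_windows(near, g, config))
    return pd.DataFrame(rows, columns=G4_COUNT_COLUMNS)


def mask_cpg(
    hits: Sequence[QuadruplexHit], cpg: Sequence[tuple[str, int, int]]
) -> list[QuadruplexHit]:
    """Drop every hit overlapping any CpG island by >= 1 bp."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in cpg:
        by_chrom.setdefault(chrom, []).append((int(s), int(e)))
    for chrom in by_chrom:
        by_chrom[chrom] = merge_intervals(by_chrom[chrom])
    out = []
    for h in hits:
        ivs = by_chrom.get(h.chrom, [])
        if not any(h.start < e and s < h.end for s, e in ivs):
            out.append(h)
    return out


@dataclass(frozen=True)
class G4GroupComparison:
    """Mann-Whitney comparison of per-gene motif counts in two groups."""

    p_value: float
    direction: str  # 'x-enriched', 'y-enriched' or 'undefined'
    median_x: float
    median_y: float
    mad_x: float
    mad_y: float
    n_x: int
    n_y: int


def compare_g4_groups(counts_x, counts_y) -> G4GroupComparison:
    """Two-sided Mann-Whitney on per-gene motif counts, with median/MAD.

    Direction is decided by mean ranks (``x-enriched`` when group x has
    the larger mean rank). Two all-identical groups carry no evidence:
    p = 1, direction ``undefined``.
    """
    x = np.asarray(counts_x, dtype=float)
    y = np.asarray(counts_y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    med_x, med_y = float(np.median(x)), float(np.median(y))
    mad_x = float(np.median(np.abs(x - med_x)))
    mad_y = float(np.median(np.abs(y - med_y)))
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return G4GroupComparison(1.0, "undefined", med_x, med_y, mad_x, mad_y, x.size, y.size)
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    ranks = stats.rankdata(pooled)
    direction = "x-enriched" if ranks[: x.size].mean() > ranks[x.size :].mean() else "y-enriched"
    return G4GroupComparison(
        float(res.pvalue), direction, med_x, med_y, mad_x, mad_y, x.size, y.size
    )


def hits_to_bed(hits: Sequence[QuadruplexHit], path) -> None:
    """Write merged hits as BED6 (name 'G4', score 0)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.chrom}\t{h.start}\t{h.end}\tG4\t0\t{h.strand}\n")


def read_bed_intervals(path) -> list[tuple[str, int, int]]:
    """Read (chrom, start, end) triples from a BED3+ file (e.g. CpG islands)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out
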