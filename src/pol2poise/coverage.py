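"""Read counting over promoter/body regions, RPKM densities, poising index.

A read is assigned to a region iff its strand-aware 5' end falls inside
the half-open interval, so a read straddling the promoter/body boundary
counts once. Replicate libraries are merged by summing counts and
library totals. Densities are RPKM (reads per kilobase of region per
million mapped reads); the poising index is promoter RPKM over body
RPKM, with a one-read pseudocount in the body when the body count is
zero (flagged ``body-pseudocounted``).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .annotations import FORWARD, GeneRegions

PI_FINITE = "finite"
PI_PSEUDO = "body-pseudocounted"


def read_bed_reads(path: str | Path) -> pd.DataFrame:
    """Load aligned reads from BED6 (chrom, start, end, name, score, strand)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 5],
        names=["chrom", "start", "end", "strand"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "strand": str},
    )
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        raise ValueError(f"{path}: {int(bad.sum())} reads with strand outside +/-")
    return df


def five_prime_positions(reads: pd.DataFrame) -> np.ndarray:
    """Strand-aware 5' end of each read: start for '+', end-1 for '-'."""
    return np.where(
        reads["strand"].to_numpy() == FORWARD,
        reads["start"].to_numpy(),
        reads["end"].to_numpy() - 1,
    )


def _count_in_intervals(
    positions: np.ndarray, starts: np.ndarray, ends: np.ndarray, idx: np.ndarray
) -> np.ndarray:
    """Count positions per interval. Intervals may overlap (tree fallback)."""
    counts = np.zeros(int(idx.max()) + 1 if idx.size else 0, dtype=np.int64)
    if idx.size == 0 or positions.size == 0:
        return counts
    order = np.argsort(starts, kind="stable")
    starts, ends, idx = starts[order], ends[order], idx[order]
    if np.all(starts[1:] >= ends[:-1]):
        # disjoint intervals: each position hits at most one
        j = np.searchsorted(starts, positions, side="right") - 1
        ok = j >= 0
        inside = np.zeros_like(ok)
        inside[ok] = positions[ok] < ends[j[ok]]
        hit_idx = idx[j[inside]]
        np.add.at(counts, hit_idx, 1)
    else:
        from intervaltree import IntervalTree

        tree = IntervalTree()
        for s, e, i in zip(starts, ends, idx):
            tree[s:e] = int(i)
        for p in positions:
            for iv in tree[int(p)]:
                counts[iv.data] += 1
    return counts


def count_reads(
    read_frames: Sequence[pd.DataFrame], regions: Sequence[GeneRegions]
) -> tuple[pd.DataFrame, int]:
    """Count 5'-end hits of the merged replicates per promoter and body.

    Returns ``(counts, library_total)`` where ``counts`` has one row per
    gene with columns ``gene_id, prom, body`` and ``library_total`` is
    the number of reads streamed over all replicates (reads on
    chromosomes without regions still count toward the total).
    """
    n = len(regions)
    prom_counts = np.zeros(n, dtype=np.int64)
    body_counts = np.zeros(n, dtype=np.int64)
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(regions):
        by_chrom.setdefault(r.chrom, []).append(i)

    library_total = 0
    for reads in read_frames:
        library_total += len(reads)
        pos_all = five_prime_positions(reads)
        chroms = reads["chrom"].to_numpy()
        for chrom, idx_list in by_chrom.items():
            mask = chroms == chrom
            if not mask.any():
                continue
            pos = pos_all[mask]
            idx = np.asarray(idx_list, dtype=np.int64)
            ps = np.asarray([regions[i].promoter_start for i in idx_list])
            pe = np.asarray([regions[i].promoter_end for i in idx_list])
            bs = np.asarray([regions[i].body_start for i in idx_list])
            be = np.asarray([regions[i].body_end for i in idx_list])
            local = np.arange(len(idx_list), dtype=np.int64)
            pc = _count_in_intervals(pos, ps, pe, local)
            bc = _count_in_intervals(pos, bs, be, local)
            prom_counts[idx] += pc
            body_counts[idx] += bc

    counts = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in regions],
            "prom": prom_counts,
            "body": body_counts,
        }
    )
    return counts, library_total


def rpkm(count, region_len, library):
    """Reads per kilobase of region per million mapped reads.

    Accepts scalars or arrays; ``region_len`` and ``library`` must be
    positive.
    """
    region_len = np.asarray(region_len, dtype=float)
    library = np.asarray(library, dtype=float)
    if np.any(region_len <= 0):
        raise ValueError("region_len must be positive")
    if np.any(library <= 0):
        raise ValueError("library must be positive")
    out = np.asarray(count, dtype=float) / ((region_len / 1e3) * (library / 1e6))
    return out.item() if np.isscalar(count) or np.ndim(count) == 0 else out


def poising_index(prom_rpkm, body_rpkm, body_len: int, polii_library: int):
    """Promoter density over body density; one-read body pseudocount at 0.

    Returns ``(pi, flag)`` with flag ``finite`` or ``body-pseudocounted``.
    """
    if prom_rpkm < 0 or body_rpkm < 0:
        raise ValueError("densities must be non-negative")
    if body_rpkm > 0:
        return prom_rpkm / body_rpkm, PI_FINITE
    return prom_rpkm / rpkm(1, body_len, polii_library), PI_PSEUDO


COUNTS_COLUMNS = [
    "gene_id",
    "polii_prom",
    "polii_body",
    "igg_prom",
    "igg_body",
    "polii_library",
    "igg_library",
    "prom_len",
    "body_len",
]


def build_region_counts(
    regions: Sequence[GeneRegions],
    polii_frames: Sequence[pd.DataFrame],
    igg_frames: Sequence[pd.DataFrame],
) -> pd.DataFrame:
    """Count Pol II and IgG replicate sets over one region table.

    Returns a RegionCounts table: one row per gene with raw counts,
    merged library totals and region lengths.
    """
    polii, polii_lib = count_reads(polii_frames, regions)
    igg, igg_lib = count_reads(igg_frames, regions)
    df = pd.DataFrame(
        {
            "gene_id": polii["gene_id"],
            "polii_prom": polii["prom"],
            "polii_body": polii["body"],
            "igg_prom": igg["prom"],
            "igg_body": igg["body"],
            "polii_library": polii_lib,
            "igg_library": igg_lib,
            "prom_len": [r.promoter_length for r in regions],
            "body_len": [r.body_length for r in regions],
        }
    )
    return df


def add_densities(counts: pd.DataFrame) -> pd.DataFrame:
    """Append Pol II RPKM densities and the poising index to a counts table.

    Adds ``prom_rpkm``, ``body_rpkm``, ``poising_index``, ``pi_flag``.
    """
    df = counts.copy()
    df["prom_rpkm"] = rpkm(
        df["polii_prom"].to_numpy(), df["prom_len"].to_numpy(), df["polii_library"].to_numpy()
    )
    df["body_rpkm"] = rpkm(
        df["polii_body"].to_numpy(), df["body_len"].to_numpy(), df["polii_library"].to_numpy()
    )
    pis = np.empty(len(df))
    flags = []
    for i, row in enumerate(df.itertuples(index=False)):
        pi, flag = poising_index(
            row.prom_rpkm, row.body_rpkm, int(row.body_len), int(row.polii_library)
        )
        pis[i] = pi
        flags.append(flag)
    df["poising_index"] = pis
    df["pi_flag"] = flags
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
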