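"""Synthetic genomes, ChIP-seq-like reads and expression with planted truth.

The generator materializes the statistical model the pipeline assumes:
read counts over promoter/body segments are Poisson with a uniform
mock-IP (IgG) background rate, and Pol II counts are that rate times a
class-specific enrichment — equal promoter/body enrichment for
non-poised (NP) genes, promoter >> body for poised (P) genes, no
enrichment for inactive (I) genes. G4 motifs are planted as a fixed
15-mer at class-dependent rates in the upstream/downstream TSS windows
of a background sequence scrubbed of spontaneous motifs, so per-gene
motif counts have exact planted truth. Expression time series give
immediate-early-like genes a burst at 30 minutes followed by monotone
decay, on top of constitutive (flat) and silent profiles.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations import FORWARD, REVERSE, GeneModel, GeneRegions, define_regions
from .config import PipelineConfig
from .quadruplex import merge_intervals, reverse_complement, scan_g4_both_strands

PLANT_MOTIF = "GGGTGGGTGGGTGGG"  # fixed 15-mer, unambiguous to count
PLANT_MOTIF_REV = reverse_complement(PLANT_MOTIF)  # CCCACCCACCCACCC on '+'

TIMEPOINTS = ("rest", "30m", "3h", "24h", "72h")

EXPR_MEANS = {
    # FPKM means per timepoint (rest, 30m, 3h, 24h, 72h):
    # IEG-like genes are already high at rest, peak at 30m, then decay.
    "IEG-like": (8.0, 24.0, 6.0, 2.5, 2.0),
    "constitutive": (5.0, 5.0, 5.0, 5.0, 5.0),
    "silent": (0.05, 0.05, 0.05, 0.05, 0.05),
}
EXPR_LOGNORMAL_SIGMA = 0.25


def _default_g4_rates() -> dict:
    # per-class (upstream, downstream) planting probabilities
    return {"I": (0.2, 0.2), "NP": (0.8, 0.2), "P": (0.2, 0.8)}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic dataset.

    Enrichment folds are multiples of the IgG density; libraries are
    total mapped reads. ``intergenic_gap`` of 6.5 kb keeps the 3 kb
    upstream G4 windows of head-facing neighbours disjoint.
    """

    n_genes: int = 2000
    class_proportions: tuple[float, float, float] = (0.45, 0.15, 0.40)  # I, NP, P
    igg_density: float = 10.0  # RPKM
    np_enrichment: float = 10.0
    p_prom_enrichment: float = 20.0
    p_body_enrichment: float = 2.0
    polii_library: int = 2_000_000
    igg_library: int = 2_000_000
    gene_length_range: tuple[int, int] = (3000, 8000)
    intergenic_gap: int = 6500
    g4_plant_rates: Mapping[str, tuple[float, float]] = field(
        default_factory=_default_g4_rates
    )
    ieg_fraction: float = 0.1
    ieg_polii_boost: float = 3.0  # extra Pol II rate for IEG-like genes
    read_length: int = 36
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        props = self.class_proportions
        if len(props) != 3 or any(p < 0 or p > 1 for p in props):
            raise ValueError("class_proportions must be three values in [0, 1]")
        if abs(sum(props) - 1.0) > 1e-9:
            raise ValueError(f"class_proportions must sum to 1, got {sum(props)}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        lo, hi = self.gene_length_range
        if lo < 2000 or hi < lo:
            raise ValueError("gene_length_range must be >= 2000 bp and ordered")
        for name in ("np_enrichment", "p_prom_enrichment", "p_body_enrichment"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1 (planted signal over background)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["g4_plant_rates"] = {k: list(v) for k, v in self.g4_plant_rates.items()}
        return d


@dataclass
class GroundTruth:
    """Planted truth: per-gene class/PI/expression label plus G4 plants."""

    genes: pd.DataFrame  # gene_id, klass, true_pi, expr_label
    plants: pd.DataFrame  # gene_id, window, strand, start, end, template

    def classes(self) -> pd.Series:
        return self.genes.set_index("gene_id")["klass"]


def _class_multipliers(config: SimulationConfig, klass: str) -> tuple[float, float]:
    if klass == "I":
        return 1.0, 1.0
    if klass == "NP":
        return config.np_enrichment, config.np_enrichment
    if klass == "P":
        return config.p_prom_enrichment, config.p_body_enrichment
    raise ValueError(f"unknown class {klass!r}")


def _scrub_spontaneous_motifs(
    seq: np.ndarray, config: PipelineConfig, rng: np.random.Generator, max_iter: int = 20
) -> np.ndarray:
    """Rejection-resample background until no G4 motif survives on either strand."""
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for _ in range(max_iter):
        text = seq.tobytes().decode("ascii")
        hits = scan_g4_both_strands(text, config)
        if not hits:
            return seq
        for h in hits:
            seq[h.start : h.end] = alphabet[rng.integers(0, 4, h.end - h.start)]
    raise RuntimeError("failed to scrub spontaneous G4 motifs from background")


def simulate_genes(
    config: SimulationConfig | None = None,
    pipeline_config: PipelineConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[str, list[GeneModel], GroundTruth]:
    """Build the genome sequence, gene models and planted ground truth.

    Genes alternate strand along one chromosome, separated by
    ``intergenic_gap``; classes are assigned by ``class_proportions``
    deterministically (exact planted counts, shuffled order). G4 motifs
    are written into upstream/downstream TSS windows per
    ``g4_plant_rates`` on a uniformly chosen strand, into a background
    scrubbed of spontaneous motifs.
    """
    config = config or SimulationConfig()
    pipeline_config = pipeline_config or PipelineConfig()
    rng = rng or np.random.default_rng(config.seed)

    n = config.n_genes
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    gap = config.intergenic_gap
    models: list[GeneModel] = []
    cursor = gap
    for i in range(n):
        strand = FORWARD if i % 2 == 0 else REVERSE
        start = cursor
        end = start + int(lengths[i])
        models.append(GeneModel(f"NM_{i:06d}", config.chrom, strand, start, end, "NM"))
        cursor = end + gap
    genome_length = cursor

    # exact planted class counts, order shuffled
    n_i = int(round(config.class_proportions[0] * n))
    n_np = int(round(config.class_proportions[1] * n))
    n_p = n - n_i - n_np
    klasses = np.array(["I"] * n_i + ["NP"] * n_np + ["P"] * n_p, dtype=object)
    rng.shuffle(klasses)

    seq = np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(0, 4, genome_length)].copy()
    seq = _scrub_spontaneous_motifs(seq, pipeline_config, rng)

    motif_fwd = np.frombuffer(PLANT_MOTIF.encode(), dtype=np.uint8)
    motif_rev = np.frombuffer(PLANT_MOTIF_REV.encode(), dtype=np.uint8)
    flank = ord("T")
    plant_rows = []
    up_w = pipeline_config.g4_upstream_window
    down_w = pipeline_config.g4_downstream_window
    for gene, klass in zip(models, klasses):
        rate_up, rate_down = config.g4_plant_rates[str(klass)]
        tss = gene.tss
        if gene.strand == FORWARD:
            windows = {"upstream": (tss - up_w, tss), "downstream": (tss, tss + down_w)}
        else:
            windows = {"upstream": (tss, tss + up_w), "downstream": (tss - down_w, tss)}
        for window, rate in (("upstream", rate_up), ("downstream", rate_down)):
            if rng.random() >= rate:
                continue
            ws, we = windows[window]
            m = len(PLANT_MOTIF)
            pos = int(rng.integers(ws + 1, we - m - 1))
            strand = FORWARD if rng.random() < 0.5 else REVERSE
            motif = motif_fwd if strand == FORWARD else motif_rev
            seq[pos : pos + m] = motif
            seq[pos - 1] = flank
            seq[pos + m] = flank
            plant_rows.append(
                {
                    "gene_id": gene.gene_id,
                    "window": window,
                    "strand": strand,
                    "start": pos,
                    "end": pos + m,
                    "template": strand != gene.strand,
                }
            )

    true_pi = np.where(
        klasses == "P", config.p_prom_enrichment / config.p_body_enrichment, 1.0
    )
    # expression labels: class I silent; a fixed fraction of NP genes IEG-like
    expr_label = np.where(klasses == "I", "silent", "constitutive").astype(object)
    np_idx = np.flatnonzero(klasses == "NP")
    n_ieg = int(round(config.ieg_fraction * np_idx.size))
    ieg_idx = rng.choice(np_idx, size=n_ieg, replace=False) if n_ieg else np.array([], int)
    expr_label[ieg_idx] = "IEG-like"

    genes_df = pd.DataFrame(
        {
            "gene_id": [m.gene_id for m in models],
            "klass": klasses,
            "true_pi": true_pi,
            "expr_label": expr_label,
        }
    )
    plants_df = pd.DataFrame(
        plant_rows, columns=["gene_id", "window", "strand", "start", "end", "template"]
    )
    truth = GroundTruth(genes_df, plants_df)
    return seq.tobytes().decode("ascii"), models, truth


def _place_reads(
    positions: np.ndarray, read_length: int, rng: np.random.Generator, chrom: str
) -> pd.DataFrame:
    """Turn 5'-end positions into stranded fixed-length BED-like reads."""
    strands = np.where(rng.random(positions.size) < 0.5, FORWARD, REVERSE)
    starts = np.where(strands == FORWARD, positions, positions - read_length + 1)
    starts = np.maximum(starts, 0)
    ends = np.where(strands == FORWARD, positions + read_length, positions + 1)
    return pd.DataFrame(
        {"chrom": chrom, "start": starts.astype(np.int64), "end": ends.astype(np.int64), "strand": strands}
    )


def _expected_count(density: float, length: int, library: int) -> float:
    return density * (length / 1e3) * (library / 1e6)


def simulate_reads(
    config: SimulationConfig,
    regions: Sequence[GeneRegions],
    truth: GroundTruth,
    genome_length: int,
    rng: np.random.Generator | None = None,
    class_override: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw Pol II and IgG reads for one cell state.

    Per-gene region counts are Poisson at the IgG rate times the class
    multiplier (``class_override`` reassigns classes for a second
    state); 5' ends are uniform within the region. The remaining library
    mass is placed uniformly in the complement of all promoter/body
    regions, so planted counts stay exact and the streamed library total
    equals the configured library size.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    classes = truth.classes()
    if class_override:
        classes = classes.copy()
        for g, k in class_override.items():
            classes[g] = k
    labels = truth.genes.set_index("gene_id")["expr_label"]

    polii_pos: list[np.ndarray] = []
    igg_pos: list[np.ndarray] = []
    occupied: list[tuple[int, int]] = []
    for r in regions:
        mult_prom, mult_body = _class_multipliers(config, str(classes[r.gene_id]))
        if labels[r.gene_id] == "IEG-like":
            # IEG-like genes are the most transcribed of the non-poised set
            mult_prom *= config.ieg_polii_boost
            mult_body *= config.ieg_polii_boost
        for (s, e), mult in (
            ((r.promoter_start, r.promoter_end), mult_prom),
            ((r.body_start, r.body_end), mult_body),
        ):
            length = e - s
            occupied.append((s, e))
            lam_polii = _expected_count(config.igg_density * mult, length, config.polii_library)
            lam_igg = _expected_count(config.igg_density, length, config.igg_library)
            n_polii = rng.poisson(lam_polii)
            n_igg = rng.poisson(lam_igg)
            polii_pos.append(rng.integers(s, e, size=n_polii))
            igg_pos.append(rng.integers(s, e, size=n_igg))

    # complement of the promoter/body union receives the background mass
    merged = merge_intervals(occupied)
    free: list[tuple[int, int]] = []
    prev = 0
    for s, e in merged:
        if s > prev:
            free.append((prev, s))
        prev = max(prev, e)
    if prev < genome_length:
        free.append((prev, genome_length))
    free_starts = np.array([s for s, _ in free], dtype=np.int64)
    free_lens = np.array([e - s for s, e in free], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(free_lens)])

    def background(n_bg: int) -> np.ndarray:
        if n_bg <= 0 or cum[-1] == 0:
            return np.array([], dtype=np.int64)
        u = rng.integers(0, cum[-1], size=n_bg)
        j = np.searchsorted(cum, u, side="right") - 1
        return free_starts[j] + (u - cum[j])

    n_polii_fg = int(sum(p.size for p in polii_pos))
    n_igg_fg = int(sum(p.size for p in igg_pos))
    polii_pos.append(background(config.polii_library - n_polii_fg))
    igg_pos.append(background(config.igg_library - n_igg_fg))

    polii = _place_reads(
        np.concatenate(polii_pos), config.read_length, rng, config.chrom
    )
    igg = _place_reads(np.concatenate(igg_pos), config.read_length, rng, config.chrom)
    return polii, igg


def simulate_expression(
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """FPKM expression table over rest/30m/3h/24h/72h.

    IEG-like genes burst at 30 minutes and decay monotonically;
    constitutive genes are flat; silent genes sit near zero. Noise is
    multiplicative lognormal.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    labels = truth.genes["expr_label"].to_numpy()
    means = np.array([EXPR_MEANS[l] for l in labels])
    noise = rng.lognormal(0.0, EXPR_LOGNORMAL_SIGMA, size=means.shape)
    values = means * noise
    df = pd.DataFrame(values, columns=list(TIMEPOINTS))
    df.insert(0, "gene_id", truth.genes["gene_id"].to_numpy())
    return df


def simulate_cpg_islands(
    truth: GroundTruth,
    chrom: str,
    fraction: float = 0.5,
    window: str = "downstream",
    margin: int = 5,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, int, int]]:
    """CpG-island intervals covering a random fraction of planted motifs.

    Used to exercise CpG masking with known attenuation: masking with
    these islands removes ~``fraction`` of the planted ``window`` hits.
    """
    rng = rng or np.random.default_rng(0)
    plants = truth.plants[truth.plants["window"] == window]
    n_cover = int(round(fraction * len(plants)))
    if n_cover == 0:
        return []
    chosen = plants.iloc[
        np.sort(rng.choice(len(plants), size=n_cover, replace=False))
    ]
    return [
        (chrom, int(row.start) - margin, int(row.end) + margin)
        for row in chosen.itertuples(index=False)
    ]


def write_fasta(sequence: str, chrom: str, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(sequence), width):
            fh.write(sequence[i : i + width] + "\n")


def write_refflat(models: Sequence[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in models:
            fh.write(
                f"{m.gene_id}\t{m.gene_id}\t{m.chrom}\t{m.strand}\t{m.tx_start}\t{m.tx_end}"
                f"\t{m.tx_start}\t{m.tx_end}\t1\t{m.tx_start},\t{m.tx_end},\n"
            )


def write_reads_bed(reads: pd.DataFrame, path: str | Path) -> None:
    df = reads.copy()
    df["name"] = "read"
    df["score"] = 0
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


@dataclass
class SimulatedDataset:
    """In-memory bundle of one simulated two-library cell state."""

    config: SimulationConfig
    sequence: str
    models: list[GeneModel]
    regions: list[GeneRegions]
    truth: GroundTruth
    polii: pd.DataFrame
    igg: pd.DataFrame
    expression: pd.DataFrame

    @property
    def genome_length(self) -> int:
        return len(self.sequence)


def simulate_dataset(
    config: SimulationConfig | None = None,
    pipeline_config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> SimulatedDataset:
    """Generate a complete single-state dataset; optionally write it out.

    Writes genome.fa, genes.refflat, polii.bed, igg.bed, expr.tsv,
    truth_genes.tsv, truth_plants.tsv and sim_config.json when
    ``out_dir`` is given.
    """
    config = config or SimulationConfig()
    pipeline_config = pipeline_config or PipelineConfig()
    rng = np.random.default_rng(config.seed)
    sequence, models, truth = simulate_genes(config, pipeline_config, rng)
    regions = [define_regions(m, pipeline_config) for m in models]
    polii, igg = simulate_reads(config, regions, truth, len(sequence), rng)
    expression = simulate_expression(truth, config, rng)
    ds = SimulatedDataset(config, sequence, models, regions, truth, polii, igg, expression)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(sequence, config.chrom, out / "genome.fa")
        write_refflat(models, out / "genes.refflat")
        write_reads_bed(polii, out / "polii.bed")
        write_reads_bed(igg, out / "igg.bed")
        expression.to_csv(out / "expr.tsv", sep="\t", index=False)
        truth.genes.to_csv(out / "truth_genes.tsv", sep="\t", index=False)
        truth.plants.to_csv(out / "truth_plants.tsv", sep="\t", index=False)
        (out / "sim_config.json").write_text(json.dumps(config.to_dict(), indent=2) + "\n")
    return ds


def flipped_state(
    ds: SimulatedDataset,
    n_flip: int,
    from_class: str = "P",
    to_class: str = "NP",
    seed_offset: int = 1000,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Second-state Pol II/IgG reads with ``n_flip`` genes reassigned.

    Re-draws all counts with a shifted seed; the listed genes change
    class (default poised -> non-poised, i.e. body enrichment raised to
    the NP level). Returns (polii, igg, flipped_gene_ids).
    """
    rng = np.random.default_rng(ds.config.seed + seed_offset)
    candidates = ds.truth.genes.loc[ds.truth.genes["klass"] == from_class, "gene_id"]
    if len(candidates) < n_flip:
        raise ValueError(f"only {len(candidates)} {from_class} genes available to flip")
    flipped = list(candidates.iloc[np.sort(rng.choice(len(candidates), n_flip, replace=False))])
    override = {g: to_class for g in flipped}
    polii, igg = simulate_reads(
        ds.config, ds.regions, ds.truth, ds.genome_length, rng, class_override=override
    )
    return polii, igg, flipped
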