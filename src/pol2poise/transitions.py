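"""Two-state comparison: class transitions, fold changes, rank statistics.

Given poising calls and densities for two cell states (e.g. resting and
activated B cells), this module builds the 3x3 class-transition matrix,
per-gene fold changes of promoter/body density, poising index and
expression, Mann-Whitney comparisons with Cohen's d effect sizes,
Spearman and partial Spearman correlations, ranking of non-poised genes
by body density (the immediate-early-gene screen), and expression-ratio
tertiles (HI/MED/LO).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .poising import CLASSES

SIMILAR = "similar"
INCREASED = "increased"
DECREASED = "decreased"

EXPR_PSEUDOCOUNT = 0.01  # FPKM


def transition_matrix(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """3x3 transition counts and row percentages over the shared genes.

    Cell (i, j) counts genes with class i in state A and class j in
    state B; rows are state-A classes. Returns ``(counts, row_pct)``.
    """
    a = calls_a.set_index("gene_id")["klass"]
    b = calls_b.set_index("gene_id")["klass"]
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no genes shared between the two states")
    counts = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES), dtype=int)
    cross = pd.crosstab(a.loc[common], b.loc[common])
    counts.loc[cross.index, cross.columns] = cross
    row_sums = counts.sum(axis=1)
    pct = counts.div(row_sums.replace(0, np.nan), axis=0) * 100.0
    return counts, pct


def _density_pseudocount(region_len: np.ndarray, library: np.ndarray) -> np.ndarray:
    """RPKM of a single read in the region at the given library depth."""
    return 1.0 / ((np.asarray(region_len, float) / 1e3) * (np.asarray(library, float) / 1e6))


def fold_changes(
    dens_a: pd.DataFrame,
    dens_b: pd.DataFrame,
    calls_a: pd.DataFrame | None = None,
    calls_b: pd.DataFrame | None = None,
    expr_a: pd.Series | None = None,
    expr_b: pd.Series | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-gene state-B over state-A fold changes with pseudocounts.

    Density fold changes use each state's one-read RPKM as the
    pseudocount; expression uses 0.01 FPKM. Adds a body-density label
    (``similar`` within (fc_low, fc_high), ``increased`` above,
    ``decreased`` below) and a ``pi_transition`` flag for genes whose
    poising index changes at least ``pi_fc_threshold``-fold in either
    direction.
    """
    config = config or PipelineConfig()
    a = dens_a.set_index("gene_id")
    b = dens_b.set_index("gene_id")
    common = a.index.intersection(b.index)
    if len(common) == 0:
        raise ValueError("no genes shared between the two states")
    a, b = a.loc[common], b.loc[common]

    def fc(col: str, length_col: str) -> np.ndarray:
        eps_a = _density_pseudocount(a[length_col], a["polii_library"])
        eps_b = _density_pseudocount(b[length_col], b["polii_library"])
        return (b[col].to_numpy() + eps_b) / (a[col].to_numpy() + eps_a)

    out = pd.DataFrame(index=common)
    out["prom_fc"] = fc("prom_rpkm", "prom_len")
    out["body_fc"] = fc("body_rpkm", "body_len")
    # poising-index fold change from the pseudocounted PI ratio
    pi_a = (a["prom_rpkm"] + _density_pseudocount(a["prom_len"], a["polii_library"])) / (
        a["body_rpkm"] + _density_pseudocount(a["body_len"], a["polii_library"])
    )
    pi_b = (b["prom_rpkm"] + _density_pseudocount(b["prom_len"], b["polii_library"])) / (
        b["body_rpkm"] + _density_pseudocount(b["body_len"], b["polii_library"])
    )
    out["pi_fc"] = (pi_b / pi_a).to_numpy()

    out["body_label"] = np.select(
        [out["body_fc"] > config.fc_high, out["body_fc"] < config.fc_low],
        [INCREASED, DECREASED],
        default=SIMILAR,
    )
    out["pi_transition"] = (out["pi_fc"] >= config.pi_fc_threshold) | (
        out["pi_fc"] <= 1.0 / config.pi_fc_threshold
    )

    if expr_a is not None and expr_b is not None:
        ea = expr_a.reindex(common)
        eb = expr_b.reindex(common)
        out["expr_fc"] = (eb + EXPR_PSEUDOCOUNT) / (ea + EXPR_PSEUDOCOUNT)
    if calls_a is not None and calls_b is not None:
        out["class_a"] = calls_a.set_index("gene_id")["klass"].reindex(common)
        out["class_b"] = calls_b.set_index("gene_id")["klass"].reindex(common)
    out.index.name = "gene_id"
    return out.reset_index()


@dataclass(frozen=True)
class GroupComparison:
    """Mann-Whitney U comparison of two samples with Cohen's d."""

    n_x: int
    n_y: int
    u_statistic: float
    p_value: float
    cohens_d: float
    median_x: float
    median_y: float


def mannwhitney_with_effect(x, y, log_transform: bool = False) -> GroupComparison:
    """Two-sided Mann-Whitney U test plus Cohen's d.

    Exact null enumeration for small tie-free samples (both n <= 20),
    normal approximation with tie correction otherwise. With
    ``log_transform`` (recommended for densities and poising indices),
    Cohen's d is computed on log10 values; inputs must then be positive.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    vx, vy = x, y
    if log_transform:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log_transform requires positive values")
        vx, vy = np.log10(x), np.log10(y)

    pooled = np.concatenate([vx, vy])
    if np.ptp(pooled) == 0:
        return GroupComparison(
            x.size, y.size, x.size * y.size / 2.0, 1.0, 0.0, float(np.median(x)), float(np.median(y))
        )

    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (max(x.size, y.size) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)

    nx, ny = vx.size, vy.size
    var_x = np.var(vx, ddof=1) if nx > 1 else 0.0
    var_y = np.var(vy, ddof=1) if ny > 1 else 0.0
    denom_df = max(nx + ny - 2, 1)
    pooled_sd = np.sqrt(((nx - 1) * var_x + (ny - 1) * var_y) / denom_df)
    d = 0.0 if pooled_sd == 0 else float((vx.mean() - vy.mean()) / pooled_sd)
    return GroupComparison(
        nx,
        ny,
        float(res.statistic),
        float(min(res.pvalue, 1.0)),
        d,
        float(np.median(x)),
        float(np.median(y)),
    )


def spearman_partial(x, y, z) -> tuple[float, float]:
    """Spearman correlation of x and y, raw and partialled on z.

    The partial coefficient is the Pearson correlation of the residuals
    of the x- and y-ranks after linear regression on the z-ranks (the
    standard rank-residual construction).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.size == y.size == z.size):
        raise ValueError("x, y, z must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0 or np.ptp(z) == 0:
        raise ValueError("constant input vector: correlation undefined")
    rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))
    rho = float(stats.pearsonr(rx, ry).statistic)

    def residual(r: np.ndarray) -> np.ndarray:
        beta = np.cov(r, rz, ddof=1)[0, 1] / np.var(rz, ddof=1)
        return r - r.mean() - beta * (rz - rz.mean())

    ex, ey = residual(rx), residual(ry)
    partial = float(np.dot(ex, ey) / np.sqrt(np.dot(ex, ex) * np.dot(ey, ey)))
    return rho, partial


def rank_np_candidates(
    calls: pd.DataFrame, densities: pd.DataFrame, k: int = 10
) -> tuple[pd.DataFrame, bool]:
    """Top-k non-poised genes by Pol II gene-body density.

    This is the screen that surfaces immediate early genes: NP genes
    transcribed at substantial levels. Ties break by gene_id. Returns
    ``(table, short)`` where ``short`` flags fewer than k NP genes.
    """
    merged = calls.drop(columns="body_rpkm", errors="ignore").merge(
        densities[["gene_id", "body_rpkm"]], on="gene_id", how="inner"
    )
    np_genes = merged[merged["klass"] == "NP"].copy()
    np_genes.sort_values(
        ["body_rpkm", "gene_id"], ascending=[False, True], inplace=True, kind="mergesort"
    )
    short = len(np_genes) < k
    return np_genes.head(k).reset_index(drop=True), short


def expression_ratio_tertiles(
    expr_t1: pd.Series, expr_t2: pd.Series, pseudocount: float = EXPR_PSEUDOCOUNT
) -> pd.Series:
    """HI/MED/LO thirds by the (expr_t1 / expr_t2) pseudocounted ratio.

    Genes are sorted ascending by ratio (ties by gene_id); the bottom
    floor(n/3) are LO, the top floor(n/3) are HI, the remainder MED.
    """
    if not expr_t1.index.equals(expr_t2.index):
        expr_t2 = expr_t2.reindex(expr_t1.index)
    n = len(expr_t1)
    if n < 3:
        raise ValueError("tertiles need at least 3 genes")
    ratio = (expr_t1 + pseudocount) / (expr_t2 + pseudocount)
    order = sorted(ratio.index, key=lambda g: (ratio[g], g))
    third = n // 3
    labels = pd.Series("MED", index=expr_t1.index, name="tertile")
    labels.loc[order[:third]] = "LO"
    labels.loc[order[n - third:]] = "HI"
    return labels
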