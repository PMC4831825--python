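"""Promoter-activity and poising calls: Class I / NP / P.

The procedure follows the two-stage testing scheme. First, each gene's
Pol II promoter count is tested against the genome-average IgG promoter
density with a one-sample Poisson test (upper tail), assuming background
read counts in short segments are Poisson; p-values are BH-adjusted and
genes with adjusted p < ``active_alpha`` (default 0.01) are Pol II+.
Second, among Pol II+ genes only, a one-sided Fisher's exact test on the
2x2 table [[Pol II promoter, Pol II body], [IgG promoter, IgG body]]
asks whether promoter density significantly exceeds body density;
BH-adjusted p < ``poised_alpha`` (default 0.001) marks a gene poised.

Classes: I (no significant promoter Pol II), NP (Pol II+ but promoter ~
body), P (Pol II+ and promoter >> body).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .coverage import add_densities, rpkm

CLASS_INACTIVE = "I"
CLASS_NONPOISED = "NP"
CLASS_POISED = "P"
CLASSES = (CLASS_INACTIVE, CLASS_NONPOISED, CLASS_POISED)


@dataclass(frozen=True)
class IgGBackground:
    """Genome-average IgG (mock-IP) densities, in RPKM, plus library size."""

    mean_prom_density: float
    mean_body_density: float
    igg_library: int


def igg_background(counts: pd.DataFrame) -> IgGBackground:
    """Average IgG promoter and body RPKM over the gene cohort."""
    if len(counts) == 0:
        raise ValueError("igg_background requires at least one gene")
    lib = int(counts["igg_library"].iloc[0])
    prom = rpkm(counts["igg_prom"].to_numpy(), counts["prom_len"].to_numpy(), lib)
    body = rpkm(counts["igg_body"].to_numpy(), counts["body_len"].to_numpy(), lib)
    return IgGBackground(float(np.mean(prom)), float(np.mean(body)), lib)


def poisson_activity_test(observed, background: IgGBackground, prom_len, polii_library):
    """Upper-tail Poisson test of a promoter count against the IgG rate.

    The Poisson mean is the expected promoter count at the Pol II library
    depth under the IgG density: ``mean_prom_density * (prom_len/1000) *
    (polii_library/1e6)``. Returns P(X >= observed). Vectorized.
    """
    observed = np.asarray(observed)
    if np.any(observed < 0):
        raise ValueError("observed count must be non-negative")
    lam = (
        background.mean_prom_density
        * (np.asarray(prom_len, dtype=float) / 1e3)
        * (float(polii_library) / 1e6)
    )
    lam = np.asarray(lam, dtype=float)
    with np.errstate(divide="ignore"):
        p = stats.poisson.sf(observed - 1, lam)
    # λ = 0: any positive observation is impossible under the null
    p = np.where(lam == 0, np.where(observed == 0, 1.0, 0.0), p)
    return p.item() if np.ndim(p) == 0 else p


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_poised_test(
    polii_prom: int, polii_body: int, igg_prom: int, igg_body: int
) -> float:
    """One-sided Fisher's exact p for promoter enrichment of the Pol II row.

    Table ``[[polii_prom, polii_body], [igg_prom, igg_body]]``; the
    alternative is odds ratio > 1 (Pol II shifted toward the promoter
    column). A zero row or zero column carries no evidence and returns 1.
    """
    a, b, c, d = (int(polii_prom), int(polii_body), int(igg_prom), int(igg_body))
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0
    # P(X >= a) for X ~ Hypergeom(N, row1, col1) == fisher_exact 'greater'
    return float(stats.hypergeom.sf(a - 1, a + b + c + d, a + b, a + c))


def fisher_poised_test_batch(
    polii_prom: np.ndarray, polii_body: np.ndarray, igg_prom: np.ndarray, igg_body: np.ndarray
) -> np.ndarray:
    """Vectorized :func:`fisher_poised_test` over aligned arrays."""
    a = np.asarray(polii_prom, dtype=np.int64)
    b = np.asarray(polii_body, dtype=np.int64)
    c = np.asarray(igg_prom, dtype=np.int64)
    d = np.asarray(igg_body, dtype=np.int64)
    if np.any(np.minimum(np.minimum(a, b), np.minimum(c, d)) < 0):
        raise ValueError("table entries must be non-negative")
    n = a + b + c + d
    p = stats.hypergeom.sf(a - 1, n, a + b, a + c)
    degenerate = (a + b == 0) | (c + d == 0) | (a + c == 0) | (b + d == 0)
    return np.where(degenerate, 1.0, p)


def expected_igg_counts(
    background: IgGBackground, prom_len, body_len
) -> tuple[np.ndarray, np.ndarray]:
    """Integer expected IgG counts per region at IgG library depth.

    Rounded to the nearest integer; floored at 1 when the rounding hits 0
    but the background density is positive (Fisher needs integers).
    """
    def expect(density: float, length) -> np.ndarray:
        raw = density * (np.asarray(length, dtype=float) / 1e3) * (background.igg_library / 1e6)
        cnt = np.rint(raw).astype(np.int64)
        if density > 0:
            cnt = np.maximum(cnt, 1)
        return cnt

    return expect(background.mean_prom_density, prom_len), expect(
        background.mean_body_density, body_len
    )


def classify(p_active_adj: float, p_poised_adj: float, config: PipelineConfig) -> str:
    """Class label from the two adjusted p-values.

    I if the activity test is not significant; otherwise P when the
    poising test is significant, NP when it is not. ``p_poised_adj`` may
    be NaN for class-I genes (it is never consulted).
    """
    if p_active_adj >= config.active_alpha:
        return CLASS_INACTIVE
    if p_poised_adj < config.poised_alpha:
        return CLASS_POISED
    return CLASS_NONPOISED


def call_poising(
    counts: pd.DataFrame,
    config: PipelineConfig | None = None,
    igg_mode: str = "expected",
) -> pd.DataFrame:
    """Run the full two-stage classification over a RegionCounts table.

    ``igg_mode`` selects the IgG row of the Fisher table: ``expected``
    (genome-average expected counts, the default) or ``per_gene`` (that
    gene's observed IgG counts). BH adjustment is applied separately to
    the activity family (all genes) and the poising family (Pol II+
    genes only). Returns a PoisingCall table with raw/adjusted p-values,
    the poising index, and the class label.
    """
    config = config or PipelineConfig()
    if igg_mode not in ("expected", "per_gene"):
        raise ValueError(f"igg_mode must be 'expected' or 'per_gene', got {igg_mode!r}")
    dens = add_densities(counts)
    background = igg_background(counts)
    polii_library = int(counts["polii_library"].iloc[0])

    p_active_raw = poisson_activity_test(
        dens["polii_prom"].to_numpy(),
        background,
        dens["prom_len"].to_numpy(),
        polii_library,
    )
    p_active_adj = bh_adjust(p_active_raw)
    active = p_active_adj < config.active_alpha

    p_poised_raw = np.full(len(dens), np.nan)
    p_poised_adj = np.full(len(dens), np.nan)
    if active.any():
        sub = dens.loc[active]
        if igg_mode == "expected":
            igg_prom, igg_body = expected_igg_counts(
                background, sub["prom_len"].to_numpy(), sub["body_len"].to_numpy()
            )
        else:
            igg_prom = sub["igg_prom"].to_numpy()
            igg_body = sub["igg_body"].to_numpy()
        raw = fisher_poised_test_batch(
            sub["polii_prom"].to_numpy(), sub["polii_body"].to_numpy(), igg_prom, igg_body
        )
        p_poised_raw[active] = raw
        p_poised_adj[active] = bh_adjust(raw)

    klass = [
        classify(pa, pp if not np.isnan(pp) else 1.0, config)
        for pa, pp in zip(p_active_adj, p_poised_adj)
    ]
    return pd.DataFrame(
        {
            "gene_id": dens["gene_id"],
            "p_active_raw": p_active_raw,
            "p_active_adj": p_active_adj,
            "p_poised_raw": p_poised_raw,
            "p_poised_adj": p_poised_adj,
            "prom_rpkm": dens["prom_rpkm"],
            "body_rpkm": dens["body_rpkm"],
            "poising_index": dens["poising_index"],
            "pi_flag": dens["pi_flag"],
            "klass": klass,
        }
    )
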