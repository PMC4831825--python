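"""G-quadruplex motif enrichment around TSSs of poised vs non-poised genes.

Builds a synthetic genome in which poised genes carry G4 motifs mostly
downstream of the TSS and non-poised genes mostly upstream, scans both
strands with the four-G-run motif definition, counts hits per
TSS-anchored window, and tests the group difference (Mann-Whitney, with
median/MAD summaries). Also shows how masking CpG islands that cover
half the downstream motifs attenuates the downstream signal.
"""

import numpy as np

from pol2poise import SimulationConfig, compare_g4_groups, count_g4_per_gene, mask_cpg, scan_g4_both_strands
from pol2poise.synthetic import simulate_cpg_islands, simulate_genes

cfg = SimulationConfig(n_genes=600, class_proportions=(0.2, 0.4, 0.4), seed=13)
sequence, models, truth = simulate_genes(cfg)
hits = scan_g4_both_strands(sequence, chrom=cfg.chrom)
print(f"{len(hits)} merged G4 hits on a {len(sequence)/1e6:.1f} Mb genome")

g4 = count_g4_per_gene(hits, models).set_index("gene_id")
klass = truth.classes().reindex(g4.index)

for window, x_label, x_cls, y_cls in (
    ("downstream_total", "poised", "P", "NP"),
    ("upstream_total", "non-poised", "NP", "P"),
):
    res = compare_g4_groups(g4.loc[(klass == x_cls).to_numpy(), window],
                            g4.loc[(klass == y_cls).to_numpy(), window])
    print(
        f"{window}: {x_label} genes enriched? direction={res.direction}, "
        f"p={res.p_value:.3g}, medians {res.median_x:.1f}/{res.median_y:.1f}, "
        f"MADs {res.mad_x:.1f}/{res.mad_y:.1f}"
    )

islands = simulate_cpg_islands(truth, cfg.chrom, fraction=0.5, rng=np.random.default_rng(1))
masked = count_g4_per_gene(mask_cpg(hits, islands), models)
before = g4["downstream_total"].sum()
after = masked["downstream_total"].sum()
print(
    f"CpG masking (islands over half the downstream motifs): "
    f"downstream counts {before} -> {after} ({100*(before-after)/before:.0f}% drop)"
)
print("(downstream G4 enrichment of poised genes largely rides on CpG-island sequence)")
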