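"""Numeric constants of the analysis, collected in one validated object.

Defaults reproduce the published analysis settings: a 600 bp promoter
window (−100/+500 around the TSS), gene body from +1 kb to the TTS, a
2 kb minimum gene length, BH-adjusted significance levels of 0.01
(promoter activity) and 0.001 (poising), fold-change bands 2/3–1.5, and
the QuadParser-style G4 motif definition (four runs of ≥3 G separated by
1–7 nt loops) counted in 3 kb upstream / 500 bp downstream TSS windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable thresholds of the poising pipeline.

    Lengths are in base pairs, alphas are probabilities applied to
    BH-adjusted p-values, fold-change bounds are plain ratios.
    """

    promoter_upstream: int = 100
    promoter_downstream: int = 500
    body_offset: int = 1000
    min_gene_length: int = 2000
    active_alpha: float = 0.01
    poised_alpha: float = 0.001
    fc_high: float = 1.5
    fc_low: float = 2.0 / 3.0
    pi_fc_threshold: float = 2.0
    g4_min_run: int = 3
    g4_n_runs: int = 4
    g4_loop_min: int = 1
    g4_loop_max: int = 7
    g4_upstream_window: int = 3000
    g4_downstream_window: int = 500

    def __post_init__(self) -> None:
        for name in (
            "promoter_upstream",
            "promoter_downstream",
            "body_offset",
            "min_gene_length",
            "g4_min_run",
            "g4_n_runs",
            "g4_loop_min",
            "g4_loop_max",
            "g4_upstream_window",
            "g4_downstream_window",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("active_alpha", "poised_alpha"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {p}")
        if not self.fc_low < 1.0 < self.fc_high:
            raise ValueError(
                f"fold-change band must straddle 1: fc_low={self.fc_low}, fc_high={self.fc_high}"
            )
        if self.g4_loop_min > self.g4_loop_max:
            raise ValueError("g4_loop_min must not exceed g4_loop_max")
        if self.min_gene_length < self.body_offset + 1:
            raise ValueError("min_gene_length must exceed body_offset (body would be empty)")

    @property
    def promoter_length(self) -> int:
        return self.promoter_upstream + self.promoter_downstream

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ValueError(f"unknown PipelineConfig keys: {sorted(unknown)}")
        return cls(**known)
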