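"""Shared pipeline configuration.

Every threshold used across the detection modules lives here so that a
single serialized config fully determines a run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields


@dataclass
class PipelineConfig:
    """Thresholds and rates shared across the detection pipeline.

    Attributes
    ----------
    het_vaf:
        Expected variant allele fraction of a heterozygous autosomal
        mutation in a clonal sample.
    error_rate:
        Per-read probability of reporting the variant allele in a
        wild-type sample (base-call error model).
    rho_threshold:
        Minimum maximum-likelihood beta-binomial overdispersion (rho)
        for a mutation to be considered phylogeny-violating.
    positive_subclade_min_vaf, positive_subclade_min_reads:
        Pooled VAF and variant-read requirements for calling a subclade
        confidently positive.
    negative_subclade_min_depth:
        Minimum pooled depth, with zero variant reads, for calling a
        subclade confidently negative.
    development_cutoff:
        Molecular time (mutations) below which a node is considered to
        fall within early development (in utero).
    mutation_rate_per_year:
        Clock-like mutation accumulation rate used to convert molecular
        time to years.
    seed:
        Seed for any stochastic step downstream of this config.
    """

    het_vaf: float = 0.5
    error_rate: float = 1e-6
    rho_threshold: float = 0.1
    positive_subclade_min_vaf: float = 0.25
    positive_subclade_min_reads: int = 3
    negative_subclade_min_depth: int = 13
    development_cutoff: float = 50.0
    mutation_rate_per_year: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.het_vaf <= 1.0:
            raise ValueError("het_vaf must be in (0, 1]")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if not 0.0 <= self.rho_threshold <= 1.0:
            raise ValueError("rho_threshold must be in [0, 1]")
        if not 0.0 <= self.positive_subclade_min_vaf <= 1.0:
            raise ValueError("positive_subclade_min_vaf must be in [0, 1]")
        if self.positive_subclade_min_reads < 0:
            raise ValueError("positive_subclade_min_reads must be >= 0")
        if self.negative_subclade_min_depth < 0:
            raise ValueError("negative_subclade_min_depth must be >= 0")
        if self.development_cutoff < 0:
            raise ValueError("development_cutoff must be >= 0")
        if self.mutation_rate_per_year <= 0:
            raise ValueError("mutation_rate_per_year must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)
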