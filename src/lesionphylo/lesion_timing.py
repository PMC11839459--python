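"""Molecular-time placement of lesions and chronological conversion."""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from lesionphylo.config import PipelineConfig
from lesionphylo.phylo_model import Phylogeny

__all__ = [
    "LesionTiming",
    "time_lesion",
    "molecular_to_years",
    "expected_mutation_rate",
    "incorporation_probability",
]


@dataclass
class LesionTiming:
    latest_acquisition: float  # molecular time of the lesion node
    earliest_resolution: float  # molecular time of the repair/loss node
    mmld: float
    in_utero: bool
    chronological_duration_low: float
    chronological_duration_high: float


def time_lesion(
    call,
    tree: Phylogeny,
    config: PipelineConfig | None = None,
    rate_low: float = 14.0,
    rate_high: float = 16.0,
) -> LesionTiming:
    """Time a pass PVV call or a classified simple/separated MAV.

    ``call`` needs ``lesion_node`` and a repair/loss node attribute.
    The lesion-node molecular time is the latest possible acquisition;
    the repair/loss node time the earliest possible resolution; their
    difference is the MMLD.
    """
    config = config or PipelineConfig()
    status = getattr(call, "status", None)
    if status is not None and status != "pass":
        raise ValueError("only pass calls can be timed")
    category = getattr(call, "category", None)
    if category is not None and category not in ("simple", "separated"):
        raise ValueError("only simple/separated MAVs can be timed")
    lesion = call.lesion_node
    repair = getattr(call, "repair_or_loss_node", None) or getattr(
        call, "lesion_repair_node", None
    )
    if lesion is None or repair is None:
        raise ValueError("call is missing lesion/repair nodes")
    t0 = tree.molecular_time(lesion)
    t1 = tree.molecular_time(repair)
    mmld = t1 - t0
    return LesionTiming(
        latest_acquisition=t0,
        earliest_resolution=t1,
        mmld=mmld,
        in_utero=t0 < config.development_cutoff,
        chronological_duration_low=molecular_to_years(mmld, rate_high),
        chronological_duration_high=molecular_to_years(mmld, rate_low),
    )


def molecular_to_years(mmld: float, rate_per_year: float) -> float:
    """Convert molecular time (mutations) to years under a clock rate."""
    if rate_per_year <= 0:
        raise ValueError("rate must be positive")
    return mmld / rate_per_year


def expected_mutation_rate(
    lesions_per_cell: float,
    misincorporation_prob: float,
    divisions_per_year: float,
) -> float:
    """Mutations per cell per year implied by steady-state lesion load."""
    if min(lesions_per_cell, misincorporation_prob, divisions_per_year) < 0:
        raise ValueError("inputs must be non-negative")
    return lesions_per_cell * misincorporation_prob * divisions_per_year


def incorporation_probability(
    n_alt_incorporations: int, n_ref_incorporations: int
) -> tuple[float, tuple[float, float]]:
    """Point estimate and exact 95% CI of the mutant-base incorporation
    probability from unbiased subclade counts.

    Counts must come from unbiased subclades only: lesion paths crossing
    more than two nodes, with the two detection-constrained subclades
    excluded (the caller applies that filter).
    """
    n = n_alt_incorporations + n_ref_incorporations
    if n == 0:
        raise ValueError("no incorporation observations")
    res = stats.binomtest(n_alt_incorporations, n)
    ci = res.proportion_ci(confidence_level=0.95, method="exact")
    return n_alt_incorporations / n, (float(ci.low), float(ci.high))
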