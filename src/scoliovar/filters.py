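"""Consequence and minor-allele-frequency rarity filters.

A variant is *rare* when, in every consulted population panel, it is
either unobserved (absent frequency) or at/below the MAF threshold.
The default comparison is inclusive (<= 0.01): the printed evidence in
the source cohort admits a variant whose Taiwan Biobank frequency equals
0.01 exactly, so the inclusive reading is the one consistent with the
reported results; strict (<) mode is kept as an option.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .models import AnnotatedVariant, CohortTable

logger = logging.getLogger(__name__)

DEFAULT_CONSEQUENCES = frozenset({"nonsynonymous SNV", "missense"})


@dataclass(frozen=True)
class FilterConfig:
    maf_threshold: float = 0.01
    threshold_inclusive: bool = True
    require_all_sources: bool = True
    allowed_consequences: frozenset[str] = field(default=DEFAULT_CONSEQUENCES)

    def __post_init__(self) -> None:
        if not (0.0 < self.maf_threshold < 1.0):
            raise ValueError(f"maf_threshold must be in (0, 1), got {self.maf_threshold}")
        if not self.allowed_consequences:
            raise ValueError("allowed_consequences must be non-empty")


def has_allowed_consequence(variant: AnnotatedVariant, config: FilterConfig) -> bool:
    """Any-transcript rule: one allowed label among the row's consequences."""
    return any(c in config.allowed_consequences for c in variant.consequence)


def filter_consequence(table: CohortTable, config: FilterConfig | None = None) -> CohortTable:
    """Retain variants with at least one allowed consequence label."""
    config = config or FilterConfig()
    keep = [i for i, v in enumerate(table.variants) if has_allowed_consequence(v, config)]
    logger.info("consequence filter: %d of %d variants retained", len(keep), table.n_variants)
    return table.subset(keep)


def _source_rare(value: float | None, config: FilterConfig) -> bool:
    if value is None:  # unobserved in this panel counts as rare
        return True
    if config.threshold_inclusive:
        return value <= config.maf_threshold
    return value < config.maf_threshold


def is_rare(variant: AnnotatedVariant, config: FilterConfig) -> bool:
    rare_flags = (_source_rare(v, config) for _, v in variant.freqs.items())
    return all(rare_flags) if config.require_all_sources else any(rare_flags)


def filter_rare(table: CohortTable, config: FilterConfig | None = None) -> CohortTable:
    """Retain variants rare in every panel (or any panel, per config)."""
    config = config or FilterConfig()
    removal_by_source = dict.fromkeys(
        [name for name, _ in table.variants[0].freqs.items()] if table.variants else [], 0
    )
    keep: list[int] = []
    for i, v in enumerate(table.variants):
        if is_rare(v, config):
            keep.append(i)
        else:
            for name, value in v.freqs.items():
                if not _source_rare(value, config):
                    removal_by_source[name] = removal_by_source.get(name, 0) + 1
    logger.info(
        "rarity filter (MAF %s %g): %d of %d variants retained; exceedances per source: %s",
        "<=" if config.threshold_inclusive else "<",
        config.maf_threshold,
        len(keep),
        table.n_variants,
        removal_by_source,
    )
    return table.subset(keep)
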