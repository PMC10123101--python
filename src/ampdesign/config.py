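"""Design configuration and named presets.

A :class:`DesignConfig` bundles every tunable of the amplicon/gRNA design
pipeline: amplicon size range, the candidate budget handed to the primer
engine, primer spacing, the guide-to-primer distance rule, homopolymer and
poly-T thresholds, specificity-screen parameters, and per-gene selection
caps.  Four presets cover the common genotyping assays:

``hiplex``   120-150 bp amplicons, 15 bp guide-primer distance (highly
             multiplexed short-read amplicon sequencing).
``pe``       220-250 bp, 15 bp (paired-end 150 bp Illumina reads).
``sanger``   400-800 bp, 150 bp (Sanger trace deconvolution tools want the
             cut site well away from the primers).
``natvar``   120-150 bp, coverage-maximising mode without gRNAs, with an
             unlimited number of non-overlapping amplicons per gene
             (natural-variation screens / eco-tilling).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional


class ConfigError(ValueError):
    """Invalid or inconsistent design configuration."""


@dataclass
class DesignConfig:
    # amplicon geometry
    size_min: int = 120
    size_max: int = 150
    max_candidates_per_gene: int = 150
    min_primer_spacing: int = 5

    # primer engine (built-in nearest-neighbour fallback defaults)
    primer_len_min: int = 18
    primer_len_opt: int = 20
    primer_len_max: int = 27
    tm_min: float = 57.0
    tm_opt: float = 60.0
    tm_max: float = 63.0
    gc_min: float = 0.20
    gc_max: float = 0.80

    # amplicon-level filters
    homopolymer_max: Optional[int] = 10  # None switches the filter off
    rpd: bool = False  # restrict design to exon neighbourhoods

    # specificity screen
    specificity_check: bool = True
    max_mismatches: int = 2
    three_prime_exact: int = 4
    max_unintended_product: int = 1000
    max_binding_sites_per_primer: int = 1

    # gRNA filters
    polyT_run: int = 4
    promoter_flank: str = ""
    scaffold_flank: str = ""
    enzymes: tuple[str, ...] = ()
    exclude_5p_frac: float = 0.0
    exclude_3p_frac: float = 0.0
    required_feature_type: Optional[str] = None
    min_specificity: Optional[float] = None

    # grouping / selection
    min_primer_guide_distance: int = 15
    max_amplicons_per_gene: Optional[int] = 2
    max_guides_per_amplicon: int = 2
    mode: str = "CRISPR"  # or "NatVar"

    # outputs
    border_length: int = 10

    def __post_init__(self) -> None:
        if self.size_min > self.size_max:
            raise ConfigError(f"size_min {self.size_min} > size_max {self.size_max}")
        if self.size_min < 2 * self.primer_len_min:
            raise ConfigError(
                f"size_min {self.size_min} smaller than two minimal primers "
                f"({2 * self.primer_len_min} bp)"
            )
        if self.mode not in ("CRISPR", "NatVar"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.exclude_5p_frac + self.exclude_3p_frac >= 1.0 and (
            self.exclude_5p_frac > 0 or self.exclude_3p_frac > 0
        ):
            raise ConfigError("exclude_5p_frac + exclude_3p_frac must be < 1")
        for name in (
            "min_primer_spacing",
            "min_primer_guide_distance",
            "polyT_run",
            "border_length",
            "max_mismatches",
            "three_prime_exact",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")

    def replace(self, **kwargs) -> "DesignConfig":
        return dataclasses.replace(self, **kwargs)


PRESETS: dict[str, dict] = {
    "hiplex": dict(size_min=120, size_max=150, min_primer_guide_distance=15),
    "pe": dict(size_min=220, size_max=250, min_primer_guide_distance=15),
    "sanger": dict(size_min=400, size_max=800, min_primer_guide_distance=150),
    "natvar": dict(
        size_min=120,
        size_max=150,
        mode="NatVar",
        max_amplicons_per_gene=None,
    ),
}


def preset(name: str, **overrides) -> DesignConfig:
    """Build a :class:`DesignConfig` from a named preset plus overrides."""
    try:
        base = dict(PRESETS[name])
    except KeyError:
        raise ConfigError(
            f"unknown preset {name!r}; choose from {sorted(PRESETS)}"
        ) from None
    base.update(overrides)
    return DesignConfig(**base)
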