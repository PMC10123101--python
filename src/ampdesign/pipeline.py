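"""End-to-end design pipeline: targets + (optional) guides -> candidate
amplicons -> specificity screen -> grouping/ranking/selection -> output
bundle, with per-gene dropout accounting and a machine-readable run report.

With a gRNA table the pipeline runs in CRISPR mode (amplicons are ranked by
the guides they cover); without one it runs in NatVar mode and selects
non-overlapping amplicons maximising reference coverage.  Specificity is
always screened against *all* reference sequences, even when design is
restricted to a subset of genes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .config import ConfigError, DesignConfig
from .guides import GuideRNA, filter_all
from .primers import (
    AmpliconCandidate,
    ReferenceIndex,
    check_specificity,
    exon_windows,
    generate_candidates,
    mask_primer_sites,
)
from .selection import (
    DropoutReason,
    GeneDesign,
    choose_guide_subset,
    cross_mixture_check,
    dropout_reason,
    group_guides,
    rank_amplicons,
    select_coverage,
    select_top,
)
from .targets import GeneTarget
from . import outputs

log = logging.getLogger(__name__)


@dataclass
class DesignResult:
    designs: list[GeneDesign]
    warnings: list[str] = field(default_factory=list)
    all_candidates: dict[str, list[AmpliconCandidate]] = field(default_factory=dict)
    filtered_candidates: dict[str, list] = field(default_factory=dict)
    guide_ledger: dict[str, list] = field(default_factory=dict)
    report: dict = field(default_factory=dict)

    @property
    def n_designed(self) -> int:
        return sum(1 for d in self.designs if d.dropout_reason is None)


def design_gene(
    gene: GeneTarget,
    guides: Sequence[GuideRNA],
    ref_index: ReferenceIndex,
    config: DesignConfig,
) -> tuple[GeneDesign, dict]:
    """Run the full per-gene design; returns the design and debug state."""
    counters: dict[str, int] = {"guides_input": len(guides)}
    debug: dict = {"all_candidates": [], "filtered": [], "guide_ledger": []}
    seq_ok = len(gene.sequence) >= config.size_min
    crispr = config.mode == "CRISPR"

    kept_guides: list[GuideRNA] = []
    if crispr:
        kept_guides, ledger = filter_all(guides, gene, config)
        debug["guide_ledger"] = ledger
        counters["guides_filtered"] = len(kept_guides)

    windows = exon_windows(gene, config) if config.rpd else None
    candidates, fail = generate_candidates(gene, config, windows=windows)
    debug["all_candidates"] = candidates
    counters["candidates_generated"] = len(candidates)

    specific = []
    for cand in candidates:
        ok, _reasons = check_specificity(cand, ref_index, config)
        if ok:
            specific.append(cand)
    counters["candidates_specific"] = len(specific)

    selected: list[tuple[AmpliconCandidate, list[GuideRNA]]] = []
    n_grouped = 0
    if crispr:
        grouped = group_guides(
            specific, kept_guides, config.min_primer_guide_distance
        )
        pairs = []
        for amp in specific:
            gs = grouped.get(amp.amplicon_id, [])
            gs = choose_guide_subset(gs, config.max_guides_per_amplicon)
            pairs.append((amp, gs))
        guided = [(a, gs) for a, gs in pairs if gs]
        n_grouped = len(guided)
        counters["amplicons_with_guides"] = n_grouped
        debug["filtered"] = guided
        ranked = rank_amplicons(guided)
        selected = select_top(ranked, config.max_amplicons_per_gene)
    else:
        debug["filtered"] = [(a, []) for a in specific]
        chosen = select_coverage(specific, config.max_amplicons_per_gene)
        selected = [(a, []) for a in chosen]
    counters["amplicons_selected"] = len(selected)

    if selected:
        design = GeneDesign(
            gene_id=gene.gene_id,
            family_id=gene.family_id,
            selected=selected,
            counters=counters,
        )
    else:
        reason = dropout_reason(
            mode=config.mode,
            sequence_long_enough=seq_ok,
            n_guides_input=len(guides),
            n_guides_filtered=len(kept_guides),
            n_specific_amplicons=len(specific),
            n_grouped_amplicons=n_grouped,
            had_selection=False,
        )
        design = GeneDesign(
            gene_id=gene.gene_id,
            family_id=gene.family_id,
            dropout_reason=reason,
            counters=counters,
        )
    return design, debug


def run_design(
    targets: Sequence[GeneTarget],
    guides: Optional[Sequence[GuideRNA]] = None,
    config: Optional[DesignConfig] = None,
    design_only: Optional[Sequence[str]] = None,
) -> DesignResult:
    """Design amplicons (and guide assignments) for every target gene.

    ``design_only`` restricts design to a gene subset while the specificity
    screen still runs against every reference sequence.
    """
    config = config or DesignConfig()
    crispr = config.mode == "CRISPR"
    if crispr and guides is None:
        guides = []
    if not crispr and guides:
        raise ConfigError("NatVar mode takes no gRNA table")

    ref_index = ReferenceIndex(targets)
    by_gene: dict[str, list[GuideRNA]] = {}
    for g in guides or []:
        by_gene.setdefault(g.gene_id, []).append(g)

    design_set = set(design_only) if design_only is not None else None
    result = DesignResult(designs=[])
    for gene in targets:
        if design_set is not None and gene.gene_id not in design_set:
            continue
        design, debug = design_gene(
            gene, by_gene.get(gene.gene_id, []), ref_index, config
        )
        result.designs.append(design)
        result.all_candidates[gene.gene_id] = debug["all_candidates"]
        result.filtered_candidates[gene.gene_id] = debug["filtered"]
        result.guide_ledger[gene.gene_id] = debug["guide_ledger"]

    result.warnings = cross_mixture_check(result.designs, ref_index, config)
    result.report = _make_report(result, config)
    return result


def run_natvar_tiling(
    targets: Sequence[GeneTarget],
    config: DesignConfig,
    rounds: int = 2,
) -> list[DesignResult]:
    """Iterative NatVar tiling: after each round the selected primer binding
    sites are masked with N and the design re-runs with the same settings,
    yielding complementary amplicon sets for parallel PCR mixtures."""
    if config.mode != "NatVar":
        raise ConfigError("tiling is a NatVar-mode workflow")
    results = []
    current = list(targets)
    for _ in range(rounds):
        res = run_design(current, guides=None, config=config)
        results.append(res)
        by_gene = {t.gene_id: t for t in current}
        for d in res.designs:
            if d.dropout_reason is None:
                by_gene[d.gene_id] = mask_primer_sites(
                    by_gene[d.gene_id], [a for a, _ in d.selected]
                )
        current = [by_gene[t.gene_id] for t in current]
    return results


def _make_report(result: DesignResult, config: DesignConfig) -> dict:
    from . import __version__

    per_gene = {
        d.gene_id: dict(d.counters)
        | {"dropout": d.dropout_reason.value if d.dropout_reason else None}
        for d in result.designs
    }
    cfg = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in vars(config).items()
    }
    return {
        "version": __version__,
        "parameters": cfg,
        "n_genes": len(result.designs),
        "n_designed": result.n_designed,
        "n_dropout": len(result.designs) - result.n_designed,
        "n_cross_mixture_warnings": len(result.warnings),
        "per_gene": per_gene,
    }


def write_bundle(
    result: DesignResult,
    targets: Sequence[GeneTarget],
    out_dir: str,
    config: DesignConfig,
    debug: bool = False,
    summary: bool = False,
) -> dict[str, str]:
    """Write the output bundle; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    p = out / "primers.tsv"
    outputs.write_primer_tsv(result.designs, str(p))
    paths["primer_tsv"] = str(p)

    gp = outputs.write_guide_tsv(
        result.designs, str(out / "guides.tsv"), mode=config.mode
    )
    if gp:
        paths["guide_tsv"] = gp

    p = out / "design.gff3"
    outputs.write_design_gff(result.designs, targets, str(p))
    paths["design_gff"] = str(p)

    p = out / "borders.gff3"
    outputs.write_border_gff(result.designs, str(p), config.border_length)
    paths["border_gff"] = str(p)

    p = out / "sites.bed"
    outputs.write_sites_bed(result.designs, str(p))
    paths["sites_bed"] = str(p)

    if summary:
        paths.update(outputs.write_summary(result.designs, str(out)))

    if debug:
        pre, post = out / "debug_all.gff3", out / "debug_filtered.gff3"
        outputs.write_debug_gffs(
            result.all_candidates, result.filtered_candidates, str(pre), str(post)
        )
        paths["debug_gff_all"] = str(pre)
        paths["debug_gff_filtered"] = str(post)

    p = out / "run_report.json"
    with open(p, "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
    paths["report"] = str(p)

    if result.warnings:
        p = out / "cross_mixture_warnings.txt"
        p.write_text("\n".join(result.warnings) + "\n")
        paths["warnings"] = str(p)
    return paths
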