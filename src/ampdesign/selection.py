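"""Guide grouping, amplicon ranking and non-overlapping selection.

CRISPR mode ranks each gene's specific amplicons by (i) number of grouped
gRNAs (more is better), (ii) number of positionally overlapping gRNA pairs
(fewer is better, ties by total overlapped bases), (iii) mean specificity
score, (iv) mean efficiency score, with a deterministic leftmost /
lexicographic tie-break, then greedily picks top-ranking amplicons whose
products do not overlap.  NatVar (natural variation) mode has no gRNAs and
instead solves weighted interval scheduling exactly to maximise the number
of reference bases covered by non-overlapping amplicons.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .config import DesignConfig
from .guides import GuideRNA
from .primers import (
    AmpliconCandidate,
    ReferenceIndex,
    convergent_products,
    find_binding_sites,
)
from .targets import GeneTarget

log = logging.getLogger(__name__)


class DropoutReason(str, Enum):
    NO_GRNAS_DESIGNED = "no gRNAs designed for this gene"
    NO_GRNAS_PASSED_FILTERS = "none of the gRNAs passed all filters"
    NO_SPECIFIC_AMPLICONS = "no specific amplicons could be designed"
    NO_GRNA_AMPLICON_OVERLAP = "no overlap between gRNAs and amplicons"
    SEQUENCE_TOO_SHORT = "sequence too short for the amplicon size range"


@dataclass
class GeneDesign:
    """Selected, ranked amplicon/guide sets for one gene (or its dropout)."""

    gene_id: str
    family_id: str = ""
    selected: list[tuple[AmpliconCandidate, list[GuideRNA]]] = field(
        default_factory=list
    )
    dropout_reason: Optional[DropoutReason] = None
    counters: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.dropout_reason is None) == (len(self.selected) == 0):
            raise ValueError(
                f"{self.gene_id}: dropout_reason must be set iff nothing selected"
            )
        ivs = sorted(a.product_interval for a, _ in self.selected)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"{self.gene_id}: selected amplicons overlap")

    @property
    def n_amplicons(self) -> int:
        return len(self.selected)

    @property
    def n_guides(self) -> int:
        return sum(len(gs) for _, gs in self.selected)


# ---------------------------------------------------------------------------
# grouping


def group_guides(
    amplicons: Sequence[AmpliconCandidate],
    guides: Sequence[GuideRNA],
    min_distance: int = 15,
) -> dict[str, list[GuideRNA]]:
    """Group each guide to every amplicon keeping >= min_distance bp between
    the primer end and the protospacer (distance exactly min_distance
    qualifies).  Guides within an amplicon are sorted by target start."""
    out: dict[str, list[GuideRNA]] = {}
    for a in amplicons:
        lo = a.fwd_interval[1] + min_distance
        hi = a.rev_interval[0] - min_distance
        grouped = [
            g
            for g in guides
            if g.target_interval[0] >= lo and g.target_interval[1] <= hi
        ]
        grouped.sort(key=lambda g: (g.target_interval, g.guide_id))
        out[a.amplicon_id] = grouped
    return out


def guide_overlap_pairs(guides: Sequence[GuideRNA]) -> int:
    """Number of unordered guide pairs whose protospacers share >= 1 bp."""
    n = 0
    for g1, g2 in itertools.combinations(guides, 2):
        if g1.target_interval[0] < g2.target_interval[1] and g2.target_interval[0] < g1.target_interval[1]:
            n += 1
    return n


def _overlap_bases(guides: Sequence[GuideRNA]) -> int:
    total = 0
    for g1, g2 in itertools.combinations(guides, 2):
        s = max(g1.target_interval[0], g2.target_interval[0])
        e = min(g1.target_interval[1], g2.target_interval[1])
        total += max(0, e - s)
    return total


def _mean_or_none(vals: list[float]) -> Optional[float]:
    return sum(vals) / len(vals) if vals else None


def _subset_key(subset: Sequence[GuideRNA]) -> tuple:
    """(overlap pairs asc, mean specificity desc, mean efficiency desc)."""
    specs = [g.specificity_score for g in subset if g.specificity_score is not None]
    effs = [g.mean_efficiency() for g in subset if g.mean_efficiency() is not None]
    mspec = _mean_or_none(specs)
    meff = _mean_or_none(effs)
    return (
        guide_overlap_pairs(subset),
        -(mspec if mspec is not None else -math.inf),
        -(meff if meff is not None else -math.inf),
        tuple(sorted((g.target_interval, g.guide_id) for g in subset)),
    )


MAX_EXACT_SUBSETS = 20_000


def choose_guide_subset(
    guides: Sequence[GuideRNA], max_guides: int
) -> list[GuideRNA]:
    """Limit an amplicon's guides to max_guides, preferring non-overlapping
    guides, then high mean specificity, then high mean efficiency.

    Small instances are solved exactly over all subsets; larger ones fall
    back to a deterministic greedy by marginal gain.  Result ordered by
    target start.
    """
    if max_guides < 1:
        raise ValueError("max_guides must be >= 1")
    guides = sorted(guides, key=lambda g: (g.target_interval, g.guide_id))
    if len(guides) <= max_guides:
        return guides
    if math.comb(len(guides), max_guides) <= MAX_EXACT_SUBSETS:
        best = min(
            itertools.combinations(guides, max_guides), key=_subset_key
        )
        return sorted(best, key=lambda g: (g.target_interval, g.guide_id))
    chosen: list[GuideRNA] = []
    pool = list(guides)
    while len(chosen) < max_guides:
        nxt = min(pool, key=lambda g: _subset_key(chosen + [g]))
        chosen.append(nxt)
        pool.remove(nxt)
    return sorted(chosen, key=lambda g: (g.target_interval, g.guide_id))


# ---------------------------------------------------------------------------
# ranking


def rank_key(
    amplicon: AmpliconCandidate, guides: Sequence[GuideRNA]
) -> tuple:
    """Strict total order: guide count desc, overlapping pairs asc (ties by
    overlapped bases), mean specificity desc, mean efficiency desc, then
    leftmost forward start and amplicon_id."""
    specs = [g.specificity_score for g in guides if g.specificity_score is not None]
    effs = [g.mean_efficiency() for g in guides if g.mean_efficiency() is not None]
    mspec = _mean_or_none(specs)
    meff = _mean_or_none(effs)
    return (
        -len(guides),
        guide_overlap_pairs(guides),
        _overlap_bases(guides),
        -(mspec if mspec is not None else -math.inf),
        -(meff if meff is not None else -math.inf),
        amplicon.fwd_interval[0],
        amplicon.amplicon_id,
    )


def rank_amplicons(
    amplicons_with_guides: Sequence[tuple[AmpliconCandidate, list[GuideRNA]]],
) -> list[tuple[AmpliconCandidate, list[GuideRNA]]]:
    return sorted(amplicons_with_guides, key=lambda ag: rank_key(*ag))


def select_top(
    ranked: Sequence[tuple[AmpliconCandidate, list[GuideRNA]]],
    max_amplicons: Optional[int],
) -> list[tuple[AmpliconCandidate, list[GuideRNA]]]:
    """Greedy scan in rank order; take an amplicon iff its product (primers
    included) is disjoint from everything already taken."""
    taken: list[tuple[AmpliconCandidate, list[GuideRNA]]] = []
    for amp, gs in ranked:
        if max_amplicons is not None and len(taken) >= max_amplicons:
            break
        s, e = amp.product_interval
        if all(
            e <= t.product_interval[0] or s >= t.product_interval[1]
            for t, _ in taken
        ):
            taken.append((amp, gs))
    return taken


# ---------------------------------------------------------------------------
# coverage mode (NatVar): exact weighted interval scheduling


def select_coverage(
    candidates: Sequence[AmpliconCandidate],
    max_amplicons: Optional[int] = None,
) -> list[AmpliconCandidate]:
    """Pairwise-disjoint subset maximising total covered bases.

    Solved exactly by dynamic programming over candidates sorted by product
    end (weight = product size).  Ties prefer fewer amplicons, then the
    leftmost start sequence.
    """
    cands = sorted(
        candidates, key=lambda c: (c.product_interval[1], c.product_interval[0], c.amplicon_id)
    )
    n = len(cands)
    if n == 0:
        return []
    kmax = n if max_amplicons is None else min(max_amplicons, n)
    if kmax == 0:
        return []

    # p[i]: rightmost j < i with product_end <= product_start of i
    starts = [c.product_interval[0] for c in cands]
    ends = [c.product_interval[1] for c in cands]
    p = []
    for i in range(n):
        j = i - 1
        while j >= 0 and ends[j] > starts[i]:
            j -= 1
        p.append(j)

    def better(a: Optional[tuple], b: Optional[tuple]) -> Optional[tuple]:
        # selection tuples of candidate indices; compare coverage desc,
        # count asc, start sequence lexicographically asc
        if a is None:
            return b
        if b is None:
            return a
        cov_a = sum(ends[i] - starts[i] for i in a)
        cov_b = sum(ends[i] - starts[i] for i in b)
        ka = (-cov_a, len(a), tuple(starts[i] for i in a), a)
        kb = (-cov_b, len(b), tuple(starts[i] for i in b), b)
        return a if ka <= kb else b

    # best[i][k]: best selection among first i candidates using <= k of them
    best: list[list[Optional[tuple]]] = [
        [() for _ in range(kmax + 1)] for _ in range(n + 1)
    ]
    for i in range(1, n + 1):
        for k in range(kmax + 1):
            skip = best[i - 1][k]
            take = None
            if k >= 1:
                prev = best[p[i - 1] + 1][k - 1]
                take = tuple(prev) + (i - 1,)
            best[i][k] = better(skip, take)

    sel = best[n][kmax] or ()
    chosen = [cands[i] for i in sel]
    chosen.sort(key=lambda c: c.product_interval)
    return chosen


# ---------------------------------------------------------------------------
# multiplex-level cross-amplification audit


def cross_mixture_check(
    designs: Sequence[GeneDesign],
    references: Sequence[GeneTarget] | ReferenceIndex,
    config: DesignConfig,
) -> list[str]:
    """Warn about convergent co-binding between primers of *different*
    amplicons in the final multiplex mixture (warnings, not removals).

    Products formed on a gene by two of its own selected amplicons are the
    expected combined span of deliberately stacked assays, not mispriming,
    and are not reported.
    """
    if not config.specificity_check:
        return []
    idx = (
        references
        if isinstance(references, ReferenceIndex)
        else ReferenceIndex(references)
    )
    # (amplicon_id, gene_id, role, sites)
    primers: list[tuple[str, str, str, list]] = []
    for d in designs:
        for amp, _ in d.selected:
            for role, seq in (("F", amp.fwd_seq), ("R", amp.rev_seq)):
                sites = find_binding_sites(
                    seq, idx, config.max_mismatches, config.three_prime_exact
                )
                primers.append((amp.amplicon_id, amp.gene_id, role, sites))

    warnings: list[str] = []
    seen: set[tuple] = set()
    for (id1, gene1, role1, sites1), (id2, gene2, role2, sites2) in (
        itertools.combinations(primers, 2)
    ):
        if id1 == id2:
            continue
        for a, b, prod in convergent_products(
            sites1, sites2, config.max_unintended_product
        ):
            if gene1 == gene2 == prod[0]:
                continue
            key = (min(id1, id2), max(id1, id2), prod)
            if key in seen:
                continue
            seen.add(key)
            warnings.append(
                f"potential cross-amplification between {id1}({role1}) and "
                f"{id2}({role2}) at {prod[0]}:{prod[1]}-{prod[2]}"
            )
    return warnings


# ---------------------------------------------------------------------------
# dropout taxonomy and retention


def dropout_reason(
    mode: str,
    sequence_long_enough: bool,
    n_guides_input: int,
    n_guides_filtered: int,
    n_specific_amplicons: int,
    n_grouped_amplicons: int,
    had_selection: bool,
) -> DropoutReason:
    """First applicable dropout reason in the fixed precedence order."""
    if had_selection:
        raise ValueError("dropout_reason called on a gene with selections")
    if mode == "NatVar":
        if not sequence_long_enough:
            return DropoutReason.SEQUENCE_TOO_SHORT
        return DropoutReason.NO_SPECIFIC_AMPLICONS
    if n_guides_input == 0:
        return DropoutReason.NO_GRNAS_DESIGNED
    if n_guides_filtered == 0:
        return DropoutReason.NO_GRNAS_PASSED_FILTERS
    if n_specific_amplicons == 0:
        return DropoutReason.NO_SPECIFIC_AMPLICONS
    return DropoutReason.NO_GRNA_AMPLICON_OVERLAP


def compute_retention(
    designs: Sequence[GeneDesign],
    min_amplicons: int = 1,
    min_guides: int = 2,
) -> dict[str, Optional[float]]:
    """Per-family retention: percentage of genes with >= min_amplicons
    selected amplicons, each counted only if it covers >= min_guides guides.

    min_guides=1 gives the genome-wide variant (>= 1 amplicon with >= 1
    gRNA per gene).  Empty families report None (NA).
    """
    by_family: dict[str, list[GeneDesign]] = {}
    for d in designs:
        by_family.setdefault(d.family_id, []).append(d)
    out: dict[str, Optional[float]] = {}
    for fam, ds in by_family.items():
        if not ds:
            out[fam] = None
            continue
        retained = sum(
            1
            for d in ds
            if sum(1 for _, gs in d.selected if len(gs) >= min_guides)
            >= min_amplicons
        )
        out[fam] = 100.0 * retained / len(ds)
    return out
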