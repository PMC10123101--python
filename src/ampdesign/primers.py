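"""Candidate amplicon generation and primer specificity screening.

Per gene, the engine enumerates primer pairs inside a configured product
size range, spaced along the sequence so the candidate amplicons spread
across the target, and scores primers with a nearest-neighbour melting
temperature model.  Every primer is then screened for mispriming against
the entire reference set: a primer may bind nowhere but its intended site
(allowing a configurable mismatch budget with an exact 3' anchor), and no
convergent pair of binding sites may yield an unintended product.

The scoring engine is pluggable.  The built-in engine uses Biopython's
nearest-neighbour thermodynamics (50 mM monovalent salt, 50 nM oligo) with
a Primer3-like penalty: |Tm - Tm_opt| plus weighted GC-bound violation and
length deviation.  An external thermodynamic engine implementing
``score(primer) -> (tm, gc, penalty)`` can be substituted.
"""

from __future__ import annotations

import functools
import logging
import re
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from Bio.SeqUtils import MeltingTemp

from .config import DesignConfig
from .dna import revcomp, validate_alphabet
from .targets import GeneTarget

log = logging.getLogger(__name__)

# penalty weights of the built-in engine (per unit violation)
W_GC = 100.0   # GC bounds are effectively hard
W_LEN = 0.5


@dataclass(frozen=True)
class AmpliconCandidate:
    """One primer pair on a gene, with intervals on the gene's + strand.

    ``rev_seq`` is the reverse complement of the gene slice at
    ``rev_interval``; the amplified product is ``product_interval ==
    [fwd_start, rev_end)`` (primers included).
    """

    amplicon_id: str
    gene_id: str
    fwd_seq: str
    rev_seq: str
    fwd_interval: tuple[int, int]
    rev_interval: tuple[int, int]
    tm_fwd: float
    tm_rev: float
    gc_fwd: float
    gc_rev: float
    penalty: float

    @property
    def product_interval(self) -> tuple[int, int]:
        return (self.fwd_interval[0], self.rev_interval[1])

    @property
    def product_size(self) -> int:
        return self.rev_interval[1] - self.fwd_interval[0]

    def product_seq(self, gene: GeneTarget) -> str:
        s, e = self.product_interval
        return gene.sequence[s:e]


# ---------------------------------------------------------------------------
# built-in thermodynamic engine


@functools.lru_cache(maxsize=1_000_000)
def _tm_nn(primer: str) -> float:
    return float(
        MeltingTemp.Tm_NN(primer, Na=50, dnac1=50, dnac2=0, saltcorr=5)
    )


def fallback_primer_score(
    primer: str, config: DesignConfig
) -> tuple[float, float, float]:
    """Score one primer: (melting temperature degC, GC fraction, penalty).

    Deterministic nearest-neighbour Tm; penalty is 0 at the optimum
    (tm == tm_opt, len == len_opt, GC within bounds) and grows linearly
    with each violation.
    """
    validate_alphabet(primer, allow_n=False)
    tm = _tm_nn(primer)
    gc = (primer.count("G") + primer.count("C")) / len(primer)
    gc_violation = max(0.0, config.gc_min - gc) + max(0.0, gc - config.gc_max)
    penalty = (
        abs(tm - config.tm_opt)
        + W_GC * gc_violation
        + W_LEN * abs(len(primer) - config.primer_len_opt)
    )
    return tm, gc, penalty


class BuiltinEngine:
    """Default scoring engine backed by nearest-neighbour thermodynamics."""

    def __init__(self, config: DesignConfig):
        self.config = config

    def score(self, primer: str) -> tuple[float, float, float]:
        return fallback_primer_score(primer, self.config)


# ---------------------------------------------------------------------------
# candidate generation


def has_homopolymer(sequence: str, threshold: int = 10) -> bool:
    """True iff some base repeats >= threshold times in a row.

    Only real bases (A/C/G/T) form runs; N is a mask character, not a
    nucleotide, so masked stretches never count as homopolymers.
    """
    if threshold < 2:
        raise ValueError("homopolymer threshold must be >= 2")
    run = 1
    prev = ""
    for b in sequence:
        run = run + 1 if (b == prev and b != "N") else 1
        prev = b
        if run >= threshold:
            return True
    return False


def _best_primer_at(
    seq: str, start: int, lengths: range, engine, forward: bool
) -> Optional[tuple[str, tuple[int, int], float, float, float]]:
    """Best-scoring primer anchored at ``start`` (5' end for forward primers,
    3'-most product position exclusive for reverse primers)."""
    best = None
    for k in lengths:
        if forward:
            s, e = start, start + k
        else:
            s, e = start - k, start
        if s < 0 or e > len(seq):
            continue
        sl = seq[s:e]
        if "N" in sl:
            continue
        primer = sl if forward else revcomp(sl)
        tm, gc, pen = engine.score(primer)
        key = (pen, k)
        if best is None or key < best[0]:
            best = (key, primer, (s, e), tm, gc, pen)
    if best is None:
        return None
    return best[1:]


def generate_candidates(
    gene: GeneTarget,
    config: DesignConfig,
    windows: Optional[Sequence[tuple[int, int]]] = None,
    engine=None,
) -> tuple[list[AmpliconCandidate], Optional[str]]:
    """Enumerate candidate amplicons for one gene.

    Returns (candidates, failure_reason).  Candidates are sorted by pair
    penalty ascending (ties by forward start), capped at
    ``max_candidates_per_gene``; forward-primer starts of the retained set
    differ by at least ``min_primer_spacing`` so amplicons spread across
    the sequence.  Primers never cover an N, and when the homopolymer
    filter is on no product contains a homopolymer run >= the threshold.
    When ``windows`` are given (exon-restricted design) every product lies
    inside one window.
    """
    seq = gene.sequence
    L = len(seq)
    if L < config.size_min:
        return [], "sequence too short"
    if set(seq) <= {"N"}:
        return [], "no primer-compatible region"
    engine = engine or BuiltinEngine(config)
    lengths = range(config.primer_len_min, config.primer_len_max + 1)

    if windows is None:
        windows = [(0, L)]

    # best primer per anchor position, shared across candidate pairs
    fwd_memo: dict[int, Optional[tuple]] = {}
    rev_memo: dict[int, Optional[tuple]] = {}

    def best_fwd(pos):
        if pos not in fwd_memo:
            fwd_memo[pos] = _best_primer_at(seq, pos, lengths, engine, forward=True)
        return fwd_memo[pos]

    def best_rev(pos):
        if pos not in rev_memo:
            rev_memo[pos] = _best_primer_at(seq, pos, lengths, engine, forward=False)
        return rev_memo[pos]

    raw: list[AmpliconCandidate] = []
    last_start = None
    for win_s, win_e in windows:
        for fwd_start in range(max(0, win_s), min(L, win_e) - config.size_min + 1):
            if last_start is not None and fwd_start - last_start < config.min_primer_spacing:
                continue
            fwd = best_fwd(fwd_start)
            if fwd is None:
                continue
            fwd_seq, fwd_iv, tm_f, gc_f, pen_f = fwd
            best_pair = None
            hi = min(fwd_start + config.size_max, win_e, L)
            for rev_end in range(fwd_start + config.size_min, hi + 1):
                rev = best_rev(rev_end)
                if rev is None:
                    continue
                rev_seq, rev_iv, tm_r, gc_r, pen_r = rev
                if rev_iv[0] < fwd_iv[1]:  # primers must not overlap
                    continue
                key = (pen_r, rev_end)
                if best_pair is None or key < best_pair[0]:
                    best_pair = (key, rev_seq, rev_iv, tm_r, gc_r, pen_r)
            if best_pair is None:
                continue
            _, rev_seq, rev_iv, tm_r, gc_r, pen_r = best_pair
            if config.homopolymer_max is not None and has_homopolymer(
                seq[fwd_start : rev_iv[1]], config.homopolymer_max
            ):
                continue
            raw.append(
                AmpliconCandidate(
                    amplicon_id="",  # assigned after sorting
                    gene_id=gene.gene_id,
                    fwd_seq=fwd_seq,
                    rev_seq=rev_seq,
                    fwd_interval=fwd_iv,
                    rev_interval=rev_iv,
                    tm_fwd=tm_f,
                    tm_rev=tm_r,
                    gc_fwd=gc_f,
                    gc_rev=gc_r,
                    penalty=pen_f + pen_r,
                )
            )
            last_start = fwd_start

    if not raw:
        return [], "no primer-compatible region"
    raw.sort(key=lambda c: (c.penalty, c.fwd_interval[0]))
    raw = raw[: config.max_candidates_per_gene]
    out = [
        AmpliconCandidate(
            amplicon_id=f"{gene.gene_id}_amp{i + 1}",
            **{k: v for k, v in vars(c).items() if k != "amplicon_id"},
        )
        for i, c in enumerate(raw)
    ]
    return out, None


# ---------------------------------------------------------------------------
# specificity screen


@dataclass(frozen=True)
class BindingSite:
    gene_id: str
    interval: tuple[int, int]
    strand: str
    mismatches: int


class ReferenceIndex:
    """Byte-encoded reference sequences for fast mismatch scanning."""

    def __init__(self, references: Sequence[GeneTarget]):
        self.order = [t.gene_id for t in references]
        self.arrays = {
            t.gene_id: np.frombuffer(t.sequence.encode(), dtype=np.uint8)
            for t in references
        }

    def windows(self, gene_id: str, k: int) -> Optional[np.ndarray]:
        arr = self.arrays[gene_id]
        if len(arr) < k:
            return None
        return np.lib.stride_tricks.sliding_window_view(arr, k)


def find_binding_sites(
    primer: str,
    references: Sequence[GeneTarget] | ReferenceIndex,
    max_mismatches: int = 2,
    three_prime_exact: int = 4,
) -> list[BindingSite]:
    """All annealing sites of ``primer`` on either strand of the references.

    A site qualifies with <= ``max_mismatches`` total mismatches and zero
    mismatches in the 3'-terminal ``three_prime_exact`` bases.  On the +
    strand the primer sequence matches the reference slice directly (the
    primer extends rightward); on the - strand it matches the reverse
    complement (extends leftward).  N in the reference never matches.
    """
    if three_prime_exact > len(primer):
        raise ValueError("three_prime_exact exceeds primer length")
    idx = (
        references
        if isinstance(references, ReferenceIndex)
        else ReferenceIndex(references)
    )
    k = len(primer)
    queries = {
        "+": np.frombuffer(primer.encode(), dtype=np.uint8),
        "-": np.frombuffer(revcomp(primer).encode(), dtype=np.uint8),
    }
    sites: list[BindingSite] = []
    for gene_id in idx.order:
        win = idx.windows(gene_id, k)
        if win is None:
            continue
        for strand, q in queries.items():
            mm = win != q
            total = mm.sum(axis=1)
            # 3' terminus: last bases of the primer = last window bases on +,
            # first window bases on - (the window holds the revcomp query)
            if three_prime_exact > 0:
                tail = (
                    mm[:, -three_prime_exact:]
                    if strand == "+"
                    else mm[:, :three_prime_exact]
                )
                ok = (total <= max_mismatches) & (tail.sum(axis=1) == 0)
            else:
                ok = total <= max_mismatches
            for pos in np.flatnonzero(ok):
                sites.append(
                    BindingSite(
                        gene_id=gene_id,
                        interval=(int(pos), int(pos) + k),
                        strand=strand,
                        mismatches=int(total[pos]),
                    )
                )
    sites.sort(key=lambda s: (s.gene_id, s.interval, s.strand))
    return sites


def convergent_products(
    sites_a: Sequence[BindingSite],
    sites_b: Sequence[BindingSite],
    max_product: int,
) -> list[tuple[BindingSite, BindingSite, tuple[str, int, int]]]:
    """Convergent site pairs that would amplify a product <= max_product bp.

    A product forms between a +-strand site (rightward extension) and a
    --strand site (leftward extension) downstream of it on the same
    reference; the product spans [plus.start, minus.end).
    """
    out = []
    for a in sites_a:
        for b in sites_b:
            if a.gene_id != b.gene_id:
                continue
            plus, minus = None, None
            if a.strand == "+" and b.strand == "-":
                plus, minus = a, b
            elif a.strand == "-" and b.strand == "+":
                plus, minus = b, a
            else:
                continue
            if minus.interval[0] < plus.interval[1]:
                continue
            size = minus.interval[1] - plus.interval[0]
            if 0 < size <= max_product:
                out.append(
                    (a, b, (a.gene_id, plus.interval[0], minus.interval[1]))
                )
    return out


def check_specificity(
    candidate: AmpliconCandidate,
    references: Sequence[GeneTarget] | ReferenceIndex,
    config: DesignConfig,
) -> tuple[bool, list[str]]:
    """Mispriming screen for one candidate against the whole reference set.

    Fails when either primer binds more than the allowed number of sites,
    or any convergent combination of the pair's sites yields an unintended
    product within ``max_unintended_product`` bp.  Returns (pass, reasons).
    """
    if not config.specificity_check:
        return True, []
    idx = (
        references
        if isinstance(references, ReferenceIndex)
        else ReferenceIndex(references)
    )
    fwd_sites = find_binding_sites(
        candidate.fwd_seq, idx, config.max_mismatches, config.three_prime_exact
    )
    rev_sites = find_binding_sites(
        candidate.rev_seq, idx, config.max_mismatches, config.three_prime_exact
    )
    reasons = []
    for name, sites in (("forward", fwd_sites), ("reverse", rev_sites)):
        if len(sites) > config.max_binding_sites_per_primer:
            reasons.append(
                f"multiple binding sites ({name} primer: {len(sites)})"
            )
    intended = (
        candidate.gene_id,
        candidate.product_interval[0],
        candidate.product_interval[1],
    )
    all_sites = [("F", s) for s in fwd_sites] + [("R", s) for s in rev_sites]
    seen = set()
    for i in range(len(all_sites)):
        for j in range(i + 1, len(all_sites)):
            for _, _, prod in convergent_products(
                [all_sites[i][1]], [all_sites[j][1]], config.max_unintended_product
            ):
                if prod != intended and prod not in seen:
                    seen.add(prod)
                    reasons.append(
                        f"cross-amplification {prod[0]}:{prod[1]}-{prod[2]}"
                    )
    return not reasons, reasons


# ---------------------------------------------------------------------------
# exon-restricted design and primer-site masking


def exon_windows(
    gene: GeneTarget, config: DesignConfig
) -> list[tuple[int, int]]:
    """Design windows around exons: each exon extended by size_max on both
    sides, clipped to the gene, overlaps merged."""
    exons = gene.features_of_type("exon")
    L = len(gene.sequence)
    if not exons:
        log.warning("%s: no exon features; using the whole gene", gene.gene_id)
        return [(0, L)]
    ivs = sorted(
        (max(0, f.rel_start - config.size_max), min(L, f.rel_end + config.size_max))
        for f in exons
    )
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def mask_primer_sites(
    gene: GeneTarget, selected: Sequence[AmpliconCandidate]
) -> GeneTarget:
    """Replace every selected primer binding site with N (iterative tiling)."""
    seq = list(gene.sequence)
    L = len(seq)
    for cand in selected:
        if cand.gene_id != gene.gene_id:
            raise ValueError(
                f"candidate {cand.amplicon_id} does not belong to {gene.gene_id}"
            )
        for s, e in (cand.fwd_interval, cand.rev_interval):
            if not (0 <= s < e <= L):
                raise ValueError(f"primer interval [{s},{e}) out of range")
            for i in range(s, e):
                seq[i] = "N"
    return GeneTarget(
        gene_id=gene.gene_id,
        sequence="".join(seq),
        family_id=gene.family_id,
        origin=gene.origin,
        flank_up=gene.flank_up,
        flank_down=gene.flank_down,
        features=list(gene.features),
    )
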