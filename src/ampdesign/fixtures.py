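"""Deterministic synthetic data: genomes, gene families with controlled
paralog identity, annotations and gRNA tables.

Real gene families frustrate specific assay design in proportion to their
sequence homology, so the generator plants families whose pairwise identity
is exact by construction: gene 1 is random at a target GC content and each
further paralog differs by exactly ``round((1 - identity) * length)``
substitutions at seeded positions.  Substitution-only divergence (no
indels) keeps coordinates aligned across paralogs, which makes
cross-amplification ground truth exact.  All randomness flows from the
spec's single seed through one named generator; the same spec always
produces byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .dna import revcomp
from .targets import Feature, GeneTarget

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FamilySpec:
    """Recipe for one synthetic gene family."""

    n_genes: int
    gene_length: int
    pairwise_identity: float = 1.0
    # alternating (intron_len, exon_len) blocks; first exon starts after the
    # first intron_len; empty means single-exon gene spanning the sequence
    exon_layout: tuple[tuple[int, int], ...] = ()
    gc: float = 0.5
    seed: int = 0
    family_id: str = "fam"

    def __post_init__(self) -> None:
        if not (0.0 <= self.pairwise_identity <= 1.0):
            raise ValueError("pairwise_identity must be in [0,1]")
        if not (0.0 < self.gc < 1.0):
            raise ValueError("gc must be in (0,1)")
        if self.n_genes < 1 or self.gene_length < 1:
            raise ValueError("n_genes and gene_length must be >= 1")

    @property
    def n_substitutions(self) -> int:
        return round((1.0 - self.pairwise_identity) * self.gene_length)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    if n_subs == 0:
        return seq
    arr = list(seq)
    positions = rng.choice(len(arr), size=n_subs, replace=False)
    for pos in positions:
        choices = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = choices[rng.integers(len(choices))]
    return "".join(arr)


def _layout_features(spec: FamilySpec, gene_id: str) -> list[Feature]:
    L = spec.gene_length
    feats = [Feature("gene", 0, L, "+", (("ID", gene_id),))]
    if not spec.exon_layout:
        feats.append(Feature("exon", 0, L, "+", (("Parent", gene_id),)))
        feats.append(Feature("CDS", 0, L, "+", (("Parent", gene_id),)))
        return feats
    pos = 0
    for i, (intron_len, exon_len) in enumerate(spec.exon_layout, start=1):
        pos += intron_len
        s, e = pos, min(pos + exon_len, L)
        if s >= L:
            break
        feats.append(Feature("exon", s, e, "+", (("Parent", gene_id),)))
        feats.append(Feature("CDS", s, e, "+", (("Parent", gene_id),)))
        pos = e
    return feats


def make_family(spec: FamilySpec) -> list[GeneTarget]:
    """One family of paralogs with exact pairwise divergence from gene 1."""
    rng = np.random.default_rng(spec.seed)
    base = _random_seq(rng, spec.gene_length, spec.gc)
    targets = []
    for i in range(spec.n_genes):
        gene_id = f"{spec.family_id}_g{i + 1}"
        seq = base if i == 0 else _mutate(rng, base, spec.n_substitutions)
        targets.append(
            GeneTarget(
                gene_id=gene_id,
                family_id=spec.family_id,
                sequence=seq,
                origin=("", 0, 0, "+"),
                features=_layout_features(spec, gene_id),
            )
        )
    return targets


def make_genome(
    families: Sequence[FamilySpec],
    spacer_bp: int = 500,
    chromosome: str = "chr1",
) -> tuple[str, list[str], list[GeneTarget]]:
    """Concatenate family genes onto one chromosome with random spacers.

    Half the genes (alternating) are placed on the minus strand to exercise
    orientation.  Returns (chromosome sequence, GFF3 lines, the planted
    oriented GeneTargets that extraction must recover).
    """
    parts: list[str] = []
    gff: list[str] = ["##gff-version 3"]
    planted: list[GeneTarget] = []
    pos = 0  # 0-based running offset
    k = 0
    for spec in families:
        rng = np.random.default_rng(spec.seed + 10_000)
        for t in make_family(spec):
            spacer = _random_seq(rng, spacer_bp, 0.5)
            parts.append(spacer)
            pos += spacer_bp
            strand = "+" if k % 2 == 0 else "-"
            k += 1
            seq = t.sequence if strand == "+" else revcomp(t.sequence)
            g_start, g_end = pos + 1, pos + len(seq)  # 1-based inclusive
            parts.append(seq)
            pos += len(seq)
            L = len(t.sequence)
            for f in t.features:
                if strand == "+":
                    fs, fe = g_start + f.rel_start, g_start + f.rel_end - 1
                    fstrand = f.strand
                else:
                    fs = g_start + (L - f.rel_end)
                    fe = g_start + (L - f.rel_start) - 1
                    fstrand = {"+": "-", "-": "+", ".": "."}[f.strand]
                attrs = ";".join(f"{a}={b}" for a, b in f.attributes) or "."
                gff.append(
                    "\t".join(
                        [chromosome, "fixtures", f.type, str(fs), str(fe),
                         ".", fstrand, ".", attrs]
                    )
                )
            planted.append(
                GeneTarget(
                    gene_id=t.gene_id,
                    family_id=t.family_id,
                    sequence=t.sequence,
                    origin=(chromosome, g_start, g_end, strand),
                    features=t.features,
                )
            )
    tail = _random_seq(np.random.default_rng(len(families)), spacer_bp, 0.5)
    parts.append(tail)
    return "".join(parts), gff, planted


def write_genome(
    families: Sequence[FamilySpec],
    fasta_path: str,
    gff_path: str,
    spacer_bp: int = 500,
    chromosome: str = "chr1",
) -> list[GeneTarget]:
    seq, gff, planted = make_genome(families, spacer_bp, chromosome)
    with open(fasta_path, "w") as fh:
        fh.write(f">{chromosome}\n")
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("\n".join(gff) + "\n")
    return planted


def find_protospacers(seq: str, spacer_len: int = 20) -> list[tuple[int, str]]:
    """All (start, strand) protospacer positions adjacent to an NGG PAM."""
    out = []
    L = len(seq)
    for i in range(L - 1):
        # + strand: PAM at [i, i+3) = NGG, protospacer ends at i
        if i + 3 <= L and seq[i + 1 : i + 3] == "GG" and i - spacer_len >= 0:
            out.append((i - spacer_len, "+"))
        # - strand: CCN at [i, i+3) on +, protospacer at [i+3, i+3+len)
        if seq[i : i + 2] == "CC" and i + 3 + spacer_len <= L:
            out.append((i + 3, "-"))
    return out


def make_guides(
    targets: Sequence[GeneTarget],
    n_per_gene: int = 10,
    seed: int = 0,
    spec_score_range: tuple[float, float] = (50.0, 100.0),
    eff_score_range: tuple[float, float] = (30.0, 80.0),
    spacer_len: int = 20,
) -> "pd.DataFrame":
    """Sample NGG-adjacent protospacers per gene into a generic-dialect
    gRNA table (columns gene/spacer/pam/strand/start/specificity/doench)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for t in targets:
        sites = find_protospacers(t.sequence, spacer_len)
        if not sites:
            continue
        take = min(n_per_gene, len(sites))
        picks = rng.choice(len(sites), size=take, replace=False)
        for j in sorted(picks):
            start, strand = sites[j]
            sl = t.sequence[start : start + spacer_len]
            spacer = sl if strand == "+" else revcomp(sl)
            if strand == "+":
                pam = t.sequence[start + spacer_len : start + spacer_len + 3]
            else:
                pam = revcomp(t.sequence[start - 3 : start])
            rows.append(
                {
                    "gene": t.gene_id,
                    "spacer": spacer,
                    "pam": pam,
                    "strand": strand,
                    "start": start,
                    "specificity": round(rng.uniform(*spec_score_range), 1),
                    "doench": round(rng.uniform(*eff_score_range), 1),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "spacer", "pam", "strand", "start",
                 "specificity", "doench"],
    )


def write_guides(df, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)
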