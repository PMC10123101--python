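"""Candidate-gene extraction and orientation.

Pulls target genes (optionally with flanking sequence) out of a genome
FASTA + GFF3, reverse-complements minus-strand genes so every CDS sits on
the positive strand of its record, and remaps all annotated features onto
the extracted sequence.  Internal coordinates are 0-based half-open;
GFF3 written by :func:`write_targets` is 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import gffutils
from pyfaidx import Fasta

from .dna import revcomp, validate_alphabet

log = logging.getLogger(__name__)


class TargetError(ValueError):
    """Unresolvable gene ID, conflicting annotation, or missing chromosome."""


@dataclass(frozen=True)
class Feature:
    """One annotated feature in coordinates relative to a gene record.

    ``rel_start``/``rel_end`` are 0-based half-open on the oriented gene
    sequence.  ``strand`` is relative to the oriented sequence, so CDS and
    exon features of a well-formed gene are always ``+``.
    """

    type: str
    rel_start: int
    rel_end: int
    strand: str = "+"
    attributes: tuple[tuple[str, str], ...] = ()

    def attr(self, key: str) -> Optional[str]:
        for k, v in self.attributes:
            if k == key:
                return v
        return None


@dataclass
class GeneTarget:
    """One oriented candidate gene with remapped features.

    ``origin`` records where the sequence came from: (chromosome, 1-based
    inclusive start, 1-based inclusive end, source strand).  ``flank_up`` /
    ``flank_down`` are the flank lengths actually obtained after clipping at
    chromosome ends, measured on the oriented (gene) strand.
    """

    gene_id: str
    sequence: str
    family_id: str = ""
    origin: tuple[str, int, int, str] = ("", 0, 0, "+")
    flank_up: int = 0
    flank_down: int = 0
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        validate_alphabet(self.sequence)
        self.features = sorted(
            self.features, key=lambda f: (f.rel_start, f.rel_end, f.type)
        )
        L = len(self.sequence)
        for f in self.features:
            if not (0 <= f.rel_start < f.rel_end <= L):
                raise TargetError(
                    f"{self.gene_id}: feature {f.type} [{f.rel_start},{f.rel_end}) "
                    f"outside sequence of length {L}"
                )

    def features_of_type(self, ftype: str) -> list[Feature]:
        return [f for f in self.features if f.type == ftype]

    @property
    def cds_length(self) -> int:
        return sum(f.rel_end - f.rel_start for f in self.features_of_type("CDS"))


# ---------------------------------------------------------------------------
# feature remapping


def remap_features(
    gene_span: tuple[int, int, str],
    features: Sequence[tuple[str, int, int, str, dict]],
    flank_up: int,
    flank_down: int,
) -> list[Feature]:
    """Convert genomic features to relative coordinates on the oriented gene.

    ``gene_span`` is (start, end, strand) with 1-based inclusive genomic
    coordinates; each feature is (type, start, end, strand, attributes) in
    the same convention.  ``flank_up``/``flank_down`` are measured on the
    oriented sequence (upstream = 5' of the CDS after orientation).
    Features partially outside the extracted window are clipped; features
    fully outside are dropped with a warning.
    """
    g_start, g_end, g_strand = gene_span
    gene_len = g_end - g_start + 1
    total_len = flank_up + gene_len + flank_down
    # genomic coordinates of the extracted window, 1-based inclusive
    if g_strand == "+":
        win_start = g_start - flank_up
    else:
        win_start = g_start - flank_down
    win_end = win_start + total_len - 1

    out: list[Feature] = []
    for ftype, f_start, f_end, f_strand, attrs in features:
        if f_end < win_start or f_start > win_end:
            log.warning(
                "feature %s [%d,%d] outside extracted span [%d,%d]; dropped",
                ftype, f_start, f_end, win_start, win_end,
            )
            continue
        s = max(f_start, win_start)
        e = min(f_end, win_end)
        rel_start = s - win_start          # 0-based on the + genomic strand
        rel_end = e - win_start + 1        # half-open
        if g_strand == "-":
            rel_start, rel_end = total_len - rel_end, total_len - rel_start
            rel_strand = {"+": "-", "-": "+", ".": "."}[f_strand]
        else:
            rel_strand = f_strand
        out.append(
            Feature(
                type=ftype,
                rel_start=rel_start,
                rel_end=rel_end,
                strand=rel_strand,
                attributes=tuple(sorted((str(k), str(v)) for k, v in attrs.items())),
            )
        )
    out.sort(key=lambda f: (f.rel_start, f.rel_end, f.type))
    return out


# ---------------------------------------------------------------------------
# extraction


def _gff_attr(feature: gffutils.Feature, key: str) -> Optional[str]:
    vals = feature.attributes.get(key)
    return vals[0] if vals else None


def extract_targets(
    genome: str,
    annotation: str,
    gene_ids: Sequence[str] | Sequence[tuple[str, str]],
    flank_bp: int = 0,
    id_attribute: str = "ID",
) -> list[GeneTarget]:
    """Extract one oriented :class:`GeneTarget` per requested gene ID.

    ``gene_ids`` entries are either bare IDs or (gene_id, family_id) pairs.
    Genes on the minus strand are reverse-complemented so the CDS lies on
    the + strand of the output.  Flanks of ``flank_bp`` are added on both
    sides and clipped at chromosome boundaries; the achieved flank lengths
    are recorded on the target.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be non-negative")
    pairs = [(g, "") if isinstance(g, str) else (g[0], g[1]) for g in gene_ids]

    fasta = Fasta(genome, as_raw=True, sequence_always_upper=True)
    db = gffutils.create_db(
        annotation,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )

    # index gene features by the configured attribute (fallback: Name)
    by_id: dict[str, list[gffutils.Feature]] = {}
    for gene in db.features_of_type("gene"):
        key = _gff_attr(gene, id_attribute) or _gff_attr(gene, "Name")
        if key is not None:
            by_id.setdefault(key, []).append(gene)

    targets: list[GeneTarget] = []
    for gene_id, family_id in pairs:
        matches = by_id.get(gene_id, [])
        if not matches:
            raise TargetError(f"gene ID {gene_id!r} not found in annotation")
        if len(matches) > 1:
            raise TargetError(
                f"gene ID {gene_id!r} matches {len(matches)} gene features"
            )
        gene = matches[0]
        if gene.seqid not in fasta:
            raise TargetError(
                f"chromosome {gene.seqid!r} of gene {gene_id!r} absent from FASTA"
            )
        chrom = fasta[gene.seqid]
        chrom_len = len(chrom)

        left = min(flank_bp, gene.start - 1)
        right = min(flank_bp, chrom_len - gene.end)
        win_start = gene.start - left
        win_end = gene.end + right
        seq = chrom[win_start - 1 : win_end]
        strand = gene.strand if gene.strand in "+-" else "+"
        if strand == "-":
            seq = revcomp(seq)
            flank_up, flank_down = right, left
        else:
            flank_up, flank_down = left, right

        region = list(
            db.region(seqid=gene.seqid, start=win_start, end=win_end)
        )
        feats = [
            (f.featuretype, f.start, f.end, f.strand, dict(f.attributes))
            for f in region
            if _owned_by(f, gene, db)
        ]
        rel = remap_features(
            (gene.start, gene.end, strand), feats, flank_up, flank_down
        )
        targets.append(
            GeneTarget(
                gene_id=gene_id,
                family_id=family_id,
                sequence=seq,
                origin=(gene.seqid, win_start, win_end, strand),
                flank_up=flank_up,
                flank_down=flank_down,
                features=rel,
            )
        )
    return targets


def _owned_by(feature: gffutils.Feature, gene: gffutils.Feature, db) -> bool:
    """True if ``feature`` is the gene itself or a (grand)child of it."""
    if feature.id == gene.id:
        return True
    seen = set()
    stack = list(feature.attributes.get("Parent", []))
    while stack:
        pid = stack.pop()
        if pid in seen:
            continue
        seen.add(pid)
        if pid == gene.id:
            return True
        try:
            parent = db[pid]
        except gffutils.FeatureNotFoundError:
            continue
        stack.extend(parent.attributes.get("Parent", []))
    return False


# ---------------------------------------------------------------------------
# per-gene FASTA / relative GFF3 IO


def write_targets(
    targets: Sequence[GeneTarget], fasta_out: str, gff_out: str
) -> None:
    """Write per-gene FASTA and relative-coordinate GFF3 (1-based inclusive)."""
    if not targets:
        raise ValueError("no targets to write")
    seen: set[str] = set()
    for t in targets:
        if t.gene_id in seen:
            raise TargetError(f"duplicate gene_id {t.gene_id!r}")
        seen.add(t.gene_id)

    with open(fasta_out, "w") as fh:
        for t in targets:
            fh.write(f">{t.gene_id}\n")
            for i in range(0, len(t.sequence), 80):
                fh.write(t.sequence[i : i + 80] + "\n")

    with open(gff_out, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in targets:
            meta = (
                f"origin={t.origin[0]}:{t.origin[1]}-{t.origin[2]}:{t.origin[3]};"
                f"family_id={t.family_id};flank_up={t.flank_up};"
                f"flank_down={t.flank_down}"
            )
            fh.write(f"##sequence-region {t.gene_id} 1 {len(t.sequence)}\n")
            fh.write(f"#!target {t.gene_id} {meta}\n")
            for f in t.features:
                attrs = ";".join(f"{k}={v}" for k, v in f.attributes) or "."
                fh.write(
                    "\t".join(
                        [
                            t.gene_id,
                            "ampdesign",
                            f.type,
                            str(f.rel_start + 1),
                            str(f.rel_end),
                            ".",
                            f.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def read_targets(fasta_in: str, gff_in: str) -> list[GeneTarget]:
    """Read back the per-gene FASTA + relative GFF3 written by write_targets."""
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fasta_in, "fasta")}

    meta: dict[str, dict] = {}
    feats: dict[str, list[Feature]] = {g: [] for g in seqs}
    with open(gff_in) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#!target "):
                _, gid, blob = line.split(" ", 2)
                kv = dict(item.split("=", 1) for item in blob.split(";"))
                chrom, rest = kv["origin"].split(":", 1)
                span, strand = rest.rsplit(":", 1)
                start, end = span.split("-")
                meta[gid] = dict(
                    origin=(chrom, int(start), int(end), strand),
                    family_id=kv["family_id"],
                    flank_up=int(kv["flank_up"]),
                    flank_down=int(kv["flank_down"]),
                )
                continue
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            gid = cols[0]
            attrs: tuple[tuple[str, str], ...] = ()
            if cols[8] != ".":
                attrs = tuple(
                    tuple(item.split("=", 1)) for item in cols[8].split(";")
                )
            feats.setdefault(gid, []).append(
                Feature(
                    type=cols[2],
                    rel_start=int(cols[3]) - 1,
                    rel_end=int(cols[4]),
                    strand=cols[6],
                    attributes=attrs,
                )
            )

    out = []
    for gid, seq in seqs.items():
        m = meta.get(gid, {})
        out.append(
            GeneTarget(
                gene_id=gid,
                sequence=seq,
                family_id=m.get("family_id", ""),
                origin=m.get("origin", ("", 0, 0, "+")),
                flank_up=m.get("flank_up", 0),
                flank_down=m.get("flank_down", 0),
                features=sorted(
                    feats.get(gid, []),
                    key=lambda f: (f.rel_start, f.rel_end, f.type),
                ),
            )
        )
    return out
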