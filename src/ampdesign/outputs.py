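"""Result-file writers: primer/gRNA TSVs, design GFF3, border GFF3 for
downstream haplotyping, sites BED, summary tables and debug GFFs.

Dialects: GFF3 is 1-based inclusive, BED is 0-based half-open, TSVs carry a
header row.  Primer IDs are numbered sequentially per gene (gene_F1/R1,
F2/R2, ...).  Genes without a design are appended to the TSVs with their
dropout reason.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .guides import GuideRNA
from .primers import AmpliconCandidate
from .selection import GeneDesign
from .targets import GeneTarget

log = logging.getLogger(__name__)

PRIMER_COLUMNS = [
    "gene_id", "amplicon_id", "primer_id", "sequence",
    "start", "end", "product_size",
]
GUIDE_COLUMNS = [
    "gene_id", "amplicon_id", "guide_id", "spacer", "pam", "strand",
    "start", "cut_site", "specificity_score", "efficiency_scores",
]


def write_primer_tsv(designs: Sequence[GeneDesign], path: str) -> None:
    """Primer TSV, 1-based inclusive coordinates, dropout reasons trailing."""
    rows = []
    dropouts = []
    for d in designs:
        if d.dropout_reason is not None:
            dropouts.append(
                {"gene_id": d.gene_id, "amplicon_id": "",
                 "primer_id": "", "sequence": "", "start": "",
                 "end": "", "product_size": d.dropout_reason.value}
            )
            continue
        for i, (amp, _) in enumerate(d.selected, start=1):
            for tag, seq, (s, e) in (
                ("F", amp.fwd_seq, amp.fwd_interval),
                ("R", amp.rev_seq, amp.rev_interval),
            ):
                rows.append(
                    {
                        "gene_id": d.gene_id,
                        "amplicon_id": amp.amplicon_id,
                        "primer_id": f"{d.gene_id}_{tag}{i}",
                        "sequence": seq,
                        "start": s + 1,
                        "end": e,
                        "product_size": amp.product_size,
                    }
                )
    pd.DataFrame(rows + dropouts, columns=PRIMER_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def write_guide_tsv(designs: Sequence[GeneDesign], path: str, mode: str = "CRISPR") -> Optional[str]:
    """Selected-gRNA TSV (CRISPR mode only; omitted in NatVar mode)."""
    if mode == "NatVar":
        log.info("NatVar mode: gRNA TSV omitted")
        return None
    rows = []
    dropouts = []
    for d in designs:
        if d.dropout_reason is not None:
            dropouts.append(
                {c: "" for c in GUIDE_COLUMNS}
                | {"gene_id": d.gene_id, "efficiency_scores": d.dropout_reason.value}
            )
            continue
        for amp, gs in d.selected:
            for g in gs:
                rows.append(
                    {
                        "gene_id": d.gene_id,
                        "amplicon_id": amp.amplicon_id,
                        "guide_id": g.guide_id,
                        "spacer": g.spacer,
                        "pam": g.pam,
                        "strand": g.strand,
                        "start": g.target_interval[0],
                        "cut_site": g.cut_site + 1,
                        "specificity_score": (
                            "" if g.specificity_score is None else g.specificity_score
                        ),
                        "efficiency_scores": ";".join(
                            f"{k}={v}" for k, v in g.efficiency_scores
                        ),
                    }
                )
    pd.DataFrame(rows + dropouts, columns=GUIDE_COLUMNS).to_csv(
        path, sep="\t", index=False
    )
    return path


def _gff_line(seqid, ftype, start0, end0, strand, attrs: dict) -> str:
    attr_str = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
    return "\t".join(
        [seqid, "ampdesign", ftype, str(start0 + 1), str(end0), ".",
         strand, ".", attr_str]
    )


def write_design_gff(
    designs: Sequence[GeneDesign],
    targets: Sequence[GeneTarget],
    path: str,
) -> None:
    """GFF3 with primer/amplicon/gRNA locations plus pass-through input
    features, seqid = gene_id, 1-based inclusive."""
    by_gene = {t.gene_id: t for t in targets}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for d in designs:
            gene = by_gene.get(d.gene_id)
            if gene is not None:
                for f in gene.features:
                    attrs = dict(f.attributes) or {"ID": f"{d.gene_id}_{f.type}"}
                    fh.write(
                        _gff_line(d.gene_id, f.type, f.rel_start, f.rel_end,
                                  f.strand, attrs) + "\n"
                    )
            for amp, gs in d.selected:
                fh.write(
                    _gff_line(d.gene_id, "amplicon", *amp.product_interval, "+",
                              {"ID": amp.amplicon_id}) + "\n"
                )
                fh.write(
                    _gff_line(d.gene_id, "primer_forward", *amp.fwd_interval, "+",
                              {"ID": f"{amp.amplicon_id}_F",
                               "Parent": amp.amplicon_id}) + "\n"
                )
                fh.write(
                    _gff_line(d.gene_id, "primer_reverse", *amp.rev_interval, "-",
                              {"ID": f"{amp.amplicon_id}_R",
                               "Parent": amp.amplicon_id}) + "\n"
                )
                for g in gs:
                    fh.write(
                        _gff_line(d.gene_id, "gRNA", *g.target_interval, g.strand,
                                  {"ID": g.guide_id, "Parent": amp.amplicon_id})
                        + "\n"
                    )


def write_border_gff(
    designs: Sequence[GeneDesign], path: str, border_length: int = 10
) -> None:
    """Border GFF for downstream haplotype windowing: per amplicon, the
    border_length bases immediately interior to each primer.  Inserts
    shorter than two borders get truncated borders and a warning."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for d in designs:
            for amp, _ in d.selected:
                insert = amp.rev_interval[0] - amp.fwd_interval[1]
                blen = border_length
                if insert < 2 * border_length:
                    blen = insert // 2
                    log.warning(
                        "%s: insert %d bp shorter than two %d bp borders; "
                        "truncated to %d bp", amp.amplicon_id, insert,
                        border_length, blen,
                    )
                up = (amp.fwd_interval[1], amp.fwd_interval[1] + blen)
                down = (amp.rev_interval[0] - blen, amp.rev_interval[0])
                fh.write(
                    _gff_line(d.gene_id, "border_upstream", *up, "+",
                              {"ID": f"{amp.amplicon_id}_border_up",
                               "Parent": amp.amplicon_id}) + "\n"
                )
                fh.write(
                    _gff_line(d.gene_id, "border_downstream", *down, "+",
                              {"ID": f"{amp.amplicon_id}_border_down",
                               "Parent": amp.amplicon_id}) + "\n"
                )


def write_sites_bed(designs: Sequence[GeneDesign], path: str) -> None:
    """BED (0-based half-open), one line per selected amplicon product."""
    with open(path, "w") as fh:
        for d in designs:
            for amp, _ in d.selected:
                s, e = amp.product_interval
                fh.write(f"{d.gene_id}\t{s}\t{e}\t{amp.amplicon_id}\n")


def summary_tables(
    designs: Sequence[GeneDesign],
    retention_min_guides: int = 2,
) -> dict[str, pd.DataFrame]:
    """Per-gene summary, per-family retention, and histogram data of
    amplicons/gene and guides/gene.  Plotting is a separate optional layer;
    these tables are the authoritative output."""
    from .selection import compute_retention

    per_gene = pd.DataFrame(
        [
            {
                "gene_id": d.gene_id,
                "family_id": d.family_id,
                "n_amplicons": d.n_amplicons,
                "n_guides": d.n_guides,
                "dropout_reason": (
                    d.dropout_reason.value if d.dropout_reason else ""
                ),
            }
            for d in designs
        ],
        columns=["gene_id", "family_id", "n_amplicons", "n_guides", "dropout_reason"],
    )
    retention = compute_retention(designs, min_guides=retention_min_guides)
    fam = pd.DataFrame(
        [{"family_id": k, "retention_pct": ("NA" if v is None else v)}
         for k, v in sorted(retention.items())],
        columns=["family_id", "retention_pct"],
    )
    amp_hist = (
        per_gene["n_amplicons"].value_counts().sort_index().rename_axis("n_amplicons")
        .reset_index(name="n_genes")
        if len(per_gene) else pd.DataFrame(columns=["n_amplicons", "n_genes"])
    )
    guide_hist = (
        per_gene["n_guides"].value_counts().sort_index().rename_axis("n_guides")
        .reset_index(name="n_genes")
        if len(per_gene) else pd.DataFrame(columns=["n_guides", "n_genes"])
    )
    return {
        "per_gene": per_gene,
        "retention": fam,
        "amplicons_per_gene": amp_hist,
        "guides_per_gene": guide_hist,
    }


def write_summary(
    designs: Sequence[GeneDesign],
    out_dir: str,
    retention_min_guides: int = 2,
    plot: bool = False,
) -> dict[str, str]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = summary_tables(designs, retention_min_guides)
    paths = {}
    for name, df in tables.items():
        p = out / f"summary_{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = str(p)
    if plot:
        paths["plot"] = plot_summary(tables, str(out / "summary.png"))
    return paths


def plot_summary(tables: dict[str, pd.DataFrame], path: str) -> str:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(8, 3))
    for ax, key, xlab in (
        (axes[0], "amplicons_per_gene", "amplicons per gene"),
        (axes[1], "guides_per_gene", "gRNAs per gene"),
    ):
        df = tables[key]
        ax.bar(df.iloc[:, 0], df["n_genes"])
        ax.set_xlabel(xlab)
        ax.set_ylabel("genes")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path


def write_debug_gffs(
    all_candidates: dict[str, list[AmpliconCandidate]],
    filtered: dict[str, list[tuple[AmpliconCandidate, list[GuideRNA]]]],
    pre_path: str,
    post_path: str,
) -> None:
    """Debug GFFs: every candidate before filtering, and every surviving
    candidate after filtering with its grouped gRNAs as child features."""
    with open(pre_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, cands in all_candidates.items():
            for amp in cands:
                fh.write(
                    _gff_line(gene_id, "amplicon", *amp.product_interval, "+",
                              {"ID": amp.amplicon_id}) + "\n"
                )
    with open(post_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene_id, pairs in filtered.items():
            for amp, gs in pairs:
                fh.write(
                    _gff_line(gene_id, "amplicon", *amp.product_interval, "+",
                              {"ID": amp.amplicon_id}) + "\n"
                )
                for g in gs:
                    fh.write(
                        _gff_line(gene_id, "gRNA", *g.target_interval, g.strand,
                                  {"ID": g.guide_id, "Parent": amp.amplicon_id})
                        + "\n"
                    )


def read_gff3(path: str) -> list[tuple]:
    """Minimal GFF3 reader used for round-trip checks: returns
    (seqid, type, start0, end0, strand, attrs) tuples, 0-based half-open."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs = {}
            if cols[8] != ".":
                for item in cols[8].split(";"):
                    k, _, v = item.partition("=")
                    attrs[k] = v
            out.append(
                (cols[0], cols[2], int(cols[3]) - 1, int(cols[4]), cols[6], attrs)
            )
    return out


def read_bed(path: str) -> list[tuple[str, int, int, str]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            out.append((cols[0], int(cols[1]), int(cols[2]),
                        cols[3] if len(cols) > 3 else ""))
    return out
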