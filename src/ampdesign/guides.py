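"""gRNA table parsing and filtering.

Guide RNAs are produced upstream by dedicated design tools (FlashFry,
CRISPOR, ...); this module consumes their tab-delimited tables and applies
the screening rules relevant to multiplex knockout experiments:

* poly-T stretches (>= 4 T by default) act as a Pol III terminator and
  abort spacer transcription — such guides are removed;
* restriction sites that would interfere with Golden-Gate cloning are
  detected in the simulated vector context (promoter + spacer + scaffold),
  on both strands;
* the expected cut site (3 bp 5' of the PAM) can be restricted to a CDS
  interior fraction and/or to a named feature type (e.g. a kinase domain);
* an optional minimum specificity score (e.g. MIT score) is enforced.

All coordinates are normalised to the + strand of the oriented gene
sequence, 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .dna import revcomp, validate_alphabet
from .targets import GeneTarget

log = logging.getLogger(__name__)


class GuideError(ValueError):
    pass


@dataclass(frozen=True)
class GuideRNA:
    """One protospacer with position, strand and third-party scores.

    ``target_interval`` is the protospacer span on the + strand of the gene
    (0-based half-open); for ``strand == '-'`` the gene slice equals the
    reverse complement of ``spacer``.  ``cut_site`` is a between-base
    coordinate 3 bp 5' of the PAM (the SpCas9 blunt-cut position).
    """

    gene_id: str
    spacer: str
    pam: str = "NGG"
    strand: str = "+"
    target_interval: tuple[int, int] = (0, 0)
    cut_site: int = 0
    specificity_score: Optional[float] = None
    efficiency_scores: tuple[tuple[str, float], ...] = ()
    guide_id: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        validate_alphabet(self.spacer, allow_n=False)
        start, end = self.target_interval
        if end - start != len(self.spacer):
            raise GuideError(
                f"{self.guide_id or self.spacer}: interval length "
                f"{end - start} != spacer length {len(self.spacer)}"
            )
        if not (start - 1 <= self.cut_site <= end + 1):
            raise GuideError(
                f"{self.guide_id or self.spacer}: cut site {self.cut_site} "
                f"outside [{start - 1},{end + 1}]"
            )
        if self.strand not in "+-":
            raise GuideError(f"invalid strand {self.strand!r}")
        for score in (self.specificity_score, *(v for _, v in self.efficiency_scores)):
            if score is not None and not (0.0 <= score <= 100.0):
                raise GuideError(f"score {score} outside [0,100]")

    def mean_efficiency(self) -> Optional[float]:
        if not self.efficiency_scores:
            return None
        return sum(v for _, v in self.efficiency_scores) / len(self.efficiency_scores)


def cut_site_for(strand: str, start: int, end: int) -> int:
    """SpCas9 blunt-cut coordinate, 3 bp 5' of the PAM (between-base)."""
    return end - 3 if strand == "+" else start + 3


# ---------------------------------------------------------------------------
# dialect-aware table parsing

#: per-dialect column mapping onto canonical keys.  ``start`` is the 0-based
#: protospacer start on the gene's + strand except where noted.
DIALECTS: dict[str, dict[str, str]] = {
    "generic": {
        "gene_id": "gene",
        "spacer": "spacer",
        "pam": "pam",
        "strand": "strand",
        "start": "start",
        "specificity": "specificity",
        "efficiency:doench": "doench",
    },
    "flashfry-like": {
        "gene_id": "contig",
        "start": "start",
        "stop": "stop",
        "target": "target",          # spacer+PAM, 5'->3' on its own strand
        "strand": "orientation",     # FWD / RVS
        "specificity": "Hsu2013",
        "efficiency:doench2014": "Doench2014OnTarget",
    },
    "crispor-like": {
        "gene_id": "seqId",
        "guide_id": "guideId",       # e.g. "33forw" / "12rev"
        "target": "guideSeq",        # spacer+PAM
        "specificity": "mitSpecScore",
        "efficiency:doench": "doenchScore",
    },
}

_STRAND_ALIASES = {
    "+": "+", "-": "-", "FWD": "+", "RVS": "-", "fwd": "+", "rvs": "-",
    "forw": "+", "rev": "-",
}


def _row_value(row, col):
    if col is None or col not in row or pd.isna(row[col]):
        return None
    return row[col]


def parse_guides(
    table: str,
    dialect: str = "generic",
    column_map: Optional[dict[str, str]] = None,
    targets: Optional[Sequence[GeneTarget]] = None,
    spacer_len: int = 20,
    pam_len: int = 3,
) -> tuple[list[GuideRNA], list[tuple[dict, str]]]:
    """Parse a third-party gRNA table into :class:`GuideRNA` records.

    Returns (guides, rejected) where ``rejected`` pairs the raw row dict
    with a reason string.  When ``targets`` are supplied the spacer is
    validated against the gene sequence and mismatching rows are rejected
    with reason ``"coordinate mismatch"``.  Rows for genes absent from the
    target set are retained but flagged ``unknown_gene``.
    """
    if dialect not in DIALECTS and column_map is None:
        raise GuideError(
            f"unknown dialect {dialect!r} and no column_map supplied"
        )
    cmap = dict(DIALECTS.get(dialect, {}))
    if column_map:
        cmap.update(column_map)

    df = pd.read_csv(table, sep="\t", dtype=str, comment=None)
    df.columns = [c.lstrip("#") for c in df.columns]
    if df.empty:
        log.warning("guide table %s contains no data rows", table)
        return [], []

    gene_seqs = {t.gene_id: t.sequence for t in targets} if targets else None

    guides: list[GuideRNA] = []
    rejected: list[tuple[dict, str]] = []
    for idx, row in df.iterrows():
        raw = row.to_dict()
        # annotation-only rows (e.g. trailing dropout reasons) carry no
        # spacer/target and are skipped silently
        if (
            _row_value(row, cmap.get("spacer")) is None
            and _row_value(row, cmap.get("target")) is None
        ):
            log.info("skipping non-guide row %d in %s", idx, table)
            continue
        try:
            g = _parse_row(row, cmap, dialect, spacer_len, pam_len, idx)
        except (GuideError, ValueError, KeyError, TypeError) as exc:
            rejected.append((raw, f"unparseable row: {exc}"))
            continue
        if gene_seqs is not None:
            seq = gene_seqs.get(g.gene_id)
            if seq is None:
                g = replace(g, flags=g.flags + ("unknown_gene",))
            else:
                s, e = g.target_interval
                sl = seq[s:e]
                expect = g.spacer if g.strand == "+" else revcomp(g.spacer)
                if sl != expect:
                    rejected.append((raw, "coordinate mismatch"))
                    continue
        guides.append(g)
    return guides, rejected


def _parse_row(row, cmap, dialect, spacer_len, pam_len, idx) -> GuideRNA:
    gene_id = str(_row_value(row, cmap.get("gene_id")))

    guide_id = _row_value(row, cmap.get("guide_id")) or f"{gene_id}_g{idx + 1}"

    strand_raw = _row_value(row, cmap.get("strand"))
    start_raw = _row_value(row, cmap.get("start"))
    if strand_raw is None and isinstance(guide_id, str):
        m = re.fullmatch(r"(\d+)(forw|rev)", guide_id)
        if m:  # CRISPOR-style positional guide IDs
            start_raw = m.group(1)
            strand_raw = m.group(2)
    strand = _STRAND_ALIASES.get(str(strand_raw), None)
    if strand is None:
        raise GuideError(f"unrecognised strand {strand_raw!r}")

    target = _row_value(row, cmap.get("target"))
    if target is not None:  # combined spacer+PAM column
        target = target.upper()
        spacer, pam = target[:-pam_len], target[-pam_len:]
    else:
        spacer = str(_row_value(row, cmap.get("spacer"))).upper()
        pam = str(_row_value(row, cmap.get("pam")) or "N" * pam_len).upper()

    if start_raw is None:
        raise GuideError("no start position")
    start = int(start_raw)
    end = start + len(spacer)

    spec = _row_value(row, cmap.get("specificity"))
    spec = float(spec) if spec is not None else None
    eff = []
    for key, col in cmap.items():
        if key.startswith("efficiency:"):
            v = _row_value(row, col)
            if v is not None:
                eff.append((key.split(":", 1)[1], float(v)))

    return GuideRNA(
        gene_id=gene_id,
        spacer=spacer,
        pam=pam,
        strand=strand,
        target_interval=(start, end),
        cut_site=cut_site_for(strand, start, end),
        specificity_score=spec,
        efficiency_scores=tuple(sorted(eff)),
        guide_id=str(guide_id),
    )


# ---------------------------------------------------------------------------
# filters: each returns (kept, removed-with-reason)

FilterResult = tuple[list[GuideRNA], list[tuple[GuideRNA, str]]]


def filter_polyT(guides: Sequence[GuideRNA], max_t_run: int = 4) -> FilterResult:
    """Remove guides whose spacer carries a Pol III terminator (>= max_t_run T)."""
    kept, removed = [], []
    needle = "T" * max_t_run
    for g in guides:
        if needle in g.spacer:
            removed.append((g, f"poly-T (>= {max_t_run} T)"))
        else:
            kept.append(g)
    return kept, removed


def filter_restriction_sites(
    guides: Sequence[GuideRNA],
    promoter_flank: str = "",
    scaffold_flank: str = "",
    enzymes: Sequence[str] = (),
) -> FilterResult:
    """Remove guides whose simulated cloning construct contains a recognition site.

    The construct promoter + spacer + scaffold is scanned on both strands for
    every enzyme recognition sequence.  IUPAC-ambiguous recognition sequences
    are not supported.
    """
    for enz in enzymes:
        validate_alphabet(enz, allow_n=False)
    promoter_flank = promoter_flank.upper()
    scaffold_flank = scaffold_flank.upper()
    kept, removed = [], []
    for g in guides:
        construct = promoter_flank + g.spacer + scaffold_flank
        rc = revcomp(construct)
        hit = next(
            (e for e in enzymes if e.upper() in construct or e.upper() in rc), None
        )
        if hit is not None:
            removed.append((g, f"restriction site {hit}"))
        else:
            kept.append(g)
    return kept, removed


def _spliced_cds_coord(gene: GeneTarget, pos: int) -> Optional[float]:
    """Map a gene-relative position onto the concatenated (spliced) CDS.

    Returns None when the position does not fall inside any CDS feature.
    """
    offset = 0
    for f in sorted(gene.features_of_type("CDS"), key=lambda f: f.rel_start):
        if f.rel_start <= pos < f.rel_end:
            return offset + (pos - f.rel_start)
        offset += f.rel_end - f.rel_start
    return None


def filter_position(
    guides: Sequence[GuideRNA],
    gene: GeneTarget,
    exclude_5p_frac: float = 0.0,
    exclude_3p_frac: float = 0.0,
    required_feature_type: Optional[str] = None,
) -> FilterResult:
    """Keep guides whose cut site falls in the allowed part of the gene.

    The anchor is the cut site mapped to spliced-CDS coordinates; the
    5'-most ``exclude_5p_frac`` and 3'-most ``exclude_3p_frac`` of the CDS
    are excluded.  When ``required_feature_type`` is given, the cut site
    must also lie inside a feature of that type.
    """
    if exclude_5p_frac + exclude_3p_frac >= 1.0 and (
        exclude_5p_frac > 0 or exclude_3p_frac > 0
    ):
        raise GuideError("exclude_5p_frac + exclude_3p_frac must be < 1")

    frac_active = exclude_5p_frac > 0 or exclude_3p_frac > 0
    L_cds = gene.cds_length
    if frac_active and L_cds == 0:
        raise GuideError(f"{gene.gene_id}: CDS-fraction filter needs CDS features")

    req_feats = (
        gene.features_of_type(required_feature_type)
        if required_feature_type
        else None
    )

    kept, removed = [], []
    for g in guides:
        if req_feats is not None:
            if not req_feats:
                removed.append((g, "no such feature"))
                continue
            if not any(f.rel_start <= g.cut_site < f.rel_end for f in req_feats):
                removed.append(
                    (g, f"cut site outside {required_feature_type} feature")
                )
                continue
        if frac_active:
            c = _spliced_cds_coord(gene, g.cut_site)
            if c is None:
                removed.append((g, "cut site outside CDS"))
                continue
            if c < exclude_5p_frac * L_cds:
                removed.append((g, "cut site in excluded 5' CDS segment"))
                continue
            if c > (1.0 - exclude_3p_frac) * L_cds:
                removed.append((g, "cut site in excluded 3' CDS segment"))
                continue
        kept.append(g)
    return kept, removed


def filter_score(
    guides: Sequence[GuideRNA], min_specificity: Optional[float] = None
) -> FilterResult:
    """Apply the minimum specificity-score threshold (inclusive: score >= min passes)."""
    if min_specificity is None:
        return list(guides), []
    kept, removed = [], []
    for g in guides:
        if g.specificity_score is None:
            removed.append((g, "no score"))
        elif g.specificity_score < min_specificity:
            removed.append(
                (g, f"specificity {g.specificity_score} < {min_specificity}")
            )
        else:
            kept.append(g)
    return kept, removed


def filter_all(
    guides: Sequence[GuideRNA], gene: GeneTarget, config
) -> FilterResult:
    """Run poly-T -> restriction -> position -> score; ledger keeps the first
    failing filter per removed guide."""
    ledger: list[tuple[GuideRNA, str]] = []
    kept, rm = filter_polyT(guides, config.polyT_run)
    ledger += rm
    kept, rm = filter_restriction_sites(
        kept, config.promoter_flank, config.scaffold_flank, config.enzymes
    )
    ledger += rm
    kept, rm = filter_position(
        kept,
        gene,
        config.exclude_5p_frac,
        config.exclude_3p_frac,
        config.required_feature_type,
    )
    ledger += rm
    kept, rm = filter_score(kept, config.min_specificity)
    ledger += rm
    return kept, ledger
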