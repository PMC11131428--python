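"""Homolog screening of protein-vs-protein alignment hits.

The candidate set for tree building is the plant proteins with a credible
full-length bacterial homolog: hits are kept when percent identity is at
least ``min_pident`` (default 35) and the alignment spans strictly more than
``min_cov`` (default 0.80) of *both* proteins.  Genes annotated as "located
in" an organelle (mitochondrion, chloroplast, etioplast, amyloplast,
proplastid, chromoplast) are excluded because organelle proteomes are of
bacterial ancestry and would flood the screen with trivial homology.
Finally, surviving hits with identity above ``contam_pident`` (default 76)
are flagged as possible assembly contamination rather than biology.

Coverage is computed from the alignment coordinates (residue spans), not the
reported alignment-length column, which counts gap positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

#: BLAST tabular "outfmt 6" columns with query/subject lengths appended.
HIT_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
    "qlen",
    "slen",
]

DEFAULT_ORGANELLE_TERMS = frozenset(
    {
        "mitochondrion",
        "chloroplast",
        "etioplast",
        "amyloplast",
        "proplastid",
        "chromoplast",
    }
)


@dataclass(frozen=True)
class HomologHit:
    query_id: str
    subject_id: str
    pident: float
    qstart: int
    qend: int
    sstart: int
    send: int
    qlen: int
    slen: int
    bitscore: float = 0.0
    evalue: float = 1.0

    def __post_init__(self) -> None:
        if not (1 <= self.qstart <= self.qend <= self.qlen):
            raise ValueError(
                f"invalid query coordinates {self.qstart}-{self.qend}/{self.qlen} "
                f"for {self.query_id}"
            )
        if not (1 <= self.sstart <= self.send <= self.slen):
            raise ValueError(
                f"invalid subject coordinates {self.sstart}-{self.send}/{self.slen} "
                f"for {self.subject_id}"
            )
        if not (0.0 <= self.pident <= 100.0):
            raise ValueError(f"pident {self.pident} outside [0, 100]")


@dataclass
class ScreenConfig:
    min_pident: float = 35.0          # inclusive lower bound, percent
    min_cov: float = 0.80             # strict lower bound, fraction of both proteins
    contam_pident: float = 76.0       # strict upper guard, percent
    organelle_terms: frozenset[str] = DEFAULT_ORGANELLE_TERMS
    min_bacteria_per_gene: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.min_cov <= 1):
            raise ValueError("min_cov must be in (0, 1]")
        if not (0 <= self.min_pident <= 100):
            raise ValueError("min_pident must be in [0, 100]")


@dataclass
class ScreenResult:
    kept_hits: list[HomologHit]
    plant_genes: set[str] = field(default_factory=set)
    bacterial_proteins: set[str] = field(default_factory=set)
    dropped_organelle: set[str] = field(default_factory=set)
    contamination_flags: list[HomologHit] = field(default_factory=list)


def coverage(hit: HomologHit) -> tuple[float, float]:
    """Fraction of the query and the subject spanned by the alignment."""
    qcov = (hit.qend - hit.qstart + 1) / hit.qlen
    scov = (hit.send - hit.sstart + 1) / hit.slen
    return qcov, scov


def filter_hits(hits: Iterable[HomologHit], cfg: Optional[ScreenConfig] = None) -> list[HomologHit]:
    """Keep hits with pident >= min_pident and both coverages > min_cov.

    Order-preserving and idempotent.  Each record is judged on its own: a
    query/subject pair survives if any single HSP passes.
    """
    cfg = cfg or ScreenConfig()
    kept = []
    for hit in hits:
        qcov, scov = coverage(hit)
        if hit.pident >= cfg.min_pident and qcov > cfg.min_cov and scov > cfg.min_cov:
            kept.append(hit)
    return kept


def drop_organelle_genes(
    hits: Iterable[HomologHit],
    annotations: pd.DataFrame,
    cfg: Optional[ScreenConfig] = None,
) -> tuple[list[HomologHit], set[str]]:
    """Remove hits whose query gene is annotated "located in" an organelle.

    ``annotations`` has columns gene_id, relationship_type, term.  Matching is
    exact on the relationship string "located in" and case-insensitive on the
    term.  Genes without annotation rows are retained.
    """
    cfg = cfg or ScreenConfig()
    required = {"gene_id", "relationship_type", "term"}
    if not required.issubset(annotations.columns):
        raise ValueError(
            f"annotation table must have columns {sorted(required)}, "
            f"got {list(annotations.columns)}"
        )
    if annotations[["gene_id", "relationship_type", "term"]].isna().any().any():
        raise ValueError("annotation table contains empty gene_id/relationship/term cells")
    located = annotations[annotations["relationship_type"] == "located in"]
    terms = {t.lower() for t in cfg.organelle_terms}
    organelle_genes = set(
        located.loc[located["term"].str.lower().isin(terms), "gene_id"]
    )
    kept = [h for h in hits if h.query_id not in organelle_genes]
    dropped = {h.query_id for h in hits if h.query_id in organelle_genes}
    return kept, dropped


def flag_contamination(
    hits: Iterable[HomologHit], cfg: Optional[ScreenConfig] = None
) -> list[HomologHit]:
    """Hits with pident strictly above the contamination bound (clean = empty)."""
    cfg = cfg or ScreenConfig()
    return [h for h in hits if h.pident > cfg.contam_pident]


def read_hits(path: str | Path) -> list[HomologHit]:
    """Parse an extended outfmt-6 hits TSV into :class:`HomologHit` records."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, names=HIT_COLUMNS)
    if df.empty:
        return []
    hits = []
    for row in df.itertuples(index=False):
        hits.append(
            HomologHit(
                query_id=str(row.qseqid),
                subject_id=str(row.sseqid),
                pident=float(row.pident),
                qstart=int(row.qstart),
                qend=int(row.qend),
                sstart=int(row.sstart),
                send=int(row.send),
                qlen=int(row.qlen),
                slen=int(row.slen),
                bitscore=float(row.bitscore),
                evalue=float(row.evalue),
            )
        )
    return hits


def hits_to_frame(hits: Iterable[HomologHit]) -> pd.DataFrame:
    rows = []
    for h in hits:
        aln = h.qend - h.qstart + 1
        rows.append(
            (h.query_id, h.subject_id, h.pident, aln, 0, 0, h.qstart, h.qend,
             h.sstart, h.send, h.evalue, h.bitscore, h.qlen, h.slen)
        )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def screen(
    hits_path: str | Path,
    annotations_path: Optional[str | Path] = None,
    cfg: Optional[ScreenConfig] = None,
) -> ScreenResult:
    """Full screen: identity/coverage filter, organelle exclusion, contamination guard."""
    cfg = cfg or ScreenConfig()
    hits = read_hits(hits_path)
    kept = filter_hits(hits, cfg)
    dropped_organelle: set[str] = set()
    if annotations_path is not None:
        ann = pd.read_csv(annotations_path, sep="\t", comment="#")
        kept, dropped_organelle = drop_organelle_genes(kept, ann, cfg)
    flags = flag_contamination(kept, cfg)
    return ScreenResult(
        kept_hits=kept,
        plant_genes={h.query_id for h in kept},
        bacterial_proteins={h.subject_id for h in kept},
        dropped_organelle=dropped_organelle,
        contamination_flags=flags,
    )


def write_screen_report(result: ScreenResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hits_to_frame(result.kept_hits).to_csv(out / "kept_hits.tsv", sep="\t", index=False)
    summary = pd.DataFrame(
        {
            "metric": [
                "kept_hits",
                "plant_genes",
                "bacterial_proteins",
                "dropped_organelle_genes",
                "contamination_flagged_hits",
            ],
            "value": [
                len(result.kept_hits),
                len(result.plant_genes),
                len(result.bacterial_proteins),
                len(result.dropped_organelle),
                len(result.contamination_flags),
            ],
        }
    )
    summary.to_csv(out / "screen_summary.tsv", sep="\t", index=False)
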