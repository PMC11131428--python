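"""Presence/absence patchiness as a signature of recent acquisition.

A recently transferred gene sits in a narrow bacterial taxon and shows a
patchy presence/absence pattern among close relatives (e.g. present in 22 of
25 genomes of one genus, absent outside it).  The score finds the narrowest
taxonomic rank (genus < family < phylum < all) whose members contain every
genome carrying the gene, and measures prevalence within that rank;
patchiness is 1 - prevalence.  A gene confined to a genus or family is
flagged recent, unless it saturates a rank broader than genus (uniform
presence across a whole family looks fixed, not recent).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd

from .taxa import TaxonMap

RANKS = ("genus", "family", "phylum")


@dataclass
class PresenceMatrix:
    """Boolean genomes-by-genes matrix plus per-genome taxonomy."""

    present: pd.DataFrame          # index = genome ids, columns = gene ids
    taxonomy: TaxonMap

    def __post_init__(self) -> None:
        for genome in self.present.index:
            self.taxonomy.info(genome)  # raises on unknown genomes

    @property
    def genomes(self) -> list[str]:
        return list(self.present.index)

    @property
    def genes(self) -> list[str]:
        return list(self.present.columns)


@dataclass
class RecencyScore:
    gene: str
    containing_rank: str           # "genus" | "family" | "phylum" | "all"
    prevalence: float
    patchiness: float
    recent_flag: bool
    n_positive: int
    n_rank_members: int


def read_presence_matrix(path: str | Path, taxonomy: TaxonMap) -> PresenceMatrix:
    """Read a 0/1 TSV with genome_id as the first column."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col="genome_id")
    return PresenceMatrix(present=df.astype(bool), taxonomy=taxonomy)


def score_recency(
    matrix: PresenceMatrix,
    gene: str,
    max_recent_rank: str = "family",
) -> RecencyScore:
    """Narrowest containing rank, within-rank prevalence and the recent flag."""
    if max_recent_rank not in RANKS:
        raise ValueError(f"max_recent_rank must be one of {RANKS}")
    if gene not in matrix.present.columns:
        raise KeyError(f"gene {gene!r} not in the presence matrix")
    col = matrix.present[gene]
    positives = [g for g in matrix.genomes if col[g]]
    if not positives:
        raise ValueError(f"gene {gene!r} is absent from every genome")

    containing_rank = "all"
    members = matrix.genomes
    for rank in RANKS:
        values = {getattr(matrix.taxonomy.info(g), rank) for g in positives}
        if len(values) == 1 and None not in values:
            taxon = values.pop()
            containing_rank = rank
            members = [
                g for g in matrix.genomes
                if getattr(matrix.taxonomy.info(g), rank) == taxon
            ]
            break

    prevalence = len(positives) / len(members)
    narrow_enough = (
        containing_rank in RANKS
        and RANKS.index(containing_rank) <= RANKS.index(max_recent_rank)
    )
    recent = narrow_enough and (prevalence < 1.0 or containing_rank == "genus")
    return RecencyScore(
        gene=gene,
        containing_rank=containing_rank,
        prevalence=prevalence,
        patchiness=1.0 - prevalence,
        recent_flag=recent,
        n_positive=len(positives),
        n_rank_members=len(members),
    )


def score_all(matrix: PresenceMatrix, max_recent_rank: str = "family") -> pd.DataFrame:
    rows = []
    for gene in matrix.genes:
        if not matrix.present[gene].any():
            continue
        s = score_recency(matrix, gene, max_recent_rank)
        rows.append(
            (s.gene, s.containing_rank, s.n_positive, s.n_rank_members,
             s.prevalence, s.patchiness, s.recent_flag)
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "containing_rank", "n_positive", "n_rank_members",
                 "prevalence", "patchiness", "recent_flag"],
    )
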