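"""Taxonomy groups and the organism -> group map.

Every downstream stage reasons about tree leaves through a small closed
vocabulary of taxon groups: the two bacterial panels (plant-associated and
non-plant-associated isolates), archaea, and the eukaryotic supergroups that
matter for calling transfer direction (vascular plants, bryophytes, algae,
SAR, Amorphea, Cryptista).  Gene-tree leaves are labelled ``organism|gene`` so
that a genome may contribute several paralogs; the organism id is everything
before the first ``|``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional


class TaxonGroup(str, enum.Enum):
    PA_BACTERIA = "PA_BACTERIA"
    NPA_BACTERIA = "NPA_BACTERIA"
    ARCHAEA = "ARCHAEA"
    VASCULAR_PLANT = "VASCULAR_PLANT"
    BRYOPHYTE = "BRYOPHYTE"
    ALGA = "ALGA"
    SAR = "SAR"
    AMORPHEA = "AMORPHEA"
    CRYPTISTA = "CRYPTISTA"
    OTHER = "OTHER"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Super-groups.  Algae are eukaryotes but deliberately NOT plants for
#: direction calling; they do count toward the ancientness annotation.
BACTERIA = frozenset({TaxonGroup.PA_BACTERIA, TaxonGroup.NPA_BACTERIA})
PLANTS = frozenset({TaxonGroup.VASCULAR_PLANT, TaxonGroup.BRYOPHYTE})
EUKARYOTES = frozenset(
    {
        TaxonGroup.VASCULAR_PLANT,
        TaxonGroup.BRYOPHYTE,
        TaxonGroup.ALGA,
        TaxonGroup.SAR,
        TaxonGroup.AMORPHEA,
        TaxonGroup.CRYPTISTA,
    }
)
ANIMAL_FUNGAL_PROXY = frozenset({TaxonGroup.AMORPHEA})


class UnknownOrganismError(KeyError):
    """Raised when an organism id is not present in the taxon map."""


@dataclass(frozen=True)
class TaxonInfo:
    group: TaxonGroup
    genus: Optional[str] = None
    family: Optional[str] = None
    phylum: Optional[str] = None


@dataclass
class TaxonMap:
    """Mapping organism id -> :class:`TaxonInfo`.

    Lookups of unknown ids raise :class:`UnknownOrganismError`; there is no
    silent default because a mis-typed genome id would otherwise corrupt every
    downstream direction call.
    """

    entries: dict[str, TaxonInfo]

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, organism_id: str) -> bool:
        return organism_id in self.entries

    def info(self, organism_id: str) -> TaxonInfo:
        try:
            return self.entries[organism_id]
        except KeyError:
            raise UnknownOrganismError(
                f"organism {organism_id!r} is not in the taxon map"
            ) from None

    def group_of(self, organism_id: str) -> TaxonGroup:
        return self.info(organism_id).group

    def organisms_in(self, groups: Iterable[TaxonGroup]) -> set[str]:
        wanted = frozenset(groups)
        return {o for o, inf in self.entries.items() if inf.group in wanted}


def organism_of(leaf_label: str) -> str:
    """Organism id of a leaf label: the substring before the first ``|``."""
    return leaf_label.split("|", 1)[0]


def group_of(taxon_map: TaxonMap, organism_id: str) -> TaxonGroup:
    """Group of one organism (module-level convenience over the map method)."""
    return taxon_map.group_of(organism_id)


_HEADER = ("organism_id", "group", "genus", "family", "phylum")


def load_taxon_map(path: str | Path) -> TaxonMap:
    """Read a taxonomy TSV (organism_id, group[, genus, family, phylum]).

    ``#`` comment lines are ignored.  Duplicate organism ids and group codes
    outside the closed vocabulary are format errors naming the offending row.
    """
    entries: dict[str, TaxonInfo] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        header: Optional[list[str]] = None
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
                if header[:2] != ["organism_id", "group"]:
                    raise ValueError(
                        f"{path}: header must start with organism_id\tgroup, "
                        f"got {header!r}"
                    )
                continue
            row = dict(zip(header, fields))
            org = row.get("organism_id", "").strip()
            if not org:
                raise ValueError(f"{path}:{lineno}: missing organism_id")
            if org in entries:
                raise ValueError(f"{path}:{lineno}: duplicate organism_id {org!r}")
            code = row.get("group", "").strip()
            try:
                group = TaxonGroup(code)
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: unknown group code {code!r} for {org!r}"
                ) from None
            entries[org] = TaxonInfo(
                group=group,
                genus=row.get("genus", "").strip() or None,
                family=row.get("family", "").strip() or None,
                phylum=row.get("phylum", "").strip() or None,
            )
    if header is None:
        raise ValueError(f"{path}: empty taxonomy file")
    return TaxonMap(entries)


def write_taxon_map(taxon_map: TaxonMap, path: str | Path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("\t".join(_HEADER) + "\n")
        for org in sorted(taxon_map.entries):
            inf = taxon_map.entries[org]
            fh.write(
                "\t".join(
                    [org, inf.group.value, inf.genus or "", inf.family or "", inf.phylum or ""]
                )
                + "\n"
            )
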