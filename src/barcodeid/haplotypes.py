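"""Haplotype collapsing, haplotype sharing across species, divergence ranges.

Two aligned records carry the same haplotype when they are identical at
every site where both show an unambiguous base; sites with gaps or
ambiguity codes (common at Sanger read ends) are non-discriminating by
default, so that a trailing run of Ns does not inflate the haplotype
count.  That tolerance makes "identical" non-transitive (AAN ~ AAT and
AAN ~ AAC while AAT !~ AAC), so haplotypes are defined as the connected
components of the compatibility graph.  A ``strict`` mode using exact
string equality is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .distances import compare
from .errors import LabellingError, ShapeError
from .refdata import ACGT, BarcodeRecord, write_fasta


@dataclass(frozen=True)
class Haplotype:
    hap_id: int
    representative: BarcodeRecord
    member_ids: tuple[str, ...]
    member_species: tuple[str | None, ...]
    species_set: frozenset[str]


@dataclass(frozen=True)
class HaplotypeTable:
    haplotypes: tuple[Haplotype, ...]

    def __len__(self) -> int:
        return len(self.haplotypes)

    @property
    def n_members(self) -> int:
        return sum(len(h.member_ids) for h in self.haplotypes)

    def partition(self) -> frozenset[frozenset[str]]:
        """Order-free view of the grouping, for equality under shuffles."""
        return frozenset(frozenset(h.member_ids) for h in self.haplotypes)

    def hap_of(self) -> dict[str, int]:
        return {m: h.hap_id for h in self.haplotypes for m in h.member_ids}


def _compatible(a: str, b: str) -> bool:
    """Identity treating non-ACGT sites in either sequence as wildcards."""
    for x, y in zip(a, b):
        if x != y and x in ACGT and y in ACGT:
            return False
    return True


def collapse(records: Sequence[BarcodeRecord], strict: bool = False) -> HaplotypeTable:
    """Collapse aligned records into haplotypes.

    Haplotype ids are consecutive from 1 in order of first appearance; the
    first-seen member is the representative.  ``strict=True`` uses exact
    string equality instead of ambiguity-tolerant identity.
    """
    if not records:
        return HaplotypeTable(haplotypes=())
    ncols = len(records[0].sequence)
    for r in records:
        if len(r.sequence) != ncols:
            raise ShapeError(
                f"record {r.record_id!r} has {len(r.sequence)} columns, "
                f"expected {ncols}: records are not mutually comparable"
            )

    if strict:
        groups: dict[str, list[BarcodeRecord]] = {}
        for r in records:
            groups.setdefault(r.sequence, []).append(r)
        components = list(groups.values())
    else:
        g: nx.Graph = nx.Graph()
        g.add_nodes_from(range(len(records)))
        for i in range(len(records)):
            for j in range(i + 1, len(records)):
                if _compatible(records[i].sequence, records[j].sequence):
                    g.add_edge(i, j)
        components = [
            [records[i] for i in sorted(comp)]
            for comp in nx.connected_components(g)
        ]

    # Deterministic numbering: order components by first appearance.
    first_index = {r.record_id: i for i, r in enumerate(records)}
    components.sort(key=lambda comp: min(first_index[r.record_id] for r in comp))
    haps = []
    for k, comp in enumerate(components, start=1):
        comp = sorted(comp, key=lambda r: first_index[r.record_id])
        haps.append(
            Haplotype(
                hap_id=k,
                representative=comp[0],
                member_ids=tuple(r.record_id for r in comp),
                member_species=tuple(r.species_label for r in comp),
                species_set=frozenset(
                    r.species_label for r in comp if r.species_label is not None
                ),
            )
        )
    return HaplotypeTable(haplotypes=tuple(haps))


def collapse_by_fragment(
    records: Sequence[BarcodeRecord], strict: bool = False
) -> dict[str, HaplotypeTable]:
    """Collapse each fragment kind separately (barcode and long fragments
    carry independent haplotype numberings)."""
    by_kind: dict[str, list[BarcodeRecord]] = {}
    for r in records:
        by_kind.setdefault(r.fragment_kind, []).append(r)
    return {kind: collapse(recs, strict=strict) for kind, recs in by_kind.items()}


def shared_haplotypes(table: HaplotypeTable) -> list[int]:
    """Haplotype ids whose members carry more than one species label.

    Shared haplotypes across species are the red flag for either true
    barcode sharing or misidentified reference material.  All members must
    be labelled.
    """
    for h in table.haplotypes:
        if any(s is None for s in h.member_species):
            missing = [
                m for m, s in zip(h.member_ids, h.member_species) if s is None
            ]
            raise LabellingError(
                f"haplotype {h.hap_id}: members without species labels: {missing}"
            )
    return [h.hap_id for h in table.haplotypes if len(h.species_set) > 1]


@dataclass(frozen=True)
class Range:
    lo: Fraction
    hi: Fraction


@dataclass(frozen=True)
class DivergenceSummary:
    """Min–max p-distance per comparison class; ``None`` when a class has
    no pairs."""

    intraspecific: Range | None
    intraspecific_by_species: Mapping[str, Range]
    congeneric: Range | None
    interspecific: Range | None  # all heterospecific pairs, congeners included


def divergence_summary(
    records: Sequence[BarcodeRecord], min_overlap: int = 1
) -> DivergenceSummary:
    """Classify every pair as intraspecific / congeneric / interspecific
    and report the min–max p-distance of each class."""
    if len(records) < 2:
        raise ShapeError("divergence_summary needs at least two records")
    for r in records:
        if r.species_label is None:
            raise LabellingError(f"record {r.record_id!r} has no species label")

    intra: list[Fraction] = []
    by_species: dict[str, list[Fraction]] = {}
    congeneric: list[Fraction] = []
    inter: list[Fraction] = []
    for i, a in enumerate(records):
        for b in records[i + 1 :]:
            p = compare(a, b, min_overlap).p_distance
            if a.species_label == b.species_label:
                intra.append(p)
                by_species.setdefault(a.species_label, []).append(p)
            else:
                inter.append(p)
                if a.genus_label and a.genus_label == b.genus_label:
                    congeneric.append(p)

    def rng(vals: list[Fraction]) -> Range | None:
        return Range(min(vals), max(vals)) if vals else None

    return DivergenceSummary(
        intraspecific=rng(intra),
        intraspecific_by_species={s: rng(v) for s, v in by_species.items()},
        congeneric=rng(congeneric),
        interspecific=rng(inter),
    )


def write_haplotype_table(
    table: HaplotypeTable, path: str | Path, fasta_path: str | Path | None = None
) -> None:
    """TSV export (hap_id, n_members, species, members, representative);
    optionally a FASTA of representative sequences."""
    with Path(path).open("w") as fh:
        fh.write("hap_id\tn_members\tspecies_set\tmember_ids\trepresentative_id\n")
        for h in table.haplotypes:
            fh.write(
                f"{h.hap_id}\t{len(h.member_ids)}\t"
                f"{';'.join(sorted(h.species_set))}\t"
                f"{';'.join(h.member_ids)}\t{h.representative.record_id}\n"
            )
    if fasta_path is not None:
        write_fasta([h.representative for h in table.haplotypes], fasta_path)
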