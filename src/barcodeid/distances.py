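"""Pairwise distance and similarity between aligned sequences.

The central quantity is the uncorrected p-distance — the proportion of
sites at which two sequences differ — and its complement, percent
similarity.  Both are kept as exact rationals (:class:`fractions.Fraction`)
because downstream tie detection compares the similarities of competing
reference hits for *exact* equality, and floating-point rounding could
create or destroy ties.

Sites where either sequence carries a gap or an ambiguity code are excluded
from the comparison (pairwise deletion), matching the convention of the
standard distance software for barcode data.  The Kimura 2-parameter
correction is provided for comparability with barcoding practice; the
identification engine itself runs on 1 − p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Sequence

from .errors import InsufficientOverlapError, SaturationError, ShapeError
from .refdata import ACGT, BarcodeRecord

#: Transitions are purine<->purine and pyrimidine<->pyrimidine exchanges.
TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


@dataclass(frozen=True)
class PairwiseComparison:
    """Counts over the comparable overlap of two aligned sequences.

    ``overlap_len`` (L) counts positions where both sequences show an
    unambiguous base; ``mismatches`` (m) the differing ones among them,
    split into ``transitions`` and ``transversions``.
    """

    id_a: str
    id_b: str
    overlap_len: int
    mismatches: int
    transitions: int
    transversions: int

    def __post_init__(self) -> None:
        if self.mismatches != self.transitions + self.transversions:
            raise ValueError("mismatches must equal transitions + transversions")
        if not 0 <= self.mismatches <= self.overlap_len:
            raise ValueError("0 <= mismatches <= overlap_len violated")

    @property
    def p_distance(self) -> Fraction:
        return Fraction(self.mismatches, self.overlap_len)

    @property
    def similarity_pct(self) -> Fraction:
        return 100 * (1 - self.p_distance)


def compare(
    a: BarcodeRecord, b: BarcodeRecord, min_overlap: int = 1
) -> PairwiseComparison:
    """Compare two aligned sequences position-wise under pairwise deletion.

    Raises :class:`ShapeError` when the aligned lengths differ and
    :class:`InsufficientOverlapError` when fewer than *min_overlap*
    unambiguous sites remain.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if len(a.sequence) != len(b.sequence):
        raise ShapeError(
            f"records {a.record_id!r} ({len(a.sequence)} cols) and "
            f"{b.record_id!r} ({len(b.sequence)} cols) are not positionally "
            "comparable"
        )
    overlap = mism = ts = 0
    for x, y in zip(a.sequence, b.sequence):
        if x not in ACGT or y not in ACGT:
            continue
        overlap += 1
        if x != y:
            mism += 1
            if (x, y) in TRANSITIONS:
                ts += 1
    if overlap < min_overlap:
        raise InsufficientOverlapError(
            overlap, min_overlap, f"{a.record_id} vs {b.record_id}"
        )
    return PairwiseComparison(
        id_a=a.record_id,
        id_b=b.record_id,
        overlap_len=overlap,
        mismatches=mism,
        transitions=ts,
        transversions=mism - ts,
    )


def k2p(comp: PairwiseComparison) -> float:
    """Kimura 2-parameter distance (substitutions/site) from the counts.

    d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)) with P, Q the transition and
    transversion proportions.  Raises :class:`SaturationError` when the
    log arguments leave their domain (substitution saturation).
    """
    L = comp.overlap_len
    P = comp.transitions / L
    Q = comp.transversions / L
    u = 1.0 - 2.0 * P - Q
    v = 1.0 - 2.0 * Q
    if u <= 0.0 or v <= 0.0:
        raise SaturationError(
            f"K2P undefined for P={P:.4f}, Q={Q:.4f} "
            f"({comp.id_a} vs {comp.id_b}): saturated"
        )
    return -0.5 * math.log(u * math.sqrt(v))


def distance_matrix(
    records: Sequence[BarcodeRecord], min_overlap: int = 1
) -> dict[tuple[str, str], PairwiseComparison]:
    """All-against-all comparisons keyed by (id_a, id_b), both orders plus
    the identity diagonal, so the mapping is a symmetric matrix."""
    if len(records) < 2:
        raise ShapeError("distance_matrix needs at least two records")
    out: dict[tuple[str, str], PairwiseComparison] = {}
    for rec in records:
        out[(rec.record_id, rec.record_id)] = compare(rec, rec, min_overlap)
    for i, a in enumerate(records):
        for b in records[i + 1 :]:
            try:
                c = compare(a, b, min_overlap)
            except (ShapeError, InsufficientOverlapError) as exc:
                raise type(exc)(
                    f"pair ({a.record_id}, {b.record_id}): {exc}"
                ) from exc
            out[(a.record_id, b.record_id)] = c
            out[(b.record_id, a.record_id)] = PairwiseComparison(
                id_a=b.record_id,
                id_b=a.record_id,
                overlap_len=c.overlap_len,
                mismatches=c.mismatches,
                transitions=c.transitions,
                transversions=c.transversions,
            )
    return out


def write_matrix_tsv(
    records: Sequence[BarcodeRecord],
    matrix: dict[tuple[str, str], PairwiseComparison],
    path: str | Path,
) -> None:
    """Square p-distance matrix, ids as labels, 6 decimal places."""
    ids = [r.record_id for r in records]
    with Path(path).open("w") as fh:
        fh.write("id\t" + "\t".join(ids) + "\n")
        for i in ids:
            row = [f"{float(matrix[(i, j)].p_distance):.6f}" for j in ids]
            fh.write(i + "\t" + "\t".join(row) + "\n")


def write_pairs_tsv(
    matrix: dict[tuple[str, str], PairwiseComparison], path: str | Path
) -> None:
    """Long-format export: one unordered pair per line."""
    with Path(path).open("w") as fh:
        fh.write("id1\tid2\tL\tm\tp_distance\tsimilarity_pct\n")
        for (i, j), c in sorted(matrix.items()):
            if i >= j:
                continue
            fh.write(
                f"{i}\t{j}\t{c.overlap_len}\t{c.mismatches}\t"
                f"{float(c.p_distance):.6f}\t{float(c.similarity_pct):.4f}\n"
            )
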