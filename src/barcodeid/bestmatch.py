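"""The best-close-match identification engine.

A query is compared against every admissible reference; references whose
similarity (100·(1 − p-distance)) is *strictly* above the threshold
(default 99%, i.e. less than 1% divergence) and whose comparable overlap
reaches the minimum (default 600 bp) are its match candidates.  The query
is then classified:

* ``NO_MATCH`` — no candidate above the threshold;
* ``UNAMBIGUOUS`` — all candidates carry one species name;
* ``AMBIGUOUS`` — candidates carry several species names.

In evaluation mode (the query's true species is known) each candidate is
additionally scored correct/incorrect by exact label equality, and a *tie*
is flagged when the best correct and the best incorrect candidates sit at
exactly the same similarity — the situation where no threshold can rescue
the identification.  Similarities are exact rationals throughout, so tie
detection is never at the mercy of float rounding.

An optional hit cap (``max_hits``) emulates identification services that
return at most a fixed number of best matches (99 for the BOLD engine);
truncation happens after a deterministic sort (similarity descending,
reference id ascending).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import json

from .distances import compare
from .errors import ConfigurationError, InsufficientOverlapError
from .refdata import BarcodeRecord, filter_provisional


class Status(str, Enum):
    NO_MATCH = "NO_MATCH"
    UNAMBIGUOUS = "UNAMBIGUOUS"
    AMBIGUOUS = "AMBIGUOUS"


class Correctness(str, Enum):
    CORRECT = "correct"
    INCORRECT = "incorrect"
    MIXED = "mixed"
    NOT_ASSESSED = "not_assessed"


@dataclass(frozen=True)
class SearchConfig:
    """Parameters of one reference-library search."""

    threshold_pct: Fraction = Fraction(99)
    min_overlap: int = 600
    max_hits: int | None = None  # 99 emulates the BOLD identification engine
    reference_filters: frozenset[str] | None = None  # admissible source tags
    fragment_kind: str = "barcode"

    def __post_init__(self) -> None:
        t = Fraction(self.threshold_pct)
        object.__setattr__(self, "threshold_pct", t)
        if not 0 < t < 100:
            raise ConfigurationError("threshold_pct must lie in (0, 100)")
        if self.max_hits is not None and self.max_hits < 1:
            raise ConfigurationError("max_hits must be >= 1 when finite")


@dataclass(frozen=True)
class MatchCandidate:
    reference_id: str
    species: str
    similarity_pct: Fraction
    overlap_len: int


@dataclass(frozen=True)
class MatchList:
    """Candidates plus search diagnostics."""

    candidates: tuple[MatchCandidate, ...]
    n_skipped_overlap: int = 0
    truncated: bool = False


@dataclass(frozen=True)
class IdentificationResult:
    query_id: str
    candidates: tuple[MatchCandidate, ...]
    status: Status
    assigned_species: frozenset[str]
    best_similarity_pct: Fraction | None
    correctness: Correctness = Correctness.NOT_ASSESSED
    tie: bool = False
    correct_closer: bool | None = None
    genus_correct: bool | None = None


def _normalize(label: str | None) -> str | None:
    return " ".join(label.split()) if label is not None else None


def find_candidates(
    query: BarcodeRecord,
    library: Sequence[BarcodeRecord],
    cfg: SearchConfig = SearchConfig(),
) -> MatchList:
    """All reference records strictly above the similarity threshold.

    The library is first restricted to the configured source tags and to
    records with nominal (binomial) species names; an empty post-filter
    library is a configuration error.  Pairs whose comparable overlap is
    below ``cfg.min_overlap`` are skipped and counted in the diagnostics.
    """
    refs = filter_provisional(library)
    if cfg.reference_filters is not None:
        refs = [r for r in refs if r.source_tag in cfg.reference_filters]
    if not refs:
        raise ConfigurationError(
            "reference library is empty after source filtering and "
            "provisional-identification exclusion"
        )
    hits: list[MatchCandidate] = []
    skipped = 0
    for ref in refs:
        try:
            comp = compare(query, ref, cfg.min_overlap)
        except InsufficientOverlapError:
            skipped += 1
            continue
        if comp.similarity_pct > cfg.threshold_pct:
            hits.append(
                MatchCandidate(
                    reference_id=ref.record_id,
                    species=_normalize(ref.species_label),
                    similarity_pct=comp.similarity_pct,
                    overlap_len=comp.overlap_len,
                )
            )
    hits.sort(key=lambda h: (-h.similarity_pct, h.reference_id))
    truncated = cfg.max_hits is not None and len(hits) > cfg.max_hits
    if truncated:
        hits = hits[: cfg.max_hits]
    return MatchList(
        candidates=tuple(hits), n_skipped_overlap=skipped, truncated=truncated
    )


def classify(
    query_id: str,
    candidates: Sequence[MatchCandidate] | MatchList,
    query_label: str | None = None,
    query_genus: str | None = None,
) -> IdentificationResult:
    """Classify a query from its sorted candidate list.

    With ``query_label`` given (evaluation mode), correctness, the tie flag
    and ``correct_closer`` are computed from exact similarity comparisons of
    the best correct versus the best incorrect candidate.  ``genus_correct``
    reports genus-level agreement separately and is never folded into
    correctness (relevant for queries identified only to genus).
    """
    if isinstance(candidates, MatchList):
        candidates = candidates.candidates
    candidates = tuple(candidates)
    species = frozenset(c.species for c in candidates)
    if not candidates:
        status = Status.NO_MATCH
        best = None
    else:
        best = candidates[0].similarity_pct
        status = Status.UNAMBIGUOUS if len(species) == 1 else Status.AMBIGUOUS

    correctness = Correctness.NOT_ASSESSED
    tie = False
    correct_closer: bool | None = None
    genus_correct: bool | None = None
    label = _normalize(query_label)
    if label is not None and candidates:
        correct = [c for c in candidates if c.species == label]
        incorrect = [c for c in candidates if c.species != label]
        if not incorrect:
            correctness = Correctness.CORRECT
        elif not correct:
            correctness = Correctness.INCORRECT
        else:
            correctness = Correctness.MIXED
        if correct and incorrect:
            best_c = max(c.similarity_pct for c in correct)
            best_i = max(c.similarity_pct for c in incorrect)
            tie = best_c == best_i
            correct_closer = best_c > best_i
    if query_genus is not None and candidates:
        genus_correct = any(
            c.species is not None and c.species.split()[0] == query_genus
            for c in candidates
        )
    return IdentificationResult(
        query_id=query_id,
        candidates=candidates,
        status=status,
        assigned_species=species,
        best_similarity_pct=best,
        correctness=correctness,
        tie=tie,
        correct_closer=correct_closer,
        genus_correct=genus_correct,
    )


def identify_all(
    queries: Sequence[BarcodeRecord],
    library: Sequence[BarcodeRecord],
    cfg: SearchConfig = SearchConfig(),
    evaluation_mode: bool = True,
) -> list[IdentificationResult]:
    """Identify every query against the library, order-preserving.

    In evaluation mode the query's own species label (when present) is used
    to score correctness and ties.
    """
    results = []
    for q in queries:
        ml = find_candidates(q, library, cfg)
        results.append(
            classify(
                q.record_id,
                ml,
                query_label=q.species_label if evaluation_mode else None,
                query_genus=q.genus_label if evaluation_mode else None,
            )
        )
    return results


def write_results_tsv(
    results: Iterable[IdentificationResult], path: str | Path
) -> None:
    with Path(path).open("w") as fh:
        fh.write(
            "query_id\tstatus\tassigned_species\tbest_similarity_pct\t"
            "tie\tcorrectness\n"
        )
        for r in results:
            best = "" if r.best_similarity_pct is None else f"{float(r.best_similarity_pct):.4f}"
            fh.write(
                f"{r.query_id}\t{r.status.value}\t"
                f"{';'.join(sorted(r.assigned_species))}\t{best}\t"
                f"{int(r.tie)}\t{r.correctness.value}\n"
            )


def write_results_json(
    results: Iterable[IdentificationResult], path: str | Path
) -> None:
    payload = []
    for r in results:
        payload.append(
            {
                "query_id": r.query_id,
                "status": r.status.value,
                "assigned_species": sorted(r.assigned_species),
                "best_similarity_pct": (
                    None if r.best_similarity_pct is None else float(r.best_similarity_pct)
                ),
                "tie": r.tie,
                "correct_closer": r.correct_closer,
                "correctness": r.correctness.value,
                "genus_correct": r.genus_correct,
                "candidates": [
                    {
                        "reference_id": c.reference_id,
                        "species": c.species,
                        "similarity_pct": float(c.similarity_pct),
                        "overlap_len": c.overlap_len,
                    }
                    for c in r.candidates
                ],
            }
        )
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
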