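"""Synthetic reference libraries and query sets.

The generator emulates the statistical structure that makes threshold
identification of blow-fly COI barcodes work: very shallow intraspecific
variation (pairwise p-distances of 0–0.5%) separated by a wide barcode gap
from congeneric divergences of roughly 6.6–16.2%.  Species are placed on a
star phylogeny — one random ancestral sequence, one branch per species —
with branch lengths drawn so that realized inter-species p-distances fall
inside the configured band (rejection-adjusted).  Members of a species are
the centroid haplotype plus variants carrying at most
``floor(intra_max_p·L/2)`` substitutions, which bounds realized *pairwise*
intraspecific distances by ``intra_max_p``.  Substitutions only, no
indels: COI barcodes of these taxa are indel-free and the whole pipeline
assumes positional comparability.

Library defects the evaluation studies — species missing from the library,
mislabelled reference records, haplotypes shared between species — are
injected on request and recorded in a :class:`TruthTable`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import GenerationError, ValidationError
from .refdata import (
    AmbiguityAnnotations,
    Annotation,
    BarcodeRecord,
    Procedure,
    Table1Fixture,
)

_BASES = np.array(list("ACGT"))

#: Epithets for synthetic species names ("Syntheta alba" ...); all synthetic
#: species are congeneric, mirroring the congeneric-divergence band.
_EPITHETS = [
    "alba", "bruna", "cana", "dura", "ebena", "fusca", "grisea", "helva",
    "ignea", "juncea", "kermesina", "lutea", "minuta", "nigra", "ochrea",
    "pallida", "quieta", "rubra", "severa", "tincta", "umbrosa", "varia",
    "xantha", "zonata",
]


def _species_name(i: int) -> str:
    if i < len(_EPITHETS):
        return f"Syntheta {_EPITHETS[i]}"
    return f"Syntheta {_EPITHETS[i % len(_EPITHETS)]}{chr(ord('a') + i // len(_EPITHETS))}"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic library.

    Divergence defaults are the observed ranges of the case study:
    intraspecific p-distances up to 0.5%, congeneric divergences between
    6.6% and 16.2%.
    """

    n_species: int = 10
    refs_per_species: int = 5
    queries_per_species: int = 2
    seq_len: int = 658
    intra_max_p: float = 0.005
    inter_min_p: float = 0.066
    inter_max_p: float = 0.162
    mislabel_rate: float = 0.0
    dropout_species: int = 0
    shared_haplotype_pairs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.intra_max_p < self.inter_min_p <= self.inter_max_p <= 0.75:
            raise ValidationError(
                "need 0 <= intra_max_p < inter_min_p <= inter_max_p <= 0.75"
            )
        if self.n_species < 1 or self.refs_per_species < 1:
            raise ValidationError("n_species and refs_per_species must be >= 1")
        if not 0 <= self.dropout_species <= self.n_species:
            raise ValidationError("dropout_species out of range")
        if not 0 <= self.mislabel_rate <= 1:
            raise ValidationError("mislabel_rate must lie in [0, 1]")


@dataclass(frozen=True)
class TruthTable:
    """Ground truth of a simulated data set."""

    true_species: dict[str, str]          # record_id -> generating species
    mislabelled: dict[str, bool]          # library record_id -> flag
    dropped_species: frozenset[str]
    centroids: dict[str, str]             # species -> centroid sequence

    @property
    def n_mislabelled(self) -> int:
        return sum(self.mislabelled.values())


def _mutate(seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Substitute at the given positions, uniformly over the 3 alternatives."""
    out = seq.copy()
    for pos in positions:
        alternatives = _BASES[_BASES != out[pos]]
        out[pos] = alternatives[rng.integers(0, 3)]
    return out


def _star_centroids(
    n_species: int,
    seq_len: int,
    inter_min_p: float,
    inter_max_p: float,
    rng: np.random.Generator,
    max_tries: int = 200,
) -> list[np.ndarray]:
    """Species centroids on a star phylogeny with realized pairwise
    p-distances inside [inter_min_p, inter_max_p]."""
    lo = math.ceil(inter_min_p * seq_len / 2) + 2
    hi = math.floor(inter_max_p * seq_len / 2) - 2
    if n_species > 1 and lo > hi:
        raise GenerationError(
            f"inter-species band [{inter_min_p}, {inter_max_p}] too narrow "
            f"for sequence length {seq_len}"
        )
    lo_sites = inter_min_p * seq_len
    hi_sites = inter_max_p * seq_len
    for _ in range(max_tries):
        root = _BASES[rng.integers(0, 4, size=seq_len)]
        cents = []
        for _i in range(n_species):
            m = int(rng.integers(lo, hi + 1)) if n_species > 1 else 0
            pos = rng.choice(seq_len, size=m, replace=False)
            cents.append(_mutate(root, pos, rng))
        ok = True
        for i in range(n_species):
            for j in range(i + 1, n_species):
                d = int((cents[i] != cents[j]).sum())
                if not lo_sites <= d <= hi_sites:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            return cents
    raise GenerationError(
        f"could not realize inter-species distances in "
        f"[{inter_min_p}, {inter_max_p}] within {max_tries} tries"
    )


def simulate(
    cfg: SimulationConfig,
) -> tuple[list[BarcodeRecord], list[BarcodeRecord], TruthTable]:
    """Generate (library, queries, truth) under the configured conditions.

    The first reference and the first query of each species sit exactly on
    the centroid (the modal haplotype); further members carry up to
    ``floor(intra_max_p·seq_len/2)`` substitutions.  Dropped species are
    removed from the library but keep their queries; mislabelling reassigns
    the species label of randomly chosen reference records.  Fully
    reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    cents = _star_centroids(
        cfg.n_species, cfg.seq_len, cfg.inter_min_p, cfg.inter_max_p, rng
    )
    species = [_species_name(i) for i in range(cfg.n_species)]
    kmax = math.floor(cfg.intra_max_p * cfg.seq_len / 2)

    def member(centroid: np.ndarray, first: bool) -> str:
        k = 0 if first else int(rng.integers(0, kmax + 1))
        pos = rng.choice(cfg.seq_len, size=k, replace=False)
        return "".join(_mutate(centroid, pos, rng))

    library: list[BarcodeRecord] = []
    queries: list[BarcodeRecord] = []
    true_species: dict[str, str] = {}
    for i, sp in enumerate(species):
        for j in range(cfg.refs_per_species):
            rid = f"REF_{i:02d}_{j:02d}"
            library.append(
                BarcodeRecord(rid, sp, member(cents[i], j == 0),
                              source_tag="published")
            )
            true_species[rid] = sp
        for j in range(cfg.queries_per_species):
            qid = f"QRY_{i:02d}_{j:02d}"
            queries.append(BarcodeRecord(qid, sp, member(cents[i], j == 0)))
            true_species[qid] = sp

    # Shared haplotypes: a foreign species deposits the centroid of another.
    for k in range(cfg.shared_haplotype_pairs):
        i, j = map(int, rng.choice(cfg.n_species, size=2, replace=False))
        rid = f"SHARE_{k:02d}"
        library.append(
            BarcodeRecord(rid, species[j], "".join(cents[i]),
                          source_tag="published")
        )
        true_species[rid] = species[i]

    # Dropout: species absent from the library, still queried.
    dropped = frozenset(
        species[int(i)]
        for i in rng.choice(cfg.n_species, size=cfg.dropout_species, replace=False)
    )
    library = [r for r in library if r.species_label not in dropped]

    # Mislabelling: reassign labels of randomly chosen reference records.
    n_mis = round(cfg.mislabel_rate * len(library))
    mislabelled = {r.record_id: False for r in library}
    keep = [sp for sp in species if sp not in dropped]
    if n_mis and len(keep) < 2:
        raise GenerationError("mislabelling needs at least two retained species")
    for idx in rng.choice(len(library), size=n_mis, replace=False):
        rec = library[int(idx)]
        others = [sp for sp in keep if sp != rec.species_label]
        wrong = others[int(rng.integers(0, len(others)))]
        library[int(idx)] = rec.with_label(wrong)
        mislabelled[rec.record_id] = True

    truth = TruthTable(
        true_species=true_species,
        mislabelled=mislabelled,
        dropped_species=dropped,
        centroids={sp: "".join(c) for sp, c in zip(species, cents)},
    )
    return library, queries, truth


def plant_mislabelled_duplicate(
    truth: TruthTable,
    true_species: str,
    wrong_label: str,
    record_id: str = "MISID_00",
) -> BarcodeRecord:
    """A reference record sitting exactly on *true_species*' centroid but
    carrying *wrong_label* — the misidentified-specimen failure mode.  The
    caller appends it to the library; queries matching the centroid then
    see equal best correct and best incorrect similarities (a tie)."""
    return BarcodeRecord(
        record_id, wrong_label, truth.centroids[true_species],
        source_tag="published",
    )


def near_threshold_scenario(
    seq_len: int = 658, seed: int = 0
) -> tuple[list[BarcodeRecord], list[BarcodeRecord]]:
    """(queries, library) where the query's congener sits between the 99%
    and 99.5% similarity thresholds (5 mismatches over 658 sites = 99.24%)
    while a conspecific reference matches exactly.  Identification is
    ambiguous at a 99% threshold and unambiguous at 99.5%."""
    rng = np.random.default_rng(seed)
    centroid = _BASES[rng.integers(0, 4, size=seq_len)]
    m = math.floor(0.0075 * seq_len)  # within (0.5%, 1%) divergence
    pos = rng.choice(seq_len, size=m, replace=False)
    congener = _mutate(centroid, pos, rng)
    queries = [BarcodeRecord("QRY_00", "Syntheta alba", "".join(centroid))]
    library = [
        BarcodeRecord("REF_CON", "Syntheta alba", "".join(centroid),
                      source_tag="published"),
        BarcodeRecord("REF_INC", "Syntheta bruna", "".join(congener),
                      source_tag="published"),
    ]
    return queries, library


# ---------------------------------------------------------------------------
# Libraries structured after the bundled case-study tables
# ---------------------------------------------------------------------------

def _hap_sequences(
    hap_species: dict[int, str],
    species: list[str],
    seq_len: int,
    rng: np.random.Generator,
) -> dict[int, str]:
    """One distinct sequence per haplotype id: species centroids on the
    star phylogeny, haplotype k of a species = centroid with the k-th
    reserved site substituted (pairwise intraspecific distance <= 2 sites)."""
    cents = _star_centroids(len(species), seq_len, 0.066, 0.162, rng)
    cent_of = dict(zip(species, cents))
    out: dict[int, str] = {}
    seen: dict[str, int] = {}
    for hap in sorted(hap_species):
        sp = hap_species[hap]
        k = seen.get(sp, 0)
        seen[sp] = k + 1
        if k == 0:
            out[hap] = "".join(cent_of[sp])
        else:
            out[hap] = "".join(_mutate(cent_of[sp], np.array([k - 1]), rng))
    return out


def fixture_structured_library(
    fixture: Table1Fixture, seed: int = 0,
    barcode_len: int = 658, long_len: int = 1535,
) -> tuple[list[BarcodeRecord], list[BarcodeRecord]]:
    """Synthetic sequences realizing the case-study haplotype structure.

    Returns (barcode_records, long_records): one record per specimen row
    (record_id = process id), one distinct sequence per haplotype id, so
    that collapsing recovers exactly the transcribed haplotype partition
    and specimen counts.  Deterministic from ``seed``.
    """
    rng = np.random.default_rng(seed)
    species = fixture.species()
    b_seq = _hap_sequences(fixture.barcode_hap_species(), species, barcode_len, rng)
    l_seq = _hap_sequences(fixture.long_hap_species(), species, long_len, rng)
    barcode_records = [
        BarcodeRecord(r.process_id, r.species, b_seq[r.barcode_hap],
                      fragment_kind="barcode")
        for r in fixture.rows
    ]
    long_records = [
        BarcodeRecord(f"{r.process_id}_L", r.species, l_seq[r.long_hap],
                      fragment_kind="long_coi")
        for r in fixture.rows
        if r.long_hap is not None
    ]
    return barcode_records, long_records


def emulated_search_library(
    fixture: Table1Fixture,
    annotations: AmbiguityAnnotations,
    procedure: Procedure,
    seed: int = 0,
    seq_len: int = 658,
) -> tuple[list[BarcodeRecord], list[BarcodeRecord]]:
    """(queries, library) reproducing one search procedure's outcome
    pattern with the live identification engine.

    One query per barcode haplotype.  Per species the library realizes the
    annotated outcome: identical conspecific references where matches were
    found; an incorrect congeneric reference 3 substitutions off the
    centroid for ambiguous outcomes; an identical incorrect duplicate per
    tied haplotype for tied outcomes; no nearby references where no match
    above the threshold was found.  Running ``identify_all`` at the 99%
    threshold and summarizing reproduces the procedure's aggregate metrics.
    """
    if procedure is Procedure.PROC5:
        raise ValidationError(
            "emulated_search_library models the barcode-fragment procedures"
        )
    rng = np.random.default_rng(seed)
    species = fixture.species()
    hap_species = fixture.barcode_hap_species()
    hap_seq = _hap_sequences(hap_species, species, seq_len, rng)
    haps_of: dict[str, list[int]] = {}
    for hap, sp in sorted(hap_species.items()):
        haps_of.setdefault(sp, []).append(hap)
    tie_col = {Procedure.PROC12: "tie_proc12", Procedure.PROC3: "tie_proc3"}.get(procedure)
    tied_haps = {
        r.barcode_hap
        for r in fixture.rows
        if tie_col is not None and getattr(r, tie_col)
    }

    queries = [
        BarcodeRecord(f"HAP_{h:02d}", hap_species[h], hap_seq[h])
        for h in sorted(hap_species)
    ]
    library: list[BarcodeRecord] = []
    for sp in species:
        ann = annotations.get(sp, procedure)
        wrong = annotations.incorrect_species.get((sp, procedure), ())
        matched_haps = [
            h for h in haps_of[sp]
            if fixture.barcode_hap_cell(h, procedure).populated
        ]
        if not matched_haps:
            continue
        centroid_hap = haps_of[sp][0]
        if ann in (Annotation.OK, Annotation.OK_PLUS, Annotation.OK_PLUS_TIE):
            for h in matched_haps:
                library.append(
                    BarcodeRecord(f"REF_{h:02d}", sp, hap_seq[h],
                                  source_tag="published")
                )
        if ann is Annotation.OK_PLUS:
            inc = _mutate(
                np.array(list(hap_seq[centroid_hap])),
                rng.choice(seq_len, size=3, replace=False), rng,
            )
            library.append(
                BarcodeRecord(f"INC_{sp.replace(' ', '_')}", wrong[0],
                              "".join(inc), source_tag="published")
            )
        elif ann is Annotation.OK_PLUS_TIE:
            for h in matched_haps:
                if h in tied_haps:
                    library.append(
                        BarcodeRecord(f"INCDUP_{h:02d}", wrong[0], hap_seq[h],
                                      source_tag="published")
                    )
        elif ann is Annotation.WRONG:
            library.append(
                BarcodeRecord(f"INC_{sp.replace(' ', '_')}", wrong[0],
                              hap_seq[matched_haps[0]], source_tag="published")
            )
        elif ann is Annotation.WRONG_AMBIGUOUS:
            base = np.array(list(hap_seq[matched_haps[0]]))
            for w_i, w in enumerate(wrong):
                seq = base if w_i == 0 else _mutate(
                    base, rng.choice(seq_len, size=1, replace=False), rng
                )
                library.append(
                    BarcodeRecord(f"INC_{sp.replace(' ', '_')}_{w_i}", w,
                                  "".join(seq), source_tag="published")
                )
    return queries, library
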