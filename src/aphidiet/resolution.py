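"""Taxon-resolution assessment of a barcode amplicon over a reference library.

Given a labeled COI library and a primer pair, this module extracts the
amplified region, filters records by amplicon coverage, computes pairwise
identities, classifies each record's resolvability (species / genus /
unresolved) at an identity threshold, searches for the threshold that best
separates conspecific from heterospecific matches, and summarizes intra- and
inter-specific similarity.

Identity convention: global (edit-distance) alignment over the mutually
covered region; internal gaps count as mismatched columns; terminal gap runs
(incomplete coverage of one sequence by the other) are excluded from the
column count.
"""

from __future__ import annotations

import itertools
import re
from typing import Literal, Sequence

import edlib
import numpy as np

from dataclasses import dataclass

from ._iupac import IUPAC

from .primers import (
    DEFAULT_SCHEME,
    DegeneratePrimer,
    MismatchScoringScheme,
    evaluate_binding,
)
from .reference import ReferenceLibrary, ReferenceRecord

_EQUALITIES = [
    (code, base) for code, bases in IUPAC.items() if len(bases) > 1 for base in bases
]

Rank = Literal["species-level", "genus-level", "unresolved"]


# --------------------------------------------------------------------------
# Amplicon extraction


@dataclass(frozen=True)
class AmpliconExtraction:
    record_id: str
    amplicon: str | None
    covered_length: int
    reason: str = ""  # why extraction failed, when it did


def extract_amplicon(
    record: ReferenceRecord,
    pair: tuple[DegeneratePrimer, DegeneratePrimer],
    scheme: MismatchScoringScheme = DEFAULT_SCHEME,
) -> AmpliconExtraction:
    """Inter-primer region of a template, excluding both primer sites.

    The forward site is located by minimum-penalty scan on the plus strand,
    the reverse site by scan on the minus strand; a site whose penalty
    exceeds the scheme's fail threshold flags the record unextractable.
    """
    fwd = next(p for p in pair if p.direction == "forward")
    rev = next(p for p in pair if p.direction == "reverse")
    seq = record.sequence
    ev_f = evaluate_binding(fwd, seq, record.id, scheme)
    if not ev_f.amplification_predicted:
        return AmpliconExtraction(record.id, None, 0, "forward site not found")
    ev_r = evaluate_binding(rev, seq, record.id, scheme)
    if not ev_r.amplification_predicted:
        return AmpliconExtraction(record.id, None, 0, "reverse site not found")
    start = ev_f.site_start + len(fwd)
    # reverse site_start is on the reverse-complement strand
    end = len(seq) - (ev_r.site_start + len(rev))
    if end <= start:
        return AmpliconExtraction(record.id, None, 0, "primer sites overlap")
    amplicon = seq[start:end]
    return AmpliconExtraction(record.id, amplicon, len(amplicon))


def filter_by_coverage(
    library: ReferenceLibrary,
    coverage: dict[str, int] | None = None,
    min_bases: int = 296,
) -> tuple[ReferenceLibrary, int]:
    """Drop records covering fewer than ``min_bases`` of the amplicon.

    ``coverage`` maps record id -> covered bases; by default each record's
    own sequence length is used (records that *are* amplicons). Returns the
    filtered library and the number of records removed.
    """
    kept = []
    for rec in library:
        cov = coverage.get(rec.id, 0) if coverage is not None else len(rec.sequence)
        if cov >= min_bases:
            kept.append(rec)
    return ReferenceLibrary(kept), len(library) - len(kept)


# --------------------------------------------------------------------------
# Identity


def alignment_identity(a: str, b: str) -> tuple[float, int]:
    """(percent identity, aligned columns) over the mutually covered region.

    Arguments are ordered canonically before alignment so the result is
    strictly symmetric even when several optimal alignments exist.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if b < a:
        a, b = b, a
    res = edlib.align(a, b, mode="NW", task="path", additionalEqualities=_EQUALITIES)
    ops = [(int(n), op) for n, op in re.findall(r"(\d+)([=XID])", res["cigar"])]
    # strip terminal indel runs: one sequence extending past the other
    while ops and ops[0][1] in "ID":
        ops.pop(0)
    while ops and ops[-1][1] in "ID":
        ops.pop()
    columns = sum(n for n, _ in ops)
    matches = sum(n for n, op in ops if op == "=")
    if columns == 0:
        return 0.0, 0
    return 100.0 * matches / columns, columns


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity under the module's global-alignment convention."""
    return alignment_identity(a, b)[0]


def identity_matrix(sequences: Sequence[str]) -> np.ndarray:
    """Symmetric pairwise identity matrix (diagonal 100)."""
    n = len(sequences)
    mat = np.full((n, n), 100.0)
    for i, j in itertools.combinations(range(n), 2):
        mat[i, j] = mat[j, i] = pairwise_identity(sequences[i], sequences[j])
    return mat


# --------------------------------------------------------------------------
# Resolvability


def classify_resolvability(
    query: ReferenceRecord,
    library: ReferenceLibrary,
    threshold: float = 98.36,
) -> Rank:
    """Classify what rank a query could be assigned to at an identity threshold.

    Matches are all other library records with identity >= threshold.  All
    conspecific -> species-level; several species within one genus ->
    genus-level; no match or cross-genus matches -> unresolved.
    """
    matches = [
        rec
        for rec in library
        if rec.id != query.id
        and pairwise_identity(query.sequence, rec.sequence) >= threshold
    ]
    return _rank_from_matches(matches)


def _rank_from_matches(matches: Sequence[ReferenceRecord]) -> Rank:
    if not matches:
        return "unresolved"
    genera = {m.genus for m in matches}
    if len(genera) > 1:
        return "unresolved"
    taxa = {(m.genus, m.species) for m in matches}
    if len(taxa) == 1 and matches[0].species is not None:
        return "species-level"
    return "genus-level"


@dataclass(frozen=True)
class ResolutionReport:
    """Per-genus species-level resolvability at one identity threshold."""

    threshold: float
    per_genus: dict[str, dict]  # genus -> {n_species, n_sequences, resolvable}
    n_genera_resolvable: int
    n_genera: int
    n_species_covered: int


def resolution_report(
    library: ReferenceLibrary, threshold: float = 98.36
) -> ResolutionReport:
    """Classify every record; a genus is species-resolvable when every one of
    its species-labeled records classifies to species level."""
    ranks = {
        rec.id: classify_resolvability(rec, library, threshold) for rec in library
    }
    per_genus: dict[str, dict] = {}
    species_covered: set[tuple[str, str]] = set()
    for genus in library.genera():
        recs = library.by_genus(genus)
        labeled = [r for r in recs if r.species is not None]
        resolvable = bool(labeled) and all(
            ranks[r.id] == "species-level" for r in labeled
        )
        per_genus[genus] = {
            "n_species": len({r.species for r in labeled}),
            "n_sequences": len(recs),
            "resolvable_to_species": resolvable,
        }
        if resolvable:
            species_covered |= {(r.genus, r.species) for r in labeled}
    n_res = sum(g["resolvable_to_species"] for g in per_genus.values())
    return ResolutionReport(
        threshold=threshold,
        per_genus=per_genus,
        n_genera_resolvable=n_res,
        n_genera=len(per_genus),
        n_species_covered=len(species_covered),
    )


# --------------------------------------------------------------------------
# Threshold optimization


@dataclass(frozen=True)
class ThresholdSearch:
    threshold: float
    n_cross_species_matches: int
    n_species_level: int
    trace: tuple[tuple[float, int, int], ...]  # (candidate, cross, species-level)


def optimize_threshold(
    library: ReferenceLibrary, start: float = 90.0
) -> ThresholdSearch:
    """Search the identity threshold separating conspecific from deviating matches.

    Candidates are the distinct observed pairwise identities >= ``start``
    plus midpoints between consecutive candidates.  The objective is
    lexicographic: first minimize retained cross-species matches (pairs at or
    above the threshold whose species labels differ), then maximize records
    classified species-level.  The smallest candidate achieving the optimum
    is returned together with the full score trace.
    """
    records = list(library)
    if len({(r.genus, r.species) for r in records if r.species}) < 2:
        raise ValueError("threshold optimization requires >= 2 species")
    idm = identity_matrix([r.sequence for r in records])
    n = len(records)
    pair_idx = list(itertools.combinations(range(n), 2))
    observed = sorted({idm[i, j] for i, j in pair_idx if idm[i, j] >= start})
    candidates = sorted(
        set(observed)
        | {(a + b) / 2 for a, b in zip(observed, observed[1:])}
    )
    if not candidates:
        candidates = [start]
    trace = []
    best: tuple[int, int, float] | None = None  # (cross, -species_level, threshold)
    for t in candidates:
        cross = sum(
            1
            for i, j in pair_idx
            if idm[i, j] >= t
            and (records[i].genus, records[i].species)
            != (records[j].genus, records[j].species)
        )
        n_species_level = 0
        for i in range(n):
            matches = [records[j] for j in range(n) if j != i and idm[i, j] >= t]
            if _rank_from_matches(matches) == "species-level":
                n_species_level += 1
        trace.append((t, cross, n_species_level))
        key = (cross, -n_species_level, t)
        if best is None or key < best:
            best = key
    cross, neg_sl, thr = best
    return ThresholdSearch(
        threshold=thr,
        n_cross_species_matches=cross,
        n_species_level=-neg_sl,
        trace=tuple(trace),
    )


# --------------------------------------------------------------------------
# Similarity summaries


@dataclass(frozen=True)
class SimilaritySummary:
    """Mean +/- SD percent identity within species and within genus-only taxa."""

    intraspecific_mean: float | None
    intraspecific_sd: float | None
    n_species: int
    within_genus_mean: float | None
    within_genus_sd: float | None
    n_genus_only_genera: int


def similarity_summary(library: ReferenceLibrary) -> SimilaritySummary:
    """Intraspecific similarity over species with >= 2 sequences; within-genus
    similarity over genus-only records in genera represented by > 2 such."""
    by_species: dict[tuple[str, str], list[ReferenceRecord]] = {}
    genus_only: dict[str, list[ReferenceRecord]] = {}
    for rec in library:
        if rec.species is not None:
            by_species.setdefault((rec.genus, rec.species), []).append(rec)
        else:
            genus_only.setdefault(rec.genus, []).append(rec)

    intra: list[float] = []
    n_species = 0
    for recs in by_species.values():
        if len(recs) < 2:
            continue
        n_species += 1
        intra.extend(
            pairwise_identity(a.sequence, b.sequence)
            for a, b in itertools.combinations(recs, 2)
        )
    within: list[float] = []
    n_genera = 0
    for recs in genus_only.values():
        if len(recs) <= 2:
            continue
        n_genera += 1
        within.extend(
            pairwise_identity(a.sequence, b.sequence)
            for a, b in itertools.combinations(recs, 2)
        )

    def _ms(vals: list[float]) -> tuple[float | None, float | None]:
        if not vals:
            return None, None
        arr = np.asarray(vals)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        return float(arr.mean()), sd

    im, isd = _ms(intra)
    wm, wsd = _ms(within)
    return SimilaritySummary(im, isd, n_species, wm, wsd, n_genera)
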