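"""Degenerate-primer representation, physical properties and in-silico PCR.

The evaluation model predicts, for a degenerate primer pair against a labeled
template library, which templates would amplify.  Binding of each primer is
scored by position-weighted mismatch penalties: mismatches near the 3' end of
the primer (where the polymerase extends) cost far more than 5' mismatches,
transversions cost more than transitions, adjacent mismatches are compounded,
and a template fails when the accumulated penalty exceeds a threshold
(default 120 points).  The penalty table itself is a documented, overridable
default — see ``docs/methods.md`` for the calibration rationale.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import edlib
import pandas as pd

from ._iupac import (
    IUPAC,
    PURINES,
    PYRIMIDINES,
    degeneracy,
    possibilities,
    reverse_complement,
    validate,
)
from .reference import ReferenceLibrary

Direction = Literal["forward", "reverse"]

# Monophosphate residue masses (g/mol); oligo MW = sum(residues) - 61.96
# (removal of HPO3 plus addition of H2O at the 5' end).
_BASE_MASS = {"A": 313.21, "C": 289.18, "G": 329.21, "T": 304.20}


@dataclass(frozen=True)
class DegeneratePrimer:
    """An IUPAC-alphabet oligo, written 5'->3', with an amplification direction."""

    name: str
    sequence: str
    direction: Direction = "forward"

    def __post_init__(self) -> None:
        validate(self.sequence)
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"direction must be forward|reverse, got {self.direction!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def degeneracy(self) -> int:
        return degeneracy(self.sequence)


# The four published primers this package was built around: the original
# general aphid COI pair and the pair modified to exclude coccinellid DNA.
APH344F = DegeneratePrimer("Aph344F", "GGAACAGGWACAGGATGAAC", "forward")
APH149R = DegeneratePrimer("Aph149R", "AATCAAAATAAATGTTGATA", "reverse")
APH344_MF = DegeneratePrimer("Aph344.MF", "GGAACAGGWACAGGATGAACWA", "forward")
APH149_MR = DegeneratePrimer("Aph149.MR", "AATCARAATARATGTTGATA", "reverse")

MODIFIED_PAIR = (APH344_MF, APH149_MR)
ORIGINAL_PAIR = (APH344F, APH149R)


def _seq(primer: DegeneratePrimer | str) -> str:
    return primer.sequence if isinstance(primer, DegeneratePrimer) else primer


def expand_degenerate(primer: DegeneratePrimer | str) -> set[str]:
    """All concrete ACGT sequences a degenerate oligo represents."""
    seq = _seq(primer)
    validate(seq)
    return {"".join(p) for p in itertools.product(*(possibilities(c) for c in seq))}


def gc_content(primer: DegeneratePrimer | str) -> float:
    """GC percentage; a degenerate position contributes its fractional G/C share."""
    seq = _seq(primer)
    validate(seq)
    gc = 0.0
    for c in seq:
        poss = possibilities(c)
        gc += sum(b in "GC" for b in poss) / len(poss)
    return 100.0 * gc / len(seq)


def molecular_weight(primer: DegeneratePrimer | str) -> float:
    """Oligo molecular weight in g/mol; degenerate positions averaged."""
    seq = _seq(primer)
    validate(seq)
    total = 0.0
    for c in seq:
        poss = possibilities(c)
        total += sum(_BASE_MASS[b] for b in poss) / len(poss)
    return total - 61.96


def melting_temperature(
    primer: DegeneratePrimer | str, method: str = "wallace"
) -> float:
    """Melting temperature in deg C.

    ``wallace``: 2(A+T) + 4(G+C) with degenerate positions averaged.
    ``nearest_neighbor``: Biopython's nearest-neighbour model, averaged over
    the expansion of the degenerate oligo (default salt conditions).
    """
    seq = _seq(primer)
    validate(seq)
    if method == "wallace":
        at = gc = 0.0
        for c in seq:
            poss = possibilities(c)
            gc += sum(b in "GC" for b in poss) / len(poss)
            at += sum(b in "AT" for b in poss) / len(poss)
        return 2.0 * at + 4.0 * gc
    if method == "nearest_neighbor":
        from Bio.SeqUtils import MeltingTemp

        variants = sorted(expand_degenerate(seq))
        return float(sum(MeltingTemp.Tm_NN(v) for v in variants) / len(variants))
    raise ValueError(f"unknown Tm method {method!r}")


# --------------------------------------------------------------------------
# Mismatch scoring


@dataclass(frozen=True)
class MismatchEvent:
    """One mismatch or indel between a primer and its template site.

    ``dist_3prime`` counts from the primer 3' terminus (0 = terminal base).
    """

    dist_3prime: int
    primer_base: str
    template_base: str  # "-" for an insertion in the primer
    kind: Literal["mismatch", "gap"] = "mismatch"


def _default_mismatch_table() -> dict[tuple[str, str], float]:
    table = {}
    for p in "ACGT":
        for t in "ACGT":
            if p == t:
                table[(p, t)] = 0.0
            elif ({p, t} <= PURINES) or ({p, t} <= PYRIMIDINES):
                table[(p, t)] = 20.0  # transition-type mismatch
            else:
                table[(p, t)] = 40.0  # transversion
    return table


@dataclass(frozen=True)
class MismatchScoringScheme:
    """Position-weighted penalty model for primer-template mismatches.

    Defaults: transitions 20, transversions 40; the five 3'-terminal primer
    positions weighted 4 / 3 / 2.5 / 2 / 1.5 (then 1.0); adjacent mismatches
    multiplied by 1.5 each; 50 points per indel; fail above 120 points.
    A single 3'-terminal transversion (40 x 4 = 160) therefore vetoes
    amplification while any single internal mismatch does not.
    """

    base_mismatch_scores: dict[tuple[str, str], float] = field(
        default_factory=_default_mismatch_table
    )
    position_weights: tuple[float, ...] = (4.0, 3.0, 2.5, 2.0, 1.5)
    adjacent_mismatch_multiplier: float = 1.5
    gap_penalty: float = 50.0
    fail_threshold: float = 120.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.base_mismatch_scores.values()):
            raise ValueError("mismatch penalties must be >= 0")
        if any(self.base_mismatch_scores[(b, b)] != 0 for b in "ACGT"):
            raise ValueError("a perfect match must score 0")
        if self.fail_threshold <= 0:
            raise ValueError("fail_threshold must be > 0")

    def weight(self, dist_3prime: int) -> float:
        if dist_3prime < len(self.position_weights):
            return self.position_weights[dist_3prime]
        return 1.0

    def mismatch_score(self, primer_code: str, template_base: str) -> float:
        """Penalty for one aligned column; degenerate codes take the best variant."""
        poss = possibilities(primer_code)
        if template_base in poss:
            return 0.0
        if template_base not in "ACGT":
            # ambiguous template base: compatible -> free, else best-case pairing
            tposs = possibilities(template_base)
            if set(tposs) & set(poss):
                return 0.0
            return min(
                self.base_mismatch_scores[(p, t)] for p in poss for t in tposs
            )
        return min(self.base_mismatch_scores[(p, template_base)] for p in poss)

    @classmethod
    def from_json(cls, path: str | Path) -> "MismatchScoringScheme":
        with open(path) as fh:
            cfg = json.load(fh)
        kwargs: dict = {}
        if "base_mismatch_scores" in cfg:
            kwargs["base_mismatch_scores"] = {
                (k[0], k[1]): float(v) for k, v in cfg["base_mismatch_scores"].items()
            }
        for key in (
            "position_weights",
            "adjacent_mismatch_multiplier",
            "gap_penalty",
            "fail_threshold",
        ):
            if key in cfg:
                kwargs[key] = (
                    tuple(cfg[key]) if key == "position_weights" else cfg[key]
                )
        return cls(**kwargs)


DEFAULT_SCHEME = MismatchScoringScheme()


@dataclass(frozen=True)
class BindingEvaluation:
    """Outcome of scoring one primer against one template."""

    primer_name: str
    template_id: str
    total_penalty: float
    mismatch_positions: tuple[MismatchEvent, ...]
    amplification_predicted: bool
    site_start: int | None = None  # on the evaluated (plus) strand


# --------------------------------------------------------------------------
# Binding-site alignment


def _ungapped_events(primer_seq: str, site: str) -> list[MismatchEvent]:
    n = len(primer_seq)
    events = []
    for i, (p, t) in enumerate(zip(primer_seq, site)):
        if t in possibilities(p) or (t not in "ACGT" and set(possibilities(t)) & set(possibilities(p))):
            continue
        events.append(MismatchEvent(dist_3prime=n - 1 - i, primer_base=p, template_base=t))
    return events


def align_binding(
    primer: DegeneratePrimer,
    template: str,
    site_start: int | None = None,
    scheme: MismatchScoringScheme = DEFAULT_SCHEME,
    gapped: bool = False,
) -> tuple[list[MismatchEvent], int]:
    """Locate and align a primer on a template; return (events, site_start).

    Reverse primers are evaluated against the reverse complement of the
    template, so events are always expressed on the primer's own strand.
    When ``site_start`` is None the binding site is located by a
    minimum-penalty scan; ties resolve to the most 3'-proximal site on the
    template.  ``site_start`` is reported in the scanned-strand coordinates.
    Default mode is ungapped; ``gapped`` permits indels (scored by
    ``scheme.gap_penalty``) via infix edit-distance alignment.
    """
    seq = primer.sequence
    strand = template if primer.direction == "forward" else reverse_complement(template)
    if len(strand) < len(seq):
        raise ValueError(
            f"template ({len(strand)} nt) shorter than primer ({len(seq)} nt)"
        )
    if gapped and site_start is None:
        return _align_gapped(seq, strand, scheme)
    if site_start is not None:
        site = strand[site_start : site_start + len(seq)]
        if len(site) < len(seq):
            raise ValueError("binding site runs past the template end")
        return _ungapped_events(seq, site), site_start
    best: tuple[float, int] | None = None
    for off in range(len(strand) - len(seq) + 1):
        ev = _ungapped_events(seq, strand[off : off + len(seq)])
        pen = binding_penalty(ev, scheme, primer.name, "scan").total_penalty
        if best is None or pen < best[0] or (pen == best[0] and off > best[1]):
            best = (pen, off)
    off = best[1]
    return _ungapped_events(seq, strand[off : off + len(seq)]), off


def _align_gapped(
    seq: str, strand: str, scheme: MismatchScoringScheme
) -> tuple[list[MismatchEvent], int]:
    equalities = [
        (code, base) for code, bases in IUPAC.items() if len(bases) > 1 for base in bases
    ]
    res = edlib.align(seq, strand, mode="HW", task="path",
                      additionalEqualities=equalities)
    start = res["locations"][0][0]
    events: list[MismatchEvent] = []
    qi, ti = 0, start
    n = len(seq)
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        ln = int(num)
        num = ""
        if ch == "=":
            qi, ti = qi + ln, ti + ln
        elif ch == "X":
            for k in range(ln):
                events.append(
                    MismatchEvent(n - 1 - (qi + k), seq[qi + k], strand[ti + k])
                )
            qi, ti = qi + ln, ti + ln
        elif ch == "D":  # deleted from primer: template insertion
            for k in range(ln):
                events.append(
                    MismatchEvent(max(n - 1 - qi, 0), "-", strand[ti + k], kind="gap")
                )
            ti += ln
        elif ch == "I":  # inserted in primer relative to template
            for k in range(ln):
                events.append(
                    MismatchEvent(n - 1 - (qi + k), seq[qi + k], "-", kind="gap")
                )
            qi += ln
    return events, start


def binding_penalty(
    events: Sequence[MismatchEvent],
    scheme: MismatchScoringScheme = DEFAULT_SCHEME,
    primer_name: str = "",
    template_id: str = "",
    site_start: int | None = None,
) -> BindingEvaluation:
    """Accumulate position-weighted penalties into a pass/fail evaluation."""
    mismatch_dists = {e.dist_3prime for e in events if e.kind == "mismatch"}
    total = 0.0
    for e in events:
        if e.kind == "gap":
            total += scheme.gap_penalty
            continue
        pen = scheme.mismatch_score(e.primer_base, e.template_base) * scheme.weight(
            e.dist_3prime
        )
        if (e.dist_3prime + 1 in mismatch_dists) or (e.dist_3prime - 1 in mismatch_dists):
            pen *= scheme.adjacent_mismatch_multiplier
        total += pen
    return BindingEvaluation(
        primer_name=primer_name,
        template_id=template_id,
        total_penalty=total,
        mismatch_positions=tuple(sorted(events, key=lambda e: e.dist_3prime)),
        amplification_predicted=total <= scheme.fail_threshold,
        site_start=site_start,
    )


def evaluate_binding(
    primer: DegeneratePrimer,
    template: str,
    template_id: str = "",
    scheme: MismatchScoringScheme = DEFAULT_SCHEME,
    site_start: int | None = None,
    gapped: bool = False,
) -> BindingEvaluation:
    events, start = align_binding(primer, template, site_start, scheme, gapped)
    ev = binding_penalty(events, scheme, primer.name, template_id, site_start=start)
    return ev


# --------------------------------------------------------------------------
# Coverage


@dataclass(frozen=True)
class CoverageReport:
    """Predicted amplification coverage for one taxon group."""

    group: str
    n_templates: int
    n_predicted_amplified: int

    @property
    def coverage(self) -> float | None:
        """Percent amplified, or None when the group is empty."""
        if self.n_templates == 0:
            return None
        return 100.0 * self.n_predicted_amplified / self.n_templates


def pair_coverage(
    pair: tuple[DegeneratePrimer, DegeneratePrimer],
    library: ReferenceLibrary,
    scheme: MismatchScoringScheme = DEFAULT_SCHEME,
    sites: dict[str, tuple[int, int]] | None = None,
) -> list[CoverageReport]:
    """Per-group percentage of templates both primers are predicted to amplify.

    ``sites`` optionally maps record id -> (forward site start, reverse site
    start on the reverse-complement strand); otherwise sites are located by
    minimum-penalty scan.
    """
    fwd = next(p for p in pair if p.direction == "forward")
    rev = next(p for p in pair if p.direction == "reverse")
    reports = []
    for group, records in sorted(library.by_group().items()):
        n_amp = 0
        for rec in records:
            fs, rs = (sites or {}).get(rec.id, (None, None))
            ev_f = evaluate_binding(fwd, rec.sequence, rec.id, scheme, site_start=fs)
            ev_r = evaluate_binding(rev, rec.sequence, rec.id, scheme, site_start=rs)
            if ev_f.amplification_predicted and ev_r.amplification_predicted:
                n_amp += 1
        reports.append(CoverageReport(group, len(records), n_amp))
    return reports


def primer_table(primers: Iterable[DegeneratePrimer] | None = None) -> pd.DataFrame:
    """Physical-property table (Tm, GC%, MW) for a primer set."""
    if primers is None:
        primers = (APH344F, APH149R, APH344_MF, APH149_MR)
    rows = [
        {
            "primer": p.name,
            "sequence": p.sequence,
            "direction": p.direction,
            "tm_wallace_C": round(melting_temperature(p, "wallace"), 1),
            "gc_percent": round(gc_content(p), 1),
            "mw_g_mol": round(molecular_weight(p), 1),
        }
        for p in primers
    ]
    return pd.DataFrame(rows)


def read_primers_tsv(path: str | Path) -> list[DegeneratePrimer]:
    """Read a name/sequence/direction TSV into primers."""
    primers = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, seq, direction = line.split("\t")[:3]
            primers.append(DegeneratePrimer(name, seq.upper(), direction))  # type: ignore[arg-type]
    return primers
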