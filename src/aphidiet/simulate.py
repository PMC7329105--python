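"""Synthetic data with known ground truth.

Three generators make the whole analysis chain testable without downloads:

* :func:`simulate_library` — a labeled COI-like barcode library with the
  hierarchical divergence structure of an aphid reference database
  (conspecific replicates ~0.2% divergent, congeneric species 1-8%
  divergent, genera essentially unrelated).
* :func:`simulate_gut_samples` — MID-tagged paired-end gut-content read
  sets dominated by predator reads, with per-cycle quality decay,
  substitution errors, PCR chimeras and cross-sample tag-jumps, all logged
  as ground truth.
* :func:`simulate_null_composition` — composition matrices under a shared
  (null) or group-shifted multinomial, for type-I-error and power checks.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._iupac import possibilities, reverse_complement
from .pipeline import FastqRead, TagScheme, write_fastq
from .primers import APH149_MR, APH344_MF, DegeneratePrimer
from .reference import ReferenceLibrary, ReferenceRecord

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))

def _mutate(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Substitute exactly ``n_subs`` distinct positions."""
    if n_subs == 0:
        return seq
    pos = rng.choice(len(seq), size=min(n_subs, len(seq)), replace=False)
    chars = list(seq)
    for p in pos:
        chars[p] = rng.choice([b for b in "ACGT" if b != chars[p]])
    return "".join(chars)


def _concrete(primer: DegeneratePrimer) -> str:
    return "".join(possibilities(c)[0] for c in primer.sequence)


# --------------------------------------------------------------------------
# Reference-library simulation


@dataclass(frozen=True)
class LibrarySimParams:
    """Shape and divergence structure of the simulated barcode library."""

    n_genera: int = 6
    species_per_genus: int = 3
    seqs_per_species: int = 3
    amplicon_length: int = 308
    intra_species_divergence: float = 0.002
    congeneric_divergence: tuple[float, float] = (0.01, 0.08)
    cross_genus_divergence: float = 0.10
    group: str = "aphid"
    genus_prefix: str = "Genus"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.congeneric_divergence
        if not (self.intra_species_divergence < lo <= hi < self.cross_genus_divergence):
            raise ValueError(
                "divergences must be ordered intra < congeneric < cross-genus"
            )
        if self.amplicon_length <= 0:
            raise ValueError("amplicon_length must be > 0")


def simulate_library(
    params: LibrarySimParams,
) -> tuple[ReferenceLibrary, pd.DataFrame]:
    """Generate a labeled library plus its ground-truth taxonomy table.

    Each genus gets an independent random root sequence; species derive from
    the root by substitutions at half a divergence drawn from the congeneric
    range, conspecific replicates by half the intra-species rate, so the
    *pairwise* divergences (the sum of two branches) land on the configured
    values: conspecific pairs ~``intra_species_divergence`` apart, congeneric
    pairs within ``congeneric_divergence``.
    """
    rng = np.random.default_rng(params.seed)
    L = params.amplicon_length
    lo, hi = params.congeneric_divergence
    records, rows = [], []
    for gi in range(params.n_genera):
        genus = f"{params.genus_prefix}{gi + 1:02d}"
        root = _random_seq(rng, L)
        for si in range(params.species_per_genus):
            species = f"sp{si + 1:02d}"
            div = rng.uniform(lo, hi)
            sp_seq = _mutate(root, max(1, round(div * L / 2)), rng)
            for ri in range(params.seqs_per_species):
                n_subs = rng.binomial(L, params.intra_species_divergence / 2)
                seq = _mutate(sp_seq, n_subs, rng)
                rid = f"{genus}_{species}_{ri + 1}"
                records.append(
                    ReferenceRecord(rid, genus, seq, species, params.group)
                )
                rows.append(
                    {"id": rid, "genus": genus, "species": species,
                     "group": params.group, "divergence_from_root": div}
                )
    return ReferenceLibrary(records), pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Gut-content read simulation


@dataclass(frozen=True)
class GutSimParams:
    """Study conditions for a simulated MiSeq gut-content run.

    ``compositions`` maps sample id -> {taxon label -> read count}; an empty
    dict marks a negative control.  Predator reads are added so they make up
    ``predator_read_fraction`` of each non-control sample, matching the
    predator-dominated read sets such studies produce.
    """

    compositions: dict[str, dict[str, int]]
    predator_read_fraction: float = 0.9
    error_rate: float = 0.001
    quality_start: float = 38.0
    quality_end: float = 25.0
    quality_jitter: float = 3.0
    chimera_rate: float = 0.005
    tagjump_rate: float = 0.01
    read_length: int = 300
    tag_length: int = 8
    forward_primer: DegeneratePrimer = APH344_MF
    reverse_primer: DegeneratePrimer = APH149_MR
    predator_group: str = "coccinellid"
    seed: int = 0

    def __post_init__(self) -> None:
        for frac in (self.predator_read_fraction, self.error_rate,
                     self.chimera_rate, self.tagjump_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("rates/fractions must lie in [0, 1]")
        if any(c < 0 for comp in self.compositions.values() for c in comp.values()):
            raise ValueError("expected read counts must be >= 0")


@dataclass
class GroundTruth:
    """What was actually put into the simulated samples."""

    true_counts: dict[str, dict[str, int]]  # sample -> taxon -> aphid reads
    predator_counts: dict[str, int]
    chimeras: list[dict]  # {id, sample, parents}
    tagjumps: list[dict]  # {taxon, source, sink, size}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1)


@dataclass
class SimulatedRun:
    pairs: list[tuple[FastqRead, FastqRead]]
    scheme: TagScheme
    truth: GroundTruth
    library: ReferenceLibrary

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fastq((r1 for r1, _ in self.pairs), outdir / "reads_R1.fastq")
        write_fastq((r2 for _, r2 in self.pairs), outdir / "reads_R2.fastq")
        self.scheme.to_oligos_tsv(outdir / "oligos.tsv")
        self.truth.to_json(outdir / "ground_truth.json")


def _make_tags(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Random MID tags with pairwise Hamming distance >= 3 (safe at 1 mismatch)."""
    tags: list[str] = []
    while len(tags) < n:
        cand = _random_seq(rng, length)
        if all(sum(a != b for a, b in zip(cand, t)) >= 3 for t in tags):
            tags.append(cand)
    return tags


def simulate_gut_samples(
    library: ReferenceLibrary, params: GutSimParams
) -> SimulatedRun:
    """Simulate tagged paired-end reads for gut-content samples.

    Each read's template is MID tag + forward primer + amplicon + reverse
    primer site + MID tag; chimeras are single-crossover recombinants of two
    sampled amplicons; tag-jumps re-label whole reads to a uniformly chosen
    other sample.  R1/R2 are the two template ends at the configured read
    length with linear mean-quality decay and substitution errors.
    """
    rng = np.random.default_rng(params.seed)
    by_taxon = {rec.taxon: rec for rec in library}
    predators = [r for r in library if r.group == params.predator_group]
    if not predators:
        raise ValueError(f"library has no {params.predator_group!r} records")
    for comp in params.compositions.values():
        for taxon in comp:
            if taxon not in by_taxon:
                raise ValueError(f"composition references unknown taxon {taxon!r}")

    samples = sorted(params.compositions)
    tags = _make_tags(rng, 2 * len(samples), params.tag_length)
    scheme = TagScheme(
        samples={
            sid: (tags[2 * i], tags[2 * i + 1]) for i, sid in enumerate(samples)
        },
        forward_primer=_concrete(params.forward_primer),
        reverse_primer=_concrete(params.reverse_primer),
    )
    fwd = scheme.forward_primer
    rev_site = reverse_complement(scheme.reverse_primer)

    # (amplicon, taxon, source sample) triples; chimeras appended per sample
    molecules: list[tuple[str, str, str]] = []
    truth_counts: dict[str, dict[str, int]] = {}
    predator_counts: dict[str, int] = {}
    chimeras: list[dict] = []
    for sid in samples:
        comp = params.compositions[sid]
        truth_counts[sid] = dict(comp)
        aphid_total = sum(comp.values())
        sample_amplicons: list[tuple[str, str]] = []
        for taxon in sorted(comp):
            seq = by_taxon[taxon].sequence
            sample_amplicons.extend([(seq, taxon)] * comp[taxon])
        f = params.predator_read_fraction
        n_pred = round(aphid_total * f / (1 - f)) if aphid_total and f < 1 else 0
        predator_counts[sid] = n_pred
        if n_pred:
            pred = predators[rng.integers(len(predators))]
            sample_amplicons.extend([(pred.sequence, pred.taxon)] * n_pred)
        n_chim = round(params.chimera_rate * len(sample_amplicons))
        for ci in range(n_chim):
            if len({t for _, t in sample_amplicons}) < 2:
                break
            (a, ta), (b, tb) = (
                sample_amplicons[rng.integers(len(sample_amplicons))],
                sample_amplicons[rng.integers(len(sample_amplicons))],
            )
            if ta == tb:
                continue
            cut = int(rng.integers(20, min(len(a), len(b)) - 20))
            chim = a[:cut] + b[cut:]
            chimeras.append({"id": f"{sid}_chim{ci}", "sample": sid,
                             "parents": [ta, tb]})
            sample_amplicons.append((chim, f"chimera:{ta}+{tb}"))
        molecules.extend((seq, taxon, sid) for seq, taxon in sample_amplicons)

    # tag-jumps: re-label a read's sample uniformly among the other samples
    jump_counts: dict[tuple[str, str, str], int] = {}
    routed: list[tuple[str, str, str]] = []
    for seq, taxon, src in molecules:
        if len(samples) > 1 and rng.random() < params.tagjump_rate:
            others = [s for s in samples if s != src]
            sink = others[rng.integers(len(others))]
            jump_counts[(taxon, src, sink)] = jump_counts.get(
                (taxon, src, sink), 0
            ) + 1
            routed.append((seq, taxon, sink))
        else:
            routed.append((seq, taxon, src))
    tagjumps = [
        {"taxon": t, "source": s, "sink": k, "size": n}
        for (t, s, k), n in sorted(jump_counts.items())
    ]

    pairs: list[tuple[FastqRead, FastqRead]] = []
    for ri, (amplicon, taxon, sid) in enumerate(routed):
        ftag, rtag = scheme.samples[sid]
        template = ftag + fwd + amplicon + rev_site + reverse_complement(rtag)
        r1 = _sequence_read(template, params, rng, f"read{ri}/1")
        r2 = _sequence_read(
            reverse_complement(template), params, rng, f"read{ri}/2"
        )
        pairs.append((r1, r2))

    truth = GroundTruth(truth_counts, predator_counts, chimeras, tagjumps)
    return SimulatedRun(pairs, scheme, truth, library)


def _sequence_read(
    template: str, params: GutSimParams, rng: np.random.Generator, read_id: str
) -> FastqRead:
    n = min(params.read_length, len(template))
    bases = list(template[:n])
    if params.error_rate > 0:
        errs = np.flatnonzero(rng.random(n) < params.error_rate)
        for p in errs:
            bases[p] = rng.choice([b for b in "ACGT" if b != bases[p]])
    cycle = np.arange(n) / max(params.read_length - 1, 1)
    mean_q = params.quality_start + (params.quality_end - params.quality_start) * cycle
    quals = np.clip(
        np.rint(mean_q + rng.normal(0, params.quality_jitter, n)), 4, 40
    ).astype(int)
    return FastqRead(read_id, "".join(bases), tuple(int(q) for q in quals))


# --------------------------------------------------------------------------
# Null / shifted composition simulation


def simulate_null_composition(
    n_units: int,
    n_taxa: int,
    groups: Sequence,
    seed: int | np.random.Generator | None = None,
    shift: float = 0.0,
    detections_per_unit: int = 20,
) -> pd.DataFrame:
    """Composition rows from a shared multinomial (null) or group-shifted ones.

    ``shift`` in [0, 1] mixes each group's base proportions with an
    independent group-specific profile (0 = exchangeable null, 1 = fully
    distinct groups).  Rows are within-unit proportions summing to 1.
    """
    if n_units < 4:
        raise ValueError("need n_units >= 4")
    if len(groups) != n_units:
        raise ValueError("groups must have one label per unit")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = rng.dirichlet(np.ones(n_taxa))
    profiles = {
        g: (1 - shift) * base + shift * rng.dirichlet(np.ones(n_taxa))
        for g in dict.fromkeys(groups)
    }
    rows = np.empty((n_units, n_taxa))
    for i, g in enumerate(groups):
        counts = rng.multinomial(detections_per_unit, profiles[g])
        rows[i] = counts / counts.sum()
    return pd.DataFrame(
        rows,
        index=[f"unit{i}" for i in range(n_units)],
        columns=[f"taxon{j}" for j in range(n_taxa)],
    )
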