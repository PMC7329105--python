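"""Reads-to-diet metabarcoding pipeline.

Raw paired-end MID-tagged reads are transformed into a per-individual
detection matrix through the stages: adapter clipping, sliding-window
quality trimming, pair merging, tag demultiplexing (one mismatch per tag),
per-sample dereplication, minimum-abundance filtering (with per-pool
tag-jump thresholds), a two-parent chimera screen, greedy 99% centroid
clustering, and identity-threshold taxonomic assignment (>= 98.36% identity
over >= 296 aligned bases).

Every stage conserves reads: input count = output count + discarded count,
with reason codes, and the orchestrator records the accounting per stage.
Stage semantics are deliberately simple reimplementations of the standard
tools' behaviour at the documented thresholds; bit-equivalence with any
particular binary is not a goal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from collections import Counter
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from ._iupac import reverse_complement
from .reference import ReferenceLibrary, ReferenceRecord
from .resolution import alignment_identity, pairwise_identity


# --------------------------------------------------------------------------
# Read containers and FASTQ I/O


@dataclass(frozen=True)
class FastqRead:
    id: str
    bases: str
    qualities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.qualities):
            raise ValueError(f"read {self.id}: bases/qualities length mismatch")
        if any(q < 0 for q in self.qualities):
            raise ValueError(f"read {self.id}: negative Phred score")

    def __len__(self) -> int:
        return len(self.bases)

    def slice(self, start: int, end: int) -> "FastqRead":
        return FastqRead(self.id, self.bases[start:end], self.qualities[start:end])

    def reverse_complement(self) -> "FastqRead":
        return FastqRead(
            self.id, reverse_complement(self.bases), self.qualities[::-1]
        )


def read_fastq(path: str | Path) -> list[FastqRead]:
    """Phred+33 FASTQ reader."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append(
            FastqRead(
                rec.id,
                str(rec.seq).upper(),
                tuple(rec.letter_annotations["phred_quality"]),
            )
        )
    return out


def write_fastq(reads: Iterable[FastqRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            quals = "".join(chr(min(q, 93) + 33) for q in r.qualities)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{quals}\n")


# --------------------------------------------------------------------------
# Stage parameters


@dataclass(frozen=True)
class QualityTrimParams:
    """Sliding-window trimming thresholds (Phred scale)."""

    window: int = 4
    min_mean_q: float = 20.0
    edge_q: int = 3
    min_length: int = 250
    adapter_seqs: tuple[str, ...] = ()
    adapter_max_mismatch: int = 2
    adapter_min_overlap: int = 8

    def __post_init__(self) -> None:
        if self.window < 1 or self.min_length < 1:
            raise ValueError("window and min_length must be >= 1")


@dataclass(frozen=True)
class TagScheme:
    """MID-tag combinations identifying samples, plus primers to strip."""

    samples: dict[str, tuple[str, str]]  # sample id -> (forward tag, reverse tag)
    forward_primer: str
    reverse_primer: str
    max_mismatch_per_tag: int = 1

    def __post_init__(self) -> None:
        pairs = list(self.samples.values())
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate tag pairs in scheme")
        if any(not f or not r for f, r in pairs):
            raise ValueError("tags must be non-empty")

    @classmethod
    def from_oligos_tsv(
        cls, path: str | Path, max_mismatch_per_tag: int = 1
    ) -> "TagScheme":
        """Mothur-style oligos file: ``primer <fwd> <rev>`` and
        ``barcode <fwdtag> <revtag> <sample>`` lines."""
        fwd = rev = ""
        samples: dict[str, tuple[str, str]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts or parts[0].startswith("#"):
                    continue
                if parts[0].lower() == "primer":
                    fwd, rev = parts[1].upper(), parts[2].upper()
                elif parts[0].lower() == "barcode":
                    samples[parts[3]] = (parts[1].upper(), parts[2].upper())
        return cls(samples, fwd, rev, max_mismatch_per_tag)

    def to_oligos_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"primer\t{self.forward_primer}\t{self.reverse_primer}\n")
            for sid, (f, r) in self.samples.items():
                fh.write(f"barcode\t{f}\t{r}\t{sid}\n")


# --------------------------------------------------------------------------
# Per-read stages


def clip_adapters(read: FastqRead, params: QualityTrimParams) -> FastqRead:
    """Remove 3' adapter read-through (exact-seed + mismatch-tolerant match)."""
    if not params.adapter_seqs:
        return read
    cut = len(read)
    for adapter in params.adapter_seqs:
        for i in range(len(read)):
            seg = read.bases[i : i + len(adapter)]
            if len(seg) < params.adapter_min_overlap:
                break
            mism = sum(a != b for a, b in zip(seg, adapter))
            if mism <= params.adapter_max_mismatch:
                cut = min(cut, i)
                break
    return read.slice(0, cut)


def quality_trim(read: FastqRead, params: QualityTrimParams) -> FastqRead | None:
    """Edge-trim low-quality bases, then cut at the first bad sliding window.

    Leading/trailing bases with Q < edge_q are removed; the remaining read is
    scanned 5'->3' with a window of ``params.window`` bases and truncated
    before the first window whose mean quality drops below ``min_mean_q``.
    Reads shorter than ``min_length`` after trimming are discarded (None).
    """
    q = read.qualities
    start, end = 0, len(q)
    while start < end and q[start] < params.edge_q:
        start += 1
    while end > start and q[end - 1] < params.edge_q:
        end -= 1
    read = read.slice(start, end)
    q = read.qualities
    w = params.window
    for i in range(len(q) - w + 1):
        if sum(q[i : i + w]) / w < params.min_mean_q:
            read = read.slice(0, i)
            break
    if len(read) < params.min_length:
        return None
    return read


def merge_pairs(
    r1: FastqRead,
    r2: FastqRead,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
) -> FastqRead | None:
    """Overlap-merge a read pair (r2 is reverse-complemented first).

    The best ungapped overlap (matches minus mismatches, ties to the longer
    overlap) with mismatch fraction <= ``max_mismatch_frac`` is accepted;
    conflicting positions take the higher-quality base.
    """
    r2c = r2.reverse_complement()
    best: tuple[int, int] | None = None  # (score, overlap)
    for o in range(min(len(r1), len(r2c)), min_overlap - 1, -1):
        if best is not None and o <= best[0]:
            break  # score <= overlap length: no longer improvable
        a, b = r1.bases[len(r1) - o :], r2c.bases[:o]
        allowed = int(max_mismatch_frac * o)
        mism = 0
        for x, y in zip(a, b):
            if x != y:
                mism += 1
                if mism > allowed:
                    break
        if mism > allowed:
            continue
        score = o - 2 * mism
        if best is None or score > best[0]:
            best = (score, o)
    if best is None:
        return None
    o = best[1]
    left = r1.slice(0, len(r1) - o)
    right = r2c.slice(o, len(r2c))
    bases, quals = [], []
    for k in range(o):
        b1, q1 = r1.bases[len(r1) - o + k], r1.qualities[len(r1) - o + k]
        b2, q2 = r2c.bases[k], r2c.qualities[k]
        if b1 == b2:
            bases.append(b1)
            quals.append(max(q1, q2))
        elif q2 > q1:
            bases.append(b2)
            quals.append(q2)
        else:
            bases.append(b1)
            quals.append(q1)
    return FastqRead(
        r1.id,
        left.bases + "".join(bases) + right.bases,
        left.qualities + tuple(quals) + right.qualities,
    )


# --------------------------------------------------------------------------
# Demultiplexing


@dataclass
class DemuxResult:
    by_sample: dict[str, list[FastqRead]]
    unassigned: list[tuple[FastqRead, str]]  # (read, reason code)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(reads: Iterable[FastqRead], scheme: TagScheme) -> DemuxResult:
    """Assign merged reads to samples by their MID-tag pair.

    A read is assigned iff exactly one sample's (forward, reverse) tag pair
    matches the read ends with <= ``max_mismatch_per_tag`` mismatches per
    tag; both orientations are tried.  Tags and primers are then stripped.
    Ambiguous reads (>= 2 candidate samples) and unmatched reads land in the
    unassigned pool with reason codes ``ambiguous`` / ``no_tag_match``.
    """
    by_sample: dict[str, list[FastqRead]] = {sid: [] for sid in scheme.samples}
    unassigned: list[tuple[FastqRead, str]] = []
    mm = scheme.max_mismatch_per_tag
    for read in reads:
        hit: tuple[str, FastqRead] | None = None
        ambiguous = False
        for oriented in (read, read.reverse_complement()):
            candidates = []
            for sid, (ftag, rtag) in scheme.samples.items():
                if len(oriented) < len(ftag) + len(rtag):
                    continue
                d_f = _hamming(oriented.bases[: len(ftag)], ftag)
                tail = oriented.bases[len(oriented) - len(rtag) :]
                d_r = _hamming(reverse_complement(tail), rtag)
                if d_f <= mm and d_r <= mm:
                    candidates.append(sid)
            if len(candidates) > 1:
                ambiguous = True
                break
            if len(candidates) == 1:
                sid = candidates[0]
                ftag, rtag = scheme.samples[sid]
                start = len(ftag) + len(scheme.forward_primer)
                end = len(oriented) - len(rtag) - len(scheme.reverse_primer)
                if end > start:
                    hit = (sid, oriented.slice(start, end))
                break
        if ambiguous:
            unassigned.append((read, "ambiguous"))
        elif hit is None:
            unassigned.append((read, "no_tag_match"))
        else:
            by_sample[hit[0]].append(hit[1])
    return DemuxResult(by_sample, unassigned)


# --------------------------------------------------------------------------
# Dereplication, abundance filtering, tag-jump thresholds


@dataclass(frozen=True)
class UniqueAmplicon:
    sequence: str
    size: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("size must be >= 1")


def dereplicate(reads: Sequence[FastqRead], sample_id: str) -> list[UniqueAmplicon]:
    """Collapse identical sequences, largest first (ties lexicographic)."""
    counts = Counter(r.bases for r in reads)
    return [
        UniqueAmplicon(seq, size, sample_id)
        for seq, size in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def abundance_filter(
    uniques: Sequence[UniqueAmplicon], min_size: int
) -> list[UniqueAmplicon]:
    """Remove uniques appearing fewer than ``min_size`` times (keep >= min_size)."""
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    return [u for u in uniques if u.size >= min_size]


def tag_jump_threshold(
    impossible_detections: Sequence[tuple[str, str, int]], base: int = 10
) -> int:
    """Per-pool minimum-abundance threshold mitigating tag-jumping.

    ``impossible_detections`` are (sequence, sample, size) triples observed
    where they cannot genuinely occur (negative controls, alien spike-ins).
    The threshold is one more than the largest impossible size, floored at
    ``base``: every observed artefact would have been removed.
    """
    if not impossible_detections:
        warnings.warn("no impossible detections observed; using base threshold")
        return base
    return max(base, 1 + max(size for _, _, size in impossible_detections))


# --------------------------------------------------------------------------
# Chimera screen


def _lcp(a: str, b: str) -> int:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            break
        n += 1
    return n


def screen_chimeras(
    uniques: Sequence[UniqueAmplicon], parent_abundance_ratio: float = 2.0
) -> tuple[list[UniqueAmplicon], list[UniqueAmplicon]]:
    """Two-parent crossover chimera screen; returns (retained, flagged).

    A unique is flagged as chimeric when it can be exactly partitioned into a
    left segment matching the prefix of one more-abundant unique and a right
    segment matching the suffix of another, with each parent at least
    ``parent_abundance_ratio`` times as abundant.  The most abundant unique
    can never be flagged.
    """
    ordered = sorted(uniques, key=lambda u: (-u.size, u.sequence))
    retained: list[UniqueAmplicon] = []
    flagged: list[UniqueAmplicon] = []
    for child in ordered:
        parents = [
            u
            for u in ordered
            if u.size >= parent_abundance_ratio * child.size
            and u.sequence != child.sequence
        ]
        if _is_chimera(child.sequence, parents):
            flagged.append(child)
        else:
            retained.append(child)
    return retained, flagged


def _is_chimera(seq: str, parents: Sequence[UniqueAmplicon]) -> bool:
    L = len(seq)
    if L < 2 or len(parents) < 2:
        return False
    lcps = {p.sequence: _lcp(seq, p.sequence) for p in parents}
    lcss = {
        p.sequence: _lcp(seq[::-1], p.sequence[::-1]) for p in parents
    }
    for a in parents:
        for b in parents:
            if a.sequence == b.sequence:
                continue
            lo = max(1, L - lcss[b.sequence])
            hi = min(L - 1, lcps[a.sequence])
            if lo <= hi:
                return True
    return False


# --------------------------------------------------------------------------
# Centroid clustering


@dataclass
class Centroid:
    sequence: str
    sample_id: str
    members: int
    total_reads: int
    taxon: str | None = None
    member_seqs: list[str] = field(default_factory=list)


def cluster_centroids(
    uniques: Sequence[UniqueAmplicon], identity: float = 99.0
) -> list[Centroid]:
    """Greedy single-pass centroid clustering (cluster_fast semantics).

    Uniques are visited in decreasing-abundance order (ties lexicographic);
    each joins the first existing centroid with identity >= threshold, else
    founds a new centroid.
    """
    ordered = sorted(uniques, key=lambda u: (-u.size, u.sequence))
    centroids: list[Centroid] = []
    for u in ordered:
        for c in centroids:
            if pairwise_identity(u.sequence, c.sequence) >= identity:
                c.members += 1
                c.total_reads += u.size
                c.member_seqs.append(u.sequence)
                break
        else:
            centroids.append(
                Centroid(u.sequence, u.sample_id, 1, u.size, member_seqs=[u.sequence])
            )
    return centroids


# --------------------------------------------------------------------------
# Taxonomic assignment


@dataclass(frozen=True)
class TaxonAssignment:
    centroid_id: str
    rank: Literal["species", "genus", "unassigned"]
    taxon: str
    best_identity: float
    aligned_length: int
    group: str = ""


def assign_taxon(
    centroid: Centroid,
    library: ReferenceLibrary,
    min_identity: float = 98.36,
    min_len: int = 296,
    centroid_id: str = "",
) -> TaxonAssignment:
    """Identity-threshold taxonomic assignment of one centroid.

    Matches are library records with identity >= ``min_identity`` over
    >= ``min_len`` aligned bases.  All matches conspecific -> species rank;
    matches spanning species within one genus -> genus rank; no match or
    cross-genus matches -> unassigned.
    """
    matches: list[tuple[ReferenceRecord, float, int]] = []
    best_ident, best_len = 0.0, 0
    for rec in library:
        ident, cols = alignment_identity(centroid.sequence, rec.sequence)
        if ident > best_ident:
            best_ident, best_len = ident, cols
        if ident >= min_identity and cols >= min_len:
            matches.append((rec, ident, cols))
    if not matches:
        return TaxonAssignment(centroid_id, "unassigned", "", best_ident, best_len)
    recs = [m[0] for m in matches]
    top = max(matches, key=lambda m: m[1])
    genera = {r.genus for r in recs}
    if len(genera) > 1:
        return TaxonAssignment(centroid_id, "unassigned", "", top[1], top[2])
    taxa = {(r.genus, r.species) for r in recs}
    group = recs[0].group
    if len(taxa) == 1 and recs[0].species is not None:
        return TaxonAssignment(
            centroid_id, "species", recs[0].taxon, top[1], top[2], group
        )
    genus = recs[0].genus
    return TaxonAssignment(
        centroid_id, "genus", f"{genus} sp.", top[1], top[2], group
    )


# --------------------------------------------------------------------------
# Detection matrix


@dataclass
class DetectionMatrix:
    """Per-individual taxon detections for the target group.

    ``reads``: DataFrame, rows = sample ids, columns = target-group taxa,
    cells = summed reads.  Off-target (predator) and unassigned reads are
    tallied separately per sample.
    """

    reads: pd.DataFrame
    offtarget_reads: pd.Series
    unassigned_reads: pd.Series

    @property
    def presence(self) -> pd.DataFrame:
        return (self.reads > 0).astype(int)


def build_detection_matrix(
    assignments: Sequence[tuple[str, Centroid, TaxonAssignment]],
    target_group: str = "aphid",
    sample_ids: Sequence[str] | None = None,
) -> DetectionMatrix:
    """Aggregate per-sample centroid assignments into a detection matrix."""
    samples = list(sample_ids) if sample_ids is not None else sorted(
        {s for s, _, _ in assignments}
    )
    taxa = sorted(
        {
            a.taxon
            for _, _, a in assignments
            if a.rank != "unassigned" and a.group == target_group
        }
    )
    reads = pd.DataFrame(0, index=samples, columns=taxa, dtype=int)
    off = pd.Series(0, index=samples, dtype=int)
    unk = pd.Series(0, index=samples, dtype=int)
    for sid, cen, a in assignments:
        if sid not in reads.index:
            continue
        if a.rank == "unassigned":
            unk[sid] += cen.total_reads
        elif a.group == target_group:
            reads.loc[sid, a.taxon] += cen.total_reads
        else:
            off[sid] += cen.total_reads
    return DetectionMatrix(reads, off, unk)


# --------------------------------------------------------------------------
# Orchestration


@dataclass
class PipelineResult:
    detections: DetectionMatrix
    assignments: list[tuple[str, Centroid, TaxonAssignment]]
    stage_log: list[dict]
    pool_thresholds: dict[str, int]
    unassigned: list[tuple[FastqRead, str]]


def run_pipeline(
    pairs: Sequence[tuple[FastqRead, FastqRead]],
    scheme: TagScheme,
    library: ReferenceLibrary,
    trim_params: QualityTrimParams = QualityTrimParams(),
    min_size: int = 10,
    pool_of_sample: dict[str, str] | None = None,
    negative_controls: Sequence[str] = (),
    cluster_identity: float = 99.0,
    min_identity: float = 98.36,
    min_len: int = 296,
    target_group: str = "aphid",
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.25,
) -> PipelineResult:
    """Run the full reads-to-diet chain with per-stage read accounting.

    When ``negative_controls`` are named, every unique observed in them is an
    impossible detection and raises that pool's abundance threshold to
    max(min_size, largest impossible size + 1).
    """
    log: list[dict] = []
    pool_of = pool_of_sample or {}

    clipped = [
        (clip_adapters(r1, trim_params), clip_adapters(r2, trim_params))
        for r1, r2 in pairs
    ]
    log.append({"stage": "clip_adapters", "in": len(pairs), "out": len(clipped),
                "discarded": 0})

    trimmed: list[tuple[FastqRead, FastqRead]] = []
    for r1, r2 in clipped:
        t1, t2 = quality_trim(r1, trim_params), quality_trim(r2, trim_params)
        if t1 is not None and t2 is not None:
            trimmed.append((t1, t2))
    log.append({"stage": "quality_trim", "in": len(clipped), "out": len(trimmed),
                "discarded": len(clipped) - len(trimmed),
                "reasons": {"low_quality_or_short": len(clipped) - len(trimmed)}})

    merged: list[FastqRead] = []
    for r1, r2 in trimmed:
        m = merge_pairs(r1, r2, min_overlap, max_mismatch_frac)
        if m is not None:
            merged.append(m)
    log.append({"stage": "merge_pairs", "in": len(trimmed), "out": len(merged),
                "discarded": len(trimmed) - len(merged),
                "reasons": {"no_overlap": len(trimmed) - len(merged)}})

    demux = demultiplex(merged, scheme)
    n_assigned = sum(len(v) for v in demux.by_sample.values())
    reasons = Counter(reason for _, reason in demux.unassigned)
    log.append({"stage": "demultiplex", "in": len(merged), "out": n_assigned,
                "discarded": len(demux.unassigned), "reasons": dict(reasons)})

    uniques_by_sample = {
        sid: dereplicate(reads, sid) for sid, reads in demux.by_sample.items()
    }
    log.append({
        "stage": "dereplicate", "in": n_assigned,
        "out": sum(u.size for us in uniques_by_sample.values() for u in us),
        "discarded": 0,
    })

    # Per-pool tag-jump thresholds from negative-control detections.
    impossible: dict[str, list[tuple[str, str, int]]] = {}
    for sid in negative_controls:
        pool = pool_of.get(sid, "pool1")
        for u in uniques_by_sample.get(sid, []):
            impossible.setdefault(pool, []).append((u.sequence, sid, u.size))
    pools = {pool_of.get(sid, "pool1") for sid in scheme.samples}
    thresholds = {
        pool: tag_jump_threshold(impossible[pool], base=min_size)
        if pool in impossible
        else min_size
        for pool in pools
    }

    n_in = n_out = 0
    filtered: dict[str, list[UniqueAmplicon]] = {}
    for sid, uniques in uniques_by_sample.items():
        thr = thresholds[pool_of.get(sid, "pool1")]
        kept = abundance_filter(uniques, thr)
        filtered[sid] = kept
        n_in += sum(u.size for u in uniques)
        n_out += sum(u.size for u in kept)
    log.append({"stage": "abundance_filter", "in": n_in, "out": n_out,
                "discarded": n_in - n_out,
                "reasons": {"below_min_size": n_in - n_out},
                "thresholds": dict(thresholds)})

    n_in = n_out = 0
    screened: dict[str, list[UniqueAmplicon]] = {}
    for sid, uniques in filtered.items():
        kept, flagged = screen_chimeras(uniques)
        screened[sid] = kept
        n_in += sum(u.size for u in uniques)
        n_out += sum(u.size for u in kept)
    log.append({"stage": "screen_chimeras", "in": n_in, "out": n_out,
                "discarded": n_in - n_out, "reasons": {"chimeric": n_in - n_out}})

    assignments: list[tuple[str, Centroid, TaxonAssignment]] = []
    n_centroids = 0
    for sid in sorted(screened):
        if sid in negative_controls:
            continue
        for k, cen in enumerate(cluster_centroids(screened[sid], cluster_identity)):
            n_centroids += 1
            a = assign_taxon(
                cen, library, min_identity, min_len, centroid_id=f"{sid}_otu{k}"
            )
            assignments.append((sid, cen, a))
    log.append({"stage": "cluster_and_assign", "in": n_out, "out": n_out,
                "discarded": 0, "n_centroids": n_centroids})

    sample_ids = sorted(sid for sid in scheme.samples if sid not in negative_controls)
    detections = build_detection_matrix(assignments, target_group, sample_ids)
    return PipelineResult(detections, assignments, log, thresholds, demux.unassigned)
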