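"""Shared fixtures: constructed templates and small synthetic libraries."""

from __future__ import annotations

import numpy as np
import pytest

from aphidiet._iupac import possibilities, reverse_complement
from aphidiet.primers import APH149_MR, APH344_MF, DegeneratePrimer
from aphidiet.reference import ReferenceLibrary, ReferenceRecord


def concrete(primer: DegeneratePrimer) -> str:
    """First concrete expansion of a degenerate primer."""
    return "".join(possibilities(c)[0] for c in primer.sequence)


def build_template(
    insert: str,
    fwd: DegeneratePrimer = APH344_MF,
    rev: DegeneratePrimer = APH149_MR,
    pad5: str = "",
    pad3: str = "",
    fwd_site: str | None = None,
    rev_site: str | None = None,
) -> str:
    """Plus-strand template: pad5 + forward site + insert + reverse site + pad3.

    The reverse primer binds the minus strand, so its plus-strand site is the
    reverse complement of the primer sequence.
    """
    fsite = fwd_site if fwd_site is not None else concrete(fwd)
    rsite = rev_site if rev_site is not None else reverse_complement(concrete(rev))
    return pad5 + fsite + insert + rsite + pad3


def mutate_at(seq: str, positions: dict[int, str]) -> str:
    chars = list(seq)
    for p, b in positions.items():
        chars[p] = b
    return "".join(chars)


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20160401)


@pytest.fixture
def tiny_library(rng) -> ReferenceLibrary:
    """Two genera x two species x two replicates of 308 bp amplicons.

    Conspecific replicates differ at 1 position (99.7% identity),
    congeneric species at 12 positions (96.1%), genera are unrelated.
    """
    records = []
    for gi, genus in enumerate(["Aphidula", "Pemphigella"]):
        root = random_seq(np.random.default_rng(100 + gi), 308)
        for si, species in enumerate(["alpha", "beta"]):
            sp = mutate_at(
                root,
                {p: "ACGT"[(("ACGT".index(root[p])) + 1) % 4]
                 for p in range(si * 12, si * 12 + 12)},
            ) if si else root
            for ri in range(2):
                seq = sp if ri == 0 else mutate_at(
                    sp, {300: "A" if sp[300] != "A" else "C"}
                )
                records.append(
                    ReferenceRecord(
                        f"{genus}_{species}_{ri}", genus, seq, species, "aphid"
                    )
                )
    return ReferenceLibrary(records)
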