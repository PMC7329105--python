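# aphidiet

Molecular diet analysis of aphid predators by COI amplicon metabarcoding:
a Python toolkit covering the full chain from primer evaluation to
community statistics, for ecologists screening predator gut contents
(e.g. ladybird beetles) for aphid prey DNA with group-specific primers.

The package implements four linked analyses plus a synthetic-data layer:

1. **Primer evaluation** (`aphidiet.primers`) — degenerate (IUPAC) primer
   properties with fractional handling of ambiguous positions
   (GC% = 100·Σ|{G,C}∩possᵢ|/|possᵢ|/L; MW from monophosphate residue
   masses; Wallace and nearest-neighbour Tm), and in-silico PCR: binding
   sites scored by a position-weighted mismatch penalty (transversion 40,
   transition 20, 3'-terminal weights 4/3/2.5/2/1.5, adjacent ×1.5), with
   amplification predicted at total penalty ≤ 120 and per-taxon-group
   coverage reports.
2. **Amplicon taxon resolution** (`aphidiet.resolution`) — pairwise
   identity over the mutually covered region of a global alignment, a
   species-/genus-level resolvability classification per barcode record,
   and an exhaustive identity-threshold search that minimizes
   cross-species matches and then maximizes species-level records
   (candidates: all observed identities ≥ 90% plus midpoints).
3. **Reads-to-diet pipeline** (`aphidiet.pipeline`) — adapter clipping,
   Q20/4-base sliding-window trimming with a 250 nt floor, overlap
   merging, dual-MID-tag demultiplexing at ≤ 1 mismatch per tag,
   dereplication, per-pool minimum-abundance filtering with tag-jump
   thresholds derived from negative controls (max impossible size + 1,
   floor 10), a two-parent chimera screen, greedy 99% centroid
   clustering, and taxonomic assignment at ≥ 98.36% identity over ≥ 296
   aligned bases — ending in a per-individual detection matrix with
   predator and unassigned reads tallied separately.
4. **Composition statistics** (`aphidiet.stats`) — DNA-recovery rates,
   Hellinger-transformed detection proportions, Euclidean distances,
   one-factor PERMANOVA with permutations restricted within strata
   (pseudo-F = (SS_A/(a−1))/(SS_W/(n−a)), p = (1+#{F\*≥F})/(1+n_perm)),
   a betadisper-style multivariate dispersion test, and NMDS (Kruskal
   stress-1 with isotonic regression and Guttman updates).
5. **Synthetic data** (`aphidiet.simulate`) — seed-deterministic barcode
   libraries with realistic divergence structure, predator-dominated
   MID-tagged paired-end gut read sets with quality decay, chimeras and
   tag-jumps (all ground-truth logged), and null/shifted composition
   matrices for calibration checks.

See `docs/methods.md` for the model details and design rationale.

## Worked example

```python
from aphidiet.primers import primer_table
from aphidiet.simulate import (LibrarySimParams, GutSimParams,
                               simulate_library, simulate_gut_samples)
from aphidiet.reference import ReferenceLibrary
from aphidiet.resolution import optimize_threshold, similarity_summary
from aphidiet.pipeline import run_pipeline

print(primer_table().to_string(index=False))

library, _ = simulate_library(LibrarySimParams(seed=7))
search = optimize_threshold(library)
summary = similarity_summary(library)
print(f"threshold {search.threshold:.2f}%  deviating matches {search.n_cross_species_matches}")
print(f"intraspecific identity {summary.intraspecific_mean:.2f}% +/- {summary.intraspecific_sd:.2f}")

predators, _ = simulate_library(LibrarySimParams(
    n_genera=1, species_per_genus=2, seqs_per_species=1,
    group="coccinellid", genus_prefix="Ladybird", seed=8))
refs = ReferenceLibrary(list(library) + list(predators))
taxa = sorted({r.taxon for r in library})
run = simulate_gut_samples(refs, GutSimParams(
    compositions={"S1": {taxa[0]: 120, taxa[1]: 70},
                  "S2": {taxa[2]: 120, taxa[3]: 70},
                  "NC1": {}},
    seed=9))
result = run_pipeline(run.pairs, run.scheme, refs, negative_controls=["NC1"])
print(result.detections.reads)
print("pool thresholds:", result.pool_thresholds)
```

prints

```
   primer               sequence direction  tm_wallace_C  gc_percent  mw_g_mol
  Aph344F   GGAACAGGWACAGGATGAAC   forward          60.0        50.0    6228.6
  Aph149R   AATCAAAATAAATGTTGATA   reverse          46.0        15.0    6156.1
Aph344.MF GGAACAGGWACAGGATGAACWA   forward          64.0        45.5    6850.6
Aph149.MR   AATCARAATARATGTTGATA   reverse          48.0        20.0    6172.1
threshold 98.70%  deviating matches 0
intraspecific identity 99.84% +/- 0.21
    Genus01 sp01  Genus01 sp02  Genus01 sp03  Genus02 sp01
S1            93            57             0             0
S2             0             0            93            52
pool thresholds: {'pool1': 10}
```

The primer table lists the two published aphid COI primer pairs (original
and modified) with their physical properties; the threshold search finds
98.70% separating conspecific from heterospecific matches on this
simulated library with zero deviating matches, and the simulated
intraspecific identity (99.84% ± 0.21) reflects the 0.2% divergence the
generator was asked for. The detection matrix recovers exactly the prey
taxa put into each simulated gut sample (read counts are slightly below
the 120/70 input depths because reads carrying simulated sequencing errors
fall under the abundance threshold), and the negative control kept the
tag-jump threshold at its floor of 10 reads.

The same operations are exposed as a CLI:
`aphidiet primer-eval | resolve | pipeline | stats | simulate` (see
`aphidiet --help`).

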