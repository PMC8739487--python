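# ighrep

Immunoglobulin heavy-chain (V<sub>H</sub>D<sub>H</sub>J<sub>H</sub>) repertoire
analysis for bulk amplicon sequencing of B-cell / plasma-cell populations,
built around the question of clonal sharing between tissues — e.g. whether
IgA⁺ plasma cells in the bone marrow (BM) and the small-intestine lamina
propria (siLP) of the same animal derive from common clones.

It is aimed at immunologists analysing paired-end MiSeq amplicon data (or
pre-annotated AIRR-style rearrangement tables) per subject and per tissue,
and at method developers who need a fully controllable synthetic repertoire
with ground truth to validate every stage.

## What it computes

Given paired reads per (subject, tissue) sample:

1. **Read QC** — mates are merged over their best ungapped overlap; reads
   with mean Phred quality < 30 are removed; remaining bases with quality
   < 30 are masked with `N`; sequences with more than 10 `N`s are removed.
2. **Annotation** — each sequence is assigned its best V and J germline gene
   by semi-global alignment (free end gaps; match +1, mismatch −1, gap open
   −4, extend −1); the CDR3 is extracted between the conserved Cys (V) and
   Trp/Phe (J) anchor codons; the framework-1 region is trimmed off (it
   contains the primer-binding site) and somatic hypermutation (SHM) is the
   percentage of mutated positions in the remaining aligned V region.
   Identical sequences collapse into unique rearrangements with a copy
   number (`duplicate_count`).
3. **Clonal inference** — within each subject, rearrangements sharing the
   same V gene, J gene and CDR3 length are clustered by single linkage on
   CDR3 amino-acid identity; members linking at ≥ 85% identity
   (1 − Hamming/L, boundary included) form a clone.
4. **Clone-size filter (50% mcf)** — clones with a copy number less than
   50% of the subject's mean clone copy number are excluded.
5. **Overlap and SHM statistics** — for each pair of samples the clone-level
   Jaccard index |A∩B| / |A∪B| (each clone counts once, disregarding size),
   labelled within- or between-subject (between-subject pairs are pooled and
   re-clustered under the same clone definition); a presence matrix of
   clones detected in ≥ 2 samples; and per-tissue histograms of per-clone
   SHM, each clone contributing the copy-weighted mean SHM
   Σ(shmᵢ·copiesᵢ)/Σ(copiesᵢ) of its members in that tissue.

The simulator (`ighrep.simulate`) generates all of this with ground truth:
for within-subject sharing fraction *s* and *N* clones per sample, the
number of tissue-shared clones is Binomial(*N*, *s*) and the expected
clone-level Jaccard between a subject's two tissues is *s*/(2 − *s*).

## Worked example

Simulate two mice, 40 clones per tissue, 30% tissue sharing, 2% SHM, and run
the full pipeline against the packaged toy germline reference:

```bash
ighrep simulate --seed 7 --subjects 2 --clones-per-sample 40 \
    --sharing-fraction 0.3 --shm-rate 0.02 --out sim
ighrep run --manifest sim/manifest.tsv --out results
```

which logs

```
[INFO] ighrep: simulated 480 unique sequences across 4 samples into sim
[INFO] ighrep: pipeline complete: 915 rearrangements, 130 clones (82 after mcf filter)
```

(915 unique rearrangements from 480 simulated sequences: sequencing errors
create additional low-copy variants), and `results/summary.json` reports

```json
{
  "rearrangements": 915,
  "non_productive": 1,
  "clones_total": 130,
  "clones_after_mcf": 82,
  "included_clones_per_sample": {"M1_BM": 22, "M1_siLP": 28, "M2_BM": 31, "M2_siLP": 25},
  "jaccard_mean_within": 0.292,
  "jaccard_mean_between": 0.0
}
```

The within-subject Jaccard (≈ 0.29) is close to the simulated sharing
relation s/(2 − s) = 0.3/1.7 ≈ 0.18 only after accounting for the 50% mcf
filter, which preferentially retains shared (larger) clones; between-subject
overlap is zero, as simulated. `results/overlap.tsv` lists every sample
pair:

```
subject_a  sample_a  subject_b  sample_b  n_shared  n_union  jaccard  relation
M1         BM        M1         siLP      11        39       0.282    within_subject
M2         BM        M2         siLP      13        43       0.302    within_subject
M1         BM        M2         BM        0         53       0.0      between_subject
```

`results/` also contains the annotated rearrangement table
(`rearrangements.tsv`, AIRR-style columns — also accepted back as input via
`ighrep run --airr`), the clone and membership tables, the multi-sample
presence matrix, and the per-tissue SHM histogram.

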