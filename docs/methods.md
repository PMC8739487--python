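# Methods

## Scope and data model

`ighrep` analyses bulk heavy-chain (VDJ) amplicon repertoires sampled per
subject and per tissue. The canonical in-memory object is a pandas
rearrangement table with AIRR-style columns (`sequence_id`, `subject_id`,
`sample_id`, `sequence`, `v_call`, `j_call`, `v_identity`, `cdr3`,
`cdr3_aa`, `productive`, `shm_percent`, `duplicate_count`); it is written
and re-read as TSV and is the hand-off point between annotation and clonal
inference, so pre-annotated data can enter the pipeline directly. All
coordinates are 0-based, half-open.

## Germline reference

Annotation requires, per gene, the CDR3 anchor codon (conserved Cys for V,
Trp/Phe for J) and, for V genes, the FR1 boundary. Rather than bundling a
curated species reference, these are carried as `key=value` tokens in the
FASTA header (`>name segment=V cdr3_anchor=288 fr1_end=75`), and a packaged
toy set (`toy_igh_v1`: 8 V, 4 J) supports simulation and testing. Toy V
genes are 97 random non-stop codons ending in TGT, regenerated until every
pair is < 90% identical so that gene assignment stays unambiguous at the
mutation loads simulated here; real-data users must supply their own
annotated reference in this dialect. The CDR3 is defined IMGT-style as the
codons strictly between the two anchor codons.

## Read QC

Mates are merged over the highest-scoring ungapped overlap (match +1,
mismatch −1, `N` neutral; ties resolved toward the longer overlap) of
length ≥ 20 with mismatch fraction ≤ 0.1; within the overlap each base is
taken from the mate with higher quality, retaining that quality (ties
favour mate 1). The quality rules then apply in a fixed order: (1) reads
with arithmetic-mean Phred < 30 are removed (exactly 30.0 is kept; the mean
is taken on integer scores, not error probabilities); (2) bases with
quality < 30 are masked to `N` (Q30 untouched); (3) reads with more than
10 `N`s are removed (exactly 10 is kept). Pre-existing `N`s count toward
the limit — the conservative reading. Masking never changes length and is
idempotent; whether mean quality is assessed before or after masking is a
genuine ambiguity, resolved here as mean-first and fixed in code.

## Annotation and SHM

Gene assignment aligns each candidate germline against the merged read with
free end gaps, scored match +1 / mismatch −1 / gap open −4 / extend −1;
`N` scores 0 against everything, since a masked base carries no evidence.
The best score wins, ties break lexicographically by gene name, and a best
score below 40 (≈ 40 net matching bases, far above the free-end-gap optimum
of an unrelated sequence, far below any true V hit) renders the sequence
unassignable. SHM is 100 × mismatches / compared positions over aligned V
positions in `[fr1_end, cdr3_anchor)` — FR1 is excluded because the primer
sits there and would deflate apparent mutation; `N` positions are excluded
from numerator and denominator, and zero comparable positions yields an
undefined-SHM outcome that excludes (and counts) the sequence. Whether the
denominator should further exclude CDR1/CDR2 is not fixed by the contract;
the whole FR1-trimmed V up to the CDR3 anchor is used. Identical
post-masking, FR1-trimmed nucleotide strings collapse into one unique
rearrangement whose `duplicate_count` conserves the read count; exact
string equality is the reproducible collapse criterion. D-segment calls are
deliberately absent — the clone definition below never uses them.

## Clonal inference

Within a subject (across its tissues jointly), productive rearrangements
are binned by (V gene, J gene, CDR3 amino-acid length) and each bin is
clustered on CDR3 identity, defined as 1 − Hamming distance / length on the
equal-length amino-acid strings; identity exactly 0.85 links. Single
linkage — the transitive closure of the ≥ 0.85 graph — is the default: a
lineage under ongoing SHM forms a ladder of variants whose extremes may
fall below threshold while adjacent rungs do not, and single linkage keeps
such ladders whole. It also admits an exact independent oracle (connected
components by exhaustive pairwise comparison), which the tests exploit.
Complete linkage is available (`method="complete"`, via scipy) for users
who prefer conservative clones. Members are sorted by `sequence_id` before
clustering and clone ids are assigned in sorted (subject, V, J, length,
representative CDR3) order, so the partition and the ids are invariant to
input order. A clone's SHM is the copy-weighted mean Σ(shmᵢ·cᵢ)/Σ(cᵢ) over
its unique members.

## Clone filtering and overlap statistics

The 50% mcf filter removes, per subject, clones with total copies strictly
below `fraction × mean(clone copies)`; equality is kept and `fraction=0` is
the identity. "Mean copy-number frequency" is read as the mean clone copy
number; dividing both sides by the subject's total copies shows the
frequency reading selects the identical set. Overlap between two samples is
the Jaccard index over clone-presence sets (presence = any copies in the
sample); an empty union is reported as 0 and flagged. Within-subject pairs
use the subject's own clones. Between-subject pairs pool the two subjects'
filtered rearrangements and re-cluster them jointly under the same
definition — clones are subject-scoped objects, and comparing relation
types on equal footing requires one consistent clone definition across the
pooled data. The presence matrix restricts to clones found in ≥ 2 samples
(rows ordered by sample support, then copies); a `mode="cdr3"` switch
groups rows by exact CDR3 amino-acid string instead, since "shared
sequence" can reasonably be read at either level. Tissue-stratified SHM
histograms recompute each clone's copy-weighted SHM from that tissue's
members only, so tissue-spanning clones contribute tissue-specific values
rather than a blurred global mean.

## Simulator

The generator emulates the assumed study design: `n_subjects` subjects,
two tissues (`BM`, `siLP`), `clones_per_sample` clones per tissue. Per
subject, Binomial(N, `sharing_fraction`) clones are founded once and
placed in both tissues (independent SHM variants per tissue); the rest are
tissue-private. Each founder draws a V and J uniformly, plus a random
in-frame stop-free junction of 8–22 codons (uniform — no empirical length
distribution is imposed). Unique sequences per clone and copies per unique
sequence are geometric with mean 3 — heavy-tailed enough that the mcf
filter has real work to do. SHM applies independent per-base substitutions
at `shm_rate` across the V region including FR1 but sparing the anchor
codon, and by default sparing the CDR3 so that simulated clone identity is
never destroyed (`mutate_cdr3=True` exists to stress clustering).
Truth SHM is recorded over the measured window `[fr1_end, cdr3_anchor)`
(213 nt in the toy V genes), making the expected truth SHM exactly
100·`shm_rate`. Read pairs cover the amplicon from both ends at
`read_length` 300 nt, giving 180–220 nt overlaps at the simulated amplicon
lengths (363–405 nt); per-base sequencing errors at `read_error_rate`, a
`frac_low_quality_reads` fraction of reads drawn entirely below Q30
(removed by rule 1), and a `low_quality_base_rate` sprinkling of sub-Q30
bases in otherwise good reads (exercising masking). Read ids embed the
truth key `subject|sample|clone|seq/copy`, so recovery is scored by exact
join rather than heuristics. Defaults (4 subjects, 100 clones/sample, 20%
sharing, 2% SHM) describe a plausible murine IgA plasma-cell experiment.

What the simulator does *not* model — PCR amplification bias, chimeras,
indel SHM, isotype switching, shared public clones beyond the optional
`between_subject_sharing` hook, and empirical CDR3 length/gene-usage
distributions — bounds what passing tests show: the pipeline's rules and
estimators are exact on data obeying its assumptions, not that real
repertoires obey them.

## Numerical and degenerate-case conventions

Probabilities validated into [0, 1] at construction; sharing with a single
sample per subject is rejected as impossible. Empty inputs yield empty
outputs and zeroed summaries, exit 0. Mixed CDR3 lengths inside a bin are
an internal error (the partition contract guarantees against it).
Translation maps `N`-containing codons to `X` (counted as mismatch in CDR3
identity) and stops to `*` (non-productive if in frame). All stochastic
components take explicit integer seeds; fixed seed implies byte-identical
FASTQ and identical tables.

## Verification problem sizes

The test and acceptance runs use an 8-subject × 2-tissue × 100-clone
end-to-end simulation with error-free reads for exact clonal recovery
(adjusted Rand index 1.0, 100% gene-call accuracy, ~4,700 unique
rearrangements), 4 subjects × 200 clones/sample for the Jaccard estimator
checks against s/(2 − s) at s ∈ {0, 0.25, 0.5, 1} (tolerance three binomial
standard errors via the delta method; the estimator is exactly the truth
Jaccard per subject, and the residual spread is the Binomial(N, s) draw
itself, plus a small Jensen excess since m/(2N − m) is convex in m), 500
random bins of ≤ 30 members against the brute-force clustering oracle, and
a 1,000-read engineered-quality fixture against the hand-applied QC rules.
These sizes give sub-percent standard errors on every stochastic check
while keeping a full run in minutes on one core.

## Known limitations

The aligner is exhaustive over the germline set — appropriate for
toy-scale references, quadratic-cost naive for the hundreds of alleles of a
full species reference (no k-mer pre-filter). Gene calls are gene-level,
not allele-level. The QC merge is ungapped, so indel sequencing errors in
the overlap defeat it. Between-subject overlap re-clusters pooled subjects
pairwise, which can in principle assign the same rearrangement different
clone boundaries in different pairings (single linkage is monotone under
pooling, so presence can only merge, not split). SHM is substitution-only
throughout.
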