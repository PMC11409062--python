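# Methods

## Problem and model

Early single-molecule protein sequencers will not read an amino-acid
sequence cleanly. Whatever the physics (nanopore currents, fluorescent
labels, Raman spectra), a realistic abstraction of the decoded output for
one molecule is a 20×L matrix of per-position posterior probabilities over
the amino-acid alphabet: partial, noisy, possibly restricted to a few
detectable residue types, and corrupted by column insertions and
deletions. `protident` asks the identification question — *which protein in
a known database produced this readout?* — rather than the harder de novo
question.

The method turns the search around relative to classical profile
annotation: the **readout is the query profile**, and the database proteins
are the targets. Each readout column becomes one match state of a
left-to-right profile HMM whose emission distribution is the posterior
column itself. Insert and delete states at every position absorb the
device's indel errors. Every database sequence is scored with the Forward
algorithm as a log-odds ratio against an i.i.d. background null model, and
the top-scoring sequence is the identification.

## The simulated device

* **Signal quality `p_max`** ∈ [0.05, 1]: posterior assigned to the true
  residue; the remaining mass is split equally over the other 19. At
  `p_max = 1/20` every column is uniform (the device conveys nothing); the
  implementation special-cases this value so the column is *exactly*
  uniform in floating point. `p_max` is constant along a readout — real
  devices will have position-dependent quality, which we do not model.
* **Detection set**: residues the device can discriminate. Residues outside
  the set yield uniform columns. Presets studied: the five most abundant
  residues in a human-like proteome (L,S,E,A,G), the five least abundant
  (W,M,C,H,Y), and the conveniently labellable C,Y,K.
* **Indel errors**: exact-count processes, not per-position coin flips. For
  rates (i, d) on a length-L readout, `round(d·L)` columns are deleted at
  uniformly chosen distinct positions, **then** `round(i·L)` columns are
  inserted at uniformly chosen gaps (with replacement), so insertions are
  never themselves deleted. Counts round half away from zero. Each inserted
  column is the posterior column of a uniformly drawn amino acid under the
  same device configuration — the device "sees" a spurious residue. The
  distribution of spurious columns is a modelling choice; it matches the
  worked example in which an inserted column suggests a concrete residue.
* **Fragments**: fixed-length windows with uniformly random starts,
  independent draws with replacement across repetitions; a protein shorter
  than the window contributes its full sequence.

## Scoring model

Transitions out of every match state are fixed a priori: M→M = 0.8,
M→I = M→D = 0.1 — permissive enough for indels while preferring matches.
Insert/delete continuations default to I→M = D→M = 0.9, I→I = D→D = 0.1
and are configurable when device error rates are known. Insert states emit
at background frequencies, so they are log-odds-neutral per residue.

**Alignment mode.** Default is glocal over the query and local over the
target: a readout is one complete sequenced molecule, so every readout
column must be matched or deleted, but a fragment may originate anywhere
inside a protein, so unaligned target residues are absorbed by flanking
states at zero log-odds cost (their emission and self-transition terms
cancel against the null model, making scores comparable across target
lengths). A local-query mode (uniform entry/exit over columns) is available
behind a flag for sensitivity analysis.

**Boundary conditions.** Entry into the first match state and exit from the
last are free (odds 1); entering through a leading delete chain costs
t_MD·t_DD^(k−1)·t_DM for k skipped columns, and symmetrically for trailing
deletes. These begin/end delete "wings" are folded into per-column entry and
exit weights (wing retraction), which excludes the degenerate alignment
using no match state at all. The boundary is therefore deliberately not a
normalized probability distribution — it is a scoring convention chosen so
that a one-state profile with emission 1 on the target's residue scores
exactly log2(1/background), and so boundary columns are not penalized
relative to interior ones.

**Numerics.** The DP runs in linear odds space with adaptive rescaling
(checked every 16 target rows, rescaled outside ~[2^-266, 2^266]) and takes
a single log at the end; scores are reported in bits. Zero-probability
emissions (e.g. `p_max = 1`) stay exact zeros — never smoothed, since
smoothing would change the perfect-signal semantics; a target with no
positive-probability alignment scores −∞. Forward and Viterbi are verified
against an independent exhaustive path-enumeration oracle on profiles of ≤5
match states and targets of ≤6 residues, to an absolute tolerance of 1e-9
bits. Kernels are JIT-compiled (numba) and bit-reproducible for fixed
inputs; database scoring is independent of evaluation order.

**Ranking and ties.** Targets are ranked by full-sequence Forward bits
(Viterbi is available but not used for ranking). Ties are broken by
lexicographically smallest accession and flagged; when the truth is known,
a tie resolved away from it counts as incorrect, so reported accuracies are
conservative. Multi-fragment identification sums each target's bits over
the fragment readouts of a molecule before the argmax — no per-fragment
normalization, mirroring plain score addition.

## Evaluation harness

For each protein of a database, a condition run simulates readout(s),
scores the whole database, and infers the source. Accuracy is the fraction
of proteins whose top hit is their true source; multi-fragment conditions
report both the per-fragment accuracy (mean over the repetitions) and the
combined accuracy. Uncertainty is a percentile bootstrap over proteins
(1000 resamples, 95% level, seeded). Conditions where scores tie are
surfaced via a tie fraction rather than silently credited through the
tie-break. Per-protein RNG substreams derive from (condition seed,
CRC32(accession)), so results are identical regardless of iteration order
or parallel partitioning; sweeps persist one TSV row per condition and skip
completed grid points on rerun.

## Synthetic databases

`generate_database` draws i.i.d. sequences from a configurable residue
background; the `human-like` preset is a fixed 20-vector approximating the
human proteome composition (top five L,S,E,A,G; bottom five W,M,C,H,Y), and
the default length distribution is log-normal with median 411 residues
(σ = 0.55, a realistic spread for a curated proteome) — so reduced-alphabet
and length experiments behave qualitatively like a real database without
any download. Curation of real FASTA databases maps U→C and O→K, drops
records with other non-canonical letters, and removes sequences whose
length is strictly above the 99th percentile (linear interpolation between
order statistics). Curation is defined against the original length
distribution: re-curating an already-curated database is a no-op, making
the operation idempotent (recomputing the percentile on the truncated
distribution would keep shaving the tail).

**What the generator does not model.** Real proteomes contain paralog
families, repeats and shared domains; i.i.d. sequences are essentially
mutually random, so identification on synthetic databases is easier than on
a real proteome wherever confusability between related sequences matters.
Two consequences observed in the test suite, both measured and left as
documented failures rather than adjusted away:

* 5-residue fragments identify ~90% of proteins in a 300-sequence synthetic
  database, whereas on a 20 000-protein real database most 5-mers occur in
  many proteins (≈4.8M windows vs 20⁵ = 3.2M possible 5-mers) and accuracy
  collapses to near chance. The collapse is a property of database scale,
  not of the method.
* At 60%/60% indel rates on full-length readouts, accuracy remains ≈0.9+ on
  synthetic databases of a few hundred (and ~0.9 at n = 2000); breakdown on
  our databases occurs around 70–80% error rates. The reported collapse at
  60% on a full-scale real proteome reflects both its size and its homology
  structure.

## Parameter summary

| parameter | default | meaning |
|---|---|---|
| `p_max` | — | posterior on the true residue, ∈ [0.05, 1] |
| `detection_set` | all 20 | residues the device discriminates |
| `insertion_rate`, `deletion_rate` | 0 | exact-count column indel rates (fractions of pre-error length) |
| `t_mm`, `t_mi`, `t_md` | 0.8, 0.1, 0.1 | match-state transitions |
| `t_im`/`t_ii`, `t_dm`/`t_dd` | 0.9/0.1 | insert/delete continuations |
| fragment `length`, `n_fragments` | — | window size (residues), repetitions per protein |
| bootstrap `n_boot`, `level` | 1000, 0.95 | percentile bootstrap settings |
| curation `percentile` | 0.99 | length cut, strict inequality |

## Problem sizes used in the checks

The bundled verification runs use synthetic databases of 200–500 sequences
with lengths uniform in 80–400 residues (and a 50-sequence toy set for the
cross-engine comparison) — sizes chosen so the full simulate–search–evaluate
loop runs on a single CPU while still exercising hundreds of thousands of
profile–target alignments per condition. The `scripts/acceptance.py` report
uses databases of 200–300 sequences under the same conditions.

## HMMER3 interoperability

`write_hmmer3_profile` emits a HMMER3/f ASCII profile (match emissions =
−ln posterior, insert emissions = background, the transition table above,
'*' for exact zeros, generic score-distribution STATS constants) so an
external `hmmsearch`/pyhmmer can consume the same query profiles with the
composition-bias filter disabled. The external engine applies its own
multihit local configuration, so absolute bit scores differ from the
internal engine by design; agreement is checked at the level of top-hit
identity. E-value calibration, MSV/bias heuristics and multihit
architecture are intentionally out of scope internally.

## Known limitations

* No open-set rejection: every readout is assigned its best hit even if the
  source is absent from the database (a bit-score threshold would be the
  natural extension).
* Constant `p_max` and uniformly placed indels; no position-dependent error
  structure.
* Synthetic databases carry no homology structure (see above), so absolute
  accuracies at small n overstate performance on real proteomes for
  conditions near the discrimination limit.
* The begin/end scoring convention is a documented improper normalization;
  scores are comparable across targets but are not literal probabilities.
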