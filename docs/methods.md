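# Methods

## Structure model

A secondary structure of a sequence of length *n* is a set of base pairs
(i, j), 1 ≤ i < j ≤ n, such that every position occurs in at most one
pair, no two pairs cross (pseudoknot-free), every hairpin loop encloses at
least three unpaired residues (j − i ≥ 4), and every pair is canonical:
A-U/A-T and G-C, plus the G-U/G-T wobble pair unless disabled. Lonely
(isolated, unstacked) pairs are permitted by default; a
`no_lonely_pairs` flag exists on the energy model and is honoured by
structure validation and by the enumeration oracle, while the
dynamic-programming engines raise `NotImplementedError` for it — the
no-lonely-pairs grammar roughly doubles the recursion state and nothing
in the desk-scale analyses needs it.

RNA and DNA are distinct, validated alphabets connected by a lossless
T↔U transliteration; folding treats them identically except for the
parameter table. Coordinates are 1-based inclusive everywhere; only file
writers convert.

## Energy models

**TOY** (default for all oracle work): each pair contributes a fixed
energy — G-C −3.0, A-U −2.0, G-U −1.0 kcal/mol — and loops are free. A
structure's energy is a plain sum over its pairs, so any independent
re-summation can check any engine to machine precision, and the whole
test suite stays self-contained.

**NEAREST_NEIGHBOR**: a loop-decomposition model. The energy of a
structure is the sum over its loops: stacked pairs score a
sequence-dependent stack term; hairpin, bulge and internal loops score a
length-dependent initiation penalty, extrapolated beyond the table with
the Jacobson–Stockmayer term 1.75·RT·ln(n/n_max); multiloops score an
affine a + b·(branches) + c·(unpaired) (defaults 3.4, 0.4, 0.0
kcal/mol); the external loop is free. Parameter tables load from small
whitespace-delimited files; the bundled defaults carry the published
Watson–Crick stack values for RNA (Turner/Xia) and DNA (unified
SantaLucia), approximate wobble-stack entries for RNA, and neutral
(0 kcal/mol) placeholders for DNA G-T stacks. Dangling ends, terminal
A-U penalties, tetraloop bonuses, loop-mismatch terms and coaxial
stacking are deliberately omitted. Consequences: predicted free energies
are systematically less detailed than a full Turner-model tool's, so
absolute energies and finely balanced shape probabilities of real
sequences should be treated as approximate; shape-level qualitative
behaviour is the supported use.

Temperature defaults to 310.15 K (37 °C), configurable; RT = R·T with
R = 1.9872 cal/(mol·K).

## Three routes over one structure space

1. **Exhaustive enumeration** (sequences ≤ 30 nt by default): every
   structure generated exactly once by interval recursion; exact
   Boltzmann probabilities follow by direct summation. This is the oracle
   every other route is tested against.
2. **Dynamic programming.** The TOY model uses a Nussinov/McCaskill-style
   interval recursion (first position unpaired, or paired with a
   partner), with no interior-loop size cap, so it covers the full
   structure space exactly. The nearest-neighbor model uses a
   Zuker/McCaskill-style recursion (paired-interval array V, multiloop
   arrays WM/WM1, external prefix array) with the conventional
   interior-loop size cap of 30 unpaired residues. Both run in log space
   and are numerically stable to at least 250 nt (the largest default
   window). Partition function and minimum free energy share the same
   recursions with (log-sum-exp, +) replaced by (min, +).
3. **Stochastic backtracking**: exact Boltzmann samples drawn by
   backtracking the partition-function tables; identical seed and inputs
   give identical samples.

MFE tie-break: among co-optimal structures the backtrack prefers pairing
over leaving a position unpaired, then the smallest partner index. This
is deterministic and reproducible but not guaranteed to return the
lexicographically smallest co-optimal dot-bracket; energies are
unaffected.

## Abstract shapes

A helix is a maximal run of stacked pairs (i, j), (i+1, j−1), …; a bulge
or internal loop terminates it. Level-1 shapes render, 5'→3', each
maximal helix as one `[`/`]` pair and each maximal unpaired run as `_`.
Level-5 shapes keep only helix nesting and adjacency: in the helix
nesting forest, every chain of parents with exactly one child (helices
separated only by bulges/internal loops) contracts to a single helix,
and unpaired runs are dropped. The open chain is `_` at both levels, so
unpairable sequences have a well-defined point distribution. Levels 2–4
of the general abstraction hierarchy are out of scope. Every level-1
shape contracts to exactly one level-5 shape, which yields the exact
aggregation identity the tests verify. Shape strings are spaceless
internally; the display form `[ ][ ]` is produced by a pretty-printer and
accepted on input.

Shape distributions are computed exactly (enumeration) for sequences
under the cutoff, or as empirical frequencies of a Boltzmann sample with
per-shape standard error √(p̂(1−p̂)/n); sampling requires n ≥ 100. The
shape-indexed dynamic programming of the general abstraction framework
(computing shape probabilities without sampling at any length) is not
implemented; enumeration plus sampling covers every analysis here, and
sampled distributions are complete by construction, which the SPS
contract requires — any future truncated-list method must pool residual
mass into an explicit remainder class first.

## The SPS statistic and the scan

SPS(A, B) = 1 − Σ_p min(P_A(p), P_B(p)), computed in its half-L1 form
½·Σ_p |P_A(p) − P_B(p)| over the sorted union of shapes so that identity
(SPS(A,A) = 0) and symmetry hold exactly in floating point. Both
distributions must share the shape level and have unit mass (tolerance
1e−6).

The scan evaluates the SPS for every window that contains the variant,
lengths from `min_len` (default 20 — the smallest window in which the
shape abstraction is meaningfully non-trivial; the referenced maximum of
250 bp is the only stated bound) to `max_len` (default 250). Windows not
containing the variant are excluded: the statistic compares a sequence
with its SNP version and is undefined without the site. Each window
folds both alleles; distributions are exact when the window fits under
the enumeration cutoff (beware: enumeration of G/C-rich windows near the
30 nt cutoff can be slow — force `method="sampled"` there), sampled with
n per allele (default 1000, giving binomial noise on the SPS of roughly
≤ 0.02) otherwise. Per-window, per-allele seeds derive deterministically
from (scan seed, window length, window offset, allele index) via
`numpy.random.SeedSequence`, so any window is recomputable in isolation
and reruns are byte-identical. The grid summary reports mean, max and the
argmax window with ties broken toward the smallest length, then the
smallest offset. DNA mode is the identical contract with a DNA-alphabet
sequence and DNA parameter table, for analyses of the amplified cDNA
rather than the transcript.

Primer-site accessibility of a structure is the fraction of
primer-binding positions left unpaired — a direct readout of
intramolecular structure competing with primer annealing.

## Synthetic fixtures

The generator emulates the shape of the real problem — a hairpin that can
overlap a priming site, with a variant either disrupting it or not —
while staying exactly analysable. A construct is A-flank + G/C-random
5' arm + A-loop + complementary arm + A-flank: A runs cannot pair with
anything present (A pairs only U/T), so the planted stem is the only
stable element. Each draw is checked against the oracle: the planted
structure must be the unique energy minimum (verified by enumeration
under the cutoff, by DP-MFE equality above it, where uniqueness is not
checked); failing draws retry on a derived seed, at most 10 times, then
error — no silent nondeterminism. Default test-scale geometry is stem 6,
loop 4, flanks 5 (26 nt), chosen to sit comfortably under the
enumeration cutoff so every expected value is exact.

Stem-centre variants substitute A into a central arm position, breaking
one pair with an allele that cannot re-pair elsewhere. Loop and flank
variants must preserve unpairability; since any of C/G/U can in principle
pair with something in the construct, candidates are verified against the
exact oracle (construct-level SPS ≤ 0.05) and re-sited if they fail.
Fixture-oracle SPS values default to **level 1**, unlike the package-wide
default of level 5: breaking a single stem pair interrupts a helix
(a level-1 event) without changing the level-5 nesting topology, so
level 1 is where the planted signal lives by construction. What passing
these tests shows is that the machinery measures ensemble shifts
correctly; it does not show that the bundled nearest-neighbor tables
reproduce any particular published free energy, and real transcripts
have competing structure everywhere rather than a single planted hairpin.

## Numerical and interface choices

- Log-space throughout the ensemble code; log Z ≥ 0 always (the open
  chain contributes weight 1 at reference energy 0); DP vs enumeration
  agreement is asserted at 1e−9 relative on the partition function.
- Distribution orderings are deterministic: descending probability, ties
  lexicographic; representative (shrep) ties break by energy then
  lexicographic dot-bracket.
- FASTA auto-detection assigns RNA when a record contains neither U nor
  T (the package's primary mode); mixing U and T in one record is an
  error; templates must be unambiguous, IUPAC degeneracy is allowed in
  primers only, where ensemble folding is never applied.
- The amplicon includes both primer footprints, since the amplified
  product does.
- The minimal VCF reader takes SNV records only (CHROM as sequence id,
  first ALT), skipping others with a logged warning.
- CLI exit codes: 0 success, 1 usage/validation, 2 data error,
  3 internal. Outputs embed tool version, effective configuration, seeds
  and input digests.

## Known limitations

- The nearest-neighbor model's omissions (dangles, mismatches, terminal
  penalties, coaxial stacking) and its approximate wobble/placeholder
  entries mean published free energies from full Turner-parameter tools
  will not be matched number-for-number; the published rat *Kdm3a* shape
  and SPS values are reproduction targets only when the external
  transcript and figure-read alleles are supplied (see README), and
  agreement is expected at the shape level rather than in kcal/mol.
- The full-transcript scan (all windows to 250 bp over a multi-kilobase
  transcript) is an hours-scale computation at these implementation
  choices; analyses in this repository run at window and fixture scale,
  with problem sizes stated in the tests and acceptance script.
- Enumeration cost grows steeply with G/C content near the 30 nt cutoff.
- No pseudoknots, suboptimal structure lists, base-pair probability
  matrices, indels/multi-nucleotide variants, primer thermodynamics or
  significance testing for SPS values.
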