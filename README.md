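# spshift

Silent (synonymous) single-nucleotide variants cannot change a protein
sequence, but they can change how the transcript — or the cDNA made from
it — folds. A SNP that reshapes the structure around a qPCR priming site
can silently wreck amplification efficiency and distort expression
estimates; the same shift can, in principle, modulate translation. This
package scores that structural impact.

`spshift` implements probabilistic **abstract shape analysis** of
nucleic-acid secondary-structure ensembles and the **Shape Probability
Shift (SPS)** statistic. An abstract shape is an equivalence class of
secondary structures characterised by the arrangement of helices,
irrespective of helix lengths and sequence content — written like
`[ ][ ]` for two adjacent hairpins. Where the probability of any single
structure in the Boltzmann ensemble is negligibly small, the probability
mass of a dominant shape is large and interpretable.

For a sequence *A* and its SNP version *B*, with shape distributions
*P_A* and *P_B*, the statistic is

    SPS(A, B) = 1 − Σ_p min(P_A(p), P_B(p))

— half the L1 distance (total-variation distance) between the two
distributions. It lies in [0, 1], equals 1 exactly when the supported
shape sets are disjoint, and reads directly as *the overall probability
mass that moves between shapes* when the variant is introduced. Because
the folding unit around a variant is usually unknown, the package also
computes the SPS for **every sequence window containing the variant** (all
lengths up to 250 bp by default, all placements), giving a landscape of
structural impact plus a mean/max summary.

It is aimed at people designing or debugging qPCR assays over polymorphic
templates and at anyone triaging candidate riboSNitch-style variants:
input is a FASTA template, a variant (`SEQID:POSREF>ALT` or a minimal
VCF), and optionally a primer pair; RNA and DNA folding-parameter modes
are both available, since a cDNA amplicon folds as DNA.

## What is inside

- `spshift.seqvar` — sequences, point variants, IUPAC primers, amplicon
  location, window enumeration (1-based inclusive coordinates
  throughout).
- `spshift.folding` — pseudoknot-free structure model; a trivially
  re-summable per-pair ("toy") energy model and a nearest-neighbor
  loop-decomposition model with loadable parameter tables; exhaustive
  enumeration (exact oracle, short sequences), partition-function and MFE
  dynamic programming, Boltzmann sampling by stochastic backtracking.
- `spshift.shapes` — level-1 and level-5 shape mapping, shape
  distributions (exact or sampled) and per-shape MFE representatives
  ("shreps").
- `spshift.sps_scan` — the SPS statistic, the windowed SNP scan, DNA-mode
  scan, primer-site accessibility.
- `spshift.fixtures` — seeded synthetic hairpin constructs with planted
  variants and oracle-verified expected values.
- `spshift.cli` — the `spshift` command: `shapes`, `sps`, `scan`,
  `amplicon`, `fixtures`.

## Worked example

Generate a synthetic hairpin fixture with a planted stem-breaking variant,
then score it:

```sh
$ spshift fixtures --seed 11 --out fx
$ spshift sps fx.fasta hairpin_s6_l4_f5_seed11:8C>A --level 1
```

The fixture sidecar (`fx.json`) records the planted truth:

```json
{
  "sequence_id": "hairpin_s6_l4_f5_seed11",
  "planted_structure": ".....((((((....)))))).....",
  "variant": "hairpin_s6_l4_f5_seed11:8C>A",
  "oracle_sps": 0.9684835082615368
}
```

and the `sps` command reports (abridged):

```json
{
  "variant": "hairpin_s6_l4_f5_seed11:8C>A",
  "sps": 0.9684835082615368,
  "level": 1,
  "method_a": {"method": "exact_enum", "n": null}
}
```

SPS ≈ 0.97 means that breaking the central stem pair moves essentially
all of the ensemble mass to different shape classes — the C→A substitution
destroys a pair in the only stable helix, so the dominant one-hairpin
shape of the reference all but vanishes in the variant ensemble. The
26 nt construct is under the enumeration cutoff, so both distributions
are exact and the value is deterministic. A windowed scan of the same
variant,

```sh
$ spshift scan fx.fasta hairpin_s6_l4_f5_seed11:8C>A --level 1 \
      --min-len 20 --max-len 24 --out fxscan_
```

writes a long-format TSV of all 25 variant-containing windows and a JSON
summary with `mean_sps ≈ 0.968` and `max_sps ≈ 0.969` at window
(length 20, offset 7): the impact is high for every window that covers
the hairpin, exactly as planted. A flank variant on the same construct
scores ≤ 0.05 throughout.

For qPCR work, `spshift amplicon template.fasta --forward ... --reverse
... --variant ...` locates the primer footprints (IUPAC-aware, unique
match required), folds both alleles of the amplicon, and reports shape
tables, per-shape primer-site accessibility (fraction of primer-binding
positions left unpaired), and the amplicon SPS.

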