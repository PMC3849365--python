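"""Seeded synthetic sequences, hairpin constructs and planted variants.

These generators stand in for real transcripts and amplicons so the whole
pipeline is testable without any download. The key construct is a single
hairpin with G/C-rich arms, an all-A loop and all-A flanks: under
canonical(+wobble) pairing rules A runs cannot pair with anything in the
construct, so the planted stem is (after a uniqueness check against the
folding oracle) the unambiguous minimum-free-energy structure, and exact
expected values for shape and SPS analyses are computable by enumeration.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np

from .errors import DataError, InputError
from .folding import (ENUMERATION_CUTOFF, EnergyModel, SecondaryStructure,
                      enumerate_structures, mfe_structure, structure_energy)
from .seqvar import Alphabet, NucleicSequence, PointVariant, write_fasta
from .shapes import shape_distribution, shape_of
from .sps_scan import sps

_MAX_RETRIES = 10


class VariantSite(str, Enum):
    STEM_CENTER = "stem_center"
    LOOP = "loop"
    FLANK = "flank"


def random_sequence(length: int, gc_fraction: float,
                    alphabet: Alphabet = Alphabet.RNA,
                    seed: int = 0, id: str | None = None) -> NucleicSequence:
    """Seeded i.i.d. random sequence with expected GC content."""
    if length < 1:
        raise InputError("length must be >= 1")
    if not 0.0 <= gc_fraction <= 1.0:
        raise InputError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    at = "AU" if alphabet is Alphabet.RNA else "AT"
    letters = ["G", "C", at[0], at[1]]
    p = [gc_fraction / 2, gc_fraction / 2,
         (1 - gc_fraction) / 2, (1 - gc_fraction) / 2]
    residues = "".join(rng.choice(letters, size=length, p=p))
    return NucleicSequence(id or f"random_L{length}_s{seed}", residues, alphabet)


@dataclass(frozen=True)
class HairpinConstruct:
    """A sequence with one planted hairpin: A-flank + G/C arm + A-loop +
    complementary arm + A-flank."""

    sequence: NucleicSequence
    structure: SecondaryStructure
    stem_len: int
    loop_len: int
    flank_len: int
    seed: int

    @property
    def stem5_range(self) -> tuple:
        start = self.flank_len + 1
        return (start, start + self.stem_len - 1)

    @property
    def loop_range(self) -> tuple:
        start = self.flank_len + self.stem_len + 1
        return (start, start + self.loop_len - 1)

    @property
    def flank_range(self) -> tuple:
        if self.flank_len == 0:
            raise DataError("construct has no flank")
        return (1, self.flank_len)


_COMPLEMENT = {"G": "C", "C": "G"}


def hairpin_construct(stem_len: int, loop_len: int, flank_len: int = 0,
                      seed: int = 0,
                      alphabet: Alphabet = Alphabet.RNA,
                      model: EnergyModel | None = None) -> HairpinConstruct:
    """Generate a hairpin construct whose planted stem is the unique MFE
    structure under the given model (TOY by default).

    Seeds are retried (bounded) when a draw admits an alternative
    equal-energy folding, e.g. a self-complementary arm.
    """
    if stem_len < 2:
        raise InputError("stem_len must be >= 2")
    if loop_len < 3:
        raise InputError("loop_len must be >= 3 (minimum hairpin loop)")
    if flank_len < 0:
        raise InputError("flank_len must be >= 0")
    model = model or EnergyModel.toy(alphabet)
    a = "A"
    for attempt in range(_MAX_RETRIES):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt]))
        arm5 = "".join(rng.choice(["G", "C"], size=stem_len))
        arm3 = "".join(_COMPLEMENT[c] for c in reversed(arm5))
        residues = a * flank_len + arm5 + a * loop_len + arm3 + a * flank_len
        seq = NucleicSequence(
            f"hairpin_s{stem_len}_l{loop_len}_f{flank_len}_seed{seed}",
            residues if alphabet is Alphabet.RNA else residues.replace("U", "T"),
            alphabet)
        total = stem_len
        first = flank_len
        last = flank_len + 2 * stem_len + loop_len
        pairs = tuple((first + k, last - k + 1) for k in range(1, total + 1))
        planted = SecondaryStructure(len(seq), tuple(sorted(pairs)))
        if _planted_is_unique_mfe(seq, planted, model):
            return HairpinConstruct(seq, planted, stem_len, loop_len,
                                    flank_len, seed)
    raise DataError(
        f"no unique-MFE hairpin found in {_MAX_RETRIES} attempts for "
        f"stem={stem_len} loop={loop_len} flank={flank_len} seed={seed}")


def _planted_is_unique_mfe(seq: NucleicSequence, planted: SecondaryStructure,
                           model: EnergyModel) -> bool:
    target = structure_energy(planted, seq, model)
    if len(seq) <= ENUMERATION_CUTOFF:
        structures = enumerate_structures(seq, model)
        minima = [s for s in structures
                  if structure_energy(s, seq, model) <= target + 1e-9]
        return len(minima) == 1 and set(minima[0].pairs) == set(planted.pairs)
    mfe, energy = mfe_structure(seq, model)
    return set(mfe.pairs) == set(planted.pairs) and abs(energy - target) < 1e-9


def construct_sps(construct: HairpinConstruct, variant: PointVariant,
                  model: EnergyModel | None = None, level: int = 1,
                  n: int = 2000, seed: int = 0) -> float:
    """Oracle SPS of a variant over the whole construct: exact when the
    construct fits under the enumeration cutoff, sampled otherwise.

    Level 1 is the default here (unlike the rest of the package, which
    defaults to level 5): breaking a single stem pair interrupts a helix
    but does not change the level-5 nesting topology, so the planted
    stem-disruption signal is a level-1 phenomenon by construction.
    """
    from .seqvar import apply_variant

    model = model or EnergyModel.toy(construct.sequence.alphabet)
    seq = construct.sequence
    alt = apply_variant(seq, variant)
    method = "exact_enum" if len(seq) <= ENUMERATION_CUTOFF else "sampled"
    dist_a = shape_distribution(seq, model, level=level, method=method,
                                n=n, seed=seed)
    dist_b = shape_distribution(alt, model, level=level, method=method,
                                n=n, seed=seed + 1)
    return sps(dist_a, dist_b).value


def plant_snp(construct: HairpinConstruct, site: VariantSite,
              model: EnergyModel | None = None,
              max_neutral_sps: float = 0.05) -> PointVariant:
    """Plant a substitution at the requested site class.

    STEM_CENTER breaks a central stem pair (G or C -> A, which cannot pair
    with anything in the construct). LOOP/FLANK substitutions must preserve
    unpairability; candidate alleles and positions are verified against the
    folding oracle and re-sited if the ensemble shifts by more than
    ``max_neutral_sps``.
    """
    model = model or EnergyModel.toy(construct.sequence.alphabet)
    seq = construct.sequence
    if site is VariantSite.STEM_CENTER:
        lo, hi = construct.stem5_range
        pos = (lo + hi) // 2
        ref = seq.residue(pos)
        return PointVariant(seq.id, pos, ref, "A")
    if site is VariantSite.LOOP:
        lo, hi = construct.loop_range
    elif site is VariantSite.FLANK:
        if construct.flank_len == 0:
            raise DataError("construct has no flank to mutate")
        lo, hi = construct.flank_range
    else:
        raise InputError(f"unknown variant site {site}")
    u_or_t = construct.sequence.alphabet.u_or_t
    positions = sorted(range(lo, hi + 1), key=lambda p: (abs(p - (lo + hi) // 2), p))
    for pos in positions:
        for alt in ("C", "G", u_or_t):
            ref = seq.residue(pos)
            if alt == ref:
                continue
            variant = PointVariant(seq.id, pos, ref, alt)
            if construct_sps(construct, variant, model) <= max_neutral_sps:
                return variant
    raise DataError(
        f"no unpairability-preserving substitution found in {site.value} of "
        f"{seq.id}")


def emit_fixture(construct: HairpinConstruct, variant: PointVariant,
                 prefix: str | Path,
                 model: EnergyModel | None = None) -> dict:
    """Write the construct as FASTA plus a sidecar JSON of planted truth
    (structure, variant, oracle shape and SPS values). Returns the sidecar."""
    model = model or EnergyModel.toy(construct.sequence.alphabet)
    prefix = Path(prefix)
    write_fasta([construct.sequence], prefix.with_suffix(".fasta"))
    sidecar = {
        "sequence_id": construct.sequence.id,
        "alphabet": construct.sequence.alphabet.value,
        "planted_structure": construct.structure.dot_bracket,
        "planted_shape_level5": shape_of(construct.structure, 5),
        "planted_energy": structure_energy(construct.structure,
                                           construct.sequence, model),
        "stem_len": construct.stem_len,
        "loop_len": construct.loop_len,
        "flank_len": construct.flank_len,
        "seed": construct.seed,
        "variant": variant.spec(),
        "oracle_sps": construct_sps(construct, variant, model),
        "model": model.describe(),
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")
    return sidecar
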