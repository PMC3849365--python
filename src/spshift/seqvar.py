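"""Sequences, point variants, primers, amplicons and scan windows.

Coordinates are 1-based and inclusive throughout the package; conversion to
half-open intervals happens only inside file writers. RNA and DNA are kept
as distinct alphabets with a lossless T<->U transliteration; templates must
be unambiguous (no IUPAC degeneracy), primers may use IUPAC codes.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .errors import DataError, InputError

log = logging.getLogger(__name__)


class Alphabet(str, Enum):
    RNA = "rna"
    DNA = "dna"

    @property
    def letters(self) -> frozenset:
        return _RNA_LETTERS if self is Alphabet.RNA else _DNA_LETTERS

    @property
    def u_or_t(self) -> str:
        return "U" if self is Alphabet.RNA else "T"


_RNA_LETTERS = frozenset("ACGU")
_DNA_LETTERS = frozenset("ACGT")
# IUPAC codes legal in primers (nucleotide codes only, T/U interchangeable)
_IUPAC_DNA = frozenset(ambiguous_dna_values)  # ACGT + RYSWKMBDHVN


@dataclass(frozen=True)
class NucleicSequence:
    """A validated, unambiguous nucleic-acid sequence."""

    id: str
    residues: str
    alphabet: Alphabet

    def __post_init__(self) -> None:
        if not self.residues:
            raise InputError(f"sequence {self.id!r}: length must be >= 1")
        bad = [(i + 1, c) for i, c in enumerate(self.residues)
               if c not in self.alphabet.letters]
        if bad:
            pos, char = bad[0]
            raise InputError(
                f"sequence {self.id!r}: invalid {self.alphabet.value.upper()} "
                f"residue {char!r} at position {pos}")

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self):
            raise InputError(
                f"position {position} out of range 1..{len(self)} "
                f"for sequence {self.id!r}")
        return self.residues[position - 1]

    def subsequence(self, start: int, end: int, id: str | None = None) -> "NucleicSequence":
        """1-based inclusive slice."""
        if not (1 <= start <= end <= len(self)):
            raise InputError(
                f"region {start}..{end} outside sequence {self.id!r} "
                f"(length {len(self)})")
        return NucleicSequence(id or f"{self.id}:{start}-{end}",
                               self.residues[start - 1:end], self.alphabet)

    def transliterate(self, alphabet: Alphabet) -> "NucleicSequence":
        """Lossless T<->U conversion between the two alphabets."""
        if alphabet is self.alphabet:
            return self
        table = str.maketrans("TU", "UT")
        return NucleicSequence(self.id, self.residues.translate(table), alphabet)


@dataclass(frozen=True)
class PointVariant:
    """A single-nucleotide substitution in 1-based transcript coordinates."""

    seq_id: str
    position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        for name, allele in (("ref", self.ref_allele), ("alt", self.alt_allele)):
            if len(allele) != 1 or allele not in "ACGTU":
                raise InputError(f"{name} allele {allele!r} is not a single nucleotide")
        if self.ref_allele == self.alt_allele:
            raise InputError(
                f"variant at position {self.position}: ref and alt alleles "
                f"are both {self.ref_allele!r}")
        if self.position < 1:
            raise InputError(f"variant position {self.position} must be >= 1")

    @property
    def inverse(self) -> "PointVariant":
        return replace(self, ref_allele=self.alt_allele, alt_allele=self.ref_allele)

    def spec(self) -> str:
        return f"{self.seq_id}:{self.position}{self.ref_allele}>{self.alt_allele}"


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse primers, both written 5'->3'; IUPAC codes allowed."""

    forward: str
    reverse: str

    def __post_init__(self) -> None:
        for name, primer in (("forward", self.forward), ("reverse", self.reverse)):
            if len(primer) < 10:
                raise InputError(f"{name} primer {primer!r}: length must be >= 10")
            bad = [c for c in primer if c not in _IUPAC_DNA and c != "U"]
            if bad:
                raise InputError(
                    f"{name} primer {primer!r}: non-IUPAC character {bad[0]!r}")


@dataclass(frozen=True)
class AmpliconRegion:
    """PCR product span on a template, primer footprints included."""

    seq_id: str
    start: int
    end: int
    forward_site: tuple[int, int]
    reverse_site: tuple[int, int]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(f"amplicon start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True, order=True)
class Window:
    """A subsequence placement: 1-based start offset and length."""

    length: int
    offset: int

    @property
    def end(self) -> int:
        return self.offset + self.length - 1

    def contains(self, position: int) -> bool:
        return self.offset <= position <= self.end


# ---------------------------------------------------------------------------
# FASTA I/O


def _detect_alphabet(residues: str, seq_id: str) -> Alphabet:
    has_u = "U" in residues
    has_t = "T" in residues
    if has_u and has_t:
        raise DataError(f"sequence {seq_id!r} mixes U and T")
    if has_t:
        return Alphabet.DNA
    # neither U nor T is undecidable from content; RNA is the primary mode
    return Alphabet.RNA


def read_fasta(path: str | Path, alphabet: Alphabet | None = None) -> list[NucleicSequence]:
    """Read a (multi-)FASTA file into validated sequences.

    The alphabet may be declared by the caller or auto-detected per record
    from the presence of U versus T; a record mixing both is an error.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"FASTA file not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise DataError(f"FASTA file {path} contains no records")
    out = []
    for rec in records:
        residues = str(rec.seq).upper()
        ab = alphabet or _detect_alphabet(residues, rec.id)
        try:
            out.append(NucleicSequence(rec.id, residues, ab))
        except InputError as exc:
            raise DataError(str(exc)) from exc
    return out


def write_fasta(seqs: Iterable[NucleicSequence], path: str | Path) -> None:
    """Write sequences as FASTA with 60-column wrapping."""
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), 60):
                fh.write(seq.residues[i:i + 60] + "\n")


# ---------------------------------------------------------------------------
# Variant parsing and application

_VARIANT_RE = re.compile(r"^(?P<id>[^:]+):(?P<pos>\d+)(?P<ref>[ACGTU])>(?P<alt>[ACGTU])$")


def parse_variant_spec(spec: str) -> PointVariant:
    """Parse `SEQID:POSREF>ALT`, e.g. ``tx:2383C>A``."""
    m = _VARIANT_RE.match(spec.strip())
    if not m:
        raise InputError(
            f"variant spec {spec!r} does not match SEQID:POSREF>ALT "
            f"(e.g. tx:2383C>A)")
    return PointVariant(m["id"], int(m["pos"]), m["ref"], m["alt"])


def read_vcf(path: str | Path) -> list[PointVariant]:
    """Minimal VCF v4.2 reader: SNV rows only, CHROM taken as the sequence
    id, first ALT used, INFO/FORMAT ignored; non-SNV rows are skipped with a
    logged warning."""
    import pysam

    path = Path(path)
    if not path.exists():
        raise DataError(f"VCF file not found: {path}")
    variants = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if len(rec.ref) != 1 or not alts or len(alts[0]) != 1:
                log.warning("skipping non-SNV VCF record %s:%d %s>%s",
                            rec.chrom, rec.pos, rec.ref, ",".join(alts) or ".")
                continue
            variants.append(PointVariant(rec.chrom, rec.pos, rec.ref, alts[0]))
    return variants


def apply_variant(seq: NucleicSequence, var: PointVariant) -> NucleicSequence:
    """Return the SNP version of a sequence (the input is untouched)."""
    if var.seq_id != seq.id:
        raise InputError(
            f"variant names sequence {var.seq_id!r} but was applied to {seq.id!r}")
    if not 1 <= var.position <= len(seq):
        raise InputError(
            f"variant position {var.position} out of range 1..{len(seq)}")
    ref = var.ref_allele if seq.alphabet is Alphabet.DNA else var.ref_allele.replace("T", "U")
    alt = var.alt_allele if seq.alphabet is Alphabet.DNA else var.alt_allele.replace("T", "U")
    if seq.alphabet is Alphabet.DNA:
        ref, alt = ref.replace("U", "T"), alt.replace("U", "T")
    found = seq.residue(var.position)
    if found != ref:
        raise DataError(
            f"reference allele mismatch at {seq.id}:{var.position}: variant "
            f"says {ref!r} but sequence has {found!r} (wrong coordinates or strand?)")
    residues = seq.residues[:var.position - 1] + alt + seq.residues[var.position:]
    return NucleicSequence(f"{seq.id}|{var.position}{ref}>{alt}", residues, seq.alphabet)


# ---------------------------------------------------------------------------
# Reverse complement and primer placement


def reverse_complement(seq: NucleicSequence) -> NucleicSequence:
    """Standard reverse complement in the sequence's own alphabet."""
    if seq.alphabet is Alphabet.RNA:
        rc = str(Seq(seq.residues).reverse_complement_rna())
    else:
        rc = str(Seq(seq.residues).reverse_complement())
    return NucleicSequence(f"{seq.id}|rc", rc, seq.alphabet)


def reverse_complement_primer(primer: str) -> str:
    """Reverse complement of a 5'->3' primer string; IUPAC codes supported."""
    has_u = "U" in primer
    as_dna = primer.replace("U", "T")
    bad = [c for c in as_dna if c not in _IUPAC_DNA]
    if bad:
        raise InputError(f"primer {primer!r}: non-IUPAC character {bad[0]!r}")
    rc = str(Seq(as_dna).reverse_complement())
    return rc.replace("T", "U") if has_u else rc


def _iupac_regex(primer: str) -> re.Pattern:
    parts = []
    for c in primer.replace("U", "T"):
        expansion = ambiguous_dna_values[c]
        parts.append(c if len(expansion) == 1 else f"[{expansion}]")
    return re.compile("".join(parts))


def _find_sites(template_dna: str, primer: str) -> list[int]:
    """All 1-based start positions where a primer matches the sense strand."""
    pattern = _iupac_regex(primer)
    return [m.start() + 1 for m in pattern.finditer(template_dna)]


def locate_amplicon(template: NucleicSequence, primers: PrimerPair) -> AmpliconRegion:
    """Place a primer pair on a template and return the amplicon region.

    The forward primer must match the sense strand and the reverse primer
    the reverse complement of the template, each exactly once; the amplicon
    spans both primer footprints inclusively.
    """
    tmpl = template.residues.replace("U", "T")
    fwd_sites = _find_sites(tmpl, primers.forward)
    rev_sites = _find_sites(tmpl, reverse_complement_primer(primers.reverse))
    for name, sites, primer in (("forward", fwd_sites, primers.forward),
                                ("reverse", rev_sites, primers.reverse)):
        if not sites:
            raise DataError(
                f"{name} primer {primer!r} not found on template {template.id!r}")
        if len(sites) > 1:
            raise DataError(
                f"{name} primer {primer!r} matches template {template.id!r} at "
                f"{len(sites)} sites ({sites}): ambiguous assay")
    f_start = fwd_sites[0]
    f_end = f_start + len(primers.forward) - 1
    r_start = rev_sites[0]
    r_end = r_start + len(primers.reverse) - 1
    if r_start <= f_end:
        raise DataError(
            f"primer pair in wrong orientation on {template.id!r}: reverse "
            f"site {r_start}..{r_end} is not downstream of forward site "
            f"{f_start}..{f_end}")
    return AmpliconRegion(template.id, f_start, r_end,
                          forward_site=(f_start, f_end),
                          reverse_site=(r_start, r_end))


# ---------------------------------------------------------------------------
# Window enumeration for the SNP scan


def enumerate_windows(seq_len: int, focus_pos: int,
                      min_len: int = 20, max_len: int = 250) -> list[Window]:
    """All windows of length min_len..max_len that lie on the sequence and
    contain the focus position, ordered by length then offset."""
    if not 1 <= focus_pos <= seq_len:
        raise InputError(f"focus position {focus_pos} out of range 1..{seq_len}")
    if min_len > max_len:
        raise InputError(f"min_len {min_len} > max_len {max_len}")
    windows = []
    for length in range(min_len, min(max_len, seq_len) + 1):
        lo = max(1, focus_pos - length + 1)
        hi = min(focus_pos, seq_len - length + 1)
        for offset in range(lo, hi + 1):
            windows.append(Window(length=length, offset=offset))
    return windows
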