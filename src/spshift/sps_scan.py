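"""The Shape Probability Shift statistic and the windowed SNP scan.

For a sequence A and its SNP version B with shape distributions P_A and
P_B, the Shape Probability Shift is

    SPS(A, B) = 1 - sum_p min(P_A(p), P_B(p))

over the union of shapes p — half the L1 distance (the total-variation
distance) between the two distributions. It lies in [0, 1], is 0 iff the
distributions coincide, reaches 1 iff their supports are disjoint, and
reads as the overall probability mass that moves between shape classes
when the SNP is introduced.

Because the relevant folding unit around a SNP is usually unknown, the
scan evaluates the SPS for every window (length x offset) that contains
the variant, up to a maximum window length (default 250 bp). Windows that
exclude the variant are not scored: the statistic compares a sequence with
its SNP version and is undefined without the site.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, InputError
from .folding import ENUMERATION_CUTOFF, EnergyModel, SecondaryStructure
from .seqvar import (Alphabet, NucleicSequence, PointVariant, Window,
                     apply_variant, enumerate_windows)
from .shapes import ShapeDistribution, shape_distribution

log = logging.getLogger(__name__)

_MASS_TOL = 1e-6


@dataclass(frozen=True)
class SpsResult:
    """A single Shape Probability Shift value with method metadata."""

    value: float
    level: int
    method_a: dict = field(default_factory=dict)
    method_b: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise InputError(f"SPS value {self.value} outside [0, 1]")


def _method_meta(dist: ShapeDistribution) -> dict:
    return {"method": dist.method.value, "n": dist.n}


def sps(dist_a: ShapeDistribution, dist_b: ShapeDistribution) -> SpsResult:
    """Shape Probability Shift between two complete shape distributions."""
    if dist_a.level != dist_b.level:
        raise InputError(
            f"cannot compare shape levels {dist_a.level} and {dist_b.level}")
    for name, dist in (("A", dist_a), ("B", dist_b)):
        total = sum(dist.probs.values())
        if not math.isclose(total, 1.0, abs_tol=_MASS_TOL):
            raise InputError(
                f"distribution {name} mass {total} deviates from 1; "
                f"pool residual mass before computing the SPS")
    # half-L1 form of 1 - sum(min): exactly 0 for identical inputs; the
    # sorted union makes the summation order (hence rounding) symmetric
    shapes = sorted(set(dist_a.probs) | set(dist_b.probs))
    value = 0.5 * sum(abs(dist_a.probability(p) - dist_b.probability(p))
                      for p in shapes)
    value = min(1.0, max(0.0, value))
    return SpsResult(value=value, level=dist_a.level,
                     method_a=_method_meta(dist_a),
                     method_b=_method_meta(dist_b))


# ---------------------------------------------------------------------------
# Windowed scan


def window_seed(seed: int, window: Window, allele: int) -> int:
    """Deterministic per-(window, allele) seed so any window of a scan is
    recomputable in isolation."""
    ss = np.random.SeedSequence([seed, window.length, window.offset, allele])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass(frozen=True)
class ScanGrid:
    """SPS values over (window length, window offset) for one variant."""

    variant: PointVariant
    seq_id: str
    seq_len: int
    level: int
    alphabet: str
    model: dict
    seed: int
    windows: tuple
    values: tuple
    methods: tuple
    sample_sizes: tuple

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def max(self) -> float:
        return float(np.max(self.values))

    @property
    def argmax_window(self) -> Window:
        # windows are ordered by (length, offset); first maximum wins, which
        # realises the smallest-length-then-smallest-offset tie-break
        return self.windows[int(np.argmax(self.values))]

    def summary(self) -> dict:
        best = self.argmax_window
        return {
            "variant": self.variant.spec(),
            "sequence": self.seq_id,
            "sequence_length": self.seq_len,
            "level": self.level,
            "alphabet": self.alphabet,
            "model": self.model,
            "seed": self.seed,
            "n_windows": len(self.windows),
            "mean_sps": self.mean,
            "max_sps": self.max,
            "argmax_window": {"length": best.length, "offset": best.offset},
        }

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "window_length": [w.length for w in self.windows],
            "window_offset": [w.offset for w in self.windows],
            "sps": self.values,
            "method": self.methods,
            "n": [n if n else "." for n in self.sample_sizes],
            "seed": [window_seed(self.seed, w, 0) for w in self.windows],
        })

    def to_matrix(self) -> pd.DataFrame:
        """One row per window length, one column per offset; NaN where the
        window is invalid (off-sequence or excluding the variant)."""
        lengths = sorted({w.length for w in self.windows})
        offsets = list(range(1, self.seq_len + 1))
        mat = pd.DataFrame(np.nan, index=lengths, columns=offsets)
        for w, v in zip(self.windows, self.values):
            mat.loc[w.length, w.offset] = v
        mat.index.name = "window_length"
        return mat


def snp_scan(seq: NucleicSequence, variant: PointVariant, model: EnergyModel,
             level: int = 5, min_len: int = 20, max_len: int = 250,
             n: int = 1000, seed: int = 0,
             method: str = "auto",
             exact_cutoff: int = ENUMERATION_CUTOFF) -> ScanGrid:
    """Compute the SPS for every window containing the variant.

    Window distributions are exact (enumeration) when the window fits under
    ``exact_cutoff`` and ``method`` is ``auto``, otherwise estimated from
    Boltzmann samples of ``n`` structures per allele with per-window seeds
    derived from ``seed``.
    """
    alt_seq = apply_variant(seq, variant)  # validates position and ref allele
    windows = enumerate_windows(len(seq), variant.position, min_len, max_len)
    values, methods, sizes = [], [], []
    for count, w in enumerate(windows, start=1):
        sub_a = seq.subsequence(w.offset, w.end, id=f"{seq.id}|w")
        sub_b = NucleicSequence(f"{alt_seq.id}|w",
                                alt_seq.residues[w.offset - 1:w.end],
                                seq.alphabet)
        try:
            dist_a = shape_distribution(
                sub_a, model, level=level, method=method, n=n,
                seed=window_seed(seed, w, 0), cutoff=exact_cutoff)
            dist_b = shape_distribution(
                sub_b, model, level=level, method=method, n=n,
                seed=window_seed(seed, w, 1), cutoff=exact_cutoff)
            result = sps(dist_a, dist_b)
        except Exception as exc:
            raise DataError(
                f"scan failed at window length={w.length} offset={w.offset}: "
                f"{exc}") from exc
        values.append(result.value)
        methods.append(result.method_a["method"])
        sizes.append(result.method_a["n"])
        if count % 200 == 0:
            log.info("scan progress: %d/%d windows", count, len(windows))
    return ScanGrid(variant=variant, seq_id=seq.id, seq_len=len(seq),
                    level=level, alphabet=seq.alphabet.value,
                    model=model.describe(), seed=seed,
                    windows=tuple(windows), values=tuple(values),
                    methods=tuple(methods), sample_sizes=tuple(sizes))


def dna_mode_scan(seq_dna: NucleicSequence, variant: PointVariant,
                  model: EnergyModel | None = None, **kwargs) -> ScanGrid:
    """The same scan contract under DNA folding parameters, for analyses of
    the cDNA/amplicon rather than the transcript."""
    if seq_dna.alphabet is not Alphabet.DNA:
        raise InputError(
            "dna_mode_scan needs a DNA-alphabet sequence; transliterate the "
            "RNA sequence first")
    if model is None:
        model = EnergyModel.nearest_neighbor(Alphabet.DNA)
    if model.alphabet is not Alphabet.DNA:
        raise InputError("dna_mode_scan needs a DNA-parameterised model")
    return snp_scan(seq_dna, variant, model, **kwargs)


# ---------------------------------------------------------------------------
# Primer-site accessibility


@dataclass(frozen=True)
class AccessibilityReport:
    """Fraction of a primer-site interval left unpaired by a structure; low
    accessibility flags intramolecular structure competing with primer
    annealing."""

    structure: SecondaryStructure
    site: tuple
    fraction_unpaired: float
    n_unpaired: int


def primer_site_accessibility(struct: SecondaryStructure,
                              site: tuple) -> AccessibilityReport:
    start, end = site
    if not (1 <= start <= end <= struct.seq_len):
        raise InputError(
            f"primer site {start}..{end} outside structure of length "
            f"{struct.seq_len}")
    unpaired = struct.unpaired()
    hits = sum(1 for p in range(start, end + 1) if p in unpaired)
    return AccessibilityReport(structure=struct, site=(start, end),
                               fraction_unpaired=hits / (end - start + 1),
                               n_unpaired=hits)


def grid_to_tsv(grid: ScanGrid, path, metadata: dict | None = None) -> None:
    """Long-format TSV with a commented metadata header."""
    with open(path, "w") as fh:
        meta = dict(metadata or {})
        meta.update(grid.summary())
        for key, value in meta.items():
            fh.write(f"# {key}: {json.dumps(value) if isinstance(value, dict) else value}\n")
        grid.to_dataframe().to_csv(fh, sep="\t", index=False, na_rep=".")
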