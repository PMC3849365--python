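"""Abstract shapes: mapping structures to shape classes and computing
shape-probability distributions.

A shape abstracts a secondary structure to its helix arrangement,
irrespective of helix lengths and sequence content. Two abstraction levels
are implemented:

* level 1 — walking 5'->3', each maximal helix (uninterrupted stack of
  pairs) renders as a ``[``/``]`` bracket pair and each maximal unpaired
  run as ``_``;
* level 5 — only helix nesting and adjacency survive: chains of helices
  separated by bulges or internal loops (a parent with exactly one child)
  are contracted into a single helix and unpaired runs are dropped.

The open chain renders as ``_`` at both levels, so unpairable sequences
still have a well-defined (point-mass) distribution. Shape strings are
spaceless internally; :func:`pretty_shape` produces the spaced display
form ``[ ][ ]``.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import math

import numpy as np
import pandas as pd

from .errors import InputError
from .folding import (ENUMERATION_CUTOFF, EnergyModel, SecondaryStructure,
                      boltzmann_probabilities, enumerate_structures,
                      sample_structures, structure_energy)
from .seqvar import NucleicSequence

OPEN_SHAPE = "_"


class DistributionMethod(str, Enum):
    EXACT_ENUM = "exact_enum"
    SAMPLED = "sampled"


# ---------------------------------------------------------------------------
# Helix decomposition and shape rendering


def _helices(pairs) -> list[list[tuple]]:
    """Split pairs into maximal uninterrupted stacks (helices); pairs are
    sorted 1-based (i, j). A bulge or internal loop terminates a helix."""
    helices: list[list[tuple]] = []
    for pair in sorted(pairs):
        if helices and (pair[0] == helices[-1][-1][0] + 1
                        and pair[1] == helices[-1][-1][1] - 1):
            helices[-1].append(pair)
        else:
            helices.append([pair])
    return helices


def _helix_children(helices: list[list[tuple]]) -> tuple:
    """Nesting forest over helices, each helix represented by its index.

    Returns (roots, children) where nesting is judged on outer pairs.
    """
    order = sorted(range(len(helices)), key=lambda h: helices[h][0][0])
    roots: list[int] = []
    children: dict = {h: [] for h in order}
    stack: list[int] = []
    for h in order:
        i, j = helices[h][0]
        while stack and i > helices[stack[-1]][0][1]:
            stack.pop()
        if stack:
            children[stack[-1]].append(h)
        else:
            roots.append(h)
        stack.append(h)
    return roots, children


def shape_of(struct: SecondaryStructure, level: int = 5) -> str:
    """Abstract shape string of a structure at level 1 or 5."""
    if level not in (1, 5):
        raise InputError(f"shape level must be 1 or 5, got {level}")
    if struct.is_open:
        return OPEN_SHAPE
    helices = _helices(struct.pairs)
    if level == 1:
        # mark bracket positions: first position of each opening and
        # closing strand; everything else in a strand is skipped
        opens = {h[0][0]: True for h in helices}
        closes = {h[-1][1]: True for h in helices}
        in_strand = set()
        for h in helices:
            for i, j in h:
                in_strand.add(i)
                in_strand.add(j)
        out = []
        pos = 1
        while pos <= struct.seq_len:
            if pos in opens:
                out.append("[")
                pos += 1
            elif pos in closes:
                out.append("]")
                pos += 1
            elif pos in in_strand:
                pos += 1
            else:
                out.append("_")
                while pos <= struct.seq_len and pos not in in_strand:
                    pos += 1
        return "".join(out)
    roots, children = _helix_children(helices)

    def render(h: int) -> str:
        kids = children[h]
        while len(kids) == 1:  # contract bulge/internal-loop chains
            kids = children[kids[0]]
        return "[" + "".join(render(k) for k in kids) + "]"

    return "".join(render(r) for r in roots)


def pretty_shape(shape: str) -> str:
    """Spaced display form: ``[][]`` -> ``[ ][ ]``."""
    return shape.replace("[]", "[ ]")


def parse_shape(text: str) -> str:
    """Accept the spaced display form and return the internal spaceless one."""
    shape = text.replace(" ", "")
    depth = 0
    for c in shape:
        if c == "[":
            depth += 1
        elif c == "]":
            depth -= 1
            if depth < 0:
                raise InputError(f"unbalanced shape string {text!r}")
        elif c != "_":
            raise InputError(f"invalid shape character {c!r} in {text!r}")
    if depth != 0:
        raise InputError(f"unbalanced shape string {text!r}")
    return shape


# ---------------------------------------------------------------------------
# Shape-probability distributions


@dataclass(frozen=True)
class ShapeDistribution:
    """Probability mass over abstract shape classes for one sequence.

    ``probs`` is ordered by descending probability (ties lexicographic).
    For SAMPLED distributions ``stderr`` carries the per-shape binomial
    standard error sqrt(p(1-p)/n).
    """

    probs: dict
    level: int
    method: DistributionMethod
    n: int | None = None
    stderr: dict | None = None

    def __post_init__(self) -> None:
        total = sum(self.probs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise InputError(f"shape distribution mass {total} != 1")

    def probability(self, shape: str) -> float:
        return self.probs.get(shape, 0.0)

    def total_variation(self, other: "ShapeDistribution") -> float:
        keys = set(self.probs) | set(other.probs)
        return 0.5 * sum(abs(self.probability(k) - other.probability(k))
                         for k in keys)


@dataclass(frozen=True)
class ShrepRecord:
    """A shape class with its minimum-free-energy representative."""

    shape: str
    probability: float
    representative: SecondaryStructure
    energy: float


def _ordered(masses: dict) -> dict:
    return dict(sorted(masses.items(), key=lambda kv: (-kv[1], kv[0])))


def _resolve_method(method, seq_len: int, cutoff: int) -> DistributionMethod:
    if isinstance(method, DistributionMethod):
        return method
    if method == "auto":
        return (DistributionMethod.EXACT_ENUM if seq_len <= cutoff
                else DistributionMethod.SAMPLED)
    return DistributionMethod(method)


def _exact_members(seq, model, level, cutoff):
    structures = enumerate_structures(seq, model, cutoff)
    probs = boltzmann_probabilities(structures, seq, model)
    by_shape: dict = {}
    for s, p in zip(structures, probs):
        by_shape.setdefault(shape_of(s, level), []).append((s, p))
    return by_shape


def shape_distribution(seq: NucleicSequence, model: EnergyModel,
                       level: int = 5,
                       method: str | DistributionMethod = "auto",
                       n: int = 1000, seed: int = 0,
                       cutoff: int = ENUMERATION_CUTOFF) -> ShapeDistribution:
    """P(shape) for a sequence, exactly (by enumeration, short sequences)
    or as empirical Boltzmann-sample frequencies."""
    resolved = _resolve_method(method, len(seq), cutoff)
    if resolved is DistributionMethod.EXACT_ENUM:
        by_shape = _exact_members(seq, model, level, cutoff)
        masses = {shape: float(sum(p for _, p in members))
                  for shape, members in by_shape.items()}
        return ShapeDistribution(_ordered(masses), level, resolved)
    if n < 100:
        raise InputError(f"sampled distributions need n >= 100, got {n}")
    sample = sample_structures(seq, model, n, seed)
    counts: dict = {}
    for s in sample.structures:
        shape = shape_of(s, level)
        counts[shape] = counts.get(shape, 0) + 1
    masses = _ordered({shape: c / n for shape, c in counts.items()})
    stderr = {shape: math.sqrt(p * (1 - p) / n) for shape, p in masses.items()}
    return ShapeDistribution(masses, level, resolved, n=n, stderr=stderr)


def shape_representatives(seq: NucleicSequence, model: EnergyModel,
                          level: int = 5,
                          method: str | DistributionMethod = "auto",
                          n: int = 1000, seed: int = 0,
                          cutoff: int = ENUMERATION_CUTOFF) -> list[ShrepRecord]:
    """Per-shape minimum-free-energy representatives (shreps) with their
    energies, ordered like the distribution (descending probability)."""
    resolved = _resolve_method(method, len(seq), cutoff)
    records = []
    if resolved is DistributionMethod.EXACT_ENUM:
        by_shape = _exact_members(seq, model, level, cutoff)
        masses = _ordered({shape: float(sum(p for _, p in members))
                           for shape, members in by_shape.items()})
        for shape, mass in masses.items():
            best = min(
                ((structure_energy(s, seq, model), s.dot_bracket, s)
                 for s, _ in by_shape[shape]),
                key=lambda t: (t[0], t[1]))
            records.append(ShrepRecord(shape, mass, best[2], float(best[0])))
        return records
    if n < 100:
        raise InputError(f"sampled representatives need n >= 100, got {n}")
    sample = sample_structures(seq, model, n, seed)
    by_shape: dict = {}
    for s in sample.structures:
        by_shape.setdefault(shape_of(s, level), []).append(s)
    masses = _ordered({shape: len(members) / n
                       for shape, members in by_shape.items()})
    for shape, mass in masses.items():
        best = min(((structure_energy(s, seq, model), s.dot_bracket, s)
                    for s in by_shape[shape]), key=lambda t: (t[0], t[1]))
        records.append(ShrepRecord(shape, mass, best[2], float(best[0])))
    return records


def distribution_table(dist: ShapeDistribution,
                       shreps: list[ShrepRecord] | None = None) -> pd.DataFrame:
    """Tabular emission: shape, probability, stderr (blank for exact),
    representative dot-bracket and energy when available."""
    reps = {r.shape: r for r in shreps or []}
    rows = []
    for shape, p in dist.probs.items():
        rep = reps.get(shape)
        rows.append({
            "shape": pretty_shape(shape),
            "probability": p,
            "stderr": (dist.stderr or {}).get(shape, np.nan),
            "representative": rep.representative.dot_bracket if rep else "",
            "energy": rep.energy if rep else np.nan,
        })
    return pd.DataFrame(rows)
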