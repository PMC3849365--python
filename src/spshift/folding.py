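"""Secondary-structure model, energetics, folding and Boltzmann sampling.

The structure space is the classical pseudoknot-free one: canonical pairs
(A-U/A-T, G-C, plus G-U/G-T wobble unless disabled), hairpin loops of at
least three unpaired residues, lonely pairs permitted. Two energy models
ship:

* ``TOY`` — per-pair energies (G-C -3.0, A-U -2.0, G-U -1.0 kcal/mol), all
  loops free. Every structure's energy is a trivially re-summable sum over
  its pairs, which keeps the exhaustive-enumeration oracle and the dynamic
  programs mutually checkable to machine precision.
* ``NEAREST_NEIGHBOR`` — a loop-decomposition model (stacks, hairpin /
  bulge / internal loop length penalties, affine multiloops) with parameter
  tables loadable from small whitespace-delimited files; bundled defaults
  carry published Watson-Crick stack values for RNA and DNA. Dangling ends,
  terminal-AU penalties, mismatches and coaxial stacking are deliberately
  omitted (documented fidelity limitation).

Three routes over the same structure space are provided and cross-checked
by the test suite: exhaustive enumeration (exact, short sequences only),
dynamic programming (partition function and MFE, log-space, stable to at
least 250 nt), and stochastic backtracking (Boltzmann sampling).

Internally sequences are normalised to RNA letters (T -> U); DNA differs
only by its parameter table, mirroring how the alphabet modes are meant to
behave.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import DataError, InputError
from .seqvar import Alphabet, NucleicSequence

GAS_CONSTANT = 1.9872e-3  # kcal / (mol K)
DEFAULT_TEMPERATURE = 310.15  # kelvin (37 C)
MIN_HAIRPIN = 3  # unpaired residues in a hairpin loop
ENUMERATION_CUTOFF = 30  # max length for the exhaustive oracle
_JS_COEFF = 1.75  # Jacobson-Stockmayer loop-entropy extrapolation

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def _norm(residues: str) -> str:
    return residues.replace("T", "U")


class EnergyModelKind(str, Enum):
    TOY = "toy"
    NEAREST_NEIGHBOR = "nn"


@dataclass(frozen=True)
class EnergyModel:
    """Energy rules for folding; see module docstring for the two kinds."""

    kind: EnergyModelKind
    alphabet: Alphabet = Alphabet.RNA
    temperature: float = DEFAULT_TEMPERATURE
    wobble: bool = True
    no_lonely_pairs: bool = False
    # TOY: energy per pair type (keys are normalised pairs like "GC")
    pair_energies: dict = field(default_factory=dict)
    # NEAREST_NEIGHBOR tables (normalised to U); stacks keyed by
    # (outer pair, inner pair) where outer=(seq[i],seq[j]), inner=(seq[i+1],seq[j-1])
    stacks: dict = field(default_factory=dict)
    hairpin_table: dict = field(default_factory=dict)
    bulge_table: dict = field(default_factory=dict)
    internal_table: dict = field(default_factory=dict)
    ml_closing: float = 0.0   # a: per multiloop
    ml_branch: float = 0.0    # b: per enclosed helix
    ml_unpaired: float = 0.0  # c: per unpaired residue in a multiloop
    max_interior: int = 30    # interior-loop size cap in the NN dynamic program
    source: str = "builtin"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise InputError("temperature must be > 0 kelvin")

    @property
    def rt(self) -> float:
        return GAS_CONSTANT * self.temperature

    def describe(self) -> dict:
        return {
            "kind": self.kind.value,
            "alphabet": self.alphabet.value,
            "temperature_K": self.temperature,
            "wobble": self.wobble,
            "no_lonely_pairs": self.no_lonely_pairs,
            "parameters": self.source,
        }

    # -- pairing rules ----------------------------------------------------

    def can_pair(self, a: str, b: str) -> bool:
        a, b = _norm(a), _norm(b)
        return (a, b) in _WC or (self.wobble and (a, b) in _WOBBLE)

    # -- TOY energetics ---------------------------------------------------

    def pair_energy(self, a: str, b: str) -> float:
        key = "".join(sorted(_norm(a) + _norm(b)))
        try:
            return self.pair_energies[key]
        except KeyError:
            raise DataError(f"pair type {a}-{b} absent from parameter table")

    # -- nearest-neighbor energetics --------------------------------------

    def stack_energy(self, outer: str, inner: str) -> float:
        try:
            return self.stacks[(_norm(outer), _norm(inner))]
        except KeyError:
            raise DataError(
                f"stack {outer}/{inner} absent from parameter table")

    def _loop_energy(self, table: dict, size: int, what: str) -> float:
        if size in table:
            return table[size]
        nmax = max(table)
        if size < min(table):
            raise DataError(f"{what} loop of size {size} below parameter table")
        return table[nmax] + _JS_COEFF * self.rt * math.log(size / nmax)

    def hairpin_energy(self, size: int) -> float:
        return self._loop_energy(self.hairpin_table, size, "hairpin")

    def bulge_energy(self, size: int) -> float:
        return self._loop_energy(self.bulge_table, size, "bulge")

    def internal_energy(self, size: int) -> float:
        return self._loop_energy(self.internal_table, size, "internal")

    # -- constructors ------------------------------------------------------

    @classmethod
    def toy(cls, alphabet: Alphabet = Alphabet.RNA, *,
            temperature: float = DEFAULT_TEMPERATURE, wobble: bool = True,
            no_lonely_pairs: bool = False) -> "EnergyModel":
        return cls(kind=EnergyModelKind.TOY, alphabet=alphabet,
                   temperature=temperature, wobble=wobble,
                   no_lonely_pairs=no_lonely_pairs,
                   pair_energies={"CG": -3.0, "AU": -2.0, "GU": -1.0},
                   source="toy(GC=-3,AU=-2,GU=-1)")

    @classmethod
    def nearest_neighbor(cls, alphabet: Alphabet = Alphabet.RNA, *,
                         path: str | Path | None = None,
                         temperature: float = DEFAULT_TEMPERATURE,
                         wobble: bool = True,
                         no_lonely_pairs: bool = False) -> "EnergyModel":
        """Load a nearest-neighbor model from a parameter file (or the
        bundled default table for the alphabet)."""
        if path is None:
            name = "rna_nn.par" if alphabet is Alphabet.RNA else "dna_nn.par"
            ref = resources.files("spshift.params").joinpath(name)
            text = ref.read_text()
            source = f"builtin:{name}"
        else:
            text = Path(path).read_text()
            source = str(path)
        tables = _parse_param_file(text)
        return cls(kind=EnergyModelKind.NEAREST_NEIGHBOR, alphabet=alphabet,
                   temperature=temperature, wobble=wobble,
                   no_lonely_pairs=no_lonely_pairs,
                   stacks=tables["stacks"],
                   hairpin_table=tables["hairpin"],
                   bulge_table=tables["bulge"],
                   internal_table=tables["internal"],
                   ml_closing=tables["multiloop"]["a"],
                   ml_branch=tables["multiloop"]["b"],
                   ml_unpaired=tables["multiloop"]["c"],
                   source=source)


def _parse_param_file(text: str) -> dict:
    """Parse the whitespace-delimited parameter layout.

    Sections: ``[stacks]`` (a ``pairs`` header row then one row per outer
    pair), ``[hairpin]`` / ``[bulge]`` / ``[internal]`` (size value rows,
    kcal/mol) and ``[multiloop]`` (affine coefficients a, b, c).
    """
    section = None
    cols: list[str] = []
    stacks: dict = {}
    loops: dict = {"hairpin": {}, "bulge": {}, "internal": {}}
    multi: dict = {}
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[]").lower()
            continue
        fields = line.split()
        if section == "stacks":
            if fields[0].lower() == "pairs":
                cols = [_norm(p) for p in fields[1:]]
                continue
            outer = _norm(fields[0])
            for inner, value in zip(cols, fields[1:]):
                stacks[(outer, inner)] = float(value)
        elif section in loops:
            loops[section][int(fields[0])] = float(fields[1])
        elif section == "multiloop":
            multi[fields[0].lower()] = float(fields[1])
        else:
            raise DataError(f"parameter file line outside a known section: {raw!r}")
    for name, table in loops.items():
        if not table:
            raise DataError(f"parameter file missing [{name}] table")
    if not stacks:
        raise DataError("parameter file missing [stacks] table")
    for key in "abc":
        multi.setdefault(key, 0.0)
    return {"stacks": stacks, "hairpin": loops["hairpin"],
            "bulge": loops["bulge"], "internal": loops["internal"],
            "multiloop": multi}


# ---------------------------------------------------------------------------
# Secondary structures


@dataclass(frozen=True)
class SecondaryStructure:
    """A pseudoknot-free pairing, pairs as sorted 1-based (i, j) with i < j."""

    seq_len: int
    pairs: tuple

    @property
    def dot_bracket(self) -> str:
        chars = ["."] * self.seq_len
        for i, j in self.pairs:
            chars[i - 1] = "("
            chars[j - 1] = ")"
        return "".join(chars)

    @property
    def is_open(self) -> bool:
        return not self.pairs

    def pair_map(self) -> dict:
        """position -> partner (both directions), 1-based."""
        pm = {}
        for i, j in self.pairs:
            pm[i] = j
            pm[j] = i
        return pm

    def unpaired(self) -> set:
        pm = self.pair_map()
        return {k for k in range(1, self.seq_len + 1) if k not in pm}


def _pairs_from_dot_bracket(db: str) -> tuple:
    stack: list[int] = []
    pairs = []
    for idx, char in enumerate(db, start=1):
        if char == "(":
            stack.append(idx)
        elif char == ")":
            if not stack:
                raise InputError(f"unbalanced ')' at position {idx}")
            pairs.append((stack.pop(), idx))
        elif char != ".":
            raise InputError(f"invalid structure character {char!r} at position {idx}")
    if stack:
        raise InputError(f"unbalanced '(' at position {stack[-1]}")
    return tuple(sorted(pairs))


def validate_structure(dot_bracket: str, seq: NucleicSequence,
                       model: EnergyModel | None = None) -> SecondaryStructure:
    """Parse and validate a dot-bracket string against a sequence."""
    model = model or EnergyModel.toy(seq.alphabet)
    if len(dot_bracket) != len(seq):
        raise InputError(
            f"structure length {len(dot_bracket)} != sequence length {len(seq)}")
    pairs = _pairs_from_dot_bracket(dot_bracket)
    for i, j in pairs:
        a, b = seq.residue(i), seq.residue(j)
        if not model.can_pair(a, b):
            raise InputError(
                f"non-canonical pair {a}{i}-{b}{j}")
        if j - i < MIN_HAIRPIN + 1:
            raise InputError(
                f"hairpin loop shorter than {MIN_HAIRPIN} at pair {i}-{j}")
    struct = SecondaryStructure(len(seq), pairs)
    if model.no_lonely_pairs:
        for i, j in pairs:
            if (i + 1, j - 1) not in struct.pairs and (i - 1, j + 1) not in struct.pairs:
                raise InputError(f"lonely pair {i}-{j} forbidden by model")
    return struct


# ---------------------------------------------------------------------------
# Free energy of a given structure


def _loop_decomposition(struct: SecondaryStructure) -> Iterator[tuple]:
    """Yield (closing_pair_or_None, children) for every loop, the external
    loop having closing pair None."""
    pairs = list(struct.pairs)
    children: dict = {None: []}
    stack: list = [None]
    events = sorted([(i, "open", (i, j)) for i, j in pairs]
                    + [(j, "close", (i, j)) for i, j in pairs])
    for _, what, pair in events:
        if what == "open":
            children.setdefault(pair, [])
            children[stack[-1]].append(pair)
            stack.append(pair)
        else:
            stack.pop()
    for closing, kids in children.items():
        yield closing, kids


def structure_energy(struct: SecondaryStructure, seq: NucleicSequence,
                     model: EnergyModel) -> float:
    """Free energy (kcal/mol) of a structure; the open chain is 0 by
    definition in both models."""
    residues = _norm(seq.residues)
    if model.kind is EnergyModelKind.TOY:
        return sum(model.pair_energy(residues[i - 1], residues[j - 1])
                   for i, j in struct.pairs)
    energy = 0.0
    for closing, kids in _loop_decomposition(struct):
        if closing is None:  # external loop is free
            continue
        i, j = closing
        if not kids:
            energy += model.hairpin_energy(j - i - 1)
        elif len(kids) == 1:
            (k, l), = kids
            left, right = k - i - 1, j - l - 1
            if left == 0 and right == 0:
                outer = residues[i - 1] + residues[j - 1]
                inner = residues[k - 1] + residues[l - 1]
                energy += model.stack_energy(outer, inner)
            elif left == 0 or right == 0:
                energy += model.bulge_energy(left + right)
            else:
                energy += model.internal_energy(left + right)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in kids)
            energy += (model.ml_closing + model.ml_branch * len(kids)
                       + model.ml_unpaired * unpaired)
    return energy


# ---------------------------------------------------------------------------
# Exhaustive enumeration (the exact oracle for short sequences)


def enumerate_structures(seq: NucleicSequence, model: EnergyModel,
                         cutoff: int = ENUMERATION_CUTOFF) -> list[SecondaryStructure]:
    """All pseudoknot-free structures over the allowed pairs, the open chain
    included, each exactly once. Only for sequences up to ``cutoff`` nt."""
    n = len(seq)
    if n > cutoff:
        raise DataError(
            f"sequence length {n} exceeds enumeration cutoff {cutoff}")
    residues = _norm(seq.residues)
    memo: dict = {}

    def rec(i: int, j: int) -> list[tuple]:
        # all pair-sets over 0-based closed interval [i, j]
        if j - i < MIN_HAIRPIN + 1:
            return [()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = list(rec(i + 1, j))
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if model.can_pair(residues[i], residues[k]):
                for inner in rec(i + 1, k - 1):
                    head = ((i + 1, k + 1),) + inner  # store 1-based
                    for rest in rec(k + 1, j):
                        out.append(head + rest)
        memo[key] = out
        return out

    structures = [SecondaryStructure(n, tuple(sorted(p))) for p in rec(0, n - 1)]
    if model.no_lonely_pairs:
        kept = []
        for s in structures:
            ps = set(s.pairs)
            if all((i + 1, j - 1) in ps or (i - 1, j + 1) in ps for i, j in s.pairs):
                kept.append(s)
        structures = kept
    return structures


def boltzmann_probabilities(structures: Sequence[SecondaryStructure],
                            seq: NucleicSequence,
                            model: EnergyModel) -> np.ndarray:
    """Exact ensemble probabilities of an enumerated structure list."""
    energies = np.array([structure_energy(s, seq, model) for s in structures])
    weights = np.exp(-(energies - energies.min()) / model.rt)
    return weights / weights.sum()


# ---------------------------------------------------------------------------
# Ensemble containers


@dataclass(frozen=True)
class EnsembleResult:
    """Partition function in log space plus the conditions it was computed
    under. log Z >= 0 always: the open chain contributes weight 1 at the
    reference energy 0."""

    log_z: float
    temperature: float
    model: dict

    @property
    def z(self) -> float:
        return math.exp(self.log_z)


@dataclass(frozen=True)
class StructureSample:
    """A Boltzmann sample of structures for one sequence."""

    structures: tuple
    n: int
    seed: int


# ---------------------------------------------------------------------------
# Dynamic programming engines (log space)

_NEG = -np.inf


def _lse(values) -> float:
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        return _NEG
    m = arr.max()
    if m == _NEG:
        return _NEG
    return m + math.log(np.exp(arr - m).sum())


def _check_supported(model: EnergyModel) -> None:
    if model.no_lonely_pairs:
        raise NotImplementedError(
            "the dynamic-programming engines support only the default "
            "lonely-pairs-permitted structure space; use enumeration for "
            "no_lonely_pairs")


class _PairSumEngine:
    """Nussinov/McCaskill-style interval DP for pair-additive energies
    (the TOY model). No interior-loop cap: the recursion covers the full
    structure space exactly."""

    def __init__(self, residues: str, model: EnergyModel):
        _check_supported(model)
        self.model = model
        self.res = residues
        self.n = n = len(residues)
        rt = model.rt
        # partners[i] = positions k > i+MIN_HAIRPIN that can pair with i
        self.partners = [
            [k for k in range(i + MIN_HAIRPIN + 1, n)
             if model.can_pair(residues[i], residues[k])]
            for i in range(n)]
        self.lw = {}
        for i in range(n):
            for k in self.partners[i]:
                self.lw[(i, k)] = -model.pair_energy(residues[i], residues[k]) / rt
        self._fill()

    def _q(self, i: int, j: int) -> float:
        return 0.0 if i > j else self.Q[i][j]

    def _m(self, i: int, j: int) -> float:
        return 0.0 if i > j else self.M[i][j]

    def _fill(self) -> None:
        n = self.n
        self.Q = [[0.0] * n for _ in range(n)]
        self.M = [[0.0] * n for _ in range(n)]
        for span in range(MIN_HAIRPIN + 1, n):
            for i in range(n - span):
                j = i + span
                terms = [self._q(i + 1, j)]
                best = self._m(i + 1, j)
                for k in self.partners[i]:
                    if k > j:
                        break
                    terms.append(self.lw[(i, k)] + self._q(i + 1, k - 1)
                                 + self._q(k + 1, j))
                    e = (-self.lw[(i, k)] * self.model.rt
                         + self._m(i + 1, k - 1) + self._m(k + 1, j))
                    if e < best:
                        best = e
                self.Q[i][j] = _lse(terms)
                self.M[i][j] = best

    @property
    def log_z(self) -> float:
        return self._q(0, self.n - 1)

    def mfe(self) -> tuple:
        pairs: list = []
        stack = [(0, self.n - 1)]
        tol = 1e-9
        while stack:
            i, j = stack.pop()
            if j - i < MIN_HAIRPIN + 1:
                continue
            target = self._m(i, j)
            chosen = None
            for k in self.partners[i]:  # prefer pairing, smallest partner
                if k > j:
                    break
                e = (-self.lw[(i, k)] * self.model.rt
                     + self._m(i + 1, k - 1) + self._m(k + 1, j))
                if e <= target + tol:
                    chosen = k
                    break
            if chosen is None:
                stack.append((i + 1, j))
            else:
                pairs.append((i + 1, chosen + 1))
                stack.append((i + 1, chosen - 1))
                stack.append((chosen + 1, j))
        return tuple(sorted(pairs)), self._m(0, self.n - 1)

    def sample(self, rng: np.random.Generator) -> tuple:
        pairs: list = []
        stack = [(0, self.n - 1)]
        while stack:
            i, j = stack.pop()
            if j - i < MIN_HAIRPIN + 1:
                continue
            total = self._q(i, j)
            u = rng.random()
            acc = math.exp(self._q(i + 1, j) - total)
            if u < acc:
                stack.append((i + 1, j))
                continue
            chosen = None
            for k in self.partners[i]:
                if k > j:
                    break
                acc += math.exp(self.lw[(i, k)] + self._q(i + 1, k - 1)
                                + self._q(k + 1, j) - total)
                if u < acc:
                    chosen = k
                    break
            if chosen is None:  # guard against rounding at the tail
                chosen = max(k for k in self.partners[i] if k <= j)
            pairs.append((i + 1, chosen + 1))
            stack.append((i + 1, chosen - 1))
            stack.append((chosen + 1, j))
        return tuple(sorted(pairs))


class _LoopEngine:
    """Zuker/McCaskill-style DP for the loop-decomposition (nearest-
    neighbor) model: V (paired), WM / WM1 (multiloop components) and an
    external-prefix array. Interior loops are capped at ``model.max_interior``
    unpaired residues, the referenced convention."""

    def __init__(self, residues: str, model: EnergyModel):
        _check_supported(model)
        self.model = model
        self.res = residues
        self.n = len(residues)
        self.rt = model.rt
        self._fill()

    # energy of the interior/stack loop closed by (i,j) with inner (k,l); 0-based
    def _interior_e(self, i: int, j: int, k: int, l: int) -> float:
        left, right = k - i - 1, j - l - 1
        if left == 0 and right == 0:
            return self.model.stack_energy(self.res[i] + self.res[j],
                                           self.res[k] + self.res[l])
        if left == 0 or right == 0:
            return self.model.bulge_energy(left + right)
        return self.model.internal_energy(left + right)

    def _fill(self) -> None:
        n, rt, m = self.n, self.rt, self.model
        can = m.can_pair
        res = self.res
        maxint = m.max_interior
        b_rt, c_rt = m.ml_branch / rt, m.ml_unpaired / rt
        NEG = _NEG
        V = np.full((n, n), NEG)
        WM = np.full((n, n), NEG)
        WM1 = np.full((n, n), NEG)
        VM = np.full((n, n), np.inf)   # MFE analogues
        WMm = np.full((n, n), np.inf)
        WM1m = np.full((n, n), np.inf)
        for span in range(MIN_HAIRPIN + 1, n):
            for i in range(n - span):
                j = i + span
                if can(res[i], res[j]):
                    terms = [-m.hairpin_energy(j - i - 1) / rt]
                    emin = m.hairpin_energy(j - i - 1)
                    for k in range(i + 1, min(i + 2 + maxint, j - MIN_HAIRPIN)):
                        lmin = max(k + MIN_HAIRPIN + 1,
                                   j - 1 - (maxint - (k - i - 1)))
                        for l in range(lmin, j):
                            if V[k, l] == NEG:
                                continue
                            e = self._interior_e(i, j, k, l)
                            terms.append(-e / rt + V[k, l])
                            emin = min(emin, e + VM[k, l])
                    # multiloop: split before the last branch
                    for u in range(i + 2, j - MIN_HAIRPIN - 1):
                        if WM[i + 1, u - 1] != NEG and WM1[u, j - 1] != NEG:
                            terms.append(-m.ml_closing / rt
                                         + WM[i + 1, u - 1] + WM1[u, j - 1])
                        eml = m.ml_closing + WMm[i + 1, u - 1] + WM1m[u, j - 1]
                        if eml < emin:
                            emin = eml
                    V[i, j] = _lse(terms)
                    VM[i, j] = emin
                # WM1: exactly one branch starting at i, trailing unpaired
                t1 = []
                e1 = np.inf
                for l in range(i + MIN_HAIRPIN + 1, j + 1):
                    if V[i, l] != NEG:
                        t1.append(V[i, l] - b_rt - c_rt * (j - l))
                    e1 = min(e1, VM[i, l] + m.ml_branch + m.ml_unpaired * (j - l))
                WM1[i, j] = _lse(t1)
                WM1m[i, j] = e1
                # WM: >= 1 branch in [i, j]
                t = []
                e = np.inf
                if j - 1 >= i and WM[i, j - 1] != NEG:
                    t.append(WM[i, j - 1] - c_rt)
                if j - 1 >= i:
                    e = WMm[i, j - 1] + m.ml_unpaired
                for k in range(i, j - MIN_HAIRPIN):
                    if V[k, j] == NEG:
                        continue
                    first = -c_rt * (k - i)
                    firstm = m.ml_unpaired * (k - i)
                    if k - 1 >= i and WM[i, k - 1] != NEG:
                        first = float(np.logaddexp(first, WM[i, k - 1]))
                    if k - 1 >= i:
                        firstm = min(firstm, WMm[i, k - 1])
                    t.append(V[k, j] - b_rt + first)
                    e = min(e, VM[k, j] + m.ml_branch + firstm)
                WM[i, j] = _lse(t)
                WMm[i, j] = e
        # external prefix: W[j] covers positions 0..j-1
        W = np.zeros(n + 1)
        Wm = np.zeros(n + 1)
        for j in range(1, n + 1):
            terms = [W[j - 1]]
            emin = Wm[j - 1]
            for k in range(0, j - MIN_HAIRPIN - 1):
                if V[k, j - 1] != NEG:
                    terms.append(W[k] + V[k, j - 1])
                emin = min(emin, Wm[k] + VM[k, j - 1])
            W[j] = _lse(terms)
            Wm[j] = emin
        self.V, self.WM, self.WM1, self.W = V, WM, WM1, W
        self.VM, self.WMm, self.WM1m, self.Wm = VM, WMm, WM1m, Wm

    @property
    def log_z(self) -> float:
        return float(self.W[self.n])

    # ----- MFE backtrack (deterministic preference order) -----------------

    def mfe(self) -> tuple:
        tol = 1e-9
        m = self.model
        pairs: list = []
        tasks = [("EXT", self.n)]
        while tasks:
            kind, *args = tasks.pop()
            if kind == "EXT":
                (j,) = args
                if j == 0:
                    continue
                target = self.Wm[j]
                chosen = None
                for k in range(0, j - MIN_HAIRPIN - 1):
                    if self.Wm[k] + self.VM[k, j - 1] <= target + tol:
                        chosen = k
                        break
                if chosen is None:
                    tasks.append(("EXT", j - 1))
                else:
                    tasks.append(("V", chosen, j - 1))
                    tasks.append(("EXT", chosen))
            elif kind == "V":
                i, j = args
                pairs.append((i + 1, j + 1))
                target = self.VM[i, j]
                hp = m.hairpin_energy(j - i - 1)
                if hp <= target + tol:
                    continue
                done = False
                for k in range(i + 1, min(i + 2 + m.max_interior,
                                          j - MIN_HAIRPIN)):
                    lmin = max(k + MIN_HAIRPIN + 1,
                               j - 1 - (m.max_interior - (k - i - 1)))
                    for l in range(lmin, j):
                        if (self.VM[k, l] < np.inf and
                                self._interior_e(i, j, k, l) + self.VM[k, l]
                                <= target + tol):
                            tasks.append(("V", k, l))
                            done = True
                            break
                    if done:
                        break
                if done:
                    continue
                for u in range(i + 2, j - MIN_HAIRPIN - 1):
                    if (m.ml_closing + self.WMm[i + 1, u - 1]
                            + self.WM1m[u, j - 1] <= target + tol):
                        tasks.append(("WM", i + 1, u - 1))
                        tasks.append(("WM1", u, j - 1))
                        done = True
                        break
                if not done:
                    raise AssertionError("MFE backtrack failed (V)")
            elif kind == "WM1":
                i, j = args
                target = self.WM1m[i, j]
                for l in range(i + MIN_HAIRPIN + 1, j + 1):
                    if (self.VM[i, l] + m.ml_branch
                            + m.ml_unpaired * (j - l) <= target + tol):
                        tasks.append(("V", i, l))
                        break
                else:
                    raise AssertionError("MFE backtrack failed (WM1)")
            else:  # WM
                i, j = args
                target = self.WMm[i, j]
                chosen = None
                for k in range(i, j - MIN_HAIRPIN):
                    if self.VM[k, j] == np.inf:
                        continue
                    base = self.VM[k, j] + m.ml_branch
                    if base + m.ml_unpaired * (k - i) <= target + tol:
                        chosen = (k, None)
                        break
                    if k - 1 >= i and base + self.WMm[i, k - 1] <= target + tol:
                        chosen = (k, "wm")
                        break
                if chosen is not None:
                    k, how = chosen
                    tasks.append(("V", k, j))
                    if how == "wm":
                        tasks.append(("WM", i, k - 1))
                elif j - 1 >= i and (self.WMm[i, j - 1] + m.ml_unpaired
                                     <= target + tol):
                    tasks.append(("WM", i, j - 1))
                else:
                    raise AssertionError("MFE backtrack failed (WM)")
        return tuple(sorted(pairs)), float(self.Wm[self.n])

    # ----- stochastic backtrack -------------------------------------------

    def sample(self, rng: np.random.Generator) -> tuple:
        m = self.model
        rt = self.rt
        b_rt, c_rt = m.ml_branch / rt, m.ml_unpaired / rt
        pairs: list = []
        tasks = [("EXT", self.n)]
        while tasks:
            kind, *args = tasks.pop()
            if kind == "EXT":
                (j,) = args
                if j == 0:
                    continue
                total = self.W[j]
                u = rng.random()
                acc = math.exp(self.W[j - 1] - total)
                if u < acc:
                    tasks.append(("EXT", j - 1))
                    continue
                chosen = None
                for k in range(0, j - MIN_HAIRPIN - 1):
                    if self.V[k, j - 1] == _NEG:
                        continue
                    acc += math.exp(self.W[k] + self.V[k, j - 1] - total)
                    chosen = k
                    if u < acc:
                        break
                tasks.append(("V", chosen, j - 1))
                tasks.append(("EXT", chosen))
            elif kind == "V":
                i, j = args
                pairs.append((i + 1, j + 1))
                total = self.V[i, j]
                u = rng.random()
                acc = math.exp(-m.hairpin_energy(j - i - 1) / rt - total)
                if u < acc:
                    continue
                done = False
                last_inner = None
                for k in range(i + 1, min(i + 2 + m.max_interior,
                                          j - MIN_HAIRPIN)):
                    lmin = max(k + MIN_HAIRPIN + 1,
                               j - 1 - (m.max_interior - (k - i - 1)))
                    for l in range(lmin, j):
                        if self.V[k, l] == _NEG:
                            continue
                        acc += math.exp(-self._interior_e(i, j, k, l) / rt
                                        + self.V[k, l] - total)
                        last_inner = (k, l)
                        if u < acc:
                            tasks.append(("V", k, l))
                            done = True
                            break
                    if done:
                        break
                if done:
                    continue
                chosen_u = None
                for v in range(i + 2, j - MIN_HAIRPIN - 1):
                    if self.WM[i + 1, v - 1] == _NEG or self.WM1[v, j - 1] == _NEG:
                        continue
                    acc += math.exp(-m.ml_closing / rt + self.WM[i + 1, v - 1]
                                    + self.WM1[v, j - 1] - total)
                    chosen_u = v
                    if u < acc:
                        break
                if chosen_u is not None:
                    tasks.append(("WM", i + 1, chosen_u - 1))
                    tasks.append(("WM1", chosen_u, j - 1))
                elif last_inner is not None:  # rounding tail guard
                    tasks.append(("V", *last_inner))
            elif kind == "WM1":
                i, j = args
                total = self.WM1[i, j]
                u = rng.random()
                acc = 0.0
                chosen = None
                for l in range(i + MIN_HAIRPIN + 1, j + 1):
                    if self.V[i, l] == _NEG:
                        continue
                    acc += math.exp(self.V[i, l] - b_rt - c_rt * (j - l) - total)
                    chosen = l
                    if u < acc:
                        break
                tasks.append(("V", i, chosen))
            else:  # WM
                i, j = args
                total = self.WM[i, j]
                u = rng.random()
                acc = 0.0
                if j - 1 >= i and self.WM[i, j - 1] != _NEG:
                    acc = math.exp(self.WM[i, j - 1] - c_rt - total)
                    if u < acc:
                        tasks.append(("WM", i, j - 1))
                        continue
                decided = False
                fallback = None
                for k in range(i, j - MIN_HAIRPIN):
                    if self.V[k, j] == _NEG:
                        continue
                    base = self.V[k, j] - b_rt - total
                    acc += math.exp(base - c_rt * (k - i))
                    fallback = (k, None)
                    if u < acc:
                        tasks.append(("V", k, j))
                        decided = True
                        break
                    if k - 1 >= i and self.WM[i, k - 1] != _NEG:
                        acc += math.exp(base + self.WM[i, k - 1])
                        fallback = (k, "wm")
                        if u < acc:
                            tasks.append(("V", k, j))
                            tasks.append(("WM", i, k - 1))
                            decided = True
                            break
                if not decided and fallback is not None:
                    k, how = fallback
                    tasks.append(("V", k, j))
                    if how == "wm":
                        tasks.append(("WM", i, k - 1))
        return tuple(sorted(pairs))


def _engine(seq: NucleicSequence, model: EnergyModel):
    residues = _norm(seq.residues)
    if model.kind is EnergyModelKind.TOY:
        return _PairSumEngine(residues, model)
    return _LoopEngine(residues, model)


# ---------------------------------------------------------------------------
# Public folding API


def partition_function(seq: NucleicSequence, model: EnergyModel) -> EnsembleResult:
    """Boltzmann partition function Z = sum over structures of exp(-E/RT),
    reported in log space; exact over the same structure space as
    :func:`enumerate_structures`."""
    eng = _engine(seq, model)
    return EnsembleResult(log_z=float(eng.log_z), temperature=model.temperature,
                          model=model.describe())


def mfe_structure(seq: NucleicSequence, model: EnergyModel) -> tuple:
    """A minimum-free-energy structure and its energy. The backtrack uses a
    fixed deterministic preference (pair rather than leave unpaired, then
    smallest partner index) so co-optimal ties resolve reproducibly."""
    eng = _engine(seq, model)
    pairs, energy = eng.mfe()
    return SecondaryStructure(len(seq), pairs), float(energy)


def sample_structures(seq: NucleicSequence, model: EnergyModel,
                      n: int, seed: int) -> StructureSample:
    """n independent draws from the Boltzmann ensemble by stochastic
    backtracking of the partition-function tables; identical (seed, inputs)
    give identical samples."""
    if n < 1:
        raise InputError("sample size must be >= 1")
    eng = _engine(seq, model)
    rng = np.random.default_rng(seed)
    structures = tuple(SecondaryStructure(len(seq), eng.sample(rng))
                       for _ in range(n))
    return StructureSample(structures=structures, n=n, seed=seed)
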