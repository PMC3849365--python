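"""Folding: structure validation, energies, enumeration oracle, partition
function, MFE and Boltzmann sampling, cross-checked against independent
re-implementations on small inputs."""
import math
from collections import Counter

import numpy as np
import pytest

from spshift import (Alphabet, DataError, EnergyModel, InputError,
                     NucleicSequence, boltzmann_probabilities,
                     enumerate_structures, mfe_structure, partition_function,
                     sample_structures, structure_energy, validate_structure)
from spshift.folding import MIN_HAIRPIN, _parse_param_file
from spshift.fixtures import random_sequence

from conftest import make_random_sequences


def rna(residues, id="s"):
    return NucleicSequence(id, residues, Alphabet.RNA)


# ---------------------------------------------------------------------------
# independent oracles, kept deliberately naive


def naive_energy(struct, seq, model):
    """Energy re-summation written independently of the main code path:
    walks the pair list and, for the nearest-neighbor model, classifies each
    loop by directly scanning the pairing table."""
    pm = {}
    for i, j in struct.pairs:
        pm[i] = j
        pm[j] = i
    res = seq.residues.replace("T", "U")
    if model.kind.value == "toy":
        return sum(model.pair_energies["".join(sorted(res[i - 1] + res[j - 1]))]
                   for i, j in struct.pairs)
    total = 0.0
    for i, j in struct.pairs:
        # find the loop closed by (i, j) by scanning inward
        kids = []
        k = i + 1
        while k < j:
            if k in pm and pm[k] > k:
                kids.append((k, pm[k]))
                k = pm[k] + 1
            else:
                k += 1
        if not kids:
            total += model.hairpin_energy(j - i - 1)
        elif len(kids) == 1:
            (k, l) = kids[0]
            left, right = k - i - 1, j - l - 1
            if left == right == 0:
                total += model.stacks[(res[i - 1] + res[j - 1],
                                       res[k - 1] + res[l - 1])]
            elif min(left, right) == 0:
                total += model.bulge_energy(left + right)
            else:
                total += model.internal_energy(left + right)
        else:
            unpaired = (j - i - 1) - sum(l - k + 1 for k, l in kids)
            total += (model.ml_closing + model.ml_branch * len(kids)
                      + model.ml_unpaired * unpaired)
    return total


def count_structures(residues, model):
    """Independent memoized count recursion over the same pairing rules."""
    n = len(residues)
    memo = {}

    def c(i, j):
        if j - i < MIN_HAIRPIN + 1:
            return 1
        if (i, j) in memo:
            return memo[(i, j)]
        total = c(i + 1, j)
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if model.can_pair(residues[i], residues[k]):
                total += c(i + 1, k - 1) * c(k + 1, j)
        memo[(i, j)] = total
        return total

    return c(0, n - 1)


# ---------------------------------------------------------------------------


class TestValidateStructure:
    def test_open_chain(self, toy):
        s = validate_structure("....", rna("ACGU"))
        assert s.is_open and s.dot_bracket == "...."

    def test_pairs_parsed(self):
        s = validate_structure("((...))", rna("GGAAACC"))
        assert s.pairs == ((1, 7), (2, 6))

    def test_non_canonical_rejected(self):
        with pytest.raises(InputError, match="non-canonical"):
            validate_structure("(...)", rna("AAAAA"))

    def test_unbalanced_rejected(self):
        with pytest.raises(InputError, match="unbalanced"):
            validate_structure("((...)", rna("GGAAAC"))

    def test_short_hairpin_rejected(self):
        with pytest.raises(InputError, match="hairpin"):
            validate_structure("(..)", rna("GAAC"))

    def test_lonely_pair_policy(self, toy):
        seq = rna("GGAAACCAGAAAC")
        model = EnergyModel.toy(no_lonely_pairs=True)
        validate_structure("((...))......", seq, model)  # stacked: fine
        with pytest.raises(InputError, match="lonely"):
            validate_structure("........(...)", seq, model)


class TestStructureEnergy:
    def test_open_chain_is_reference_state(self, toy, nn_rna):
        seq = rna("GGGAAACCC")
        s = validate_structure(".........", seq)
        assert structure_energy(s, seq, toy) == 0.0
        assert structure_energy(s, seq, nn_rna) == 0.0

    def test_toy_pair_sum(self, toy):
        seq = rna("GGAAACC")
        s = validate_structure("((...))", seq)
        assert structure_energy(s, seq, toy) == pytest.approx(-6.0)

    @pytest.mark.parametrize("model_name", ["toy", "nn_rna"])
    def test_matches_naive_resummation(self, model_name, request):
        model = request.getfixturevalue(model_name)
        for seed, seq in enumerate(make_random_sequences(8, 15, 22, base_seed=40)):
            for s in sample_structures(seq, EnergyModel.toy(), 20, seed).structures:
                try:
                    expected = naive_energy(s, seq, model)
                except DataError:
                    continue
                assert structure_energy(s, seq, model) == pytest.approx(expected)


class TestEnumeration:
    def test_unpairable_sequence_has_only_open_chain(self, toy):
        assert len(enumerate_structures(rna("AAAA"), toy)) == 1

    def test_single_possible_pair(self, toy):
        structs = enumerate_structures(rna("GAAAC"), toy)
        assert sorted(s.dot_bracket for s in structs) == ["(...)", "....."]

    @pytest.mark.parametrize("residues", ["GGGAAAACCC", "GCGCAAAGCGC",
                                          "GGAUAUCCAAGG"])
    def test_count_matches_independent_recursion(self, residues, toy):
        structs = enumerate_structures(rna(residues), toy)
        assert len(structs) == count_structures(residues, toy)
        assert len({s.pairs for s in structs}) == len(structs)  # exactly once
        assert any(s.is_open for s in structs)

    def test_cutoff_enforced(self, toy):
        with pytest.raises(DataError, match="cutoff"):
            enumerate_structures(random_sequence(40, 0.5, seed=1), toy)

    def test_no_lonely_pairs_filter(self):
        model = EnergyModel.toy(no_lonely_pairs=True)
        structs = enumerate_structures(rna("GGAAACC"), model)
        for s in structs:
            ps = set(s.pairs)
            for i, j in s.pairs:
                assert (i + 1, j - 1) in ps or (i - 1, j + 1) in ps


class TestPartitionFunction:
    def test_unpairable_z_is_one(self, toy):
        assert partition_function(rna("AAAA"), toy).z == pytest.approx(1.0)

    @pytest.mark.parametrize("model_name", ["toy", "nn_rna"])
    def test_dp_equals_enumeration(self, model_name, request):
        model = request.getfixturevalue(model_name)
        for seq in make_random_sequences(12, 15, 25, base_seed=7):
            structs = enumerate_structures(seq, model)
            z_brute = sum(math.exp(-structure_energy(s, seq, model) / model.rt)
                          for s in structs)
            z_dp = partition_function(seq, model).z
            assert abs(z_dp - z_brute) / z_brute < 1e-9

    def test_invariant_under_transliteration(self, toy, toy_dna):
        seq = random_sequence(30, 0.5, seed=5)
        z_rna = partition_function(seq, toy).log_z
        z_dna = partition_function(seq.transliterate(Alphabet.DNA), toy_dna).log_z
        assert z_rna == pytest.approx(z_dna, abs=1e-12)

    def test_log_z_nonnegative_and_bounds_mfe_weight(self, toy):
        for seq in make_random_sequences(6, 18, 24, base_seed=21):
            result = partition_function(seq, toy)
            assert result.log_z >= 0
            _, energy = mfe_structure(seq, toy)
            # the MFE structure's weight is part of the ensemble
            assert result.log_z >= -energy / toy.rt - 1e-9

    def test_stable_at_250nt(self, toy):
        seq = random_sequence(250, 0.6, seed=3)
        result = partition_function(seq, toy)
        assert np.isfinite(result.log_z) and result.log_z > 0

    def test_dp_rejects_no_lonely_pairs(self):
        model = EnergyModel.toy(no_lonely_pairs=True)
        with pytest.raises(NotImplementedError):
            partition_function(rna("GGAAACC"), model)


class TestMfe:
    def test_unpairable_gives_open_chain(self, toy):
        s, e = mfe_structure(rna("AAAA"), toy)
        assert s.is_open and e == 0.0

    @pytest.mark.parametrize("model_name", ["toy", "nn_rna"])
    def test_energy_matches_enumeration_minimum(self, model_name, request):
        model = request.getfixturevalue(model_name)
        for seq in make_random_sequences(12, 15, 25, base_seed=60):
            structs = enumerate_structures(seq, model)
            best = min(structure_energy(s, seq, model) for s in structs)
            mfe, energy = mfe_structure(seq, model)
            assert energy == pytest.approx(best, abs=1e-9)
            assert structure_energy(mfe, seq, model) == pytest.approx(energy)

    def test_unpaired_flank_never_raises_toy_mfe(self, toy):
        # unpaired bases cost nothing, so adding flanks cannot hurt
        for seq in make_random_sequences(5, 15, 20, base_seed=77):
            _, e0 = mfe_structure(seq, toy)
            flanked = rna("AAAA" + seq.residues + "AAAA")
            _, e1 = mfe_structure(flanked, toy)
            assert e1 <= e0 + 1e-9


class TestSampling:
    def test_unpairable_yields_open_chains(self, toy):
        sample = sample_structures(rna("AAAA"), toy, 10, seed=1)
        assert all(s.is_open for s in sample.structures)

    def test_reproducible_and_seed_sensitive(self, toy):
        seq = random_sequence(25, 0.6, seed=2)
        a = sample_structures(seq, toy, 50, seed=9)
        b = sample_structures(seq, toy, 50, seed=9)
        c = sample_structures(seq, toy, 50, seed=10)
        assert a.structures == b.structures
        assert a.structures != c.structures

    @pytest.mark.parametrize("model_name", ["toy", "nn_rna"])
    def test_frequencies_match_boltzmann(self, model_name, request):
        """Empirical structure frequencies agree with exact ensemble
        probabilities within 3 standard errors (using the more conservative
        of the exact and empirical binomial variances, which keeps the
        bound meaningful for rare structures)."""
        model = request.getfixturevalue(model_name)
        seq = random_sequence(22, 0.5, seed=14)
        structs = enumerate_structures(seq, model)
        probs = boltzmann_probabilities(structs, seq, model)
        n = 5000
        counts = Counter(
            s.pairs for s in sample_structures(seq, model, n, seed=4).structures)
        assert sum(counts.values()) == n
        for s, p in zip(structs, probs):
            emp = counts.get(s.pairs, 0) / n
            var = max(p * (1 - p), emp * (1 - emp), 1.0 / n)
            assert abs(emp - p) <= 3 * math.sqrt(var / n)

    def test_sampled_structures_are_valid(self, toy):
        seq = random_sequence(30, 0.6, seed=8)
        for s in sample_structures(seq, toy, 50, seed=3).structures:
            validate_structure(s.dot_bracket, seq, toy)  # raises on violation


class TestParameterFiles:
    def test_custom_file_roundtrip(self, tmp_path):
        p = tmp_path / "mini.par"
        p.write_text("[stacks]\npairs GC CG\nGC -3.3 -3.4\nCG -2.4 -3.3\n"
                     "[hairpin]\n3 5.0\n[bulge]\n1 3.0\n[internal]\n2 2.0\n"
                     "[multiloop]\na 3.0\nb 0.5\nc 0.1\n")
        model = EnergyModel.nearest_neighbor(path=p)
        assert model.stack_energy("GC", "CG") == -3.4
        assert model.ml_branch == 0.5
        # Jacobson-Stockmayer extrapolation beyond the table
        assert model.hairpin_energy(6) == pytest.approx(
            5.0 + 1.75 * model.rt * math.log(2))

    def test_missing_section_rejected(self):
        with pytest.raises(DataError, match="missing"):
            _parse_param_file("[stacks]\npairs GC\nGC -3.3\n")

    def test_missing_stack_entry_raises(self, tmp_path):
        p = tmp_path / "mini.par"
        p.write_text("[stacks]\npairs GC\nGC -3.3\n[hairpin]\n3 5.0\n"
                     "[bulge]\n1 3.0\n[internal]\n2 2.0\n[multiloop]\na 3\n")
        model = EnergyModel.nearest_neighbor(path=p)
        with pytest.raises(DataError, match="absent"):
            model.stack_energy("AU", "GC")

    def test_bundled_tables_cover_all_allowed_pairs(self, nn_rna, nn_dna):
        pairs = ["AU", "UA", "CG", "GC", "GU", "UG"]
        for model in (nn_rna, nn_dna):
            for a in pairs:
                for b in pairs:
                    assert np.isfinite(model.stack_energy(a, b))
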