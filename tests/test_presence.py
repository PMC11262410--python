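import logging
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from gliaprot.io import Assay, Compartment, FormatError
from gliaprot.presence import (ConsensusSet, PresenceMatrix, SpeciesHomologBridge,
                               bridge_species, build_consensus, call_presence,
                               log2_fold_change, presence_matrix, translated_subset)
from .conftest import make_library, make_manifest


class TestCallPresence:
    @pytest.mark.parametrize("tpm,expected", [
        (10.0, False),       # strictly greater than the threshold
        (10.000001, True),
        (10.1, True),
        (0.0, False),
    ])
    def test_threshold_is_strict(self, tpm, expected):
        lib = make_library({"g1": [tpm]})
        assert bool(call_presence(lib)["g1"]) is expected

    def test_max_over_samples(self):
        lib = make_library({"g1": [4.0, 12.0], "g2": [4.0, 9.0]})
        calls = call_presence(lib)
        assert bool(calls["g1"]) and not bool(calls["g2"])

    def test_mean_aggregate_available(self):
        lib = make_library({"g1": [4.0, 12.0]})
        assert not bool(call_presence(lib, aggregate="mean")["g1"])

    def test_zero_samples_rejected(self):
        with pytest.raises(FormatError, match="no sample columns"):
            make_library({"g1": []})

    def test_lower_threshold_never_shrinks(self, rng):
        lib = make_library({f"g{i}": list(rng.uniform(0, 30, 3)) for i in range(40)})
        loose = set(call_presence(lib, threshold=5).pipe(lambda s: s.index[s]))
        tight = set(call_presence(lib, threshold=15).pipe(lambda s: s.index[s]))
        assert tight <= loose


class TestBridgeSpecies:
    def test_or_merge(self):
        calls = pd.Series({"r1": True, "r2": False})
        bridge = SpeciesHomologBridge.from_pairs([("r1", "m1"), ("r2", "m1")])
        assert bool(bridge_species(calls, bridge)["m1"])

    def test_fan_out(self):
        calls = pd.Series({"r1": True})
        bridge = SpeciesHomologBridge.from_pairs([("r1", "m1"), ("r1", "m2")])
        out = bridge_species(calls, bridge)
        assert bool(out["m1"]) and bool(out["m2"])

    def test_unmapped_dropped_and_logged(self, caplog):
        calls = pd.Series({"r1": True, "r3": True})
        bridge = SpeciesHomologBridge.from_pairs([("r1", "m1")])
        with caplog.at_level(logging.INFO):
            out = bridge_species(calls, bridge)
        assert "1 unmapped" in caplog.text
        assert "r3" not in out.index and list(out.index) == ["m1"]

    def test_empty_bridge_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            SpeciesHomologBridge.from_pairs([])

    def test_self_pair_rejected(self):
        with pytest.raises(ValueError, match="self-pair"):
            SpeciesHomologBridge.from_pairs([("g1", "g1")])

    def test_presence_preserved_on_random_bridges(self, rng):
        # a target is present iff at least one mapped source is present
        sources = [f"r{i}" for i in range(20)]
        targets = [f"m{i}" for i in range(10)]
        pairs = [(s, targets[rng.integers(10)]) for s in sources]
        calls = pd.Series(rng.random(20) < 0.4, index=sources)
        out = bridge_species(calls, SpeciesHomologBridge.from_pairs(pairs))
        for t in out.index:
            expect = any(calls[s] for s, tt in pairs if tt == t)
            assert bool(out[t]) is expect


def _matrix(columns: dict[str, list[bool]], genes: list[str],
            assays=None, compartments=None) -> PresenceMatrix:
    manifests = []
    for i, lib_id in enumerate(columns):
        manifests.append(make_manifest(
            lib_id,
            assay=(assays or {}).get(lib_id, Assay.TRANSCRIPTOME),
            compartment=(compartments or {}).get(lib_id, Compartment.PROTRUSION)))
    calls = pd.DataFrame(columns, index=genes)
    return PresenceMatrix(calls, manifests, threshold_used=10.0)


class TestConsensus:
    def test_counting_rule(self):
        genes = ["g1", "g2"]
        cols = {f"l{i}": [i < 7, i < 6] for i in range(11)}
        cons = build_consensus(_matrix(cols, genes), min_support=7)
        assert cons.members() == frozenset({"g1"})
        assert cons.support["g2"] == 6

    def test_min_support_zero_returns_whole_space(self):
        cols = {"l1": [True, False], "l2": [False, False]}
        cons = build_consensus(_matrix(cols, ["g1", "g2"]), min_support=0)
        assert cons.members() == frozenset({"g1", "g2"})

    def test_two_by_three_enumeration(self):
        cols = {"l1": [True, True], "l2": [True, False], "l3": [False, False]}
        cons = build_consensus(_matrix(cols, ["g1", "g2"]), min_support=2)
        assert cons.members() == frozenset({"g1"})

    def test_min_support_above_library_count_rejected(self):
        cols = {"l1": [True], "l2": [True]}
        with pytest.raises(ValueError, match="min_support"):
            build_consensus(_matrix(cols, ["g1"]), min_support=3)

    def test_soma_columns_never_vote(self):
        cols = {"l1": [True], "l2": [True], "soma": [True]}
        m = _matrix(cols, ["g1"], compartments={"soma": Compartment.SOMA})
        cons = build_consensus(m, min_support=3 - 1)
        assert cons.n_libraries == 2

    def test_matches_brute_force_recount(self, rng):
        for _ in range(20):
            n_genes = int(rng.integers(1, 51))
            genes = [f"g{i}" for i in range(n_genes)]
            cols = {f"l{j}": list(rng.random(n_genes) < 0.5) for j in range(11)}
            m = _matrix(cols, genes)
            k = int(rng.integers(0, 12))
            cons = build_consensus(m, min_support=k)
            brute = {g for i, g in enumerate(genes)
                     if sum(cols[f"l{j}"][i] for j in range(11)) >= k}
            assert cons.members() == frozenset(brute)

    @given(st.lists(st.lists(st.booleans(), min_size=11, max_size=11),
                    min_size=1, max_size=50),
           st.integers(min_value=0, max_value=11))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_consensus_equals_recount_hypothesis(self, rows, k):
        genes = [f"g{i}" for i in range(len(rows))]
        cols = {f"l{j}": [rows[i][j] for i in range(len(rows))] for j in range(11)}
        cons = build_consensus(_matrix(cols, genes), min_support=k)
        brute = {g for g, row in zip(genes, rows) if sum(row) >= k}
        assert cons.members() == frozenset(brute)

    def test_members_nested_in_support(self):
        cols = {f"l{i}": [True] * (i + 1) + [False] * (10 - i) for i in range(5)}
        cons = build_consensus(_matrix(cols, [f"g{i}" for i in range(11)]), min_support=0)
        for k in range(5):
            assert cons.members(k + 1) <= cons.members(k)


class TestTranslatedSubset:
    def _trap_matrix(self, calls_per_lib):
        genes = ["g1", "g2", "g3"]
        assays = {f"t{i}": Assay.TRAP for i in range(4)}
        return _matrix({f"t{i}": calls_per_lib[i] for i in range(4)}, genes, assays=assays)

    def test_all_four_retained(self):
        trap = self._trap_matrix([[True, True, False]] * 4)
        out = translated_subset(frozenset({"g1", "g3"}), trap, min_trap=4)
        assert out == frozenset({"g1"})  # g3 not in 4/4; g2 not in consensus

    def test_three_of_four_setting(self):
        calls = [[True], [True], [True], [False]]
        trap = self._trap_matrix([[c[0], False, False] for c in calls])
        members = frozenset({"g1"})
        assert translated_subset(members, trap, min_trap=4) == frozenset()
        assert translated_subset(members, trap, min_trap=3) == members

    def test_subset_of_consensus(self):
        trap = self._trap_matrix([[True, True, True]] * 4)
        for k in range(5):
            out = translated_subset(frozenset({"g2"}), trap, min_trap=k)
            assert out <= frozenset({"g2"})

    def test_min_trap_above_library_count_rejected(self):
        trap = self._trap_matrix([[True]] * 4)
        with pytest.raises(ValueError, match="min_trap"):
            translated_subset(frozenset(), trap, min_trap=5)


class TestLog2FoldChange:
    def test_values(self):
        assert log2_fold_change(30, 10, pseudocount=0) == pytest.approx(math.log2(3))
        assert log2_fold_change(10, 10, pseudocount=5) == 0.0
        assert log2_fold_change(0, 0, pseudocount=1) == 0.0

    def test_zero_with_zero_pseudocount_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            log2_fold_change(0, 0, pseudocount=0)


class TestPresenceMatrixConstruction:
    def test_bridged_library_harmonized(self):
        mouse = make_library({"m1": [50.0], "m2": [1.0]}, library_id="libM")
        rat = make_library({"r1": [50.0]}, library_id="libR")
        bridge = SpeciesHomologBridge.from_pairs([("r1", "m2")])
        m = presence_matrix([mouse, rat], bridges={"libR": bridge})
        assert bool(m.calls.loc["m2", "libR"])
        assert not bool(m.calls.loc["m2", "libM"])
        # genes absent from a library's table are not-present there
        assert not bool(m.calls.loc["m1", "libR"])
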