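import numpy as np
import pytest

import premirclass as pm
from premirclass.errors import DegenerateInputError
from premirclass.features import FEATURE_GROUPS

from conftest import random_rna


def test_canonical_name_blocks():
    assert len(pm.TRIPLET_NAMES) == 32
    assert len(pm.BASE_PAIR_NAMES) == 15
    assert len(pm.THERMO_NAMES) == 18
    assert len(pm.ALL_FEATURE_NAMES) == 65
    assert len(set(pm.ALL_FEATURE_NAMES)) == 65
    assert {FEATURE_GROUPS[n] for n in pm.ALL_FEATURE_NAMES} == {
        "triplet",
        "base_pair",
        "thermodynamic",
    }


def test_triplet_single_category():
    rec = pm.SequenceRecord("a", "AAAAA")
    feats = pm.triplet_features(rec, ".....")
    assert feats["A..."] == 1.0
    assert sum(v for k, v in feats.items() if k != "A...") == 0.0


def test_triplet_hand_enumeration(gc_hairpin):
    """The 8 windows of (((....))) classified by hand."""
    feats = pm.triplet_features(gc_hairpin, "(((....)))")
    expected = {
        "G(((": 1 / 8,
        "G((.": 1 / 8,
        "A(..": 1 / 8,
        "A...": 2 / 8,
        "A..(": 1 / 8,
        "C.((": 1 / 8,
        "C(((": 1 / 8,
    }
    for name, value in expected.items():
        assert feats[name] == pytest.approx(value), name
    assert sum(feats.values()) == pytest.approx(1.0)


def test_triplet_frequencies_sum_to_one(model):
    rng = np.random.default_rng(0)
    for t in range(20):
        rec = pm.SequenceRecord(f"r{t}", random_rna(rng, int(rng.integers(3, 50))))
        structure, _ = pm.fold_mfe(rec, model)
        assert sum(pm.triplet_features(rec, structure).values()) == pytest.approx(1.0)


def test_triplet_needs_three_nucleotides():
    with pytest.raises(DegenerateInputError):
        pm.triplet_features(pm.SequenceRecord("s", "AC"), "..")


def test_base_pair_hand_values(gc_hairpin, model):
    fold = pm.partition_function(gc_hairpin, model)
    stats = pm.structure_stats(gc_hairpin, fold.structure)
    feats = pm.base_pair_features(gc_hairpin, stats, fold)
    assert feats["dP"] == pytest.approx(0.3)
    assert feats["Avg_BP_Stem"] == pytest.approx(3.0)
    assert feats["|G-C|/L"] == pytest.approx(0.3)
    assert feats["dP/n_loops"] == pytest.approx(0.3)
    assert feats["%(G-C)/n_loops"] == pytest.approx(1.0)
    assert feats["%(A-U)/n_loops"] == pytest.approx(0.0)
    assert feats["G/C_ratio"] == pytest.approx(1.0)
    assert feats["%C+G"] == pytest.approx(60.0)


def test_degenerate_denominators_resolve_to_zero(model):
    rec = pm.SequenceRecord("a", "AAAAAAAA")  # unpairable, C-free
    fold = pm.partition_function(rec, model)
    stats = pm.structure_stats(rec, fold.structure)
    feats = pm.base_pair_features(rec, stats, fold)
    for name in ["G/C_ratio", "dP", "Avg_BP_Stem", "dP/n_loops", "%(G-C)/n_loops"]:
        assert feats[name] == 0.0
    null = pm.null_statistics(rec, model, n=3, seed=0)
    thermo = pm.thermo_features(rec, stats, fold, null, model)
    assert thermo["dG"] == 0.0
    assert all(thermo[f"MFEI_{i}"] == 0.0 for i in (1, 2, 3, 4))
    assert thermo["Freq"] == 1.0 and thermo["NEFE"] == 0.0 and thermo["Diff"] == 0.0
    assert thermo["z-score_MFE"] == 0.0 and thermo["p-value_MFE"] == 1.0


def test_multi_loop_features_halve_with_two_loops(two_branch, model):
    """At fixed dP, dP/n_loops with two loops is half the one-loop value."""
    rec, struct = two_branch
    fold = pm.partition_function(rec, model)
    stats = pm.structure_stats(rec, struct)
    feats = pm.base_pair_features(rec, stats, fold)
    assert stats.n_loops == 2
    assert feats["dP/n_loops"] == pytest.approx(feats["dP"] / 2)
    assert feats["%(G-C)/n_loops"] == pytest.approx(0.5)  # all pairs GC, 2 loops


def test_thermo_hand_values(gc_hairpin, model):
    fold = pm.partition_function(gc_hairpin, model)
    stats = pm.structure_stats(gc_hairpin, fold.structure)
    null = pm.null_statistics(gc_hairpin, model, n=10, seed=0)
    feats = pm.thermo_features(gc_hairpin, stats, fold, null, model)
    assert feats["dG"] == pytest.approx(-0.9)
    assert feats["MFEI_1"] == pytest.approx(-0.9 / 60)
    assert feats["MFEI_2"] == pytest.approx(-0.9)
    assert feats["MFEI_3"] == pytest.approx(-0.9)
    assert feats["MFEI_4"] == pytest.approx(-3.0)
    assert feats["NEFE"] == pytest.approx(fold.efe / 10)
    assert feats["Diff"] == pytest.approx(abs(fold.mfe - fold.efe) / 10)
    # two GC/GC stacks of the (unbulged) 3-pair stem
    assert feats["dH"] == pytest.approx(2 * -13.39)


def test_mfei34_swap(gc_hairpin, model):
    fold = pm.partition_function(gc_hairpin, model)
    stats = pm.structure_stats(gc_hairpin, fold.structure)
    null = pm.null_statistics(gc_hairpin, model, n=5, seed=0)
    default = pm.thermo_features(gc_hairpin, stats, fold, null, model)
    swapped = pm.thermo_features(gc_hairpin, stats, fold, null, model, mfei34_swapped=True)
    assert swapped["MFEI_3"] == default["MFEI_4"]
    assert swapped["MFEI_4"] == default["MFEI_3"]


def test_extract_all_shape_and_determinism(gc_hairpin):
    v1 = pm.extract_all(gc_hairpin, n_shuffles=10, seed=4)
    v2 = pm.extract_all(gc_hairpin, n_shuffles=10, seed=4)
    assert v1.names == pm.ALL_FEATURE_NAMES and len(v1.values) == 65
    assert np.all(np.isfinite(v1.values))
    assert np.array_equal(v1.values, v2.values)


def test_extraction_invariant_to_record_order(gc_hairpin):
    other = pm.SequenceRecord("o", "GGGGAAAACCCCAAAAGGGG")
    m1 = pm.extract_matrix([gc_hairpin, other], n_shuffles=10, seed=4)
    m2 = pm.extract_matrix([other, gc_hairpin], n_shuffles=10, seed=4)
    assert np.array_equal(m1.X[0], m2.X[1]) and np.array_equal(m1.X[1], m2.X[0])


def test_feature_matrix_tsv_round_trip(tmp_path, separable_table):
    path = tmp_path / "features.tsv"
    separable_table.to_tsv(path)
    back = pm.FeatureMatrix.from_tsv(path)
    assert back.ids == separable_table.ids
    assert back.names == separable_table.names
    assert np.allclose(back.X, separable_table.X)
    assert np.array_equal(back.labels, separable_table.labels)
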