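import numpy as np
import pytest

import premirclass as pm
from premirclass.errors import InconsistentStructureError, StructureParseError

from conftest import random_rna


def brute_force_ensemble(seq, model):
    """Z, MFE and pair weights by exhaustive enumeration (independent oracle)."""
    z = 0.0
    mfe = 0.0
    pair_weight = {}
    for pairs in pm.enumerate_structures(seq, model):
        e = pm.structure_energy(seq, pairs, model)
        w = np.exp(-e / model.rt)
        z += w
        mfe = min(mfe, e)
        for p in pairs:
            pair_weight[p] = pair_weight.get(p, 0.0) + w
    return z, mfe, pair_weight


def test_unpairable_sequence_folds_open(model):
    rec = pm.SequenceRecord("a", "AAAA")
    assert pm.fold_mfe(rec, model) == ("....", 0.0)
    fr = pm.partition_function(rec, model)
    assert fr.log_z == 0.0 and fr.efe == 0.0 and fr.freq == 1.0 and fr.diversity == 0.0


def test_gc_hairpin_optimum(gc_hairpin, model):
    structure, mfe = pm.fold_mfe(gc_hairpin, model)
    assert structure == "(((....)))" and mfe == -9.0
    _, brute_mfe, _ = brute_force_ensemble(gc_hairpin.seq, model)
    assert mfe == brute_mfe


def test_dp_matches_enumeration_on_random_sequences(model):
    """MFE exactly, Z / bp probabilities / diversity to 1e-9 on small inputs."""
    rng = np.random.default_rng(42)
    for t in range(50):
        seq = random_rna(rng, int(rng.integers(1, 15)))
        rec = pm.SequenceRecord(f"r{t}", seq)
        z, mfe, pw = brute_force_ensemble(seq, model)
        _, dp_mfe = pm.fold_mfe(rec, model)
        fr = pm.partition_function(rec, model)
        assert dp_mfe == pytest.approx(mfe, abs=1e-12)
        assert np.exp(fr.log_z) == pytest.approx(z, rel=1e-9)
        for pair in set(pw) | set(fr.bp_probs):
            assert fr.bp_probs.get(pair, 0.0) == pytest.approx(
                pw.get(pair, 0.0) / z, abs=1e-9
            )


def test_efe_never_exceeds_mfe(model):
    rng = np.random.default_rng(3)
    for t in range(20):
        rec = pm.SequenceRecord(f"r{t}", random_rna(rng, int(rng.integers(5, 40))))
        fr = pm.partition_function(rec, model)
        assert fr.efe <= fr.mfe + 1e-9
        assert 0.0 < fr.freq <= 1.0


@pytest.mark.parametrize(
    "structure,pairs",
    [("....", []), ("((...))", [(1, 7), (2, 6)]), ("(.)", [(1, 3)])],
)
def test_parse_dot_bracket(structure, pairs):
    assert pm.parse_dot_bracket(structure) == pairs


@pytest.mark.parametrize("structure", ["((.", ".)", "(x)"])
def test_parse_dot_bracket_errors(structure):
    with pytest.raises(StructureParseError):
        pm.parse_dot_bracket(structure)


def test_structure_stats_single_hairpin(gc_hairpin):
    stats = pm.structure_stats(gc_hairpin, "(((....)))")
    assert stats.n_bp == 3 and stats.n_stems == 1 and stats.n_loops == 1
    assert stats.pair_type_counts == {"AU": 0, "GC": 3, "GU": 0}


def test_structure_stats_two_branch(two_branch):
    rec, struct = two_branch
    stats = pm.structure_stats(rec, struct)
    assert stats.n_loops == 2 and stats.n_stems == 3 and stats.n_bp == 6


def test_structure_stats_all_dots(gc_hairpin):
    stats = pm.structure_stats(gc_hairpin, "." * 10)
    assert stats.n_bp == stats.n_stems == stats.n_loops == 0


def test_structure_stats_rejects_illegal_pair():
    rec = pm.SequenceRecord("bad", "GGGGAAAAGGGG")
    with pytest.raises(InconsistentStructureError):
        pm.structure_stats(rec, "((((....))))")  # G-G cannot pair


def test_stats_ignore_unpaired_sequence_content(two_branch):
    rec, struct = two_branch
    base = pm.structure_stats(rec, struct)
    mutated = list(rec.seq)
    for pos, ch in enumerate(struct):
        if ch == ".":
            mutated[pos] = "A"
    other = pm.structure_stats(pm.SequenceRecord("mut", "".join(mutated)), struct)
    assert (base.n_bp, base.n_stems, base.n_loops) == (
        other.n_bp,
        other.n_stems,
        other.n_loops,
    )
    assert base.pair_type_counts == other.pair_type_counts


def test_traceback_is_deterministic(model):
    rng = np.random.default_rng(9)
    for t in range(10):
        rec = pm.SequenceRecord(f"r{t}", random_rna(rng, 30))
        assert pm.fold_mfe(rec, model) == pm.fold_mfe(rec, model)
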