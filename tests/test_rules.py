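"""Rule-based predictors: worked examples, commutativity, closure."""

import numpy as np
import pytest

from metasyn.rules import (
    RuleVariant,
    predict_combined,
    predict_dataset,
    predict_lssc,
    predict_ss,
    transitive_closure,
)
from metasyn.synthgen import SynthConfig, generate
from metasyn.vocab import AtomTuple, build_atoms

DIS = frozenset({"Disorders"})


def closure_bruteforce(atoms) -> np.ndarray:
    """Floyd-Warshall reachability over the pairwise combined-rule graph."""
    n = len(atoms)
    m = np.zeros((n, n), dtype=bool)
    for i, a in enumerate(atoms):
        for j, b in enumerate(atoms):
            m[i, j] = i == j or bool(predict_combined(a, b))
    for k in range(n):
        m |= m[:, k : k + 1] & m[k : k + 1, :]
    return m


def test_source_synonymy_worked_example(headache_atoms):
    t1, t2, t3, t4, t5, t6 = headache_atoms
    assert predict_ss(t1, t3) == 1  # same SCUI within one source
    assert predict_ss(t4, t5) == 0  # same string, different sources
    assert predict_ss(t1, t5) == 0
    assert predict_ss(t1, t1) == 1  # reflexive with SCUI present


def test_source_synonymy_requires_same_source():
    a, b = build_atoms(
        [AtomTuple("x", "SRC1", "123", DIS), AtomTuple("y", "SRC2", "123", DIS)]
    )
    assert predict_ss(a, b) == 0


def test_absent_scui_never_fires():
    a, b = build_atoms(
        [AtomTuple("x", "SRC", None, DIS), AtomTuple("x", "SRC", None, DIS)]
    )
    assert predict_ss(a, b) == 0


def test_lexical_semantic_worked_example(headache_atoms):
    t1, t2, t3, t4, t5, t6 = headache_atoms
    assert predict_lssc(t4, t5) == 1  # shared LUI, shared group
    assert predict_lssc(t1, t3) == 0  # different LUIs
    assert predict_lssc(t1, t5) == 0


def test_homonym_pattern_blocked_by_semantic_groups():
    nail_anat = AtomTuple("nail", "ANAT", None, frozenset({"Anatomy"}))
    nail_dev = AtomTuple("nail", "DEV", None, frozenset({"Device"}))
    a, b = build_atoms([nail_anat, nail_dev])
    assert a.lui == b.lui
    assert predict_lssc(a, b) == 0


def test_combined_rule_worked_example(headache_atoms):
    t1, t2, t3, t4, t5, t6 = headache_atoms
    assert predict_combined(t1, t3) == 1
    assert predict_combined(t4, t5) == 1
    assert predict_combined(t1, t5) == 0


def test_combined_dominates_components(small_corpus):
    atoms = small_corpus.atoms[:60]
    for a in atoms[:20]:
        for b in atoms[:20]:
            ss, ls, comb = predict_ss(a, b), predict_lssc(a, b), predict_combined(a, b)
            assert ss <= comb and ls <= comb
            # commutativity
            assert ss == predict_ss(b, a)
            assert ls == predict_lssc(b, a)
            assert comb == predict_combined(b, a)


def test_closure_links_whole_worked_example_concept(headache_atoms):
    part = transitive_closure(headache_atoms)
    comps = part.components()
    assert len(comps) == 1  # SS chains + the shared-string bridge connect all six


def test_closure_without_edges_is_singletons():
    atoms = build_atoms(
        [AtomTuple("alpha", "S1", None, DIS), AtomTuple("beta", "S2", None, DIS)]
    )
    part = transitive_closure(atoms)
    assert len(part.components()) == 2
    single = transitive_closure(atoms[:1])
    assert len(single.components()) == 1


@pytest.mark.parametrize("seed", range(10))
def test_closure_matches_bruteforce_on_random_corpora(seed):
    s = generate(SynthConfig(seed=seed + 100, n_concepts=12))
    atoms = s.atoms[:80]
    part = transitive_closure(atoms)
    expected = closure_bruteforce(atoms)
    for i, a in enumerate(atoms):
        for j, b in enumerate(atoms):
            assert part.predict(a.aui, b.aui) == int(expected[i, j])


def test_predict_dataset_variants(headache_atoms):
    t1, t2, t3, t4, t5, t6 = headache_atoms
    pairs = [(t1.aui, t3.aui), (t4.aui, t5.aui), (t1.aui, t5.aui)]
    combined = predict_dataset(pairs, RuleVariant.SS_LS_SC, headache_atoms)
    assert combined.tolist() == [1, 1, 0]  # 2 of 3 correct against all-positive labels
    trans = predict_dataset(pairs, RuleVariant.SS_LS_SC_TRANS, headache_atoms)
    assert trans.tolist() == [1, 1, 1]
    assert predict_dataset([], RuleVariant.SS, headache_atoms).tolist() == []


def test_closure_chains_through_atoms_outside_the_pair_list(headache_atoms):
    t1, t5 = headache_atoms[0], headache_atoms[4]
    # (t1, t5) alone is 0 pairwise; the chain runs through t3/t4
    preds = predict_dataset([(t1.aui, t5.aui)], RuleVariant.SS_LS_SC_TRANS, headache_atoms)
    assert preds.tolist() == [1]


def test_unknown_aui_is_named():
    atoms = build_atoms([AtomTuple("x", "S", None, DIS), AtomTuple("y", "S", None, DIS)])
    with pytest.raises(KeyError, match="A9999999"):
        predict_dataset([(atoms[0].aui, "A9999999")], RuleVariant.SS, atoms)


def test_recall_monotonic_over_variants(small_corpus):
    """Adding rules and closure can only add predicted-positive pairs."""
    s = small_corpus
    pairs = [(a, b) for (a, b) in list(s.pair_tags)[:500]]
    prev = np.zeros(len(pairs), dtype=int)
    for variant in (RuleVariant.SS, RuleVariant.SS_LS_SC, RuleVariant.SS_LS_SC_TRANS):
        pred = predict_dataset(pairs, variant, s.atoms)
        assert (pred >= prev).all()
        prev = pred
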