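"""Pair-dataset generation: quotas, flags, splits, determinism."""

from collections import Counter

import numpy as np
import pytest

from metasyn.lexsim import build_word_index, jaccard
from metasyn.pairgen import (
    NOSIM,
    SIM,
    DatasetVariant,
    assemble_variant,
    dataset_stats,
    enumerate_pos,
    sample_negatives,
    write_pairs,
)
from metasyn.vocab import ConceptIndex


def _concepts(sizes):
    mapping = {}
    i = 0
    for c, size in enumerate(sizes):
        for _ in range(size):
            mapping[f"A{i:07d}"] = f"C{c}"
            i += 1
    return ConceptIndex(mapping)


@pytest.mark.parametrize(
    "sizes, expected",
    [
        ([6], 30),       # n*(n-1) ordered pairs
        ([1], 0),        # singleton concept: k = 0
        ([2, 2], 4),
        ([3, 1, 2], 8),
    ],
)
def test_positive_pair_counts(sizes, expected):
    pairs = enumerate_pos(_concepts(sizes))
    assert len(pairs) == expected
    assert all(p.label == 1 and p.sim_flag is None for p in pairs)


def test_negative_quotas_and_flags(small_corpus):
    s = small_corpus
    index = build_word_index(s.atoms)
    by_aui = s.atoms_by_aui
    rng = np.random.default_rng(3)
    for atom in s.atoms[:40]:
        k = s.concepts.concept_size(atom.aui) - 1
        claimed: set[str] = set()
        for variant, flag in [
            (DatasetVariant.TOPN_SIM, SIM),
            (DatasetVariant.RAN_SIM, SIM),
            (DatasetVariant.RAN_NOSIM, NOSIM),
        ]:
            pairs = sample_negatives(
                atom, k, variant, index, by_aui, s.concepts, rng, frozenset(claimed)
            )
            quota = 2 * k
            if k == 0:
                quota = 1 if flag == SIM else 0
            assert len(pairs) <= quota
            for p in pairs:
                assert p.label == 0
                assert not s.concepts.same_concept(p.aui_a, p.aui_b)
                score = jaccard(by_aui[p.aui_a], by_aui[p.aui_b])
                assert (score > 0) == (p.sim_flag == SIM)
                assert p.sim_flag == flag
                assert p.aui_b not in claimed
            claimed.update(p.aui_b for p in pairs)


def test_sampling_all_variant_is_union_error(small_corpus):
    s = small_corpus
    index = build_word_index(s.atoms)
    rng = np.random.default_rng(0)
    with pytest.raises(ValueError):
        sample_negatives(
            s.atoms[0], 1, DatasetVariant.ALL, index, s.atoms_by_aui, s.concepts, rng
        )


@pytest.fixture(scope="module")
def all_dataset(small_corpus):
    return assemble_variant(
        small_corpus.atoms, small_corpus.concepts, DatasetVariant.ALL, seed=5
    )


def test_split_arithmetic_and_disjointness(small_corpus, all_dataset):
    ds = all_dataset
    stats = dataset_stats(ds)
    n_pos = stats["learning"]["POS"] + stats["generalization"]["POS"]
    # 80:20 positive split on unordered pairs, each carrying its mirror
    assert abs(stats["learning"]["POS"] - 0.8 * n_pos) <= 2
    # learning further split 75:25
    total_learning = stats["learning"]["TOTAL"]
    assert stats["training"]["TOTAL"] == int(total_learning * 0.75 + 0.5)
    assert stats["training"]["TOTAL"] + stats["validation"]["TOTAL"] == total_learning
    # disjoint as unordered pair sets
    learn_keys = {p.key for p in ds.learning}
    gen_keys = {p.key for p in ds.generalization}
    assert not learn_keys & gen_keys


def test_no_label_leakage(small_corpus, all_dataset):
    concepts = small_corpus.concepts
    by_aui = small_corpus.atoms_by_aui
    for p in all_dataset.learning + all_dataset.generalization:
        assert p.label == int(concepts.same_concept(p.aui_a, p.aui_b))
        if p.label == 0:
            score = jaccard(by_aui[p.aui_a], by_aui[p.aui_b])
            assert (score > 0) == (p.sim_flag == SIM)


def test_per_atom_quota_bound(small_corpus, all_dataset):
    concepts = small_corpus.concepts
    neg_by_atom = Counter(
        p.aui_a
        for p in all_dataset.learning + all_dataset.generalization
        if p.label == 0
    )
    for aui, count in neg_by_atom.items():
        k = concepts.concept_size(aui) - 1
        assert count <= max(6 * k, 2)  # 6k for ALL; k = 0 keeps the two SIM singles


def test_regeneration_is_byte_identical(small_corpus, all_dataset, tmp_path):
    again = assemble_variant(
        small_corpus.atoms, small_corpus.concepts, DatasetVariant.ALL, seed=5
    )
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    write_pairs(all_dataset.learning + all_dataset.generalization, p1)
    write_pairs(again.learning + again.generalization, p2)
    assert p1.read_bytes() == p2.read_bytes()


def test_seed_changes_random_but_not_topn_membership(small_corpus):
    def members(variant, seed):
        ds = assemble_variant(small_corpus.atoms, small_corpus.concepts, variant, seed)
        return {
            (p.aui_a, p.aui_b) for p in ds.learning + ds.generalization if p.label == 0
        }

    assert members(DatasetVariant.TOPN_SIM, 1) == members(DatasetVariant.TOPN_SIM, 2)
    assert members(DatasetVariant.RAN_SIM, 1) != members(DatasetVariant.RAN_SIM, 2)


def test_all_is_union_of_regimes(small_corpus, all_dataset):
    flags = Counter(
        p.sim_flag for p in all_dataset.learning + all_dataset.generalization
        if p.label == 0
    )
    assert flags[SIM] > 0 and flags[NOSIM] > 0
    # negatives of ALL are unique as ordered pairs (regimes are disjoint)
    negs = [
        (p.aui_a, p.aui_b)
        for p in all_dataset.learning + all_dataset.generalization
        if p.label == 0
    ]
    assert len(negs) == len(set(negs))


def test_dedupe_switch_removes_mirrors(small_corpus):
    ds = assemble_variant(
        small_corpus.atoms,
        small_corpus.concepts,
        DatasetVariant.TOPN_SIM,
        seed=5,
        dedupe_unordered=True,
    )
    keys = [p.key for p in ds.learning]
    assert len(keys) == len(set(keys))


def test_stats_partition(all_dataset):
    stats = dataset_stats(all_dataset)
    for side in stats.values():
        assert side["NEG"] + side["POS"] == side["TOTAL"]
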