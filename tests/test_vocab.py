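"""Identifier model, normalizers and file dialects."""

import string

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metasyn.vocab import (
    AtomTuple,
    RRFColumnMap,
    SemanticGroupConfig,
    build_atoms,
    normalize_embed,
    normalize_lvg,
    read_rrf,
    read_sg_config,
    read_tsv,
    write_rrf,
    write_sg_config,
    write_tsv,
)

DIS = frozenset({"Disorders"})

words = st.text(alphabet=string.ascii_lowercase, min_size=1, max_size=8)
terms = st.lists(words, min_size=1, max_size=5).map(" ".join)


@pytest.mark.parametrize(
    "raw, normalized",
    [
        ("Headache", "headache"),
        ("Headaches", "headache"),
        ("headache", "headache"),
        ("Cranial Pains", "cranial pain"),
        ("Headache (finding)", "finding headache"),
        ("Pains, Cranial", "cranial pain"),
        ("bodies", "body"),
        ("classes", "class"),
        ("alpha-1 receptors", "alpha-1 receptor"),
    ],
)
def test_lvg_normalization_folds_variation(raw, normalized):
    assert normalize_lvg(raw) == normalized


@pytest.mark.parametrize(
    "raw, tokens",
    [
        ("Headache (finding)", ["headache", "finding"]),
        ("alpha-1", ["alpha-1"]),
        ("Cranial Pains", ["cranial", "pains"]),
    ],
)
def test_embed_tokenization_preserves_order_and_inflection(raw, tokens):
    assert normalize_embed(raw) == tokens


@given(terms)
@settings(max_examples=200, derandomize=True)
def test_lvg_idempotent_and_order_case_insensitive(term):
    norm = normalize_lvg(term)
    assert normalize_lvg(norm) == norm if norm else True
    assert normalize_lvg(term.upper()) == norm
    reordered = " ".join(reversed(term.split()))
    assert normalize_lvg(reordered) == norm


@given(st.lists(words, min_size=1, max_size=4))
@settings(max_examples=200, derandomize=True)
def test_lvg_singularization_collapses_simple_plurals(tokens):
    term = " ".join(tokens)
    # regular plurals only: -s/-y/-u/-i endings pluralize irregularly
    plural = " ".join(
        t + "s" if not t.endswith(("s", "y", "u", "i")) else t for t in tokens
    )
    assert normalize_lvg(plural) == normalize_lvg(term)


def test_identifier_equality_structure(headache_atoms):
    t1, t2, t3, t4, t5, t6 = headache_atoms
    # same string across sources: one SUI class
    assert t4.sui == t5.sui
    # singular vs plural: different SUIs, same LUI
    assert t1.sui != t2.sui
    assert t1.lui == t2.lui
    # distinct AUIs per occurrence
    assert len({a.aui for a in headache_atoms}) == 6
    # qualifier changes the lexical class
    assert t6.lui != t1.lui


def test_duplicate_rows_are_distinct_atoms():
    tup = AtomTuple("Headache", "MSH", "M0009824", DIS)
    atoms = build_atoms([tup, tup])
    assert atoms[0].aui != atoms[1].aui
    assert atoms[0].sui == atoms[1].sui
    assert atoms[0].lui == atoms[1].lui


@given(st.lists(st.sampled_from(["nail", "Nail", "nails", "ulcer", "sore"]), min_size=1, max_size=8))
@settings(max_examples=100, derandomize=True)
def test_sui_equality_is_exactly_string_equality(strings):
    atoms = build_atoms([AtomTuple(s, "SRC", None, DIS) for s in strings])
    for a in atoms:
        for b in atoms:
            assert (a.sui == b.sui) == (a.term == b.term)
            assert (a.lui == b.lui) == (normalize_lvg(a.term) == normalize_lvg(b.term))


def test_empty_normalization_yields_no_lexical_class():
    atoms = build_atoms([AtomTuple("?!", "SRC", None, DIS)])
    assert atoms[0].lui is None
    assert atoms[0].norm_tokens == frozenset()


def test_atom_tuple_validation():
    with pytest.raises(ValueError):
        AtomTuple("  ", "SRC", None, DIS)
    with pytest.raises(ValueError):
        AtomTuple("term", "SRC", None, frozenset())


def test_rrf_round_trip(tmp_path, headache_atoms):
    sg = SemanticGroupConfig({"MSH": ["Disorders"], "SNOMEDCT_US": ["Disorders"]})
    path = tmp_path / "atoms.rrf"
    write_rrf(headache_atoms, path)
    tuples, index = read_rrf(path, sg)
    assert tuples == [a.tup for a in headache_atoms]
    assert index is None  # no CUI column written
    rebuilt = build_atoms(tuples)
    assert [(a.aui, a.sui, a.lui) for a in rebuilt] == [
        (a.aui, a.sui, a.lui) for a in headache_atoms
    ]


def test_rrf_errors(tmp_path):
    sg = SemanticGroupConfig({"MSH": ["Disorders"]})
    ragged = tmp_path / "ragged.rrf"
    ragged.write_text("C1|ENG|x\n")
    with pytest.raises(ValueError, match="line 1"):
        read_rrf(ragged, sg)
    n = RRFColumnMap().n_cols
    row = [""] * n
    row[11] = "XYZ"
    row[14] = "term"
    unknown = tmp_path / "unknown.rrf"
    unknown.write_text("|".join(row) + "|\n")
    with pytest.raises(ValueError, match="XYZ"):
        read_rrf(unknown, sg)
    empty = tmp_path / "empty.rrf"
    empty.write_text("")
    assert read_rrf(empty, sg) == ([], None)


def test_tsv_round_trip_with_concepts(tmp_path, small_corpus):
    path = tmp_path / "atoms.tsv"
    write_tsv(small_corpus.atoms, path, small_corpus.concepts)
    tuples, index = read_tsv(path)
    assert tuples == small_corpus.tuples
    assert dict(index.items()) == dict(small_corpus.concepts.items())


def test_sg_config_round_trip(tmp_path):
    cfg = SemanticGroupConfig({"MSH": ["Disorders"], "BIG:anat": ["Anatomy", "Disorders"]})
    path = tmp_path / "sg.tsv"
    write_sg_config(cfg, path)
    again = read_sg_config(path)
    assert again.as_dict() == cfg.as_dict()
    assert again.groups_for("BIG", subtree="anat") == frozenset({"Anatomy", "Disorders"})
    with pytest.raises(KeyError, match="NOPE"):
        again.groups_for("NOPE")
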