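"""Exact Jaccard lexical similarity with inverted-index candidate search.

Similarity between two atoms is the Jaccard index of their *normalized*
word sets (the LUI normalizer folds case, punctuation, inflection and word
order, so "Headache" vs "Headaches" scores 1.0).  Scores are exact
rationals (:class:`fractions.Fraction`) so that tie-breaking in top-N
selection is well defined.

An inverted word index maps each normalized token to the atoms containing
it; an atom's similarity candidates are exactly the other atoms sharing at
least one token, which is all that is needed because every other pair
scores zero.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Mapping, NamedTuple, Sequence

from metasyn.vocab import Atom, ConceptIndex

__all__ = [
    "ScoredPair",
    "WordIndex",
    "jaccard",
    "build_word_index",
    "sim_candidates",
    "top_scoring_pairs",
]


class ScoredPair(NamedTuple):
    """A scored candidate pair; ``score`` is an exact rational in [0, 1]."""

    aui_a: str
    aui_b: str
    score: Fraction


def jaccard(a: Atom, b: Atom) -> Fraction:
    """Jaccard index of the two atoms' normalized word sets.

    Symmetric, bounded in [0, 1], exactly 1 on identical token sets.
    Raises on an atom with an empty normalized form — such atoms carry no
    lexical signal and are excluded upstream.
    """
    if not a.norm_tokens or not b.norm_tokens:
        empty = a.aui if not a.norm_tokens else b.aui
        raise ValueError(f"atom {empty} has an empty normalized token set")
    inter = len(a.norm_tokens & b.norm_tokens)
    union = len(a.norm_tokens | b.norm_tokens)
    return Fraction(inter, union)


class WordIndex:
    """Inverted index: normalized token -> set of AUIs containing it."""

    def __init__(self, postings: Mapping[str, set[str]]):
        self._postings = {tok: set(auis) for tok, auis in postings.items()}

    def atoms_with(self, token: str) -> frozenset[str]:
        return frozenset(self._postings.get(token, ()))

    @property
    def tokens(self) -> list[str]:
        return sorted(self._postings)

    def __len__(self) -> int:
        return len(self._postings)


def build_word_index(atoms: Sequence[Atom]) -> WordIndex:
    """Build the inverted word index over an atom universe.

    Atoms with an empty normalized form are absent from every posting
    list.
    """
    postings: dict[str, set[str]] = {}
    for atom in atoms:
        for tok in atom.norm_tokens:
            postings.setdefault(tok, set()).add(atom.aui)
    return WordIndex(postings)


def sim_candidates(
    a: Atom,
    index: WordIndex,
    concepts: ConceptIndex | None = None,
) -> set[str]:
    """AUIs sharing at least one normalized token with ``a``.

    Excludes ``a`` itself and, when a concept index is given, every atom in
    the same concept (so the result contains negative-pair candidates
    only).  Every returned candidate has a strictly positive Jaccard score
    against ``a``.
    """
    out: set[str] = set()
    for tok in a.norm_tokens:
        out |= index.atoms_with(tok)
    out.discard(a.aui)
    if concepts is not None and a.aui in concepts:
        out -= concepts.atoms_of(concepts.cui_of(a.aui))
    return out


def top_scoring_pairs(
    a: Atom,
    quota: int,
    index: WordIndex,
    atoms_by_aui: Mapping[str, Atom],
    concepts: ConceptIndex | None = None,
) -> list[ScoredPair]:
    """Up to ``quota`` highest-scoring candidate pairs for one atom.

    Sorted by score descending with ties broken by candidate AUI ascending,
    so the selection is deterministic.  Fewer candidates than the quota
    yield a shorter list.
    """
    if quota < 0:
        raise ValueError("quota must be >= 0")
    if quota == 0:
        return []
    scored = [
        ScoredPair(a.aui, cand, jaccard(a, atoms_by_aui[cand]))
        for cand in sim_candidates(a, index, concepts)
    ]
    scored.sort(key=lambda p: (-p.score, p.aui_b))
    return scored[:quota]
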