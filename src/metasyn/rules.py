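"""Rule-based approximation (RBA) of the thesaurus construction process.

Two editorial principles are formalized as pairwise prediction functions
over built atoms:

* **SS** (source synonymy): two atoms are synonymous when their source
  vocabulary assigned them the same source concept identifier.  SCUI
  equality is scoped to the source: a numeric collision between unrelated
  sources must not fire the rule.
* **LS_SC** (lexical similarity + semantic compatibility): two atoms are
  synonymous when they share a normalized-string class (LUI) and their
  semantic-group sets intersect.  This blocks homonyms such as "nail"
  (Anatomy) vs "nail" (Device).

The disjunction **SS_LS_SC** combines them, and **SS_LS_SC_TRANS**
amplifies the combination by transitive closure, realized as connected
components of the rule graph (union-find over rule edges, equivalent to
iterating pairwise composition to fixpoint).

All prediction functions are commutative.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from metasyn.vocab import Atom

__all__ = [
    "RuleVariant",
    "SynonymPartition",
    "predict_ss",
    "predict_lssc",
    "predict_combined",
    "transitive_closure",
    "predict_dataset",
]


class RuleVariant(str, Enum):
    """The four rule-based predictor variants."""

    SS = "ss"
    LS_SC = "ls_sc"
    SS_LS_SC = "ss_ls_sc"
    SS_LS_SC_TRANS = "ss_ls_sc_trans"


def predict_ss(t: Atom, u: Atom) -> int:
    """Source-synonymy rule: 1 iff both SCUIs are present, equal and from
    the same source."""
    if t.scui is None or u.scui is None:
        return 0
    return int(t.src == u.src and t.scui == u.scui)


def predict_lssc(t: Atom, u: Atom) -> int:
    """Lexical-similarity/semantic-compatibility rule: 1 iff the LUI
    classes are equal (both defined) and the semantic-group sets
    intersect."""
    if t.lui is None or u.lui is None:
        return 0
    return int(t.lui == u.lui and bool(t.sg & u.sg))


def predict_combined(t: Atom, u: Atom) -> int:
    """Disjunction of the SS and LS_SC rules."""
    return predict_ss(t, u) or predict_lssc(t, u)


_PAIRWISE = {
    RuleVariant.SS: predict_ss,
    RuleVariant.LS_SC: predict_lssc,
    RuleVariant.SS_LS_SC: predict_combined,
}


class _DSU:
    """Union-find with path halving and union by size."""

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]


class SynonymPartition:
    """Partition of atoms into synonym components.

    A pair is predicted synonymous iff both members fall in the same
    component.
    """

    def __init__(self, component_of: Mapping[str, int]):
        self._comp = dict(component_of)

    def component_of(self, aui: str) -> int:
        return self._comp[aui]

    def predict(self, aui_a: str, aui_b: str) -> int:
        return int(self._comp[aui_a] == self._comp[aui_b])

    def components(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for aui, comp in self._comp.items():
            out.setdefault(comp, set()).add(aui)
        return out

    def __len__(self) -> int:
        return len(self._comp)


def transitive_closure(
    atoms: Sequence[Atom], base: RuleVariant = RuleVariant.SS_LS_SC
) -> SynonymPartition:
    """Full transitive closure of a base rule over an atom universe.

    Components are built with union-find over the rule edges rather than by
    enumerating all pairs: SS edges join atoms grouped by ``(src, scui)``;
    LS_SC edges join atoms grouped by ``(lui, semantic group)``.  Grouping
    by each single shared group is exact under closure — two atoms whose
    group sets intersect share at least one ``(lui, g)`` bucket, and a
    bucket chain is itself a valid rule chain.
    """
    if base == RuleVariant.SS_LS_SC_TRANS:
        raise ValueError("base must be one of SS, LS_SC, SS_LS_SC")
    n = len(atoms)
    dsu = _DSU(n)

    if base in (RuleVariant.SS, RuleVariant.SS_LS_SC):
        buckets: dict[tuple[str, str], int] = {}
        for i, atom in enumerate(atoms):
            if atom.scui is None:
                continue
            key = (atom.src, atom.scui)
            if key in buckets:
                dsu.union(buckets[key], i)
            else:
                buckets[key] = i

    if base in (RuleVariant.LS_SC, RuleVariant.SS_LS_SC):
        lbuckets: dict[tuple[str, str], int] = {}
        for i, atom in enumerate(atoms):
            if atom.lui is None:
                continue
            for g in atom.sg:
                key = (atom.lui, g)
                if key in lbuckets:
                    dsu.union(lbuckets[key], i)
                else:
                    lbuckets[key] = i

    # canonicalize component ids to the smallest member index
    root_to_comp: dict[int, int] = {}
    comp_of: dict[str, int] = {}
    for i, atom in enumerate(atoms):
        root = dsu.find(i)
        comp_of[atom.aui] = root_to_comp.setdefault(root, i)
    return SynonymPartition(comp_of)


def predict_dataset(
    pairs: Iterable[tuple[str, str]],
    variant: RuleVariant,
    atoms: Sequence[Atom],
) -> np.ndarray:
    """Predict synonymy for (auiA, auiB) pairs under one rule variant.

    For ``SS_LS_SC_TRANS`` the closure is computed over the *full* atom
    universe supplied, so chains through atoms absent from the evaluated
    pairs still connect them.  An unknown AUI raises, naming it.
    """
    by_aui = {a.aui: a for a in atoms}
    pair_list = list(pairs)
    for a, b in pair_list:
        for aui in (a, b):
            if aui not in by_aui:
                raise KeyError(f"unknown AUI in pair list: {aui!r}")
    if variant == RuleVariant.SS_LS_SC_TRANS:
        part = transitive_closure(atoms, RuleVariant.SS_LS_SC)
        return np.array([part.predict(a, b) for a, b in pair_list], dtype=np.int8)
    fn = _PAIRWISE[variant]
    return np.array([fn(by_aui[a], by_aui[b]) for a, b in pair_list], dtype=np.int8)
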