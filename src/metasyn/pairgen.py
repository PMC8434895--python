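"""Labeled pair-dataset generation with similarity-stratified negatives.

Ground truth: a pair of atoms is positive iff the concept index assigns
both the same CUI.  For every atom ``a`` in a concept of size ``n(a)`` the
generator emits the ``k = n(a) - 1`` ordered positive pairs ``(a, *)``.
Negatives are sampled per atom in three mutually exclusive regimes of
lexical similarity:

``TOPN_SIM``
    the 2k candidates with the highest Jaccard scores (deterministic);
``RAN_SIM``
    2k uniform draws (without replacement) from the remaining candidates
    with Jaccard > 0;
``RAN_NOSIM``
    2k uniform draws from atoms sharing no normalized token (Jaccard = 0).

A singleton-concept atom (k = 0) contributes a single ``TOPN_SIM`` and a
single ``RAN_SIM`` pair when it has any similar candidate, and no
``RAN_NOSIM`` pair.  ``ALL`` is the union of the three regimes (up to 6k
pairs per atom).  Twice as many negatives as needed for training are drawn
so each regime splits equally between the learning and generalization
sides; positives split 80:20, and the learning side splits 75:25 into
training and validation.

Learning and generalization are kept disjoint *as unordered pair sets*: a
registry forces the mirror of an already-placed pair onto the same side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from metasyn.lexsim import WordIndex, build_word_index, sim_candidates, top_scoring_pairs
from metasyn.vocab import Atom, ConceptIndex

__all__ = [
    "LabeledPair",
    "DatasetVariant",
    "SplitDataset",
    "enumerate_pos",
    "sample_negatives",
    "assemble_variant",
    "dataset_stats",
    "write_pairs",
    "read_pairs",
]

SIM = "SIM"
NOSIM = "NOSIM"


@dataclass(frozen=True)
class LabeledPair:
    """An ordered (auiA, auiB) pair with its label.

    ``sim_flag`` partitions negatives into SIM (Jaccard > 0) and NOSIM
    (Jaccard = 0); it is ``None`` for positives.
    """

    aui_a: str
    aui_b: str
    label: int
    sim_flag: str | None = None

    def __post_init__(self) -> None:
        if self.aui_a == self.aui_b:
            raise ValueError(f"pair members must differ: {self.aui_a}")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")

    @property
    def key(self) -> frozenset[str]:
        return frozenset((self.aui_a, self.aui_b))


class DatasetVariant(str, Enum):
    TOPN_SIM = "topn_sim"
    RAN_SIM = "ran_sim"
    RAN_NOSIM = "ran_nosim"
    ALL = "all"


@dataclass
class SplitDataset:
    """Learning / generalization split of a labeled pair dataset.

    ``learning`` = ``training`` + ``validation`` (as multisets; training
    and validation are a shuffled 75:25 partition of the learning side).
    """

    learning: list[LabeledPair]
    generalization: list[LabeledPair]
    training: list[LabeledPair]
    validation: list[LabeledPair]
    variant: DatasetVariant
    seed: int


def enumerate_pos(concepts: ConceptIndex) -> list[LabeledPair]:
    """All ordered positive pairs, k = n(a) - 1 per atom.

    Deterministic order: concepts by CUI, members by AUI.  Singleton
    concepts emit nothing.
    """
    pairs: list[LabeledPair] = []
    for cui in sorted(concepts.cuis):
        members = sorted(concepts.atoms_of(cui))
        if len(members) < 2:
            continue
        for a in members:
            for b in members:
                if a != b:
                    pairs.append(LabeledPair(a, b, 1))
    return pairs


def _rng_for_atom(seed: int, atom_index: int) -> np.random.Generator:
    # per-atom stream: stable under changes to iteration order
    return np.random.default_rng(np.random.SeedSequence([seed, atom_index]))


def sample_negatives(
    a: Atom,
    k: int,
    variant: DatasetVariant,
    index: WordIndex,
    atoms_by_aui: Mapping[str, Atom],
    concepts: ConceptIndex,
    rng: np.random.Generator,
    exclude: frozenset[str] = frozenset(),
) -> list[LabeledPair]:
    """Negative pairs ``(a, *)`` for one atom under one regime.

    ``exclude`` removes candidate AUIs already claimed by another regime
    for the same atom (keeps the regimes mutually exclusive before the
    union into ALL).  Fewer eligible candidates than the quota yield a
    shorter list.
    """
    if variant == DatasetVariant.ALL:
        raise ValueError("ALL is assembled as the union of the three regimes")
    quota = 2 * k
    if k == 0:
        quota = 1 if variant in (DatasetVariant.TOPN_SIM, DatasetVariant.RAN_SIM) else 0
    if quota == 0 or not a.norm_tokens:
        return []

    if variant == DatasetVariant.TOPN_SIM:
        scored = top_scoring_pairs(a, quota + len(exclude), index, atoms_by_aui, concepts)
        picks = [p.aui_b for p in scored if p.aui_b not in exclude][:quota]
        return [LabeledPair(a.aui, b, 0, SIM) for b in picks]

    if variant == DatasetVariant.RAN_SIM:
        cands = sorted(sim_candidates(a, index, concepts) - exclude)
        if not cands:
            return []
        take = min(quota, len(cands))
        picks = rng.choice(len(cands), size=take, replace=False)
        return [LabeledPair(a.aui, cands[i], 0, SIM) for i in sorted(picks)]

    # RAN_NOSIM: rejection-sample atoms with zero token overlap
    universe = list(atoms_by_aui)
    similar = sim_candidates(a, index, None)
    same_cui = concepts.atoms_of(concepts.cui_of(a.aui)) if a.aui in concepts else {a.aui}

    def eligible(aui: str) -> bool:
        if aui in similar or aui in same_cui or aui == a.aui or aui in exclude:
            return False
        return bool(atoms_by_aui[aui].norm_tokens)

    chosen: list[str] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = 100 + 20 * quota
    while len(chosen) < quota and attempts < max_attempts:
        attempts += 1
        cand = universe[int(rng.integers(len(universe)))]
        if cand in seen or not eligible(cand):
            continue
        seen.add(cand)
        chosen.append(cand)
    if len(chosen) < quota:
        # dense corpus: fall back to materializing the complement
        rest = [aui for aui in universe if aui not in seen and eligible(aui)]
        need = min(quota - len(chosen), len(rest))
        if need:
            picks = rng.choice(len(rest), size=need, replace=False)
            chosen.extend(rest[i] for i in sorted(picks))
    return [LabeledPair(a.aui, b, 0, NOSIM) for b in chosen]


def _atom_negative_lists(
    a: Atom,
    k: int,
    variants: Sequence[DatasetVariant],
    index: WordIndex,
    atoms_by_aui: Mapping[str, Atom],
    concepts: ConceptIndex,
    rng: np.random.Generator,
) -> dict[DatasetVariant, list[LabeledPair]]:
    """The per-atom regime lists, mutually exclusive across regimes."""
    out: dict[DatasetVariant, list[LabeledPair]] = {}
    claimed: set[str] = set()
    for variant in (DatasetVariant.TOPN_SIM, DatasetVariant.RAN_SIM, DatasetVariant.RAN_NOSIM):
        if variant not in variants:
            continue
        pairs = sample_negatives(
            a, k, variant, index, atoms_by_aui, concepts, rng, frozenset(claimed)
        )
        claimed.update(p.aui_b for p in pairs)
        out[variant] = pairs
    return out


def _split_sides(
    pairs: Iterable[LabeledPair],
    registry: dict[frozenset[str], str],
    learn: list[LabeledPair],
    gen: list[LabeledPair],
) -> None:
    """Alternate pairs between sides, mirrors forced onto one side."""
    n_l = n_g = 0
    for p in pairs:
        side = registry.get(p.key)
        if side is None:
            side = "L" if n_l <= n_g else "G"
            registry[p.key] = side
        if side == "L":
            learn.append(p)
            n_l += 1
        else:
            gen.append(p)
            n_g += 1


def assemble_variant(
    atoms: Sequence[Atom],
    concepts: ConceptIndex,
    variant: DatasetVariant,
    seed: int,
    index: WordIndex | None = None,
    dedupe_unordered: bool = False,
) -> SplitDataset:
    """Build one dataset variant with its learning/generalization split.

    Deterministic under ``seed``: regenerating reproduces the dataset
    exactly, and different seeds change the RAN_* membership but never the
    (deterministic) TOPN_SIM membership.  With ``dedupe_unordered`` only
    the lexicographically first ordered representative of each unordered
    pair is kept.
    """
    index = index or build_word_index(atoms)
    atoms_by_aui = {a.aui: a for a in atoms}
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))

    # positives: split unordered keys 80:20, mirrors stay together
    pos = enumerate_pos(concepts)
    keys = sorted({p.key for p in pos}, key=sorted)
    perm = rng.permutation(len(keys))
    n_learn = int(len(keys) * 0.8 + 0.5)
    pos_side = {keys[j]: ("L" if rank < n_learn else "G") for rank, j in enumerate(perm)}
    pos_learn = [p for p in pos if pos_side[p.key] == "L"]
    pos_gen = [p for p in pos if pos_side[p.key] == "G"]

    wanted = (
        (DatasetVariant.TOPN_SIM, DatasetVariant.RAN_SIM, DatasetVariant.RAN_NOSIM)
        if variant == DatasetVariant.ALL
        else (variant,)
    )
    neg_learn: list[LabeledPair] = []
    neg_gen: list[LabeledPair] = []
    registry: dict[frozenset[str], str] = {}
    for i, atom in enumerate(atoms):
        k = concepts.concept_size(atom.aui) - 1 if atom.aui in concepts else 0
        lists = _atom_negative_lists(
            atom, k, wanted, index, atoms_by_aui, concepts, _rng_for_atom(seed, i)
        )
        for v in wanted:
            _split_sides(lists.get(v, ()), registry, neg_learn, neg_gen)

    learning = pos_learn + neg_learn
    generalization = pos_gen + neg_gen
    if dedupe_unordered:
        learning = _dedupe(learning)
        generalization = _dedupe(generalization)

    # training/validation: shuffled 75:25 partition of the learning side
    perm = rng.permutation(len(learning))
    n_train = int(len(learning) * 0.75 + 0.5)
    training = [learning[j] for j in perm[:n_train]]
    validation = [learning[j] for j in perm[n_train:]]
    return SplitDataset(
        learning=learning,
        generalization=generalization,
        training=training,
        validation=validation,
        variant=variant,
        seed=seed,
    )


def _dedupe(pairs: list[LabeledPair]) -> list[LabeledPair]:
    seen: set[frozenset[str]] = set()
    out = []
    for p in pairs:
        if p.key in seen:
            continue
        seen.add(p.key)
        out.append(p)
    return out


def dataset_stats(ds: SplitDataset) -> dict[str, dict[str, int]]:
    """NEG / POS / TOTAL counts per dataset side."""
    out: dict[str, dict[str, int]] = {}
    for side in ("learning", "generalization", "training", "validation"):
        pairs: list[LabeledPair] = getattr(ds, side)
        pos = sum(p.label for p in pairs)
        out[side] = {"NEG": len(pairs) - pos, "POS": pos, "TOTAL": len(pairs)}
    return out


# ---------------------------------------------------------------------------
# pair-file TSV dialect
# ---------------------------------------------------------------------------

_PAIR_COLS = ("aui_a", "aui_b", "label", "sim_flag")


def write_pairs(pairs: Iterable[LabeledPair], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_PAIR_COLS) + "\n")
        for p in pairs:
            fh.write(f"{p.aui_a}\t{p.aui_b}\t{p.label}\t{p.sim_flag or ''}\n")


def read_pairs(path: str | Path) -> list[LabeledPair]:
    out: list[LabeledPair] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _PAIR_COLS:
            raise ValueError(f"{path}: expected header {_PAIR_COLS}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns")
            out.append(LabeledPair(fields[0], fields[1], int(fields[2]), fields[3] or None))
    return out
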