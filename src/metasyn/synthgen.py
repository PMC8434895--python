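"""Synthetic mini-metathesaurus generator with analytic oracles.

The generator emulates the statistical structure the alignment method
assumes, with known ground truth:

* concepts holding lexical-variant atoms (plural, word-order, case,
  punctuation/qualifier, synonym-substitution variants of a base term)
  spread over multiple sources, plus *loose variants* that swap one
  modifier for an unrelated one — emulating source entry terms that are
  synonymous without being lexical variants of each other;
* source-level synonym clusters (SCUIs) that mostly — but not always —
  agree with concept membership (configurable coverage and a small
  cross-concept disagreement rate);
* homonymous strings injected into concepts of *different* semantic
  groups (the "nail": anatomy-vs-device pattern);
* negative pairs spanning the full range of lexical similarity: base
  terms reuse a small pool of modifier and head tokens, and a
  configurable fraction of concepts are *siblings*, derived from an
  earlier concept's base term by swapping a single token — the
  "lung disease" vs "head disease" regime of near-identical
  non-synonymous terms that makes hard negatives genuinely hard.

Term material is a packaged synthetic lexicon (plausible biomedical-ish
tokens plus a one-to-one synonym map), so the corpus is license-free and
needs no download.  Only the statistical structure matters.

Per-atom provenance (base term, operators applied) and per-positive-pair
tags (``ss_derivable``, ``lssc_derivable``, ``lexically_similar``) are
recorded at generation time by running the rule and similarity engines
themselves, so the tags are recomputable by construction.
:`func:`expected_rba_metrics` provides a brute-force all-pairs oracle for
the rule-based predictors, independent of the union-find engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from metasyn.lexsim import build_word_index, jaccard, sim_candidates
from metasyn.metrics import ConfusionCounts, MetricsReport, prf1
from metasyn.rules import RuleVariant, predict_lssc, predict_ss
from metasyn.vocab import Atom, AtomTuple, ConceptIndex, SemanticGroupConfig, build_atoms

__all__ = ["SynthConfig", "SynthMetathesaurus", "generate", "expected_rba_metrics"]

# ---------------------------------------------------------------------------
# packaged lexicon
# ---------------------------------------------------------------------------

MODIFIERS = [
    "cranial", "renal", "hepatic", "cardiac", "gastric", "dermal",
    "ocular", "neural", "spinal", "pulmonary", "femoral", "carpal",
    "nasal", "oral", "pelvic", "thoracic", "lumbar", "cervical",
    "distal", "proximal", "lateral", "medial", "anterior", "posterior",
    "chronic", "acute", "focal", "diffuse", "primary", "secondary",
    "congenital", "recurrent", "benign", "malignant", "partial", "total",
]

HEADS = {
    "Disorders": [
        "pain", "disorder", "disease", "lesion", "syndrome", "inflammation",
        "stenosis", "atrophy", "fibrosis", "edema", "cyst", "ulcer",
    ],
    "Anatomy": [
        "lobe", "duct", "membrane", "fiber", "artery", "vein",
        "fossa", "canal", "plexus", "ligament", "node", "septum",
    ],
    "Procedures": [
        "biopsy", "resection", "imaging", "screening", "repair", "drainage",
        "ablation", "graft", "scan", "bypass", "lavage", "suture",
    ],
}

# one-to-one synonym map; keys and values are globally disjoint so every
# token belongs to exactly one synonym class
SYNONYMS = {
    "pain": "ache", "disorder": "dysfunction", "disease": "illness",
    "lesion": "defect", "syndrome": "complex", "inflammation": "swelling",
    "stenosis": "narrowing", "atrophy": "wasting", "fibrosis": "scarring",
    "edema": "dropsy", "cyst": "sac", "ulcer": "sore",
    "lobe": "lobule", "duct": "channel", "membrane": "lining",
    "fiber": "filament", "artery": "vessel", "vein": "venule",
    "fossa": "hollow", "canal": "passage", "plexus": "network",
    "ligament": "band", "node": "nodule", "septum": "partition",
    "biopsy": "sampling", "resection": "excision", "imaging": "visualization",
    "screening": "surveillance", "repair": "reconstruction",
    "drainage": "aspiration", "ablation": "cautery", "graft": "implant",
    "scan": "tomogram", "bypass": "shunt", "lavage": "irrigation",
    "suture": "stitch",
    "cranial": "cephalic", "renal": "nephric", "hepatic": "liver",
    "cardiac": "heart", "gastric": "stomach", "dermal": "cutaneous",
    "ocular": "orbital", "neural": "neurogenic", "spinal": "vertebral",
    "pulmonary": "lung", "femoral": "thigh", "carpal": "wrist",
    "nasal": "rhinal", "oral": "buccal", "pelvic": "iliac",
    "thoracic": "chest", "lumbar": "loin", "cervical": "neck",
    "distal": "terminal", "proximal": "basal", "lateral": "outer",
    "medial": "inner", "anterior": "frontal", "posterior": "dorsal",
    "chronic": "persistent", "acute": "sudden", "focal": "localized",
    "diffuse": "generalized", "primary": "idiopathic",
    "secondary": "derived", "congenital": "inborn",
    "recurrent": "relapsing", "benign": "harmless",
    "malignant": "invasive", "partial": "incomplete", "total": "complete",
}

# representative of each synonym class, for cross-concept uniqueness keys
_CLASS_ROOT = {tok: tok for tok in SYNONYMS}
_CLASS_ROOT.update({alt: tok for tok, alt in SYNONYMS.items()})

_DEFAULT_SOURCES = {
    "DISVOC1": "Disorders",
    "DISVOC2": "Disorders",
    "ANAVOC1": "Anatomy",
    "ANAVOC2": "Anatomy",
    "PROVOC1": "Procedures",
    "PROVOC2": "Procedures",
}


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic corpus.

    ``sources`` maps each source vocabulary to its (single) semantic
    group; concepts are assigned a group and draw their atoms from that
    group's sources.  Operator probabilities control how lexical variants
    of a concept's base term are produced.  ``scui_coverage`` is the
    probability that a same-concept, same-source atom joins the source's
    synonym cluster (otherwise its SCUI is absent); ``scui_disagreement``
    is the probability that an atom instead adopts a cluster from a
    *different* concept, making source synonymy fallible.
    ``sibling_rate`` is the probability that a concept's base term is
    derived from an earlier same-group concept by swapping exactly one
    token, which populates the high end of the negative-pair similarity
    range.  ``p_modswap`` controls the loose-variant operator (a
    within-concept modifier swap), which makes single-token substitution
    an ambiguous signal: sometimes synonymous, sometimes the mark of a
    sibling concept.  ``seed`` is mandatory: the corpus is a pure
    function of the config.
    """

    seed: int
    n_concepts: int = 500
    sources: Mapping[str, str] = field(default_factory=lambda: dict(_DEFAULT_SOURCES))
    atoms_per_concept_mean: float = 4.0
    p_pluralize: float = 0.3
    p_reorder: float = 0.2
    p_case: float = 0.3
    p_punct: float = 0.2
    p_synonym: float = 0.25
    p_modswap: float = 0.25
    homonym_rate: float = 0.05
    scui_coverage: float = 0.9
    scui_disagreement: float = 0.02
    sibling_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.n_concepts < 1:
            raise ValueError("n_concepts must be >= 1")
        if len(self.sources) < 2:
            raise ValueError("at least 2 sources are required")
        if self.atoms_per_concept_mean < 1:
            raise ValueError("atoms_per_concept_mean must be >= 1")
        for name in ("p_pluralize", "p_reorder", "p_case", "p_punct", "p_synonym",
                     "p_modswap", "homonym_rate", "scui_coverage",
                     "scui_disagreement", "sibling_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        groups = set(self.sources.values())
        missing = groups - set(HEADS)
        if missing:
            raise ValueError(f"no head-token pool for groups {sorted(missing)}")


@dataclass
class SynthMetathesaurus:
    """Generated corpus: tuples, ground truth, provenance and pair tags."""

    config: SynthConfig
    tuples: list[AtomTuple]
    atoms: list[Atom]
    concepts: ConceptIndex
    sg_config: SemanticGroupConfig
    provenance: list[dict]
    pair_tags: dict[tuple[str, str], dict[str, int]]

    @property
    def atoms_by_aui(self) -> dict[str, Atom]:
        return {a.aui: a for a in self.atoms}

    def regime_counts(self) -> dict[str, int]:
        """Pair counts per qualitative regime.

        Positives split by lexical similarity (a lexically dissimilar
        positive comes from synonym substitution); negatives with some
        similarity are counted through the word index.
        """
        pos_sim = sum(t["lexically_similar"] for t in self.pair_tags.values())
        index = build_word_index(self.atoms)
        neg_sim = sum(
            len(sim_candidates(a, index, self.concepts)) for a in self.atoms
        ) // 2
        return {
            "positives": len(self.pair_tags),
            "positives_lexically_similar": pos_sim,
            "positives_lexically_dissimilar": len(self.pair_tags) - pos_sim,
            "negatives_lexically_similar": neg_sim,
        }


def _variant_term(
    base: list[str],
    group: str,
    cfg: SynthConfig,
    rng: np.random.Generator,
    used_keys: set[tuple[str, ...]],
) -> tuple[str, list[str]]:
    """Apply seeded variant operators to a base token list.

    The modifier-swap ("loose variant") operator replaces one modifier
    with an arbitrary other one; a swap whose class-root key collides
    with another concept's base term is rejected, so loose variants
    never duplicate a foreign concept's string.
    """
    tokens = list(base)
    ops: list[str] = []
    if len(tokens) > 1 and rng.random() < cfg.p_modswap:
        for _attempt in range(10):
            cand = list(tokens)
            pos = int(rng.integers(len(cand) - 1))
            choices = [w for w in MODIFIERS if w not in cand]
            cand[pos] = choices[int(rng.integers(len(choices)))]
            key = tuple(sorted(_CLASS_ROOT.get(t, t) for t in cand))
            if key not in used_keys:
                tokens = cand
                ops.append("modswap")
                break
    if rng.random() < cfg.p_synonym:
        tokens = [SYNONYMS.get(t, t) for t in tokens]
        ops.append("synonym")
    if len(tokens) > 1 and rng.random() < cfg.p_reorder:
        order = rng.permutation(len(tokens))
        tokens = [tokens[i] for i in order]
        ops.append("reorder")
    if rng.random() < cfg.p_pluralize and not tokens[-1].endswith("s"):
        tokens = tokens[:-1] + [tokens[-1] + "s"]
        ops.append("pluralize")
    if rng.random() < cfg.p_punct:
        tokens = tokens + [f"({group.lower()})"]
        ops.append("qualifier")
    if rng.random() < cfg.p_case:
        tokens = [t.capitalize() for t in tokens]
        ops.append("case")
    return " ".join(tokens), ops


def generate(cfg: SynthConfig) -> SynthMetathesaurus:
    """Generate a corpus: deterministic under ``cfg.seed``.

    Every concept has at least one atom.  Base token combinations are
    unique across concepts *per synonym class*, so with a zero homonym
    rate no string can appear in two concepts; homonym injection copies a
    base string from a concept of a different semantic group (disjoint
    group sets by construction).
    """
    rng = np.random.default_rng(cfg.seed)
    groups = sorted(set(cfg.sources.values()))
    sources_of = {g: sorted(s for s, gg in cfg.sources.items() if gg == g) for g in groups}
    sg_config = SemanticGroupConfig({s: [g] for s, g in cfg.sources.items()})

    used_keys: set[tuple[str, ...]] = set()
    concept_group: list[str] = []
    concept_base: list[list[str]] = []

    def _key(base: list[str]) -> tuple[str, ...]:
        return tuple(sorted(_CLASS_ROOT.get(t, t) for t in base))

    def _fresh_base(g: str) -> list[str] | None:
        for _attempt in range(1000):
            n_mods = int(rng.choice([2, 3, 4], p=[0.35, 0.45, 0.2]))
            mods = [MODIFIERS[i] for i in rng.choice(len(MODIFIERS), n_mods, replace=False)]
            head = HEADS[g][int(rng.integers(len(HEADS[g])))]
            base = mods + [head]
            if _key(base) not in used_keys:
                return base
        return None  # pragma: no cover - pool exhaustion

    def _sibling_base(g: str) -> list[str] | None:
        """Copy an earlier same-group base term and swap exactly one token."""
        peers = [i for i, gg in enumerate(concept_group) if gg == g]
        if not peers:
            return None
        for _attempt in range(50):
            base = list(concept_base[peers[int(rng.integers(len(peers)))]])
            pos = int(rng.integers(len(base)))
            pool = HEADS[g] if pos == len(base) - 1 else MODIFIERS
            choices = [w for w in pool if w not in base]
            base[pos] = choices[int(rng.integers(len(choices)))]
            if _key(base) not in used_keys:
                return base
        return None

    for _ in range(cfg.n_concepts):
        g = groups[int(rng.integers(len(groups)))]
        base = None
        if rng.random() < cfg.sibling_rate:
            base = _sibling_base(g)
        if base is None:
            base = _fresh_base(g)
        if base is None:  # pragma: no cover - pool exhaustion
            raise RuntimeError("could not find an unused base term; reduce n_concepts")
        used_keys.add(_key(base))
        concept_group.append(g)
        concept_base.append(base)

    tuples: list[AtomTuple] = []
    cuis: list[str] = []
    provenance: list[dict] = []
    # per-source synonym clusters: src -> list of (concept index, scui)
    clusters: dict[str, list[tuple[int, str]]] = {s: [] for s in cfg.sources}
    cluster_of: dict[tuple[int, str], str] = {}
    scui_counter = 0

    def assign_scui(ci: int, src: str) -> str | None:
        nonlocal scui_counter
        u = rng.random()
        if u < cfg.scui_disagreement:
            foreign = [scui for cj, scui in clusters[src] if cj != ci]
            if foreign:
                return foreign[int(rng.integers(len(foreign)))]
        if rng.random() < cfg.scui_coverage:
            key = (ci, src)
            if key not in cluster_of:
                scui_counter += 1
                cluster_of[key] = f"{src}-{scui_counter:05d}"
                clusters[src].append((ci, cluster_of[key]))
            return cluster_of[key]
        return None

    def add_atom(ci: int, term: str, src: str, base: str, ops: list[str]) -> None:
        g = cfg.sources[src]
        tuples.append(AtomTuple(term=term, src=src, scui=assign_scui(ci, src),
                                sg=frozenset({g})))
        cuis.append(f"C{ci + 1:07d}")
        provenance.append({"concept": ci, "base": base, "ops": ops})

    for ci in range(cfg.n_concepts):
        g = concept_group[ci]
        base = concept_base[ci]
        base_term = " ".join(base)
        n_atoms = 1 + int(rng.poisson(cfg.atoms_per_concept_mean - 1.0))
        srcs = sources_of[g]
        add_atom(ci, base_term, srcs[int(rng.integers(len(srcs)))], base_term, [])
        for _ in range(n_atoms - 1):
            term, ops = _variant_term(base, g, cfg, rng, used_keys)
            add_atom(ci, term, srcs[int(rng.integers(len(srcs)))], base_term, ops)

    # homonym injection: same string, concept of a different group; each
    # base term is copied at most once so a string never lands in two
    # concepts of the same group
    donated: set[int] = set()
    for ci in range(cfg.n_concepts):
        if rng.random() >= cfg.homonym_rate:
            continue
        others = [
            cj for cj in range(cfg.n_concepts)
            if concept_group[cj] != concept_group[ci] and cj not in donated
        ]
        if not others:
            continue
        cj = others[int(rng.integers(len(others)))]
        donated.add(cj)
        term = " ".join(concept_base[cj])
        srcs = sources_of[concept_group[ci]]
        add_atom(ci, term, srcs[int(rng.integers(len(srcs)))], term, ["homonym"])

    atoms = build_atoms(tuples)
    concepts = ConceptIndex({a.aui: cuis[i] for i, a in enumerate(atoms)})
    for i, a in enumerate(atoms):
        provenance[i]["aui"] = a.aui

    # positive-pair tags, recomputed by the engines at generation time
    pair_tags: dict[tuple[str, str], dict[str, int]] = {}
    by_cui: dict[str, list[Atom]] = {}
    for a in atoms:
        by_cui.setdefault(concepts.cui_of(a.aui), []).append(a)
    for members in by_cui.values():
        members = sorted(members, key=lambda a: a.aui)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                pair_tags[(a.aui, b.aui)] = {
                    "ss_derivable": predict_ss(a, b),
                    "lssc_derivable": predict_lssc(a, b),
                    "lexically_similar": int(jaccard(a, b) > 0),
                }

    return SynthMetathesaurus(
        config=cfg,
        tuples=tuples,
        atoms=atoms,
        concepts=concepts,
        sg_config=sg_config,
        provenance=provenance,
        pair_tags=pair_tags,
    )


# ---------------------------------------------------------------------------
# brute-force RBA oracle
# ---------------------------------------------------------------------------

_MAX_ORACLE_ATOMS = 5000


def _encode(atoms: Sequence[Atom], concepts: ConceptIndex):
    """Integer encodings for vectorized all-pairs rule evaluation."""
    scui_ids: dict[tuple[str, str], int] = {}
    lui_ids: dict[str, int] = {}
    group_bits: dict[str, int] = {}
    n = len(atoms)
    scui = np.full(n, -1, dtype=np.int64)
    lui = np.full(n, -1, dtype=np.int64)
    sg = np.zeros(n, dtype=np.int64)
    cui_ids: dict[str, int] = {}
    cui = np.zeros(n, dtype=np.int64)
    for i, a in enumerate(atoms):
        if a.scui is not None:
            scui[i] = scui_ids.setdefault((a.src, a.scui), len(scui_ids))
        if a.lui is not None:
            lui[i] = lui_ids.setdefault(a.lui, len(lui_ids))
        for g in a.sg:
            sg[i] |= 1 << group_bits.setdefault(g, len(group_bits))
        cui[i] = cui_ids.setdefault(concepts.cui_of(a.aui), len(cui_ids))
    return scui, lui, sg, cui


def expected_rba_metrics(
    s: SynthMetathesaurus,
    variant: RuleVariant,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> MetricsReport:
    """Brute-force evaluation of a rule variant against ground truth.

    With ``pairs=None`` every unordered atom pair of the corpus is
    evaluated (refused on corpora too large for the dense matrices —
    evaluate a sampled pair list instead); with an explicit pair list only
    those pairs are scored.  The transitive closure is taken over the full
    corpus either way, computed here as connected components of the dense
    rule matrix via networkx — a route independent of the union-find
    engine it serves as oracle for.
    """
    atoms = s.atoms
    n = len(atoms)
    if pairs is None and n > _MAX_ORACLE_ATOMS:
        raise ValueError(
            f"corpus has {n} atoms; all-pairs oracle is limited to "
            f"{_MAX_ORACLE_ATOMS} - evaluate a sampled pair list instead"
        )
    scui, lui, sg, cui = _encode(atoms, s.concepts)

    ss = (scui[:, None] == scui[None, :]) & (scui[:, None] >= 0)
    lssc = (
        (lui[:, None] == lui[None, :])
        & (lui[:, None] >= 0)
        & ((sg[:, None] & sg[None, :]) > 0)
    )
    if variant == RuleVariant.SS:
        pred_mat = ss
    elif variant == RuleVariant.LS_SC:
        pred_mat = lssc
    else:
        pred_mat = ss | lssc
    if variant == RuleVariant.SS_LS_SC_TRANS:
        g = nx.Graph()
        g.add_nodes_from(range(n))
        iu, ju = np.nonzero(np.triu(pred_mat, k=1))
        g.add_edges_from(zip(iu.tolist(), ju.tolist()))
        comp = np.zeros(n, dtype=np.int64)
        for cid, members in enumerate(nx.connected_components(g)):
            comp[list(members)] = cid
        pred_mat = comp[:, None] == comp[None, :]

    label_mat = cui[:, None] == cui[None, :]
    if pairs is None:
        iu = np.triu_indices(n, k=1)
        pred = pred_mat[iu]
        label = label_mat[iu]
    else:
        pos_of = {a.aui: i for i, a in enumerate(atoms)}
        ia = np.array([pos_of[a] for a, _ in pairs], dtype=np.int64)
        ib = np.array([pos_of[b] for _, b in pairs], dtype=np.int64)
        pred = pred_mat[ia, ib]
        label = label_mat[ia, ib]
    counts = ConfusionCounts(
        tp=int(np.sum(pred & label)),
        fp=int(np.sum(pred & ~label)),
        tn=int(np.sum(~pred & ~label)),
        fn=int(np.sum(~pred & label)),
    )
    return prf1(counts, threshold=0.5)
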