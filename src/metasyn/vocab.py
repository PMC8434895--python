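"""Identifier model, string normalizers and file dialects.

An *atom* is one occurrence of a term string in one source vocabulary.  The
integration process characterizes atoms with several identifier types:

AUI
    atom identifier, unique per occurrence;
SUI
    string identifier, shared iff two atoms have character-identical strings;
LUI
    lexical identifier, shared iff two atoms have the same *normalized*
    string (case, punctuation, inflection and word order folded away);
SCUI
    optional concept identifier assigned by the source vocabulary itself;
CUI
    concept identifier of the integrated thesaurus — the ground truth for
    the synonymy-prediction task, never an input to it.

Semantic groups (broad categories such as ``Disorders`` or ``Anatomy``) are
assigned per source vocabulary (or per top-level subdivision of a
heterogeneous source) through a :class:`SemanticGroupConfig`; every atom
inherits the group(s) of its source.

Identifier literals minted here are surrogates (zero-padded sequential
strings with the conventional ``A``/``S``/``L`` prefixes).  Only their
equality structure is meaningful.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "AtomTuple",
    "Atom",
    "SemanticGroupConfig",
    "ConceptIndex",
    "RRFColumnMap",
    "normalize_lvg",
    "normalize_embed",
    "build_atoms",
    "read_rrf",
    "write_rrf",
    "read_tsv",
    "write_tsv",
    "read_sg_config",
    "write_sg_config",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomTuple:
    """Input record ``(term, src, scui, sg)`` the whole method operates on.

    Parameters
    ----------
    term:
        Original term string from the source; non-empty after trimming.
    src:
        Source-vocabulary identifier.
    scui:
        Optional source concept identifier (``None`` when the source does
        not assert one).
    sg:
        Non-empty set of semantic-group labels inherited from the source.
    """

    term: str
    src: str
    scui: str | None
    sg: frozenset[str]

    def __post_init__(self) -> None:
        if not self.term or not self.term.strip():
            raise ValueError("AtomTuple.term must be non-empty after trimming")
        if not self.src:
            raise ValueError("AtomTuple.src must be non-empty")
        object.__setattr__(self, "sg", frozenset(self.sg))
        if not self.sg:
            raise ValueError(f"AtomTuple for {self.term!r} has an empty semantic-group set")


@dataclass(frozen=True)
class Atom:
    """An :class:`AtomTuple` enriched with minted identifiers.

    ``lui`` is ``None`` for atoms whose normalized form is empty; such atoms
    belong to no lexical class and are skipped by the word index.
    ``norm_tokens`` caches the normalized token set used for Jaccard
    similarity.
    """

    aui: str
    tup: AtomTuple
    sui: str
    lui: str | None
    norm_tokens: frozenset[str] = field(default_factory=frozenset)

    @property
    def term(self) -> str:
        return self.tup.term

    @property
    def src(self) -> str:
        return self.tup.src

    @property
    def scui(self) -> str | None:
        return self.tup.scui

    @property
    def sg(self) -> frozenset[str]:
        return self.tup.sg


class SemanticGroupConfig:
    """Mapping from source (or ``source:subtree``) to semantic groups.

    Keys are source-vocabulary identifiers; an optional ``src:subtree`` key
    overrides the source-level entry for atoms tagged with that top-level
    subdivision.
    """

    def __init__(self, mapping: Mapping[str, Iterable[str]]):
        self._map: dict[str, frozenset[str]] = {}
        for key, groups in mapping.items():
            gs = frozenset(groups)
            if not gs:
                raise ValueError(f"semantic-group entry for {key!r} is empty")
            self._map[key] = gs

    def groups_for(self, src: str, subtree: str | None = None) -> frozenset[str]:
        if subtree is not None:
            key = f"{src}:{subtree}"
            if key in self._map:
                return self._map[key]
        try:
            return self._map[src]
        except KeyError:
            raise KeyError(
                f"source {src!r} has no semantic-group entry; every source in the "
                "input must be mapped to at least one semantic group"
            ) from None

    def sources(self) -> list[str]:
        return sorted(self._map)

    def as_dict(self) -> dict[str, frozenset[str]]:
        return dict(self._map)

    def __contains__(self, src: str) -> bool:
        return src in self._map


class ConceptIndex:
    """Bidirectional AUI <-> CUI ground-truth mapping.

    The mapping is a partition: every atom maps to exactly one concept and
    the two directions are kept mutually consistent.
    """

    def __init__(self, aui_to_cui: Mapping[str, str]):
        self._a2c: dict[str, str] = dict(aui_to_cui)
        self._c2a: dict[str, set[str]] = {}
        for aui, cui in self._a2c.items():
            self._c2a.setdefault(cui, set()).add(aui)

    def cui_of(self, aui: str) -> str:
        return self._a2c[aui]

    def atoms_of(self, cui: str) -> frozenset[str]:
        return frozenset(self._c2a[cui])

    def concept_size(self, aui: str) -> int:
        """n(a): number of atoms sharing a's concept (including a)."""
        return len(self._c2a[self._a2c[aui]])

    def same_concept(self, aui_a: str, aui_b: str) -> bool:
        return self._a2c[aui_a] == self._a2c[aui_b]

    @property
    def auis(self) -> list[str]:
        return list(self._a2c)

    @property
    def cuis(self) -> list[str]:
        return list(self._c2a)

    def items(self):
        return self._a2c.items()

    def __len__(self) -> int:
        return len(self._a2c)

    def __contains__(self, aui: str) -> bool:
        return aui in self._a2c


# ---------------------------------------------------------------------------
# normalizers
# ---------------------------------------------------------------------------

_PUNCT_RE = re.compile(r"[^0-9a-z\s-]")
# stems whose plural drops a full "es" rather than just the "s"
_ES_DROP = ("sses", "xes", "zes", "zzes")


def _singularize(token: str) -> str:
    """Rule-based English singularization of one lowercase token."""
    if token.endswith("ies") and len(token) > 4:
        return token[:-3] + "y"
    if token.endswith(_ES_DROP) and len(token) > 3:
        return token[:-2]
    if token.endswith("s") and len(token) > 1 and not token.endswith(("ss", "us", "is")):
        return token[:-1]
    return token


def _clean(text: str) -> str:
    """Lowercase and strip punctuation except hyphen."""
    return _PUNCT_RE.sub(" ", text.lower())


def normalize_lvg(text: str) -> str:
    """Lexical-variant normalization: the equivalence behind LUIs.

    Lowercases, strips punctuation except hyphen, singularizes each token by
    rule (``-ies`` to ``-y``; a sibilant-stem exception list dropping
    ``-es``; otherwise ``-s`` dropped except after ``-ss``/``-us``/``-is``)
    and sorts the tokens lexicographically, joining with single spaces.  The
    function is deterministic and idempotent; strings that differ only by
    case, punctuation, singular/plural inflection or word order normalize
    identically.

    An input that is punctuation-only normalizes to the empty string; the
    caller decides whether to exclude such atoms.
    """
    if not text:
        raise ValueError("normalize_lvg requires non-empty input")
    tokens = sorted(_singularize(tok) for tok in _clean(text).split())
    return " ".join(tokens)


def normalize_embed(text: str) -> list[str]:
    """Order-preserving tokenization used for the embedding pipeline.

    Lowercases, removes punctuation except hyphen and splits on whitespace.
    No singularization and no sorting: the recurrent encoder consumes tokens
    in their original order.  Punctuation-only input yields an empty list.
    """
    if not text:
        raise ValueError("normalize_embed requires non-empty input")
    return _clean(text).split()


# ---------------------------------------------------------------------------
# atom construction
# ---------------------------------------------------------------------------


def _mint(prefix: str, n: int) -> str:
    return f"{prefix}{n:07d}"


def build_atoms(tuples: Sequence[AtomTuple]) -> list[Atom]:
    """Mint AUI/SUI/LUI identifiers for a sequence of input tuples.

    AUIs are minted sequentially in input order (one per occurrence, so
    duplicate rows remain distinct atoms).  SUIs are assigned per
    exact-string equality class and LUIs per :func:`normalize_lvg`
    equivalence class, both numbered by first occurrence.  Atoms whose
    normalized form is empty get ``lui=None`` and are logged.
    """
    atoms: list[Atom] = []
    sui_of: dict[str, str] = {}
    lui_of: dict[str, str] = {}
    for i, tup in enumerate(tuples):
        aui = _mint("A", i + 1)
        sui = sui_of.setdefault(tup.term, _mint("S", len(sui_of) + 1))
        norm = normalize_lvg(tup.term)
        if norm:
            lui: str | None = lui_of.setdefault(norm, _mint("L", len(lui_of) + 1))
            tokens = frozenset(norm.split())
        else:
            lui = None
            tokens = frozenset()
            logger.warning("atom %s (%r) normalizes to the empty string; excluded "
                           "from lexical classes", aui, tup.term)
        atoms.append(Atom(aui=aui, tup=tup, sui=sui, lui=lui, norm_tokens=tokens))
    return atoms


# ---------------------------------------------------------------------------
# RRF dialect
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RRFColumnMap:
    """Column positions in a pipe-delimited RRF file.

    Defaults follow the MRCONSO layout (CUI first; AUI, SUI, LUI, SCUI, SAB
    and STR at their standard indices).  ``lat`` / ``suppress`` enable the
    language and suppressibility filters when set on :func:`read_rrf`.
    """

    cui: int = 0
    lat: int = 1
    lui: int = 3
    sui: int = 5
    aui: int = 7
    scui: int = 9
    sab: int = 11
    term: int = 14
    suppress: int = 16
    n_cols: int = 18


def read_rrf(
    path: str | Path,
    sg_config: SemanticGroupConfig,
    colmap: RRFColumnMap | None = None,
    language: str | None = None,
    drop_suppressible: bool = False,
) -> tuple[list[AtomTuple], ConceptIndex | None]:
    """Read a pipe-delimited RRF file into :class:`AtomTuple` records.

    Semantic groups are looked up per source in ``sg_config``; a source
    without an entry is an error naming the source.  When the CUI column is
    populated a :class:`ConceptIndex` over the *minted* AUI order (the
    ``i``-th row becomes the ``i``-th atom of :func:`build_atoms`) is
    returned as well.  Rows with the wrong column count raise with their
    line number.  A trailing pipe is tolerated; no quoting.
    """
    cm = colmap or RRFColumnMap()
    tuples: list[AtomTuple] = []
    cuis: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.endswith("|"):
                line = line[:-1]
            fields = line.split("|")
            if len(fields) != cm.n_cols:
                raise ValueError(
                    f"{path}: line {lineno}: expected {cm.n_cols} pipe-delimited "
                    f"fields, got {len(fields)}"
                )
            if language is not None and fields[cm.lat] and fields[cm.lat] != language:
                continue
            if drop_suppressible and fields[cm.suppress] in ("Y", "O", "E"):
                continue
            src = fields[cm.sab]
            if src not in sg_config:
                raise ValueError(
                    f"{path}: line {lineno}: source {src!r} has no semantic-group entry"
                )
            scui = fields[cm.scui] or None
            tuples.append(
                AtomTuple(term=fields[cm.term], src=src, scui=scui,
                          sg=sg_config.groups_for(src))
            )
            cuis.append(fields[cm.cui])
    index = None
    if any(cuis):
        if not all(cuis):
            raise ValueError(f"{path}: CUI column is only partially populated")
        index = ConceptIndex({_mint("A", i + 1): cui for i, cui in enumerate(cuis)})
    return tuples, index


def write_rrf(
    atoms: Sequence[Atom],
    path: str | Path,
    concepts: ConceptIndex | None = None,
    colmap: RRFColumnMap | None = None,
    language: str = "ENG",
) -> None:
    """Write atoms in the pipe-delimited RRF dialect (round-trips read_rrf)."""
    cm = colmap or RRFColumnMap()
    with open(path, "w", encoding="utf-8") as fh:
        for atom in atoms:
            fields = [""] * cm.n_cols
            fields[cm.cui] = concepts.cui_of(atom.aui) if concepts else ""
            fields[cm.lat] = language
            fields[cm.lui] = atom.lui or ""
            fields[cm.sui] = atom.sui
            fields[cm.aui] = atom.aui
            fields[cm.scui] = atom.scui or ""
            fields[cm.sab] = atom.src
            fields[cm.term] = atom.term
            fields[cm.suppress] = "N"
            fh.write("|".join(fields) + "|\n")


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

_TSV_COLS = ("str", "src", "scui", "sg")


def read_tsv(path: str | Path) -> tuple[list[AtomTuple], ConceptIndex | None]:
    """Read the simple TSV dialect: header ``str src scui sg [cui]``.

    ``sg`` holds comma-separated group labels; ``scui`` may be empty.  When
    the optional ``cui`` column is present a ground-truth
    :class:`ConceptIndex` (over minted AUI order) is returned.
    """
    tuples: list[AtomTuple] = []
    cuis: list[str] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[:4]) != _TSV_COLS:
            raise ValueError(f"{path}: expected header starting with {_TSV_COLS}, got {header}")
        has_cui = len(header) > 4 and header[4] == "cui"
        want = 5 if has_cui else 4
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != want:
                raise ValueError(f"{path}: line {lineno}: expected {want} columns, got {len(fields)}")
            term, src, scui, sg = fields[:4]
            tuples.append(
                AtomTuple(term=term, src=src, scui=scui or None,
                          sg=frozenset(g for g in sg.split(",") if g))
            )
            if has_cui:
                cuis.append(fields[4])
    index = None
    if cuis:
        index = ConceptIndex({_mint("A", i + 1): cui for i, cui in enumerate(cuis)})
    return tuples, index


def write_tsv(
    atoms: Sequence[Atom] | Sequence[AtomTuple],
    path: str | Path,
    concepts: ConceptIndex | None = None,
) -> None:
    """Write atoms (or bare tuples) in the TSV dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        cols = list(_TSV_COLS) + (["cui"] if concepts else [])
        fh.write("\t".join(cols) + "\n")
        for i, atom in enumerate(atoms):
            tup = atom.tup if isinstance(atom, Atom) else atom
            row = [tup.term, tup.src, tup.scui or "", ",".join(sorted(tup.sg))]
            if concepts:
                aui = atom.aui if isinstance(atom, Atom) else _mint("A", i + 1)
                row.append(concepts.cui_of(aui))
            fh.write("\t".join(row) + "\n")


def read_sg_config(path: str | Path) -> SemanticGroupConfig:
    """Read a two-column table: ``source[:subtree] <TAB> group1,group2``."""
    mapping: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns, got {len(fields)}")
            mapping[fields[0]] = [g for g in fields[1].split(",") if g]
    return SemanticGroupConfig(mapping)


def write_sg_config(config: SemanticGroupConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for src, groups in sorted(config.as_dict().items()):
            fh.write(f"{src}\t{','.join(sorted(groups))}\n")
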