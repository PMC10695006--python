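"""Disassembled cage representation.

A Tri4Di6 porous organic cage (POC) is represented by three components
rather than one giant SMILES string: a tri-topic vertex precursor (BB1,
categorical id into a skeleton catalog), a di-topic edge precursor (BB2, a
SMILES string carrying exactly two ``[Lr]`` placeholder tokens marking the
reactive end-group sites), and a categorical reaction type (the dynamic
covalent chemistry joining them). An optional binary shape-persistence
label records whether molecular-dynamics validation found the cage cavity
to collapse on desolvation.

This module provides the catalogs, the character-level SMILES tokeniser
(with a fixed surrogate table replacing multi-character tokens by single
characters), label normalisation, and the validity/symmetry predicates used
throughout generation filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "COLLAPSED",
    "NOT_COLLAPSED",
    "UNLABELED",
    "SITE_TOKEN",
    "SPECIAL_TOKENS",
    "SURROGATE_TABLE",
    "InvalidSmilesError",
    "CageRecord",
    "ReactionCatalog",
    "BB1Catalog",
    "TokenVocabulary",
    "build_vocabulary",
    "tokenize",
    "detokenize",
    "scan_smiles",
    "relabel",
    "count_reaction_sites",
    "is_symmetric_bb2",
    "is_precursor_valid",
    "canonical_bb2",
    "cage_key",
]

# Label domain. Numerically, collapse maps to 1 (the predictor outputs the
# probability of collapse) and shape persistence to 0.
COLLAPSED = "collapsed"
NOT_COLLAPSED = "not_collapsed"
UNLABELED = "unlabeled"

SITE_TOKEN = "[Lr]"
PAD, SOS, EOS = "[pad]", "[sos]", "[eos]"
SPECIAL_TOKENS = (PAD, SOS, EOS, SITE_TOKEN)

# Versioned surrogate table (v1): multi-character SMILES tokens are replaced
# by single characters before indexing so the vocabulary is strictly
# character-level. The site token is handled separately as a special.
# Surrogate characters are chosen outside the organic-subset SMILES alphabet.
SURROGATE_TABLE: dict[str, str] = {
    "Cl": "X",
    "Br": "Y",
    "Si": "A",
    "Se": "U",
    "[nH]": "Z",
    "[NH]": "z",
    "[N+]": "Q",
    "[O-]": "V",
    "[NH2+]": "q",
    "[NH3+]": "w",
    "@@": "D",
    "%10": "m",
    "%11": "M",
    "%12": "W",
}
_SURROGATE_INVERSE = {v: k for k, v in SURROGATE_TABLE.items()}
# Longest-match-first scan order; the site token outranks everything.
_SCAN_TOKENS = [SITE_TOKEN] + sorted(SURROGATE_TABLE, key=len, reverse=True)


class InvalidSmilesError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecular graph."""


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"unparseable SMILES: {smiles!r}")
    return mol


@dataclass(frozen=True)
class ReactionCatalog:
    """Ordinal encoding of reaction types (imine condensation, alkyne
    metathesis, ...). Ids are the contiguous 0-based positions in `names`."""

    names: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.names)) != len(self.names):
            raise ValueError("reaction names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def id_of(self, name: str) -> int:
        return self.names.index(name)


@dataclass(frozen=True)
class BB1Catalog:
    """Ordered catalog of tri-topic vertex-precursor skeleton SMILES.

    Generation only ever emits ids inside this catalog, which is what makes
    the categorical encoding of BB1 safe: no invalid vertex SMILES can be
    produced.
    """

    skeletons: tuple[str, ...]

    def __post_init__(self):
        for s in self.skeletons:
            _mol_from_smiles(s)

    def __len__(self) -> int:
        return len(self.skeletons)


@dataclass(frozen=True)
class CageRecord:
    """One disassembled cage: (BB1 id, BB2 SMILES, reaction id, label)."""

    bb1_id: int
    bb2: str
    reaction_id: int
    label: str = UNLABELED

    def __post_init__(self):
        if self.label not in (COLLAPSED, NOT_COLLAPSED, UNLABELED):
            raise ValueError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class TokenVocabulary:
    """Bijective token<->index map with the four specials always first."""

    tokens: tuple[str, ...]
    max_len: int
    token_to_index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "token_to_index", {t: i for i, t in enumerate(self.tokens)})
        if len(self.token_to_index) != len(self.tokens):
            raise ValueError("vocabulary tokens must be unique")
        for i, s in enumerate(SPECIAL_TOKENS):
            if self.token_to_index.get(s) != i:
                raise ValueError(
                    f"special token {s} must sit at index {i} "
                    "([pad], [sos], [eos], [Lr] lead the vocabulary)"
                )

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def pad(self) -> int:
        return self.token_to_index[PAD]

    @property
    def sos(self) -> int:
        return self.token_to_index[SOS]

    @property
    def eos(self) -> int:
        return self.token_to_index[EOS]

    @property
    def site(self) -> int:
        return self.token_to_index[SITE_TOKEN]


def scan_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into vocabulary tokens.

    Multi-character tokens from the surrogate table are emitted as their
    single-character surrogates; the ``[Lr]`` site token is kept whole.
    Unrecognised bracket atoms raise, so the vocabulary stays closed.
    """
    tokens: list[str] = []
    i = 0
    while i < len(smiles):
        for tok in _SCAN_TOKENS:
            if smiles.startswith(tok, i):
                tokens.append(SITE_TOKEN if tok == SITE_TOKEN else SURROGATE_TABLE[tok])
                i += len(tok)
                break
        else:
            ch = smiles[i]
            if ch == "[":
                end = smiles.find("]", i)
                raise ValueError(
                    f"bracket atom {smiles[i:end + 1]!r} not in the surrogate table"
                )
            tokens.append(ch)
            i += 1
    return tokens


def build_vocabulary(corpus, max_len: int | None = None) -> TokenVocabulary:
    """Character-level vocabulary over a BB2 SMILES corpus plus specials.

    Ordering is deterministic: the four specials first, then the corpus
    tokens sorted lexicographically. Every corpus string must parse.
    """
    seen: set[str] = set()
    longest = 0
    for smiles in corpus:
        _mol_from_smiles(smiles)
        toks = scan_smiles(smiles)
        seen.update(toks)
        longest = max(longest, len(toks))
    seen.discard(SITE_TOKEN)
    tokens = tuple(SPECIAL_TOKENS) + tuple(sorted(seen))
    if max_len is None:
        max_len = longest + 2  # room for [sos] and [eos]
    return TokenVocabulary(tokens=tokens, max_len=max_len)


def tokenize(bb2: str, vocab: TokenVocabulary) -> np.ndarray:
    """Encode a BB2 SMILES as a fixed-length integer sequence.

    Layout: ``[sos] tokens... [eos] [pad]*`` of length ``vocab.max_len``.
    """
    toks = scan_smiles(bb2)
    if len(toks) + 2 > vocab.max_len:
        raise ValueError(f"sequence of {len(toks)} tokens exceeds max_len {vocab.max_len}")
    indices = [vocab.sos]
    for t in toks:
        idx = vocab.token_to_index.get(t)
        if idx is None:
            original = _SURROGATE_INVERSE.get(t, t)
            raise ValueError(f"token {original!r} not in vocabulary")
        indices.append(idx)
    indices.append(vocab.eos)
    indices.extend([vocab.pad] * (vocab.max_len - len(indices)))
    return np.asarray(indices, dtype=np.int64)


def detokenize(indices, vocab: TokenVocabulary) -> str:
    """Decode an index sequence back to a SMILES string.

    Specials are stripped, surrogates expanded; decoding stops at the first
    ``[eos]`` (or runs to the end if none is present). The result may be an
    unparseable SMILES — validity is judged downstream.
    """
    out: list[str] = []
    for idx in np.asarray(indices).tolist():
        if idx == vocab.eos:
            break
        if idx in (vocab.sos, vocab.pad):
            continue
        tok = vocab.tokens[idx]
        out.append(tok if tok == SITE_TOKEN else _SURROGATE_INVERSE.get(tok, tok))
    return "".join(out)


def relabel(raw: str) -> str:
    """Normalise raw labels to the closed ternary domain.

    ``undetermined`` collapses to ``collapsed``: ambiguous cages are treated
    pessimistically so the persistence target stays binary.
    """
    key = raw.strip().lower().replace(" ", "_").replace("-", "_")
    if key == "undetermined" or key == COLLAPSED:
        return COLLAPSED
    if key in ("non_collapsed", "not_collapsed"):
        return NOT_COLLAPSED
    if key in ("", UNLABELED, "none"):
        return UNLABELED
    raise ValueError(f"unknown label text {raw!r}")


def count_reaction_sites(bb2: str) -> int:
    """Number of ``[Lr]`` placeholder sites; a usable edge precursor has 2."""
    mol = _mol_from_smiles(bb2)
    return sum(1 for atom in mol.GetAtoms() if atom.GetAtomicNum() == 103)


def is_precursor_valid(bb2: str) -> bool:
    """Parseable and carrying exactly two reactive-site placeholders."""
    try:
        return count_reaction_sites(bb2) == 2
    except InvalidSmilesError:
        return False


def _molecular_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        g.add_node(atom.GetIdx(), element=atom.GetAtomicNum())
    for bond in mol.GetBonds():
        g.add_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(),
                   order=bond.GetBondTypeAsDouble())
    return g


def is_symmetric_bb2(bb2: str) -> bool:
    """C2 molecular symmetry approximated by graph symmetry.

    True iff the two site atoms lie in the same automorphism orbit of the
    heavy-atom molecular graph (nodes coloured by element, edges by bond
    order) of the canonical form, i.e. some colour-preserving automorphism
    exchanges them. Cage assembly needs C2-symmetric edge precursors for the
    Tri4Di6 topology to close cleanly.
    """
    mol = _mol_from_smiles(canonical_bb2(bb2))
    sites = [a.GetIdx() for a in mol.GetAtoms() if a.GetAtomicNum() == 103]
    if len(sites) != 2:
        raise ValueError(f"expected exactly 2 site tokens, found {len(sites)}")
    graph = _molecular_graph(mol)
    matcher = nx.algorithms.isomorphism.GraphMatcher(
        graph, graph,
        node_match=nx.algorithms.isomorphism.categorical_node_match("element", None),
        edge_match=nx.algorithms.isomorphism.categorical_edge_match("order", None),
    )
    a, b = sites
    return any(mapping[a] == b for mapping in matcher.isomorphisms_iter())


def canonical_bb2(bb2: str) -> str:
    """Canonical SMILES of a BB2 skeleton (canonicalisation backend output
    is taken as the canonical form)."""
    return Chem.MolToSmiles(_mol_from_smiles(bb2))


def cage_key(record: CageRecord) -> str:
    """Canonical identity string for novelty/uniqueness bookkeeping.

    Two records get equal keys iff they denote the same cage: same BB1
    ordinal, same BB2 molecular graph (canonical SMILES), same reaction.
    """
    return f"{record.bb1_id}|{canonical_bb2(record.bb2)}|{record.reaction_id}"
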