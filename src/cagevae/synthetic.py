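"""Desk-scale synthetic cage datasets with the statistical structure the
method assumes.

The generator emulates the schema of a curated Tri4Di6 POC dataset — small
BB1/reaction catalogs, grammar-assembled BB2 skeletons with exactly two
``[Lr]`` sites and a controllable fraction of C2-symmetric members, and a
binary shape-persistence label. Labels follow a known deterministic rule of
the disassembled representation (small or ring-free edge precursors
collapse, unless the reaction is a designated rigid chemistry), so that a
trained predictor can in principle reach perfect accuracy and predictor
recovery is a meaningful test. Chemistry is not simulated: reaction names
mirror the real families (imine condensation, alkyne metathesis, ...) as
tags only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from rdkit import Chem

from .augmentation import FragmentLibrary, assemble_bb2
from .representation import (
    BB1Catalog,
    CageRecord,
    COLLAPSED,
    NOT_COLLAPSED,
    ReactionCatalog,
    UNLABELED,
    count_reaction_sites,
    canonical_bb2,
    is_symmetric_bb2,
    InvalidSmilesError,
)

__all__ = [
    "FixtureSpec",
    "DEFAULT_BB1_SKELETONS",
    "DEFAULT_REACTION_NAMES",
    "make_bb2_grammar",
    "label_rule",
    "make_dataset",
    "make_catalogs",
    "calibrate_threshold",
]

# Tri-topic vertex skeletons: trialdehyde / triamine benzene and
# aliphatic cores of the kind used in imine cage synthesis.
DEFAULT_BB1_SKELETONS = (
    "Nc1cc(N)cc(N)c1",
    "O=Cc1cc(C=O)cc(C=O)c1",
    "NCC(CN)(CN)CC",
    "O=Cc1c(C)c(C=O)c(C)c(C=O)c1C",
    "Nc1ccc(N)c(N)c1",
    "C#Cc1cc(C#C)cc(C#C)c1",
    "NCCN(CCN)CCN",
    "O=Cc1ccc(-c2cc(-c3ccc(C=O)cc3)cc(-c3ccc(C=O)cc3)c2)cc1",
)

DEFAULT_REACTION_NAMES = (
    "alkyne_metathesis",
    "aldehyde2amine3",
    "amine2aldehyde3",
    "amide_condensation",
    "alkene_metathesis",
    "disulfide_exchange",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Conditions for one synthetic dataset.

    `heavy_atom_threshold` and `rigid_reaction_id` parameterise the label
    rule; `unlabeled_fraction` blanks that share of labels to exercise the
    semi-supervised masking.
    """

    n_bb1: int = 4
    n_reactions: int = 3
    n_bb2: int = 60
    n_cages: int = 500
    unlabeled_fraction: float = 0.3
    symmetric_fraction: float = 0.7
    heavy_atom_threshold: int = 18
    rigid_reaction_id: int = 0
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("unlabeled_fraction", "symmetric_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("n_bb1", "n_reactions", "n_bb2", "n_cages"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


def make_catalogs(spec: FixtureSpec) -> tuple[BB1Catalog, ReactionCatalog]:
    if spec.n_bb1 > len(DEFAULT_BB1_SKELETONS):
        raise ValueError(f"at most {len(DEFAULT_BB1_SKELETONS)} BB1 skeletons available")
    if spec.n_reactions > len(DEFAULT_REACTION_NAMES):
        raise ValueError(f"at most {len(DEFAULT_REACTION_NAMES)} reactions available")
    return (
        BB1Catalog(DEFAULT_BB1_SKELETONS[: spec.n_bb1]),
        ReactionCatalog(DEFAULT_REACTION_NAMES[: spec.n_reactions]),
    )


def make_bb2_grammar(
    n: int,
    symmetric_fraction: float,
    rng_seed: int,
    library: FragmentLibrary | None = None,
) -> list[str]:
    """Grammar-assembled BB2 skeletons, all parseable with exactly two sites.

    Exactly ``round(n * symmetric_fraction)`` of the outputs satisfy
    ``is_symmetric_bb2``; candidates are assembled from the fragment grammar
    and bucketed by the symmetry predicate until both buckets fill.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    library = library or FragmentLibrary()
    rng = np.random.default_rng(rng_seed)
    n_sym = round(n * symmetric_fraction)
    n_asym = n - n_sym
    arms = library.arm_tuples()
    sym: list[str] = []
    asym: list[str] = []
    seen: set[str] = set()
    cores = library.symmetric_cores + library.asymmetric_cores
    budget = 200 * n + 1000
    while (len(sym) < n_sym or len(asym) < n_asym) and budget > 0:
        budget -= 1
        core = cores[rng.integers(len(cores))]
        left = arms[rng.integers(len(arms))]
        if rng.random() < symmetric_fraction:
            right = left
        else:
            right = arms[rng.integers(len(arms))]
        candidate = assemble_bb2(core, left, right)
        try:
            if count_reaction_sites(candidate) != 2:
                continue
        except InvalidSmilesError:
            continue
        key = canonical_bb2(candidate)
        if key in seen:
            continue
        bucket = sym if is_symmetric_bb2(candidate) else asym
        want = n_sym if bucket is sym else n_asym
        if len(bucket) < want:
            seen.add(key)
            bucket.append(candidate)
    if len(sym) < n_sym or len(asym) < n_asym:
        raise ValueError("grammar could not produce the requested pool; enlarge the library")
    out = sym + asym
    rng.shuffle(out)
    return out


def _bb2_heavy_atoms(bb2: str) -> int:
    """Heavy atoms of the skeleton, the two placeholder sites excluded."""
    mol = Chem.MolFromSmiles(bb2)
    if mol is None:
        raise InvalidSmilesError(f"unparseable SMILES: {bb2!r}")
    return sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() != 103)


def _bb2_has_ring(bb2: str) -> bool:
    mol = Chem.MolFromSmiles(bb2)
    if mol is None:
        raise InvalidSmilesError(f"unparseable SMILES: {bb2!r}")
    return mol.GetRingInfo().NumRings() > 0


def label_rule(record: CageRecord, spec: FixtureSpec) -> str:
    """Deterministic shape-persistence rule for fixtures.

    A cage collapses iff its BB2 is small (heavy atoms below the threshold)
    or ring-free (floppy backbone) — except when the reaction is the
    designated rigid chemistry, which always yields a persistent cage.
    """
    if record.reaction_id == spec.rigid_reaction_id:
        return NOT_COLLAPSED
    floppy = (
        _bb2_heavy_atoms(record.bb2) < spec.heavy_atom_threshold
        or not _bb2_has_ring(record.bb2)
    )
    return COLLAPSED if floppy else NOT_COLLAPSED


def make_dataset(
    spec: FixtureSpec,
) -> tuple[list[CageRecord], BB1Catalog, ReactionCatalog]:
    """Sample `n_cages` labelled cages from the fixture grid.

    Cages are drawn without replacement from BB1 x BB2 x reaction, labelled
    by `label_rule`, then `unlabeled_fraction` of labels are blanked.
    """
    from .augmentation import enumerate_cages  # local to avoid cycle at import

    bb1_catalog, reactions = make_catalogs(spec)
    bb2_pool = make_bb2_grammar(spec.n_bb2, spec.symmetric_fraction, spec.rng_seed)
    total = len(bb1_catalog) * len(bb2_pool) * len(reactions)
    if spec.n_cages > total:
        raise ValueError(f"n_cages {spec.n_cages} exceeds grid size {total}")
    skeleton = enumerate_cages(
        bb1_catalog, bb2_pool, reactions, spec.n_cages, rng_seed=spec.rng_seed + 1
    )
    rng = np.random.default_rng(spec.rng_seed + 2)
    blank = rng.random(len(skeleton)) < spec.unlabeled_fraction
    records = [
        replace(
            rec,
            label=UNLABELED if blank[i] else label_rule(rec, spec),
        )
        for i, rec in enumerate(skeleton)
    ]
    return records, bb1_catalog, reactions


def calibrate_threshold(
    spec: FixtureSpec,
    target_collapsed_fraction: float,
    thresholds: range = range(3, 30),
) -> FixtureSpec:
    """Search the heavy-atom threshold whose label rule best matches a
    requested collapsed-class balance on the spec's own grid."""
    best_spec, best_err = spec, float("inf")
    for t in thresholds:
        trial = replace(spec, heavy_atom_threshold=t, unlabeled_fraction=0.0)
        records, _, _ = make_dataset(trial)
        frac = sum(r.label == COLLAPSED for r in records) / len(records)
        err = abs(frac - target_collapsed_fraction)
        if err < best_err:
            best_err = err
            best_spec = replace(spec, heavy_atom_threshold=t)
    return best_spec
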