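"""Combinatorial expansion of the edge-precursor (BB2) pool.

Training a sequence VAE needs far more cages than any curated set of
synthesised or simulated POCs provides. Because the cage is stored
disassembled, the BB2 component — the only free-text part of the encoding —
can be augmented combinatorially: new di-topic skeletons are assembled from
a fragment library (step one), and hypothetical unlabeled cages are then
enumerated over the enlarged BB1 x BB2 x reaction grid (step two).

A BB2 skeleton is assembled as ``[Lr] <left arm> <core> <right arm> [Lr]``:
the core is a divalent fragment written as a SMILES template with one
substitution slot, and each arm is a chain of small divalent pieces. When
the two arms are mirror images of each other and the core's two attachment
points are graph-equivalent, the product is C2-symmetric by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .representation import (
    BB1Catalog,
    CageRecord,
    ReactionCatalog,
    canonical_bb2,
    count_reaction_sites,
    InvalidSmilesError,
)

__all__ = ["FragmentLibrary", "assemble_bb2", "augment_bb2_pool", "enumerate_cages"]

# Cores whose two attachment points share an automorphism orbit: para-, meta-
# and ortho-disubstituted benzene, 2,5-heteroles, 4,4'-biphenylene, 1,4-di-
# substituted cyclohexane, 2,6-naphthalene and a plain single bond ("" core).
SYMMETRIC_CORES = (
    "c1ccc({r})cc1",    # para-benzene
    "c1cccc({r})c1",    # meta-benzene
    "c1c({r})cccc1",    # ortho-benzene
    "c1ccc({r})o1",     # 2,5-furan
    "c1ccc({r})s1",     # 2,5-thiophene
    "c1ccc(-c2ccc({r})cc2)cc1",  # 4,4'-biphenylene
    "C1CCC({r})CC1",    # 1,4-cyclohexylene
    "{r}",              # direct chain, no core
)
# Cores with graph-inequivalent attachment points (ring decoration or the
# heteroatom position breaks the orbit).
ASYMMETRIC_CORES = (
    "c1cc(C)c({r})cc1",
    "c1ccnc({r})c1",
    "c1cc(F)c({r})cc1",
    "c1ccc(C(=O){r})cc1",
)
# Divalent arm pieces, each palindromic as an atom chain so that mirror arms
# are obtained by reversing the piece order only.
ARM_PIECES = ("C", "CC", "CCC", "C#C", "C=C", "COC", "CS(=O)(=O)C")


@dataclass(frozen=True)
class FragmentLibrary:
    """Divalent cores (SMILES templates with one ``{r}`` slot) and arm pieces."""

    symmetric_cores: tuple[str, ...] = SYMMETRIC_CORES
    asymmetric_cores: tuple[str, ...] = ASYMMETRIC_CORES
    arm_pieces: tuple[str, ...] = ARM_PIECES
    max_arm_pieces: int = 2

    def arm_tuples(self) -> list[tuple[str, ...]]:
        arms: list[tuple[str, ...]] = [()]
        for k in range(1, self.max_arm_pieces + 1):
            arms.extend(itertools.product(self.arm_pieces, repeat=k))
        return arms


def assemble_bb2(core: str, left_arm: tuple[str, ...], right_arm: tuple[str, ...]) -> str:
    """Assemble ``[Lr]<left><core with right in slot>[Lr]``.

    The right arm is written piece-reversed so that equal ``left_arm`` and
    ``right_arm`` tuples yield a mirror-symmetric skeleton.
    """
    left = "".join(left_arm)
    right = "".join(reversed(right_arm))
    body = core.format(r=right + "[Lr]")
    return f"[Lr]{left}{body}"


def _is_usable(smiles: str) -> bool:
    if smiles == "[Lr][Lr]":  # degenerate coreless, armless assembly
        return False
    try:
        return count_reaction_sites(smiles) == 2
    except InvalidSmilesError:
        return False


def augment_bb2_pool(
    seed_bb2s: list[str],
    library: FragmentLibrary,
    target_count: int,
    rng_seed: int,
    symmetric_fraction: float = 0.7,
) -> list[str]:
    """Grow the BB2 pool to `target_count` distinct precursor-valid skeletons.

    All seeds are kept; new skeletons are assembled from the library with
    roughly `symmetric_fraction` of the additions built mirror-symmetrically.
    Raises ``ValueError`` when the library cannot reach the target.
    """
    if target_count < len(seed_bb2s):
        raise ValueError("target_count must be at least the number of seeds")
    rng = np.random.default_rng(rng_seed)
    pool: list[str] = list(seed_bb2s)
    seen = {canonical_bb2(s) for s in seed_bb2s}
    if len(seen) != len(seed_bb2s):
        raise ValueError("seed BB2s contain duplicates after canonicalisation")

    arms = library.arm_tuples()
    # Deterministic shuffled enumeration of the full product space: every
    # combination is visited at most once, so exhaustion is detectable.
    sym_combos = [(c, a, a) for c in library.symmetric_cores for a in arms]
    asym_combos = [
        (c, a, b)
        for c in library.symmetric_cores + library.asymmetric_cores
        for a, b in itertools.product(arms, arms)
        if not (a == b and c in library.symmetric_cores)
    ]
    rng.shuffle(sym_combos)
    rng.shuffle(asym_combos)
    queues = {"sym": iter(sym_combos), "asym": iter(asym_combos)}
    exhausted: set[str] = set()

    while len(pool) < target_count and len(exhausted) < 2:
        want = "sym" if rng.random() < symmetric_fraction else "asym"
        if want in exhausted:
            want = ({"sym", "asym"} - exhausted).pop()
        try:
            core, left, right = next(queues[want])
        except StopIteration:
            exhausted.add(want)
            continue
        candidate = assemble_bb2(core, left, right)
        if not _is_usable(candidate):
            continue
        key = canonical_bb2(candidate)
        if key in seen:
            continue
        seen.add(key)
        pool.append(candidate)
    if len(pool) < target_count:
        raise ValueError(
            f"fragment library exhausted at {len(pool)} skeletons "
            f"(target {target_count})"
        )
    return pool


def enumerate_cages(
    bb1_catalog: BB1Catalog,
    bb2_pool: list[str],
    reactions: ReactionCatalog,
    max_count: int,
    rng_seed: int,
) -> list[CageRecord]:
    """Sample up to `max_count` distinct unlabeled cages from the full
    BB1 x BB2 x reaction grid, without replacement."""
    if not (len(bb1_catalog) and len(bb2_pool) and len(reactions)):
        raise ValueError("catalogs must be non-empty")
    total = len(bb1_catalog) * len(bb2_pool) * len(reactions)
    if max_count > total:
        raise ValueError(f"max_count {max_count} exceeds grid size {total}")
    rng = np.random.default_rng(rng_seed)
    flat = rng.choice(total, size=max_count, replace=False)
    n_rxn = len(reactions)
    n_bb2 = len(bb2_pool)
    records = []
    for idx in flat.tolist():
        rxn = idx % n_rxn
        bb2 = (idx // n_rxn) % n_bb2
        bb1 = idx // (n_rxn * n_bb2)
        records.append(CageRecord(bb1_id=bb1, bb2=bb2_pool[bb2], reaction_id=rxn))
    return records
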