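"""Generation filter cascade and batch evaluation metrics.

Decoded candidates pass through five heuristic stages in a fixed order —
validity (BB2 parses), novelty (cage key unseen), precursor validity
(parses with recognised site tokens), reaction sites (exactly two) and
symmetry (both sites in one automorphism orbit). A failure at any stage
discards the candidate and triggers resampling, so generation keeps cycling
until the requested number of cages pass or the attempt budget runs out.

`compute_metrics` scores a decoded batch the way generation benchmarks are
reported: validity over all samples; novelty, uniqueness and precursor
validity conditioned on the valid ones; symmetry conditioned on the
precursor-valid ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from sklearn.decomposition import PCA
import numpy as np

from .representation import (
    CageRecord,
    InvalidSmilesError,
    cage_key,
    canonical_bb2,
    count_reaction_sites,
    is_symmetric_bb2,
)

__all__ = [
    "FilterOutcome",
    "GenerationReport",
    "FILTER_STAGES",
    "filter_cage",
    "generate_with_filter",
    "compute_metrics",
    "pca_latent",
]

FILTER_STAGES = ("validity", "novelty", "precursor_validity", "reaction_sites", "symmetry")


@dataclass(frozen=True)
class FilterOutcome:
    passed: bool
    failed_stage: str  # one of FILTER_STAGES or "none"

    def __post_init__(self):
        if (self.failed_stage == "none") != self.passed:
            raise ValueError("failed_stage must be 'none' exactly when passed")
        if not self.passed and self.failed_stage not in FILTER_STAGES:
            raise ValueError(f"unknown stage {self.failed_stage!r}")


@dataclass(frozen=True)
class GenerationReport:
    """Metric rates for one generated batch (conditioning as named)."""

    n_sampled: int
    validity: float
    novelty_original_given_valid: float
    novelty_combined_given_valid: float
    uniqueness_given_valid: float
    precursor_validity_given_valid: float
    symmetry_given_precursor_valid: float

    def __post_init__(self):
        for name in ("validity", "novelty_original_given_valid",
                     "novelty_combined_given_valid", "uniqueness_given_valid",
                     "precursor_validity_given_valid", "symmetry_given_precursor_valid"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")

    def as_dict(self) -> dict:
        return {
            "n_sampled": self.n_sampled,
            "validity": self.validity,
            "novelty_original_given_valid": self.novelty_original_given_valid,
            "novelty_combined_given_valid": self.novelty_combined_given_valid,
            "uniqueness_given_valid": self.uniqueness_given_valid,
            "precursor_validity_given_valid": self.precursor_validity_given_valid,
            "symmetry_given_precursor_valid": self.symmetry_given_precursor_valid,
        }


def filter_cage(candidate: CageRecord, reference_keys: set[str]) -> FilterOutcome:
    """Apply the five stages strictly in order; record the first failure."""
    try:
        canonical_bb2(candidate.bb2)
    except InvalidSmilesError:
        return FilterOutcome(False, "validity")
    if cage_key(candidate) in reference_keys:
        return FilterOutcome(False, "novelty")
    try:
        n_sites = count_reaction_sites(candidate.bb2)
    except InvalidSmilesError:  # pragma: no cover - validity already parsed
        return FilterOutcome(False, "precursor_validity")
    if n_sites == 0:
        return FilterOutcome(False, "precursor_validity")
    if n_sites != 2:
        return FilterOutcome(False, "reaction_sites")
    if not is_symmetric_bb2(candidate.bb2):
        return FilterOutcome(False, "symmetry")
    return FilterOutcome(True, "none")


def generate_with_filter(
    sampler,
    reference_keys: set[str],
    n_required: int,
    max_attempts: int,
):
    """Resampling feedback loop around the filter.

    `sampler()` yields one candidate ``CageRecord`` per call. On each
    failure a new candidate is drawn, until `n_required` cages pass or the
    attempt budget is exhausted (the partial result is then flagged).
    Returns ``(passing, log, exhausted)``; the log records every outcome.
    """
    if max_attempts < n_required:
        raise ValueError("max_attempts must be >= n_required")
    passing: list[CageRecord] = []
    log: list[tuple[CageRecord, FilterOutcome]] = []
    seen_keys = set(reference_keys)
    attempts = 0
    while len(passing) < n_required and attempts < max_attempts:
        candidate = sampler()
        attempts += 1
        outcome = filter_cage(candidate, seen_keys)
        log.append((candidate, outcome))
        if outcome.passed:
            passing.append(candidate)
            seen_keys.add(cage_key(candidate))  # passed cages count as seen
    return passing, log, len(passing) < n_required


def compute_metrics(
    batch: list[CageRecord],
    reference_keys_original: set[str],
    reference_keys_combined: set[str],
) -> GenerationReport:
    """Score a decoded batch with the standard conditioned rates."""
    if not batch:
        raise ValueError("empty batch")
    valid: list[tuple[CageRecord, str]] = []
    for rec in batch:
        try:
            valid.append((rec, cage_key(rec)))
        except InvalidSmilesError:
            continue
    n = len(batch)
    if not valid:
        return GenerationReport(n, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    keys = [k for _, k in valid]
    novelty_orig = sum(k not in reference_keys_original for k in keys) / len(valid)
    novelty_comb = sum(k not in reference_keys_combined for k in keys) / len(valid)
    counts: dict[str, int] = {}
    for k in keys:
        counts[k] = counts.get(k, 0) + 1
    # cages appearing multiple times are counted once
    uniqueness = len(counts) / len(valid)
    precursor_valid = [rec for rec, _ in valid if count_reaction_sites(rec.bb2) == 2]
    precursor_rate = len(precursor_valid) / len(valid)
    if precursor_valid:
        symmetry = sum(is_symmetric_bb2(r.bb2) for r in precursor_valid) / len(precursor_valid)
    else:
        symmetry = 0.0
    return GenerationReport(
        n_sampled=n,
        validity=len(valid) / n,
        novelty_original_given_valid=novelty_orig,
        novelty_combined_given_valid=novelty_comb,
        uniqueness_given_valid=uniqueness,
        precursor_validity_given_valid=precursor_rate,
        symmetry_given_precursor_valid=symmetry,
    )


def pca_latent(latents: np.ndarray, n_components: int = 2):
    """Centered principal-component projection of latent vectors.

    Returns ``(coordinates, explained_variance_ratios)``; deterministic up
    to component sign.
    """
    latents = np.asarray(latents, dtype=np.float64)
    if latents.shape[0] < n_components:
        raise ValueError("need at least n_components latent vectors")
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(latents)
    return coords, pca.explained_variance_ratio_
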