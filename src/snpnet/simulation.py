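"""Genotype-shuffling null models, rank conservation and the segregation curve.

Two permutation nulls probe the robustness of the knockout ranking while
keeping single-marker association statistics fixed:

* Type 1 (genotype-preserving): each marker's column of genotype calls is
  permuted across the individuals of each group, so per-marker genotype
  counts are conserved exactly -- both within every group and pooled.
* Type 2 (allele-preserving): each marker's alleles are pooled within
  each group, permuted and re-paired into new genotypes, so per-marker
  allele counts are conserved but genotype (homozygote/heterozygote)
  counts may change.

Group labels stay attached to individuals in both nulls.  Because the
permutation acts within groups, every single-marker case-control
statistic (genotype or allele chi-square) is exactly unchanged under the
respective null: the shuffles destroy only the *combinatorial* structure
linking SNPs within an individual, which is what the superset network
exploits.  Rank
conservation is the percentage of shuffled replicates in which a marker
re-occupies its original knockout rank.  The segregation curve tracks how
many genotype supersets remain shared between cases and controls as the
number of SNPs in a random subset grows.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geno_core import CohortDataset
from .knockout import knockout_scan, rank_markers

__all__ = [
    "ShuffleSpec",
    "shuffle_type1",
    "shuffle_type2",
    "rank_conservation",
    "segregation_curve",
    "shared_superset_count",
]

_SEED_MOD = 2**31


@dataclass(frozen=True)
class ShuffleSpec:
    """Which null to draw from, how many replicates, and the master seed."""

    method: str  # "type1_genotype_preserving" | "type2_allele_preserving"
    n_reps: int
    seed: int

    def __post_init__(self) -> None:
        if self.method not in ("type1_genotype_preserving", "type2_allele_preserving"):
            raise ValueError(f"unknown shuffle method {self.method!r}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


def _replicate_rng(seed: int, rep: int) -> np.random.Generator:
    # independent substream per replicate: reproducible and order-free
    return np.random.default_rng((seed + rep) % _SEED_MOD)


def shuffle_type1(dataset: CohortDataset, seed: int | np.random.Generator) -> CohortDataset:
    """Genotype-preserving shuffle (Method 1).

    Each marker's column of calls is independently permuted across the
    individuals of each group, so per-marker genotype counts -- and hence
    every single-marker case-control statistic -- are exactly conserved;
    group labels are untouched.  Only the pairing of genotypes across
    markers within an individual is randomized.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = dataset.codes.copy()
    for gi in range(len(dataset.groups)):
        rows = np.flatnonzero(dataset.group_codes == gi)
        for j in range(codes.shape[1]):
            codes[rows, j] = codes[rng.permutation(rows), j]
    return CohortDataset(
        marker_names=dataset.marker_names, groups=dataset.groups,
        sample_ids=dataset.sample_ids, group_codes=dataset.group_codes,
        codes=codes,
    )


def shuffle_type2(dataset: CohortDataset, seed: int | np.random.Generator) -> CohortDataset:
    """Allele-preserving shuffle (Method 2).

    Per marker and group, the 2n alleles are pooled, permuted, and
    consecutive pairs re-form genotypes (heterozygote order
    canonicalized).  Allele counts are conserved exactly; genotype
    counts may change.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    codes = np.empty_like(dataset.codes)
    for gi in range(len(dataset.groups)):
        rows = np.flatnonzero(dataset.group_codes == gi)
        for j in range(codes.shape[1]):
            n_variant = int(dataset.codes[rows, j].sum())  # dosage sums = allele-"2" count
            alleles = np.zeros(2 * len(rows), dtype=np.uint8)
            alleles[:n_variant] = 1
            rng.shuffle(alleles)
            codes[rows, j] = alleles[0::2] + alleles[1::2]  # 1+0 and 0+1 both -> "12"
    return CohortDataset(
        marker_names=dataset.marker_names, groups=dataset.groups,
        sample_ids=dataset.sample_ids, group_codes=dataset.group_codes,
        codes=codes,
    )


_SHUFFLERS = {
    "type1_genotype_preserving": shuffle_type1,
    "type2_allele_preserving": shuffle_type2,
}


def rank_conservation(
    dataset: CohortDataset,
    spec: ShuffleSpec,
    criterion: str,
    focal: str,
    reference: str,
) -> pd.DataFrame:
    """Exact-rank conservation of the knockout ranking under a shuffle null.

    Computes the original ranking, then for each replicate shuffles the
    dataset, re-runs the knockout scan and ranking, and counts how often
    each marker re-appears at its exact original rank.

    Returns a DataFrame with columns ``rank`` (1 = strongest risk
    candidate), ``marker`` (the original occupant) and
    ``conservation_pct`` (100 x matches / n_reps).
    """
    shuffler = _SHUFFLERS[spec.method]
    original = rank_markers(knockout_scan(dataset, focal, reference), criterion)
    matches = np.zeros(len(original), dtype=np.int64)
    for rep in range(spec.n_reps):
        shuffled = shuffler(dataset, _replicate_rng(spec.seed, rep))
        ranking = rank_markers(knockout_scan(shuffled, focal, reference), criterion)
        for pos, marker in enumerate(original):
            if ranking[pos] == marker:
                matches[pos] += 1
    return pd.DataFrame({
        "rank": np.arange(1, len(original) + 1),
        "marker": original,
        "conservation_pct": 100.0 * matches / spec.n_reps,
    })


def shared_superset_count(
    dataset: CohortDataset,
    marker_indices: Sequence[int] | None = None,
    groups: tuple[str, str] | None = None,
) -> int:
    """Number of genotype supersets observed in *both* of two groups."""
    if groups is None:
        if len(dataset.groups) < 2:
            raise ValueError("need two groups to count shared supersets")
        groups = (dataset.groups[0], dataset.groups[1])
    ga, gb = (dataset.groups.index(g) for g in groups)
    codes = dataset.codes if marker_indices is None else dataset.codes[:, list(marker_indices)]
    rows_a = codes[dataset.group_codes == ga]
    rows_b = codes[dataset.group_codes == gb]
    set_a = {r.tobytes() for r in rows_a}
    set_b = {r.tobytes() for r in rows_b}
    return len(set_a & set_b)


def segregation_curve(
    dataset: CohortDataset,
    sizes: Sequence[int],
    n_reps: int,
    seed: int,
    groups: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Shared-superset count as a function of SNP-subset size.

    For each subset size and replicate, that many marker columns are
    sampled uniformly without replacement, supersets are formed for the
    two groups, and the number of supersets present in both is recorded.
    Returns mean and standard deviation per size (columns ``n_markers``,
    ``mean_shared``, ``sd_shared``).
    """
    sizes = list(sizes)
    if any(s < 1 or s > dataset.n_markers for s in sizes):
        raise ValueError(f"subset sizes must lie in [1, {dataset.n_markers}]")
    rows = []
    for si, size in enumerate(sizes):
        counts = np.empty(n_reps, dtype=np.int64)
        for rep in range(n_reps):
            rng = _replicate_rng(seed, rep * len(sizes) + si)
            cols = rng.choice(dataset.n_markers, size=size, replace=False)
            counts[rep] = shared_superset_count(dataset, cols, groups)
        rows.append({"n_markers": size, "mean_shared": float(counts.mean()),
                     "sd_shared": float(counts.std(ddof=0))})
    return pd.DataFrame(rows)
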