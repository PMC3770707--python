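"""Seeded synthetic genotype cohorts with the structure the method assumes.

The generator draws genotypes per group under Hardy-Weinberg equilibrium
from group-specific minor-allele frequencies; a "risk" SNP is planted as
a minor-allele-frequency difference between groups, and a pair of linked
markers is generated by drawing two haplotypes per individual from an
explicit four-haplotype distribution.  Uniform missingness can be
injected to exercise the parser's removal rule.

Three presets emulate the study conditions used throughout the package:

* ``acs-like`` -- two groups of 91 cases / 86 controls over 5 SNPs, with
  the risk SNP at position 4 (minor-allele frequency 0.40 in cases vs
  0.03 in controls, the contrast seen at the strongest locus of an
  ACS cohort) and an LD pair at positions 3 and 5 tuned to r² = 0.70.
* ``oral-like`` -- three groups (control/leukoplakia/cancer of sizes
  369/219/298) over 5 SNPs with a moderate risk SNP in the cancer group.
* ``panel-like`` -- a large two-group panel of 1804 independent SNPs for
  635 individuals with minor-allele frequencies uniform on [0.05, 0.5].
"""

from __future__ import annotations

import json
from collections.abc import Callable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geno_core import CALLS, CohortDataset, parse_dataset

__all__ = [
    "GroupSpec",
    "LDPairSpec",
    "SynthConfig",
    "generate_table",
    "generate_cohort",
    "generate_large_panel",
    "acs_like",
    "oral_like",
    "panel_like",
    "PRESETS",
    "config_from_json",
]

_SEED_MOD = 2**31


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: label, size and per-marker minor-allele frequencies."""

    label: str
    n: int
    maf: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.label!r} must have n >= 1")
        if any(not 0 <= f <= 1 for f in self.maf):
            raise ValueError("minor-allele frequencies must lie in [0, 1]")


@dataclass(frozen=True)
class LDPairSpec:
    """Two linked markers drawn jointly from a haplotype distribution.

    `freqs` = (f11, f12, f21, f22) over (allele at first marker, allele at
    second marker) with 1 = wild, 2 = variant; must sum to 1.  The pair's
    haplotype distribution overrides the per-group maf at both positions.
    """

    markers: tuple[int, int]
    freqs: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if abs(sum(self.freqs) - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")
        if self.markers[0] == self.markers[1]:
            raise ValueError("an LD pair needs two distinct markers")


@dataclass(frozen=True)
class SynthConfig:
    """Full description of a synthetic cohort."""

    groups: tuple[GroupSpec, ...]
    marker_names: tuple[str, ...]
    ld_pairs: tuple[LDPairSpec, ...] = ()
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        m = len(self.marker_names)
        for g in self.groups:
            if len(g.maf) != m:
                raise ValueError(f"group {g.label!r} maf vector length != {m} markers")
        used: set[int] = set()
        for pair in self.ld_pairs:
            for idx in pair.markers:
                if not 0 <= idx < m:
                    raise ValueError(f"LD pair marker index {idx} out of range")
                if idx in used:
                    raise ValueError("LD pairs must use disjoint marker sets")
                used.add(idx)


def generate_table(cfg: SynthConfig) -> pd.DataFrame:
    """Draw a genotype table (string calls, ``NA`` for missing) from `cfg`.

    Unlinked markers: per individual, two alleles Bernoulli(maf) under
    HWE within each group.  LD-pair markers: two haplotypes per
    individual from the pair's four-haplotype distribution, combined into
    the two genotype calls.  Fully deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed % _SEED_MOD)
    ld_markers = {i for pair in cfg.ld_pairs for i in pair.markers}
    frames = []
    offset = 0
    for g in cfg.groups:
        codes = np.zeros((g.n, len(cfg.marker_names)), dtype=np.uint8)
        for j, maf in enumerate(g.maf):
            if j in ld_markers:
                continue
            codes[:, j] = rng.binomial(2, maf, size=g.n)
        for pair in cfg.ld_pairs:
            i, j = pair.markers
            haps = rng.choice(4, size=(g.n, 2), p=np.asarray(pair.freqs))
            # haplotype index -> (allele at i, allele at j), 0 = wild, 1 = variant
            codes[:, i] = (haps // 2).sum(axis=1)
            codes[:, j] = (haps % 2).sum(axis=1)
        calls = np.array(CALLS, dtype=object)[codes]
        if cfg.missing_rate > 0:
            miss = rng.random(codes.shape) < cfg.missing_rate
            calls[miss] = "NA"
        df = pd.DataFrame(calls, columns=list(cfg.marker_names))
        df.insert(0, "group", g.label)
        df.insert(0, "sample_id", [f"{g.label}_{offset + r + 1:04d}" for r in range(g.n)])
        offset += g.n
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def generate_cohort(cfg: SynthConfig) -> CohortDataset:
    """Generate a table and run it through the parser (drops missing calls)."""
    return parse_dataset(generate_table(cfg), groups=[g.label for g in cfg.groups])


def generate_large_panel(
    n_snps: int,
    n_individuals: int,
    maf_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int = 0,
    case_fraction: float = 0.5,
) -> CohortDataset:
    """Two-group panel of independent HWE markers with sampled frequencies.

    Per-marker minor-allele frequencies come from `maf_sampler`
    (default: uniform on [0.05, 0.5], shared by both groups, i.e. a null
    panel with no planted association).  Individuals are split into
    ``case``/``control`` by `case_fraction` (cases rounded up).
    """
    if n_snps < 1 or n_individuals < 1:
        raise ValueError("panel dimensions must be >= 1")
    rng = np.random.default_rng(seed % _SEED_MOD)
    if maf_sampler is None:
        maf = rng.uniform(0.05, 0.5, size=n_snps)
    else:
        maf = np.asarray(maf_sampler(rng, n_snps), dtype=float)
    n_case = max(1, int(np.ceil(case_fraction * n_individuals))) if n_individuals > 1 else 1
    n_case = min(n_case, n_individuals)
    codes = rng.binomial(2, maf[None, :], size=(n_individuals, n_snps)).astype(np.uint8)
    group_codes = np.zeros(n_individuals, dtype=np.intp)
    group_codes[n_case:] = 1
    groups = ("case", "control") if n_case < n_individuals else ("case",)
    return CohortDataset(
        marker_names=tuple(f"SNP{i + 1}" for i in range(n_snps)),
        groups=groups,
        sample_ids=tuple(f"ind{i + 1:04d}" for i in range(n_individuals)),
        group_codes=group_codes,
        codes=codes,
    )


def _ld_pair_freqs(maf_a: float, maf_b: float, r2: float) -> tuple[float, float, float, float]:
    """Haplotype frequencies for two loci with given mafs and positive-D r²."""
    d = np.sqrt(r2 * maf_a * (1 - maf_a) * maf_b * (1 - maf_b))
    f22 = maf_a * maf_b + d  # variant-variant haplotype in coupling phase
    f21 = maf_a - f22
    f12 = maf_b - f22
    f11 = 1.0 - f22 - f21 - f12
    if min(f11, f12, f21, f22) < 0:
        raise ValueError("requested r² not attainable at these allele frequencies")
    return (f11, f12, f21, f22)


def acs_like(seed: int = 0, missing_rate: float = 0.0) -> SynthConfig:
    """Two-group cohort (91 cases / 86 controls, 5 SNPs).

    SNP4 is the single planted risk marker (minor-allele frequency 0.40
    in cases vs 0.03 in controls, the contrast seen at the strongest
    locus of an ACS cohort); all other markers are exchangeable
    background with identical frequencies in both groups, so SNP4 is the
    only marker carrying case-control information.  SNP3 and SNP5 form
    an LD pair at r² = 0.70 with shared minor-allele frequency 0.15.
    """
    markers = ("SNP1", "SNP2", "SNP3", "SNP4", "SNP5")
    return SynthConfig(
        groups=(
            GroupSpec("case", 91, (0.18, 0.12, 0.15, 0.40, 0.15)),
            GroupSpec("control", 86, (0.18, 0.12, 0.15, 0.03, 0.15)),
        ),
        marker_names=markers,
        ld_pairs=(LDPairSpec(markers=(2, 4), freqs=_ld_pair_freqs(0.15, 0.15, 0.70)),),
        missing_rate=missing_rate,
        seed=seed,
    )


def oral_like(seed: int = 0, missing_rate: float = 0.0) -> SynthConfig:
    """Three-group cohort (369 controls / 219 leukoplakia / 298 cancers, 5 SNPs).

    SNP2 carries an elevated minor-allele frequency in the cancer group
    (the risk marker); the other markers are shared moderate-frequency
    background, unlinked (the five oral-cohort loci sit on different
    chromosomes).
    """
    markers = ("SNP1", "SNP2", "SNP3", "SNP4", "SNP5")
    return SynthConfig(
        groups=(
            GroupSpec("control", 369, (0.25, 0.20, 0.22, 0.30, 0.28)),
            GroupSpec("leukoplakia", 219, (0.25, 0.24, 0.22, 0.30, 0.28)),
            GroupSpec("cancer", 298, (0.25, 0.35, 0.22, 0.30, 0.28)),
        ),
        marker_names=markers,
        missing_rate=missing_rate,
        seed=seed,
    )


def panel_like(seed: int = 0) -> CohortDataset:
    """Large null panel: 1804 independent SNPs x 635 individuals."""
    return generate_large_panel(1804, 635, seed=seed)


PRESETS: dict[str, Callable[..., SynthConfig | CohortDataset]] = {
    "acs-like": acs_like,
    "oral-like": oral_like,
    "panel-like": panel_like,
}


def config_from_json(source: str | Path) -> SynthConfig:
    """Load a :class:`SynthConfig` from a JSON document."""
    doc = json.loads(Path(source).read_text(encoding="utf-8"))
    groups = tuple(
        GroupSpec(g["label"], int(g["n"]), tuple(float(x) for x in g["maf"]))
        for g in doc["groups"]
    )
    pairs = tuple(
        LDPairSpec(tuple(p["markers"]), tuple(float(x) for x in p["freqs"]))
        for p in doc.get("ld_pairs", [])
    )
    markers = tuple(doc.get("marker_names")
                    or (f"SNP{i + 1}" for i in range(len(groups[0].maf))))
    return SynthConfig(groups=groups, marker_names=markers, ld_pairs=pairs,
                       missing_rate=float(doc.get("missing_rate", 0.0)),
                       seed=int(doc.get("seed", 0)))
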