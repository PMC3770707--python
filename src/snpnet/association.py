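"""Case-control association statistics supporting the network analysis.

Covers the conventional single-locus and two-locus statistics run
alongside the genotype-network method: Yates-corrected chi-square on 2x2
tables, odds ratios with Woolf (log-odds) 95% confidence intervals,
one-vs-rest haplotype odds ratios, two-locus haplotype frequency
estimation by EM from unphased genotypes, and the standard pairwise
linkage-disequilibrium summaries D, D' and r².
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .geno_core import CohortDataset

__all__ = [
    "AssociationResult",
    "TwoLocusHaplotypes",
    "LDStats",
    "DegenerateLDError",
    "yates_chi_square",
    "odds_ratio_woolf",
    "haplotype_case_control_or",
    "em_two_locus",
    "ld_stats",
]


class DegenerateLDError(ValueError):
    """Raised when LD quantities are undefined (monomorphic locus)."""


@dataclass(frozen=True)
class AssociationResult:
    """Chi-square, p and odds ratio with 95% CI for one 2x2 contrast."""

    chi2: float
    p: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    continuity_corrected: bool = False  # Haldane-Anscombe +0.5 applied to the OR


def _check_table(a: float, b: float, c: float, d: float) -> None:
    if min(a, b, c, d) < 0:
        raise ValueError("contingency counts must be non-negative")


def yates_chi_square(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """Pearson chi-square with Yates continuity correction on a 2x2 table.

    Rows are (case exposed, case unexposed) and (control exposed,
    control unexposed).  chi2 = sum (max(|O-E| - 0.5, 0))^2 / E with df=1;
    the 0.5 is floored at |O-E| so the correction never overshoots.

    Raises
    ------
    ValueError
        If any row or column margin is zero (test undefined).
    """
    _check_table(a, b, c, d)
    n = a + b + c + d
    margins = (a + b, c + d, a + c, b + d)
    if min(margins) == 0:
        raise ValueError("chi-square test undefined: a table margin is zero")
    obs = np.array([[a, b], [c, d]], dtype=float)
    exp = np.outer([a + b, c + d], [a + c, b + d]) / n
    adj = np.maximum(np.abs(obs - exp) - 0.5, 0.0)
    chi2 = float((adj**2 / exp).sum())
    return chi2, float(chi2_dist.sf(chi2, df=1))


def odds_ratio_woolf(a: float, b: float, c: float, d: float) -> AssociationResult:
    """Odds ratio with Woolf 95% confidence interval.

    OR = (a/b)/(c/d); CI = exp(ln OR +/- 1.96 sqrt(1/a+1/b+1/c+1/d)).
    If any cell is zero, the Haldane-Anscombe correction adds 0.5 to all
    four cells first (flagged in the result).  The chi-square/p fields are
    filled from :func:`yates_chi_square` on the *uncorrected* table when
    that test is defined, else NaN.
    """
    _check_table(a, b, c, d)
    if (a == 0 and b == 0) or (c == 0 and d == 0):
        raise ValueError("odds ratio undefined: a whole row is zero")
    try:
        chi2, p = yates_chi_square(a, b, c, d)
    except ValueError:
        chi2, p = float("nan"), float("nan")
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a / b) / (c / d)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(or_) - 1.96 * se), math.exp(math.log(or_) + 1.96 * se)
    return AssociationResult(chi2=chi2, p=p, odds_ratio=or_, ci_low=lo,
                             ci_high=hi, continuity_corrected=corrected)


def haplotype_case_control_or(
    hap_counts: Mapping[str, tuple[int, int]],
    n_case: int,
    n_control: int,
    min_freq: float = 0.03,
) -> pd.DataFrame:
    """One-vs-rest odds ratios for two-locus haplotypes.

    `hap_counts` maps a haplotype label to its chromosome counts in cases
    and controls; `n_case`/`n_control` are the total chromosome counts
    (2 x individuals).  Haplotypes below `min_freq` in *both* groups are
    excluded from risk assessment.  For each remaining haplotype the 2x2
    contrast is (this haplotype vs all others) x (case vs control), giving
    an OR oriented as odds of carrying the haplotype in cases over
    controls, with Woolf CI and Yates p.
    """
    rows = []
    for hap, (ca, co) in hap_counts.items():
        if ca > n_case or co > n_control:
            raise ValueError(f"haplotype {hap!r} count exceeds total chromosomes")
        if ca / n_case <= min_freq and co / n_control <= min_freq:
            continue
        res = odds_ratio_woolf(ca, n_case - ca, co, n_control - co)
        rows.append({"haplotype": hap, "case_count": ca, "control_count": co,
                     "odds_ratio": res.odds_ratio, "ci_low": res.ci_low,
                     "ci_high": res.ci_high, "chi2": res.chi2, "p": res.p})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TwoLocusHaplotypes:
    """ML two-locus haplotype frequencies from unphased genotypes.

    Haplotype ``p11`` carries the wild allele at both loci, ``p12`` wild
    at the first and variant at the second, etc.  ``p_a``/``p_b`` are the
    wild-allele frequencies at each locus (p11+p12 and p11+p21).
    """

    p11: float
    p12: float
    p21: float
    p22: float
    loglik: float
    n_iterations: int
    n_individuals: int

    @property
    def p_a(self) -> float:
        return self.p11 + self.p12

    @property
    def p_b(self) -> float:
        return self.p11 + self.p21

    @property
    def freqs(self) -> np.ndarray:
        return np.array([self.p11, self.p12, self.p21, self.p22])


def two_locus_genotype_counts(
    dataset: CohortDataset, i: int, j: int, groups: Sequence[str] | None = None
) -> np.ndarray:
    """3x3 table of joint allele-"2" dosages at markers `i` and `j`."""
    mask = np.ones(dataset.n_individuals, dtype=bool)
    if groups is not None:
        keep = {dataset.groups.index(g) for g in groups}
        mask = np.isin(dataset.group_codes, list(keep))
    gi = dataset.codes[mask, i].astype(np.intp)
    gj = dataset.codes[mask, j].astype(np.intp)
    counts = np.zeros((3, 3), dtype=np.int64)
    np.add.at(counts, (gi, gj), 1)
    return counts


def _two_locus_loglik(f: np.ndarray, n: np.ndarray) -> float:
    """Multinomial log-likelihood of the 3x3 dosage table `n` given
    haplotype frequencies f = (f11, f12, f21, f22) under random mating."""
    f11, f12, f21, f22 = f
    probs = np.array([
        [f11**2, 2 * f11 * f12, f12**2],
        [2 * f11 * f21, 2 * f11 * f22 + 2 * f12 * f21, 2 * f12 * f22],
        [f21**2, 2 * f21 * f22, f22**2],
    ])
    with np.errstate(divide="ignore"):
        logp = np.where(n > 0, np.log(np.maximum(probs, 1e-300)), 0.0)
    return float((n * logp).sum())


def em_two_locus(
    dataset: CohortDataset,
    i: int,
    j: int,
    groups: Sequence[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
    init: Sequence[float] | None = None,
) -> TwoLocusHaplotypes:
    """EM estimate of two-locus haplotype frequencies from genotype data.

    Under Hardy-Weinberg random mating every genotype pair resolves its
    two gametes unambiguously except the double heterozygote, which is
    split between the cis (11/22) and trans (12/21) resolutions in
    proportion to the current f11*f22 vs f12*f21.  Iterates the E/M steps
    until max |delta f| < `tol` (default 1e-8) or `max_iter`; the
    log-likelihood is asserted non-decreasing at every step.

    Raises
    ------
    DegenerateLDError
        If either marker is monomorphic within the chosen scope.
    """
    n = two_locus_genotype_counts(dataset, i, j, groups)
    total = n.sum()
    dosage_a = n.sum(axis=1) @ np.array([0, 1, 2])
    dosage_b = n.sum(axis=0) @ np.array([0, 1, 2])
    if dosage_a in (0, 2 * total) or dosage_b in (0, 2 * total):
        raise DegenerateLDError("marker monomorphic in the chosen scope; LD undefined")

    f = np.full(4, 0.25) if init is None else np.asarray(init, dtype=float)
    f = f / f.sum()
    loglik = _two_locus_loglik(f, n)
    # fixed gamete contributions from unambiguous genotype cells
    # cell (da, db) with da,db in {0,1,2}: gametes known unless da==db==1
    it = 0
    for it in range(1, max_iter + 1):
        f11, f12, f21, f22 = f
        cis = f11 * f22
        trans = f12 * f21
        frac_cis = 0.5 if cis + trans == 0 else cis / (cis + trans)
        dh = n[1, 1]
        h = np.zeros(4)  # expected haplotype counts (11, 12, 21, 22)
        h[0] = 2 * n[0, 0] + n[0, 1] + n[1, 0] + dh * frac_cis
        h[1] = 2 * n[0, 2] + n[0, 1] + n[1, 2] + dh * (1 - frac_cis)
        h[2] = 2 * n[2, 0] + n[1, 0] + n[2, 1] + dh * (1 - frac_cis)
        h[3] = 2 * n[2, 2] + n[1, 2] + n[2, 1] + dh * frac_cis
        new_f = h / (2 * total)
        new_loglik = _two_locus_loglik(new_f, n)
        assert new_loglik >= loglik - 1e-9, "EM log-likelihood decreased"
        delta = np.abs(new_f - f).max()
        f, loglik = new_f, new_loglik
        if delta < tol:
            break
    return TwoLocusHaplotypes(p11=float(f[0]), p12=float(f[1]), p21=float(f[2]),
                              p22=float(f[3]), loglik=loglik, n_iterations=it,
                              n_individuals=int(total))


@dataclass(frozen=True)
class LDStats:
    """Pairwise linkage disequilibrium: D, normalized D' and r²."""

    d: float
    d_prime: float
    r2: float


def ld_stats(h: TwoLocusHaplotypes) -> LDStats:
    """D, D' and r² from two-locus haplotype frequencies.

    D = p11 - pA*pB; r² = D² / (pA(1-pA) pB(1-pB)); D' = D/Dmax with
    Dmax = min(pA(1-pB), (1-pA)pB) for D > 0 and
    Dmax = min(pA pB, (1-pA)(1-pB)) for D < 0.
    """
    pa, pb = h.p_a, h.p_b
    if not (0 < pa < 1 and 0 < pb < 1):
        raise DegenerateLDError("allele frequencies on the boundary; LD undefined")
    d = h.p11 - pa * pb
    r2 = d**2 / (pa * (1 - pa) * pb * (1 - pb))
    if d > 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    elif d < 0:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    else:
        return LDStats(d=0.0, d_prime=0.0, r2=0.0)
    return LDStats(d=d, d_prime=d / dmax, r2=r2)
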