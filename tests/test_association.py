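"""Yates chi-square, odds ratios, haplotype ORs, two-locus EM and LD."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from snpnet.association import (
    DegenerateLDError,
    _two_locus_loglik,
    em_two_locus,
    haplotype_case_control_or,
    ld_stats,
    odds_ratio_woolf,
    two_locus_genotype_counts,
    yates_chi_square,
)
from snpnet.geno_core import CohortDataset

from conftest import make_dataset, random_dataset


# ---------------------------------------------------------------- chi-square

@pytest.mark.parametrize(
    "table, p_2dp",
    [((73, 15, 66, 11), 0.79), ((9, 79, 14, 63), 0.21)],
)
def test_yates_p_values_on_allele_count_tables(table, p_2dp):
    _, p = yates_chi_square(*table)
    assert round(p, 2) == p_2dp


def test_yates_on_perfectly_independent_table():
    chi2, p = yates_chi_square(10, 10, 10, 10)
    assert chi2 == 0.0
    assert p == 1.0


def test_yates_rejects_zero_margin():
    with pytest.raises(ValueError, match="margin"):
        yates_chi_square(0, 0, 5, 5)
    with pytest.raises(ValueError, match="margin"):
        yates_chi_square(0, 5, 0, 5)


@settings(max_examples=50, deadline=None)
@given(st.tuples(*[st.integers(1, 200)] * 4))
def test_yates_never_exceeds_pearson_and_matches_scipy(table):
    a, b, c, d = table
    chi2_yates, p_yates = yates_chi_square(a, b, c, d)
    obs = np.array([[a, b], [c, d]])
    pearson = chi2_contingency(obs, correction=False)
    scipy_yates = chi2_contingency(obs, correction=True)
    assert chi2_yates <= pearson.statistic + 1e-12
    assert chi2_yates == pytest.approx(scipy_yates.statistic, abs=1e-9)
    assert p_yates == pytest.approx(scipy_yates.pvalue, abs=1e-9)


# --------------------------------------------------------------- odds ratios

def test_haplotype_tc_odds_ratio_is_protective():
    res = odds_ratio_woolf(102, 74, 135, 19)
    assert round(res.odds_ratio, 2) == 0.19


def test_symmetric_table_gives_unit_odds_ratio():
    res = odds_ratio_woolf(5, 5, 5, 5)
    assert res.odds_ratio == pytest.approx(1.0)
    assert res.ci_low < 1 < res.ci_high


def test_woolf_interval_closed_form():
    res = odds_ratio_woolf(61, 115, 2, 152)
    assert res.odds_ratio == pytest.approx(40.31, abs=0.01)
    assert res.ci_low == pytest.approx(9.66, abs=0.01)
    assert res.ci_high == pytest.approx(168.4, abs=0.1)


def test_zero_cell_triggers_haldane_correction():
    res = odds_ratio_woolf(10, 5, 0, 12)
    assert res.continuity_corrected
    assert np.isfinite(res.odds_ratio) and np.isfinite(res.ci_high)
    with pytest.raises(ValueError):
        odds_ratio_woolf(0, 0, 3, 4)


def test_woolf_matches_statsmodels():
    statsmodels = pytest.importorskip("statsmodels.stats.contingency_tables")
    t = statsmodels.Table2x2(np.array([[102, 74], [135, 19]]))
    res = odds_ratio_woolf(102, 74, 135, 19)
    assert res.odds_ratio == pytest.approx(t.oddsratio)
    lo, hi = t.oddsratio_confint(0.05)
    assert res.ci_low == pytest.approx(lo, rel=1e-3)
    assert res.ci_high == pytest.approx(hi, rel=1e-3)


@settings(max_examples=30, deadline=None)
@given(st.tuples(*[st.integers(1, 100)] * 4))
def test_exposure_flip_inverts_odds_ratio(table):
    a, b, c, d = table
    or1 = odds_ratio_woolf(a, b, c, d).odds_ratio
    or2 = odds_ratio_woolf(b, a, d, c).odds_ratio
    assert or1 * or2 == pytest.approx(1.0)


def test_haplotype_risk_table():
    counts = {"C-C": (13, 17), "T-C": (102, 135), "T-T": (61, 2),
              "rare": (2, 1)}  # ~1% in both groups -> filtered
    table = haplotype_case_control_or(counts, n_case=176, n_control=154)
    assert set(table["haplotype"]) == {"C-C", "T-C", "T-T"}
    tc = table.set_index("haplotype").loc["T-C"]
    assert round(tc["odds_ratio"], 2) == 0.19
    assert tc["p"] < 1e-4
    # each row equals the closed-form one-vs-rest computation
    for hap, (ca, co) in counts.items():
        if hap == "rare":
            continue
        ref = odds_ratio_woolf(ca, 176 - ca, co, 154 - co)
        row = table.set_index("haplotype").loc[hap]
        assert row["odds_ratio"] == pytest.approx(ref.odds_ratio)


# ------------------------------------------------------------ two-locus EM

def _dataset_from_codes(codes):
    codes = np.asarray(codes, dtype=np.uint8)
    n = len(codes)
    return CohortDataset(
        marker_names=("A", "B"),
        groups=("g",),
        sample_ids=tuple(f"s{i}" for i in range(n)),
        group_codes=np.zeros(n, dtype=np.intp),
        codes=codes,
    )


def test_em_without_double_heterozygotes_counts_gametes_directly():
    # genotypes chosen so every gamete is unambiguous
    ds = _dataset_from_codes([(0, 0), (0, 2), (2, 2), (2, 0), (1, 0), (0, 1)])
    h = em_two_locus(ds, 0, 1)
    # direct gamete counts over 12 chromosomes:
    # 11: 2+0+0+0+1+1 = 4; 12: 2+1 = 3; 21: 2+1 = 3; 22: 2
    assert h.freqs == pytest.approx([4 / 12, 3 / 12, 3 / 12, 2 / 12], abs=1e-9)


def test_em_matches_grid_search_oracle():
    """EM optimum agrees with a 1e-3 grid over the admissible D range.

    At the multinomial ML solution the allele frequencies equal the
    sample frequencies, so the likelihood is maximized over the single
    remaining degree of freedom D.
    """
    rng = np.random.default_rng(42)
    codes = np.column_stack([rng.integers(0, 3, 20), rng.integers(0, 3, 20)])
    ds = _dataset_from_codes(codes)
    h = em_two_locus(ds, 0, 1)
    n = two_locus_genotype_counts(ds, 0, 1)
    total = n.sum()
    pa = 1 - (n.sum(axis=1) @ np.array([0, 1, 2])) / (2 * total)  # wild at A
    pb = 1 - (n.sum(axis=0) @ np.array([0, 1, 2])) / (2 * total)
    assert h.p_a == pytest.approx(pa, abs=1e-6)
    assert h.p_b == pytest.approx(pb, abs=1e-6)
    best_ll, best_d = -np.inf, None
    for d in np.arange(-0.25, 0.25, 1e-3):
        f = np.array([pa * pb + d, pa * (1 - pb) - d,
                      (1 - pa) * pb - d, (1 - pa) * (1 - pb) + d])
        if f.min() < 0:
            continue
        ll = _two_locus_loglik(f, n)
        if ll > best_ll:
            best_ll, best_d = ll, d
    assert h.p11 - pa * pb == pytest.approx(best_d, abs=1e-3)
    assert h.loglik >= best_ll - 1e-4


def test_em_multistart_converges_to_same_optimum():
    rng = np.random.default_rng(7)
    codes = np.column_stack([rng.integers(0, 3, 50), rng.integers(0, 3, 50)])
    ds = _dataset_from_codes(codes)
    h1 = em_two_locus(ds, 0, 1)
    h2 = em_two_locus(ds, 0, 1, init=(0.4, 0.1, 0.2, 0.3))
    assert h1.freqs == pytest.approx(h2.freqs, abs=1e-6)


def test_em_rejects_monomorphic_marker():
    ds = _dataset_from_codes([(0, 0), (0, 1), (0, 2)])
    with pytest.raises(DegenerateLDError):
        em_two_locus(ds, 0, 1)


def test_em_scope_restricts_to_groups():
    ds = make_dataset(
        [("s1", "case", "11", "12"), ("s2", "case", "12", "11"),
         ("s3", "control", "22", "22")]
    )
    h = em_two_locus(ds, 0, 1, groups=["case"])
    assert h.n_individuals == 2


# ------------------------------------------------------------------ LD stats

def test_independent_loci_have_zero_ld():
    ds = _dataset_from_codes([(0, 0), (0, 2), (2, 0), (2, 2)])
    stats = ld_stats(em_two_locus(ds, 0, 1))
    assert stats.d == pytest.approx(0.0, abs=1e-9)
    assert stats.r2 == pytest.approx(0.0, abs=1e-9)


def test_perfect_coupling_has_complete_ld():
    ds = _dataset_from_codes([(0, 0), (0, 0), (2, 2), (2, 2), (1, 1)])
    stats = ld_stats(em_two_locus(ds, 0, 1))
    assert stats.d_prime == pytest.approx(1.0, abs=1e-6)
    assert stats.r2 == pytest.approx(1.0, abs=1e-6)


def test_ld_invariant_under_allele_relabeling():
    rng = np.random.default_rng(3)
    codes = np.column_stack([rng.integers(0, 3, 60), rng.integers(0, 3, 60)])
    ds = _dataset_from_codes(codes)
    base = ld_stats(em_two_locus(ds, 0, 1))
    flipped = codes.copy()
    flipped[:, 0] = 2 - flipped[:, 0]  # swap which allele is "1" at locus A
    ds_f = _dataset_from_codes(flipped)
    other = ld_stats(em_two_locus(ds_f, 0, 1))
    assert other.r2 == pytest.approx(base.r2, abs=1e-6)
    assert abs(other.d_prime) == pytest.approx(abs(base.d_prime), abs=1e-6)
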