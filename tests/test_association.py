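"""Phenotype normalization, the rank-sum test, and allele association."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu

from amphase import association as assoc
from amphase.io_formats import FloweringPeriod, PhenotypeRow


P2012 = FloweringPeriod(2012, 153, 169)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "day, expected",
    [(153, 1 / 17), (169, 1.0), (161, 9 / 17)],
)
def test_normalize_flowering_day(day, expected):
    row = PhenotypeRow("i", 2012, day)
    assert assoc.normalize_flowering_day(row, P2012) == pytest.approx(expected)


def test_normalize_out_of_window_clamped():
    assert assoc.normalize_flowering_day(
        PhenotypeRow("i", 2012, 150), P2012
    ) == pytest.approx(1 / 17)
    assert assoc.normalize_flowering_day(
        PhenotypeRow("i", 2012, 180), P2012
    ) == pytest.approx(1.0)


def test_normalize_year_mismatch_error():
    with pytest.raises(ValueError):
        assoc.normalize_flowering_day(PhenotypeRow("i", 2013, 160), P2012)


@settings(derandomize=True, max_examples=50)
@given(
    start=st.integers(100, 200),
    length=st.integers(1, 40),
    offset=st.integers(0, 39),
    shift=st.integers(-50, 50),
)
def test_normalization_translation_invariance(start, length, offset, shift):
    """Shifting bloom day and window together leaves the value unchanged."""
    offset = min(offset, length - 1)
    day = start + offset
    p1 = FloweringPeriod(2000, start, start + length - 1)
    p2 = FloweringPeriod(2000, start + shift, start + shift + length - 1)
    v1 = assoc.normalize_flowering_day(PhenotypeRow("i", 2000, day), p1)
    v2 = assoc.normalize_flowering_day(PhenotypeRow("i", 2000, day + shift), p2)
    assert v1 == pytest.approx(v2)


def test_median_flowering():
    assert assoc.median_flowering([0.2, 0.4, 0.9]) == pytest.approx(0.4)
    assert assoc.median_flowering([0.2, 0.4]) == pytest.approx(0.3)
    with pytest.raises(ValueError):
        assoc.median_flowering([])


def test_median_phenotypes_excludes_individual_without_years():
    rows = [PhenotypeRow("a", 2012, 160)]
    med = assoc.median_phenotypes(rows, [P2012])
    assert set(med) == {"a"}  # "b" never appears: no rows, hence excluded


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def test_exact_p_for_separated_triples():
    w, p = assoc.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="exact")
    assert w == 6.0
    assert p == pytest.approx(0.100, abs=1e-9)


def test_identical_groups_p_one():
    _, p = assoc.wilcoxon_rank_sum([1, 2, 3], [1, 2, 3], mode="exact")
    assert p == pytest.approx(1.0)


def test_empty_group_error():
    with pytest.raises(ValueError):
        assoc.wilcoxon_rank_sum([], [1.0])


def test_exact_vs_approx_agreement():
    """|p_exact - p_approx| <= 0.02 for n=10+10 standard normal draws."""
    rng = np.random.default_rng(12)
    for _ in range(200):
        a, b = rng.normal(size=10), rng.normal(size=10)
        _, pe = assoc.wilcoxon_rank_sum(a, b, mode="exact")
        _, pa = assoc.wilcoxon_rank_sum(a, b, mode="approx")
        assert abs(pe - pa) <= 0.02


def test_exact_matches_scipy_reference():
    """Independent cross-check of the enumerated exact test against
    scipy's implementation (no ties, small n)."""
    rng = np.random.default_rng(3)
    for _ in range(25):
        a = rng.permutation(20)[:6].astype(float)
        b = rng.permutation(40)[20:28].astype(float)
        if len(np.unique(np.r_[a, b])) < a.size + b.size:
            continue
        _, p = assoc.wilcoxon_rank_sum(a, b, mode="exact")
        ref = mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(ref, abs=1e-9)


def test_approx_matches_scipy_reference_with_ties():
    rng = np.random.default_rng(6)
    for _ in range(25):
        a = rng.integers(0, 6, size=30).astype(float)
        b = rng.integers(1, 7, size=25).astype(float)
        _, p = assoc.wilcoxon_rank_sum(a, b, mode="approx")
        ref = mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
        assert p == pytest.approx(ref, rel=1e-6)


def test_rank_test_invariant_under_monotone_transform():
    rng = np.random.default_rng(8)
    a, b = rng.normal(size=12), rng.normal(size=15)
    _, p1 = assoc.wilcoxon_rank_sum(a, b, mode="approx")
    _, p2 = assoc.wilcoxon_rank_sum(np.exp(a), np.exp(b), mode="approx")
    assert p1 == pytest.approx(p2)


def test_equal_medians_can_still_be_significant():
    """Rank-sum is not a median test: equal group medians with shifted tails
    still reject."""
    a = [1, 2, 3, 4, 5, 5, 5, 5, 5]
    b = [5, 5, 5, 5, 5, 6, 7, 8, 9]
    assert float(np.median(a)) == float(np.median(b)) == 5.0
    _, p = assoc.wilcoxon_rank_sum(a, b, mode="approx")
    assert p < 0.05


def test_auto_mode_guards():
    # 21 values without ties -> approx; 20 -> exact
    a = list(range(10))
    b = [x + 0.5 for x in range(11)]
    _, p_big = assoc.wilcoxon_rank_sum(a, b, mode="auto")
    _, p_approx = assoc.wilcoxon_rank_sum(a, b, mode="approx")
    assert p_big == pytest.approx(p_approx)
    _, p_small = assoc.wilcoxon_rank_sum(a, b[:10], mode="auto")
    _, p_exact = assoc.wilcoxon_rank_sum(a, b[:10], mode="exact")
    assert p_small == pytest.approx(p_exact)


# ---------------------------------------------------------------------------
# Allele association
# ---------------------------------------------------------------------------

def _phenos(n, rng):
    return {f"i{k}": float(rng.uniform()) for k in range(n)}


def test_associate_allele_not_determined_when_all_carry():
    rng = np.random.default_rng(0)
    phen = _phenos(10, rng)
    (res,) = assoc.associate_allele({"E1": list(phen)}, phen, gene_id="g")
    assert not res.determined and res.p_value is None


def test_associate_allele_detects_shift():
    rng = np.random.default_rng(1)
    carriers = [f"i{k}" for k in range(20)]
    others = [f"i{k}" for k in range(20, 40)]
    phen = {i: float(rng.normal(0.3, 0.05)) for i in carriers}
    phen.update({i: float(rng.normal(0.7, 0.05)) for i in others})
    (res,) = assoc.associate_allele({"E1": carriers}, phen, gene_id="g")
    assert res.significant and res.p_value <= 0.05
    assert res.carriers == 20 and res.non_carriers == 20
    assert res.carrier_median < res.non_carrier_median


def test_associate_allele_bh_correction_monotone():
    rng = np.random.default_rng(2)
    phen = _phenos(30, rng)
    carrier_sets = {
        lab: [f"i{k}" for k in rng.choice(30, size=12, replace=False)]
        for lab in ("E1", "E2", "L1", "L2")
    }
    raw = assoc.associate_allele(carrier_sets, phen)
    adj = assoc.associate_allele(carrier_sets, phen, bh_correct=True)
    for r, q in zip(raw, adj):
        assert q.p_value >= r.p_value - 1e-12


# ---------------------------------------------------------------------------
# Flowering classes
# ---------------------------------------------------------------------------

def test_classify_flowering_six_distinct():
    med = {f"i{k}": k / 10 for k in range(6)}
    classes = assoc.classify_flowering(med)
    assert [c.flowering_class for c in classes] == [1, 2, 3, 4, 5, 6]
    assert [c.merged_class for c in classes] == [1, 1, 2, 2, 3, 3]


def test_classify_flowering_tie_break_deterministic():
    med = {"b": 0.5, "a": 0.5, "c": 0.1, "d": 0.2, "e": 0.8, "f": 0.9}
    classes = {c.individual_id: c.flowering_class for c in assoc.classify_flowering(med)}
    assert classes["a"] < classes["b"]  # earlier id sorts first at a tie


def test_classify_flowering_requires_six():
    with pytest.raises(ValueError):
        assoc.classify_flowering({"a": 0.1})
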