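"""Noncentral hypergeometric differential test, RPM/TR arithmetic and Holm.

The tail computation is cross-checked against two independent oracles:
exact rational-arithmetic enumeration (fractions + math.comb) and
scipy.stats.nchypergeom_fisher.
"""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dgetp.differential import (DifferentialConfig, FeatureCountMatrix,
                                holm_adjust, nchg_pmf, nchg_tail,
                                rpm_normalize, run_differential,
                                transcription_ratio)
from dgetp.differential import test_feature as boundary_test


def exact_tail(x_t, n_t, x_c, n_c, psi, tail):
    """Exact-arithmetic enumeration of the conditional tail."""
    k = x_t + x_c
    lo, hi = max(0, k - n_c), min(k, n_t)
    psi = Fraction(psi).limit_denominator(10**9) if not isinstance(psi, Fraction) else psi
    weights = {
        x: Fraction(math.comb(n_t, x) * math.comb(n_c, k - x)) * psi**x
        for x in range(lo, hi + 1)
    }
    total = sum(weights.values())
    if tail == "upper":
        part = sum(w for x, w in weights.items() if x >= x_t)
    else:
        part = sum(w for x, w in weights.items() if x <= x_t)
    return part / total


# --- RPM and transcription ratio -------------------------------------------

@pytest.mark.parametrize("count, total, expected", [
    (100, 2_000_000, 50.0), (0, 5, 0.0), (7, 7, 1e6),
])
def test_rpm(count, total, expected):
    assert rpm_normalize(count, total) == pytest.approx(expected)


def test_rpm_rejects_zero_total():
    with pytest.raises(ValueError):
        rpm_normalize(1, 0)


@pytest.mark.parametrize("rpm_t, rpm_c, expected", [
    (10.0, 10.0, 1.0), (0.0, 0.0, 1.0), (19.8, 0.0, 100.0),
])
def test_transcription_ratio_examples(rpm_t, rpm_c, expected):
    assert transcription_ratio(rpm_t, rpm_c, 0.2) == pytest.approx(expected)


def test_transcription_ratio_reciprocal():
    rng = np.random.default_rng(0)
    for a, b in rng.uniform(0, 100, size=(20, 2)):
        assert transcription_ratio(a, b) * transcription_ratio(b, a) == pytest.approx(1.0)


# --- noncentral hypergeometric tail ----------------------------------------

def test_central_case_hand_enumeration():
    # N_t = N_c = 10, k = 2: weights 45, 100, 45
    assert nchg_tail(2, 10, 0, 10, 1.0, "upper") == pytest.approx(45 / 190, abs=1e-12)


def test_noncentral_case_hand_enumeration():
    # psi = 2: weights 45, 200, 180
    assert nchg_tail(2, 10, 0, 10, 2.0, "upper") == pytest.approx(180 / 425, abs=1e-12)


def test_support_minimum_upper_tail_is_one():
    for psi in (0.3, 1.0, 5.0):
        assert nchg_tail(0, 10, 4, 10, psi, "upper") == pytest.approx(1.0)
        # support minimum above zero: k > N_c forces x_t >= k - N_c
        assert nchg_tail(2, 10, 3, 3, psi, "upper") == pytest.approx(1.0)


def test_margin_validation():
    with pytest.raises(ValueError):
        nchg_tail(11, 10, 0, 10, 1.0)
    with pytest.raises(ValueError):
        nchg_tail(0, 10, 0, 10, 1.0)  # k = 0
    with pytest.raises(ValueError):
        nchg_tail(1, 10, 1, 10, -2.0)


def test_central_tail_equals_hypergeometric():
    rng = np.random.default_rng(1)
    for _ in range(40):
        n_t, n_c = int(rng.integers(5, 200)), int(rng.integers(5, 200))
        k = int(rng.integers(1, min(50, n_t + n_c)))
        lo, hi = max(0, k - n_c), min(k, n_t)
        x_t = int(rng.integers(lo, hi + 1))
        ours = nchg_tail(x_t, n_t, x_c=k - x_t, n_c=n_c, psi=1.0, tail="upper")
        ref = stats.hypergeom.sf(x_t - 1, n_t + n_c, n_t, k)
        assert ours == pytest.approx(ref, abs=1e-11)


def test_tails_and_pmf_are_coherent():
    rng = np.random.default_rng(2)
    for _ in range(30):
        n_t, n_c = int(rng.integers(10, 1000)), int(rng.integers(10, 1000))
        k = int(rng.integers(1, 100))
        lo, hi = max(0, k - n_c), min(k, n_t)
        x_t = int(rng.integers(lo, hi + 1))
        psi = float(rng.uniform(0.2, 5.0))
        up = nchg_tail(x_t, n_t, k - x_t, n_c, psi, "upper")
        low = nchg_tail(x_t, n_t, k - x_t, n_c, psi, "lower")
        pmf = nchg_pmf(x_t, n_t, n_c, k, psi)
        assert up + low - pmf == pytest.approx(1.0, abs=1e-10)


def test_matches_exact_enumeration():
    rng = np.random.default_rng(3)
    for _ in range(50):
        n_t, n_c = int(rng.integers(10, 10_000)), int(rng.integers(10, 10_000))
        k = int(rng.integers(1, 200))
        lo, hi = max(0, k - n_c), min(k, n_t)
        x_t = int(rng.integers(lo, hi + 1))
        psi = rng.choice([0.5, 1.0, 2.0, 3.7])
        for tail in ("upper", "lower"):
            got = nchg_tail(x_t, n_t, k - x_t, n_c, float(psi), tail)
            want = float(exact_tail(x_t, n_t, k - x_t, n_c, psi, tail))
            assert got == pytest.approx(want, abs=1e-12)


def test_matches_scipy_noncentral_hypergeometric():
    rng = np.random.default_rng(4)
    for _ in range(40):
        n_t, n_c = int(rng.integers(20, 5000)), int(rng.integers(20, 5000))
        k = int(rng.integers(1, 150))
        lo, hi = max(0, k - n_c), min(k, n_t)
        x_t = int(rng.integers(lo, hi + 1))
        psi = float(rng.uniform(0.3, 4.0))
        ref_up = stats.nchypergeom_fisher.sf(x_t - 1, n_t + n_c, n_t, k, psi)
        ref_low = stats.nchypergeom_fisher.cdf(x_t, n_t + n_c, n_t, k, psi)
        assert nchg_tail(x_t, n_t, k - x_t, n_c, psi, "upper") == pytest.approx(ref_up, abs=1e-9)
        assert nchg_tail(x_t, n_t, k - x_t, n_c, psi, "lower") == pytest.approx(ref_low, abs=1e-9)


def test_upper_tail_monotone_in_treated_count():
    n_t = n_c = 10**6
    k = 500
    ps = [nchg_tail(x, n_t, k - x, n_c, 2.0, "upper") for x in range(100, 401, 25)]
    assert all(a >= b for a, b in zip(ps, ps[1:]))


# --- directional boundary test ---------------------------------------------

def test_symmetric_counts_tie_broken_to_over():
    p, direction = boundary_test(50, 10**6, 50, 10**6)
    assert direction == "over"
    assert 0 < p <= 1


def test_heavy_overrepresentation_is_extreme():
    p, direction = boundary_test(400, 10**6, 100, 10**6)
    assert direction == "over"
    assert p < 1e-7
    want = float(exact_tail(400, 10**6, 100, 10**6, 2, "upper"))
    assert p == pytest.approx(want, rel=1e-9)


def test_double_min_combination_doubles():
    cfg = DifferentialConfig(p_combination="double_min")
    p_min, _ = boundary_test(30, 10**6, 60, 10**6)
    p_dbl, _ = boundary_test(30, 10**6, 60, 10**6, cfg)
    assert p_dbl == pytest.approx(min(1.0, 2 * p_min))


# --- Holm -------------------------------------------------------------------

def test_holm_textbook_example():
    np.testing.assert_allclose(
        holm_adjust([0.001, 0.01, 0.04]), [0.003, 0.02, 0.04], atol=1e-12)


def test_holm_single_p_unchanged():
    assert holm_adjust([0.2])[0] == pytest.approx(0.2)


def test_holm_all_equal():
    p = [0.02] * 5
    np.testing.assert_allclose(holm_adjust(p), [min(1.0, 5 * 0.02)] * 5, atol=1e-12)


def test_holm_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(5)
    p = rng.uniform(0, 1, size=200)
    _, ref, _, _ = multipletests(p, method="holm")
    np.testing.assert_allclose(holm_adjust(p), ref, atol=1e-12)


def test_holm_rejects_invalid():
    with pytest.raises(ValueError):
        holm_adjust([0.1, 1.5])
    with pytest.raises(ValueError):
        holm_adjust([])


# --- run_differential -------------------------------------------------------

def _matrix(counts: dict, totals: dict) -> FeatureCountMatrix:
    return FeatureCountMatrix(
        counts=pd.DataFrame(counts).T.astype(int),
        norm_totals=pd.Series(totals, dtype=float),
    )


def test_run_differential_detects_spike_and_skips_empty():
    totals = {"Ctrl": 1_000_000, "Trt": 1_000_000}
    m = _matrix({
        "spiked": {"Ctrl": 100, "Trt": 800},
        "flat": {"Ctrl": 300, "Trt": 310},
        "absent": {"Ctrl": 0, "Trt": 0},
    }, totals)
    res = run_differential(m, "Ctrl")
    assert set(res["feature"]) == {"spiked", "flat"}  # k = 0 pair skipped
    spiked = res.set_index("feature").loc["spiked"]
    assert spiked["significant"] and spiked["direction"] == "over"
    assert spiked["tr"] == pytest.approx(
        transcription_ratio(800.0, 100.0, 0.2))
    flat = res.set_index("feature").loc["flat"]
    assert not flat["significant"]
    assert flat["tr"] == pytest.approx(1.0, rel=0.1)


def test_run_differential_order_invariance_and_holm_family():
    rng = np.random.default_rng(6)
    features = {f"f{i}": {"Ctrl": int(c), "A": int(a), "B": int(b)}
                for i, (c, a, b) in enumerate(rng.integers(0, 500, size=(30, 3)))}
    totals = {"Ctrl": 500_000, "A": 600_000, "B": 400_000}
    m = _matrix(features, totals)
    res = run_differential(m, "Ctrl").set_index(["feature", "condition"]).sort_index()
    shuffled = {k: features[k] for k in reversed(list(features))}
    res2 = run_differential(_matrix(shuffled, totals), "Ctrl") \
        .set_index(["feature", "condition"]).sort_index()
    pd.testing.assert_frame_equal(res, res2)
    # Holm family is per condition: adjusted p within each condition obeys
    # the step-down formula recomputed independently
    for cond in ("A", "B"):
        sub = res.xs(cond, level="condition")
        np.testing.assert_allclose(
            sub["p_adj"], holm_adjust(sub["p_raw"].to_numpy()), atol=1e-12)


def test_run_differential_unknown_control():
    m = _matrix({"f": {"Ctrl": 1, "T": 2}}, {"Ctrl": 10, "T": 10})
    with pytest.raises(ValueError):
        run_differential(m, "nope")


def test_feature_counts_cannot_exceed_totals():
    with pytest.raises(ValueError):
        _matrix({"f": {"Ctrl": 20, "T": 2}}, {"Ctrl": 10, "T": 10})
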