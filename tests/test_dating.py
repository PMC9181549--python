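"""K2P distances, LTR-pair and RT-read insertion dating, age profiles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from retroscape.dating import (AgeEstimate, SaturationError, age_profile, k2p,
                               k2p_to_mya, ltr_pair_age, rt_read_dating)
from retroscape.simulate import mutate_k2p, random_sequence, simulate_reads
from retroscape.io import Genome

# ---------------------------------------------------------------------------
# K2P distance
# ---------------------------------------------------------------------------

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _brute_force_k2p(a: str, b: str):
    """Independent oracle: direct counting of transitions/transversions over
    gap-free columns, then the closed form."""
    pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    n = len(pairs)
    ts = sum((x, y) in _TRANSITIONS for x, y in pairs)
    tv = sum(x != y and (x, y) not in _TRANSITIONS for x, y in pairs)
    P, Q = ts / n, tv / n
    return -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q)), P, Q, n


def test_identical_sequences_have_zero_distance():
    d = k2p("ACGTACGT", "ACGTACGT")
    assert (d.P, d.Q, d.K) == (0.0, 0.0, 0.0)
    assert d.sites_compared == 8


def test_closed_form_values():
    # P=0.1, Q=0.05 -> K = -0.5 ln(0.75 sqrt(0.90))
    a = "A" * 20
    b = "G" * 2 + "C" * 1 + "A" * 17
    d = k2p(a, b)
    assert (d.P, d.Q) == (0.1, 0.05)
    assert d.K == pytest.approx(0.1701811651403471, abs=1e-12)
    # single transition among four sites -> -0.5 ln(0.5)
    d = k2p("AAAA", "AGAA")
    assert (d.P, d.Q) == (0.25, 0.0)
    assert d.K == pytest.approx(0.34657359027997264, abs=1e-12)


def test_gap_columns_are_excluded():
    d = k2p("AC-TA", "ACG-G")
    assert d.sites_compared == 3
    assert d.P == pytest.approx(1 / 3)


def test_saturation_raises():
    with pytest.raises(SaturationError):
        k2p("A" * 10, "G" * 10)
    with pytest.raises(ValueError):
        k2p("----", "----")
    with pytest.raises(ValueError):
        k2p("ACG", "ACGT")


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 32 - 1))
def test_k2p_matches_brute_force_oracle(seed):
    """Property: k2p equals direct pair counting + closed form, exactly."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 101))
    a = random_sequence(n, rng)
    b = mutate_k2p(a, float(rng.uniform(0, 0.25)), seed=rng)
    if rng.random() < 0.5:  # sprinkle aligned gap columns
        a = list(a)
        b = list(b)
        for i in rng.choice(n, size=max(1, n // 10), replace=False):
            (a if rng.random() < 0.5 else b)[i] = "-"
        a, b = "".join(a), "".join(b)
    try:
        expect = _brute_force_k2p(a, b)
    except ValueError:
        expect = None
    if expect is None or expect[0] != expect[0]:
        return
    d = k2p(a, b)
    assert d.K == pytest.approx(expect[0], abs=1e-12)
    assert (d.P, d.Q, d.sites_compared) == (expect[1], expect[2], expect[3])


# ---------------------------------------------------------------------------
# LTR-pair dating
# ---------------------------------------------------------------------------

def test_identical_ltrs_date_to_zero():
    ltr = random_sequence(800, np.random.default_rng(1))
    assert ltr_pair_age(ltr, ltr).T == 0.0


def test_k_to_age_arithmetic():
    # K = 0.04 at r = 2e-8 /site/year -> T = K/(2r) = 1 MYA
    assert k2p_to_mya(0.04, 2e-8) == pytest.approx(1.0)
    assert k2p_to_mya(0.08, 2e-8) == pytest.approx(2.0)


def test_age_scales_inversely_with_rate():
    rng = np.random.default_rng(2)
    l5 = random_sequence(1000, rng)
    l3 = mutate_k2p(l5, 0.05, seed=3)
    t1 = ltr_pair_age(l5, l3, rate=2e-8).T
    t2 = ltr_pair_age(l5, l3, rate=4e-8).T
    assert t2 == pytest.approx(t1 / 2, rel=1e-12)


@pytest.mark.parametrize("true_age", [0.5, 1.0, 2.0])
def test_cohort_mean_age_recovery(true_age):
    """Bias |mean(T) - T| / T <= 0.15 on 100-element cohorts, 1-kb LTRs."""
    rng = np.random.default_rng(int(true_age * 10))
    ltr = random_sequence(1000, rng)
    d = 2e-8 * true_age * 1e6
    ages = []
    for i in range(100):
        l5 = mutate_k2p(ltr, d, seed=2 * i)
        l3 = mutate_k2p(ltr, d, seed=2 * i + 1)
        ages.append(ltr_pair_age(l5, l3).T)
    assert abs(np.mean(ages) - true_age) / true_age <= 0.15


# ---------------------------------------------------------------------------
# RT-read dating
# ---------------------------------------------------------------------------

def test_error_free_reads_from_single_rt_all_age_zero():
    rng = np.random.default_rng(4)
    rt = random_sequence(600, rng)
    reads = simulate_reads(Genome({"rt": rt}), coverage=8.0, error_rate=0.0,
                           seed=5)
    ages = rt_read_dating({"rt1": ("Copia/Angela", rt)}, reads)
    ests = ages["Copia/Angela"]
    assert len(ests) > 10
    assert all(e.T == 0.0 for e in ests)


def test_burst_copies_date_to_two_mya():
    """Reads from many element copies of a single 2-MYA burst (each copy
    r*T diverged from the master) give pairwise ages whose profile peaks
    near 2 MYA: cross-copy pairs are K = 2 r T apart and dominate."""
    rng = np.random.default_rng(6)
    master = random_sequence(1500, rng)
    d = 2e-8 * 2.0 * 1e6  # per-copy divergence accumulated since the burst
    copies = [mutate_k2p(master, d, seed=i) for i in range(8)]
    reads = []
    for i, h in enumerate(copies):
        reads += [(f"h{i}_{r[0]}", r[1]) for r in
                  simulate_reads(Genome({"h": h}), coverage=2.0,
                                 error_rate=0.0, seed=10 + i)]
    ages = rt_read_dating({"rt1": ("Copia/SIRE", master)}, reads, seed=1)
    ests = np.array([e.T for e in ages["Copia/SIRE"]])
    assert len(ests) > 100
    profile = age_profile(ages["Copia/SIRE"], bin_width_mya=0.5)
    main_peak = max(profile.peak_ages,
                    key=lambda p: profile.counts[
                        np.searchsorted(profile.bin_edges, p, "right") - 1])
    assert 1.4 <= main_peak <= 2.6
    # cross-copy pairs (the vast majority) average to the burst age
    assert abs(np.median(ests) - 2.0) < 0.5


def test_short_reference_rejected():
    with pytest.raises(ValueError, match="150"):
        rt_read_dating({"r": ("x", "ACGT" * 10)}, [("r1", "ACGT" * 21)])


def test_reference_with_single_read_contributes_nothing():
    rng = np.random.default_rng(7)
    rt = random_sequence(300, rng)
    ages = rt_read_dating({"rt1": ("L", rt)}, [("r1", rt[:85])])
    assert ages.get("L", []) == []


# ---------------------------------------------------------------------------
# age profiles
# ---------------------------------------------------------------------------

def test_constant_estimates_single_peak():
    p = age_profile([1.0] * 50, bin_width_mya=0.25)
    assert p.mean_age == pytest.approx(1.0)
    assert len(p.peak_ages) == 1
    assert p.peak_ages[0] == pytest.approx(1.0, abs=0.25)


def test_single_estimate_profile():
    p = age_profile([AgeEstimate("e", 0.04, 1.0, 2e-8)], bin_width_mya=0.5)
    assert p.mean_age == 1.0
    assert p.counts.sum() == 1


def test_bimodal_mixture_gives_two_peaks():
    rng = np.random.default_rng(8)
    ages = np.concatenate([rng.normal(1.0, 0.1, 1000),
                           rng.normal(10.0, 1.0, 1000)])
    p = age_profile(np.abs(ages), bin_width_mya=0.25)
    assert len(p.peak_ages) == 2
    assert abs(p.peak_ages[0] - 1.0) < 0.5
    assert abs(p.peak_ages[1] - 10.0) < 1.0


def test_empty_estimates_rejected():
    with pytest.raises(ValueError):
        age_profile([])
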