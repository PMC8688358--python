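"""Contamination QC: tag fractions, exact Wilcoxon signed-rank, library verdicts."""

from itertools import product

import numpy as np
import pytest
from scipy.stats import rankdata, wilcoxon as scipy_wilcoxon

from paremodes.contamination_qc import (
    library_qc,
    tag_fractions,
    wilcoxon_signed_rank,
)
from paremodes.io_formats import HairpinRecord, Interval, TagCountTable
from paremodes.profiles import extract_profile, key_positions
from paremodes.simulate import SimConfig, simulate_hairpin, simulate_tags


def _hairpin(pid):
    return HairpinRecord(pid, "A" * 200, mir5p=Interval(10, 31), mir3p=Interval(100, 121))


def _profiles_from(md: dict[str, tuple[int, int]], lib="L1"):
    """Build profiles with m reads at p0 and d reads at pe per precursor."""
    profiles, keypos = {}, {}
    for pid, (m, d) in md.items():
        hp = _hairpin(pid)
        tags = TagCountTable(library_id=lib)
        if m:
            tags.add(pid, 100, "+", m)
        if d:
            tags.add(pid, 121, "+", d)
        profiles[pid] = extract_profile(tags, hp)
        keypos[pid] = key_positions(hp)
    return profiles, keypos


class TestTagFractions:
    def test_set_wide_percentages(self):
        # two miRNAs, m=(0,1), d=(30,15): set total 46, pct_d = 65.2/32.6
        profiles, keypos = _profiles_from({"a": (0, 30), "b": (1, 15)})
        recs = {r.precursor_id: r for r in tag_fractions(profiles, keypos, ["a", "b"])}
        assert len(recs) == 2  # sums 30 and 16 both > 10
        assert recs["a"].pct_d == pytest.approx(100 * 30 / 46)
        assert recs["b"].pct_d == pytest.approx(100 * 15 / 46)

    def test_sum_filter_is_strict(self):
        profiles, keypos = _profiles_from({"a": (0, 10), "b": (0, 500)})
        recs = tag_fractions(profiles, keypos, ["a", "b"])
        assert [r.precursor_id for r in recs] == ["b"]  # m+d == 10 dropped

    def test_percentage_filter_is_strict(self):
        # a has 0.4% on both sides of a big set total -> dropped
        profiles, keypos = _profiles_from({"a": (20, 20), "b": (0, 9960)})
        recs = tag_fractions(profiles, keypos, ["a", "b"])
        assert [r.precursor_id for r in recs] == ["b"]

    def test_empty_reference_set_rejected(self):
        profiles, keypos = _profiles_from({"a": (0, 30)})
        with pytest.raises(ValueError):
            tag_fractions(profiles, keypos, [])


def brute_force_wilcoxon(diffs: np.ndarray) -> float:
    """Literal 2^n enumeration of sign assignments (average ranks for ties)."""
    ranks = rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    n = len(diffs)
    hits = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        if w >= w_obs - 1e-12:
            hits += 1
    return hits / 2**n


class TestWilcoxon:
    def test_six_concordant_pairs(self):
        # all y > x with distinct magnitudes: W=21 is the unique maximum,
        # p = 1/64
        pairs = [(0.0, float(i)) for i in range(1, 7)]
        p, degen = wilcoxon_signed_rank(pairs, "y_greater")
        assert p == pytest.approx(1 / 64)
        assert not degen

    def test_all_zero_differences_degenerate(self):
        p, degen = wilcoxon_signed_rank([(1.0, 1.0)] * 5)
        assert (p, degen) == (1.0, True)

    def test_direction_flip(self):
        pairs = [(float(i), 0.0) for i in range(1, 7)]
        p, _ = wilcoxon_signed_rank(pairs, "x_greater")
        assert p == pytest.approx(1 / 64)

    def test_exact_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(1, 9))
            x = rng.integers(0, 6, size=n).astype(float)  # small ints force ties
            y = rng.integers(0, 6, size=n).astype(float)
            d = y - x
            d = d[d != 0]
            if len(d) == 0:
                continue
            p, _ = wilcoxon_signed_rank(list(zip(x, y)), "y_greater")
            assert p == pytest.approx(brute_force_wilcoxon(d))

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = 10
            x = rng.normal(size=n)
            y = x + rng.normal(size=n)
            p, _ = wilcoxon_signed_rank(list(zip(x, y)), "y_greater")
            ref = scipy_wilcoxon(y, x, alternative="greater", method="exact").pvalue
            assert p == pytest.approx(ref)

    def test_large_n_normal_approximation_close_to_exact(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        y = x + rng.normal(loc=0.5, size=30)
        pairs = list(zip(x, y))
        p_approx, _ = wilcoxon_signed_rank(pairs, "y_greater")  # n=30 > 25
        p_exact, _ = wilcoxon_signed_rank(pairs, "y_greater", exact_max_n=40)
        assert p_approx == pytest.approx(p_exact, rel=0.2, abs=1e-4)

    def test_ranks_invariant_under_global_rescaling(self):
        # set-wide percentages are a rescaling of raw counts, so the signed
        # ranks and hence the p-value are identical
        rng = np.random.default_rng(8)
        m = rng.integers(0, 10, size=12).astype(float)
        d = rng.integers(5, 60, size=12).astype(float)
        total = (m + d).sum()
        p_raw, _ = wilcoxon_signed_rank(list(zip(m, d)))
        p_pct, _ = wilcoxon_signed_rank(list(zip(100 * m / total, 100 * d / total)))
        assert p_raw == p_pct


def _simulated_library(rho, seed, n_bl=20, depth=100):
    cfg = SimConfig(seed=seed, n_per_mode=n_bl, depth=depth, depth_model="fixed",
                    jitter_prob=0.05, contamination_rho=rho)
    rng = np.random.default_rng(seed)
    profiles, keypos, bl, lb = {}, {}, [], []
    for i in range(n_bl):
        hp = simulate_hairpin(cfg, "shBL", rng, index=i)
        tags = simulate_tags(hp, "shBL", cfg, rng, library_id="sim")
        profiles[hp.precursor_id] = extract_profile(tags, hp)
        keypos[hp.precursor_id] = key_positions(hp)
        bl.append(hp.precursor_id)
    for i in range(n_bl):
        hp = simulate_hairpin(cfg, "shLB", rng, index=i)
        tags = simulate_tags(hp, "shLB", cfg, rng, library_id="sim")
        profiles[hp.precursor_id] = extract_profile(tags, hp)
        keypos[hp.precursor_id] = key_positions(hp)
        lb.append(hp.precursor_id)
    return profiles, keypos, bl, lb


class TestLibraryQC:
    def test_clean_library_passes(self):
        profiles, keypos, bl, lb = _simulated_library(rho=0.0, seed=1)
        res = library_qc(profiles, keypos, bl, lb, alpha=0.005)
        assert res.passed
        assert res.p_lb is not None and res.p_lb < 0.005  # LB positive control
        assert res.contamination_fraction < 0.05

    def test_contaminated_library_fails(self):
        profiles, keypos, bl, lb = _simulated_library(rho=0.5, seed=2)
        res = library_qc(profiles, keypos, bl, lb, alpha=0.005)
        assert not res.passed
        assert res.contamination_fraction == pytest.approx(0.5, abs=0.08)

    def test_contamination_fraction_tracks_rho(self):
        for seed, rho in [(3, 0.1), (4, 0.3)]:
            profiles, keypos, bl, lb = _simulated_library(rho=rho, seed=seed)
            res = library_qc(profiles, keypos, bl, lb)
            assert res.contamination_fraction == pytest.approx(rho, abs=0.05)

    def test_noiseless_clean_bl_records_have_zero_m(self):
        cfg = SimConfig(seed=9, n_per_mode=10, jitter_prob=0.0, contamination_rho=0.0)
        rng = np.random.default_rng(9)
        profiles, keypos, bl = {}, {}, []
        for i in range(10):
            hp = simulate_hairpin(cfg, "shBL", rng, index=i)
            tags = simulate_tags(hp, "shBL", cfg, rng)
            profiles[hp.precursor_id] = extract_profile(tags, hp)
            keypos[hp.precursor_id] = key_positions(hp)
            bl.append(hp.precursor_id)
        from paremodes.contamination_qc import tag_fractions

        assert all(r.m == 0 for r in tag_fractions(profiles, keypos, bl))

    def test_pass_is_monotone_in_alpha(self):
        profiles, keypos, bl, lb = _simulated_library(rho=0.0, seed=5)
        strict = library_qc(profiles, keypos, bl, lb, alpha=0.005)
        relaxed = library_qc(profiles, keypos, bl, lb, alpha=0.05)
        if strict.passed:
            assert relaxed.passed

    def test_empty_signal_rejected(self):
        profiles, keypos = _profiles_from({"a": (0, 0)})
        with pytest.raises(ValueError, match="no evaluable signal"):
            library_qc(profiles, keypos, ["a"], [])
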