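"""Mature-miRNA contamination QC for PARE libraries.

PARE clones 20-nt 5'-end tags of uncapped polyadenylated RNA — exactly the
length of a mature miRNA, so mature miR-3p molecules that slip into a
library are indistinguishable from cleavage remnants starting at the miR-3p
5' end (``p0``).  Base-to-loop processed miRNAs provide a built-in negative
control: their only polyadenylated remnant starts right after the miR-3p 3'
end (``pe``), so any p0 signal on them is contamination.  A library passes
QC when, over a reference set of known base-to-loop miRNAs, downstream
(``pe``) tags significantly exceed miR-3p (``p0``) tags by a one-sided
Wilcoxon signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import erfc, sqrt

import numpy as np
from scipy.stats import rankdata

from .profiles import KeyPositions, Tag5pProfile

__all__ = [
    "TagFractionRecord",
    "LibraryQC",
    "tag_fractions",
    "wilcoxon_signed_rank",
    "rank_sum_test",
    "library_qc",
]


@dataclass
class TagFractionRecord:
    """Per-miRNA tag counts at the two core positions, as set-wide percentages.

    ``m`` counts tags in the miR-3p class (p0 +/- tol_core), ``d`` tags in
    the downstream class (pe +/- tol_core); percentages are of the summed
    (m + d) over the whole reference set in this library.
    """

    precursor_id: str
    m: int
    d: int
    pct_m: float
    pct_d: float


@dataclass
class LibraryQC:
    library_id: str
    n_bl_used: int
    n_lb_used: int
    p_bl: float | None
    p_lb: float | None
    contamination_fraction: float | None
    passed: bool
    alpha: float
    notes: str = ""


def tag_fractions(
    profiles: dict[str, Tag5pProfile],
    keypos: dict[str, KeyPositions],
    reference_set: list[str],
    pct_min: float = 0.5,
    sum_min: int = 10,
) -> list[TagFractionRecord]:
    """Per-miRNA (m, d) counts and set-wide percentages over a reference set.

    Records are retained iff max(pct_m, pct_d) > ``pct_min`` percent AND
    m + d > ``sum_min`` (both strict), mirroring the display filter used
    when assessing contamination.
    """
    if not reference_set:
        raise ValueError("empty reference set")
    raw: list[tuple[str, int, int]] = []
    for pid in reference_set:
        if pid not in profiles:
            raise KeyError(f"no profile for reference precursor {pid!r}")
        prof = profiles[pid]
        kp = keypos[pid]
        m = prof.count_in(kp.p0 - kp.tol_core, kp.p0 + kp.tol_core)
        d = prof.count_in(kp.pe - kp.tol_core, kp.pe + kp.tol_core)
        raw.append((pid, m, d))
    set_total = sum(m + d for _, m, d in raw)
    out = []
    for pid, m, d in raw:
        pct_m = 100.0 * m / set_total if set_total else 0.0
        pct_d = 100.0 * d / set_total if set_total else 0.0
        if max(pct_m, pct_d) > pct_min and (m + d) > sum_min:
            out.append(TagFractionRecord(pid, m, d, pct_m, pct_d))
    return out


def _exact_sf(weights2: np.ndarray, w2_obs: int) -> float:
    """P(W >= w_obs) where W sums a random subset of ranks (doubled to
    integers so tied average ranks stay exact).

    Computed by dynamic programming over the distribution of the doubled
    rank sum — identical to enumerating all 2^n sign assignments, without
    the exponential loop.
    """
    total = int(weights2.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for w2 in weights2:
        shifted = np.zeros_like(dist)
        shifted[w2:] = dist[: total + 1 - w2]
        dist = dist + shifted
    n = len(weights2)
    return float(dist[max(w2_obs, 0) :].sum() / (2.0 ** n))


def wilcoxon_signed_rank(
    pairs: list[tuple[float, float]],
    alternative: str = "y_greater",
    exact_max_n: int = 25,
) -> tuple[float, bool]:
    """One-sided Wilcoxon signed-rank test on paired observations.

    Differences ``y - x`` are ranked by absolute value with average ranks
    for ties; zero differences are dropped (Wilcoxon's convention).  For
    n <= ``exact_max_n`` the p-value is exact over all 2^n sign assignments;
    above that a normal approximation with tie and continuity corrections is
    used.  Returns ``(p, degenerate)`` where ``degenerate`` is True when all
    differences are zero (then p = 1.0).
    """
    if alternative not in ("y_greater", "x_greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    d = np.array([y - x for x, y in pairs], dtype=float)
    if alternative == "x_greater":
        d = -d
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return 1.0, True
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        # double the ranks: average ranks are multiples of 1/2
        weights2 = np.round(2 * ranks).astype(np.int64)
        w2_obs = int(round(2 * w_plus))
        return _exact_sf(weights2, w2_obs), False
    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    # tie correction
    _, counts = np.unique(np.abs(d), return_counts=True)
    var -= (counts**3 - counts).sum() / 48.0
    z = (w_plus - mean - 0.5) / sqrt(var)
    return 0.5 * erfc(z / sqrt(2.0)), False


def rank_sum_test(
    xs: list[float], ys: list[float], alternative: str = "y_greater"
) -> float:
    """Mann-Whitney/Wilcoxon rank-sum alternative (unpaired), offered for
    sensitivity analysis next to the paired default."""
    from scipy.stats import mannwhitneyu

    alt = "less" if alternative == "y_greater" else "greater"
    return float(mannwhitneyu(xs, ys, alternative=alt).pvalue)


def library_qc(
    profiles: dict[str, Tag5pProfile],
    keypos: dict[str, KeyPositions],
    known_bl_set: list[str],
    known_lb_set: list[str],
    alpha: float = 0.005,
    paired: bool = True,
) -> LibraryQC:
    """Run contamination QC for one library.

    ``p_bl`` tests, over the base-to-loop reference set, that downstream
    tags exceed miR-3p tags (the clean-library expectation); ``p_lb`` tests
    the reverse direction over the loop-to-base set (a positive control that
    real p0 remnants are detected).  The pass verdict uses ``p_bl`` alone;
    ``contamination_fraction`` is the miR-3p share of BL-set signal,
    Σm / Σ(m + d).
    """
    profs = list(profiles.values())
    lib = profs[0].library_id if profs else "?"
    records_bl = tag_fractions(profiles, keypos, known_bl_set) if known_bl_set else []
    records_lb = tag_fractions(profiles, keypos, known_lb_set) if known_lb_set else []
    notes = []
    if not known_bl_set:
        raise ValueError("empty base-to-loop reference set")
    total_signal = sum(r.m + r.d for r in records_bl) + sum(r.m + r.d for r in records_lb)
    if total_signal == 0:
        raise ValueError(f"{lib}: no evaluable signal over reference sets")

    p_bl: float | None = None
    contamination: float | None = None
    if records_bl:
        if paired:
            p_bl, degen = wilcoxon_signed_rank(
                [(r.pct_m, r.pct_d) for r in records_bl], alternative="y_greater"
            )
            if degen:
                notes.append("BL test degenerate (all m == d)")
        else:
            p_bl = rank_sum_test([r.pct_m for r in records_bl], [r.pct_d for r in records_bl])
        denom = sum(r.m + r.d for r in records_bl)
        contamination = sum(r.m for r in records_bl) / denom if denom else None
    else:
        notes.append("no BL records after filtering; BL test skipped")

    p_lb: float | None = None
    if records_lb:
        if paired:
            p_lb, degen = wilcoxon_signed_rank(
                [(r.pct_d, r.pct_m) for r in records_lb], alternative="y_greater"
            )
            if degen:
                notes.append("LB test degenerate (all m == d)")
        else:
            p_lb = rank_sum_test([r.pct_d for r in records_lb], [r.pct_m for r in records_lb])
    elif known_lb_set:
        notes.append("no LB records after filtering; LB test skipped")

    passed = p_bl is not None and p_bl < alpha
    return LibraryQC(
        library_id=lib,
        n_bl_used=len(records_bl),
        n_lb_used=len(records_lb),
        p_bl=p_bl,
        p_lb=p_lb,
        contamination_fraction=contamination,
        passed=passed,
        alpha=alpha,
        notes="; ".join(notes),
    )
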