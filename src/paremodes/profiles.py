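"""Per-precursor PARE 5'-end tag profiles around miR-3p.

A profile is the vector of degradome 5'-end counts in a +/-50 nt window
around the annotated (or inferred) miR-3p.  Processing-mode diagnosis rests
on a handful of key positions inside that window:

* ``p0``  — the miR-3p 5' start (3' remnant of the loop-proximal cut in
  loop-to-base processing; also where contaminating mature miR-3p lands);
* ``pe``  — the position immediately after the miR-3p 3' end (3' remnant of
  the loop-distal / first base-to-loop cut);
* an upstream grid ``p0 - 21k`` (extra loop-to-base cuts) and a downstream
  point ``pe + 21`` (the first-cut remnant of sequential base-to-loop
  processing), 21 nt being the duplex periodicity of consecutive DCL1 cuts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import HairpinRecord, TagCountTable

__all__ = [
    "Tag5pProfile",
    "KeyPositions",
    "Peak",
    "extract_profile",
    "expression_filter",
    "key_positions",
    "detect_peaks",
    "class_counts",
]


@dataclass
class Tag5pProfile:
    precursor_id: str
    library_id: str
    window_start: int
    window_end: int
    counts: np.ndarray
    clipped: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != self.window_end - self.window_start:
            raise ValueError("counts length does not match window")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def count_at(self, position: int) -> int:
        """Count at an absolute precursor position (0 outside the window)."""
        if self.window_start <= position < self.window_end:
            return int(self.counts[position - self.window_start])
        return 0

    def count_in(self, lo: int, hi: int) -> int:
        """Sum of counts over absolute positions [lo, hi] inclusive."""
        lo = max(lo, self.window_start)
        hi = min(hi, self.window_end - 1)
        if lo > hi:
            return 0
        return int(self.counts[lo - self.window_start : hi - self.window_start + 1].sum())


@dataclass
class KeyPositions:
    """Mode-diagnostic positions for one precursor (absolute coordinates)."""

    p0: int
    pe: int
    upstream: list[int]
    downstream_1: int
    step: int = 21
    tol_core: int = 2
    tol_seq: int = 3

    def classes(self) -> list[tuple[str, int, int]]:
        """(label, position, tolerance) for every key position; upstream grid
        points all share the ``upstream_seq`` label."""
        out = [("at_p0", self.p0, self.tol_core), ("at_pe", self.pe, self.tol_core)]
        out += [("upstream_seq", u, self.tol_seq) for u in self.upstream]
        out.append(("downstream_seq", self.downstream_1, self.tol_seq))
        return out

    def classify_position(self, pos: int) -> str:
        """Assign a position to at most one class: nearest key position
        within its tolerance; equidistant ties prefer the core classes
        (p0/pe), then the smaller key position."""
        best: tuple[int, int, int, str] | None = None  # (dist, core_rank, key_pos, label)
        for label, kp, tol in self.classes():
            d = abs(pos - kp)
            if d <= tol:
                rank = 0 if label in ("at_p0", "at_pe") else 1
                cand = (d, rank, kp, label)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        return best[3] if best is not None else "other"


@dataclass
class Peak:
    position: int
    count: int
    fraction_of_window: float
    class_label: str = "other"

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction_of_window <= 1.0):
            raise ValueError("fraction must be in [0, 1]")


def extract_profile(
    tags: TagCountTable, hairpin: HairpinRecord, W: int = 50
) -> Tag5pProfile:
    """Build the 5'-end tag profile in ``[mir3p.start - W, mir3p.end + W)``.

    Only tags on the precursor's own strand ('+' in local coordinates) are
    counted.  The window is clipped at the precursor boundaries with the clip
    recorded on the profile.
    """
    if hairpin.mir3p is None:
        raise ValueError(
            f"{hairpin.precursor_id}: miR-3p not set; run hairpin_geometry.infer_mir3p first"
        )
    L = len(hairpin.sequence)
    raw_start = hairpin.mir3p.start - W
    raw_end = hairpin.mir3p.end + W
    start = max(0, raw_start)
    end = min(L, raw_end)
    counts = np.zeros(end - start, dtype=np.int64)
    for (ref, pos, strand), n in tags.counts.items():
        if ref != hairpin.precursor_id or strand != "+":
            continue
        if start <= pos < end:
            counts[pos - start] += n
    return Tag5pProfile(
        precursor_id=hairpin.precursor_id,
        library_id=tags.library_id,
        window_start=start,
        window_end=end,
        counts=counts,
        clipped=(start != raw_start or end != raw_end),
    )


def expression_filter(profiles: list[Tag5pProfile]) -> bool:
    """Minimum-evidence filter: keep a precursor iff some sample has >= 10
    tags in the window, or at least two samples have >= 5."""
    if not profiles:
        raise ValueError("at least one sample profile required")
    totals = [p.total for p in profiles]
    return max(totals) >= 10 or sum(t >= 5 for t in totals) >= 2


def key_positions(
    hairpin: HairpinRecord,
    step: int = 21,
    K: int = 3,
    tol_core: int = 2,
    tol_seq: int = 3,
) -> KeyPositions:
    """Key diagnostic positions for a precursor with a set miR-3p."""
    if hairpin.mir3p is None:
        raise ValueError(f"{hairpin.precursor_id}: miR-3p not set")
    p0 = hairpin.mir3p.start
    pe = hairpin.mir3p.end
    return KeyPositions(
        p0=p0,
        pe=pe,
        upstream=[p0 - k * step for k in range(1, K + 1)],
        downstream_1=pe + step,
        step=step,
        tol_core=tol_core,
        tol_seq=tol_seq,
    )


def detect_peaks(
    profile: Tag5pProfile,
    keypos: KeyPositions | None = None,
    min_count: int = 5,
    min_frac: float = 0.05,
) -> list[Peak]:
    """Call peaks in a profile and label them by nearest key-position class.

    A position is a peak iff its count is >= ``min_count``, carries at least
    ``min_frac`` of the window total, and is a local maximum over +/-2 nt
    (ties broken toward the smaller position).  Returns peaks sorted by
    position; empty for an empty profile.
    """
    total = profile.total
    if total == 0:
        return []
    c = profile.counts
    n = len(c)
    peaks: list[Peak] = []
    for i in range(n):
        v = c[i]
        if v < min_count or v / total < min_frac:
            continue
        left = c[max(0, i - 2) : i]
        right = c[i + 1 : i + 3]
        # tie toward smaller position: strictly greater than earlier
        # neighbours, >= later ones
        if len(left) and (left >= v).any():
            continue
        if len(right) and (right > v).any():
            continue
        pos = profile.window_start + i
        label = keypos.classify_position(pos) if keypos is not None else "other"
        peaks.append(Peak(position=pos, count=int(v), fraction_of_window=float(v / total), class_label=label))
    return peaks


def class_counts(profile: Tag5pProfile, keypos: KeyPositions) -> dict[str, int]:
    """Total tag counts per key-position class over the whole window.

    Every window position contributes to at most one class (nearest key
    position within tolerance, core classes win ties), so the class sums
    never double-count and their total is <= the profile total.
    """
    sums = {"at_p0": 0, "at_pe": 0, "upstream_seq": 0, "downstream_seq": 0, "other": 0}
    for i, v in enumerate(profile.counts):
        if v == 0:
            continue
        label = keypos.classify_position(profile.window_start + i)
        sums[label] += int(v)
    return sums
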