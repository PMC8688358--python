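"""miR-3p boundary correction from degradome remnant peaks.

DCL1 cleavage remnants pin the true mature-miRNA borders more sharply than
the ragged 3' ends seen in sRNA-seq: for a base-to-loop miRNA the remnant's
5' base is the first nucleotide after the mature 3' end, and for a
loop-to-base miRNA the remnant 5' end IS the mature 5' start.  When the
dominant PARE peak near an annotated border sits a few nucleotides off, the
annotation — not the peak — is usually wrong, and the corrected version is
the one that satisfies the 2-nt 3' overhang rule on the hairpin.
"""

from __future__ import annotations

from dataclasses import dataclass

from .hairpin_geometry import CannotInfer, PairingMap, overhang_lengths_from
from .io_formats import Interval
from .mode_classifier import ConsensusCall
from .profiles import Peak, Tag5pProfile

__all__ = [
    "BoundaryCorrection",
    "correct_three_prime_end",
    "correct_five_prime_start",
    "overhang_check",
    "pare_support_flag",
]

MIN_MATURE_LEN = 16  # corrected mature length must stay > 15 nt


@dataclass
class BoundaryCorrection:
    precursor_id: str
    annotated: Interval
    corrected: Interval
    edge: str  # {five_prime, three_prime}
    offset: int  # signed, corrected - annotated at the edge
    supporting_peak: Peak | None
    overhang_ok: bool | None = None
    changed: bool = True
    reason: str = ""

    def __post_init__(self) -> None:
        if self.edge not in ("five_prime", "three_prime"):
            raise ValueError(f"bad edge {self.edge!r}")
        if len(self.corrected) <= MIN_MATURE_LEN - 1:
            raise ValueError("corrected mature interval implausibly short")


def _no_change(pid: str, annotated: Interval, edge: str, reason: str) -> BoundaryCorrection:
    return BoundaryCorrection(
        precursor_id=pid,
        annotated=annotated,
        corrected=annotated,
        edge=edge,
        offset=0,
        supporting_peak=None,
        changed=False,
        reason=reason,
    )


def _dominant_peak(
    profile: Tag5pProfile, lo: int, hi: int, center: int, min_count: int, min_frac: float
) -> Peak | None:
    """Highest qualifying position in [lo, hi]; ties resolve to the smaller
    |offset| from ``center``, then the smaller position."""
    total = profile.total
    if total == 0:
        return None
    best: tuple[int, int, int] | None = None  # (-count, |offset|, pos)
    for pos in range(lo, hi + 1):
        v = profile.count_at(pos)
        if v < min_count or v / total < min_frac:
            continue
        key = (-v, abs(pos - center), pos)
        if best is None or key < best:
            best = key
    if best is None:
        return None
    count, pos = -best[0], best[2]
    return Peak(position=pos, count=count, fraction_of_window=count / total)


def correct_three_prime_end(
    profile: Tag5pProfile,
    annotated_mir3p: Interval,
    radius: int = 3,
    min_count: int = 5,
    min_frac: float = 0.05,
) -> BoundaryCorrection:
    """Correct the miR-3p 3' end of a base-to-loop miRNA from its remnant peak.

    The downstream remnant's 5' base is the first nucleotide after the
    mature 3' end, so with the dominant peak at position q within
    ``annotated.end +/- radius``, the corrected (exclusive) 3' end is q.  A
    peak exactly at the annotated end therefore means no change.
    """
    pid = profile.precursor_id
    center = annotated_mir3p.end
    peak = _dominant_peak(
        profile, center - radius, center + radius, center, min_count, min_frac
    )
    if peak is None:
        return _no_change(pid, annotated_mir3p, "three_prime", "no qualifying peak in radius")
    corrected_end = peak.position
    offset = corrected_end - annotated_mir3p.end
    if offset == 0:
        return _no_change(pid, annotated_mir3p, "three_prime", "peak at annotated end")
    return BoundaryCorrection(
        precursor_id=pid,
        annotated=annotated_mir3p,
        corrected=Interval(annotated_mir3p.start, corrected_end),
        edge="three_prime",
        offset=offset,
        supporting_peak=peak,
    )


def correct_five_prime_start(
    profile: Tag5pProfile,
    annotated_mir3p: Interval,
    radius: int = 3,
    min_count: int = 5,
    min_frac: float = 0.05,
    preserve_length: bool = True,
) -> BoundaryCorrection:
    """Correct the miR-3p 5' start of a loop-to-base miRNA.

    For loop-to-base processing the second-cut remnant's 5' end is the
    mature 5' start itself, so the corrected start is the dominant peak
    position within ``annotated.start +/- radius``.  The mature length is
    preserved by default (the whole interval shifts); pass
    ``preserve_length=False`` to move only the 5' border when independent 3'
    evidence exists.
    """
    pid = profile.precursor_id
    center = annotated_mir3p.start
    peak = _dominant_peak(
        profile, center - radius, center + radius, center, min_count, min_frac
    )
    if peak is None:
        return _no_change(pid, annotated_mir3p, "five_prime", "no qualifying peak in radius")
    offset = peak.position - annotated_mir3p.start
    if offset == 0:
        return _no_change(pid, annotated_mir3p, "five_prime", "peak at annotated start")
    end = annotated_mir3p.end + offset if preserve_length else annotated_mir3p.end
    return BoundaryCorrection(
        precursor_id=pid,
        annotated=annotated_mir3p,
        corrected=Interval(peak.position, end),
        edge="five_prime",
        offset=offset,
        supporting_peak=peak,
    )


def overhang_check(
    corrected_mir3p: Interval, mir5p: Interval, pairing: PairingMap
) -> bool | None:
    """True iff the miR-5p/miR-3p duplex has exactly 2-nt 3' overhangs at
    both ends (zero tolerance); None when geometry cannot be evaluated."""
    try:
        ov3, ov5 = overhang_lengths_from(pairing, mir5p, corrected_mir3p)
    except CannotInfer:
        return None
    return ov3 == 2 and ov5 == 2


def pare_support_flag(consensus: ConsensusCall) -> str:
    """'supported' when the degradome evidence yields a determined
    processing mode for the precursor, else 'unsupported'."""
    return "supported" if consensus.consensus_mode != "undetermined" else "unsupported"
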