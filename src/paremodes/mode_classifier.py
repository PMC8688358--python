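"""Processing-mode classification from peak-labeled degradome profiles.

Plant pri-miRNAs are diced in one of four modes — short/sequential x
base-to-loop/loop-to-base — and each mode leaves a distinct fingerprint of
polyadenylated 3' cleavage remnants around miR-3p:

* shBL: a single remnant starting right after the miR-3p 3' end (pe);
* seBL: the only cloned remnant starts one duplex length below, at pe + 21;
* shLB: remnants at both the miR-3p 5' start (p0, major) and pe (minor);
* seLB: additional remnants on the upstream 21-nt grid (p0 - 21k).

The classifier turns the window's class-assigned tag counts
(C0 at p0, Ce at pe, Cup on the upstream grid, Cdown at pe + 21) into a
mode call, with thresholds exposed because real libraries mix signal
sources (partial cleavage, AGO1 slicing) that the class windows exclude
but do not remove.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .profiles import KeyPositions, Peak, Tag5pProfile, class_counts, detect_peaks

__all__ = [
    "MODES",
    "ModeCall",
    "ConsensusCall",
    "ModeThresholds",
    "classify_mode",
    "expected_first_cut",
    "first_cut_accuracy",
    "consensus_across_libraries",
    "family_conservation",
]

MODES = ("shBL", "seBL", "shLB", "seLB", "undetermined")


@dataclass
class ModeThresholds:
    """t_lb: minimum p0 share to call loop-to-base; t_seq: minimum upstream-
    grid share to call sequential LB; min_total: minimum classed tags."""

    t_lb: float = 0.2
    t_seq: float = 0.1
    min_total: int = 10


@dataclass
class ModeCall:
    precursor_id: str
    library_id: str
    mode: str
    class_counts: dict[str, int]
    evidence: list[Peak] = field(default_factory=list)
    first_cut_accuracy: float | None = None
    confidence_note: str = ""

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class ConsensusCall:
    precursor_id: str
    consensus_mode: str
    n_supporting: int
    n_conflicting: int
    n_undetermined: int
    note: str = ""


def classify_mode(
    profile: Tag5pProfile,
    keypos: KeyPositions,
    thresholds: ModeThresholds | None = None,
    min_count: int = 5,
    min_frac: float = 0.05,
) -> ModeCall:
    """Call the processing mode of one precursor in one library.

    Decision order: a genuine p0 signal is mechanistically diagnostic for
    loop-to-base (base-to-loop processing leaves no polyadenylated remnant
    starting at p0; contamination false-positives are handled by library QC,
    not here), so LB is tested first.  Within each direction, upstream-grid
    (LB) or downstream (BL) signal separates sequential from short.
    ``undetermined`` is a value, not an error.
    """
    th = thresholds or ModeThresholds()
    cc = class_counts(profile, keypos)
    c0, ce = cc["at_p0"], cc["at_pe"]
    cup, cdown = cc["upstream_seq"], cc["downstream_seq"]
    T = c0 + ce + cup + cdown
    evidence = detect_peaks(profile, keypos, min_count=min_count, min_frac=min_frac)
    note = ""
    if T < th.min_total:
        mode = "undetermined"
        note = f"only {T} tags at key positions (min_total={th.min_total})"
    elif c0 / T >= th.t_lb:
        mode = "seLB" if cup / T >= th.t_seq else "shLB"
    elif ce >= cdown:
        mode = "shBL"
    else:
        mode = "seBL"
    call = ModeCall(
        precursor_id=profile.precursor_id,
        library_id=profile.library_id,
        mode=mode,
        class_counts=cc,
        evidence=evidence,
        confidence_note=note,
    )
    if mode != "undetermined":
        call.first_cut_accuracy = first_cut_accuracy(
            profile, expected_first_cut(mode, keypos, profile)
        )
    return call


def expected_first_cut(
    mode: str, keypos: KeyPositions, profile: Tag5pProfile | None = None
) -> int:
    """Position of the 3' remnant of the FIRST DCL1 cut for a given mode.

    shBL -> pe; seBL -> pe + step; shLB -> p0; seLB -> the most 5' upstream
    grid point with tag support in the profile (the loop-most cut comes
    first in loop-to-base processing).
    """
    if mode == "shBL":
        return keypos.pe
    if mode == "seBL":
        return keypos.pe + keypos.step
    if mode == "shLB":
        return keypos.p0
    if mode == "seLB":
        hits = []
        if profile is not None:
            for u in keypos.upstream:
                if profile.count_in(u - keypos.tol_seq, u + keypos.tol_seq) > 0:
                    hits.append(u)
        return min(hits) if hits else keypos.upstream[0]
    raise ValueError(f"no expected first cut for mode {mode!r}")


def first_cut_accuracy(
    profile: Tag5pProfile, expected_position: int, flank: int = 3
) -> float | None:
    """Fraction of near-site remnant tags landing exactly on the expected
    first-cut position: count(expected) / count(expected +/- flank).
    None when the flank window is empty."""
    denom = profile.count_in(expected_position - flank, expected_position + flank)
    if denom == 0:
        return None
    return profile.count_at(expected_position) / denom


def consensus_across_libraries(calls: list[ModeCall]) -> ConsensusCall:
    """Aggregate per-library calls into one verdict per precursor.

    The consensus is the modal determined call; a tie between modes yields
    ``undetermined`` with both noted.  Undetermined calls never vote but are
    counted.
    """
    if not calls:
        raise ValueError("at least one call required")
    pid = calls[0].precursor_id
    determined = [c.mode for c in calls if c.mode != "undetermined"]
    n_undet = len(calls) - len(determined)
    if not determined:
        return ConsensusCall(pid, "undetermined", 0, 0, n_undet)
    tally = Counter(determined)
    top = max(tally.values())
    winners = sorted(m for m, n in tally.items() if n == top)
    if len(winners) > 1:
        return ConsensusCall(
            pid, "undetermined", 0, len(determined), n_undet,
            note="tie between " + "/".join(winners),
        )
    mode = winners[0]
    support = tally[mode]
    return ConsensusCall(pid, mode, support, len(determined) - support, n_undet)


def _direction(mode: str) -> str:
    return "LB" if mode.endswith("LB") else "BL"


def family_conservation(
    consensus: list[ConsensusCall],
    families: dict[str, str],
    species: dict[str, str],
) -> dict[tuple[str, str], tuple[str, float | None]]:
    """Family x species conservation table at the direction level.

    Short/sequential variants collapse to their direction (LB or BL).  A
    cell is that direction when every determined member of the family in the
    species agrees, ``mixed`` otherwise, and ``n.d.`` with no determined
    members.  The second element is the intraspecific agreement fraction
    (majority share among determined members; None for n.d.).
    """
    cells: dict[tuple[str, str], list[str]] = {}
    for call in consensus:
        fam = families.get(call.precursor_id)
        if fam is None:
            continue
        sp = species.get(call.precursor_id, "?")
        cells.setdefault((fam, sp), []).append(call.consensus_mode)
    out: dict[tuple[str, str], tuple[str, float | None]] = {}
    for key, modes in cells.items():
        dirs = [_direction(m) for m in modes if m != "undetermined"]
        if not dirs:
            out[key] = ("n.d.", None)
            continue
        tally = Counter(dirs)
        agreement = max(tally.values()) / len(dirs)
        out[key] = (dirs[0] if len(tally) == 1 else "mixed", agreement)
    return out
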