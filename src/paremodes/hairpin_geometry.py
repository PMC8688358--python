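"""Hairpin secondary-structure handling and miR-5p/miR-3p duplex inference.

The central operation is :func:`infer_mir3p`: given a folded precursor and
the miR-5p interval, deduce the miR-3p interval via the 2-nt 3' overhang
rule that governs DCL1 duplex release — the miR-3p 3' end extends two
nucleotides past the base pairing with the miR-5p 5' start, and the miR-3p
5' start pairs with the base two nucleotides upstream of the miR-5p 3' end.

Structures come in as dot-bracket strings (e.g. from RNAfold); a
deterministic maximum-base-pair Nussinov fold is bundled as a
non-thermodynamic fallback for synthetic hairpins and tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import HairpinRecord, Interval, SrnaTagTable

__all__ = [
    "UNPAIRED",
    "PairingMap",
    "DuplexGeometry",
    "InsufficientEvidence",
    "CannotInfer",
    "fold_nussinov",
    "pairing_map",
    "dominant_arm",
    "loop_midpoint",
    "infer_mir3p",
    "infer_mir5p",
    "overhang_lengths",
]

UNPAIRED = -1

_CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def _can_pair(a: str, b: str) -> bool:
    a = "U" if a == "T" else a
    b = "U" if b == "T" else b
    return (a, b) in _CANONICAL


class InsufficientEvidence(Exception):
    """No usable sRNA evidence on the hairpin."""


class CannotInfer(Exception):
    """Duplex geometry cannot be inferred (no paired anchor near miR-5p)."""


@dataclass
class PairingMap:
    """partner[i] = j when (i, j) base-paired, UNPAIRED (-1) otherwise."""

    partner: np.ndarray

    def __len__(self) -> int:
        return len(self.partner)

    def is_paired(self, i: int) -> bool:
        return self.partner[i] != UNPAIRED


@dataclass
class DuplexGeometry:
    """A miR-5p/miR-3p duplex with its realized 3' overhangs.

    ``overhang_3p_side`` is the unpaired 3' tail of the miR-3p strand (at the
    base of the hairpin); ``overhang_5p_side`` the tail of the miR-5p strand
    (loop side).  ``clipped`` flags an interval truncated at a sequence
    boundary, in which case a realized overhang can fall short of 2.
    """

    mir5p: Interval
    mir3p: Interval
    overhang_3p_side: int
    overhang_5p_side: int
    clipped: bool = False


# ---------------------------------------------------------------------------
# Folding


def fold_nussinov(sequence: str, min_loop: int = 3) -> str:
    """Maximum-base-pair nested fold (Nussinov DP), deterministic traceback.

    Allowed pairs: AU/UA, GC/CG, GU/UG (T read as U); N never pairs.
    Hairpin loops are at least ``min_loop`` nt.  Not a thermodynamic fold —
    use RNAfold structures for real precursors; this is the fallback for
    synthetic perfect-stem hairpins where the maximum pairing is unique.

    Traceback preference: pair the smaller index first, then extend the
    longer helix continuation, so equal-score structures resolve identically
    across runs.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper().replace("T", "U")
    n = len(seq)
    dp = np.zeros((n, n), dtype=np.int32)
    # dp[i][j] = max pairs in seq[i..j]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1][j]  # i unpaired
            if dp[i][j - 1] > best:
                best = dp[i][j - 1]
            if _can_pair(seq[i], seq[j]):
                cand = dp[i + 1][j - 1] + 1
                if cand > best:
                    best = cand
            for k in range(i + min_loop + 1, j):
                if _can_pair(seq[i], seq[k]):
                    cand = dp[i + 1][k - 1] + 1 + dp[k + 1][j]
                    if cand > best:
                        best = cand
            dp[i][j] = best
    structure = ["."] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or dp[i][j] == 0:
            continue
        # Prefer pairing the smaller index i; among partners prefer the
        # farthest j' (longer helix continuation), then scan inward.
        paired = False
        if _can_pair(seq[i], seq[j]) and dp[i][j] == dp[i + 1][j - 1] + 1:
            structure[i], structure[j] = "(", ")"
            stack.append((i + 1, j - 1))
            paired = True
        else:
            for k in range(j - 1, i + min_loop, -1):
                if _can_pair(seq[i], seq[k]) and dp[i][j] == dp[i + 1][k - 1] + 1 + dp[k + 1][j]:
                    structure[i], structure[k] = "(", ")"
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    return "".join(structure)


def pairing_map(dotbracket: str) -> PairingMap:
    """Parse a dot-bracket string into a symmetric partner array.

    The parser is permissive about loop sizes (only folding enforces
    ``min_loop``); unbalanced brackets raise with the offending position.
    """
    partner = np.full(len(dotbracket), UNPAIRED, dtype=np.int64)
    stack: list[int] = []
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            partner[j] = i
            partner[i] = j
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return PairingMap(partner)


# ---------------------------------------------------------------------------
# Arm assignment


def loop_midpoint(pairing: PairingMap) -> int:
    """Midpoint of the terminal loop: the longest contiguous unpaired run
    between the outermost base pair."""
    partner = pairing.partner
    paired_idx = np.nonzero(partner != UNPAIRED)[0]
    if len(paired_idx) == 0:
        return len(partner) // 2
    lo, hi = paired_idx[0], paired_idx[-1]
    best_len, best_start = 0, (lo + hi) // 2
    run_start = None
    for i in range(lo, hi + 1):
        if partner[i] == UNPAIRED:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and i - run_start > best_len:
                best_len, best_start = i - run_start, run_start
            run_start = None
    if run_start is not None and hi + 1 - run_start > best_len:
        best_len, best_start = hi + 1 - run_start, run_start
    return best_start + best_len // 2


def dominant_arm(
    srna_tags: SrnaTagTable,
    hairpin: HairpinRecord,
    length_range: tuple[int, int] = (17, 26),
) -> tuple[str, Interval]:
    """Locate the most abundant sRNA read species on the hairpin and report
    which arm it sits on.

    The winner is the single (5'-position, length) species with the highest
    count among reads whose length falls in ``length_range`` (the standard
    sRNA size selection); ties break toward the smaller position, then the
    smaller length.  The arm is '5p' when the read starts 5' of the terminal
    loop midpoint, '3p' otherwise.
    """
    if hairpin.structure is None:
        raise ValueError(f"{hairpin.precursor_id}: structure required for arm assignment")
    lo, hi = length_range
    species = {
        (pos, ln): n
        for (pos, ln), n in srna_tags.species_on(hairpin.precursor_id, "+").items()
        if lo <= ln <= hi and n > 0
    }
    if not species:
        raise InsufficientEvidence(
            f"no sRNA reads of length {lo}-{hi} on {hairpin.precursor_id}"
        )
    (pos, ln), _ = max(species.items(), key=lambda kv: (kv[1], -kv[0][0], -kv[0][1]))
    mid = loop_midpoint(pairing_map(hairpin.structure))
    arm = "5p" if pos < mid else "3p"
    return arm, Interval(pos, pos + ln)


# ---------------------------------------------------------------------------
# Duplex inference (2-nt 3' overhang rule)


def _nearest_paired(pairing: PairingMap, pos: int, max_dist: int = 5) -> int | None:
    """Nearest paired position within ``max_dist`` nt of ``pos`` (in-bounds).
    Ties between equidistant candidates resolve to the smaller position."""
    n = len(pairing)
    for d in range(0, max_dist + 1):
        for cand in (pos - d, pos + d):
            if 0 <= cand < n and pairing.partner[cand] != UNPAIRED:
                return cand
    return None


def infer_mir3p(
    hairpin: HairpinRecord, mir5p: Interval | None = None, anchor_search: int = 5
) -> DuplexGeometry:
    """Deduce the miR-3p interval from miR-5p via the 2-nt 3' overhang rule.

    On a bulge-free stem: miR-3p last base = partner(miR-5p first base) + 2,
    and miR-3p first base = partner(miR-5p third-to-last base).  When an
    anchor base is unpaired (bulge), the nearest paired base within
    ``anchor_search`` nt is used and the positional offset is compensated, so
    small asymmetric bulges do not shift the inferred arm.  Intervals are
    clipped at the sequence boundary, with the clip flagged and the realized
    overhang reported as-is.
    """
    if hairpin.structure is None:
        raise ValueError(f"{hairpin.precursor_id}: structure required")
    mir5p = mir5p if mir5p is not None else hairpin.mir5p
    if mir5p is None:
        raise ValueError(f"{hairpin.precursor_id}: miR-5p interval required")
    pairing = pairing_map(hairpin.structure)
    L = len(hairpin.sequence)

    # 3' end anchor: the miR-5p 5' start.
    a1 = _nearest_paired(pairing, mir5p.start, anchor_search)
    # 5' start anchor: two nt upstream of the miR-5p 3' (inclusive) end.
    t2 = mir5p.end - 3
    a2 = _nearest_paired(pairing, t2, anchor_search)
    if a1 is None or a2 is None:
        raise CannotInfer(
            f"{hairpin.precursor_id}: no paired anchor within {anchor_search} nt of miR-5p ends"
        )
    end_incl = int(pairing.partner[a1]) + (a1 - mir5p.start) + 2
    start = int(pairing.partner[a2]) + (a2 - t2)
    clipped = False
    if end_incl > L - 1:
        end_incl = L - 1
        clipped = True
    if start < 0:
        start = 0
        clipped = True
    if start > end_incl:
        raise CannotInfer(f"{hairpin.precursor_id}: degenerate inferred miR-3p interval")
    mir3p = Interval(start, end_incl + 1)
    ov3, ov5 = overhang_lengths_from(pairing, mir5p, mir3p, anchor_search)
    return DuplexGeometry(
        mir5p=mir5p, mir3p=mir3p, overhang_3p_side=ov3, overhang_5p_side=ov5, clipped=clipped
    )


def infer_mir5p(
    hairpin: HairpinRecord, mir3p: Interval | None = None, anchor_search: int = 5
) -> DuplexGeometry:
    """Mirror of :func:`infer_mir3p`: deduce miR-5p from a known miR-3p.

    On bulge-free stems this inverts :func:`infer_mir3p` exactly.
    """
    if hairpin.structure is None:
        raise ValueError(f"{hairpin.precursor_id}: structure required")
    mir3p = mir3p if mir3p is not None else hairpin.mir3p
    if mir3p is None:
        raise ValueError(f"{hairpin.precursor_id}: miR-3p interval required")
    pairing = pairing_map(hairpin.structure)
    L = len(hairpin.sequence)
    a1 = _nearest_paired(pairing, mir3p.start, anchor_search)
    t2 = mir3p.end - 3
    a2 = _nearest_paired(pairing, t2, anchor_search)
    if a1 is None or a2 is None:
        raise CannotInfer(
            f"{hairpin.precursor_id}: no paired anchor within {anchor_search} nt of miR-3p ends"
        )
    end_incl = int(pairing.partner[a1]) + (a1 - mir3p.start) + 2
    start = int(pairing.partner[a2]) + (a2 - t2)
    clipped = False
    if end_incl > L - 1:
        end_incl = L - 1
        clipped = True
    if start < 0:
        start = 0
        clipped = True
    if start > end_incl:
        raise CannotInfer(f"{hairpin.precursor_id}: degenerate inferred miR-5p interval")
    mir5p = Interval(start, end_incl + 1)
    ov3, ov5 = overhang_lengths_from(pairing, mir5p, mir3p, anchor_search)
    return DuplexGeometry(
        mir5p=mir5p, mir3p=mir3p, overhang_3p_side=ov3, overhang_5p_side=ov5, clipped=clipped
    )


def overhang_lengths_from(
    pairing: PairingMap, mir5p: Interval, mir3p: Interval, anchor_search: int = 5
) -> tuple[int, int]:
    """Realized 3' overhangs of a duplex given a pairing map.

    Returns ``(overhang_3p_side, overhang_5p_side)``: how far the 3' end of
    each strand protrudes past the partner strand's 5' end.  A mature miRNA
    duplex released by DCL1 has (2, 2); blunt ends give 0.  Anchors on
    unpaired bases are compensated as in :func:`infer_mir3p`.
    """
    a1 = _nearest_paired(pairing, mir5p.start, anchor_search)
    a2 = _nearest_paired(pairing, mir3p.start, anchor_search)
    if a1 is None or a2 is None:
        raise CannotInfer("no paired anchor for overhang computation")
    # miR-3p 3' tail past the base pairing with the miR-5p 5' start:
    ov3 = (mir3p.end - 1) - (int(pairing.partner[a1]) + (a1 - mir5p.start))
    # miR-5p 3' tail past the base pairing with the miR-3p 5' start:
    ov5 = (mir5p.end - 1) - (int(pairing.partner[a2]) + (a2 - mir3p.start))
    return ov3, ov5


def overhang_lengths(geometry: DuplexGeometry, pairing: PairingMap) -> tuple[int, int]:
    """Overhangs of an existing :class:`DuplexGeometry` (see
    :func:`overhang_lengths_from`)."""
    return overhang_lengths_from(pairing, geometry.mir5p, geometry.mir3p)
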