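"""Bundled worked examples of miR-3p boundary correction.

Two published miRBase annotation errors that degradome remnant peaks
resolve, reconstructed as self-contained fixtures:

* **ath-miR169a-3p** (base-to-loop): annotated 20-nt
  ``GGCAAGUUGUCCUUGGCUAC``; the downstream-remnant peak sits one nucleotide
  of gap after the annotated 3' end, so the mature sequence is really 21 nt
  (``GGCAAGUUGUCCUUGGCUACA``).
* **gma-miR408c-3p** (loop-to-base): annotated 21-nt
  ``AUGCACUGCCUCUUCCCUGGC``; the second-cut remnant peak — whose 5' end IS
  the mature 5' start — begins 1 nt after the annotated start, giving
  ``UGCACUGCCUCUUCCCUGGCU``.

The mature sequences are the published ones; the flanking precursor context
and the perfect-stem structures are synthetic (the corrections depend only
on the peak position relative to the annotation, and the structures are
built so the *corrected* interval satisfies the 2-nt 3' overhang rule, as
reported for the real loci).
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_formats import HairpinRecord, Interval, TagCountTable

__all__ = ["WorkedExample", "mir169a_example", "mir408c_example", "perfect_stem_structure"]

ATH_MIR169A_ANNOTATED = "GGCAAGUUGUCCUUGGCUAC"
ATH_MIR169A_CORRECTED = "GGCAAGUUGUCCUUGGCUACA"
GMA_MIR408C_ANNOTATED = "AUGCACUGCCUCUUCCCUGGC"
GMA_MIR408C_CORRECTED = "UGCACUGCCUCUUCCCUGGCU"


@dataclass
class WorkedExample:
    hairpin: HairpinRecord
    annotated: Interval
    tags: TagCountTable
    mir5p: Interval
    corrected_sequence: str


def perfect_stem_structure(
    length: int, mir5p: Interval, mir3p: Interval
) -> str:
    """Dot-bracket of a synthetic perfect stem in which ``mir5p``/``mir3p``
    form a duplex with exact 2-nt 3' overhangs at both ends.

    Pairs position p with C - p over the mature regions, where
    C = mir5p.start + mir3p.end - 3 places the miR-3p 3' end two
    nucleotides past the base pairing with the miR-5p 5' start.
    """
    if len(mir5p) != len(mir3p):
        raise ValueError("duplex strands must have equal length")
    C = mir5p.start + mir3p.end - 3
    chars = ["."] * length
    for p in range(mir5p.start, mir5p.end):
        q = C - p
        if not (mir5p.end <= q < length):
            raise ValueError("intervals too close for a nested stem")
        chars[p] = "("
        chars[q] = ")"
    return "".join(chars)


def _embed(mature_context: str, offset: int, tail: int) -> str:
    """Place a mature-arm context at ``offset`` inside a low-complexity
    flanking sequence that cannot spuriously contain it."""
    return "C" * offset + mature_context + "C" * tail


def mir169a_example(peak_count: int = 100) -> WorkedExample:
    """The ath-miR169a-3p 3'-end correction scenario.

    The annotated 20-mer sits at [30, 50); the dominant degradome peak (the
    remnant 5' base) is at position 51 — one nucleotide of gap after the
    annotated end — so the corrected mature interval is [30, 51), 21 nt.
    """
    offset = 30
    context = ATH_MIR169A_CORRECTED  # annotated 20-mer + the trailing A
    seq = _embed(context, offset, tail=30)
    annotated = Interval(offset, offset + len(ATH_MIR169A_ANNOTATED))
    corrected = Interval(offset, offset + len(ATH_MIR169A_CORRECTED))
    mir5p = Interval(2, 2 + len(corrected))
    structure = perfect_stem_structure(len(seq), mir5p, corrected)
    hp = HairpinRecord(
        precursor_id="ath-MIR169a",
        sequence=seq,
        mir5p=mir5p,
        mir3p=annotated,
        structure=structure,
        family="miR169",
        species="ath",
    )
    tags = TagCountTable(library_id="worked-example")
    tags.add(hp.precursor_id, annotated.end + 1, "+", peak_count)
    return WorkedExample(hp, annotated, tags, mir5p, ATH_MIR169A_CORRECTED)


def mir408c_example(peak_count: int = 100) -> WorkedExample:
    """The gma-miR408c-3p 5'-start correction scenario.

    The precursor contains both the annotated and the corrected 21-mers
    (they overlap by 20 nt); the dominant peak is placed at the position
    where the corrected sequence begins, located by string match.
    """
    offset = 30
    context = GMA_MIR408C_ANNOTATED + "U"  # contains both versions
    assert GMA_MIR408C_CORRECTED in context
    seq = _embed(context, offset, tail=30)
    annotated = Interval(offset, offset + len(GMA_MIR408C_ANNOTATED))
    corrected_start = seq.find(GMA_MIR408C_CORRECTED)
    corrected = Interval(corrected_start, corrected_start + len(GMA_MIR408C_CORRECTED))
    mir5p = Interval(2, 2 + len(corrected))
    structure = perfect_stem_structure(len(seq), mir5p, corrected)
    hp = HairpinRecord(
        precursor_id="gma-MIR408c",
        sequence=seq,
        mir5p=mir5p,
        mir3p=annotated,
        structure=structure,
        family="miR408",
        species="gma",
    )
    tags = TagCountTable(library_id="worked-example")
    tags.add(hp.precursor_id, corrected_start, "+", peak_count)
    return WorkedExample(hp, annotated, tags, mir5p, GMA_MIR408C_CORRECTED)
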