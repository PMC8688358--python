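"""Synthetic degradome study generator with known ground truth.

Emulates the essential structure of a plant PARE experiment: hairpin
precursors with perfect-complement stems and exact 2-nt 3' overhang
miR-5p/miR-3p duplexes, 20-nt 5'-end tags concentrated at the cleavage-
remnant positions characteristic of each processing mode (with +/-1 nt
positional jitter standing in for DCL1 imprecision), Poisson or fixed
per-precursor depth, and an adjustable fraction of mature-miR-3p
contaminant reads placed exactly at the miR-3p 5' start — the worst case
for the contamination statistic.

Everything is driven by one seeded generator, so a config with the same
seed reproduces the same study byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import (
    HairpinRecord,
    Interval,
    SrnaTagTable,
    TagCountTable,
    write_fasta,
)

__all__ = ["SimConfig", "simulate_hairpin", "simulate_tags", "simulate_srna", "simulate_study"]

_RNA = np.array(["A", "C", "G", "U"])
_COMP = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass
class SimConfig:
    """Full parameterization of the synthetic degradome study.

    Defaults describe a clean wild-type-like library: 50 precursors per
    mode, fixed depth 100, +/-1 nt jitter on 10% of tags, no mature-miRNA
    contamination, and the 70:30 first:second remnant split seen for short
    loop-to-base miRNAs.
    """

    seed: int
    n_per_mode: int = 50
    duplex_len: int = 21
    stem_len: int = 45
    loop_len: int = 8
    flank5_len: int = 10
    flank3_len: int = 30
    mir5p_offset: int = 5  # nt into the stem at which miR-5p starts
    depth: int = 100
    depth_model: str = "fixed"  # {fixed, poisson}
    jitter_prob: float = 0.1
    contamination_rho: float = 0.0
    lb_ratio: tuple[float, float] = (0.7, 0.3)  # first:second remnant for shLB
    seq_extra_cuts: int = 2  # K extra cuts for sequential modes
    step: int = 21
    n_samples: int = 1
    misannotation_shift: int = 0  # shift applied to EMITTED annotations only

    def __post_init__(self) -> None:
        for p in (self.jitter_prob, self.contamination_rho):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.stem_len < self.duplex_len + 17:
            raise ValueError(
                f"stem_len must be >= duplex_len + 17 "
                f"({self.duplex_len + 17}), got {self.stem_len}"
            )
        if self.depth_model not in ("fixed", "poisson"):
            raise ValueError(f"unknown depth_model {self.depth_model!r}")
        if abs(sum(self.lb_ratio) - 1.0) > 1e-9:
            raise ValueError("lb_ratio must sum to 1")


MODES_SIM = ("shBL", "seBL", "shLB", "seLB")


def simulate_hairpin(
    config: SimConfig, mode: str, rng: np.random.Generator, index: int = 0
) -> HairpinRecord:
    """One synthetic precursor: flank + perfect stem + loop + stem' + flank,
    with miR-5p/miR-3p placed so the duplex carries exact 2-nt 3' overhangs
    and the dot-bracket recorded by construction."""
    c = config
    F5, S, L, F3 = c.flank5_len, c.stem_len, c.loop_len, c.flank3_len
    stem5 = "".join(rng.choice(_RNA, size=S))
    loop = "".join(rng.choice(_RNA, size=L))
    flank5 = "".join(rng.choice(_RNA, size=F5))
    flank3 = "".join(rng.choice(_RNA, size=F3))
    stem3 = "".join(_COMP[b] for b in reversed(stem5))
    sequence = flank5 + stem5 + loop + stem3 + flank3
    structure = "." * F5 + "(" * S + "." * L + ")" * S + "." * F3
    mir5p = Interval(F5 + c.mir5p_offset, F5 + c.mir5p_offset + c.duplex_len)
    # partner of stem position p (within stem5) is 2*F5 + 2*S + L - 1 - p
    partner_of = lambda p: 2 * F5 + 2 * S + L - 1 - p  # noqa: E731
    p0 = partner_of(mir5p.end - 3)
    end_incl = partner_of(mir5p.start) + 2
    mir3p = Interval(p0, end_incl + 1)
    total = len(sequence)
    if mir3p.end + c.step + 3 > total:
        raise ValueError("flank3_len too short for the downstream sequential remnant")
    if mir3p.start - c.seq_extra_cuts * c.step < 0:
        raise ValueError("precursor too short for the upstream sequential remnants")
    return HairpinRecord(
        precursor_id=f"sim-{mode}-{index:03d}",
        sequence=sequence,
        mir5p=mir5p,
        mir3p=mir3p,
        structure=structure,
        family=f"fam-{mode}-{index:03d}",
        species="synthetic",
    )


def _signal_positions(hairpin: HairpinRecord, mode: str, config: SimConfig) -> tuple[list[int], list[float]]:
    p0, pe = hairpin.mir3p.start, hairpin.mir3p.end
    step, K = config.step, config.seq_extra_cuts
    if mode == "shBL":
        return [pe], [1.0]
    if mode == "seBL":
        return [pe + step], [1.0]
    if mode == "shLB":
        w1, w2 = config.lb_ratio
        return [p0, pe], [w1, w2]
    if mode == "seLB":
        # first cuts on the upstream grid, then p0, then the final pe remnant
        ups = [p0 - k * step for k in range(1, K + 1)]
        w_up = 0.4 / K
        return ups + [p0, pe], [w_up] * K + [0.4, 0.2]
    raise ValueError(f"unknown mode {mode!r}")


def simulate_tags(
    hairpin: HairpinRecord,
    mode: str,
    config: SimConfig,
    rng: np.random.Generator,
    library_id: str = "sim",
    table: TagCountTable | None = None,
) -> TagCountTable:
    """Draw one library's PARE tags for one precursor.

    Signal tags land on the mode's remnant positions (jittered +/-1 nt with
    probability ``jitter_prob``); an independent Binomial(depth, rho) count
    of contaminant tags is stacked exactly at p0.
    """
    c = config
    table = table if table is not None else TagCountTable(library_id=library_id)
    depth = c.depth if c.depth_model == "fixed" else int(rng.poisson(c.depth))
    positions, weights = _signal_positions(hairpin, mode, c)
    # rho is the contaminant FRACTION of the library: of `depth` tags,
    # Binomial(depth, rho) are mature miR-3p molecules, the rest remnants
    n_contam = int(rng.binomial(depth, c.contamination_rho)) if depth > 0 else 0
    n_signal = depth - n_contam
    if n_signal > 0:
        alloc = rng.multinomial(n_signal, weights)
        for pos, n in zip(positions, alloc):
            if n == 0:
                continue
            jittered = rng.random(n) < c.jitter_prob
            n_jit = int(jittered.sum())
            shifts = rng.choice([-1, 1], size=n_jit)
            table.add(hairpin.precursor_id, pos, "+", n - n_jit)
            for s in shifts:
                p = min(max(pos + int(s), 0), len(hairpin.sequence) - 1)
                table.add(hairpin.precursor_id, p, "+", 1)
    if n_contam:
        table.add(hairpin.precursor_id, hairpin.mir3p.start, "+", n_contam)
    return table


def simulate_srna(
    hairpin: HairpinRecord,
    depth: int,
    rng: np.random.Generator,
    majority_arm: str = "5p",
    library_id: str = "srna",
    table: SrnaTagTable | None = None,
) -> SrnaTagTable:
    """Draw a length-aware sRNA table: the majority species is the exact
    mature read of ``majority_arm``, with a minority on the other arm and
    +/-1 isomiRs of the majority."""
    table = table if table is not None else SrnaTagTable(library_id=library_id)
    if depth <= 0:
        return table
    major = hairpin.mir5p if majority_arm == "5p" else hairpin.mir3p
    minor = hairpin.mir3p if majority_arm == "5p" else hairpin.mir5p
    species = [
        (major.start, len(major)),
        (minor.start, len(minor)),
        (major.start - 1, len(major)),
        (major.start + 1, len(major)),
    ]
    alloc = rng.multinomial(depth, [0.7, 0.15, 0.075, 0.075])
    for (pos, ln), n in zip(species, alloc):
        if n and 0 <= pos and pos + ln <= len(hairpin.sequence):
            table.add(hairpin.precursor_id, pos, "+", ln, n)
    return table


def simulate_study(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a complete self-describing synthetic study to ``outdir``.

    Emits precursors.fasta, annotations.tsv (1-based, optionally
    mis-annotated by ``misannotation_shift``), structures.tsv, one
    tags_<library>.tsv per sample, srna.tsv, and truth.tsv with the
    generating mode and true boundaries.  Deterministic for a given seed.
    Returns the emitted paths keyed by role.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    hairpins: list[tuple[HairpinRecord, str]] = []
    for mode in MODES_SIM:
        for i in range(config.n_per_mode):
            hairpins.append((simulate_hairpin(config, mode, rng, index=i), mode))

    lib_ids = [f"lib{j + 1:02d}" for j in range(config.n_samples)]
    tag_tables = {lib: TagCountTable(library_id=lib) for lib in lib_ids}
    depths: dict[tuple[str, str], int] = {}
    for hp, mode in hairpins:
        for lib in lib_ids:
            before = tag_tables[lib].total()
            simulate_tags(hp, mode, config, rng, table=tag_tables[lib])
            depths[(hp.precursor_id, lib)] = tag_tables[lib].total() - before
    srna = SrnaTagTable(library_id="srna")
    for hp, _ in hairpins:
        simulate_srna(hp, depth=200, rng=rng, table=srna)

    paths: dict[str, Path] = {}
    paths["fasta"] = outdir / "precursors.fasta"
    write_fasta([(hp.precursor_id, hp.sequence) for hp, _ in hairpins], paths["fasta"])

    shift = config.misannotation_shift
    ann_rows = []
    for hp, _ in hairpins:
        ann_rows.append(
            {
                "precursor_id": hp.precursor_id,
                "mir5p_start": hp.mir5p.start + 1,
                "mir5p_end": hp.mir5p.end,
                "mir3p_start": hp.mir3p.start + 1 + shift,
                "mir3p_end": hp.mir3p.end + shift,
                "family": hp.family,
                "species": hp.species,
            }
        )
    paths["annotations"] = outdir / "annotations.tsv"
    pd.DataFrame(ann_rows).to_csv(paths["annotations"], sep="\t", index=False)

    paths["structures"] = outdir / "structures.tsv"
    with open(paths["structures"], "w") as fh:
        for hp, _ in hairpins:
            fh.write(f"{hp.precursor_id}\t{hp.structure}\n")

    for lib in lib_ids:
        p = outdir / f"tags_{lib}.tsv"
        rows = [
            {"ref_id": r, "pos_1based": pos + 1, "strand": s, "count": n}
            for (r, pos, s), n in sorted(tag_tables[lib].counts.items())
        ]
        pd.DataFrame(rows, columns=["ref_id", "pos_1based", "strand", "count"]).to_csv(
            p, sep="\t", index=False
        )
        paths[f"tags_{lib}"] = p

    paths["srna"] = outdir / "srna.tsv"
    rows = [
        {"ref_id": r, "pos_1based": pos + 1, "strand": s, "length": ln, "count": n}
        for (r, pos, s, ln), n in sorted(srna.counts.items())
    ]
    pd.DataFrame(rows, columns=["ref_id", "pos_1based", "strand", "length", "count"]).to_csv(
        paths["srna"], sep="\t", index=False
    )

    truth_rows = []
    for hp, mode in hairpins:
        row = {
            "precursor_id": hp.precursor_id,
            "true_mode": mode,
            "true_mir3p_start": hp.mir3p.start + 1,
            "true_mir3p_end": hp.mir3p.end,
            "rho": config.contamination_rho,
            "epsilon": config.jitter_prob,
        }
        for lib in lib_ids:
            row[f"depth_{lib}"] = depths[(hp.precursor_id, lib)]
        truth_rows.append(row)
    paths["truth"] = outdir / "truth.tsv"
    pd.DataFrame(truth_rows).to_csv(paths["truth"], sep="\t", index=False)
    return paths
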