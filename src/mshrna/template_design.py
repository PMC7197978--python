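"""Multimeric-shRNA repeat units and circularizable ssDNA templates.

One repeat unit of the transcript is ``arm1 + loop + arm2 + spacer`` where
the arms are an siRNA candidate's sense and guide strands (complementary
over a 19-bp core) and fold back on themselves into a hairpin; the spacer
separates consecutive hairpins along the multimer. Under the defaults
(21 + 9 + 21 + 10) a unit is 61 nt, so a trivalent template is 183 nt.

The DNA template is the reverse complement of the concatenated unit RNAs,
closed into a circle: continuous (rolling-circle) transcription of the
circle then reproduces the unit RNAs in order, lap after lap. The linear
synthesis form opens the circle at a nick placed mid-stem so the two ends
of the self-annealed molecule meet inside a duplex region, presenting a
nicked double helix that T4 DNA ligase can seal without a splint.

Circle coordinates: position 0 is the template base encoding the first
base of unit 1's first arm; features and the nick are reported in these
coordinates, 0-based half-open, and never wrap past the origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

from .sequence_io import (
    Alphabet,
    NucleotideSequence,
    Topology,
    _revcomp_str,
)
from .sirna_design import (
    CORE_LEN,
    SirnaCandidate,
    DesignError,
    apply_filters,
    enumerate_candidates,
    score_asymmetry,
    select_top_nonoverlapping,
)

logger = logging.getLogger("mshrna")

__all__ = [
    "DEFAULT_LOOP",
    "DEFAULT_SPACER",
    "ShrnaUnit",
    "Feature",
    "MshrnaTemplate",
    "build_unit",
    "build_template",
    "simulate_rct",
    "design_from_mrna",
]

DEFAULT_LOOP = "UUCAAGAGA"  # widely used 9-nt shRNA loop
DEFAULT_SPACER = "U" * 10  # maximally A/U-rich; cannot extend any passing stem

_MIN_COMP_WINDOW = 6  # loop/spacer windows complementary to an arm at >= this length are rejected
_DNA_TO_RNA_COMP = str.maketrans("ACGT", "UGCA")


class Feature(NamedTuple):
    """A labelled circle-coordinate interval, half-open."""

    label: str
    start: int
    end: int
    unit_index: int


@dataclass(frozen=True)
class ShrnaUnit:
    """One shRNA repeat: two complementary arms, a loop and a spacer.

    ``sense_first`` controls transcript order: sense-loop-antisense-spacer
    (default, guide is the 3' arm) or antisense-loop-sense-spacer.
    """

    sense_arm: str
    loop: str
    antisense_arm: str
    spacer: str
    sense_first: bool = True
    source: SirnaCandidate | None = None

    @property
    def arm1(self) -> str:
        return self.sense_arm if self.sense_first else self.antisense_arm

    @property
    def arm2(self) -> str:
        return self.antisense_arm if self.sense_first else self.sense_arm

    @property
    def rna(self) -> str:
        return self.arm1 + self.loop + self.arm2 + self.spacer

    def __len__(self) -> int:
        return len(self.rna)

    def parts(self) -> list[tuple[str, str]]:
        """(label, residues) in transcript order."""
        a1 = "sense" if self.sense_first else "antisense"
        a2 = "antisense" if self.sense_first else "sense"
        return [
            (a1, self.arm1),
            ("loop", self.loop),
            (a2, self.arm2),
            ("spacer", self.spacer),
        ]

    def stem_pairs(self) -> list[tuple[int, int]]:
        """Intra-unit base pairs (unit RNA coordinates), 19 per unit.

        Both arms carry their paired core at positions [0, 19) and the 2-nt
        3' overhang at [19, 21), so arm1 position i pairs arm2 position
        18 - i.
        """
        off = len(self.arm1) + len(self.loop)
        return [(i, off + CORE_LEN - 1 - i) for i in range(CORE_LEN)]


@dataclass(frozen=True)
class MshrnaTemplate:
    """A linear ssDNA template for a mono-, bi- or trivalent mshRNA."""

    valence: int
    linear_sequence: NucleotideSequence
    nick_index: int
    features: tuple[Feature, ...]
    units: tuple[ShrnaUnit, ...]
    dotbracket: str | None = None

    def __len__(self) -> int:
        return len(self.linear_sequence)

    @property
    def circle_sequence(self) -> NucleotideSequence:
        """The circularized template (nick sealed), circle coordinates."""
        lin = self.linear_sequence.residues
        rot = len(lin) - self.nick_index
        return NucleotideSequence(
            id=self.linear_sequence.id + "_circle",
            residues=lin[rot:] + lin[:rot],
            alphabet=Alphabet.DNA,
            topology=Topology.CIRCULAR,
        )

    def designed_pairs(self) -> list[tuple[int, int]]:
        """All stem base pairs in circle coordinates, 19 per unit."""
        L = len(self)
        s1 = len(self.units[0].arm1)
        pairs = []
        offset = 0
        for unit in self.units:
            for i, j in unit.stem_pairs():
                a = (s1 - 1 - (offset + i)) % L
                b = (s1 - 1 - (offset + j)) % L
                pairs.append((min(a, b), max(a, b)))
            offset += len(unit)
        return pairs


def _complementary_window(segment: str, arm: str) -> str | None:
    """First >=6-nt window of ``segment`` whose revcomp occurs in ``arm``."""
    for k in range(len(segment) - _MIN_COMP_WINDOW + 1):
        window = segment[k : k + _MIN_COMP_WINDOW]
        if _revcomp_str(window, Alphabet.RNA) in arm:
            return window
    return None


def build_unit(
    candidate: SirnaCandidate,
    loop: str = DEFAULT_LOOP,
    spacer: str = DEFAULT_SPACER,
    sense_first: bool = True,
) -> ShrnaUnit:
    """Assemble one repeat unit from a scored candidate.

    The loop and spacer must not be complementary to either arm over six
    or more contiguous nucleotides — such a segment would extend the stem
    and distort the designed hairpin.
    """
    loop = loop.upper().replace("T", "U")
    spacer = spacer.upper().replace("T", "U")
    if len(loop) < 3:
        raise DesignError(f"loop too short ({len(loop)} nt): steric minimum is 3")
    for name, seg in (("loop", loop), ("spacer", spacer)):
        if any(ch not in "ACGU" for ch in seg):
            raise DesignError(f"{name} {seg!r} is not a pure RNA sequence")
        for arm_name, arm in (
            ("sense", candidate.sense_strand),
            ("antisense", candidate.guide_strand),
        ):
            window = _complementary_window(seg, arm)
            if window is not None:
                raise DesignError(
                    f"loop or spacer would extend the stem: {name} window "
                    f"{window!r} is complementary to the {arm_name} arm"
                )
    return ShrnaUnit(
        sense_arm=candidate.sense_strand,
        loop=loop,
        antisense_arm=candidate.guide_strand,
        spacer=spacer,
        sense_first=sense_first,
        source=candidate,
    )


def _footprints_overlap(a: SirnaCandidate, b: SirnaCandidate) -> bool:
    if a.target_id != b.target_id:
        return False
    (alo, ahi), (blo, bhi) = a.footprint, b.footprint
    return alo < bhi and blo < ahi


def build_template(
    units: Sequence[ShrnaUnit], template_id: str = "mshRNA_template"
) -> MshrnaTemplate:
    """Construct the circularizable linear ssDNA template for these units.

    The circular template is the DNA reverse complement of the concatenated
    unit RNAs, so one transcription lap starting in phase reproduces the
    unit RNAs exactly. The linear form opens the circle at the midpoint of
    unit 1's first stem side, leaving >= 5 bp of duplex on each side of the
    nick once the molecule self-anneals.
    """
    valence = len(units)
    if not 1 <= valence <= 3:
        raise DesignError(f"unsupported valence {valence}: must be 1, 2 or 3")
    sourced = [u for u in units if u.source is not None]
    for i, a in enumerate(sourced):
        for b in sourced[i + 1 :]:
            if _footprints_overlap(a.source, b.source):
                raise DesignError(
                    "units overlap on target: footprints "
                    f"{a.source.footprint} and {b.source.footprint} intersect"
                )

    rna_concat = "".join(u.rna for u in units)
    L = len(rna_concat)
    s1 = len(units[0].arm1)
    # circle[c] encodes rna position (s1 - 1 - c) mod L, i.e. the circle is
    # the reverse complement of the RNA rotated so that coordinate 0 is the
    # base encoding the first base of unit 1's first arm.
    dna = rna_concat.replace("U", "T")
    rc = _revcomp_str(dna, Alphabet.DNA)
    circle = rc[L - s1 :] + rc[: L - s1]

    features: list[Feature] = []
    offset = 0
    for idx, unit in enumerate(units):
        for label, residues in unit.parts():
            a, b = offset, offset + len(residues)
            start = (s1 - b) % L
            end = s1 - a if a < s1 else ((s1 - a) % L or L)
            features.append(Feature(label, start, end, idx))
            offset = b

    # midpoint of unit 1's first stem side (circle interval [s1-19, s1))
    stem_lo, stem_hi = s1 - CORE_LEN, s1
    nick = (stem_lo + stem_hi) // 2
    linear = circle[nick:] + circle[:nick]

    return MshrnaTemplate(
        valence=valence,
        linear_sequence=NucleotideSequence(
            id=template_id, residues=linear, alphabet=Alphabet.DNA
        ),
        nick_index=nick,
        features=tuple(features),
        units=tuple(units),
    )


def simulate_rct_circle(
    circle_residues: str, laps: int, start_phase: int, origin_arm_len: int
) -> str:
    """Rolling-circle product of a template circle, as an RNA string.

    Purely geometric: the polymerase reads the circle 3'->5' (descending
    circle coordinates) emitting complements; ``start_phase`` is the
    product-RNA position (within the repeat) where transcription begins.
    """
    if laps < 1:
        raise DesignError("laps must be >= 1")
    L = len(circle_residues)
    c0 = (origin_arm_len - 1 - start_phase) % L
    out = []
    for j in range(laps * L):
        out.append(circle_residues[(c0 - j) % L].translate(_DNA_TO_RNA_COMP))
    return "".join(out)


def simulate_rct(
    template: MshrnaTemplate, laps: int, start_phase: int = 0
) -> NucleotideSequence:
    """Simulate rolling-circle transcription of the circularized template.

    For ``start_phase`` 0 the first lap equals the concatenated unit RNAs
    exactly; ``laps`` k yields the 1-lap product repeated k times; any
    phase yields a rotation of the phase-0 product.
    """
    circle = template.circle_sequence.residues
    rna = simulate_rct_circle(
        circle, laps, start_phase, len(template.units[0].arm1)
    )
    return NucleotideSequence(
        id=f"{template.linear_sequence.id}_rct_{laps}lap",
        residues=rna,
        alphabet=Alphabet.RNA,
    )


def design_from_mrna(
    target: NucleotideSequence, valence: int, config
) -> tuple[list[SirnaCandidate], MshrnaTemplate]:
    """One-stop pipeline: enumerate, score, filter, select, assemble.

    Selects the ``valence`` most functional non-overlapping siRNAs along
    the target and builds the corresponding mshRNA template.
    """
    table = config.table()
    candidates = [
        apply_filters(
            score_asymmetry(c, config.window_bp, table), config
        )
        for c in enumerate_candidates(target)
    ]
    winners = select_top_nonoverlapping(candidates, valence)
    if len(winners) < valence:
        raise DesignError(
            f"target '{target.id}' cannot host {valence} disjoint passing "
            f"siRNA footprints (found {len(winners)})"
        )
    units = [
        build_unit(
            w,
            loop=config.loop,
            spacer=config.spacer,
            sense_first=config.arm_order == "sense-first",
        )
        for w in winners
    ]
    template = build_template(units, template_id=f"{target.id}_mshrna_v{valence}")
    return winners, template
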