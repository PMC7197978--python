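"""siRNA candidate enumeration and thermodynamic-asymmetry ranking.

The effector is a ~21-nt RNA duplex with 2-nt 3' overhangs on both strands.
Candidates are enumerated as 23-nt footprints along the target mRNA in the
standard Tuschl realization: for a footprint t = target[start, start+23),

    sense strand  = t[2:23]                (21 nt, 5'->3', target sense)
    guide strand  = revcomp(t[0:21])       (21 nt, 5'->3', antisense)

so the duplex shares a 19-bp core (t[2:21] with its complement) and each
strand dangles 2 nt at its 3' end.

Ranking encodes thermodynamic end asymmetry: the RISC complex preferentially
loads the strand whose 5' end sits at the *weaker* duplex end, so a candidate
whose guide-5' end is less stable (less negative nearest-neighbor dG) than
its sense-5' end silences better. The score is

    asymmetry = dG(guide-5' end window) - dG(sense-5' end window)

summed over nearest-neighbor stacks in a terminal window (default 5 bp,
i.e. 4 stacks); larger asymmetry ranks as more functional. The duplex
initiation penalty cancels in the difference and is not included.
"""

from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

from .sequence_io import (
    Alphabet,
    NucleotideSequence,
    SequenceError,
    Topology,
    _revcomp_str,
)

logger = logging.getLogger("mshrna")

__all__ = [
    "DesignError",
    "NearestNeighborTable",
    "SirnaCandidate",
    "SENSE_5",
    "GUIDE_5",
    "FOOTPRINT_LEN",
    "STRAND_LEN",
    "CORE_LEN",
    "load_default_table",
    "enumerate_candidates",
    "end_free_energy",
    "score_asymmetry",
    "apply_filters",
    "select_by_position",
    "select_top_nonoverlapping",
]

FOOTPRINT_LEN = 23
STRAND_LEN = 21
CORE_LEN = 19

SENSE_5 = "SENSE_5"
GUIDE_5 = "GUIDE_5"

_DEFAULT_TABLE_RESOURCE = "xia1998_rna_nn.tsv"


class DesignError(ValueError):
    """Raised when a design request cannot be satisfied."""


@dataclass(frozen=True)
class NearestNeighborTable:
    """RNA/RNA dinucleotide-stack free energies (dG37, kcal/mol).

    Keys are the 16 top-strand dinucleotides read 5'->3' over their
    Watson-Crick complement. The table must satisfy Watson-Crick symmetry:
    the value for stack XY equals the value for its reverse-complement
    stack, because both spellings name the same physical stack.
    """

    stacks: dict[str, float]
    init_penalty: float
    source_label: str

    def __post_init__(self) -> None:
        if set(self.stacks) != {
            a + b for a in "ACGU" for b in "ACGU"
        }:
            raise ValueError("NN table must contain exactly the 16 RNA stacks")
        for key, val in self.stacks.items():
            if not math.isfinite(val):
                raise ValueError(f"NN stack {key}: non-finite value {val}")
            mirror = _revcomp_str(key, Alphabet.RNA)
            if abs(val - self.stacks[mirror]) > 1e-9:
                raise ValueError(
                    f"NN table violates Watson-Crick symmetry: "
                    f"{key}={val} but {mirror}={self.stacks[mirror]}"
                )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NearestNeighborTable":
        """Load a ``stack<TAB>dg_kcal_mol`` table.

        ``# source:`` and ``# init_penalty:`` comment lines carry provenance;
        the header row is required.
        """
        source = str(path)
        init_penalty = 0.0
        stacks: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    body = line.lstrip("#").strip()
                    if body.lower().startswith("source:"):
                        source = body.split(":", 1)[1].strip()
                    elif body.lower().startswith("init_penalty:"):
                        init_penalty = float(body.split(":", 1)[1])
                    continue
                key, _, val = line.partition("\t")
                if key == "stack":
                    continue
                stacks[key.strip().upper().replace("T", "U")] = float(val)
        return cls(stacks=stacks, init_penalty=init_penalty, source_label=source)

    def checksum(self) -> str:
        """Order-independent sha256 over the parameter content."""
        canon = ";".join(
            f"{k}={self.stacks[k]:.6f}" for k in sorted(self.stacks)
        ) + f";init={self.init_penalty:.6f}"
        return hashlib.sha256(canon.encode()).hexdigest()


def load_default_table() -> NearestNeighborTable:
    """The shipped Xia 1998 RNA/RNA Watson-Crick dG37 parameters."""
    ref = resources.files("mshrna").joinpath("data", _DEFAULT_TABLE_RESOURCE)
    with resources.as_file(ref) as path:
        return NearestNeighborTable.from_tsv(path)


@dataclass(frozen=True)
class SirnaCandidate:
    """One 23-nt footprint with its duplex strands and end energies.

    ``filter_flags`` is empty for a passing candidate. Energies are None
    until :func:`score_asymmetry` fills them.
    """

    target_id: str
    start: int
    sense_strand: str
    guide_strand: str
    dg_sense_end: float | None = None
    dg_guide_end: float | None = None
    asymmetry: float | None = None
    filter_flags: frozenset[str] = field(default_factory=frozenset)

    @property
    def footprint(self) -> tuple[int, int]:
        """Half-open target interval [start, start+23)."""
        return (self.start, self.start + FOOTPRINT_LEN)

    @property
    def core(self) -> str:
        """The 19-bp paired core, top (sense) strand 5'->3'."""
        return self.sense_strand[:CORE_LEN]

    @property
    def passing(self) -> bool:
        return not self.filter_flags


def _candidate_at(target: NucleotideSequence, start: int) -> SirnaCandidate:
    window = target[start : start + FOOTPRINT_LEN]
    return SirnaCandidate(
        target_id=target.id,
        start=start,
        sense_strand=window[2:FOOTPRINT_LEN],
        guide_strand=_revcomp_str(window[0:STRAND_LEN], Alphabet.RNA),
    )


def enumerate_candidates(target: NucleotideSequence) -> list[SirnaCandidate]:
    """All 23-nt-footprint candidates along ``target``, ascending start."""
    if target.alphabet is not Alphabet.RNA:
        raise DesignError(f"target '{target.id}': expected an RNA sequence")
    if target.topology is not Topology.LINEAR:
        raise DesignError(f"target '{target.id}': expected LINEAR topology")
    if len(target) < FOOTPRINT_LEN:
        raise DesignError(
            f"target '{target.id}' too short: {len(target)} nt < {FOOTPRINT_LEN}"
        )
    return [
        _candidate_at(target, s)
        for s in range(len(target) - FOOTPRINT_LEN + 1)
    ]


def end_free_energy(
    duplex_core: str, end: str, window_bp: int, table: NearestNeighborTable
) -> float:
    """Nearest-neighbor dG of one duplex end over a terminal window.

    ``duplex_core`` is the top (sense) strand of a perfectly paired duplex
    read 5'->3'; the bottom strand is implied. The result is the sum of the
    ``window_bp - 1`` stack values over the terminal ``window_bp`` base
    pairs at the named end. No initiation penalty is included: it cancels
    in the asymmetry difference.
    """
    if window_bp < 2:
        raise DesignError("window too small to contain a stack (window_bp >= 2)")
    if window_bp > len(duplex_core):
        raise DesignError(
            f"window_bp {window_bp} exceeds duplex core length {len(duplex_core)}"
        )
    if end == SENSE_5:
        stacks = range(0, window_bp - 1)
    elif end == GUIDE_5:
        stacks = range(len(duplex_core) - window_bp, len(duplex_core) - 1)
    else:
        raise DesignError(f"unknown duplex end {end!r}")
    # fsum: correctly rounded regardless of stack order, so the asymmetry
    # antisymmetry under strand swap holds exactly
    return math.fsum(table.stacks[duplex_core[k : k + 2]] for k in stacks)


def score_asymmetry(
    candidate: SirnaCandidate,
    window_bp: int,
    table: NearestNeighborTable,
) -> SirnaCandidate:
    """Fill end energies and the asymmetry score.

    asymmetry = dG(guide-5' end) - dG(sense-5' end); larger (guide end
    weaker) means preferential guide-strand loading, i.e. more functional.
    """
    core = candidate.core
    dg_sense = end_free_energy(core, SENSE_5, window_bp, table)
    dg_guide = end_free_energy(core, GUIDE_5, window_bp, table)
    return replace(
        candidate,
        dg_sense_end=dg_sense,
        dg_guide_end=dg_guide,
        asymmetry=dg_guide - dg_sense,
    )


def _max_run(s: str) -> int:
    best = run = 1
    for a, b in zip(s, s[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _max_base_run(s: str, base: str) -> int:
    best = run = 0
    for ch in s:
        run = run + 1 if ch == base else 0
        best = max(best, run)
    return best


def apply_filters(candidate: SirnaCandidate, config) -> SirnaCandidate:
    """Flag candidates violating composition rules; passing iff no flags.

    Rules (thresholds from DesignConfig): GC fraction of the 19-bp core in
    [gc_min, gc_max]; no homopolymer run longer than homopolymer_max in
    either strand; no G run longer than g_run_max in either strand.
    """
    flags = set()
    core = candidate.core
    gc = (core.count("G") + core.count("C")) / len(core)
    if not config.gc_min <= gc <= config.gc_max:
        flags.add("gc_out_of_range")
    strands = (candidate.sense_strand, candidate.guide_strand)
    if any(_max_run(s) > config.homopolymer_max for s in strands):
        flags.add("homopolymer")
    if any(_max_base_run(s, "G") > config.g_run_max for s in strands):
        flags.add("g_run")
    return replace(candidate, filter_flags=frozenset(flags))


def select_by_position(
    candidates: list[SirnaCandidate], start: int
) -> SirnaCandidate:
    """The candidate whose footprint begins at ``start``."""
    for cand in candidates:
        if cand.start == start:
            return cand
    valid = (
        f"[0, {max(c.start for c in candidates)}]" if candidates else "(empty)"
    )
    raise DesignError(
        f"position out of range: no candidate starts at {start}; valid range {valid}"
    )


def select_top_nonoverlapping(
    candidates: list[SirnaCandidate], n: int
) -> list[SirnaCandidate]:
    """Greedy selection of up to ``n`` best non-overlapping candidates.

    Passing candidates are ranked by asymmetry descending (ties: smaller
    start first); a candidate is accepted iff its 23-nt footprint is
    disjoint from every previously accepted footprint. Returns fewer than
    ``n`` (with a logged warning) when the target cannot host ``n``
    disjoint footprints.
    """
    if n not in (1, 2, 3):
        raise DesignError(f"unsupported selection count {n}: must be 1, 2 or 3")
    passing = [c for c in candidates if c.passing]
    if not passing:
        raise DesignError("no designable siRNA: every candidate was filtered out")
    if any(c.asymmetry is None for c in passing):
        raise DesignError("candidates must be scored before selection")
    ranked = sorted(passing, key=lambda c: (-c.asymmetry, c.start))
    accepted: list[SirnaCandidate] = []
    for cand in ranked:
        lo, hi = cand.footprint
        if all(hi <= a.footprint[0] or lo >= a.footprint[1] for a in accepted):
            accepted.append(cand)
            if len(accepted) == n:
                break
    if len(accepted) < n:
        logger.warning(
            "only %d of %d requested disjoint siRNAs could be placed",
            len(accepted),
            n,
        )
    return accepted
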