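"""Secondary-structure verification of mshRNA templates.

Two complementary views of a template's fold:

* :func:`designed_fold` writes down the *intended* dumbbell structure
  directly from the template's feature annotations — one 19-bp stem per
  shRNA unit, everything else unpaired — and verifies that every asserted
  pair really is Watson-Crick on the template sequence.

* :func:`max_pairing_fold` is an independent Nussinov-style base-pair
  maximization (no energy model) used to confirm that the designed stems
  are compatible with a maximal non-crossing structure and that nothing in
  the loops or spacers creates longer competing duplexes.

Templates are DNA, so template folding uses Watson-Crick pairs only
(G.T wobble excluded — conservative stem verification); RNA inputs also
admit G.U. Dot-brackets follow Vienna conventions and are reported in the
nick-opened linear coordinates, where the designed pairs are non-crossing.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import lru_cache

from .sequence_io import Alphabet, NucleotideSequence
from .template_design import MshrnaTemplate

__all__ = [
    "Verdict",
    "StructureResult",
    "designed_fold",
    "max_pairing_fold",
    "constrained_max_pairing",
]

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_WC_RNA = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


class Verdict(enum.Enum):
    AS_DESIGNED = "AS_DESIGNED"
    DEVIANT = "DEVIANT"


@dataclass(frozen=True)
class StructureResult:
    """A secondary structure with its pair list and stem decomposition."""

    dotbracket: str
    pair_count: int
    stems: tuple[tuple[tuple[int, int], tuple[int, int]], ...]
    verdict: Verdict | None = None
    pairs: tuple[tuple[int, int], ...] = ()
    mismatches: tuple[tuple[int, int], ...] = ()


def _pair_test(alphabet: Alphabet):
    if alphabet is Alphabet.DNA:
        allowed = _WC
    else:
        allowed = _WC_RNA | _WOBBLE
    return lambda x, y: (x, y) in allowed


def _to_dotbracket(pairs: list[tuple[int, int]], n: int) -> str:
    chars = ["."] * n
    ordered = sorted(pairs)
    stack: list[int] = []
    for i, j in ordered:
        while stack and stack[-1] < i:
            stack.pop()
        if stack and i < stack[-1] < j:
            raise ValueError(f"crossing pairs at ({i}, {j})")
        chars[i] = "("
        chars[j] = ")"
        stack.append(j)
    return "".join(chars)


def _stems(pairs: list[tuple[int, int]]):
    """Group stacked pairs into maximal helices, as half-open interval pairs."""
    remaining = sorted(pairs)
    pairset = set(remaining)
    stems = []
    seen: set[tuple[int, int]] = set()
    for i, j in remaining:
        if (i, j) in seen or (i - 1, j + 1) in pairset:
            continue
        k = 0
        while (i + k, j - k) in pairset:
            seen.add((i + k, j - k))
            k += 1
        stems.append(((i, i + k), (j - k + 1, j + 1)))
    return tuple(stems)


def designed_fold(template: MshrnaTemplate) -> StructureResult:
    """The intended dumbbell fold, asserted from the template's features.

    Each unit contributes 19 stem pairs; all other template positions are
    unpaired. The verdict is AS_DESIGNED iff every asserted pair is
    Watson-Crick on the actual template sequence; otherwise DEVIANT, with
    the offending (circle-coordinate) position pairs reported.
    """
    if not template.features:
        raise ValueError("template has no feature annotations")
    circle = template.circle_sequence.residues
    L = len(circle)
    nick = template.nick_index
    circ_pairs = template.designed_pairs()

    mismatches = [
        (a, b) for a, b in circ_pairs if (circle[a], circle[b]) not in _WC
    ]
    linear_pairs = [
        tuple(sorted(((a - nick) % L, (b - nick) % L))) for a, b in circ_pairs
    ]
    dotbracket = _to_dotbracket(linear_pairs, L)
    return StructureResult(
        dotbracket=dotbracket,
        pair_count=len(linear_pairs),
        stems=_stems(linear_pairs),
        verdict=Verdict.DEVIANT if mismatches else Verdict.AS_DESIGNED,
        pairs=tuple(sorted(linear_pairs)),
        mismatches=tuple(mismatches),
    )


def _nussinov(residues: str, min_loop: int, can_pair) -> list[tuple[int, int]]:
    n = len(residues)
    N = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i + 1][j]
            row_i1 = N[i + 1]
            for k in range(i + min_loop + 1, j + 1):
                if can_pair(i, k):
                    inner = row_i1[k - 1] if k - 1 > i else 0
                    rest = N[k + 1][j] if k + 1 <= j else 0
                    cand = inner + rest + 1
                    if cand > best:
                        best = cand
            N[i][j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        target = N[i][j]
        paired = False
        # tie-break: pairing i preferred over leaving it unpaired,
        # smaller partner index preferred — deterministic traceback
        for k in range(i + min_loop + 1, j + 1):
            if can_pair(i, k):
                inner = N[i + 1][k - 1] if k - 1 > i else 0
                rest = N[k + 1][j] if k + 1 <= j else 0
                if inner + rest + 1 == target:
                    pairs.append((i, k))
                    if k - 1 > i + 1:
                        stack.append((i + 1, k - 1))
                    if k + 1 < j:
                        stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    return pairs


def max_pairing_fold(
    seq: NucleotideSequence, min_loop: int = 3
) -> StructureResult:
    """One base-pair-maximizing non-crossing structure (Nussinov).

    Watson-Crick plus G.U wobble for RNA; Watson-Crick only for DNA.
    Traceback is deterministic (see inline tie-breaks) so the dot-bracket
    is reproducible. Circularized templates are folded at their stored
    (nick) opening.
    """
    residues = seq.residues
    if len(residues) < min_loop + 2:
        raise ValueError(
            f"sequence too short to pair: {len(residues)} < {min_loop + 2}"
        )
    wc = _pair_test(seq.alphabet)
    can_pair = lambda i, j: wc(residues[i], residues[j])
    pairs = _nussinov(residues, min_loop, can_pair)
    return StructureResult(
        dotbracket=_to_dotbracket(pairs, len(residues)),
        pair_count=len(pairs),
        stems=_stems(pairs),
        verdict=None,
        pairs=tuple(sorted(pairs)),
    )


def constrained_max_pairing(
    seq: NucleotideSequence,
    forced_pairs: list[tuple[int, int]],
    min_loop: int = 3,
) -> StructureResult:
    """Pair maximization with a set of designed pairs reserved.

    Positions belonging to ``forced_pairs`` may only pair with their
    designated partner; free positions pair as usual. Because each forced
    pair is individually optimal for its two positions and the forced set
    is non-crossing, every maximal structure under this constraint
    contains all forced pairs — this is the re-fold used to confirm that
    a template's designed stems coexist in one maximal structure.
    """
    residues = seq.residues
    wc = _pair_test(seq.alphabet)
    partner = {}
    for a, b in forced_pairs:
        partner[a] = b
        partner[b] = a

    def can_pair(i: int, j: int) -> bool:
        if i in partner or j in partner:
            return partner.get(i) == j
        return wc(residues[i], residues[j])

    pairs = _nussinov(residues, min_loop, can_pair)
    return StructureResult(
        dotbracket=_to_dotbracket(pairs, len(residues)),
        pair_count=len(pairs),
        stems=_stems(pairs),
        verdict=None,
        pairs=tuple(sorted(pairs)),
    )
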