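"""Nearest-neighbor free-energy parameters for RNA:RNA duplexes.

The duplex model treats hybridization of two strands (miRNA vs. target
window) as a chain of base pairs read 5'->3' along the query strand and
3'->5' along the target, scored with the Turner 2004 nearest-neighbor
parameterization at 37 degC:

    dG = initiation + sum(stack or loop terms) + terminal AU/GU penalties

Stacked adjacent pairs contribute tabulated doublet free energies; gaps
between consecutive pairs are scored as bulges (one strand) or internal
loops (both strands) with length-dependent initiation plus a Ninio-style
asymmetry term. No intramolecular structure, no multibranch loops.

All energies are kcal/mol; negative is stabilizing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

INF = math.inf

#: Base pairs allowed in a helix (query base, target base). G:U wobble allowed.
CANONICAL_PAIRS = frozenset(
    {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}
)

#: Pairs incurring the terminal helix-end penalty (everything but G:C).
_WEAK_END = frozenset({("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")})

# Stacking free energies dG37 (kcal/mol), Turner 2004, stated as
# (top dinucleotide, bottom dinucleotide): a doublet 5'-X1X2-3'/3'-Y1Y2-5'
# where the top strand is the query 5'->3' and the bottom the antiparallel
# target.  Watson-Crick entries are the exact published values; wobble
# entries are the published table at 0.1 kcal/mol precision.
_WOBBLE_DOUBLETS = {
    ("CU", "GG"): -2.10,
    ("CG", "GU"): -1.40,
    ("GU", "CG"): -2.50,
    ("GG", "CU"): -1.50,
    ("GG", "UC"): -2.10,
    ("GC", "UG"): -2.50,
    ("GU", "UG"): +1.30,
    ("GG", "UU"): -0.50,
    ("GU", "UA"): -1.40,
    ("GA", "UU"): -1.30,
    ("UG", "GC"): -1.40,
    ("UC", "GG"): -1.50,
    ("UU", "GG"): -0.50,
    ("UG", "GU"): +0.30,
    ("UU", "GA"): -0.60,
    ("UA", "GU"): -1.00,
    ("AU", "UG"): -1.40,
    ("AG", "UU"): -0.60,
    ("UU", "AG"): -1.30,
    ("UG", "AU"): -1.00,
}

_WC_DOUBLETS = {
    ("AA", "UU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("CU", "GA"): -2.08,
    ("CA", "GU"): -2.11,
    ("GU", "CA"): -2.24,
    ("GA", "CU"): -2.35,
    ("CG", "GC"): -2.36,
    ("GG", "CC"): -3.26,
    ("GC", "CG"): -3.42,
}


def _build_stack_table() -> dict:
    """Expand (top dinuc, bottom dinuc) doublets into pair-keyed entries.

    Each doublet 5'-X1X2-3'/3'-Y1Y2-5' yields key ((X1,Y1),(X2,Y2)); the
    same physical stack read from the other strand yields ((Y2,X2),(Y1,X1)),
    so the table is closed under that symmetry.
    """
    table: dict = {}
    for (top, bottom), dg in {**_WC_DOUBLETS, **_WOBBLE_DOUBLETS}.items():
        p1 = (top[0], bottom[0])
        p2 = (top[1], bottom[1])
        table[(p1, p2)] = dg
        # symmetric reading from the complementary strand
        table[((p2[1], p2[0]), (p1[1], p1[0]))] = dg
    return table


#: Bulge-loop initiation dG37 by length 1..15 (kcal/mol), Turner 2004.
_BULGE = (
    INF,
    3.8, 2.8, 3.2, 3.6, 4.0, 4.4, 4.6, 4.7, 4.8, 4.9,
    5.0, 5.1, 5.2, 5.3, 5.4,
)

#: Internal-loop initiation dG37 by total length 2..30 (kcal/mol).
#: Sizes 2-3 use the small-loop value (the model applies the generic
#: initiation to 1x1 and 2x1 loops rather than special mismatch tables).
_INTERNAL = (
    INF, INF,
    1.0, 1.0, 1.1, 2.0, 2.0, 2.1, 2.3, 2.4, 2.5,
    2.6, 2.7, 2.8, 2.9, 2.9, 3.0, 3.1, 3.1, 3.2, 3.3,
    3.3, 3.4, 3.4, 3.5, 3.5, 3.5, 3.6, 3.6, 3.7, 3.7,
)


@dataclass(frozen=True)
class EnergyTable:
    """Nearest-neighbor duplex energy parameters (kcal/mol, 37 degC)."""

    stack: Mapping[tuple, float] = field(default_factory=_build_stack_table)
    bulge: tuple = _BULGE
    internal: tuple = _INTERNAL
    asym_per_nt: float = 0.6
    asym_max: float = 3.0
    init: float = 4.09
    terminal_penalty: float = 0.45
    max_loop: int = 15

    def __post_init__(self) -> None:
        for p1 in CANONICAL_PAIRS:
            for p2 in CANONICAL_PAIRS:
                if (p1, p2) not in self.stack:
                    raise ValueError(f"missing stack entry {(p1, p2)}")
        wc = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
        for p1 in wc:
            for p2 in wc:
                if self.stack[(p1, p2)] >= 0:
                    raise ValueError(f"WC/WC stack {(p1, p2)} must be < 0")
        if any(v < 0 for v in self.bulge[1:]) or any(
            v < 0 for v in self.internal[2:]
        ):
            raise ValueError("loop penalties must be >= 0")

    def can_pair(self, x: str, y: str) -> bool:
        return (x, y) in CANONICAL_PAIRS

    def end_penalty(self, pair: tuple) -> float:
        """Helix-end penalty: applied at each terminal AU or GU pair."""
        return self.terminal_penalty if pair in _WEAK_END else 0.0

    def gap_energy(self, lx: int, ly: int, pair1: tuple, pair2: tuple) -> float:
        """Energy of the junction between two consecutive base pairs.

        ``lx``/``ly`` are the unpaired nucleotide counts between the pairs
        on the query and target strands.  (0, 0) is a stack; one-sided gaps
        are bulges; two-sided gaps are internal loops with an asymmetry
        term.  Gaps longer than ``max_loop`` on either side are forbidden.
        """
        if lx < 0 or ly < 0 or lx > self.max_loop or ly > self.max_loop:
            return INF
        if lx == 0 and ly == 0:
            return self.stack[(pair1, pair2)]
        if lx == 0 or ly == 0:
            return self.bulge[lx + ly]
        size = lx + ly
        asym = min(self.asym_max, self.asym_per_nt * abs(lx - ly))
        return self.internal[size] + asym


def default_table() -> EnergyTable:
    """The packaged Turner 2004 parameter set."""
    return EnergyTable()
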