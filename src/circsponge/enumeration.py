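"""Exhaustive reference evaluation of duplex free energies.

Enumerates every legal intermolecular duplex structure for a (query,
window) pair — all chains of canonical base pairs, monotone on both
strands, with inter-pair gaps bounded by the energy table's loop limit —
and scores each with the same nearest-neighbor rules as
:func:`circsponge.hybrid.duplex_mfe`.  Being a direct enumeration rather
than a dynamic program, it serves as an independent oracle for the DP on
small inputs; it is exponential and only usable for sequences of roughly
ten nucleotides each.
"""

from __future__ import annotations

from typing import Optional

from .energy import EnergyTable, INF, default_table


def enumerate_duplex_mfe(
    query: str, window: str, table: Optional[EnergyTable] = None
) -> Optional[float]:
    """Minimum dG over all duplex structures, by explicit enumeration.

    Returns ``None`` when no canonical pair exists (the "no duplex"
    sentinel).  Sequences are plain RNA strings (A/C/G/U, uppercase).
    """
    table = table or default_table()
    x = query
    y = window[::-1]  # antiparallel orientation, as in the DP
    M, N = len(x), len(y)
    pairable = [
        (i, j)
        for i in range(M)
        for j in range(N)
        if table.can_pair(x[i], y[j])
    ]
    if not pairable:
        return None

    span = table.max_loop + 1
    best = INF

    def extend(i: int, j: int, energy: float) -> None:
        """Recursively grow the chain whose current 3'-most pair is (i, j)."""
        nonlocal best
        closed = energy + table.end_penalty((x[i], y[j]))
        if closed < best:
            best = closed
        for i2 in range(i + 1, min(M, i + 1 + span)):
            for j2 in range(j + 1, min(N, j + 1 + span)):
                if not table.can_pair(x[i2], y[j2]):
                    continue
                gap = table.gap_energy(
                    i2 - i - 1, j2 - j - 1, (x[i], y[j]), (x[i2], y[j2])
                )
                if gap == INF:
                    continue
                extend(i2, j2, energy + gap)

    for i, j in pairable:
        opening = table.init + table.end_penalty((x[i], y[j]))
        extend(i, j, opening)
    return best
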