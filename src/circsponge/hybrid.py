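"""miRNA binding-site discovery on circRNA sequences.

The scan follows the logic used for circRNA "sponge" candidate screening:
candidate sites are anchored by a Watson-Crick seed match (miRNA positions
2-8), each candidate is scored by the minimum free energy of the
intermolecular RNA:RNA duplex formed between the miRNA and a bounded
target window (nearest-neighbor model, no intramolecular structure), and
sites are retained when the duplex energy falls below a threshold —
-20 kcal/mol by default, the cutoff used to count circRNA-miRNA bindings.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional, Sequence

from .energy import EnergyTable, INF, default_table

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_ALPHABET = frozenset("ACGU")


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA string (Watson-Crick, U<->A)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RnaSeq:
    """A named RNA sequence with optional genomic locus and conserved regions.

    ``seq`` is normalized to uppercase RNA (T -> U) and validated against
    {A, C, G, U}.  ``conserved`` holds non-overlapping (start, end)
    sub-intervals, 0-based half-open, e.g. the conserved portions of a
    circRNA within which binding sites are scanned.
    """

    id: str
    seq: str
    locus: Optional[tuple] = None  # (chrom, start, end, strand)
    conserved: Optional[tuple] = None

    def __post_init__(self) -> None:
        norm = self.seq.upper().replace("T", "U")
        object.__setattr__(self, "seq", norm)
        if not norm:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(norm) - _ALPHABET
        if bad:
            raise ValueError(f"{self.id}: non-RNA characters {sorted(bad)}")
        if self.conserved is not None:
            iv = tuple(tuple(x) for x in self.conserved)
            object.__setattr__(self, "conserved", iv)
            prev_end = -1
            for start, end in sorted(iv):
                if not (0 <= start < end <= len(norm)):
                    raise ValueError(
                        f"{self.id}: conserved interval ({start},{end}) out of bounds"
                    )
                if start < prev_end:
                    raise ValueError(f"{self.id}: overlapping conserved intervals")
                prev_end = end

    def __len__(self) -> int:
        return len(self.seq)


class SeedClass(str, Enum):
    """Canonical seed-match tiers (most to least specific)."""

    seed7_m8 = "seed7_m8"  # WC match to miRNA positions 2-8
    seed7_A1 = "seed7_A1"  # WC match to 2-7 plus target A opposite position 1
    seed6 = "seed6"        # WC match to positions 2-7
    none = "none"


@dataclass(frozen=True)
class SeedMatch:
    """A candidate site anchor: target position paired with miRNA position 2.

    ``anchor`` is the 0-based target index of the base pairing the second
    miRNA nucleotide (the 3'-most seed-paired target base).
    """

    anchor: int
    seed_class: SeedClass


@dataclass
class DuplexResult:
    """Minimum-free-energy intermolecular duplex for one (miRNA, window)."""

    dG: float
    pairing_string: str
    pairs: tuple  # ((mirna_idx, window_idx), ...) window idx 5'->3'
    mirna_span: tuple  # (start, end) paired region on the miRNA
    target_span: tuple  # (start, end) paired region on the window


@dataclass
class DuplexHit:
    """One retained miRNA binding site on a target RNA."""

    mirna_id: str
    target_id: str
    target_offset: int  # target position paired with the miRNA 3'-most paired base
    seed_class: SeedClass
    dG: float
    pairing_string: str
    target_span: tuple = (0, 0)
    ago_supported: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.dG > 0:
            raise ValueError("a reported hit must have dG <= 0")


def find_seed_matches(mirna: RnaSeq, target: RnaSeq) -> list[SeedMatch]:
    """Locate canonical seed matches of ``mirna`` on ``target``.

    Seeds are strict Watson-Crick (G:U does not count).  Matches are
    reported at the most specific tier: 7mer-m8 (positions 2-8), 7mer-A1
    (positions 2-7 with an A opposite position 1), then 6mer (2-7).
    """
    m = mirna.seq
    if len(m) < 8:
        raise ValueError(f"miRNA {mirna.id} shorter than 8 nt")
    t = target.seq
    site6 = revcomp(m[1:7])  # pairs target[s..s+6): target[s+5] pairs m[1]
    m8_partner = m[7].translate(_COMPLEMENT)  # target base pairing miRNA nt 8
    matches: dict[int, SeedClass] = {}
    start = 0
    while (s := t.find(site6, start)) != -1:
        anchor = s + 5
        if s >= 1 and t[s - 1] == m8_partner:
            matches[anchor] = SeedClass.seed7_m8
        elif s + 6 < len(t) and t[s + 6] == "A":
            matches[anchor] = SeedClass.seed7_A1
        else:
            matches[anchor] = SeedClass.seed6
        start = s + 1
    return [SeedMatch(a, c) for a, c in sorted(matches.items())]


def duplex_mfe(
    mirna: RnaSeq | str,
    window: RnaSeq | str,
    table: Optional[EnergyTable] = None,
    max_window: int = 40,
) -> Optional[DuplexResult]:
    """Minimum free energy of the intermolecular duplex miRNA:window.

    Dynamic program over all duplex secondary structures made of stacked
    pairs, bulges and internal loops (both sides bounded by
    ``table.max_loop``), no multibranch, no intramolecular pairs — the
    model class of hybridization tools such as RNAhybrid.  Returns ``None``
    ("no duplex") when the two sequences admit no canonical base pair.
    """
    table = table or default_table()
    x = mirna.seq if isinstance(mirna, RnaSeq) else RnaSeq("q", mirna).seq
    w = window.seq if isinstance(window, RnaSeq) else RnaSeq("t", window).seq
    if len(w) > max_window:
        raise ValueError(
            f"window of {len(w)} nt exceeds max {max_window}; use scan_sites "
            "to tile long targets"
        )
    y = w[::-1]  # antiparallel: walk both strands 5'->3' on x, 3'->5' on w
    M, N = len(x), len(y)
    span = table.max_loop + 1

    # E[i][j]: best energy of a duplex whose 3'-most pair is (x_i, y_j),
    # including initiation and the penalty of its opening terminal pair.
    E = [[INF] * N for _ in range(M)]
    back: list[list[Optional[tuple]]] = [[None] * N for _ in range(M)]
    for i in range(M):
        for j in range(N):
            pair = (x[i], y[j])
            if not table.can_pair(*pair):
                continue
            best = table.init + table.end_penalty(pair)
            origin = None
            for i0 in range(max(0, i - span), i):
                row = E[i0]
                for j0 in range(max(0, j - span), j):
                    e0 = row[j0]
                    if e0 == INF:
                        continue
                    gap = table.gap_energy(
                        i - i0 - 1, j - j0 - 1, (x[i0], y[j0]), pair
                    )
                    if e0 + gap < best:
                        best = e0 + gap
                        origin = (i0, j0)
            E[i][j] = best
            back[i][j] = origin

    best_dg = INF
    best_end = None
    for i in range(M):
        for j in range(N):
            if E[i][j] == INF:
                continue
            total = E[i][j] + table.end_penalty((x[i], y[j]))
            if total < best_dg:
                best_dg = total
                best_end = (i, j)
    if best_end is None:
        return None

    pairs_rev = []
    node: Optional[tuple] = best_end
    while node is not None:
        pairs_rev.append(node)
        node = back[node[0]][node[1]]
    pairs_y = pairs_rev[::-1]
    # convert y (reversed-window) indices back to window 5'->3' coordinates
    pairs = tuple((i, N - 1 - j) for i, j in pairs_y)

    x_marks = ["."] * M
    w_marks = ["."] * len(w)
    for i, jw in pairs:
        x_marks[i] = "("
        w_marks[jw] = ")"
    mi = [p[0] for p in pairs]
    wi = [p[1] for p in pairs]
    return DuplexResult(
        dG=best_dg,
        pairing_string="".join(x_marks) + "&" + "".join(w_marks),
        pairs=pairs,
        mirna_span=(min(mi), max(mi) + 1),
        target_span=(min(wi), max(wi) + 1),
    )


def scan_sites(
    mirna: RnaSeq,
    circ: RnaSeq,
    table: Optional[EnergyTable] = None,
    dg_threshold: float = -20.0,
    window_upstream: int = 15,
    max_window: int = 40,
) -> list[DuplexHit]:
    """Scan a circRNA for energetically favorable miRNA binding sites.

    Restricted to the circRNA's conserved intervals when present.  Each
    seed match anchors a window of miRNA length + ``window_upstream`` nt
    extending toward the target 5' side (where the miRNA 3' region pairs);
    the window duplex MFE is computed and sites with dG strictly below
    ``dg_threshold`` are retained.  Overlapping sites are resolved
    greedily, keeping the lowest-dG site first; the result is sorted by
    ascending dG.
    """
    table = table or default_table()
    regions = list(circ.conserved) if circ.conserved else [(0, len(circ))]
    win_len = len(mirna) + window_upstream

    candidates = []
    for rstart, rend in regions:
        sub = RnaSeq(circ.id, circ.seq[rstart:rend])
        for match in find_seed_matches(mirna, sub):
            # include the position opposite miRNA nt 1 (3' of the anchor)
            wend = min(rend - rstart, match.anchor + 2)
            wstart = max(0, wend - win_len)
            res = duplex_mfe(mirna, sub.seq[wstart:wend], table, max_window)
            if res is None or res.dG >= dg_threshold:
                continue
            span = (rstart + wstart + res.target_span[0],
                    rstart + wstart + res.target_span[1])
            candidates.append(
                DuplexHit(
                    mirna_id=mirna.id,
                    target_id=circ.id,
                    target_offset=span[0],
                    seed_class=match.seed_class,
                    dG=res.dG,
                    pairing_string=res.pairing_string,
                    target_span=span,
                )
            )

    kept: list[DuplexHit] = []
    for hit in sorted(candidates, key=lambda h: (h.dG, h.target_offset)):
        if all(
            hit.target_span[1] <= k.target_span[0]
            or hit.target_span[0] >= k.target_span[1]
            for k in kept
        ):
            kept.append(hit)
    return kept


def annotate_ago_support(
    hits: Sequence[DuplexHit], intervals: Iterable[tuple]
) -> list[DuplexHit]:
    """Flag hits whose site overlaps any AGO-occupancy interval.

    ``intervals`` are (start, end) 0-based half-open on the same target
    coordinates as the hits (e.g. from a PAR-CLIP-derived BED track).
    """
    ivs = [(int(s), int(e)) for s, e in intervals]
    for hit in hits:
        s, e = hit.target_span
        hit.ago_supported = any(s < ie and is_ < e for is_, ie in ivs)
    return list(hits)
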