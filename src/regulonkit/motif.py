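"""Degenerate-consensus motif representation and strand-aware scanning.

The binding sequence studied here is a degenerate consensus written over an
extended nucleotide alphabet (``w`` = A/T, ``n`` = any base; the full IUPAC
code is accepted). Matching is position-wise set membership — no weight
matrix — so a window's score is simply the number of consensus positions it
satisfies, out of the motif length.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio.Seq import reverse_complement as _bio_revcomp

#: Degenerate consensus binding sequence for the carbon-starvation master
#: regulator studied here (a 22-bp palindrome; w = A/T, n = any).
DEFAULT_CONSENSUS = "wwwTATGTTnTAnAACATAwww"

#: Number of consensus positions matched by the one binding site with direct
#: experimental support; used as the default reporting cutoff. The consensus
#: itself comes with no numeric mismatch tolerance, so genome-wide site
#: counts depend on this choice.
DEFAULT_MIN_MATCHES = 17

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def reverse_complement(seq: str) -> str:
    """Reverse complement over the IUPAC alphabet (w↔w, n↔n, r↔y, ...)."""
    bad = set(seq.upper()) - set(IUPAC_SETS)
    if bad:
        raise ValueError(f"cannot complement symbols {sorted(bad)}")
    return _bio_revcomp(seq)


@dataclass(frozen=True)
class MotifConsensus:
    """A degenerate consensus pattern over the IUPAC alphabet."""

    symbols: str

    def __post_init__(self) -> None:
        if len(self.symbols) == 0:
            raise ValueError("empty consensus")
        bad = set(self.symbols.upper()) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"unknown consensus symbols {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return self.symbols

    def base_sets(self) -> list[frozenset[str]]:
        """Allowed base set at each position."""
        return [IUPAC_SETS[s] for s in self.symbols.upper()]

    @cached_property
    def _allowed(self) -> np.ndarray:
        """Boolean (length × 4) lookup: position i allows base j (ACGT)."""
        table = np.zeros((len(self.symbols), 4), dtype=bool)
        for i, allowed in enumerate(self.base_sets()):
            for base in allowed:
                table[i, _BASE_INDEX[base]] = True
        return table

    @cached_property
    def is_palindromic(self) -> bool:
        """True iff the pattern equals its own reverse complement symbol-wise."""
        return self.symbols.upper() == reverse_complement(self.symbols).upper()


@dataclass(frozen=True)
class MotifHit:
    """One scanned window, reported on forward-strand coordinates.

    ``position`` is the 0-based forward-strand start of the window
    regardless of ``strand``; a palindromic consensus therefore yields
    coincident +/− hits (mirror pairs) at every site.
    """

    position: int
    strand: str
    match_count: int
    window: str
    is_mirror: bool = False


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.full(256, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[ord(base)] = idx
    encoded = codes[arr]
    if (encoded < 0).any():
        bad = sorted({seq[i] for i in np.nonzero(encoded < 0)[0][:5]})
        raise ValueError(f"sequence contains non-ACGT symbols {bad}")
    return encoded


def match_count(consensus: MotifConsensus | str, window: str) -> int:
    """Number of positions at which ``window`` satisfies the consensus.

    Raises on length mismatch or non-ACGT window symbols.
    """
    if isinstance(consensus, str):
        consensus = MotifConsensus(consensus)
    if len(window) != len(consensus):
        raise ValueError(
            f"window length {len(window)} != consensus length {len(consensus)}"
        )
    encoded = _encode(window)
    return int(consensus._allowed[np.arange(len(consensus)), encoded].sum())


def is_palindromic(consensus: MotifConsensus | str) -> bool:
    """True iff the consensus is its own reverse complement."""
    if isinstance(consensus, str):
        consensus = MotifConsensus(consensus)
    return consensus.is_palindromic


def _window_counts(encoded: np.ndarray, consensus: MotifConsensus) -> np.ndarray:
    """match_count for every window start, vectorized over the sequence."""
    k = len(consensus)
    n_windows = len(encoded) - k + 1
    counts = np.zeros(n_windows, dtype=np.int32)
    allowed = consensus._allowed
    for j in range(k):
        counts += allowed[j, encoded[j : j + n_windows]]
    return counts


def scan(
    sequence: str,
    consensus: MotifConsensus | str,
    min_matches: int = DEFAULT_MIN_MATCHES,
    dedupe_mirrors: bool = False,
) -> list[MotifHit]:
    """Scan both strands for windows matching ≥ ``min_matches`` positions.

    Minus-strand windows are scored against the reverse-complemented
    consensus and reported at their forward-strand start, so hits sort by
    position then strand. For a palindromic consensus every site appears as
    a coincident +/− mirror pair, flagged ``is_mirror`` on the − member;
    ``dedupe_mirrors`` keeps only the + member of each such pair.
    """
    if isinstance(consensus, str):
        consensus = MotifConsensus(consensus)
    if min_matches > len(consensus):
        raise ValueError("min_matches exceeds consensus length")
    k = len(consensus)
    if len(sequence) < k:
        return []
    encoded = _encode(sequence)
    fwd = _window_counts(encoded, consensus)
    rc = MotifConsensus(reverse_complement(consensus.symbols))
    rev = _window_counts(encoded, rc)

    hits: list[MotifHit] = []
    for pos in np.nonzero((fwd >= min_matches) | (rev >= min_matches))[0]:
        pos = int(pos)
        window = sequence[pos : pos + k].upper()
        plus = int(fwd[pos]) >= min_matches
        minus = int(rev[pos]) >= min_matches
        if plus:
            hits.append(MotifHit(pos, "+", int(fwd[pos]), window))
        if minus:
            mirror = plus and int(fwd[pos]) == int(rev[pos])
            if not (dedupe_mirrors and mirror):
                hits.append(MotifHit(pos, "-", int(rev[pos]), window, is_mirror=mirror))
    return hits


def write_hits_bed(
    hits: Iterable[MotifHit], contig: str, motif_length: int, path: str | Path
) -> None:
    """Write hits as BED6 (name and score both carry the match count)."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        contig, str(h.position), str(h.position + motif_length),
                        str(h.match_count), str(h.match_count), h.strand,
                    ]
                )
                + "\n"
            )
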