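"""Physicochemical chaos-game encoding of nucleotide sequences.

A sequence is re-alphabeted three ways, by ring structure (purine R = {A,G}
vs pyrimidine Y = {C,T}), by functional group (amino M = {A,C} vs keto
K = {G,T}) and by hydrogen-bond strength (strong S = {C,G} vs weak
W = {A,T}).  Each binary string then drives a one-dimensional chaos game on
the integer interval [1, 2**k]: starting from the midpoint 2**(k-1), every
symbol moves the walker halfway toward one endpoint,

    ind_j = ceil((ind_{j-1} + a) / 2),   a = 0 for the low symbol,
                                         a = 2**k for the high symbol,

and the landed cell is incremented.  Once k symbols have been consumed the
walker's position is a bijective function of the last k binary symbols
(most recent symbol = most significant bit), so the three 2**k-cell count
vectors are grouped k-mer spectra: each cell sums the counts of the 2**k
nucleotide k-mers sharing one binary image.  The concatenated feature
vector has 3 * 2**k entries instead of the 4**k of a classical k-mer /
FCGR profile.

Two counting modes are exposed.  ``all_positions`` increments at every
position j = 1..len(s), matching the published flowchart, and therefore
includes the first k-1 partial-prefix landings; ``kmer_only`` increments
only once a full window of k symbols is in scope, giving exact k-mer
counts (sum = len(s) - k + 1 on a clean sequence).  Characters outside
A/C/G/T split the sequence: the walk restarts from the midpoint after the
break, as a k-mer counter would.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "GroupingScheme",
    "SCHEMES",
    "SCHEME_NAMES",
    "BREAK_SYMBOL",
    "WalkState",
    "PCmerProfile",
    "FCGRProfile",
    "transform_sequence",
    "cgr_step",
    "encode_pcmer",
    "encode_fcgr",
    "group_collapse",
    "brute_force_binary_kmer_counts",
    "pcmer_feature_count",
    "fcgr_feature_count",
    "MAX_K_PCMER",
    "MAX_K_FCGR",
]

Mode = Literal["all_positions", "kmer_only"]

#: largest supported k for the 3 * 2**k encoding (vector still fits in RAM)
MAX_K_PCMER = 24
#: largest supported k for the dense 4**k baseline profile
MAX_K_FCGR = 12

#: sentinel emitted by :func:`transform_sequence` for non-ACGT characters
BREAK_SYMBOL = "#"

_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class GroupingScheme:
    """One binary re-alphabeting of the nucleotides.

    ``low_symbol`` is the endpoint mapped to 0 in the chaos-game update,
    ``high_symbol`` the endpoint mapped to 2**k.  ``nucleotide_map`` sends
    each of A/C/G/T to one of the two symbols.
    """

    name: str
    low_symbol: str
    high_symbol: str
    nucleotide_map: dict[str, str]

    def __post_init__(self) -> None:
        lows = [b for b, s in self.nucleotide_map.items() if s == self.low_symbol]
        highs = [b for b, s in self.nucleotide_map.items() if s == self.high_symbol]
        if sorted(lows + highs) != list(_BASES) or len(lows) != 2:
            raise ValueError(f"scheme {self.name!r} must split ACGT into two pairs")

    @property
    def high_bits(self) -> np.ndarray:
        """Per-base indicator (A,C,G,T order) of mapping to the high endpoint."""
        return np.array(
            [self.nucleotide_map[b] == self.high_symbol for b in _BASES],
            dtype=np.int64,
        )


#: the three physicochemical groupings, in the fixed serialization order
SCHEMES: tuple[GroupingScheme, ...] = (
    GroupingScheme(
        "purine_pyrimidine", "R", "Y", {"A": "R", "G": "R", "C": "Y", "T": "Y"}
    ),
    GroupingScheme("amino_keto", "M", "K", {"A": "M", "C": "M", "G": "K", "T": "K"}),
    GroupingScheme("weak_strong", "S", "W", {"C": "S", "G": "S", "A": "W", "T": "W"}),
)

SCHEME_NAMES: tuple[str, ...] = tuple(s.name for s in SCHEMES)


@dataclass(frozen=True)
class WalkState:
    """Position of the 1-D chaos-game walker: ``index`` in [1, 2**k]."""

    index: int
    k: int

    def __post_init__(self) -> None:
        if not 1 <= self.index <= (1 << self.k):
            raise ValueError(f"index {self.index} outside [1, {1 << self.k}]")

    @classmethod
    def initial(cls, k: int) -> "WalkState":
        return cls(index=1 << (k - 1), k=k)


def cgr_step(state: WalkState, endpoint: int) -> WalkState:
    """One chaos-game update: move halfway toward ``endpoint``, rounding up.

    ``endpoint`` must be 0 (low symbol) or 2**k (high symbol); the result
    stays in [1, 2**k].
    """
    if endpoint not in (0, 1 << state.k):
        raise ValueError(f"endpoint must be 0 or {1 << state.k}, got {endpoint}")
    return replace(state, index=math.ceil((state.index + endpoint) / 2))


@dataclass
class PCmerProfile:
    """Three 2**k count vectors for one sequence, in scheme order.

    ``counts[i][c]`` is the count of chaos-game cell ``c + 1`` (cells are
    1-based in the recurrence) for scheme ``SCHEMES[i]``.  Each vector sums
    to ``positions_counted``.
    """

    k: int
    counts: tuple[np.ndarray, np.ndarray, np.ndarray]
    positions_counted: int
    mode: Mode
    normalized: bool = False

    def concat(self) -> np.ndarray:
        """The 3 * 2**k feature vector in fixed block order."""
        return np.concatenate(self.counts)

    def normalize(self) -> "PCmerProfile":
        """Frequency form: each vector divided by ``positions_counted``."""
        if self.normalized:
            return self
        denom = max(self.positions_counted, 1)
        return PCmerProfile(
            k=self.k,
            counts=tuple(c / denom for c in self.counts),  # type: ignore[arg-type]
            positions_counted=self.positions_counted,
            mode=self.mode,
            normalized=True,
        )


@dataclass
class FCGRProfile:
    """Classical 4**k k-mer spectrum (the four-letter chaos game baseline).

    Cell ``x`` holds the count of the k-mer whose 0-based offset-p character
    has base code ``(x >> 2p) & 3`` with A=0, C=1, G=2, T=3 — i.e. the most
    recent character occupies the most significant base-4 digit, mirroring
    the binary encoding.
    """

    k: int
    counts: np.ndarray
    positions_counted: int
    mode: Mode

    def kmer_index(self, kmer: str) -> int:
        """Cell index of a nucleotide k-mer (documents the bijection)."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got {kmer!r}")
        return sum(_BASE_CODE[ch] << (2 * p) for p, ch in enumerate(kmer.upper()))


def pcmer_feature_count(k: int) -> int:
    """Length of the concatenated physicochemical profile: 3 * 2**k."""
    _check_k(k, MAX_K_PCMER)
    return 3 * (1 << k)


def fcgr_feature_count(k: int) -> int:
    """Length of the classical k-mer spectrum: 4**k."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return 4**k


def _check_k(k: int, maximum: int) -> None:
    if not 1 <= k <= maximum:
        raise ValueError(f"k must be in [1, {maximum}], got {k}")


def transform_sequence(residues: str, scheme: GroupingScheme) -> str:
    """Re-alphabet a normalized (upper-case, U→T) sequence under one scheme.

    Ambiguity codes and any other non-ACGT character become
    :data:`BREAK_SYMBOL`, which downstream encoders treat as a segment
    boundary.
    """
    table = {ord(b): scheme.nucleotide_map[b] for b in _BASES}
    return "".join(
        ch if ch in (scheme.low_symbol, scheme.high_symbol) else BREAK_SYMBOL
        for ch in residues.translate(table)
    )


def _codes(residues: str) -> np.ndarray:
    """A=0, C=1, G=2, T=3; anything else (ambiguity codes) = -1."""
    raw = np.frombuffer(residues.encode("ascii", errors="replace"), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int64)
    for b, c in _BASE_CODE.items():
        lut[ord(b)] = c
    return lut[raw]


def _segments(codes: np.ndarray) -> list[np.ndarray]:
    """Maximal runs of valid (non-negative) codes."""
    valid = codes >= 0
    if not valid.any():
        return []
    edges = np.flatnonzero(np.diff(valid.astype(np.int8)))
    bounds = np.concatenate(([0], edges + 1, [len(codes)]))
    return [
        codes[a:b] for a, b in zip(bounds[:-1], bounds[1:]) if b > a and valid[a]
    ]


def _walk_cells(bits: np.ndarray, k: int) -> np.ndarray:
    """0-based cell index landed on at each position of one clean segment.

    Implements the recurrence ind_j = ceil((ind_{j-1} + a)/2) in shifted
    form: with x = ind - 1 the update is x' = (x >> 1) | (bit << (k-1)),
    so the first min(n, k-1) positions still carry bits of the midpoint
    start x0 = 2**(k-1) - 1 and are computed by the loop; from position
    k-1 on, the index is exactly the window value sum_p bits[j-k+1+p]*2**p.
    """
    n = len(bits)
    out = np.empty(n, dtype=np.int64)
    x = (1 << (k - 1)) - 1
    for j in range(min(n, k - 1)):
        x = (x >> 1) | (int(bits[j]) << (k - 1))
        out[j] = x
    if n >= k:
        weights = 1 << np.arange(k, dtype=np.int64)
        out[k - 1 :] = sliding_window_view(bits, k) @ weights
    return out


def encode_pcmer(
    residues: str, k: int, mode: Mode = "all_positions"
) -> PCmerProfile:
    """Encode one sequence into its three 2**k chaos-game count vectors.

    The three schemes are walked concurrently over a single pass.  In
    ``all_positions`` mode every non-break position contributes a count; in
    ``kmer_only`` mode only positions with a full k-window inside the
    current unbroken segment contribute, so each vector sums to the exact
    number of valid k-mers.
    """
    _check_k(k, MAX_K_PCMER)
    if not residues:
        raise ValueError("cannot encode an empty sequence")
    if mode not in ("all_positions", "kmer_only"):
        raise ValueError(f"unknown mode {mode!r}")

    size = 1 << k
    counts = [np.zeros(size, dtype=np.int64) for _ in SCHEMES]
    positions = 0
    for seg in _segments(_codes(residues)):
        start = k - 1 if mode == "kmer_only" else 0
        if len(seg) <= start:
            continue
        for i, scheme in enumerate(SCHEMES):
            cells = _walk_cells(scheme.high_bits[seg], k)[start:]
            counts[i] += np.bincount(cells, minlength=size)
        positions += len(seg) - start
    return PCmerProfile(
        k=k,
        counts=tuple(counts),  # type: ignore[arg-type]
        positions_counted=positions,
        mode=mode,
    )


def _walk_cells_quaternary(codes: np.ndarray, k: int) -> np.ndarray:
    """Four-letter analogue of :func:`_walk_cells` with 2-bit digits."""
    n = len(codes)
    out = np.empty(n, dtype=np.int64)
    x = (4**k >> 1) - 1  # midpoint start, as in the binary walk
    for j in range(min(n, k - 1)):
        x = (x >> 2) | (int(codes[j]) << (2 * (k - 1)))
        out[j] = x
    if n >= k:
        weights = 1 << (2 * np.arange(k, dtype=np.int64))
        out[k - 1 :] = sliding_window_view(codes, k) @ weights
    return out


def encode_fcgr(residues: str, k: int, mode: Mode = "all_positions") -> FCGRProfile:
    """Classical 4**k chaos-game / k-mer profile of one sequence."""
    _check_k(k, MAX_K_FCGR)
    if not residues:
        raise ValueError("cannot encode an empty sequence")
    if mode not in ("all_positions", "kmer_only"):
        raise ValueError(f"unknown mode {mode!r}")

    size = 4**k
    counts = np.zeros(size, dtype=np.int64)
    positions = 0
    for seg in _segments(_codes(residues)):
        start = k - 1 if mode == "kmer_only" else 0
        if len(seg) <= start:
            continue
        cells = _walk_cells_quaternary(seg, k)[start:]
        counts += np.bincount(cells, minlength=size)
        positions += len(seg) - start
    return FCGRProfile(k=k, counts=counts, positions_counted=positions, mode=mode)


def group_collapse(fcgr: FCGRProfile) -> PCmerProfile:
    """Collapse a 4**k k-mer spectrum onto the three 2**k grouped spectra.

    Each binary cell sums the 2**k nucleotide k-mers whose per-position
    scheme images spell that binary k-mer; digit m of the quaternary index
    maps to bit m of the binary index (same significance = same position
    in the window).
    """
    if fcgr.mode != "kmer_only":
        raise ValueError("group_collapse requires a kmer_only profile")
    k = fcgr.k
    idx = np.arange(4**k, dtype=np.int64)
    out = []
    for scheme in SCHEMES:
        bits = scheme.high_bits
        binary = np.zeros_like(idx)
        for m in range(k):
            binary |= bits[(idx >> (2 * m)) & 3] << m
        out.append(
            np.bincount(binary, weights=fcgr.counts, minlength=1 << k).astype(np.int64)
        )
    return PCmerProfile(
        k=k,
        counts=tuple(out),  # type: ignore[arg-type]
        positions_counted=fcgr.positions_counted,
        mode="kmer_only",
    )


def brute_force_binary_kmer_counts(
    binary_string: str, k: int, high_symbol: str | None = None
) -> np.ndarray:
    """Direct sliding-window k-mer counter over a two-symbol string.

    Independent oracle for the chaos-game encoders: every overlapping
    window of length k is placed at 0-based cell
    ``sum_p [window[p] == high] * 2**p`` (window offset p counted from the
    oldest character, so the most recent symbol is the most significant
    bit).  Strings shorter than k give an all-zero vector.  ``high_symbol``
    defaults to the known high endpoint present in the string (Y, K or W).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    symbols = set(binary_string)
    if len(symbols) > 2:
        raise ValueError(f"expected a 2-symbol string, saw {sorted(symbols)}")
    if high_symbol is None:
        highs = symbols & {s.high_symbol for s in SCHEMES}
        if len(highs) > 1:
            raise ValueError("ambiguous high symbol; pass high_symbol explicitly")
        high_symbol = highs.pop() if highs else ""
    counts = np.zeros(1 << k, dtype=np.int64)
    for j in range(len(binary_string) - k + 1):
        window = binary_string[j : j + k]
        cell = sum(1 << p for p, ch in enumerate(window) if ch == high_symbol)
        counts[cell] += 1
    return counts
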