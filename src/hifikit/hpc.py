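"""Homopolymer compression and compressed/uncompressed coordinate mapping.

High-fidelity long reads concentrate their residual errors in homopolymer run
lengths: the instrument reports the wrong number of identical consecutive
bases far more often than it reports the wrong base.  Collapsing every
maximal run of one nucleotide to a single base ("AAA" -> "A") therefore hides
the dominant error mode while preserving the base-transition structure that
distinguishes reads from different loci.  All overlapping, error adjustment
and layout construction downstream operate on these compressed sequences;
the per-run lengths recorded here allow lossless expansion back to the
original read and bidirectional interval mapping for the final consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CoordMap:
    """Per-run correspondence between compressed and uncompressed coordinates.

    ``run_starts[i]`` is the uncompressed start of the homopolymer run that
    compressed position ``i`` represents and ``run_lengths[i]`` its length.
    Together they satisfy ``run_starts[i+1] == run_starts[i] + run_lengths[i]``
    and ``run_lengths.sum() == total_uncompressed_length``.
    """

    run_starts: np.ndarray
    run_lengths: np.ndarray
    total_uncompressed_length: int

    def __len__(self) -> int:
        return len(self.run_starts)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CoordMap):
            return NotImplemented
        return (
            self.total_uncompressed_length == other.total_uncompressed_length
            and np.array_equal(self.run_starts, other.run_starts)
            and np.array_equal(self.run_lengths, other.run_lengths)
        )

    def validate(self) -> None:
        """Raise ``ValueError`` if the invariants do not hold."""
        rs, rl = self.run_starts, self.run_lengths
        if len(rs) != len(rl):
            raise ValueError("run_starts and run_lengths differ in length")
        if len(rs) == 0:
            if self.total_uncompressed_length != 0:
                raise ValueError("empty map with nonzero uncompressed length")
            return
        if rs[0] != 0:
            raise ValueError("first run must start at 0")
        if (rl < 1).any():
            raise ValueError("run lengths must be >= 1")
        if not np.array_equal(rs[1:], rs[:-1] + rl[:-1]):
            raise ValueError("runs are not contiguous")
        if int(rl.sum()) != self.total_uncompressed_length:
            raise ValueError("run lengths do not sum to uncompressed length")

    def to_uncompressed(self, interval: tuple[int, int]) -> tuple[int, int]:
        """Map a half-open compressed interval to uncompressed coordinates.

        The returned half-open interval covers exactly the homopolymer runs
        of the compressed interval.
        """
        s, e = interval
        n = len(self.run_starts)
        if not (0 <= s <= e <= n):
            raise ValueError(f"interval {interval!r} out of range for length {n}")
        if s == e:
            u = int(self.run_starts[s]) if s < n else self.total_uncompressed_length
            return (u, u)
        u_start = int(self.run_starts[s])
        u_end = (
            int(self.run_starts[e])
            if e < n
            else self.total_uncompressed_length
        )
        return (u_start, u_end)


def compress(raw_seq: str) -> tuple[str, CoordMap]:
    """Homopolymer-compress a sequence.

    Every maximal run of one nucleotide becomes a single base; the coordinate
    map records where each run started and how long it was, which makes the
    operation losslessly invertible by :func:`expand`.  An empty input yields
    empty outputs.  Characters outside {A,C,G,T,N} are rejected.
    """
    if not raw_seq:
        return "", CoordMap(np.empty(0, np.int64), np.empty(0, np.int64), 0)
    bad = set(raw_seq) - VALID_BASES
    if bad:
        raise ValueError(f"non-nucleotide character(s) in sequence: {sorted(bad)}")
    arr = np.frombuffer(raw_seq.encode("ascii"), dtype=np.uint8)
    is_start = np.empty(len(arr), dtype=bool)
    is_start[0] = True
    np.not_equal(arr[1:], arr[:-1], out=is_start[1:])
    run_starts = np.flatnonzero(is_start).astype(np.int64)
    run_lengths = np.diff(np.append(run_starts, len(arr)))
    hpc_seq = arr[run_starts].tobytes().decode("ascii")
    return hpc_seq, CoordMap(run_starts, run_lengths, len(arr))


def expand(hpc_seq: str, coord_map: CoordMap) -> str:
    """Invert :func:`compress`: repeat each base by its run length."""
    if len(hpc_seq) != len(coord_map):
        raise ValueError(
            f"compressed sequence length {len(hpc_seq)} does not match "
            f"coordinate map length {len(coord_map)}"
        )
    if not hpc_seq:
        return ""
    arr = np.frombuffer(hpc_seq.encode("ascii"), dtype=np.uint8)
    return np.repeat(arr, coord_map.run_lengths).tobytes().decode("ascii")


@dataclass
class Read:
    """An input read with its compressed form and trim interval.

    ``trim`` is a half-open interval in compressed coordinates set by the
    overlap-based trimming stage; it starts out as the full read.  ``flags``
    collects bookkeeping notes such as ``"no_overlaps"``.
    """

    id: str
    raw_seq: str
    hpc_seq: str
    coord_map: CoordMap
    trim: tuple[int, int] = (0, 0)
    flags: set = field(default_factory=set)

    @classmethod
    def from_raw(cls, read_id: str, raw_seq: str) -> "Read":
        hpc_seq, cmap = compress(raw_seq)
        return cls(read_id, raw_seq, hpc_seq, cmap, trim=(0, len(hpc_seq)))

    def __len__(self) -> int:
        return len(self.hpc_seq)

    @property
    def trimmed_length(self) -> int:
        return self.trim[1] - self.trim[0]

    def trimmed_hpc(self, orient: str = "+") -> str:
        seq = self.hpc_seq[self.trim[0] : self.trim[1]]
        return seq if orient == "+" else revcomp(seq)

    def trimmed_run_lengths(self, orient: str = "+") -> np.ndarray:
        rl = self.coord_map.run_lengths[self.trim[0] : self.trim[1]]
        return rl if orient == "+" else rl[::-1]

    def trimmed_raw(self) -> str:
        """The uncompressed sequence corresponding to the trimmed interval."""
        u = self.coord_map.to_uncompressed(self.trim)
        return self.raw_seq[u[0] : u[1]]
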