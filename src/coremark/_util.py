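"""Shared helpers: interval arithmetic, sequence ops, per-role RNG streams.

Intervals are 0-based half-open ``(start, end)`` tuples throughout the
package, matching BED/PAF conventions.
"""

from __future__ import annotations

import gzip
import zlib
from typing import Iterable, Sequence

import numpy as np

Interval = tuple[int, int]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions; sequences must be equal length."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def stream_rng(seed: int, role: str) -> np.random.Generator:
    """One independent RNG stream per output role.

    Seeded as ``(seed + crc32(role)) mod 2**31`` so adding a new output
    never perturbs the stream of an existing one.
    """
    return np.random.default_rng((int(seed) + zlib.crc32(role.encode())) % (2**31))


# ---------------------------------------------------------------------------
# interval arithmetic


def merge_intervals(ivs: Iterable[Interval]) -> list[Interval]:
    """Union of intervals, returned sorted and non-overlapping."""
    ivs = sorted((int(s), int(e)) for s, e in ivs if e > s)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect_intervals(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Intersection of two sorted non-overlapping interval lists."""
    out: list[Interval] = []
    i = j = 0
    a, b = list(a), list(b)
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def intersect_many(sets: Sequence[Sequence[Interval]]) -> list[Interval]:
    if not sets:
        return []
    acc = merge_intervals(sets[0])
    for ivs in sets[1:]:
        acc = intersect_intervals(acc, merge_intervals(ivs))
    return acc


def complement_intervals(ivs: Sequence[Interval], length: int) -> list[Interval]:
    """Complement of a union of intervals within ``[0, length)``."""
    out: list[Interval] = []
    pos = 0
    for s, e in merge_intervals(ivs):
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < length:
        out.append((pos, length))
    return out


def total_length(ivs: Iterable[Interval]) -> int:
    return sum(e - s for s, e in ivs)


def jaccard(a: Sequence[Interval], b: Sequence[Interval]) -> float:
    """Jaccard index of two interval sets by base overlap."""
    a = merge_intervals(a)
    b = merge_intervals(b)
    inter = total_length(intersect_intervals(a, b))
    union = total_length(a) + total_length(b) - inter
    return inter / union if union else 1.0


# ---------------------------------------------------------------------------
# small-format IO


def write_fasta(path, records: Iterable[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def open_maybe_gzip(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)
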