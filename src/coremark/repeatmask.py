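"""K-mer-frequency repeat masking.

Repetitive tracts (transposable elements, tandem arrays) break the
one-to-one assumption of whole-genome alignment and attract off-target
primer binding.  Before any uniqueness check or alignment-based step the
genomes are therefore masked: every base covered by at least one k-mer
window whose canonical (strand-collapsed) frequency in the counting
corpus exceeds ``max_freq`` is replaced with 'N'.  Defaults are k=31 and
max_freq=2, i.e. any 31-mer seen more than twice across the pooled
reference-plus-assemblies corpus marks its window as repetitive.

Counting is canonical: a k-mer and its reverse complement are the same
key (the lexicographically smaller spelling).  Windows containing any
non-ACGT symbol are skipped.  K-mers are held as 2-bit-packed integers
in sorted numpy arrays, so genome-scale tables stay compact; the
dict-like interface decodes lazily.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np

from ._util import revcomp

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase

_DECODE = "ACGT"


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical 2-bit codes for every k-window plus a validity mask.

    Returns (canonical uint64 array of length n-k+1, boolean valid mask).
    """
    n = codes.size
    m = n - k + 1
    if m <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    bases = codes.astype(np.int64)
    invalid = (bases < 0).astype(np.int64)
    safe = np.where(bases < 0, 0, bases).astype(np.uint64)
    comp = (3 - safe.astype(np.int64)).astype(np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    for j in range(k):
        fwd = (fwd << np.uint64(2)) | safe[j : m + j]
        # reverse complement accumulates complemented bases back-to-front
        rev = (rev << np.uint64(2)) | comp[k - 1 - j : m + k - 1 - j]
    bad = np.convolve(invalid, np.ones(k, dtype=np.int64), mode="valid") > 0
    return np.minimum(fwd, rev), ~bad


def _decode_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_DECODE[code & 3])
        code >>= 2
    return "".join(reversed(out))


class KmerCountTable:
    """Canonical k-mer counts over a sequence corpus.

    Behaves as a read-only mapping from k-mer string to count; either
    spelling of a k-mer may be used as a key.
    """

    def __init__(self, k: int, codes: np.ndarray, counts: np.ndarray):
        if k < 2:
            raise ValueError("k must be >= 2")
        if k > 31:
            raise ValueError("k > 31 does not fit the 2-bit packing")
        order = np.argsort(codes)
        self.k = k
        self._codes = codes[order]
        self._counts = counts[order].astype(np.int64)

    def __len__(self) -> int:
        return self._codes.size

    def _lookup(self, window_codes: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self._codes, window_codes)
        idx = np.minimum(idx, max(self._codes.size - 1, 0))
        hit = self._codes.size > 0
        found = hit & (self._codes[idx] == window_codes) if hit else np.zeros_like(idx, bool)
        out = np.zeros(window_codes.size, dtype=np.int64)
        out[found] = self._counts[idx[found]]
        return out

    def __getitem__(self, kmer: str) -> int:
        if len(kmer) != self.k:
            raise KeyError(kmer)
        canon = min(kmer.upper(), revcomp(kmer.upper()))
        codes, valid = _window_codes(_encode(canon), self.k)
        if not valid.size or not valid[0]:
            raise KeyError(kmer)
        count = int(self._lookup(codes[:1])[0])
        if count == 0:
            raise KeyError(kmer)
        return count

    def get(self, kmer: str, default: int = 0) -> int:
        try:
            return self[kmer]
        except KeyError:
            return default

    def items(self) -> Iterator[tuple[str, int]]:
        for code, count in zip(self._codes, self._counts):
            yield _decode_kmer(int(code), self.k), int(count)

    def to_dict(self) -> dict[str, int]:
        return dict(self.items())


def count_kmers(sequences: Iterable[tuple[str, str]] | dict[str, str], k: int = 31) -> KmerCountTable:
    """Count canonical k-mers over ``(name, sequence)`` records.

    Windows containing non-ACGT symbols are skipped.
    """
    if isinstance(sequences, dict):
        sequences = list(sequences.items())
    else:
        sequences = list(sequences)
    if not sequences:
        raise ValueError("empty sequence corpus")
    chunks = []
    for _name, seq in sequences:
        codes, valid = _window_codes(_encode(seq), k)
        chunks.append(codes[valid])
    allcodes = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.uint64)
    uniq, counts = np.unique(allcodes, return_counts=True)
    return KmerCountTable(k, uniq, counts)


def mask_sequence(seq: str, table: KmerCountTable, max_freq: int = 2) -> str:
    """Mask one sequence: bases covered by any window with count > max_freq become 'N'."""
    k = table.k
    if len(seq) < k:
        return seq
    codes, valid = _window_codes(_encode(seq), k)
    counts = table._lookup(codes)
    frequent = valid & (counts > max_freq)
    if not frequent.any():
        return seq
    # window-coverage via difference array
    diff = np.zeros(len(seq) + 1, dtype=np.int64)
    starts = np.nonzero(frequent)[0]
    np.add.at(diff, starts, 1)
    np.add.at(diff, starts + k, -1)
    covered = np.cumsum(diff[:-1]) > 0
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    arr[covered] = ord("N")
    return arr.tobytes().decode()


def mask_repeats(
    sequences: Iterable[tuple[str, str]] | dict[str, str],
    table: KmerCountTable,
    max_freq: int = 2,
) -> dict[str, str]:
    """Mask every sequence against a shared k-mer table; lengths preserved."""
    if isinstance(sequences, dict):
        sequences = list(sequences.items())
    return {name: mask_sequence(seq, table, max_freq) for name, seq in sequences}
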