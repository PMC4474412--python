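"""Exact k-mer occurrence index over the target regions.

Every window of length K that contains only A/C/G/T is recorded.  With
``strand_mode="both"`` (the default) each position additionally contributes
a minus-strand occurrence, filed under the reverse-complement reading of
the window, so a word's count accumulates its appearances on either strand.
A palindromic word therefore counts twice at a single position, once per
strand.

The index is the workhorse behind seed selection and seed generalisation;
its contract is exact counts and locations, checked in the test suite
against a naive sliding-window counter.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .io import Region

__all__ = ["KmerIndex", "build_index", "naive_kmer_counts", "naive_locate", "revcomp"]

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Base codes A=0 C=1 G=2 T=3; anything else (N, mask) is -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def word_to_code(word: str) -> int:
    codes = encode(word)
    if np.any(codes < 0):
        return -1
    powers = 4 ** np.arange(len(word) - 1, -1, -1, dtype=np.int64)
    return int(codes.astype(np.int64) @ powers)


def code_to_word(code: int, K: int) -> str:
    bases = "ACGT"
    out = []
    for _ in range(K):
        out.append(bases[code % 4])
        code //= 4
    return "".join(reversed(out))


class KmerIndex:
    """Sorted-array (CSR-style) store of all k-mer occurrences."""

    def __init__(
        self,
        K: int,
        strand_mode: str,
        kcodes: np.ndarray,
        region_idx: np.ndarray,
        offsets: np.ndarray,
        strands: np.ndarray,
        total_positions: int,
        n_windows_scanned: int,
    ):
        self.K = K
        self.strand_mode = strand_mode
        order = np.argsort(kcodes, kind="stable")
        self._kcodes = kcodes[order]
        self._region_idx = region_idx[order]
        self._offsets = offsets[order]
        self._strands = strands[order]
        self._unique, self._starts = np.unique(self._kcodes, return_index=True)
        self._counts = np.diff(np.append(self._starts, len(self._kcodes)))
        self.total_positions = total_positions
        # work counter for the near-linear-build property (windows examined)
        self.n_windows_scanned = n_windows_scanned

    # -- queries ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self._unique)

    @property
    def n_occurrences(self) -> int:
        return len(self._kcodes)

    def _slice(self, code: int) -> slice:
        i = np.searchsorted(self._unique, code)
        if i == len(self._unique) or self._unique[i] != code:
            return slice(0, 0)
        start = self._starts[i]
        return slice(start, start + self._counts[i])

    def count(self, word: str) -> int:
        if len(word) != self.K:
            raise ValueError(f"word length {len(word)} != K={self.K}")
        code = word_to_code(word)
        if code < 0:
            return 0
        sl = self._slice(code)
        return sl.stop - sl.start

    def locate(self, word: str) -> list[tuple[int, int, str]]:
        """All occurrences of ``word`` as (region_index, offset, strand)."""
        if len(word) != self.K:
            raise ValueError(f"word length {len(word)} != K={self.K}")
        code = word_to_code(word)
        if code < 0:
            return []
        sl = self._slice(code)
        return [
            (int(r), int(o), "+" if s == 0 else "-")
            for r, o, s in zip(self._region_idx[sl], self._offsets[sl], self._strands[sl])
        ]

    def counts(self) -> dict[str, int]:
        """Full word -> count mapping (materialises all words)."""
        return {
            code_to_word(int(c), self.K): int(n)
            for c, n in zip(self._unique, self._counts)
        }

    def unique_codes(self) -> tuple[np.ndarray, np.ndarray]:
        """(codes, counts) arrays over all distinct indexed k-mers."""
        return self._unique, self._counts

    def words(self) -> list[str]:
        return [code_to_word(int(c), self.K) for c in self._unique]


def build_index(
    regions: Sequence[Region] | Sequence[str],
    K: int,
    strand_mode: str = "both",
) -> KmerIndex:
    """Index every N-free window of length K in ``regions``.

    Accepts :class:`Region` objects or bare strings.  Windows containing N
    (or masked bases turned into N at read time) are skipped.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if strand_mode not in ("both", "forward"):
        raise ValueError("strand_mode must be 'both' or 'forward'")
    if not regions:
        raise ValueError("no regions to index")
    seqs = [r.sequence if isinstance(r, Region) else r for r in regions]
    if K > max(len(s) for s in seqs):
        import warnings

        warnings.warn(f"K={K} exceeds the longest region; index is empty")

    powers = 4 ** np.arange(K - 1, -1, -1, dtype=np.int64)
    all_codes, all_region, all_offset, all_strand = [], [], [], []
    total_positions = 0
    n_windows = 0
    for ridx, seq in enumerate(seqs):
        if len(seq) < K:
            continue
        b = encode(seq).astype(np.int64)
        win = np.lib.stride_tricks.sliding_window_view(b, K)
        valid = np.all(win >= 0, axis=1)
        n_windows += win.shape[0]
        if not np.any(valid):
            continue
        offs = np.flatnonzero(valid)
        total_positions += len(offs)
        fwd = win[valid] @ powers
        all_codes.append(fwd)
        all_region.append(np.full(len(offs), ridx, dtype=np.int32))
        all_offset.append(offs.astype(np.int32))
        all_strand.append(np.zeros(len(offs), dtype=np.int8))
        if strand_mode == "both":
            rc = (3 - win[valid])[:, ::-1] @ powers
            all_codes.append(rc)
            all_region.append(np.full(len(offs), ridx, dtype=np.int32))
            all_offset.append(offs.astype(np.int32))
            all_strand.append(np.ones(len(offs), dtype=np.int8))
            n_windows += len(offs)
    if all_codes:
        kcodes = np.concatenate(all_codes)
        region_idx = np.concatenate(all_region)
        offsets = np.concatenate(all_offset)
        strands = np.concatenate(all_strand)
    else:
        kcodes = np.empty(0, dtype=np.int64)
        region_idx = np.empty(0, dtype=np.int32)
        offsets = np.empty(0, dtype=np.int32)
        strands = np.empty(0, dtype=np.int8)
    return KmerIndex(K, strand_mode, kcodes, region_idx, offsets, strands, total_positions, n_windows)


# ---------------------------------------------------------------------------
# Naive oracle (kept deliberately dumb; used by the test suite)
# ---------------------------------------------------------------------------

def naive_kmer_counts(
    regions: Sequence[Region] | Sequence[str], K: int, strand_mode: str = "both"
) -> dict[str, int]:
    """Sliding-window dictionary count; the reference the index must match."""
    counts: dict[str, int] = {}
    seqs = [r.sequence if isinstance(r, Region) else r for r in regions]
    for seq in seqs:
        for i in range(len(seq) - K + 1):
            w = seq[i : i + K]
            if any(c not in "ACGT" for c in w):
                continue
            counts[w] = counts.get(w, 0) + 1
            if strand_mode == "both":
                rc = revcomp(w)
                counts[rc] = counts.get(rc, 0) + 1
    return counts


def naive_locate(
    regions: Sequence[Region] | Sequence[str], K: int, word: str, strand_mode: str = "both"
) -> list[tuple[int, int, str]]:
    out = []
    seqs = [r.sequence if isinstance(r, Region) else r for r in regions]
    rc_word = revcomp(word)
    for ridx, seq in enumerate(seqs):
        for i in range(len(seq) - K + 1):
            w = seq[i : i + K]
            if any(c not in "ACGT" for c in w):
                continue
            if w == word:
                out.append((ridx, i, "+"))
            if strand_mode == "both" and rc_word == w:
                out.append((ridx, i, "-"))
    return out
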