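"""Adapter masking and read clipping.

Library adapters (including broken-poly-T oligo-dT primers) are masked
wherever they occur in a read — on either strand, allowing a bounded
mismatch fraction — and each read is then clipped to its longest run of
unmasked bases. Reads whose longest clean run falls below a minimum length
are removed. This mirrors the conventional mask-then-extract cleanup applied
to pyrosequencing libraries before clustering.

Masking is a bounded-mismatch sliding-window scan rather than a full
Smith-Waterman screen: every full-length adapter window, plus partial
adapter overlaps hanging off either read end, is tested against a mismatch
budget of ``floor(max_mismatch_frac * overlap)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import Read, revcomp


@dataclass
class ClipReport:
    """Aggregate accounting for a batch cleaning run."""

    n_input: int
    n_clean: int
    n_removed: int
    bases_input: int
    bases_clean: int
    mean_len_before: float
    mean_len_after: float

    def __post_init__(self) -> None:
        if self.n_clean + self.n_removed != self.n_input:
            raise ValueError("clean + removed must equal input count")
        if self.bases_clean > self.bases_input:
            raise ValueError("clean bases cannot exceed input bases")


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and non-overlapping."""
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def _window_mismatches(seq_arr: np.ndarray, pat_arr: np.ndarray) -> np.ndarray:
    """Mismatch count of the pattern against every full window of the sequence."""
    windows = np.lib.stride_tricks.sliding_window_view(seq_arr, len(pat_arr))
    return (windows != pat_arr).sum(axis=1)


def _mask_one(seq: str, adapter: str, max_mismatch_frac: float, min_match: int) -> list[tuple[int, int]]:
    hits: list[tuple[int, int]] = []
    n, m = len(seq), len(adapter)
    seq_arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    pat_arr = np.frombuffer(adapter.encode(), dtype=np.uint8)
    effective_min = min(min_match, m)  # short adapters must match in full
    if n >= m:
        budget = int(max_mismatch_frac * m)
        mm = _window_mismatches(seq_arr, pat_arr)
        for start in np.nonzero(mm <= budget)[0]:
            hits.append((int(start), int(start) + m))
    # partial adapter hanging off the 5' end: adapter suffix == read prefix
    for ov in range(effective_min, min(m, n)):
        budget = int(max_mismatch_frac * ov)
        if sum(x != y for x, y in zip(seq[:ov], adapter[m - ov :])) <= budget:
            hits.append((0, ov))
    # partial adapter hanging off the 3' end: adapter prefix == read suffix
    for ov in range(effective_min, min(m, n)):
        budget = int(max_mismatch_frac * ov)
        if sum(x != y for x, y in zip(seq[n - ov :], adapter[:ov])) <= budget:
            hits.append((n - ov, n))
    return hits


def mask_adapters(
    read: Read,
    adapters: list[str],
    max_mismatch_frac: float = 0.1,
    min_match: int = 10,
) -> Read:
    """Return a copy of the read with adapter occurrences added to ``masked``.

    Each adapter and its reverse complement are scanned; overlapping masks
    are merged. A read with no adapter occurrence is returned unchanged
    (masked stays empty).
    """
    if not adapters:
        raise ValueError("adapter list is empty")
    hits: list[tuple[int, int]] = list(read.masked)
    for adapter in adapters:
        adapter = adapter.upper()
        for pattern in {adapter, revcomp(adapter)}:
            hits.extend(_mask_one(read.seq, pattern, max_mismatch_frac, min_match))
    return Read(id=read.id, seq=read.seq, masked=merge_intervals(hits))


REMOVED = None  # sentinel: read dropped by clipping


def clip_to_largest_unmasked(read: Read, min_len: int = 20) -> Read | None:
    """Clip a read to its longest maximal run of unmasked bases.

    Returns the clipped read with ``/clip`` appended to the id, the read
    unchanged if nothing is masked, or ``None`` (removed) when the longest
    clean run is shorter than ``min_len``. Ties between equal-length runs go
    to the 5'-most run.
    """
    if not read.masked:
        return read
    runs: list[tuple[int, int]] = []
    pos = 0
    for start, end in read.masked:
        if start > pos:
            runs.append((pos, start))
        pos = end
    if pos < len(read.seq):
        runs.append((pos, len(read.seq)))
    if not runs:
        return REMOVED
    best = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
    if best[1] - best[0] < min_len:
        return REMOVED
    return Read(id=read.id + "/clip", seq=read.seq[best[0] : best[1]])


def clip_batch(
    reads: list[Read],
    adapters: list[str],
    max_mismatch_frac: float = 0.1,
    min_match: int = 10,
    min_len: int = 20,
) -> tuple[list[Read], ClipReport]:
    """Mask and clip every read; return surviving reads plus a summary report."""
    clean: list[Read] = []
    bases_in = 0
    for read in reads:
        bases_in += len(read.seq)
        masked = mask_adapters(read, adapters, max_mismatch_frac, min_match)
        clipped = clip_to_largest_unmasked(masked, min_len)
        if clipped is not REMOVED:
            clean.append(clipped)
    bases_clean = sum(len(r.seq) for r in clean)
    report = ClipReport(
        n_input=len(reads),
        n_clean=len(clean),
        n_removed=len(reads) - len(clean),
        bases_input=bases_in,
        bases_clean=bases_clean,
        mean_len_before=bases_in / len(reads) if reads else 0.0,
        mean_len_after=bases_clean / len(clean) if clean else 0.0,
    )
    return clean, report
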