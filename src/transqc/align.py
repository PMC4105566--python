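"""Deterministic local pairwise alignment engine.

Both consistency indexes reduce to the best local alignment between two DNA
sequences, so the engine is exact rather than heuristic: a Smith-Waterman /
Gotoh dynamic program under an affine gap scheme (default +1 match, -2
mismatch, -3 first gap column, -1 each further gap column).

Among co-optimal alignments the engine maximizes the number of matched bases
as a secondary objective, which makes the reported ``(score, n_ident)`` pair
a well-defined function of the inputs. This is implemented by running the DP
over integer-encoded ``score * 2**20 + n_ident`` values: lexicographic
comparison of the pairs coincides with numeric comparison of the encoding,
and both components are additive along an alignment path.

``N`` bases score as mismatches and never count as matched.

The forward pass is vectorized one row at a time. The within-row dependence
of the horizontal gap state is eliminated with the standard prefix-maximum
identity: because re-opening a gap immediately after closing one is never
optimal (gap_open <= gap_extend), every horizontal gap can be taken to start
from a cell whose best path does not itself end in a horizontal gap, and the
best such origin is a running maximum over the row.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import revcomp

# Identity counts occupy the low bits of the encoded DP value; path identity
# is bounded by sequence length, so 2**20 leaves ample headroom.
_IDENT_BITS = 20
_K = 1 << _IDENT_BITS

DEFAULT_MATCH = 1
DEFAULT_MISMATCH = -2
DEFAULT_GAP_OPEN = -3
DEFAULT_GAP_EXTEND = -1


@dataclass(frozen=True)
class LocalAlignment:
    """Best local alignment between a query and a subject sequence.

    Spans are 0-based half-open on the original (plus-strand) sequences;
    ``strand`` is '-' when the subject was reverse-complemented.
    """

    q_span: tuple[int, int]
    s_span: tuple[int, int]
    n_ident: int
    aln_cols: int
    score: float
    strand: str = "+"

    @property
    def identity_frac(self) -> float:
        return self.n_ident / self.aln_cols if self.aln_cols else 0.0


def _encode_seq(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def shares_kmer(a: str, b: str, k: int = 11, both_strands: bool = True) -> bool:
    """True if the two sequences share any exact k-mer (optionally either strand)."""
    if len(a) < k or len(b) < k:
        return False
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    if any(b[i : i + k] in kmers for i in range(len(b) - k + 1)):
        return True
    if both_strands:
        rb = revcomp(b)
        return any(rb[i : i + k] in kmers for i in range(len(rb) - k + 1))
    return False


def _forward(
    a: np.ndarray,
    b: np.ndarray,
    match_enc: int,
    mismatch_enc: int,
    go: int,
    ge: int,
) -> np.ndarray:
    """Fill the encoded H matrix, shape (len(a)+1, len(b)+1)."""
    na, nb = len(a), len(b)
    H = np.zeros((na + 1, nb + 1), dtype=np.int64)
    NEG = np.int64(-(1 << 50))
    F = np.full(nb + 1, NEG, dtype=np.int64)
    n_code = np.uint8(ord("N"))
    cols = np.arange(1, nb + 1, dtype=np.int64)
    for i in range(1, na + 1):
        ai = a[i - 1]
        is_match = (b == ai) & (b != n_code) & (ai != n_code)
        sub = np.where(is_match, match_enc, mismatch_enc)
        diag = H[i - 1, :-1] + sub
        F[1:] = np.maximum(H[i - 1, 1:] + go, F[1:] + ge)
        h0 = np.maximum(np.maximum(diag, F[1:]), 0)
        # horizontal gaps: best origin k maximizes h0[k] - k*ge
        w = np.maximum.accumulate(h0 - cols * ge)
        E = np.full(nb, NEG, dtype=np.int64)
        E[1:] = w[:-1] + go + (cols[1:] - 1) * ge
        H[i, 1:] = np.maximum(h0, E)
    return H


def _traceback(
    H: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    end: tuple[int, int],
    match_enc: int,
    mismatch_enc: int,
    go: int,
    ge: int,
) -> tuple[int, int, int]:
    """Walk back from ``end``; return (q_start, s_start, aln_cols)."""
    i, j = end
    n_code = ord("N")
    aln_cols = 0
    while H[i, j] != 0:
        v = H[i, j]
        if i > 0 and j > 0:
            matched = a[i - 1] == b[j - 1] and a[i - 1] != n_code
            sub = match_enc if matched else mismatch_enc
            if v == H[i - 1, j - 1] + sub:
                i -= 1
                j -= 1
                aln_cols += 1
                continue
        found = False
        # vertical gap of length g (consumes query rows)
        cost = go
        for g in range(1, i + 1):
            if v == H[i - g, j] + cost:
                i -= g
                aln_cols += g
                found = True
                break
            cost += ge
        if found:
            continue
        # horizontal gap of length g (consumes subject columns)
        cost = go
        for g in range(1, j + 1):
            if v == H[i, j - g] + cost:
                j -= g
                aln_cols += g
                found = True
                break
            cost += ge
        if not found:  # pragma: no cover - would indicate a DP defect
            raise AssertionError("traceback failed to decompose DP cell")
    return i, j, aln_cols


def _best_cell(H: np.ndarray) -> tuple[int, int, int]:
    flat = int(np.argmax(H))
    i, j = divmod(flat, H.shape[1])
    return int(H[i, j]), i, j


def local_align(
    a: str,
    b: str,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
    both_strands: bool = True,
    prefilter_k: int | None = None,
) -> LocalAlignment | None:
    """Optimal local alignment of ``a`` (query) vs ``b`` (subject).

    Returns ``None`` when no alignment scores at least ``match`` (no
    positive-scoring base pair exists), or when ``prefilter_k`` is set and the
    sequences share no exact k-mer of that length. The prefilter is a speed
    device for all-vs-all scans; alignments it skips are short by construction
    but callers asserting exact scores should leave it off.

    Gap costs: a gap of length L scores ``gap_open + (L-1) * gap_extend``.
    Tie policy: maximal score, then maximal matched-base count, then the
    smallest end coordinates (query-major) on the plus strand first.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    if prefilter_k is not None and not shares_kmer(a, b, prefilter_k, both_strands):
        return None

    match_enc = match * _K + 1
    mismatch_enc = mismatch * _K
    go = gap_open * _K
    ge = gap_extend * _K

    arr_a = _encode_seq(a)
    candidates: list[tuple[int, str, np.ndarray, np.ndarray]] = []
    arr_b = _encode_seq(b)
    candidates.append((0, "+", arr_b, None))
    if both_strands:
        candidates.append((1, "-", _encode_seq(revcomp(b)), None))

    best = None  # (value, strand_order, strand, H, arr_b, end)
    for order, strand, bs, _ in candidates:
        H = _forward(arr_a, bs, match_enc, mismatch_enc, go, ge)
        value, i, j = _best_cell(H)
        key = (value, -order)  # plus strand wins ties
        if best is None or key > best[0]:
            best = (key, strand, H, bs, (i, j))

    (value, _), strand, H, bs, end = best
    score = value >> _IDENT_BITS
    n_ident = value & (_K - 1)
    if score < match:
        return None
    qs, ss, aln_cols = _traceback(H, arr_a, bs, end, match_enc, mismatch_enc, go, ge)
    q_span = (qs, end[0])
    s_span = (ss, end[1])
    if strand == "-":
        s_span = (len(b) - s_span[1], len(b) - s_span[0])
    return LocalAlignment(
        q_span=q_span,
        s_span=s_span,
        n_ident=int(n_ident),
        aln_cols=aln_cols,
        score=float(score),
        strand=strand,
    )
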