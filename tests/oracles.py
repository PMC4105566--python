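"""Independent brute-force oracles used only by the test suite.

Each oracle is a deliberately naive implementation kept separate from the
package code paths it checks: a scalar-loop Gotoh DP for local alignment, a
per-residue bitmap for subject coverage, and an exhaustive tandem-repeat
enumerator for SSR detection.
"""

from __future__ import annotations

NEG = float("-inf")


def dp_local_align(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -2,
    gap_open: int = -3,
    gap_extend: int = -1,
) -> tuple[int, int]:
    """Scalar Smith-Waterman/Gotoh returning (best score, matched bases).

    Optimizes score first and matched-base count second, via lexicographic
    comparison of (score, n_ident) pairs; gap of length L costs
    gap_open + (L-1)*gap_extend. N never matches.
    """
    na, nb = len(a), len(b)
    zero = (0, 0)
    neg = (NEG, 0)
    H = [[zero] * (nb + 1) for _ in range(na + 1)]
    E = [[neg] * (nb + 1) for _ in range(na + 1)]
    F = [[neg] * (nb + 1) for _ in range(na + 1)]
    best = zero
    for i in range(1, na + 1):
        ai = a[i - 1]
        for j in range(1, nb + 1):
            bj = b[j - 1]
            is_match = ai == bj and ai != "N"
            s = (match, 1) if is_match else (mismatch, 0)
            diag = (H[i - 1][j - 1][0] + s[0], H[i - 1][j - 1][1] + s[1])
            e_open = (H[i][j - 1][0] + gap_open, H[i][j - 1][1])
            e_ext = (E[i][j - 1][0] + gap_extend, E[i][j - 1][1])
            E[i][j] = max(e_open, e_ext)
            f_open = (H[i - 1][j][0] + gap_open, H[i - 1][j][1])
            f_ext = (F[i - 1][j][0] + gap_extend, F[i - 1][j][1])
            F[i][j] = max(f_open, f_ext)
            H[i][j] = max(zero, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return int(best[0]), best[1]


def bitmap_subject_coverage(intervals_1based: list[tuple[int, int]], slen: int) -> float:
    """Covered fraction of a subject via an explicit per-residue bitmap."""
    covered = [False] * slen
    for start, end in intervals_1based:
        for pos in range(start, end + 1):
            covered[pos - 1] = True
    return sum(covered) / slen


def brute_force_ssrs(
    seq: str, min_units: dict[int, int] | None = None
) -> list[tuple[int, int, str, int]]:
    """Exhaustive perfect-tandem-repeat enumeration.

    Tries every start and motif length 2-6, extends maximally in whole units,
    keeps primitive motifs meeting the unit minimum, then resolves overlaps
    leftmost-first, longest-first. Returns (start, end, motif, n_units)
    with half-open spans.
    """
    if min_units is None:
        min_units = {2: 6, 3: 4, 4: 3, 5: 3, 6: 3}
    n = len(seq)
    candidates = []
    for start in range(n):
        for m in range(2, 7):
            motif = seq[start : start + m]
            if len(motif) < m or "N" in motif:
                continue
            if _is_repeat_of_shorter(motif):
                continue
            units = 1
            while seq[start + units * m : start + (units + 1) * m] == motif:
                units += 1
            if units >= min_units[m]:
                candidates.append((start, start + units * m, motif, units))
    candidates.sort(key=lambda c: (c[0], -(c[1] - c[0]), len(c[2])))
    chosen: list[tuple[int, int, str, int]] = []
    occupied_end = -1
    for cand in candidates:
        if cand[0] > occupied_end:
            chosen.append(cand)
            occupied_end = cand[1] - 1
    return chosen


def _is_repeat_of_shorter(motif: str) -> bool:
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return True
    return False
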