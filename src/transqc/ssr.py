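"""Perfect microsatellite (SSR) detection and summarisation.

Finds maximal perfect tandem repeats of primitive 2-6 base motifs (di- to
hexanucleotide) subject to per-class minimum unit counts — defaults
``{di: 6, tri: 4, tetra: 3, penta: 3, hexa: 3}``, the conventional
MISA-style setting for transcriptome marker scans. Mononucleotide runs are
deliberately out of scope: in pyrosequencing data they are dominated by
homopolymer over/undercall artifacts rather than genuine repeats.

Motifs are grouped by their canonical form — the lexicographically smallest
string among all rotations of the motif and of its reverse complement — so
that e.g. TA, AT, and their complements all tally under "AT".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .core_io import revcomp

CLASS_NAMES = {2: "di", 3: "tri", 4: "tetra", 5: "penta", 6: "hexa"}
CLASS_SIZES = {v: k for k, v in CLASS_NAMES.items()}

DEFAULT_MIN_UNITS: dict[str, int] = {
    "di": 6,
    "tri": 4,
    "tetra": 3,
    "penta": 3,
    "hexa": 3,
}


@dataclass(frozen=True)
class SsrLocus:
    """A perfect tandem repeat: ``seq[start:end] == motif * n_repeats``."""

    seq_id: str
    start: int
    end: int
    motif: str
    canonical: str
    n_repeats: int
    cls: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.motif) * self.n_repeats:
            raise ValueError("span length must equal motif length * repeat count")
        if CLASS_NAMES.get(len(self.motif)) != self.cls:
            raise ValueError("class must match motif length")


@dataclass
class SsrSummary:
    """Class and canonical-motif frequency tables.

    ``class_counts``/``class_pct`` are keyed by class name; ``motif_counts``
    and ``motif_pct_within_class`` are keyed by (class, canonical motif),
    percentages within each class. Percentages are rounded to 2 decimals.
    """

    n_loci: int
    class_counts: dict[str, int]
    class_pct: dict[str, float]
    motif_counts: dict[tuple[str, str], int]
    motif_pct_within_class: dict[tuple[str, str], float]


def is_primitive(motif: str) -> bool:
    """True unless the motif is itself a tandem repeat of a shorter motif."""
    m = len(motif)
    for d in range(1, m):
        if m % d == 0 and motif == motif[:d] * (m // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Smallest string over all rotations of the motif and its revcomp."""
    if not (2 <= len(motif) <= 6):
        raise ValueError("motif length must be 2-6")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    forms = []
    for s in (motif, revcomp(motif)):
        forms.extend(s[i:] + s[:i] for i in range(len(s)))
    return min(forms)


def find_ssrs(
    seq_id: str,
    seq: str,
    min_units: Mapping[str, int] | None = None,
) -> list[SsrLocus]:
    """Maximal non-overlapping perfect SSRs in one sequence.

    Scans every start position for motif lengths 2-6 and extends in whole
    units; runs containing N never form a locus. Overlapping candidates are
    resolved leftmost-first, then longest, then shortest motif — a
    deterministic greedy that keeps the reported loci disjoint.
    """
    units_by_len = _units_by_len(min_units)
    n = len(seq)
    candidates: list[tuple[int, int, str, int]] = []
    for m in range(2, 7):
        min_u = units_by_len[m]
        for i in range(0, n - m * min_u + 1):
            motif = seq[i : i + m]
            if "N" in motif or not is_primitive(motif):
                continue
            units = 1
            while seq[i + units * m : i + (units + 1) * m] == motif:
                units += 1
            if units >= min_u:
                candidates.append((i, i + units * m, motif, units))
    candidates.sort(key=lambda c: (c[0], -(c[1] - c[0]), len(c[2])))
    loci: list[SsrLocus] = []
    occupied_end = 0
    for start, end, motif, units in candidates:
        if start >= occupied_end:
            loci.append(
                SsrLocus(
                    seq_id=seq_id,
                    start=start,
                    end=end,
                    motif=motif,
                    canonical=canonical_motif(motif),
                    n_repeats=units,
                    cls=CLASS_NAMES[len(motif)],
                )
            )
            occupied_end = end
    return loci


def _units_by_len(min_units: Mapping[str, int] | None) -> dict[int, int]:
    table = dict(DEFAULT_MIN_UNITS)
    if min_units:
        table.update(min_units)
    return {CLASS_SIZES[cls]: u for cls, u in table.items()}


def find_ssrs_in_records(
    records: Iterable, min_units: Mapping[str, int] | None = None
) -> list[SsrLocus]:
    """Run :func:`find_ssrs` over Read/Contig records."""
    loci: list[SsrLocus] = []
    for rec in records:
        seq = getattr(rec, "seq", None) or getattr(rec, "consensus")
        loci.extend(find_ssrs(rec.id, seq, min_units))
    return loci


def ssr_summary(loci: list[SsrLocus]) -> SsrSummary:
    """Class and canonical-motif frequency tables with percentages."""
    class_counts = {cls: 0 for cls in CLASS_SIZES}
    motif_counts: dict[tuple[str, str], int] = {}
    for locus in loci:
        class_counts[locus.cls] += 1
        key = (locus.cls, locus.canonical)
        motif_counts[key] = motif_counts.get(key, 0) + 1
    n = len(loci)
    class_pct = {
        cls: round(100.0 * c / n, 2) if n else 0.0 for cls, c in class_counts.items()
    }
    motif_pct = {
        (cls, motif): round(100.0 * c / class_counts[cls], 2)
        for (cls, motif), c in motif_counts.items()
    }
    return SsrSummary(
        n_loci=n,
        class_counts=class_counts,
        class_pct=class_pct,
        motif_counts=motif_counts,
        motif_pct_within_class=motif_pct,
    )


def marker_candidates(loci: list[SsrLocus], annotated_qids: set[str]) -> list[str]:
    """SSR-bearing sequences that are also functionally annotated.

    An SSR inside an annotated unigene is unlikely to be a sequencing
    artifact (annotating a random error is improbable), so these are the
    priority microsatellite marker candidates. Returns sorted distinct ids.
    """
    with_ssr = {locus.seq_id for locus in loci}
    return sorted(with_ssr & annotated_qids)
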