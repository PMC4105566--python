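"""Best-hit annotation summaries and reference-proteome coverage.

Consumes 12/14-column tabular protein-homology hits. Hits are filtered at an
inclusive e-value cutoff (default 1e-5), each query is annotated by its best
hit (highest bit score, ties by lowest e-value then subject id), and subject
coverage is computed by interval union of a query's HSPs on the subject. A
reference protein counted as "full length" is one whose sequence is covered
to at least a threshold fraction (default 0.90, inclusive) by a single
query's merged HSPs; a union-across-queries mode is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .core_io import TabularHit

DEFAULT_EVALUE_MAX = 1e-5
DEFAULT_FULL_LENGTH_THRESHOLD = 0.90


@dataclass
class AnnotationSummary:
    """Annotated/unannotated unigene counts against one database."""

    db_name: str
    n_unigenes: int
    n_annotated: int
    n_unannotated: int
    pct_annotated: int

    def __post_init__(self) -> None:
        if self.n_annotated + self.n_unannotated != self.n_unigenes:
            raise ValueError("annotated + unannotated must equal total unigenes")


@dataclass
class CoverageRecord:
    """Best single-query coverage of one reference subject."""

    sid: str
    slen: int
    best_qid: Optional[str]
    best_coverage_frac: float
    is_full_length: bool


def filter_hits(
    hits: list[TabularHit], evalue_max: float = DEFAULT_EVALUE_MAX
) -> list[TabularHit]:
    """Keep hits with evalue <= cutoff (inclusive), preserving order."""
    return [h for h in hits if h.evalue <= evalue_max]


def best_hit(hits: Iterable[TabularHit]) -> Optional[TabularHit]:
    """Best hit for one query: highest bitscore, then lowest e-value, then sid."""
    best: Optional[TabularHit] = None
    for h in hits:
        if best is None:
            best = h
            continue
        if (-h.bitscore, h.evalue, h.sid) < (-best.bitscore, best.evalue, best.sid):
            best = h
    return best


def best_hits_per_query(hits: Iterable[TabularHit]) -> dict[str, TabularHit]:
    """Best hit for every query id present in the hit list."""
    by_query: dict[str, TabularHit] = {}
    for h in hits:
        current = by_query.get(h.qid)
        if current is None or (-h.bitscore, h.evalue, h.sid) < (
            -current.bitscore,
            current.evalue,
            current.sid,
        ):
            by_query[h.qid] = h
    return by_query


def annotation_summary(
    n_unigenes: int,
    hits: list[TabularHit],
    db_name: str,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> AnnotationSummary:
    """Count distinct annotated queries against one database."""
    passing = filter_hits(hits, evalue_max)
    n_annotated = len({h.qid for h in passing})
    if n_annotated > n_unigenes:
        raise ValueError(
            f"{n_annotated} annotated queries exceed {n_unigenes} unigenes"
        )
    return AnnotationSummary(
        db_name=db_name,
        n_unigenes=n_unigenes,
        n_annotated=n_annotated,
        n_unannotated=n_unigenes - n_annotated,
        pct_annotated=round(100 * n_annotated / n_unigenes) if n_unigenes else 0,
    )


def _merged_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    cur_start = cur_end = None
    for start, end in sorted(intervals):
        if cur_end is None or start > cur_end:
            if cur_end is not None:
                total += cur_end - cur_start
            cur_start, cur_end = start, end
        else:
            cur_end = max(cur_end, end)
    if cur_end is not None:
        total += cur_end - cur_start
    return total


def subject_coverage(hits: list[TabularHit], slen: int) -> float:
    """Covered fraction of a subject by one query's HSPs (interval union).

    All hits must belong to the same (query, subject) pair in intent; the
    function merges their subject spans. Spans outside [1, slen] are an
    error.
    """
    if slen <= 0:
        raise ValueError("subject length must be positive")
    intervals = []
    for h in hits:
        if h.sstart < 1 or h.send > slen:
            raise ValueError(
                f"hit {h.qid}->{h.sid}: subject span ({h.sstart},{h.send}) "
                f"outside [1,{slen}]"
            )
        intervals.append(h.s_interval0)
    return _merged_length(intervals) / slen


def count_full_length(
    hits: list[TabularHit],
    slen_table: Mapping[str, int],
    threshold: float = DEFAULT_FULL_LENGTH_THRESHOLD,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    union_across_queries: bool = False,
) -> tuple[int, list[CoverageRecord]]:
    """Count subjects covered to >= threshold and report per-subject coverage.

    Default mode: per subject, take the maximum over single queries of that
    query's merged subject coverage (HSPs of different queries never merge).
    ``union_across_queries=True`` instead merges every passing HSP on the
    subject regardless of query. The threshold is inclusive.
    """
    passing = filter_hits(hits, evalue_max)
    by_subject: dict[str, dict[str, list[TabularHit]]] = {}
    for h in passing:
        if h.sid not in slen_table:
            raise KeyError(f"subject {h.sid!r} missing from length table")
        by_subject.setdefault(h.sid, {}).setdefault(h.qid, []).append(h)
    records: list[CoverageRecord] = []
    for sid in sorted(by_subject):
        slen = slen_table[sid]
        queries = by_subject[sid]
        if union_across_queries:
            all_hits = [h for hs in queries.values() for h in hs]
            cov = subject_coverage(all_hits, slen)
            best_qid = min(queries) if queries else None
            best_cov = cov
        else:
            best_qid, best_cov = None, 0.0
            for qid in sorted(queries):
                cov = subject_coverage(queries[qid], slen)
                if cov > best_cov:
                    best_qid, best_cov = qid, cov
        records.append(
            CoverageRecord(
                sid=sid,
                slen=slen,
                best_qid=best_qid,
                best_coverage_frac=best_cov,
                is_full_length=best_cov >= threshold,
            )
        )
    count = sum(1 for r in records if r.is_full_length)
    return count, records


def transcriptome_coverage(
    hits: list[TabularHit],
    slen_table: Optional[Mapping[str, int]] = None,
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> tuple[int, int]:
    """(distinct queries with a passing hit, distinct subjects hit)."""
    passing = filter_hits(hits, evalue_max)
    return len({h.qid for h in passing}), len({h.sid for h in passing})


def keyword_tally(
    annotations: Mapping[str, str],
    families: Mapping[str, list[str]],
) -> dict[str, int]:
    """Count queries whose best-hit description matches each gene family.

    Patterns are case-insensitive substrings; a query may count toward more
    than one family.
    """
    counts = {family: 0 for family in families}
    lowered = {qid: desc.lower() for qid, desc in annotations.items()}
    for family, patterns in families.items():
        pats = [p.lower() for p in patterns]
        counts[family] = sum(
            1 for desc in lowered.values() if any(p in desc for p in pats)
        )
    return counts
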