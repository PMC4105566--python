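"""Aggregate reporting: evaluation tables, annotation tables, reads-per-contig
histograms, and run-configuration capture.

Every table is written both as TSV (human-facing, columns mirroring the
classic assembly-selection summary layout) and as a JSON twin with the same
fields. Outputs contain no timestamps, so a rerun from a saved configuration
is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from . import __version__
from .annotation import AnnotationSummary
from .consistency import AssemblyEvaluation
from .core_io import Assembly


@dataclass
class RunConfig:
    """All tunables of a toolkit run, serialized into every output directory.

    ``provenance`` marks each knob "default" or "user"; reruns from a saved
    config reproduce outputs byte-identically.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = -3
    gap_extend: int = -1
    evalue_max: float = 1e-5
    full_length_threshold: float = 0.90
    merge_threshold: float = 75.0
    ssr_min_units: dict[str, int] = field(
        default_factory=lambda: {"di": 6, "tri": 4, "tetra": 3, "penta": 3, "hexa": 3}
    )
    clip_min_len: int = 20
    adapter_max_mismatch_frac: float = 0.1
    adapter_min_match: int = 10
    seed: int = 0
    provenance: dict[str, str] = field(default_factory=dict)

    def with_overrides(self, **kwargs) -> "RunConfig":
        cfg = dataclasses.replace(self)
        for key, value in kwargs.items():
            if not hasattr(cfg, key):
                raise AttributeError(f"unknown config key {key!r}")
            setattr(cfg, key, value)
            cfg.provenance[key] = "user"
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["tool_version"] = __version__
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        payload.pop("tool_version", None)
        return cls(**payload)


def reads_per_contig_histogram(
    assembly: Assembly, membership: Mapping[str, str]
) -> dict[int, int]:
    """Histogram over contigs of member-read count; singletons excluded.

    The membership map must agree with the assembly's contig membership.
    """
    contig_ids = {c.id for c in assembly.contigs}
    counts: dict[str, int] = {cid: 0 for cid in contig_ids}
    for rid, cid in membership.items():
        if cid in counts:
            counts[cid] += 1
    for contig in assembly.contigs:
        if counts[contig.id] != len(contig.members):
            raise ValueError(
                f"membership disagrees with contig {contig.id!r} member list"
            )
    histogram: dict[int, int] = {}
    for n in counts.values():
        histogram[n] = histogram.get(n, 0) + 1
    return histogram


_EVAL_COLUMNS = [
    ("ASSEMBLY", "assembly_name"),
    ("NUMBER_OF_SEQUENCES_CLUSTERED", "n_clustered_reads"),
    ("NUMBER_OF_CONTIGS", "n_contigs"),
    ("AVERAGE_CONTIG_SIZE", "mean_contig_len"),
    ("NUMBER_OF_UNIGENES", "n_unigenes"),
    ("AVERAGE_UNIGENE_SIZE", "mean_unigene_len"),
    ("AVERAGE_ICI_SCORE", "mean_ici"),
    ("AVERAGE_ECI_SCORE", "mean_eci"),
    ("UNIGENES_ANNOTATED", "n_annotated"),
]


def _format_cell(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return f"{value:.2f}"
    return str(value)


def render_reports(
    outdir: str | Path,
    evaluations: Optional[Sequence[AssemblyEvaluation]] = None,
    summaries: Optional[Sequence[AnnotationSummary]] = None,
    histogram: Optional[Mapping[int, int]] = None,
    config: Optional[RunConfig] = None,
) -> list[Path]:
    """Write the requested report files into ``outdir``; return paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if evaluations is not None:
        tsv = outdir / "evaluation.tsv"
        with tsv.open("w") as fh:
            fh.write("\t".join(name for name, _ in _EVAL_COLUMNS) + "\n")
            for row in evaluations:
                fh.write(
                    "\t".join(
                        _format_cell(getattr(row, attr)) for _, attr in _EVAL_COLUMNS
                    )
                    + "\n"
                )
        js = outdir / "evaluation.json"
        js.write_text(
            json.dumps(
                [dataclasses.asdict(row) for row in evaluations],
                indent=1,
                sort_keys=True,
            )
        )
        written += [tsv, js]

    if summaries is not None:
        tsv = outdir / "annotation.tsv"
        with tsv.open("w") as fh:
            fh.write("DATABASE\tN_UNIGENES\tN_ANNOTATED\tN_NOT_ANNOTATED\tPCT_ANNOTATED\n")
            for s in summaries:
                fh.write(
                    f"{s.db_name}\t{s.n_unigenes}\t{s.n_annotated}\t"
                    f"{s.n_unannotated}\t{s.pct_annotated}\n"
                )
        js = outdir / "annotation.json"
        js.write_text(
            json.dumps(
                [dataclasses.asdict(s) for s in summaries], indent=1, sort_keys=True
            )
        )
        written += [tsv, js]

    if histogram is not None:
        tsv = outdir / "reads_per_contig.tsv"
        with tsv.open("w") as fh:
            fh.write("N_READS\tN_CONTIGS\n")
            for n_reads in sorted(histogram):
                fh.write(f"{n_reads}\t{histogram[n_reads]}\n")
        written.append(tsv)

    if config is not None:
        cfg_path = outdir / "config.used.yaml"
        config.to_yaml(cfg_path)
        written.append(cfg_path)

    return written


def plot_reads_per_contig(histogram: Mapping[int, int], path: str | Path) -> None:
    """Optional SVG scatter of contig count by member-read count."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = sorted(histogram)
    ys = [histogram[x] for x in xs]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(xs, ys, marker="^", linestyle="none")
    ax.set_xlabel("reads per contig")
    ax.set_ylabel("number of contigs")
    ax.set_yscale("log")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
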