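"""TSV/BED/GFF3 readers and writers and the run configuration.

All tabular formats are tab-separated with a ``#``-prefixed comment
header carrying the schema version, the seed and a config hash; readers
skip comment lines. Internal coordinates are 1-based inclusive: BED
(0-based half-open) is converted on read, GFF3 (1-based inclusive)
passes through.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome import (
    ElementTrack,
    ExpressionTable,
    GenomeLayout,
    Segment,
    segment_from_markers,
)
from .rates import CountTable, RateEstimate
from .starvation import StarvationSeries, TimeRateEstimate

__all__ = [
    "SCHEMA_VERSION",
    "RunConfig",
    "read_layout",
    "read_segments",
    "read_count_table",
    "write_count_tables",
    "read_tracks",
    "read_expression",
    "write_rate_estimates",
    "read_starvation_series",
    "write_starvation_series",
]

SCHEMA_VERSION = "1"

_COUNT_COLS = ["strain", "chrom", "arm", "medium", "replicate", "count", "N", "s"]
_STARV_COLS = [
    "strain", "chrom", "arm", "medium", "day",
    "viable_count", "mutant_count", "viable_fraction", "mutant_fraction",
]


@dataclass
class RunConfig:
    """Validated paths and options for a full pipeline run."""

    counts_path: Path
    segments_path: Path
    layout_path: Path | None = None
    tracks_path: Path | None = None
    expression_path: Path | None = None
    starvation_path: Path | None = None
    outdir: Path = Path("lohscape_out")
    seed: int = 0
    bootstrap: int = 10_000
    ci_level: float = 0.95
    exclude: tuple[str, ...] = ()
    verbose: bool = False

    def validate(self) -> None:
        for name in ("counts_path", "segments_path", "layout_path",
                     "tracks_path", "expression_path", "starvation_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p} does not exist")

    def config_hash(self) -> str:
        payload = {
            k: str(v) for k, v in sorted(self.__dict__.items())
        }
        return hashlib.sha256(json.dumps(payload).encode()).hexdigest()[:12]


def _header(seed: int | None = None, config_hash: str = "") -> str:
    parts = [f"# lohscape schema={SCHEMA_VERSION}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    if config_hash:
        parts.append(f"config={config_hash}")
    return " ".join(parts)


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return df


def read_layout(path: str | Path) -> GenomeLayout:
    df = _read_tsv(path, ["chrom", "length", "cen_pos"])
    return GenomeLayout.from_records(
        (r.chrom, int(r.length), int(r.cen_pos)) for r in df.itertuples()
    )


def read_segments(path: str | Path, layout: GenomeLayout) -> list[Segment]:
    df = _read_tsv(path, ["chrom", "kan_pos", "ura3_pos"])
    return [
        segment_from_markers(layout, r.chrom, int(r.kan_pos), int(r.ura3_pos))
        for r in df.itertuples()
    ]


def write_segments(segments: Sequence[Segment], path: str | Path,
                   seed: int | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed) + "\n")
        fh.write("chrom\tarm\tkan_pos\tura3_pos\n")
        for s in segments:
            fh.write(f"{s.chromosome}\t{s.arm}\t{s.kan_pos}\t{s.ura3_pos}\n")


def read_count_table(
    path: str | Path, segments: Mapping[str, Segment] | None = None
) -> list[CountTable]:
    """Read replicate colony counts grouped into CountTables.

    Rows are grouped by (strain, chrom+arm, medium); ``N`` and ``s`` must
    be constant within a group. Malformed rows are rejected with their
    line numbers (1-based, counting comments and the header).
    """
    path = Path(path)
    df = _read_tsv(path, _COUNT_COLS)
    # recover original line numbers for error messages
    with open(path) as fh:
        lines = fh.readlines()
    data_lines = [
        i + 1
        for i, l in enumerate(lines)
        if not l.startswith("#") and l.strip()
    ][1:]  # skip header line
    bad = df.index[(df["count"] < 0) | (df["count"] != df["count"].astype(int))]
    if len(bad):
        lineno = data_lines[bad[0]] if bad[0] < len(data_lines) else "?"
        raise ValueError(
            f"{path}:{lineno}: negative or non-integer count {df.loc[bad[0], 'count']}"
        )
    tables = []
    for (strain, chrom, arm, medium), grp in df.groupby(
        ["strain", "chrom", "arm", "medium"], sort=True
    ):
        if grp["N"].nunique() > 1 or grp["s"].nunique() > 1:
            raise ValueError(
                f"{path}: N or s varies within {strain}/{chrom}{arm}/{medium}"
            )
        seg_name = f"{chrom}{arm}"
        seg = segments.get(seg_name) if segments else None
        tables.append(
            CountTable(
                counts=tuple(int(c) for c in grp.sort_values("replicate")["count"]),
                N=float(grp["N"].iloc[0]),
                s=float(grp["s"].iloc[0]),
                strain=str(strain),
                segment=seg,
                segment_name=seg_name,
                medium=str(medium),
            )
        )
    return tables


def write_count_tables(
    tables: Iterable[CountTable], path: str | Path, seed: int | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed) + "\n")
        fh.write("\t".join(_COUNT_COLS) + "\n")
        for t in tables:
            if t.segment is not None:
                chrom, arm = t.segment.chromosome, t.segment.arm
            else:
                name = t.segment_name or "?"
                chrom, arm = name[:-1], name[-1:]
            for i, c in enumerate(t.counts, start=1):
                fh.write(
                    f"{t.strain}\t{chrom}\t{arm}\t{t.medium}\t{i}\t{c}"
                    f"\t{t.N:.6g}\t{t.s:.6g}\n"
                )


def read_tracks(path: str | Path, fmt: str | None = None) -> list[ElementTrack]:
    """Read element intervals from BED or GFF3, one track per class.

    BED: 0-based half-open, name column (4th) is the element class;
    converted to 1-based inclusive. GFF3: 1-based inclusive, class from
    the type column (3rd). Format inferred from the suffix when ``fmt``
    is None.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "bed"
    by_class: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fmt == "bed":
                chrom, start0, end0 = fields[0], int(fields[1]), int(fields[2])
                cls = fields[3] if len(fields) > 3 else "element"
                start, end = start0 + 1, end0  # to 1-based inclusive
            else:
                chrom, cls = fields[0], fields[2]
                start, end = int(fields[3]), int(fields[4])
            if end < start:
                raise ValueError(f"{path}:{lineno}: end {end} < start {start}")
            by_class.setdefault(cls, []).append((chrom, start, end))
    return [
        ElementTrack(element_class=cls, intervals=tuple(ivs))
        for cls, ivs in sorted(by_class.items())
    ]


def read_expression(path: str | Path) -> ExpressionTable:
    """TSV with gene, chrom, start, end plus one abundance column per
    environment; abundances are renormalised to fractions of total."""
    df = _read_tsv(path, ["gene", "chrom", "start", "end"])
    envs = [c for c in df.columns if c not in ("gene", "chrom", "start", "end")]
    if not envs:
        raise ValueError(f"{path}: no abundance columns")
    genes = [
        (str(r.gene), str(r.chrom), int(r.start), int(r.end))
        for r in df.itertuples()
    ]
    raw = {env: df[env].astype(float).tolist() for env in envs}
    return ExpressionTable.from_raw(genes, raw)


def write_rate_estimates(
    estimates: Iterable[RateEstimate], path: str | Path, seed: int | None = None
) -> None:
    cols = [
        "strain", "segment", "medium", "mu", "ci_low", "ci_high",
        "corrected", "unit", "f_hat", "n_replicates", "zero_fraction", "nondetect",
    ]
    with open(path, "w") as fh:
        fh.write(_header(seed) + "\n")
        fh.write("\t".join(cols) + "\n")
        for e in estimates:
            seg = e.segment.name if e.segment is not None else ""
            fh.write(
                f"{e.strain}\t{seg}\t{e.medium}\t{e.mu:.6g}\t{e.ci_low:.6g}"
                f"\t{e.ci_high:.6g}\t{int(e.corrected)}\t{e.unit}\t{e.f_hat:.6g}"
                f"\t{e.n_replicates}\t{e.zero_fraction:.6g}\t{int(e.nondetect)}\n"
            )


def read_starvation_series(path: str | Path) -> list[StarvationSeries]:
    df = _read_tsv(path, _STARV_COLS)
    out = []
    for (strain, chrom, arm, medium), grp in df.groupby(
        ["strain", "chrom", "arm", "medium"], sort=True
    ):
        grp = grp.sort_values("day")
        out.append(
            StarvationSeries(
                strain=str(strain),
                timepoints=tuple(float(d) for d in grp["day"]),
                viable_counts=tuple(int(v) for v in grp["viable_count"]),
                mutant_counts=tuple(int(m) for m in grp["mutant_count"]),
                viable_sampled_fraction=float(grp["viable_fraction"].iloc[0]),
                mutant_sampled_fraction=float(grp["mutant_fraction"].iloc[0]),
                segment_name=f"{chrom}{arm}",
                medium=str(medium),
            )
        )
    return out


def write_starvation_series(
    series: Iterable[StarvationSeries], path: str | Path, seed: int | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed) + "\n")
        fh.write("\t".join(_STARV_COLS) + "\n")
        for s in series:
            if s.segment is not None:
                chrom, arm = s.segment.chromosome, s.segment.arm
            else:
                name = s.segment_name or "?"
                chrom, arm = name[:-1], name[-1:]
            for day, v, m in zip(s.timepoints, s.viable_counts, s.mutant_counts):
                fh.write(
                    f"{s.strain}\t{chrom}\t{arm}\t{s.medium}\t{day:g}\t{v}\t{m}"
                    f"\t{s.viable_sampled_fraction:.6g}"
                    f"\t{s.mutant_sampled_fraction:.6g}\n"
                )


def write_time_rates(
    estimates: Iterable[TimeRateEstimate], path: str | Path, seed: int | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed) + "\n")
        fh.write("strain\tsegment\tmedium\tslope_per_2h\tintercept\tslope_se\tpvalue\tn\n")
        for e in estimates:
            fh.write(
                f"{e.strain}\t{e.segment_name}\t{e.medium}\t{e.slope:.6g}"
                f"\t{e.intercept:.6g}\t{e.slope_se:.6g}\t{e.pvalue:.6g}\t{e.n_points}\n"
            )
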