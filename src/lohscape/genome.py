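"""Chromosome, arm and segment geometry plus annotation tracks.

Coordinates are 1-based inclusive throughout (SGD convention); distances in
bp; densities normalised per 10,000 bp. A *segment* is a between-marker
stretch of one chromosome arm: a *kan* (geneticin-resistance) insert near
the centromere and a *URA3* (5-FOA counterselectable) insert further out,
so that selection on geneticin + 5-FOA reports recombination between the
two markers rather than whole-chromosome loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Chromosome",
    "GenomeLayout",
    "Segment",
    "ElementTrack",
    "ExpressionTable",
    "segment_from_markers",
    "element_density",
    "transcription_intensity",
]

DENSITY_WINDOW = 10_000  # bp; densities are reported per 10 kb


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere: int

    def __post_init__(self) -> None:
        if not (0 < self.centromere < self.length):
            raise ValueError(
                f"{self.name}: centromere {self.centromere} outside (0, {self.length})"
            )


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome lengths and centromere positions for one genome build."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        object.__setattr__(
            self, "_by_name", {c.name: c for c in self.chromosomes}
        )

    def __getitem__(self, name: str) -> Chromosome:
        try:
            return self._by_name[name]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._by_name  # type: ignore[attr-defined]

    def __len__(self) -> int:
        return len(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int]]
    ) -> "GenomeLayout":
        return cls(tuple(Chromosome(n, int(l), int(c)) for n, l, c in records))


@dataclass(frozen=True)
class Segment:
    """A marked between-marker interval on one chromosome arm.

    ``d`` is the physical kan--URA3 distance, the denominator of every
    per-10 kb density. ``dist_cen`` / ``dist_tel`` are the distances from
    the segment to the centromere and telomere respectively (measured to
    the marker nearer each landmark).
    """

    chromosome: str
    arm: str  # "L" or "R"
    kan_pos: int
    ura3_pos: int
    d: int
    dist_cen: int
    dist_tel: int

    def __post_init__(self) -> None:
        if self.arm not in ("L", "R"):
            raise ValueError(f"arm must be 'L' or 'R', got {self.arm!r}")
        if self.d <= 0:
            raise ValueError("inter-marker distance d must be positive")
        if self.dist_cen < 0 or self.dist_tel < 0:
            raise ValueError("distances to landmarks must be non-negative")

    @property
    def name(self) -> str:
        return f"{self.chromosome}{self.arm}"

    @property
    def start(self) -> int:
        return min(self.kan_pos, self.ura3_pos)

    @property
    def end(self) -> int:
        return max(self.kan_pos, self.ura3_pos)


def segment_from_markers(
    layout: GenomeLayout, chromosome: str, kan_pos: int, ura3_pos: int
) -> Segment:
    """Build a :class:`Segment` from marker coordinates.

    The arm is inferred from the side of the centromere both markers lie
    on; a marker pair straddling the centromere is an invalid design and
    raises ``ValueError``.
    """
    chrom = layout[chromosome]
    for label, pos in (("kan", kan_pos), ("URA3", ura3_pos)):
        if not (1 <= pos <= chrom.length):
            raise ValueError(
                f"{label} position {pos} outside {chromosome} (1..{chrom.length})"
            )
    d = abs(ura3_pos - kan_pos)
    if d == 0:
        raise ValueError("kan and URA3 positions coincide (d = 0)")
    cen = chrom.centromere
    if (kan_pos - cen) * (ura3_pos - cen) < 0 or kan_pos == cen or ura3_pos == cen:
        raise ValueError(
            f"markers {kan_pos} and {ura3_pos} straddle the centromere at {cen}"
        )
    arm = "R" if kan_pos > cen else "L"
    if arm == "R":
        dist_cen = min(kan_pos, ura3_pos) - cen
        dist_tel = chrom.length - max(kan_pos, ura3_pos)
    else:
        dist_cen = cen - max(kan_pos, ura3_pos)
        dist_tel = min(kan_pos, ura3_pos) - 1
    return Segment(
        chromosome=chromosome,
        arm=arm,
        kan_pos=kan_pos,
        ura3_pos=ura3_pos,
        d=d,
        dist_cen=dist_cen,
        dist_tel=dist_tel,
    )


def arm_length(layout: GenomeLayout, segment: Segment) -> int:
    """Physical length of the chromosome arm hosting ``segment``."""
    chrom = layout[segment.chromosome]
    if segment.arm == "R":
        return chrom.length - chrom.centromere
    return chrom.centromere - 1


@dataclass(frozen=True)
class ElementTrack:
    """Intervals of one repetitive-element class (ARS, LTR, tRNA, ...).

    The class label is configuration, not code: any label may be used.
    Intervals are (chromosome, start, end), 1-based inclusive.
    """

    element_class: str
    intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(
                    f"{self.element_class} interval on {chrom}: start {start} >= end {end}"
                )

    def __len__(self) -> int:
        return len(self.intervals)


def element_density(track: ElementTrack, segment: Segment) -> float:
    """Number of track intervals per 10 kb of the between-marker stretch.

    Membership is by interval midpoint, closed on both ends of the
    segment, so splitting a segment in two conserves total counts.
    """
    lo, hi = segment.start, segment.end
    count = 0
    for chrom, start, end in track.intervals:
        if chrom != segment.chromosome:
            continue
        mid = (start + end) / 2
        if lo <= mid <= hi:
            count += 1
    return count / (segment.d / DENSITY_WINDOW)


@dataclass(frozen=True)
class ExpressionTable:
    """Per-gene mRNA abundances (fraction of total cellular mRNA).

    One abundance column per environment; abundances within an environment
    are normalised to sum to 1.
    """

    genes: tuple[tuple[str, str, int, int], ...]  # (gene_id, chrom, start, end)
    abundances: Mapping[str, tuple[float, ...]]  # environment -> per-gene fractions
    _TOL: float = field(default=1e-6, repr=False)

    def __post_init__(self) -> None:
        n = len(self.genes)
        for env, vals in self.abundances.items():
            if len(vals) != n:
                raise ValueError(f"environment {env!r}: {len(vals)} values for {n} genes")
            if any(v < 0 for v in vals):
                raise ValueError(f"environment {env!r}: negative abundance")
            total = sum(vals)
            if total > 0 and abs(total - 1.0) > self._TOL:
                raise ValueError(
                    f"environment {env!r}: abundances sum to {total}, not 1"
                )

    @property
    def environments(self) -> tuple[str, ...]:
        return tuple(self.abundances)

    @classmethod
    def from_raw(
        cls,
        genes: Sequence[tuple[str, str, int, int]],
        raw: Mapping[str, Sequence[float]],
    ) -> "ExpressionTable":
        """Normalise raw per-environment abundances to fractions of total."""
        norm = {}
        for env, vals in raw.items():
            total = float(sum(vals))
            norm[env] = tuple(v / total for v in vals) if total > 0 else tuple(vals)
        return cls(tuple(genes), norm)


def transcription_intensity(
    expr: ExpressionTable, segment: Segment, environment: str
) -> float:
    """Fraction of total cellular mRNA produced per 10 kb of the segment.

    Genes are assigned by midpoint, closed on both segment ends, matching
    :func:`element_density`.
    """
    if environment not in expr.abundances:
        raise KeyError(
            f"unknown environment {environment!r}; have {list(expr.abundances)}"
        )
    vals = expr.abundances[environment]
    lo, hi = segment.start, segment.end
    total = 0.0
    for (gene, chrom, start, end), v in zip(expr.genes, vals):
        if chrom != segment.chromosome:
            continue
        mid = (start + end) / 2
        if lo <= mid <= hi:
            total += v
    return total / (segment.d / DENSITY_WINDOW)
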