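"""Packaged fixtures: the yeast genome layout and marker-panel builders."""

from __future__ import annotations

from importlib import resources

from .genome import GenomeLayout, Segment, segment_from_markers

__all__ = ["yeast_layout", "midarm_panel", "variable_panel", "ROMAN"]

ROMAN = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII",
    "IX", "X", "XI", "XII", "XIII", "XIV", "XV", "XVI",
]


def yeast_layout() -> GenomeLayout:
    """The packaged approximate S. cerevisiae chromosome layout."""
    records = []
    text = (
        resources.files("lohscape").joinpath("data/genome_sc.tsv").read_text()
    )
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("chrom\t"):
            continue
        name, length, cen = line.split("\t")
        records.append((name, int(length), int(cen)))
    return GenomeLayout.from_records(records)


def midarm_panel(
    layout: GenomeLayout | None = None,
    cen_offset: int = 10_000,
    min_arm: int = 30_000,
) -> list[Segment]:
    """Build the 32-segment mid-arm marker panel (1L .. 16R).

    Emulates the single-arm marking design: on every chromosome arm, kan
    is inserted ``cen_offset`` bp from the centromere and URA3 at the arm
    midpoint, so each segment spans the inner half of its arm. Arms
    shorter than ``min_arm`` would leave no room between the markers and
    are skipped (none are, with the packaged layout).
    """
    if layout is None:
        layout = yeast_layout()
    segments = []
    for chrom in layout.chromosomes:
        left_len = chrom.centromere - 1
        right_len = chrom.length - chrom.centromere
        if left_len >= min_arm:
            kan = chrom.centromere - cen_offset
            ura3 = chrom.centromere - left_len // 2
            segments.append(
                segment_from_markers(layout, chrom.name, kan, ura3)
            )
        if right_len >= min_arm:
            kan = chrom.centromere + cen_offset
            ura3 = chrom.centromere + right_len // 2
            segments.append(
                segment_from_markers(layout, chrom.name, kan, ura3)
            )
    return segments


def variable_panel(
    layout: GenomeLayout | None = None,
    n: int = 23,
    segment_length: int = 40_000,
    margin: int = 20_000,
) -> list[Segment]:
    """Build a panel of ~40 kb segments at variable arm positions.

    Emulates the variably-positioned marker design: segments of fixed
    length placed at different fractional positions along different arms
    (kan on the centromere-proximal end, URA3 distal), so that distances
    to centromere and telomere vary across the panel. Deterministic:
    arms are taken longest-first and position fractions cycle through a
    fixed ladder.
    """
    if layout is None:
        layout = yeast_layout()
    half = segment_length // 2
    fractions = [0.2, 0.35, 0.5, 0.65, 0.8]
    arms = []
    for chrom in layout.chromosomes:
        arms.append((chrom.centromere - 1, chrom.name, "L"))
        arms.append((chrom.length - chrom.centromere, chrom.name, "R"))
    arms.sort(reverse=True)
    segments = []
    i = 0
    for arm_len, name, side in arms:
        if len(segments) >= n:
            break
        frac = fractions[i % len(fractions)]
        i += 1
        center = int(round(frac * arm_len))
        if center - half < margin or center + half > arm_len - margin:
            center = min(max(center, margin + half), arm_len - margin - half)
            if center - half < margin:
                continue  # arm too short for this design
        chrom = layout[name]
        if side == "R":
            kan = chrom.centromere + center - half
            ura3 = chrom.centromere + center + half
        else:
            kan = chrom.centromere - (center - half)
            ura3 = chrom.centromere - (center + half)
        segments.append(segment_from_markers(layout, name, kan, ura3))
    return segments
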