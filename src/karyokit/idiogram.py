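"""Deterministic SVG idiograms.

One glyph pair per rank, left-to-right by rank, short arm up, centromere gap
placed so the drawn arm proportions equal the arm ratio.  Satellites render
as a small circle above the short-arm terminus, secondary constrictions as a
notch line, NOR-bearing pairs as a filled triangle — all on the short-arm
terminus, where terminal constrictions sit in these karyotypes.  The SVG is
assembled as plain text so re-rendering the same karyotype is byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .types import Karyotype, PairProfile

__all__ = ["IdiogramLayout", "render_idiogram"]

_TYPE_FILL = {
    "m": "#4daf4a",
    "sm": "#377eb8",
    "st": "#ff7f00",
    "t": "#e41a1c",
}


@dataclass
class IdiogramLayout:
    """Geometry and styling of an idiogram.

    ``scale`` is pixels per relative-length percent (idiograms default to
    relative units so diploids and tetraploids are directly comparable).
    """

    scale: float = 28.0
    chrom_width: float = 14.0
    homolog_gap: float = 6.0
    pair_spacing: float = 52.0
    margin: float = 40.0
    centromere_gap: float = 4.0
    label_offset: float = 16.0
    type_fill: dict = field(default_factory=lambda: dict(_TYPE_FILL))


def _chromosome_glyph(
    x: float,
    y_centromere: float,
    rel_length: float,
    ratio: float,
    levan: str,
    layout: IdiogramLayout,
    satellite: bool,
    constriction: bool,
    nor: bool,
) -> list[str]:
    h = rel_length * layout.scale
    short = h / (1.0 + ratio)
    long = h - short
    w = layout.chrom_width
    g = layout.centromere_gap / 2.0
    fill = layout.type_fill.get(levan, "#999999")
    parts = [
        f'<rect x="{x:.2f}" y="{y_centromere - g - short:.2f}" width="{w:.2f}" '
        f'height="{short:.2f}" rx="3" fill="{fill}" stroke="#333" stroke-width="1"/>',
        f'<rect x="{x:.2f}" y="{y_centromere + g:.2f}" width="{w:.2f}" '
        f'height="{long:.2f}" rx="3" fill="{fill}" stroke="#333" stroke-width="1"/>',
    ]
    top = y_centromere - g - short
    if constriction:
        yc = top + 0.15 * short
        parts.append(
            f'<line x1="{x - 2:.2f}" y1="{yc:.2f}" x2="{x + w + 2:.2f}" '
            f'y2="{yc:.2f}" stroke="#fff" stroke-width="2"/>'
        )
    if satellite:
        parts.append(
            f'<circle cx="{x + w / 2:.2f}" cy="{top - 5:.2f}" r="3" '
            f'fill="{fill}" stroke="#333" stroke-width="1"/>'
        )
    if nor:
        parts.append(
            f'<path d="M {x + w / 2 - 4:.2f} {top - 12:.2f} h 8 l -4 6 z" '
            f'fill="#000"/>'
        )
    return parts


def render_idiogram(k: Karyotype, layout: IdiogramLayout | None = None) -> str:
    """Render a classified karyotype as an SVG document (a string)."""
    if not k.pairs:
        raise ValueError("cannot render an empty karyotype")
    layout = layout or IdiogramLayout()
    max_rel = max(p.mean_rel_length_pct for p in k.pairs)
    # centromere line placed so the longest long arm fits below it
    max_short = max(
        p.mean_rel_length_pct / (1.0 + min(p.homolog_ratios)) for p in k.pairs
    )
    max_long = max(
        p.mean_rel_length_pct * r / (1.0 + r)
        for p in k.pairs
        for r in (min(p.homolog_ratios),)
    )
    y_cent = layout.margin + max_short * layout.scale + 20
    height = y_cent + max_long * layout.scale + layout.margin
    width = layout.margin * 2 + len(k.pairs) * layout.pair_spacing
    body: list[str] = []
    for idx, p in enumerate(k.pairs):
        x0 = layout.margin + idx * layout.pair_spacing
        sat_a = p.satellite_seen in ("one_homolog", "both")
        sat_b = p.satellite_seen == "both"
        for hom, (ratio, levan, sat) in enumerate(
            [(p.arm_ratio_a, p.type_a, sat_a), (p.arm_ratio_b, p.type_b, sat_b)]
        ):
            x = x0 + hom * (layout.chrom_width + layout.homolog_gap)
            body += _chromosome_glyph(
                x,
                y_cent,
                _homolog_rel(p, hom),
                ratio,
                levan or "m",
                layout,
                satellite=sat,
                constriction=sat,
                nor=p.nor,
            )
        label_x = x0 + layout.chrom_width + layout.homolog_gap / 2
        body.append(
            f'<text x="{label_x:.2f}" y="{height - layout.label_offset:.2f}" '
            f'font-size="11" text-anchor="middle" font-family="sans-serif">'
            f"{p.rank}</text>"
        )
    title = f"{k.accession_id}  2n={k.two_n}  {k.formula}  {k.stebbins}"
    doc = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width:.0f}" '
        f'height="{height:.0f}" viewBox="0 0 {width:.0f} {height:.0f}">',
        f'<title>{title}</title>',
        f'<text x="{layout.margin:.2f}" y="{layout.margin / 2:.2f}" '
        f'font-size="13" font-family="sans-serif">{title}</text>',
        *body,
        "</svg>",
    ]
    _ = max_rel
    return "\n".join(doc) + "\n"


def _homolog_rel(p: PairProfile, hom: int) -> float:
    if p.rel_length_pct_b is None or hom == 0:
        return p.rel_length_pct
    return p.rel_length_pct_b


def save_idiogram(k: Karyotype, path: str | Path, layout: IdiogramLayout | None = None) -> None:
    Path(path).write_text(render_idiogram(k, layout))
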