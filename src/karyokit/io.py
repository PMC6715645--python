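"""Readers and writers for measurement tables, pair-profile tables and reports.

Formats (tab- or comma-delimited, auto-detected from the header line; '#'
lines are comments; decimal point only):

measurement table — one row per chromosome per metaphase spread::

    accession  cell  chrom  short_um  long_um  satellite  sec_constriction  nor

  the three annotation columns are optional and default to false / ``none``.

pair-profile table — one row per homologous pair, mirroring published
karyotype tables; ``rel_length_pct`` and ``arm_ratio`` accept double entries
``a/b`` for pairs whose homologs were measured separately (heteromorphic
candidates)::

    accession  rank  rel_length_pct  arm_ratio

The karyotype report written by :func:`write_karyotype_report` is a valid
pair-profile table (extra columns and '#' metadata lines are ignored on
re-read), so reports round-trip losslessly at the printed 2-decimal
precision.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path
from typing import Sequence

from .metrics import round_half_up
from .types import (
    ChromosomeMeasurement,
    Karyotype,
    KaryotypeFormula,
    MetaphaseCell,
    PairProfile,
    StebbinsClass,
)

__all__ = [
    "read_measurement_table",
    "write_measurement_table",
    "read_pair_profiles",
    "write_karyotype_report",
    "karyotype_to_json",
    "karyotype_from_json",
]

logger = logging.getLogger("karyokit.io")

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n", ""}


def _parse_bool(s: str, where: str) -> bool:
    v = s.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise ValueError(f"{where}: cannot parse boolean {s!r}")


def _read_rows(path: str | Path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Split a delimited text file into header and (line_number, fields) rows."""
    text = Path(path).read_text()
    lines = [
        (i, ln)
        for i, ln in enumerate(text.splitlines(), start=1)
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise ValueError(f"{path}: empty table")
    header_line = lines[0][1]
    sep = "\t" if "\t" in header_line else ","
    header = [h.strip().lower() for h in header_line.split(sep)]
    rows = [(i, [f.strip() for f in ln.split(sep)]) for i, ln in lines[1:]]
    return header, rows


def _infer_ploidy(two_n: int) -> int:
    return 4 if two_n >= 48 else 2


def read_measurement_table(path: str | Path) -> list[MetaphaseCell]:
    """Read per-chromosome arm measurements grouped into metaphase cells.

    Arms are normalised so long >= short (a notice is logged when a swap was
    needed); each cell's chromosome count becomes its 2n.  Rows with missing
    or non-positive arm lengths are rejected with a row-numbered error, and a
    cell with an odd chromosome count is an error naming the cell.
    """
    header, rows = _read_rows(path)
    required = ["accession", "cell", "chrom", "short_um", "long_um"]
    for col in required:
        if col not in header:
            raise ValueError(f"{path}: missing required column {col!r}")
    idx = {c: header.index(c) for c in header}

    cells: dict[tuple[str, str], list[ChromosomeMeasurement]] = {}
    order: list[tuple[str, str]] = []
    for lineno, fields in rows:
        if len(fields) < len(required):
            raise ValueError(f"{path}:{lineno}: expected >= {len(required)} fields")

        def get(col: str, default: str = "") -> str:
            i = idx.get(col)
            return fields[i] if i is not None and i < len(fields) else default

        try:
            short = float(get("short_um"))
            long = float(get("long_um"))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: unparseable arm length") from exc
        if not (short > 0 and long > 0) or math.isnan(short) or math.isnan(long):
            raise ValueError(
                f"{path}:{lineno}: arm lengths must be positive, got "
                f"({get('short_um')}, {get('long_um')})"
            )
        m = ChromosomeMeasurement(
            cell_id=get("cell"),
            chrom_id=get("chrom"),
            short_arm_um=short,
            long_arm_um=long,
            satellite=_parse_bool(get("satellite", "0"), f"{path}:{lineno}"),
            secondary_constriction=_parse_bool(
                get("sec_constriction", "0"), f"{path}:{lineno}"
            ),
            nor_signal=get("nor", "none") or "none",
        )
        if m.swapped:
            logger.info(
                "%s:%d: arms swapped to enforce long >= short for chromosome %s",
                path,
                lineno,
                m.chrom_id,
            )
        key = (get("accession"), get("cell"))
        if key not in cells:
            cells[key] = []
            order.append(key)
        cells[key].append(m)

    out: list[MetaphaseCell] = []
    for accession, cell_id in order:
        ms = cells[(accession, cell_id)]
        if len(ms) % 2:
            raise ValueError(
                f"{path}: odd chromosome count ({len(ms)}) in cell "
                f"{cell_id!r} of accession {accession!r}"
            )
        two_n = len(ms)
        out.append(
            MetaphaseCell(
                accession_id=accession,
                cell_id=cell_id,
                ploidy=_infer_ploidy(two_n),
                two_n=two_n,
                measurements=ms,
            )
        )
    return out


def write_measurement_table(cells: Sequence[MetaphaseCell], path: str | Path) -> None:
    """Write cells in the measurement-table format (tab-delimited)."""
    lines = ["accession\tcell\tchrom\tshort_um\tlong_um\tsatellite\tsec_constriction\tnor"]
    for c in cells:
        for m in c.measurements:
            lines.append(
                f"{c.accession_id}\t{c.cell_id}\t{m.chrom_id}\t"
                f"{m.short_arm_um:.4f}\t{m.long_arm_um:.4f}\t"
                f"{int(m.satellite)}\t{int(m.secondary_constriction)}\t{m.nor_signal}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def _split_ab(field: str, where: str, minimum: float | None = None) -> tuple[float, float]:
    """Parse a single value or an ``a/b`` double entry."""
    parts = field.split("/")
    if len(parts) == 1:
        parts = parts * 2
    if len(parts) != 2:
        raise ValueError(f"{where}: malformed double entry {field!r}")
    try:
        a, b = (float(p) for p in parts)
    except ValueError as exc:
        raise ValueError(f"{where}: malformed double entry {field!r}") from exc
    if minimum is not None and (a < minimum or b < minimum):
        raise ValueError(
            f"{where}: value below {minimum} in {field!r} "
            "(arm ratios are long arm / short arm, >= 1)"
        )
    return a, b


def read_pair_profiles(path: str | Path) -> list[tuple[str, list[PairProfile]]]:
    """Read a pair-profile table, one ``(accession, profiles)`` per accession.

    Double entries ``a/b`` are split into per-homolog values and the pair is
    marked heteromorphic-candidate when the two ratios differ; single values
    are duplicated to both homologs.
    """
    header, rows = _read_rows(path)
    for col in ("accession", "rank", "rel_length_pct", "arm_ratio"):
        if col not in header:
            raise ValueError(f"{path}: missing required column {col!r}")
    idx = {c: header.index(c) for c in header}

    acc_pairs: dict[str, list[PairProfile]] = {}
    order: list[str] = []
    for lineno, fields in rows:
        where = f"{path}:{lineno}"

        def get(col: str, default: str = "") -> str:
            i = idx.get(col)
            return fields[i] if i is not None and i < len(fields) else default

        rel_a, rel_b = _split_ab(get("rel_length_pct"), where, minimum=0.0)
        ratio_a, ratio_b = _split_ab(get("arm_ratio"), where, minimum=1.0)
        sat = get("satellite_seen", "none") or "none"
        p = PairProfile(
            rank=int(get("rank")),
            rel_length_pct=rel_a,
            rel_length_pct_b=None if rel_b == rel_a else rel_b,
            arm_ratio_a=ratio_a,
            arm_ratio_b=ratio_b,
            heteromorphic=ratio_a != ratio_b,
            satellite_seen=sat,
            nor=_parse_bool(get("nor", "0"), where),
            note=get("note", ""),
        )
        acc = get("accession")
        if acc not in acc_pairs:
            acc_pairs[acc] = []
            order.append(acc)
        acc_pairs[acc].append(p)
    return [(acc, acc_pairs[acc]) for acc in order]


def _fmt_ab(a: float, b: float) -> str:
    if a == b:
        return f"{round_half_up(a):.2f}"
    return f"{round_half_up(a):.2f}/{round_half_up(b):.2f}"


def write_karyotype_report(k: Karyotype, path: str | Path) -> None:
    """Write a karyotype report: metadata comments + a pair-profile table.

    The table part re-reads through :func:`read_pair_profiles` and reproduces
    the pair profiles exactly at 2-decimal precision.
    """
    if not k.pairs:
        raise ValueError("cannot write a report for an empty karyotype")
    meta = [
        f"# accession: {k.accession_id}",
        f"# 2n: {k.two_n}  ploidy: {k.ploidy}",
        f"# formula: {k.formula}",
        f"# stebbins: {k.stebbins}",
    ]
    if k.haploid_total_um is not None:
        meta.append(f"# haploid_total_um: {round_half_up(k.haploid_total_um):.2f}")
    if k.size_ratio is not None:
        meta.append(f"# size_ratio: {round_half_up(k.size_ratio):.2f}")
    if k.largest_um is not None and k.smallest_um is not None:
        meta.append(
            f"# length_range_um: {round_half_up(k.largest_um):.2f}"
            f"-{round_half_up(k.smallest_um):.2f}"
        )
    for key, val in k.metadata.items():
        meta.append(f"# {key}: {val}")
    lines = meta + [
        "accession\trank\trel_length_pct\tarm_ratio\ttype\theteromorphic"
        "\tsatellite_seen\tnor\tnote"
    ]
    for p in k.pairs:
        rel_b = p.rel_length_pct if p.rel_length_pct_b is None else p.rel_length_pct_b
        type_s = p.type_a if p.type_a == p.type_b else f"{p.type_a}/{p.type_b}"
        lines.append(
            f"{k.accession_id}\t{p.rank}\t{_fmt_ab(p.rel_length_pct, rel_b)}\t"
            f"{_fmt_ab(p.arm_ratio_a, p.arm_ratio_b)}\t{type_s}\t"
            f"{int(p.heteromorphic)}\t{p.satellite_seen}\t{int(p.nor)}\t{p.note}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def karyotype_to_json(k: Karyotype) -> str:
    """Serialise a karyotype (round-trips with :func:`karyotype_from_json`)."""
    d = {
        "accession_id": k.accession_id,
        "ploidy": k.ploidy,
        "two_n": k.two_n,
        "haploid_total_um": k.haploid_total_um,
        "largest_um": k.largest_um,
        "smallest_um": k.smallest_um,
        "size_ratio": k.size_ratio,
        "formula": str(k.formula) if k.formula else None,
        "stebbins": str(k.stebbins) if k.stebbins else None,
        "metadata": k.metadata,
        "pairs": [
            {
                "rank": p.rank,
                "rel_length_pct": p.rel_length_pct,
                "rel_length_pct_b": p.rel_length_pct_b,
                "arm_ratio_a": p.arm_ratio_a,
                "arm_ratio_b": p.arm_ratio_b,
                "type_a": p.type_a,
                "type_b": p.type_b,
                "heteromorphic": p.heteromorphic,
                "satellite_seen": p.satellite_seen,
                "nor": p.nor,
                "note": p.note,
            }
            for p in k.pairs
        ],
    }
    return json.dumps(d, indent=2)


def karyotype_from_json(s: str) -> Karyotype:
    d = json.loads(s)
    pairs = [PairProfile(**pd) for pd in d["pairs"]]
    return Karyotype(
        accession_id=d["accession_id"],
        ploidy=d["ploidy"],
        two_n=d["two_n"],
        pairs=pairs,
        haploid_total_um=d.get("haploid_total_um"),
        largest_um=d.get("largest_um"),
        smallest_um=d.get("smallest_um"),
        size_ratio=d.get("size_ratio"),
        formula=KaryotypeFormula.parse(d["formula"]) if d.get("formula") else None,
        stebbins=StebbinsClass.parse(d["stebbins"]) if d.get("stebbins") else None,
        metadata=d.get("metadata", {}),
    )
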