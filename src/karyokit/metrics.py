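"""Numeric karyotype descriptors.

Two relative-length conventions are used in comparative cytogenetics and both
appear here, explicitly:

* per-cell relative lengths (``relative_lengths``): each chromosome as a
  percentage of the *full complement* total, summing to 100 over all 2n
  chromosomes of a spread — the scale-free representation used internally to
  remove per-cell condensation differences;
* per-pair relative lengths (``PairProfile.rel_length_pct``): a chromosome as
  a percentage of the *haploid-set* total (exactly twice the per-cell value),
  the convention of published karyotype tables, summing to ~100 over the n
  pairs.

All published-table comparisons are rounded to 2 decimals, half-up, applied
to the exact binary value of the computed quotient; internal computation is
never rounded.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .types import Karyotype, MetaphaseCell

__all__ = [
    "round_half_up",
    "CellMetrics",
    "arm_ratio",
    "relative_lengths",
    "size_ratio",
    "haploid_set_length",
    "monoploid_relative_lengths",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` half-up at ``ndigits`` decimals, on the binary value of x.

    ``Decimal(x)`` (not ``Decimal(repr(x))``) is essential: quotients such as
    5.51/2.00 are stored as 2.754999…, which prints as 2.755 but must round
    to 2.75 to agree with quotient tables computed in double precision.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(x).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CellMetrics:
    """Scale-free descriptors of one metaphase spread."""

    cell_id: str
    total_length_um: float
    rel_lengths: np.ndarray  # % of full-complement total; sums to 100
    arm_ratios: np.ndarray  # elementwise >= 1


def arm_ratio(long_um: float, short_um: float) -> float:
    """Long-arm / short-arm ratio; operands are reordered so the result >= 1."""
    if long_um <= 0 or short_um <= 0:
        raise ValueError(f"arm lengths must be positive, got ({long_um}, {short_um})")
    if long_um < short_um:
        long_um, short_um = short_um, long_um
    return long_um / short_um


def relative_lengths(cell: MetaphaseCell) -> CellMetrics:
    """Per-chromosome relative lengths (%) over the cell's full complement.

    The vector sums to exactly 100 before any rounding, for every input; this
    removes the per-cell condensation scale.
    """
    if not cell.measurements:
        raise ValueError(f"cell {cell.cell_id!r} has no measurements")
    lengths = np.array([m.total_um for m in cell.measurements], dtype=float)
    total = float(lengths.sum())
    ratios = np.array([m.arm_ratio for m in cell.measurements], dtype=float)
    return CellMetrics(
        cell_id=cell.cell_id,
        total_length_um=total,
        rel_lengths=100.0 * lengths / total,
        arm_ratios=ratios,
    )


def size_ratio(largest_um: float, smallest_um: float) -> float:
    """Largest/smallest chromosome length ratio (reported rounded to 2 dp)."""
    if smallest_um <= 0:
        raise ValueError("smallest chromosome length must be positive")
    if largest_um < smallest_um:
        raise ValueError(
            f"largest ({largest_um}) must be >= smallest ({smallest_um})"
        )
    return largest_um / smallest_um


def haploid_set_length(obj: Karyotype | MetaphaseCell) -> float:
    """Sum of mean homolog lengths over the n pairs (µm).

    For a paired complement this equals half the cell's total length.  A
    ``MetaphaseCell`` is accepted directly because pairing does not change
    the sum; a :class:`~karyokit.types.Karyotype` must carry its measured
    ``haploid_total_um``.
    """
    if isinstance(obj, MetaphaseCell):
        return obj.total_length_um / 2.0
    if isinstance(obj, Karyotype):
        if obj.haploid_total_um is None:
            raise ValueError(
                "karyotype has no haploid_total_um; build it from measured "
                "cells via consensus_karyotype (pair_homologs pairs the "
                "complement first)"
            )
        return obj.haploid_total_um
    raise TypeError(f"expected Karyotype or MetaphaseCell, got {type(obj).__name__}")


def monoploid_relative_lengths(k: Karyotype) -> np.ndarray:
    """Per-pair relative lengths expressed per monoploid genome (x).

    For diploids this is the canonical haploid-set-denominated vector
    unchanged.  For tetraploids the denominator becomes half the haploid-set
    total (one ancestral genome), so every value doubles; this is the
    convention that makes diploid-tetraploid comparisons commensurate.
    """
    vals = np.array([p.mean_rel_length_pct for p in k.pairs], dtype=float)
    if k.ploidy == 2:
        return vals
    if k.ploidy == 4:
        return 2.0 * vals
    raise ValueError(f"unsupported ploidy {k.ploidy} (expected 2 or 4)")
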