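"""Levan centromere typing, karyotype formulas and Stebbins asymmetry.

Levan (1964) nomenclature assigns a centromere-position class from the arm
ratio r = long arm / short arm.  The interval edition used here is
lower-inclusive:

=====  ==================  ==========================
type   arm-ratio interval  name
=====  ==================  ==========================
m      [1.0, 1.7)          metacentric
sm     [1.7, 3.0)          submetacentric
st     [3.0, 7.0)          subtelocentric
t      [7.0, inf)          telocentric
=====  ==================  ==========================

This boundary inclusivity is the unique assignment consistent with published
Smilax tables in which 1.70 is typed sm, 3.00 st and 7.5/8.0 t.  The
thresholds are configurable through :class:`LevanThresholds`.

The Stebbins (1971) two-way asymmetry classification combines the proportion
p of chromosomes with arm ratio > 2 (rows 1-4) with the largest/smallest
size ratio s (columns A-C): row 1 if p = 0, row 2 if 0 < p <= 0.5, row 3 if
0.5 < p < 1, row 4 if p = 1; column A if s < 2, B if 2 <= s <= 4, C if
s > 4.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

from .metrics import size_ratio as _size_ratio
from .types import (
    Karyotype,
    KaryotypeFormula,
    PairProfile,
    StebbinsClass,
)

__all__ = [
    "LevanThresholds",
    "HeteromorphismPolicy",
    "levan_type",
    "pair_types",
    "karyotype_formula",
    "proportion_arm_ratio_above",
    "stebbins_class",
    "classify_karyotype",
]


@dataclass(frozen=True)
class LevanThresholds:
    """Lower-inclusive arm-ratio cut points between Levan classes."""

    m_max: float = 1.7
    sm_max: float = 3.0
    st_max: float = 7.0

    def __post_init__(self) -> None:
        if not (1.0 < self.m_max < self.sm_max < self.st_max):
            raise ValueError(
                "thresholds must satisfy 1 < m_max < sm_max < st_max, got "
                f"({self.m_max}, {self.sm_max}, {self.st_max})"
            )


@dataclass(frozen=True)
class HeteromorphismPolicy:
    """When is a pair called heteromorphic?

    Default: when the two homologs fall in different Levan classes.  The
    stricter optional rule additionally flags same-type pairs whose homolog
    ratios differ by more than ``ratio_gap`` — off by default because the
    published karyotypes report only type-level heteromorphism.
    """

    same_type_gap: bool = False
    ratio_gap: float = 0.4


def levan_type(r: float, thresholds: LevanThresholds | None = None) -> str:
    """Classify an arm ratio into m / sm / st / t."""
    thr = thresholds or LevanThresholds()
    if r < 1 - 1e-9:
        raise ValueError(f"arm ratio {r} < 1; ratios are long arm / short arm")
    if r < thr.m_max:
        return "m"
    if r < thr.sm_max:
        return "sm"
    if r < thr.st_max:
        return "st"
    return "t"


def pair_types(
    p: PairProfile,
    thresholds: LevanThresholds | None = None,
    policy: HeteromorphismPolicy | None = None,
) -> tuple[str, str, bool]:
    """Type each homolog independently and call heteromorphism."""
    policy = policy or HeteromorphismPolicy()
    ta = levan_type(p.arm_ratio_a, thresholds)
    tb = levan_type(p.arm_ratio_b, thresholds)
    het = ta != tb
    if not het and policy.same_type_gap:
        het = abs(p.arm_ratio_a - p.arm_ratio_b) > policy.ratio_gap
    return ta, tb, het


def karyotype_formula(pairs: Sequence[PairProfile]) -> KaryotypeFormula:
    """Assemble the formula from typed pairs.

    A homomorphic pair contributes 1 to its type; each homolog of a
    heteromorphic pair contributes 0.5 to its own type, which is where the
    half-integer counts of published formulas come from.
    """
    counts: dict[str, float] = {}
    for p in pairs:
        if p.type_a is None or p.type_b is None:
            raise ValueError(f"pair {p.rank} is untyped; run pair_types first")
        if p.type_a == p.type_b:
            counts[p.type_a] = counts.get(p.type_a, 0.0) + 1.0
        else:
            counts[p.type_a] = counts.get(p.type_a, 0.0) + 0.5
            counts[p.type_b] = counts.get(p.type_b, 0.0) + 0.5
    return KaryotypeFormula(counts)


def proportion_arm_ratio_above(
    pairs: Sequence[PairProfile],
    threshold: float = 2.0,
    convention: str = "homolog",
) -> Fraction:
    """Proportion of chromosomes with arm ratio strictly above ``threshold``.

    ``convention='homolog'`` (default) counts every one of the 2n homologs
    individually; ``convention='pair_any'`` counts a pair once if either
    homolog exceeds the threshold.  The result is an exact fraction so the
    Stebbins row boundaries p = 0, 0.5, 1 can be tested without float fuzz.
    """
    if convention == "homolog":
        hits = sum(
            (p.arm_ratio_a > threshold) + (p.arm_ratio_b > threshold) for p in pairs
        )
        return Fraction(hits, 2 * len(pairs))
    if convention == "pair_any":
        hits = sum(
            1
            for p in pairs
            if p.arm_ratio_a > threshold or p.arm_ratio_b > threshold
        )
        return Fraction(hits, len(pairs))
    raise ValueError(f"unknown convention {convention!r}")


def stebbins_class(
    proportion_above_2: Fraction | float,
    largest_smallest_ratio: float,
) -> StebbinsClass:
    """Stebbins (1971) two-way asymmetry class from p and s."""
    p = proportion_above_2
    if not 0 <= p <= 1:
        raise ValueError(f"proportion {p} outside [0, 1]")
    if p == 0:
        row = 1
    elif p <= Fraction(1, 2):
        row = 2
    elif p < 1:
        row = 3
    else:
        row = 4
    s = largest_smallest_ratio
    if s < 1:
        raise ValueError(f"size ratio {s} < 1")
    column = "A" if s < 2 else ("B" if s <= 4 else "C")
    return StebbinsClass(row, column)


def classify_karyotype(
    accession_id: str,
    pairs: Iterable[PairProfile],
    *,
    ploidy: int = 2,
    largest_um: float | None = None,
    smallest_um: float | None = None,
    haploid_total_um: float | None = None,
    thresholds: LevanThresholds | None = None,
    policy: HeteromorphismPolicy | None = None,
    proportion_convention: str = "homolog",
) -> Karyotype:
    """Produce a fully annotated :class:`~karyokit.types.Karyotype`.

    Pairs are re-ranked by decreasing mean relative length, homologs are
    typed, the formula and Stebbins class are derived.  The size ratio is
    taken from absolute largest/smallest lengths when provided, otherwise
    from the (scale-invariant) extreme relative lengths.  The conventions
    used are recorded in ``Karyotype.metadata``.
    """
    thr = thresholds or LevanThresholds()
    ranked = sorted(
        pairs, key=lambda p: (-p.mean_rel_length_pct, 0.5 * sum(p.homolog_ratios))
    )
    if not ranked:
        raise ValueError("cannot classify an empty pair list")
    typed: list[PairProfile] = []
    for rank, p in enumerate(ranked, start=1):
        ta, tb, het = pair_types(p, thr, policy)
        q = PairProfile(
            rank=rank,
            rel_length_pct=p.rel_length_pct,
            rel_length_pct_b=p.rel_length_pct_b,
            arm_ratio_a=p.arm_ratio_a,
            arm_ratio_b=p.arm_ratio_b,
            type_a=ta,
            type_b=tb,
            heteromorphic=het,
            satellite_seen=p.satellite_seen,
            nor=p.nor,
            note=p.note,
        )
        typed.append(q)
    if largest_um is not None and smallest_um is not None:
        s = _size_ratio(largest_um, smallest_um)
    else:
        rels = [p.mean_rel_length_pct for p in typed]
        s = _size_ratio(max(rels), min(rels))
    prop = proportion_arm_ratio_above(typed, 2.0, proportion_convention)
    return Karyotype(
        accession_id=accession_id,
        ploidy=ploidy,
        two_n=2 * len(typed),
        pairs=typed,
        haploid_total_um=haploid_total_um,
        largest_um=largest_um,
        smallest_um=smallest_um,
        size_ratio=s,
        formula=karyotype_formula(typed),
        stebbins=stebbins_class(prop, s),
        metadata={
            "levan_thresholds": (thr.m_max, thr.sm_max, thr.st_max),
            "proportion_convention": proportion_convention,
            "proportion_above_2": float(prop),
            "heteromorphic_note": (
                "heteromorphic pairs are reported as such only; whether they "
                "are sex chromosomes is not inferred"
            ),
        },
    )
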