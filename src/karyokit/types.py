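"""Core value objects for karyotype analysis.

The containers here mirror how plant cytogeneticists record a karyotype:
raw per-chromosome arm measurements from metaphase spreads, per-pair
consensus profiles (relative length, arm ratio, centromere type), and the
karyotype summary (formula string, asymmetry class, haploid-set length).

All containers are plain dataclasses with eager validation; arm ordering
(long >= short) is normalised on construction so downstream code never has
to re-check it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

__all__ = [
    "NOR_SIGNALS",
    "LEVAN_TYPES",
    "SATELLITE_STATES",
    "ChromosomeMeasurement",
    "MetaphaseCell",
    "PairProfile",
    "KaryotypeFormula",
    "StebbinsClass",
    "Karyotype",
]

#: Valid NOR-signal annotations (silver staining marks activity, FISH marks
#: sequence presence; ``both`` when the signals colocalise).
NOR_SIGNALS = ("none", "silver", "fish", "both")

#: Levan centromere-position classes, ordered from most asymmetric arms
#: (telocentric) to symmetric (metacentric).
LEVAN_TYPES = ("t", "st", "sm", "m")

#: How a satellite / secondary constriction was seen across a pair's homologs.
SATELLITE_STATES = ("none", "one_homolog", "both")


@dataclass
class ChromosomeMeasurement:
    """One measured chromosome of one metaphase spread.

    Arm lengths are in micrometres.  If ``short_arm_um > long_arm_um`` the two
    are swapped on construction (the identity of the arms is a convention, not
    an observation); ``swapped`` records that this happened.  Satellite length,
    when present, is assumed included in the short-arm measurement.
    """

    cell_id: str
    chrom_id: str
    short_arm_um: float
    long_arm_um: float
    satellite: bool = False
    secondary_constriction: bool = False
    nor_signal: str = "none"
    swapped: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not (self.short_arm_um > 0 and self.long_arm_um > 0):
            raise ValueError(
                f"chromosome {self.chrom_id!r} in cell {self.cell_id!r}: "
                f"arm lengths must be positive, got "
                f"({self.short_arm_um}, {self.long_arm_um})"
            )
        if self.short_arm_um > self.long_arm_um:
            self.short_arm_um, self.long_arm_um = self.long_arm_um, self.short_arm_um
            self.swapped = True
        if self.nor_signal not in NOR_SIGNALS:
            raise ValueError(f"nor_signal must be one of {NOR_SIGNALS}")

    @property
    def total_um(self) -> float:
        """Total chromosome length (µm)."""
        return self.short_arm_um + self.long_arm_um

    @property
    def arm_ratio(self) -> float:
        """Long-arm / short-arm ratio (>= 1 by construction)."""
        return self.long_arm_um / self.short_arm_um


@dataclass
class MetaphaseCell:
    """All ``2n`` chromosome measurements of one metaphase spread."""

    accession_id: str
    cell_id: str
    ploidy: int
    two_n: int
    measurements: list[ChromosomeMeasurement]

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 4):
            raise ValueError(f"ploidy must be 2 or 4, got {self.ploidy}")
        if self.two_n <= 0 or self.two_n % 2:
            raise ValueError(
                f"cell {self.cell_id!r}: odd chromosome count "
                f"(two_n={self.two_n}); homologs cannot be paired"
            )
        if len(self.measurements) != self.two_n:
            raise ValueError(
                f"cell {self.cell_id!r}: {len(self.measurements)} measurements "
                f"but two_n={self.two_n}"
            )
        if self.two_n != 16 * self.ploidy:
            warnings.warn(
                f"cell {self.cell_id!r}: 2n={self.two_n} is not 16·ploidy "
                f"(x=16 is the basic number in Smilax); proceeding anyway",
                stacklevel=2,
            )

    @property
    def total_length_um(self) -> float:
        return sum(m.total_um for m in self.measurements)


@dataclass
class PairProfile:
    """Consensus description of one homologous pair.

    ``arm_ratio_a``/``arm_ratio_b`` hold the two homolog ratios; they are
    equal for homomorphic pairs.  ``type_a``/``type_b`` are filled by the
    Levan classifier.  Convention: homolog *a* carries the larger ratio.
    """

    rank: int
    rel_length_pct: float
    arm_ratio_a: float
    arm_ratio_b: float
    type_a: str | None = None
    type_b: str | None = None
    heteromorphic: bool = False
    satellite_seen: str = "none"
    nor: bool = False
    note: str = ""
    rel_length_pct_b: float | None = None  # second homolog, if reported separately

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("rank is 1-based")
        if self.rel_length_pct <= 0 or self.rel_length_pct > 100:
            raise ValueError(
                f"pair {self.rank}: relative length {self.rel_length_pct} "
                "must be in (0, 100]"
            )
        for r in (self.arm_ratio_a, self.arm_ratio_b):
            if r < 1 - 1e-9:
                raise ValueError(
                    f"pair {self.rank}: arm ratio {r} < 1 "
                    "(ratios are long arm / short arm)"
                )
        if self.satellite_seen not in SATELLITE_STATES:
            raise ValueError(f"satellite_seen must be one of {SATELLITE_STATES}")
        for t in (self.type_a, self.type_b):
            if t is not None and t not in LEVAN_TYPES:
                raise ValueError(f"unknown Levan type {t!r}")

    @property
    def mean_rel_length_pct(self) -> float:
        if self.rel_length_pct_b is None:
            return self.rel_length_pct
        return 0.5 * (self.rel_length_pct + self.rel_length_pct_b)

    @property
    def homolog_ratios(self) -> tuple[float, float]:
        return (self.arm_ratio_a, self.arm_ratio_b)


@dataclass(frozen=True)
class KaryotypeFormula:
    """Pair counts per Levan type, e.g. ``7st+6.5sm+2.5m``.

    Counts are multiples of 0.5: a homomorphic pair contributes 1 to its
    type, each homolog of a heteromorphic pair contributes 0.5 to its own
    type.  The canonical string orders types t, st, sm, m and omits zeros.
    """

    counts: Mapping[str, float]

    def __post_init__(self) -> None:
        for t, c in self.counts.items():
            if t not in LEVAN_TYPES:
                raise ValueError(f"unknown Levan type {t!r}")
            if c < 0 or round(2 * c) != 2 * c:
                raise ValueError(f"count for {t!r} must be a multiple of 0.5, got {c}")

    @property
    def n_pairs(self) -> float:
        return sum(self.counts.values())

    def __str__(self) -> str:
        parts = []
        for t in LEVAN_TYPES:
            c = self.counts.get(t, 0.0)
            if c == 0:
                continue
            num = f"{int(c)}" if c == int(c) else f"{c:.1f}"
            parts.append(f"{num}{t}")
        return "+".join(parts)

    @classmethod
    def parse(cls, s: str) -> "KaryotypeFormula":
        counts: dict[str, float] = {}
        for part in s.replace(" ", "").split("+"):
            for t in LEVAN_TYPES:
                if part.endswith(t) and (t != "t" or not part.endswith("st")):
                    counts[t] = float(part[: -len(t)])
                    break
            else:
                raise ValueError(f"cannot parse formula term {part!r}")
        return cls(counts)


@dataclass(frozen=True)
class StebbinsClass:
    """Two-way Stebbins (1971) asymmetry class, e.g. row 3 column B -> '3B'."""

    row: int
    column: str

    def __post_init__(self) -> None:
        if self.row not in (1, 2, 3, 4):
            raise ValueError("Stebbins row must be 1..4")
        if self.column not in ("A", "B", "C"):
            raise ValueError("Stebbins column must be A, B or C")

    def __str__(self) -> str:
        return f"{self.row}{self.column}"

    @classmethod
    def parse(cls, s: str) -> "StebbinsClass":
        s = s.strip()
        return cls(int(s[:-1]), s[-1])


@dataclass
class Karyotype:
    """A fully described karyotype: ranked pairs plus summary statistics."""

    accession_id: str
    ploidy: int
    two_n: int
    pairs: list[PairProfile]
    haploid_total_um: float | None = None
    largest_um: float | None = None
    smallest_um: float | None = None
    size_ratio: float | None = None
    formula: KaryotypeFormula | None = None
    stebbins: StebbinsClass | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.pairs) != self.two_n // 2:
            raise ValueError(
                f"{self.accession_id}: {len(self.pairs)} pairs but 2n={self.two_n}"
            )
        total = sum(p.mean_rel_length_pct for p in self.pairs)
        # Published tables can deviate noticeably from 100; warn, don't fail.
        if not math.isclose(total, 100.0, abs_tol=0.5):
            warnings.warn(
                f"{self.accession_id}: relative lengths sum to {total:.2f}"
                " per haploid complement (expected ~100 within 0.5)",
                stacklevel=2,
            )
        if (
            self.size_ratio is not None
            and self.largest_um is not None
            and self.smallest_um is not None
            and not math.isclose(
                self.size_ratio, self.largest_um / self.smallest_um, rel_tol=5e-3
            )
        ):
            warnings.warn(
                f"{self.accession_id}: size_ratio {self.size_ratio} inconsistent "
                f"with largest/smallest = {self.largest_um / self.smallest_um:.4f}",
                stacklevel=2,
            )

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def with_pairs(self, pairs: Sequence[PairProfile]) -> "Karyotype":
        return replace(self, pairs=list(pairs))
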