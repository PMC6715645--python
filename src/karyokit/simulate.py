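"""Synthetic metaphase-measurement generator.

The generator emulates the structure of Feulgen-stained metaphase data from
asymmetric, modal plant karyotypes: chromosomes gradually decreasing in size
(geometric decay of pair lengths), a mix of st/sm/m (optionally t) centromere
types, diploid (2n = 32) and tetraploid (2n = 64) complements, at most one
heteromorphic pair, NOR-bearing pairs whose terminal secondary constriction
is stochastically detected — less often in more condensed spreads — plus a
multiplicative per-cell condensation scale and multiplicative per-arm
measurement noise.

What it deliberately does *not* emulate: overlapping or bent chromosomes,
chromatid-level measurement asymmetry, satellite length (satellites are
flags; their length is assumed inside the short-arm measurement), or any
rDNA activity biology.  Recovery results on these data therefore speak to
the numerical pipeline, not to microscope segmentation quality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .classify import LevanThresholds, classify_karyotype
from .consensus import consensus_karyotype
from .types import ChromosomeMeasurement, Karyotype, MetaphaseCell, PairProfile

__all__ = [
    "SimSpec",
    "TruthBundle",
    "RecoveryReport",
    "default_type_sequence",
    "generate_true_karyotype",
    "simulate_cell",
    "simulate_cells",
    "run_recovery",
]

#: Generated arm ratios stay at least this far inside their Levan interval so
#: the true type is never boundary-ambiguous under small noise.
TYPE_MARGIN = 0.05

#: Upper cap on generated telocentric ratios (open Levan interval).
T_RATIO_MAX = 9.0


def default_type_sequence(n_pairs: int) -> list[str]:
    """A Smilax-like type sequence: large/medium pairs st, medium sm, small m.

    Proportions 7:7:2 (st:sm:m) over 16 pairs, scaled for other sizes —
    the modal asymmetric karyotype organisation of the genus.
    """
    n_st = round(n_pairs * 7 / 16)
    n_m = max(1, round(n_pairs * 2 / 16))
    n_sm = n_pairs - n_st - n_m
    return ["st"] * n_st + ["sm"] * n_sm + ["m"] * n_m


@dataclass
class SimSpec:
    """Generative description of a true karyotype and its noise model.

    Defaults describe a diploid complement of the kind reported for
    Brazilian Smilax: 16 pairs, largest pair 5.6 µm, successive pair lengths
    decaying by 7% (largest/smallest ~= 0.93^-15 ~= 2.97, inside the
    published 2.75-3.18 diploid range), 2% per-arm measurement CV, and a
    lognormal per-cell condensation scale with sigma = 0.15.
    """

    n_pairs: int = 16
    ploidy: int = 2
    size_decay: float = 0.93
    largest_um: float = 5.6
    type_sequence: list[str] | None = None
    heteromorphic_pair: tuple[int, str, str] | None = None  # (rank, type_a, type_b)
    nor_pairs: frozenset[int] = field(default_factory=frozenset)
    condensation_sd: float = 0.15
    noise_cv: float = 0.02
    sat_detect_base: float = 0.5
    sat_condensation_coupling: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.size_decay <= 1:
            raise ValueError("size_decay must be in (0, 1]")
        if self.type_sequence is not None and len(self.type_sequence) != self.n_pairs:
            raise ValueError(
                f"type_sequence has {len(self.type_sequence)} entries "
                f"but n_pairs={self.n_pairs}"
            )
        if self.heteromorphic_pair is not None:
            rank = self.heteromorphic_pair[0]
            if not 1 <= rank <= self.n_pairs:
                raise ValueError(f"heteromorphic pair rank {rank} out of range")
        self.nor_pairs = frozenset(self.nor_pairs)

    def resolved_types(self) -> list[str]:
        return list(self.type_sequence or default_type_sequence(self.n_pairs))


@dataclass
class TruthBundle:
    """A generated truth plus the noisy cells measured from it."""

    truth: Karyotype
    cells: list[MetaphaseCell]
    spec: SimSpec
    seed: int


@dataclass
class RecoveryReport:
    """Truth-vs-pipeline comparison for one simulated accession."""

    type_accuracy: float  # fraction of ranks with matching unordered type pair
    formula_match: bool
    stebbins_match: bool
    truth_formula: str
    recovered_formula: str
    truth_stebbins: str
    recovered_stebbins: str
    n_cells: int
    seed: int


def _ratio_interval(
    levan: str, thresholds: LevanThresholds, margin: float = TYPE_MARGIN
) -> tuple[float, float]:
    thr = thresholds
    if levan == "m":
        return (1.0, thr.m_max - margin)
    if levan == "sm":
        return (thr.m_max + margin, thr.sm_max - margin)
    if levan == "st":
        return (thr.sm_max + margin, thr.st_max - margin)
    if levan == "t":
        return (thr.st_max + margin, T_RATIO_MAX)
    raise ValueError(f"unknown Levan type {levan!r}")


def generate_true_karyotype(
    spec: SimSpec, thresholds: LevanThresholds | None = None
) -> Karyotype:
    """Draw a true karyotype: geometric pair lengths, ratios inside targets.

    Deterministic given ``spec.seed``.  Pair k (1-based) has length
    ``largest_um * size_decay**(k-1)``; each pair's arm ratio is drawn
    uniformly inside its target Levan interval shrunk by the safety margin,
    so truth types survive small measurement noise.
    """
    thr = thresholds or LevanThresholds()
    rng = np.random.default_rng(spec.seed)
    types = spec.resolved_types()
    het = spec.heteromorphic_pair
    lengths = [spec.largest_um * spec.size_decay ** k for k in range(spec.n_pairs)]
    total = sum(lengths)
    profiles = []
    for rank in range(1, spec.n_pairs + 1):
        length = lengths[rank - 1]
        if het is not None and rank == het[0]:
            ta, tb = het[1], het[2]
        else:
            ta = tb = types[rank - 1]
        lo_a, hi_a = _ratio_interval(ta, thr)
        ra = float(rng.uniform(lo_a, hi_a))
        if tb == ta:
            rb = ra
        else:
            lo_b, hi_b = _ratio_interval(tb, thr)
            rb = float(rng.uniform(lo_b, hi_b))
        if rb > ra:
            ra, rb = rb, ra
        profiles.append(
            PairProfile(
                rank=rank,
                rel_length_pct=100.0 * length / total,
                arm_ratio_a=ra,
                arm_ratio_b=rb,
                satellite_seen="both" if rank in spec.nor_pairs else "none",
                nor=rank in spec.nor_pairs,
            )
        )
    k = classify_karyotype(
        f"sim-seed{spec.seed}",
        profiles,
        ploidy=spec.ploidy,
        largest_um=lengths[0],
        smallest_um=lengths[-1],
        haploid_total_um=total,
        thresholds=thr,
    )
    k.metadata["simulated"] = True
    return k


def _arm_lengths(length_um: float, ratio: float) -> tuple[float, float]:
    short = length_um / (1.0 + ratio)
    return short, length_um - short


def simulate_cell(
    truth: Karyotype,
    spec: SimSpec,
    cell_id: str,
    rng: np.random.Generator,
) -> MetaphaseCell:
    """Measure one noisy metaphase spread of ``truth``.

    One lognormal condensation scale ``s`` multiplies every arm of the cell;
    each arm additionally gets independent multiplicative lognormal noise
    with coefficient of variation ``noise_cv`` (mean exactly 1).  A NOR
    pair's secondary constriction is detected per homolog with probability
    ``sat_detect_base * exp(-coupling * max(1/s - 1, 0))`` — more condensed
    (shorter) spreads hide terminal constrictions more often.  Chromosomes
    are emitted in random order: downstream code must re-pair them.
    """
    s = float(rng.lognormal(0.0, spec.condensation_sd)) if spec.condensation_sd else 1.0
    sigma = math.sqrt(math.log1p(spec.noise_cv**2))
    condensation = max(1.0 / s - 1.0, 0.0)
    p_detect = min(
        1.0,
        spec.sat_detect_base
        * math.exp(-spec.sat_condensation_coupling * condensation),
    )
    measurements = []
    for p in truth.pairs:
        # haploid-set % -> absolute truth length of one homolog
        length = p.mean_rel_length_pct / 100.0 * truth.haploid_total_um
        for hom, ratio in enumerate(p.homolog_ratios):
            short, long = _arm_lengths(length, ratio)
            if sigma:
                short *= float(rng.lognormal(-0.5 * sigma**2, sigma))
                long *= float(rng.lognormal(-0.5 * sigma**2, sigma))
            detected = p.nor and bool(rng.random() < p_detect)
            measurements.append(
                ChromosomeMeasurement(
                    cell_id=cell_id,
                    chrom_id=f"{p.rank}{'ab'[hom]}",
                    short_arm_um=short * s,
                    long_arm_um=long * s,
                    satellite=detected,
                    secondary_constriction=detected,
                    nor_signal="both" if p.nor else "none",
                )
            )
    order = rng.permutation(len(measurements))
    measurements = [measurements[i] for i in order]
    return MetaphaseCell(
        accession_id=truth.accession_id,
        cell_id=cell_id,
        ploidy=truth.ploidy,
        two_n=truth.two_n,
        measurements=measurements,
    )


def simulate_cells(spec: SimSpec, n_cells: int) -> TruthBundle:
    """Generate a truth and ``n_cells`` spreads from one seeded stream."""
    truth = generate_true_karyotype(spec)
    rng = np.random.default_rng([spec.seed, 1])
    cells = [
        simulate_cell(truth, spec, f"cell{i + 1}", rng) for i in range(n_cells)
    ]
    return TruthBundle(truth=truth, cells=cells, spec=spec, seed=spec.seed)


def run_recovery(spec: SimSpec, n_cells: int, seed: int | None = None) -> RecoveryReport:
    """Generate truth + cells, run the full pipeline, compare to truth."""
    if seed is not None:
        spec = replace(spec, seed=seed)
    bundle = simulate_cells(spec, n_cells)
    recovered = consensus_karyotype(bundle.cells, min_cells=1)
    truth = bundle.truth
    hits = sum(
        1
        for pt, pr in zip(truth.pairs, recovered.pairs)
        if {pt.type_a, pt.type_b} == {pr.type_a, pr.type_b}
    )
    return RecoveryReport(
        type_accuracy=hits / truth.n_pairs,
        formula_match=str(recovered.formula) == str(truth.formula),
        stebbins_match=str(recovered.stebbins) == str(truth.stebbins),
        truth_formula=str(truth.formula),
        recovered_formula=str(recovered.formula),
        truth_stebbins=str(truth.stebbins),
        recovered_stebbins=str(recovered.stebbins),
        n_cells=n_cells,
        seed=spec.seed,
    )
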