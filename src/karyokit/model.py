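"""statsmodels-style front door: build a model from data, ``fit()``, summarise.

``KaryotypeModel`` wraps either raw per-chromosome measurements (one or more
metaphase spreads) or an already-averaged pair-profile table; ``fit()`` runs
pairing → ranking → cross-cell averaging → Levan/Stebbins classification and
returns a :class:`KaryotypeResults` carrying the estimates, their
cross-cell dispersions and a printable summary table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import (
    HeteromorphismPolicy,
    LevanThresholds,
    classify_karyotype,
)
from .compare import compare_accessions
from .consensus import DEFAULT_SPLIT_GAP, consensus_karyotype, pair_homologs, rank_pairs
from .idiogram import IdiogramLayout, render_idiogram
from .io import read_measurement_table, read_pair_profiles, write_karyotype_report
from .metrics import round_half_up
from .types import Karyotype, MetaphaseCell, PairProfile

__all__ = ["KaryotypeModel", "KaryotypeResults"]


class KaryotypeModel:
    """A karyotype to be estimated from cytological data.

    Parameters
    ----------
    cells
        Metaphase spreads of one accession (raw measurements), or ``None``
        when constructing from pre-averaged pair profiles.
    profiles
        Pre-averaged pair profiles (published-table style input).
    """

    def __init__(
        self,
        cells: list[MetaphaseCell] | None = None,
        profiles: list[PairProfile] | None = None,
        accession_id: str | None = None,
        ploidy: int | None = None,
        **summary_lengths,
    ) -> None:
        if (cells is None) == (profiles is None):
            raise ValueError("provide exactly one of cells= or profiles=")
        self.cells = cells
        self.profiles = profiles
        self.accession_id = accession_id or (cells[0].accession_id if cells else "karyotype")
        self.ploidy = ploidy if ploidy is not None else (cells[0].ploidy if cells else 2)
        self.summary_lengths = summary_lengths

    @classmethod
    def from_measurements(cls, path: str | Path, accession: str | None = None) -> "KaryotypeModel":
        """Build from a measurement table file (one accession)."""
        cells = read_measurement_table(path)
        if accession is not None:
            cells = [c for c in cells if c.accession_id == accession]
        if not cells:
            raise ValueError(f"no cells found in {path}")
        accs = {c.accession_id for c in cells}
        if len(accs) > 1:
            raise ValueError(
                f"measurement table holds several accessions {sorted(accs)}; "
                "pass accession= to select one"
            )
        return cls(cells=cells)

    @classmethod
    def from_profiles(
        cls, path: str | Path, accession: str | None = None, **kwargs
    ) -> "KaryotypeModel":
        """Build from a pair-profile table file (published-table style)."""
        entries = read_pair_profiles(path)
        if accession is not None:
            entries = [e for e in entries if e[0] == accession]
        if len(entries) != 1:
            raise ValueError(
                f"{path}: expected exactly one accession, got "
                f"{[a for a, _ in entries]}; pass accession= to select"
            )
        acc, profiles = entries[0]
        return cls(profiles=profiles, accession_id=acc, **kwargs)

    def fit(
        self,
        thresholds: LevanThresholds | None = None,
        policy: HeteromorphismPolicy | None = None,
        weights: tuple[float, float] = (1.0, 1.0),
        split_gap: float = DEFAULT_SPLIT_GAP,
    ) -> "KaryotypeResults":
        if self.cells is not None:
            k = consensus_karyotype(
                self.cells,
                weights=weights,
                thresholds=thresholds,
                policy=policy,
                split_gap=split_gap,
            )
            disp = self._dispersions(weights)
        else:
            k = classify_karyotype(
                self.accession_id,
                self.profiles,
                ploidy=self.ploidy,
                thresholds=thresholds,
                policy=policy,
                **self.summary_lengths,
            )
            disp = None
        return KaryotypeResults(model=self, karyotype=k, dispersions=disp)

    def _dispersions(self, weights: tuple[float, float]) -> pd.DataFrame:
        """Cross-cell SDs of per-rank relative length and log arm ratio."""
        rel: dict[int, list[float]] = {}
        logr: dict[int, list[float]] = {}
        for c in self.cells:
            ranked = rank_pairs(c, pair_homologs(c, weights))
            for rp in ranked:
                rel.setdefault(rp.rank, []).append(rp.mean_rel_length_pct)
                logr.setdefault(rp.rank, []).extend(np.log(rp.ratios))
        rows = [
            {
                "rank": r,
                "rel_length_sd": float(np.std(rel[r], ddof=1)) if len(rel[r]) > 1 else 0.0,
                "log_ratio_sd": float(np.std(logr[r], ddof=1)) if len(logr[r]) > 1 else 0.0,
            }
            for r in sorted(rel)
        ]
        return pd.DataFrame(rows).set_index("rank")


@dataclass
class KaryotypeResults:
    """Fitted karyotype: estimates, dispersions, rendering and reporting."""

    model: KaryotypeModel
    karyotype: Karyotype
    dispersions: pd.DataFrame | None = None
    _table: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def formula(self) -> str:
        return str(self.karyotype.formula)

    @property
    def stebbins(self) -> str:
        return str(self.karyotype.stebbins)

    def pair_table(self) -> pd.DataFrame:
        if self._table is None:
            k = self.karyotype
            rows = []
            for p in k.pairs:
                row = {
                    "rank": p.rank,
                    "rel_length_pct": round_half_up(p.mean_rel_length_pct),
                    "arm_ratio_a": round_half_up(p.arm_ratio_a),
                    "arm_ratio_b": round_half_up(p.arm_ratio_b),
                    "type": p.type_a if p.type_a == p.type_b else f"{p.type_a}/{p.type_b}",
                    "heteromorphic": p.heteromorphic,
                    "satellite_seen": p.satellite_seen,
                    "nor": p.nor,
                }
                if self.dispersions is not None and p.rank in self.dispersions.index:
                    row["rel_length_sd"] = round_half_up(
                        float(self.dispersions.loc[p.rank, "rel_length_sd"]), 3
                    )
                rows.append(row)
            self._table = pd.DataFrame(rows).set_index("rank")
        return self._table

    def summary(self) -> str:
        k = self.karyotype
        lines = [
            "Karyotype estimation results",
            "=" * 60,
            f"accession:        {k.accession_id}",
            f"2n:               {k.two_n}   (ploidy {k.ploidy})",
            f"formula:          {k.formula}",
            f"Stebbins class:   {k.stebbins}",
        ]
        if k.size_ratio is not None:
            lines.append(f"size ratio:       {round_half_up(k.size_ratio):.2f}")
        if k.haploid_total_um is not None:
            lines.append(f"haploid set (um): {round_half_up(k.haploid_total_um):.2f}")
        if "n_cells" in k.metadata:
            lines.append(f"cells averaged:   {k.metadata['n_cells']}")
        het = [p.rank for p in k.pairs if p.heteromorphic]
        if het:
            lines.append(f"heteromorphic:    pair(s) {', '.join(map(str, het))}")
        nor = [p.rank for p in k.pairs if p.nor]
        if nor:
            lines.append(f"NOR-bearing:      pair(s) {', '.join(map(str, nor))}")
        lines.append("-" * 60)
        lines.append(self.pair_table().to_string())
        return "\n".join(lines)

    def to_report(self, path: str | Path) -> None:
        write_karyotype_report(self.karyotype, path)

    def render_idiogram(self, layout: IdiogramLayout | None = None) -> str:
        return render_idiogram(self.karyotype, layout)

    def compare_with(self, *others: "KaryotypeResults | Karyotype") -> pd.DataFrame:
        ks = [self.karyotype] + [
            o.karyotype if isinstance(o, KaryotypeResults) else o for o in others
        ]
        return compare_accessions(ks)
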