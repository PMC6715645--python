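"""Comparative karyotype tables across accessions."""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from .metrics import round_half_up
from .types import Karyotype

__all__ = ["compare_accessions"]


def compare_accessions(karyotypes: Sequence[Karyotype]) -> pd.DataFrame:
    """Summarise one row per accession: 2n, size ratio, haploid total, formula, class.

    Mirrors the layout of published comparative karyotype tables; values are
    rounded to the 2-decimal table precision.
    """
    if not karyotypes:
        raise ValueError("need at least one karyotype")
    rows = []
    for k in karyotypes:
        rows.append(
            {
                "accession": k.accession_id,
                "2n": k.two_n,
                "ploidy": k.ploidy,
                "largest_um": None if k.largest_um is None else round_half_up(k.largest_um),
                "smallest_um": None
                if k.smallest_um is None
                else round_half_up(k.smallest_um),
                "size_ratio": None
                if k.size_ratio is None
                else round_half_up(k.size_ratio),
                "haploid_um": None
                if k.haploid_total_um is None
                else round_half_up(k.haploid_total_um),
                "formula": str(k.formula) if k.formula else None,
                "stebbins": str(k.stebbins) if k.stebbins else None,
                "n_heteromorphic": sum(p.heteromorphic for p in k.pairs),
                "nor_pairs": ",".join(str(p.rank) for p in k.pairs if p.nor),
            }
        )
    return pd.DataFrame(rows)
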