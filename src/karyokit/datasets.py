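"""Bundled published karyotype tables for nine Brazilian Smilax accessions.

See ``data/NOTES.md`` for provenance and the two documented corrections.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .classify import classify_karyotype
from .io import read_pair_profiles
from .types import Karyotype, PairProfile

__all__ = [
    "ACCESSIONS",
    "load_published_summary",
    "load_published_profiles",
    "load_published_types",
    "published_karyotypes",
]

ACCESSIONS = (
    "S_rufescens",
    "S_fluminensis_Uruana",
    "S_fluminensis_Itirapina",
    "S_polyantha_Botucatu",
    "S_polyantha_MogiGuacu",
    "S_brasiliensis",
    "S_campestris",
    "S_cissoides",
    "S_goyazana",
)


def _data_dir() -> Path:
    return Path(resources.files("karyokit") / "data")


def profile_path(accession: str) -> Path:
    p = _data_dir() / "profiles" / f"{accession}.tsv"
    if not p.exists():
        raise KeyError(f"no bundled profile for accession {accession!r}")
    return p


def load_published_summary() -> pd.DataFrame:
    """Summary table: length range, size ratio, haploid total, formula, class."""
    return pd.read_csv(_data_dir() / "table1.tsv", sep="\t")


def load_published_profiles(accession: str) -> list[PairProfile]:
    """Pair profiles (relative length, arm ratio) for one accession."""
    [(acc, pairs)] = read_pair_profiles(profile_path(accession))
    assert acc == accession
    return pairs


def load_published_types(accession: str) -> list[str]:
    """The printed per-pair type letters (``sm/m`` style for heteromorphic)."""
    df = pd.read_csv(profile_path(accession), sep="\t")
    return list(df["type"])


def published_karyotypes(**classify_kwargs) -> dict[str, Karyotype]:
    """Classify every bundled accession from its published arm ratios.

    Size ratio and haploid total are taken from the published summary table;
    formulas and classes are recomputed, not copied.
    """
    summary = load_published_summary().set_index("accession")
    out: dict[str, Karyotype] = {}
    for acc in ACCESSIONS:
        row = summary.loc[acc]
        out[acc] = classify_karyotype(
            acc,
            load_published_profiles(acc),
            ploidy=int(row["ploidy"]),
            largest_um=float(row["largest_um"]),
            smallest_um=float(row["smallest_um"]),
            haploid_total_um=float(row["haploid_um"]),
            **classify_kwargs,
        )
    return out
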