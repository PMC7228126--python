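"""Nucleotide property tables: 3 chemical + 32 dinucleotide + 12 trinucleotide.

The chemical table encodes each base by ring structure (purine 0 /
pyrimidine 1), hydrogen-bond strength (strong 0 / weak 1) and functional
group (amino 0 / keto 1).  The dinucleotide and trinucleotide tables hold
one standardized real value per k-mer per physicochemical property
(helical step parameters, duplex thermodynamics, bendability, nucleosome
affinity, ...).

The packaged dinucleotide/trinucleotide value files are SYNTHETIC
stand-ins: deterministic GC-correlated standardized values under the
field's conventional property names, shipped so the full pipeline runs
self-contained.  Real property tables in the same CSV layout
(``property,AA,...,TT`` rows) drop in via :func:`load_property_table`.
Every table is (re-)standardized per property at load — a no-op when the
file already holds standard scores.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PropertyTable", "load_property_table", "HELIX_PROPERTIES"]

#: The six helical step parameters used as the default PseKNC property set.
HELIX_PROPERTIES = ("Rise", "Slide", "Shift", "Twist", "Roll", "Tilt")


def _kmers(k: int) -> list[str]:
    return ["".join(t) for t in itertools.product("ACGT", repeat=k)]


def _standardize(df: pd.DataFrame) -> pd.DataFrame:
    """Per-property standard scores over the k-mer axis (columns)."""
    values = df.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    if np.any(sd == 0):
        bad = df.index[np.where(sd[:, 0] == 0)[0][0]]
        raise ValueError(f"property {bad!r} is constant over k-mers")
    return pd.DataFrame((values - mean) / sd, index=df.index, columns=df.columns)


@dataclass(frozen=True)
class PropertyTable:
    """Standardized nucleotide property lookup.

    ``chemical`` maps each base to its 3 binary chemical property values;
    ``dinucleotide`` (32 × 16) and ``trinucleotide`` (12 × 64) hold one
    standardized value per property (row) per k-mer (column).
    """

    chemical: pd.DataFrame
    dinucleotide: pd.DataFrame
    trinucleotide: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.chemical.columns) != list("ACGT"):
            raise ValueError("chemical table must have columns A,C,G,T")
        for df, k in ((self.dinucleotide, 2), (self.trinucleotide, 3)):
            missing = set(_kmers(k)) - set(df.columns)
            if missing:
                raise ValueError(f"{k}-mer table is missing columns {sorted(missing)}")

    @property
    def names(self) -> list[str]:
        return (
            list(self.chemical.index)
            + list(self.dinucleotide.index)
            + list(self.trinucleotide.index)
        )

    @property
    def n_properties(self) -> int:
        return len(self.chemical) + len(self.dinucleotide) + len(self.trinucleotide)

    def dinucleotide_profile(self, properties) -> pd.DataFrame:
        """Rows for the requested dinucleotide properties, in request order."""
        missing = [p for p in properties if p not in self.dinucleotide.index]
        if missing:
            raise KeyError(f"unknown dinucleotide properties: {missing}")
        return self.dinucleotide.loc[list(properties)]


def _read_table(path, k: int) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.columns = [c.strip().upper() for c in df.columns]
    return df[_kmers(k)]


def load_property_table(
    chemical: str | Path | None = None,
    dinucleotide: str | Path | None = None,
    trinucleotide: str | Path | None = None,
) -> PropertyTable:
    """Load the packaged tables, or user-supplied CSVs in the same layout."""
    data = resources.files("pseterm") / "data"
    chem = pd.read_csv(chemical or str(data / "chemical_properties.csv"), index_col=0)
    di = _read_table(
        dinucleotide or str(data / "dinucleotide_properties_synthetic.csv"), 2
    )
    tri = _read_table(
        trinucleotide or str(data / "trinucleotide_properties_synthetic.csv"), 3
    )
    return PropertyTable(
        chemical=chem[list("ACGT")],
        dinucleotide=_standardize(di),
        trinucleotide=_standardize(tri),
    )
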