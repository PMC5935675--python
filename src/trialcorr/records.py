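"""Shared cell-level vocabulary: population labels and the cell-table schema.

Cells carry two binary phenotype/genotype axes — pSTAT3 positivity and JAK2
amplification (spot-count ratio vs. the CEP9 reference) — which define four
populations. The canonical ordering below is used everywhere a 4-vector of
fractions or counts appears.
"""

from __future__ import annotations

import pandas as pd

#: Canonical population order: index = pstat3_pos + 2 * jak2_amp.
POPULATIONS: tuple[str, str, str, str] = (
    "pSTAT3-/JAK2noamp",
    "pSTAT3+/JAK2noamp",
    "pSTAT3-/JAK2amp",
    "pSTAT3+/JAK2amp",
)

#: Column order of the cell-record CSV written by the generator and the caller.
CELL_COLUMNS = [
    "cell_id",
    "x",
    "y",
    "jak2_spots",
    "cep9_spots",
    "pstat3_intensity",
    "pstat3_pos",
    "jak2_amp",
    "cd8",
    "gzmb",
    "population",
]

#: Multi-page TIFF channel order.
CHANNELS = ("dapi", "jak2", "cep9", "pstat3")


def population_label(pstat3_pos: bool, jak2_amp: bool) -> str:
    """Map the two per-cell booleans to the canonical population label."""
    return POPULATIONS[int(bool(pstat3_pos)) + 2 * int(bool(jak2_amp))]


def population_index(label: str) -> int:
    """Inverse of :func:`population_label` on the canonical ordering."""
    return POPULATIONS.index(label)


def validate_cell_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check a cell table against the schema; returns the frame unchanged.

    Raises
    ------
    ValueError
        If required columns are missing, spot counts are negative, or a
        population label is not one of the four canonical labels.
    """
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    if (df["jak2_spots"] < 0).any() or (df["cep9_spots"] < 0).any():
        raise ValueError("spot counts must be nonnegative")
    bad = set(df["population"].unique()) - set(POPULATIONS)
    if bad:
        raise ValueError(f"unknown population labels: {sorted(bad)}")
    return df


def read_cell_table(path) -> pd.DataFrame:
    """Read and validate a cell-record CSV."""
    return validate_cell_table(pd.read_csv(path))


def write_cell_table(df: pd.DataFrame, path) -> None:
    """Write a cell-record CSV in canonical column order."""
    validate_cell_table(df)
    df.loc[:, CELL_COLUMNS].to_csv(path, index=False)
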