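"""Label-free protein quantification from peptide intensities.

The procedure: normalize each sample to the total ion current (scaled so
every sample total equals the mean of the raw totals), estimate each
protein's abundance as the sum of its three most intense *unique*
peptides per sample, and log2-transform for downstream statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["peptide_sample_columns", "tic_normalize", "top3_quantify",
           "log2_abundance", "quantify"]

_META_COLS = ("protein", "unique")


def peptide_sample_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in _META_COLS]


def _validate(table: pd.DataFrame) -> list[str]:
    for col in _META_COLS:
        if col not in table.columns:
            raise ValueError(f"peptide table lacks the '{col}' column")
    samples = peptide_sample_columns(table)
    if not samples:
        raise ValueError("peptide table has no sample columns")
    if (table[samples] < 0).any().any():
        raise ValueError("peptide intensities must be non-negative")
    return samples


def tic_normalize(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Scale every sample so its total intensity equals the mean of the
    raw sample totals; returns ``(normalized_table, scaling_factors)``."""
    samples = _validate(table)
    totals = table[samples].sum(axis=0)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0][0]
        raise ValueError(f"sample {bad!r} has zero total ion current")
    factors = totals.mean() / totals
    out = table.copy()
    out[samples] = table[samples] * factors
    return out, factors


def top3_quantify(table: pd.DataFrame) -> pd.DataFrame:
    """Per protein and sample, the sum of the three most intense unique
    peptides (fewer than three -> sum of what exists; no unique peptides
    -> protein absent from the output).  Ranking is per-sample."""
    samples = _validate(table)
    unique = table[table["unique"].astype(bool)]
    if unique.empty:
        return pd.DataFrame(columns=samples,
                            index=pd.Index([], name="protein"))
    rows = {}
    for protein, grp in unique.groupby("protein", sort=True):
        vals = grp[samples].to_numpy(dtype=float)
        top3 = -np.sort(-vals, axis=0)[:3]
        rows[protein] = top3.sum(axis=0)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    out.index.name = "protein"
    return out


def log2_abundance(table: pd.DataFrame) -> pd.DataFrame:
    """log2 of positive abundances; zeros become missing, never -inf."""
    if (table < 0).any().any():
        raise ValueError("protein abundances must be non-negative")
    return table.where(table > 0).transform(np.log2)


def quantify(peptides: pd.DataFrame, log2: bool = True) -> pd.DataFrame:
    """TIC-normalize, top-3 sum, and (optionally) log2-transform."""
    normalized, _ = tic_normalize(peptides)
    abundance = top3_quantify(normalized)
    return log2_abundance(abundance) if log2 else abundance
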