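"""qPCR quantification: 2^-ddCt relative expression and ChIP percent-of-input.

The relative-quantification route assumes a doubling of product per
cycle (amplification efficiency fixed at 2).  Per replicate,

    dCt  = Ct_target - Ct_reference
    ddCt = dCt - mean(dCt of the calibrator condition)
    rq   = 2^(-ddCt)

so the calibrator condition averages to rq = 1 by construction.  With
dual reference genes the geometric-mean option combines their Cts by
arithmetic mean on the cycle scale (equivalent to a geometric mean of
the implied quantities).

ChIP enrichment relative to input uses the standard percent-of-input
convention: the input Ct is first adjusted for the input dilution
(``Ct_input - log2(1/input_fraction)``), then

    %input = 100 * 2^(adjusted_input_Ct - Ct_IP).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log2
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["RelativeQuant", "ddct", "chip_enrichment", "read_ct_table"]

CT_RANGE = (0.0, 45.0)

REQUIRED_CT_COLUMNS = [
    "sample_id",
    "condition",
    "target_gene",
    "reference_gene",
    "ct_target",
    "ct_reference",
    "replicate",
]


@dataclass(frozen=True)
class RelativeQuant:
    target_gene: str
    condition: str
    delta_ct: float        # mean dCt over replicates, cycles
    delta_delta_ct: float  # mean ddCt vs calibrator, cycles
    rq: float              # mean 2^-ddCt over replicates
    sem: float             # SEM of rq across replicates (0 for n=1)
    n_replicates: int


def _validate_ct(df: pd.DataFrame) -> None:
    missing_cols = [c for c in REQUIRED_CT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"Ct table missing columns: {missing_cols}")
    for col in ("ct_target", "ct_reference"):
        bad = df[df[col].isna()]
        if len(bad):
            rec = bad.iloc[0]
            raise ValueError(
                f"missing {col} for sample {rec['sample_id']!r}, "
                f"gene {rec['target_gene']!r}, replicate {rec['replicate']}"
            )
        vals = df[col]
        if ((vals <= CT_RANGE[0]) | (vals >= CT_RANGE[1])).any():
            raise ValueError(f"{col} values must lie in ({CT_RANGE[0]}, {CT_RANGE[1]})")


def ddct(
    ct: pd.DataFrame,
    calibrator_condition: str,
    aggregate: str = "rq",
) -> list[RelativeQuant]:
    """2^-ddCt relative quantification against a calibrator condition.

    One result per (target gene, condition).  ``aggregate`` chooses the
    scale on which replicates are averaged: ``"rq"`` (mean and SEM of the
    per-replicate fold changes, the plotting convention) or ``"log"``
    (mean ddCt first, then a single fold change; SEM reported on the rq
    values either way).
    """
    _validate_ct(ct)
    if aggregate not in ("rq", "log"):
        raise ValueError(f"unknown aggregate mode {aggregate!r}")
    df = ct.copy()
    df["delta_ct"] = df["ct_target"] - df["ct_reference"]

    results: list[RelativeQuant] = []
    for gene, gdf in df.groupby("target_gene", sort=True):
        calib = gdf[gdf["condition"] == calibrator_condition]
        if calib.empty:
            raise ValueError(
                f"calibrator condition {calibrator_condition!r} absent for gene {gene!r}"
            )
        calib_mean = calib["delta_ct"].mean()
        for cond, cdf in gdf.groupby("condition", sort=True):
            ddct_vals = (cdf["delta_ct"] - calib_mean).to_numpy()
            rq_vals = np.exp2(-ddct_vals)
            if aggregate == "rq":
                rq_mean = float(rq_vals.mean())
            else:
                rq_mean = float(2.0 ** (-ddct_vals.mean()))
            sem = float(rq_vals.std(ddof=1) / np.sqrt(len(rq_vals))) if len(rq_vals) > 1 else 0.0
            results.append(
                RelativeQuant(
                    target_gene=gene,
                    condition=cond,
                    delta_ct=float(cdf["delta_ct"].mean()),
                    delta_delta_ct=float(ddct_vals.mean()),
                    rq=rq_mean,
                    sem=sem,
                    n_replicates=len(rq_vals),
                )
            )
    return results


def combine_references(ct_refs: pd.DataFrame) -> pd.Series:
    """Geometric-mean combination of multiple reference genes.

    Input: one column of Cts per reference gene, one row per reaction.
    The combined Ct is the arithmetic mean of the reference Cts, which
    corresponds to the geometric mean of the implied template amounts.
    """
    return ct_refs.mean(axis=1)


def chip_enrichment(ct_ip: float, ct_input: float, input_fraction: float) -> float:
    """ChIP-qPCR enrichment as percent of (dilution-adjusted) input.

    ``input_fraction`` is the share of chromatin kept as input (e.g. 0.01
    for a 1% input).  Returns a percentage; 100 means the IP recovered as
    much template as the whole input.
    """
    if not (0.0 < input_fraction <= 1.0):
        raise ValueError(f"input_fraction must be in (0, 1], got {input_fraction}")
    adjusted_input = ct_input - log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted_input - ct_ip)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _validate_ct(df)
    return df
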