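"""Two-group miRNA differential expression with an FPKM fold-change filter.

The screen asks a deliberately simple question of a small-RNA count
matrix: which miRNAs are *up-regulated* in the treated condition at a
fold-change of at least ``fc_threshold`` (default 2.5, on the ratio of
mean FPKM values) with a BH-adjusted p-value below ``alpha`` (default
0.05)?

Three test engines are available:

``nb_wald`` (default)
    A negative-binomial Wald test on size-factor-normalised counts with a
    per-miRNA method-of-moments dispersion pooled across both conditions
    (floored at 1e-8).  The Wald statistic is referred to a t distribution
    with ``n1 + n2 - 2`` degrees of freedom, which keeps the test close
    to nominal size with the 3-vs-3 replicate designs it is meant for.
``log_fpkm_welch``
    Welch's t-test on log2(FPKM + 1).
``fc_only``
    No hypothesis test: the filter reduces to the fold-change rule
    (adjusted p is set to 0).  The only engine usable with single
    replicates.

Fold change uses a pseudocount on both means,
``(mean_treated + eps) / (mean_control + eps)``, so all-zero controls
give a finite ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _st

from .genesets import GeneSet
from .nchg import bh_adjust

__all__ = [
    "CountMatrix",
    "DEConfig",
    "fpkm_normalise",
    "size_factors",
    "de_test",
    "apply_cutoffs",
    "read_count_matrix",
    "write_de_results",
]


@dataclass
class CountMatrix:
    """Integer miRNA x sample counts with condition labels and lengths.

    counts
        DataFrame indexed by miRNA id, one column per sample.
    condition
        Series mapping sample id -> condition label (exactly two levels).
    lengths
        Series mapping miRNA id -> mature length in nucleotides.
    """

    counts: pd.DataFrame
    condition: pd.Series
    lengths: pd.Series

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate miRNA ids: {dups}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = self.counts.columns.difference(self.condition.index)
        if len(missing):
            raise ValueError(f"samples without condition label: {missing.tolist()}")
        self.condition = self.condition.reindex(self.counts.columns)
        missing_len = self.counts.index.difference(self.lengths.index)
        if len(missing_len):
            raise ValueError(f"miRNAs without length: {missing_len.tolist()}")
        self.lengths = self.lengths.reindex(self.counts.index).astype(float)
        if (self.lengths <= 0).any():
            raise ValueError("mature lengths must be > 0")

    @property
    def levels(self) -> list[str]:
        return sorted(self.condition.unique().tolist())


@dataclass
class DEConfig:
    test: str = "nb_wald"
    fc_threshold: float = 2.5
    alpha: float = 0.05
    fc_pseudocount: float = 0.25  # FPKM units, keeps all-zero controls finite
    dispersion_floor: float = 1e-8


def fpkm_normalise(cm: CountMatrix) -> pd.DataFrame:
    """FPKM: counts / (length in kb x library size in millions).

    Library size is the per-sample column sum of the matrix.  A sample
    with zero total counts cannot be normalised and raises, naming it.
    """
    totals = cm.counts.sum(axis=0).astype(float)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {zero.index.tolist()}")
    kb = cm.lengths.to_numpy()[:, None] / 1e3
    millions = totals.to_numpy()[None, :] / 1e6
    return pd.DataFrame(
        cm.counts.to_numpy(dtype=float) / (kb * millions),
        index=cm.counts.index,
        columns=cm.counts.columns,
    )


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors, excluding all-zero rows.

    Rows containing any zero are dropped from the geometric-mean
    reference (the standard convention), so factors are driven by miRNAs
    quantified in every sample.
    """
    x = counts.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no miRNA with non-zero counts in all samples; cannot estimate size factors")
    logs = np.log(x[positive])
    log_geomean = logs.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logs - log_geomean, axis=0))
    return pd.Series(sf, index=counts.columns)


def _group_split(cm: CountMatrix, control: str, treated: str) -> tuple[list[str], list[str]]:
    ctrl = cm.condition[cm.condition == control].index.tolist()
    trt = cm.condition[cm.condition == treated].index.tolist()
    return ctrl, trt


def _nb_wald_pvalues(
    norm: np.ndarray,
    idx_c: np.ndarray,
    idx_t: np.ndarray,
    dispersion_floor: float,
    dispersion_prior_df: float = 10.0,
) -> np.ndarray:
    """Wald p-values for the log mean difference under an NB variance model.

    Per-miRNA method-of-moments dispersions (pooled across conditions)
    are moderated toward the matrix-wide median dispersion with
    ``dispersion_prior_df`` pseudo-degrees of freedom — with a handful of
    replicates the raw per-miRNA estimate is too noisy to referee a Wald
    statistic on its own.  The moderated statistic is referred to a t
    distribution whose degrees of freedom are the residual df augmented
    by the prior df, reflecting the information the moderation borrows.
    """
    xc, xt = norm[:, idx_c], norm[:, idx_t]
    n1, n2 = xc.shape[1], xt.shape[1]
    mu1, mu2 = xc.mean(axis=1), xt.mean(axis=1)
    v1 = xc.var(axis=1, ddof=1)
    v2 = xt.var(axis=1, ddof=1)
    # pooled method-of-moments dispersion: var = mu + alpha mu^2 per group
    num = (n1 - 1) * (v1 - mu1) + (n2 - 1) * (v2 - mu2)
    den = (n1 - 1) * mu1**2 + (n2 - 1) * mu2**2
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_hat = np.where(den > 0, num / den, 0.0)
    alpha_hat = np.maximum(alpha_hat, dispersion_floor)

    informative = den > 0
    alpha_trend = (
        float(np.median(alpha_hat[informative])) if informative.any() else dispersion_floor
    )
    df = n1 + n2 - 2
    alpha_mod = (df * alpha_hat + dispersion_prior_df * alpha_trend) / (
        df + dispersion_prior_df
    )
    alpha_mod = np.maximum(alpha_mod, dispersion_floor)

    eps = 0.5  # normalised-count offset: finite log ratio at zero means
    m1, m2 = mu1 + eps, mu2 + eps
    var_log1 = (m1 + alpha_mod * m1**2) / (n1 * m1**2)
    var_log2 = (m2 + alpha_mod * m2**2) / (n2 * m2**2)
    se = np.sqrt(var_log1 + var_log2)
    w = (np.log(m2) - np.log(m1)) / se
    return 2.0 * _st.t.sf(np.abs(w), df + dispersion_prior_df)


def de_test(
    cm: CountMatrix,
    config: DEConfig | None = None,
    control: str | None = None,
    treated: str | None = None,
) -> pd.DataFrame:
    """Per-miRNA two-group test; returns one row per miRNA.

    Columns: mean_fpkm_control, mean_fpkm_treated, fold_change, log2fc,
    p_raw, p_adj, passes_filter.  Condition levels default to sorted
    order (first = control) unless named explicitly.
    """
    config = config or DEConfig()
    levels = cm.levels
    if len(levels) != 2:
        raise ValueError(f"need exactly two condition levels, got {levels}")
    control = control or levels[0]
    treated = treated or (levels[1] if control == levels[0] else levels[0])
    ctrl, trt = _group_split(cm, control, treated)
    if (len(ctrl) < 2 or len(trt) < 2) and config.test != "fc_only":
        raise ValueError(
            f"test {config.test!r} needs >=2 replicates per group "
            f"(control={len(ctrl)}, treated={len(trt)}); use test='fc_only'"
        )

    fpkm = fpkm_normalise(cm)
    mean_c = fpkm[ctrl].mean(axis=1)
    mean_t = fpkm[trt].mean(axis=1)
    eps = config.fc_pseudocount
    fc = (mean_t + eps) / (mean_c + eps)

    if config.test == "nb_wald":
        sf = size_factors(cm.counts)
        norm = cm.counts.to_numpy(dtype=float) / sf.to_numpy()[None, :]
        cols = cm.counts.columns
        p_raw = _nb_wald_pvalues(
            norm,
            cols.get_indexer(ctrl),
            cols.get_indexer(trt),
            config.dispersion_floor,
        )
        # degenerate rows (identical values in both groups) are null by fiat
        p_raw = np.where(np.isnan(p_raw), 1.0, np.clip(p_raw, 0.0, 1.0))
        p_adj = np.asarray(bh_adjust(p_raw).adjusted)
    elif config.test == "log_fpkm_welch":
        lc = np.log2(fpkm[ctrl].to_numpy() + 1.0)
        lt = np.log2(fpkm[trt].to_numpy() + 1.0)
        p_raw = _st.ttest_ind(lt, lc, axis=1, equal_var=False).pvalue
        p_raw = np.where(np.isnan(p_raw), 1.0, p_raw)
        p_adj = np.asarray(bh_adjust(p_raw).adjusted)
    elif config.test == "fc_only":
        p_raw = np.full(len(fpkm), np.nan)
        p_adj = np.zeros(len(fpkm))
    else:
        raise ValueError(f"unknown test engine {config.test!r}")

    out = pd.DataFrame(
        {
            "mirna_id": cm.counts.index,
            "mean_fpkm_control": mean_c.to_numpy(),
            "mean_fpkm_treated": mean_t.to_numpy(),
            "fold_change": fc.to_numpy(),
            "log2fc": np.log2(fc.to_numpy()),
            "p_raw": p_raw,
            "p_adj": p_adj,
        }
    )
    out["passes_filter"] = (out["fold_change"] >= config.fc_threshold) & (
        out["p_adj"] < config.alpha
    )
    return out


def apply_cutoffs(
    results: pd.DataFrame, fc_threshold: float = 2.5, alpha: float = 0.05
) -> GeneSet:
    """Upregulated survivor set: fold_change >= threshold AND p_adj < alpha.

    The boundary is inclusive on fold change.  Order is deterministic:
    ascending adjusted p, ties broken by id.
    """
    if results.empty:
        raise ValueError("empty DE result table")
    surv = results[
        (results["fold_change"] >= fc_threshold) & (results["p_adj"] < alpha)
    ].sort_values(["p_adj", "mirna_id"], kind="mergesort")
    return GeneSet.from_iterable("upregulated", surv["mirna_id"].tolist())


# ---------------------------------------------------------------------------
# file plumbing
# ---------------------------------------------------------------------------

def read_count_matrix(
    counts_path: str | Path, samples_path: str | Path, lengths_path: str | Path
) -> CountMatrix:
    """Counts TSV (first column miRNA id) + samples.tsv + lengths.tsv."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t")
    lengths = pd.read_csv(lengths_path, sep="\t")
    return CountMatrix(
        counts=counts,
        condition=samples.set_index("sample_id")["condition"],
        lengths=lengths.set_index("mirna_id")["length_nt"],
    )


def write_de_results(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False)
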