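"""Mutant-vs-wild-type accumulation statistics.

Per-circRNA differences use a Welch two-sample t-test on log2(normalized
count + pseudocount) across replicates; the significance flag mirrors the
conventional raw-p rule (p <= 0.05 AND at least a two-fold change), with
Benjamini-Hochberg adjusted p-values reported alongside.  Genotype-level
shifts use a two-sided Mann-Whitney U on pooled per-circRNA-per-replicate
normalized counts, and the coupling between circular and linear species is
summarized by a Pearson correlation over paired abundances.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "circ_fold_change_test",
    "global_accumulation_test",
    "GlobalTestResult",
    "circ_linear_correlation",
    "CorrelationResult",
    "linear_abundance_test",
]

P_CUTOFF = 0.05
FOLD_CUTOFF = 2.0


def _values_frame(matrix) -> pd.DataFrame:
    return matrix.normalized if hasattr(matrix, "normalized") else matrix


def _group_columns(samples: pd.DataFrame, genotype: str) -> list[str]:
    cols = list(samples.loc[samples.genotype == genotype, "sample_id"])
    if not cols:
        raise KeyError(f"genotype {genotype!r} absent from the sample sheet")
    return cols


def circ_fold_change_test(matrix, samples: pd.DataFrame,
                          genotype_ref: str, genotype_alt: str,
                          pseudocount: float = 0.5,
                          universe: Sequence[str] | None = None,
                          p_cutoff: float = P_CUTOFF,
                          fold_cutoff: float = FOLD_CUTOFF) -> pd.DataFrame:
    """Per-feature Welch t-test of ``genotype_alt`` against ``genotype_ref``.

    Operates on log2(normalized + pseudocount); reports the fold change as
    log2((mean_alt + c) / (mean_ref + c)) on the normalized scale.
    Features that are zero in every replicate of both groups are excluded
    (logged), never reported significant.  Raises if either group has
    fewer than two replicates.
    """
    values = _values_frame(matrix)
    if universe is not None:
        universe = [f for f in universe if f in values.index]
        values = values.loc[universe]
    cols_ref = _group_columns(samples, genotype_ref)
    cols_alt = _group_columns(samples, genotype_alt)
    for name, cols in ((genotype_ref, cols_ref), (genotype_alt, cols_alt)):
        if len(cols) < 2:
            raise ValueError(
                f"group {name!r} has {len(cols)} replicate(s); need >= 2")

    a = values[cols_ref].to_numpy(dtype=float)
    b = values[cols_alt].to_numpy(dtype=float)
    nonzero = (a.sum(axis=1) + b.sum(axis=1)) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("dropping %d all-zero features from testing", n_dropped)
    a, b = a[nonzero], b[nonzero]
    ids = values.index[nonzero]

    la = np.log2(a + pseudocount)
    lb = np.log2(b + pseudocount)
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        # identical groups yield a zero-variance t; reported as p = 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = sps.ttest_ind(lb, la, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical groups
    mean_ref = a.mean(axis=1)
    mean_alt = b.mean(axis=1)
    log2_fc = np.log2((mean_alt + pseudocount) / (mean_ref + pseudocount))
    p_adj = multipletests(p, method="fdr_bh")[1] if len(p) else p
    significant = (p <= p_cutoff) & (np.abs(log2_fc) >= np.log2(fold_cutoff))
    return pd.DataFrame({
        "circ_id": ids,
        "mean_wt": mean_ref,
        "mean_mut": mean_alt,
        "log2_fc": log2_fc,
        "p_value": p,
        "p_adj": p_adj,
        "significant": significant,
    }).set_index("circ_id")


@dataclass
class GlobalTestResult:
    """Mann-Whitney comparison of pooled normalized circRNA counts."""

    p_value: float
    median_ref: float
    median_alt: float
    n_ref: int
    n_alt: int
    stars: str
    message: str = ""

    @property
    def ok(self) -> bool:
        return not math.isnan(self.p_value)


def _stars(p: float) -> str:
    if math.isnan(p):
        return ""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def global_accumulation_test(matrix, samples: pd.DataFrame,
                             genotype: str, reference: str,
                             universe_alt: Sequence[str] | None = None,
                             universe_ref: Sequence[str] | None = None
                             ) -> GlobalTestResult:
    """Genotype-level abundance shift: two-sided Mann-Whitney U.

    Observations are per-circRNA-per-replicate normalized counts; each
    side is restricted to its own universe (typically the genotype's
    consensus set; pass ``None`` for all features).  Reports p, medians
    and the conventional star coding (** for p <= 0.01, *** for 0.001).
    """
    values = _values_frame(matrix)

    def pooled(genotype_, universe_):
        cols = _group_columns(samples, genotype_)
        sub = values if universe_ is None else values.loc[
            [f for f in universe_ if f in values.index]]
        return sub[cols].to_numpy(dtype=float).ravel()

    x_alt = pooled(genotype, universe_alt)
    x_ref = pooled(reference, universe_ref)
    if len(x_alt) == 0 or len(x_ref) == 0:
        return GlobalTestResult(
            p_value=math.nan, median_ref=math.nan, median_alt=math.nan,
            n_ref=len(x_ref), n_alt=len(x_alt), stars="",
            message="empty observation universe")
    if len(x_alt) < 2 or len(x_ref) < 2:
        raise ValueError("need at least two observations per side")
    res = sps.mannwhitneyu(x_alt, x_ref, alternative="two-sided")
    p = float(res.pvalue)
    return GlobalTestResult(
        p_value=p, median_ref=float(np.median(x_ref)),
        median_alt=float(np.median(x_alt)),
        n_ref=len(x_ref), n_alt=len(x_alt), stars=_stars(p))


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n_pairs: int
    message: str = ""

    @property
    def ok(self) -> bool:
        return not math.isnan(self.r)


def circ_linear_correlation(circ_matrix, linear_matrix,
                            pairs: Mapping[str, str],
                            samples: pd.DataFrame | None = None,
                            genotype: str | None = None) -> CorrelationResult:
    """Pearson correlation between circular and linear abundances.

    ``pairs`` maps circRNA ids to their linear-counterpart feature ids
    (boundary-read or host-gene features).  Per feature, abundances are
    averaged across the genotype's replicates (all samples when no
    genotype is given).  Requires >= 3 pairs with variance on both sides.
    """
    circ = _values_frame(circ_matrix)
    lin = _values_frame(linear_matrix)
    if samples is not None and genotype is not None:
        cols = _group_columns(samples, genotype)
        circ, lin = circ[cols], lin[[c for c in cols if c in lin.columns]]
    usable = [(c, l) for c, l in pairs.items()
              if c in circ.index and l in lin.index]
    if len(usable) < 3:
        return CorrelationResult(r=math.nan, p_value=math.nan,
                                 n_pairs=len(usable),
                                 message="fewer than 3 overlapping pairs")
    x = np.array([circ.loc[c].mean() for c, _ in usable], dtype=float)
    y = np.array([lin.loc[l].mean() for _, l in usable], dtype=float)
    if x.std() == 0 or y.std() == 0:
        return CorrelationResult(r=math.nan, p_value=math.nan,
                                 n_pairs=len(usable),
                                 message="zero variance on one side")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic),
                             p_value=float(res.pvalue), n_pairs=len(usable))


def linear_abundance_test(linear_matrix, samples: pd.DataFrame,
                          genotype: str, reference: str,
                          universe: Sequence[str] | None = None
                          ) -> GlobalTestResult:
    """Mann-Whitney shift test on the linear counterparts of a genotype's
    consensus circRNAs (same machinery as the circular global test)."""
    return global_accumulation_test(linear_matrix, samples, genotype,
                                    reference, universe_alt=universe,
                                    universe_ref=universe)
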