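"""Replicate reproducibility, consensus sets and correlation diagnostics.

Most circRNAs in replicated libraries appear in a single biological
replicate; the analyses downstream therefore focus on the *consensus*
circRNAs detected in all (or at least k) replicates of a genotype, and on
variant-specific circRNAs absent from the reference genotype.  The
replicate-correlation contrast (low Pearson r between circRNA profiles,
near-perfect r between mRNA profiles from the same libraries) is the
diagnostic separating biological stochasticity from data-quality issues.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .detect import CircCall

logger = logging.getLogger(__name__)

__all__ = [
    "ConsensusRecord",
    "detection_sets",
    "reproducibility_spectrum",
    "consensus_set",
    "unique_to_variant",
    "replicate_correlation",
]


@dataclass
class ConsensusRecord:
    """Reproducibility of one circRNA across a genotype's replicates."""

    circ_id: str
    genotype: str
    n_detected: int
    n_replicates: int
    in_consensus: bool
    detection_pattern: tuple[bool, ...]


def _replicate_samples(samples: pd.DataFrame, genotype: str) -> list[str]:
    sel = samples[samples.genotype == genotype]
    if sel.empty:
        raise KeyError(f"genotype {genotype!r} absent from the sample sheet")
    return list(sel.sort_values("replicate").sample_id)


def detection_sets(calls_by_sample: Mapping[str, Sequence[CircCall]],
                   samples: pd.DataFrame, genotype: str) -> list[set[str]]:
    """Per-replicate sets of called circRNA ids for one genotype."""
    return [
        {c.id for c in calls_by_sample.get(sid, [])}
        for sid in _replicate_samples(samples, genotype)
    ]


def reproducibility_spectrum(calls_by_sample: Mapping[str, Sequence[CircCall]],
                             samples: pd.DataFrame,
                             genotype: str) -> pd.Series:
    """Fractions of circRNAs detected in exactly 1..n replicates.

    Fractions are over the union of circRNAs seen in at least one
    replicate of the genotype and sum to 1 (empty union gives zeros).
    """
    detected = detection_sets(calls_by_sample, samples, genotype)
    n = len(detected)
    if n < 2:
        raise ValueError(
            f"reproducibility spectrum needs >=2 replicates for {genotype!r}")
    union = set().union(*detected)
    counts = np.zeros(n, dtype=int)
    for cid in union:
        k = sum(cid in d for d in detected)
        counts[k - 1] += 1
    total = counts.sum()
    frac = counts / total if total else counts.astype(float)
    return pd.Series(frac, index=pd.RangeIndex(1, n + 1, name="n_replicates"),
                     name=genotype)


def consensus_set(calls_by_sample: Mapping[str, Sequence[CircCall]],
                  samples: pd.DataFrame, genotype: str,
                  k: int | None = None
                  ) -> tuple[set[str], list[ConsensusRecord]]:
    """circRNAs detected in >= k replicates (default k = all replicates).

    Returns the consensus id set and a :class:`ConsensusRecord` for every
    circRNA seen at least once in the genotype.
    """
    detected = detection_sets(calls_by_sample, samples, genotype)
    n = len(detected)
    if k is None:
        k = n
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} replicates of {genotype!r}")
    union = sorted(set().union(*detected))
    records = []
    consensus: set[str] = set()
    for cid in union:
        pattern = tuple(cid in d for d in detected)
        nd = sum(pattern)
        inc = nd >= k
        if inc:
            consensus.add(cid)
        records.append(ConsensusRecord(
            circ_id=cid, genotype=genotype, n_detected=nd, n_replicates=n,
            in_consensus=inc, detection_pattern=pattern))
    return consensus, records


def unique_to_variant(variant_set: set[str],
                      reference_calls: Sequence[set[str]] | Mapping[str, set[str]],
                      mode: str = "strict") -> set[str]:
    """Variant-consensus circRNAs absent from the reference genotype.

    ``reference_calls`` are the per-replicate detection sets of the
    reference.  In ``strict`` mode any id seen in *any* reference
    replicate (even once) is removed — circRNAs "detected in none of the
    reference replicates" remain.  In ``consensus`` mode only ids in the
    reference's all-replicate consensus are removed.
    """
    if isinstance(reference_calls, Mapping):
        ref_sets = list(reference_calls.values())
    else:
        ref_sets = list(reference_calls)
    if not ref_sets:
        return set(variant_set)
    if mode == "strict":
        ref = set().union(*ref_sets)
    elif mode == "consensus":
        ref = set.intersection(*ref_sets)
    else:
        raise ValueError(f"unknown uniqueness mode {mode!r}")
    return set(variant_set) - ref


def replicate_correlation(values: pd.DataFrame, samples: pd.DataFrame,
                          genotype: str, log: bool = False
                          ) -> tuple[pd.DataFrame, float]:
    """Pairwise Pearson r between a genotype's replicate profiles.

    ``values`` is a features x samples matrix of normalized abundances
    (a :class:`~circleaf.quantify.CountMatrix`'s ``normalized`` frame).
    For each replicate pair, features that are zero in both members are
    dropped (their shared absence carries no signal); features present in
    only one member are kept as zeros — presence/absence variability is
    precisely what distinguishes circRNA from mRNA profiles.  Returns the
    pair table and the mean r.
    """
    if hasattr(values, "normalized"):  # accept a CountMatrix
        values = values.normalized
    reps = _replicate_samples(samples, genotype)
    if len(reps) < 2:
        raise ValueError(f"need >=2 replicates for {genotype!r}")
    rows = []
    for a, b in itertools.combinations(reps, 2):
        x = values[a].to_numpy(dtype=float)
        y = values[b].to_numpy(dtype=float)
        keep = (x != 0) | (y != 0)
        x, y = x[keep], y[keep]
        if log:
            x, y = np.log2(x + 1), np.log2(y + 1)
        if len(x) < 2 or x.std() == 0 or y.std() == 0:
            logger.warning("degenerate replicate pair (%s, %s)", a, b)
            r = math.nan
        else:
            r = float(sps.pearsonr(x, y).statistic)
        rows.append({"rep_a": a, "rep_b": b, "n_features": len(x), "r": r})
    table = pd.DataFrame(rows)
    finite = table.r.dropna()
    mean_r = float(finite.mean()) if len(finite) else math.nan
    return table, mean_r
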