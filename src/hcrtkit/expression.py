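"""Between-sample normalization and replicate handling for count matrices.

The study design has three sample groups — FACS-sorted fluorescent Hcrt
neurons (``egfp_pos``), the non-fluorescent cells from the same dissociation
(``egfp_neg``), and unsorted whole-head tissue (``whole_head``) — each with a
small number of sequencing replicates.  This module provides:

* :class:`CountMatrix`, the validated gene x sample container of raw read
  counts with per-gene transcript lengths and a sample -> group mapping;
* :func:`compute_tpm`, transcripts-per-million normalization;
* :func:`tmm_factors`, a trimmed-mean-of-M-values style between-sample
  scaling factor;
* :func:`pool_replicates`, summation of replicate columns into one column
  per group;
* :func:`fold_change`, the pseudocounted ratio of the target group TPM to
  the larger of the two control TPMs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "CountMatrix",
    "compute_tpm",
    "tmm_factors",
    "pool_replicates",
    "fold_change",
]

#: canonical sample groups: target population and the two controls
GROUPS = ("egfp_pos", "egfp_neg", "whole_head")


@dataclass
class CountMatrix:
    """Gene x sample raw read counts with transcript lengths and group tags.

    Parameters
    ----------
    counts
        Non-negative integer counts, index = gene ids (unique), columns =
        sample names.
    lengths
        Transcript length in bp per gene (same index as ``counts``), > 0.
    groups
        Mapping sample name -> group label, covering every column.
    """

    counts: pd.DataFrame
    lengths: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            self.counts = pd.DataFrame(self.counts)
        self.lengths = pd.Series(self.lengths)
        if isinstance(self.groups, Mapping):
            self.groups = pd.Series(self.groups)
        self.groups = pd.Series(self.groups)

        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if not self.counts.index.equals(self.lengths.index):
            self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths.index[self.lengths.isna()][0]
            raise ValueError(f"missing transcript length for gene {missing!r}")
        if (self.lengths <= 0).any():
            bad = self.lengths.index[self.lengths <= 0][0]
            raise ValueError(f"non-positive transcript length for gene {bad!r}")
        untagged = [s for s in self.counts.columns if s not in self.groups.index]
        if untagged:
            raise ValueError(f"samples without a group tag: {untagged}")
        self.groups = self.groups.reindex(self.counts.columns)
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative counts are not allowed")
        if not np.allclose(arr, np.round(arr)):
            raise ValueError("counts must be integers")

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    def library_sizes(self) -> pd.Series:
        """Total read count per sample."""
        return self.counts.sum(axis=0)

    def samples_of(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]

    def group_names(self) -> list[str]:
        seen: list[str] = []
        for s in self.counts.columns:
            g = self.groups[s]
            if g not in seen:
                seen.append(g)
        return seen


def compute_tpm(counts: CountMatrix) -> pd.DataFrame:
    """Transcripts-per-million normalization.

    For each sample, ``TPM_g = 1e6 * (c_g / l_g) / sum_j (c_j / l_j)`` where
    ``c`` is the raw count and ``l`` the transcript length.  Columns therefore
    sum to 1e6, except all-zero columns, which map to all-zero with a warning.
    """
    rate = counts.counts.div(counts.lengths, axis=0)
    totals = rate.sum(axis=0)
    zero_cols = totals[totals == 0].index
    if len(zero_cols):
        warnings.warn(
            f"all-zero sample column(s) {list(zero_cols)}: TPM left at zero",
            RuntimeWarning,
            stacklevel=2,
        )
        totals = totals.replace(0, np.nan)
    tpm = rate.div(totals, axis=1) * 1e6
    return tpm.fillna(0.0)


def _trimmed_keep_mask(values: np.ndarray, trim: float) -> np.ndarray:
    """Boolean mask keeping the central ``1 - 2*trim`` fraction by rank."""
    n = values.size
    lo = int(np.floor(n * trim))
    hi = n - lo
    if hi <= lo:  # tiny inputs: trimming would discard everything
        return np.ones(n, dtype=bool)
    order = np.argsort(values, kind="stable")
    keep = np.zeros(n, dtype=bool)
    keep[order[lo:hi]] = True
    return keep


def tmm_factors(
    counts: CountMatrix,
    reference_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    weighted: bool = True,
) -> pd.Series:
    """Trimmed-mean-of-M-values style scaling factor per sample.

    For each sample, over genes with nonzero counts in both the sample and
    the reference, per-gene log-ratios ``M = log2(c_s / c_r)`` and abundances
    ``A = 0.5 * log2(c_s * c_r)`` are formed; the most extreme ``trim_m``
    fraction of M (two-sided) and ``trim_a`` fraction of A (two-sided) are
    discarded, and the factor is ``2 ** mean(M)`` over the kept genes,
    weighted (when ``weighted``) by the inverse asymptotic variance of M,
    ``1 / (1/c_s + 1/c_r)``.

    The convention is that the factor multiplies the reference scale to
    match the sample: a sample equal to the reference with every count
    doubled gets factor 2 exactly.  The reference sample's factor is 1.

    Parameters
    ----------
    reference_sample
        Column to compare against; defaults to the sample whose library
        size is the median (lower median for even sample counts).
    """
    if not 0 <= trim_m < 0.5 or not 0 <= trim_a < 0.5:
        raise ValueError("trim fractions must be in [0, 0.5)")
    lib = counts.library_sizes()
    if reference_sample is None:
        order = lib.sort_values(kind="stable").index
        reference_sample = order[(len(order) - 1) // 2]
    if reference_sample not in counts.samples:
        raise KeyError(f"unknown reference sample {reference_sample!r}")
    ref = counts.counts[reference_sample].to_numpy(dtype=float)
    if ref.sum() <= 0:
        raise ValueError("reference sample has zero total count")

    factors = {}
    for s in counts.samples:
        if s == reference_sample:
            factors[s] = 1.0
            continue
        obs = counts.counts[s].to_numpy(dtype=float)
        shared = (obs > 0) & (ref > 0)
        if not shared.any():
            raise ValueError(f"sample {s!r} shares no nonzero genes with the reference")
        c_s, c_r = obs[shared], ref[shared]
        m = np.log2(c_s / c_r)
        a = 0.5 * np.log2(c_s * c_r)
        keep = _trimmed_keep_mask(m, trim_m) & _trimmed_keep_mask(a, trim_a)
        if not keep.any():
            keep = np.ones(m.size, dtype=bool)
        w = 1.0 / (1.0 / c_s + 1.0 / c_r) if weighted else np.ones_like(c_s)
        factors[s] = float(2 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep])))
    return pd.Series(factors, index=counts.samples, name="tmm_factor")


def pool_replicates(counts: CountMatrix) -> CountMatrix:
    """Sum replicate columns into one column per group.

    The pooled column for a group is the gene-wise sum over its replicates,
    so pooled library sizes equal the sums of replicate library sizes.  The
    pooled sample name is the group label itself.
    """
    pooled = {}
    for g in counts.group_names():
        cols = counts.samples_of(g)
        pooled[g] = counts.counts[cols].sum(axis=1)
    frame = pd.DataFrame(pooled)
    groups = pd.Series({g: g for g in frame.columns})
    return CountMatrix(frame, counts.lengths.copy(), groups)


def fold_change(
    tpm_pos: float,
    tpm_controls: Iterable[float] | float,
    pseudocount: float = 1.0,
) -> float:
    """Enrichment fold of the target over the *larger* of the controls.

    ``fold = (tpm_pos + pseudocount) / (max(controls) + pseudocount)``.  The
    max-of-controls denominator encodes the requirement that the transcript
    be more abundant in the target than in *both* control groups; the
    pseudocount (default 1 TPM) keeps the ratio finite when a control is 0.
    """
    if np.isscalar(tpm_controls):
        tpm_controls = [float(tpm_controls)]  # type: ignore[list-item]
    controls = [float(v) for v in tpm_controls]  # type: ignore[union-attr]
    if tpm_pos < 0 or any(v < 0 for v in controls):
        raise ValueError("TPM values must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if not controls:
        raise ValueError("at least one control TPM is required")
    return (tpm_pos + pseudocount) / (max(controls) + pseudocount)
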