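"""Calling Hcrt-neuron-enriched transcripts from a three-group count matrix.

The caller asks, per gene, whether the read counts in the sorted fluorescent
population exceed what Poisson sequencing noise around a common rate would
allow relative to *each* of the two control groups.  The test is an exact
conditional binomial: given the (overdispersion-deflated) total of the two
counts, the target count is binomial with success probability given by the
relative effective library sizes; a gene's p-value is the worse (max) of the
two pairwise comparisons, Bonferroni-corrected over the genes that pass the
raw-read floor.  Significant genes are then classified into two tiers by TPM
level and fold over the larger control:

* strict:  >= 100 TPM in the target group and >= 7-fold enrichment;
* relaxed: >= 10 TPM and >= 3.6-fold enrichment.

Amplification of picogram RNA inputs inflates replicate-to-replicate variance
beyond Poisson; a single variance-inflation factor ``phi`` (variance =
phi * mean) is estimated from the replicates and used to deflate counts
before the exact test (quasi-Poisson correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import binom

from .expression import (
    GROUPS,
    CountMatrix,
    compute_tpm,
    fold_change,
    pool_replicates,
    tmm_factors,
)

__all__ = [
    "TestConfig",
    "enrichment_statistics",
    "EnrichmentRecord",
    "estimate_overdispersion",
    "poisson_pair_test",
    "bonferroni",
    "classify_enrichment",
    "run_enrichment_pipeline",
    "records_to_frame",
]


@dataclass
class TestConfig:
    """Thresholds and modes of the enrichment caller (defaults as published).

    ``alpha`` applies to the Bonferroni-adjusted p-value.  ``reads_floor`` is
    the minimum average raw read count across target-group replicates for a
    gene to be analyzed at all (strictly greater than).  ``overdispersion_mode``
    selects between estimating phi from replicates and using ``phi_fixed``.
    ``pooling_mode`` selects between testing pooled group counts (default)
    and testing every target/control replicate pair and keeping the max p.
    """

    alpha: float = 0.01
    strict_tpm: float = 100.0
    strict_fold: float = 7.0
    relaxed_tpm: float = 10.0
    relaxed_fold: float = 3.6
    reads_floor: float = 15.0
    pseudocount: float = 1.0
    overdispersion_mode: str = "estimate"  # or "fixed"
    phi_fixed: float = 1.0
    pooling_mode: str = "pooled"  # or "per_replicate"
    use_tmm: bool = True

    __test__ = False  # not a test class despite the name

    def __post_init__(self) -> None:
        if self.relaxed_tpm > self.strict_tpm or self.relaxed_fold > self.strict_fold:
            raise ValueError("relaxed thresholds must not exceed strict thresholds")
        if self.overdispersion_mode not in ("estimate", "fixed"):
            raise ValueError(f"unknown overdispersion_mode {self.overdispersion_mode!r}")
        if self.pooling_mode not in ("pooled", "per_replicate"):
            raise ValueError(f"unknown pooling_mode {self.pooling_mode!r}")


@dataclass
class EnrichmentRecord:
    """Per-transcript result of the enrichment caller."""

    gene_id: str
    tpm_egfp_pos: float
    tpm_egfp_neg: float
    tpm_whole_head: float
    fold_vs_max_control: float
    mean_raw_reads_egfp_pos: float
    p_raw: float
    p_adjusted: float
    tier: str  # strict | relaxed | none


def estimate_overdispersion(counts: CountMatrix, min_mean: float = 10.0) -> float:
    """Estimate the variance-inflation factor phi from within-group replicates.

    phi is the median, over well-expressed genes (within-group mean count
    >= ``min_mean``) in every group with >= 2 replicates, of the within-group
    variance/mean ratio, floored at 1 (pure Poisson).  Because the sample
    variance over k replicates is approximately ``phi * mean * chi2(k-1)/(k-1)``,
    the raw median underestimates phi (the chi-square median sits below its
    mean); each group's ratios are therefore divided by the median of
    ``chi2(k-1)/(k-1)`` before pooling, which makes the estimator median-
    unbiased for Poisson data.  With no replicated group, returns 1 with a
    warning.
    """
    from scipy.stats import chi2

    ratios: list[np.ndarray] = []
    for g in counts.group_names():
        cols = counts.samples_of(g)
        if len(cols) < 2:
            continue
        sub = counts.counts[cols].to_numpy(dtype=float)
        mean = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        sel = mean >= min_mean
        df = len(cols) - 1
        correction = chi2.median(df) / df
        if sel.any():
            ratios.append(var[sel] / mean[sel] / correction)
    if not ratios:
        warnings.warn(
            "no group with >=2 replicates (or no well-expressed genes); "
            "assuming pure Poisson (phi=1)",
            RuntimeWarning,
            stacklevel=2,
        )
        return 1.0
    return float(max(1.0, np.median(np.concatenate(ratios))))


def _two_sided_binom_p(a: np.ndarray, n: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Two-sided conditional binomial p: double the smaller tail, cap at 1."""
    a = np.asarray(a)
    n = np.asarray(n)
    p = np.broadcast_to(np.asarray(p, dtype=float), a.shape)
    lower = binom.cdf(a, n, p)
    upper = binom.sf(a - 1, n, p)
    out = np.minimum(1.0, 2.0 * np.minimum(lower, upper))
    return np.where(n == 0, 1.0, out)


def poisson_pair_test(
    count_a: float,
    lib_a: float,
    count_b: float,
    lib_b: float,
    phi: float = 1.0,
) -> float:
    """Exact test of equal Poisson rates for one gene in two samples.

    Under the null that both counts share one underlying rate, conditioning
    on the total ``n = a + b`` makes ``a ~ Binomial(n, lib_a/(lib_a+lib_b))``.
    The two-sided p-value doubles the smaller tail and caps at 1.  With
    ``phi > 1`` both counts are deflated by phi (and rounded) before
    conditioning, which corrects the variance inflation of amplified
    libraries while keeping the test exact on the deflated counts.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if lib_a <= 0 or lib_b <= 0:
        raise ValueError("library sizes must be positive")
    if phi < 1:
        raise ValueError("phi must be >= 1")
    a = int(round(count_a / phi))
    b = int(round(count_b / phi))
    n = a + b
    if n == 0:
        return 1.0
    p = lib_a / (lib_a + lib_b)
    return float(_two_sided_binom_p(np.array([a]), np.array([n]), np.array([p]))[0])


def bonferroni(p_raw: np.ndarray, m: int) -> np.ndarray:
    """Bonferroni family-wise adjustment: ``min(1, m * p)``."""
    return np.minimum(1.0, np.asarray(p_raw, dtype=float) * m)


def classify_enrichment(
    tpm_pos: float,
    fold: float,
    p_adjusted: float,
    mean_raw_reads: float,
    config: TestConfig,
) -> str:
    """Assign strict / relaxed / none given the record quantities."""
    if not (p_adjusted < config.alpha and mean_raw_reads > config.reads_floor):
        return "none"
    if tpm_pos >= config.strict_tpm and fold >= config.strict_fold:
        return "strict"
    if tpm_pos >= config.relaxed_tpm and fold >= config.relaxed_fold:
        return "relaxed"
    return "none"


def _pairwise_p_pooled(
    pooled: CountMatrix, phi: float, eff_libs: pd.Series, controls: list[str]
) -> np.ndarray:
    """Per-gene max p over the two target-vs-control pooled comparisons."""
    pos = np.round(pooled.counts["egfp_pos"].to_numpy(dtype=float) / phi)
    p_max = np.zeros(len(pos))
    for ctrl in controls:
        c = np.round(pooled.counts[ctrl].to_numpy(dtype=float) / phi)
        n = pos + c
        frac = eff_libs["egfp_pos"] / (eff_libs["egfp_pos"] + eff_libs[ctrl])
        p = _two_sided_binom_p(pos, n, np.full_like(pos, frac))
        p_max = np.maximum(p_max, p)
    return p_max


def _pairwise_p_per_replicate(
    counts: CountMatrix, phi: float, eff_libs: pd.Series, controls: list[str]
) -> np.ndarray:
    """Per-gene max p over all target-replicate x control-replicate pairs."""
    pos_cols = counts.samples_of("egfp_pos")
    p_max = np.zeros(len(counts.gene_ids))
    for pc in pos_cols:
        a = np.round(counts.counts[pc].to_numpy(dtype=float) / phi)
        for ctrl in controls:
            for cc in counts.samples_of(ctrl):
                b = np.round(counts.counts[cc].to_numpy(dtype=float) / phi)
                n = a + b
                frac = eff_libs[pc] / (eff_libs[pc] + eff_libs[cc])
                p = _two_sided_binom_p(a, n, np.full_like(a, frac))
                p_max = np.maximum(p_max, p)
    return p_max


def enrichment_statistics(
    counts: CountMatrix, config: TestConfig | None = None
) -> dict:
    """Per-gene quantities of the enrichment caller, before tier filtering.

    Returns a dict with the pooled-group TPM frame (``tpm``), the per-gene
    mean raw reads in the target group (``mean_raw``), the raw and
    Bonferroni-adjusted p-values (``p_raw``, ``p_adj``, aligned with
    ``counts.gene_ids``), the tested mask (reads floor), the multiplicity
    ``m``, and the estimated variance-inflation ``phi``.
    """
    config = config or TestConfig()
    present = set(counts.group_names())
    missing = [g for g in GROUPS if g not in present]
    if missing:
        raise ValueError(f"missing sample group(s): {missing}")
    controls = ["egfp_neg", "whole_head"]

    if config.overdispersion_mode == "estimate":
        has_reps = any(len(counts.samples_of(g)) >= 2 for g in present)
        phi = estimate_overdispersion(counts) if has_reps else 1.0
    else:
        phi = config.phi_fixed

    pooled = pool_replicates(counts)
    tpm = compute_tpm(pooled)
    mean_raw = counts.counts[counts.samples_of("egfp_pos")].mean(axis=1)

    if config.pooling_mode == "pooled":
        if config.use_tmm:
            eff_libs = tmm_factors(pooled, reference_sample="egfp_pos")
        else:
            eff_libs = pooled.library_sizes()
        p_raw = _pairwise_p_pooled(pooled, phi, eff_libs, controls)
    else:
        if config.use_tmm:
            ref = counts.samples_of("egfp_pos")[0]
            eff_libs = tmm_factors(counts, reference_sample=ref)
        else:
            eff_libs = counts.library_sizes()
        p_raw = _pairwise_p_per_replicate(counts, phi, eff_libs, controls)

    tested = (mean_raw > config.reads_floor).to_numpy()
    m = int(tested.sum())
    p_adj = bonferroni(p_raw, max(m, 1))
    return {
        "tpm": tpm,
        "mean_raw": mean_raw,
        "p_raw": p_raw,
        "p_adj": p_adj,
        "tested": tested,
        "m": m,
        "phi": phi,
    }


def run_enrichment_pipeline(
    counts: CountMatrix, config: TestConfig | None = None
) -> list[EnrichmentRecord]:
    """Full enrichment caller: pool, normalize, test, adjust, classify, rank.

    Returns records sorted by fold (descending, ties broken by gene id); only
    genes whose fold over the larger control exceeds the relaxed fold
    threshold are emitted.
    """
    config = config or TestConfig()
    stats = enrichment_statistics(counts, config)
    tpm = stats["tpm"]
    mean_raw = stats["mean_raw"]
    p_raw = stats["p_raw"]
    p_adj = stats["p_adj"]

    records: list[EnrichmentRecord] = []
    for i, gene in enumerate(counts.gene_ids):
        t_pos = float(tpm.at[gene, "egfp_pos"])
        t_neg = float(tpm.at[gene, "egfp_neg"])
        t_head = float(tpm.at[gene, "whole_head"])
        fold = fold_change(t_pos, (t_neg, t_head), config.pseudocount)
        if fold <= config.relaxed_fold:
            continue
        tier = classify_enrichment(t_pos, fold, p_adj[i], float(mean_raw.iloc[i]), config)
        records.append(
            EnrichmentRecord(
                gene_id=str(gene),
                tpm_egfp_pos=t_pos,
                tpm_egfp_neg=t_neg,
                tpm_whole_head=t_head,
                fold_vs_max_control=fold,
                mean_raw_reads_egfp_pos=float(mean_raw.iloc[i]),
                p_raw=float(p_raw[i]),
                p_adjusted=float(p_adj[i]),
                tier=tier,
            )
        )
    records.sort(key=lambda r: (-r.fold_vs_max_control, r.gene_id))
    return records


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    """Tabulate enrichment records (one row per transcript, ranked)."""
    if not records:
        return pd.DataFrame(
            columns=[f.name for f in EnrichmentRecord.__dataclass_fields__.values()]
        )
    return pd.DataFrame([asdict(r) for r in records])
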