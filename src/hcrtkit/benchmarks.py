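"""End-to-end validation benchmarks exercised by the test suite and the
acceptance script.

Each function here regenerates its inputs with the package's own synthetic
generators (or constructs the hand-sized instances directly), runs the
corresponding analysis stage, and measures either agreement with an
independent oracle (exact enumeration, brute-force scanning) or recovery of
the generators' ground truth.  All randomness flows from the explicit seed
arguments.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .enrichment import (
    TestConfig,
    enrichment_statistics,
    poisson_pair_test,
    run_enrichment_pipeline,
)
from .expression import CountMatrix, compute_tpm, tmm_factors
from .motifs import (
    PositionWeightMatrix,
    combined_gene_score,
    conserved_hits_by_gene,
    scan_sequence,
    tf_set_enrichment,
)
from .simulate import (
    CountSimConfig,
    PhaseParams,
    SleepSimConfig,
    simulate_activity_cohort,
    simulate_count_experiment,
    simulate_promoter_set,
)
from .sleep import (
    ActivityTrace,
    call_sleep_bouts,
    compare_genotypes,
    permutation_diff_test,
    score_cohort,
    summarize_sleep,
)

__all__ = [
    "pair_test_vs_enumeration",
    "null_calibration",
    "planted_recovery",
    "normalization_invariants",
    "motif_scan_vs_brute_force",
    "tf_enrichment_power",
    "hypergeom_vs_enumeration",
    "sleep_hand_traces",
    "sleep_recovery_and_detection",
    "permutation_vs_enumeration",
]


# ---------------------------------------------------------------------------
# enrichment statistics
# ---------------------------------------------------------------------------

def _exact_binom_two_sided(a: int, n: int, p: float) -> float:
    """Oracle: enumerate the binomial pmf and double the smaller tail."""
    pmf = [math.comb(n, k) * p**k * (1 - p) ** (n - k) for k in range(n + 1)]
    lower = sum(pmf[: a + 1])
    upper = sum(pmf[a:])
    return min(1.0, 2 * min(lower, upper))


def pair_test_vs_enumeration(
    max_count: int = 50, ratios: tuple[float, ...] = (1.0, 2.0, 5.0)
) -> dict:
    """Max |p - oracle| over all count pairs up to ``max_count`` and the
    given library-size ratios, at phi = 1."""
    worst = 0.0
    n_pairs = 0
    for ratio in ratios:
        p_null = ratio / (ratio + 1.0)
        for a in range(max_count + 1):
            for b in range(max_count + 1):
                got = poisson_pair_test(a, ratio, b, 1.0)
                want = _exact_binom_two_sided(a, a + b, p_null)
                worst = max(worst, abs(got - want))
                n_pairs += 1
    return {"max_abs_dev": worst, "n": n_pairs}


def null_calibration(
    n_runs: int = 100,
    n_genes: int = 10_000,
    alpha: float = 0.01,
    seed: int = 0,
) -> dict:
    """Family-wise error of the Bonferroni procedure on null simulations.

    Every run simulates a pure-Poisson dataset with no planted genes, so any
    adjusted p below alpha among tested genes is a false rejection and any
    strict-tier call is a false positive.
    """
    rng = np.random.default_rng(seed)
    config = TestConfig(alpha=alpha)
    runs_with_rejection = 0
    runs_with_zero_strict = 0
    for _ in range(n_runs):
        sim = CountSimConfig(
            n_genes=n_genes,
            n_planted=0,
            overdispersion_factor=1.0,
            seed=int(rng.integers(2**31)),
        )
        cm, _ = simulate_count_experiment(sim)
        stats = enrichment_statistics(cm, config)
        rejected = (stats["p_adj"] < alpha) & stats["tested"]
        if rejected.any():
            runs_with_rejection += 1
        records = run_enrichment_pipeline(cm, config)
        if not any(r.tier == "strict" for r in records):
            runs_with_zero_strict += 1
    return {
        "fwer": runs_with_rejection / n_runs,
        "zero_strict_runs": runs_with_zero_strict,
        "n": n_runs,
    }


def planted_recovery(
    n_seeds: int = 20,
    n_genes: int = 10_000,
    n_planted: int = 50,
    planted_fold: float = 10.0,
    planted_min_tpm: float = 150.0,
    phi: float = 2.0,
    seed: int = 0,
) -> dict:
    """Mean strict-tier sensitivity and planted-set false discovery over seeds."""
    rng = np.random.default_rng(seed)
    sens, fdr = [], []
    for _ in range(n_seeds):
        sim = CountSimConfig(
            n_genes=n_genes,
            n_planted=n_planted,
            planted_fold=planted_fold,
            planted_min_tpm=planted_min_tpm,
            overdispersion_factor=phi,
            seed=int(rng.integers(2**31)),
        )
        cm, truth = simulate_count_experiment(sim)
        records = run_enrichment_pipeline(cm)
        strict = {r.gene_id for r in records if r.tier == "strict"}
        planted = set(truth.planted_genes)
        sens.append(len(strict & planted) / len(planted))
        fdr.append(len(strict - planted) / len(strict) if strict else 0.0)
    return {
        "sensitivity": float(np.mean(sens)),
        "fdr": float(np.mean(fdr)),
        "n": n_seeds,
    }


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalization_invariants(n_matrices: int = 1000, seed: int = 0) -> dict:
    """TPM column-sum deviation and TMM identity/scaling exactness.

    For each random matrix: TPM columns must sum to 1e6; the TMM factor of a
    sample identical to the reference must be 1; the factor of a uniformly
    k-scaled copy must be exactly k.
    """
    rng = np.random.default_rng(seed)
    tpm_dev = 0.0
    tmm_identity_dev = 0.0
    tmm_scaling_dev = 0.0
    for _ in range(n_matrices):
        n = int(rng.integers(20, 120))
        genes = [f"g{i}" for i in range(n)]
        base = rng.integers(1, 2000, n)
        k = float(rng.integers(2, 8))
        counts = pd.DataFrame(
            {
                "ref": base,
                "same": base,
                "scaled": np.round(base * k).astype(int),
            },
            index=genes,
        )
        cm = CountMatrix(
            counts,
            pd.Series(rng.integers(200, 5000, n), index=genes),
            pd.Series({"ref": "egfp_pos", "same": "egfp_neg", "scaled": "whole_head"}),
        )
        tpm = compute_tpm(cm)
        tpm_dev = max(tpm_dev, float(np.abs(tpm.sum(axis=0) / 1e6 - 1.0).max()))
        factors = tmm_factors(cm, reference_sample="ref")
        tmm_identity_dev = max(tmm_identity_dev, abs(factors["same"] - 1.0))
        tmm_scaling_dev = max(tmm_scaling_dev, abs(factors["scaled"] / k - 1.0))
    return {
        "tpm_colsum_max_rel_dev": tpm_dev,
        "tmm_identity_max_abs_dev": tmm_identity_dev,
        "tmm_scaling_max_rel_dev": tmm_scaling_dev,
        "n": n_matrices,
    }


# ---------------------------------------------------------------------------
# motif scanning and TF enrichment
# ---------------------------------------------------------------------------

_ORDER = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _brute_force_scan(seq: str, pwm: PositionWeightMatrix):
    """Oracle: per-window log-odds summation in plain Python, both strands."""
    L = len(pwm)
    hits = []
    for o in range(len(seq) - L + 1):
        window = seq[o : o + L]
        if any(b not in _ORDER for b in window):
            continue
        rc = "".join(_COMP[b] for b in reversed(window))
        for strand, w in (("+", window), ("-", rc)):
            score = sum(pwm.log_odds[i, _ORDER.index(b)] for i, b in enumerate(w))
            if score >= pwm.threshold:
                hits.append((o, strand, round(score, 9)))
    return hits


def motif_scan_vs_brute_force(
    n_sequences: int = 100,
    seq_length: int = 500,
    n_pwms: int = 20,
    seed: int = 0,
) -> dict:
    """Count hit-set mismatches between the scanner and the brute-force oracle."""
    rng = np.random.default_rng(seed)
    pwms = [
        PositionWeightMatrix(
            f"M{j:02d}",
            rng.dirichlet(np.full(4, 0.5), size=int(rng.integers(6, 13))),
            threshold_fraction=0.75,
        )
        for j in range(n_pwms)
    ]
    sequences = [
        "".join(np.array(list(_ORDER))[rng.integers(0, 4, seq_length)])
        for _ in range(n_sequences)
    ]
    mismatches = 0
    n_hits = 0
    for seq in sequences:
        for pwm in pwms:
            got = [
                (h.offset, h.strand, round(h.score, 9))
                for h in scan_sequence(seq, pwm)
            ]
            want = _brute_force_scan(seq, pwm)
            n_hits += len(want)
            if got != want:
                mismatches += 1
    return {"mismatched_scans": mismatches, "total_hits": n_hits,
            "n": n_sequences * n_pwms}


def _sharp_pwm(consensus: str = "ACGTACGTGA", p: float = 0.997) -> PositionWeightMatrix:
    off = (1 - p) / 3
    matrix = np.full((len(consensus), 4), off)
    for i, base in enumerate(consensus):
        matrix[i, _ORDER.index(base)] = p
    return PositionWeightMatrix(consensus, matrix, threshold_fraction=0.85)


def tf_enrichment_power(
    n_runs: int = 100,
    n_genes: int = 480,
    promoter_length: int = 500,
    n_foreground: int = 48,
    n_planted: int = 30,
    background_rate: float = 0.05,
    n_species: int = 3,
    seed: int = 0,
) -> dict:
    """Fraction of seeded runs where the planted TF attains BH-adjusted p < 0.05.

    Each run scans the planted matrix plus decoy matrices so the BH
    adjustment spans several TFs.
    """
    rng = np.random.default_rng(seed)
    planted_pwm = _sharp_pwm("ACGTACGTGA")
    decoys = [_sharp_pwm(c) for c in ("TTGACCTCAG", "GGATCCATGC")]
    significant = 0
    for _ in range(n_runs):
        prom, truth = simulate_promoter_set(
            n_genes=n_genes,
            promoter_length=promoter_length,
            motif=planted_pwm,
            planted_fraction_foreground=n_planted / n_foreground,
            background_rate=background_rate,
            n_species=n_species,
            n_foreground=n_foreground,
            seed=int(rng.integers(2**31)),
        )
        hits_by_tf = {}
        for pwm in [planted_pwm, *decoys]:
            conserved = conserved_hits_by_gene(prom, pwm)
            hits_by_tf[pwm.tf_name] = {
                g: combined_gene_score(h, pwm) for g, h in conserved.items() if h
            }
        results = tf_set_enrichment(truth.foreground_genes, prom.genes, hits_by_tf)
        by_name = {r.tf_name: r for r in results}
        if by_name[planted_pwm.tf_name].p_bh < 0.05:
            significant += 1
    return {"significant_runs": significant, "n": n_runs}


def hypergeom_vs_enumeration(max_population: int = 100, seed: int = 0) -> dict:
    """Max |p - oracle| of the TF-set hypergeometric tail on small populations."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    n_cases = 0
    for _ in range(60):
        N = int(rng.integers(10, max_population + 1))
        n = int(rng.integers(2, N))
        K = int(rng.integers(0, N + 1))
        bg = [f"g{i}" for i in range(N)]
        fg = bg[:n]
        carriers = set(rng.choice(bg, K, replace=False))
        res = tf_set_enrichment(fg, bg, {"T": {g: 1.0 for g in carriers}})
        k = res[0].n_foreground_hits
        want = sum(
            math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
            for x in range(k, min(K, n) + 1)
        )
        worst = max(worst, abs(res[0].p_raw - want))
        n_cases += 1
    return {"max_abs_dev": worst, "n": n_cases}


# ---------------------------------------------------------------------------
# sleep scoring
# ---------------------------------------------------------------------------

def sleep_hand_traces() -> dict:
    """Hand-worked bout-calling instances scored through the package."""
    t1 = ActivityTrace("h1", "wt", np.array([0.0, 0.0, 0.0, 5.0, 0.0]))
    b1 = call_sleep_bouts(t1)
    t2 = ActivityTrace("h2", "wt", np.zeros(60))
    b2 = call_sleep_bouts(t2)
    t3 = ActivityTrace("h3", "wt", np.array([1.0, 0.0] * 30))
    b3 = call_sleep_bouts(t3)
    s3 = summarize_sleep(b3, t3)
    return {
        "trace1_sleep_min": int(sum(b.length_min for b in b1)),
        "trace1_n_bouts": len(b1),
        "allzero_hour_bout_len": b2[0].length_min if len(b2) == 1 else -1,
        "alternation_transitions_per_h": int(s3.hourly.loc[0, "n_transitions"]),
        "alternation_mean_bout_len": float(s3.hourly.loc[0, "mean_bout_len"]),
    }


def sleep_recovery_and_detection(
    n_runs: int = 100,
    n_larvae: int = 90,
    n_permutations: int = 2000,
    alpha: float = 0.01,
    seed: int = 0,
) -> dict:
    """Scored-vs-generative sleep means plus phase-specific detection rates.

    Mutant and wild-type cohorts are generated with the study-calibrated
    night sleep means (13.08 vs 15.46 min/h) and closely matched day means
    (2.76 vs 2.87 min/h); each run scores the cohort and permutation-tests
    the genotype difference per phase.
    """
    rng = np.random.default_rng(seed)
    params = {
        "hom": {"day": PhaseParams(2.76, 1.3, 1.9),
                "night": PhaseParams(13.08, 2.21, 1.35)},
        "wt": {"day": PhaseParams(2.87, 1.3, 1.9),
               "night": PhaseParams(15.46, 2.43, 1.35)},
    }
    night_flagged = 0
    day_flagged = 0
    night_means = {"hom": [], "wt": []}
    day_means = {"hom": [], "wt": []}
    for _ in range(n_runs):
        config = SleepSimConfig(
            n_larvae_per_genotype=n_larvae,
            genotype_params=params,
            seed=int(rng.integers(2**31)),
        )
        traces, _ = simulate_activity_cohort(config)
        cohort = score_cohort(traces)
        for g in ("hom", "wt"):
            sub = cohort[cohort["genotype"] == g]
            night_means[g].append(sub["night_sleep_min_per_h"].mean())
            day_means[g].append(sub["day_sleep_min_per_h"].mean())
        _, p_night = compare_genotypes(
            cohort, "hom", "wt", "night", "sleep_min_per_h",
            n_permutations=n_permutations, seed=int(rng.integers(2**31)),
        )
        _, p_day = compare_genotypes(
            cohort, "hom", "wt", "day", "sleep_min_per_h",
            n_permutations=n_permutations, seed=int(rng.integers(2**31)),
        )
        night_flagged += p_night < alpha
        day_flagged += p_day < alpha
    return {
        "night_detection_runs": night_flagged,
        "day_flag_runs": day_flagged,
        "night_sleep_mean_mutant": float(np.mean(night_means["hom"])),
        "night_sleep_mean_wt": float(np.mean(night_means["wt"])),
        "day_sleep_mean_mutant": float(np.mean(day_means["hom"])),
        "day_sleep_mean_wt": float(np.mean(day_means["wt"])),
        "n": n_runs,
    }


def permutation_vs_enumeration(n_cases: int = 10, seed: int = 0) -> dict:
    """Max |p - oracle| of the permutation test against exhaustive label
    enumeration for 4 + 4 observations."""
    rng = np.random.default_rng(seed)
    from itertools import combinations

    worst = 0.0
    for _ in range(n_cases):
        a = rng.normal(1.0, 1.0, 4)
        b = rng.normal(0.0, 1.0, 4)
        _, p = permutation_diff_test(a, b, seed=0)
        pooled = np.concatenate([a, b])
        obs = a.mean() - b.mean()
        count = total = 0
        for idx in combinations(range(8), 4):
            mask = np.zeros(8, dtype=bool)
            mask[list(idx)] = True
            stat = pooled[mask].mean() - pooled[~mask].mean()
            if abs(stat) >= abs(obs) - 1e-12:
                count += 1
            total += 1
        worst = max(worst, abs(p - count / total))
    return {"max_abs_dev": worst, "n": n_cases}
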