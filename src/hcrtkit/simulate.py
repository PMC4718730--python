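"""Synthetic data with known ground truth for every pipeline stage.

Three generators emulate the study's data modalities:

* :func:`simulate_count_experiment` — gene-level read counts for 3 sample
  groups (sorted fluorescent neurons and two controls) x replicates, with
  Poisson sampling, optional amplification overdispersion (negative binomial
  with variance = phi * mean), and a planted set of neuron-enriched genes;
* :func:`simulate_promoter_set` — per-gene promoters across several species
  with motif instances planted at conserved positions in a foreground gene
  subset plus non-conserved single-species background instances;
* :func:`simulate_activity_cohort` — 24 h minute-binned larval activity
  traces under a 14:10 light/dark cycle, from an alternating wake/sleep
  two-state renewal process with geometric bout lengths whose stationary
  sleep fraction and mean sleep-bout length are set per genotype and phase.

Every generator takes an explicit seed and is deterministic given it; each
returns a :class:`TruthTable` recording what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import GROUPS, CountMatrix
from .motifs import PositionWeightMatrix, PromoterSet
from .sleep import ActivityTrace

__all__ = [
    "CountSimConfig",
    "SleepSimConfig",
    "PhaseParams",
    "TruthTable",
    "simulate_count_experiment",
    "simulate_promoter_set",
    "simulate_activity_cohort",
]

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class TruthTable:
    """Ground truth of one synthetic dataset: what was planted, and how."""

    seed: int
    config: dict
    planted_genes: list[str] | None = None
    motif_placements: list[tuple[str, str, int, str]] | None = None  # gene, species, offset, strand
    foreground_genes: list[str] | None = None
    sleep_params: dict | None = None


# ---------------------------------------------------------------------------
# count experiment
# ---------------------------------------------------------------------------

@dataclass
class CountSimConfig:
    """Configuration of the synthetic three-group count experiment.

    Library sizes default to the study's read depths per group (about 24M,
    22M and 175M reads for the sorted-positive, sorted-negative and
    whole-head groups), split evenly across replicates.  True per-gene
    relative abundance is log-normal; planted genes are elevated by
    ``planted_fold`` in the positive group only, with their control-group
    TPM floored at ``planted_min_tpm / planted_fold`` so the planted tier is
    actually attainable.  ``overdispersion_factor`` phi = 1 gives pure
    Poisson counts; phi > 1 gives negative-binomial counts with
    variance = phi * mean.
    """

    n_genes: int = 10000
    n_replicates_per_group: int = 3
    library_size_per_group: Mapping[str, float] = field(
        default_factory=lambda: {
            "egfp_pos": 24e6,
            "egfp_neg": 22e6,
            "whole_head": 175e6,
        }
    )
    baseline_log_mean: float = 1.0  # natural-log scale of relative abundance
    baseline_log_sd: float = 2.0
    n_planted: int = 0
    planted_fold: float = 10.0
    planted_min_tpm: float = 150.0
    overdispersion_factor: float = 1.0
    length_range: tuple[int, int] = (500, 5000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_replicates_per_group <= 0:
            raise ValueError("n_genes and n_replicates_per_group must be positive")
        if self.n_planted < 0 or self.n_planted > self.n_genes:
            raise ValueError("n_planted must be in [0, n_genes]")
        if self.n_planted and self.planted_fold <= 1:
            raise ValueError("planted_fold must exceed 1")
        if self.planted_min_tpm <= 0:
            raise ValueError("planted_min_tpm must be positive")
        if self.overdispersion_factor < 1:
            raise ValueError("overdispersion_factor must be >= 1")
        missing = [g for g in GROUPS if g not in self.library_size_per_group]
        if missing:
            raise ValueError(f"library sizes missing for group(s): {missing}")


def _nb_counts(rng: np.random.Generator, lam: np.ndarray, phi: float) -> np.ndarray:
    """Counts with mean lam and variance phi*lam (Poisson when phi == 1)."""
    if phi == 1.0:
        return rng.poisson(lam)
    out = np.zeros_like(lam, dtype=np.int64)
    pos = lam > 0
    r = lam[pos] / (phi - 1.0)
    out[pos] = rng.negative_binomial(r, 1.0 / phi)
    return out


def simulate_count_experiment(config: CountSimConfig) -> tuple[CountMatrix, TruthTable]:
    """Generate a replicated three-group count matrix with planted enrichment.

    Per gene and replicate, the expected count is the group's per-replicate
    library size times the gene's read proportion (true TPM weighted by
    transcript length); counts are Poisson or negative-binomial draws around
    it.  Planted genes have their positive-group abundance multiplied by
    ``planted_fold`` over both controls.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]
    lengths = rng.integers(config.length_range[0], config.length_range[1] + 1, n)

    base = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, n)
    planted_idx = (
        np.sort(rng.choice(n, config.n_planted, replace=False))
        if config.n_planted
        else np.array([], dtype=int)
    )
    # control-group true TPM (sums to 1e6); floor planted baselines so that
    # fold * control TPM clears planted_min_tpm with margin for the
    # compositional renormalization of the positive group
    tpm_ctrl = base / base.sum() * 1e6
    if config.n_planted:
        floor = 1.1 * config.planted_min_tpm / config.planted_fold
        tpm_ctrl[planted_idx] = np.maximum(tpm_ctrl[planted_idx], floor)
        tpm_ctrl = tpm_ctrl / tpm_ctrl.sum() * 1e6

    expr_pos = tpm_ctrl.copy()
    expr_pos[planted_idx] *= config.planted_fold
    tpm_by_group = {
        "egfp_pos": expr_pos / expr_pos.sum() * 1e6,
        "egfp_neg": tpm_ctrl,
        "whole_head": tpm_ctrl,
    }

    columns: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    for g in GROUPS:
        tpm = tpm_by_group[g]
        weights = tpm * lengths
        read_prob = weights / weights.sum()
        lib_per_rep = config.library_size_per_group[g] / config.n_replicates_per_group
        lam = lib_per_rep * read_prob
        for r in range(1, config.n_replicates_per_group + 1):
            name = f"{g}_r{r}"
            columns[name] = _nb_counts(rng, lam, config.overdispersion_factor)
            groups[name] = g

    counts = pd.DataFrame(columns, index=gene_ids)
    cm = CountMatrix(counts, pd.Series(lengths, index=gene_ids), pd.Series(groups))
    truth = TruthTable(
        seed=config.seed,
        config=asdict(config),
        planted_genes=[gene_ids[i] for i in planted_idx],
    )
    return cm, truth


# ---------------------------------------------------------------------------
# promoter set
# ---------------------------------------------------------------------------

def simulate_promoter_set(
    n_genes: int,
    promoter_length: int,
    motif: PositionWeightMatrix,
    planted_fraction_foreground: float,
    background_rate: float,
    n_species: int = 3,
    n_foreground: int = 48,
    seed: int = 0,
) -> tuple[PromoterSet, TruthTable]:
    """Random promoters with conserved planted motif instances in a foreground.

    The first ``n_foreground`` genes form the foreground set; a
    ``planted_fraction_foreground`` fraction of them receives a
    motif-sampled instance at the *same* offset and strand in every species
    (a conserved site).  Every non-planted gene may independently receive an
    instance in a single random species with probability ``background_rate``
    (a non-conserved site).  Promoter backbones are i.i.d. draws from the
    motif's background nucleotide distribution.
    """
    if promoter_length < len(motif):
        raise ValueError("motif longer than promoter")
    if not (0 <= planted_fraction_foreground <= 1 and 0 <= background_rate <= 1):
        raise ValueError("rates must lie in [0, 1]")
    if not 0 < n_foreground <= n_genes:
        raise ValueError("n_foreground must be in (0, n_genes]")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    species = [f"sp{i + 1}" for i in range(n_species)]
    L = len(motif)

    # backbone: i.i.d. draws from the motif's background distribution,
    # generated in one block for speed
    ascii_bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    cum = np.cumsum(motif.background)
    draws = np.searchsorted(cum, rng.random((n_genes * n_species, promoter_length)))
    seqs: dict[tuple[str, str], str] = {}
    row = 0
    for gene in genes:
        for sp in species:
            seqs[(gene, sp)] = ascii_bases[draws[row]].tobytes().decode("ascii")
            row += 1

    foreground = genes[:n_foreground]
    n_planted = int(round(planted_fraction_foreground * n_foreground))
    planted = list(rng.choice(foreground, n_planted, replace=False)) if n_planted else []
    placements: list[tuple[str, str, int, str]] = []

    def _insert(gene: str, sp: str, offset: int, strand: str, site: str) -> None:
        s = site if strand == "+" else site.translate(_COMPLEMENT)[::-1]
        seq = seqs[(gene, sp)]
        seqs[(gene, sp)] = seq[:offset] + s + seq[offset + L:]

    for gene in planted:
        offset = int(rng.integers(0, promoter_length - L + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        site = motif.sample_site(rng)
        for sp in species:
            _insert(gene, sp, offset, strand, site)
            placements.append((gene, sp, offset, strand))

    planted_set = set(planted)
    for gene in genes:
        if gene in planted_set:
            continue
        if rng.random() < background_rate:
            sp = species[int(rng.integers(0, n_species))]
            offset = int(rng.integers(0, promoter_length - L + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            _insert(gene, sp, offset, strand, motif.sample_site(rng))
            placements.append((gene, sp, offset, strand))

    promoters = PromoterSet(sequences=seqs, species=species, genes=genes)
    truth = TruthTable(
        seed=seed,
        config={
            "n_genes": n_genes,
            "promoter_length": promoter_length,
            "tf_name": motif.tf_name,
            "planted_fraction_foreground": planted_fraction_foreground,
            "background_rate": background_rate,
            "n_species": n_species,
            "n_foreground": n_foreground,
        },
        planted_genes=sorted(planted),
        motif_placements=placements,
        foreground_genes=foreground,
    )
    return promoters, truth


# ---------------------------------------------------------------------------
# activity cohort
# ---------------------------------------------------------------------------

@dataclass
class PhaseParams:
    """Target sleep structure for one phase.

    ``sleep_min_per_hour`` (0-60) and ``mean_bout_len`` (minutes, >= 1) set
    the cohort-level targets.  ``between_larva_sd`` adds biological
    heterogeneity: each larva's own sleep target is drawn from a gamma
    distribution with this standard deviation around the cohort mean
    (mean-preserving; 0 disables it).  Real cohorts show substantially more
    larva-to-larva spread than a shared renewal process produces, so the
    default genotype parameters carry nonzero values calibrated to observed
    cohort dispersions.
    """

    sleep_min_per_hour: float
    mean_bout_len: float
    between_larva_sd: float = 0.0

    def validate(self) -> None:
        if not 0 <= self.sleep_min_per_hour <= 60:
            raise ValueError("sleep minutes per hour must lie in [0, 60]")
        if self.mean_bout_len < 1:
            raise ValueError("mean bout length must be >= 1 minute")
        if self.between_larva_sd < 0:
            raise ValueError("between_larva_sd must be non-negative")

    def per_larva_targets(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Per-larva sleep-minute targets (gamma around the cohort mean)."""
        m, s = self.sleep_min_per_hour, self.between_larva_sd
        if s == 0 or m == 0:
            return np.full(n, m)
        shape = (m / s) ** 2
        return np.minimum(rng.gamma(shape, m / shape, size=n), 60.0)

    @property
    def sleep_fraction(self) -> float:
        return self.sleep_min_per_hour / 60.0

    @property
    def transition_rate_per_hour(self) -> float:
        """Implied wake->sleep onsets per hour at stationarity."""
        return 60.0 * self.sleep_fraction / self.mean_bout_len


def _default_genotype_params() -> dict[str, dict[str, PhaseParams]]:
    # Night sleep times and bout lengths follow the study's printed genotype
    # means (wt 15.46, het 14.78, hom 13.08 min/h; bouts wt 2.43, hom 2.21
    # min; het interpolated).  Day sleep likewise (2.87/2.80/2.76 min/h);
    # the printed day transition counts would imply sub-minute day bouts,
    # impossible at minute resolution, so day bout length is set to 1.3 min
    # for all genotypes.  between_larva_sd reproduces the study's cohort
    # dispersion (per-larva SD ~2.5 min/h at night, ~2.0 by day, from the
    # printed SEMs and group sizes) after subtracting the within-trace
    # sampling component of the renewal process.
    return {
        "wt": {
            "day": PhaseParams(2.87, 1.3, 1.9),
            "night": PhaseParams(15.46, 2.43, 1.35),
        },
        "het": {
            "day": PhaseParams(2.80, 1.3, 1.9),
            "night": PhaseParams(14.78, 2.32, 1.35),
        },
        "hom": {
            "day": PhaseParams(2.76, 1.3, 1.9),
            "night": PhaseParams(13.08, 2.21, 1.35),
        },
    }


@dataclass
class SleepSimConfig:
    """Configuration of the synthetic larval activity cohort.

    One trace per larva covers ``recording_hours`` starting at lights-on
    under a ``light_hours``:``dark_hours`` cycle.  Sleep/wake alternates as
    a two-state renewal process with geometric bout lengths at minute
    resolution; per genotype and phase, the stationary sleep fraction and
    mean sleep-bout length match :class:`PhaseParams`.  Wake-minute activity
    is gamma-distributed in arbitrary units (the tracking software's units
    are not standardized); sleep minutes have activity exactly 0.
    """

    n_larvae_per_genotype: int = 90
    light_hours: float = 14.0
    dark_hours: float = 10.0
    recording_hours: float = 24.0
    genotype_params: dict[str, dict[str, PhaseParams]] = field(
        default_factory=_default_genotype_params
    )
    activity_amplitude: float = 10.0  # mean wake-minute activity, arbitrary units
    activity_shape: float = 2.0  # gamma shape of wake-minute activity
    seed: int = 0

    def validate(self) -> None:
        if self.n_larvae_per_genotype <= 0:
            raise ValueError("n_larvae_per_genotype must be positive")
        if self.light_hours <= 0 or self.dark_hours <= 0:
            raise ValueError("photoperiod hours must be positive")
        if self.recording_hours <= 0:
            raise ValueError("recording_hours must be positive")
        if self.activity_amplitude <= 0 or self.activity_shape <= 0:
            raise ValueError("activity parameters must be positive")
        for phases in self.genotype_params.values():
            for key in ("day", "night"):
                if key not in phases:
                    raise ValueError(f"phase parameters missing {key!r}")
                phases[key].validate()


def simulate_activity_cohort(
    config: SleepSimConfig,
) -> tuple[list[ActivityTrace], TruthTable]:
    """Generate minute-binned activity traces for a multi-genotype cohort."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_minutes = int(round(config.recording_hours * 60))
    light_min = config.light_hours * 60
    cycle = (config.light_hours + config.dark_hours) * 60

    traces: list[ActivityTrace] = []
    for genotype in config.genotype_params:
        phases = config.genotype_params[genotype]
        n = config.n_larvae_per_genotype
        # per-larva sleep targets (between-larva heterogeneity), shared bout
        # length within a phase
        probs = {}
        for ph in ("day", "night"):
            p = phases[ph]
            f = p.per_larva_targets(rng, n) / 60.0
            p_sw = 1.0 / p.mean_bout_len
            with np.errstate(divide="ignore", invalid="ignore"):
                p_ws = np.where(
                    f >= 1.0, 1.0,
                    np.minimum(1.0, f / ((1.0 - f) * p.mean_bout_len)),
                )
            probs[ph] = (p_ws, np.where(f >= 1.0, 0.0, p_sw), f)
        init_phase = "day" if 0 < light_min else "night"
        f0 = probs[init_phase][2]
        state = rng.random(n) < f0  # True = asleep
        asleep = np.empty((n, n_minutes), dtype=bool)
        for minute in range(n_minutes):
            phase = "day" if (minute % cycle) < light_min else "night"
            p_ws, p_sw, _ = probs[phase]
            u = rng.random(n)
            wake_now = ~state
            # wake -> sleep with p_ws; sleep -> wake with p_sw
            state = np.where(wake_now, u < p_ws, u >= p_sw)
            asleep[:, minute] = state
        scale = config.activity_amplitude / config.activity_shape
        wake_activity = rng.gamma(config.activity_shape, scale, size=(n, n_minutes))
        # gamma draws are continuous and almost surely positive; clip away
        # exact zeros so wake minutes are never scored as immobile
        wake_activity = np.maximum(wake_activity, 1e-9)
        activity = np.where(asleep, 0.0, wake_activity)
        for i in range(n):
            traces.append(
                ActivityTrace(
                    larva_id=f"{genotype}_{i + 1:03d}",
                    genotype=genotype,
                    activity=activity[i],
                    light_hours=config.light_hours,
                    dark_hours=config.dark_hours,
                )
            )

    truth = TruthTable(
        seed=config.seed,
        config={
            "n_larvae_per_genotype": config.n_larvae_per_genotype,
            "light_hours": config.light_hours,
            "dark_hours": config.dark_hours,
            "recording_hours": config.recording_hours,
            "activity_amplitude": config.activity_amplitude,
            "activity_shape": config.activity_shape,
        },
        sleep_params={
            g: {
                ph: {
                    "sleep_min_per_hour": p[ph].sleep_min_per_hour,
                    "mean_bout_len": p[ph].mean_bout_len,
                    "between_larva_sd": p[ph].between_larva_sd,
                    "transition_rate_per_hour": p[ph].transition_rate_per_hour,
                }
                for ph in ("day", "night")
            }
            for g, p in config.genotype_params.items()
        },
    )
    return traces, truth
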