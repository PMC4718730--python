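"""Promoter motif scanning, conservation filtering, and TF-set enrichment.

Given position-frequency matrices for transcription factors and promoter
sequences (optionally one promoter per species for a set of species), this
module

* scans both strands of each promoter with a log-odds position weight
  matrix and a per-matrix score threshold (:func:`scan_sequence`);
* keeps a hit in the reference species only when every other species has a
  threshold-passing hit for the same matrix at an overlapping position
  (:func:`filter_conserved_hits`) — a cheap surrogate for scanning a true
  multiple alignment;
* aggregates a gene's conserved hits for one TF into a combined score
  (:func:`combined_gene_score`), so genes whose promoter over-represents a
  TF's site score high;
* tests each TF's conserved-hit targets for over-representation in a
  foreground gene set with a one-sided hypergeometric test and
  Benjamini-Hochberg adjustment (:func:`tf_set_enrichment`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PositionWeightMatrix",
    "MotifHit",
    "TFResult",
    "PromoterSet",
    "read_transfac",
    "scan_sequence",
    "scan_promoters",
    "filter_conserved_hits",
    "conserved_hits_by_gene",
    "combined_gene_score",
    "tf_set_enrichment",
    "bh_adjust",
]

_BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class PositionWeightMatrix:
    """Nucleotide frequency matrix with background model and score threshold.

    ``matrix`` holds per-position frequencies (or counts; rows are
    renormalized) over A, C, G, T.  Scoring uses log2 odds against the
    background after pseudocount smoothing:
    ``score(window) = sum_i log2(f'_i[base_i] / bg[base_i])`` with
    ``f' = (f + pseudocount * bg) / (1 + pseudocount)``.

    ``threshold`` is the minimum acceptable log-odds score for a hit.  When
    not given it defaults to ``threshold_fraction`` of the maximal attainable
    score, mirroring the common practice of per-matrix thresholds expressed
    relative to the best possible match.
    """

    tf_name: str
    matrix: np.ndarray
    pseudocount: float = 0.25
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    threshold: float | None = None
    threshold_fraction: float = 0.85

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("matrix must have shape (L, 4)")
        if len(self.matrix) < 4:
            raise ValueError("matrix length must be >= 4")
        if (self.matrix < 0).any():
            raise ValueError("matrix entries must be non-negative")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (4,) or not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must be 4 probabilities summing to 1")
        row_sums = self.matrix.sum(axis=1, keepdims=True)
        if (row_sums == 0).any():
            raise ValueError("matrix has an all-zero position")
        freqs = self.matrix / row_sums
        smoothed = (freqs + self.pseudocount * self.background) / (1 + self.pseudocount)
        self._freqs = freqs
        self.log_odds = np.log2(smoothed / self.background)
        if self.threshold is None:
            self.threshold = self.threshold_fraction * self.max_score
        if self.threshold > self.max_score + 1e-9:
            raise ValueError("threshold exceeds the maximal attainable score")

    def __len__(self) -> int:
        return len(self.matrix)

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.log_odds.min(axis=1).sum())

    def sample_site(self, rng: np.random.Generator) -> str:
        """Draw one site from the per-position frequency distribution."""
        return "".join(
            _BASES[rng.choice(4, p=row / row.sum())] for row in self._freqs
        )


@dataclass(frozen=True)
class MotifHit:
    """One above-threshold PWM match on a promoter."""

    gene_id: str
    species: str
    offset: int  # 0-based match start on the promoter
    strand: str  # '+' or '-'
    score: float
    tf_name: str = ""


@dataclass
class TFResult:
    """Enrichment of one TF's conserved-hit targets in the foreground set."""

    tf_name: str
    target_genes: list[str]
    combined_scores: dict[str, float]
    n_foreground_hits: int
    n_background_hits: int
    p_raw: float
    p_bh: float = float("nan")


@dataclass
class PromoterSet:
    """Promoter sequences keyed by (gene, species); first species = reference."""

    sequences: dict[tuple[str, str], str]
    species: list[str]
    genes: list[str]

    @property
    def reference_species(self) -> str:
        return self.species[0]

    def promoter(self, gene: str, species: str) -> str:
        return self.sequences[(gene, species)]


def read_transfac(
    path,
    pseudocount: float = 0.25,
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    threshold_fraction: float = 0.85,
) -> list[PositionWeightMatrix]:
    """Read TRANSFAC-style plain-text matrices into scoring-ready PWMs."""
    from Bio import motifs as bio_motifs

    with open(path) as handle:
        records = bio_motifs.parse(handle, "TRANSFAC")
    out = []
    for rec in records:
        name = rec.get("ID") or rec.get("AC") or rec.get("NA") or "motif"
        counts = np.column_stack([rec.counts[b] for b in _BASES])
        out.append(
            PositionWeightMatrix(
                tf_name=str(name),
                matrix=counts,
                pseudocount=pseudocount,
                background=np.asarray(background, dtype=float),
                threshold_fraction=threshold_fraction,
            )
        )
    return out


def _encode(seq: str) -> np.ndarray:
    """Map A,C,G,T to 0..3 and anything else (N, gaps) to -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int64)
    for base, i in _CODE.items():
        codes[arr == ord(base)] = i
    return codes


def scan_sequence(
    seq: str,
    pwm: PositionWeightMatrix,
    gene_id: str = "",
    species: str = "",
) -> list[MotifHit]:
    """All above-threshold matches of the PWM on both strands of ``seq``.

    Windows containing any non-ACGT character are skipped.  Hits are
    returned in ascending offset order, '+' strand before '-' at equal
    offset.  A minus-strand hit at offset o scores the reverse complement
    of the window starting at o.
    """
    L = len(pwm)
    codes = _encode(seq)
    n_win = len(codes) - L + 1
    if n_win <= 0:
        return []
    # windows x L index matrix
    idx = np.arange(n_win)[:, None] + np.arange(L)[None, :]
    win = codes[idx]
    valid = (win >= 0).all(axis=1)
    pos_scores = np.full(n_win, -np.inf)
    neg_scores = np.full(n_win, -np.inf)
    if valid.any():
        v = win[valid]
        pos = np.arange(L)
        pos_scores[valid] = pwm.log_odds[pos, v].sum(axis=1)
        # reverse complement: base at window position i maps to complement of
        # the base at L-1-i
        rc = 3 - v[:, ::-1]
        neg_scores[valid] = pwm.log_odds[pos, rc].sum(axis=1)
    hits: list[MotifHit] = []
    thr = pwm.threshold
    for o in range(n_win):
        if pos_scores[o] >= thr:
            hits.append(MotifHit(gene_id, species, o, "+", float(pos_scores[o]), pwm.tf_name))
        if neg_scores[o] >= thr:
            hits.append(MotifHit(gene_id, species, o, "-", float(neg_scores[o]), pwm.tf_name))
    return hits


def scan_promoters(
    promoters: PromoterSet, pwm: PositionWeightMatrix
) -> dict[str, dict[str, list[MotifHit]]]:
    """Scan every promoter; result[gene][species] = hits."""
    out: dict[str, dict[str, list[MotifHit]]] = {}
    for gene in promoters.genes:
        out[gene] = {
            sp: scan_sequence(promoters.promoter(gene, sp), pwm, gene, sp)
            for sp in promoters.species
        }
    return out


def filter_conserved_hits(
    hits_by_species: Mapping[str, Sequence[MotifHit]],
    reference_species: str,
    window: int = 10,
) -> list[MotifHit]:
    """Keep reference-species hits supported in every other species.

    A reference hit survives iff, for each other species, some hit of the
    same matrix starts within ``window`` bp of the reference hit's offset
    (promoters are assumed positionally comparable, e.g. equal windows
    upstream of orthologous TSSs).  With a single species all hits survive.
    """
    others = [sp for sp in hits_by_species if sp != reference_species]
    ref_hits = list(hits_by_species.get(reference_species, []))
    if not others:
        return ref_hits
    kept = []
    for hit in ref_hits:
        supported = all(
            any(
                other.tf_name == hit.tf_name and abs(other.offset - hit.offset) <= window
                for other in hits_by_species[sp]
            )
            for sp in others
        )
        if supported:
            kept.append(hit)
    return kept


def conserved_hits_by_gene(
    promoters: PromoterSet, pwm: PositionWeightMatrix, window: int = 10
) -> dict[str, list[MotifHit]]:
    """Scan all species and apply the conservation filter, per gene."""
    scanned = scan_promoters(promoters, pwm)
    return {
        gene: filter_conserved_hits(by_sp, promoters.reference_species, window)
        for gene, by_sp in scanned.items()
    }


def combined_gene_score(
    hits: Sequence[MotifHit],
    pwm: PositionWeightMatrix,
    method: str = "excess_sum",
) -> float:
    """Aggregate one gene's conserved hits for one TF into a single score.

    ``excess_sum`` (default) sums the above-threshold excess
    ``score - threshold`` over hits, so every additional site and every
    stronger site increases the score and a hit-free gene scores 0.
    ``max`` takes the largest excess; ``count`` the number of hits.
    """
    if not hits:
        return 0.0
    if any(h.tf_name not in ("", pwm.tf_name) for h in hits):
        raise ValueError("hits from a different matrix passed to combined_gene_score")
    excess = [h.score - pwm.threshold for h in hits]
    if method == "excess_sum":
        return float(sum(excess))
    if method == "max":
        return float(max(excess))
    if method == "count":
        return float(len(hits))
    raise ValueError(f"unknown aggregation method {method!r}")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def tf_set_enrichment(
    foreground: Iterable[str],
    background: Iterable[str],
    hits_by_tf: Mapping[str, Mapping[str, float]],
) -> list[TFResult]:
    """Hypergeometric over-representation of each TF's targets in the foreground.

    ``hits_by_tf[tf]`` maps each gene carrying >= 1 conserved hit for that TF
    to its combined score.  For a background of N genes of which K carry a
    hit, and a foreground of n genes of which k carry a hit, the one-sided
    p-value is ``P[X >= k]`` for hypergeometric X.  BH adjustment is applied
    across TFs; results are sorted by raw p, ties by TF name.
    """
    fg = list(dict.fromkeys(foreground))
    bg = list(dict.fromkeys(background))
    if not fg:
        raise ValueError("foreground gene set is empty")
    bg_set = set(bg)
    stray = [g for g in fg if g not in bg_set]
    if stray:
        raise ValueError(f"foreground genes missing from background: {stray[:5]}")
    if not hits_by_tf:
        raise ValueError("at least one TF is required")
    N, n = len(bg), len(fg)
    fg_set = set(fg)
    results = []
    for tf, gene_scores in hits_by_tf.items():
        carriers = set(gene_scores) & bg_set
        K = len(carriers)
        fg_carriers = sorted(carriers & fg_set)
        k = len(fg_carriers)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        results.append(
            TFResult(
                tf_name=tf,
                target_genes=fg_carriers,
                combined_scores={g: float(gene_scores[g]) for g in fg_carriers},
                n_foreground_hits=k,
                n_background_hits=K,
                p_raw=min(p, 1.0),
            )
        )
    adjusted = bh_adjust([r.p_raw for r in results])
    for r, q in zip(results, adjusted):
        r.p_bh = float(q)
    results.sort(key=lambda r: (r.p_raw, r.tf_name))
    return results
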