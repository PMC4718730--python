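"""Plain-text readers/writers and the end-to-end pipeline driver.

Dialects
--------
* Count matrix TSV: columns ``gene_id``, ``length_bp``, then one column per
  sample named ``sample|group``; lines starting with ``#`` are comments.
* Promoters: FASTA with record ids ``gene|species``.
* Activity cohort CSV: long format with columns larva_id, genotype,
  minute_index, activity, light_phase.
* Hits: BED6 (0-based half-open, score column = log-odds).
* All tabular outputs carry ``#`` header comments echoing the parameters
  that produced them.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .enrichment import EnrichmentRecord, TestConfig, records_to_frame, run_enrichment_pipeline
from .expression import CountMatrix
from .motifs import (
    MotifHit,
    PromoterSet,
    TFResult,
    combined_gene_score,
    conserved_hits_by_gene,
    read_transfac,
    tf_set_enrichment,
)
from .simulate import TruthTable
from .sleep import ActivityTrace, score_cohort

__all__ = [
    "ParseError",
    "PipelineConfig",
    "read_count_matrix",
    "write_count_matrix",
    "write_tpm_matrix",
    "read_promoters",
    "write_promoters",
    "read_activity_cohort",
    "write_activity_cohort",
    "write_truth_table",
    "write_hits_bed",
    "write_enrichment_table",
    "write_tf_results",
    "run_pipeline",
]

logger = logging.getLogger("hcrtkit")


class ParseError(ValueError):
    """Malformed input file (message carries the offending line or field)."""


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

def write_count_matrix(cm: CountMatrix, path, comments: Sequence[str] = ()) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        cols = [f"{s}|{cm.groups[s]}" for s in cm.samples]
        fh.write("\t".join(["gene_id", "length_bp", *cols]) + "\n")
        lengths = cm.lengths
        for gene in cm.gene_ids:
            row = cm.counts.loc[gene]
            vals = "\t".join(str(int(v)) for v in row)
            fh.write(f"{gene}\t{int(lengths[gene])}\t{vals}\n")


def read_count_matrix(path) -> CountMatrix:
    """Read the count-matrix TSV dialect with validation.

    Raises :class:`ParseError` naming the line number for malformed rows,
    duplicate gene ids, non-integer counts, or samples without a group tag.
    """
    path = Path(path)
    samples: list[str] = []
    groups: dict[str, str] = {}
    gene_ids: list[str] = []
    lengths: list[int] = []
    rows: list[list[int]] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if not header_seen:
                if parts[:2] != ["gene_id", "length_bp"]:
                    raise ParseError(
                        f"{path}:{lineno}: header must start with gene_id, length_bp"
                    )
                for col in parts[2:]:
                    if "|" not in col:
                        raise ParseError(
                            f"{path}:{lineno}: sample column {col!r} lacks a "
                            "group tag (expected sample|group)"
                        )
                    name, group = col.split("|", 1)
                    if not group:
                        raise ParseError(
                            f"{path}:{lineno}: sample {name!r} has an empty group tag"
                        )
                    samples.append(name)
                    groups[name] = group
                if not samples:
                    raise ParseError(f"{path}:{lineno}: no sample columns")
                header_seen = True
                continue
            if len(parts) != 2 + len(samples):
                raise ParseError(
                    f"{path}:{lineno}: expected {2 + len(samples)} fields, got {len(parts)}"
                )
            gene = parts[0]
            try:
                length = int(parts[1])
                counts = [int(v) for v in parts[2:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer value ({exc})") from None
            if any(c < 0 for c in counts):
                raise ParseError(f"{path}:{lineno}: negative count")
            gene_ids.append(gene)
            lengths.append(length)
            rows.append(counts)
    if not header_seen:
        raise ParseError(f"{path}: empty file")
    if len(set(gene_ids)) != len(gene_ids):
        seen: set[str] = set()
        for i, g in enumerate(gene_ids):
            if g in seen:
                raise ParseError(f"{path}: duplicated gene id {g!r}")
            seen.add(g)
    frame = pd.DataFrame(rows, index=gene_ids, columns=samples)
    try:
        return CountMatrix(frame, pd.Series(lengths, index=gene_ids), pd.Series(groups))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_tpm_matrix(tpm: pd.DataFrame, path, comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        fh.write("# transcripts per million (columns sum to 1e6)\n")
        for c in comments:
            fh.write(f"# {c}\n")
        tpm.to_csv(fh, sep="\t", index_label="gene_id", float_format="%.6g")


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def write_promoters(promoters: PromoterSet, path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(promoters.sequences[(gene, sp)]), id=f"{gene}|{sp}", description="")
        for gene in promoters.genes
        for sp in promoters.species
    ]
    seqio_write(records, str(path), "fasta")


def read_promoters(path) -> PromoterSet:
    from Bio import SeqIO

    sequences: dict[tuple[str, str], str] = {}
    genes: list[str] = []
    species: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ParseError(f"{path}: record id {rec.id!r} is not gene|species")
        gene, sp = rec.id.split("|", 1)
        sequences[(gene, sp)] = str(rec.seq).upper()
        if gene not in genes:
            genes.append(gene)
        if sp not in species:
            species.append(sp)
    if not sequences:
        raise ParseError(f"{path}: no FASTA records")
    return PromoterSet(sequences=sequences, species=species, genes=genes)


# ---------------------------------------------------------------------------
# activity traces
# ---------------------------------------------------------------------------

def write_activity_cohort(traces: Iterable[ActivityTrace], path) -> None:
    rows = []
    for t in traces:
        phases = t.light_phase()
        for i, (a, ph) in enumerate(zip(t.activity, phases)):
            rows.append((t.larva_id, t.genotype, i, a, ph))
    frame = pd.DataFrame(
        rows, columns=["larva_id", "genotype", "minute_index", "activity", "light_phase"]
    )
    frame.to_csv(path, index=False)


def read_activity_cohort(
    path, light_hours: float = 14.0, dark_hours: float = 10.0
) -> list[ActivityTrace]:
    frame = pd.read_csv(path)
    required = {"larva_id", "genotype", "minute_index", "activity"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    traces = []
    for larva_id, sub in frame.groupby("larva_id", sort=False):
        sub = sub.sort_values("minute_index")
        idx = sub["minute_index"].to_numpy()
        if not np.array_equal(idx, np.arange(len(idx))):
            raise ParseError(f"{path}: larva {larva_id!r} has non-contiguous minutes")
        traces.append(
            ActivityTrace(
                larva_id=str(larva_id),
                genotype=str(sub["genotype"].iloc[0]),
                activity=sub["activity"].to_numpy(dtype=float),
                light_hours=light_hours,
                dark_hours=dark_hours,
            )
        )
    return traces


# ---------------------------------------------------------------------------
# truth tables, hits, results
# ---------------------------------------------------------------------------

def write_truth_table(truth: TruthTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# seed\t{truth.seed}\n")
        for key, value in truth.config.items():
            fh.write(f"# config.{key}\t{value}\n")
        if truth.planted_genes is not None:
            fh.write("planted_gene\n")
            for g in truth.planted_genes:
                fh.write(f"{g}\n")
        if truth.motif_placements is not None:
            fh.write("gene\tspecies\toffset\tstrand\n")
            for gene, sp, offset, strand in truth.motif_placements:
                fh.write(f"{gene}\t{sp}\t{offset}\t{strand}\n")
        if truth.sleep_params is not None:
            fh.write("genotype\tphase\tsleep_min_per_hour\tmean_bout_len\ttransition_rate_per_hour\n")
            for g, phases in truth.sleep_params.items():
                for ph, p in phases.items():
                    fh.write(
                        f"{g}\t{ph}\t{p['sleep_min_per_hour']}\t{p['mean_bout_len']}"
                        f"\t{p['transition_rate_per_hour']}\n"
                    )


def write_hits_bed(hits: Iterable[MotifHit], pwm_length: int, path) -> None:
    """BED6: chrom = gene|species, half-open coordinates, score = log-odds."""
    with open(path, "w") as fh:
        for h in hits:
            chrom = f"{h.gene_id}|{h.species}" if h.species else h.gene_id
            fh.write(
                f"{chrom}\t{h.offset}\t{h.offset + pwm_length}\t{h.tf_name}"
                f"\t{h.score:.4f}\t{h.strand}\n"
            )


def write_enrichment_table(
    records: Sequence[EnrichmentRecord], config: TestConfig, path
) -> None:
    frame = records_to_frame(list(records))
    with open(path, "w") as fh:
        for key, value in asdict(config).items():
            fh.write(f"# {key}\t{value}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g", na_rep=".")


def write_tf_results(results: Sequence[TFResult], path, comments: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        fh.write("tf_name\tn_foreground_hits\tn_background_hits\tp_raw\tp_bh\ttarget_genes\n")
        for r in results:
            targets = ",".join(r.target_genes) if r.target_genes else "."
            fh.write(
                f"{r.tf_name}\t{r.n_foreground_hits}\t{r.n_background_hits}"
                f"\t{r.p_raw:.6g}\t{r.p_bh:.6g}\t{targets}\n"
            )


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Paths and stage parameters for the end-to-end run.

    The enrichment stage is mandatory (``counts_path``); the TF stage runs
    only when both ``promoters_path`` and ``matrices_path`` are set, using
    the top ``tf_foreground_size`` enriched transcripts as the foreground.
    """

    counts_path: str = ""
    promoters_path: str | None = None
    matrices_path: str | None = None
    traces_path: str | None = None
    out_dir: str = "results"
    # enrichment stage
    alpha: float = 0.01
    strict_tpm: float = 100.0
    strict_fold: float = 7.0
    relaxed_tpm: float = 10.0
    relaxed_fold: float = 3.6
    reads_floor: float = 15.0
    pooling_mode: str = "pooled"
    # TF stage
    pwm_threshold_fraction: float = 0.85
    conservation_window: int = 10
    tf_foreground_size: int = 48
    # sleep stage
    light_hours: float = 14.0
    dark_hours: float = 10.0
    immobility_epsilon: float = 0.0
    # misc
    seed: int = 0

    def test_config(self) -> TestConfig:
        return TestConfig(
            alpha=self.alpha,
            strict_tpm=self.strict_tpm,
            strict_fold=self.strict_fold,
            relaxed_tpm=self.relaxed_tpm,
            relaxed_fold=self.relaxed_fold,
            reads_floor=self.reads_floor,
            pooling_mode=self.pooling_mode,
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParseError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**data)


def _stage(name: str):
    """Context manager logging stage timing and tagging stage failures."""
    import contextlib

    @contextlib.contextmanager
    def cm():
        t0 = time.monotonic()
        logger.info("stage %s: start", name)
        try:
            yield
        except Exception as exc:
            raise RuntimeError(f"[{name}] {exc}") from exc
        logger.info("stage %s: done in %.2fs", name, time.monotonic() - t0)

    return cm()


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Run enrichment (and optionally TF analysis) and write the result bundle.

    Returns a mapping of output names to paths.  Deterministic given the
    config (the stages themselves are deterministic; the seed is recorded
    in the output headers for provenance).
    """
    if not config.counts_path:
        raise ValueError("config.counts_path is required")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    with _stage("enrich"):
        cm = read_count_matrix(config.counts_path)
        test_cfg = config.test_config()
        records = run_enrichment_pipeline(cm, test_cfg)
        enriched_path = out_dir / "enriched.tsv"
        write_enrichment_table(records, test_cfg, enriched_path)
        outputs["enriched"] = enriched_path
        logger.info(
            "enrich: %d records (%d strict, %d relaxed)",
            len(records),
            sum(r.tier == "strict" for r in records),
            sum(r.tier == "relaxed" for r in records),
        )

    if config.promoters_path and config.matrices_path:
        with _stage("tfscan"):
            promoters = read_promoters(config.promoters_path)
            pwms = read_transfac(
                config.matrices_path, threshold_fraction=config.pwm_threshold_fraction
            )
            enriched_ids = [r.gene_id for r in records if r.tier != "none"]
            foreground = [g for g in enriched_ids if g in set(promoters.genes)]
            foreground = foreground[: config.tf_foreground_size]
            if not foreground:
                raise ValueError("no enriched genes have promoters; cannot run TF stage")
            hits_by_tf = {}
            all_hits = []
            for pwm in pwms:
                conserved = conserved_hits_by_gene(promoters, pwm, config.conservation_window)
                hits_by_tf[pwm.tf_name] = {
                    gene: combined_gene_score(hits, pwm)
                    for gene, hits in conserved.items()
                    if hits
                }
                for hits in conserved.values():
                    all_hits.extend(hits)
            results = tf_set_enrichment(foreground, promoters.genes, hits_by_tf)
            tf_path = out_dir / "tf_results.tsv"
            write_tf_results(
                results,
                tf_path,
                comments=[
                    f"foreground_size\t{len(foreground)}",
                    f"pwm_threshold_fraction\t{config.pwm_threshold_fraction}",
                    f"conservation_window\t{config.conservation_window}",
                ],
            )
            outputs["tf_results"] = tf_path
            if pwms:
                bed_path = out_dir / "conserved_hits.bed"
                write_hits_bed(all_hits, len(pwms[0]), bed_path)
                outputs["conserved_hits"] = bed_path

    if config.traces_path:
        with _stage("sleep"):
            traces = read_activity_cohort(
                config.traces_path, config.light_hours, config.dark_hours
            )
            cohort = score_cohort(traces, config.immobility_epsilon)
            sleep_path = out_dir / "sleep_summary.tsv"
            with open(sleep_path, "w") as fh:
                fh.write(f"# immobility_epsilon\t{config.immobility_epsilon}\n")
                fh.write(
                    f"# photoperiod\t{config.light_hours}:{config.dark_hours}\n"
                )
                cohort.to_csv(fh, sep="\t", index=False, float_format="%.6g", na_rep=".")
            outputs["sleep_summary"] = sleep_path

    config.save(out_dir / "config_used.yaml")
    outputs["config"] = out_dir / "config_used.yaml"
    return outputs
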