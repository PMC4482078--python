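"""End-to-end orchestration: simulate/load -> filter -> test -> codon analysis.

A single global seed fans out to per-stage seeds through a fixed
stage-name-keyed derivation, so re-running one stage never perturbs the
randomness of another and full runs are bitwise reproducible.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import codonbias, diffstats, formats, quantfilter, synthdata

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_all",
           "coverage_summary", "tally_significant", "stage_seed",
           "load_run_config"]

log = logging.getLogger(__name__)

_STAGE_IDS = {"simulate": 1, "filter": 2, "test": 3, "codons": 4, "rescue": 5}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    ss = np.random.SeedSequence([int(seed), _STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0])


@dataclass
class RunConfig:
    outdir: Path
    seed: int = 0
    generator: synthdata.GeneratorConfig | None = None
    peptide_table: Path | None = None
    fasta: Path | None = None
    filter: quantfilter.FilterConfig = field(
        default_factory=quantfilter.FilterConfig)
    alpha: float = 0.01
    run_codon_stage: bool = True
    n_trees: int = 1000
    rescue_generator: synthdata.GeneratorConfig | None = None
    rescue_peptide_table: Path | None = None
    reference_n: int | None = None  # denominator for coverage reporting

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        if (self.generator is None) == (self.peptide_table is None):
            raise ValueError(
                "exactly one of generator / peptide_table must be set")
        if self.generator is None and self.run_codon_stage and self.fasta is None:
            raise ValueError(
                "codon stage requested but no FASTA supplied in user mode")
        if (self.rescue_generator is not None
                and self.rescue_peptide_table is not None):
            raise ValueError("configure at most one rescue input")


@dataclass
class RunReport:
    """Per-stage bookkeeping for one run."""

    counts: dict[str, int] = field(default_factory=dict)
    coverage_percent: float | None = None
    elapsed: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        c = self.counts
        chain = ["peptides_in", "high_confidence", "consistent"]
        for a, b in zip(chain, chain[1:]):
            if a in c and b in c and c[b] > c[a]:
                raise ValueError(f"count {b} exceeds {a}")
        if {"significant", "sig_up37", "sig_down37"} <= c.keys():
            if c["sig_up37"] + c["sig_down37"] != c["significant"]:
                raise ValueError("up + down must equal total significant")

    def to_frame(self) -> pd.DataFrame:
        rows = [(k, v) for k, v in self.counts.items()]
        if self.coverage_percent is not None:
            rows.append(("coverage_percent", self.coverage_percent))
        return pd.DataFrame(rows, columns=["stage", "count"])

    def write(self, path: Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False,
                               lineterminator="\n")


def coverage_summary(n_quantified: int, n_reference: int) -> float:
    """Percentage of a reference gene set quantified, two decimals."""
    if n_reference <= 0:
        raise ValueError("reference set must be non-empty")
    if n_quantified > n_reference:
        raise ValueError("quantified count exceeds reference count")
    return round(100.0 * n_quantified / n_reference, 2)


def tally_significant(results) -> tuple[int, int, int]:
    """(total significant, up at 37°C, down at 37°C); ns excluded."""
    up = sum(1 for r in results if r.call == "up37")
    down = sum(1 for r in results if r.call == "down37")
    return up + down, up, down


def _timed(report: RunReport, stage: str):
    class _Timer:
        def __enter__(self_inner):
            self_inner.t0 = time.perf_counter()
            return self_inner

        def __exit__(self_inner, exc_type, exc, tb):
            report.elapsed[stage] = time.perf_counter() - self_inner.t0
            log.info("stage %-8s %.2fs", stage, report.elapsed[stage])
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(f"stage {stage}: {exc}") from exc
            return False
    return _Timer()


def _filter_and_test(peptides: pd.DataFrame, config: RunConfig,
                     prefix: str, report: RunReport):
    matrix, counts = quantfilter.run_filter(peptides, config.filter)
    for key, val in counts.items():
        report.counts[f"{prefix}{key}"] = val
    formats.write_matrix_table(matrix.to_long(),
                               config.outdir / f"{prefix}matrix.tsv")
    results = diffstats.moderated_test(matrix, "estimate", alpha=config.alpha)
    report.counts[f"{prefix}tested"] = len(results)
    total, up, down = tally_significant(results)
    report.counts[f"{prefix}significant"] = total
    report.counts[f"{prefix}sig_up37"] = up
    report.counts[f"{prefix}sig_down37"] = down
    formats.write_result_table(diffstats.results_frame(results),
                               config.outdir / f"{prefix}results.tsv")
    return results


def run_all(config: RunConfig) -> RunReport:
    """Execute every configured stage, writing all intermediate tables.

    Outputs under ``config.outdir``: truth.tsv / orfs.fasta / peptides.tsv
    (simulate mode), matrix.tsv, results.tsv, importance.tsv, the rescue
    counterparts when configured, rescue.tsv, report.tsv.
    """
    config.outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()

    with _timed(report, "simulate"):
        if config.generator is not None:
            gen = synthdata.GeneratorConfig(
                **{**config.generator.__dict__,
                   "seed": stage_seed(config.seed, "simulate")})
            truth, orfs, peptides = synthdata.simulate_dataset(gen)
            formats.write_truth_table(synthdata.truth_frame(truth),
                                      config.outdir / "truth.tsv")
            formats.write_fasta(orfs, config.outdir / "orfs.fasta")
            formats.write_peptide_table(peptides, config.outdir / "peptides.tsv")
        else:
            peptides = formats.read_peptide_table(config.peptide_table)
            orfs = formats.read_fasta(config.fasta) if config.fasta else None

    with _timed(report, "filter"):
        results = _filter_and_test(peptides, config, "", report)
    if config.reference_n is not None:
        report.coverage_percent = coverage_summary(
            report.counts["proteins_retained"], config.reference_n)

    rescue_results = None
    if config.rescue_generator is not None or config.rescue_peptide_table is not None:
        with _timed(report, "rescue"):
            if config.rescue_generator is not None:
                gen = synthdata.GeneratorConfig(
                    **{**config.rescue_generator.__dict__,
                       "seed": stage_seed(config.seed, "rescue")})
                r_truth, _, r_peptides = synthdata.simulate_dataset(gen)
                formats.write_truth_table(synthdata.truth_frame(r_truth),
                                          config.outdir / "rescue_truth.tsv")
                formats.write_peptide_table(r_peptides,
                                            config.outdir / "rescue_peptides.tsv")
            else:
                r_peptides = formats.read_peptide_table(config.rescue_peptide_table)
            rescue_results = _filter_and_test(r_peptides, config, "rescue_",
                                              report)

    if config.run_codon_stage:
        with _timed(report, "codons"):
            profiles = codonbias.codon_frequencies(orfs)
            codonbias.profiles_frame(profiles).to_csv(
                config.outdir / "profiles.tsv", sep="\t", index=False,
                float_format=formats.FLOAT_FMT, lineterminator="\n")
            by_id = {p.gene_id: p for p in profiles}
            labelled = [r for r in results
                        if r.call != "ns" and r.protein_id in by_id]
            classes = {r.call for r in labelled}
            if classes == {"up37", "down37"}:
                imp = codonbias.rf_importance(
                    [by_id[r.protein_id] for r in labelled],
                    [r.call for r in labelled],
                    n_trees=config.n_trees,
                    seed=stage_seed(config.seed, "codons"))
                table = imp.table.copy()
                table["threshold"] = imp.threshold
                table.to_csv(config.outdir / "importance.tsv", sep="\t",
                             index=False, float_format=formats.FLOAT_FMT,
                             lineterminator="\n")
            else:
                log.warning("codon importance skipped: classes present = %s",
                            sorted(classes))
            if rescue_results is not None:
                rl = codonbias.rescue_list(results, rescue_results, profiles,
                                           alpha=config.alpha)
                rl.to_csv(config.outdir / "rescue.tsv", sep="\t", index=False,
                          float_format=formats.FLOAT_FMT, lineterminator="\n")

    report.validate()
    report.write(config.outdir / "report.tsv")
    return report


# ---------------------------------------------------------------------------
# flat key-value run configuration files (YAML mapping, one level deep)
# ---------------------------------------------------------------------------

_GENERATOR_KEYS = {f.strip() for f in (
    "n_proteins n_replicates frac_biased bias_effect sigma_bio sigma_meas "
    "frac_wrong sigma_wrong codon_bias_multiplier npep_intercept npep_slope "
    "npep_noise dropout").split()}
_FILTER_KEYS = {"fdr_target", "c", "min_high_conf_peptides",
                "require_both_designs", "aggregator", "normalize"}


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a flat YAML mapping.

    Generator and filter parameters share the namespace with the run-level
    keys (outdir, seed, alpha, n_trees, peptide_table, fasta,
    reference_n, simulate: true/false).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must be a flat key-value mapping")
    gen_kwargs = {k: v for k, v in raw.items() if k in _GENERATOR_KEYS}
    filt_kwargs = {k: v for k, v in raw.items() if k in _FILTER_KEYS}
    simulate = bool(raw.get("simulate", "n_proteins" in raw))
    known = (_GENERATOR_KEYS | _FILTER_KEYS
             | {"simulate", "outdir", "seed", "alpha", "n_trees",
                "peptide_table", "fasta", "reference_n", "run_codon_stage"})
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(
        outdir=Path(raw.get("outdir", "run_out")),
        seed=int(raw.get("seed", 0)),
        generator=synthdata.GeneratorConfig(**gen_kwargs) if simulate else None,
        peptide_table=(Path(raw["peptide_table"])
                       if raw.get("peptide_table") else None),
        fasta=Path(raw["fasta"]) if raw.get("fasta") else None,
        filter=quantfilter.FilterConfig(**filt_kwargs),
        alpha=float(raw.get("alpha", 0.01)),
        run_codon_stage=bool(raw.get("run_codon_stage", True)),
        n_trees=int(raw.get("n_trees", 1000)),
        reference_n=(int(raw["reference_n"])
                     if raw.get("reference_n") is not None else None),
    )
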