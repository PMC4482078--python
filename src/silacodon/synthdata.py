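"""Synthetic SILAC label-switch datasets with known ground truth.

Generates, from a single seed: per-protein ground truth (true oriented
log2 ratios, abundances, codon-bias class), coding sequences whose codon
composition is optionally enriched for AAA/GAA/CAA, and peptide-level
heavy/light ratio observations with the label-switch sign structure,
measurement noise and a contaminating fraction of erroneous
quantifications.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codonbias import SENSE_CODONS

__all__ = ["GeneratorConfig", "TruthRecord", "generate_truth",
           "generate_orfs", "generate_peptides", "simulate_dataset",
           "truth_frame", "BIASED_CODONS"]

#: codons read by thiolation-dependent tRNAs; enriched in "biased" genes
BIASED_CODONS = ("AAA", "GAA", "CAA")

# fixed sub-stream keys so each generation stage has its own rng
_STAGE_KEYS = {"truth": 11, "orfs": 23, "peptides": 37}


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STAGE_KEYS[stage]]))


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic dataset generator.

    ``design_assignment`` holds one sign per replicate: +1 means the 30°C
    culture carries the heavy label in that replicate. The default is the
    alternating 3-replicate label-switch design (+1, -1, +1).
    """

    n_proteins: int
    n_replicates: int = 3
    design_assignment: tuple[int, ...] | None = None
    frac_biased: float = 0.1
    bias_effect: float = 1.0
    sigma_bio: float = 0.2
    sigma_meas: float = 0.4
    frac_wrong: float = 0.05
    sigma_wrong: float = 2.0
    abundance_log10_range: tuple[float, float] = (1.0, 6.0)
    gene_length_codons: tuple[int, int] = (100, 500)
    codon_bias_multiplier: float = 3.0
    # n_peptides = round(intercept + slope * log10(copies)) + U{-noise..noise},
    # clipped at 1; defaults give a corpus-wide mean of about 21
    npep_intercept: float = 0.0
    npep_slope: float = 6.0
    npep_noise: int = 2
    dropout: float = 0.0
    # Beta(a, b) for identification probabilities
    prob_correct_beta: tuple[float, float] = (60.0, 1.0)
    prob_wrong_beta: tuple[float, float] = (4.0, 4.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be a positive integer")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be a positive integer")
        if self.design_assignment is None:
            if self.n_replicates < 2:
                raise ValueError(
                    "default design needs >= 2 replicates to cover both signs")
            self.design_assignment = tuple(
                1 if i % 2 == 0 else -1 for i in range(self.n_replicates))
        else:
            self.design_assignment = tuple(int(d) for d in self.design_assignment)
        if len(self.design_assignment) != self.n_replicates:
            raise ValueError("design_assignment length must equal n_replicates")
        if not set(self.design_assignment) <= {1, -1}:
            raise ValueError("designs must be +1 or -1")
        if not ({1, -1} <= set(self.design_assignment)):
            raise ValueError("design_assignment must contain both signs")
        for name in ("frac_biased", "frac_wrong", "dropout"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("sigma_bio", "sigma_meas", "sigma_wrong"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.codon_bias_multiplier < 1.0:
            raise ValueError("codon_bias_multiplier must be >= 1")
        lo, hi = self.gene_length_codons
        if lo < 3 or hi < lo:
            raise ValueError("gene_length_codons must be an interval with lo >= 3")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated protein."""

    protein_id: str
    true_log2_ratio: float  # oriented log2(30°C / 37°C)
    bias_class: str  # "biased" | "unbiased"
    copies_per_cell: float
    n_peptides: int


def generate_truth(config: GeneratorConfig) -> list[TruthRecord]:
    """Draw per-protein ground truth.

    Exactly ``floor(frac_biased * n_proteins)`` proteins are flagged
    biased; their true oriented ratio is shifted by ``bias_effect``
    (positive = less abundant at 37°C).
    """
    rng = _stage_rng(config.seed, "truth")
    n = config.n_proteins
    width = max(6, len(str(n)))
    ids = [f"P{i:0{width}d}" for i in range(1, n + 1)]

    ratios = rng.normal(0.0, config.sigma_bio, size=n) if config.sigma_bio > 0 \
        else np.zeros(n)
    n_biased = int(np.floor(config.frac_biased * n))
    biased_idx = rng.permutation(n)[:n_biased]
    biased = np.zeros(n, dtype=bool)
    biased[biased_idx] = True
    ratios = ratios + np.where(biased, config.bias_effect, 0.0)

    lo, hi = config.abundance_log10_range
    log10_copies = rng.uniform(lo, hi, size=n)
    copies = 10.0 ** log10_copies

    base = np.rint(config.npep_intercept + config.npep_slope * log10_copies)
    noise = rng.integers(-config.npep_noise, config.npep_noise + 1, size=n) \
        if config.npep_noise > 0 else np.zeros(n, dtype=np.int64)
    n_pep = np.maximum(1, base.astype(np.int64) + noise)

    return [TruthRecord(ids[i], float(ratios[i]),
                        "biased" if biased[i] else "unbiased",
                        float(copies[i]), int(n_pep[i]))
            for i in range(n)]


def truth_frame(truth: list[TruthRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "protein_id": [t.protein_id for t in truth],
        "true_log2_ratio": [t.true_log2_ratio for t in truth],
        "bias_class": [t.bias_class for t in truth],
        "copies_per_cell": [t.copies_per_cell for t in truth],
        "n_peptides": [t.n_peptides for t in truth],
    })


def generate_orfs(truth: list[TruthRecord],
                  config: GeneratorConfig) -> list[tuple[str, str]]:
    """Sample one coding sequence per protein.

    Every sequence starts with ATG, ends with a single TAA stop, has
    length divisible by 3 and no internal stop codons (interior codons are
    sampled from the 61 sense codons only). For biased genes the sampling
    weights of AAA/GAA/CAA are multiplied by ``codon_bias_multiplier``
    before renormalization.
    """
    if not truth:
        raise ValueError("truth must be non-empty")
    rng = _stage_rng(config.seed, "orfs")

    n_codons = len(SENSE_CODONS)
    base_w = np.full(n_codons, 1.0 / n_codons)
    biased_w = base_w.copy()
    for codon in BIASED_CODONS:
        biased_w[SENSE_CODONS.index(codon)] *= config.codon_bias_multiplier
    biased_w /= biased_w.sum()

    codon_arr = np.array(SENSE_CODONS)
    lo, hi = config.gene_length_codons
    records: list[tuple[str, str]] = []
    for rec in truth:
        total = int(rng.integers(lo, hi + 1))  # codons incl. start and stop
        weights = biased_w if rec.bias_class == "biased" else base_w
        interior = rng.choice(n_codons, size=total - 2, p=weights)
        seq = "ATG" + "".join(codon_arr[interior]) + "TAA"
        records.append((rec.protein_id, seq))
    return records


def generate_peptides(truth: list[TruthRecord],
                      config: GeneratorConfig) -> pd.DataFrame:
    """Simulate peptide-level heavy/light observations for every replicate.

    With probability ``1 - frac_wrong`` an observation is correct:
    ``log2_hl = design * true_log2_ratio + N(0, sigma_meas)`` with an
    identification probability concentrated near 1. Otherwise it is
    erroneous: ``log2_hl ~ N(0, sigma_wrong)`` with a low-centered
    probability. Whole (protein, replicate) blocks drop out with
    probability ``dropout``.
    """
    if not truth:
        raise ValueError("truth must be non-empty")
    rng = _stage_rng(config.seed, "peptides")

    n_pep = np.array([t.n_peptides for t in truth])
    true_ratio = np.array([t.true_log2_ratio for t in truth])
    pep_width = max(3, len(str(int(n_pep.max()))))
    pep_ids = np.array([f"{t.protein_id}_pep{j + 1:0{pep_width}d}"
                        for t in truth for j in range(t.n_peptides)])
    prot_ids = np.repeat([t.protein_id for t in truth], n_pep)
    true_rep = np.repeat(true_ratio, n_pep)
    total = int(n_pep.sum())

    frames = []
    ac, bc = config.prob_correct_beta
    aw, bw = config.prob_wrong_beta
    for r, design in enumerate(config.design_assignment, start=1):
        # draw every stream unconditionally so the rng sequence does not
        # depend on the masks (keeps outputs reproducible across configs)
        is_correct = rng.random(total) >= config.frac_wrong
        noise_ok = rng.normal(0.0, 1.0, size=total) * config.sigma_meas
        noise_bad = rng.normal(0.0, 1.0, size=total) * config.sigma_wrong
        p_ok = rng.beta(ac, bc, size=total)
        p_bad = rng.beta(aw, bw, size=total)
        drop = rng.random(len(truth)) < config.dropout

        log2_hl = np.where(is_correct, design * true_rep + noise_ok, noise_bad)
        prob = np.where(is_correct, p_ok, p_bad)
        keep = ~np.repeat(drop, n_pep)
        frames.append(pd.DataFrame({
            "peptide_id": pep_ids[keep],
            "protein_id": prot_ids[keep],
            "replicate_id": f"rep{r}",
            "design": np.int64(design),
            "log2_hl": log2_hl[keep],
            "probability": prob[keep],
            "correct": is_correct[keep],
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_dataset(config: GeneratorConfig):
    """Convenience wrapper: truth, ORFs and peptides from one config."""
    truth = generate_truth(config)
    orfs = generate_orfs(truth, config)
    peptides = generate_peptides(truth, config)
    return truth, orfs, peptides
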