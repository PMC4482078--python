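"""Label-switch quantification workflow.

Stages: identification-probability thresholding at a target FDR, ratio
orientation to the fixed log2(30°C/37°C) convention, per-peptide
cross-design consistency filtering, protein retention, and aggregation to
a per-protein, per-replicate ratio matrix.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["FilterConfig", "ProteinRatioMatrix", "probability_threshold_at_fdr",
           "orient", "high_confidence", "consistency_filter", "retain_proteins",
           "aggregate", "run_filter"]


@dataclass
class FilterConfig:
    fdr_target: float = 0.01
    c: float = 0.4  # per-measurement SD allowance; consistency bound is sqrt(2)*c
    min_high_conf_peptides: int = 2
    require_both_designs: bool = True
    aggregator: str = "median"
    normalize: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_target < 1.0:
            raise ValueError("fdr_target must be in (0, 1)")
        if self.c <= 0:
            raise ValueError("c must be positive")
        if self.min_high_conf_peptides < 1:
            raise ValueError("min_high_conf_peptides must be >= 1")
        if self.aggregator not in ("median", "mean"):
            raise ValueError("aggregator must be 'median' or 'mean'")

    @property
    def consistency_bound(self) -> float:
        return math.sqrt(2.0) * self.c


@dataclass
class ProteinRatioMatrix:
    """Oriented log2(30°C/37°C) ratios, proteins x replicates.

    ``ratios`` holds NaN for missing cells; ``counts`` the number of
    supporting peptides per cell (0 where missing).
    """

    ratios: pd.DataFrame
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        stored = self.ratios.to_numpy()
        present = ~np.isnan(stored)
        if not np.all(np.isfinite(stored[present])):
            raise ValueError("stored ratios must be finite")
        if not present.any(axis=1).all():
            raise ValueError("every protein needs >= 1 non-missing cell")
        if not self.ratios.shape == self.counts.shape:
            raise ValueError("ratio and count shapes differ")

    def to_long(self) -> pd.DataFrame:
        rows = []
        for protein in self.ratios.index:
            for rep in self.ratios.columns:
                val = self.ratios.at[protein, rep]
                if not np.isnan(val):
                    rows.append((protein, rep, val,
                                 int(self.counts.at[protein, rep])))
        return pd.DataFrame(rows, columns=["protein_id", "replicate_id",
                                           "ratio", "n_peptides"])

    @classmethod
    def from_long(cls, table: pd.DataFrame) -> "ProteinRatioMatrix":
        ratios = table.pivot(index="protein_id", columns="replicate_id",
                             values="ratio")
        counts = table.pivot(index="protein_id", columns="replicate_id",
                             values="n_peptides").fillna(0).astype(int)
        return cls(ratios=ratios, counts=counts)


def probability_threshold_at_fdr(probabilities, fdr_target: float) -> float:
    """Probability cutoff achieving an estimated identification FDR.

    Sort descending; the estimated FDR of the top-k prefix is
    ``sum(1 - p_i) / k``. Returns the probability of the last element of
    the largest prefix whose estimated FDR is <= ``fdr_target``; if no
    prefix qualifies, returns ``inf`` so that nothing passes.
    """
    p = np.asarray(probabilities, dtype=float)
    if p.size == 0:
        raise ValueError("probabilities must be non-empty")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    order = np.sort(p)[::-1]
    fdr = np.cumsum(1.0 - order) / np.arange(1, p.size + 1)
    # tiny relative slack so exact-boundary prefixes survive float roundoff
    ok = np.flatnonzero(fdr <= fdr_target * (1.0 + 1e-9))
    if ok.size == 0:
        return math.inf
    return float(order[ok.max()])


def high_confidence(observations: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Keep observations with identification probability >= threshold."""
    return observations[observations["probability"] >= threshold].reset_index(drop=True)


def orient(observations: pd.DataFrame) -> pd.DataFrame:
    """Add the oriented ratio column: ``design * log2_hl``.

    Positive oriented values mean more abundant at 30°C, i.e.
    down-regulated at 37°C.
    """
    out = observations.copy()
    out["oriented"] = out["design"].to_numpy() * out["log2_hl"].to_numpy()
    return out


def consistency_filter(observations: pd.DataFrame,
                       config: FilterConfig) -> pd.DataFrame:
    """Retain peptides whose per-design mean oriented ratios agree.

    For each peptide (keyed by protein_id, peptide_id) compute the mean
    oriented ratio over design +1 replicates and over design -1
    replicates; retain its observations iff both means exist and
    ``|m(+1) - m(-1)| < sqrt(2) * c``. Peptides seen in only one design
    are dropped.
    """
    if observations.empty:
        return observations.copy()
    means = (observations.groupby(["protein_id", "peptide_id", "design"],
                                  sort=True)["oriented"]
             .mean().unstack("design"))
    if 1 not in means.columns or -1 not in means.columns:
        keep_keys = means.iloc[0:0].index
    else:
        both = means[1].notna() & means[-1].notna()
        ok = both & ((means[1] - means[-1]).abs() < config.consistency_bound)
        keep_keys = means.index[ok]
    key = pd.MultiIndex.from_frame(observations[["protein_id", "peptide_id"]])
    return observations[key.isin(keep_keys)].reset_index(drop=True)


def retain_proteins(retained: pd.DataFrame, config: FilterConfig) -> set[str]:
    """Proteins with enough retained peptides covering both designs.

    A protein is kept iff it has at least ``min_high_conf_peptides``
    distinct retained peptides and (when ``require_both_designs``) those
    peptides jointly cover both label designs.
    """
    if retained.empty:
        return set()
    kept: set[str] = set()
    for protein, grp in retained.groupby("protein_id", sort=True):
        if grp["peptide_id"].nunique() < config.min_high_conf_peptides:
            continue
        if config.require_both_designs and set(grp["design"]) != {1, -1}:
            continue
        kept.add(protein)
    return kept


def aggregate(retained: pd.DataFrame, proteins: set[str],
              config: FilterConfig) -> ProteinRatioMatrix:
    """Collapse retained peptide ratios to a protein x replicate matrix.

    Each cell is the aggregator (median or mean) of that protein's
    retained oriented peptide ratios in that replicate. When
    ``normalize`` is set, each replicate column is centered by
    subtracting its median cell value.
    """
    if not proteins:
        raise ValueError("no proteins to aggregate")
    missing = proteins - set(retained["protein_id"])
    if missing:
        raise ValueError(f"proteins not present in retained table: {sorted(missing)[:5]}")
    sub = retained[retained["protein_id"].isin(proteins)]
    ratios = sub.pivot_table(index="protein_id", columns="replicate_id",
                             values="oriented", aggfunc=config.aggregator,
                             sort=True)
    counts = sub.pivot_table(index="protein_id", columns="replicate_id",
                             values="oriented", aggfunc="size", sort=True)
    counts = counts.fillna(0).astype(int)
    if config.normalize:
        ratios = ratios - ratios.median(axis=0, skipna=True)
    return ProteinRatioMatrix(ratios=ratios, counts=counts)


def run_filter(observations: pd.DataFrame,
               config: FilterConfig) -> tuple[ProteinRatioMatrix, dict[str, int]]:
    """Full chain: threshold -> orient -> consistency -> retain -> aggregate.

    Returns the matrix plus per-stage counts for logging.
    """
    counts = {"peptides_in": int(len(observations))}
    threshold = probability_threshold_at_fdr(
        observations["probability"], config.fdr_target)
    conf = high_confidence(observations, threshold)
    counts["high_confidence"] = int(len(conf))
    oriented = orient(conf)
    consistent = consistency_filter(oriented, config)
    counts["consistent"] = int(len(consistent))
    proteins = retain_proteins(consistent, config)
    counts["proteins_retained"] = len(proteins)
    matrix = aggregate(consistent, proteins, config)
    return matrix, counts
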