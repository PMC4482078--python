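"""Codon-usage profiling and codon importance for up/down protein classes.

Per-gene relative codon frequencies over the 61 sense codons feed a
random-forest classifier separating up- from down-regulated proteins;
codon importance is permutation importance on out-of-bag samples, with
the selection threshold set to the absolute value of the lowest
(most negative) predictor. Also provides top-percentile codon-frequency
gene subsets and the tRNA-overexpression rescue comparison.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

__all__ = ["SENSE_CODONS", "STOP_CODONS", "CodonProfile", "ImportanceTable",
           "codon_frequencies", "rf_importance", "top_codon_subset",
           "subset_volcano", "rescue_list", "profiles_frame"]

log = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")
#: the 61 sense codons, alphabetical
SENSE_CODONS: list[str] = [
    "".join(c) for c in itertools.product("ACGT", repeat=3)
    if "".join(c) not in STOP_CODONS
]


@dataclass(frozen=True)
class CodonProfile:
    """Relative sense-codon frequencies of one coding sequence."""

    gene_id: str
    frequencies: np.ndarray  # length 61, sums to 1

    def __post_init__(self) -> None:
        if self.frequencies.shape != (len(SENSE_CODONS),):
            raise ValueError("frequency vector must have length 61")
        if abs(float(self.frequencies.sum()) - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")

    def frequency(self, codon: str) -> float:
        return float(self.frequencies[SENSE_CODONS.index(codon)])


@dataclass
class ImportanceTable:
    """Per-codon importance scores with the lowest-predictor threshold."""

    table: pd.DataFrame  # columns: codon, importance, rank, selected
    threshold: float


def _validate_orf(gene_id: str, seq: str) -> list[str]:
    if len(seq) % 3 != 0:
        raise ValueError(f"gene {gene_id}: length {len(seq)} not divisible by 3")
    codons = [seq[i:i + 3] for i in range(0, len(seq), 3)]
    if codons[0] != "ATG":
        raise ValueError(f"gene {gene_id}: does not begin with ATG")
    if codons[-1] not in STOP_CODONS:
        raise ValueError(f"gene {gene_id}: missing terminal stop codon")
    internal = [i for i, c in enumerate(codons[:-1]) if c in STOP_CODONS]
    if internal:
        raise ValueError(
            f"gene {gene_id}: internal stop codon at codon index {internal[0]}")
    return codons


def codon_frequencies(sequences) -> list[CodonProfile]:
    """Per-gene relative frequencies over the 61 sense codons.

    Counts every codon including the initial ATG and excluding the single
    terminal stop. Input: iterable of (gene_id, sequence).
    """
    index = {c: i for i, c in enumerate(SENSE_CODONS)}
    profiles = []
    for gene_id, seq in sequences:
        codons = _validate_orf(gene_id, seq)
        counts = np.zeros(len(SENSE_CODONS))
        for codon in codons[:-1]:
            pos = index.get(codon)
            if pos is None:  # codons containing N are not countable
                raise ValueError(f"gene {gene_id}: ambiguous codon {codon!r}")
            counts[pos] += 1
        profiles.append(CodonProfile(gene_id, counts / counts.sum()))
    return profiles


def profiles_frame(profiles: list[CodonProfile]) -> pd.DataFrame:
    frame = pd.DataFrame(
        np.vstack([p.frequencies for p in profiles]), columns=SENSE_CODONS)
    frame.insert(0, "gene_id", [p.gene_id for p in profiles])
    return frame


def rf_importance(profiles: list[CodonProfile], labels,
                  n_trees: int = 1000, seed: int = 0) -> ImportanceTable:
    """Out-of-bag permutation importance of each codon for class separation.

    Trains a random forest on the 61 codon frequencies against the
    ``up37``/``down37`` labels. For every tree, each feature column is
    permuted among that tree's out-of-bag samples and the drop in
    out-of-bag accuracy is averaged over trees. The selection threshold is
    the absolute value of the most negative importance (0 if none are
    negative); a codon is selected iff its importance exceeds it.
    """
    labels = np.asarray(labels)
    if len(labels) != len(profiles):
        raise ValueError("profiles and labels must be aligned")
    classes = set(labels.tolist())
    if len(classes) < 2:
        raise ValueError("need both an up and a down class")
    X = np.vstack([p.frequencies for p in profiles])
    n, n_feat = X.shape

    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", bootstrap=True,
        random_state=int(seed), n_jobs=1)
    forest.fit(X, labels)
    y_enc = np.searchsorted(forest.classes_, labels).astype(float)

    rng = np.random.default_rng(int(seed))
    decreases = np.zeros(n_feat)
    used_trees = 0
    all_idx = np.arange(n)
    for tree, sampled in zip(forest.estimators_, forest.estimators_samples_):
        oob = np.setdiff1d(all_idx, sampled, assume_unique=False)
        if oob.size < 2:
            continue
        X_oob = X[oob]
        y_oob = y_enc[oob]
        base_acc = float(np.mean(tree.predict(X_oob) == y_oob))
        # one stacked predict per tree: all 61 permuted copies at once
        stacked = np.tile(X_oob, (n_feat, 1))
        m = oob.size
        for j in range(n_feat):
            stacked[j * m:(j + 1) * m, j] = rng.permutation(X_oob[:, j])
        perm_pred = tree.predict(stacked).reshape(n_feat, m)
        perm_acc = (perm_pred == y_oob).mean(axis=1)
        decreases += base_acc - perm_acc
        used_trees += 1
    if used_trees == 0:
        raise ValueError("no tree had enough out-of-bag samples")
    importance = decreases / used_trees

    threshold = float(abs(min(importance.min(), 0.0)))
    # rank 1 = most important; ties broken alphabetically for determinism
    order = np.lexsort((np.array(SENSE_CODONS), -importance))
    rank = np.empty(n_feat, dtype=int)
    rank[order] = np.arange(1, n_feat + 1)
    table = pd.DataFrame({
        "codon": SENSE_CODONS,
        "importance": importance,
        "rank": rank,
        "selected": importance > threshold,
    })
    return ImportanceTable(table=table, threshold=threshold)


def top_codon_subset(profiles: list[CodonProfile], codon: str,
                     percentile: float) -> set[str]:
    """Genes in the top percentile by frequency of one codon.

    Ranks genes by descending codon frequency (ties broken by ascending
    gene id) and returns the top ``ceil(n * percentile / 100)``.
    """
    if codon not in SENSE_CODONS:
        raise ValueError(f"unknown codon {codon!r}")
    if not 0.0 < percentile < 100.0:
        raise ValueError("percentile must be in (0, 100)")
    ranked = sorted(profiles, key=lambda p: (-p.frequency(codon), p.gene_id))
    k = math.ceil(len(profiles) * percentile / 100.0)
    return {p.gene_id for p in ranked[:k]}


def subset_volcano(results, subset: set[str]) -> pd.DataFrame:
    """Volcano-ready table for a gene subset.

    Columns: gene_id, mean_log2, neglog10_adj_p. The 1% FDR reference
    line corresponds to neglog10_adj_p = 2. Subset members missing from
    the results are logged and skipped.
    """
    by_id = {r.protein_id: r for r in results}
    missing = sorted(subset - by_id.keys())
    for gene in missing:
        log.warning("subset gene %s absent from results; skipped", gene)
    rows = []
    for gene in sorted(subset & by_id.keys()):
        r = by_id[gene]
        with np.errstate(divide="ignore"):
            y = float(-np.log10(r.adj_p)) if r.adj_p > 0 else math.inf
        rows.append((gene, r.mean_log2, y))
    return pd.DataFrame(rows, columns=["gene_id", "mean_log2", "neglog10_adj_p"])


def rescue_list(results_normal, results_rescue, profiles: list[CodonProfile],
                codons: tuple[str, ...] = ("AAA", "CAA", "GAA"),
                percentile: float = 10.0, alpha: float = 0.01) -> pd.DataFrame:
    """Genes down-regulated normally but rescued in the second dataset.

    Restricted to genes present in both result sets, keeps those that are
    in the union of top-percentile subsets for the given codons, called
    down37 (adj_p <= alpha, positive mean) in the normal dataset, and not
    so called in the rescue dataset. Sorted by normal-dataset adj_p.
    """
    normal = {r.protein_id: r for r in results_normal}
    rescue = {r.protein_id: r for r in results_rescue}
    common = normal.keys() & rescue.keys()
    in_subset: set[str] = set()
    for codon in codons:
        in_subset |= top_codon_subset(profiles, codon, percentile)

    def is_down(r) -> bool:
        return r.adj_p <= alpha and r.mean_log2 > 0

    rows = []
    for gene in common:
        rn, rr = normal[gene], rescue[gene]
        flags = (gene in in_subset, is_down(rn), not is_down(rr))
        if all(flags):
            rows.append((gene, rn.adj_p, *flags))
    rows.sort(key=lambda row: (row[1], row[0]))
    return pd.DataFrame(rows, columns=["gene_id", "adj_p_normal",
                                       "in_codon_subset", "down_normal",
                                       "not_down_rescue"])
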