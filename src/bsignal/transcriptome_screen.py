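"""Time-course transcriptome screen for feedback-regulator candidates.

The screening pipeline mirrors the microarray analysis that nominated the
feedback regulators: per gene, test whether expression changes over the
stimulation time course relative to the time-0 baseline; control the false
discovery rate by Benjamini–Hochberg; partition the responsive genes across
stimulation conditions (Venn set algebra); cluster the responsive genes'
standardized time profiles with k-means (k = 8); and triage the
earliest-peaking cluster — where classical immediate-early feedback
regulators such as A20 fall — for candidate regulators, ranked by induction
amplitude.

Input is a log-scale gene x (condition, time, replicate) matrix.  The
per-gene statistic is a one-way ANOVA across timepoints (including the
baseline group), which requires at least two replicate measurements per
timepoint; matrices without replication are rejected rather than guessed at.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "ClusterResult",
    "select_responsive",
    "partition_by_condition",
    "cluster_profiles",
    "triage_candidates",
]


class ExpressionMatrix:
    """Log-scale expression values, genes x (condition, time, replicate).

    Wraps a DataFrame whose columns are a MultiIndex (condition, time_min,
    replicate); every condition must include the time-0 baseline and the
    matrix must be complete (no missing values — imputation is out of scope).
    """

    def __init__(self, df: pd.DataFrame):
        if not isinstance(df.columns, pd.MultiIndex) or df.columns.nlevels != 3:
            raise ValueError("columns must be a (condition, time_min, replicate) MultiIndex")
        if df.isna().any().any():
            raise ValueError("matrix contains missing values; imputation is out of scope")
        for cond in df.columns.get_level_values(0).unique():
            times = df[cond].columns.get_level_values(0)
            if 0.0 not in set(float(t) for t in times):
                raise ValueError(f"condition {cond!r} lacks the time-0 baseline")
        self.df = df

    @property
    def gene_ids(self) -> pd.Index:
        return self.df.index

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.df.columns.get_level_values(0)))

    def timepoints(self, condition: str) -> np.ndarray:
        if condition not in self.conditions:
            raise KeyError(f"condition {condition!r} not in matrix (have {self.conditions})")
        return np.array(sorted({float(t) for t in self.df[condition].columns.get_level_values(0)}))

    def replicate_groups(self, condition: str) -> list[np.ndarray]:
        """Per timepoint, the (genes x replicates) value block."""
        sub = self.df[condition]
        return [sub.xs(t, level="time_min", axis=1).to_numpy(float) for t in self.timepoints(condition)]

    def mean_profiles(self, condition: str, genes=None) -> pd.DataFrame:
        """Replicate-averaged profiles, genes x timepoints."""
        sub = self.df[condition]
        prof = sub.T.groupby(level="time_min").mean().T
        prof = prof[sorted(prof.columns, key=float)]
        return prof.loc[genes] if genes is not None else prof

    # -- serialization (gene ids in first column, "condition:time" headers,
    #    replicates as repeated headers) --

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out.columns = [f"{c}:{t:g}" for c, t, _ in self.df.columns]
        out.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        cols, counters = [], {}
        for name in df.columns:
            # pandas mangles duplicate headers to "name.1", "name.2", ...
            base = name.rsplit(".", 1)[0] if name.rsplit(".", 1)[-1].isdigit() else name
            if ":" not in base:
                raise ValueError(f"column {name!r} is not in 'condition:time' form")
            cond, t = base.rsplit(":", 1)
            key = (cond, float(t))
            counters[key] = counters.get(key, 0) + 1
            cols.append((cond, float(t), counters[key]))
        df.columns = pd.MultiIndex.from_tuples(cols, names=["condition", "time_min", "replicate"])
        values = df.to_numpy(float)
        span = np.nanmax(values) - np.nanmin(values)
        if np.nanmin(values) < 0 and span > 50:
            raise ValueError("dynamic range inconsistent with log-scale expression; refusing to guess the scale")
        return cls(df)


@dataclass(frozen=True)
class ClusterResult:
    """k-means clustering of standardized time profiles.

    Cluster ids are renumbered by centroid peak time ascending, so cluster 1
    is always the earliest-peaking (immediate-response) cluster.
    ``amplitudes`` holds each gene's raw induction amplitude (max of the
    replicate-averaged profile minus its time-0 value) for triage ranking.
    """

    labels: pd.Series
    centroids: pd.DataFrame
    k: int
    seed: int
    amplitudes: pd.Series

    def members(self, cluster_id: int) -> list[str]:
        return list(self.labels.index[self.labels == cluster_id])


def select_responsive(matrix: ExpressionMatrix, condition: str, fdr: float = 0.05):
    """Genes whose time course differs from baseline at the given FDR.

    One-way ANOVA across timepoint groups (replicates within each timepoint),
    Benjamini–Hochberg adjusted over all genes.  Returns the selected gene
    list and the per-gene q-value series.
    """
    if condition not in matrix.conditions:
        raise KeyError(f"condition {condition!r} not in matrix (have {matrix.conditions})")
    if not 0 <= fdr <= 1:
        raise ValueError("fdr must be in [0, 1]")
    groups = matrix.replicate_groups(condition)
    if len(groups) < 3:
        raise ValueError("need the baseline plus >= 2 later timepoints")
    if any(g.shape[1] < 2 for g in groups):
        raise ValueError("need >= 2 replicates per timepoint for the within-group variance")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant genes give 0/0 -> nan
        res = stats.f_oneway(*groups, axis=1)
    pvals = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    qseries = pd.Series(qvals, index=matrix.gene_ids, name="q_value")
    selected = list(matrix.gene_ids[qvals < fdr])
    return selected, qseries


def partition_by_condition(selected: dict[str, list[str]]) -> dict:
    """Venn partition of responsive-gene lists across conditions.

    Returns, for every non-empty combination of conditions, the genes
    responsive in exactly that combination, plus the region sizes.
    """
    if len(selected) < 2:
        raise ValueError("need >= 2 conditions to partition")
    sets = {c: set(g) for c, g in selected.items()}
    conds = list(sets)
    regions: dict[frozenset, set] = {}
    for r in range(1, len(conds) + 1):
        for combo in combinations(conds, r):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set.union(set(), *(sets[c] for c in conds if c not in combo))
            regions[frozenset(combo)] = inside - outside
    return {
        "regions": {"&".join(sorted(key)): sorted(genes) for key, genes in regions.items()},
        "counts": {"&".join(sorted(key)): len(genes) for key, genes in regions.items()},
    }


def cluster_profiles(
    matrix: ExpressionMatrix,
    genes: list[str],
    condition: str | None = None,
    k: int = 8,
    seed: int = 0,
    n_restarts: int = 50,
) -> ClusterResult:
    """k-means on per-gene z-scored time profiles, clusters ordered by peak time.

    Profiles are replicate-averaged, standardized to mean 0 / sd 1 across
    timepoints (shape, not amplitude, drives the clustering), and clustered
    with k-means++ seeding and ``n_restarts`` restarts; the best inertia
    wins.  Clusters are renumbered so that cluster 1 peaks earliest.
    """
    if condition is None:
        condition = matrix.conditions[0]
    genes = list(genes)
    if len(genes) < k:
        raise ValueError(f"need at least k={k} genes, got {len(genes)}")
    prof = matrix.mean_profiles(condition, genes)
    times = prof.columns.to_numpy(float)
    x = prof.to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant profiles standardized to zero")
    z = np.where(sd > 0, (x - mu) / np.where(sd == 0, 1.0, sd), 0.0)

    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed)
    raw_labels = km.fit_predict(z)

    # centroid := mean of member standardized profiles; order by induction
    # peak time. A centroid whose maximum sits at t = 0 was never induced
    # (down-regulated or flat profiles) and sorts after every rising cluster.
    centroids = np.vstack([z[raw_labels == c].mean(axis=0) for c in range(k)])
    argmax = np.argmax(centroids, axis=1)
    peak_times = np.where(argmax == 0, np.inf, times[argmax])
    order = np.lexsort((np.arange(k), peak_times))  # stable tie-break by raw id
    rank = np.empty(k, dtype=int)
    rank[order] = np.arange(1, k + 1)
    labels = pd.Series(rank[raw_labels], index=prof.index, name="cluster")
    centroid_df = pd.DataFrame(centroids[order], index=pd.RangeIndex(1, k + 1, name="cluster"), columns=times)

    amplitudes = pd.Series(x.max(axis=1) - x[:, 0], index=prof.index, name="induction_amplitude")
    return ClusterResult(labels=labels, centroids=centroid_df, k=k, seed=seed, amplitudes=amplitudes)


def triage_candidates(result: ClusterResult, target_cluster: int = 1) -> list[str]:
    """Members of the earliest-peaking cluster, ranked by induction amplitude."""
    if not 1 <= target_cluster <= result.k:
        raise ValueError(f"target_cluster must be in 1..{result.k}")
    members = result.members(target_cluster)
    if not members:
        warnings.warn(f"cluster {target_cluster} is empty")
        return []
    return sorted(members, key=lambda g: (-result.amplitudes[g], g))
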