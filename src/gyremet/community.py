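"""Community-level processing: lineage filtering, rarefaction, diversity,
dissimilarity, ordination and the nonparametric tests used for seasonal
contrasts.

The in-memory ASV table is a pandas DataFrame of non-negative integer counts
with samples as rows and ASVs as columns.  Chloroplast- and mitochondria-
derived ASVs are removed before rarefaction; all samples are then subsampled
without replacement to a common depth so that diversity and dissimilarity
statistics are comparable across stations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from gyremet.io import RANKS

__all__ = [
    "remove_lineages",
    "rarefy",
    "richness",
    "shannon",
    "diversity_table",
    "bray_curtis",
    "bray_curtis_matrix",
    "PCoAResult",
    "pcoa",
    "permanova",
    "wilcoxon_ranksum",
    "aggregate_taxa",
]

DEFAULT_BANNED = ("chloroplast", "mitochondria")


def remove_lineages(
    table: pd.DataFrame,
    tax: pd.DataFrame,
    banned: tuple[str, ...] = DEFAULT_BANNED,
) -> tuple[pd.DataFrame, dict]:
    """Drop ASVs whose lineage matches any banned label.

    Matching is case-insensitive substring over all ranks.  ASVs missing from
    the taxonomy are retained and listed in the report.
    """
    if not banned:
        raise ValueError("banned label set must be non-empty")
    banned_lower = [b.lower() for b in banned]

    missing = [a for a in table.columns if a not in tax.index]
    removed = []
    for asv in table.columns:
        if asv not in tax.index:
            continue
        lineage = " ".join(str(v) for v in tax.loc[asv, list(RANKS)]).lower()
        if any(b in lineage for b in banned_lower):
            removed.append(asv)

    filtered = table.drop(columns=removed)
    report = {"removed": removed, "missing_taxonomy": missing}
    return filtered, report


def rarefy(table: pd.DataFrame, depth: int, seed: int) -> tuple[pd.DataFrame, list]:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped and reported.  A sample
    whose total equals ``depth`` is passed through unchanged.  The draw is a
    multivariate hypergeometric per sample, seeded, so repeated calls with the
    same seed are bit-identical.
    """
    if depth < 1:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    kept_ids: list = []
    kept_rows: list[np.ndarray] = []
    dropped: list = []
    for sid in table.index:
        row = table.loc[sid].to_numpy(dtype=np.int64)
        total = int(row.sum())
        if total < depth:
            dropped.append(sid)
            continue
        if total == depth:
            kept_rows.append(row.copy())
        else:
            kept_rows.append(rng.multivariate_hypergeometric(row, depth))
        kept_ids.append(sid)
    out = pd.DataFrame(
        np.asarray(kept_rows, dtype=np.int64) if kept_rows else
        np.empty((0, table.shape[1]), dtype=np.int64),
        index=pd.Index(kept_ids, name=table.index.name),
        columns=table.columns,
    )
    return out, dropped


def richness(counts) -> int:
    """Number of ASVs with at least one read (S)."""
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("empty count vector")
    return int((counts > 0).sum())


def shannon(counts, base: float = math.e) -> float:
    """Shannon entropy H = −Σ p ln p of a count vector (nats by default)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero sample")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum() / math.log(base))


def diversity_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample richness and Shannon index."""
    records = [
        {"sample_id": sid, "richness": richness(row), "shannon": shannon(row)}
        for sid, row in zip(table.index, table.to_numpy())
    ]
    return pd.DataFrame(records, columns=["sample_id", "richness", "shannon"])


def bray_curtis(x, y) -> float:
    """Bray–Curtis dissimilarity Σ|x−y| / Σ(x+y) between two count vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.sum() <= 0 or y.sum() <= 0:
        raise ValueError("Bray-Curtis undefined for an all-zero sample")
    return float(np.abs(x - y).sum() / (x + y).sum())


def bray_curtis_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Square symmetric Bray–Curtis distance matrix over the samples."""
    dist = squareform(pdist(table.to_numpy(dtype=float), metric="braycurtis"))
    return pd.DataFrame(dist, index=table.index, columns=table.index)


@dataclass
class PCoAResult:
    """Classical-scaling result.

    ``coordinates`` holds axes for positive eigenvalues only (columns
    PCo1, PCo2, ...); ``eigenvalues`` reports the full descending spectrum,
    including any negative eigenvalues arising from non-Euclidean distances,
    which are reported but receive no axis.  ``proportion_explained`` is
    relative to the sum of positive eigenvalues.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    @property
    def negative_eigenvalues(self) -> np.ndarray:
        return self.eigenvalues[self.eigenvalues < 0]


def pcoa(dist: pd.DataFrame | np.ndarray, atol: float = 1e-8) -> PCoAResult:
    """Principal coordinate analysis (classical MDS) of a distance matrix.

    Double-centers −½D² and eigendecomposes it; axes are ordered by
    eigenvalue.  For Euclidean input the coordinates reproduce the distances.
    """
    if isinstance(dist, pd.DataFrame):
        ids = dist.index
        d = dist.to_numpy(dtype=float)
    else:
        d = np.asarray(dist, dtype=float)
        ids = pd.RangeIndex(d.shape[0])
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.abs(d - d.T).max(initial=0.0) > atol:
        raise ValueError("distance matrix is not symmetric")
    if np.abs(np.diag(d)).max(initial=0.0) > atol or (d < -atol).any():
        raise ValueError("distance matrix must be non-negative with zero diagonal")

    n = d.shape[0]
    a = -0.5 * d**2
    row_means = a.mean(axis=1, keepdims=True)
    b = a - row_means - row_means.T + a.mean()
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]

    tol = max(np.abs(eigvals).max(initial=0.0), 1.0) * 1e-12
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    pos_sum = eigvals[positive].sum()
    proportion = eigvals[positive] / pos_sum if pos_sum > 0 else eigvals[positive]
    columns = [f"PCo{i + 1}" for i in range(int(positive.sum()))]
    coordinates = pd.DataFrame(coords, index=ids, columns=columns)
    return PCoAResult(coordinates, eigvals, proportion)


def _permanova_f(d2: np.ndarray, masks: list[np.ndarray], sst: float, n: int) -> float:
    ss_within = 0.0
    for mask in masks:
        n_g = int(mask.sum())
        ss_within += d2[np.ix_(mask, mask)].sum() / (2.0 * n_g)
    a = len(masks)
    ss_among = sst - ss_within
    with np.errstate(divide="ignore", invalid="ignore"):
        # zero within-group variance (duplicated points) gives F = inf
        return float((ss_among / (a - 1)) / (ss_within / (n - a)))


def permanova(
    dist: pd.DataFrame | np.ndarray,
    groups,
    n_perm: int = 999,
    seed: int = 0,
    exact: bool = False,
) -> tuple[float, float]:
    """Permutational multivariate ANOVA on a distance matrix.

    The pseudo-F partitions the total sum of squared distances into among- and
    within-group components.  The p-value is ``(1 + #{F_perm >= F_obs}) /
    (1 + n_perm)`` over seeded random relabelings, or an exact proportion over
    all label permutations when ``exact=True`` (feasible for small designs).
    """
    d = dist.to_numpy(dtype=float) if isinstance(dist, pd.DataFrame) else np.asarray(dist, float)
    labels = np.asarray(groups)
    n = d.shape[0]
    if labels.shape[0] != n:
        raise ValueError("grouping length does not match distance matrix")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 members each")
    if not exact and n_perm < 99:
        raise ValueError(f"n_perm must be >= 99, got {n_perm}")

    d2 = d**2
    sst = d2.sum() / (2.0 * n)

    def f_for(lab: np.ndarray) -> float:
        return _permanova_f(d2, [lab == g for g in uniq], sst, n)

    f_obs = f_for(labels)
    if exact:
        if n > 9:
            raise ValueError(f"exact enumeration is infeasible for n={n} (> 9)")
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            lab = labels[list(perm)]
            total += 1
            if f_for(lab) >= f_obs - 1e-12:
                hits += 1
        return f_obs, hits / total

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if f_for(rng.permutation(labels)) >= f_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return f_obs, p


def wilcoxon_ranksum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) test.

    Returns the rank-sum statistic W of the first sample and the two-sided
    p-value: exact enumeration when both samples have n <= 8 and no ties span
    the pooled data, otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0
    return w, float(res.pvalue)


def aggregate_taxa(table: pd.DataFrame, tax: pd.DataFrame, rank: str) -> pd.DataFrame:
    """Relative abundance per taxon at a given rank (rows sum to 1).

    ASVs without an annotation at ``rank`` (empty label or absent from the
    taxonomy) are pooled into ``"Unassigned"``.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = []
    for asv in table.columns:
        if asv in tax.index and str(tax.loc[asv, rank]).strip():
            labels.append(str(tax.loc[asv, rank]))
        else:
            labels.append("Unassigned")
    grouped = table.T.groupby(pd.Index(labels, name=rank)).sum().T
    totals = grouped.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("cannot compute relative abundance for all-zero samples")
    return grouped.div(totals, axis=0)
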