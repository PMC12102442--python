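"""Coupling/decoupling analysis between metabolic rates and community modules.

The central question is whether bacterial production (BP) and respiration
(BR) covary: a survey in which BA and BP move together while BR tracks the
abundance of a particular network module, not BP, shows the two arms of
bacterial carbon processing decoupled.  This module assembles the
correlation panel over Chl a / BA / BP / BR, regresses max-scaled BR on
module abundance per season, and renders a descriptive coupled/decoupled
verdict per variable pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "scale_to_max",
    "linreg",
    "CorrelationPanel",
    "correlation_panel",
    "PCAResult",
    "pca_panel",
    "DecouplingReport",
    "decoupling_report",
]

RATE_VARS = ("chl_a", "ba", "bp", "br")


def scale_to_max(values) -> np.ndarray:
    """Divide a vector by its overall maximum; the maximum maps to 1."""
    values = np.asarray(values, dtype=float)
    m = np.nanmax(values) if values.size else np.nan
    if not np.isfinite(m) or m <= 0:
        raise ValueError(f"maximum must be positive to scale, got {m!r}")
    return values / m


def linreg(x, y) -> dict:
    """Ordinary least squares of y on x.

    Returns slope, intercept, R² (= 1 − SSE/SST, equal to the squared Pearson
    correlation), the two-sided p-value of the slope t-test, and n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need >= 3 complete observations, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2)
    p = float(res.pvalue)
    if np.ptp(y) == 0:  # constant response: slope 0, no variance explained
        r2, p = 0.0, 1.0
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": r2,
        "p": p,
        "n": int(x.size),
    }


def _stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class CorrelationPanel:
    """Pairwise correlation matrix with p-values and significance stars."""

    method: str
    coefficients: pd.DataFrame
    p_values: pd.DataFrame
    stars: pd.DataFrame
    n: pd.DataFrame

    def to_records(self) -> pd.DataFrame:
        """Long form: one row per unordered variable pair."""
        rows = []
        cols = list(self.coefficients.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                rows.append(
                    {
                        "var_a": a,
                        "var_b": b,
                        "coefficient": self.coefficients.loc[a, b],
                        "p": self.p_values.loc[a, b],
                        "stars": self.stars.loc[a, b],
                        "n": self.n.loc[a, b],
                    }
                )
        return pd.DataFrame(rows)


def correlation_panel(variables: pd.DataFrame, method: str = "spearman") -> CorrelationPanel:
    """All-pairs correlations with pairwise-complete observation handling.

    Entries with fewer than 3 complete pairs are recorded as missing.  Stars:
    ``*`` for p < 0.05, ``**`` for p < 0.01 (no correction across the panel).
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"method must be 'spearman' or 'pearson', got {method!r}")
    corr_fn = stats.spearmanr if method == "spearman" else stats.pearsonr
    cols = list(variables.columns)
    k = len(cols)
    coef = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    pval = pd.DataFrame(np.full((k, k), np.nan), index=cols, columns=cols)
    n_df = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    for i, a in enumerate(cols):
        n_df.loc[a, a] = int(variables[a].notna().sum())
        for b in cols[i + 1 :]:
            pair = variables[[a, b]].dropna()
            n_df.loc[a, b] = n_df.loc[b, a] = len(pair)
            if len(pair) < 3:
                coef.loc[a, b] = coef.loc[b, a] = np.nan
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", stats.ConstantInputWarning)
                res = corr_fn(pair[a], pair[b])
            coef.loc[a, b] = coef.loc[b, a] = float(res.statistic)
            pval.loc[a, b] = pval.loc[b, a] = float(res.pvalue)
    stars = pval.map(_stars)
    np.fill_diagonal(stars.values, "")
    return CorrelationPanel(method, coef, pval, stars, n_df)


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # variables x PCs
    scores: pd.DataFrame  # samples x PCs
    pct_variance: np.ndarray  # per axis, sums to 100
    dropped: list = field(default_factory=list)


def pca_panel(matrix: pd.DataFrame) -> PCAResult:
    """Correlation-matrix PCA of a samples × variables panel.

    Columns are z-scored before decomposition (the variables mix units), so
    the eigenvalues are those of the correlation matrix and the reported
    percentages of variance sum to 100 over all axes.  Zero-variance columns
    are dropped with a warning.  Sign convention: within each axis the
    largest-magnitude loading is positive.
    """
    if matrix.shape[0] < 3 or matrix.shape[1] < 2:
        raise ValueError("need >= 3 samples and >= 2 variables")
    sd = matrix.std(axis=0, ddof=1)
    dropped = [c for c in matrix.columns if not np.isfinite(sd[c]) or sd[c] == 0]
    if dropped:
        warnings.warn(f"dropping zero-variance variables: {dropped}", UserWarning)
        matrix = matrix.drop(columns=dropped)
        if matrix.shape[1] < 2:
            raise ValueError("fewer than 2 variables remain after dropping")
    z = (matrix - matrix.mean(axis=0)) / matrix.std(axis=0, ddof=1)
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    for j in range(eigvecs.shape[1]):
        pivot = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[pivot, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    pcs = [f"PC{i + 1}" for i in range(eigvecs.shape[1])]
    loadings = pd.DataFrame(eigvecs, index=matrix.columns, columns=pcs)
    scores = pd.DataFrame(z.to_numpy() @ eigvecs, index=matrix.index, columns=pcs)
    pct = 100.0 * eigvals / eigvals.sum()
    return PCAResult(loadings, scores, pct, dropped)


@dataclass
class DecouplingReport:
    """Descriptive coupling summary; not a causal claim."""

    correlations: CorrelationPanel
    regressions: pd.DataFrame  # season, module, slope, intercept, r2, p, n
    coupled: list
    decoupled: list
    alpha: float


def decoupling_report(
    panel: pd.DataFrame,
    module_abund: pd.DataFrame,
    seasons: pd.Series | None = None,
    method: str = "spearman",
    alpha: float = 0.05,
) -> DecouplingReport:
    """Assemble the rate-coupling panel and per-season module regressions.

    Parameters
    ----------
    panel:
        Samples × variables with at least columns ``chl_a, ba, bp, br``
        (and optionally ``season`` if ``seasons`` is not given).
    module_abund:
        Samples × module z-score abundances (``module_1``, ...).
    seasons:
        Per-sample season labels; regressions of max-scaled BR on each module
        abundance run within each season's analysis set.

    Pairs with p < alpha are labeled coupled, the rest decoupled — a
    descriptive dichotomy at the stated threshold.
    """
    if seasons is None:
        if "season" not in panel.columns:
            raise ValueError("season labels required (column or argument)")
        seasons = panel["season"]
    shared = sorted(set(panel.index) & set(module_abund.index) & set(seasons.index))
    if len(shared) < 3:
        raise ValueError(f"need >= 3 matched samples, got {len(shared)}")
    panel = panel.loc[shared]
    module_abund = module_abund.loc[shared]
    seasons = seasons.loc[shared]

    corr = correlation_panel(panel[list(RATE_VARS)], method=method)

    reg_rows = []
    for season in sorted(seasons.unique()):
        mask = seasons == season
        br = panel.loc[mask, "br"].to_numpy(dtype=float)
        if not np.isfinite(br).any() or np.nanmax(br) <= 0 or np.ptp(br[np.isfinite(br)]) == 0:
            continue  # constant or absent BR: nothing to regress
        br_scaled = scale_to_max(br)
        for module in module_abund.columns:
            x = module_abund.loc[mask, module].to_numpy(dtype=float)
            try:
                fit = linreg(x, br_scaled)
            except ValueError:
                continue
            reg_rows.append({"season": season, "module": module, **fit})
    regressions = pd.DataFrame(
        reg_rows, columns=["season", "module", "slope", "intercept", "r2", "p", "n"]
    )

    coupled, decoupled = [], []
    pairs = corr.to_records()
    for rec in pairs.itertuples(index=False):
        entry = (rec.var_a, rec.var_b, float(rec.p))
        if np.isnan(rec.p):
            continue
        (coupled if rec.p < alpha else decoupled).append(entry)
    return DecouplingReport(corr, regressions, coupled, decoupled, alpha)
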