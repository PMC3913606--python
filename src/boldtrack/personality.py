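"""PC1-based personality scores.

Two behavioural axes are scored the same way: *boldness* collapses the
novel-object ethogram counts (pecks, lunges, vocalisations, snaps, seconds
sitting) and the *foraging personality score* collapses the four trip
metrics (duration, range, northerly and southerly latitude extents).  Both
use the first principal component of the correlation matrix, oriented so
the behavioural-intensity marker (pecking, respectively foraging range)
loads positive.  Per-individual scores come from fixed-effect linear models
and are mean-centred across birds so fitness models estimate selection
gradients on the trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

BOLDNESS_VARS = ["peck_count", "lunge_count", "vocalise_count", "snap_count", "sitting_s"]
FORAGING_VARS = ["duration_h", "max_range_km", "max_lat_north", "max_lat_south"]

# which variable anchors the PC1 sign for each score
SIGN_ANCHOR = {"boldness": "peck_count", "foraging": "max_range_km"}


@dataclass
class PCAResult:
    variables: list[str]
    loadings: np.ndarray  # (p, p), columns = components, orthonormal
    eigenvalues: np.ndarray  # descending; sums to p (correlation PCA)
    proportion_variance: np.ndarray
    means: np.ndarray
    scales: np.ndarray  # sample std, ddof=1


def pca_correlation(df: pd.DataFrame, variables: list[str], sign_anchor: str | None = None) -> PCAResult:
    """PCA of the correlation matrix (standardised variables).

    Rows with missing cells are dropped with a log entry; a constant column
    is an error (its correlation is undefined).  PC1 is oriented so
    ``sign_anchor`` loads positive; remaining components are oriented so
    their largest-|loading| variable is positive, which makes the
    decomposition reproducible under row permutation.
    """
    X = df[variables]
    n0 = len(X)
    X = X.dropna()
    if len(X) < n0:
        logger.info("PCA: dropped %d row(s) with missing cells", n0 - len(X))
    if len(X) < 2:
        raise ValueError("PCA needs at least 2 complete rows")
    M = X.to_numpy(float)
    means = M.mean(axis=0)
    scales = M.std(axis=0, ddof=1)
    const = np.flatnonzero(scales == 0)
    if len(const):
        raise ValueError(f"constant column(s): {[variables[i] for i in const]}")
    Z = (M - means) / scales
    R = np.corrcoef(Z, rowvar=False)
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    w = np.clip(w, 0.0, None)
    # sign conventions
    for k in range(V.shape[1]):
        if k == 0 and sign_anchor is not None:
            j = variables.index(sign_anchor)
        else:
            j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
    return PCAResult(
        variables=list(variables),
        loadings=V,
        eigenvalues=w,
        proportion_variance=w / len(variables),
        means=means,
        scales=scales,
    )


def project_pc1(result: PCAResult, df: pd.DataFrame) -> np.ndarray:
    """Score each row on PC1: standardised row · PC1 loading vector."""
    missing = [v for v in result.variables if v not in df.columns]
    if missing:
        raise ValueError(f"missing variable(s) for projection: {missing}")
    Z = (df[result.variables].to_numpy(float) - result.means) / result.scales
    return Z @ result.loadings[:, 0]


def individual_boldness(obs: pd.DataFrame, score_col: str = "pc1") -> pd.Series:
    """Per-bird boldness from a fixed-effect linear model, mean-centred.

    The observation score is regressed on observation number (first or
    second test of the bird), date (day of season, numeric) and bird
    identity (sum-to-zero contrasts, so the covariate effects stay
    identifiable); the bird effects are returned, centred across birds.
    Degenerate covariates (a single distinct value) are dropped with a
    warning.
    """
    df = obs.copy()
    if np.issubdtype(df["date"].dtype, np.datetime64):
        df["date"] = (df["date"] - df["date"].min()).dt.days.astype(float)
    covars = []
    for c in ("obs_number", "date"):
        if df[c].nunique() > 1:
            covars.append(c)
        else:
            logger.warning("individual_boldness: covariate %r constant, dropped", c)
    birds = np.sort(df["bird_id"].unique())
    if len(birds) < 2:
        raise ValueError("need at least 2 birds")
    y = df[score_col].to_numpy(float)
    n, b = len(df), len(birds)
    bird_idx = pd.Categorical(df["bird_id"], categories=birds).codes
    # sum-to-zero bird contrasts: b-1 columns, last bird = -sum of others
    B = np.zeros((n, b - 1))
    for j in range(b - 1):
        B[bird_idx == j, j] = 1.0
    B[bird_idx == b - 1, :] = -1.0
    X = np.column_stack([np.ones(n)] + [df[c].to_numpy(float) for c in covars] + [B])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    eff = np.concatenate([beta[-(b - 1):], [-beta[-(b - 1):].sum()]])
    eff = eff - eff.mean()
    return pd.Series(eff, index=birds, name="boldness")


def individual_foraging_score(trip_scores: pd.DataFrame, score_col: str = "pc1") -> pd.Series:
    """Per-bird foraging personality: fixed-effect fit of trip PC1 on bird
    identity, which for this one-factor design equals the per-bird mean
    (asserted); mean-centred across birds."""
    means = trip_scores.groupby("bird_id")[score_col].mean()
    # fixed-effect route, kept as a structural check of the equivalence
    birds = means.index.to_numpy()
    codes = pd.Categorical(trip_scores["bird_id"], categories=birds).codes
    X = np.zeros((len(trip_scores), len(birds)))
    X[np.arange(len(trip_scores)), codes] = 1.0
    beta, *_ = np.linalg.lstsq(X, trip_scores[score_col].to_numpy(float), rcond=None)
    assert np.allclose(beta, means.to_numpy(), atol=1e-9), "fixed-effect fit != group means"
    out = means - means.mean()
    return out.rename("foraging_score")


def score_correlation(boldness: pd.Series, foraging: pd.Series):
    """Spearman rank correlation between the two personality scores on
    birds holding both (average ranks for ties; t-approximation p)."""
    joined = pd.concat([boldness, foraging], axis=1, join="inner").dropna()
    if len(joined) < 4:
        raise ValueError(f"need >= 4 paired scores, have {len(joined)}")
    rho, p = stats.spearmanr(joined.iloc[:, 0], joined.iloc[:, 1])
    return float(rho), float(p)
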