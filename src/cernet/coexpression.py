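"""lincRNA-mRNA coexpression network: Pearson r with an |r| >= 0.85 screen.

Edges are retained purely on the magnitude of the sample Pearson
correlation between expression profiles; the p-value (t transform with
n - 2 degrees of freedom) is computed and reported but plays no role in
screening.  Negative correlations survive via the absolute value, and the
edge sign is recorded.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.85


def pearson_edge(x, y) -> tuple[float, float]:
    """Sample Pearson r and two-sided p for one candidate edge.

    Raises InputError for unequal lengths, n < 3, or a constant profile
    (callers treat the latter as 'edge skipped: constant profile').
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("profiles have different lengths")
    if x.size < 3:
        raise InputError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("constant profile")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def build_network(
    linc_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs bipartite correlation screen between two expression matrices.

    Both matrices are features x samples over identical sample columns.
    Returns (edges, degree summary); edges have columns lincRNA, mRNA, r, p,
    sign and satisfy |r| >= threshold.  Zero-variance features are skipped
    with a log message; features with no retained edge do not appear in the
    degree summary.
    """
    if list(linc_expr.columns) != list(mrna_expr.columns):
        raise InputError("sample columns differ between the two matrices")
    n = linc_expr.shape[1]
    if n < 3:
        raise InputError("need at least 3 samples")

    def standardise(df):
        mat = df.to_numpy(dtype=float)
        sd = mat.std(axis=1, ddof=1)
        keep = sd > 0
        dropped = df.index[~keep]
        if len(dropped):
            logger.info("skipped %d constant profiles", len(dropped))
        mat = mat[keep]
        z = (mat - mat.mean(axis=1, keepdims=True)) / sd[keep, None]
        return df.index[keep], z

    linc_ids, zl = standardise(linc_expr)
    mrna_ids, zm = standardise(mrna_expr)
    r = zl @ zm.T / (n - 1)
    np.clip(r, -1.0, 1.0, out=r)

    ii, jj = np.nonzero(np.abs(r) >= threshold)
    rv = r[ii, jj]
    with np.errstate(divide="ignore"):
        t = rv * np.sqrt((n - 2) / np.maximum(1.0 - rv**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    edges = pd.DataFrame(
        {
            "lincRNA": linc_ids[ii],
            "mRNA": mrna_ids[jj],
            "r": rv,
            "p": p,
            "sign": np.where(rv >= 0, "positive", "negative"),
        }
    ).sort_values(["lincRNA", "mRNA"], kind="stable").reset_index(drop=True)

    degree = pd.concat(
        [
            edges.groupby("lincRNA").size().rename("degree"),
            edges.groupby("mRNA").size().rename("degree"),
        ]
    ).rename_axis("node").reset_index()
    return edges, degree


def edge_sign_counts(edges: pd.DataFrame) -> dict[str, int]:
    """Positive/negative edge decomposition of a network."""
    counts = edges["sign"].value_counts()
    return {
        "positive": int(counts.get("positive", 0)),
        "negative": int(counts.get("negative", 0)),
        "total": int(len(edges)),
    }
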