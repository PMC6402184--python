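"""Differential expression on pooled count libraries.

The test statistic is the Audic-Claverie exact count comparison: given a
feature observed ``x`` times in a library of size ``N1``, the count ``y`` in
a second library of size ``N2`` follows

    P(Y = y | x) = rho^y (x+y)! / (x! y! (1+rho)^(x+y+1)),   rho = N2/N1,

which is exactly a negative-binomial distribution with ``x+1`` successes and
success probability ``1/(1+rho)``.  Two-sided p-values double the smaller
tail and cap at 1.  Effect sizes are RPKM fold changes with a pseudocount;
multiplicity is controlled per feature class with Benjamini-Hochberg
q-values; the screening standard is |log2 fold change| >= 1 with q < 0.001
for lncRNA/mRNA and q < 0.05 for miRNA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, DomainError, InputError

logger = logging.getLogger(__name__)

GROUPS = ("case", "control")
FEATURE_CLASSES = ("lncRNA", "miRNA", "mRNA")


@dataclass
class CountMatrix:
    """Non-negative integer counts, features x samples, with sample groups.

    ``library_size`` defaults to per-sample column sums but may be supplied
    externally (e.g. total mapped reads); it is not required to dominate the
    column sum.
    """

    counts: pd.DataFrame
    groups: pd.Series
    feature_length: pd.Series
    feature_class: pd.Series
    library_size: pd.Series | None = None

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise InputError("negative counts")
        if self.counts.index.duplicated().any():
            raise InputError("duplicate feature ids")
        if self.counts.columns.duplicated().any():
            raise InputError("duplicate sample ids")
        unknown = set(self.groups.unique()) - set(GROUPS)
        if unknown:
            raise InputError(f"unknown group labels: {sorted(unknown)}")
        if set(self.groups.index) != set(self.counts.columns):
            raise InputError("group labels do not match sample columns")
        if self.library_size is None:
            self.library_size = self.counts.sum(axis=0)
        if (self.library_size <= 0).any():
            raise InputError("library sizes must be positive")

    @property
    def feature_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])


def rpkm(count, feature_length, library_size):
    """Reads per kilobase of transcript per million mapped reads.

    count x 1e9 / (feature_length x library_size); vectorised over arrays.
    """
    feature_length = np.asarray(feature_length, dtype=float)
    library_size = np.asarray(library_size, dtype=float)
    if (feature_length <= 0).any():
        raise DomainError("feature_length must be positive")
    if (library_size <= 0).any():
        raise DomainError("library_size must be positive")
    return np.asarray(count, dtype=float) * 1e9 / (feature_length * library_size)


def ac_pvalue(x, y, n1, n2):
    """Two-sided Audic-Claverie p-value for counts in two libraries.

    Evaluated through the negative-binomial identity above (regularised
    incomplete beta under the hood), so it is stable for counts up to ~1e5
    and beyond.  Accepts scalars or arrays.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if (x < 0).any() or (y < 0).any():
        raise DomainError("counts must be non-negative")
    if n1 <= 0 or n2 <= 0:
        raise DomainError("library sizes must be positive")
    rho = n2 / n1
    p_success = 1.0 / (1.0 + rho)
    lower = stats.nbinom.cdf(y, x + 1, p_success)   # P(Y <= y | x)
    upper = stats.nbinom.sf(y - 1, x + 1, p_success)  # P(Y >= y | x)
    p = 2.0 * np.minimum(lower, upper)
    return np.minimum(p, 1.0) if p.ndim else min(float(p), 1.0)


def bh_adjust(pvals):
    """Benjamini-Hochberg step-up q-values, in input order."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if ((pvals < 0) | (pvals > 1)).any():
        raise DomainError("p-values must lie in [0, 1]")
    return multipletests(pvals, method="fdr_bh")[1]


@dataclass
class DEThresholds:
    """Screening standard: effect-size gate plus class-specific q cutoffs."""

    min_abs_log2fc: float = 1.0
    max_q: dict = field(
        default_factory=lambda: {"lncRNA": 1e-3, "mRNA": 1e-3, "miRNA": 0.05}
    )


def classify_de(log2fc: float, q: float, feature_class: str,
                thresholds: DEThresholds | None = None) -> str:
    """'up' / 'down' / 'ns' under the class-specific screening standard."""
    thresholds = thresholds or DEThresholds()
    if feature_class not in thresholds.max_q:
        raise ConfigError(f"unknown feature class: {feature_class!r}")
    if q < thresholds.max_q[feature_class]:
        if log2fc >= thresholds.min_abs_log2fc:
            return "up"
        if log2fc <= -thresholds.min_abs_log2fc:
            return "down"
    return "ns"


def run_de(cm: CountMatrix, thresholds: DEThresholds | None = None,
           pseudocount_rpkm: float = 0.1) -> pd.DataFrame:
    """Pool samples per group, test each feature, screen, and rank by q.

    Returns one row per feature with columns feature, class, rpkm_case,
    rpkm_control, fold_change (magnitude, >= 1), log2fc, p, q, direction.
    q-values are computed within each feature class.  Features with missing
    or non-positive length are skipped with a warning.
    """
    thresholds = thresholds or DEThresholds()
    case = cm.samples_in("case")
    control = cm.samples_in("control")
    if not case or not control:
        raise InputError("need at least one sample in each group")

    lengths = cm.feature_length.reindex(cm.feature_ids)
    ok = lengths.notna() & (lengths > 0)
    if (~ok).any():
        logger.warning("skipping %d features with missing length", int((~ok).sum()))
    ids = cm.feature_ids[ok]

    x = cm.counts.loc[ids, case].sum(axis=1).to_numpy()
    y = cm.counts.loc[ids, control].sum(axis=1).to_numpy()
    n1 = float(cm.library_size[case].sum())
    n2 = float(cm.library_size[control].sum())

    rpkm_case = rpkm(x, lengths[ok], n1)
    rpkm_control = rpkm(y, lengths[ok], n2)
    log2fc = np.log2((rpkm_case + pseudocount_rpkm)
                     / (rpkm_control + pseudocount_rpkm))
    p = ac_pvalue(x, y, n1, n2)

    table = pd.DataFrame(
        {
            "feature": ids,
            "class": cm.feature_class.reindex(ids).to_numpy(),
            "rpkm_case": rpkm_case,
            "rpkm_control": rpkm_control,
            "fold_change": np.power(2.0, np.abs(log2fc)),
            "log2fc": log2fc,
            "p": p,
        }
    )
    table["q"] = np.nan
    for cls, idx in table.groupby("class").groups.items():
        table.loc[idx, "q"] = bh_adjust(table.loc[idx, "p"].to_numpy())
    table["direction"] = [
        classify_de(lfc, q, cls, thresholds)
        for lfc, q, cls in zip(table["log2fc"], table["q"], table["class"])
    ]
    return table.sort_values(["q", "feature"], kind="stable").reset_index(drop=True)
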