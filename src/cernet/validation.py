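"""Statistics for the wet-lab validation arm.

Relative qPCR quantification by the Livak 2^-ddCt method against a
reference gene and a control group; Welch's t test for two-group
comparisons; Spearman rank correlation for biomarker-vs-clinical-score
association (e.g. IFN-alpha against the SLEDAI activity index).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, InputError


def ddct_fold_change(records: pd.DataFrame) -> pd.Series:
    """Per-sample 2^-ddCt fold change relative to the control-group mean.

    ``records`` needs columns sample, group ('case'/'control'), target_ct,
    reference_ct.  dCt = target - reference per sample; ddCt subtracts the
    mean control dCt; fold change = 2^-ddCt.  Returned for every sample
    (controls included, so their geometric mean is exactly 1).
    """
    required = {"sample", "group", "target_ct", "reference_ct"}
    if not required <= set(records.columns):
        raise InputError(f"missing columns: {sorted(required - set(records.columns))}")
    controls = records[records["group"] == "control"]
    if controls.empty:
        raise DomainError("no control samples")
    dct = records["target_ct"] - records["reference_ct"]
    ddct = dct - (controls["target_ct"] - controls["reference_ct"]).mean()
    return pd.Series(
        np.power(2.0, -ddct.to_numpy()), index=records["sample"], name="fold_change"
    )


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InputError("vectors have different lengths")
    if x.size < 3:
        raise InputError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def two_group_test(case, control, pooled: bool = False) -> tuple[float, float]:
    """Two-sided t test; Welch (unequal variance) unless ``pooled``.

    Two identical groups return (0.0, 1.0) rather than the 0/0 indeterminate
    form.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.size < 2 or control.size < 2:
        raise DomainError("each group needs at least 2 observations")
    if (case.mean() == control.mean()
            and np.ptp(case) == 0 and np.ptp(control) == 0):
        return 0.0, 1.0
    t, p = stats.ttest_ind(case, control, equal_var=pooled)
    return float(t), float(p)
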