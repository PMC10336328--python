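"""Statistical comparisons for dose-response tables.

One-way ANOVA with Tukey HSD across treatment arms, Pearson correlations,
and the z-score linear-regression coefficient that couples hemolysis to
fibrinolysis: both readouts are z-scored across the pressure sweep and fit
with a least-squares line; the slope (equal to the Pearson correlation of
the raw pairs) is ~1 when histotripsy promotes hemolysis and fibrinolysis
proportionally, and is undefined when one readout has zero variance (e.g.
nearly pure-fibrin sections where hemoglobin never changes).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["anova_tukey", "pearson", "linear_regression_coefficient"]


def anova_tukey(groups: dict[str, np.ndarray], alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA F test plus Tukey-HSD-adjusted pairwise decisions.

    Returns a table with one row per group pair: mean difference, adjusted
    p-value and the reject decision at ``alpha``; the F statistic and its
    p-value are attached as DataFrame attrs.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("each group needs at least two samples")
    f_stat, f_p = sps.f_oneway(*arrays.values())
    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * a.size for k, a in arrays.items()])
    tk = pairwise_tukeyhsd(values, labels, alpha=alpha)
    table = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
    table.attrs["f_statistic"] = float(f_stat)
    table.attrs["f_pvalue"] = float(f_p)
    return table


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; raises on degenerate input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(sps.pearsonr(x, y).statistic)


def linear_regression_coefficient(hemoglobin: np.ndarray, fdp: np.ndarray) -> float:
    """Slope of the least-squares line through z-scored (Hg, FDP) pairs.

    Returns NaN (reported as missing, never coerced to 0) when either
    variable has zero variance across the sweep.
    """
    hg = np.asarray(hemoglobin, dtype=float)
    fd = np.asarray(fdp, dtype=float)
    if hg.size != fd.size or hg.size < 2:
        raise ValueError("need paired samples of size >= 2")
    s_h, s_f = hg.std(), fd.std()
    if s_h == 0 or s_f == 0:
        return float("nan")
    zh = (hg - hg.mean()) / s_h
    zf = (fd - fd.mean()) / s_f
    return float(np.polyfit(zh, zf, 1)[0])
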