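"""Task modulation of the pupil response (the ANTI-effect).

For each pupil measure, the per-participant effect is the ANTI-condition
median minus the PRO-condition median; the group-level null of zero median
effect is tested with the two-sided Wilcoxon signed-rank test at
alpha = 0.05 (exact null distribution at small n, normal approximation
with continuity correction otherwise; zero effects dropped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import MEASURE_NAMES

__all__ = ["AntiEffectResult", "anti_effect", "anti_effect_test",
           "anti_effect_table"]


@dataclass
class AntiEffectResult:
    measure: str
    effects: np.ndarray          # per-participant ANTI - PRO
    n: int                       # non-zero effects used by the test
    statistic: float             # Wilcoxon signed-rank W
    p_value: float
    significant: bool            # p < alpha
    degenerate: bool = False     # all effects zero


def anti_effect(medians: pd.DataFrame,
                measures: list[str] | None = None) -> pd.DataFrame:
    """Per-participant ANTI - PRO effects from condition medians.

    Parameters
    ----------
    medians : DataFrame
        One row per (participant, condition); must contain ``id`` and
        ``condition`` columns plus measure columns.  Participants missing
        either condition median for a measure are omitted for that
        measure.

    Returns
    -------
    DataFrame indexed by participant id, one column per measure, holding
    ANTI - PRO (NaN where either condition median is undefined).
    """
    if measures is None:
        measures = [m for m in MEASURE_NAMES if m in medians.columns]
    wide = medians.pivot(index="id", columns="condition", values=measures)
    out = {}
    for m in measures:
        if ("ANTI" not in wide[m].columns) or ("PRO" not in wide[m].columns):
            out[m] = pd.Series(np.nan, index=wide.index)
            continue
        out[m] = wide[(m, "ANTI")] - wide[(m, "PRO")]
    return pd.DataFrame(out)


def anti_effect_test(effects: np.ndarray, measure: str = "",
                     alpha: float = 0.05,
                     exact_max_n: int = 25) -> AntiEffectResult:
    """Wilcoxon signed-rank test of the effects against zero.

    Zero effects are dropped (standard signed-rank practice); the exact
    null distribution is used for n <= ``exact_max_n`` when there are no
    ties, the normal approximation with continuity correction above.
    """
    x = np.asarray(effects, dtype=float)
    x = x[np.isfinite(x)]
    nonzero = x[x != 0.0]
    if nonzero.size == 0:
        return AntiEffectResult(measure=measure, effects=x, n=0,
                                statistic=np.nan, p_value=1.0,
                                significant=False, degenerate=True)
    if nonzero.size < 6:
        raise ValueError("need at least 6 non-zero effects for the "
                         "signed-rank test")
    ties = np.unique(np.abs(nonzero)).size < nonzero.size
    if nonzero.size <= exact_max_n and not ties:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(nonzero, zero_method="wilcox", correction=True,
                         alternative="two-sided", method=method)
    return AntiEffectResult(
        measure=measure, effects=x, n=int(nonzero.size),
        statistic=float(res.statistic), p_value=float(res.pvalue),
        significant=bool(res.pvalue < alpha))


def anti_effect_table(effects: pd.DataFrame,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Group-level ANTI-effect summary, one row per measure."""
    rows = []
    for m in effects.columns:
        x = effects[m].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        res = anti_effect_test(x, measure=m, alpha=alpha)
        rows.append({
            "measure": m, "n": res.n,
            "median_effect": float(np.median(x)) if x.size else np.nan,
            "wilcoxon_w": res.statistic, "p_value": res.p_value,
            "significant": res.significant})
    return pd.DataFrame(rows)
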