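"""Cohort-level metric summaries with t-distribution confidence intervals."""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["summarize", "summarize_cohort"]


def summarize(values: Sequence[float], confidence: float = 0.95
              ) -> Dict[str, Optional[float]]:
    """Mean, sample SD, and t-based CI for one metric across subjects.

    CI = mean +/- t_{(1+c)/2, n-1} * SD / sqrt(n).  With n < 2 the CI is
    undefined and flagged (ci bounds None); constant samples collapse the
    CI onto the mean.
    """
    vals = np.asarray([v for v in values if v is not None], dtype=float)
    n = vals.size
    if n == 0:
        raise ValueError("summarize requires at least one value")
    mean = float(vals.mean())
    if n < 2:
        return {"mean": mean, "sd": None, "ci_low": None, "ci_high": None,
                "n": n}
    sd = float(vals.std(ddof=1))
    tcrit = float(stats.t.ppf(0.5 + confidence / 2.0, n - 1))
    half = tcrit * sd / np.sqrt(n)
    return {"mean": mean, "sd": sd, "ci_low": mean - half,
            "ci_high": mean + half, "n": n}


def summarize_cohort(subject_rows: Iterable[List[dict]]) -> pd.DataFrame:
    """Aggregate per-subject metric rows into a summary table.

    Parameters
    ----------
    subject_rows:
        One list of rows per subject, as produced by
        :func:`avpseg.metrics.evaluate_subject`.

    Returns
    -------
    DataFrame with columns structure, metric, mean, ci_low, ci_high, sd, n.
    """
    from .metrics import METRIC_NAMES

    pooled: Dict[tuple, List[float]] = {}
    for rows in subject_rows:
        for row in rows:
            for metric in METRIC_NAMES:
                val = row.get(metric)
                if val is not None:
                    pooled.setdefault((row["structure"], metric), []).append(
                        float(val))
    records = []
    for (structure, metric), vals in pooled.items():
        s = summarize(vals)
        records.append({"structure": structure, "metric": metric,
                        "mean": s["mean"], "ci_low": s["ci_low"],
                        "ci_high": s["ci_high"], "sd": s["sd"], "n": s["n"]})
    return pd.DataFrame.from_records(
        records, columns=["structure", "metric", "mean", "ci_low",
                          "ci_high", "sd", "n"])
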