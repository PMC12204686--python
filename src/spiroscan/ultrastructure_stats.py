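"""Statistics for spirosome length and conformation measurements.

Negative-stain measurements of spirosome populations are compared with a
rank-based two-sample test: the Mann-Whitney U statistic with midranks for
ties, an exact permutation p-value for small samples (full enumeration of
label assignments) and a tie- and continuity-corrected normal approximation
otherwise.  Two-sided p-values double the smaller one-sided tail, capped at
one.  The module also provides per-group length summaries (including the
fraction of spirosomes longer than a threshold, 100 nm by default) and
conformation proportions with Wilson score intervals.

The test is implemented here rather than delegated so that the exact
small-sample path and its tie handling are fully specified; scipy's
implementation serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb, erf, sqrt
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "LengthDataset",
    "RankTestResult",
    "mann_whitney_u",
    "length_summary",
    "conformation_proportions",
    "wilson_interval",
    "read_length_csv",
]

EXACT_LIMIT = 12  # n1 + n2 at or below this uses full enumeration in "auto"


@dataclass
class LengthDataset:
    groups: dict[str, np.ndarray]                       # label -> lengths (nm)
    conformations: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("dataset needs at least one group")
        for label, vals in self.groups.items():
            vals = np.asarray(vals, dtype=float)
            if len(vals) == 0:
                raise ValueError(f"group {label!r} has no measurements")
            if np.any(vals <= 0):
                raise ValueError(f"group {label!r} contains non-positive lengths")
            self.groups[label] = vals


@dataclass
class RankTestResult:
    U: float
    p_two_sided: float
    method: str        # "exact" | "normal_approx"
    n1: int
    n2: int


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x, from midrank sums (ties get average ranks)."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def _exact_p(pooled: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided exact p by enumerating all assignments of labels to values."""
    n = len(pooled)
    ranks = rankdata(pooled)
    total = comb(n, n1)
    le = ge = 0
    tol = 1e-9
    for idx in combinations(range(n), n1):
        r1 = ranks[list(idx)].sum()
        u = r1 - n1 * (n1 + 1) / 2.0
        if u <= u_obs + tol:
            le += 1
        if u >= u_obs - tol:
            ge += 1
    p = 2.0 * min(le, ge) / total
    return min(1.0, p)


def _normal_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided normal approximation with tie correction and continuity correction."""
    n1, n2 = len(x), len(y)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return 1.0
    sigma = sqrt(sigma2)
    # continuity correction toward the mean
    z = (u_obs - mu - 0.5 * np.sign(u_obs - mu)) / sigma if u_obs != mu else 0.0
    p_one = 0.5 * (1.0 - erf(abs(z) / sqrt(2.0)))
    return min(1.0, 2.0 * p_one)


def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "auto",
) -> RankTestResult:
    """Two-sided Mann-Whitney U test.

    ``method`` is ``"auto"`` (exact when n1+n2 <= 12, else normal
    approximation), ``"exact"`` or ``"normal_approx"``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    if method not in ("auto", "exact", "normal_approx"):
        raise ValueError(f"unknown method {method!r}")
    n1, n2 = len(x), len(y)
    u = _u_statistic(x, y)
    if method == "auto":
        method = "exact" if n1 + n2 <= EXACT_LIMIT else "normal_approx"
    if method == "exact":
        p = _exact_p(np.concatenate([x, y]), n1, u)
    else:
        p = _normal_p(x, y, u)
    return RankTestResult(U=u, p_two_sided=p, method=method, n1=n1, n2=n2)


def length_summary(data: LengthDataset, long_threshold: float = 100.0) -> pd.DataFrame:
    """Per-group n, mean, SD, median and fraction of lengths above a threshold (nm)."""
    rows = []
    for label, vals in data.groups.items():
        rows.append({
            "group": label,
            "n": len(vals),
            "mean_nm": float(vals.mean()),
            "sd_nm": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            "median_nm": float(np.median(vals)),
            f"fraction_gt_{int(long_threshold)}nm": float((vals > long_threshold).mean()),
        })
    return pd.DataFrame(rows).set_index("group")


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be > 0")
    from scipy.stats import norm
    z = float(norm.ppf(0.5 + conf / 2.0))
    p = k / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return max(0.0, centre - half), min(1.0, centre + half)


def conformation_proportions(
    counts: dict[str, dict[str, int]],
    conf: float = 0.95,
) -> pd.DataFrame:
    """Extended/compact fractions per group with Wilson intervals.

    ``counts`` maps group label -> {conformation: count}.
    """
    rows = []
    for group, by_class in counts.items():
        total = sum(by_class.values())
        if total <= 0:
            raise ValueError(f"group {group!r} has zero total count")
        for cls, k in by_class.items():
            lo, hi = wilson_interval(k, total, conf)
            rows.append({
                "group": group, "conformation": cls, "count": k, "total": total,
                "fraction": k / total, "ci_low": lo, "ci_high": hi,
            })
    return pd.DataFrame(rows)


def read_length_csv(path) -> LengthDataset:
    """Read measurements from a CSV with columns group, length_nm[, conformation]."""
    df = pd.read_csv(path)
    required = {"group", "length_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    groups = {str(g): sub["length_nm"].to_numpy(dtype=float) for g, sub in df.groupby("group", sort=False)}
    confs = {}
    if "conformation" in df.columns:
        confs = {str(g): sub["conformation"].astype(str).tolist() for g, sub in df.groupby("group", sort=False)}
    return LengthDataset(groups=groups, conformations=confs)
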