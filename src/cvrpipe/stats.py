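"""Two-group statistics for small cohorts split by glycemic control.

Implements the inference layer the way small-sample clinical packages report
it: Mann-Whitney U with mean ranks, the tie-corrected asymptotic z (no
continuity correction), and an exact two-sided p from the full null
distribution; Fisher's exact test by two-sided point-probability summation;
and Pearson's product-moment correlation with a t-based p.

Subjects are grouped by HbA1c at the time of acute stroke: > 7% is the
chronic-hyperglycemia group, otherwise (including exactly 7.0%) controlled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

HBA1C_SPLIT = 7.0
_MAX_ENUMERATION = 200_000  # subsets; caps the tied-data exact permutation

log = logging.getLogger(__name__)

__all__ = [
    "HBA1C_SPLIT",
    "RankTestResult",
    "split_by_hba1c",
    "midranks",
    "u_null_counts",
    "u_to_z",
    "mann_whitney",
    "mean_rank_from_u",
    "fisher_exact_2x2",
    "pearson_r",
    "summarize_table1",
]


@dataclass
class RankTestResult:
    n1: int
    n2: int
    u: float                  # U statistic for the first group
    u_complement: float       # n1*n2 - u (U for the second group)
    mean_rank_1: float
    mean_rank_2: float
    z: float                  # tie-corrected, no continuity correction
    p_exact: float | None     # None when ties make enumeration infeasible
    p_asymptotic: float

    @property
    def p(self) -> float:
        return self.p_exact if self.p_exact is not None else self.p_asymptotic


def split_by_hba1c(profiles, threshold: float = HBA1C_SPLIT):
    """Partition subjects into (controlled, hyperglycemic) by HbA1c.

    High group iff hba1c > threshold; exactly ``threshold`` counts as
    controlled.  Subjects with missing HbA1c are excluded with a warning.
    """
    low, high = [], []
    for p in profiles:
        a1c = getattr(p, "hba1c", None)
        if a1c is None or (isinstance(a1c, float) and math.isnan(a1c)):
            log.warning("subject %s has no HbA1c; excluded from grouping",
                        getattr(p, "subject_id", "?"))
            continue
        (high if a1c > threshold else low).append(p)
    return low, high


def midranks(values) -> np.ndarray:
    """Ranks 1..N with ties sharing the average of the ranks they span."""
    return sps.rankdata(np.asarray(values, dtype=float), method="average")


def u_null_counts(n1: int, n2: int) -> list:
    """Exact null distribution of U as integer counts over 0..n1*n2.

    Uses the standard recursion c(a, b, u) = c(a-1, b, u-b) + c(a, b-1, u)
    in exact integer arithmetic; counts sum to C(n1+n2, n1).
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("group sizes must be nonnegative")
    row = [[1] for _ in range(n2 + 1)]          # a = 0: U is always 0
    for a in range(1, n1 + 1):
        new = [[1]]                             # b = 0: U is always 0
        for b in range(1, n2 + 1):
            prev_ab = row[b]                    # c(a-1, b, .)
            left = new[b - 1]                   # c(a, b-1, .)
            size = a * b + 1
            cur = [0] * size
            for u in range(size):
                s = left[u] if u < len(left) else 0
                if 0 <= u - b < len(prev_ab):
                    s += prev_ab[u - b]
                cur[u] = s
            new.append(cur)
        row = new
    return row[n2]


def u_to_z(u: float, n1: int, n2: int, tie_term: float = 0.0) -> float:
    """Standard-normal deviate of U under H0, without continuity correction.

    ``tie_term`` is sum(t^3 - t) over tie groups in the pooled sample (0 for
    continuous data).
    """
    n = n1 + n2
    mu = n1 * n2 / 2.0
    var = (n1 * n2 / 12.0) * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return float("nan")
    return (u - mu) / math.sqrt(var)


def _exact_p_no_ties(u: int, n1: int, n2: int) -> float:
    counts = u_null_counts(n1, n2)
    total = comb(n1 + n2, n1)
    lo = sum(counts[: u + 1])
    hi = sum(counts[u:])
    return min(1.0, 2.0 * min(lo, hi) / total)


def _exact_p_with_ties(ranks: np.ndarray, u_obs: float, n1: int) -> float | None:
    n = len(ranks)
    if comb(n, n1) > _MAX_ENUMERATION:
        return None
    offset = n1 * (n1 + 1) / 2.0
    lo = hi = 0
    total = 0
    for idx in combinations(range(n), n1):
        u = sum(ranks[i] for i in idx) - offset
        total += 1
        if u <= u_obs + 1e-9:
            lo += 1
        if u >= u_obs - 1e-9:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def mann_whitney(group_a, group_b) -> RankTestResult:
    """Mann-Whitney U test; ``u`` and ``mean_rank_1`` refer to ``group_a``.

    The exact two-sided p doubles the smaller tail (point mass included) and
    caps at 1; with ties it enumerates all group assignments of the midranks
    when feasible, otherwise ``p_exact`` is None.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be nonempty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("inputs must be finite")
    n1, n2 = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = midranks(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0
    u2 = n1 * n2 - u1

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3) - tie_counts).sum())
    z = u_to_z(u1, n1, n2, tie_term)
    p_asym = 2.0 * sps.norm.sf(abs(z)) if math.isfinite(z) else float("nan")

    if tie_term == 0 and n1 * n2 <= 2500:
        p_exact = _exact_p_no_ties(int(round(u1)), n1, n2)
    elif tie_term > 0:
        p_exact = _exact_p_with_ties(ranks, u1, n1)
    else:
        p_exact = None  # exact enumeration infeasible; asymptotic stands in

    return RankTestResult(
        n1=n1, n2=n2, u=u1, u_complement=u2,
        mean_rank_1=r1 / n1,
        mean_rank_2=float(ranks[n1:].sum()) / n2,
        z=z, p_exact=p_exact, p_asymptotic=float(p_asym),
    )


def mean_rank_from_u(u: float, n_group: int, n_total: int) -> float:
    """Recover a group's mean rank from its U statistic.

    U = R - n(n+1)/2 with R the group rank sum, so
    mean rank = (U + n(n+1)/2) / n.
    """
    u_max = n_group * (n_total - n_group)
    if not (0 <= u <= u_max):
        raise ValueError(f"U must lie in [0, {u_max}]")
    return (u + n_group * (n_group + 1) / 2.0) / n_group


def _hypergeom_pmf(x: int, r1: int, r2: int, c1: int) -> Fraction:
    return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(r1 + r2, c1))


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Sums hypergeometric point probabilities (margins fixed) over all tables
    whose probability does not exceed the observed one (within a 1e-7
    relative guard), in exact rational arithmetic.  Degenerate margins give
    p = 1.
    """
    for x in (a, b, c, d):
        if not isinstance(x, (int, np.integer)) or x < 0:
            raise ValueError("cell counts must be nonnegative integers")
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return 1.0
    x_lo, x_hi = max(0, c1 - r2), min(r1, c1)
    p_obs = _hypergeom_pmf(a, r1, r2, c1)
    cutoff = p_obs * (1 + Fraction(1, 10 ** 7))
    p = Fraction(0)
    for x in range(x_lo, x_hi + 1):
        px = _hypergeom_pmf(x, r1, r2, c1)
        if px <= cutoff:
            p += px
    return float(min(p, Fraction(1)))


def pearson_r(x, y) -> tuple:
    """Sample Pearson correlation with two-sided t-based p on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input has undefined correlation")
    r = float(np.corrcoef(x, y)[0, 1])
    n = len(x)
    if abs(r) >= 1.0:
        return (math.copysign(1.0, r), 0.0)
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return r, float(p)


# ---------------------------------------------------------------------------
# Table-1-style group summary

_CATEGORICAL = [("sex_male", "Fisher exact"), ("smoker", "Fisher exact"),
                ("hypertension", "Fisher exact")]


def _continuous_row(name, low_vals, high_vals):
    low_vals = pd.Series(low_vals).dropna()
    high_vals = pd.Series(high_vals).dropna()
    row = {
        "variable": name, "kind": "continuous",
        "low_n": len(low_vals), "high_n": len(high_vals),
        "low_mean": low_vals.mean() if len(low_vals) else np.nan,
        "low_sd": low_vals.std(ddof=1) if len(low_vals) > 1 else np.nan,
        "high_mean": high_vals.mean() if len(high_vals) else np.nan,
        "high_sd": high_vals.std(ddof=1) if len(high_vals) > 1 else np.nan,
        "test": "Mann-Whitney U", "p_value": np.nan,
    }
    if len(low_vals) and len(high_vals):
        res = mann_whitney(high_vals.to_numpy(), low_vals.to_numpy())
        row["p_value"] = res.p
        row["u"] = res.u
        row["z"] = res.z
    return row


def _categorical_row(name, low_flags, high_flags):
    low_flags = pd.Series(low_flags).dropna().astype(bool)
    high_flags = pd.Series(high_flags).dropna().astype(bool)
    a, b = int(low_flags.sum()), int((~low_flags).sum())
    c, d = int(high_flags.sum()), int((~high_flags).sum())
    return {
        "variable": name, "kind": "categorical",
        "low_n": a + b, "high_n": c + d,
        "low_count": a, "low_pct": 100.0 * a / (a + b) if a + b else np.nan,
        "high_count": c, "high_pct": 100.0 * c / (c + d) if c + d else np.nan,
        "test": "Fisher exact",
        "p_value": fisher_exact_2x2(a, b, c, d) if (a + b and c + d) else np.nan,
    }


def summarize_table1(subjects: pd.DataFrame, results: pd.DataFrame,
                     alpha: float = 0.05,
                     threshold: float = HBA1C_SPLIT) -> pd.DataFrame:
    """Group summary table: mean +/- SD and rank-test p per continuous row,
    count [%] and Fisher p per categorical row.

    ``subjects`` needs subject_id, hba1c, sex plus optional bmi/smoker/
    hypertension/age columns; ``results`` is the long per-subject outcome
    table (subject_id, hemisphere, mcav_rest, mcav_ss, cvr, pct_change).
    Subjects missing an outcome are excluded row-wise (logged).
    """
    subj = subjects.copy()
    subj["group"] = np.where(subj["hba1c"] > threshold, "high", "low")

    wide = results.pivot_table(
        index="subject_id", columns="hemisphere",
        values=["mcav_rest", "cvr", "pct_change"], aggfunc="mean")
    wide.columns = [f"{h}_{m}" for m, h in wide.columns]
    merged = subj.merge(wide, on="subject_id", how="left")
    n_missing = merged.filter(like="_cvr").isna().any(axis=1).sum()
    if n_missing:
        log.warning("%d subject(s) missing outcomes; excluded row-wise", n_missing)

    lo = merged[merged["group"] == "low"]
    hi = merged[merged["group"] == "high"]
    rows = []
    if "sex" in merged:
        rows.append(_categorical_row("sex_male", lo["sex"] == "male",
                                     hi["sex"] == "male"))
    for name, _ in _CATEGORICAL[1:]:
        if name in merged:
            rows.append(_categorical_row(name, lo[name], hi[name]))
    for name in ("age", "bmi"):
        if name in merged:
            rows.append(_continuous_row(name, lo[name], hi[name]))
    outcome_cols = [
        ("stroke_affected_mcav_rest", "resting MCAv (stroke-affected)"),
        ("stroke_affected_cvr", "CVR (stroke-affected)"),
        ("stroke_affected_pct_change", "%dMCAv (stroke-affected)"),
        ("non_affected_mcav_rest", "resting MCAv (non-affected)"),
        ("non_affected_cvr", "CVR (non-affected)"),
        ("non_affected_pct_change", "%dMCAv (non-affected)"),
    ]
    for col, label in outcome_cols:
        if col in merged:
            rows.append(_continuous_row(label, lo[col], hi[col]))

    table = pd.DataFrame(rows)
    table["significant"] = table["p_value"] < alpha
    return table
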