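"""Differential transcription analysis for two-library tag counts.

The experimental design is one pooled library per condition, so the test
is an exact two-library comparison.  For a feature with ``x_t`` reads out
of ``N_t`` in a treated library and ``x_c`` out of ``N_c`` in the
control, condition on the margins (N_t, N_c, k = x_t + x_c): under an
odds ratio psi the treated count follows Fisher's noncentral
hypergeometric distribution,

    pmf(x) ∝ C(N_t, x) * C(N_c, k - x) * psi**x ,
    x in [max(0, k - N_c), min(k, N_t)].

Because feature counts are tiny relative to the library totals, the odds
ratio is essentially the RPM ratio, so testing "more than 2-fold change"
means an upper tail at psi = 2 and a lower tail at psi = 1/2.  The raw
p-value is the smaller of the two one-sided boundary tails (any null
fold inside [1/2, 2] can make at most one of them small, so the minimum
is a valid boundary-level test); Holm's step-down correction then
controls the familywise error over all features tested within one
condition.

Effect sizes are reported as transcription ratios of reads-per-million
with a pseudocount:  TR = (RPM_t + x) / (RPM_c + x), x = 0.2 by default
(about one read per million in a typical library).

All tail computations run in log space via the pmf ratio recurrence

    pmf(x+1)/pmf(x) = psi * (N_t - x)(k - x) / ((x + 1)(N_c - k + x + 1)),

normalized from the mode — no factorials of library-sized numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class DifferentialConfig:
    """Test settings.

    pseudocount
        Added to both RPM values in the transcription ratio (RPM units).
    fold_boundary
        The odds-ratio boundary psi0 of the null band [1/psi0, psi0].
    alpha
        Threshold on the Holm-adjusted p-value.
    adjustment
        'holm' or 'none'.
    p_combination
        'min' (default) or 'double_min' (Bonferroni over the two tails).
    pooled_family
        If True, Holm runs over all (feature, condition) pairs at once
        instead of per condition.
    """

    pseudocount: float = 0.2
    fold_boundary: float = 2.0
    alpha: float = 1e-3
    adjustment: str = "holm"
    p_combination: Literal["min", "double_min"] = "min"
    pooled_family: bool = False

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if self.fold_boundary <= 1:
            raise ValueError("fold_boundary must be > 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.adjustment not in ("holm", "none"):
            raise ValueError(f"unknown adjustment {self.adjustment!r}")
        if self.p_combination not in ("min", "double_min"):
            raise ValueError(f"unknown p_combination {self.p_combination!r}")


@dataclass
class FeatureCountMatrix:
    """Feature x library integer counts plus normalization totals.

    ``norm_totals`` are the per-library denominators for RPM and the test
    margins; by convention these are the post-background-filter library
    totals, of which the feature counts are a subset.
    """

    counts: pd.DataFrame
    norm_totals: pd.Series

    def __post_init__(self) -> None:
        missing = set(self.counts.columns) - set(self.norm_totals.index)
        if missing:
            raise ValueError(f"norm_totals missing libraries: {sorted(missing)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        colsums = self.counts.sum(axis=0)
        over = colsums > self.norm_totals[self.counts.columns]
        if over.any():
            raise ValueError(
                f"feature counts exceed normalization totals in {list(colsums.index[over])}"
            )


def rpm_normalize(count: float, total: float) -> float:
    """Reads per million: 1e6 * count / total."""
    if total <= 0:
        raise ValueError("library total must be > 0")
    return 1e6 * count / total


def transcription_ratio(rpm_treated: float, rpm_control: float, pseudocount: float = 0.2) -> float:
    """Pseudocounted RPM ratio; satisfies TR(a, b) = 1 / TR(b, a)."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    return (rpm_treated + pseudocount) / (rpm_control + pseudocount)


def _nchg_weights(n_t: int, n_c: int, k: int, psi: float) -> tuple[int, np.ndarray]:
    """Support minimum and mode-normalized pmf weights over the support."""
    lo = max(0, k - n_c)
    hi = min(k, n_t)
    x = np.arange(lo, hi, dtype=float)  # ratios pmf(x+1)/pmf(x) for x = lo..hi-1
    with np.errstate(divide="ignore"):
        log_ratio = (
            math.log(psi)
            + np.log(n_t - x)
            + np.log(k - x)
            - np.log(x + 1)
            - np.log(n_c - k + x + 1)
        )
    log_pmf = np.concatenate(([0.0], np.cumsum(log_ratio)))
    log_pmf -= log_pmf.max()  # anchor at the mode for stability
    return lo, np.exp(log_pmf)


def nchg_tail(
    x_t: int, n_t: int, x_c: int, n_c: int, psi: float,
    tail: Literal["upper", "lower"] = "upper",
) -> float:
    """Exact one-sided tail of Fisher's noncentral hypergeometric law.

    Returns P(X >= x_t) (upper) or P(X <= x_t) (lower) for the treated
    count conditioned on margins (N_t, N_c, k = x_t + x_c) at odds ratio
    ``psi``.  The observed point mass is included in both tails.
    """
    if not 0 <= x_t <= n_t:
        raise ValueError(f"x_t={x_t} outside [0, N_t={n_t}]")
    if not 0 <= x_c <= n_c:
        raise ValueError(f"x_c={x_c} outside [0, N_c={n_c}]")
    if psi <= 0:
        raise ValueError("psi must be > 0")
    k = x_t + x_c
    if k < 1:
        raise ValueError("k = x_t + x_c must be >= 1")
    if tail not in ("upper", "lower"):
        raise ValueError(f"unknown tail {tail!r}")
    lo, w = _nchg_weights(n_t, n_c, k, psi)
    i = x_t - lo
    total = math.fsum(w)
    part = math.fsum(w[i:]) if tail == "upper" else math.fsum(w[: i + 1])
    return min(part / total, 1.0)


def nchg_pmf(x: int, n_t: int, n_c: int, k: int, psi: float) -> float:
    """Point mass P(X = x) under the same conditioning."""
    lo, w = _nchg_weights(n_t, n_c, k, psi)
    hi = min(k, n_t)
    if not lo <= x <= hi:
        return 0.0
    return w[x - lo] / math.fsum(w)


def test_feature(
    x_t: int, n_t: int, x_c: int, n_c: int, cfg: DifferentialConfig | None = None
) -> tuple[float, str]:
    """Boundary test for >psi0-fold change in either direction.

    p_over  = upper tail at psi = psi0   (over-transcription boundary)
    p_under = lower tail at psi = 1/psi0 (under-transcription boundary)

    Combined per ``cfg.p_combination``; ties in direction go to 'over'.
    """
    cfg = cfg or DifferentialConfig()
    psi0 = cfg.fold_boundary
    p_over = nchg_tail(x_t, n_t, x_c, n_c, psi0, "upper")
    p_under = nchg_tail(x_t, n_t, x_c, n_c, 1.0 / psi0, "lower")
    direction = "over" if p_over <= p_under else "under"
    p = min(p_over, p_under)
    if cfg.p_combination == "double_min":
        p = min(1.0, 2.0 * p)
    return p, direction


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in input order.

    adjusted_(i) = max_{j <= i} min(1, (m - j + 1) * p_(j)) over the
    ascending order statistics.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a non-empty 1-d array of p-values")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adjusted_sorted = np.maximum.accumulate(scaled)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out


def run_differential(
    matrix: FeatureCountMatrix,
    control: str,
    cfg: DifferentialConfig | None = None,
) -> pd.DataFrame:
    """Test every feature in every treatment library against the control.

    Feature/condition pairs with zero reads in both compared libraries
    are skipped (the conditional test is undefined at k = 0).  Returns a
    frame with one row per tested pair: counts, RPM, TR, log10 TR, raw
    and Holm-adjusted p, direction, and the significance call
    (adjusted p < alpha).
    """
    cfg = cfg or DifferentialConfig()
    if control not in matrix.counts.columns:
        raise ValueError(f"control library {control!r} not in count matrix")
    treatments = [c for c in matrix.counts.columns if c != control]
    n_c = int(matrix.norm_totals[control])
    rows = []
    for cond in treatments:
        n_t = int(matrix.norm_totals[cond])
        xs_t = matrix.counts[cond]
        xs_c = matrix.counts[control]
        for feat in matrix.counts.index:
            x_t, x_c = int(xs_t[feat]), int(xs_c[feat])
            if x_t + x_c == 0:
                continue
            rpm_t = rpm_normalize(x_t, n_t)
            rpm_c = rpm_normalize(x_c, n_c)
            tr = transcription_ratio(rpm_t, rpm_c, cfg.pseudocount)
            p_raw, direction = test_feature(x_t, n_t, x_c, n_c, cfg)
            rows.append({
                "feature": feat, "condition": cond,
                "count_treated": x_t, "count_control": x_c,
                "rpm_treated": rpm_t, "rpm_control": rpm_c,
                "tr": tr, "log10_tr": math.log10(tr),
                "p_raw": p_raw, "direction": direction,
            })
    res = pd.DataFrame(rows)
    if res.empty:
        res = pd.DataFrame(columns=[
            "feature", "condition", "count_treated", "count_control",
            "rpm_treated", "rpm_control", "tr", "log10_tr", "p_raw",
            "direction", "p_adj", "significant",
        ])
        return res
    if cfg.adjustment == "none":
        res["p_adj"] = res["p_raw"]
    elif cfg.pooled_family:
        res["p_adj"] = holm_adjust(res["p_raw"].to_numpy())
    else:
        res["p_adj"] = np.nan
        for cond, idx in res.groupby("condition").groups.items():
            res.loc[idx, "p_adj"] = holm_adjust(res.loc[idx, "p_raw"].to_numpy())
    res["significant"] = res["p_adj"] < cfg.alpha
    return res
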