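"""Proportion intervals, exact tests, group comparisons, and dose-response.

The quantities here back every summary number the imaging pipeline reports:

* Wilson score intervals for proportions (with a continuity-corrected variant
  for near-boundary counts),
* the exact binomial test (two-sided by doubling the smaller tail),
* the Freeman–Halton generalisation of Fisher's exact test to 2×k tables by
  full enumeration (Monte Carlo via the Patefield sampler for large or r×c
  tables),
* pooled/Welch two-sample t tests with a CI on the mean difference,
* luminescence-plate normalisation and dose-wise two-way-ANOVA contrasts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

__all__ = [
    "ProportionEstimate",
    "wilson_ci",
    "proportion_estimates",
    "binomial_test",
    "FisherResult",
    "fisher_exact_rxc",
    "TTestResult",
    "two_sample_t",
    "normalize_viability",
    "dosewise_comparison",
]


# ---------------------------------------------------------------------------
# proportions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProportionEstimate:
    successes: int
    n: int
    point_pct: float
    ci_low_pct: float
    ci_high_pct: float
    method: str
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if not 0 <= self.successes <= self.n:
            raise ValueError("need 0 <= successes <= n")
        if not self.ci_low_pct - 1e-9 <= self.point_pct <= self.ci_high_pct + 1e-9:
            raise ValueError("interval must contain the point estimate")


def _wilson_bounds(x: int, n: int, z: float) -> tuple[float, float]:
    p = x / n
    denom = 1.0 + z * z / n
    centre = p + z * z / (2 * n)
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    return (centre - half) / denom, (centre + half) / denom


def _wilson_cc_bounds(x: int, n: int, z: float) -> tuple[float, float]:
    # Newcombe's continuity-corrected Wilson score interval.
    p = x / n
    if x == 0:
        low = 0.0
    else:
        low = (2 * n * p + z * z - 1
               - z * math.sqrt(z * z - 2 - 1 / n + 4 * p * (n * (1 - p) + 1))
               ) / (2 * (n + z * z))
    if x == n:
        high = 1.0
    else:
        high = (2 * n * p + z * z + 1
                + z * math.sqrt(z * z + 2 - 1 / n + 4 * p * (n * (1 - p) - 1))
                ) / (2 * (n + z * z))
    return max(0.0, low), min(1.0, high)


def wilson_ci(
    successes: int, n: int, confidence: float = 0.95, method: str = "wilson"
) -> ProportionEstimate:
    """Wilson score interval for a binomial proportion, in percent.

    ``method="wilson_cc"`` applies Newcombe's continuity correction, which is
    the variant common stats packages switch to near the 0/n boundaries.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("need 0 <= successes <= n")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    z = sps.norm.ppf(1 - (1 - confidence) / 2)
    if method == "wilson":
        low, high = _wilson_bounds(successes, n, z)
    elif method == "wilson_cc":
        low, high = _wilson_cc_bounds(successes, n, z)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ProportionEstimate(
        successes=successes,
        n=n,
        point_pct=100.0 * successes / n,
        ci_low_pct=100.0 * max(0.0, low),
        ci_high_pct=100.0 * min(1.0, high),
        method=method,
        confidence=confidence,
    )


def proportion_estimates(
    successes: int, n: int, confidence: float = 0.95
) -> list[ProportionEstimate]:
    """Wilson estimate, plus the continuity-corrected one near the boundary.

    When ``successes <= 2`` or ``successes >= n - 2`` both variants are
    returned (plain Wilson first), since the score interval is least reliable
    at extreme counts.
    """
    out = [wilson_ci(successes, n, confidence)]
    if successes <= 2 or successes >= n - 2:
        out.append(wilson_ci(successes, n, confidence, method="wilson_cc"))
    return out


# ---------------------------------------------------------------------------
# exact tests
# ---------------------------------------------------------------------------

def binomial_test(
    successes: int, n: int, null_p: float = 0.5, two_sided: bool = True
) -> float:
    """Exact binomial test by tail summation.

    Two-sided p is twice the smaller tail, capped at 1 (the convention used
    when the reported statistic is a directional proportion against a null).
    """
    if not 0 <= successes <= n or n < 1:
        raise ValueError("need 0 <= successes <= n, n >= 1")
    if not 0 < null_p < 1:
        raise ValueError("null_p must be in (0, 1)")
    lower = sps.binom.cdf(successes, n, null_p)
    upper = sps.binom.sf(successes - 1, n, null_p)
    if not two_sided:
        return float(min(lower, upper))
    return float(min(1.0, 2.0 * min(lower, upper)))


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    method: str  # "enumeration" | "monte_carlo"
    n_tables: int
    mc_se: float | None = None


def _log_table_prob(table: np.ndarray, lgN: float, lg_rows: float, lg_cols: float) -> float:
    return float(lg_rows + lg_cols - lgN - gammaln(table + 1).sum())


def _enumerate_2xk(col_sums: np.ndarray, m: int, log_obs: float, tol: float) -> float:
    """Sum hypergeometric probabilities of 2×k tables at least as extreme.

    States are (row-1 partial sum, partial log-choose); the last column is
    forced by the margin, so enumeration cost is the product over the first
    k-1 columns of (col_sum + 1), pruned by feasibility.
    """
    N = int(col_sums.sum())
    log_denom = float(gammaln(N + 1) - gammaln(m + 1) - gammaln(N - m + 1))
    # log C(c, x) tables per column
    states_s = np.array([0], dtype=np.int64)
    states_lp = np.array([0.0])
    remaining = int(col_sums.sum())
    for c in col_sums[:-1]:
        c = int(c)
        remaining -= c
        x = np.arange(c + 1)
        logc = gammaln(c + 1) - gammaln(x + 1) - gammaln(c - x + 1)
        new_s = (states_s[:, None] + x[None, :]).ravel()
        new_lp = (states_lp[:, None] + logc[None, :]).ravel()
        keep = (new_s <= m) & (new_s >= m - remaining)
        states_s, states_lp = new_s[keep], new_lp[keep]
    # last column is forced by the row margin
    c = int(col_sums[-1])
    x = m - states_s
    states_lp = states_lp + gammaln(c + 1) - gammaln(x + 1) - gammaln(c - x + 1)
    log_probs = states_lp - log_denom
    sel = log_probs <= log_obs + tol
    return float(np.exp(log_probs[sel]).sum()), int(states_s.size)


def fisher_exact_rxc(
    table,
    max_tables: float = 2e7,
    n_mc: int = 1_000_000,
    seed: int = 0,
    full_result: bool = False,
):
    """Freeman–Halton exact test on an r×c contingency table.

    The p-value is the total conditional (fixed-margins) probability of all
    tables whose hypergeometric probability is <= the observed table's
    (within relative tolerance 1e-9 in log space).  2×k tables below
    ``max_tables`` candidate states are fully enumerated; otherwise a Monte
    Carlo estimate over Patefield-sampled tables is returned together with
    its standard error.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    if (row_sums == 0).any() or (col_sums == 0).any():
        raise ValueError("degenerate table: a margin sums to zero")

    N = int(t.sum())
    lgN = gammaln(N + 1)
    lg_rows = gammaln(row_sums + 1).sum()
    lg_cols = gammaln(col_sums + 1).sum()
    log_obs = _log_table_prob(t, lgN, lg_rows, lg_cols)
    tol = 1e-9

    n_states = float(np.prod(col_sums[:-1] + 1.0))
    if t.shape[0] == 2 and n_states <= max_tables:
        p, n_tab = _enumerate_2xk(col_sums, int(row_sums[0]), log_obs, tol)
        res = FisherResult(min(1.0, p), "enumeration", n_tab)
    else:
        rng = np.random.default_rng(seed)
        dist = sps.random_table(row_sums, col_sums)
        hits = 0
        done = 0
        chunk = 100_000
        while done < n_mc:
            k = min(chunk, n_mc - done)
            samp = dist.rvs(size=k, random_state=rng)
            lp = lg_rows + lg_cols - lgN - gammaln(samp + 1).sum(axis=(1, 2))
            hits += int((lp <= log_obs + tol).sum())
            done += k
        p = hits / n_mc
        se = math.sqrt(max(p * (1 - p), 1.0 / n_mc) / n_mc)
        res = FisherResult(p, "monte_carlo", n_mc, mc_se=se)
    return res if full_result else res.p_value


# ---------------------------------------------------------------------------
# two-sample comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    t: float
    p_value: float
    df: float
    mean_diff: float
    ci_low: float
    ci_high: float
    welch: bool


def two_sample_t(a, b, welch: bool = False, confidence: float = 0.95) -> TTestResult:
    """Unpaired two-sample t test (pooled by default; Welch optional).

    Returns the t statistic for ``mean(a) - mean(b)`` with a CI on the
    difference.  Zero pooled variance with unequal means raises, since the
    statistic is undefined there.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    na, nb = a.size, b.size
    diff = a.mean() - b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if welch:
        se2 = va / na + vb / nb
        if se2 == 0:
            raise ValueError("zero variance in both groups: t undefined")
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        if sp2 == 0:
            if diff != 0:
                raise ValueError("zero pooled variance with unequal means: t undefined")
            sp2 = np.nan
        se2 = sp2 * (1 / na + 1 / nb)
        df = na + nb - 2
    if np.isnan(se2):  # identical constant groups
        return TTestResult(0.0, 1.0, df, 0.0, 0.0, 0.0, welch)
    se = math.sqrt(se2)
    tstat = diff / se
    p = 2 * sps.t.sf(abs(tstat), df)
    tcrit = sps.t.ppf(1 - (1 - confidence) / 2, df)
    return TTestResult(float(tstat), float(p), float(df), float(diff),
                       float(diff - tcrit * se), float(diff + tcrit * se), welch)


# ---------------------------------------------------------------------------
# dose-response viability
# ---------------------------------------------------------------------------

def normalize_viability(table: pd.DataFrame) -> pd.DataFrame:
    """Background-subtract and rescale a luminescence plate to percent viability.

    ``table`` needs columns ``condition``, ``dose_uM``, ``luminescence`` and a
    boolean ``is_background`` marking media-only wells.  The mean background is
    subtracted from every well and the result is expressed as percent of the
    highest background-subtracted well (that well defines 100% viability).
    """
    required = {"condition", "dose_uM", "luminescence", "is_background"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    bg = table.loc[table["is_background"], "luminescence"]
    if bg.empty:
        raise ValueError("no background wells")
    treated = table.loc[~table["is_background"]]
    if treated.empty:
        raise ValueError("no treated wells")
    out = table.copy()
    corrected = out["luminescence"] - bg.mean()
    top = corrected[~out["is_background"]].max()
    if top <= 0:
        raise ValueError("maximum well does not exceed background")
    out["viability_pct"] = 100.0 * corrected / top
    return out


def dosewise_comparison(
    control: pd.DataFrame,
    treated: pd.DataFrame,
    adjust: str = "sidak",
) -> pd.DataFrame:
    """Per-dose contrasts between two normalised dose-response tables.

    Fits a two-way (condition × dose) ANOVA on ``viability_pct`` and reports,
    per dose, the control-minus-treated mean difference, its CI, the raw
    t-test p and the multiplicity-adjusted p (Šidák by default, Bonferroni
    optional).  Requires matched dose grids with >= 2 dose levels.
    """
    for name, df in (("control", control), ("treated", treated)):
        if "viability_pct" not in df.columns:
            raise ValueError(f"{name} table lacks viability_pct (run normalize_viability)")
    c = control.loc[~control["is_background"]]
    t = treated.loc[~treated["is_background"]]
    doses_c = np.sort(c["dose_uM"].unique())
    doses_t = np.sort(t["dose_uM"].unique())
    if len(doses_c) != len(doses_t) or not np.allclose(doses_c, doses_t):
        raise ValueError("dose grids do not match")
    if len(doses_c) < 2:
        raise ValueError("need >= 2 dose levels for the dose factor")

    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    both = pd.concat(
        [c.assign(group="control"), t.assign(group="treated")], ignore_index=True
    )
    model = smf.ols("viability_pct ~ C(group) * C(dose_uM)", data=both).fit()
    anova = anova_lm(model, typ=2)

    m = len(doses_c)
    rows = []
    for d in doses_c:
        res = two_sample_t(
            c.loc[c["dose_uM"] == d, "viability_pct"],
            t.loc[t["dose_uM"] == d, "viability_pct"],
        )
        p = res.p_value
        if adjust == "sidak":
            p_adj = 1.0 - (1.0 - p) ** m
        elif adjust == "bonferroni":
            p_adj = min(1.0, p * m)
        else:
            raise ValueError(f"unknown adjustment {adjust!r}")
        rows.append(
            dict(dose_uM=d, mean_diff=res.mean_diff, ci_low=res.ci_low,
                 ci_high=res.ci_high, p_raw=p, p_adjusted=min(1.0, p_adj))
        )
    out = pd.DataFrame(rows)
    out.attrs["anova"] = anova
    out.attrs["adjustment"] = adjust
    return out
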