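"""Bilateral-asymmetry statistics: exact small-sample nonparametric tests,
Dahlberg reliability, and the four cohort result tables.

With n = 14 subjects per group, asymptotic p-values are unreliable, so the
exact null distributions are used wherever the data permit:

* Mann-Whitney U: exact permutation distribution of U (count recursion)
  when both samples have at most 20 observations and there are no ties;
  mid-ranks with a tie-corrected normal approximation (no continuity
  correction) otherwise.
* Wilcoxon signed-rank: exact sign-flip distribution of W+ for up to 20
  nonzero differences without tied magnitudes; zero differences are
  dropped (Wilcoxon's rule) with a logged note.
* Spearman rank correlation: rho from mid-ranks; exact permutation p for
  n <= 10, Student-t approximation otherwise.

All p-values are two-sided.  No multiple-testing correction is applied by
default; Holm adjustment is available as an opt-in helper.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps

from .reference import MEASUREMENTS

__all__ = [
    "TestResult",
    "ResultTables",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "spearman_rho",
    "dahlberg_error",
    "holm_adjust",
    "build_tables",
    "significance_stars",
    "mann_whitney_type_i_error",
]

log = logging.getLogger(__name__)

#: largest per-sample size for which the exact distributions are used
EXACT_LIMIT = 20
#: largest n for which the exact Spearman permutation p is computed
SPEARMAN_EXACT_LIMIT = 10


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    p_value: float
    method: str  # "exact" or "normal-approx" (or "t-approx" for Spearman)
    n: tuple

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


def _clean_sample(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if a.size == 0:
        raise ValueError(f"{name}: empty sample")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name}: non-finite values")
    return a


# ---------------------------------------------------------------------------
# Mann-Whitney U


@lru_cache(maxsize=None)
def _mwu_counts(n: int, m: int) -> np.ndarray:
    """Number of rank configurations giving each U value, U = 0..n*m."""
    if n == 0 or m == 0:
        return np.ones(1)
    a = _mwu_counts(n - 1, m)  # U reduced by m when the largest obs is in x
    b = _mwu_counts(n, m - 1)
    out = np.zeros(n * m + 1)
    out[m : m + a.size] += a
    out[: b.size] += b
    return out


def _mwu_cdf(n: int, m: int) -> np.ndarray:
    counts = _mwu_counts(n, m)
    return np.cumsum(counts) / counts.sum()


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    The statistic reported is U for the first sample.
    """
    x = _clean_sample(x, "x")
    y = _clean_sample(y, "y")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    has_ties = np.unique(pooled).size < pooled.size

    if not has_ties and max(n, m) <= EXACT_LIMIT:
        cdf = _mwu_cdf(n, m)
        lo = int(round(min(u, n * m - u)))
        p = min(1.0, 2.0 * cdf[lo])
        return TestResult(u, p, "exact", (n, m))

    mean = n * m / 2.0
    N = n + m
    _, t = np.unique(pooled, return_counts=True)
    tie_term = float(((t**3 - t).sum()) / (N * (N - 1))) if N > 1 else 0.0
    var = n * m / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return TestResult(u, 1.0, "normal-approx", (n, m))
    z = (u - mean) / math.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return TestResult(u, min(p, 1.0), "normal-approx", (n, m))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


@lru_cache(maxsize=None)
def _wsr_counts(n: int) -> np.ndarray:
    """Number of sign patterns giving each W+ value, W+ = 0..n(n+1)/2."""
    poly = np.ones(1)
    for i in range(1, n + 1):
        nxt = np.zeros(poly.size + i)
        nxt[: poly.size] += poly
        nxt[i:] += poly
        poly = nxt
    return poly


def wilcoxon_signed_rank(d) -> TestResult:
    """Two-sided Wilcoxon signed-rank test of paired differences.

    Zero differences are dropped before ranking; if every difference is
    zero the test is degenerate and p = 1 is returned with a warning.
    """
    d = _clean_sample(d, "d")
    nz = d[d != 0.0]
    n_dropped = d.size - nz.size
    if n_dropped:
        log.info("wilcoxon: dropped %d zero difference(s)", n_dropped)
    if nz.size == 0:
        log.warning("wilcoxon: all differences are zero; degenerate test, p = 1")
        return TestResult(0.0, 1.0, "exact", (0,))
    n = nz.size
    mags = np.abs(nz)
    ranks = sps.rankdata(mags)
    w_plus = float(ranks[nz > 0].sum())
    has_ties = np.unique(mags).size < mags.size

    if not has_ties and n <= EXACT_LIMIT:
        counts = _wsr_counts(n)
        cdf = np.cumsum(counts) / counts.sum()
        total = n * (n + 1) / 2.0
        lo = int(round(min(w_plus, total - w_plus)))
        p = min(1.0, 2.0 * cdf[lo])
        return TestResult(w_plus, p, "exact", (n,))

    mean = n * (n + 1) / 4.0
    _, t = np.unique(mags, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float((t**3 - t).sum()) / 48.0
    if var <= 0:
        return TestResult(w_plus, 1.0, "normal-approx", (n,))
    z = (w_plus - mean) / math.sqrt(var)
    p = float(2.0 * sps.norm.sf(abs(z)))
    return TestResult(w_plus, min(p, 1.0), "normal-approx", (n,))


# ---------------------------------------------------------------------------
# Spearman rank correlation


@lru_cache(maxsize=None)
def _spearman_d2_distribution(n: int) -> tuple[np.ndarray, np.ndarray]:
    """(values, counts) of sum of squared rank differences over all n!
    permutations of untied ranks."""
    base = np.arange(n)
    acc: dict[int, int] = {}
    chunk: list = []

    def flush() -> None:
        if not chunk:
            return
        arr = np.asarray(chunk)
        d2 = ((arr - base) ** 2).sum(axis=1)
        vals, cnts = np.unique(d2, return_counts=True)
        for v, c in zip(vals.tolist(), cnts.tolist()):
            acc[v] = acc.get(v, 0) + c
        chunk.clear()

    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) >= 200_000:
            flush()
    flush()
    vals = np.array(sorted(acc))
    return vals, np.array([acc[v] for v in vals], dtype=float)


def _spearman_exact_p_tied(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Exact permutation p with ties: enumerate all pairings of the
    observed rank vectors."""
    n = rx.size
    cx = rx - rx.mean()
    cy = ry - ry.mean()
    denom = math.sqrt(float((cx**2).sum() * (cy**2).sum()))
    hits = 0
    total = 0
    chunk: list = []

    def count(arr: np.ndarray) -> int:
        rhos = (arr @ cx) / denom
        return int(np.count_nonzero(np.abs(rhos) >= abs(rho_obs) - 1e-12))

    for perm in itertools.permutations(cy.tolist()):
        chunk.append(perm)
        total += 1
        if len(chunk) >= 200_000:
            hits += count(np.asarray(chunk))
            chunk.clear()
    if chunk:
        hits += count(np.asarray(chunk))
    return hits / total


def spearman_rho(x, y) -> TestResult:
    """Spearman rank correlation with two-sided p.

    Exact permutation p for n <= 10, t-approximation otherwise.  Raises
    ``ValueError`` for a constant input vector (undefined correlation).
    """
    x = _clean_sample(x, "x")
    y = _clean_sample(y, "y")
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant input: correlation undefined")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if n <= SPEARMAN_EXACT_LIMIT:
        tied = np.unique(x).size < n or np.unique(y).size < n
        if not tied:
            vals, counts = _spearman_d2_distribution(n)
            rhos = 1.0 - 6.0 * vals / (n * (n**2 - 1))
            hits = counts[np.abs(rhos) >= abs(rho) - 1e-12].sum()
            p = float(hits / counts.sum())
        else:
            p = _spearman_exact_p_tied(rx, ry, rho)
        return TestResult(rho, min(p, 1.0), "exact", (n,))

    if abs(rho) >= 1.0:
        return TestResult(rho, 0.0, "t-approx", (n,))
    t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return TestResult(rho, min(p, 1.0), "t-approx", (n,))


# ---------------------------------------------------------------------------
# Reliability and helpers


def dahlberg_error(first, second) -> float:
    """Dahlberg's duplicate-measurement error Se = sqrt(sum(D^2) / (2n))."""
    a = _clean_sample(first, "first")
    b = _clean_sample(second, "second")
    if a.size != b.size:
        raise ValueError("repeated-measurement series must have equal length")
    d = a - b
    return float(np.sqrt((d**2).sum() / (2.0 * d.size)))


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (opt-in; not applied by default)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def significance_stars(p: float) -> str:
    """'**' for p < 0.01, '*' for p < 0.05, '' otherwise (NaN -> '')."""
    if p != p:  # NaN
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# Cohort tables


@dataclass
class ResultTables:
    """The four cohort result tables.

    differences      : group means/SDs of bilateral differences + Mann-Whitney p
    sides            : per-group side means/SDs + Wilcoxon p
    side_comparisons : FA side vs NA measurement Mann-Whitney p per side
    correlation_rho / correlation_p : Spearman matrix of |menton deviation|
                       and the six deviated/nondeviated ratios within FA
    """

    differences: pd.DataFrame
    sides: pd.DataFrame
    side_comparisons: pd.DataFrame
    correlation_rho: pd.DataFrame
    correlation_p: pd.DataFrame

    def as_dict(self) -> dict:
        return {
            "differences": self.differences.to_dict(orient="records"),
            "sides": self.sides.to_dict(orient="records"),
            "side_comparisons": self.side_comparisons.to_dict(orient="records"),
            "correlation_rho": self.correlation_rho.to_dict(),
            "correlation_p": self.correlation_p.to_dict(),
        }


def _side_values(df: pd.DataFrame, which: str, measurement: str) -> np.ndarray:
    """Per-subject values of one measurement on the deviated or nondeviated side."""
    dev_left = df["deviated_side"] == "left"
    left = df[f"left_{measurement}"].to_numpy()
    right = df[f"right_{measurement}"].to_numpy()
    if which == "deviated":
        return np.where(dev_left, left, right)
    return np.where(dev_left, right, left)


def build_tables(cohort: pd.DataFrame, side_comparison_mode: str = "matched") -> ResultTables:
    """Build the four result tables from the canonical per-subject frame.

    ``side_comparison_mode`` selects the FA-vs-NA side comparison: "matched" tests
    FA deviated vs NA deviated and FA nondeviated vs NA nondeviated;
    "pooled" tests each FA side against both NA sides pooled.

    A group with fewer than 2 subjects gets descriptive columns only
    (p-values NaN).
    """
    if side_comparison_mode not in ("matched", "pooled"):
        raise ValueError(f"unknown side_comparison_mode {side_comparison_mode!r}")
    for g in ("FA", "NA"):
        if (cohort["group"] == g).sum() == 0:
            raise ValueError(f"cohort has no {g} subjects")
    fa = cohort[cohort["group"] == "FA"]
    na = cohort[cohort["group"] == "NA"]

    def can_test(*frames) -> bool:
        return all(len(f) >= 2 for f in frames)

    # --- bilateral differences (FA vs NA) -------------------------------
    rows = []
    for m in MEASUREMENTS:
        dfa = fa[f"diff_{m}"].to_numpy()
        dna = na[f"diff_{m}"].to_numpy()
        p = mann_whitney_u(dfa, dna).p_value if can_test(fa, na) else float("nan")
        rows.append(
            {
                "measurement": m,
                "FA_mean": dfa.mean(),
                "FA_sd": dfa.std(ddof=1) if len(dfa) > 1 else float("nan"),
                "NA_mean": dna.mean(),
                "NA_sd": dna.std(ddof=1) if len(dna) > 1 else float("nan"),
                "p_value": p,
                "significance": significance_stars(p),
            }
        )
    differences = pd.DataFrame(rows)

    # --- per-side summaries with within-group Wilcoxon -------------------
    rows = []
    for g, gdf in (("FA", fa), ("NA", na)):
        for m in MEASUREMENTS:
            dev = _side_values(gdf, "deviated", m)
            nond = _side_values(gdf, "nondeviated", m)
            p = (
                wilcoxon_signed_rank(nond - dev).p_value
                if can_test(gdf)
                else float("nan")
            )
            rows.append(
                {
                    "group": g,
                    "measurement": m,
                    "deviated_mean": dev.mean(),
                    "deviated_sd": dev.std(ddof=1) if len(dev) > 1 else float("nan"),
                    "nondeviated_mean": nond.mean(),
                    "nondeviated_sd": nond.std(ddof=1) if len(nond) > 1 else float("nan"),
                    "p_value": p,
                    "significance": significance_stars(p),
                }
            )
    sides = pd.DataFrame(rows)

    # --- FA sides vs NA --------------------------------------------------
    rows = []
    for m in MEASUREMENTS:
        row = {"measurement": m}
        for which in ("deviated", "nondeviated"):
            fa_vals = _side_values(fa, which, m)
            if side_comparison_mode == "matched":
                na_vals = _side_values(na, which, m)
            else:
                na_vals = np.concatenate(
                    [_side_values(na, "deviated", m), _side_values(na, "nondeviated", m)]
                )
            p = mann_whitney_u(fa_vals, na_vals).p_value if can_test(fa, na) else float("nan")
            row[f"p_{which}"] = p
            row[f"significance_{which}"] = significance_stars(p)
        rows.append(row)
    side_comparisons = pd.DataFrame(rows)

    # --- Spearman matrix within FA ---------------------------------------
    labels = ["menton_deviation"] + [f"ratio_{m}" for m in MEASUREMENTS]
    cols = {
        "menton_deviation": fa["menton_deviation"].abs().to_numpy(),
        **{f"ratio_{m}": fa[f"ratio_{m}"].to_numpy() for m in MEASUREMENTS},
    }
    k = len(labels)
    rho = np.eye(k)
    pmat = np.full((k, k), np.nan)
    if len(fa) >= 3:
        for i in range(k):
            for j in range(i + 1, k):
                try:
                    res = spearman_rho(cols[labels[i]], cols[labels[j]])
                    rho[i, j] = rho[j, i] = res.statistic
                    pmat[i, j] = pmat[j, i] = res.p_value
                except ValueError:
                    rho[i, j] = rho[j, i] = np.nan
    else:
        rho[:] = np.nan
        np.fill_diagonal(rho, 1.0)
    correlation_rho = pd.DataFrame(rho, index=labels, columns=labels)
    correlation_p = pd.DataFrame(pmat, index=labels, columns=labels)

    return ResultTables(differences, sides, side_comparisons, correlation_rho, correlation_p)


# ---------------------------------------------------------------------------
# Simulation utilities


def mann_whitney_type_i_error(
    n: int, m: int, replicates: int, seed: int, alpha: float = 0.05
) -> float:
    """Empirical rejection rate of the exact Mann-Whitney test when both
    samples come from the same continuous distribution.

    Vectorised over replicates: continuous draws are tie-free almost
    surely, so the exact U null distribution applies and p-values reduce
    to a table lookup.
    """
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((replicates, n + m))
    ranks = data.argsort(axis=1).argsort(axis=1) + 1.0
    u = ranks[:, :n].sum(axis=1) - n * (n + 1) / 2.0
    cdf = _mwu_cdf(n, m)
    lo = np.minimum(u, n * m - u).astype(int)
    p = np.minimum(1.0, 2.0 * cdf[lo])
    return float((p <= alpha).mean())
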