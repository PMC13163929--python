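"""Assay-performance and clinical statistics for methylation PCR assays.

Covers the quantitative backbone of assay development after design:

* **dilution series** — geometric concentration ladders for sensitivity and
  dynamic-range testing;
* **single-molecule screens** — at ~0.17 copies/reaction most replicate
  wells hold zero molecules; under Poisson loading the expected positive
  fraction is 1 - e^(-lambda), and observed positivity rates between assays
  are compared with Fisher's exact test, with exact binomial
  (Clopper-Pearson) confidence intervals;
* **digital PCR** — with N partitions of which k are positive, the mean
  molecules per partition is lambda = -ln(1 - k/N) and copies per reaction
  is lambda * N; results scale to copies per mL plasma through the
  extraction/input factor;
* **clinical comparison** — per-sample absolute marker concentration and
  marker as a percent of total cfDNA (a conversion-specific reference
  target such as ACTB), compared across clinical groups with the
  Kruskal-Wallis test.

Also included: reconstruction of positive/total counts from published
summary statistics (rounded positivity rate, confidence interval, replicate
range), the standard meta-analytic route when raw counts are not printed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SampleSheet

__all__ = [
    "ReplicateScreen",
    "DilutionSeries",
    "PartitionResult",
    "ConfidenceInterval",
    "DpcrQuant",
    "dilution_series_points",
    "poisson_positivity",
    "clopper_pearson",
    "binomial_ci",
    "fisher_exact",
    "dpcr_concentration",
    "percent_methylation",
    "kruskal_wallis",
    "clinical_summary",
    "ClinicalSummary",
    "reconstruct_binomial_counts",
    "single_copy_comparison",
]


@dataclass(frozen=True)
class ReplicateScreen:
    """Positive/total counts of one replicate qPCR screen."""

    assay_id: str
    n_replicates: int
    k_positive: int
    nominal_copies: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.k_positive <= self.n_replicates:
            raise ValueError("k_positive must lie in [0, n_replicates]")

    @property
    def positivity(self) -> float:
        return self.k_positive / self.n_replicates


@dataclass(frozen=True)
class DilutionSeries:
    """A geometric dilution ladder, optionally with observed positives."""

    start_copies: float
    fold: float
    n_points: int
    replicates_per_point: int = 8
    observed_positive: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.start_copies <= 0 or self.fold <= 1 or self.n_points < 1:
            raise ValueError("need start > 0, fold > 1, n_points >= 1")

    @property
    def concentrations(self) -> np.ndarray:
        return dilution_series_points(self.start_copies, self.fold, self.n_points)


@dataclass(frozen=True)
class PartitionResult:
    """Digital-PCR partition counts for one sample and target."""

    sample_id: str
    target: str                      # e.g. "marker" or "total_reference"
    n_partitions: int
    k_positive: int
    partition_volume: float = 0.34   # microlitres (nanoplate-style default)
    reaction_to_plasma_factor: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.k_positive <= self.n_partitions:
            raise ValueError("k_positive must lie in [0, n_partitions]")
        if self.partition_volume <= 0 or self.reaction_to_plasma_factor <= 0:
            raise ValueError("volumes and scale factors must be positive")


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    level: float = 0.95
    method: str = "clopper_pearson"

    def __post_init__(self) -> None:
        if not 0 <= self.lower <= self.upper <= 1:
            raise ValueError("interval must satisfy 0 <= lower <= upper <= 1")


# ---------------------------------------------------------------------------
# Elementary quantities
# ---------------------------------------------------------------------------

def dilution_series_points(start: float, fold: float, n_points: int) -> np.ndarray:
    """Geometric dilution series: start / fold**i for i = 0..n_points-1."""
    if start <= 0 or fold <= 1 or n_points < 1:
        raise ValueError("need start > 0, fold > 1, n_points >= 1")
    return start / fold ** np.arange(n_points)


def poisson_positivity(copies_per_reaction) -> float | np.ndarray:
    """Expected positive fraction under Poisson loading: 1 - e^(-lambda)."""
    lam = np.asarray(copies_per_reaction, dtype=float)
    if np.any(lam < 0):
        raise ValueError("lambda must be non-negative")
    out = -np.expm1(-lam)
    return float(out) if out.ndim == 0 else out


def clopper_pearson(k: int, n: int, level: float = 0.95) -> ConfidenceInterval:
    """Exact binomial confidence interval from beta quantiles."""
    if n < 1 or not 0 <= k <= n:
        raise ValueError("need n >= 1 and 0 <= k <= n")
    alpha = 1 - level
    lower = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return ConfidenceInterval(lower, upper, level, "clopper_pearson")


def binomial_ci(k: int, n: int, level: float = 0.95,
                method: str = "clopper_pearson") -> ConfidenceInterval:
    """Binomial CI with a selectable method (exact by default)."""
    if method == "clopper_pearson":
        return clopper_pearson(k, n, level)
    if method == "wilson":
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
        return ConfidenceInterval(float(lo), float(hi), level, "wilson")
    raise ValueError(f"unknown CI method {method!r}")


def fisher_exact(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher's exact p for positivity k1/n1 vs k2/n2.

    Two-sidedness by probability-mass summation: all tables with the same
    margins whose hypergeometric probability does not exceed the observed
    table's contribute to p.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not 0 <= k <= n:
            raise ValueError("invalid counts")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    return min(p, 1.0)


@dataclass(frozen=True)
class DpcrQuant:
    """Digital-PCR quantification with its confidence interval on lambda."""

    sample_id: str
    target: str
    lambda_per_partition: float
    copies_per_reaction: float
    copies_per_ml: float
    lambda_ci: tuple[float, float]
    n_partitions: int
    k_positive: int


def dpcr_concentration(result: PartitionResult, level: float = 0.95) -> DpcrQuant:
    """Poisson quantification from partition counts.

    lambda = -ln(1 - k/N) molecules per partition; copies/reaction =
    lambda * N; copies/mL plasma applies ``reaction_to_plasma_factor``.
    The CI on lambda propagates the exact binomial CI on the positive
    fraction through the same transform.  Saturated plates (k = N) carry no
    finite estimate and raise.
    """
    k, n = result.k_positive, result.n_partitions
    if k == n:
        raise ValueError(
            f"all {n} partitions positive for {result.sample_id}/{result.target}: "
            "saturated, concentration not estimable")
    lam = 0.0 if k == 0 else -math.log1p(-k / n)
    ci = clopper_pearson(k, n, level)
    lam_ci = (abs(-math.log1p(-ci.lower)), abs(-math.log1p(-ci.upper)))
    copies = lam * n
    return DpcrQuant(
        sample_id=result.sample_id, target=result.target,
        lambda_per_partition=lam, copies_per_reaction=copies,
        copies_per_ml=copies * result.reaction_to_plasma_factor,
        lambda_ci=lam_ci, n_partitions=n, k_positive=k)


def percent_methylation(target_copies: float, reference_copies: float) -> float:
    """Marker copies as percent of the total-cfDNA reference target.

    A zero reference leaves the ratio undefined; NaN is returned with a
    warning so callers can flag the sample rather than silently drop it.
    """
    if target_copies < 0 or reference_copies < 0:
        raise ValueError("copy numbers must be non-negative")
    if reference_copies == 0:
        warnings.warn("zero reference copies: percent methylation undefined",
                      stacklevel=2)
        return float("nan")
    return 100.0 * target_copies / reference_copies


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def _kw_statistic(ranks: np.ndarray, sizes: Sequence[int], tie_term: float) -> float:
    n = ranks.size
    h = 0.0
    i = 0
    for sz in sizes:
        r = ranks[i:i + sz].sum()
        h += r * r / sz
        i += sz
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    if tie_term < 1.0:
        h /= tie_term
    return h


def _tie_term(values: np.ndarray) -> float:
    n = values.size
    _, counts = np.unique(values, return_counts=True)
    return 1.0 - float(((counts ** 3 - counts).sum()) / (n ** 3 - n))


_EXACT_KW_MAX_N = 10


def kruskal_wallis(groups: Sequence[Sequence[float]],
                   method: str = "chi2") -> tuple[float, float]:
    """Kruskal-Wallis H test across two or more groups.

    ``method='chi2'`` (default) takes p from the chi-square distribution
    with (groups - 1) degrees of freedom, with tie correction on H.
    ``method='exact'`` enumerates every assignment of the pooled values to
    the group sizes (total n <= 10) and reports the fraction with H at
    least as large.  Identical values across all groups give H = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[~np.isnan(g)] for g in groups]
    if sum(1 for g in groups if g.size > 0) < 2:
        raise ValueError("need at least two non-empty groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group needs at least one value")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    sizes = [g.size for g in groups]
    ranks = stats.rankdata(pooled)
    tie = _tie_term(pooled)
    h = _kw_statistic(ranks, sizes, tie)
    if method == "chi2":
        p = float(stats.chi2.sf(h, len(groups) - 1))
        return h, max(min(p, 1.0), np.finfo(float).tiny)
    if method == "exact":
        n = pooled.size
        if n > _EXACT_KW_MAX_N:
            raise ValueError(f"exact enumeration limited to n <= {_EXACT_KW_MAX_N}")
        idx = list(range(n))
        count = 0
        total = 0

        def recurse(remaining: list[int], gi: int, chosen: list[np.ndarray]):
            nonlocal count, total
            if gi == len(sizes) - 1:
                assign = chosen + [np.array(remaining, dtype=int)]
                perm_ranks = np.concatenate([ranks[a] for a in assign])
                h_perm = _kw_statistic(perm_ranks, sizes, tie)
                total += 1
                if h_perm >= h - 1e-12:
                    count += 1
                return
            for comb in combinations(remaining, sizes[gi]):
                rest = [i for i in remaining if i not in set(comb)]
                recurse(rest, gi + 1, chosen + [np.array(comb, dtype=int)])

        recurse(idx, 0, [])
        return h, count / total
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Clinical cohort summary
# ---------------------------------------------------------------------------

@dataclass
class ClinicalSummary:
    per_sample: pd.DataFrame
    group_summary: pd.DataFrame
    kw_absolute: tuple[float, float]
    kw_relative: tuple[float, float]


def clinical_summary(results: Sequence[PartitionResult], sheet: SampleSheet,
                     marker: str = "marker",
                     reference: str = "total_reference") -> ClinicalSummary:
    """Per-sample and per-group marker cfDNA quantification.

    For every sample with both a marker and a reference partition result,
    computes absolute marker copies/mL plasma and marker percent of total
    cfDNA, then group medians/IQRs and a Kruskal-Wallis test on each
    measure.  Samples missing either target are excluded with a warning.
    Undetectable markers (k = 0) are genuine zeroes, not missing.
    """
    by_sample: dict[str, dict[str, PartitionResult]] = {}
    for r in results:
        by_sample.setdefault(r.sample_id, {})[r.target] = r
    group_of = dict(zip(sheet.table["sample_id"], sheet.table["group"]))

    rows = []
    skipped = []
    for sid, targets in by_sample.items():
        if marker not in targets or reference not in targets:
            skipped.append(sid)
            continue
        mq = dpcr_concentration(targets[marker])
        rq = dpcr_concentration(targets[reference])
        pct = (percent_methylation(mq.copies_per_ml, rq.copies_per_ml)
               if rq.copies_per_ml > 0 else float("nan"))
        rows.append((sid, group_of.get(sid), mq.copies_per_ml,
                     rq.copies_per_ml, pct))
    if skipped:
        warnings.warn(f"samples missing marker or reference target, excluded: "
                      f"{skipped[:5]}", stacklevel=2)
    per_sample = pd.DataFrame(rows, columns=[
        "sample_id", "group", "marker_copies_per_ml",
        "total_copies_per_ml", "marker_pct_of_total"])

    grouped = per_sample.groupby("group", dropna=True)
    if grouped.ngroups < 2:
        raise ValueError("Kruskal-Wallis needs at least two clinical groups")
    summary = grouped.agg(
        n=("sample_id", "size"),
        marker_median=("marker_copies_per_ml", "median"),
        marker_q1=("marker_copies_per_ml", lambda v: v.quantile(0.25)),
        marker_q3=("marker_copies_per_ml", lambda v: v.quantile(0.75)),
        pct_median=("marker_pct_of_total", "median"),
        pct_q1=("marker_pct_of_total", lambda v: v.quantile(0.25)),
        pct_q3=("marker_pct_of_total", lambda v: v.quantile(0.75)),
    ).reset_index()

    abs_groups = [g["marker_copies_per_ml"].to_numpy() for _, g in grouped]
    rel_groups = [g["marker_pct_of_total"].dropna().to_numpy() for _, g in grouped]
    kw_abs = kruskal_wallis(abs_groups)
    kw_rel = kruskal_wallis(rel_groups)
    return ClinicalSummary(per_sample=per_sample, group_summary=summary,
                           kw_absolute=kw_abs, kw_relative=kw_rel)


# ---------------------------------------------------------------------------
# Reconstruction of counts from published summaries
# ---------------------------------------------------------------------------

def reconstruct_binomial_counts(rate_pct: float, n_range: tuple[int, int],
                                ci_pct: tuple[float, float] | None = None,
                                ci_tol_pct: float = 0.1,
                                level: float = 0.95) -> list[dict]:
    """Candidate (k, n) pairs consistent with a published positivity summary.

    Enumerates all totals in ``n_range`` (inclusive) and counts whose
    positivity rounds to ``rate_pct`` at one decimal.  When a published
    confidence interval is given, candidates are kept only if the exact
    binomial CI reproduces both printed bounds within ``ci_tol_pct``
    percentage points (default one unit in the last printed digit).
    Returned sorted by CI deviation, closest first.
    """
    lo_n, hi_n = n_range
    out = []
    for n in range(lo_n, hi_n + 1):
        for k in range(n + 1):
            if round(100 * k / n, 1) != round(rate_pct, 1):
                continue
            dev = 0.0
            if ci_pct is not None:
                ci = clopper_pearson(k, n, level)
                d_lo = abs(100 * ci.lower - ci_pct[0])
                d_hi = abs(100 * ci.upper - ci_pct[1])
                if max(d_lo, d_hi) > ci_tol_pct + 1e-12:
                    continue
                dev = max(d_lo, d_hi)
            out.append({"k": k, "n": n, "ci_deviation_pct": dev})
    out.sort(key=lambda c: (c["ci_deviation_pct"], -c["n"]))
    return out


def single_copy_comparison(rate_a_pct: float, ci_a_pct: tuple[float, float],
                           rate_b_pct: float, ci_b_pct: tuple[float, float],
                           n_range: tuple[int, int],
                           published_p: float | None = None) -> dict:
    """Compare two assays' single-molecule positivity from published summaries.

    Reconstructs each assay's (k, n) from its printed rate and CI (see
    :func:`reconstruct_binomial_counts`), then evaluates Fisher's exact test
    on every consistent pair of reconstructions.  When a published p-value
    is supplied, the pair whose p matches it at the printed precision is
    preferred (the p-value is one more published constraint on the unknown
    counts); otherwise, and among remaining ties, the pair with the smallest
    joint CI deviation wins.

    Returns the chosen counts, the Fisher p, and both assays' recomputed
    rates and CIs.
    """
    cand_a = reconstruct_binomial_counts(rate_a_pct, n_range, ci_a_pct)
    cand_b = reconstruct_binomial_counts(rate_b_pct, n_range, ci_b_pct)
    if not cand_a or not cand_b:
        raise ValueError("no counts consistent with the published summaries")

    def digits(x: float) -> int:
        s = f"{x}"
        return len(s.split(".")[1]) if "." in s else 0

    best = None
    for a in cand_a:
        for b in cand_b:
            p = fisher_exact(a["k"], a["n"], b["k"], b["n"])
            if published_p is not None:
                nd = digits(published_p)
                p_match = round(p, nd) == published_p
            else:
                p_match = True
            key = (not p_match,
                   abs(p - published_p) if published_p is not None else 0.0,
                   a["ci_deviation_pct"] + b["ci_deviation_pct"])
            if best is None or key < best[0]:
                best = (key, a, b, p)
    _, a, b, p = best
    ci_a = clopper_pearson(a["k"], a["n"])
    ci_b = clopper_pearson(b["k"], b["n"])
    return {
        "assay_a": {"k": a["k"], "n": a["n"],
                    "rate_pct": 100 * a["k"] / a["n"],
                    "ci_pct": (100 * ci_a.lower, 100 * ci_a.upper)},
        "assay_b": {"k": b["k"], "n": b["n"],
                    "rate_pct": 100 * b["k"] / b["n"],
                    "ci_pct": (100 * ci_b.lower, 100 * ci_b.upper)},
        "fisher_p": p,
    }
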