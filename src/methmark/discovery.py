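"""Differentially methylated region (DMR) discovery for one target tissue.

The discovery strategy finds CpG probes that are hypermethylated in a target
tissue (here, typically kidney) and unmethylated everywhere else, then keeps
only probes that sit in locally dense clusters — amenable to a short PCR
amplicon — and finally removes probes with any appreciable methylation in
blood, the dominant source of circulating cell-free DNA.

Stages, each with strict thresholds exactly as applied:

1. per-probe two-sample Wilcoxon rank-sum test of target vs. all other
   tissues, Benjamini-Hochberg adjusted across all tested probes;
2. probe filter: FDR < 1e-10, delta-beta > 0.3, mean beta in other
   tissues < 0.1 (all strict);
3. regional density: a probe survives iff >= 2 passing probes (itself
   included) lie within +/-2.5 kb of it (a 5 kb window centred on the CpG,
   boundary inclusive);
4. DMR assembly: single-linkage clustering of surviving probes at a 2.5 kb
   gap threshold; a DMR spans the min-to-max member position;
5. blood exclusion: probes with median blood beta > 0.1 or blood positivity
   (beta > 0.2) above 2% are excluded, and DMRs falling below the minimum
   probe count are dropped.

Missing beta-values are excluded pairwise: each probe is tested on its
non-missing samples only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import BetaMatrix, ProbeAnnotation, SampleSheet

__all__ = [
    "DmcThresholds",
    "Dmr",
    "DiscoveryRun",
    "rank_sum_test",
    "bh_adjust",
    "differential_methylation",
    "dmc_filter",
    "region_density_filter",
    "assemble_dmrs",
    "blood_metrics",
    "blood_exclude",
    "discover",
]


@dataclass(frozen=True)
class DmcThresholds:
    """Thresholds of the probe and region filters (strict inequalities)."""

    fdr_max: float = 1e-10
    delta_min: float = 0.3
    other_mean_max: float = 0.1
    window_bp: int = 5000
    min_probes_in_window: int = 2

    def __post_init__(self) -> None:
        if min(self.fdr_max, self.delta_min, self.other_mean_max,
               self.window_bp, self.min_probes_in_window) <= 0:
            raise ValueError("all thresholds must be positive")
        if self.delta_min > 1:
            raise ValueError("delta_min cannot exceed 1")

    @property
    def half_window(self) -> float:
        return self.window_bp / 2


@dataclass(frozen=True)
class Dmr:
    """A differentially methylated region: span of clustered member probes."""

    chrom: str
    start: int
    end: int
    probe_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"DMR start {self.start} > end {self.end}")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)


# ---------------------------------------------------------------------------
# Per-probe statistics
# ---------------------------------------------------------------------------

_EXACT_MAX_N = 12


def rank_sum_test(a, b) -> tuple[float, float]:
    """Two-sample Wilcoxon rank-sum (Mann-Whitney) test, two-sided.

    Uses the exact null distribution when the combined sample size is at
    most 12 and there are no ties; otherwise the normal approximation with
    tie-corrected variance.  Returns ``(U statistic of a, p)``.  Degenerate
    all-tied data yields p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("each group needs at least one non-missing value")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return a.size * b.size / 2.0, 1.0
    n = a.size + b.size
    ties = np.unique(pooled).size < n
    method = "exact" if (n <= _EXACT_MAX_N and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = min(float(res.pvalue), 1.0)
    return float(res.statistic), p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_methylation(matrix: BetaMatrix, sheet: SampleSheet,
                             target_tissue: str) -> pd.DataFrame:
    """Per-probe differential methylation of target vs. all other tissues.

    Only ``discovery``-role samples enter the comparison.  Probes lacking a
    non-missing value in either group are reported with NaN statistics and
    excluded from the joint BH adjustment.

    Returns a DataFrame with columns probe_id, mean_target, mean_other,
    delta, p_value, fdr, n_target, n_other.
    """
    target_samples = sheet.samples(role="discovery", tissue=target_tissue)
    if len(target_samples) < 2:
        raise ValueError(
            f"target tissue {target_tissue!r} needs >= 2 discovery samples"
        )
    disc = sheet.table[sheet.table["role"] == "discovery"]
    other_samples = list(disc.loc[disc["tissue"] != target_tissue, "sample_id"])
    if not other_samples:
        raise ValueError("no non-target discovery samples")
    for s in target_samples + other_samples:
        if s not in matrix.values.columns:
            raise KeyError(f"sample {s!r} not present in beta-matrix")

    tgt = matrix.values[target_samples].to_numpy()
    oth = matrix.values[other_samples].to_numpy()
    rows = []
    for i, probe in enumerate(matrix.probe_ids):
        a = tgt[i][~np.isnan(tgt[i])]
        b = oth[i][~np.isnan(oth[i])]
        if a.size == 0 or b.size == 0:
            rows.append((probe, np.nan, np.nan, np.nan, np.nan, a.size, b.size))
            continue
        _, p = rank_sum_test(a, b)
        rows.append((probe, a.mean(), b.mean(), a.mean() - b.mean(), p,
                     a.size, b.size))
    df = pd.DataFrame(rows, columns=["probe_id", "mean_target", "mean_other",
                                     "delta", "p_value", "n_target", "n_other"])
    df["fdr"] = np.nan
    tested = df["p_value"].notna()
    if tested.any():
        df.loc[tested, "fdr"] = bh_adjust(df.loc[tested, "p_value"].to_numpy())
    return df[["probe_id", "mean_target", "mean_other", "delta",
               "p_value", "fdr", "n_target", "n_other"]]


# ---------------------------------------------------------------------------
# Filters and DMR assembly
# ---------------------------------------------------------------------------

def dmc_filter(results: pd.DataFrame,
               thresholds: DmcThresholds = DmcThresholds()) -> list[str]:
    """Probes passing the three probe-level criteria (strict inequalities)."""
    ok = (
        (results["fdr"] < thresholds.fdr_max)
        & (results["delta"] > thresholds.delta_min)
        & (results["mean_other"] < thresholds.other_mean_max)
    )
    return list(results.loc[ok.fillna(False), "probe_id"])


def _positions(probe_ids: Sequence[str], annotation: ProbeAnnotation) -> pd.DataFrame:
    try:
        ann = annotation.lookup(probe_ids)
    except KeyError as e:
        raise ValueError(f"passing probes lack annotation: {e}") from None
    return ann


def region_density_filter(probe_ids: Sequence[str], annotation: ProbeAnnotation,
                          thresholds: DmcThresholds = DmcThresholds()) -> list[str]:
    """Keep probes with enough passing neighbours within the half-window.

    A probe is retained iff >= ``min_probes_in_window`` passing probes
    (itself included) sit on its chromosome within ``window_bp / 2`` of its
    position; a distance of exactly half a window counts as inside.
    """
    if not probe_ids:
        return []
    ann = _positions(probe_ids, annotation)
    keep: list[str] = []
    for _, sub in ann.groupby("chrom", sort=False):
        pos = np.sort(sub["position"].to_numpy())
        for _, row in sub.iterrows():
            lo = np.searchsorted(pos, row["position"] - thresholds.half_window, "left")
            hi = np.searchsorted(pos, row["position"] + thresholds.half_window, "right")
            if hi - lo >= thresholds.min_probes_in_window:
                keep.append(row["probe_id"])
    order = {p: i for i, p in enumerate(probe_ids)}
    return sorted(keep, key=order.__getitem__)


def assemble_dmrs(probe_ids: Sequence[str], annotation: ProbeAnnotation,
                  thresholds: DmcThresholds = DmcThresholds()) -> list[Dmr]:
    """Single-linkage clustering of retained probes into DMRs.

    Probes on one chromosome join a cluster when consecutive positions are
    at most ``window_bp / 2`` apart; each cluster becomes one DMR spanning
    the min-to-max member position.  Clusters are disjoint and cover every
    retained probe with enough members.
    """
    if not probe_ids:
        return []
    ann = _positions(probe_ids, annotation).sort_values(["chrom", "position"])
    dmrs: list[Dmr] = []
    for chrom, sub in ann.groupby("chrom", sort=True):
        pos = sub["position"].to_numpy()
        ids = sub["probe_id"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > thresholds.half_window) + 1
        for cluster in np.split(np.arange(len(pos)), breaks):
            members = tuple(ids[cluster])
            if len(members) >= thresholds.min_probes_in_window:
                dmrs.append(Dmr(chrom=chrom, start=int(pos[cluster[0]]),
                                end=int(pos[cluster[-1]]), probe_ids=members))
    return dmrs


# ---------------------------------------------------------------------------
# Blood background
# ---------------------------------------------------------------------------

def blood_metrics(blood: BetaMatrix, probe_ids: Sequence[str],
                  positivity_cutoff: float = 0.2) -> pd.DataFrame:
    """Median blood beta and positivity fraction per probe.

    Positivity is the fraction of non-missing blood samples with beta above
    ``positivity_cutoff``.  Probes absent from the blood matrix are flagged
    unavailable (NaN metrics) and carried forward with a warning rather than
    scored.
    """
    if blood.shape[1] < 1:
        raise ValueError("blood matrix needs at least one sample")
    rows = []
    absent = []
    for probe in probe_ids:
        if probe not in blood.values.index:
            absent.append(probe)
            rows.append((probe, np.nan, np.nan, 0, False))
            continue
        v = blood.values.loc[probe].to_numpy(dtype=float)
        v = v[~np.isnan(v)]
        if v.size == 0:
            absent.append(probe)
            rows.append((probe, np.nan, np.nan, 0, False))
            continue
        rows.append((probe, float(np.median(v)),
                     float(np.mean(v > positivity_cutoff)), v.size, True))
    if absent:
        warnings.warn(
            f"{len(absent)} probe(s) not measured in blood reference; "
            f"carried forward unscored: {absent[:5]}", stacklevel=2)
    return pd.DataFrame(rows, columns=["probe_id", "median_beta", "positivity",
                                       "n_samples", "available"])


def blood_exclude(metrics: pd.DataFrame, median_max: float = 0.1,
                  positivity_max: float = 0.02) -> list[str]:
    """Probes surviving the blood-background exclusion.

    A probe is excluded when its blood median beta exceeds ``median_max`` OR
    its positivity exceeds ``positivity_max`` (both strictly greater-than,
    so values exactly on a boundary are retained).  Unscored probes are
    retained.
    """
    excl = (metrics["median_beta"] > median_max) | (metrics["positivity"] > positivity_max)
    return list(metrics.loc[~excl.fillna(False), "probe_id"])


# ---------------------------------------------------------------------------
# Full discovery pipeline
# ---------------------------------------------------------------------------

@dataclass
class DiscoveryRun:
    """All intermediate tables and stage-by-stage probe accounting."""

    dmc: pd.DataFrame
    dmc_pass: list[str]
    region_pass: list[str]
    dmrs_pre_blood: list[Dmr]
    blood: pd.DataFrame | None
    blood_pass: list[str]
    dmrs: list[Dmr]
    thresholds: DmcThresholds
    stage_counts: dict = field(default_factory=dict)


def discover(matrix: BetaMatrix, sheet: SampleSheet, annotation: ProbeAnnotation,
             target_tissue: str, blood: BetaMatrix | None = None,
             thresholds: DmcThresholds = DmcThresholds(),
             positivity_cutoff: float = 0.2, median_max: float = 0.1,
             positivity_max: float = 0.02) -> DiscoveryRun:
    """Run the full discovery pipeline for one target tissue.

    When ``blood`` is None the blood-exclusion stage is skipped and the
    region-stage DMRs are final.
    """
    dmc = differential_methylation(matrix, sheet, target_tissue)
    dmc_pass = dmc_filter(dmc, thresholds)
    region_pass = region_density_filter(dmc_pass, annotation, thresholds)
    dmrs_pre = assemble_dmrs(region_pass, annotation, thresholds)

    if blood is not None:
        metrics = blood_metrics(blood, region_pass, positivity_cutoff)
        blood_pass = blood_exclude(metrics, median_max, positivity_max)
        dmrs = assemble_dmrs(blood_pass, annotation, thresholds)
    else:
        metrics = None
        blood_pass = list(region_pass)
        dmrs = dmrs_pre

    counts = {
        "probes_in": len(matrix.probe_ids),
        "probes_tested": int(dmc["p_value"].notna().sum()),
        "dmc_pass": len(dmc_pass),
        "region_pass": len(region_pass),
        "dmrs_pre_blood": len(dmrs_pre),
        "blood_pass": len(blood_pass),
        "dmrs": len(dmrs),
        "dmr_probes": sum(d.n_probes for d in dmrs),
    }
    return DiscoveryRun(dmc=dmc, dmc_pass=dmc_pass, region_pass=region_pass,
                        dmrs_pre_blood=dmrs_pre, blood=metrics,
                        blood_pass=blood_pass, dmrs=dmrs,
                        thresholds=thresholds, stage_counts=counts)
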