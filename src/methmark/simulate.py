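"""Seeded generators for every input the biomarker pipeline consumes.

These generators emulate the statistical structure of the data a real
discovery-to-validation campaign would use, with planted ground truth so
recovery can be measured:

* **tissue atlas beta-matrices** — background methylation drawn from a
  low-mean Beta distribution (unimodal near 0, respecting the [0, 1]
  support of beta-values), with hypermethylated probes planted in the
  target tissue at a chosen delta-beta.  Default cohort sizes mirror a
  typical 450K atlas discovery setting: 45 target-tissue samples against
  489 spread over 16 other tissues;
* **blood reference panels** — whole-blood profiles (default n = 662) with
  optional sporadically positive probes, for the blood-exclusion filter;
* **genomic regions** — random sequence with CpG dinucleotides planted at a
  chosen density (optionally clustered centrally, as in a CpG island) for
  primer-design fixtures;
* **replicate screens and digital-PCR partitions** — Bernoulli/Binomial
  counts driven by the Poisson single-molecule occupancy model
  P(positive) = 1 - e^(-efficiency * lambda);
* **clinical cohorts** — per-sample marker and total-reference partition
  counts for group sizes mirroring a small transplant study (HC 9,
  Pre-Tx 5, D1 7, D7 2), with kidney marker absent outside the
  post-transplant groups.

A single integer seed drives a hierarchy of independent named streams, so
adding one generator call never perturbs the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import GenomicSequence
from .discovery import Dmr
from .evaluate import PartitionResult, ReplicateScreen
from .io import BetaMatrix, ProbeAnnotation, SampleSheet

__all__ = [
    "SyntheticTruth",
    "stream",
    "default_other_tissues",
    "simulate_beta_matrix",
    "simulate_blood_reference",
    "simulate_genomic_region",
    "simulate_replicate_screen",
    "simulate_partitions",
    "simulate_clinical_cohort",
]


def stream(seed: int, purpose: str) -> np.random.Generator:
    """Independent RNG stream derived from (seed, purpose name)."""
    tag = zlib.crc32(purpose.encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, tag]))


@dataclass
class SyntheticTruth:
    """Planted effects behind a simulated dataset, for recovery testing."""

    seed: int
    planted_dmrs: list[Dmr] = field(default_factory=list)
    planted_delta: float = 0.0
    blood_contaminated_probes: dict = field(default_factory=dict)
    group_lambdas: dict = field(default_factory=dict)


def _beta_params(mean: float, concentration: float) -> tuple[float, float]:
    if not 0 < mean < 1:
        raise ValueError(f"Beta mean must lie in (0, 1), got {mean}")
    return mean * concentration, (1 - mean) * concentration


def default_other_tissues() -> dict[str, int]:
    """16 non-target tissue labels with sample counts summing to 489."""
    names = ["Bile duct", "Bladder", "Breast", "Cervix", "Colon", "Oesophagus",
             "Head and Neck", "Liver", "Lung", "Pancreas", "Prostate",
             "Rectum", "Stomach", "Thymus", "Thyroid gland", "Uterus"]
    sizes = [31] * 9 + [30] * 7
    return dict(zip(names, sizes))


# ---------------------------------------------------------------------------
# Atlas beta-matrix
# ---------------------------------------------------------------------------

def simulate_beta_matrix(
    seed: int,
    target_tissue: str = "Kidney",
    n_target: int = 45,
    other_tissues: Mapping[str, int] | None = None,
    n_background_probes: int = 200,
    n_dmrs: int = 3,
    probes_per_dmr: int = 2,
    dmr_probe_spacing: int = 1000,
    delta: float = 0.5,
    background_mean: float = 0.03,
    concentration: float = 20.0,
    missing_rate: float = 0.0,
) -> tuple[BetaMatrix, SampleSheet, ProbeAnnotation, SyntheticTruth]:
    """Simulate a tissue methylation atlas with planted hypermethylated DMRs.

    Background probes are laid out in pairs ~2 kb apart (so the regional
    density filter is exercised, not bypassed); planted DMR probes cluster
    within a 5 kb span and carry ``delta`` extra methylation in the target
    tissue only.  ``delta = 0`` gives a pure null matrix whose truth lists
    the planted regions with zero effect.
    """
    if other_tissues is None:
        other_tissues = default_other_tissues()
    if not 0 <= background_mean + delta <= 1:
        raise ValueError("background_mean + delta must stay within [0, 1]")

    rng = stream(seed, "beta_matrix")

    # --- probe layout: background pairs on chr1.., planted DMRs on chr20..
    probe_ids, chroms, positions = [], [], []
    for i in range(n_background_probes):
        pair, member = divmod(i, 2)
        probe_ids.append(f"cg_bg{i:05d}")
        chroms.append(f"chr{1 + (pair % 10)}")
        # pair members 2 kb apart (inside one window), pairs 50 kb apart
        positions.append(1_000_000 + (pair // 10) * 50_000 + member * 2_000)
    planted: list[Dmr] = []
    for d in range(n_dmrs):
        ids = []
        base = 5_000_000 + d * 100_000
        chrom = f"chr{20 + (d % 3)}"
        for j in range(probes_per_dmr):
            pid = f"cg_dmr{d}_{j}"
            ids.append(pid)
            probe_ids.append(pid)
            chroms.append(chrom)
            positions.append(base + j * dmr_probe_spacing)
        planted.append(Dmr(chrom=chrom, start=base,
                           end=base + (probes_per_dmr - 1) * dmr_probe_spacing,
                           probe_ids=tuple(ids)))

    annotation = ProbeAnnotation(pd.DataFrame(
        {"probe_id": probe_ids, "chrom": chroms, "position": positions}))

    # --- samples
    sample_ids, tissues = [], []
    for t, n in [(target_tissue, n_target)] + list(other_tissues.items()):
        for i in range(n):
            sample_ids.append(f"{t.replace(' ', '_')}_{i:03d}")
            tissues.append(t)
    sheet = SampleSheet(pd.DataFrame(
        {"sample_id": sample_ids, "tissue": tissues,
         "role": "discovery", "group": pd.NA}))

    # --- values
    a_bg, b_bg = _beta_params(background_mean, concentration)
    n_probes, n_samples = len(probe_ids), len(sample_ids)
    values = rng.beta(a_bg, b_bg, size=(n_probes, n_samples))
    if delta > 0:
        a_hi, b_hi = _beta_params(background_mean + delta, concentration)
        is_target = np.array([t == target_tissue for t in tissues])
        planted_rows = [probe_ids.index(p) for d in planted for p in d.probe_ids]
        hot = rng.beta(a_hi, b_hi, size=(len(planted_rows), int(is_target.sum())))
        for r, row in enumerate(planted_rows):
            values[row, is_target] = hot[r]
    if missing_rate > 0:
        mask = rng.random((n_probes, n_samples)) < missing_rate
        values = np.where(mask, np.nan, values)

    matrix = BetaMatrix(pd.DataFrame(values, index=probe_ids, columns=sample_ids))
    truth = SyntheticTruth(seed=seed, planted_dmrs=planted, planted_delta=delta)
    return matrix, sheet, annotation, truth


def simulate_blood_reference(
    seed: int,
    probe_ids: Sequence[str],
    n_samples: int = 662,
    background_mean: float = 0.03,
    concentration: float = 30.0,
    contaminated: Mapping[str, float] | None = None,
    contaminated_mean: float = 0.4,
) -> BetaMatrix:
    """Simulate a whole-blood reference panel.

    ``contaminated`` maps probe ids to a per-sample probability of an
    elevated (beta above the 0.2 positivity cutoff, in expectation) value,
    modelling sporadic blood-positive probes that the blood filter must
    catch.
    """
    contaminated = dict(contaminated or {})
    rng = stream(seed, "blood_reference")
    a_bg, b_bg = _beta_params(background_mean, concentration)
    a_hi, b_hi = _beta_params(contaminated_mean, concentration)
    values = rng.beta(a_bg, b_bg, size=(len(probe_ids), n_samples))
    for i, probe in enumerate(probe_ids):
        rate = contaminated.get(probe, 0.0)
        if rate > 0:
            hit = rng.random(n_samples) < rate
            values[i, hit] = rng.beta(a_hi, b_hi, size=int(hit.sum()))
    cols = [f"WB_{i:04d}" for i in range(n_samples)]
    return BetaMatrix(pd.DataFrame(values, index=list(probe_ids), columns=cols))


# ---------------------------------------------------------------------------
# Genomic regions
# ---------------------------------------------------------------------------

def simulate_genomic_region(
    seed: int,
    length: int = 300,
    cpg_density: float = 0.05,
    gc_background: float = 0.4,
    clustered: bool = False,
    chrom: str = "chrS",
    start: int = 1,
) -> GenomicSequence:
    """Random sequence with CpG dinucleotides planted at a target density.

    The number of CpGs is Binomial(length, density); sites are placed
    non-adjacently (optionally restricted to the central third, emulating a
    CpG island) and the remaining bases are drawn at ``gc_background`` GC
    content with accidental CG dinucleotides broken, so the realised CpG
    count equals the planted one.
    """
    if not 0 <= cpg_density <= 0.2:
        raise ValueError("cpg_density must lie in [0, 0.2]")
    rng = stream(seed, "genomic_region")
    n_cpg = int(rng.binomial(length, cpg_density))
    if clustered:
        lo, hi = length // 3, 2 * length // 3
    else:
        lo, hi = 0, length - 1
    # candidate left positions of CG, spaced >= 2 apart
    slots = np.arange(lo, hi, 2)
    n_cpg = min(n_cpg, len(slots))
    sites = np.sort(rng.choice(slots, size=n_cpg, replace=False))

    seq = [""] * length
    p_gc = gc_background / 2
    bases = rng.choice(np.array(list("ACGT")), size=length,
                       p=[(1 - gc_background) / 2, p_gc, p_gc,
                          (1 - gc_background) / 2])
    for i in range(length):
        seq[i] = bases[i]
    for s in sites:
        seq[s], seq[s + 1] = "C", "G"
    # break accidental CpGs outside planted sites
    planted_left = set(int(s) for s in sites)
    for i in range(length - 1):
        if seq[i] == "C" and seq[i + 1] == "G" and i not in planted_left:
            seq[i + 1] = "A"
    # the fix can only remove, never create, CG (A follows C harmlessly)
    return GenomicSequence(chrom=chrom, start=start, seq="".join(seq))


# ---------------------------------------------------------------------------
# Screens, partitions, cohorts
# ---------------------------------------------------------------------------

def simulate_replicate_screen(
    seed: int,
    lam: float,
    detection_efficiency: float = 1.0,
    n_replicates: int = 343,
    assay_id: str = "assay",
) -> ReplicateScreen:
    """Replicate screen at mean ``lam`` copies/reaction.

    Each replicate is positive with probability
    1 - exp(-efficiency * lam): Poisson loading of single molecules thinned
    by the assay's per-molecule detection efficiency.
    """
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    if not 0 <= detection_efficiency <= 1:
        raise ValueError("detection efficiency must lie in [0, 1]")
    rng = stream(seed, f"screen:{assay_id}")
    p = -np.expm1(-detection_efficiency * lam)
    k = int(rng.binomial(n_replicates, p))
    return ReplicateScreen(assay_id=assay_id, n_replicates=n_replicates,
                           k_positive=k, nominal_copies=lam)


def simulate_partitions(
    seed: int,
    lam: float,
    n_partitions: int = 26_000,
    sample_id: str = "sample",
    target: str = "marker",
    reaction_to_plasma_factor: float = 1.0,
) -> PartitionResult:
    """Digital-PCR plate: each partition positive with prob 1 - e^(-lam)."""
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    rng = stream(seed, f"partitions:{sample_id}:{target}")
    k = int(rng.binomial(n_partitions, -np.expm1(-lam)))
    return PartitionResult(sample_id=sample_id, target=target,
                           n_partitions=n_partitions, k_positive=k,
                           reaction_to_plasma_factor=reaction_to_plasma_factor)


DEFAULT_GROUP_SIZES = {"HC": 9, "Pre-Tx": 5, "D1": 7, "D7": 2}
#: Mean marker molecules per partition by clinical group.  Kidney marker is
#: absent outside the post-transplant groups; the reference (total cfDNA)
#: target is present everywhere.
DEFAULT_MARKER_LAMBDAS = {"HC": 0.0, "Pre-Tx": 0.0, "D1": 0.005, "D7": 0.001}
DEFAULT_REFERENCE_LAMBDA = 0.05


def simulate_clinical_cohort(
    seed: int,
    group_sizes: Mapping[str, int] | None = None,
    marker_lambdas: Mapping[str, float] | None = None,
    reference_lambda: float | Mapping[str, float] = DEFAULT_REFERENCE_LAMBDA,
    n_partitions: int = 26_000,
    reaction_to_plasma_factor: float = 1.0,
) -> tuple[list[PartitionResult], SampleSheet, SyntheticTruth]:
    """Simulate a clinical plasma cohort measured by digital PCR.

    Returns marker and total-reference partition results per sample, a
    sample sheet with clinical group labels, and the planted group lambdas.
    """
    group_sizes = dict(group_sizes or DEFAULT_GROUP_SIZES)
    marker_lambdas = dict(marker_lambdas or DEFAULT_MARKER_LAMBDAS)
    missing = set(group_sizes) - set(marker_lambdas)
    if missing:
        raise ValueError(f"groups without a marker lambda: {sorted(missing)}")
    if any(l < 0 for l in marker_lambdas.values()):
        raise ValueError("lambdas must be non-negative")

    results: list[PartitionResult] = []
    rows = []
    i = 0
    for group, size in group_sizes.items():
        ref_lam = (reference_lambda[group]
                   if isinstance(reference_lambda, Mapping) else reference_lambda)
        for _ in range(size):
            sid = f"P{i:03d}"
            i += 1
            rows.append((sid, "Plasma", "validation", group))
            results.append(simulate_partitions(
                seed, marker_lambdas[group], n_partitions, sid, "marker",
                reaction_to_plasma_factor))
            results.append(simulate_partitions(
                seed, ref_lam, n_partitions, sid, "total_reference",
                reaction_to_plasma_factor))
    sheet = SampleSheet(pd.DataFrame(
        rows, columns=["sample_id", "tissue", "role", "group"]))
    truth = SyntheticTruth(seed=seed, group_lambdas={
        "marker": marker_lambdas,
        "reference": (dict(reference_lambda)
                      if isinstance(reference_lambda, Mapping)
                      else reference_lambda)})
    return results, sheet, truth
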