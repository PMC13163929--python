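"""Core data containers and plain-text I/O for methylation-array data.

Methylation on Illumina BeadChip arrays is summarised per CpG probe as a
beta-value, the fraction of methylated signal

    beta = M / (M + U + 100)

where ``M`` and ``U`` are the methylated and unmethylated probe intensities
and the constant 100 stabilises the ratio at low total intensity.  Beta
ranges from 0 (fully unmethylated) to 1 (fully methylated) and is the unit
every downstream statistic in this package operates on; percentages are for
display only.

Containers here are thin, validated wrappers around :class:`pandas.DataFrame`
so the rest of the package can rely on their invariants (values in [0, 1],
unique identifiers, known column sets) without re-checking them.

Genomic coordinates are 1-based inclusive internally, matching the Illumina
manifest convention; BED export converts to 0-based half-open at the
boundary.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "IntensityPair",
    "BetaMatrix",
    "SampleSheet",
    "ProbeAnnotation",
    "ROLES",
    "beta_from_intensities",
    "beta_to_percent",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "read_probe_annotation",
    "write_regions_bed",
    "read_bed_intervals",
    "read_fasta_regions",
    "load_config",
]

#: Closed set of cohort roles a sample may take.
ROLES = frozenset({"discovery", "blood_reference", "validation"})

#: Offset added to the intensity denominator (Illumina convention).
BETA_OFFSET = 100.0


@dataclass(frozen=True)
class IntensityPair:
    """Methylated/unmethylated probe intensity pair for one CpG."""

    M: float
    U: float

    def __post_init__(self) -> None:
        for name, v in (("M", self.M), ("U", self.U)):
            if not np.isfinite(v):
                raise ValueError(f"intensity {name} must be finite, got {v!r}")
            if v < 0:
                raise ValueError(f"intensity {name} must be non-negative, got {v!r}")

    @property
    def beta(self) -> float:
        return beta_from_intensities(self.M, self.U)


def beta_from_intensities(m, u, offset: float = BETA_OFFSET):
    """Beta-value from methylated/unmethylated intensities: M / (M + U + offset).

    Accepts scalars or arrays.  Strictly below 1 for finite input, monotone
    increasing in ``m`` and decreasing in ``u``.
    """
    m = np.asarray(m, dtype=float)
    u = np.asarray(u, dtype=float)
    if not (np.all(np.isfinite(m)) and np.all(np.isfinite(u))):
        raise ValueError("intensities must be finite")
    if np.any(m < 0) or np.any(u < 0):
        raise ValueError("intensities must be non-negative")
    out = m / (m + u + offset)
    return float(out) if out.ndim == 0 else out


def beta_to_percent(beta):
    """Scale beta-values to percent methylation (display only).

    Statistics are always computed on the original beta scale; this exists
    solely for reporting.
    """
    b = np.asarray(beta, dtype=float)
    if np.any((b < 0) | (b > 1) | ~np.isfinite(b)):
        raise ValueError("beta-values must lie in [0, 1]")
    out = b * 100.0
    return float(out) if out.ndim == 0 else out


def _check_unique(ids: Iterable[str], kind: str) -> None:
    ids = list(ids)
    seen: set[str] = set()
    dups = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
    if dups:
        raise ValueError(f"duplicate {kind} identifiers: {dups[:5]}")


@dataclass
class BetaMatrix:
    """Probes x samples matrix of beta-values with missing values allowed.

    ``values`` is a float DataFrame indexed by probe id with sample ids as
    columns; NaN marks a missing measurement (failed probe on an array).
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        self.values = self.values.astype(float)
        self.values.index = self.values.index.rename("probe_id")
        self.values.columns = self.values.columns.rename(None)
        _check_unique(self.values.index, "probe")
        _check_unique(self.values.columns, "sample")
        arr = self.values.to_numpy()
        bad = (arr < 0) | (arr > 1)
        bad &= ~np.isnan(arr)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"beta-value out of [0, 1] at probe {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r}: {arr[r, c]}"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        return BetaMatrix(self.values.loc[:, list(sample_ids)])


@dataclass
class SampleSheet:
    """Sample metadata: tissue label, cohort role, optional clinical group."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "tissue", "role")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValueError(f"sample sheet missing column {col!r}")
        if "group" not in t.columns:
            t = t.assign(group=pd.NA)
        _check_unique(t["sample_id"], "sample")
        if t["tissue"].isna().any() or (t["tissue"].astype(str).str.len() == 0).any():
            raise ValueError("tissue labels must be non-empty")
        bad_roles = sorted(set(t["role"]) - ROLES)
        if bad_roles:
            raise ValueError(f"unknown roles {bad_roles}; allowed: {sorted(ROLES)}")
        self.table = t.reset_index(drop=True)

    def samples(self, role: str | None = None, tissue: str | None = None,
                group: str | None = None) -> list[str]:
        t = self.table
        if role is not None:
            t = t[t["role"] == role]
        if tissue is not None:
            t = t[t["tissue"] == tissue]
        if group is not None:
            t = t[t["group"] == group]
        return list(t["sample_id"])

    @property
    def tissues(self) -> list[str]:
        return sorted(self.table["tissue"].unique())

    def group_of(self) -> dict[str, str]:
        return dict(zip(self.table["sample_id"], self.table["group"]))


@dataclass
class ProbeAnnotation:
    """Genomic coordinates of array probes (manifest-style, 1-based)."""

    table: pd.DataFrame

    REQUIRED = ("probe_id", "chrom", "position")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValueError(f"probe annotation missing column {col!r}")
        if "strand" not in t.columns:
            t = t.assign(strand="+")
        _check_unique(t["probe_id"], "probe")
        t = t.astype({"position": int})
        if (t["position"] < 1).any():
            raise ValueError("positions must be >= 1 (1-based coordinates)")
        if t["chrom"].isna().any() or (t["chrom"].astype(str).str.len() == 0).any():
            raise ValueError("chrom must be non-empty")
        self.table = t.reset_index(drop=True)

    def lookup(self, probe_ids: Sequence[str]) -> pd.DataFrame:
        t = self.table.set_index("probe_id")
        missing = [p for p in probe_ids if p not in t.index]
        if missing:
            raise KeyError(f"probes without annotation: {missing[:10]}")
        return t.loc[list(probe_ids)].reset_index()


# ---------------------------------------------------------------------------
# Delimited-text readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: str | Path, sep: str | None) -> str:
    if sep is not None:
        return sep
    return "," if str(path).endswith(".csv") else "\t"


def read_beta_matrix(path: str | Path, sep: str | None = None,
                     missing_token: str = "NA") -> BetaMatrix:
    """Read a probes x samples beta-matrix from delimited text.

    First column holds probe ids, header row holds sample ids.  Cells equal
    to ``missing_token`` (or empty) become missing.  Non-numeric or
    out-of-range cells are rejected with row/column context.
    """
    sep = _sep_for(path, sep)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                     keep_default_na=False)
    df.index = df.index.astype(str)
    _check_unique(df.index, "probe")
    _check_unique(df.columns, "sample")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        for probe, cell in df[col].items():
            if cell == missing_token or cell == "":
                out.at[probe, col] = np.nan
                continue
            try:
                v = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell at probe {probe!r}, sample {col!r}: {cell!r}"
                ) from None
            out.at[probe, col] = v
    return BetaMatrix(out)


def write_beta_matrix(matrix: BetaMatrix, path: str | Path,
                      sep: str | None = None, missing_token: str = "NA") -> None:
    sep = _sep_for(path, sep)
    matrix.values.to_csv(path, sep=sep, na_rep=missing_token,
                         index_label="probe_id")


def read_sample_sheet(path: str | Path, sep: str | None = None) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep=_sep_for(path, sep), dtype=str))


def read_probe_annotation(path: str | Path, sep: str | None = None) -> ProbeAnnotation:
    return ProbeAnnotation(pd.read_csv(path, sep=_sep_for(path, sep)))


# ---------------------------------------------------------------------------
# BED / FASTA
# ---------------------------------------------------------------------------

def write_regions_bed(dmrs: Sequence, path: str | Path) -> None:
    """Write regions to BED (0-based half-open), sorted by chrom then start.

    ``dmrs`` are objects with 1-based inclusive ``chrom``/``start``/``end``
    and a ``probe_ids`` collection whose size becomes the BED score column.
    """
    rows = []
    for d in dmrs:
        if d.start < 1 or d.end < d.start:
            raise ValueError(f"bad region coordinates {d.chrom}:{d.start}-{d.end}")
        rows.append((d.chrom, d.start - 1, d.end, len(d.probe_ids)))
    rows.sort(key=lambda r: (r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("# chrom\tstart\tend\tname\tscore\tstrand\n")
        for i, (chrom, start, end, n) in enumerate(rows, 1):
            fh.write(f"{chrom}\t{start}\t{end}\tdmr_{i}\t{n}\t.\n")


def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    """Read BED intervals into 1-based inclusive internal coordinates."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line needs >= 3 columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start < 0 or end < start:
                raise ValueError(f"{path}:{ln}: bad interval {start}-{end}")
            rows.append((chrom, start + 1, end))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


_FASTA_COORD = re.compile(r"^(?P<chrom>[^:\s]+):(?P<start>\d+)-(?P<end>\d+)$")


def read_fasta_regions(path: str | Path):
    """Read FASTA records as genomic regions.

    Headers of the form ``chrom:start-end`` (1-based inclusive) carry
    absolute coordinates; otherwise the record id is the region name and
    coordinates start at 1.  Returns :class:`~methmark.design.GenomicSequence`
    objects.
    """
    from Bio import SeqIO

    from .design import GenomicSequence

    regions = []
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _FASTA_COORD.match(rec.id)
        if m:
            chrom = m.group("chrom")
            start = int(m.group("start"))
        else:
            chrom, start = rec.id, 1
        regions.append(GenomicSequence(chrom=chrom, start=start,
                                       seq=str(rec.seq).upper()))
    return regions


def load_config(path: str | Path) -> dict:
    """Load a YAML key/value configuration file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, Mapping):
        raise ValueError("config file must contain a key/value mapping")
    return dict(cfg)
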