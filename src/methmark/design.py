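"""In-silico bisulphite conversion and methylation-specific PCR design.

Bisulphite treatment converts unmethylated cytosine to uracil (read as T by
the polymerase) while 5-methylcytosine — in mammals essentially confined to
CpG dinucleotides — is left intact.  Methylation differences thereby become
sequence differences, and a methylation-specific PCR (MSP) assay exploits
them twice over:

* **methylation specificity** — primers and probe each cover at least two
  CpGs, and each primer's 3' terminal base interrogates a CpG (the CpG
  cytosine itself for the forward primer, its paired guanine for the
  reverse), so only the methylated, retained-C template primes efficiently;
* **conversion specificity** — non-CpG cytosines (CH) always convert, so CH
  positions inside an oligo mismatch any unconverted genomic DNA.

Designs target short amplicons (58-72 bp by default) because circulating
cell-free DNA is fragmented to nucleosome-sized pieces; each candidate is
scored against practical MSP rules with a green / yellow / red
traffic-light rating per criterion, the overall rating being the worst.

All design happens on the bisulphite-converted, fully methylated template
of one strand (top by default); positions carrying known variants (SNVs or
indels) may be masked and are never covered by an emitted oligo.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from Bio.Seq import Seq

__all__ = [
    "GenomicSequence",
    "ConvertedTemplate",
    "AmpliconWindow",
    "Oligo",
    "AmpliconDesign",
    "DesignRules",
    "bisulfite_convert",
    "enumerate_amplicons",
    "design_oligos",
    "score_design",
    "rank_designs",
    "design_assays",
    "RATING_ORDER",
]

_VALID = frozenset("ACGTN")

#: green sorts before yellow before red.
RATING_ORDER = {"green": 0, "yellow": 1, "red": 2}


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GenomicSequence:
    """A reference (unconverted) region with optional variant-masked positions.

    ``start`` is the 1-based genomic coordinate of the first base;
    ``variant_mask`` holds absolute 1-based positions to avoid (known SNVs
    or indels).
    """

    chrom: str
    start: int
    seq: str
    variant_mask: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        bad = set(self.seq) - _VALID
        if bad:
            raise ValueError(f"invalid sequence characters: {sorted(bad)}")
        if self.start < 1:
            raise ValueError("start must be >= 1")
        out = [p for p in self.variant_mask if not (self.start <= p <= self.end)]
        if out:
            raise ValueError(f"masked positions outside region span: {sorted(out)[:5]}")

    @property
    def end(self) -> int:
        return self.start + len(self.seq) - 1

    def local_mask(self) -> frozenset[int]:
        """Masked positions as 0-based offsets into ``seq``."""
        return frozenset(p - self.start for p in self.variant_mask)


@dataclass(frozen=True)
class ConvertedTemplate:
    """A bisulphite-converted strand with its retained-CpG map.

    ``cpg_positions`` are 0-based indices (in converted coordinates, which
    equal source coordinates — conversion preserves length) of CpG cytosines
    retained on a methylated template.  ``source_seq`` is the unconverted
    sequence in template orientation, kept so conversion-specific (CH)
    positions can be counted for any oligo.
    """

    seq: str
    strand: str
    methylation_state: str
    cpg_positions: tuple[int, ...]
    source_seq: str
    terminal_c_ambiguous: bool = False

    @property
    def length(self) -> int:
        return len(self.seq)


def bisulfite_convert(seq: str, methylated: bool = True,
                      strand: str = "top") -> ConvertedTemplate:
    """Bisulphite-convert one strand of a sequence.

    Every cytosine not followed by guanine converts to T; a CpG cytosine is
    retained as C only on a methylated template.  The bottom strand is the
    reverse complement converted by the same rule.  A terminal C whose next
    base is unknown cannot be classified and is conservatively converted
    (flagged via ``terminal_c_ambiguous``).
    """
    if strand not in ("top", "bottom"):
        raise ValueError("strand must be 'top' or 'bottom'")
    work = seq.upper()
    bad = set(work) - _VALID
    if bad:
        raise ValueError(f"invalid sequence characters: {sorted(bad)}")
    if strand == "bottom":
        work = _revcomp(work)
    out = []
    cpgs = []
    terminal_flag = False
    n = len(work)
    for i, c in enumerate(work):
        if c != "C":
            out.append(c)
            continue
        nxt = work[i + 1] if i + 1 < n else None
        if nxt == "G":
            if methylated:
                out.append("C")
                cpgs.append(i)
            else:
                out.append("T")
        else:
            if nxt is None:
                terminal_flag = True
            out.append("T")
    return ConvertedTemplate(
        seq="".join(out), strand=strand,
        methylation_state="methylated" if methylated else "unmethylated",
        cpg_positions=tuple(cpgs), source_seq=work,
        terminal_c_ambiguous=terminal_flag,
    )


# ---------------------------------------------------------------------------
# Candidate windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AmpliconWindow:
    """A candidate amplicon span, 0-based half-open on the template."""

    start: int
    end: int
    n_cpg: int

    @property
    def length(self) -> int:
        return self.end - self.start


def enumerate_amplicons(template: ConvertedTemplate, min_len: int = 58,
                        max_len: int = 72, min_cpg: int = 6) -> list[AmpliconWindow]:
    """All windows with length in [min_len, max_len] and >= ``min_cpg`` CpGs.

    Six CpGs is the minimum consistent with two per oligo across forward
    primer, probe, and reverse primer.  Sorted by CpG count descending, then
    start, then length.
    """
    n = template.length
    if n < min_len:
        import warnings

        warnings.warn(f"template length {n} below minimum amplicon length "
                      f"{min_len}; no candidates", stacklevel=2)
        return []
    # prefix[i] = number of CpG positions < i
    prefix = [0] * (n + 1)
    cpg_set = set(template.cpg_positions)
    for i in range(n):
        prefix[i + 1] = prefix[i] + (1 if i in cpg_set else 0)
    windows = []
    for start in range(0, n - min_len + 1):
        for length in range(min_len, min(max_len, n - start) + 1):
            c = prefix[start + length] - prefix[start]
            if c >= min_cpg:
                windows.append(AmpliconWindow(start, start + length, c))
    windows.sort(key=lambda w: (-w.n_cpg, w.start, w.length))
    return windows


# ---------------------------------------------------------------------------
# Oligo and design containers
# ---------------------------------------------------------------------------

def _max_run(seq: str, base: str) -> int:
    runs = re.findall(f"{base}+", seq)
    return max((len(r) for r in runs), default=0)


@dataclass(frozen=True)
class Oligo:
    """One primer or probe.

    ``start``/``end`` are 1-based inclusive positions of the binding site on
    the converted template (sense-strand coordinates for all three roles;
    the reverse primer's sequence is the reverse complement of its site).
    """

    role: str
    seq: str
    start: int
    end: int
    n_cpg: int
    n_ch: int
    gc_fraction: float
    three_prime_on_cpg: bool
    max_g_run: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class AmpliconDesign:
    """A full MSP candidate: forward primer, probe, reverse primer."""

    region: str
    start: int                     # 1-based inclusive, template coordinates
    end: int
    forward: Oligo
    reverse: Oligo
    probe: Oligo
    ratings: dict = field(default_factory=dict)
    overall: str = "unrated"

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def total_cpg(self) -> int:
        return self.forward.n_cpg + self.reverse.n_cpg + self.probe.n_cpg


@dataclass(frozen=True)
class DesignRules:
    """Hard constraints and traffic-light boundaries for MSP design.

    Hard constraints (a design is never emitted if violated): oligo CpG
    minimum, primer 3'-on-CpG anchoring, variant-mask avoidance, no
    ambiguous (N) bases under an oligo.  Rating boundaries: amplicon length
    green within [amplicon_min, amplicon_max], yellow up to
    ``amplicon_long_max`` (the conventional upper recommendation), red
    beyond; GC green within ``gc_green`` and yellow within ``gc_slack``
    outside it; CH (non-CpG cytosine) count green at >= 3, yellow at 1-2,
    red at 0; poly-G green at runs <= 3, yellow at 4, red at >= 5.
    """

    primer_min: int = 18
    primer_max: int = 30
    probe_min: int = 18
    probe_max: int = 30
    min_cpg_per_oligo: int = 2
    amplicon_min: int = 58
    amplicon_max: int = 72
    amplicon_long_max: int = 120
    gc_green: tuple[float, float] = (0.40, 0.60)
    gc_slack: float = 0.05
    ch_green_min: int = 3
    polyg_green_max: int = 3
    polyg_yellow_max: int = 4


def _count_ch(source: str, start: int, end: int) -> int:
    """Non-CpG cytosines of the source strand within [start, end) 0-based."""
    n = 0
    for i in range(start, end):
        if source[i] == "C" and not (i + 1 < len(source) and source[i + 1] == "G"):
            n += 1
    return n


def _gc(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def _make_oligo(template: ConvertedTemplate, role: str, start0: int,
                end0: int, cpg_sorted: Sequence[int]) -> Oligo:
    """Build an oligo for binding site [start0, end0) (0-based template)."""
    import bisect

    site = template.seq[start0:end0]
    seq = _revcomp(site) if role == "reverse" else site
    lo = bisect.bisect_left(cpg_sorted, start0)
    hi = bisect.bisect_left(cpg_sorted, end0)
    n_cpg = hi - lo
    if role == "forward":
        three = (end0 - 1) in template.cpg_positions
    elif role == "reverse":
        three = start0 in template.cpg_positions
    else:
        three = False
    return Oligo(role=role, seq=seq, start=start0 + 1, end=end0,
                 n_cpg=n_cpg, n_ch=_count_ch(template.source_seq, start0, end0),
                 gc_fraction=_gc(seq), three_prime_on_cpg=three,
                 max_g_run=_max_run(seq, "G"))


def design_oligos(template: ConvertedTemplate, window: AmpliconWindow,
                  mask: Iterable[int] = (), rules: DesignRules = DesignRules(),
                  region_name: str = "region") -> tuple[list[AmpliconDesign], dict]:
    """Enumerate primer/probe combinations for one amplicon window.

    The forward primer starts at the window start, the reverse primer ends
    at the window end (sequence given as reverse complement of the converted
    sense strand), and the probe lies strictly between the two primers.

    Hard constraints: each oligo covers >= ``min_cpg_per_oligo`` CpGs; the
    forward primer's 3' terminal base is a retained CpG cytosine; the
    reverse primer's 3' terminal base pairs with one (its binding site
    starts on a CpG C); no oligo overlaps a masked variant position or an N.

    Returns the passing designs (unrated) and a per-constraint count of
    rejected candidates.
    """
    mask = frozenset(mask)
    cpg_sorted = sorted(template.cpg_positions)
    fails = {"forward_3prime_cpg": 0, "reverse_3prime_cpg": 0,
             "cpg_count": 0, "variant_mask": 0, "ambiguous_base": 0,
             "probe_placement": 0}

    def span_ok(start0: int, end0: int, counter: list[str]) -> bool:
        if any(p in mask for p in range(start0, end0)):
            counter.append("variant_mask")
            return False
        if "N" in template.seq[start0:end0]:
            counter.append("ambiguous_base")
            return False
        return True

    forwards = []
    for lf in range(rules.primer_min, rules.primer_max + 1):
        end0 = window.start + lf
        if end0 > window.end:
            break
        if (end0 - 1) not in template.cpg_positions:
            fails["forward_3prime_cpg"] += 1
            continue
        why: list[str] = []
        if not span_ok(window.start, end0, why):
            fails[why[0]] += 1
            continue
        olig = _make_oligo(template, "forward", window.start, end0, cpg_sorted)
        if olig.n_cpg < rules.min_cpg_per_oligo:
            fails["cpg_count"] += 1
            continue
        forwards.append(olig)

    reverses = []
    for lr in range(rules.primer_min, rules.primer_max + 1):
        start0 = window.end - lr
        if start0 < window.start:
            break
        if start0 not in template.cpg_positions:
            fails["reverse_3prime_cpg"] += 1
            continue
        why = []
        if not span_ok(start0, window.end, why):
            fails[why[0]] += 1
            continue
        olig = _make_oligo(template, "reverse", start0, window.end, cpg_sorted)
        if olig.n_cpg < rules.min_cpg_per_oligo:
            fails["cpg_count"] += 1
            continue
        reverses.append(olig)

    designs = []
    for fwd in forwards:
        for rev in reverses:
            inner_lo = fwd.end          # 0-based start of inter-primer gap
            inner_hi = rev.start - 1    # 0-based end (exclusive)
            if inner_hi - inner_lo < rules.probe_min:
                fails["probe_placement"] += 1
                continue
            for ps in range(inner_lo, inner_hi - rules.probe_min + 1):
                for lp in range(rules.probe_min, rules.probe_max + 1):
                    pe = ps + lp
                    if pe > inner_hi:
                        break
                    why = []
                    if not span_ok(ps, pe, why):
                        fails[why[0]] += 1
                        continue
                    probe = _make_oligo(template, "probe", ps, pe, cpg_sorted)
                    if probe.n_cpg < rules.min_cpg_per_oligo:
                        fails["cpg_count"] += 1
                        continue
                    designs.append(AmpliconDesign(
                        region=region_name, start=window.start + 1,
                        end=window.end, forward=fwd, reverse=rev, probe=probe))
    return designs, fails


# ---------------------------------------------------------------------------
# Scoring and ranking
# ---------------------------------------------------------------------------

def _worst(ratings: Iterable[str]) -> str:
    return max(ratings, key=RATING_ORDER.__getitem__)


def _rate_gc(gc: float, rules: DesignRules) -> str:
    lo, hi = rules.gc_green
    if lo <= gc <= hi:
        return "green"
    if lo - rules.gc_slack <= gc <= hi + rules.gc_slack:
        return "yellow"
    return "red"


def _rate_ch(n_ch: int, rules: DesignRules) -> str:
    if n_ch >= rules.ch_green_min:
        return "green"
    return "yellow" if n_ch >= 1 else "red"


def _rate_polyg(run: int, rules: DesignRules) -> str:
    if run <= rules.polyg_green_max:
        return "green"
    return "yellow" if run <= rules.polyg_yellow_max else "red"


def _rate_length(length: int, rules: DesignRules) -> str:
    if rules.amplicon_min <= length <= rules.amplicon_max:
        return "green"
    if length <= rules.amplicon_long_max:
        return "yellow"
    return "red"


def score_design(design: AmpliconDesign,
                 rules: DesignRules = DesignRules()) -> AmpliconDesign:
    """Attach per-criterion traffic-light ratings; overall is the worst."""
    ratings = {"amplicon_length": _rate_length(design.length, rules)}
    for oligo in (design.forward, design.reverse, design.probe):
        ratings[f"gc_{oligo.role}"] = _rate_gc(oligo.gc_fraction, rules)
        ratings[f"ch_{oligo.role}"] = _rate_ch(oligo.n_ch, rules)
        ratings[f"polyg_{oligo.role}"] = _rate_polyg(oligo.max_g_run, rules)
    return replace(design, ratings=ratings, overall=_worst(ratings.values()))


def rank_designs(designs: Sequence[AmpliconDesign]) -> list[AmpliconDesign]:
    """Deterministic best-first ordering of scored designs.

    Overall rating first (green < yellow < red), then more CpGs covered,
    then shorter amplicon, then leftmost start, finally lexicographic oligo
    sequences for full determinism.
    """
    return sorted(designs, key=lambda d: (
        RATING_ORDER.get(d.overall, 3), -d.total_cpg, d.length, d.start,
        d.forward.seq, d.reverse.seq, d.probe.seq))


def design_assays(region: GenomicSequence, methylated: bool = True,
                  strand: str = "top", rules: DesignRules = DesignRules(),
                  max_windows: int = 10,
                  max_per_window: int | None = None) -> tuple[list[AmpliconDesign], dict]:
    """Full design pass on one genomic region.

    Converts the region (methylated template of the chosen strand),
    enumerates amplicon windows (CpG-richest first, capped at
    ``max_windows``), designs and scores oligo sets, and returns the ranked
    candidates plus aggregate constraint-failure counts.
    """
    template = bisulfite_convert(region.seq, methylated=methylated, strand=strand)
    local = region.local_mask()
    if strand == "bottom":
        n = len(region.seq)
        local = frozenset(n - 1 - p for p in local)
    windows = enumerate_amplicons(template, rules.amplicon_min,
                                  rules.amplicon_max,
                                  min_cpg=3 * rules.min_cpg_per_oligo)
    all_designs: list[AmpliconDesign] = []
    totals: dict[str, int] = {}
    name = f"{region.chrom}:{region.start}-{region.end}"
    for window in windows[:max_windows]:
        designs, fails = design_oligos(template, window, local, rules, name)
        for k, v in fails.items():
            totals[k] = totals.get(k, 0) + v
        scored = [score_design(d, rules) for d in designs]
        scored = rank_designs(scored)
        if max_per_window is not None:
            scored = scored[:max_per_window]
        all_designs.extend(scored)
    return rank_designs(all_designs), totals
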