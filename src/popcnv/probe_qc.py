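"""Probe suitability filtering and inter-probe spacing statistics.

Array probe sets that sit on a restriction site, compete with a neighbouring
probe for the same genomic template, or share their 25-mer with another probe
produce unreliable intensity signal and are removed before CNV calling.  The
genomic target is digested with NspI and StyI before hybridisation, so any
probe whose 25-mer (plus up to 12 bp of reference flank on each side)
contains an NspI (RCATGY) or StyI (CCWWGG) recognition site is discarded.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .core_io import ProbeSet

# Both enzymes' sites are palindromic, so one strand suffices.
NSPI = "[AG]CATG[CT]"
STYI = "CC[AT][AT]GG"
_SITE_RE = re.compile(f"(?={NSPI})|(?={STYI})")

PROBE_LEN = 25
MAX_FLANK = 12


@dataclass
class ProbeFilterReport:
    """Counts of removed probes by reason plus the spacing statistic."""

    n_input: int
    removed: dict[str, int] = field(default_factory=dict)
    n_retained: int = 0
    median_interprobe_distance: float | None = None

    def __post_init__(self):
        if self.n_input != self.n_retained + sum(self.removed.values()):
            raise ValueError("retained + removed must equal input count")


def flag_restriction_sites(
    probe: ProbeSet, flank_5p: str = "", flank_3p: str = ""
) -> bool:
    """True iff flank + probe sequence + flank contains an NspI/StyI site.

    Sites spanning the probe/flank boundary count: the scan runs over the
    concatenated string.
    """
    if probe.sequence is None:
        raise ValueError(f"probe {probe.id}: sequence required")
    if len(flank_5p) > MAX_FLANK or len(flank_3p) > MAX_FLANK:
        raise ValueError(f"flanks must be at most {MAX_FLANK} bp")
    context = (flank_5p + probe.sequence + flank_3p).upper()
    if not re.fullmatch("[ACGT]*", context):
        raise ValueError("sequences must be over {A,C,G,T}")
    return _SITE_RE.search(context) is not None


def remove_overlapping_probes(
    probes: list[ProbeSet], probe_len: int = PROBE_LEN
) -> list[ProbeSet]:
    """Drop every probe whose [pos, pos+24] target overlaps another probe's.

    Removal is symmetric: both members of an overlapping pair go, so a chain
    of mutually overlapping probes is removed entirely.  Strand is ignored
    (sense and antisense probes target the same duplex locus).
    """
    ordered = sorted(probes, key=lambda p: (p.chrom, p.pos))
    doomed = set()
    for a, b in zip(ordered, ordered[1:]):
        if a.chrom == b.chrom and b.pos <= a.pos + probe_len - 1:
            doomed.add(a.id)
            doomed.add(b.id)
    return [p for p in ordered if p.id not in doomed]


def interprobe_median(probes: list[ProbeSet]) -> float:
    """Median inter-probe-set distance after trimming above-Q3 outliers.

    Gaps are computed between consecutive probes within each chromosome
    only.  Because large probe deserts would inflate the statistic, gaps
    strictly greater than the third quartile (linear-interpolation
    definition) are discarded before taking the median.
    """
    if len(probes) < 2:
        raise ValueError("need at least 2 probes")
    ordered = sorted(probes, key=lambda p: (p.chrom, p.pos))
    gaps = [
        b.pos - a.pos
        for a, b in zip(ordered, ordered[1:])
        if a.chrom == b.chrom
    ]
    if not gaps:
        raise ValueError("no within-chromosome gaps")
    gaps = np.asarray(gaps, dtype=float)
    q3 = np.quantile(gaps, 0.75)  # linear interpolation (numpy default)
    kept = gaps[gaps <= q3]
    return float(np.median(kept))


def filter_probes(
    probes: list[ProbeSet],
    flanks: dict[str, tuple[str, str]] | None = None,
) -> tuple[list[ProbeSet], ProbeFilterReport]:
    """Apply the full probe-suitability screen and report removal counts.

    Order of reasons (first failing reason is charged): bad_length,
    duplicate_sequence, restriction_site, overlaps_other.  *flanks* maps
    probe id -> (5' flank, 3' flank); when absent the restriction screen
    runs on the probe sequence alone (a partial screen, noted in the
    report via the ``partial_restriction_screen`` flag on the reason key).
    Probes without sequence skip the sequence-based screens.
    """
    flanks = flanks or {}
    removed = {
        "bad_length": 0,
        "duplicate_sequence": 0,
        "restriction_site": 0,
        "overlaps_other": 0,
    }
    survivors = []
    for p in probes:
        if p.sequence is not None and len(p.sequence) != 25:
            removed["bad_length"] += 1  # unreachable via ProbeSet invariant
            continue
        if "duplicate_sequence" in p.flags:
            removed["duplicate_sequence"] += 1
            continue
        if p.sequence is not None:
            f5, f3 = flanks.get(p.id, ("", ""))
            if flag_restriction_sites(p, f5, f3):
                removed["restriction_site"] += 1
                continue
        survivors.append(p)
    kept = remove_overlapping_probes(survivors)
    removed["overlaps_other"] = len(survivors) - len(kept)
    median = interprobe_median(kept) if len(kept) >= 2 else None
    return kept, ProbeFilterReport(
        n_input=len(probes),
        removed=removed,
        n_retained=len(kept),
        median_interprobe_distance=median,
    )
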