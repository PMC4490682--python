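"""Heterozygosity-based false-discovery estimation for deletion calls.

SNP genotypes inside a true deletion (copy state 0 or 1) cannot be
heterozygous, so a deletion call in which more than 10 % of the genotype
calls are AB is deemed a false positive.  NoCall entries are not genotype
calls and are excluded from the denominator.  Amplifications are never
tested.  The same machinery supports group-wise comparisons of in-call
heterozygous and no-call rates (Wilcoxon rank-sum).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CnvCall, GenotypeMatrix, ProbeSet

logger = logging.getLogger("popcnv")

HET_THRESHOLD = 0.10


def _snp_positions(probes: list[ProbeSet]) -> dict[str, tuple[np.ndarray, list[str]]]:
    by_chrom: dict[str, list[ProbeSet]] = {}
    for p in probes:
        if p.probe_type == "SNP":
            by_chrom.setdefault(p.chrom, []).append(p)
    out = {}
    for chrom, plist in by_chrom.items():
        plist.sort(key=lambda p: p.pos)
        out[chrom] = (np.array([p.pos for p in plist]), [p.id for p in plist])
    return out


def _genotypes_in_call(
    call: CnvCall,
    genotypes: GenotypeMatrix,
    snp_index: dict[str, tuple[np.ndarray, list[str]]],
) -> pd.Series:
    entry = snp_index.get(call.chrom)
    if entry is None:
        return pd.Series(dtype=object)
    positions, ids = entry
    lo = int(np.searchsorted(positions, call.start, side="left"))
    hi = int(np.searchsorted(positions, call.end, side="right"))
    inside = [i for i in ids[lo:hi] if i in genotypes.table.index]
    return genotypes.table.loc[inside, call.sample_id]


def call_het_fraction(
    call: CnvCall,
    genotypes: GenotypeMatrix,
    probes: list[ProbeSet],
    _snp_index=None,
) -> float | None:
    """Fraction of called SNP genotypes inside a deletion that are AB.

    Returns None when the call contains no called SNP probe (the call is
    then excluded from FDR testing).  Raises for non-deletion calls.
    """
    if call.copy_state not in (0, 1):
        raise ValueError("heterozygosity screen applies to deletions only")
    snp_index = _snp_index if _snp_index is not None else _snp_positions(probes)
    geno = _genotypes_in_call(call, genotypes, snp_index)
    called = geno[geno != "NoCall"]
    if len(called) == 0:
        return None
    return float((called == "AB").sum() / len(called))


@dataclass
class FdrReport:
    n_deletions: int          # deletion calls supplied
    n_tested: int             # deletions containing >= 1 called SNP probe
    n_excluded: int
    n_flagged: int
    fdr: float                # pooled: flagged / tested
    per_sample_fdr_mean: float
    het_fractions: dict[int, float] = field(default_factory=dict)

    def __post_init__(self):
        if not 0 <= self.fdr <= 1:
            raise ValueError("fdr outside [0, 1]")


def estimate_fdr(
    calls: list[CnvCall],
    genotypes: GenotypeMatrix,
    probes: list[ProbeSet],
    het_threshold: float = HET_THRESHOLD,
) -> FdrReport:
    """Flag deletions whose in-call heterozygous fraction exceeds the
    threshold (strictly) and report the flagged fraction.

    Reports both the pooled rate (flagged / tested, over all samples) and
    the mean of per-sample rates.
    """
    deletions = [
        (i, c) for i, c in enumerate(calls) if c.copy_state in (0, 1)
    ]
    if not deletions:
        raise ValueError("no deletion calls to test")
    snp_index = _snp_positions(probes)
    fractions: dict[int, float] = {}
    flagged_by_sample: dict[str, list[bool]] = {}
    n_excluded = 0
    for i, c in deletions:
        frac = call_het_fraction(c, genotypes, probes, _snp_index=snp_index)
        if frac is None:
            n_excluded += 1
            continue
        fractions[i] = frac
        flagged_by_sample.setdefault(c.sample_id, []).append(
            frac > het_threshold
        )
    n_tested = len(fractions)
    if n_tested == 0:
        raise ValueError("no testable deletions (no called SNP probes inside)")
    n_flagged = sum(f > het_threshold for f in fractions.values())
    per_sample = [np.mean(v) for v in flagged_by_sample.values()]
    return FdrReport(
        n_deletions=len(deletions),
        n_tested=n_tested,
        n_excluded=n_excluded,
        n_flagged=n_flagged,
        fdr=n_flagged / n_tested,
        per_sample_fdr_mean=float(np.mean(per_sample)),
        het_fractions=fractions,
    )


def group_rate_test(
    calls: list[CnvCall],
    genotypes: GenotypeMatrix,
    probes: list[ProbeSet],
    group_a: set[str],
    group_b: set[str],
    rate: str = "het",
    region: str = "deletions",
) -> tuple[pd.DataFrame, float]:
    """Compare per-sample in-call genotype rates between two sample groups.

    The per-sample rate is the fraction of genotype entries of the given
    kind (``het`` = AB among called genotypes; ``nocall`` = NoCall among
    all entries) at SNP probes inside that sample's calls of the given
    region type (``deletions`` = states 0/1, ``amplifications`` = states
    > 2).  Samples with no in-call SNP probes are omitted with a log line.
    Returns the per-sample table and a two-sided Wilcoxon rank-sum
    p-value (scipy's Mann-Whitney U, exact for small groups).
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if rate not in ("het", "nocall"):
        raise ValueError(f"unknown rate {rate!r}")
    if region not in ("deletions", "amplifications"):
        raise ValueError(f"unknown region {region!r}")
    snp_index = _snp_positions(probes)
    wanted = (
        (lambda s: s in (0, 1)) if region == "deletions" else (lambda s: s > 2)
    )
    per_sample_geno: dict[str, list[pd.Series]] = {}
    for c in calls:
        if c.sample_id in (group_a | group_b) and wanted(c.copy_state):
            per_sample_geno.setdefault(c.sample_id, []).append(
                _genotypes_in_call(c, genotypes, snp_index)
            )
    rows = []
    for sample in sorted(group_a | group_b):
        series = per_sample_geno.get(sample, [])
        geno = pd.concat(series) if series else pd.Series(dtype=object)
        if len(geno) == 0:
            logger.info("sample %s: no in-call SNP probes, omitted", sample)
            continue
        if rate == "het":
            called = geno[geno != "NoCall"]
            if len(called) == 0:
                logger.info("sample %s: no called genotypes, omitted", sample)
                continue
            value = float((called == "AB").sum() / len(called))
        else:
            value = float((geno == "NoCall").sum() / len(geno))
        rows.append(
            {
                "sample_id": sample,
                "group": "A" if sample in group_a else "B",
                "rate": value,
            }
        )
    table = pd.DataFrame(rows, columns=["sample_id", "group", "rate"])
    a = table.loc[table["group"] == "A", "rate"]
    b = table.loc[table["group"] == "B", "rate"]
    if len(a) == 0 or len(b) == 0:
        raise ValueError("a group lost all samples to the in-call probe filter")
    p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return table, p
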