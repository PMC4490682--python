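"""Panel-level summary tables: call counts by group and copy state,
deletion/amplification and unique/recurrent ratios, genome fraction
affected, and length statistics.

The deletion/amplification ratio is (state-0 + state-1 call count) divided
by the 3+ count; displayed ratios are rounded half-up to two decimals, as
in the conventional presentation of such tables, while the full-precision
values remain available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CnvCall, GenomeDef, SampleMeta

logger = logging.getLogger("popcnv")


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at the given decimals (display convention)."""
    if math.isinf(x) or math.isnan(x):
        return x
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SummaryRow:
    group: str
    n_samples: int
    n_calls: int
    state0: int
    state1: int
    state3plus: int
    n_unique: int
    n_recurrent: int

    def __post_init__(self):
        for name in ("n_samples", "n_calls", "state0", "state1", "state3plus",
                     "n_unique", "n_recurrent"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_calls != self.state0 + self.state1 + self.state3plus:
            raise ValueError("state counts must sum to n_calls")
        if self.n_unique + self.n_recurrent != self.n_calls:
            raise ValueError("unique + recurrent must equal n_calls")

    @property
    def calls_per_sample(self) -> float:
        return self.n_calls / self.n_samples

    @property
    def del_amp_ratio(self) -> float:
        dels = self.state0 + self.state1
        return dels / self.state3plus if self.state3plus else math.inf

    @property
    def unique_recurrent_ratio(self) -> float:
        return (
            self.n_unique / self.n_recurrent if self.n_recurrent else math.inf
        )

    def display(self) -> dict:
        """Row with ratios rounded half-up to 2 decimals for tabulation."""
        return {
            "group": self.group,
            "n_samples": self.n_samples,
            "n_calls": self.n_calls,
            "calls_per_sample": round_half_up(self.calls_per_sample),
            "state0": self.state0,
            "state1": self.state1,
            "state3plus": self.state3plus,
            "del_amp_ratio": round_half_up(self.del_amp_ratio),
            "n_unique": self.n_unique,
            "n_recurrent": self.n_recurrent,
            "unique_recurrent_ratio": round_half_up(self.unique_recurrent_ratio),
        }


def row_from_counts(
    group: str,
    n_samples: int,
    state0: int,
    state1: int,
    state3plus: int,
    n_unique: int = 0,
    n_recurrent: int | None = None,
) -> SummaryRow:
    """Build a SummaryRow directly from tabulated counts."""
    n_calls = state0 + state1 + state3plus
    if n_recurrent is None:
        n_recurrent = n_calls - n_unique
    return SummaryRow(
        group=group,
        n_samples=n_samples,
        n_calls=n_calls,
        state0=state0,
        state1=state1,
        state3plus=state3plus,
        n_unique=n_unique,
        n_recurrent=n_recurrent,
    )


def summarize(
    calls: list[CnvCall],
    meta: list[SampleMeta],
    uniqueness: dict[int, str] | None = None,
) -> list[SummaryRow]:
    """One row per classification group plus an 'All' row.

    *uniqueness* maps call index (into *calls*) to 'unique'/'recurrent',
    classified on the full panel; when omitted all calls count as unique.
    Groups without samples are omitted with a warning.  Subgroups need not
    partition the panel, so group rows may not sum to 'All'.
    """
    meta_by_id = {m.sample_id: m for m in meta}
    uniq = uniqueness or {}

    def _build(group: str, sample_ids: set[str], indices: list[int]) -> SummaryRow:
        st = {0: 0, 1: 0, 3: 0}
        n_unique = 0
        for i in indices:
            c = calls[i]
            key = 3 if c.copy_state >= 3 else c.copy_state
            if key == 2:
                raise ValueError("copy state 2 is not a CNV on autosomes")
            st[key] += 1
            if uniq.get(i, "unique") == "unique":
                n_unique += 1
        return SummaryRow(
            group=group,
            n_samples=len(sample_ids),
            n_calls=len(indices),
            state0=st[0],
            state1=st[1],
            state3plus=st[3],
            n_unique=n_unique,
            n_recurrent=len(indices) - n_unique,
        )

    rows = [_build("All", {m.sample_id for m in meta}, list(range(len(calls))))]
    groups = sorted({m.classification for m in meta})
    for group in groups:
        sample_ids = {
            m.sample_id for m in meta if m.classification == group
        }
        if not sample_ids:
            logger.warning("group %s has no samples, omitted", group)
            continue
        indices = [
            i for i, c in enumerate(calls) if c.sample_id in sample_ids
        ]
        rows.append(_build(group, sample_ids, indices))
    return rows


def summary_table(rows: list[SummaryRow]) -> pd.DataFrame:
    return pd.DataFrame([r.display() for r in rows])


def _union_length(intervals: list[tuple[int, int]]) -> int:
    intervals.sort()
    total = 0
    cur_s, cur_e = None, None
    for s, e in intervals:
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s + 1
    return total


def genome_fraction_affected(
    calls: list[CnvCall],
    genome: GenomeDef,
    scope: str = "autosomes",
    per_sample: bool = False,
) -> tuple[float, float]:
    """Fraction (and Mb) of the genome covered by the union of calls.

    Scope is ``autosomes`` or ``autosomes_plus_X``; calls outside the scope
    are ignored.  In per-sample mode the union is computed within each
    sample and the (fraction, Mb) pair is the mean over samples.
    """
    chroms = set(genome.autosomes)
    if scope == "autosomes_plus_X":
        chroms |= {c for c in ("chrX",) if c in genome.lengths}
    elif scope != "autosomes":
        raise ValueError(f"unknown scope {scope!r}")
    total = sum(genome.lengths[c] for c in chroms)
    in_scope = [c for c in calls if c.chrom in chroms]

    def _covered(call_subset: list[CnvCall]) -> int:
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for c in call_subset:
            by_chrom.setdefault(c.chrom, []).append((c.start, c.end))
        return sum(_union_length(ivs) for ivs in by_chrom.values())

    if per_sample:
        by_sample: dict[str, list[CnvCall]] = {}
        for c in in_scope:
            by_sample.setdefault(c.sample_id, []).append(c)
        if not by_sample:
            return 0.0, 0.0
        covered = [_covered(v) for v in by_sample.values()]
        mean_cov = float(np.mean(covered))
        return mean_cov / total, mean_cov / 1e6
    covered_bp = _covered(in_scope)
    return covered_bp / total, covered_bp / 1e6


def length_stats(
    calls: list[CnvCall],
) -> pd.DataFrame:
    """Median/mean lengths by call class and Mann-Whitney contrasts.

    Rows: all, deletion, amplification, state0, state1, plus contrast rows
    ``amp_vs_del`` and ``state0_vs_state1`` carrying two-sided p-values.
    Empty groups skip their contrast with a warning.
    """
    groups = {
        "all": [c.length for c in calls],
        "deletion": [c.length for c in calls if c.copy_state < 2],
        "amplification": [c.length for c in calls if c.copy_state > 2],
        "state0": [c.length for c in calls if c.copy_state == 0],
        "state1": [c.length for c in calls if c.copy_state == 1],
    }
    rows = []
    for name, lens in groups.items():
        rows.append(
            {
                "group": name,
                "n": len(lens),
                "median_bp": float(np.median(lens)) if lens else math.nan,
                "mean_bp": float(np.mean(lens)) if lens else math.nan,
                "p_value": math.nan,
            }
        )
    for label, (ga, gb) in {
        "amp_vs_del": ("amplification", "deletion"),
        "state0_vs_state1": ("state0", "state1"),
    }.items():
        a, b = groups[ga], groups[gb]
        if not a or not b:
            logger.warning("contrast %s skipped: empty group", label)
            continue
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append(
            {
                "group": label,
                "n": len(a) + len(b),
                "median_bp": math.nan,
                "mean_bp": math.nan,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows, columns=["group", "n", "median_bp", "mean_bp", "p_value"])
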