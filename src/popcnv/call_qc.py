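"""Sample-level QC gates and call-level filtering.

Samples with noisy arrays (high log-R-ratio standard deviation or drifting
B-allele frequency) are excluded outright; surviving samples' calls must be
500 bp - 1 Mb long, supported by at least three markers, and reach a marker
density of 0.00013 markers/bp (roughly one probe per 7700 bp).
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_io import CnvCall, GenomeDef, SampleMeta


@dataclass(frozen=True)
class QcThresholds:
    min_len: int = 500
    max_len: int = 1_000_000
    min_markers: int = 3
    min_density: float = 0.00013  # markers per bp
    max_lrr_sd: float = 0.35
    max_baf_drift: float = 0.01

    def __post_init__(self):
        if not self.min_len < self.max_len:
            raise ValueError("min_len must be below max_len")
        for name in ("min_len", "max_len", "min_markers", "min_density",
                     "max_lrr_sd", "max_baf_drift"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def sample_passes_qc(meta: SampleMeta, t: QcThresholds = QcThresholds()) -> bool:
    """True iff lrr_sd < max_lrr_sd and baf_drift < max_baf_drift (strict)."""
    if meta.lrr_sd is None or meta.baf_drift is None:
        raise ValueError(f"{meta.sample_id}: missing QC metric")
    return meta.lrr_sd < t.max_lrr_sd and meta.baf_drift < t.max_baf_drift


# removal reasons are charged in this fixed order so reports are deterministic
_REASONS = ("length", "markers", "density")


def filter_calls(
    calls: list[CnvCall], t: QcThresholds = QcThresholds()
) -> tuple[list[CnvCall], dict[str, int]]:
    """Keep calls passing length, marker-count and density rules.

    Length bounds are inclusive; density is inclusive (>= min_density).
    The report charges each removal to the first failing rule in the order
    length, markers, density.
    """
    kept: list[CnvCall] = []
    report = {r: 0 for r in _REASONS}
    for c in calls:
        if not t.min_len <= c.length <= t.max_len:
            report["length"] += 1
        elif c.n_markers < t.min_markers:
            report["markers"] += 1
        elif c.n_markers / c.length < t.min_density:
            report["density"] += 1
        else:
            kept.append(c)
    return kept, report


def expected_baseline(chrom: str, sex: str, genome: GenomeDef) -> int:
    """Expected copy number: 2 on autosomes; on X, 1 for males, 2 for females.

    Y is 1 for males (females are expected to have no Y calls at all)."""
    if chrom not in genome:
        raise ValueError(f"chromosome {chrom!r} not in genome")
    if chrom in genome.autosomes:
        return 2
    if sex not in ("M", "F"):
        raise ValueError(f"unknown sex {sex!r}")
    if chrom.endswith("X"):
        return 1 if sex == "M" else 2
    return 1  # chrY, males


def classify_call(
    call: CnvCall, sex: str, genome: GenomeDef
) -> tuple[str, str]:
    """Classify a call as deletion/amplification with a collapsed state label.

    The baseline is sex-aware on the sex chromosomes.  States below baseline
    are deletions labelled with the integer state; states above are
    amplifications, with autosomal states >= 3 collapsed to "3+".  A state
    equal to the baseline is not a CNV and raises.
    """
    base = expected_baseline(call.chrom, sex, genome)
    if call.copy_state == base:
        raise ValueError(
            f"{call.chrom}:{call.start}-{call.end} state {call.copy_state} "
            f"equals baseline: not a CNV"
        )
    if call.copy_state < base:
        return "deletion", str(call.copy_state)
    return "amplification", "3+" if call.copy_state >= 3 else str(call.copy_state)
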