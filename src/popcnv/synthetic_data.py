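"""Synthetic inputs for every pipeline stage: genome, probe map, strain
panel, CNV calls with planted structure, genotypes and feature tracks.

The generator plants a known truth and emits exactly the file formats the
readers consume, so each downstream stage can be tested against that truth
without any external data:

* recurrent CNVRs are placed in disjoint genomic slots; member calls of one
  region are boundary-jittered within +-10 % of the anchor length, keeping
  every pairwise reciprocal overlap above ~0.67 (comfortably over the 0.40
  detection threshold), while calls of different regions and unique calls
  never overlap at all;
* CNV lengths are log-normal (right-skewed, median tens of kb), deletions
  shorter than amplifications, mirroring array-derived call sets;
* a configurable fraction of deletion calls is planted as false positives:
  genotypes inside them follow Hardy-Weinberg (heterozygote-rich), whereas
  true deletions are forced homozygous or NoCall;
* genotypes carry group structure (per-group divergence from a shared
  ancestral allele) so SNP and CNV distances share the same panel
  structure;
* feature tracks are Poisson-placed with a configurable density multiplier
  inside the planted call footprint.

All randomness flows from a single integer seed; a fixed seed reproduces
the outputs byte for byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import (
    CnvCall,
    FeatureTrack,
    GenomeDef,
    GenotypeMatrix,
    ProbeSet,
    SampleMeta,
    write_bed,
    write_cnv_calls,
    write_genome,
    write_genotypes,
    write_probe_annotation,
    write_sample_meta,
)

GROUPS = ("classical", "wild_derived", "wild_caught_dom", "wild_caught_mus")

_CLASSIFICATION = {
    "classical": ("classical", None),
    "wild_derived": ("wild_derived", None),
    "wild_caught_dom": ("wild_caught", "domesticus"),
    "wild_caught_mus": ("wild_caught", "musculus"),
}

_PREFIX = {
    "classical": "CL",
    "wild_derived": "WD",
    "wild_caught_dom": "WCD",
    "wild_caught_mus": "WCM",
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic panel.

    Scale mirrors array-based mouse CNV surveys: log-normal call lengths
    with deletion median ~20 kb and amplification median ~37 kb (dispersion
    sigma 1.2 reproduces a mean roughly double the median), probe spacing
    with median 500 bp, wild groups carrying more (and more heterozygous /
    uncalled) variation than classical strains.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 12_000_000
    probe_spacing_median: int = 500
    max_probe_gap: int = 2000          # guarantees marker support for calls
    snp_probe_fraction: float = 0.85
    n_samples: dict[str, int] = field(
        default_factory=lambda: {
            "classical": 12,
            "wild_derived": 8,
            "wild_caught_dom": 8,
            "wild_caught_mus": 8,
        }
    )
    n_cnvrs: int = 12
    cnvr_home_freq: tuple[float, float] = (0.7, 0.95)
    cnvr_n_home_groups: tuple[int, int] = (1, 2)
    n_unique_per_sample: dict[str, int] = field(
        default_factory=lambda: {
            "classical": 2,
            "wild_derived": 4,
            "wild_caught_dom": 5,
            "wild_caught_mus": 5,
        }
    )
    # deletion probability per group (ratio del:amp 0.84 / 2.25 / 2.92)
    del_prob: dict[str, float] = field(
        default_factory=lambda: {
            "classical": 0.457,
            "wild_derived": 0.692,
            "wild_caught_dom": 0.745,
            "wild_caught_mus": 0.745,
        }
    )
    cnvr_state_mode: str = "region"    # region | carrier
    del_len_median: float = 20_091.0
    amp_len_median: float = 36_708.0
    len_sigma: float = 1.2
    min_anchor_len: int = 10_000
    max_anchor_len: int = 800_000
    boundary_jitter_frac: float = 0.10
    slot_gap: int = 20_000
    state0_prob: float = 0.3           # deletions at state 0 vs 1
    state4_prob: float = 0.1           # amplifications at state 4 vs 3
    false_positive_deletion_fraction: float = 0.25
    # genotype model
    group_divergence: dict[str, float] = field(
        default_factory=lambda: {
            "classical": 0.05,
            "wild_derived": 0.15,
            "wild_caught_dom": 0.25,
            "wild_caught_mus": 0.35,
        }
    )
    individual_flip_rate: float = 0.005
    baseline_het_rate: dict[str, float] = field(
        default_factory=lambda: {
            "classical": 0.01,
            "wild_derived": 0.03,
            "wild_caught_dom": 0.03,
            "wild_caught_mus": 0.03,
        }
    )
    baseline_nocall_rate: dict[str, float] = field(
        default_factory=lambda: {
            "classical": 0.011,
            "wild_derived": 0.03,
            "wild_caught_dom": 0.03,
            "wild_caught_mus": 0.03,
        }
    )
    incall_nocall_rate: dict[str, float] = field(
        default_factory=lambda: {
            "classical": 0.011,
            "wild_derived": 0.03,
            "wild_caught_dom": 0.03,
            "wild_caught_mus": 0.03,
        }
    )
    # sample QC metadata
    n_qc_failures: int = 0
    # feature tracks
    feature_enrichment_factor: float = 2.0
    feature_interval_len: int = 500
    feature_density: float = 2e-5      # intervals per bp, outside call zones
    # QC-violating spike-ins (to exercise the call filter)
    spiked_fail_per_sample: int = 0


@dataclass
class SimTruth:
    """Planted ground truth, consistent with the emitted calls."""

    cnvrs: list[dict]                      # anchor chrom/start/end/state kind
    membership: dict[int, int | None]      # call index -> CNVR index (None = unique)
    carriers: dict[int, list[str]]         # CNVR index -> carrier sample ids
    false_positive_calls: set[int]         # call indices planted as FP deletions
    spiked_fail_calls: set[int]            # call indices built to fail call QC
    group_of: dict[str, str]               # sample id -> generator group
    feature_enrichment_factor: float


@dataclass
class SimInputs:
    """Everything the pipeline reads, as in-memory objects."""

    genome: GenomeDef
    probes: list[ProbeSet]
    calls: list[CnvCall]
    meta: list[SampleMeta]
    genotypes: GenotypeMatrix
    tracks: dict[str, FeatureTrack]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit every input as the text formats core_io reads."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.tsv",
            "probes": outdir / "probes.tsv",
            "calls": outdir / "calls.tsv",
            "meta": outdir / "samples.tsv",
            "genotypes": outdir / "genotypes.tsv",
        }
        write_genome(self.genome, paths["genome"])
        write_probe_annotation(self.probes, paths["probes"])
        write_cnv_calls(self.calls, paths["calls"])
        write_sample_meta(self.meta, paths["meta"])
        write_genotypes(self.genotypes, paths["genotypes"])
        for name, track in self.tracks.items():
            p = outdir / f"track_{name}.bed"
            write_bed(track.intervals, p)
            paths[f"track_{name}"] = p
        return paths


def _lognormal_len(
    rng: np.random.Generator, median: float, sigma: float, lo: int, hi: int
) -> int:
    return int(np.clip(rng.lognormal(math.log(median), sigma), lo, hi))


def simulate(config: SimConfig | None = None) -> tuple[SimInputs, SimTruth]:
    """Generate a full synthetic panel plus its planted truth."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(cfg.seed)

    # --- genome ---------------------------------------------------------
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    genome = GenomeDef(lengths={c: cfg.chrom_length for c in chrom_names})

    # --- probe map ------------------------------------------------------
    scale = cfg.probe_spacing_median / math.log(2)
    probes: list[ProbeSet] = []
    probe_pos: dict[str, np.ndarray] = {}
    for chrom in chrom_names:
        n_guess = int(cfg.chrom_length / cfg.probe_spacing_median * 1.6) + 100
        gaps = np.minimum(
            rng.exponential(scale, size=n_guess), cfg.max_probe_gap
        ).astype(np.int64)
        gaps = np.maximum(gaps, 1)
        pos = np.cumsum(gaps)
        pos = pos[pos < cfg.chrom_length]
        is_snp = rng.random(len(pos)) < cfg.snp_probe_fraction
        probe_pos[chrom] = pos
        for k, (p, snp) in enumerate(zip(pos, is_snp)):
            probes.append(
                ProbeSet(
                    id=f"{chrom}_p{k:06d}",
                    chrom=chrom,
                    pos=int(p),
                    probe_type="SNP" if snp else "IGP",
                )
            )

    # --- strain panel ---------------------------------------------------
    meta: list[SampleMeta] = []
    group_of: dict[str, str] = {}
    for group in GROUPS:
        classification, subspecies = _CLASSIFICATION[group]
        for k in range(cfg.n_samples.get(group, 0)):
            sid = f"{_PREFIX[group]}{k + 1:02d}"
            meta.append(
                SampleMeta(
                    sample_id=sid,
                    classification=classification,
                    subspecies=subspecies,
                    sex="M" if k % 2 == 0 else "F",
                    lrr_sd=round(float(rng.uniform(0.05, 0.30)), 4),
                    baf_drift=round(float(rng.uniform(0.001, 0.009)), 5),
                )
            )
            group_of[sid] = group
    if cfg.n_qc_failures:
        fail_idx = rng.choice(len(meta), size=cfg.n_qc_failures, replace=False)
        for i in fail_idx:
            m = meta[i]
            meta[i] = SampleMeta(
                sample_id=m.sample_id,
                classification=m.classification,
                subspecies=m.subspecies,
                sex=m.sex,
                lrr_sd=round(float(rng.uniform(0.36, 0.8)), 4),
                baf_drift=m.baf_drift,
            )
    sample_ids = [m.sample_id for m in meta]

    # --- plan placements (disjoint slots) -------------------------------
    jitter = cfg.boundary_jitter_frac

    def _draw_len(is_del: bool) -> int:
        median = cfg.del_len_median if is_del else cfg.amp_len_median
        return _lognormal_len(
            rng, median, cfg.len_sigma, cfg.min_anchor_len, cfg.max_anchor_len
        )

    cnvr_plans = []
    for _ in range(cfg.n_cnvrs):
        is_del = rng.random() < 0.55
        length = _draw_len(is_del)
        n_home = int(rng.integers(cfg.cnvr_n_home_groups[0],
                                  cfg.cnvr_n_home_groups[1] + 1))
        home = list(rng.choice(GROUPS, size=n_home, replace=False))
        freq = {
            g: float(rng.uniform(*cfg.cnvr_home_freq)) if g in home else 0.0
            for g in GROUPS
        }
        cnvr_plans.append({"is_del": is_del, "length": length, "freq": freq})

    unique_plans = []
    for m in meta:
        group = group_of[m.sample_id]
        for _ in range(cfg.n_unique_per_sample.get(group, 0)):
            is_del = rng.random() < cfg.del_prob[group]
            unique_plans.append(
                {"sample": m.sample_id, "is_del": is_del,
                 "length": _draw_len(is_del)}
            )

    # pack slots sequentially across chromosomes; the envelope of a CNVR
    # slot includes the jitter margin so members never leave it
    items = [("cnvr", i, int(p["length"] * (1 + 2 * jitter)) + 2)
             for i, p in enumerate(cnvr_plans)]
    items += [("unique", i, p["length"]) for i, p in enumerate(unique_plans)]
    order = rng.permutation(len(items))
    cursors = {c: cfg.slot_gap for c in chrom_names}
    chrom_cycle = 0
    slots: dict[tuple[str, int], tuple[str, int]] = {}
    for idx in order:
        kind, i, env = items[idx]
        placed = False
        for _ in range(len(chrom_names)):
            chrom = chrom_names[chrom_cycle % len(chrom_names)]
            chrom_cycle += 1
            if cursors[chrom] + env + cfg.slot_gap < cfg.chrom_length:
                slots[(kind, i)] = (chrom, cursors[chrom])
                cursors[chrom] += env + cfg.slot_gap
                placed = True
                break
        if not placed:
            raise ValueError(
                "infeasible packing: planted intervals exceed the genome; "
                "increase chrom_length or reduce counts/lengths"
            )

    # --- emit calls ------------------------------------------------------
    def _state(is_del: bool) -> int:
        if is_del:
            return 0 if rng.random() < cfg.state0_prob else 1
        return 4 if rng.random() < cfg.state4_prob else 3

    def _n_markers(chrom: str, start: int, end: int) -> int:
        pos = probe_pos[chrom]
        return int(
            np.searchsorted(pos, end, side="right")
            - np.searchsorted(pos, start, side="left")
        )

    calls: list[CnvCall] = []
    membership: dict[int, int | None] = {}
    carriers: dict[int, list[str]] = {i: [] for i in range(cfg.n_cnvrs)}
    cnvr_records = []
    for i, plan in enumerate(cnvr_plans):
        chrom, slot_start = slots[("cnvr", i)]
        length = plan["length"]
        m = int(length * jitter)
        anchor_start = slot_start + m + 1
        anchor_end = anchor_start + length - 1
        cnvr_records.append(
            {
                "chrom": chrom,
                "start": anchor_start,
                "end": anchor_end,
                "kind": "deletion" if plan["is_del"] else "amplification",
                "freq": plan["freq"],
            }
        )
        region_state = _state(plan["is_del"])
        for sid in sample_ids:
            g = group_of[sid]
            if rng.random() >= plan["freq"][g]:
                continue
            s = anchor_start + int(rng.integers(-m, m + 1)) if m else anchor_start
            e = anchor_end + int(rng.integers(-m, m + 1)) if m else anchor_end
            if cfg.cnvr_state_mode == "carrier":
                state = _state(rng.random() < cfg.del_prob[g])
            else:
                state = region_state
            calls.append(
                CnvCall(
                    sample_id=sid,
                    chrom=chrom,
                    start=s,
                    end=e,
                    copy_state=state,
                    n_markers=_n_markers(chrom, s, e),
                )
            )
            membership[len(calls) - 1] = i
            carriers[i].append(sid)

    for i, plan in enumerate(unique_plans):
        chrom, slot_start = slots[("unique", i)]
        s = slot_start + 1
        e = s + plan["length"] - 1
        calls.append(
            CnvCall(
                sample_id=plan["sample"],
                chrom=chrom,
                start=s,
                end=e,
                copy_state=_state(plan["is_del"]),
                n_markers=_n_markers(chrom, s, e),
            )
        )
        membership[len(calls) - 1] = None

    # spiked QC failures: too short to pass the length filter
    spiked: set[int] = set()
    if cfg.spiked_fail_per_sample:
        for m_ in meta:
            for _ in range(cfg.spiked_fail_per_sample):
                chrom = chrom_names[int(rng.integers(len(chrom_names)))]
                s = int(rng.integers(1, cfg.chrom_length - 500))
                calls.append(
                    CnvCall(
                        sample_id=m_.sample_id,
                        chrom=chrom,
                        start=s,
                        end=s + 399,
                        copy_state=1,
                        n_markers=1,
                    )
                )
                membership[len(calls) - 1] = None
                spiked.add(len(calls) - 1)

    # --- false-positive deletions ---------------------------------------
    del_indices = [
        i for i, c in enumerate(calls)
        if c.copy_state in (0, 1) and i not in spiked
    ]
    n_fp = int(round(cfg.false_positive_deletion_fraction * len(del_indices)))
    fp_calls = (
        set(rng.choice(del_indices, size=n_fp, replace=False).tolist())
        if n_fp
        else set()
    )

    # --- genotypes -------------------------------------------------------
    snp_probes = [p for p in probes if p.probe_type == "SNP"]
    snp_ids = [p.id for p in snp_probes]
    snp_pos_by_chrom: dict[str, np.ndarray] = {}
    snp_row_by_chrom: dict[str, np.ndarray] = {}
    for row, p in enumerate(snp_probes):
        snp_pos_by_chrom.setdefault(p.chrom, []).append(p.pos)
        snp_row_by_chrom.setdefault(p.chrom, []).append(row)
    for chrom in snp_pos_by_chrom:
        snp_pos_by_chrom[chrom] = np.asarray(snp_pos_by_chrom[chrom])
        snp_row_by_chrom[chrom] = np.asarray(snp_row_by_chrom[chrom])

    n_probes = len(snp_probes)
    n_s = len(sample_ids)
    # group allele: 0 = ancestral hom (AA), 2 = derived hom (BB)
    group_allele = {}
    for g in GROUPS:
        flips = rng.random(n_probes) < cfg.group_divergence[g]
        group_allele[g] = np.where(flips, 2, 0).astype(np.int8)
    geno = np.empty((n_probes, n_s), dtype=np.int8)  # 0 AA, 1 AB, 2 BB, 3 NoCall
    for k, sid in enumerate(sample_ids):
        g = group_of[sid]
        base = group_allele[g].copy()
        flip = rng.random(n_probes) < cfg.individual_flip_rate
        base[flip] = 2 - base[flip]
        u = rng.random(n_probes)
        het = u < cfg.baseline_het_rate[g]
        nc = (u >= cfg.baseline_het_rate[g]) & (
            u < cfg.baseline_het_rate[g] + cfg.baseline_nocall_rate[g]
        )
        base[het] = 1
        base[nc] = 3
        geno[:, k] = base

    maf = rng.uniform(0.05, 0.5, size=n_probes)
    sample_index = {s: k for k, s in enumerate(sample_ids)}
    for i, c in enumerate(calls):
        if c.copy_state not in (0, 1) or i in spiked:
            continue
        pos = snp_pos_by_chrom.get(c.chrom)
        if pos is None:
            continue
        lo = int(np.searchsorted(pos, c.start, side="left"))
        hi = int(np.searchsorted(pos, c.end, side="right"))
        if hi <= lo:
            continue
        rows = snp_row_by_chrom[c.chrom][lo:hi]
        k = sample_index[c.sample_id]
        g = group_of[c.sample_id]
        n_in = len(rows)
        if i in fp_calls:
            # Hardy-Weinberg: heterozygote-rich, exposing the false call
            m_ = maf[rows]
            u = rng.random(n_in)
            vals = np.where(
                u < (1 - m_) ** 2, 0, np.where(u < (1 - m_) ** 2 + 2 * m_ * (1 - m_), 1, 2)
            ).astype(np.int8)
        else:
            # a real deletion cannot be heterozygous
            vals = group_allele[g][rows].copy()
        nc = rng.random(n_in) < cfg.incall_nocall_rate[g]
        vals[nc] = 3
        geno[rows, k] = vals

    code_to_str = np.array(["AA", "AB", "BB", "NoCall"])
    genotypes = GenotypeMatrix(
        pd.DataFrame(code_to_str[geno], index=snp_ids, columns=sample_ids)
    )

    # --- feature tracks --------------------------------------------------
    call_union: dict[str, list[tuple[int, int]]] = {}
    for c in calls:
        call_union.setdefault(c.chrom, []).append((c.start, c.end))

    def _merged(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
        ivs = sorted(ivs)
        out: list[list[int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1] + 1:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        return [(s, e) for s, e in out]

    def _poisson_track(name: str, factor: float) -> FeatureTrack:
        flen = cfg.feature_interval_len
        intervals = []
        for chrom in chrom_names:
            lam = cfg.feature_density * cfg.chrom_length
            n_base = rng.poisson(lam)
            starts = rng.integers(1, cfg.chrom_length - flen, size=n_base)
            for s in np.sort(starts):
                intervals.append((chrom, int(s), int(s) + flen - 1))
            if factor > 1 and chrom in call_union:
                merged = _merged(call_union[chrom])
                lens = np.array([e - s + 1 for s, e in merged])
                covered = int(lens.sum())
                n_extra = rng.poisson((factor - 1) * cfg.feature_density * covered)
                if n_extra:
                    offs = rng.integers(0, covered, size=n_extra)
                    cum = np.concatenate([[0], np.cumsum(lens)])
                    for off in np.sort(offs):
                        seg = int(np.searchsorted(cum, off, side="right")) - 1
                        s = merged[seg][0] + (int(off) - int(cum[seg]))
                        e = min(s + flen - 1, cfg.chrom_length)
                        intervals.append((chrom, s, e))
        intervals.sort()
        return FeatureTrack(name=name, intervals=tuple(intervals))

    tracks = {
        "planted": _poisson_track("planted", cfg.feature_enrichment_factor),
        "neutral": _poisson_track("neutral", 1.0),
    }

    inputs = SimInputs(
        genome=genome,
        probes=probes,
        calls=calls,
        meta=meta,
        genotypes=genotypes,
        tracks=tracks,
    )
    truth = SimTruth(
        cnvrs=cnvr_records,
        membership=membership,
        carriers={i: sorted(v) for i, v in carriers.items()},
        false_positive_calls=fp_calls,
        spiked_fail_calls=spiked,
        group_of=group_of,
        feature_enrichment_factor=cfg.feature_enrichment_factor,
    )
    return inputs, truth


def emulate_paper_panel(seed: int = 0) -> tuple[SimInputs, SimTruth]:
    """A scaled demo panel (~50 samples, ~1500 calls) with group proportions
    and deletion/amplification balance mirroring a large mouse array survey:
    classical strains dominate the panel but wild groups carry roughly twice
    the calls per sample, with a higher deletion share.
    """
    cfg = SimConfig(
        seed=seed,
        n_chromosomes=4,
        chrom_length=14_000_000,
        n_samples={
            "classical": 25,
            "wild_derived": 9,
            "wild_caught_dom": 8,
            "wild_caught_mus": 8,
        },
        n_cnvrs=60,
        cnvr_home_freq=(0.5, 0.9),
        cnvr_n_home_groups=(1, 3),
        cnvr_state_mode="carrier",
        n_unique_per_sample={
            "classical": 4,
            "wild_derived": 9,
            "wild_caught_dom": 10,
            "wild_caught_mus": 10,
        },
        max_anchor_len=250_000,
    )
    return simulate(cfg)
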