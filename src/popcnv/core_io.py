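"""Domain types and file I/O for array-based CNV analysis.

All genomic coordinates held in memory are 1-based inclusive, the convention
used by PennCNV output and the UCSC browser position box.  BED files are
converted to and from 0-based half-open at the read/write boundary and
nowhere else.  Interval length is always ``end - start + 1``.

Chromosome names are normalised to the ``chr``-prefixed form on input, so
``1`` and ``chr1`` refer to the same sequence.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger("popcnv")

GENOTYPES = ("AA", "AB", "BB", "NoCall")
PROBE_TYPES = ("SNP", "IGP")
CLASSIFICATIONS = (
    "classical",
    "wild_derived",
    "wild_caught",
    "BXD",
    "CC",
    "F1",
    "consomic",
    "congenic",
)
SUBSPECIES = ("domesticus", "musculus", "castaneus")


def normalize_chrom(name: str) -> str:
    """Return the ``chr``-prefixed chromosome name."""
    name = str(name).strip()
    if not name:
        raise ValueError("empty chromosome name")
    return name if name.startswith("chr") else f"chr{name}"


def interval_length(start: int, end: int) -> int:
    """Length of a 1-based inclusive interval."""
    return end - start + 1


@dataclass(frozen=True)
class GenomeDef:
    """Chromosome names, lengths and the autosome / sex-chromosome split.

    Parameters
    ----------
    lengths
        Mapping chromosome name -> length in bp.  Names are normalised to
        the ``chr`` prefix.
    sex_chroms
        Chromosome names treated as sex chromosomes (default ``chrX``,
        ``chrY`` when present in *lengths*).
    """

    lengths: Mapping[str, int]
    sex_chroms: frozenset[str] = frozenset()

    def __post_init__(self):
        norm = {normalize_chrom(c): int(l) for c, l in self.lengths.items()}
        if len(norm) != len(self.lengths):
            raise ValueError("duplicate chromosome names after normalisation")
        for c, l in norm.items():
            if l <= 0:
                raise ValueError(f"chromosome {c} has non-positive length {l}")
        object.__setattr__(self, "lengths", norm)
        sex = frozenset(normalize_chrom(c) for c in self.sex_chroms)
        if not sex:
            sex = frozenset(c for c in ("chrX", "chrY") if c in norm)
        unknown = sex - set(norm)
        if unknown:
            raise ValueError(f"sex chromosomes not in genome: {sorted(unknown)}")
        object.__setattr__(self, "sex_chroms", sex)

    @property
    def autosomes(self) -> frozenset[str]:
        return frozenset(self.lengths) - self.sex_chroms

    def __contains__(self, chrom: str) -> bool:
        return normalize_chrom(chrom) in self.lengths

    def length(self, chrom: str) -> int:
        return self.lengths[normalize_chrom(chrom)]

    def total_length(self, scope: str = "autosomes") -> int:
        """Summed length of ``autosomes`` or ``autosomes_plus_X``."""
        chroms = set(self.autosomes)
        if scope == "autosomes_plus_X":
            if "chrX" in self.lengths:
                chroms.add("chrX")
        elif scope != "autosomes":
            raise ValueError(f"unknown scope {scope!r}")
        return sum(self.lengths[c] for c in chroms)


@dataclass(frozen=True)
class ProbeSet:
    """One array probe set: a 25-mer targeting a fixed genomic locus."""

    id: str
    chrom: str
    pos: int
    probe_type: str = "SNP"
    sequence: str | None = None
    flags: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.pos < 1:
            raise ValueError(f"probe {self.id}: position {self.pos} < 1")
        if self.probe_type not in PROBE_TYPES:
            raise ValueError(f"probe {self.id}: unknown type {self.probe_type!r}")
        if self.sequence is not None and len(self.sequence) != 25:
            raise ValueError(
                f"probe {self.id}: sequence length {len(self.sequence)} != 25"
            )
        object.__setattr__(self, "flags", frozenset(self.flags))


@dataclass(frozen=True)
class CnvCall:
    """One sample's putative CNV: an interval plus integer copy state.

    A call is by definition a departure from the expected baseline state,
    so ``copy_state`` never equals the baseline for its chromosome and the
    carrier's sex (2 on autosomes; checked downstream where sex is known).
    Copy states above 3 are preserved as read; classification collapses
    them to "3+".
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    copy_state: int
    n_markers: int = 0
    source: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 1 or self.end < self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.copy_state < 0:
            raise ValueError(f"negative copy state {self.copy_state}")

    @property
    def length(self) -> int:
        return interval_length(self.start, self.end)

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)


@dataclass(frozen=True)
class SampleMeta:
    """Per-sample metadata: strain classification, subspecies, sex, array QC."""

    sample_id: str
    classification: str
    sex: str
    subspecies: str | None = None
    lrr_sd: float | None = None
    baf_drift: float | None = None

    def __post_init__(self):
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(
                f"{self.sample_id}: unknown classification {self.classification!r}"
            )
        if self.sex not in ("M", "F"):
            raise ValueError(f"{self.sample_id}: sex must be M or F")
        if self.subspecies is not None and self.subspecies not in SUBSPECIES:
            raise ValueError(
                f"{self.sample_id}: unknown subspecies {self.subspecies!r}"
            )
        if self.lrr_sd is not None and self.lrr_sd < 0:
            raise ValueError(f"{self.sample_id}: negative LRR_SD")
        if self.baf_drift is not None and not 0 <= self.baf_drift <= 1:
            raise ValueError(f"{self.sample_id}: BAF drift outside [0, 1]")


@dataclass(frozen=True)
class FeatureTrack:
    """A named set of genomic intervals (CpG islands, repeats, ...)."""

    name: str
    intervals: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        norm = []
        for chrom, start, end in self.intervals:
            chrom = normalize_chrom(chrom)
            if end < start or start < 1:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            norm.append((chrom, int(start), int(end)))
        object.__setattr__(self, "intervals", tuple(norm))

    def __len__(self) -> int:
        return len(self.intervals)


class GenotypeMatrix:
    """SNP genotype calls, probe set x sample, values AA/AB/BB/NoCall.

    Thin wrapper over a pandas DataFrame (index = probe ids, columns =
    sample ids, values = genotype strings).
    """

    def __init__(self, table: pd.DataFrame):
        bad = set(pd.unique(table.values.ravel())) - set(GENOTYPES)
        if bad:
            raise ValueError(f"unknown genotype values: {sorted(bad)}")
        if table.index.has_duplicates or table.columns.has_duplicates:
            raise ValueError("duplicate probe or sample ids")
        self.table = table

    @property
    def probe_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.columns)

    def validate_against(self, probes: Sequence[ProbeSet]) -> None:
        """Every genotyped probe must exist in the probe annotation."""
        known = {p.id for p in probes}
        missing = set(self.table.index) - known
        if missing:
            raise ValueError(
                f"{len(missing)} genotyped probes absent from annotation, "
                f"e.g. {sorted(missing)[:3]}"
            )

    def __eq__(self, other) -> bool:
        return isinstance(other, GenotypeMatrix) and self.table.equals(other.table)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

_PENNCNV_RE = re.compile(
    r"^(?P<chrom>\S+):(?P<start>\d+)-(?P<end>\d+)\s+"
    r"numsnp=(?P<numsnp>\d+)\s+.*?"
    r"state\d+,cn=(?P<cn>\d+)\s+"
    r"(?P<sample>\S+)"
)


def read_cnv_calls(
    path: str | Path,
    dialect: str = "tsv",
    genome: GenomeDef | None = None,
) -> list[CnvCall]:
    """Read CNV calls from ``penncnv_rawcnv``, ``tsv`` or ``bed`` files.

    BED coordinates (0-based half-open) are converted to 1-based inclusive.
    TSV must have header columns sample_id, chrom, start, end, copy_state,
    n_markers.  BED columns are chrom, start, end, sample_id, copy_state,
    n_markers.  When *genome* is given, unknown chromosomes are an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    calls: list[CnvCall] = []

    def _check_chrom(chrom: str, lineno: int) -> str:
        chrom = normalize_chrom(chrom)
        if genome is not None and chrom not in genome:
            raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
        return chrom

    lines = path.read_text().splitlines()
    if dialect == "penncnv_rawcnv":
        for i, line in enumerate(lines, 1):
            if not line.strip():
                continue
            m = _PENNCNV_RE.match(line.strip())
            if m is None:
                raise ValueError(f"{path}:{i}: malformed rawcnv line")
            calls.append(
                CnvCall(
                    sample_id=m["sample"],
                    chrom=_check_chrom(m["chrom"], i),
                    start=int(m["start"]),
                    end=int(m["end"]),
                    copy_state=int(m["cn"]),
                    n_markers=int(m["numsnp"]),
                )
            )
    elif dialect in ("tsv", "bed"):
        start_offset = 1 if dialect == "bed" else 0
        body = lines
        if dialect == "tsv":
            if not lines:
                logger.warning("%s: empty call file", path)
                return []
            header = lines[0].rstrip("\n").split("\t")
            required = {"sample_id", "chrom", "start", "end", "copy_state", "n_markers"}
            if not required <= set(header):
                raise ValueError(f"{path}: missing columns {required - set(header)}")
            idx = {name: header.index(name) for name in required}
            body = lines[1:]
        for i, line in enumerate(body, 2 if dialect == "tsv" else 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                if dialect == "bed":
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    sample = fields[3] if len(fields) > 3 else "NA"
                    state = int(fields[4]) if len(fields) > 4 else 0
                    nmark = int(fields[5]) if len(fields) > 5 else 0
                else:
                    chrom = fields[idx["chrom"]]
                    start = int(fields[idx["start"]])
                    end = int(fields[idx["end"]])
                    sample = fields[idx["sample_id"]]
                    state = int(fields[idx["copy_state"]])
                    nmark = int(fields[idx["n_markers"]])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{i}: malformed line ({exc})") from None
            calls.append(
                CnvCall(
                    sample_id=sample,
                    chrom=_check_chrom(chrom, i),
                    start=start + start_offset,
                    end=end,
                    copy_state=state,
                    n_markers=nmark,
                )
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not calls:
        logger.warning("%s: no CNV calls read", path)
    return calls


def read_probe_annotation(path: str | Path) -> list[ProbeSet]:
    """Read a probe annotation TSV (columns id, chrom, pos, type[, sequence]).

    Probes are returned sorted by (chrom, pos).  When sequences are present,
    any sequence shared by two or more probes flags all of them
    ``duplicate_sequence``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "chrom", "pos", "type"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"{path}: duplicate probe id {dup!r}")
    have_seq = "sequence" in df.columns
    dup_seqs: set[str] = set()
    if have_seq:
        seqs = df["sequence"].dropna()
        counts = seqs.value_counts()
        dup_seqs = set(counts[counts > 1].index)
    probes = []
    for row in df.itertuples(index=False):
        seq = getattr(row, "sequence", None) if have_seq else None
        if isinstance(seq, float):  # NaN from pandas
            seq = None
        flags = frozenset({"duplicate_sequence"} if seq in dup_seqs else set())
        probes.append(
            ProbeSet(
                id=row.id,
                chrom=row.chrom,
                pos=int(row.pos),
                probe_type=row.type,
                sequence=seq,
                flags=flags,
            )
        )
    probes.sort(key=lambda p: (p.chrom, p.pos))
    return probes


def read_genome(path: str | Path) -> GenomeDef:
    """Read a two-column chromosome-length TSV (chrom, length)."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: int})
    cols = list(df.columns)
    return GenomeDef(lengths=dict(zip(df[cols[0]], df[cols[1]])))


def read_sample_meta(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata TSV.

    Columns: sample_id, classification, sex and optionally subspecies,
    lrr_sd, baf_drift.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    metas = []
    for row in df.itertuples(index=False):
        sub = getattr(row, "subspecies", None)
        if isinstance(sub, float) or sub in ("", "NA", None):
            sub = None
        lrr = getattr(row, "lrr_sd", None)
        baf = getattr(row, "baf_drift", None)
        metas.append(
            SampleMeta(
                sample_id=row.sample_id,
                classification=row.classification,
                sex=row.sex,
                subspecies=sub,
                lrr_sd=float(lrr) if lrr not in (None, "") else None,
                baf_drift=float(baf) if baf not in (None, "") else None,
            )
        )
    return metas


def read_feature_track(path: str | Path, name: str | None = None) -> FeatureTrack:
    """Read a BED file into a FeatureTrack (converting to 1-based inclusive)."""
    path = Path(path)
    intervals = []
    for i, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        try:
            intervals.append((fields[0], int(fields[1]) + 1, int(fields[2])))
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}:{i}: malformed BED line ({exc})") from None
    return FeatureTrack(name=name or path.stem, intervals=tuple(intervals))


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a genotype matrix TSV (rows = probe ids, columns = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return GenotypeMatrix(df)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_bed(intervals: Iterable, path: str | Path) -> None:
    """Write intervals (CnvCalls or (chrom, start, end[, ...]) tuples) as BED.

    Internal 1-based inclusive coordinates become 0-based half-open, the
    exact inverse of :func:`read_cnv_calls` with ``dialect="bed"``.
    """
    path = Path(path)
    with path.open("w") as fh:
        for iv in intervals:
            if isinstance(iv, CnvCall):
                fh.write(
                    f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.sample_id}"
                    f"\t{iv.copy_state}\t{iv.n_markers}\n"
                )
            else:
                chrom, start, end, *rest = iv
                cols = [normalize_chrom(chrom), str(start - 1), str(end)]
                cols += [str(x) for x in rest]
                fh.write("\t".join(cols) + "\n")


def write_cnv_calls(calls: Sequence[CnvCall], path: str | Path) -> None:
    """Write calls as a TSV readable by ``read_cnv_calls(dialect="tsv")``."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\tchrom\tstart\tend\tcopy_state\tn_markers\n")
        for c in calls:
            fh.write(
                f"{c.sample_id}\t{c.chrom}\t{c.start}\t{c.end}"
                f"\t{c.copy_state}\t{c.n_markers}\n"
            )


def write_tsv(table: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    table.to_csv(path, sep="\t", index=index)


def write_probe_annotation(probes: Sequence[ProbeSet], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("id\tchrom\tpos\ttype\tsequence\n")
        for p in probes:
            fh.write(
                f"{p.id}\t{p.chrom}\t{p.pos}\t{p.probe_type}\t{p.sequence or ''}\n"
            )


def write_sample_meta(metas: Sequence[SampleMeta], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\tclassification\tsex\tsubspecies\tlrr_sd\tbaf_drift\n")
        for m in metas:
            fh.write(
                f"{m.sample_id}\t{m.classification}\t{m.sex}\t{m.subspecies or ''}"
                f"\t{'' if m.lrr_sd is None else m.lrr_sd}"
                f"\t{'' if m.baf_drift is None else m.baf_drift}\n"
            )


def write_genome(genome: GenomeDef, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("chrom\tlength\n")
        for chrom in sorted(genome.lengths):
            fh.write(f"{chrom}\t{genome.lengths[chrom]}\n")


def write_genotypes(gm: GenotypeMatrix, path: str | Path) -> None:
    gm.table.to_csv(path, sep="\t", index_label="probe_id")
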