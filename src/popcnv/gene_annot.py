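"""Gene overlap classification, negative-control screening and
subspecies-private CNV detection.

Call/gene geometry is classified as: the call entirely encompasses the gene,
the call lies entirely inside the gene, or the two merely share >= 1 bp
(partial).  Complete-overlap gene lists (the first two relations) are the
export for external GO/pathway tools.  A packaged list of dosage-sensitive
genes, conserved across mammals, serves as a negative control: deletions
there are suspect.

A CNV region is private to a wild-caught subspecies when more than five
wild-caught individuals of that subspecies carry member calls and no
wild-caught individual of the other subspecies has any call overlapping the
region span by even 1 bp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .core_io import CnvCall, SampleMeta, normalize_chrom
from .recurrence import extract_regions

BIOTYPES = ("protein_coding", "pseudogene", "rna", "antisense", "other")

# Dosage-sensitive genes conserved across mammalian species, haploinsufficient
# or lethal when lost; deletions overlapping them warrant scrutiny.
CONTROL_GENES_AUTOSOMAL = (
    "Adam17", "Cdk8", "Col7a1", "Dll1", "Dnmt3b", "Dyrk1a", "Eed", "Eln",
    "Ezh2", "Igf1", "Lama5", "Med1", "Med24", "Med21", "Med30", "Pex7",
    "Pknox1", "Pdpk1", "Slc2a1", "Suz12", "Vps35", "Tfrc",
)
CONTROL_GENES_X = (
    "Aifm1", "Alas2", "Amer1", "Bcor", "Cask", "Cul4b", "Ebp", "Flna",
    "G6pdx", "Gyk", "Ikbkg", "Mecp2", "Med12", "Mtm1", "Nsdhl", "Ofd1",
    "Piga", "Porcn",
)


def map_biotype(ensembl_biotype: str) -> str:
    """Collapse an Ensembl biotype string to the packaged classification."""
    bt = ensembl_biotype.strip()
    if bt == "protein_coding":
        return "protein_coding"
    if bt.endswith("pseudogene"):
        return "pseudogene"
    if bt == "antisense":
        return "antisense"
    if bt.endswith("RNA") or bt.endswith("rna"):
        return "rna"
    return "other"


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    biotype: str = "protein_coding"

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.biotype not in BIOTYPES:
            object.__setattr__(self, "biotype", map_biotype(self.biotype))


def read_genes(path) -> list[GeneModel]:
    """Read a gene TSV (gene_id, symbol, chrom, start, end, biotype)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        GeneModel(
            gene_id=r.gene_id,
            symbol=r.symbol,
            chrom=r.chrom,
            start=int(r.start),
            end=int(r.end),
            biotype=getattr(r, "biotype", "protein_coding"),
        )
        for r in df.itertuples(index=False)
    ]


def classify_gene_overlap(call: CnvCall, gene: GeneModel) -> str | None:
    """Relation of a call to a gene, or None without >= 1 bp of overlap.

    Ties resolve to ``encompasses_gene``: identical intervals count as the
    call encompassing the gene.
    """
    if call.chrom != gene.chrom:
        return None
    if call.start <= gene.start and call.end >= gene.end:
        return "encompasses_gene"
    if gene.start <= call.start and gene.end >= call.end:
        return "inside_gene"
    if call.start <= gene.end and call.end >= gene.start:
        return "partial"
    return None


def gene_overlap_table(
    calls: Sequence[CnvCall], genes: Sequence[GeneModel]
) -> pd.DataFrame:
    """All >= 1 bp call/gene overlaps with their relation."""
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for glist in by_chrom.values():
        glist.sort(key=lambda g: g.start)
    rows = []
    for ci, c in enumerate(calls):
        for g in by_chrom.get(c.chrom, ()):
            if g.start > c.end:
                break
            rel = classify_gene_overlap(c, g)
            if rel is not None:
                rows.append(
                    {
                        "call_index": ci,
                        "sample_id": c.sample_id,
                        "gene_id": g.gene_id,
                        "symbol": g.symbol,
                        "biotype": g.biotype,
                        "relation": rel,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["call_index", "sample_id", "gene_id", "symbol", "biotype",
                 "relation"],
    )


def complete_overlap_gene_lists(
    calls: Sequence[CnvCall], genes: Sequence[GeneModel]
) -> list[str]:
    """Symbols of genes in complete overlap with any call, for GO export.

    Complete overlap means the gene is entirely inside a call or the call
    entirely inside the gene.  Pseudogenes carrying a protein-coding
    biotype upstream are already mapped by the caller; everything passed
    in is eligible.  One symbol per gene, sorted.
    """
    table = gene_overlap_table(calls, genes)
    if table.empty:
        return []
    hit = table[table["relation"].isin(["encompasses_gene", "inside_gene"])]
    return sorted(set(hit["symbol"]))


def export_gene_list(symbols: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for s in symbols:
            fh.write(f"{s}\n")


def screen_negative_controls(
    calls: Sequence[CnvCall],
    control_genes: Sequence[GeneModel],
    mode: str = "any_deletion",
) -> pd.DataFrame:
    """Deletions overlapping dosage-sensitive control genes by >= 1 bp.

    ``any_deletion`` screens states 0 and 1; ``state_zero`` only full
    deletions.  Each violation reports the copy state, the fraction of the
    gene removed, and a severity rank (state-0 hits rank highest).
    """
    if mode not in ("any_deletion", "state_zero"):
        raise ValueError(f"unknown mode {mode!r}")
    states = (0,) if mode == "state_zero" else (0, 1)
    rows = []
    for c in calls:
        if c.copy_state not in states:
            continue
        for g in control_genes:
            if g.chrom != c.chrom or c.start > g.end or c.end < g.start:
                continue
            ov = min(c.end, g.end) - max(c.start, g.start) + 1
            frac = ov / (g.end - g.start + 1)
            rows.append(
                {
                    "sample_id": c.sample_id,
                    "symbol": g.symbol,
                    "chrom": c.chrom,
                    "call_start": c.start,
                    "call_end": c.end,
                    "copy_state": c.copy_state,
                    "gene_fraction_lost": round(frac, 4),
                    "severity": "high" if c.copy_state == 0 else "moderate",
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "symbol", "chrom", "call_start", "call_end",
                 "copy_state", "gene_fraction_lost", "severity"],
    )
    return df.sort_values(
        ["severity", "gene_fraction_lost"], ascending=[True, False]
    ).reset_index(drop=True)


def private_subspecies_cnvs(
    calls: Sequence[CnvCall],
    meta: Sequence[SampleMeta],
    region_graph: nx.Graph,
    min_carriers: int = 6,
) -> pd.DataFrame:
    """Regions carried by >= min_carriers wild-caught mice of one subspecies
    and absent (no >= 1 bp overlap) from the other subspecies' wild-caught
    mice.

    Carrier membership is defined by the 40 % reciprocal-overlap recurrence
    component; absence in the other subspecies uses the stricter 1 bp rule
    against the region span.  Also reports whether any classical or
    wild-derived sample overlaps the span by >= 1 bp.
    """
    meta_by_id = {m.sample_id: m for m in meta}
    wild_sub = {
        m.sample_id: m.subspecies
        for m in meta
        if m.classification == "wild_caught"
    }
    if wild_sub and all(s is None for s in wild_sub.values()):
        raise ValueError("wild-caught samples lack subspecies labels")

    def _class_of(sample_id: str) -> str | None:
        m = meta_by_id.get(sample_id)
        return m.classification if m else None

    regions = extract_regions(region_graph)
    rows = []
    for region in regions:
        carriers: dict[str, set[str]] = {"domesticus": set(), "musculus": set()}
        for m in region.members:
            sub = wild_sub.get(m.sample_id)
            if sub in carriers:
                carriers[sub].add(m.sample_id)
        for sub, other in (("domesticus", "musculus"), ("musculus", "domesticus")):
            if len(carriers[sub]) < min_carriers:
                continue
            # 1 bp screen of the other subspecies against the region span
            other_hit = any(
                c.chrom == region.chrom
                and c.start <= region.end
                and c.end >= region.start
                and wild_sub.get(c.sample_id) == other
                for c in calls
            )
            if other_hit:
                continue
            seen_classical = any(
                c.chrom == region.chrom
                and c.start <= region.end
                and c.end >= region.start
                and _class_of(c.sample_id) == "classical"
                for c in calls
            )
            seen_wild_derived = any(
                c.chrom == region.chrom
                and c.start <= region.end
                and c.end >= region.start
                and _class_of(c.sample_id) == "wild_derived"
                for c in calls
            )
            member_states = {m.copy_state for m in region.members}
            kind = (
                "Del" if all(s < 2 for s in member_states)
                else "Amp" if all(s > 2 for s in member_states)
                else "Mixed"
            )
            rows.append(
                {
                    "chrom": region.chrom,
                    "start": region.start,
                    "end": region.end,
                    "type": kind,
                    "subspecies": sub,
                    "n_carriers": len(carriers[sub]),
                    "seen_in_classical": seen_classical,
                    "seen_in_wild_derived": seen_wild_derived,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "type", "subspecies", "n_carriers",
                 "seen_in_classical", "seen_in_wild_derived"],
    )
    return df.sort_values(["subspecies", "chrom", "start"]).reset_index(drop=True)
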