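"""Genetic distances from genotypes and CNV states, with NJ trees,
principal-coordinate ordination and the Mantel test.

SNP distance between two samples is the fraction of co-called SNP loci with
differing genotypes (a locus where either sample is NoCall drops out of both
numerator and denominator; AB differs from both homozygotes).  CNV distance
assigns every autosomal probe set a collapsed copy state per sample
(baseline 2 unless inside one of that sample's calls, then 0/1/3+) and is
the fraction of probe sets at which the two samples' states differ.  Both
distances live in [0, 1], making them directly comparable in a Mantel test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import CnvCall, GenotypeMatrix, ProbeSet

_GENO_CODE = {"AA": 0, "AB": 1, "BB": 2, "NoCall": -1}


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative pairwise distances with a zero diagonal."""

    ids: tuple[str, ...]
    matrix: np.ndarray
    kind: str  # snp / cnv

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0):
            raise ValueError("diagonal must be zero")
        if (m < -1e-12).any():
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "matrix", m)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def snp_distance(genotypes: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise fraction of differing genotypes over co-called SNP loci."""
    ids = tuple(genotypes.sample_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 samples")
    raw = genotypes.table.to_numpy(dtype=object)
    codes = np.empty(raw.shape, dtype=np.int8)
    for name, value in _GENO_CODE.items():
        codes[raw == name] = value
    n = len(ids)
    d = np.zeros((n, n))
    called = codes >= 0
    for i in range(n):
        for j in range(i + 1, n):
            both = called[:, i] & called[:, j]
            denom = int(both.sum())
            if denom == 0:
                raise ValueError(
                    f"samples {ids[i]!r} and {ids[j]!r} share no called loci"
                )
            diff = int((codes[both, i] != codes[both, j]).sum())
            d[i, j] = d[j, i] = diff / denom
    return DistanceMatrix(ids=ids, matrix=d, kind="snp")


def _collapse(state: int) -> int:
    return 3 if state >= 3 else state


def probe_state_matrix(
    calls: list[CnvCall],
    probes: list[ProbeSet],
    sample_ids: list[str],
    exclude_sex_chroms: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Per-sample collapsed copy state (0/1/2/3) at every autosomal probe set.

    A probe inside two overlapping same-sample calls with different states
    takes the most extreme departure from 2; on a tie the deletion wins.
    Returns (probes x samples int8 matrix, probe ids in matrix order).
    """
    import logging

    kept = [
        p
        for p in probes
        if not (exclude_sex_chroms and p.chrom in ("chrX", "chrY"))
    ]
    kept.sort(key=lambda p: (p.chrom, p.pos))
    pos_by_chrom: dict[str, np.ndarray] = {}
    offset_by_chrom: dict[str, int] = {}
    off = 0
    for p in kept:
        pos_by_chrom.setdefault(p.chrom, []).append(p.pos)  # type: ignore[union-attr]
    for chrom in sorted(pos_by_chrom):
        arr = np.asarray(pos_by_chrom[chrom])
        pos_by_chrom[chrom] = arr
        offset_by_chrom[chrom] = off
        off += len(arr)
    # kept is sorted by (chrom, pos) and chroms sorted lexically, consistent
    sample_index = {s: k for k, s in enumerate(sample_ids)}
    states = np.full((len(kept), len(sample_ids)), 2, dtype=np.int8)
    conflicts = 0
    for c in calls:
        k = sample_index.get(c.sample_id)
        if k is None or c.chrom not in pos_by_chrom:
            continue
        positions = pos_by_chrom[c.chrom]
        lo = int(np.searchsorted(positions, c.start, side="left"))
        hi = int(np.searchsorted(positions, c.end, side="right"))
        if hi <= lo:
            continue
        new = _collapse(c.copy_state)
        rows = slice(offset_by_chrom[c.chrom] + lo, offset_by_chrom[c.chrom] + hi)
        cur = states[rows, k]
        # most extreme departure from 2 wins; tie resolves to the deletion
        new_dep = abs(new - 2)
        cur_dep = np.abs(cur.astype(int) - 2)
        replace = (new_dep > cur_dep) | ((new_dep == cur_dep) & (new < cur))
        if ((cur != 2) & (cur != new)).any():
            conflicts += 1
        states[rows, k] = np.where(replace, new, cur)
    if conflicts:
        logging.getLogger("popcnv").warning(
            "%d calls hit probes already assigned a different state", conflicts
        )
    return states, [p.id for p in kept]


def cnv_distance(
    calls: list[CnvCall],
    probes: list[ProbeSet],
    sample_ids: list[str],
) -> DistanceMatrix:
    """Fraction of autosomal probe sets with differing collapsed copy states."""
    if len(sample_ids) < 2:
        raise ValueError("need at least 2 samples")
    states, _ = probe_state_matrix(calls, probes, sample_ids)
    if states.shape[0] == 0:
        raise ValueError("no autosomal probes available")
    n = len(sample_ids)
    d = np.zeros((n, n))
    total = states.shape[0]
    for i in range(n):
        diff = (states != states[:, [i]]).sum(axis=0)
        d[i, :] = diff / total
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids=tuple(sample_ids), matrix=d, kind="cnv")


def exclude_high_call_samples(
    calls: list[CnvCall], percentile: float = 95.0
) -> tuple[list[CnvCall], set[str]]:
    """Drop samples whose call count is at or above the given percentile.

    Samples with extreme call counts can dominate distance-based
    ordinations; this optional filter (off by default in the pipeline)
    removes them before distance computation.  Returns the retained calls
    and the excluded sample ids.
    """
    counts: dict[str, int] = {}
    for c in calls:
        counts[c.sample_id] = counts.get(c.sample_id, 0) + 1
    if not counts:
        return list(calls), set()
    cutoff = float(np.percentile(list(counts.values()), percentile))
    excluded = {s for s, n in counts.items() if n >= cutoff}
    if len(excluded) == len(counts):  # degenerate: all samples tie
        return list(calls), set()
    return [c for c in calls if c.sample_id not in excluded], excluded


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Tree:
    """Unrooted tree as a Newick string plus its leaf set.

    Negative branch lengths can arise from the NJ arithmetic and are kept,
    flagged by :attr:`has_negative_lengths`.
    """

    newick: str
    leaves: tuple[str, ...]
    has_negative_lengths: bool


def nj_tree(d: DistanceMatrix) -> Tree:
    """Classical Saitou-Nei neighbor joining with deterministic tie-breaks.

    Ties in the Q-criterion resolve to the lexicographically smallest pair
    of clade labels (a clade is labelled by its smallest leaf), so the
    output is independent of input order.
    """
    n = len(d.ids)
    if n < 3:
        raise ValueError("need at least 3 samples")
    m = d.matrix.copy()
    if not np.allclose(m, m.T):
        raise ValueError("non-symmetric distance matrix")
    # active nodes: (tie-break label, newick fragment)
    labels = list(d.ids)
    newicks = [str(x) for x in d.ids]
    active = list(range(n))
    dist = {(i, j): m[i, j] for i in range(n) for j in range(n) if i < j}

    def getd(i: int, j: int) -> float:
        return 0.0 if i == j else dist[(min(i, j), max(i, j))]

    next_id = n
    negative = False
    while len(active) > 3:
        k = len(active)
        r = {i: sum(getd(i, j) for j in active if j != i) for i in active}
        best = None
        for ai in range(k):
            for aj in range(ai + 1, k):
                i, j = active[ai], active[aj]
                q = (k - 2) * getd(i, j) - r[i] - r[j]
                lab = tuple(sorted((labels[i], labels[j])))
                key = (q, lab)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = getd(i, j)
        li = dij / 2 + (r[i] - r[j]) / (2 * (k - 2))
        lj = dij - li
        negative |= li < 0 or lj < 0
        u = next_id
        next_id += 1
        labels.append(min(labels[i], labels[j]))
        newicks.append(
            f"({newicks[i]}:{li:.10g},{newicks[j]}:{lj:.10g})"
        )
        for x in active:
            if x in (i, j):
                continue
            dux = (getd(i, x) + getd(j, x) - dij) / 2
            dist[(min(u, x), max(u, x))] = dux
        active = [x for x in active if x not in (i, j)] + [u]

    a, b, c = sorted(active, key=lambda x: labels[x])
    dab, dac, dbc = getd(a, b), getd(a, c), getd(b, c)
    la = (dab + dac - dbc) / 2
    lb = (dab + dbc - dac) / 2
    lc = (dac + dbc - dab) / 2
    negative |= min(la, lb, lc) < 0
    newick = (
        f"({newicks[a]}:{la:.10g},{newicks[b]}:{lb:.10g},"
        f"{newicks[c]}:{lc:.10g});"
    )
    return Tree(newick=newick, leaves=tuple(d.ids), has_negative_lengths=negative)


# ---------------------------------------------------------------------------
# Ordination and Mantel
# ---------------------------------------------------------------------------

def classical_mds(d: DistanceMatrix, k: int = 2) -> np.ndarray:
    """Principal coordinates: eigendecomposition of the double-centred
    Gram matrix, returning the top-k axes ordered by eigenvalue.

    Axes with non-positive eigenvalues are returned as zeros.  Sign
    convention: the largest-magnitude loading on each axis is positive.
    """
    n = len(d.ids)
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for k={k}")
    sq = d.matrix ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ sq @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    coords = np.zeros((n, k))
    for axis, idx in enumerate(order):
        lam = vals[idx]
        if lam <= 1e-12:
            continue
        v = vecs[:, idx] * np.sqrt(lam)
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        coords[:, axis] = v
    return coords


def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 9999,
    rng_seed: int = 0,
) -> tuple[float, float]:
    """One-sided (positive-association) Mantel test.

    r is the Pearson correlation of the strictly-lower-triangle entries;
    the p-value is (1 + #{permuted r* >= r}) / (1 + n_perm) under random
    simultaneous row/column permutations of d2.
    """
    if d1.ids != d2.ids:
        raise ValueError("matrices must share the same samples in order")
    n = len(d1.ids)
    tri = np.tril_indices(n, k=-1)
    x = d1.matrix[tri]
    y = d2.matrix[tri]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant distance matrix: correlation undefined")

    def _pearson(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(a @ b / np.sqrt((a @ a) * (b @ b)))

    r = _pearson(x, y)
    rng = np.random.default_rng(rng_seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = d2.matrix[np.ix_(perm, perm)][tri]
        if _pearson(x, yp) >= r:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return r, p
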