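"""SNP/CNV distances, neighbor joining, principal coordinates and Mantel,
cross-checked against closed forms and scikit-bio."""

import io

import numpy as np
import pandas as pd
import pytest

from popcnv.core_io import CnvCall, GenotypeMatrix, ProbeSet
from popcnv.distance_phylo import (
    DistanceMatrix,
    classical_mds,
    cnv_distance,
    mantel_test,
    nj_tree,
    probe_state_matrix,
    snp_distance,
)


def _gm(columns: dict) -> GenotypeMatrix:
    n = len(next(iter(columns.values())))
    return GenotypeMatrix(
        pd.DataFrame(columns, index=[f"p{i}" for i in range(n)])
    )


def _probe(pos, chrom="chr1", ptype="SNP", pid=None):
    return ProbeSet(id=pid or f"{chrom}_{pos}", chrom=chrom, pos=pos,
                    probe_type=ptype)


def _call(sample, start, end, state, chrom="chr1"):
    return CnvCall(sample_id=sample, chrom=chrom, start=start, end=end,
                   copy_state=state, n_markers=3)


class TestSnpDistance:
    def test_identical_columns_zero(self):
        d = snp_distance(_gm({"a": ["AA", "BB"], "b": ["AA", "BB"]}))
        assert d.matrix[0, 1] == 0.0

    def test_shared_nocall_not_a_difference(self):
        d = snp_distance(
            _gm({"a": ["AA", "AB", "NoCall", "BB"],
                 "b": ["AA", "BB", "NoCall", "BB"]})
        )
        assert d.matrix[0, 1] == pytest.approx(1 / 3)

    def test_het_differs_from_both_homozygotes(self):
        d = snp_distance(_gm({"a": ["AB", "AB"], "b": ["AA", "BB"]}))
        assert d.matrix[0, 1] == 1.0

    def test_zero_cocalled_loci_error(self):
        with pytest.raises(ValueError, match="share no called loci"):
            snp_distance(_gm({"a": ["AA", "NoCall"], "b": ["NoCall", "AA"]}))

    def test_matches_per_locus_bruteforce(self):
        rng = np.random.default_rng(0)
        vals = np.array(["AA", "AB", "BB", "NoCall"])
        table = pd.DataFrame(
            vals[rng.integers(0, 4, size=(200, 6))],
            index=[f"p{i}" for i in range(200)],
            columns=[f"s{i}" for i in range(6)],
        )
        d = snp_distance(GenotypeMatrix(table))
        for i in range(6):
            for j in range(6):
                num = den = 0
                for k in range(200):
                    gi, gj = table.iloc[k, i], table.iloc[k, j]
                    if gi == "NoCall" or gj == "NoCall":
                        continue
                    den += 1
                    num += gi != gj
                assert d.matrix[i, j] == pytest.approx(num / den)


class TestCnvDistance:
    def test_worked_example(self):
        probes = [_probe(100), _probe(200), _probe(300), _probe(400)]
        calls = [
            _call("a", 250, 350, 1),   # probe 300 -> 1
            _call("a", 350, 450, 4),   # probe 400 -> 3+
            _call("b", 350, 450, 4),
        ]
        d = cnv_distance(calls, probes, ["a", "b"])
        assert d.matrix[0, 1] == pytest.approx(0.25)

    def test_no_calls_zero_matrix(self):
        probes = [_probe(100), _probe(200)]
        d = cnv_distance([], probes, ["a", "b"])
        assert (d.matrix == 0).all()

    def test_sex_chromosome_probes_excluded(self):
        probes = [_probe(100), _probe(100, chrom="chrX", pid="xp")]
        states, ids = probe_state_matrix([], probes, ["a"])
        assert ids == ["chr1_100"]

    def test_overlapping_same_sample_calls_extreme_deletion_wins(self):
        probes = [_probe(100)]
        calls = [_call("a", 50, 150, 3), _call("a", 60, 140, 1)]
        states, _ = probe_state_matrix(calls, probes, ["a"])
        assert states[0, 0] == 1  # tie in departure: deletion wins
        calls = [_call("a", 50, 150, 0), _call("a", 60, 140, 3)]
        states, _ = probe_state_matrix(calls, probes, ["a"])
        assert states[0, 0] == 0  # larger departure wins

    def test_matches_per_probe_bruteforce(self, toy_genome):
        rng = np.random.default_rng(1)
        probes = [
            _probe(int(p), pid=f"q{i}")
            for i, p in enumerate(
                np.sort(rng.choice(900_000, size=150, replace=False)) + 1
            )
        ]
        samples = [f"s{i}" for i in range(5)]
        calls = []
        for s in samples:
            for _ in range(4):
                start = int(rng.integers(1, 800_000))
                calls.append(
                    _call(s, start, start + int(rng.integers(1000, 80_000)),
                          int(rng.choice([0, 1, 3, 4])))
                )
        d = cnv_distance(calls, probes, samples)
        # brute force: assign states probe by probe
        def state_of(sample, probe):
            best = 2
            for c in calls:
                if c.sample_id != sample or not (c.start <= probe.pos <= c.end):
                    continue
                s = 3 if c.copy_state >= 3 else c.copy_state
                if abs(s - 2) > abs(best - 2) or (
                    abs(s - 2) == abs(best - 2) and s < best
                ):
                    best = s
            return best

        for i, a in enumerate(samples):
            for j, b in enumerate(samples):
                diff = sum(
                    state_of(a, p) != state_of(b, p) for p in probes
                )
                assert d.matrix[i, j] == pytest.approx(diff / len(probes))

    def test_zero_iff_identical_state_vectors(self):
        probes = [_probe(100), _probe(5000)]
        calls = [_call("a", 50, 150, 1), _call("b", 50, 150, 1)]
        d = cnv_distance(calls, probes, ["a", "b"])
        assert d.matrix[0, 1] == 0.0


def _additive_tree_distances(rng, n):
    """Random additive tree: build a random topology with positive branch
    lengths via dendropy and return its path-length matrix."""
    import dendropy
    from dendropy.simulate import treesim

    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n)])
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n, taxon_namespace=taxa,
        rng=__import__("random").Random(int(rng.integers(1 << 30))),
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(rng.uniform(0.5, 2.0))
    pdm = tree.phylogenetic_distance_matrix()
    ids = [t.label for t in taxa]
    m = np.zeros((n, n))
    for i, ti in enumerate(taxa):
        for j, tj in enumerate(taxa):
            if i != j:
                m[i, j] = pdm.distance(ti, tj)
    return DistanceMatrix(ids=tuple(ids), matrix=m, kind="snp"), tree


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(
            ids=("A", "B", "C"),
            matrix=np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float),
            kind="snp",
        )
        tree = nj_tree(d)
        import dendropy

        t = dendropy.Tree.get(data=tree.newick, schema="newick")
        lengths = {leaf.taxon.label: leaf.edge.length for leaf in t.leaf_node_iter()}
        assert lengths == {"A": 1.0, "B": 1.0, "C": 3.0}

    def test_additive_four_taxon_recovery(self):
        # ((A:1,B:2):1,(C:3,D:1)) -> distances are additive
        d = DistanceMatrix(
            ids=("A", "B", "C", "D"),
            matrix=np.array(
                [[0, 3, 5, 3], [3, 0, 6, 4], [5, 6, 0, 4], [3, 4, 4, 0]],
                dtype=float,
            ),
            kind="snp",
        )
        tree = nj_tree(d)
        import dendropy

        t = dendropy.Tree.get(data=tree.newick, schema="newick")
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in t.taxon_namespace}
        for i, a in enumerate(d.ids):
            for j, b in enumerate(d.ids):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                        d.matrix[i, j]
                    )

    def test_identical_pair_zero_length_cherry(self):
        d = DistanceMatrix(
            ids=("A", "B", "C", "D"),
            matrix=np.array(
                [[0, 0, 4, 4], [0, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]],
                dtype=float,
            ),
            kind="snp",
        )
        tree = nj_tree(d)
        assert "A:0" in tree.newick and "B:0" in tree.newick

    @pytest.mark.parametrize("n", [5, 8, 10])
    def test_random_additive_tree_topology_recovered(self, n):
        """NJ is consistent on additive distances: exact topology and
        path lengths back."""
        import dendropy

        rng = np.random.default_rng(100 + n)
        d, true_tree = _additive_tree_distances(rng, n)
        est = nj_tree(d)
        t = dendropy.Tree.get(
            data=est.newick, schema="newick",
            taxon_namespace=true_tree.taxon_namespace,
        )
        for tree in (true_tree, t):
            tree.is_rooted = False
            tree.update_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(
            true_tree, t, is_bipartitions_updated=True
        )
        assert rf == 0
        pdm = t.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in true_tree.taxon_namespace}
        for i, a in enumerate(d.ids):
            for j, b in enumerate(d.ids):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                        d.matrix[i, j], abs=1e-8
                    )

    def test_agrees_with_skbio_on_random_matrix(self):
        """Independent oracle: scikit-bio's NJ on a random (noisy) matrix
        produces the same topology under our deterministic tie-breaks."""
        import dendropy
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(7)
        n = 7
        base = rng.uniform(0.1, 1.0, size=(n, n))
        m = (base + base.T) / 2
        np.fill_diagonal(m, 0)
        ids = tuple(f"s{i}" for i in range(n))
        ours = nj_tree(DistanceMatrix(ids=ids, matrix=m, kind="snp"))
        theirs = skbio_nj(SkbioDM(m, ids=list(ids)))
        tns = dendropy.TaxonNamespace(list(ids))
        t1 = dendropy.Tree.get(data=ours.newick, schema="newick",
                               taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=str(theirs).replace("root", ""),
                               schema="newick", taxon_namespace=tns)
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(
                ids=("a", "b"), matrix=np.array([[0, 1], [2, 0]]), kind="snp"
            )


class TestClassicalMds:
    def test_collinear_points(self):
        d = DistanceMatrix(
            ids=("a", "b", "c"),
            matrix=np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=float),
            kind="snp",
        )
        coords = classical_mds(d, k=2)
        # the line is recovered on axis 1; axis 2 is degenerate
        got = np.abs(np.diff(np.sort(coords[:, 0])))
        assert got == pytest.approx([1.0, 1.0], abs=1e-9)
        assert np.abs(coords[:, 1]).max() == pytest.approx(0.0, abs=1e-9)

    def test_known_2d_configuration_recovered(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(12, 2))
        m = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        d = DistanceMatrix(
            ids=tuple(f"s{i}" for i in range(12)), matrix=m, kind="snp"
        )
        coords = classical_mds(d, k=2)
        re_d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        assert np.abs(re_d - m).max() < 1e-9

    def test_duplicate_samples_identical_coordinates(self):
        d = DistanceMatrix(
            ids=("a", "b", "c", "d"),
            matrix=np.array(
                [[0, 0, 3, 3], [0, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]],
                dtype=float,
            ),
            kind="snp",
        )
        coords = classical_mds(d, k=2)
        assert coords[0] == pytest.approx(coords[1], abs=1e-9)

    def test_agrees_with_skbio_pcoa(self):
        from skbio.stats.ordination import pcoa

        rng = np.random.default_rng(2)
        pts = rng.normal(size=(9, 3))
        m = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        d = DistanceMatrix(
            ids=tuple(f"s{i}" for i in range(9)), matrix=m, kind="snp"
        )
        ours = classical_mds(d, k=2)
        from skbio import DistanceMatrix as SkbioDM

        theirs = pcoa(SkbioDM(m, ids=list(d.ids))).samples.values[:, :2]
        for axis in range(2):
            v = theirs[:, axis]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            assert ours[:, axis] == pytest.approx(v, abs=1e-8)


class TestMantel:
    def _random_dm(self, rng, n, ids=None):
        base = rng.uniform(0.1, 1.0, size=(n, n))
        m = (base + base.T) / 2
        np.fill_diagonal(m, 0)
        return DistanceMatrix(
            ids=ids or tuple(f"s{i}" for i in range(n)), matrix=m, kind="snp"
        )

    def test_identity_r_one(self):
        rng = np.random.default_rng(0)
        d = self._random_dm(rng, 8)
        r, p = mantel_test(d, d, n_perm=99, rng_seed=0)
        assert r == pytest.approx(1.0)
        assert p <= 0.05

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        d = self._random_dm(rng, 8)
        d2 = DistanceMatrix(ids=d.ids, matrix=2 * d.matrix, kind="cnv")
        r, _ = mantel_test(d, d2, n_perm=49, rng_seed=0)
        assert r == pytest.approx(1.0)

    def test_constant_matrix_rejected(self):
        d = DistanceMatrix(
            ids=("a", "b", "c"),
            matrix=np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float),
            kind="snp",
        )
        with pytest.raises(ValueError, match="constant"):
            mantel_test(d, d, n_perm=9)

    def test_null_calibration(self):
        """Independent random matrices: p below 0.05 in roughly 5 % of
        seeded replicates."""
        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            d1 = self._random_dm(rng, 10)
            d2 = self._random_dm(rng, 10)
            _, p = mantel_test(d1, d2, n_perm=199,
                               rng_seed=int(rng.integers(1 << 30)))
            hits += p < 0.05
        assert hits / n_rep < 0.2

    def test_agrees_with_skbio(self):
        from skbio.stats.distance import mantel as skbio_mantel
        from skbio import DistanceMatrix as SkbioDM

        rng = np.random.default_rng(3)
        d1 = self._random_dm(rng, 9)
        noise = rng.normal(scale=0.05, size=d1.matrix.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        m2 = np.abs(d1.matrix + noise)
        m2 = (m2 + m2.T) / 2
        np.fill_diagonal(m2, 0)
        d2 = DistanceMatrix(ids=d1.ids, matrix=m2, kind="cnv")
        r_ours, _ = mantel_test(d1, d2, n_perm=99, rng_seed=0)
        r_theirs, _, _ = skbio_mantel(
            SkbioDM(d1.matrix, ids=list(d1.ids)),
            SkbioDM(d2.matrix, ids=list(d2.ids)),
            method="pearson", permutations=0,
        )
        assert r_ours == pytest.approx(float(r_theirs), abs=1e-12)


def test_high_call_count_filter():
    """Samples at/above the 95th percentile of call counts are dropped;
    the filter is optional and leaves degenerate all-equal panels alone."""
    from popcnv.distance_phylo import exclude_high_call_samples

    calls = []
    for s, n in (("a", 3), ("b", 3), ("c", 3), ("d", 30)):
        for k in range(n):
            calls.append(_call(s, 1000 * (k + 1), 1000 * (k + 1) + 500, 1))
    kept, excluded = exclude_high_call_samples(calls)
    assert excluded == {"d"}
    assert {c.sample_id for c in kept} == {"a", "b", "c"}
    # all-equal counts: nothing removed
    kept2, excluded2 = exclude_high_call_samples(
        [c for c in calls if c.sample_id != "d"]
    )
    assert excluded2 == set()
    assert len(kept2) == 9


def test_group_structure_flows_from_cnv_to_distances(default_panel):
    """Planted group-structured CNVRs: within-group CNV distance is below
    between-group, and SNP/CNV distances correlate positively (Mantel)."""
    inputs, truth = default_panel
    ids = [m.sample_id for m in inputs.meta]
    d_cnv = cnv_distance(inputs.calls, inputs.probes, ids)
    d_snp = snp_distance(inputs.genotypes)
    group = truth.group_of
    within, between = [], []
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            (within if group[a] == group[ids[j]] else between).append(
                d_cnv.matrix[i, j]
            )
    assert np.mean(within) < np.mean(between)
    r, p = mantel_test(d_snp, d_cnv, n_perm=499, rng_seed=1)
    assert r > 0
    assert p < 0.05
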