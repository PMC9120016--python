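import itertools
import math

import numpy as np
import pytest

from dynevo import couplings, synthetic
from dynevo.couplings import StringAlignment, StructuralAlphabet


def brute_force_nmi(ci, cj):
    """Independent oracle: exhaustive joint-count plug-in I and H plus the
    Miller–Madow finite-size bias, from first principles."""
    m = len(ci)
    letters_i = sorted(set(ci))
    letters_j = sorted(set(cj))
    joint = {}
    for a, b in zip(ci, cj):
        joint[(a, b)] = joint.get((a, b), 0) + 1
    h_ij = -sum((n / m) * math.log(n / m) for n in joint.values())
    pi = {a: sum(1 for x in ci if x == a) / m for a in letters_i}
    pj = {b: sum(1 for x in cj if x == b) / m for b in letters_j}
    h_i = -sum(p * math.log(p) for p in pi.values())
    h_j = -sum(p * math.log(p) for p in pj.values())
    mi = h_i + h_j - h_ij
    eps = (len(letters_i) - 1) * (len(letters_j) - 1) / (2 * m)
    if h_ij == 0:
        return 0.0, mi, h_ij, eps
    return min(1.0, max(0.0, (mi - eps) / h_ij)), mi, h_ij, eps


def alignment_from_matrix(mat):
    mat = np.asarray(mat)
    windows = [("A", i) for i in range(mat.shape[1])]
    k = int(mat.max()) + 1
    protos = np.zeros((max(k, 2), 5))
    protos[:, 0] = np.arange(max(k, 2))
    return StringAlignment(matrix=mat, windows=windows,
                           alphabet=StructuralAlphabet(protos))


class TestAlphabet:
    def test_generic_table_loads(self):
        a = StructuralAlphabet.generic()
        assert a.k == 25

    def test_exact_prototype_maps_to_itself(self):
        a = StructuralAlphabet.generic()
        letters = a.encode_descriptors(a.prototypes)
        assert list(letters) == list(range(25))

    def test_tie_breaks_to_lowest_index(self):
        protos = np.zeros((2, 5))
        protos[0, 0] = 1.0
        protos[1, 0] = 3.0
        a = StructuralAlphabet(protos)
        # descriptor equidistant from both prototypes
        mid = np.array([[2.0, 0, 0, 0, 0]])
        assert a.encode_descriptors(mid)[0] == 0

    def test_identical_conformers_identical_rows(self, monomer50):
        coords = np.repeat(monomer50.coords[None], 4, axis=0)
        from conftest import make_ensemble

        aln = couplings.encode(make_ensemble(monomer50, coords))
        assert (aln.matrix == aln.matrix[0]).all()

    def test_fit_alphabet_round_trip(self, monomer50):
        e, _ = synthetic.synth_ensemble(monomer50, m=100, seed=1)
        a = couplings.fit_alphabet(e, k=8, seed=0)
        assert a.k == 8
        aln = couplings.encode(e, a)
        assert aln.matrix.max() < 8


class TestNmi:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        """Plug-in nMI equals an exhaustive joint-count oracle to 1e-12 on
        small alphabets (≤ 5 letters, M ≤ 200)."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(20, 200))
        k = int(rng.integers(2, 6))
        ci = rng.integers(0, k, m)
        cj = np.where(rng.random(m) < 0.6, ci, rng.integers(0, k, m))
        aln = alignment_from_matrix(np.stack([ci, cj], axis=1))
        got = couplings.nmi(aln, 0, 1)
        want = brute_force_nmi(ci.tolist(), cj.tolist())
        assert got.nmi == pytest.approx(want[0], abs=1e-12)
        assert got.mi == pytest.approx(want[1], abs=1e-12)
        assert got.h_joint == pytest.approx(want[2], abs=1e-12)
        assert got.epsilon == pytest.approx(want[3], abs=1e-12)

    def test_identical_two_letter_columns(self):
        """C_i = C_j, two equiprobable letters: I = H = ln 2 and
        nMI = (ln 2 − ε)/ln 2 with ε = 1/(2M)."""
        m = 1000
        ci = np.array([0, 1] * (m // 2))
        aln = alignment_from_matrix(np.stack([ci, ci], axis=1))
        r = couplings.nmi(aln, 0, 1)
        ln2 = math.log(2)
        assert r.mi == pytest.approx(ln2, abs=1e-12)
        assert r.h_joint == pytest.approx(ln2, abs=1e-12)
        assert r.epsilon == pytest.approx(1 / (2 * m), abs=1e-15)
        assert r.nmi == pytest.approx((ln2 - 1 / (2 * m)) / ln2, abs=1e-12)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(42)
        mat = rng.integers(0, 4, (10_000, 2))
        aln = alignment_from_matrix(mat)
        assert couplings.nmi(aln, 0, 1).nmi < 0.02

    def test_constant_columns_zero(self):
        aln = alignment_from_matrix(np.zeros((100, 2), dtype=int))
        assert couplings.nmi(aln, 0, 1).nmi == 0.0

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        ci = rng.integers(0, 4, 500)
        cj = rng.integers(0, 4, 500)
        perm = np.array([2, 0, 3, 1])
        a1 = alignment_from_matrix(np.stack([ci, cj], axis=1))
        a2 = alignment_from_matrix(np.stack([perm[ci], cj], axis=1))
        assert couplings.nmi(a1, 0, 1).nmi == pytest.approx(
            couplings.nmi(a2, 0, 1).nmi, abs=1e-12
        )

    def test_copy_noise_monotonicity(self, monomer50):
        """Raising the copy noise on a planted fragment coupling strictly
        lowers its nMI."""
        vals = []
        for noise in (0.0, 0.15, 0.3, 0.45):
            e, _ = synthetic.synth_ensemble(
                monomer50, spectrum=(0.3,), coupled_pairs=[(2, 30)],
                noise=noise, m=800, seed=21, coord_sigma=0.05,
            )
            aln = couplings.encode(e)
            vals.append(couplings.nmi(aln, 2, 30).nmi)
        assert all(a > b for a, b in zip(vals[:-1], vals[1:]))


class TestNetwork:
    def test_constant_alignment_no_edges(self):
        aln = alignment_from_matrix(np.zeros((50, 8), dtype=int))
        net = couplings.build_network(aln)
        assert net.n_edges == 0

    def test_planted_pair_top_ranked(self, monomer50):
        """A noiselessly coupled fragment pair yields the top-ranked edge
        of the separation-filtered network; the deformation spans the two
        middle residues of each window, so the winning windows must cover
        the planted ones (window smear of ± 2 residues)."""
        e, _ = synthetic.synth_ensemble(
            monomer50, spectrum=(0.3,), coupled_pairs=[(2, 30)],
            noise=0.0, m=1500, seed=2, coord_sigma=0.05,
        )
        aln = couplings.encode(e)
        net = couplings.build_network(aln, nmi_threshold=0.15, min_sep=4)
        assert net.n_edges >= 1
        best = net.edges.sort_values("nmi", ascending=False).iloc[0]
        lo, hi = sorted((int(best.i), int(best.j)))
        assert abs(lo - 2) <= 2 and abs(hi - 30) <= 2

    def test_min_sep_filters_adjacent_windows(self, monomer50):
        e, _ = synthetic.synth_ensemble(monomer50, m=400, seed=5, coord_sigma=0.05)
        aln = couplings.encode(e)
        net = couplings.build_network(aln, nmi_threshold=-1.0, min_sep=4,
                                      significance=False)
        for row in net.edges.itertuples():
            _, si = aln.windows[int(row.i)]
            _, sj = aln.windows[int(row.j)]
            assert abs(si - sj) > 4


class TestCentrality:
    def test_two_nodes_equal(self):
        net = _net_from_edges(2, [(0, 1, 1.0)])
        c = couplings.centrality(net)
        assert np.allclose(c, [1 / np.sqrt(2)] * 2, atol=1e-12)

    def test_path_ratio_sqrt2(self):
        """3-node path with equal weights: center/end centrality = √2."""
        net = _net_from_edges(3, [(0, 1, 0.5), (1, 2, 0.5)])
        c = couplings.centrality(net)
        assert c[1] / c[0] == pytest.approx(np.sqrt(2), abs=1e-9)

    def test_star_hub_maximal(self):
        net = _net_from_edges(5, [(0, k, 0.4) for k in range(1, 5)])
        c = couplings.centrality(net)
        assert c[0] > c[1:].max()

    def test_power_iteration_agreement(self):
        """Eigenvector centrality agrees with power iteration to 1e-8."""
        rng = np.random.default_rng(8)
        edges = [
            (i, j, float(rng.random()))
            for i, j in itertools.combinations(range(12), 2)
            if rng.random() < 0.4
        ]
        net = _net_from_edges(12, edges)
        c = couplings.centrality(net)
        v = np.ones(12) / np.sqrt(12)
        for _ in range(5000):
            v = net.matrix @ v
            v /= np.linalg.norm(v)
        mask = v > 1e-12
        assert np.allclose(c[mask], v[mask], atol=1e-8)

    def test_residue_profile_uniform_network_flat(self):
        net = _net_from_edges(4, [(i, j, 0.3) for i, j in
                                  itertools.combinations(range(4), 2)])
        couplings.centrality(net)
        prof = couplings.residue_profile(net)
        vals = np.array(list(prof.values()))
        assert np.allclose(vals, vals[0], atol=1e-12)

    def test_empty_network_error(self):
        net = _net_from_edges(3, [])
        with pytest.raises(ValueError):
            couplings.centrality(net)


def _net_from_edges(n_nodes, edges):
    import pandas as pd

    mat = np.zeros((n_nodes, n_nodes))
    rows = []
    for i, j, w in edges:
        mat[i, j] = mat[j, i] = w
        rows.append((i, j, w, w, 1.0, 0.0))
    return couplings.CouplingNetwork(
        edges=pd.DataFrame(rows, columns=["i", "j", "nmi", "mi", "h_joint", "epsilon"]),
        matrix=mat,
        windows=[("A", 4 * k) for k in range(n_nodes)],
        nmi_threshold=0.0,
        significance_threshold=0.0,
    )


from hypothesis import given, settings
from hypothesis import strategies as st


class TestNmiProperties:
    """Hypothesis-driven invariants of the corrected nMI estimator."""

    @staticmethod
    def _columns(draw):
        m = draw(st.integers(4, 120))
        k = draw(st.integers(2, 5))
        ci = draw(st.lists(st.integers(0, k - 1), min_size=m, max_size=m))
        cj = draw(st.lists(st.integers(0, k - 1), min_size=m, max_size=m))
        return np.array(ci), np.array(cj)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.data())
    def test_bounded_and_symmetric(self, data):
        """nMI stays in [0, 1] and is symmetric in its two columns."""
        ci, cj = self._columns(data.draw)
        aln = alignment_from_matrix(np.stack([ci, cj], axis=1))
        r_ij = couplings.nmi(aln, 0, 1)
        r_ji = couplings.nmi(aln, 1, 0)
        assert 0.0 <= r_ij.nmi <= 1.0
        assert r_ij.nmi == pytest.approx(r_ji.nmi, abs=1e-12)
        assert r_ij.h_joint == pytest.approx(r_ji.h_joint, abs=1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.data())
    def test_self_coupling_maximal_given_columns(self, data):
        """A column against itself never scores below that column against
        any other column of the same alignment (nMI of a copy is maximal
        up to the bias correction on non-degenerate columns)."""
        ci, cj = self._columns(data.draw)
        if len(set(ci.tolist())) < 2:
            return
        aln = alignment_from_matrix(np.stack([ci, ci, cj], axis=1))
        self_r = couplings.nmi(aln, 0, 1)
        cross_r = couplings.nmi(aln, 0, 2)
        assert self_r.nmi >= cross_r.nmi - 1e-9
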