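import numpy as np
import pytest

from shapemotif.index import build_index, revcomp
from shapemotif.motifs import (
    Motif,
    build_distance_matrix,
    cluster_motifs,
    consensus_mismatches,
    generalize_seed,
    merge_cluster,
    motif_distance,
    rank_motifs,
    trim_motif,
)
from shapemotif.simulate import default_planted_pfm, _sample_pfm_instance


def random_motif(rng, L=8, scale=50):
    return Motif(counts=rng.dirichlet(np.ones(4), size=L) * scale, support=scale)


class TestGeneralizeSeed:
    def test_enumerates_4k_variants(self):
        # K = 8 -> exactly 32 single-substitution lookups fill an 8x4 matrix
        seed = "ACGTACGT"
        idx = build_index([seed], 8, "forward")
        m = generalize_seed(seed, idx)
        assert m.counts.shape == (8, 4)
        variants = {seed[:i] + b + seed[i + 1:] for i in range(8) for b in "ACGT"}
        assert len(variants) == 3 * 8 + 1  # 24 distinct substitutions + the seed
        assert m.counts.size == 4 * 8  # the 4*K enumerated cells

    def test_seed_only_fixture(self):
        seed = "AAACCCGG"
        idx = build_index([seed], 8, "forward")
        m = generalize_seed(seed, idx)
        base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for i, c in enumerate(seed):
            assert m.counts[i, base_idx[c]] == 1
            off = [b for b in range(4) if b != base_idx[c]]
            assert np.all(m.counts[i, off] == 0)
        assert m.support == 1

    def test_absent_seed_rejected(self):
        idx = build_index(["AAAAAAAA"], 8, "forward")
        with pytest.raises(KeyError):
            generalize_seed("CCCCCCCC", idx)

    def test_planted_pfm_column_recovery(self):
        # 500 instances drawn from a known PFM; single-substitution counts
        # recover the column frequencies within 0.05
        rng = np.random.default_rng(0)
        # single-substitution enumeration conditions on the other K-1
        # columns matching the seed, so the effective depth is
        # 500 * dominant**(K-1); 0.9 keeps that depth compatible with the
        # 0.05 tolerance
        pfm = default_planted_pfm(dominant=0.9)
        consensus = "TCAAGGTCA"
        bases = np.array(list("ACGT"))
        regions = []
        for _ in range(500):
            bgseq = "".join(bases[rng.integers(0, 4, 60)])
            inst = _sample_pfm_instance(pfm, rng)
            regions.append(bgseq[:25] + inst + bgseq[34:])
        idx = build_index(regions, 9, "forward")
        m = generalize_seed(consensus, idx)
        freqs = m.counts / m.counts.sum(axis=1, keepdims=True)
        assert np.max(np.abs(freqs - pfm)) < 0.05


class TestMotifDistance:
    def test_identical_motifs_distance_zero(self):
        rng = np.random.default_rng(1)
        m = random_motif(rng)
        d, off, orient = motif_distance(m, m)
        assert d == pytest.approx(0.0, abs=1e-12)
        assert (off, orient) == (0, "+")

    def test_reverse_complement_distance_zero(self):
        rng = np.random.default_rng(2)
        m = random_motif(rng)
        d, off, orient = motif_distance(m, m.reverse_complement())
        assert d == pytest.approx(0.0, abs=1e-12)
        assert orient == "-"

    def test_matches_bruteforce_enumeration(self):
        # independent re-enumeration of every offset/orientation
        def brute(m1, m2, min_overlap):
            p1, L1 = m1.probs(), m1.length
            best = -np.inf
            for orient in ("+", "-"):
                p2 = m2.probs() if orient == "+" else m2.probs()[::-1, ::-1]
                L2 = m2.length
                for off in range(-L2 + 1, L1):
                    lo1, hi1 = max(0, off), min(L1, off + L2)
                    if hi1 - lo1 < min_overlap:
                        continue
                    a = p1[lo1:hi1].ravel()
                    b = p2[lo1 - off : hi1 - off].ravel()
                    r = np.corrcoef(a, b)[0, 1]
                    best = max(best, r)
            return 1 - best

        rng = np.random.default_rng(3)
        for _ in range(25):
            m1 = random_motif(rng, L=int(rng.integers(5, 10)))
            m2 = random_motif(rng, L=int(rng.integers(5, 10)))
            min_ov = max(4, int(np.ceil(min(m1.length, m2.length) / 2)))
            d, _, _ = motif_distance(m1, m2)
            assert d == pytest.approx(brute(m1, m2, min_ov), abs=1e-9)

    def test_distance_matrix_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(4)
        motifs = [random_motif(rng) for _ in range(6)]
        D, meta = build_distance_matrix(motifs)
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)
        assert np.all(D >= 0) and np.all(D <= 2)
        assert set(meta) == {(i, j) for i in range(6) for j in range(i + 1, 6)}


class TestClustering:
    def test_duplicate_plus_orthogonal_separates(self):
        rng = np.random.default_rng(5)
        a = random_motif(rng)
        b = Motif(counts=a.counts.copy(), support=a.support)
        c = random_motif(rng)
        motifs = [a, b, c]
        for i, m in enumerate(motifs):
            m.score = 1.0
        D, _ = build_distance_matrix(motifs)
        clusters = cluster_motifs(motifs, D, seed=0)
        as_sets = sorted(sorted(cl) for cl in clusters)
        assert [0, 1] in as_sets and [2] in as_sets

    def test_single_motif_single_cluster(self):
        m = random_motif(np.random.default_rng(6))
        assert cluster_motifs([m], np.zeros((1, 1))) == [[0]]

    def test_all_distant_motifs_stay_singletons(self):
        M = 5
        D = np.full((M, M), 2.0)
        np.fill_diagonal(D, 0.0)
        rng = np.random.default_rng(7)
        motifs = [random_motif(rng) for _ in range(M)]
        clusters = cluster_motifs(motifs, D, seed=1)
        assert sorted(len(c) for c in clusters) == [1] * M

    def test_three_planted_families_recovered(self):
        # 3 distinct PFM families, 4 shifted/perturbed members each
        rng = np.random.default_rng(8)
        families = []
        for f in range(3):
            base = rng.dirichlet(np.ones(4) * 0.2, size=10) * 80
            members = []
            for _ in range(4):
                noisy = base + rng.random(base.shape) * 4
                members.append(Motif(counts=noisy, support=80, score=1.0))
            families.append(members)
        motifs = [m for fam in families for m in fam]
        D, _ = build_distance_matrix(motifs)
        clusters = cluster_motifs(motifs, D, seed=2)
        labels = {}
        for ci, cl in enumerate(clusters):
            for i in cl:
                labels[i] = ci
        for f in range(3):
            fam_labels = {labels[f * 4 + j] for j in range(4)}
            assert len(fam_labels) == 1  # family stays together
        assert len(clusters) == 3

    def test_distance_threshold_override(self):
        rng = np.random.default_rng(9)
        motifs = [random_motif(rng) for _ in range(4)]
        D, _ = build_distance_matrix(motifs)
        clusters = cluster_motifs(motifs, D, distance_threshold=1e-9, seed=0)
        assert len(clusters) == 4  # stringent cut: nothing merges


class TestMergeCluster:
    def test_singleton_cluster_unchanged(self):
        m = random_motif(np.random.default_rng(10))
        merged = merge_cluster([m])
        assert np.allclose(merged.counts, m.counts)
        assert merged.support == m.support

    def test_identical_members_double_counts(self):
        rng = np.random.default_rng(11)
        a = random_motif(rng)
        b = Motif(counts=a.counts.copy(), support=a.support)
        merged = merge_cluster([a, b])
        assert np.allclose(merged.counts, 2 * a.counts)
        assert np.allclose(merged.probs(), a.probs(), atol=0.02)
        assert merged.support == 2 * a.support

    def test_offset_members_extend_length(self):
        # two strongly-informative motifs offset by one column
        core = np.array([[40, 1, 1, 1], [1, 40, 1, 1], [1, 1, 40, 1], [1, 1, 1, 40]] * 2, float)
        m1 = Motif(counts=core[:5], support=40, score=2.0)
        m2 = Motif(counts=core[1:6], support=40, score=1.0)
        d, off, orient = motif_distance(m1, m2)
        assert (off, orient) == (1, "+")
        merged = merge_cluster([m1, m2])
        assert merged.length == 6
        assert np.allclose(merged.counts[1:5], m1.counts[1:5] + m2.counts[:4])
        assert np.allclose(merged.counts[0], m1.counts[0])
        assert np.allclose(merged.counts[5], m2.counts[4])

    def test_revcomp_pair_merges_orientation_consistent(self):
        rng = np.random.default_rng(12)
        m = random_motif(rng)
        m.score = 2.0
        r = m.reverse_complement()
        r.score = 1.0
        merged = merge_cluster([m, r])
        assert merged.length == m.length
        assert np.allclose(merged.counts, 2 * m.counts)


class TestTrim:
    def _flanked(self, core_cols, flank_cols, n_flank=2):
        rows = [flank_cols] * n_flank + core_cols + [flank_cols] * n_flank
        return Motif(counts=np.array(rows, dtype=float), support=100)

    def test_uniform_flanks_trimmed_to_core(self):
        core = [[100, 2, 2, 2]] * 6
        m = self._flanked(core, [25, 25, 25, 25])
        t = trim_motif(m, min_info=0.3, min_support_frac=0.0)
        assert t.length == 6
        assert np.allclose(t.counts, core)

    def test_informative_motif_unchanged(self):
        m = Motif(counts=np.array([[100, 1, 1, 1]] * 8, float), support=100)
        t = trim_motif(m)
        assert t.length == 8

    def test_low_ic_ends_trimmed(self):
        # 0.3/0.3/0.2/0.2 columns carry ~0.03 bits: below any sane cutoff
        weak = [30, 30, 20, 20]
        core = [[100, 2, 2, 2]] * 6
        m = self._flanked(core, weak, n_flank=1)
        t = trim_motif(m, min_info=0.3, min_support_frac=0.0)
        assert t.length == 6

    def test_never_below_four_columns(self):
        m = Motif(counts=np.full((6, 4), 10.0), support=10)
        with pytest.warns(UserWarning):
            t = trim_motif(m, min_info=0.3)
        assert t.length >= 4

    def test_low_support_ends_trimmed(self):
        core = [[200, 5, 5, 5]] * 5
        m = self._flanked(core, [4, 1, 1, 1], n_flank=1)  # informative but rare
        t = trim_motif(m, min_info=0.0, min_support_frac=0.1)
        assert t.length == 5


class TestRankingAndConsensus:
    def test_rank_by_support_times_score(self):
        a = Motif(counts=np.full((4, 4), 5.0), support=10, score=1.0)
        b = Motif(counts=np.full((4, 4), 5.0), support=100, score=0.5)
        c = Motif(counts=np.full((4, 4), 5.0), support=10, score=10.0)
        assert rank_motifs([a, b, c]) == [c, b, a]

    def test_consensus_ties_become_iupac(self):
        m = Motif(counts=np.array([[10, 10, 0, 0], [0, 0, 10, 0], [5, 5, 5, 5]], float))
        assert m.consensus == "MGN"

    @pytest.mark.parametrize(
        "target,consensus,expect",
        [
            ("TCAAGGTCA", "TCAAGGTCA", 0),
            ("TCAAGGTCA", "TGACCTTGA", 0),  # reverse complement
            ("TCAAGGTCA", "GGTCAAGGTCACC", 0),  # embedded
            ("TCAAGGTCA", "TCAAGGTCC", 1),
            ("TCAAGGTCA", "TCAARGTCA", 0),  # IUPAC R covers A/G
            ("TCAAGGTCA", "CAAGGTCA", 1),  # one uncovered position
        ],
    )
    def test_consensus_mismatch_helper(self, target, consensus, expect):
        assert consensus_mismatches(target, consensus) == expect
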