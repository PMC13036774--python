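"""C_Starter harvesting, alignment, diversity profiles, dot plots, trees,
and duplication/deletion detection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from depsitools.bgc import (
    AlignmentScoring,
    DomainAnnotation,
    NrpsBgc,
    align_global,
    detect_deletion,
    detect_duplications,
    dot_plot,
    harvest_cstarter,
    infer_modules,
    nj_tree,
    pairwise_identity,
    sliding_window_pi,
)
from depsitools.simulate import (
    BgcSimConfig,
    Deletion,
    Duplication,
    Recombination,
    simulate_bgc_family,
)
from oracles import brute_force_global_alignment_score

SMALL = dict(len_c=300, len_a=400, len_t=80, len_e=300, len_linker=30, len_te=150)


def _toy_bgc(n_a: int, with_cstarter=True, bgc_id="toy") -> NrpsBgc:
    domains = []
    pos = 0
    for m in range(n_a):
        kind = "C_Starter" if (m == 0 and with_cstarter) else "C"
        domains.append(DomainAnnotation(kind, "g1", pos, pos + 100,
                                        aa_sequence="MSTART" if kind == "C_Starter" else None))
        pos += 110
        domains.append(DomainAnnotation("A", "g1", pos, pos + 150))
        pos += 160
        domains.append(DomainAnnotation("T", "g1", pos, pos + 40))
        pos += 50
    return NrpsBgc(bgc_id, ["g1"], domains)


class TestHarvest:
    def test_large_cluster_with_cstarter_extracted(self):
        records = harvest_cstarter([_toy_bgc(12)])
        assert records == [("toy", "MSTART")]

    def test_small_cluster_excluded(self):
        assert harvest_cstarter([_toy_bgc(4)]) == []
        assert harvest_cstarter([_toy_bgc(5)]) == []
        assert harvest_cstarter([_toy_bgc(6)]) != []

    def test_no_cstarter_excluded(self):
        assert harvest_cstarter([_toy_bgc(8, with_cstarter=False)]) == []


class TestAlignGlobal:
    def test_identical_sequences_gapless(self):
        a, b, score = align_global("ACGTACGT", "ACGTACGT")
        assert a == b == "ACGTACGT"
        assert score == 8.0

    def test_single_mismatch(self):
        a, b, score = align_global("A", "G")
        assert (a, b) == ("A", "G")
        assert score == -1.0

    def test_single_gap_optimum(self):
        a, b, score = align_global("ACGT", "ACT")
        assert score == brute_force_global_alignment_score("ACGT", "ACT")
        assert sum(c == "-" for c in b) == 1

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = "".join(rng.choice(list("ACGT"), rng.integers(1, 6)))
        b = "".join(rng.choice(list("ACGT"), rng.integers(1, 6)))
        _, _, score = align_global(a, b)
        assert score == pytest.approx(brute_force_global_alignment_score(a, b), abs=1e-9)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_global("", "ACGT")


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACGT", "ACGT") == 100.0

    def test_half_identical(self):
        assert pairwise_identity("ACGT", "ACTT") == 75.0
        assert pairwise_identity("AAAA", "AATT") == 50.0

    def test_gap_column_handling(self):
        assert pairwise_identity("AC-T", "ACGT") == pytest.approx(75.0)
        assert pairwise_identity("AC-T", "ACGT", include_gap_columns=False) == pytest.approx(100.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pairwise_identity("ACG", "AC")

    def test_planted_divergence_recovered(self):
        cfg = BgcSimConfig(n_modules=6, e_modules=(), background_divergence=0.0,
                           member_events=[[Duplication((3, 4), 92.0)]], seed=21, **SMALL)
        (member,), _ = simulate_bgc_family(cfg)
        reps = detect_duplications(member, identity_threshold=85.0)
        tandem = [r for r in reps if r.window_a == (3, 4)]
        assert tandem
        assert tandem[0].identity == pytest.approx(92.0, abs=1.0)


class TestSlidingWindowPi:
    def test_identical_sequences_zero(self):
        prof = sliding_window_pi(["A" * 600, "A" * 600])
        assert all(v == 0.0 for v in prof.values)

    def test_fifteen_differences_in_one_window(self):
        a = "A" * 900
        b = list(a)
        for k in range(300, 600, 20):  # 15 substitutions inside window 2
            b[k] = "C"
        prof = sliding_window_pi([a, "".join(b)], width=300, step=300)
        assert prof.values[1] == pytest.approx(15 / 300)
        assert prof.values[0] == 0.0 and prof.values[2] == 0.0

    def test_swap_invariance_and_range(self):
        rng = np.random.default_rng(2)
        a = "".join(rng.choice(list("ACGT"), 700))
        b = "".join(rng.choice(list("ACGT"), 700))
        p1 = sliding_window_pi([a, b])
        p2 = sliding_window_pi([b, a])
        assert p1.values == p2.values
        assert all(0.0 <= v <= 1.0 for v in p1.values)

    def test_gap_columns_excluded(self):
        a = "ACGT" * 100
        b = "-" + a[1:]
        prof = sliding_window_pi([a, b], width=300, step=150)
        assert prof.values[0] == 0.0  # the gap column does not count as a difference

    def test_widening_window_never_raises_maximum(self):
        rng = np.random.default_rng(3)
        a = "".join(rng.choice(list("ACGT"), 1200))
        b = "".join(c if rng.random() > 0.1 else "A" for c in a)
        narrow = sliding_window_pi([a, b], width=300, step=150)
        wide = sliding_window_pi([a, b], width=600, step=150)
        assert max(wide.values) <= max(narrow.values) + 1e-12

    def test_short_alignment_rejected(self):
        with pytest.raises(ValueError):
            sliding_window_pi(["ACGT", "ACGT"], width=300)


class TestDotPlot:
    def test_self_comparison_full_diagonal(self):
        rng = np.random.default_rng(4)
        s = "".join(rng.choice(list("ACGT"), 300))
        dp = dot_plot(s, s)
        assert dp.main_diagonal_density() == 1.0

    def test_duplication_off_diagonal(self):
        rng = np.random.default_rng(5)
        block = "".join(rng.choice(list("ACGT"), 200))
        s = block + "".join(rng.choice(list("ACGT"), 100)) + block
        dp = dot_plot(s, s)
        assert (0, 300) in dp.matches  # duplicated block at offset 300

    def test_random_sequences_empty(self):
        rng = np.random.default_rng(6)
        a = "".join(rng.choice(list("ACGT"), 500))
        b = "".join(rng.choice(list("ACGT"), 500))
        assert dot_plot(a, b).matches == []

    def test_word_size_validation(self):
        with pytest.raises(ValueError):
            dot_plot("ACGT", "ACGT", word=0)
        with pytest.raises(ValueError):
            dot_plot("ACG", "ACGT", word=10)


def _additive_matrix_from_tree(branch, topo_pairs, n):
    """Path-length matrix for a tree given leaf-to-leaf branch paths."""
    d = np.zeros((n, n))
    for (i, j), length in topo_pairs.items():
        d[i, j] = d[j, i] = length
    return d


class TestNjTree:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        t = nj_tree(d, ["x", "y", "z"])
        assert t.path_length("x", "y") == pytest.approx(3.0, abs=1e-9)
        assert t.path_length("x", "z") == pytest.approx(4.0, abs=1e-9)
        assert t.path_length("y", "z") == pytest.approx(5.0, abs=1e-9)

    def test_four_taxon_additive_recovered(self):
        # tree ((A:2,B:3):1,(C:4,D:5)): additive path lengths
        d = np.array(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]], float
        )
        t = nj_tree(d, list("ABCD"))
        for (i, a), (j, b) in itertools.combinations(enumerate("ABCD"), 2):
            assert t.path_length(a, b) == pytest.approx(d[i, j], abs=1e-9)

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_random_additive_matrices_reproduced(self, n):
        rng = np.random.default_rng(n)
        # build a random additive matrix by attaching taxa to a random tree
        import dendropy

        taxa = dendropy.TaxonNamespace([f"t{k}" for k in range(n)])
        tree = dendropy.simulate.treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=n, taxon_namespace=taxa,
            rng=__import__("random").Random(n),
        )
        for edge in tree.edges():
            if edge.length is not None:
                edge.length = float(rng.uniform(0.5, 3.0))
        pdm = tree.phylogenetic_distance_matrix()
        d = np.zeros((n, n))
        names = [t.label for t in taxa]
        for i, j in itertools.combinations(range(n), 2):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
        t = nj_tree(d, names)
        for i, j in itertools.combinations(range(n), 2):
            assert t.path_length(names[i], names[j]) == pytest.approx(d[i, j], abs=1e-9)

    def test_zero_distances_star(self):
        d = np.zeros((4, 4))
        t = nj_tree(d, list("ABCD"))
        assert t.path_length("A", "C") == pytest.approx(0.0, abs=1e-12)

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(np.zeros((2, 2)), ["a", "b"])

    def test_bootstrap_support_on_clean_split(self):
        seqs = [
            "A" * 30 + "C" * 30,
            "A" * 30 + "C" * 28 + "TT",
            "G" * 30 + "C" * 30,
            "G" * 28 + "TT" + "C" * 30,
        ]
        t = nj_tree(seqs, list("abcd"), bootstrap=100, seed=0)
        assert t.support
        assert max(t.support.values()) > 0.8


class TestDetectDuplications:
    def test_planted_tandem_duplication_reported(self):
        cfg = BgcSimConfig(n_modules=10, e_modules=(7,), background_divergence=0.05,
                           member_events=[[Duplication((7, 8), 95.0)]], seed=11, **SMALL)
        (member,), _ = simulate_bgc_family(cfg)
        reps = detect_duplications(member, 90.0)
        assert any(r.window_a == (7, 8) and r.window_b == (9, 10) for r in reps)
        tandem = next(r for r in reps if r.window_a == (7, 8) and r.window_b == (9, 10))
        assert tandem.identity == pytest.approx(95.0, abs=2.0)

    def test_no_duplication_background_empty(self):
        cfg = BgcSimConfig(n_modules=6, e_modules=(), background_divergence=0.0,
                           member_events=[[]], seed=12, **SMALL)
        (member,), _ = simulate_bgc_family(cfg)
        assert detect_duplications(member, 90.0) == []

    def test_threshold_monotonicity(self):
        cfg = BgcSimConfig(n_modules=8, e_modules=(), background_divergence=0.0,
                           member_events=[[Duplication((3, 4), 93.0)]], seed=13, **SMALL)
        (member,), _ = simulate_bgc_family(cfg)
        low = detect_duplications(member, 90.0)
        high = detect_duplications(member, 97.0)
        assert high == []  # above the planted identity
        low_pairs = {(r.window_a, r.window_b) for r in low}
        assert {( (3,4), (5,6) )} <= low_pairs

    def test_missing_sequence_rejected(self):
        with pytest.raises(ValueError):
            detect_duplications(_toy_bgc(6), 90.0)


class TestDetectDeletion:
    def _family(self, seed, background=0.0):
        cfg = BgcSimConfig(n_modules=12, e_modules=(7, 9), background_divergence=background,
                           member_events=[[], [Deletion((5, 6))]], seed=seed, **SMALL)
        return simulate_bgc_family(cfg)

    def test_planted_deletion_localized_to_linker(self):
        (ref, qry), log = self._family(31)
        rep = detect_deletion(ref, qry)
        assert rep is not None and not rep.truncation
        truth = log["bgc_1"]["deletions"][0]
        assert abs(rep.query_junction - truth["junction"]) <= 25
        assert rep.junction_linker == "module 4 A-T linker"
        assert set(truth["modules"]) <= set(rep.deleted_modules) | {5, 6}
        assert 5 in rep.deleted_modules

    def test_identical_clusters_report_nothing(self):
        (ref, _), _ = self._family(32)
        assert detect_deletion(ref, ref) is None

    def test_terminal_loss_flagged_as_truncation(self):
        (ref, _), _ = self._family(33)
        modules = infer_modules(ref)
        cut = modules[-1].domains[0].start
        truncated = NrpsBgc(
            "trunc", ref.genes,
            [d for d in ref.domains if d.end <= cut],
            ref.sequence[:cut],
        )
        rep = detect_deletion(ref, truncated)
        assert rep is not None and rep.truncation

    def test_unrelated_sequences_raise(self):
        rng = np.random.default_rng(34)
        a = NrpsBgc("a", ["g"], [], "".join(rng.choice(list("ACGT"), 2000)))
        b = NrpsBgc("b", ["g"], [], "".join(rng.choice(list("ACGT"), 2000)))
        with pytest.raises(ValueError):
            detect_deletion(a, b)
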