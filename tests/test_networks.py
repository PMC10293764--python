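"""Fragments-network construction, grading and selection."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fragnets import (
    Candidate,
    NetworkCapExceeded,
    build_network,
    count_networks,
    formula,
    format_formula,
    ion_mz,
    select_best,
)


def cand(text, error=0.0):
    v = formula(text, charge=1) if not text.endswith(("+", "-")) else formula(text)
    return Candidate(v, ion_mz(v), error)


class TestCountNetworks:
    def test_five_by_five(self):
        assert count_networks([5, 5, 5, 5, 5]) == 3125

    def test_product_rule(self):
        assert count_networks([1]) == 1
        assert count_networks([2, 3, 4]) == 24

    def test_zero_candidates_rejected(self):
        with pytest.raises(ValueError):
            count_networks([3, 0, 2])


class TestBuildNetwork:
    def test_fully_consistent_chain_reaches_max_grade(self):
        chain = [cand("C4H8+"), cand("C3H6+"), cand("C2H4+"), cand("CH2+")]
        net = build_network(chain)
        assert net.grade == 6 == 4 * 3 // 2

    def test_unrelated_pair_has_grade_zero(self):
        net = build_network([cand("C4H8+"), cand("N3+")])
        assert net.grade == 0

    def test_precursor_fragment_pair(self):
        net = build_network([cand("C10SO3N3H12+"), cand("C6SO2NH6+")])
        assert net.grade == 1

    def test_edges_have_nonempty_neutral_losses(self):
        net = build_network([cand("C10SO3N3H12+"), cand("C6SO2NH6+"),
                             cand("C6NH6+"), cand("C5H5+")])
        for loss in net.neutral_losses().values():
            assert all(c >= 0 for c in loss.counts)
            assert sum(loss.counts) > 0
            assert loss.charge == 0

    def test_total_error_accumulates(self):
        net = build_network([cand("C4H8+", 1.0), cand("C2H4+", 0.5)])
        assert net.total_error_ppm == pytest.approx(1.5)

    def test_graph_export(self):
        net = build_network([cand("C4H8+"), cand("C2H4+")])
        g = net.to_graph()
        assert g.number_of_nodes() == 2 and g.number_of_edges() == 1
        assert g.edges[0, 1]["neutral_loss"] == "C2H4"

    @given(st.data())
    def test_grade_never_exceeds_pair_count(self, data):
        n = data.draw(st.integers(2, 8))
        pool = ["C4H8+", "C3H6+", "C2H4+", "CH2+", "C2O2H4+", "N3H3+",
                "C5OH10+", "O2H2+"]
        chosen = data.draw(st.lists(st.sampled_from(pool), min_size=n,
                                    max_size=n))
        net = build_network([cand(t) for t in chosen])
        assert 0 <= net.grade <= n * (n - 1) // 2


def brute_force_best(cands_per_peak):
    """Independent oracle: enumerate every assignment with itertools."""
    best = None
    for combo in itertools.product(*cands_per_peak):
        net = build_network(combo)
        key = (-net.grade, net.total_error_ppm, net.formulas())
        if best is None or key < best[0]:
            best = (key, net)
    return best[1]


def random_instances(seed, n_instances):
    """Small random selection problems built from CH(O) sub-formula pools."""
    rng = np.random.default_rng(seed)
    pool = [f"C{c}H{h}+" for c in range(1, 6) for h in range(1, 9)]
    for _ in range(n_instances):
        n_peaks = int(rng.integers(2, 6))
        yield [
            [cand(pool[k], error=float(rng.uniform(0, 10)))
             for k in rng.choice(len(pool), size=int(rng.integers(1, 5)),
                                 replace=False)]
            for _ in range(n_peaks)
        ]


class TestSelectBest:
    def test_higher_grade_wins(self):
        # grade-1 option (consistent pair) beats grade-0 despite worse error
        peak1 = [cand("C4H8+", 5.0), cand("N3H3+", 0.1)]
        peak2 = [cand("C2H4+", 5.0)]
        net = select_best([peak1, peak2], mode="exact")
        assert net.formulas() == ("C4H8+", "C2H4+")
        assert net.grade == 1

    def test_equal_grade_breaks_tie_on_total_error(self):
        peak1 = [cand("C4H8+", 1.2), cand("C4O2H8+", 0.4)]
        net = select_best([peak1], mode="exact")
        assert net.formulas() == ("C4O2H8+",)

    def test_deterministic_lexicographic_final_tie_break(self):
        peak1 = [cand("C2O2H4+", 1.0), cand("C3OH8+", 1.0)]
        assert select_best([peak1]).formulas() == ("C2O2H4+",)

    def test_exact_matches_brute_force_on_random_instances(self):
        for inst in random_instances(7, 25):
            assert count_networks([len(p) for p in inst]) <= 10_000
            exact = select_best(inst, mode="exact")
            oracle = brute_force_best(inst)
            assert exact.grade == oracle.grade
            assert exact.total_error_ppm == pytest.approx(oracle.total_error_ppm)
            assert exact.formulas() == oracle.formulas()

    def test_greedy_is_locally_optimal_and_often_globally(self):
        matched = 0
        for inst in random_instances(11, 20):
            greedy = select_best(inst, mode="greedy")
            oracle = brute_force_best(inst)
            assert greedy.grade <= oracle.grade
            # no single-candidate swap may improve the greedy result
            idx = [next(i for i, c in enumerate(peak)
                        if c is chosen or c == chosen)
                   for peak, chosen in zip(inst, greedy.assignment)]
            for i, peak in enumerate(inst):
                for a, alt in enumerate(peak):
                    if a == idx[i]:
                        continue
                    trial = list(greedy.assignment)
                    trial[i] = alt
                    assert build_network(trial).grade <= greedy.grade
            matched += greedy.formulas() == oracle.formulas()
        assert matched >= 15  # hill climbing finds the optimum most of the time

    def test_cap_raises_with_advice(self):
        inst = [[cand("C4H8+"), cand("C3H6+")]] * 21  # 2^21 > 10^6 assignments
        with pytest.raises(NetworkCapExceeded, match="greedy"):
            select_best(inst, mode="exact", cap=10**6)

    def test_adding_a_consistent_peak_never_lowers_grade(self):
        base = [[cand("C4H8+")], [cand("C2H4+")]]
        extended = base + [[cand("CH2+")]]
        assert select_best(extended).grade >= select_best(base).grade

    def test_empty_candidate_list_rejected(self):
        with pytest.raises(ValueError):
            select_best([[cand("C4H8+")], []])
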