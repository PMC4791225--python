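import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itrkit.errors import ValidationError
from itrkit.knowledge_io import PriorEdge, build_prior_network
from itrkit.omics_contrasts import EvidenceSet
from itrkit.regulator_activity import (
    activation_z,
    call_state,
    contributions,
    infer_itrs,
    overlap_pvalue,
    read_ranking,
    write_ranking,
)


def hypergeom_upper_tail(K, n, M, k):
    """Enumeration oracle: sum of hypergeometric pmf over the upper tail."""
    total = 0.0
    for j in range(k, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(M - K, n - j) / math.comb(M, n)
    return total


class TestOverlapPvalue:
    def test_zero_overlap_is_one(self):
        assert overlap_pvalue(5, 7, 30, 0) == 1.0

    def test_saturated_draw(self):
        # all 5 targets drawn in 5 evidence genes from 10
        assert overlap_pvalue(5, 5, 10, 5) == pytest.approx(
            1 / math.comb(10, 5), rel=1e-12
        )

    def test_small_enumeration_example(self):
        expected = sum(
            math.comb(3, k) * math.comb(5, 4 - k) / math.comb(8, 4) for k in (2, 3)
        )
        assert overlap_pvalue(3, 4, 8, 2) == pytest.approx(expected, rel=1e-12)

    def test_matches_enumeration_on_small_universes(self):
        for M in (5, 10, 25):
            for K in range(0, M + 1, max(1, M // 5)):
                for n in range(0, M + 1, max(1, M // 5)):
                    for k in range(0, min(K, n) + 1):
                        assert overlap_pvalue(K, n, M, k) == pytest.approx(
                            hypergeom_upper_tail(K, n, M, k), abs=1e-12
                        )

    def test_growing_universe_shrinks_p(self):
        # adding a gene that is neither target nor evidence
        for M in range(10, 25):
            assert overlap_pvalue(4, 5, M + 1, 3) <= overlap_pvalue(4, 5, M, 3)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValidationError):
            overlap_pvalue(3, 4, 8, 5)
        with pytest.raises(ValidationError):
            overlap_pvalue(10, 4, 8, 2)


def edges_for(regulator, signs, weights=None):
    weights = weights or [1.0] * len(signs)
    return [
        PriorEdge(regulator, f"T{i}", sign=s, weight=w)
        for i, (s, w) in enumerate(zip(signs, weights))
    ]


class TestActivationZ:
    def test_all_consistent_unit_weights(self):
        edges = edges_for("R", ["activates"] * 4)
        dirs = {f"T{i}": 1 for i in range(4)}
        assert activation_z(edges, dirs) == pytest.approx(2.0)

    def test_balanced_is_zero(self):
        edges = edges_for("R", ["activates"] * 4)
        dirs = {"T0": 1, "T1": 1, "T2": -1, "T3": -1}
        assert activation_z(edges, dirs) == pytest.approx(0.0)

    def test_undefined_without_signed_overlap(self):
        edges = edges_for("R", ["unknown", "unknown"])
        assert activation_z(edges, {"T0": 1, "T1": -1}) is None
        assert activation_z(edges_for("R", ["activates"]), {}) is None

    def test_bruteforce_over_all_direction_assignments(self, rng):
        """z equals direct evaluation of sum(w*m)/sqrt(sum(w^2)) for every
        one of the 2^n direction assignments, n <= 6, random signs/weights."""
        sign_value = {"activates": 1, "represses": -1}
        for _ in range(10):
            n = int(rng.integers(1, 7))
            signs = [["activates", "represses"][rng.integers(2)] for _ in range(n)]
            weights = [float(rng.uniform(0.2, 3.0)) for _ in range(n)]
            edges = edges_for("R", signs, weights)
            for assignment in itertools.product([-1, 1], repeat=n):
                dirs = {f"T{i}": d for i, d in enumerate(assignment)}
                num = sum(
                    w * (1 if sign_value[s] == d else -1)
                    for s, w, d in zip(signs, weights, assignment)
                )
                expected = num / math.sqrt(sum(w * w for w in weights))
                assert activation_z(edges, dirs) == pytest.approx(expected, rel=1e-12)

    def test_unknown_edges_excluded(self):
        edges = edges_for("R", ["activates", "unknown"])
        dirs = {"T0": 1, "T1": -1}
        assert activation_z(edges, dirs) == pytest.approx(1.0)

    def test_multiple_regulators_rejected(self):
        edges = [PriorEdge("R1", "A", sign="activates"),
                 PriorEdge("R2", "B", sign="activates")]
        with pytest.raises(ValidationError):
            activation_z(edges, {"A": 1})

    def test_bad_direction_value_rejected(self):
        with pytest.raises(ValidationError):
            activation_z(edges_for("R", ["activates"]), {"T0": 0})


class TestCallState:
    @pytest.mark.parametrize(
        "z,expected",
        [
            (2.5, "activated"),
            (2.0, "activated"),
            (-2.0, "inhibited"),
            (1.9, "indeterminate"),
            (None, "indeterminate"),
        ],
    )
    def test_threshold_convention(self, z, expected):
        assert call_state(z, 2.0) == expected

    def test_positive_threshold_required(self):
        with pytest.raises(ValidationError):
            call_state(1.0, 0.0)


class TestInferItrs:
    def test_hand_computed_example(self, tiny_network, tiny_evidence):
        ranking = infer_itrs(tiny_network, tiny_evidence, z_threshold=2.0)
        assert ranking.calls[0].regulator == "R1"
        r1 = ranking.calls[0]
        assert r1.n_overlap == 2
        assert r1.z == pytest.approx(math.sqrt(2))
        assert r1.state == "indeterminate"
        assert r1.p_overlap == pytest.approx(1 / 6)  # C(2,2)/C(4,2)
        r2 = ranking.calls[1]
        assert r2.n_overlap == 0 and r2.p_overlap == 1.0

    def test_nondirectional_evidence_gives_undefined_z(self, tiny_network):
        ev = EvidenceSet(
            condition="bound", genes={"A", "C"}, universe={"A", "B", "C", "D"},
            kind="bound",
        )
        ranking = infer_itrs(tiny_network, ev)
        assert all(c.z is None for c in ranking.calls)
        assert all(c.state == "indeterminate" for c in ranking.calls)
        assert ranking.calls[0].p_overlap <= ranking.calls[-1].p_overlap

    def test_empty_universe_rejected(self, tiny_network):
        ev = EvidenceSet(condition="c", genes=set(), universe=set())
        with pytest.raises(ValidationError):
            infer_itrs(tiny_network, ev)

    def test_sign_antisymmetry(self, scenario_outputs):
        """Negating every observed direction negates z and preserves the
        overlap p-values and hence the ranking order."""
        network, tables, _ = scenario_outputs
        from itrkit.omics_contrasts import significant_set

        ev = significant_set(tables["trio_1"])
        flipped = EvidenceSet(
            condition=ev.condition,
            genes=ev.genes,
            universe=ev.universe,
            directions={g: -d for g, d in ev.directions.items()},
        )
        a = infer_itrs(network, ev)
        b = infer_itrs(network, flipped)
        pa = {c.regulator: c for c in a.calls}
        pb = {c.regulator: c for c in b.calls}
        assert set(pa) == set(pb)
        for reg in pa:
            assert pa[reg].p_overlap == pb[reg].p_overlap
            if pa[reg].z is None:
                assert pb[reg].z is None
            else:
                assert pb[reg].z == pytest.approx(-pa[reg].z)
        assert [c.regulator for c in a.calls] == [c.regulator for c in b.calls]

    def test_fdr_nondecreasing_in_rank_order(self, scenario_outputs):
        network, tables, _ = scenario_outputs
        from itrkit.omics_contrasts import significant_set

        ranking = infer_itrs(network, significant_set(tables["trio_2"]))
        fdrs = [c.fdr_overlap for c in ranking.calls]
        ps = [c.p_overlap for c in ranking.calls]
        assert ps == sorted(ps)
        assert all(b >= a - 1e-12 for a, b in zip(fdrs, fdrs[1:]))

    def test_deterministic_tie_break(self):
        # two regulators with identical overlap stats but different |z|
        net = build_prior_network(
            [
                PriorEdge("RA", "A", sign="activates"),
                PriorEdge("RB", "B", sign="represses"),
                PriorEdge("RC", "C", sign="activates"),
            ]
        )
        ev = EvidenceSet(
            condition="c",
            genes={"A", "B", "C"},
            universe={"A", "B", "C", "D", "E", "F"},
            directions={"A": 1, "B": 1, "C": 1},
        )
        ranking = infer_itrs(net, ev)
        # equal p; |z| equal (1.0 each) -> lexicographic order
        assert [c.regulator for c in ranking.calls] == ["RA", "RB", "RC"]

    def test_planted_regulator_recovered(self, rng):
        """A planted activated regulator (30 targets, consistency 0.9)
        dominates the ranking of a small synthetic screen."""
        from itrkit import synthetic_data as synth

        wins = 0
        for seed in range(20):
            cfg = synth.ScenarioConfig(
                seed=seed,
                n_genes=1000,
                n_regulators=40,
                out_degree_mean=30,
                conditions=[
                    synth.ConditionSpec(
                        name="c", planted={"R001": 1}, consistency=0.9,
                        background_rate=0.05,
                    )
                ],
            )
            net = synth.generate_prior_network(cfg)
            tables, _ = synth.generate_contrasts(net, cfg)
            from itrkit.omics_contrasts import significant_set

            ranking = infer_itrs(net, significant_set(tables["c"]))
            if ranking.calls[0].regulator == "R001" and ranking.calls[0].z > 0:
                wins += 1
        assert wins >= 19


class TestContributions:
    def test_overlapping_targets_with_observed_directions(
        self, tiny_network, tiny_evidence
    ):
        assert contributions(tiny_network, tiny_evidence, "R1") == {"A": 1, "B": 1}
        assert contributions(tiny_network, tiny_evidence, "R2") == {}

    def test_requires_directional_evidence(self, tiny_network):
        ev = EvidenceSet(condition="c", genes={"A"}, universe={"A"}, kind="bound")
        with pytest.raises(ValidationError):
            contributions(tiny_network, ev, "R1")


class TestRankingIO:
    def test_roundtrip(self, tmp_path, tiny_network, tiny_evidence):
        ranking = infer_itrs(tiny_network, tiny_evidence)
        f = tmp_path / "itrs.tsv"
        write_ranking(ranking, f)
        back = read_ranking(f)
        assert back.condition == ranking.condition
        assert [c.regulator for c in back.calls] == [c.regulator for c in ranking.calls]
        for a, b in zip(back.calls, ranking.calls):
            assert a.p_overlap == pytest.approx(b.p_overlap)
            assert (a.z is None) == (b.z is None)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    signs=st.lists(st.sampled_from(["activates", "represses"]), min_size=1, max_size=6),
    data=st.data(),
)
def test_activation_z_bounded_by_sqrt_n(signs, data):
    """|z| <= sqrt(n) with unit weights, with equality iff all edges agree."""
    dirs = {
        f"T{i}": data.draw(st.sampled_from([-1, 1])) for i in range(len(signs))
    }
    edges = [PriorEdge("R", f"T{i}", sign=s) for i, s in enumerate(signs)]
    z = activation_z(edges, dirs)
    n = len(signs)
    assert abs(z) <= math.sqrt(n) + 1e-12
    matches = [
        (1 if {"activates": 1, "represses": -1}[s] == dirs[f"T{i}"] else -1)
        for i, s in enumerate(signs)
    ]
    if len(set(matches)) == 1:
        assert abs(z) == pytest.approx(math.sqrt(n))
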