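from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hgtcooc.occurrence import (
    OccurrenceMatrix,
    bh_adjust,
    call_presence,
    classify_fraction_enrichment,
    hypergeom_cooccurrence,
    prevalence_filter,
    simple_cooccurrence,
)


def hypergeom_upper_oracle(N: int, n1: int, n2: int, k: int) -> float:
    """P(overlap >= k) by exhaustive enumeration over all C(N, n1)
    placements of genome 1, with genome 2 fixed on the first n2 samples."""
    fixed = set(range(n2))
    total = hits = 0
    for subset in combinations(range(N), n1):
        total += 1
        if len(fixed.intersection(subset)) >= k:
            hits += 1
    return hits / total


def coverage_frame(breadth_by_genome: dict[str, list[float]]) -> pd.DataFrame:
    rows = []
    n = len(next(iter(breadth_by_genome.values())))
    for g, vals in breadth_by_genome.items():
        for i, b in enumerate(vals):
            rows.append([f"S{i + 1}", g, b, 5.0 if b > 0 else 0.0])
    return pd.DataFrame(rows, columns=["sample", "genome", "breadth", "rpkm"])


class TestCallPresence:
    def test_threshold_is_inclusive(self):
        cov = coverage_frame({"G1": [0.30, 0.299, 0.8], "G2": [0.5, 0.5, 0.5]})
        m = call_presence(cov)
        assert bool(m.presence.loc["S1", "G1"]) is True
        assert bool(m.presence.loc["S2", "G1"]) is False
        assert m.abundance.loc["S2", "G1"] == 0.0

    def test_empty_samples_dropped(self):
        cov = coverage_frame({"G1": [0.8, 0.0], "G2": [0.5, 0.1]})
        m = call_presence(cov)
        assert m.samples == ["S1"]

    def test_negative_breadth_rejected(self):
        cov = coverage_frame({"G1": [-0.1, 0.5], "G2": [0.5, 0.5]})
        with pytest.raises(ValueError):
            call_presence(cov)


class TestPrevalenceFilter:
    @pytest.mark.parametrize("n_present, kept", [(10, True), (9, False)])
    def test_at_least_ten(self, presence_matrix, n_present, kept):
        m = presence_matrix(
            {
                "G1": [1] * n_present + [0] * (12 - n_present),
                "G2": [1] * 12,
            }
        )
        out = prevalence_filter(m, 10)
        assert ("G1" in out.genomes) is kept

    def test_all_below_threshold(self, presence_matrix):
        m = presence_matrix({"G1": [1, 0, 0], "G2": [0, 1, 0]})
        out = prevalence_filter(m, 10)
        assert out.genomes == []


class TestHypergeom:
    def test_frozen_enumeration_examples(self, presence_matrix):
        # N=10, n1=n2=5, k=5 -> 1/252 ; computed by the enumeration oracle
        m = presence_matrix(
            {"G1": [1] * 5 + [0] * 5, "G2": [1] * 5 + [0] * 5}
        )
        res = hypergeom_cooccurrence(m).iloc[0]
        assert res["p"] == pytest.approx(1 / 252, abs=1e-12)
        assert hypergeom_upper_oracle(10, 5, 5, 5) == pytest.approx(1 / 252)

        # N=10, n1=4, n2=5, k=3 -> 55/210 ; ratio 1.5
        m = presence_matrix(
            {
                "G1": [1, 1, 1, 1, 0, 0, 0, 0, 0, 0],
                "G2": [1, 1, 1, 0, 1, 1, 0, 0, 0, 0],
            }
        )
        res = hypergeom_cooccurrence(m).iloc[0]
        assert res["p"] == pytest.approx(55 / 210, abs=1e-12)
        assert res["ratio"] == pytest.approx(1.5)
        assert hypergeom_upper_oracle(10, 4, 5, 3) == pytest.approx(55 / 210)

    def test_zero_overlap_p_is_one(self, presence_matrix):
        m = presence_matrix(
            {"G1": [1, 1, 0, 0, 1], "G2": [0, 0, 1, 1, 0]}
        )
        res = hypergeom_cooccurrence(m).iloc[0]
        assert res["p"] == pytest.approx(1.0)
        assert res["ratio"] == 0.0

    def test_swap_invariance(self, presence_matrix):
        m1 = presence_matrix(
            {"G1": [1, 1, 1, 0, 0, 0], "G2": [1, 1, 0, 1, 1, 0]}
        )
        m2 = presence_matrix(
            {"G1": [1, 1, 0, 1, 1, 0], "G2": [1, 1, 1, 0, 0, 0]}
        )
        r1 = hypergeom_cooccurrence(m1).iloc[0]
        r2 = hypergeom_cooccurrence(m2).iloc[0]
        assert r1["p"] == pytest.approx(r2["p"])
        assert r1["ratio"] == pytest.approx(r2["ratio"])

    def test_permutation_null_calibration(self):
        """Shuffling each genome's presence vector independently gives a
        raw p < 0.05 rate near the nominal level."""
        rng = np.random.default_rng(0)
        n_samples, n_genomes = 200, 12
        base = rng.random((n_samples, n_genomes)) < rng.uniform(
            0.3, 0.7, size=n_genomes
        )
        hits = trials = 0
        for _rep in range(500):
            perm = np.column_stack(
                [base[rng.permutation(n_samples), j] for j in range(n_genomes)]
            )
            presence = pd.DataFrame(
                perm, columns=[f"G{j}" for j in range(n_genomes)],
                index=[f"S{i}" for i in range(n_samples)],
            )
            m = OccurrenceMatrix(
                presence=presence, abundance=presence.astype(float)
            )
            res = hypergeom_cooccurrence(m)
            hits += int((res["p"] < 0.05).sum())
            trials += len(res)
        rate = hits / trials
        assert 0.03 <= rate <= 0.07


class TestSimpleCooccurrence:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ({"s1", "s2", "s3"}, {"s2", "s3", "s4"}, 2 / 3),
            ({"s1"}, {"s1", "s2", "s3"}, 1.0),  # subset -> trivially 1.0
            ({"s1", "s2"}, {"s3"}, 0.0),
        ],
    )
    def test_formula(self, a, b, expected):
        assert simple_cooccurrence(a, b) == pytest.approx(expected)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            simple_cooccurrence(set(), {"s1"})

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.sets(st.integers(0, 20), min_size=1),
        st.sets(st.integers(0, 20), min_size=1),
    )
    def test_bounds_and_symmetry(self, a, b):
        v = simple_cooccurrence(a, b)
        assert 0.0 <= v <= 1.0
        assert v == simple_cooccurrence(b, a)


def bh_oracle(p):
    """Direct step-up evaluation: sort ascending, adj(i) = min over j >= i
    of p(j) * m / j, capped at 1, returned in input order."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


class TestBhAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ((0.01, 0.02, 0.03, 0.04), (0.04, 0.04, 0.04, 0.04)),
            ((0.5,), (0.5,)),
            ((0.5, 1.0), (1.0, 1.0)),
        ],
    )
    def test_step_up_examples(self, p, expected):
        assert bh_adjust(list(p)) == pytest.approx(list(expected))
        assert bh_oracle(list(p)) == pytest.approx(list(expected))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_oracle_and_dominates_raw(self, p):
        adj = bh_adjust(p)
        assert adj == pytest.approx(bh_oracle(p))
        order = np.argsort(p)
        sorted_adj = np.asarray(adj)[order]
        assert (np.diff(sorted_adj) >= -1e-12).all()
        assert all(a >= r - 1e-12 for a, r in zip(adj, p))


class TestFractionClassification:
    def _matrix(self, presence_matrix, small_flags, abund_small=3.0, abund_lf=1.0):
        n = len(small_flags)
        fractions = {
            f"S{i + 1}": ((0.22, 3.0) if small else (0.22, 200.0))
            for i, small in enumerate(small_flags)
        }
        m = presence_matrix({"G1": [1] * n, "G2": [1] * n}, fractions)
        for i, small in enumerate(small_flags):
            m.abundance.iloc[i] = abund_small if small else abund_lf
        return m

    def test_majority_and_median_met(self, presence_matrix):
        m = self._matrix(presence_matrix, [True] * 8 + [False] * 2)
        assert classify_fraction_enrichment(m)["G1"] == "small"

    def test_exact_majority_boundary_unclassified(self, presence_matrix):
        m = self._matrix(presence_matrix, [True] * 6 + [False] * 2)  # 75%
        assert classify_fraction_enrichment(m)["G1"] == "unclassified"

    def test_median_condition_fails(self, presence_matrix):
        m = self._matrix(
            presence_matrix, [True] * 8 + [False] * 2,
            abund_small=1.0, abund_lf=3.0,
        )
        assert classify_fraction_enrichment(m)["G1"] == "unclassified"

    def test_intermediate_fraction_in_neither_group(self, presence_matrix):
        fractions = {f"S{i + 1}": (0.22, 5.0) for i in range(4)}
        m = presence_matrix({"G1": [1] * 4, "G2": [1] * 4}, fractions)
        assert classify_fraction_enrichment(m)["G1"] == "unclassified"
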