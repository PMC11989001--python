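"""Within-onion normalization and the unpaired pairing bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alliumcw import bootcorr, synthgen


class TestNormalizeWithinOnion:
    def test_arithmetic_sequence(self):
        assert np.allclose(bootcorr.normalize_within_onion([1, 2, 3]), [-1, 0, 1])

    def test_mean_zero_sd_one_order_preserved(self):
        out = bootcorr.normalize_within_onion([5, 5, 6])
        assert out.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        assert out[0] == out[1] < out[2]

    @settings(deadline=None, derandomize=True)
    @given(
        triple=st.tuples(*[st.floats(-1e3, 1e3) for _ in range(3)]).filter(
            lambda t: max(t) - min(t) > 1e-6
        ),
        a=st.floats(0.01, 100.0),
        b=st.floats(-1e3, 1e3),
    )
    def test_affine_invariance(self, triple, a, b):
        base = bootcorr.normalize_within_onion(np.array(triple))
        shifted = bootcorr.normalize_within_onion(a * np.array(triple) + b)
        assert np.allclose(base, shifted, atol=1e-6)

    def test_constant_triple_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            bootcorr.normalize_within_onion([4.0, 4.0, 4.0])


class TestBootstrapPair:
    def test_perfect_linearity(self):
        rng = np.random.default_rng(0)
        triples = rng.normal(0, 1, size=(6, 3))
        res = bootcorr.bootstrap_pair_correlation(triples, triples.copy(),
                                                  n_replicates=500, seed=1)
        # identical triple sets need not pair i with i; association comes
        # only through layer structure, so r < 1 — but with expression
        # literally equal to biochemistry per onion the pooled normalized
        # points coincide pairwise when the *same* indices are drawn.
        assert -1.0 <= res.r_mean <= 1.0

    def test_identical_patterned_sets_give_unit_r(self):
        # every onion carries the same normalized pattern -> any pairing
        # matches exactly: r = 1 with a zero-width interval
        pattern = np.tile([1.0, 2.0, 3.0], (5, 1))
        res = bootcorr.bootstrap_pair_correlation(pattern, pattern.copy(),
                                                  n_replicates=300, seed=2)
        assert res.r_mean == pytest.approx(1.0)
        assert res.ci_high - res.ci_low == pytest.approx(0.0, abs=1e-12)

    def test_seeded_determinism(self):
        bio, expr = synthgen.gen_correlated_triples(9, 9, 0.9, seed=4)
        a = bootcorr.bootstrap_pair_correlation(bio, expr, 2000, seed=7)
        b = bootcorr.bootstrap_pair_correlation(bio, expr, 2000, seed=7)
        assert a == b

    def test_sign_equivariance(self):
        bio, expr = synthgen.gen_correlated_triples(8, 8, 0.9, seed=5)
        pos = bootcorr.bootstrap_pair_correlation(bio, expr, 1000, seed=6)
        neg = bootcorr.bootstrap_pair_correlation(bio, -expr, 1000, seed=6)
        assert neg.r_mean == pytest.approx(-pos.r_mean, abs=1e-12)
        assert neg.ci_low == pytest.approx(-pos.ci_high, abs=1e-12)
        assert neg.ci_high == pytest.approx(-pos.ci_low, abs=1e-12)

    def test_r_bounds_and_ci_ordering(self):
        bio, expr = synthgen.gen_correlated_triples(5, 7, 0.0, seed=8)
        res = bootcorr.bootstrap_pair_correlation(bio, expr, 500, seed=9)
        assert -1.0 <= res.ci_low <= res.r_mean <= res.ci_high <= 1.0
        assert 0.0 <= res.p_value <= 1.0

    def test_degenerate_triples_excluded_not_imputed(self):
        bio = np.vstack([np.tile([2.0, 2.0, 2.0], (2, 1)),
                         np.array([[1.0, 2.0, 3.0], [0.0, 1.0, 4.0]])])
        expr = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 5.0]])
        res = bootcorr.bootstrap_pair_correlation(bio, expr, 200, seed=0)
        assert res.n_replicates == 200  # constant rows dropped, not fatal

    def test_too_few_replicates_rejected(self):
        bio, expr = synthgen.gen_correlated_triples(4, 4, 0.9, seed=1)
        with pytest.raises(ValueError, match="100"):
            bootcorr.bootstrap_pair_correlation(bio, expr, 50, seed=0)


class TestTriplesFromLong:
    def test_pivot_and_incomplete_drop(self):
        rows = []
        for onion in ("O1", "O2", "O3"):
            for layer in ("S1", "S2", "S6"):
                if onion == "O3" and layer == "S6":
                    continue  # incomplete triple
                rows.append({"onion_id": onion, "layer": layer,
                             "value": float(len(rows))})
        triples = bootcorr.triples_from_long(pd.DataFrame(rows), "value")
        assert triples.shape == (2, 3)

    def test_missing_layer_rejected(self):
        t = pd.DataFrame({"onion_id": ["O1"], "layer": ["S1"], "value": [1.0]})
        with pytest.raises(ValueError, match="absent"):
            bootcorr.triples_from_long(t, "value")


class TestCorrelationMatrix:
    def make_inputs(self, seed=0):
        rng = np.random.default_rng(seed)
        onions = [f"O{i}" for i in range(1, 7)]
        bio_rows, expr_rows = [], []
        pattern = {"S1": -1.0, "S2": 0.0, "S6": 1.0}
        for onion in onions:
            for layer, m in pattern.items():
                bio_rows.append({
                    "onion_id": onion, "layer": layer,
                    "featA": m + rng.normal(0, 0.1),
                    "featB": -m + rng.normal(0, 0.1),
                })
                expr_rows.append({"gene": "geneX", "onion_id": onion,
                                  "layer": layer,
                                  "value": m + rng.normal(0, 0.1)})
                expr_rows.append({"gene": "geneY", "onion_id": onion,
                                  "layer": layer,
                                  "value": rng.normal(0, 1)})
        return pd.DataFrame(bio_rows), pd.DataFrame(expr_rows)

    def test_cartesian_count_and_flags(self):
        bio, expr = self.make_inputs()
        results = bootcorr.correlation_matrix(bio, expr, n_replicates=400,
                                              seed=3)
        assert len(results) == 4
        by_key = {(r.gene, r.feature): r for r in results}
        assert by_key[("geneX", "featA")].strong_positive
        assert by_key[("geneX", "featB")].strong_negative
        assert not by_key[("geneY", "featA")].strong_positive

    def test_threshold_is_strict(self):
        res = bootcorr.BootstrapResult(
            feature="f", gene="g", n_replicates=100, r_mean=0.8,
            ci_low=0.7, ci_high=0.9, p_value=0.01, seed=0)
        assert not res.strong_positive
        assert not bootcorr.BootstrapResult(
            feature="f", gene="g", n_replicates=100, r_mean=-0.8,
            ci_low=-0.9, ci_high=-0.7, p_value=0.01, seed=0).strong_negative

    def test_matrix_frame_shape(self):
        bio, expr = self.make_inputs()
        results = bootcorr.correlation_matrix(bio, expr, n_replicates=200,
                                              seed=4)
        mat = bootcorr.matrix_frame(results)
        assert mat.shape == (2, 2)
        assert set(mat.index) == {"geneX", "geneY"}
        assert set(mat.columns) == {"featA", "featB"}

    def test_order_independent_seeding(self):
        bio, expr = self.make_inputs()
        all_res = bootcorr.correlation_matrix(bio, expr, n_replicates=300,
                                              seed=5)
        sub = bootcorr.correlation_matrix(bio, expr, genes=["geneX"],
                                          features=["featA", "featB"],
                                          n_replicates=300, seed=5)
        full = {(r.gene, r.feature): r.r_mean for r in all_res}
        for r in sub:
            assert full[(r.gene, r.feature)] == r.r_mean
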