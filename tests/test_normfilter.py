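"""CPM, presence filter (incl. black-and-white rescue) and TMM tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from tepomics import CountMatrix, cpm, normalize, presence_filter, tmm_factors
from tepomics.normfilter import REASON_BLACK_WHITE, REASON_DROPPED, REASON_GLOBAL

from conftest import make_matrix


class TestCountMatrix:
    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError, match="negative"):
            make_matrix([[-1, 2, 3, 4]], 2, 2)

    def test_rejects_unlabeled_samples(self):
        df = pd.DataFrame([[1, 2]], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="without group"):
            CountMatrix("mrna", df, pd.Series({"s1": "A"}))

    def test_rejects_bad_norm_factor_geomean(self, two_group_matrix):
        with pytest.raises(ValueError, match="geometric mean"):
            two_group_matrix.set_norm_factors(
                pd.Series(2.0, index=two_group_matrix.samples)
            )


class TestCpm:
    def test_single_feature_is_one_million(self):
        m = make_matrix([[7, 3, 12, 5]], 2, 2)
        assert np.allclose(cpm(m).to_numpy(), 1e6)

    def test_two_feature_column(self):
        m = make_matrix([[1, 1, 1, 1], [3, 3, 3, 3]], 2, 2)
        assert np.allclose(cpm(m).iloc[:, 0], [250000.0, 750000.0])

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(5)
        m = make_matrix(rng.integers(0, 100, size=(20, 6)) + 1, 3, 3)
        assert np.allclose(cpm(m).sum(axis=0), 1e6, atol=1e-6)

    def test_zero_sum_column_names_sample(self):
        m = make_matrix([[1, 0, 2, 3]], 2, 2)
        with pytest.raises(ValueError, match="A01"):
            cpm(m)


def _filter_toy():
    """22-sample toy: global pass, black-and-white pass, and fail cases."""
    n = 11
    mk = lambda a_vals, b_vals: list(a_vals) + list(b_vals)
    rows = {
        # high everywhere -> global
        "f_global": mk([50] * n, [50] * n),
        # CPM >= 1 in 10 of 22 samples only (45% > 40%) -> global
        "f_margin": mk([50] * 10 + [0], [0] * n),
        # zero in all A, nonzero in 10/11 B (zero-frac 1/11 = 0.09) but only
        # 8 samples at >= 1 CPM (8/22 fails the global rule) -> black_white
        "f_bw": mk([0] * n, [30] * 8 + [1, 1, 0]),
        # zero in all A, nonzero in 8/11 B: fails bw (0.27 > 0.18) and global (8/22)
        "f_bw_fail": mk([0] * n, [30] * 8 + [0] * 3),
        # low CPM everywhere -> dropped
        "f_low": mk([0] * n, [0] * 10 + [1]),
        # expressed in a handful of both groups -> dropped
        "f_sparse": mk([40] * 3 + [0] * 8, [40] * 3 + [0] * 8),
    }
    samples = [f"A{i:02d}" for i in range(n)] + [f"B{i:02d}" for i in range(n)]
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    # large background keeps libraries comparable and single counts < 1 CPM
    counts.loc["f_bg"] = 2_000_000
    groups = pd.Series(["A"] * n + ["B"] * n, index=samples)
    return CountMatrix("mrna", counts, groups)


class TestPresenceFilter:
    def test_toy_matrix_reasons_exact(self):
        m = _filter_toy()
        kept, reasons = presence_filter(m)
        assert reasons["f_global"] == REASON_GLOBAL
        assert reasons["f_margin"] == REASON_GLOBAL
        assert reasons["f_bw"] == REASON_BLACK_WHITE
        assert reasons["f_bw_fail"] == REASON_DROPPED
        assert reasons["f_low"] == REASON_DROPPED
        assert reasons["f_sparse"] == REASON_DROPPED
        assert kept == ["f_global", "f_margin", "f_bw", "f_bg"]

    def test_order_stability(self):
        m = _filter_toy()
        kept, _ = presence_filter(m)
        order = {f: i for i, f in enumerate(m.features)}
        assert kept == sorted(kept, key=order.get)

    def test_loose_black_white_switch(self):
        # one sub-CPM stray count in group A, mostly-on pattern in group B;
        # the large background keeps single counts below 1 CPM
        n = 11
        f0 = [0] * 10 + [1] + [30] * 8 + [1, 1, 0]
        vals = [f0, [2_000_000] * 2 * n]
        m = make_matrix(np.array(vals), n, n)
        _, strict = presence_filter(m)
        _, loose = presence_filter(m, require_other_all_zero=False)
        assert strict["f000"] == REASON_DROPPED
        assert loose["f000"] == REASON_BLACK_WHITE

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_global_rule_matches_cpm_fraction(self, seed):
        rng = np.random.default_rng(seed)
        m = make_matrix(rng.integers(0, 40, size=(12, 10)), 5, 5)
        if (m.counts.sum(axis=0) == 0).any():
            return
        kept, reasons = presence_filter(m)
        frac = (cpm(m) >= 1.0).sum(axis=1) / 10
        for f in m.features:
            assert (reasons[f] == REASON_GLOBAL) == (frac[f] > 0.40)
            if reasons[f] == REASON_BLACK_WHITE:
                row = m.counts.loc[f]
                zero_a = (row[m.samples_in_group("A")] == 0).all()
                zero_b = (row[m.samples_in_group("B")] == 0).all()
                assert zero_a != zero_b  # exactly one silent group


def _tmm_oracle(counts, trim_m=0.30, trim_a=0.05):
    """Direct-formula TMM, coded independently of the implementation."""
    counts = np.asarray(counts, dtype=float)
    libs = counts.sum(axis=0)
    q75 = np.percentile(counts / libs * 1e6, 75, axis=0)
    ref_j = int(np.argmin(np.abs(q75 - q75.mean())))
    out = []
    for j in range(counts.shape[1]):
        y, r = counts[:, j], counts[:, ref_j]
        keep = (y > 0) & (r > 0)
        p, q = y[keep] / libs[j], r[keep] / libs[ref_j]
        m_val = np.log2(p / q)
        a_val = 0.5 * np.log2(p * q)
        w = 1.0 / ((libs[j] - y[keep]) / (libs[j] * y[keep])
                   + (libs[ref_j] - r[keep]) / (libs[ref_j] * r[keep]))
        n = m_val.size
        lo_m, lo_a = np.floor(n * trim_m) + 1, np.floor(n * trim_a) + 1
        sel = (
            (rankdata(m_val) >= lo_m) & (rankdata(m_val) <= n + 1 - lo_m)
            & (rankdata(a_val) >= lo_a) & (rankdata(a_val) <= n + 1 - lo_a)
        )
        out.append(2 ** (np.sum(w[sel] * m_val[sel]) / np.sum(w[sel])))
    out = np.asarray(out)
    return out / np.exp(np.mean(np.log(out)))


class TestTmm:
    def test_identical_columns_give_unit_factors(self):
        col = np.arange(1, 31)
        m = make_matrix(np.tile(col[:, None], (1, 6)), 3, 3)
        assert np.allclose(tmm_factors(m), 1.0, atol=1e-9)

    def test_pure_depth_change_gives_unit_factors(self):
        rng = np.random.default_rng(2)
        base = rng.integers(10, 500, size=30)
        counts = np.column_stack([base, base * 2, base, base * 2, base, base])
        m = make_matrix(counts, 3, 3)
        assert np.allclose(tmm_factors(m), 1.0, atol=0.01)

    def test_contaminated_toy_matches_direct_formula_oracle(self):
        counts = np.array(
            [
                [100, 110, 95],
                [200, 190, 210],
                [50, 55, 48],
                [80, 85, 90],
                [120, 115, 118],
                [60, 65, 5000],  # contaminant dominating sample 3
            ]
        )
        m = make_matrix(counts, 2, 1)
        got = tmm_factors(m, min_features=1).to_numpy()
        assert np.allclose(got, _tmm_oracle(counts), atol=1e-6)

    def test_oracle_agreement_on_random_matrix(self):
        rng = np.random.default_rng(9)
        counts = rng.negative_binomial(10, 0.05, size=(200, 8))
        m = make_matrix(counts, 4, 4)
        assert np.allclose(tmm_factors(m).to_numpy(), _tmm_oracle(counts), atol=1e-9)

    def test_invariant_to_global_rescaling(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(1, 300, size=(60, 6))
        f1 = tmm_factors(make_matrix(counts, 3, 3))
        f2 = tmm_factors(make_matrix(counts * 4, 3, 3))
        assert np.allclose(f1, f2, atol=1e-9)

    def test_too_few_features_falls_back_to_unit(self, caplog):
        m = make_matrix(np.ones((4, 4), dtype=int) * 10, 2, 2)
        assert np.allclose(tmm_factors(m), 1.0)


class TestNormalize:
    def test_identity_factors_equal_plain_cpm(self, two_group_matrix):
        assert np.allclose(normalize(two_group_matrix), cpm(two_group_matrix))

    def test_doubling_counts_leaves_values_unchanged(self, two_group_matrix):
        doubled = CountMatrix(
            "mrna", two_group_matrix.counts * 2, two_group_matrix.groups
        )
        assert np.allclose(normalize(two_group_matrix), normalize(doubled))

    def test_factors_rescale_effective_libraries(self, two_group_matrix):
        m = two_group_matrix
        f = tmm_factors(m)
        m.set_norm_factors(f)
        libs = m.lib_sizes * f
        expected = m.counts.div(libs, axis=1) * 1e6
        assert np.allclose(normalize(m), expected)

    def test_log_option_adds_prior(self, two_group_matrix):
        out = normalize(two_group_matrix, log2=True)
        assert np.allclose(out, np.log2(cpm(two_group_matrix) + 1))
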