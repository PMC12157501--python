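import math

import numpy as np
import pandas as pd
import pytest

from srnaclass.diffabund import (
    bh_adjust,
    diff_table,
    log2_fold_change,
    nb_test,
    spike_size_factors,
)
from srnaclass.io_formats import CountMatrix, ValidationError


def _cm(data, spikes, conditions, columns=None):
    columns = columns or [f"s{i}" for i in range(len(spikes))]
    counts = pd.DataFrame(data, columns=columns,
                          index=[f"f{i}" for i in range(len(data))])
    return CountMatrix(counts, pd.Series(spikes, index=columns),
                       pd.Series(conditions, index=columns))


class TestSpikeSizeFactors:
    def test_uniform_spikes_identity(self):
        cm = _cm([[1, 2, 3, 4]], [100, 100, 100, 100], ["a", "a", "b", "b"])
        assert spike_size_factors(cm).tolist() == [1.0, 1.0, 1.0, 1.0]

    def test_stated_formula(self):
        cm = _cm([[1, 1]], [100, 300], ["a", "b"])
        assert spike_size_factors(cm).tolist() == [0.5, 1.5]

    def test_mean_is_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            spikes = rng.integers(1, 10000, size=6)
            cm = _cm(rng.integers(0, 100, (4, 6)), spikes, ["a"] * 3 + ["b"] * 3)
            assert spike_size_factors(cm).mean() == pytest.approx(1.0, abs=1e-12)

    def test_normalization_invariance_under_sample_scaling(self):
        rng = np.random.default_rng(1)
        data = rng.integers(10, 100, (5, 4)).astype(float)
        spikes = [200.0, 300.0, 150.0, 250.0]
        cm = _cm(data, spikes, ["a", "a", "b", "b"])
        norm1 = cm.counts.div(spike_size_factors(cm), axis=1)
        data2 = data.copy()
        data2[:, 1] *= 7.0
        spikes2 = list(spikes)
        spikes2[1] *= 7.0
        cm2 = _cm(data2, spikes2, ["a", "a", "b", "b"])
        norm2 = cm2.counts.div(spike_size_factors(cm2), axis=1)
        # technical rescaling of one sample changes every normalized count by
        # one common global factor only: all between-sample ratios (and hence
        # every fold change) are invariant
        ratio = (norm2 / norm1).to_numpy()
        assert np.allclose(ratio, ratio[0, 0])
        lfc1 = log2_fold_change(cm, spike_size_factors(cm), ("a", "b"))
        lfc2 = log2_fold_change(cm2, spike_size_factors(cm2), ("a", "b"))
        assert np.allclose(lfc1, lfc2, atol=0.05)  # exact up to pseudocount effect


class TestLog2FoldChange:
    def test_direct_arithmetic(self):
        cm = _cm([[40, 40, 10, 10]], [100] * 4, ["t", "t", "c", "c"])
        lfc = log2_fold_change(cm, spike_size_factors(cm), ("t", "c"))
        assert lfc.iloc[0] == pytest.approx(math.log2(40.5 / 10.5))

    def test_identical_groups_zero(self):
        cm = _cm([[7, 7, 7, 7]], [100] * 4, ["t", "t", "c", "c"])
        assert log2_fold_change(cm, spike_size_factors(cm), ("t", "c")).iloc[0] == 0.0

    def test_all_zero_feature_zero(self):
        cm = _cm([[0, 0, 0, 0]], [100] * 4, ["t", "t", "c", "c"])
        assert log2_fold_change(cm, spike_size_factors(cm), ("t", "c")).iloc[0] == 0.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        cm = _cm(rng.integers(0, 500, (10, 6)), rng.integers(50, 150, 6),
                 ["t"] * 3 + ["c"] * 3)
        sf = spike_size_factors(cm)
        fwd = log2_fold_change(cm, sf, ("t", "c"))
        rev = log2_fold_change(cm, sf, ("c", "t"))
        assert np.allclose(fwd, -rev)

    def test_missing_condition_errors(self):
        cm = _cm([[1, 1]], [100, 100], ["t", "t"])
        with pytest.raises(ValidationError, match="no samples"):
            log2_fold_change(cm, spike_size_factors(cm), ("t", "c"))


def bh_bruteforce(p):
    """Step-up definition: p_adj_(i) = min_{j>=i} m p_(j)/j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        adj_sorted[rank - 1] = min(running, 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


class TestBhAdjust:
    def test_hand_computed_stepup(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])

    def test_empty(self):
        assert bh_adjust([]).size == 0

    def test_monotone_and_at_least_p(self):
        rng = np.random.default_rng(3)
        p = np.sort(rng.uniform(size=40))
        adj = bh_adjust(p)
        assert (np.diff(adj) >= -1e-12).all()
        assert (adj >= p - 1e-12).all()

    def test_matches_bruteforce_definition(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 40))
            assert bh_adjust(p) == pytest.approx(bh_bruteforce(p))


class TestNbTest:
    def test_underdispersed_data_uses_poisson_floor(self):
        # constant counts within groups: s2 = 0 <= mean, so alpha truncates to
        # 0 and the SE is the Poisson delta-method value, computable by hand
        cm = _cm([[100, 100, 100, 100, 100, 100]], [100] * 6, ["t"] * 3 + ["c"] * 3)
        res = nb_test(cm, spike_size_factors(cm), ("t", "c"),
                      moderate_dispersion=False)
        assert res["lfc"].iloc[0] == 0.0
        assert res["p"].iloc[0] == 1.0  # z = 0

    def test_requires_two_replicates(self):
        cm = _cm([[1, 2]], [100, 100], ["t", "c"])
        with pytest.raises(ValidationError, match="2 replicates"):
            nb_test(cm, spike_size_factors(cm), ("t", "c"))

    def test_strong_planted_effect_significant(self):
        rng = np.random.default_rng(5)
        treat = rng.poisson(250, size=(20, 3))
        ctrl = rng.poisson(2000, size=(20, 3))
        cm = _cm(np.hstack([treat, ctrl]), [1000] * 6, ["t"] * 3 + ["c"] * 3)
        res = diff_table(cm, ("t", "c"))
        assert (res["p_adj"] < 0.05).mean() > 0.9
        assert res["lfc"].mean() == pytest.approx(-3.0, abs=0.5)

    def test_base_mean_is_over_all_samples(self):
        cm = _cm([[10, 10, 30, 30]], [100] * 4, ["t", "t", "c", "c"])
        res = nb_test(cm, spike_size_factors(cm), ("t", "c"))
        assert res["baseMean"].iloc[0] == pytest.approx(20.0)
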