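import numpy as np
import pandas as pd
import pytest

from mirqpcr.errors import ValidationError
from mirqpcr.normalizer_selection import (
    genorm_m_values,
    genorm_stepwise_rank,
    normalizer_report,
    normfinder_stability,
    prefilter_normalizer_candidates,
    spikein_sd_report,
)
from mirqpcr.qpcr_io import CtMatrix


def _ct(data: dict, index=None) -> CtMatrix:
    frame = pd.DataFrame(data, index=index)
    return CtMatrix(frame, ~frame.isna())


class TestPrefilter:
    def test_high_expression_passes(self):
        m = _ct({"a": [30.0] * 6}, index=[f"S{i}" for i in range(6)])
        assert prefilter_normalizer_candidates(m) == ["a"]

    def test_low_expression_fails(self):
        m = _ct({"a": [35.0] * 6}, index=[f"S{i}" for i in range(6)])
        assert prefilter_normalizer_candidates(m) == []

    def test_valid_fraction_edge(self):
        vals = [30.0, 30.0, 30.0, 30.0, np.nan, np.nan]
        m = _ct({"a": vals}, index=[f"S{i}" for i in range(6)])
        assert prefilter_normalizer_candidates(m, min_valid_fraction=0.8) == []
        assert prefilter_normalizer_candidates(m, min_valid_fraction=0.5) == ["a"]


def _pairwise_sd_oracle(expr: pd.DataFrame) -> pd.Series:
    """Independent geNorm oracle: explicit loops over every assay pair."""
    out = {}
    for j in expr.columns:
        sds = []
        for k in expr.columns:
            if k == j:
                continue
            ratio = expr[j] - expr[k]
            sds.append(float(np.std(ratio, ddof=1)))
        out[j] = float(np.mean(sds))
    return pd.Series(out)


class TestGeNorm:
    def test_constant_ratio_gives_zero_m(self):
        expr = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        m = genorm_m_values(expr)
        assert m["a"] == pytest.approx(0.0)
        assert m["b"] == pytest.approx(0.0)

    def test_matches_exhaustive_pairwise_oracle(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(4, 3)), columns=["a", "b", "c"]
        )
        m = genorm_m_values(expr)
        oracle = _pairwise_sd_oracle(expr)
        pd.testing.assert_series_equal(m, oracle, check_names=False)

    def test_per_sample_shift_invariance(self, rng):
        expr = pd.DataFrame(rng.normal(size=(6, 4)))
        shift = rng.normal(size=(6, 1))
        pd.testing.assert_series_equal(
            genorm_m_values(expr), genorm_m_values(expr + shift)
        )

    def test_missing_cells_instruct_upstream(self):
        expr = pd.DataFrame({"a": [1.0, np.nan], "b": [2.0, 3.0]})
        with pytest.raises(ValidationError, match="impute|exclude"):
            genorm_m_values(expr)


class TestGeNormStepwise:
    def test_noisy_assay_excluded_first(self, rng):
        base = rng.normal(size=20)
        expr = pd.DataFrame(
            {
                "stable1": base + rng.normal(0, 0.05, 20),
                "stable2": base + rng.normal(0, 0.05, 20),
                "noisy": base + rng.normal(0, 2.0, 20),
            }
        )
        ranks = genorm_stepwise_rank(expr)
        assert ranks["noisy"] == 3
        assert ranks["stable1"] == 1 and ranks["stable2"] == 1

    def test_degenerate_identical_assays_tie_break(self):
        expr = pd.DataFrame({c: [1.0, 2.0, 3.0] for c in ["b", "a", "c"]})
        ranks = genorm_stepwise_rank(expr)
        # deterministic: lexicographically last exact tie excluded first
        assert ranks["c"] == 3
        assert ranks["a"] == 1 and ranks["b"] == 1

    def test_input_order_invariance(self, rng):
        expr = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("dbca"))
        ranks = genorm_stepwise_rank(expr)
        shuffled = genorm_stepwise_rank(expr[list("abcd")])
        pd.testing.assert_series_equal(
            ranks.sort_index(), shuffled.sort_index()
        )


def _normfinder_oracle(expr: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """Brute-force variance decomposition, solved numerically per group."""
    values = expr.to_numpy(float)
    k = values.shape[1]
    centered = values - values.mean(axis=1, keepdims=True)
    labels = groups.to_numpy()
    unique = list(dict.fromkeys(labels))
    sig, d = {}, {}
    for g in unique:
        z = centered[labels == g]
        u2 = z.var(axis=0, ddof=1)
        # solve u2_j = sigma2_j (1 - 2/k) + sum(sigma2) / k^2 exactly
        a = np.full((k, k), 1.0 / k**2) + np.eye(k) * (1.0 - 2.0 / k)
        sigma2 = np.linalg.solve(a, u2)
        sig[g] = np.clip(sigma2, 0.0, None)
        d[g] = z.mean(axis=0)
    d_mat = np.array([d[g] for g in unique])
    d_mat = d_mat - d_mat.mean(axis=0)
    n_g = np.array([(labels == g).sum() for g in unique], float)[:, None]
    samp = np.array([sig[g] for g in unique]) / n_g
    n_groups = len(unique)
    gamma2 = max(
        0.0,
        d_mat.var(ddof=0) * (n_groups * k) / (n_groups * k - 1) - samp.mean(),
    )
    if gamma2 > 0:
        shrink = gamma2 / (gamma2 + samp)
        stability = (np.abs(d_mat * shrink) + np.sqrt(samp * shrink)).mean(axis=0)
    else:
        stability = np.sqrt(samp).mean(axis=0)
    return pd.Series(stability, index=expr.columns)


class TestNormFinder:
    def test_matches_bruteforce_decomposition(self, rng):
        expr = pd.DataFrame(
            rng.normal(size=(12, 5)), columns=list("abcde"),
            index=[f"S{i}" for i in range(12)],
        )
        groups = pd.Series(["g1"] * 6 + ["g2"] * 6, index=expr.index)
        ours = normfinder_stability(expr, groups)
        oracle = _normfinder_oracle(expr, groups)
        pd.testing.assert_series_equal(ours, oracle, check_names=False)

    def test_zero_deviation_assay_is_most_stable(self, rng):
        raw = rng.normal(size=(10, 4))
        expr = pd.DataFrame(raw, columns=list("abcd"))
        expr["mean_like"] = raw.mean(axis=1)  # tracks the per-sample mean
        stability = normfinder_stability(expr)
        assert stability.idxmin() == "mean_like"

    def test_planted_intergroup_bias_ranked_least_stable(self, rng):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            values = r.normal(0, 0.3, size=(10, 4))
            values[5:, 0] += 2.0  # assay 0 biased in group 2
            expr = pd.DataFrame(values, columns=list("abcd"))
            groups = pd.Series(["g1"] * 5 + ["g2"] * 5, index=expr.index)
            stability = normfinder_stability(expr, groups)
            hits += stability.idxmax() == "a"
        assert hits >= 19

    def test_per_sample_shift_invariance(self, rng):
        expr = pd.DataFrame(rng.normal(size=(8, 4)))
        groups = pd.Series(["g1"] * 4 + ["g2"] * 4, index=expr.index)
        shift = rng.normal(size=(8, 1))
        base = normfinder_stability(expr, groups)
        shifted = normfinder_stability(expr + shift, groups)
        pd.testing.assert_series_equal(base, shifted)

    def test_small_group_rejected(self):
        expr = pd.DataFrame(np.zeros((3, 2)) + [[0.0, 1.0]] * 3)
        groups = pd.Series(["g1", "g1", "g2"], index=expr.index)
        with pytest.raises(ValidationError, match="<2"):
            normfinder_stability(expr, groups)


class TestSpikeinSdReport:
    def test_constant_ct_sd_zero(self):
        m = _ct({"spike": [20.0, 20.0, 20.0]}, index=["S1", "S2", "S3"])
        report = spikein_sd_report(m)
        assert report.loc[0, "sd_ct"] == 0.0

    def test_two_point_sample_sd(self):
        m = _ct({"spike": [20.0, 22.0]}, index=["S1", "S2"])
        assert spikein_sd_report(m).loc[0, "sd_ct"] == pytest.approx(np.sqrt(2))

    def test_recovers_planted_sds_at_n48(self):
        from mirqpcr.synthetic_data import (
            AssaySpec,
            CohortConfig,
            generate_validation_cohort,
        )

        config = CohortConfig(
            n_per_group={"RA": 48, "HC": 48},
            assays=[AssaySpec("endog", baseline_ct=26.0, sd_ct=1.2)],
            spike_in_sd=0.5,
            correlations=[],
            seed=7,
        )
        cohort = generate_validation_cohort(config)
        report = spikein_sd_report(cohort.ct).set_index("assay")
        # sampling error of SD at n=96: ~7% relative
        assert report.loc["cel-miR-39", "sd_ct"] == pytest.approx(0.5, rel=0.25)
        assert report.loc["endog", "sd_ct"] == pytest.approx(1.2, rel=0.25)
        assert report.loc["cel-miR-39", "sd_ct"] < 1.0


class TestNormalizerReport:
    def test_ranks_are_permutations(self, rng):
        expr = pd.DataFrame(
            rng.normal(25, 1, size=(10, 4)), columns=list("abcd"),
            index=[f"S{i}" for i in range(10)],
        )
        ct = _ct({c: 30 - expr[c] for c in expr.columns}, index=expr.index)
        groups = pd.Series(["g1"] * 5 + ["g2"] * 5, index=expr.index)
        report = normalizer_report(ct, expr, groups)
        assert sorted(report["rank_normfinder"]) == [1, 2, 3, 4]
        assert set(report["rank_genorm"]) == {1, 3, 4}  # final two share rank 1
        assert (report["m_value"] >= 0).all()
        assert (report["stability_value"] >= 0).all()

    def test_average_reference_beats_single_candidates(self, rng):
        # the mean of independent-noise candidates is itself the most stable
        # "assay" by geNorm M
        base = rng.normal(size=30)
        expr = pd.DataFrame(
            {f"c{j}": base + rng.normal(0, 0.5, 30) for j in range(4)}
        )
        expr["average"] = expr.mean(axis=1)
        m = genorm_m_values(expr)
        assert m.idxmin() == "average"
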