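"""Group-level inference contracts: GLM/LR, Kruskal–Wallis/Dunn/BH, PCA, LMM."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

import mozkin as mk
from mozkin import (metric_group_test, pca_flight, response_rate,
                    response_rate_test, ssr_mixed_model)
from mozkin.io_config import spike_records_from_table


def response_table(counts: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Build a one-row-per-animal table from {group: (responders, total)}."""
    rows = []
    for g, (k, n) in counts.items():
        rows += [(g, True)] * k + [(g, False)] * (n - k)
    return pd.DataFrame(rows, columns=["group", "responded"])


def closed_form_lr(counts: dict[str, tuple[int, int]]) -> float:
    """Two-proportion (or k-proportion) binomial LR statistic by direct arithmetic."""
    def ll(k, n, p):
        out = 0.0
        if k > 0:
            out += k * np.log(p)
        if n - k > 0:
            out += (n - k) * np.log(1 - p)
        return out
    k_tot = sum(k for k, _ in counts.values())
    n_tot = sum(n for _, n in counts.values())
    ll_null = ll(k_tot, n_tot, k_tot / n_tot)
    ll_full = sum(ll(k, n, k / n) if 0 < k < n else ll(k, n, max(k / n, 1e-300))
                  for k, n in counts.values())
    return 2 * (ll_full - ll_null)


class TestResponseRate:
    def test_rate_percentages(self):
        tab = response_table({"solvent": (8, 30), "blend": (25, 30)})
        rates = response_rate(tab).set_index("group")["rate_percent"]
        assert rates["solvent"] == pytest.approx(100 * 8 / 30)
        assert rates["blend"] == pytest.approx(100 * 25 / 30)

    def test_identical_groups_null(self):
        tab = response_table({"a": (10, 30), "b": (10, 30)})
        res = response_rate_test(tab)
        assert res.omnibus["p"].iloc[0] == pytest.approx(1.0)
        assert res.contrasts["estimate"].iloc[0] == 0.0

    def test_lr_matches_hand_computed_deviance(self):
        counts = {"a": (8, 30), "b": (25, 30)}
        res = response_rate_test(response_table(counts))
        assert res.omnibus["statistic"].iloc[0] == pytest.approx(closed_form_lr(counts), abs=1e-6)

    @pytest.mark.parametrize("counts", [
        {"a": (3, 11), "b": (9, 14)},
        {"a": (1, 20), "b": (19, 20), "c": (10, 20)},
        {"a": (5, 10), "b": (5, 10), "c": (5, 10)},
    ])
    def test_agrees_with_closed_form(self, counts):
        res = response_rate_test(response_table(counts))
        assert res.omnibus["statistic"].iloc[0] == pytest.approx(closed_form_lr(counts), abs=1e-6)

    def test_two_factor_omnibus(self):
        rng = np.random.default_rng(0)
        n = 40
        tab = pd.DataFrame({
            "genotype": rng.choice(["wt", "ko"], n),
            "age": rng.choice(["1dpe", "4dpe"], n),
        })
        logit = np.where(tab["age"] == "4dpe", 1.5, -0.5)
        tab["responded"] = rng.random(n) < 1 / (1 + np.exp(-logit))
        res = response_rate_test(tab, factors=["genotype", "age"])
        assert set(res.omnibus["term"]) == {"genotype", "age"}
        assert ((res.omnibus["p"] >= 0) & (res.omnibus["p"] <= 1)).all()

    def test_complete_separation_flagged(self):
        res = response_rate_test(response_table({"a": (0, 15), "b": (15, 15)}))
        assert "separation" in res.flags
        assert np.isfinite(res.omnibus["statistic"].iloc[0])

    def test_tukey_adjustment_bounds(self):
        res = response_rate_test(response_table({"a": (5, 30), "b": (12, 30), "c": (20, 30)}))
        c = res.contrasts
        assert (c["p_adj"] >= c["p_raw"] - 1e-12).all()
        assert (c["p_adj"] <= 1.0).all()


class TestMetricGroupTest:
    def test_fully_separated_groups_minimal_p(self):
        # two groups of 5 with complete rank separation; H computed by
        # explicit rank arithmetic
        tab = pd.DataFrame({"group": ["a"] * 5 + ["b"] * 5,
                            "value": [1, 2, 3, 4, 5, 10, 11, 12, 13, 14.0]})
        res = metric_group_test(tab)
        n = 10
        r_a, r_b = 3.0, 8.0
        h_ref = 12 / (n * (n + 1)) * (5 * (r_a - 5.5) ** 2 + 5 * (r_b - 5.5) ** 2)
        assert res.omnibus["statistic"].iloc[0] == pytest.approx(h_ref)
        assert res.omnibus["p"].iloc[0] == pytest.approx(sps.chi2.sf(h_ref, 1))

    def test_identical_values_h_zero(self):
        tab = pd.DataFrame({"group": ["a"] * 4 + ["b"] * 4, "value": 7.0})
        res = metric_group_test(tab)
        assert res.omnibus["statistic"].iloc[0] == 0.0
        assert res.omnibus["p"].iloc[0] == 1.0
        assert "ties" in res.flags

    def test_small_group_excluded(self, caplog):
        tab = pd.DataFrame({"group": ["a"] * 6 + ["b"] * 6 + ["c"],
                            "value": np.arange(13.0)})
        with caplog.at_level("WARNING"):
            res = metric_group_test(tab)
        assert set(res.omnibus["term"]) == {"group"}
        assert all("c" not in c for c in res.contrasts["contrast"])

    def test_dunn_bh_monotone_and_above_raw(self):
        rng = np.random.default_rng(1)
        tab = pd.DataFrame({"group": np.repeat(["a", "b", "c", "d"], 12),
                            "value": rng.normal(np.repeat([0, 0.3, 0.8, 1.5], 12), 1.0)})
        res = metric_group_test(tab)
        c = res.contrasts.sort_values("p_raw")
        assert (c["p_adj"] >= c["p_raw"] - 1e-12).all()
        assert (c["p_adj"] <= 1 + 1e-12).all()
        # BH preserves the significance ordering
        assert (np.diff(c["p_adj"]) >= -1e-12).all()

    def test_matches_scipy_kruskal_with_ties(self):
        rng = np.random.default_rng(2)
        vals = rng.integers(0, 6, 30).astype(float)
        tab = pd.DataFrame({"group": np.repeat(["a", "b", "c"], 10), "value": vals})
        res = metric_group_test(tab)
        h, p = sps.kruskal(vals[:10], vals[10:20], vals[20:])
        assert res.omnibus["statistic"].iloc[0] == pytest.approx(h)
        assert res.omnibus["p"].iloc[0] == pytest.approx(p)


class TestPca:
    def _metrics_frame(self, x):
        df = pd.DataFrame(x, columns=mk.FLIGHT_VARIABLES)
        df.insert(0, "trial_id", [f"t{i}" for i in range(len(df))])
        return df

    def test_collinear_data_single_component(self):
        t = np.linspace(0, 1, 12)
        x = np.outer(t, [1.0, -2.0, 0.5, 3.0, 1.5]) + 5
        res = pca_flight(self._metrics_frame(x))
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)

    def test_reconstruction_complete(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (40, 5)) @ rng.normal(0, 1, (5, 5)) + rng.normal(0, 5, 5)
        res = pca_flight(self._metrics_frame(x))
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T
        np.testing.assert_allclose(recon, z, atol=1e-8)
        # orthonormal loadings, non-negative fractions summing to one
        np.testing.assert_allclose(res.loadings.to_numpy().T @ res.loadings.to_numpy(),
                                   np.eye(5), atol=1e-8)
        assert res.variance_fractions.sum() == pytest.approx(1.0)
        assert (res.variance_fractions >= 0).all()

    def test_sign_convention(self):
        rng = np.random.default_rng(4)
        x = rng.normal(0, 1, (30, 5))
        res = pca_flight(self._metrics_frame(x))
        load = res.loadings.to_numpy()
        for j in range(load.shape[1]):
            assert load[np.argmax(np.abs(load[:, j])), j] > 0

    def test_isotropic_fractions_near_equal(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, (4000, 5))
        res = pca_flight(self._metrics_frame(x))
        np.testing.assert_allclose(res.variance_fractions, 0.2, atol=0.02)

    def test_zero_variance_variable_named(self):
        x = np.random.default_rng(6).normal(0, 1, (10, 5))
        x[:, 2] = 3.0
        with pytest.raises(ValueError, match="prop_voi"):
            pca_flight(self._metrics_frame(x))

    def test_incomplete_rows_dropped(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, (12, 5))
        df = self._metrics_frame(x)
        df.loc[3, "turn_consistency"] = np.nan
        res = pca_flight(df)
        assert res.n_dropped == 1
        assert len(res.scores) == 11


class TestSsrMixedModel:
    @staticmethod
    def simulated_points(seed_wt, seed_ko, **kw):
        wt = mk.simulate_spikes(mk.spike_preset("wildtype", seed=seed_wt, **kw))[0]
        ko = mk.simulate_spikes(mk.spike_preset("knockout", seed=seed_ko, **kw))[0]
        return pd.concat([mk.dose_response(spike_records_from_table(wt)),
                          mk.dose_response(spike_records_from_table(ko))],
                         ignore_index=True)

    def test_knockout_contrast_recovery(self):
        # 12 sensilla per genotype at simulator defaults: the wild-type evoked
        # increment is 40 spikes/s at the reference dose, knockout 0
        pts = self.simulated_points(11, 12)
        res = ssr_mixed_model(pts)
        est = res.contrasts["estimate"].iloc[0]        # ko - wt
        assert est == pytest.approx(-40.0, abs=8.0)
        p_geno = res.omnibus.set_index("term").loc["genotype", "p"]
        assert p_geno < 1e-6

    def test_containment_df_convention(self):
        pts = self.simulated_points(21, 22)
        res = ssr_mixed_model(pts)
        om = res.omnibus.set_index("term")
        n_sensilla = pts["sensillum_id"].nunique()
        n_obs = len(pts)
        assert om.loc["genotype", "df_den"] == n_sensilla - 2
        assert om.loc["log10_dose", "df_den"] == n_obs - n_sensilla - 1

    def test_interaction_term_optional(self):
        pts = self.simulated_points(31, 32)
        res = ssr_mixed_model(pts, include_interaction=True)
        assert any("log10_dose" in t and "genotype" in t for t in res.omnibus["term"])

    def test_single_observation_sensillum_retained(self):
        pts = self.simulated_points(41, 42)
        extra = pts.iloc[[0]].copy()
        extra["sensillum_id"] = "lonely"
        res = ssr_mixed_model(pd.concat([pts, extra], ignore_index=True))
        assert np.isfinite(res.omnibus["statistic"]).all()

    def test_identical_rates_singular(self):
        pts = pd.DataFrame({
            "sensillum_id": np.repeat([f"s{i}" for i in range(6)], 3),
            "genotype": np.repeat(["wt", "ko"], 9),
            "log10_dose": np.tile([-4.0, -3.0, -2.0], 6),
            "rate_spikes_s": 12.0,
        })
        res = ssr_mixed_model(pts)
        assert "singular" in res.flags
        assert (res.omnibus["statistic"] == 0).all()
        assert (res.omnibus["p"] == 1).all()
        assert (res.contrasts["estimate"] == 0).all()
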