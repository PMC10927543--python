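"""Generator determinism, config validation and generative-model oracles."""

import numpy as np
import pandas as pd
import pytest

from pollentrends.synthetic import (
    ConfigurationError,
    DISTURBANCE_TAXA,
    SyntheticConfig,
    generate_archipelago,
    generate_name_table,
)
from pollentrends.taxonomy import TaxonStatus


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"delta": 1.5},
            {"delta": -0.1},
            {"pool_size": 2},
            {"n_islands": 20, "n_sites": 15},
            {"pct_only_fraction": 1.2},
            {"count_depth_range": (0, 100)},
            {"count_depth_range": (500, 100)},
            {"time_span": (100.0, 4000.0)},
            {"messy_name_fraction": -0.5},
        ],
    )
    def test_inconsistent_config_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            generate_archipelago(SyntheticConfig(**kwargs))

    def test_settlement_table_must_cover_all_islands(self):
        cfg = SyntheticConfig(n_sites=3, n_islands=3,
                              settlement_ages={"I01": 3000.0})
        with pytest.raises(ConfigurationError, match="cover all islands"):
            generate_archipelago(cfg)

    def test_never_settled_island_accepted(self):
        cfg = SyntheticConfig(
            n_sites=3, n_islands=3, samples_per_site=5,
            settlement_ages={"I01": 3000.0, "I02": "never", "I03": 700.0},
        )
        _, settlements, _, _, truth = generate_archipelago(cfg)
        assert np.isnan(truth.settlement_ages["I02"])


class TestDeterminism:
    def test_identical_config_identical_output(self):
        cfg = SyntheticConfig(n_sites=4, n_islands=4, samples_per_site=10, seed=42)
        a = generate_archipelago(cfg)
        b = generate_archipelago(cfg)
        for x, y in zip(a[:2], b[:2]):
            pd.testing.assert_frame_equal(x, y)
        pd.testing.assert_frame_equal(a[2].to_frame(), b[2].to_frame())
        pd.testing.assert_frame_equal(a[3], b[3])
        pd.testing.assert_frame_equal(a[4].baseline, b[4].baseline)

    def test_name_table_matches_archipelago_emission(self, small_config):
        table = generate_name_table(small_config)
        _, _, emitted, _, _ = generate_archipelago(small_config)
        pd.testing.assert_frame_equal(table.to_frame(), emitted.to_frame())


class TestStructure:
    def test_shapes_and_kinds(self, small_archipelago, small_config):
        site_meta, settlements, name_table, samples, truth = small_archipelago
        assert len(site_meta) == small_config.n_sites
        assert len(settlements) == small_config.n_islands
        kinds = samples.groupby("site_id")["value_kind"].unique()
        assert all(len(k) == 1 for k in kinds)
        n_pct = (kinds.apply(lambda k: k[0]) == "percentages").sum()
        assert n_pct == round(small_config.pct_only_fraction * small_config.n_sites)

    def test_count_samples_sum_to_drawn_depth(self, small_archipelago, small_config):
        _, _, _, samples, _ = small_archipelago
        lo, hi = small_config.count_depth_range
        totals = (
            samples.loc[samples["value_kind"] == "counts"]
            .groupby(["site_id", "age_bp"])["value"].sum()
        )
        assert ((totals >= lo) & (totals <= hi)).all()
        assert (totals == totals.astype(int)).all()

    def test_percentage_sites_sum_to_100(self, small_archipelago):
        _, _, _, samples, _ = small_archipelago
        pct = samples.loc[samples["value_kind"] == "percentages"]
        if len(pct):
            sums = pct.groupby(["site_id", "age_bp"])["value"].sum()
            assert np.allclose(sums, 100.0)

    def test_truth_compositions_are_distributions(self, small_archipelago):
        truth = small_archipelago[4]
        assert (truth.baseline.to_numpy() >= 0).all()
        assert np.allclose(truth.baseline.sum(axis=1), 1.0)


class TestNameTableContent:
    def test_no_messiness_means_raw_equals_accepted(self):
        cfg = SyntheticConfig(messy_name_fraction=0.0)
        table = generate_name_table(cfg)
        for e in table.entries.values():
            if e.status is TaxonStatus.ACCEPTED:
                assert e.raw_name == e.accepted_name

    def test_every_raw_name_unique_and_messy_kinds_present(self, small_config):
        table = generate_name_table(small_config)
        df = table.to_frame()
        assert df["raw_name"].is_unique
        statuses = set(df["status"])
        assert {"synonym", "cf_species", "multi_match", "indeterminate"} <= statuses

    def test_multi_match_members_share_recorded_family(self, small_config):
        from pollentrends.synthetic import DEFAULT_POOL

        lineage = {name: family for name, rank, genus, family in DEFAULT_POOL}
        table = generate_name_table(small_config)
        for e in table.entries.values():
            if e.status is TaxonStatus.MULTI_MATCH:
                fams = {lineage[m] for m in e.multi_match_members}
                assert fams == {e.family}


class TestGenerativeModel:
    def test_zero_effect_pre_post_compositions_equal(self):
        """With delta = 0 the expected composition never shifts at
        settlement: mean pre/post compositions agree to multinomial error."""
        cfg = SyntheticConfig(
            n_sites=2, n_islands=2, delta=0.0, samples_per_site=500,
            pct_only_fraction=0.0, messy_name_fraction=0.0,
            settlement_ages={"I01": 3000.0, "I02": 3000.0}, seed=5,
        )
        site_meta, settlements, table, samples, truth = generate_archipelago(cfg)
        wide = samples.pivot_table(
            index=["site_id", "age_bp"], columns="taxon", values="value", fill_value=0.0
        )
        wide = wide.div(wide.sum(axis=1), axis=0)
        site = wide.xs("S01", level="site_id")
        pre = site.loc[site.index > 3000.0].mean()
        post = site.loc[site.index < 2500.0].mean()
        assert (pre - post).abs().mean() < 0.005

    def test_delta_recovered_by_monte_carlo(self):
        """Brute-force averaging over ~10,000 samples recovers the injected
        post-settlement disturbance shift delta * (1 - baseline share)."""
        cfg = SyntheticConfig(
            n_sites=2, n_islands=2, delta=0.4, samples_per_site=5000,
            pct_only_fraction=0.0, messy_name_fraction=0.0, unknown_fraction=0.0,
            settlement_ages={"I01": 3000.0, "I02": 3000.0}, seed=8,
        )
        site_meta, settlements, table, samples, truth = generate_archipelago(cfg)
        dist = samples["taxon"].isin(DISTURBANCE_TAXA)
        per_sample = samples.assign(d=samples["value"].where(dist, 0.0)).groupby(
            ["site_id", "age_bp"]
        ).agg(total=("value", "sum"), d=("d", "sum"))
        share = per_sample["d"] / per_sample["total"]
        ages = share.index.get_level_values("age_bp")
        post = share[ages < 2500.0]
        pre = share[ages > 3000.0]
        observed = post.mean() - pre.mean()
        s0 = truth.baseline[list(DISTURBANCE_TAXA)].sum(axis=1).mean()
        expected = 0.4 * (1.0 - s0)
        assert observed == pytest.approx(expected, abs=0.01)
        assert observed == pytest.approx(0.4, abs=0.1)
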