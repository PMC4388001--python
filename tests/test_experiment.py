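"""Selection driver: truncation, mating, metrics and replicate invariants."""

import numpy as np
import pandas as pd
import pytest

from coansel import (
    GenomeMap,
    InvalidArgumentError,
    InvalidStateError,
    Pedigree,
    ScenarioConfig,
    build_base_population,
    draw_founders,
    init_base,
    log_ratio_metric,
    mate_selected,
    run_replicate,
    run_scenario_grid,
    truncation_select,
)


def tiny_config(**over):
    defaults = dict(
        N=5,
        h2=0.25,
        markers_per_chromosome=150,
        selection_matrix="A",
        n_random_generations=2,
        n_selection_generations=3,
        n_qtl=20,
        n_chromosomes=2,
        loci_per_chromosome=150,
        base_size=40,
        base_generations=10,
        reml_n_iter=150,
        reml_burnin=30,
        roh_min_run=20,
    )
    defaults.update(over)
    return ScenarioConfig(**defaults)


@pytest.fixture(scope="module")
def tiny_base():
    cfg = tiny_config()
    return build_base_population(cfg, np.random.default_rng(77))


class TestTruncationSelect:
    def test_half_of_each_sex(self, rng):
        ebv = rng.normal(size=20)
        sexes = np.array([0] * 10 + [1] * 10)
        sel = truncation_select(ebv, sexes, 0.5)
        assert sel.size == 10
        assert (sexes[sel] == 0).sum() == 5 and (sexes[sel] == 1).sum() == 5

    def test_fraction_one_selects_everyone(self, rng):
        ebv = rng.normal(size=8)
        sexes = np.array([0, 1] * 4)
        assert truncation_select(ebv, sexes, 1.0).size == 8

    def test_matches_sort_and_slice_oracle(self, rng):
        for _ in range(10):
            ebv = rng.normal(size=16)
            sexes = rng.integers(0, 2, 16)
            if min((sexes == 0).sum(), (sexes == 1).sum()) < 2:
                continue
            sel = set(truncation_select(ebv, sexes, 0.5).tolist())
            expected = set()
            for sex in (0, 1):
                members = np.flatnonzero(sexes == sex)
                ranked = members[np.argsort(-ebv[members])]
                expected |= set(ranked[: len(members) // 2].tolist())
            assert sel == expected

    def test_ties_broken_by_lower_id(self):
        ebv = np.array([1.0, 1.0, 0.0, 1.0, 1.0, 0.0])
        sexes = np.array([0, 0, 0, 1, 1, 1])
        ids = np.array([12, 3, 1, 9, 2, 5])
        sel = truncation_select(ebv, sexes, 0.4, ids)  # 1 per sex
        assert set(ids[sel]) == {3, 2}

    def test_empty_sex_class_rejected(self):
        with pytest.raises(InvalidStateError):
            truncation_select(np.ones(4), np.zeros(4), 0.5)


class TestMateSelected:
    def test_offspring_counts_and_parentage(self, rng):
        base = init_base(GenomeMap(1, 50), 20, rng)
        pop, ped = draw_founders(base, 5, rng)
        sires = pop.ids[pop.males()[:2]]
        dams = pop.ids[pop.females()[:3]]
        off, ped = mate_selected(pop, sires, dams, 5, 0.0, rng, ped)
        assert off.n_individuals == 10
        assert (off.sexes == 0).sum() == 5
        newest = ped.to_frame().tail(10)
        assert set(newest["sire"]) <= set(sires.tolist())
        assert set(newest["dam"]) <= set(dams.tolist())

    def test_offspring_spread_over_selected_sires(self, rng):
        """Each selected sire expects 2N/n_sires offspring under random
        mating with replacement."""
        base = init_base(GenomeMap(1, 20), 20, rng)
        pop, ped = draw_founders(base, 5, rng)
        sires = pop.ids[pop.males()]  # 5 sires
        dams = pop.ids[pop.females()]
        counts = np.zeros(5)
        n_rounds = 200
        for _ in range(n_rounds):
            ped_i = Pedigree(ped.ids.copy(), ped.sire.copy(), ped.dam.copy(),
                             ped.sex.copy(), ped.generation.copy())
            off, ped_i = mate_selected(pop, sires, dams, 5, 0.0, rng, ped_i)
            tail = ped_i.to_frame().tail(10)
            for j, s in enumerate(sires):
                counts[j] += (tail["sire"] == s).sum()
        expected = n_rounds * 10 / 5
        se = np.sqrt(n_rounds * 10 * (1 / 5) * (4 / 5))
        assert np.all(np.abs(counts - expected) < 4 * se)


class TestLogRatioMetric:
    def test_equal_coancestries_zero(self):
        assert log_ratio_metric(0.3, 0.3) == 0.0

    def test_direct_value(self):
        assert log_ratio_metric(0.5, 0.0) == pytest.approx(np.log(0.5))

    def test_monotone_decreasing_in_f(self):
        vals = [log_ratio_metric(f, 0.1) for f in (0.1, 0.3, 0.5, 0.9)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_degenerate_f_rejected(self):
        with pytest.raises(InvalidArgumentError):
            log_ratio_metric(1.0, 0.5)


@pytest.fixture(scope="module")
def result(tiny_base):
    return run_replicate(tiny_config(), tiny_base, 0, base_seed=5)


class TestRunReplicate:

    def test_generation_indexing(self, result):
        cfg = tiny_config()
        gens = result["generation"].tolist()
        assert gens == list(
            range(cfg.n_random_generations + cfg.n_selection_generations + 1)
        )

    def test_baseline_anchors_scaled_metrics(self, result):
        base_row = result[result["generation"] == 2].iloc[0]
        assert base_row["delta_tbv"] == 0.0
        for kind in "AGRV":
            assert base_row[f"log_ratio_f_{kind}"] == 0.0

    def test_all_four_coancestries_tracked_under_one_mode(self, result):
        for kind in "AGRV":
            assert result[f"mean_f_{kind}"].notna().all()
            assert result[f"mean_F_{kind}"].notna().all()

    def test_pedigree_coancestry_never_decreases(self, tiny_base):
        """In a closed population mean genealogical coancestry of successive
        cohorts cannot decrease."""
        df = run_replicate(tiny_config(selection_matrix="G"), tiny_base, 1, 5)
        f_a = df["mean_f_A"].to_numpy()
        assert np.all(np.diff(f_a) >= -1e-12)

    def test_variance_estimates_logged_for_selection_generations(self, result):
        cfg = tiny_config()
        sel = result[result["generation"] > cfg.n_random_generations]
        assert sel["sigma2_a_hat"].notna().all()
        pre = result[result["generation"] <= cfg.n_random_generations]
        assert pre["sigma2_a_hat"].isna().all()

    def test_no_selection_pressure_gives_no_systematic_gain(self, tiny_base):
        """With fraction = 1 (everyone selected) mean TBV only drifts."""
        deltas = []
        for r in range(6):
            df = run_replicate(
                tiny_config(select_fraction=1.0, use_true_variances=True),
                tiny_base, r, 99,
            )
            deltas.append(df["delta_tbv"].iloc[-1])
        se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas)) < 4 * se

    def test_replicates_are_paired_across_selection_modes(self, tiny_base):
        """Scenarios differing only in the selection matrix share the QTL
        draw, founders and the whole pre-selection phase."""
        df_a = run_replicate(tiny_config(selection_matrix="A"), tiny_base, 2, 5)
        df_g = run_replicate(tiny_config(selection_matrix="G"), tiny_base, 2, 5)
        pre_a = df_a[df_a["generation"] <= 2]["mean_tbv"].to_numpy()
        pre_g = df_g[df_g["generation"] <= 2]["mean_tbv"].to_numpy()
        np.testing.assert_allclose(pre_a, pre_g)

    def test_deterministic_under_fixed_seed(self, tiny_base, result):
        again = run_replicate(tiny_config(), tiny_base, 0, base_seed=5)
        pd.testing.assert_frame_equal(result, again)


class TestRunScenarioGrid:
    def test_single_config_single_replicate_reduces_to_run_replicate(
        self, tiny_base
    ):
        cfg = tiny_config()
        per_rep, agg = run_scenario_grid([cfg], 1, 5, base=tiny_base)
        direct = run_replicate(cfg, tiny_base, 0, base_seed=5)
        pd.testing.assert_frame_equal(per_rep, direct)
        assert (agg["mean_tbv_mean"] == direct["mean_tbv"].to_numpy()).all()

    def test_aggregate_se_is_sd_over_sqrt_r(self, tiny_base):
        per_rep, agg = run_scenario_grid([tiny_config()], 3, 5, base=tiny_base)
        g = per_rep[per_rep["generation"] == 4]["mean_tbv"]
        row = agg[agg["generation"] == 4].iloc[0]
        assert row["mean_tbv_se"] == pytest.approx(
            g.std(ddof=1) / np.sqrt(3)
        )
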