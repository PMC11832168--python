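"""ERP averaging, cluster permutation, ROI tests and the split-plot ANOVA."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest

from slentrain import erp, montage, simeeg, streamgen


@pytest.fixture(scope="module")
def test_recording():
    lex = streamgen.build_lexicon("phoneme", "A")
    rng = np.random.default_rng(0)
    blocks = [streamgen.make_test_block(lex, rng) for _ in range(10)]
    cfg = simeeg.SimulationConfig(n_channels=8, seed=0, erp_effect=0.0)
    return simeeg.simulate_test_eeg(blocks, cfg, rng=rng)


class TestEpochAverage:
    def test_clean_run_yields_90_trials_per_condition(self, test_recording):
        s = erp.epoch_and_average(test_recording, subject_id="s0", group="phoneme")
        assert s.n_trials == {"word": 90, "partword": 90} or s.n_trials == {
            "partword": 90,
            "word": 90,
        }
        assert s.meets_trial_criterion
        assert s.erps["word"].shape == (1, 8, 551)

    def test_analysis_window_has_376_points(self, test_recording):
        s = erp.epoch_and_average(test_recording)
        assert s.analysis_window().sum() == 376

    def test_trial_criterion_fails_below_45(self, test_recording):
        s = erp.epoch_and_average(test_recording)
        s.n_trials = {"word": 44, "partword": 90}
        assert not s.meets_trial_criterion

    def test_null_effect_averages_differ_only_by_noise(self, test_recording):
        s = erp.epoch_and_average(test_recording)
        diff = s.erps["word"][0] - s.erps["partword"][0]
        joint = 0.5 * (s.erps["word"][0] + s.erps["partword"][0])
        assert np.abs(diff).mean() < 0.5 * np.abs(joint).max()

    def test_artifact_trials_rejected(self, test_recording):
        import dataclasses

        mask = np.zeros_like(test_recording.artifact_mask)
        onset = test_recording.events["onset"].iloc[0]
        i = int(onset * test_recording.srate_hz)
        mask[0, i : i + 10] = True
        rec = dataclasses.replace(test_recording, artifact_mask=mask)
        s_clean = erp.epoch_and_average(test_recording)
        s = erp.epoch_and_average(rec)
        assert sum(s.n_trials.values()) == sum(s_clean.n_trials.values()) - 1


class TestClusterAlgorithm:
    def brute_force_components(self, supra, adj):
        """Independent connected-components oracle on a tiny grid."""
        import networkx as nx

        g = nx.Graph()
        nodes = list(zip(*np.nonzero(supra)))
        g.add_nodes_from(nodes)
        for c, t in nodes:
            for c2 in np.flatnonzero(adj[c]):
                if supra[c2, t]:
                    g.add_edge((c, t), (c2, t))
            if t + 1 < supra.shape[1] and supra[c, t + 1]:
                g.add_edge((c, t), (c, t + 1))
        return [frozenset(cc) for cc in nx.connected_components(g)]

    @pytest.mark.parametrize("seed", range(5))
    def test_components_equal_graph_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_ch, n_t = 6, 10
        t_map = rng.normal(size=(n_ch, n_t))
        adj = np.zeros((n_ch, n_ch), bool)
        for i in range(n_ch - 1):  # chain adjacency
            adj[i, i + 1] = adj[i + 1, i] = True
        found = erp.find_clusters(t_map, 0.5, adj, min_electrodes=1)
        got = {
            frozenset(map(tuple, m)): round(mass, 10) for m, mass, _ in found
        }
        for sign in (1, -1):
            supra = sign * t_map > 0.5
            for comp in self.brute_force_components(supra, adj):
                assert comp in got
                assert got[comp] == round(float(sum(t_map[c, t] for c, t in comp)), 10)

    def test_min_electrode_rule_trims_thin_slices(self):
        adj = np.ones((4, 4), bool)
        np.fill_diagonal(adj, False)
        t_map = np.zeros((4, 6))
        t_map[:3, 1:4] = 5.0  # 3 electrodes wide, ok
        t_map[0, 4] = 5.0  # 1-electrode tail, must be trimmed
        found = erp.find_clusters(t_map, 2.0, adj, min_electrodes=3)
        assert len(found) == 1
        members, mass, sign = found[0]
        assert sign == 1
        assert set(members[:, 1]) == {1, 2, 3}
        assert mass == pytest.approx(45.0)

    def test_identical_conditions_give_no_clusters(self, positions_16):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(6, 16, 40))
        res = erp.cluster_permutation(
            a, a.copy(), positions_16, np.arange(40) / 250.0,
            neighbour_cm=6.0, n_perm=50, seed=0,
        )
        assert res.clusters == []

    def test_effect_recovered_with_both_polarities(self):
        # chain montage: consecutive channels 2 cm apart are neighbours, so
        # the injected 6-channel patches are spatially contiguous
        positions = np.column_stack(
            [2.0 * np.arange(16), np.zeros(16), np.zeros(16)]
        )
        rng = np.random.default_rng(5)
        n, n_t = 10, 100
        topo = np.zeros(16)
        topo[:6] = 1.0
        topo[10:] = -1.0
        a = rng.normal(0, 1, size=(n, 16, n_t))
        b = rng.normal(0, 1, size=(n, 16, n_t))
        a[:, :, 30:70] += 1.8 * topo[None, :, None]
        res = erp.cluster_permutation(
            a, b, positions, np.arange(n_t) / 250.0,
            neighbour_cm=2.5, n_perm=300, seed=2,
        )
        sig = res.significant(0.05)
        assert any(c.polarity == 1 for c in sig)
        assert any(c.polarity == -1 for c in sig)
        best = sig[0]
        assert 25 <= best.time_indices.min() <= 35
        assert 65 <= best.time_indices.max() <= 75

    def test_requires_two_subjects(self, positions_16):
        with pytest.raises(ValueError):
            erp.cluster_permutation(
                np.zeros((1, 16, 10)), np.zeros((1, 16, 10)),
                positions_16, np.arange(10) / 250.0,
            )


class TestROI:
    def test_family_size_is_2632(self, positions_128, rng):
        rois = montage.default_rois(positions_128)
        a = rng.normal(size=(6, 128, 376))
        b = rng.normal(size=(6, 128, 376))
        res = erp.roi_tests(a, b, rois, np.arange(376) / 250.0)
        assert res.family_size == 2632

    def test_effect_found_only_in_target_roi(self, positions_128, rng):
        rois = montage.default_rois(positions_128)
        a = rng.normal(size=(10, 128, 80))
        b = rng.normal(size=(10, 128, 80))
        target = rois["Occipital"]
        a[:, target, 20:60] += 1.5
        res = erp.roi_tests(a, b, rois, np.arange(80) / 250.0)
        assert (res.p_fdr["Occipital"][20:60] <= 0.05).mean() > 0.9
        for name in rois:
            if name != "Occipital":
                assert (res.p_fdr[name] <= 0.05).mean() < 0.05

    def test_paired_t_equals_closed_form(self, positions_128):
        rois = {"Central": np.array([0])}
        a = np.array([[[3.0]], [[5.0]], [[4.0]], [[6.0]]])
        b = np.array([[[2.0]], [[4.0]], [[2.0]], [[5.0]]])
        res = erp.roi_tests(a, b, rois, np.array([0.0]))
        d = (a - b)[:, 0, 0]
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        assert res.t["Central"][0] == pytest.approx(expected)

    def test_empty_roi_rejected(self, rng):
        with pytest.raises(ValueError):
            erp.roi_tests(
                rng.normal(size=(4, 8, 10)),
                rng.normal(size=(4, 8, 10)),
                {"Empty": np.array([], dtype=int)},
                np.arange(10) / 250.0,
            )


class TestMixedAnova:
    @staticmethod
    def table(seed, n1=27, n2=30, eff1=0.35, eff2=0.1):
        rng = np.random.default_rng(seed)
        rows = []
        for g, n, eff in (("phoneme", n1, eff1), ("voice", n2, eff2)):
            for i in range(n):
                base = rng.normal(3.5, 0.8)
                for c, e in (("word", eff), ("partword", 0.0)):
                    rows.append(
                        dict(subject=f"{g}{i}", group=g, condition=c,
                             value=base + e + rng.normal(0, 0.5))
                    )
        return pd.DataFrame(rows)

    def test_printed_design_degrees_of_freedom(self):
        res = erp.mixed_anova(self.table(0))
        assert (res.table["df1"] == 1).all()
        assert (res.table["df2"] == 55).all()

    def test_matches_pingouin_oracle(self):
        df = self.table(3)
        res = erp.mixed_anova(df).table.set_index("effect")
        oracle = pg.mixed_anova(
            df, dv="value", within="condition", subject="subject",
            between="group", effsize="ng2",
        ).set_index("Source")
        for mine, theirs in [
            ("group", "group"), ("condition", "condition"),
            ("interaction", "Interaction"),
        ]:
            assert res.loc[mine, "F"] == pytest.approx(oracle.loc[theirs, "F"])
            assert res.loc[mine, "p"] == pytest.approx(oracle.loc[theirs, "p-unc"]
                if "p-unc" in oracle.columns else oracle.loc[theirs, "p_unc"])
            assert res.loc[mine, "eta_g_sq"] == pytest.approx(
                oracle.loc[theirs, "ng2"]
            )

    def test_identical_within_effects_leave_interaction_null(self):
        fs = [
            erp.mixed_anova(self.table(s, eff1=0.3, eff2=0.3))
            .effect("interaction")["F"]
            for s in range(12)
        ]
        assert np.mean(fs) < 2.5

    def test_missing_cell_rejected(self):
        df = self.table(0).iloc[1:]
        with pytest.raises(ValueError):
            erp.mixed_anova(df)

    def test_single_condition_rejected(self):
        df = self.table(0)
        with pytest.raises(ValueError):
            erp.mixed_anova(df[df["condition"] == "word"])
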