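"""Pair classification, Fisher z, within/between tables, region summaries."""

import numpy as np
import pandas as pd
import pytest

from hemibias import (
    NetworkLayout,
    between_subject_table,
    classify_pairs,
    fisher_z,
    generate_dataset,
    preset_spec,
    region_summary,
    within_subject_table,
)
from hemibias.synthetic import LatentSpec, PairClass, ROITimecourseDataset

from reference_impl import loop_between_zr, loop_within_rows


def class_counts(layout):
    pairs = classify_pairs(layout)
    out = {cls: 0 for cls in ("inter_corresponding", "inter_noncorresponding",
                              "intra")}
    for p in pairs:
        out[p.pair_class.value] += 1
    return len(pairs), out


class TestClassifyPairs:
    def test_face_layout_counts(self, face_layout):
        total, counts = class_counts(face_layout)
        assert total == 28
        assert counts == {"inter_corresponding": 4,
                          "inter_noncorresponding": 12, "intra": 12}

    def test_scene_layout_counts(self, scene_layout):
        total, counts = class_counts(scene_layout)
        assert total == 15
        assert counts == {"inter_corresponding": 3,
                          "inter_noncorresponding": 6, "intra": 6}

    def test_single_region_layout(self):
        layout = NetworkLayout(name="solo", regions=("X",))
        pairs = classify_pairs(layout)
        assert len(pairs) == 1
        assert pairs[0].pair_class is PairClass.INTER_CORRESPONDING


class TestFisherZ:
    def test_known_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(np.log(3) / 2, abs=1e-12)

    def test_antisymmetry(self):
        assert fisher_z(-0.73) == pytest.approx(-fisher_z(0.73), abs=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fisher_z(1.2)

    def test_unit_correlation_raises_unless_clipped(self):
        with pytest.raises(ValueError):
            fisher_z(1.0)
        assert fisher_z(1.0, clip=True) == pytest.approx(np.arctanh(1 - 1e-7))


class TestWithinSubjectTable:
    def test_identical_hemispheres_give_unit_r(self):
        rng = np.random.default_rng(0)
        series = rng.normal(size=50)
        data = np.stack([series, series])[None, None]  # 1 subj, 1 region
        ds = ROITimecourseDataset(data=data, regions=("X",), run_lengths=(50,))
        layout = NetworkLayout(name="solo", regions=("X",))
        table = within_subject_table(ds, layout)
        assert table["r"].iloc[0] == pytest.approx(1.0)
        assert np.isfinite(table["Zr"].iloc[0])  # clipped, not infinite

    def test_white_noise_correlations_are_small(self):
        spec = LatentSpec(regions=("A", "B", "C"), alpha=0, beta=0, gamma=0,
                          sigma=1)
        ds = generate_dataset(spec, 1, [50_000], seed=9)
        table = within_subject_table(ds, NetworkLayout(name="n", regions=spec.regions))
        assert table["r"].abs().max() <= 0.02

    def test_matches_loop_recomputation(self, small_face_dataset, face_layout):
        table = within_subject_table(small_face_dataset, face_layout)
        expected = loop_within_rows(small_face_dataset.data,
                                    face_layout.regions)
        assert len(table) == 3 * 28
        for row in table.itertuples():
            assert row.r == pytest.approx(
                expected[(row.subject, row.node_a, row.node_b)], abs=1e-10)

    def test_face_regime_orders_classes(self):
        ds = generate_dataset(preset_spec("face"), 6, [2000], seed=21,
                              network="face")
        table = within_subject_table(ds, NetworkLayout.named("face"))
        means = table.groupby("pair_class")["Zr"].mean()
        assert means["inter_corresponding"] > means["intra"]

    def test_zero_variance_series_flagged_missing(self):
        data = np.zeros((1, 2, 2, 30))
        data[0, 0, 0] = np.random.default_rng(1).normal(size=30)
        data[0, 0, 1] = np.random.default_rng(2).normal(size=30)
        data[0, 1, 0] = np.random.default_rng(3).normal(size=30)
        # node (B, R) is constant -> its pairs are NaN, not zero
        ds = ROITimecourseDataset(data=data, regions=("A", "B"),
                                  run_lengths=(30,))
        table = within_subject_table(ds, NetworkLayout(name="n", regions=("A", "B")))
        flagged = table[table["node_b"] == "B_R"]
        assert flagged["r"].isna().all()
        assert table[table["node_b"] != "B_R"]["r"].notna().all()


class TestBetweenSubjectTable:
    def test_identical_subjects_reduce_to_within(self, rng):
        base = rng.normal(size=(2, 2, 60))  # regions x hemis x T
        data = np.stack([base, base, base])
        ds = ROITimecourseDataset(data=data, regions=("A", "B"),
                                  run_lengths=(60,))
        layout = NetworkLayout(name="n", regions=("A", "B"))
        within = within_subject_table(ds, layout)
        between = between_subject_table(ds, layout)
        merged = within.merge(between, on=["subject", "node_a", "node_b"],
                              suffixes=("_w", "_b"))
        assert np.allclose(merged["Zr_w"], merged["Zr_b"], atol=1e-10)

    def test_two_subject_definition_instance(self, rng):
        data = rng.normal(size=(2, 2, 2, 80))
        ds = ROITimecourseDataset(data=data, regions=("A", "B"),
                                  run_lengths=(80,))
        layout = NetworkLayout(name="n", regions=("A", "B"))
        table = between_subject_table(ds, layout)
        row = table[(table["subject"] == 0) & (table["node_a"] == "A_L")
                    & (table["node_b"] == "B_L")].iloc[0]
        r1 = np.corrcoef(data[0, 0, 0], data[1, 1, 0])[0, 1]  # A_0 : B_1
        r2 = np.corrcoef(data[0, 1, 0], data[1, 0, 0])[0, 1]  # B_0 : A_1
        assert row.Zr == pytest.approx(
            (np.arctanh(r1) + np.arctanh(r2)) / 2, abs=1e-12)

    def test_no_shared_stimulus_gives_near_zero(self):
        spec = preset_spec("face", alpha=0.0)
        ds = generate_dataset(spec, 2, [50_000], seed=31, network="face")
        table = between_subject_table(ds, NetworkLayout.named("face"))
        assert table["Zr"].abs().max() <= 0.02

    def test_matches_loop_recomputation(self, two_region_spec):
        ds = generate_dataset(two_region_spec, 3, [60], seed=17)
        layout = NetworkLayout(name="n", regions=two_region_spec.regions)
        table = between_subject_table(ds, layout)
        expected = loop_between_zr(ds.data, layout.regions)
        for row in table.itertuples():
            assert row.Zr == pytest.approx(
                expected[(row.subject, row.node_a, row.node_b)], abs=1e-10)

    def test_invariant_to_order_of_other_subjects(self, two_region_spec):
        ds = generate_dataset(two_region_spec, 4, [80], seed=5)
        layout = NetworkLayout(name="n", regions=two_region_spec.regions)
        base = between_subject_table(ds, layout)
        permuted = ROITimecourseDataset(
            data=ds.data[[0, 3, 1, 2]], regions=ds.regions,
            run_lengths=ds.run_lengths)
        perm = between_subject_table(permuted, layout)
        # subject 0's averaged values ignore the order of the others
        a = base[base["subject"] == 0].set_index(["node_a", "node_b"])["Zr"]
        b = perm[perm["subject"] == 0].set_index(["node_a", "node_b"])["Zr"]
        assert np.allclose(a, b, atol=1e-12)

    def test_single_subject_rejected(self, two_region_spec):
        ds = generate_dataset(two_region_spec, 1, [50], seed=1)
        with pytest.raises(ValueError):
            between_subject_table(ds, NetworkLayout(name="n",
                                                    regions=two_region_spec.regions))


class TestRegionSummary:
    def toy_table(self):
        """Hand-built 3-subject within table on a 3-region layout."""
        rows = []
        rng = np.random.default_rng(8)
        layout = NetworkLayout(name="toy", regions=("X", "Y", "Z"))
        for s in range(3):
            for p in classify_pairs(layout):
                la = f"{p.node_a[0]}_{p.node_a[1]}"
                lb = f"{p.node_b[0]}_{p.node_b[1]}"
                r = float(rng.uniform(-0.5, 0.9))
                rows.append((s, la, lb, p.pair_class.value, r, np.arctanh(r),
                             "within"))
        return pd.DataFrame(rows, columns=["subject", "node_a", "node_b",
                                           "pair_class", "r", "Zr", "mode"])

    def test_matches_spreadsheet_recomputation(self):
        table = self.toy_table()
        summary = region_summary(table, "X").set_index("subject")
        labels = {"X_L", "X_R"}
        for s in range(3):
            sub = table[table["subject"] == s]
            intra = sub[(sub["pair_class"] == "intra")
                        & (sub["node_a"].isin(labels) | sub["node_b"].isin(labels))]
            assert summary.loc[s, "intra_avg_Zr"] == pytest.approx(
                intra["Zr"].mean(), abs=1e-12)
            inter = sub[(sub["pair_class"] == "inter_corresponding")
                        & sub["node_a"].isin(labels)]
            assert summary.loc[s, "inter_corresponding_Zr"] == pytest.approx(
                inter["Zr"].iloc[0], abs=1e-12)
        # group-level highest pair: maximises the pair's mean Zr over subjects
        intra_all = table[(table["pair_class"] == "intra")
                          & (table["node_a"].isin(labels)
                             | table["node_b"].isin(labels))]
        best = (intra_all.assign(pair=intra_all["node_a"] + ":" + intra_all["node_b"])
                .groupby("pair")["Zr"].mean().idxmax())
        assert (summary["intra_high_Zr_pair"] == best).all()

    def test_two_region_layout_avg_equals_high(self):
        layout = NetworkLayout(name="duo", regions=("X", "Y"))
        rows = []
        for s in range(3):
            for p in classify_pairs(layout):
                la = f"{p.node_a[0]}_{p.node_a[1]}"
                lb = f"{p.node_b[0]}_{p.node_b[1]}"
                rows.append((s, la, lb, p.pair_class.value, 0.3,
                             np.arctanh(0.3), "within"))
        table = pd.DataFrame(rows, columns=["subject", "node_a", "node_b",
                                            "pair_class", "r", "Zr", "mode"])
        summary = region_summary(table, "X")
        assert np.allclose(summary["intra_avg_Zr"], summary["intra_high_Zr"])

    def test_group_selection_is_shared_across_subjects(self):
        ds = generate_dataset(preset_spec("face"), 5, [400], seed=77,
                              network="face")
        table = within_subject_table(ds, NetworkLayout.named("face"))
        summary = region_summary(table, "OFA", selection="group")
        assert summary["intra_high_Zr_pair"].nunique() == 1

    def test_single_region_layout_flags_missing_intra(self):
        layout = NetworkLayout(name="solo", regions=("X",))
        rows = [(0, "X_L", "X_R", "inter_corresponding", 0.4,
                 np.arctanh(0.4), "within")]
        table = pd.DataFrame(rows, columns=["subject", "node_a", "node_b",
                                            "pair_class", "r", "Zr", "mode"])
        summary = region_summary(table, "X")
        assert np.isnan(summary["intra_avg_Zr"]).all()
        assert np.isnan(summary["intra_high_Zr"]).all()
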