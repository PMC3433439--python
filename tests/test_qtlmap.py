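"""Single-marker LOD scan, binning, and cis/trans labels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from spruceqtl import qtlmap, synth
from spruceqtl.qtlmap import single_marker_scan, map_trait, map_all_expression

from .oracles import gaussian_lod_oracle


class TestSingleMarkerScan:
    def test_constant_trait_gives_zero_lod(self, two_class_codes):
        res = single_marker_scan(np.full(8, 3.3), two_class_codes)
        assert res.lod == 0.0
        assert res.pct_var == 0.0

    def test_perfect_separation_capped(self, two_class_codes):
        y = np.where(two_class_codes == 1.0, 1.0, 2.0)
        res = single_marker_scan(y, two_class_codes)
        assert res.lod == qtlmap.LOD_CAP
        assert res.pct_var == 100.0
        assert res.allele_effect == pytest.approx(-0.5)

    def test_worked_example_matches_likelihood_oracle(self, two_class_codes):
        y = np.array([2.0, 2.2, 1.8, 2.1, 3.0, 2.9, 3.2, 3.1])
        res = single_marker_scan(y, two_class_codes)
        lod, eff, pct = gaussian_lod_oracle(y, two_class_codes)
        assert res.lod == pytest.approx(lod, abs=1e-9)
        assert res.allele_effect == pytest.approx(eff, abs=1e-6)
        assert res.pct_var == pytest.approx(pct, abs=1e-4)
        assert res.n_used == 8

    def test_matches_oracle_on_random_small_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(5, 13))
            codes = np.array([1.0] * 2 + [2.0] * 2 + list(rng.integers(1, 3, n - 4)))
            y = rng.normal(0, 1, n) + 0.8 * (codes == 1)
            res = single_marker_scan(y, codes)
            lod, _, _ = gaussian_lod_oracle(y, codes)
            assert res.lod == pytest.approx(lod, abs=1e-9)

    def test_missing_codes_dropped_pairwise(self, two_class_codes):
        codes = two_class_codes.copy()
        codes[0] = np.nan
        y = np.arange(8.0)
        res = single_marker_scan(y, codes)
        ref = single_marker_scan(y[1:], codes[1:])
        assert res == ref
        assert res.n_used == 7

    def test_class_with_one_progeny_rejected(self):
        with pytest.raises(ValueError, match="transmission class"):
            single_marker_scan(np.arange(5.0), np.array([1, 2, 2, 2, 2.0]))

    @settings(derandomize=True, max_examples=30)
    @given(
        shift=st.floats(-50, 50),
        scale=st.floats(0.01, 40),
        seed=st.integers(0, 10_000),
    )
    def test_lod_invariant_under_affine_trait_transform(self, shift, scale, seed):
        rng = np.random.default_rng(seed)
        codes = np.array([1.0] * 5 + [2.0] * 5)
        y = rng.normal(size=10) + (codes == 1)
        a = single_marker_scan(y, codes)
        b = single_marker_scan(scale * y + shift, codes)
        assert b.lod == pytest.approx(a.lod, rel=1e-9, abs=1e-9)
        assert b.pct_var == pytest.approx(a.pct_var, rel=1e-9, abs=1e-9)

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 10_000))
    def test_swapping_transmission_labels_flips_effect_sign(self, seed):
        rng = np.random.default_rng(seed)
        codes = np.array([1.0] * 4 + [2.0] * 6)
        y = rng.normal(size=10)
        a = single_marker_scan(y, codes)
        b = single_marker_scan(y, 3.0 - codes)
        assert b.lod == pytest.approx(a.lod, abs=1e-12)
        assert b.allele_effect == pytest.approx(-a.allele_effect, abs=1e-12)


def _planted_study(seed, n=200, effect=1.0, marker="SNP050"):
    cfg = synth.SimConfig(crosses=[synth.Cross("d", "s", n)], n_transcripts=1)
    rng = np.random.default_rng(seed)
    map_df, tms, cross_df = synth.simulate_pedigree(cfg, rng)
    truth = synth.TruthTable(records=[synth.TruthRecord("T0001", marker, "d", effect)])
    expr, _, _ = synth.simulate_traits(map_df, tms, truth, cfg, rng)
    return map_df, tms, cross_df, expr


class TestMapTrait:
    def test_planted_qtl_recovered_within_10cm(self):
        map_df, tms, cross_df, expr = _planted_study(seed=0)
        table = map_trait(expr["T0001"], tms, map_df, cross_of=cross_df["cross"])
        assert not table.empty
        best = table.loc[table["lod"].idxmax()]
        causal = map_df.set_index("marker").loc["SNP050"]
        assert best["lg"] == causal["lg"]
        assert abs(best["cm"] - causal["cm"]) <= 10.0

    def test_one_record_per_bin_for_linked_markers(self):
        # two markers 2 cM apart flank one causal locus: binning keeps one
        cfg = synth.SimConfig(
            n_linkage_groups=1,
            markers_per_lg=2,
            crosses=[synth.Cross("d", "s", 300)],
            n_transcripts=1,
            marker_positions_cm=[[4.0, 6.0]],
        )
        rng = np.random.default_rng(1)
        map_df, tms, cross_df = synth.simulate_pedigree(cfg, rng)
        truth = synth.TruthTable(records=[synth.TruthRecord("T0001", "SNP001", "d", 1.5)])
        expr, _, _ = synth.simulate_traits(map_df, tms, truth, cfg, rng)
        table = map_trait(expr["T0001"], tms, map_df, cross_of=cross_df["cross"])
        by_parent = table[table["parent"] == "d"]
        assert len(by_parent) == 1

    def test_empty_map_rejected(self, study):
        with pytest.raises(ValueError, match="empty genetic map"):
            map_trait(
                study["expression"].iloc[:, 0],
                study["transmissions"],
                study["map"].iloc[0:0],
            )

    def test_too_few_progeny_rejected(self, study):
        y = study["expression"].iloc[:10, 0]
        with pytest.raises(ValueError, match="progeny"):
            map_trait(y, study["transmissions"], study["map"])

    def test_cross_centering_removes_family_effect(self, study):
        # a family mean offset must not create spurious QTLs
        expr = study["expression"].iloc[:, -1]  # a null transcript
        shifted = expr + study["cross_df"]["cross"].map(
            {c: 50.0 * i for i, c in enumerate(study["cross_df"]["cross"].unique())}
        )
        with_centering = map_trait(
            shifted, study["transmissions"], study["map"],
            cross_of=study["cross_df"]["cross"],
        )
        assert len(with_centering) <= 1  # essentially a null scan


class TestMapExpression:
    def test_zero_transcripts_give_empty_table(self, study):
        empty = study["expression"].iloc[:, 0:0]
        table = map_all_expression(empty, study["transmissions"], study["map"])
        assert table.empty
        assert list(table.columns) == qtlmap.QTL_COLUMNS

    def test_matches_per_trait_mapping(self, study):
        expr = study["expression"].iloc[:, :5]
        joint = map_all_expression(
            expr, study["transmissions"], study["map"],
            cross_of=study["cross_df"]["cross"],
        )
        single = pd.concat(
            [
                map_trait(expr[c], study["transmissions"], study["map"],
                          cross_of=study["cross_df"]["cross"])
                for c in expr.columns
            ],
            ignore_index=True,
        )
        j = joint.sort_values(["trait", "parent", "marker"]).reset_index(drop=True)
        s = single.sort_values(["trait", "parent", "marker"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(j, s, check_exact=False, atol=1e-10)

    def test_deterministic_given_same_input(self, study):
        kw = dict(cross_of=study["cross_df"]["cross"])
        a = map_all_expression(study["expression"], study["transmissions"], study["map"], **kw)
        b = map_all_expression(study["expression"], study["transmissions"], study["map"], **kw)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_architecture_recovered(self, study):
        """Transcripts with planted 1 SD eQTLs map back to the causal bin."""
        truth = study["truth"]
        table = map_all_expression(
            study["expression"], study["transmissions"], study["map"],
            cross_of=study["cross_df"]["cross"],
        )
        info = study["map"].set_index("marker")
        planted = [r for r in truth.records if r.target.startswith("T")]
        recovered = 0
        for rec in planted:
            causal = info.loc[rec.marker]
            sub = table[(table["trait"] == rec.target) & (table["lg"] == causal["lg"])]
            if ((sub["cm"] - causal["cm"]).abs() <= 10.0).any():
                recovered += 1
        assert recovered >= 0.9 * len(planted)


class TestCisTrans:
    def test_labels_against_truth(self, study):
        truth = study["truth"]
        table = map_all_expression(
            study["expression"], study["transmissions"], study["map"],
            cross_of=study["cross_df"]["cross"],
        )
        labelled = qtlmap.classify_cis_trans(table, truth.transcript_locations)
        info = study["map"].set_index("marker")
        planted = {r.target: r for r in truth.records if r.target.startswith("T")}
        checked = agreed = 0
        for row in labelled.itertuples():
            rec = planted.get(row.trait)
            if rec is None or row.marker != rec.marker:
                continue  # only score records at the exact causal marker
            loc = truth.transcript_locations.loc[row.trait]
            causal = info.loc[rec.marker]
            truth_label = (
                "cis"
                if causal["lg"] == loc["lg"] and abs(causal["cm"] - loc["cm"]) <= 10.0
                else "trans"
            )
            checked += 1
            agreed += row.regulation == truth_label
        assert checked >= 10
        assert agreed / checked >= 0.95

    def test_unknown_location_labelled_unknown(self, tiny_map):
        table = pd.DataFrame(
            [["T1", "M1", 1, 0.0, "d", 5.0, 0.3, 10.0, 100]],
            columns=qtlmap.QTL_COLUMNS,
        )
        out = qtlmap.classify_cis_trans(table, None)
        assert list(out["regulation"]) == ["unknown"]

    def test_same_marker_is_cis_other_lg_is_trans(self, tiny_map):
        table = pd.DataFrame(
            [
                ["T1", "M1", 1, 0.0, "d", 5.0, 0.3, 10.0, 100],
                ["T1", "M4", 2, 0.0, "d", 5.0, 0.3, 10.0, 100],
            ],
            columns=qtlmap.QTL_COLUMNS,
        )
        loc = pd.DataFrame({"lg": [1], "cm": [0.0]}, index=pd.Index(["T1"], name="transcript"))
        out = qtlmap.classify_cis_trans(table, loc)
        assert list(out["regulation"]) == ["cis", "trans"]
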