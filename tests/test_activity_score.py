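import numpy as np
import pandas as pd
import pytest

from proteoscreen import activity_score as act
from proteoscreen import standard_postprocess
from proteoscreen.io_formats import AnnotationSet
from proteoscreen.preprocessing import LINEAR, LOG10, AbundanceMatrix


def df(rows, index, columns):
    return pd.DataFrame(rows, index=index, columns=columns, dtype=float)


LINES = ["L1", "L2", "L3"]


@pytest.fixture()
def annotations():
    return AnnotationSet(
        kinase_ids={"KINA", "KINB"},
        activation_loop_sites={"KINA": {"KINA_T10"}},
        substrate_sites={"KINA": {"SUB_S5"}, "KINB": {"SUB_S5"}},
        druggable_kinases={"KINA"},
    )


class TestLayers:
    def test_layer_a_zscore_convention(self, annotations):
        prot = AbundanceMatrix(
            df([[1, 2, 3], [5, 5, 5], [9, 1, 4]],
               ["KINA", "KINB", "NOTAKINASE"], LINES), LOG10)
        z = act.layer_a_kinase_abundance(prot, annotations)
        assert "NOTAKINASE" not in z.index
        assert np.allclose(z.loc["KINA"], [-1, 0, 1])  # sample SD = 1
        assert np.allclose(z.loc["KINB"], 0.0)  # constant row -> 0, not NaN

    def test_layer_b_sums_linear_then_log10(self, annotations):
        phos = AbundanceMatrix(
            df([[1e5, np.nan, 2e5], [3e5, 1e5, np.nan]],
               ["KINA_T10", "KINA_S20"], LINES), LINEAR)
        summed = act._sum_sites_per_kinase(
            phos, {"KINA": {"KINA_T10", "KINA_S20"}})
        # missing counts as 0 inside a sum with >=1 observed site
        assert summed.loc["KINA", "L1"] == pytest.approx(np.log10(4e5))
        assert summed.loc["KINA", "L2"] == pytest.approx(np.log10(1e5))
        assert summed.loc["KINA", "L3"] == pytest.approx(np.log10(2e5))

    def test_kinase_without_sites_absent(self, annotations):
        phos = AbundanceMatrix(df([[1e5, 1e5, 1e5]], ["KINA_T10"], LINES),
                               LINEAR)
        z = act.layer_b_kinase_phospho(phos, annotations)
        assert "KINB" not in z.index

    def test_single_site_kinase_reduces_to_site_profile(self, annotations):
        phos = AbundanceMatrix(df([[1e4, 1e5, 1e6]], ["KINA_T10"], LINES),
                               LINEAR)
        z = act.layer_b_kinase_phospho(phos, annotations)
        site_z = act.zscore_rows(np.log10(phos.values))
        assert np.allclose(z.loc["KINA"], site_z.loc["KINA_T10"])

    def test_substrate_shared_by_two_kinases_counts_for_both(self, annotations):
        phos = AbundanceMatrix(df([[1e5, 2e5, 4e5]], ["SUB_S5"], LINES),
                               LINEAR)
        z = act.layer_d_substrates(phos, annotations)
        assert set(z.index) == {"KINA", "KINB"}
        assert np.allclose(z.loc["KINA"], z.loc["KINB"])

    def test_loop_site_also_counts_in_layer_b(self, annotations):
        phos = AbundanceMatrix(df([[1e5, 2e5, 4e5]], ["KINA_T10"], LINES),
                               LINEAR)
        zb = act.layer_b_kinase_phospho(phos, annotations)
        zc = act.layer_c_activation_loop(phos, annotations)
        assert "KINA" in zb.index and "KINA" in zc.index


class TestCombine:
    def _landscape(self, a_val, b_val=None, d_val=None):
        idx, cols = ["K"], ["L1"]
        a = df([[a_val]], idx, cols)
        b = df([[b_val if b_val is not None else np.nan]], idx, cols)
        c = df([[np.nan]], idx, cols)
        d = df([[d_val if d_val is not None else np.nan]], idx, cols)
        return act.combine(a, b, c, d)

    def test_additivity_all_layers(self):
        idx, cols = ["K"], ["L1"]
        one = df([[1.0]], idx, cols)
        land = act.combine(one, one, one, one)
        assert land.scores.loc["K", "L1"] == 4.0
        assert land.layer_mask.loc["K", "L1"] == "abcd"

    def test_abundance_only_gives_no_score(self):
        land = self._landscape(2.0)
        assert np.isnan(land.scores.loc["K", "L1"])
        assert land.abundance_only.loc["K", "L1"]

    def test_a_plus_d(self):
        land = self._landscape(1.5, d_val=0.5)
        assert land.scores.loc["K", "L1"] == 2.0
        assert land.layer_mask.loc["K", "L1"] == "ad"

    def test_no_abundance_no_score(self):
        idx, cols = ["K"], ["L1"]
        a = df([[np.nan]], idx, cols)
        b = df([[3.0]], idx, cols)
        land = act.combine(a, b, a.copy(), a.copy())
        assert np.isnan(land.scores.loc["K", "L1"])


class TestRanking:
    def test_druggable_only_restriction(self, annotations):
        scores = df([[3.0], [5.0]], ["KINA", "KINB"], ["L1"])
        land = act.ActivityLandscape(
            scores=scores, layers={}, layer_mask=scores.astype(str),
            abundance_only=scores.isna())
        assert act.rank_kinases(land, "L1")[0] == "KINB"
        assert act.rank_kinases(land, "L1", annotations,
                                druggable_only=True) == ["KINA"]

    def test_unknown_cell_line(self):
        scores = df([[1.0]], ["KINA"], ["L1"])
        land = act.ActivityLandscape(scores, {}, scores.astype(str),
                                     scores.isna())
        with pytest.raises(KeyError, match="unknown cell line"):
            act.rank_kinases(land, "L99")

    def test_all_missing_line_gives_empty_ranking(self):
        scores = df([[np.nan]], ["KINA"], ["L1"])
        land = act.ActivityLandscape(scores, {}, scores.astype(str),
                                     scores.isna())
        assert act.rank_kinases(land, "L1") == []


class TestInvariants:
    def test_z_rows_mean_zero_sd_one(self, rng):
        vals = pd.DataFrame(rng.normal(size=(20, 8)))
        vals[rng.random(vals.shape) < 0.2] = np.nan
        z = act.zscore_rows(vals)
        informative = z.std(axis=1, ddof=1) > 0
        assert np.allclose(z.mean(axis=1, skipna=True), 0, atol=1e-9)
        assert np.allclose(z[informative].std(axis=1, ddof=1), 1, atol=1e-9)

    def test_score_invariant_to_sample_offsets(self, small_panel):
        # a loading-amount offset on one sample (x10^0.8 on the linear
        # scale) is removed by median-centring, so scores are unchanged
        proteome, phospho, ann, _, _ = small_panel
        s, _ = standard_postprocess(phospho)
        p1, _ = standard_postprocess(proteome)
        land1 = act.compute_landscape(p1, s.to_linear(), ann)
        shifted = proteome.copy()
        shifted.values.iloc[:, 0] *= 10.0 ** 0.8
        p2, _ = standard_postprocess(shifted)
        land2 = act.compute_landscape(p2, s.to_linear(), ann)
        a, b = land1.scores.to_numpy(), land2.scores.to_numpy()
        assert np.allclose(a[~np.isnan(a)], b[~np.isnan(b)], atol=1e-9)

    def test_planted_kinase_recovery_on_small_panel(self, small_panel):
        proteome, phospho, ann, _, truth = small_panel
        p, _ = standard_postprocess(proteome)
        s, _ = standard_postprocess(phospho)
        land = act.compute_landscape(p, s.to_linear(), ann)
        hits = total = 0
        for line, kinases in truth.active_kinases.items():
            top5 = act.rank_kinases(land, line)[:5]
            for k in kinases:
                total += 1
                hits += k in top5
        assert hits / total >= 0.9
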