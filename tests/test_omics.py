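"""Housekeeping normalisation, expression filter, DE, overlaps, pairing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import gutmotion as gm


def toy_matrix(counts: dict, groups: dict, housekeeping=("Actb", "B2m")) -> gm.CountMatrix:
    df = pd.DataFrame(counts).T  # feature -> {sample: value}
    return gm.CountMatrix(counts=df, groups=pd.Series(groups),
                          housekeeping=list(housekeeping))


@pytest.fixture
def small_matrix() -> gm.CountMatrix:
    samples = ["w1", "w2", "c1", "c2"]
    counts = {
        "Actb": dict(zip(samples, [1000.0, 1000, 1000, 1000])),
        "B2m": dict(zip(samples, [400.0, 400, 400, 400])),
        "miR-a": dict(zip(samples, [200.0, 220, 400, 440])),
        "miR-b": dict(zip(samples, [50.0, 55, 52, 48])),
    }
    groups = dict(zip(samples, ["WT", "WT", "case", "case"]))
    return toy_matrix(counts, groups)


class TestNormalizeCounts:
    def test_sample_scaling_is_exactly_inverted(self, small_matrix):
        scaled = gm.CountMatrix(
            counts=small_matrix.counts.assign(w1=small_matrix.counts["w1"] * 2),
            groups=small_matrix.groups, housekeeping=small_matrix.housekeeping)
        norm = gm.normalize_counts(scaled)
        ref = gm.normalize_counts(small_matrix)
        # the x2 sample rejoins the others exactly, up to the single global
        # level set by the across-sample housekeeping average
        ratio = (norm.counts / ref.counts).to_numpy()
        assert np.allclose(ratio, ratio.flat[0])
        assert np.allclose(norm.counts["w1"] / norm.counts["w2"],
                           ref.counts["w1"] / ref.counts["w2"])

    def test_idempotence(self, small_matrix):
        once = gm.normalize_counts(small_matrix)
        twice = gm.normalize_counts(once)
        assert np.allclose(once.counts, twice.counts)

    def test_known_scale_factors_recovered_exactly(self):
        base = pd.Series({"Actb": 1000.0, "B2m": 400.0, "miR-a": 300.0})
        scales = {"w1": 1.0, "w2": 1.5, "c1": 0.7, "c2": 1.0}
        counts = {f: {s: base[f] * k for s, k in scales.items()} for f in base.index}
        m = toy_matrix(counts, {"w1": "WT", "w2": "WT", "c1": "case", "c2": "case"})
        norm = gm.normalize_counts(m)
        # all samples collapse onto a common column after normalisation
        for f in base.index:
            vals = norm.counts.loc[f]
            assert np.allclose(vals, vals.iloc[0], rtol=0, atol=1e-9 * base[f])

    def test_zero_housekeeping_count_names_culprit(self, small_matrix):
        broken = small_matrix.counts.copy()
        broken.loc["B2m", "c1"] = 0.0
        m = gm.CountMatrix(counts=broken, groups=small_matrix.groups,
                           housekeeping=small_matrix.housekeeping)
        with pytest.raises(ValueError, match="B2m.*c1"):
            gm.normalize_counts(m)


class TestExpressionFilter:
    def test_boundary_is_inclusive(self, small_matrix):
        counts = small_matrix.counts.copy()
        counts.loc["miR-a"] = [99.9, 99.9, 99.9, 99.9]
        counts.loc["miR-b"] = [100.0, 100, 100, 100]
        m = gm.CountMatrix(counts=counts, groups=small_matrix.groups,
                           housekeeping=small_matrix.housekeeping)
        flags = gm.expression_filter(m, min_count=100)
        assert not flags["miR-a"] and flags["miR-b"]

    def test_zero_threshold_keeps_everything(self, small_matrix):
        assert gm.expression_filter(small_matrix, min_count=0).all()

    def test_survivors_non_increasing_in_min_count(self, spiked_matrix):
        norm, _, _ = spiked_matrix
        survivors = [int(gm.expression_filter(norm, mc).sum())
                     for mc in (0, 10, 100, 500, 5000)]
        assert all(a >= b for a, b in zip(survivors, survivors[1:]))


class TestDifferentialExpression:
    def test_identical_groups_are_null(self, small_matrix):
        counts = small_matrix.counts.copy()
        counts.loc["miR-a"] = [300.0, 300, 300, 300]
        m = gm.CountMatrix(counts=counts, groups=small_matrix.groups,
                           housekeeping=small_matrix.housekeeping)
        de = gm.differential_expression(m, min_count=0)
        row = de.loc["miR-a"]
        assert row["p_value"] == 1.0
        assert row["fold_change"] == pytest.approx(1.0)
        assert not row["significant"]

    def test_twofold_feature_direction_and_log2fc(self):
        samples = [f"w{i}" for i in range(3)] + [f"c{i}" for i in range(3)]
        rng = np.random.default_rng(0)
        jitter = rng.normal(0, 0.5, 6)
        counts = {
            "Actb": dict(zip(samples, [1000.0] * 6)),
            "B2m": dict(zip(samples, [400.0] * 6)),
            "miR-x": dict(zip(samples, np.array([100.0] * 3 + [200.0] * 3) + jitter)),
        }
        groups = dict(zip(samples, ["WT"] * 3 + ["case"] * 3))
        de = gm.differential_expression(toy_matrix(counts, groups), min_count=0)
        row = de.loc["miR-x"]
        assert row["direction"] == "up"
        assert row["log2fc"] == pytest.approx(1.0, abs=0.02)

    def test_zero_variance_unequal_means_flagged_missing(self, small_matrix):
        counts = small_matrix.counts.copy()
        counts.loc["miR-a"] = [100.0, 100, 200, 200]
        m = gm.CountMatrix(counts=counts, groups=small_matrix.groups,
                           housekeeping=small_matrix.housekeeping)
        de = gm.differential_expression(m, min_count=0)
        assert np.isnan(de.loc["miR-a", "p_value"])
        assert de.loc["miR-a", "degenerate"]

    def test_significant_implies_expressed(self, spiked_matrix):
        norm, _, _ = spiked_matrix
        de = gm.differential_expression(norm)
        assert (de.loc[de["significant"], "expressed"]).all()

    def test_p_values_stable_under_global_rescaling(self, spiked_matrix):
        norm, _, _ = spiked_matrix
        de1 = gm.differential_expression(norm)
        doubled = gm.CountMatrix(counts=norm.counts * 2, groups=norm.groups,
                                 housekeeping=norm.housekeeping)
        de2 = gm.differential_expression(gm.normalize_counts(doubled))
        expressed = de1["expressed"]
        assert np.allclose(de1.loc[expressed, "p_value"],
                           de2.loc[expressed, "p_value"], atol=1e-3)

    def test_spiked_features_recovered(self, spiked_matrix):
        norm, truth, design = spiked_matrix
        de = gm.differential_expression(norm)
        spiked = truth.index[truth["spiked"]]
        recovered = (de.loc[spiked, "significant"] & (de.loc[spiked, "direction"] == "up"))
        assert recovered.mean() >= 0.9


class TestSetOverlap:
    @pytest.mark.parametrize("a,b,expected", [
        ({"p1", "p2", "p3"}, {"p3", "p4"}, (2, 1, 1)),
        ({"p1"}, {"p2"}, (1, 1, 0)),
        (set(), {"p1"}, (0, 1, 0)),
    ])
    def test_partition_counts(self, a, b, expected):
        assert gm.set_overlap(a, b) == expected

    def test_si_li_sized_sets_partition(self):
        # sets sized like the two intestinal significant-protein lists
        shared = {f"s{i}" for i in range(13)}
        si = shared | {f"a{i}" for i in range(61)}
        li = shared | {f"b{i}" for i in range(134)}
        assert gm.set_overlap(si, li) == (61, 134, 13)

    @settings(max_examples=50, derandomize=True)
    @given(st.sets(st.integers(0, 50)), st.sets(st.integers(0, 50)))
    def test_partition_sums_to_union(self, a, b):
        a_only, b_only, both = gm.set_overlap(a, b)
        assert a_only + b_only + both == len(a | b)


class TestProportionSignificant:
    @pytest.mark.parametrize("n_sig,n_total,expected", [
        (74, 1044, 7),
        (147, 1044, 14),
        (0, 1044, 0),
        (15, 200, 8),  # .5 rounds up, not to even
    ])
    def test_rounding(self, n_sig, n_total, expected):
        assert gm.proportion_significant(n_sig, n_total) == expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            gm.proportion_significant(1, 0)
        with pytest.raises(ValueError):
            gm.proportion_significant(5, 4)


def de_stub(features, significant, direction) -> pd.DataFrame:
    return pd.DataFrame({
        "significant": [f in significant for f in features],
        "direction": [direction.get(f, "up") for f in features],
    }, index=pd.Index(features, name="feature"))


class TestCounterRegulationPairs:
    def test_single_valid_pair(self):
        mirna = de_stub(["m1"], {"m1"}, {"m1": "up"})
        protein = de_stub(["P1"], {"P1"}, {"P1": "down"})
        res = gm.counter_regulation_pairs(mirna, protein, {"m1": ["P1"]})
        assert (res.n_interactions, res.n_mirnas, res.n_proteins) == (1, 1, 1)

    def test_wrong_direction_is_excluded(self):
        mirna = de_stub(["m1"], {"m1"}, {"m1": "up"})
        protein = de_stub(["P1"], {"P1"}, {"P1": "up"})
        res = gm.counter_regulation_pairs(mirna, protein, {"m1": ["P1"]})
        assert res.n_interactions == 0

    def test_engineered_network_cardinalities(self):
        # 77 valid interactions over 31 up miRNAs and 25 down proteins,
        # buried among decoy map entries
        mirnas = [f"miR-{i}" for i in range(40)]
        proteins = [f"P{i}" for i in range(30)]
        up = set(mirnas[:31])
        down = set(proteins[:25])
        pairs = [(mirnas[i], proteins[i % 25]) for i in range(31)]
        extra = [(m, p) for m in mirnas[:31] for p in proteins[:25]
                 if (m, p) not in pairs]
        pairs += extra[:46]  # 31 + 46 = 77 distinct valid pairs
        decoys = [(mirnas[35], proteins[28]), (mirnas[36], proteins[1])]
        target_map = pd.DataFrame(pairs + decoys)
        mirna_de = de_stub(mirnas, up, {m: "up" for m in mirnas})
        protein_de = de_stub(proteins, down, {p: "down" for p in proteins})
        res = gm.counter_regulation_pairs(mirna_de, protein_de, target_map)
        assert (res.n_interactions, res.n_mirnas, res.n_proteins) == (77, 31, 25)

    def test_empty_map_warns(self):
        mirna = de_stub(["m1"], {"m1"}, {"m1": "up"})
        protein = de_stub(["P1"], {"P1"}, {"P1": "down"})
        with pytest.warns(UserWarning, match="empty target map"):
            res = gm.counter_regulation_pairs(mirna, protein, {})
        assert res.n_interactions == 0


class TestVolcanoTable:
    def test_guide_line_and_axis_conventions(self, tmp_path):
        de = pd.DataFrame({
            "log2fc": [0.0, 1.0, -2.0],
            "p_value": [0.05, 0.001, np.nan],
            "fold_change": [1.0, 2.0, 0.25],
            "significant": [False, True, False],
        }, index=["f1", "f2", "f3"])
        table = gm.volcano_table(de, alpha=0.05, out_png=tmp_path / "v.png")
        assert "f3" not in table.index  # missing p omitted
        assert table.loc["f1", "neg_log10_p"] == pytest.approx(-np.log10(0.05))
        assert table.loc["f1", "log2fc"] == 0.0
        assert (tmp_path / "v.png").exists()

    def test_spiked_features_sit_in_upper_right_quadrant(self, spiked_matrix):
        norm, truth, _ = spiked_matrix
        de = gm.differential_expression(norm)
        table = gm.volcano_table(de)
        spiked = truth.index[truth["spiked"]]
        sub = table.loc[table.index.intersection(spiked)]
        assert (sub["log2fc"] > 0).mean() > 0.95
        assert sub["neg_log10_p"].median() > -np.log10(0.05)


class TestCountMatrixIO:
    def test_tsv_round_trip(self, small_matrix, tmp_path):
        cpath, gpath = tmp_path / "counts.tsv", tmp_path / "groups.tsv"
        small_matrix.counts.to_csv(cpath, sep="\t")
        small_matrix.groups.to_csv(gpath, sep="\t", header=False)
        back = gm.read_counts_tsv(cpath, gpath, housekeeping=["Actb", "B2m"])
        assert np.allclose(back.counts, small_matrix.counts)
        assert list(back.groups.loc[back.counts.columns]) == \
            list(small_matrix.groups.loc[small_matrix.counts.columns])

    def test_matrix_validation(self, small_matrix):
        with pytest.raises(ValueError, match="two groups"):
            gm.CountMatrix(counts=small_matrix.counts,
                           groups=pd.Series({s: "WT" for s in small_matrix.counts.columns}),
                           housekeeping=["Actb"])
        with pytest.raises(ValueError, match="housekeeping"):
            gm.CountMatrix(counts=small_matrix.counts.drop(index="Actb"),
                           groups=small_matrix.groups, housekeeping=["Actb"])
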