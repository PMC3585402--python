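import numpy as np
import pandas as pd
import pytest

from circanet.motifs import (
    PWM,
    build_network,
    call_motif_targets,
    collapse_motif_groups,
    estimate_background,
    extract_promoter_coords,
    ortholog_group_motif_test,
    parse_jaspar,
    parse_transfac,
    reverse_complement,
    scan_promoter,
    tf_called_targets,
    tissue_specific_tfs,
)

JASPAR_TEXT = """\
>M1 test
A [ 8 0 0 2 ]
C [ 0 8 0 2 ]
G [ 0 0 8 2 ]
T [ 0 0 0 2 ]
>M2
1 0 0 0
0 1 0 0
0 0 1 0
0 0 0 1
"""

TRANSFAC_TEXT = """\
AC M0001
XX
ID EBOX_TEST
XX
P0 A C G T
01 10 0 0 0
02 0 10 0 0
03 0 0 10 0
04 0 0 0 10
XX
//
"""


class TestParsers:
    def test_jaspar_both_dialects(self):
        pwms = parse_jaspar(JASPAR_TEXT)
        assert [p.id for p in pwms] == ["M1", "M2"]
        assert pwms[0].length == 4
        assert pwms[0].consensus == "ACGA"
        assert pwms[1].consensus == "ACGT"

    def test_transfac_p0_block(self):
        pwms = parse_transfac(TRANSFAC_TEXT)
        assert len(pwms) == 1
        assert pwms[0].id == "M0001"
        assert pwms[0].consensus == "ACGT"

    def test_bad_matrix_shape_rejected(self):
        with pytest.raises(ValueError):
            PWM("bad", np.ones((3, 8)))


class TestPromoterCoords:
    def test_plus_strand_window(self):
        assert extract_promoter_coords(5000, "+", 100_000) == (4000, 5200)

    def test_minus_strand_mirror(self):
        assert extract_promoter_coords(5000, "-", 100_000) == (4800, 6000)

    def test_truncated_at_sequence_start(self):
        assert extract_promoter_coords(500, "+", 10_000) == (0, 700)

    def test_tss_outside_sequence_rejected(self):
        with pytest.raises(ValueError):
            extract_promoter_coords(10_000, "+", 10_000)


def brute_force_best_score(pwm: PWM, seq: str, background) -> float:
    """All-offsets, both-strands scan in pure Python."""
    lo = pwm.log_odds(np.asarray(background))
    bg = np.asarray(background)
    expected = (bg[:, None] * lo).sum(axis=0)
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}

    def score(s):
        best = -np.inf
        for off in range(len(s) - pwm.length + 1):
            total = 0.0
            for j, base in enumerate(s[off : off + pwm.length]):
                total += lo[idx[base], j] if base in idx else expected[j]
            best = max(best, total)
        return best

    return max(score(seq), score(reverse_complement(seq)))


class TestScanning:
    @pytest.fixture()
    def pwm(self):
        rng = np.random.default_rng(0)
        cons = rng.integers(0, 4, 10)
        counts = np.full((4, 10), 1.0)
        counts[cons, np.arange(10)] = 50.0
        return PWM("M", counts, pseudocount=0.01)

    def test_planted_consensus_reaches_max_score(self, pwm):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 200))
        planted = seq[:60] + pwm.consensus + seq[70:]
        score = scan_promoter(pwm, planted)
        assert score == pytest.approx(pwm.max_score(), rel=1e-9)

    def test_reverse_complement_symmetry(self, pwm):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), 300))
        assert scan_promoter(pwm, seq) == pytest.approx(
            scan_promoter(pwm, reverse_complement(seq)), rel=1e-12
        )

    def test_matches_brute_force_oracle(self, pwm):
        rng = np.random.default_rng(3)
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        seq = "".join(rng.choice(list("ACGTN"), 200, p=[0.28, 0.18, 0.18, 0.28, 0.08]))
        assert scan_promoter(pwm, seq, bg) == pytest.approx(
            brute_force_best_score(pwm, seq, bg), rel=1e-10
        )

    def test_sequence_shorter_than_motif_rejected(self, pwm):
        with pytest.raises(ValueError):
            scan_promoter(pwm, "ACGT")

    def test_reported_position_and_strand(self, pwm):
        rng = np.random.default_rng(4)
        seq = list(rng.choice(list("ACGT"), 200))
        site = reverse_complement(pwm.consensus)
        seq[100:110] = list(site)
        _, pos, strand = scan_promoter(pwm, "".join(seq), return_position=True)
        assert (pos, strand) == (100, "-")


class TestGroupTest:
    def test_group_at_background_mean_is_null(self):
        rng = np.random.default_rng(5)
        bg = rng.normal(10, 2, 500)
        z, p = ortholog_group_motif_test([bg.mean()] * 5, bg)
        assert z == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(0.5, abs=1e-9)

    def test_antisymmetry_under_swap(self):
        rng = np.random.default_rng(6)
        bg = rng.normal(0, 1, 1000)
        group = bg.mean() + np.array([1.0, 1.2, 0.8, 1.1, 0.9])
        z_hi, _ = ortholog_group_motif_test(group, bg)
        z_lo, _ = ortholog_group_motif_test(2 * bg.mean() - group, bg)
        assert z_hi == pytest.approx(-z_lo, rel=1e-9)

    def test_zero_background_variance_rejected(self):
        with pytest.raises(ValueError):
            ortholog_group_motif_test([1.0], [2.0, 2.0, 2.0])


class TestSelectionRules:
    def _tests_frame(self):
        rows = []
        for m in range(30):
            rows.append({"motif": f"M{m:02d}", "gene": "gA", "z": 3.0, "p": 0.001 * (m + 1)})
        return pd.DataFrame(rows)

    def test_top_gene_rank_cutoff(self):
        calls = call_motif_targets(self._tests_frame(), p_max=0.05, top_gene=20)
        assert len(calls) == 20
        assert calls["rank_in_gene"].max() == 20
        # rank 25 candidate (p = 0.026 < 0.05) dropped by rank rule alone
        assert "M24" not in set(calls["motif"])

    def test_p_threshold_applies_before_rank(self):
        calls = call_motif_targets(self._tests_frame(), p_max=0.01, top_gene=20)
        assert set(calls["motif"]) == {f"M{m:02d}" for m in range(9)}

    def test_retention_monotone_in_thresholds(self):
        rng = np.random.default_rng(7)
        rows = [
            {"motif": f"M{m}", "gene": f"g{g}", "z": 1.0, "p": rng.uniform(0, 0.05)}
            for m in range(10)
            for g in range(10)
        ]
        df = pd.DataFrame(rows)
        loose = set(map(tuple, call_motif_targets(df, 0.02, 8)[["motif", "gene"]].to_numpy()))
        tight_p = set(map(tuple, call_motif_targets(df, 0.01, 8)[["motif", "gene"]].to_numpy()))
        tight_k = set(map(tuple, call_motif_targets(df, 0.02, 4)[["motif", "gene"]].to_numpy()))
        assert tight_p <= loose and tight_k <= loose

    def test_group_collapse_min_rule(self):
        calls = pd.DataFrame(
            [
                {"motif": "M1a", "gene": "g", "z": 2.0, "p": 0.005},
                {"motif": "M1b", "gene": "g", "z": 5.0, "p": 0.02},
                {"motif": "M2", "gene": "g", "z": 1.0, "p": 0.5},
            ]
        )
        grouped = collapse_motif_groups(calls, {"M1a": "G1", "M1b": "G1"})
        g1 = grouped[grouped["motif_group"] == "G1"].iloc[0]
        assert g1["p"] == 0.005 and g1["z"] == 2.0 and g1["motif"] == "M1a"
        # ungrouped motif forms its own singleton group
        assert (grouped["motif_group"] == "M2").sum() == 1


class TestNetwork:
    def test_top_five_targets_per_motif(self):
        calls = pd.DataFrame(
            [
                {"motif_group": "G1", "gene": f"g{i}", "motif": "M", "z": 2.0, "p": 0.001 * (i + 1)}
                for i in range(7)
            ]
        )
        tf_map = pd.DataFrame([{"tf": "tf1", "motif_group": "G1"}])
        net = build_network(calls, tf_map, p_max=0.01, top_targets=5)
        targets = tf_called_targets(net, "tf1")
        assert targets == {f"g{i}" for i in range(5)}

    def test_empty_calls_leave_only_binding_edges(self):
        tf_map = pd.DataFrame([{"tf": "tf1", "motif_group": "G1"}])
        net = build_network(pd.DataFrame(columns=["motif_group", "gene", "motif", "z", "p"]), tf_map)
        assert set(net.edges) == {("tf1", "G1")}

    def test_tissue_specific_tf_flagged_by_hypergeometric(self):
        # 7 of 10 targets in the TF's tissue against a 5% background rate
        calls = pd.DataFrame(
            [
                {"motif_group": "G1", "gene": f"g{i}", "motif": "M", "z": 3.0, "p": 1e-4}
                for i in range(10)
            ]
        )
        tf_map = pd.DataFrame([{"tf": "tf1", "motif_group": "G1"}])
        net = build_network(calls, tf_map, top_targets=10)
        atlas = {f"g{i}": ("liver" if i < 7 else "retina") for i in range(10)}
        atlas.update({f"bg{i}": ("liver" if i < 10 else "other") for i in range(200)})
        atlas["tf1"] = "liver"
        table = tissue_specific_tfs(net, atlas)
        assert bool(table.loc["tf1", "tissue_specific"])
        assert table.loc["tf1", "p"] < 1e-4

    def test_background_matched_targets_not_flagged(self):
        calls = pd.DataFrame(
            [
                {"motif_group": "G1", "gene": f"g{i}", "motif": "M", "z": 3.0, "p": 1e-4}
                for i in range(10)
            ]
        )
        tf_map = pd.DataFrame([{"tf": "tf1", "motif_group": "G1"}])
        net = build_network(calls, tf_map, top_targets=10)
        # targets hit 'liver' at exactly the background rate (50%)
        atlas = {f"g{i}": ("liver" if i < 5 else "retina") for i in range(10)}
        atlas.update({f"bg{i}": ("liver" if i % 2 else "retina") for i in range(200)})
        atlas["tf1"] = "liver"
        table = tissue_specific_tfs(net, atlas)
        assert not bool(table.loc["tf1", "tissue_specific"])

    def test_tf_missing_from_atlas_skipped_with_warning(self):
        tf_map = pd.DataFrame([{"tf": "ghost", "motif_group": "G1"}])
        net = build_network(pd.DataFrame(columns=["motif_group", "gene", "motif", "z", "p"]), tf_map)
        with pytest.warns(UserWarning, match="absent"):
            table = tissue_specific_tfs(net, {"other": "liver"})
        assert "ghost" not in table.index


def test_estimate_background_counts_only_acgt():
    freqs = estimate_background(["AACC", "GGTTNN"])
    assert freqs.sum() == pytest.approx(1.0)
    assert freqs[0] == pytest.approx(0.25)
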