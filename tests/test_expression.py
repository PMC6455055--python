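import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirkit.expression import (
    assign_trend,
    class_ratio_percent,
    ddct,
    differential_expression,
    replicate_correlation,
    summarize_trends,
    tissue_specific,
    tpm_normalize,
)
from mirkit.tables import TISSUE_SPECIFIC


class TestTpm:
    def test_printed_ratio_cell(self):
        assert class_ratio_percent(145547, 13025496) == 1.12

    def test_simple_tpm(self):
        counts = pd.DataFrame({"L": [5]}, index=["m1"])
        tpm = tpm_normalize(counts, {"L": 2_000_000})
        assert tpm.loc["m1", "L"] == 2.5

    def test_library_tpm_sums_to_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame({"L": rng.integers(0, 500, size=50)})
        total = int(counts["L"].sum())
        tpm = tpm_normalize(counts, {"L": total})
        assert tpm["L"].sum() == pytest.approx(1e6)

    def test_linearity(self):
        counts = pd.DataFrame({"L": [5, 10]}, index=["m1", "m2"])
        tpm = tpm_normalize(counts, {"L": 1000})
        assert tpm.loc["m2", "L"] == 2 * tpm.loc["m1", "L"]

    def test_zero_total_fails(self):
        counts = pd.DataFrame({"L": [5]})
        with pytest.raises(ValueError):
            tpm_normalize(counts, {"L": 0})


class TestReplicateCorrelation:
    def test_identical_replicates(self):
        tpm = pd.DataFrame({"t-1": [1.0, 5, 9], "t-2": [1.0, 5, 9]})
        out = replicate_correlation(tpm, {"t-1": "t", "t-2": "t"})
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_scalar_multiple_not_unity_on_log_scale_but_close(self):
        # log2(TPM+1) of a scalar multiple is affine only approximately;
        # exact unity holds for log2(TPM) which is recovered at large TPM
        tpm = pd.DataFrame({"t-1": [100.0, 800, 6400], "t-2": [200.0, 1600, 12800]})
        out = replicate_correlation(tpm, {"t-1": "t", "t-2": "t"})
        assert out["r"].iloc[0] == pytest.approx(1.0, abs=1e-4)

    def test_constant_vector_reported_missing(self):
        tpm = pd.DataFrame({"t-1": [1.0, 1.0], "t-2": [1.0, 2.0]})
        out = replicate_correlation(tpm, {"t-1": "t", "t-2": "t"})
        assert math.isnan(out["r"].iloc[0])

    def test_within_tissue_exceeds_between_on_simulation(self, small_study):
        cfg, bundle, truth, paths = small_study
        counts = pd.DataFrame(
            {
                f"{t}-{r}": [round(truth.tissue_means[m][t]) for m in truth.true_mirnas]
                for t in cfg.tissues
                for r in (1, 2, 3)
            },
            index=truth.true_mirnas,
        )
        tissue_of = {c: c.rsplit("-", 1)[0] for c in counts.columns}
        totals = {c: cfg.reads_per_library for c in counts.columns}
        tpm = tpm_normalize(counts, totals)
        within = replicate_correlation(tpm, tissue_of)["r"].mean()
        x = np.log2(tpm["sBud-1"] + 1)
        y = np.log2(tpm["sS2-1"] + 1)
        between = stats.pearsonr(x, y).statistic
        assert within > between


class TestDifferentialExpression:
    TOTALS = {"a1": 1_000_000, "b1": 1_000_000}

    def test_equal_counts_symmetric(self):
        counts = pd.DataFrame({"a1": [100], "b1": [100]}, index=["m"])
        res = differential_expression(counts, ["a1"], ["b1"], self.TOTALS)[0]
        assert res.log2_fold_change == 0.0
        assert not res.significant

    def test_present_absent_significant(self):
        counts = pd.DataFrame({"a1": [200], "b1": [0]}, index=["m"])
        res = differential_expression(counts, ["a1"], ["b1"], self.TOTALS)[0]
        assert res.significant
        # oracle: exact doubled hypergeometric tail
        rv = stats.hypergeom(2_000_000, 200, 1_000_000)
        assert res.p_value == pytest.approx(min(1.0, 2 * rv.sf(199)))

    def test_swap_antisymmetric(self):
        counts = pd.DataFrame({"a1": [150], "b1": [30]}, index=["m"])
        fwd = differential_expression(counts, ["a1"], ["b1"], self.TOTALS)[0]
        rev = differential_expression(counts, ["b1"], ["a1"], self.TOTALS)[0]
        assert fwd.log2_fold_change == pytest.approx(-rev.log2_fold_change)
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_replicate_permutation_invariance(self):
        totals = {"a1": 10_000, "a2": 20_000, "b1": 15_000}
        counts = pd.DataFrame({"a1": [5], "a2": [50], "b1": [10]}, index=["m"])
        r1 = differential_expression(counts, ["a1", "a2"], ["b1"], totals)[0]
        r2 = differential_expression(counts, ["a2", "a1"], ["b1"], totals)[0]
        assert r1.p_value == r2.p_value
        assert r1.log2_fold_change == r2.log2_fold_change

    def test_threshold_needs_both_p_and_lfc(self):
        # huge counts, tiny fold change: significant p but small lfc
        counts = pd.DataFrame({"a1": [120_000], "b1": [100_000]}, index=["m"])
        res = differential_expression(counts, ["a1"], ["b1"], self.TOTALS)[0]
        assert res.p_value < 0.05
        assert abs(res.log2_fold_change) < 2
        assert not res.significant


class TestTissueSpecific:
    LIBS = [f"{t}-{r}" for t in ("sBud", "sL1", "sL2", "sS1", "sS2") for r in (1, 2, 3)]
    TISSUE_OF = {l: l.rsplit("-", 1)[0] for l in LIBS}

    def _matrix(self, rows):
        return pd.DataFrame(rows, columns=self.LIBS)

    def test_leaf_only_counts(self):
        row = [0] * 15
        row[3] = row[4] = 5  # sL1-1, sL1-2
        counts = pd.DataFrame([row], columns=self.LIBS, index=["m"])
        specific, _ = tissue_specific(counts, self.TISSUE_OF)
        assert specific["leaf"] == ["m"]

    def test_leaf_and_stem_not_specific(self):
        row = [0] * 15
        row[3] = row[4] = 5  # sL1
        row[12] = row[13] = 5  # sS2
        counts = pd.DataFrame([row], columns=self.LIBS, index=["m"])
        specific, venn = tissue_specific(counts, self.TISSUE_OF)
        assert all("m" not in v for v in specific.values())
        assert "m" in venn[frozenset({"leaf", "stem"})]

    def test_single_replicate_not_expressed(self):
        row = [0] * 15
        row[3] = 5  # only sL1-1
        counts = pd.DataFrame([row], columns=self.LIBS, index=["m"])
        specific, venn = tissue_specific(counts, self.TISSUE_OF)
        assert venn == {}

    def test_printed_membership_counts(self):
        rows, index = [], []
        offsets = {"bud": (0,), "leaf": (3, 6), "stem": (9, 12)}
        for cls, mirnas in TISSUE_SPECIFIC.items():
            for m in mirnas:
                row = [0] * 15
                for off in offsets[cls]:
                    for r in range(3):
                        row[off + r] = 10
                rows.append(row)
                index.append(m)
        counts = pd.DataFrame(rows, columns=self.LIBS, index=index)
        specific, _ = tissue_specific(counts, self.TISSUE_OF)
        assert len(specific["bud"]) == 5
        assert len(specific["leaf"]) == 31
        assert len(specific["stem"]) == 28


class TestTrends:
    def test_double_down(self):
        a = assign_trend("m", [100, 40, 10])
        assert a.signature == (-1, -1)
        assert a.trend_class == "down"
        assert a.profile_index == 0

    def test_flat_excluded(self):
        a = assign_trend("m", [10, 10, 10])
        assert a.trend_class == "flat"
        assert a.profile_index is None

    def test_peak(self):
        a = assign_trend("m", [10, 100, 10])
        assert a.signature == (1, -1)
        assert a.trend_class == "peak"

    def test_rescaling_invariance(self):
        base = assign_trend("m", [10.0, 40.0, 20.0])
        scaled = assign_trend("m", [1000.0, 4000.0, 2000.0])
        assert base.signature == scaled.signature

    def test_summary_percentages(self):
        assignments = []
        for sig, n in [((-1, -1), 75), ((-1, 0), 67), ((0, -1), 15),
                       ((1, 1), 40), ((1, 0), 12), ((0, 1), 1),
                       ((1, -1), 9), ((-1, 1), 7)]:
            means = {
                (-1, -1): [100, 10, 1], (-1, 0): [100, 10, 10],
                (0, -1): [100, 100, 10], (1, 1): [1, 10, 100],
                (1, 0): [10, 100, 100], (0, 1): [10, 10, 100],
                (1, -1): [10, 100, 10], (-1, 1): [100, 10, 100],
            }[sig]
            for i in range(n):
                assignments.append(assign_trend(f"m{sig}{i}", means))
        summary = summarize_trends(assignments)
        assert summary["total"] == 226
        assert summary["percent"]["down"] == 69.5

    def test_all_up(self):
        assignments = [assign_trend(f"m{i}", [1, 10, 100]) for i in range(4)]
        assert summarize_trends(assignments)["percent"]["up"] == 100.0

    def test_recovers_planted_signatures(self, small_study):
        cfg, bundle, truth, _ = small_study
        scale = 1e6 / cfg.reads_per_library
        groups = {"G1": ("sBud", "sL1", "sL2"), "G2": ("sBud", "sS1", "sS2")}
        for mid in truth.true_mirnas:
            for grp, tissues in groups.items():
                means = [round(truth.tissue_means[mid][t]) * scale for t in tissues]
                a = assign_trend(mid, means, grp)
                assert a.signature == tuple(truth.true_trend[mid][grp])


class TestDdct:
    def test_zero_ddct(self):
        assert ddct(20, 15, 22, 17) == 1.0

    def test_one_cycle(self):
        assert ddct(21, 15, 22, 17) == 0.5

    def test_minus_two(self):
        assert ddct(18, 15, 22, 17) == 4.0

    def test_rejects_nan(self):
        with pytest.raises(ValueError):
            ddct(float("nan"), 1, 2, 3)
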