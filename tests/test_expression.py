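"""TPM, median-of-medians tissue profiles and the expressed-gene rules."""

import numpy as np
import pandas as pd
import pytest

from geneatlas.expression import (
    SampleTable,
    compute_tpm,
    flag_expressed,
    flag_expressed_per_sex,
    tissue_medians,
)


def sheet(rows):
    return SampleTable(pd.DataFrame(
        rows, columns=["sample_id", "tissue", "project", "sex"]
    ))


class TestTpm:
    def test_single_gene_gets_the_whole_million(self):
        counts = pd.DataFrame({"s1": [50]}, index=["g1"])
        tpm = compute_tpm(counts, pd.Series({"g1": 1_000}))
        assert tpm.loc["g1", "s1"] == pytest.approx(1e6)

    def test_length_normalization_hand_case(self):
        counts = pd.DataFrame({"s1": [100, 100]}, index=["g1", "g2"])
        tpm = compute_tpm(counts, pd.Series({"g1": 1_000, "g2": 2_000}))
        assert tpm.loc["g1", "s1"] == pytest.approx(666_666.6667)
        assert tpm.loc["g2", "s1"] == pytest.approx(333_333.3333)

    def test_columns_sum_to_one_million(self, rng):
        counts = pd.DataFrame(
            rng.poisson(50, size=(30, 5)),
            index=[f"g{i}" for i in range(30)],
        )
        lengths = pd.Series(rng.integers(200, 5_000, 30).astype(float),
                            index=counts.index)
        assert np.allclose(compute_tpm(counts, lengths).sum(axis=0), 1e6)

    def test_invariant_to_sample_depth(self, rng):
        counts = pd.DataFrame(
            rng.poisson(50, size=(20, 1)), index=[f"g{i}" for i in range(20)]
        )
        lengths = pd.Series(rng.integers(200, 5_000, 20).astype(float),
                            index=counts.index)
        assert np.allclose(
            compute_tpm(counts, lengths), compute_tpm(counts * 7, lengths)
        )

    def test_zero_length_gene_rejected(self):
        counts = pd.DataFrame({"s1": [1]}, index=["g1"])
        with pytest.raises(ValueError):
            compute_tpm(counts, pd.Series({"g1": 0}))

    def test_all_zero_sample_flagged_and_kept_zero(self):
        counts = pd.DataFrame({"s1": [5], "s2": [0]}, index=["g1"])
        with pytest.warns(UserWarning, match="zero total"):
            tpm = compute_tpm(counts, pd.Series({"g1": 1_000}))
        assert tpm.loc["g1", "s2"] == 0.0


class TestTissueMedians:
    def test_plain_median_single_project(self):
        tpm = pd.DataFrame({"a": [1.0], "b": [3.0], "c": [5.0]}, index=["g1"])
        st = sheet([("a", "liver", "P1", "M"), ("b", "liver", "P1", "F"),
                    ("c", "liver", "P1", "M")])
        assert tissue_medians(tpm, st).loc["g1", "liver"] == 3.0

    def test_median_of_project_medians(self):
        tpm = pd.DataFrame(
            {"a": [1.0], "b": [3.0], "c": [6.0], "d": [6.0]}, index=["g1"]
        )  # P1 median 2, P2 median 6 -> tissue median 4
        st = sheet([("a", "liver", "P1", "M"), ("b", "liver", "P1", "F"),
                    ("c", "liver", "P2", "M"), ("d", "liver", "P2", "F")])
        assert tissue_medians(tpm, st).loc["g1", "liver"] == 4.0

    def test_unbalanced_projects_weighted_equally(self):
        # 10 samples at 2 TPM in P1 vs 2 samples at 6 TPM in P2
        cols = {f"p1_{i}": [2.0] for i in range(10)}
        cols.update({"p2_0": [6.0], "p2_1": [6.0]})
        tpm = pd.DataFrame(cols, index=["g1"])
        rows = [(f"p1_{i}", "liver", "P1", "M") for i in range(10)]
        rows += [("p2_0", "liver", "P2", "F"), ("p2_1", "liver", "P2", "F")]
        assert tissue_medians(tpm, sheet(rows)).loc["g1", "liver"] == 4.0

    def test_invariant_to_sample_order_and_project_duplication(self, rng):
        genes = [f"g{i}" for i in range(5)]
        tpm = pd.DataFrame(rng.uniform(0, 10, (5, 6)), index=genes,
                           columns=[f"s{i}" for i in range(6)])
        rows = [(f"s{i}", "liver" if i < 3 else "brain", "P1", "M")
                for i in range(6)]
        st = sheet(rows)
        base = tissue_medians(tpm, st)
        shuffled = st.frame.sample(frac=1, random_state=0)
        assert tissue_medians(tpm, SampleTable(shuffled)).equals(base)
        # appending a copy of P1's samples under new ids changes nothing
        dup_tpm = pd.concat(
            [tpm, tpm.rename(columns=lambda c: c + "_dup")], axis=1
        )
        dup_rows = rows + [(f"s{i}_dup", "liver" if i < 3 else "brain",
                            "P1", "M") for i in range(6)]
        assert tissue_medians(dup_tpm, sheet(dup_rows)).equals(base)


def _layers(counts, tpm_val=None, tmm_val=None):
    """Convenience: build tpm/tmm layers sharing counts' shape."""
    tpm = counts.astype(float) if tpm_val is None else counts * 0 + tpm_val
    tmm = tpm if tmm_val is None else counts * 0 + tmm_val
    return tpm, tmm


class TestExpressedFlag:
    def test_all_zero_gene_not_expressed(self):
        counts = pd.DataFrame(
            0, index=["g1"], columns=["a", "b", "c", "d"]
        )
        st = sheet([(s, "liver", "P1", "M") for s in counts.columns])
        tpm, tmm = _layers(counts)
        medians = tissue_medians(tpm, st)
        out = flag_expressed(medians, counts, tpm, tmm, st)
        assert not out.loc["g1", "expressed"]
        assert out.loc["g1", "category"] == "lt_0.1"

    def test_three_of_four_passing_samples_qualifies(self):
        counts = pd.DataFrame([[10, 10, 10, 0]], index=["g1"],
                              columns=["a", "b", "c", "d"])
        tpm = pd.DataFrame([[0.5, 0.5, 0.5, 0.0]], index=["g1"],
                           columns=counts.columns)
        st = sheet([(s, "liver", "P1", "M") for s in counts.columns])
        medians = tissue_medians(tpm, st)
        out = flag_expressed(medians, counts, tpm, tpm, st)
        assert out.loc["g1", "expressed"]
        assert out.loc["g1", "category"] == "from_0.1_to_1"

    def test_high_median_but_one_of_four_samples_fails(self):
        # only one sample passes the (reads, TPM, TMM) triple: not expressed
        counts = pd.DataFrame([[20, 2, 2, 2]], index=["g1"],
                              columns=["a", "b", "c", "d"])
        tpm = pd.DataFrame([[5.0, 5.0, 5.0, 5.0]], index=["g1"],
                           columns=counts.columns)
        st = sheet([(s, "liver", "P1", "M") for s in counts.columns])
        medians = tissue_medians(tpm, st)
        out = flag_expressed(medians, counts, tpm, tpm, st)
        assert not out.loc["g1", "expressed"]
        assert out.loc["g1", "category"] == "ge_1"

    def test_category_thresholds(self):
        medians = pd.DataFrame(
            {"liver": [0.05, 0.5, 2.0]}, index=["lo", "mid", "hi"]
        )
        counts = pd.DataFrame(
            [[10]] * 3, index=medians.index, columns=["a"]
        )
        st = sheet([("a", "liver", "P1", "M")])
        tpm, tmm = _layers(counts, 1.0)
        out = flag_expressed(medians, counts, tpm, tmm, st)
        assert list(out["category"]) == ["lt_0.1", "from_0.1_to_1", "ge_1"]

    def test_monotone_in_counts(self, rng):
        genes = [f"g{i}" for i in range(20)]
        cols = [f"s{i}" for i in range(8)]
        counts = pd.DataFrame(rng.poisson(8, (20, 8)), index=genes,
                              columns=cols)
        lengths = pd.Series(1_000.0, index=genes)
        st = sheet([(c, "liver" if i < 4 else "brain", "P1", "M")
                    for i, c in enumerate(cols)])

        def flags(c):
            tpm = compute_tpm(c, lengths)
            med = tissue_medians(tpm, st)
            return flag_expressed(med, c, tpm, tpm, st)["expressed"]

        base = flags(counts)
        for _ in range(10):
            bumped = counts.copy()
            g = rng.integers(20)
            s = rng.integers(8)
            bumped.iloc[g, s] += int(rng.integers(1, 50))
            after = flags(bumped)
            gid = genes[g]
            assert not (base[gid] and not after[gid])


class TestPerSexFlag:
    def _design(self, n_per_sex=8):
        cols = [f"m{i}" for i in range(n_per_sex)] + \
               [f"f{i}" for i in range(n_per_sex)]
        rows = [(c, "liver", "P1", "M" if c.startswith("m") else "F")
                for c in cols]
        return cols, sheet(rows)

    def test_one_sex_passing_is_enough(self):
        cols, st = self._design()
        counts = pd.DataFrame([[10] * 8 + [0] * 8], index=["g1"], columns=cols)
        tpm, tmm = _layers(counts, 1.0)
        assert flag_expressed_per_sex(counts, tpm, tmm, st, "liver", "P1")["g1"]

    def test_75pct_in_each_sex_fails(self):
        cols, st = self._design()
        row = [10] * 6 + [0] * 2 + [10] * 6 + [0] * 2
        counts = pd.DataFrame([row], index=["g1"], columns=cols)
        tpm, tmm = _layers(counts, 1.0)
        assert not flag_expressed_per_sex(
            counts, tpm, tmm, st, "liver", "P1"
        )["g1"]

    def test_all_samples_passing(self):
        cols, st = self._design()
        counts = pd.DataFrame([[10] * 16], index=["g1"], columns=cols)
        tpm, tmm = _layers(counts, 1.0)
        assert flag_expressed_per_sex(counts, tpm, tmm, st, "liver", "P1")["g1"]

    def test_fewer_than_eight_per_sex_is_ineligible(self):
        cols, st = self._design(n_per_sex=4)
        counts = pd.DataFrame([[10] * 8], index=["g1"], columns=cols)
        tpm, tmm = _layers(counts, 1.0)
        with pytest.raises(ValueError, match="liver"):
            flag_expressed_per_sex(counts, tpm, tmm, st, "liver", "P1")
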