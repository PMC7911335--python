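"""The trace engine, its config, and the downstream analyses."""

import numpy as np
import pytest

from homodist.alignment import Alignment
from homodist.core import (
    HomoDistError,
    HomoDistTrace,
    MethodScores,
    RunConfig,
    TraceStep,
    ci_distance_correlation,
    delimit_hi_groups,
    find_center,
    first_homoplasy_step,
    order_by_center_distance,
    run_homodist,
    trace_from_tsv,
)
from homodist.distances import DistanceMatrix

from oracles import pearson_r


def make_dm(labels, rows):
    return DistanceMatrix(tuple(labels), np.array(rows, dtype=float))


def synthetic_trace(hi_series, maxd_series=None, method="nj"):
    """Assemble a trace directly from HI/MaxD series (for analysis tests)."""
    n = len(hi_series)
    if maxd_series is None:
        maxd_series = [0.1 * (i + 1) for i in range(n)]
    steps = []
    series = [f"s{i}" for i in range(n + 3)]
    for i, (hi, maxd) in enumerate(zip(hi_series, maxd_series)):
        ci = 1.0 - hi
        sc = MethodScores(
            S=100, M=int(round(100 * ci)), G=150, ci=ci, ri=None, hi=hi,
            rci=None, shi=0.0 if maxd == 0 else hi / maxd,
        )
        steps.append(
            TraceStep(
                step_index=i + 1,
                added_taxon=series[i + 3],
                taxa=tuple(series[: i + 4]),
                dis_cen=maxd * 0.8,
                max_d=maxd,
                scores={method: sc},
            )
        )
    cfg = RunConfig(methods=(method,))
    return HomoDistTrace(
        center=series[0], series=tuple(series), steps=tuple(steps), config=cfg
    )


class TestRunConfig:
    def test_manual_center_required(self):
        with pytest.raises(HomoDistError, match="center"):
            RunConfig(auto_center=False)

    def test_bad_model_rejected(self):
        with pytest.raises(HomoDistError, match="unsupported model"):
            RunConfig(model="GTR")

    def test_bad_method_rejected(self):
        with pytest.raises(HomoDistError, match="tree methods"):
            RunConfig(methods=("nj", "bionj"))

    def test_from_file_classic_names(self, tmp_path):
        p = tmp_path / "cfg"
        p.write_text("autCen = False\ndefCen = 2\ndistmodel = K80\n# comment\n")
        cfg = RunConfig.from_file(p)
        assert cfg.auto_center is False
        assert cfg.center == 2
        assert cfg.model == "K80"

    def test_from_file_unknown_key(self, tmp_path):
        p = tmp_path / "cfg"
        p.write_text("speed = fast\n")
        with pytest.raises(HomoDistError, match="unknown config key"):
            RunConfig.from_file(p)


class TestFindCenter:
    def test_lowest_row_mean_wins(self):
        D = make_dm("abc", [[0, 0.1, 0.1], [0.1, 0, 0.06], [0.1, 0.06, 0]])
        assert find_center(D) == "b"

    def test_tie_goes_to_input_order(self):
        D = make_dm("abc", [[0, 0.2, 0.2], [0.2, 0, 0.2], [0.2, 0.2, 0]])
        assert find_center(D) == "a"

    def test_star_hub_is_center(self):
        # hub at distance r from everyone; satellites at 2r from each other
        labels = ("hub", "s1", "s2", "s3")
        d = np.full((4, 4), 0.4)
        d[0, :] = d[:, 0] = 0.2
        np.fill_diagonal(d, 0)
        D = DistanceMatrix(labels, d)
        means = {lab: d[i][d[i] > 0].mean() for i, lab in enumerate(labels)}
        assert find_center(D) == min(means, key=means.get) == "hub"

    def test_undefined_cells_rejected(self):
        d = np.array([[0, np.nan], [np.nan, 0]])
        D = DistanceMatrix(("a", "b"), d, (("a", "b"),))
        with pytest.raises(HomoDistError, match="undefined"):
            find_center(D)


class TestOrdering:
    def test_sorted_by_distance_from_center(self):
        D = make_dm("cab", [[0, 0.3, 0.1], [0.3, 0, 0.2], [0.1, 0.2, 0]])
        assert order_by_center_distance(D, "c") == ("c", "b", "a")

    def test_ties_keep_input_order(self):
        D = make_dm("cxy", [[0, 0.2, 0.2], [0.2, 0, 0.1], [0.2, 0.1, 0]])
        assert order_by_center_distance(D, "c") == ("c", "x", "y")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_sort(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        d = rng.uniform(0.05, 0.9, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        labels = tuple(f"z{i}" for i in range(n))
        D = DistanceMatrix(labels, d)
        got = order_by_center_distance(D, "z0")
        expected = ("z0",) + tuple(
            sorted(labels[1:], key=lambda l: d[0, labels.index(l)])
        )
        assert got == expected


class TestRunHomodist:
    def test_four_taxa_single_step(self):
        aln = Alignment(
            ("a", "b", "c", "d"), ("ACGTAC", "ACGTAA", "ACGAAA", "ACCAAA")
        )
        trace = run_homodist(aln, RunConfig(model="raw"))
        assert len(trace.steps) == 1
        assert set(trace.steps[0].taxa) == {"a", "b", "c", "d"}

    def test_too_few_taxa(self):
        aln = Alignment(("a", "b", "c"), ("AC", "AG", "AT"))
        with pytest.raises(HomoDistError, match=">= 4"):
            run_homodist(aln, RunConfig(model="raw"))

    def test_fixture_series_and_detection(self, convergent_fixture):
        fx = convergent_fixture
        trace = run_homodist(fx.alignment, RunConfig(model="raw"))
        assert trace.center == "t0"
        assert trace.series == fx.expected_series
        assert len(trace.steps) == len(fx.labels) - 3
        for st, (s, m) in zip(trace.steps, fx.expected_sm):
            assert (st.scores["nj"].S, st.scores["nj"].M) == (s, m)

    def test_monotone_discen_and_maxd(self, convergent_fixture):
        trace = run_homodist(convergent_fixture.alignment, RunConfig(model="raw"))
        discen = [st.dis_cen for st in trace.steps]
        maxd = [st.max_d for st in trace.steps]
        assert discen == sorted(discen)
        assert maxd == sorted(maxd)

    def test_manual_center_by_position_and_label(self, convergent_fixture):
        aln = convergent_fixture.alignment
        by_pos = run_homodist(aln, RunConfig(auto_center=False, center=3, model="raw"))
        by_lab = run_homodist(aln, RunConfig(auto_center=False, center="t2", model="raw"))
        assert by_pos.center == by_lab.center == "t2"

    def test_final_step_hi_independent_of_center(self, convergent_fixture):
        """With all taxa included and identical final topology, the
        final HI cannot depend on where the series started."""
        aln = convergent_fixture.alignment
        t_auto = run_homodist(aln, RunConfig(model="raw"))
        t_alt = run_homodist(
            aln, RunConfig(auto_center=False, center="t7", model="raw")
        )
        assert (
            t_auto.steps[-1].scores["nj"].hi
            == t_alt.steps[-1].scores["nj"].hi
        )

    def test_nj_only_config(self, convergent_fixture):
        trace = run_homodist(
            convergent_fixture.alignment, RunConfig(model="raw", methods=("nj",))
        )
        assert "upgma" not in trace.steps[0].scores


class TestFirstHomoplasy:
    def test_detection_at_known_step(self, convergent_fixture):
        fx = convergent_fixture
        trace = run_homodist(fx.alignment, RunConfig(model="raw"))
        st = first_homoplasy_step(trace, "nj")
        assert st.step_index == fx.first_homoplasy_step_index
        assert st.added_taxon == "t6"
        assert st.dis_cen == pytest.approx(19 / 51)

    def test_none_when_hi_always_zero(self):
        trace = synthetic_trace([0.0, 0.0, 0.0])
        assert first_homoplasy_step(trace, "nj") is None

    def test_series_with_late_onset(self):
        trace = synthetic_trace([0.0, 0.0, 0.02, 0.05])
        assert first_homoplasy_step(trace, "nj").step_index == 3


class TestCiDistanceCorrelation:
    def test_perfectly_linear_negative(self):
        maxd = [0.1, 0.2, 0.3, 0.4]
        hi = [0.1 + 0.5 * m for m in maxd]  # CI = 0.9 - 0.5*MaxD, linear
        trace = synthetic_trace(hi, maxd)
        assert ci_distance_correlation(trace, "nj") == pytest.approx(-1.0)

    def test_fewer_than_three_qualifying_steps(self):
        trace = synthetic_trace([0.0, 0.0, 0.1, 0.2])
        assert ci_distance_correlation(trace, "nj") is None

    def test_steps_with_ci_one_excluded_and_matches_textbook_formula(self):
        maxd = [0.1, 0.2, 0.3, 0.4, 0.5]
        hi = [0.0, 0.03, 0.05, 0.06, 0.09]
        trace = synthetic_trace(hi, maxd)
        r = ci_distance_correlation(trace, "nj")
        expected = pearson_r(maxd[1:], [1 - h for h in hi[1:]])
        assert r == pytest.approx(expected)

    def test_zero_variance_returns_none(self):
        trace = synthetic_trace([0.05, 0.05, 0.05], [0.2, 0.3, 0.4])
        assert ci_distance_correlation(trace, "nj") is None


class TestDelimitHiGroups:
    def test_fixture_partitions_at_hi_changes(self, convergent_fixture):
        trace = run_homodist(convergent_fixture.alignment, RunConfig(model="raw"))
        part = delimit_hi_groups(trace, "nj")
        assert [grp for grp, _ in part.groups] == [
            ("t0", "t1", "t2", "t3", "t4", "t5"),
            ("t6",),
            ("t7",),
        ]
        assert part.boundaries == (4, 5)
        assert part.labels() == trace.series

    def test_constant_hi_single_group(self):
        trace = synthetic_trace([0.0, 0.0, 0.0])
        part = delimit_hi_groups(trace, "nj")
        assert part.n_groups == 1
        assert part.boundaries == ()

    def test_strictly_increasing_hi_one_group_per_taxon(self):
        trace = synthetic_trace([0.01, 0.02, 0.03, 0.04])
        part = delimit_hi_groups(trace, "nj")
        assert part.n_groups == 4
        sizes = [len(grp) for grp, _ in part.groups]
        assert sizes == [4, 1, 1, 1]

    def test_rounding_merges_near_equal_hi(self):
        trace = synthetic_trace([0.10001, 0.10002, 0.2])
        part = delimit_hi_groups(trace, "nj", decimals=3)
        assert part.n_groups == 2

    def test_spec_series_example(self):
        trace = synthetic_trace([0.0, 0.10, 0.10, 0.20])
        part = delimit_hi_groups(trace, "nj")
        assert [hi for _, hi in part.groups] == [0.0, 0.10, 0.20]


class TestTraceExport:
    def test_tsv_round_trip_preserves_analyses(self, tmp_path, convergent_fixture):
        trace = run_homodist(convergent_fixture.alignment, RunConfig(model="raw"))
        p = tmp_path / "trace.tsv"
        trace.to_tsv(p)
        back = trace_from_tsv(p)
        assert len(back.steps) == len(trace.steps)
        r_orig = ci_distance_correlation(trace, "nj")
        r_back = ci_distance_correlation(back, "nj")
        if r_orig is None:
            assert r_back is None
        else:
            assert r_back == pytest.approx(r_orig, abs=1e-9)
        assert (
            first_homoplasy_step(back, "nj").step_index
            == first_homoplasy_step(trace, "nj").step_index
        )
        assert delimit_hi_groups(back, "nj").boundaries == delimit_hi_groups(
            trace, "nj"
        ).boundaries

    def test_tsv_spells_na(self, tmp_path):
        aln = Alignment(("a", "b", "c", "d"), ("AAAA", "AAAA", "AAAA", "AAAA"))
        trace = run_homodist(aln, RunConfig(model="raw"))
        p = tmp_path / "t.tsv"
        trace.to_tsv(p)
        assert "NA" in p.read_text()  # RI undefined on invariant data

    def test_dataframe_identities(self, convergent_fixture):
        trace = run_homodist(convergent_fixture.alignment, RunConfig(model="raw"))
        df = trace.to_dataframe()
        assert np.allclose(df["nj_HI"], 1.0 - df["nj_CI"])
        nz = df["MaxD"] > 0
        assert np.allclose(
            df.loc[nz, "nj_SHI"] * df.loc[nz, "MaxD"], df.loc[nz, "nj_HI"]
        )
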