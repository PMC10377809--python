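"""Summary tables, condition deltas, timeline plots and the CLI."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import pytest

from ocublink import (
    BlinkWindow,
    CohortSpec,
    Condition,
    Recording,
    TearFilmParams,
    ValidationError,
    compare_conditions,
    generate_cohort,
    load_reference_pilot_table,
    plot_timeline,
    summaries_to_frame,
    summarize,
    write_annotations,
    write_tfbut_table,
)
from ocublink.cli import main
from ocublink.report import _draw_timeline


def _pattern_recordings(patterns) -> list[Recording]:
    return [
        Recording(participant_id=name, condition=Condition.BASELINE, windows=(w,))
        for name, w in patterns.items()
    ]


@pytest.fixture()
def pattern_tfbut(patterns):
    return {name: TearFilmParams(tfbut_s=10.0) for name in patterns}


class TestSummarize:
    def test_worked_examples_reproduce_reference_row_values(self, patterns, pattern_tfbut):
        """The four patterns at TFBUT 10 s give the canonical summary table."""
        frame = summaries_to_frame(
            summarize(_pattern_recordings(patterns), pattern_tfbut)
        ).set_index("participant_id")
        expect = {
            "A": (6.0, 0.0, 0.0, 16.7),
            "B": (6.0, 33.3, 0.0, 50.0),
            "C": (6.0, 0.0, 140.3, 53.3),
            "D": (6.0, 33.3, 140.3, 63.3),
        }
        for name, (sebr, inc, cv, exp) in expect.items():
            row = frame.loc[name]
            assert row["baseline_sebr"] == sebr
            assert row["baseline_incomplete_pct"] == inc
            assert row["baseline_cv_pct"] == cv
            assert row["baseline_exposure_pct"] == exp

    def test_missing_tfbut_names_participant(self, patterns):
        recs = _pattern_recordings(patterns)
        with pytest.raises(ValidationError, match="'C'"):
            summarize(recs, {"A": TearFilmParams(10.0), "B": TearFilmParams(10.0),
                             "D": TearFilmParams(10.0)})

    def test_empty_input_gives_empty_summary(self):
        assert summarize([], {}) == []

    def test_deterministic_and_idempotent(self, patterns, pattern_tfbut):
        recs = _pattern_recordings(patterns)
        a = summaries_to_frame(summarize(recs, pattern_tfbut))
        b = summaries_to_frame(summarize(recs, pattern_tfbut))
        pd.testing.assert_frame_equal(a, b)


class TestCompareConditions:
    def _summaries(self, n=10, seed=101):
        recs, tfbut = generate_cohort(CohortSpec(n_participants=n, seed=seed))
        from ocublink import average_tfbut
        return summarize(recs, {p: average_tfbut(r) for p, r in tfbut.items()})

    def test_reading_preset_gives_negative_mean_sebr_delta(self):
        deltas = compare_conditions(self._summaries(n=20))
        means = deltas[deltas["participant_id"] == "mean"].set_index("condition")
        assert means.loc["display", "d_sebr"] < 0
        assert means.loc["hardcopy", "d_sebr"] < 0

    def test_identical_conditions_give_zero_deltas(self, patterns):
        w = patterns["C"]
        recs = [Recording("P1", c, (w,)) for c in Condition]
        deltas = compare_conditions(summarize(recs, {"P1": TearFilmParams(10.0)}))
        num = deltas[[c for c in deltas.columns if c.startswith("d_")]]
        assert (num.fillna(0.0) == 0.0).all().all()

    def test_single_participant_deltas_equal_their_differences(self, patterns):
        recs = [
            Recording("P1", Condition.BASELINE, (patterns["A"],)),
            Recording("P1", Condition.DISPLAY, (patterns["D"],)),
        ]
        deltas = compare_conditions(summarize(recs, {"P1": TearFilmParams(10.0)}))
        per = deltas[deltas["participant_id"] == "P1"].iloc[0]
        mean = deltas[deltas["participant_id"] == "mean"].iloc[0]
        assert per["d_exposure_pct"] == pytest.approx(100 * (38 - 10) / 60)
        assert per["d_cv_pct"] == pytest.approx(mean["d_cv_pct"])

    def test_requires_a_baseline_row(self, patterns):
        recs = [Recording("P1", Condition.DISPLAY, (patterns["A"],))]
        with pytest.raises(ValidationError, match="baseline"):
            compare_conditions(summarize(recs, {"P1": TearFilmParams(10.0)}))


class TestReferencePilotTable:
    def test_shape_and_bounds(self):
        table = load_reference_pilot_table()
        assert table.shape == (8, 16)
        pct_cols = [c for c in table.columns if c.endswith("_pct")]
        for c in pct_cols:
            assert table[c].between(0, 150).all()  # CV may exceed 100 %
        for c in pct_cols:
            if "cv" not in c:
                assert table[c].between(0, 100).all()

    def test_values_echoed_verbatim(self):
        """The packaged table is pass-through data, never recomputed."""
        table = load_reference_pilot_table().set_index("participant_id")
        assert table.loc["P6", "baseline_cv_pct"] == 130.5
        assert table.loc["P6", "baseline_sebr"] == 4
        assert table.loc["P4", "baseline_exposure_pct"] == 42.1
        assert table.loc["P1", "hardcopy_cv_pct"] == 93.4


class TestTimelinePlot:
    def test_pattern_a_marks_and_bands(self, patterns, tear10, tmp_path):
        """Pattern A: 6 solid marks and 5 equal 2 s shaded exposure bands."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        counts = _draw_timeline(ax, patterns["A"], tear10)
        plt.close(fig)
        assert counts["complete_marks"] == 6
        assert counts["incomplete_marks"] == 0
        assert counts["shaded_spans"] == 5
        widths = [hi - lo for lo, hi in counts["span_bounds"]]
        assert widths == pytest.approx([2.0] * 5)

    def test_pattern_b_has_dashed_incomplete_marks(self, patterns, tear10):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        counts = _draw_timeline(ax, patterns["B"], tear10)
        plt.close(fig)
        assert counts["incomplete_marks"] == 2
        dashed = [ln for ln in ax.get_lines() if ln.get_linestyle() == "--"]
        assert len(dashed) == 2

    def test_no_shading_when_tfbut_exceeds_every_ibi(self, patterns, tmp_path):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        counts = _draw_timeline(ax, patterns["A"], TearFilmParams(tfbut_s=15.0))
        plt.close(fig)
        assert counts["shaded_spans"] == 0

    def test_figure_file_written(self, patterns, tear10, tmp_path):
        out = plot_timeline(patterns["D"], tear10, tmp_path / "d.png", title="D")
        assert out.exists() and out.stat().st_size > 0


class TestCli:
    def test_examples_subcommand_recomputes_reference_table(self, tmp_path):
        assert main(["examples", "--out-dir", str(tmp_path)]) == 0
        table = pd.read_csv(tmp_path / "worked_examples_summary.csv").set_index("pattern")
        assert list(table["exposure_pct"]) == [16.7, 50.0, 53.3, 63.3]
        assert list(table["opi"]) == [0.83] * 4
        manifest = json.loads((tmp_path / "run_manifest.json").read_text())
        assert manifest["command"] == "examples"

    def test_simulate_then_report_end_to_end(self, tmp_path):
        assert main(["simulate", "--seed", "7", "--out-dir", str(tmp_path)]) == 0
        assert main([
            "report",
            "--input", str(tmp_path / "cohort.csv"),
            "--tfbut", str(tmp_path / "cohort_tfbut.csv"),
            "--out-dir", str(tmp_path / "rep"),
        ]) == 0
        summary = pd.read_csv(tmp_path / "rep" / "summary.csv")
        assert len(summary) == 8  # default cohort size
        deltas = pd.read_csv(tmp_path / "rep" / "condition_deltas.csv")
        assert {"display", "hardcopy"} <= set(deltas["condition"])

    def test_metrics_subcommand(self, tmp_path, patterns):
        recs = _pattern_recordings(patterns)
        ann = write_annotations(recs, tmp_path / "ann.csv")
        assert main(["metrics", "--input", str(ann), "--out-dir", str(tmp_path)]) == 0
        table = pd.read_csv(tmp_path / "metrics.csv")
        assert set(table["sebr"]) == {6.0}

    def test_plot_subcommand_writes_figures(self, tmp_path, patterns):
        recs = _pattern_recordings(patterns)[:1]
        ann = write_annotations(recs, tmp_path / "ann.csv")
        tfb = write_tfbut_table({"A": (10.0, 10.0, 10.0)}, tmp_path / "t.csv")
        assert main(["plot", "--input", str(ann), "--tfbut", str(tfb),
                     "--out-dir", str(tmp_path)]) == 0
        assert (tmp_path / "timeline_A_baseline.png").exists()

    def test_validation_failure_exits_nonzero(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("not,a,valid,header\n1,2,3,4\n")
        assert main(["metrics", "--input", str(bad), "--out-dir", str(tmp_path)]) == 1

    def test_missing_input_exits_nonzero(self, tmp_path):
        assert main(["metrics", "--input", str(tmp_path / "nope.csv"),
                     "--out-dir", str(tmp_path)]) == 1
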