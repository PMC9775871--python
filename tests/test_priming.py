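"""RT pipeline: exclusion and trimming rules on constructed fixtures, the
priming statistic against the published worked examples, and the mixed-model
fit against reductions and an independent lme4 fit."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from mentalex import (
    RtSimSpec,
    ValidationError,
    filter_participants,
    fit_priming_model,
    preprocess_rt,
    priming_effect,
    simulate_rt,
)


def make_trials(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "subject", "item", "language_condition", "stimulus_type",
            "phase", "rt_ms", "correct",
        ],
    )


def uniform_subject(subject, n_correct, n_total, rt=400.0):
    rows = []
    for i in range(n_total):
        rows.append(
            (subject, f"i{i}", "D1-D2", "learned" if i % 2 else "unlearned",
             "test", rt, 1 if i < n_correct else 0)
        )
    return rows


class TestParticipantFilter:
    def test_below_threshold_excluded_boundary_retained(self):
        trials = make_trials(
            uniform_subject("s79", 79, 100)
            + uniform_subject("s80", 80, 100)
            + uniform_subject("s95", 95, 100)
        )
        kept, report = filter_participants(trials)
        assert report.excluded_subjects == ["s79"]
        assert set(kept["subject"]) == {"s80", "s95"}
        assert report.n_trials_removed == 100

    def test_exclusion_count_matches_brute_recount(self):
        rng = np.random.default_rng(42)
        rows = []
        truth = {}
        for i in range(30):
            total = 50
            acc = float(np.clip(rng.normal(0.85, 0.06), 0, 1))
            n_correct = int(round(acc * total))
            truth[f"s{i:02d}"] = n_correct / total
            rows += uniform_subject(f"s{i:02d}", n_correct, total)
        trials = make_trials(rows)
        kept, report = filter_participants(trials, threshold=0.80)
        expected = sorted(s for s, a in truth.items() if a < 0.80)
        assert report.excluded_subjects == expected
        assert expected  # the fixture does produce exclusions

    def test_all_excluded_raises(self):
        trials = make_trials(uniform_subject("s0", 10, 100))
        with pytest.raises(ValidationError):
            filter_participants(trials)


class TestPreprocess:
    def test_constant_rts_never_trimmed(self):
        trials = make_trials(uniform_subject("s0", 20, 20, rt=400.0))
        out, report = preprocess_rt(trials, scope="global")
        assert report.n_trimmed == 0
        assert len(out) == 20

    def test_log_transform_value(self):
        trials = make_trials([("s0", "i0", "D1-D2", "learned", "test", 403.4288, 1),
                              ("s0", "i1", "D1-D2", "unlearned", "test", 403.4288, 1)])
        out, _ = preprocess_rt(trials, scope="global")
        assert out["log_rt"].iloc[0] == pytest.approx(6.0, abs=5e-5)

    def test_single_outlier_removed_under_global_scope(self):
        rows = [(f"s{i}", f"i{i}", "D1-D2", "learned", "test", 400.0, 1)
                for i in range(19)]
        rows.append(("s19", "i19", "D1-D2", "learned", "test", 4000.0, 1))
        out, report = preprocess_rt(make_trials(rows), k=2.5, scope="global")
        assert report.n_trimmed == 1
        assert 4000.0 not in out["rt_ms"].values
        assert len(out) == 19

    def test_incorrect_trials_dropped_before_trimming(self):
        rows = [(f"s{i}", f"i{i}", "D1-D2", "learned", "test", 400.0, 1)
                for i in range(10)]
        # a wild RT that is incorrect: must not influence the trimming stats
        rows.append(("sx", "ix", "D1-D2", "learned", "test", 99999.0, 0))
        out, report = preprocess_rt(make_trials(rows), scope="global")
        assert report.n_incorrect_removed == 1
        assert report.n_trimmed == 0

    def test_filters_are_idempotent(self):
        trials = simulate_rt(RtSimSpec(n_subjects=8, n_items_per_cell=6,
                                       accuracy=0.9, seed=77))
        kept, _ = filter_participants(trials)
        twice, rep2 = filter_participants(kept)
        pd.testing.assert_frame_equal(kept, twice)
        assert rep2.excluded_subjects == []
        once, _ = preprocess_rt(kept, scope="cell")
        again, rep = preprocess_rt(once.drop(columns="log_rt"), scope="cell")
        pd.testing.assert_frame_equal(once.reset_index(drop=True),
                                      again.reset_index(drop=True))
        assert rep.n_trimmed == 0

    def test_log_preserves_rank_order(self):
        trials = simulate_rt(RtSimSpec(n_subjects=6, n_items_per_cell=4, seed=3))
        out, _ = preprocess_rt(trials, scope="cell")
        assert (out["rt_ms"].rank() == out["log_rt"].rank()).all()


class TestPrimingEffect:
    @pytest.mark.parametrize(
        "unlearned,learned,expected",
        [
            (444.996, 427.850, 17.146),  # reported D2-D1 conceptual-task row
            (372.725, 369.599, 3.126),   # reported D1-D2 lexical-task row
            (500.0, 500.0, 0.0),
        ],
    )
    def test_worked_examples(self, unlearned, learned, expected):
        assert priming_effect(unlearned, learned) == pytest.approx(expected, abs=1e-9)

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            priming_effect(np.nan, 400.0)


class TestModelFit:
    def test_zero_variance_reduces_to_cell_mean_difference(self):
        """With no subject/item variance the backward selection collapses the
        structure and the slope equals the plain difference of group means."""
        trials = simulate_rt(RtSimSpec(
            n_subjects=10, n_items_per_cell=6, priming_beta=-0.1,
            sd_subject=0.0, sd_item=0.0, sd_resid=0.25, accuracy=1.0, seed=5,
        ))
        # wide trimming band keeps the design exactly balanced, so the fixed
        # effect is invariant to whatever random terms survive selection
        processed, _ = preprocess_rt(trials, k=10.0, scope="global")
        res = fit_priming_model(processed, "D1-D2", selection="lrt")
        data = processed[processed["language_condition"] == "D1-D2"]
        means = data.groupby("stimulus_type")["log_rt"].mean()
        direct = means["learned"] - means["unlearned"]
        assert res.stimulus_type.estimate == pytest.approx(direct, abs=1e-6)

    def test_selection_keeps_subject_term_when_variance_is_large(self):
        trials = simulate_rt(RtSimSpec(
            n_subjects=12, n_items_per_cell=8, priming_beta=-0.1,
            sd_subject=0.5, sd_item=0.0, sd_resid=0.2, accuracy=1.0, seed=8,
        ))
        processed, _ = preprocess_rt(trials, scope="cell")
        res = fit_priming_model(processed, "D1-D2", selection="lrt")
        assert "subject" in res.random_structure

    def test_sign_convention_matches_generator(self):
        """Unlearned is the reference level, so the fitted slope recovers
        priming_beta with its own sign (negative under facilitation) while
        the ms priming effect is positive."""
        trials = simulate_rt(RtSimSpec(
            n_subjects=16, n_items_per_cell=10, priming_beta=-0.3,
            sd_subject=0.1, sd_item=0.05, sd_resid=0.2, accuracy=1.0, seed=13,
        ))
        processed, _ = preprocess_rt(trials, scope="cell")
        res = fit_priming_model(processed, "D2-D1", selection="none",
                                structure="intercepts")
        assert res.stimulus_type.estimate < 0
        assert res.priming_effect_ms > 0

    def test_requires_preprocessing_and_both_levels(self):
        trials = simulate_rt(RtSimSpec(n_subjects=4, n_items_per_cell=3, seed=1))
        with pytest.raises(ValidationError):
            fit_priming_model(trials, "D1-D2")
        processed, _ = preprocess_rt(trials, scope="cell")
        only_learned = processed[processed["stimulus_type"] == "learned"]
        with pytest.raises(ValidationError):
            fit_priming_model(only_learned, "D1-D2")

    def test_matches_lme4_crossed_intercepts(self, tmp_path):
        """Independent oracle: lme4 REML fit of the same crossed-intercepts
        model reproduces the fixed-effect estimate and SE."""
        trials = simulate_rt(RtSimSpec(
            n_subjects=10, n_items_per_cell=6, priming_beta=-0.15,
            sd_subject=0.15, sd_item=0.08, sd_resid=0.25, accuracy=1.0, seed=4,
        ))
        processed, _ = preprocess_rt(trials, scope="cell")
        res = fit_priming_model(processed, "D1-D2", selection="none",
                                structure="intercepts")
        data = processed[processed["language_condition"] == "D1-D2"].copy()
        data["is_learned"] = (data["stimulus_type"] == "learned").astype(float)
        csv = tmp_path / "trials.csv"
        data.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(log_rt ~ is_learned + (1|subject) + (1|item), data=d, REML=TRUE)
            co <- summary(m)$coefficients
            cat(sprintf("%.10f %.10f\\n", co["is_learned","Estimate"],
                        co["is_learned","Std. Error"]))
        """))
        out = subprocess.run(
            ["Rscript", "--vanilla", str(script)],
            capture_output=True, text=True, check=True,
        )
        est, se = map(float, out.stdout.split())
        assert res.stimulus_type.estimate == pytest.approx(est, abs=1e-5)
        assert res.stimulus_type.se == pytest.approx(se, rel=1e-3)
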