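"""Long-term repetition-priming reaction-time analysis.

Pipeline, in the order the filters are defined: (1) drop every trial of any
participant whose overall accuracy is below threshold (default 80%; exactly
80% is retained); (2) keep correct trials only; (3) single-pass +/-k SD
trimming of RTs (default k = 2.5) within a configurable scope; (4) natural
log transform.  The priming effect is mean RT(unlearned) - mean RT(learned)
in ms: positive = facilitation of learned items.

The inferential model is a linear mixed-effects regression of log RT on
stimulus type (treatment-coded, unlearned as reference), fitted separately
per language condition, with crossed by-subject and by-item random effects.
The maximal structure has by-subject and by-item intercepts and
stimulus-type slopes; a backward stepwise procedure prunes random terms
(slopes before their intercepts) using REML likelihood-ratio tests at
alpha = 0.05 (or AIC).  Because the reference level is "unlearned", the
stimulus-type coefficient is the learned-item shift on the log scale:
under facilitation it is negative while the ms priming effect is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fluency import ValidationError

REQUIRED_COLUMNS = (
    "subject", "item", "language_condition", "stimulus_type", "phase",
    "rt_ms", "correct",
)
LANGUAGE_CONDITIONS = ("D1-D2", "D2-D1")
STIMULUS_TYPES = ("learned", "unlearned")

#: random-effect terms, in maximal-model order; slopes precede the
#: intercept they depend on in the removal ladder
RANDOM_TERMS = ("subject_slope", "item_slope", "subject", "item")


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Schema check for a trial table; returns the frame unchanged."""
    missing = [c for c in REQUIRED_COLUMNS if c not in trials.columns]
    if missing:
        raise ValidationError(f"trial table missing columns: {missing}")
    if not np.all(np.isfinite(trials["rt_ms"])) or (trials["rt_ms"] <= 0).any():
        raise ValidationError("rt_ms must be finite and positive")
    bad = set(trials["language_condition"].unique()) - set(LANGUAGE_CONDITIONS)
    if bad:
        raise ValidationError(f"unknown language_condition levels: {bad}")
    bad = set(trials["stimulus_type"].unique()) - set(STIMULUS_TYPES)
    if bad:
        raise ValidationError(f"unknown stimulus_type levels: {bad}")
    if not set(trials["correct"].unique()) <= {0, 1}:
        raise ValidationError("correct must be 0/1")
    return trials


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

@dataclass
class ExclusionReport:
    threshold: float
    accuracies: dict
    excluded_subjects: list
    n_trials_in: int
    n_trials_out: int

    @property
    def n_trials_removed(self) -> int:
        return self.n_trials_in - self.n_trials_out


def filter_participants(
    trials: pd.DataFrame, threshold: float = 0.80
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Remove all trials of subjects with overall accuracy < threshold.

    The boundary case (accuracy exactly at threshold) is retained.
    """
    validate_trials(trials)
    acc = trials.groupby("subject")["correct"].mean()
    excluded = sorted(acc.index[acc < threshold])
    kept = trials[~trials["subject"].isin(excluded)].copy()
    report = ExclusionReport(
        threshold=threshold,
        accuracies={str(k): float(v) for k, v in acc.items()},
        excluded_subjects=[str(s) for s in excluded],
        n_trials_in=len(trials),
        n_trials_out=len(kept),
    )
    if kept.empty:
        raise ValidationError(
            f"all subjects excluded at threshold {threshold}; "
            f"accuracies: {report.accuracies}"
        )
    return kept, report


@dataclass
class TrimReport:
    k: float
    scope: str
    n_incorrect_removed: int
    n_trimmed: int
    n_trials_in: int
    n_trials_out: int
    skipped_cells: list = field(default_factory=list)


def preprocess_rt(
    trials: pd.DataFrame, k: float = 2.5, scope: str = "cell"
) -> tuple[pd.DataFrame, TrimReport]:
    """Correct-only filter, +/-k SD trimming, and natural-log transform.

    Trimming is a single pass on the correct trials: a trial is removed when
    |rt - mean| > k * SD, with mean and SD (ddof=1) computed within the
    chosen scope — ``cell`` (subject x stimulus-type, the dominant RT
    convention), ``subject``, or ``global``.  Scopes with fewer than two
    trials are skipped with a warning.  Surviving trials gain
    ``log_rt = ln(rt_ms)``.
    """
    if scope not in ("cell", "subject", "global"):
        raise ValidationError("scope must be cell|subject|global")
    validate_trials(trials)
    n_in = len(trials)
    correct = trials[trials["correct"] == 1].copy()
    n_incorrect = n_in - len(correct)
    if scope == "global":
        groups = [((), correct)]
    elif scope == "subject":
        groups = list(correct.groupby("subject", sort=False))
    else:
        groups = list(correct.groupby(["subject", "stimulus_type"], sort=False))
    keep_idx = []
    skipped = []
    for key, grp in groups:
        if len(grp) < 2:
            skipped.append(key)
            keep_idx.append(grp.index)
            continue
        mu = grp["rt_ms"].mean()
        sd = grp["rt_ms"].std(ddof=1)
        if sd == 0:
            keep_idx.append(grp.index)
            continue
        ok = (grp["rt_ms"] - mu).abs() <= k * sd
        keep_idx.append(grp.index[ok])
    if skipped:
        warnings.warn(f"trimming skipped for {len(skipped)} scope cell(s) with <2 trials")
    kept = correct.loc[np.sort(np.concatenate([np.asarray(ix) for ix in keep_idx]))].copy()
    kept["log_rt"] = np.log(kept["rt_ms"])
    report = TrimReport(
        k=k,
        scope=scope,
        n_incorrect_removed=n_incorrect,
        n_trimmed=len(correct) - len(kept),
        n_trials_in=n_in,
        n_trials_out=len(kept),
        skipped_cells=[str(s) for s in skipped],
    )
    return kept, report


def priming_effect(mean_unlearned: float, mean_learned: float) -> float:
    """Priming effect in ms: mean RT(unlearned) - mean RT(learned);
    positive values indicate facilitation of learned items."""
    if not (np.isfinite(mean_unlearned) and np.isfinite(mean_learned)):
        raise ValidationError("means must be finite")
    return float(mean_unlearned) - float(mean_learned)


# ---------------------------------------------------------------------------
# mixed-effects fit with backward random-structure selection
# ---------------------------------------------------------------------------

@dataclass
class FixedEffect:
    term: str
    estimate: float
    se: float
    t: float
    p: float


@dataclass
class PrimingResult:
    condition: str
    mean_unlearned: float
    mean_learned: float
    sd_unlearned: float
    sd_learned: float
    priming_effect_ms: float
    intercept: FixedEffect
    stimulus_type: FixedEffect
    random_structure: tuple
    selection: str
    selection_trace: list
    converged: bool
    n_trials: int
    n_subjects: int
    n_items: int

    def to_dict(self) -> dict:
        return {
            "condition": self.condition,
            "mean_unlearned_ms": self.mean_unlearned,
            "mean_learned_ms": self.mean_learned,
            "sd_unlearned_ms": self.sd_unlearned,
            "sd_learned_ms": self.sd_learned,
            "priming_effect_ms": self.priming_effect_ms,
            "fixed_effects": {
                "intercept": vars(self.intercept),
                "stimulus_type": vars(self.stimulus_type),
            },
            "random_structure": list(self.random_structure),
            "selection": self.selection,
            "selection_trace": self.selection_trace,
            "converged": self.converged,
            "n_trials": self.n_trials,
            "n_subjects": self.n_subjects,
            "n_items": self.n_items,
        }


def _vc_formula(terms) -> dict:
    vc = {}
    if "subject" in terms:
        vc["subject"] = "0 + C(subject)"
    if "item" in terms:
        vc["item"] = "0 + C(item)"
    if "subject_slope" in terms:
        vc["subject_slope"] = "0 + C(subject):is_learned"
    if "item_slope" in terms:
        vc["item_slope"] = "0 + C(item):is_learned"
    return vc


class _FitResult:
    """Uniform view over a MixedLM or OLS result."""

    def __init__(self, params, bse, llf, converged, aic):
        self.params = params
        self.bse = bse
        self.llf = llf
        self.converged = converged
        self.aic = aic


def _fit_structure(data: pd.DataFrame, terms: tuple, reml: bool = True) -> _FitResult:
    import statsmodels.formula.api as smf

    if terms:
        df = data.copy()
        df["_group"] = 1
        model = smf.mixedlm(
            "log_rt ~ is_learned",
            df,
            groups="_group",
            vc_formula=_vc_formula(terms),
            re_formula="0",
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=reml, method=["lbfgs", "bfgs"])
        k_params = 2 + len(terms) + 1  # fixed + variance components + resid
        return _FitResult(
            params=res.params, bse=res.bse,
            llf=float(res.llf), converged=bool(res.converged),
            aic=2 * k_params - 2 * float(res.llf),
        )
    model = smf.ols("log_rt ~ is_learned", data)
    res = model.fit()
    return _FitResult(
        params=res.params, bse=res.bse,
        llf=float(res.llf), converged=True, aic=float(res.aic),
    )


def _removable(terms: tuple) -> list:
    """Slopes are removable any time; an intercept only once its slope is gone."""
    out = []
    for t in terms:
        if t in ("subject_slope", "item_slope"):
            out.append(t)
        elif t == "subject" and "subject_slope" not in terms:
            out.append(t)
        elif t == "item" and "item_slope" not in terms:
            out.append(t)
    return out


def fit_priming_model(
    trials: pd.DataFrame,
    condition: str,
    selection: str = "lrt",
    alpha: float = 0.05,
    structure: str = "maximal",
) -> PrimingResult:
    """Fit log RT ~ stimulus type for one language condition.

    ``structure`` sets the starting random structure: ``maximal``
    (by-subject and by-item intercepts + stimulus-type slopes) or
    ``intercepts`` (crossed intercepts only).  ``selection``: ``lrt``
    (backward REML likelihood-ratio pruning at ``alpha``), ``aic``, or
    ``none`` (keep the starting structure).  Non-convergence triggers an
    automatic fallback down the same ladder, recorded in the trace.
    """
    if "log_rt" not in trials.columns:
        raise ValidationError("run preprocess_rt first (log_rt column missing)")
    if selection not in ("lrt", "aic", "none"):
        raise ValidationError("selection must be lrt|aic|none")
    data = trials[trials["language_condition"] == condition].copy()
    if data.empty:
        raise ValidationError(f"no trials for condition {condition}")
    if data["subject"].nunique() < 2 or data["item"].nunique() < 2:
        raise ValidationError("need >= 2 subjects and >= 2 items")
    if set(data["stimulus_type"].unique()) != set(STIMULUS_TYPES):
        raise ValidationError("both stimulus types must be present")
    data["is_learned"] = (data["stimulus_type"] == "learned").astype(float)

    terms = RANDOM_TERMS if structure == "maximal" else ("subject", "item")
    if structure not in ("maximal", "intercepts"):
        raise ValidationError("structure must be maximal|intercepts")

    trace: list = []
    res = None
    terms = tuple(terms)
    # fallback ladder for a non-converging start: peel terms until a fit works
    while True:
        try:
            res = _fit_structure(data, terms)
            if res.converged or not terms:
                break
            trace.append({"action": "fallback", "dropped": terms[0],
                          "reason": "non-convergence"})
            terms = terms[1:]
        except (np.linalg.LinAlgError, ValueError) as err:
            if not terms:
                raise
            trace.append({"action": "fallback", "dropped": terms[0],
                          "reason": f"fit error: {err}"})
            terms = terms[1:]

    if selection != "none":
        while terms:
            candidates = _removable(terms)
            if not candidates:
                break
            best = None
            for cand in candidates:
                reduced = tuple(t for t in terms if t != cand)
                try:
                    res_red = _fit_structure(data, reduced)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if selection == "lrt":
                    lr = max(0.0, 2.0 * (res.llf - res_red.llf))
                    p = float(sps.chi2.sf(lr, df=1))
                    score = p
                    keep_if = p <= alpha
                else:
                    score = res.aic - res_red.aic  # positive: reduced is better
                    keep_if = res_red.aic >= res.aic
                if not keep_if and (best is None or score > best[0]):
                    best = (score, cand, reduced, res_red)
            if best is None:
                break
            score, cand, terms, res = best[0], best[1], best[2], best[3]
            trace.append({
                "action": "removed", "term": cand,
                ("lrt_p" if selection == "lrt" else "aic_gain"): score,
            })

    # between-within (containment) reference df: stimulus type varies
    # between items, so its t is referred to n_items - 2; the intercept to
    # n_subjects - 1.  A plain normal reference is anti-conservative with
    # tens of items.
    df_slope = max(int(data["item"].nunique()) - 2, 1)
    df_icept = max(int(data["subject"].nunique()) - 1, 1)
    est = float(res.params["is_learned"])
    se = float(res.bse["is_learned"])
    t = est / se if se > 0 else np.nan
    p = 2 * float(sps.t.sf(abs(t), df_slope)) if np.isfinite(t) else np.nan
    i_est = float(res.params["Intercept"])
    i_se = float(res.bse["Intercept"])
    i_t = i_est / i_se if i_se > 0 else np.nan
    i_p = 2 * float(sps.t.sf(abs(i_t), df_icept)) if np.isfinite(i_t) else np.nan

    unlearned = data.loc[data["is_learned"] == 0, "rt_ms"]
    learned = data.loc[data["is_learned"] == 1, "rt_ms"]
    mu_u, mu_l = float(unlearned.mean()), float(learned.mean())
    return PrimingResult(
        condition=condition,
        mean_unlearned=mu_u,
        mean_learned=mu_l,
        sd_unlearned=float(unlearned.std(ddof=1)),
        sd_learned=float(learned.std(ddof=1)),
        priming_effect_ms=priming_effect(mu_u, mu_l),
        intercept=FixedEffect("(intercept)", i_est, i_se, i_t, i_p),
        stimulus_type=FixedEffect("stimulus_type[learned]", est, se, t, p),
        random_structure=terms,
        selection=selection,
        selection_trace=trace,
        converged=bool(res.converged),
        n_trials=len(data),
        n_subjects=int(data["subject"].nunique()),
        n_items=int(data["item"].nunique()),
    )


def format_results_table(results: list[PrimingResult]) -> str:
    """Text table mirroring the layout of the reported RT tables: condition
    means (SD), priming effect, then the fixed-effect rows per condition."""
    lines = [
        f"{'Language':<10} {'Mean (SD) Unlearned':>22} {'Mean (SD) Learned':>22} "
        f"{'Priming Effect':>15}"
    ]
    for r in results:
        lines.append(
            f"{r.condition:<10} "
            f"{r.mean_unlearned:>14.3f} ({r.sd_unlearned:>4.0f}) "
            f"{r.mean_learned:>14.3f} ({r.sd_learned:>4.0f}) "
            f"{r.priming_effect_ms:>15.3f}"
        )
    lines.append("")
    lines.append("Fixed effects")
    lines.append(
        f"{'Condition':<10} {'Term':<24} {'Estimate':>9} {'SE':>7} {'t':>8} {'p':>8}"
    )
    for r in results:
        for fe in (r.intercept, r.stimulus_type):
            lines.append(
                f"{r.condition:<10} {fe.term:<24} {fe.estimate:>9.3f} "
                f"{fe.se:>7.3f} {fe.t:>8.3f} {fe.p:>8.3g}"
            )
        lines.append(
            f"{r.condition:<10} random structure: "
            f"{', '.join(r.random_structure) if r.random_structure else 'none (OLS)'}"
        )
    return "\n".join(lines)
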