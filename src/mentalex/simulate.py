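"""Synthetic fluency and reaction-time data with known generative structure.

Fluency side: a planted-cluster Bernoulli model.  The vocabulary is split
into latent semantic clusters; each participant "knows" a fixed number of
clusters and produces each word of a known cluster with probability
``p_within`` and any other word with probability ``p_between``.  This is the
simplest generative model under which word co-production is cluster-driven,
so community detection and small-world metrics on the derived correlation
network have a known ground truth.

RT side: a lognormal reaction-time model with crossed Gaussian random
effects on the log scale — exactly the data-generating process the
mixed-model analysis assumes, so parameter recovery is well-posed:

    log RT = mu + b_subject + b_item + beta * [item learned] + eps

``priming_beta`` is the learned-item shift in log-ms (negative =
facilitation, i.e. learned items answered faster).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd

from .fluency import FluencyDataset, ValidationError

LANGUAGE_CONDITIONS = ("D1-D2", "D2-D1")
STIMULUS_TYPES = ("unlearned", "learned")


@dataclass(frozen=True)
class FluencySimSpec:
    """Planted-cluster fluency generator settings.

    Defaults emulate the empirical study conditions: 32 participants and a
    vocabulary in the 40-55 word range (5 clusters x 9 words = 45) with
    strong within-cluster production and a low background rate.
    """

    n_participants: int = 32
    clusters: tuple[tuple[str, int], ...] = (
        ("c1", 9), ("c2", 9), ("c3", 9), ("c4", 9), ("c5", 9),
    )
    p_within: float = 0.9
    p_between: float = 0.05
    clusters_per_participant: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p_between <= self.p_within <= 1):
            raise ValidationError("need 0 <= p_between <= p_within <= 1")
        if self.n_participants < 2:
            raise ValidationError("n_participants must be >= 2")
        if len(self.clusters) == 0 or any(k < 1 for _, k in self.clusters):
            raise ValidationError("each cluster needs word_count >= 1")
        if not (1 <= self.clusters_per_participant <= len(self.clusters)):
            raise ValidationError(
                "clusters_per_participant must be in [1, number of clusters]"
            )


def simulate_fluency(
    spec: FluencySimSpec, language: str = "D1", category: str = "animal"
) -> FluencyDataset:
    """Draw one fluency incidence matrix from the planted-cluster model.

    Words produced by zero participants are retained as all-zero columns;
    downstream policy decides their fate.  The realized per-participant
    cluster assignments and the word->cluster map are stored in
    ``dataset.meta`` so tests can recompute expectations from the realization.
    """
    rng = np.random.default_rng(spec.seed)
    word_labels: list[str] = []
    word_cluster: list[str] = []
    for cid, k in spec.clusters:
        for j in range(k):
            word_labels.append(f"{cid}_w{j:02d}")
            word_cluster.append(cid)
    cluster_ids = [cid for cid, _ in spec.clusters]
    n_words = len(word_labels)
    assignments: list[list[str]] = []
    probs = np.empty((spec.n_participants, n_words))
    for i in range(spec.n_participants):
        owned = rng.choice(
            len(cluster_ids), size=spec.clusters_per_participant, replace=False
        )
        owned_set = {cluster_ids[c] for c in owned}
        assignments.append(sorted(owned_set))
        probs[i] = [
            spec.p_within if c in owned_set else spec.p_between for c in word_cluster
        ]
    inc = (rng.random((spec.n_participants, n_words)) < probs).astype(np.int8)
    return FluencyDataset(
        incidence=inc,
        word_labels=word_labels,
        language=language,
        category=category,
        meta={
            "spec": asdict(spec),
            "word_cluster": word_cluster,
            "participant_clusters": assignments,
        },
    )


@dataclass(frozen=True)
class RtSimSpec:
    """Lognormal RT generator settings.

    ``grand_mean_log_rt`` of 6.0 corresponds to e^6 ~ 403 ms, in the range
    of the empirical condition means; ``priming_beta`` of -0.12 matches the
    magnitude of the reported stimulus-type effect on the log scale.  SDs
    are log-ms scale.
    """

    n_subjects: int = 32
    n_items_per_cell: int = 20
    grand_mean_log_rt: float = 6.0
    priming_beta: float = -0.12
    sd_subject: float = 0.2
    sd_item: float = 0.1
    sd_resid: float = 0.3
    accuracy: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValidationError("n_subjects must be >= 2 (model fit degenerate)")
        if self.n_items_per_cell < 2:
            raise ValidationError("n_items_per_cell must be >= 2 (model fit degenerate)")
        if min(self.sd_subject, self.sd_item, self.sd_resid) < 0:
            raise ValidationError("standard deviations must be >= 0")
        if not (0 <= self.accuracy <= 1):
            raise ValidationError("accuracy must be in [0, 1]")


def simulate_rt(spec: RtSimSpec) -> pd.DataFrame:
    """Draw one trial table: every subject responds to every item.

    Items are distinct across language condition x stimulus type cells
    (as in the priming design, where each condition has its own learned and
    unlearned item sets); subject effects are shared across conditions
    (within-subject design).  Columns: subject, item, language_condition,
    stimulus_type, phase, rt_ms, correct.
    """
    rng = np.random.default_rng(spec.seed)
    subjects = [f"s{i:03d}" for i in range(spec.n_subjects)]
    b_subj = rng.normal(0.0, spec.sd_subject, spec.n_subjects)
    rows_sub, rows_item, rows_cond, rows_type = [], [], [], []
    item_effects = {}
    for cond in LANGUAGE_CONDITIONS:
        for stype in STIMULUS_TYPES:
            for j in range(spec.n_items_per_cell):
                item = f"{cond}_{stype}_i{j:03d}"
                item_effects[item] = rng.normal(0.0, spec.sd_item)
                for i in range(spec.n_subjects):
                    rows_sub.append(i)
                    rows_item.append(item)
                    rows_cond.append(cond)
                    rows_type.append(stype)
    n = len(rows_sub)
    sub_idx = np.asarray(rows_sub)
    learned = np.asarray([t == "learned" for t in rows_type], dtype=float)
    log_rt = (
        spec.grand_mean_log_rt
        + b_subj[sub_idx]
        + np.asarray([item_effects[i] for i in rows_item])
        + spec.priming_beta * learned
        + rng.normal(0.0, spec.sd_resid, n)
    )
    correct = (rng.random(n) < spec.accuracy).astype(int)
    return pd.DataFrame(
        {
            "subject": [subjects[i] for i in sub_idx],
            "item": rows_item,
            "language_condition": rows_cond,
            "stimulus_type": rows_type,
            "phase": "test",
            "rt_ms": np.exp(log_rt),
            "correct": correct,
        }
    )


# ---------------------------------------------------------------------------
# I/O with sidecar spec
# ---------------------------------------------------------------------------

def _write_sidecar(spec, path) -> None:
    with open(str(path) + ".json", "w") as fh:
        json.dump({"spec": asdict(spec), "type": type(spec).__name__}, fh, indent=2)


def write_fluency(dataset: FluencyDataset, spec: FluencySimSpec, path) -> None:
    dataset.to_frame().to_csv(path, index_label="participant")
    _write_sidecar(spec, path)


def write_trials(trials: pd.DataFrame, spec: RtSimSpec, path) -> None:
    trials.to_csv(path, index=False)
    _write_sidecar(spec, path)
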