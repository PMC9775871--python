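"""Erdős–Rényi null ensembles and significance tests against them.

The validation recipe: for an empirical network with n nodes, generate an
ensemble of G(n, p) random graphs at a fixed edge probability (p = 0.5 in
the reference procedure, 1000 replicates), compute unweighted CC, hop ASPL
(largest component) and greedy-modularity Q per replicate, and contrast the
empirical values with the ensemble.

Two statistics are reported per metric:

* ``t`` — one-sample t of the ensemble values against the empirical value
  (df = reps - 1), signed so that t > 0 means the empirical value exceeds
  the ensemble mean.  This is the ensemble-mean comparison and grows with
  sqrt(reps) for any genuinely different network.
* ``z`` — (empirical - mean) / SD, locating the empirical value within the
  null distribution.  Under the null (empirical value drawn from the same
  law) |z| > 1.96 rejects at ~5%, so z is the calibrated quantity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .fluency import LexicalNetwork, ValidationError
from .metrics import (
    NetworkMetrics,
    average_shortest_path_length,
    clustering_coefficient,
    detect_communities,
)


def er_random_graph(n: int, p: float, seed: int) -> LexicalNetwork:
    """G(n, p): each of the n(n-1)/2 unordered pairs is an edge independently
    with probability p; unit weights."""
    if n < 2:
        raise ValidationError("n must be >= 2")
    if not (0 <= p <= 1):
        raise ValidationError("p must be in [0, 1]")
    G = nx.fast_gnp_random_graph(n, p, seed=int(seed))
    nx.set_edge_attributes(G, 1.0, "weight")
    return LexicalNetwork(G, weight_interpretation="similarity")


@dataclass
class NullEnsemble:
    """Per-replicate metric distributions from an ER ensemble."""

    n: int
    p: float
    reps: int
    seed: int
    cc: np.ndarray
    aspl: np.ndarray
    q: np.ndarray
    edges: np.ndarray
    metrics_computed: tuple = ("cc", "aspl", "q")

    def values(self, metric: str) -> np.ndarray:
        if metric not in ("cc", "aspl", "q", "edges"):
            raise ValidationError(f"unknown metric: {metric}")
        v = getattr(self, metric)
        if v.size == 0:
            raise ValidationError(f"metric {metric} was not computed in this ensemble")
        return v

    def mean(self, metric: str) -> float:
        return float(np.mean(self.values(metric)))

    def sd(self, metric: str) -> float:
        return float(np.std(self.values(metric), ddof=1))

    def summary(self) -> dict:
        out = {"n": self.n, "p": self.p, "reps": self.reps, "seed": self.seed}
        for m in (*self.metrics_computed, "edges"):
            out[f"{m}_mean"] = self.mean(m)
            out[f"{m}_sd"] = self.sd(m)
        return out


def null_ensemble(
    n: int,
    p: float,
    reps: int = 1000,
    seed: int = 0,
    metrics: tuple = ("cc", "aspl", "q"),
) -> NullEnsemble:
    """Generate the ER ensemble and its per-replicate metric vectors.

    Random graphs are unweighted, so the unweighted metric definitions are
    used throughout: Watts-Strogatz CC, hop ASPL on the largest component,
    and greedy-modularity (CNM) Q.  Replicate r uses seed ``seed + r``, so
    the ensemble is reproducible and replicates are independent.
    """
    if reps < 2:
        raise ValidationError("reps must be >= 2")
    cc, aspl, q, edges = [], [], [], []
    for r in range(reps):
        net = er_random_graph(n, p, seed=seed + r)
        G = net.graph
        edges.append(G.number_of_edges())
        if "cc" in metrics:
            cc.append(clustering_coefficient(net, mode="unweighted"))
        if "aspl" in metrics:
            if G.number_of_edges() == 0:
                aspl.append(np.nan)
            else:
                import warnings as _w

                with _w.catch_warnings():
                    _w.simplefilter("ignore")
                    aspl.append(average_shortest_path_length(net, mode="hops"))
        if "q" in metrics:
            q.append(detect_communities(net, method="greedy", weighted=False).q)
    return NullEnsemble(
        n=n,
        p=p,
        reps=reps,
        seed=seed,
        cc=np.asarray(cc),
        aspl=np.asarray(aspl),
        q=np.asarray(q),
        edges=np.asarray(edges, dtype=float),
        metrics_computed=tuple(m for m in ("cc", "aspl", "q") if m in metrics),
    )


@dataclass
class NullComparison:
    """Empirical value vs ER ensemble for one metric."""

    metric: str
    empirical: float
    ensemble_mean: float
    ensemble_sd: float
    t: float
    p_value: float
    z: float
    df: int
    direction: str
    degenerate: bool = False

    def significant(self, alpha: float = 0.05) -> bool:
        return (not self.degenerate) and self.p_value < alpha

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "empirical": self.empirical,
            "ensemble_mean": self.ensemble_mean,
            "ensemble_sd": self.ensemble_sd,
            "t": self.t,
            "p_value": self.p_value,
            "z": self.z,
            "df": self.df,
            "direction": self.direction,
            "degenerate": self.degenerate,
        }


def compare_to_null(
    empirical: "NetworkMetrics | float", ensemble: NullEnsemble, metric: str
) -> NullComparison:
    """One-sample t-test of the ensemble against the empirical value, plus
    the z location of the empirical value in the null distribution."""
    if isinstance(empirical, NetworkMetrics):
        value = float(getattr(empirical, metric))
    else:
        value = float(empirical)
    vals = ensemble.values(metric)
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValidationError("ensemble needs >= 2 finite values")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1))
    df = vals.size - 1
    if sd == 0:
        return NullComparison(
            metric, value, mean, sd, np.nan, np.nan, np.nan, df,
            direction="degenerate", degenerate=True,
        )
    res = stats.ttest_1samp(vals, popmean=value)
    t = -float(res.statistic)  # signed: positive when empirical > ensemble mean
    p = float(res.pvalue)
    z = (value - mean) / sd
    direction = "above" if value > mean else ("below" if value < mean else "equal")
    return NullComparison(metric, value, mean, sd, t, p, z, df, direction)


def compare_to_null_pooled(
    pairs: list[tuple[float, NullEnsemble]], metric: str
) -> NullComparison:
    """Pooled-across-networks variant: standardize each empirical value by
    its own ensemble and t-test the z-scores against zero."""
    zs = []
    for value, ens in pairs:
        vals = ens.values(metric)
        vals = vals[np.isfinite(vals)]
        sd = float(np.std(vals, ddof=1))
        if sd == 0:
            raise ValidationError("zero ensemble SD in pooled comparison")
        zs.append((float(value) - float(np.mean(vals))) / sd)
    zs = np.asarray(zs)
    if zs.size < 2:
        raise ValidationError("pooled comparison needs >= 2 networks")
    res = stats.ttest_1samp(zs, popmean=0.0)
    mean_z = float(np.mean(zs))
    return NullComparison(
        metric=metric,
        empirical=mean_z,
        ensemble_mean=0.0,
        ensemble_sd=float(np.std(zs, ddof=1)),
        t=float(res.statistic),
        p_value=float(res.pvalue),
        z=mean_z,
        df=zs.size - 1,
        direction="above" if mean_z > 0 else "below",
    )
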