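"""Construction of word-correlation lexical networks from semantic-fluency data.

The pipeline implemented here mirrors the standard fluency-network recipe:
ordered word lists per participant are collapsed into a binary incidence
matrix (participants x words), the word columns are correlated across
participants, and the correlation matrix becomes the weight matrix of an
undirected graph over words.  A spanning-tree backbone can then be extracted
to expose the strongest topological skeleton of the lexicon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class FluencyDataset:
    """Binary incidence of word production: participants x distinct words.

    ``incidence[i, j] == 1`` iff participant ``i`` produced word ``j`` at
    least once.  ``word_labels`` are unique and ordered (first-appearance
    order when built from raw responses).
    """

    incidence: np.ndarray
    word_labels: list[str]
    language: str = "D1"
    category: str = "animal"
    participant_ids: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence)
        if self.incidence.ndim != 2:
            raise ValidationError("incidence must be 2-D (participants x words)")
        vals = np.unique(self.incidence)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValidationError("incidence entries must be 0/1")
        if len(self.word_labels) != self.incidence.shape[1]:
            raise ValidationError("word_labels length must match column count")
        if len(set(self.word_labels)) != len(self.word_labels):
            raise ValidationError("word_labels must be unique")
        if self.incidence.shape[0] < 2 or self.incidence.shape[1] < 2:
            raise ValidationError("need at least 2 participants and 2 words")
        if self.participant_ids is None:
            self.participant_ids = [f"p{i:02d}" for i in range(self.incidence.shape[0])]

    @property
    def n_participants(self) -> int:
        return self.incidence.shape[0]

    @property
    def n_words(self) -> int:
        return self.incidence.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.incidence, index=self.participant_ids, columns=self.word_labels
        )


@dataclass
class WeightMatrix:
    """Symmetric word-by-word correlation matrix with degeneracy flags.

    ``degenerate[j]`` marks words with zero variance across participants
    (produced by everyone or by no one); their correlations are undefined and
    are handled per the policy chosen in :func:`correlation_matrix`.
    """

    weights: np.ndarray
    word_labels: list[str]
    degenerate: np.ndarray | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValidationError("weights must be square")
        if len(self.word_labels) != w.shape[0]:
            raise ValidationError("word_labels length must match matrix size")
        finite = np.isfinite(w)
        if not np.allclose(w[finite & finite.T], w.T[finite & finite.T], atol=1e-12):
            raise ValidationError("weights must be symmetric")
        if finite.any() and np.max(np.abs(w[finite])) > 1 + 1e-9:
            raise ValidationError("correlation weights must lie in [-1, 1]")
        self.weights = w
        if self.degenerate is None:
            self.degenerate = np.zeros(w.shape[0], dtype=bool)


class LexicalNetwork:
    """Undirected weighted graph over word nodes.

    Thin wrapper around :class:`networkx.Graph` that records whether the
    edge weights are similarities (correlations; larger = closer) or
    distances, and whether the network is a spanning tree.
    """

    def __init__(
        self,
        graph: nx.Graph,
        weight_interpretation: str = "similarity",
        is_tree: bool = False,
    ) -> None:
        if weight_interpretation not in ("similarity", "distance"):
            raise ValidationError("weight_interpretation must be similarity|distance")
        self.graph = graph
        self.weight_interpretation = weight_interpretation
        self.is_tree = is_tree
        if is_tree:
            n, m = graph.number_of_nodes(), graph.number_of_edges()
            if m != n - 1 or not nx.is_connected(graph):
                raise ValidationError("is_tree set but graph is not a spanning tree")

    @property
    def word_labels(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]

    def total_weight(self) -> float:
        return float(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_incidence(
    responses: Sequence[Iterable[str]],
    language: str = "D1",
    category: str = "animal",
    participant_ids: Sequence[str] | None = None,
) -> FluencyDataset:
    """Collapse ordered per-participant word lists into a binary incidence matrix.

    Columns are the union of distinct words across participants in
    first-appearance order; within-participant repetitions collapse to a
    single 1.  Participants with zero responses are kept as all-zero rows
    (with a warning), so the row set matches the sample.
    """
    responses = [list(r) for r in responses]
    if len(responses) == 0 or all(len(r) == 0 for r in responses):
        raise ValidationError("empty response set")
    words: list[str] = []
    seen: set[str] = set()
    for r in responses:
        for w in r:
            w = w.strip()
            if w and w not in seen:
                seen.add(w)
                words.append(w)
    col = {w: j for j, w in enumerate(words)}
    inc = np.zeros((len(responses), len(words)), dtype=np.int8)
    for i, r in enumerate(responses):
        if not r:
            warnings.warn(f"participant {i} produced zero words; all-zero row kept")
        for w in r:
            w = w.strip()
            if w:
                inc[i, col[w]] = 1
    return FluencyDataset(
        incidence=inc,
        word_labels=words,
        language=language,
        category=category,
        participant_ids=list(participant_ids) if participant_ids is not None else None,
    )


def expand_responses(dataset: FluencyDataset) -> list[list[str]]:
    """Inverse of :func:`build_incidence` up to response order: one word list
    per participant containing each produced word once, in column order."""
    return [
        [w for w, v in zip(dataset.word_labels, row) if v]
        for row in dataset.incidence
    ]


def correlation_matrix(
    dataset: FluencyDataset,
    method: str = "pearson",
    degenerate_policy: str = "zero",
) -> WeightMatrix:
    """Correlate word columns across participants.

    On binary columns the Pearson coefficient is the phi coefficient, the
    classical co-production association measure for fluency data.

    degenerate_policy:
      ``zero`` (default) — zero-variance words keep their node; their
      correlations are set to 0 and the word is flagged;
      ``nan`` — flagged, correlations left NaN;
      ``drop`` — zero-variance columns removed from the matrix.
    """
    if dataset.n_participants < 2:
        raise ValidationError("need at least 2 participants to correlate")
    if degenerate_policy not in ("zero", "nan", "drop"):
        raise ValidationError("degenerate_policy must be zero|nan|drop")
    X = dataset.incidence.astype(float)
    degen = X.std(axis=0) == 0
    labels = list(dataset.word_labels)
    if degenerate_policy == "drop":
        keep = ~degen
        X = X[:, keep]
        labels = [w for w, k in zip(labels, keep) if k]
        degen = np.zeros(X.shape[1], dtype=bool)
    if method == "pearson":
        with np.errstate(invalid="ignore", divide="ignore"):
            R = np.corrcoef(X, rowvar=False)
    elif method == "spearman":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            R = stats.spearmanr(X).statistic
        R = np.atleast_2d(R)
    else:
        raise ValidationError(f"unknown correlation method: {method}")
    R = np.asarray(R, dtype=float)
    if degenerate_policy == "zero":
        R[degen, :] = 0.0
        R[:, degen] = 0.0
    np.fill_diagonal(R, 1.0)
    # clip tiny numerical excursions outside [-1, 1]
    finite = np.isfinite(R)
    R[finite] = np.clip(R[finite], -1.0, 1.0)
    return WeightMatrix(weights=R, word_labels=labels, degenerate=degen)


def build_network(
    weights: WeightMatrix,
    policy: str = "all",
    tau: float | None = None,
) -> LexicalNetwork:
    """Turn a weight matrix into an undirected weighted graph over words.

    policy:
      ``all`` — every finite off-diagonal weight becomes an edge;
      ``positive`` — only strictly positive weights;
      ``threshold`` — only weights strictly above ``tau``.

    The node set is always the full word list: isolated words stay as nodes.
    """
    if policy not in ("all", "positive", "threshold"):
        raise ValidationError("policy must be all|positive|threshold")
    if policy == "threshold" and tau is None:
        raise ValidationError("threshold policy requires tau")
    W = weights.weights
    G = nx.Graph()
    G.add_nodes_from(weights.word_labels)
    n = len(weights.word_labels)
    for i in range(n):
        for j in range(i + 1, n):
            w = W[i, j]
            if not np.isfinite(w):
                continue
            if policy == "positive" and w <= 0:
                continue
            if policy == "threshold" and w <= tau:
                continue
            G.add_edge(weights.word_labels[i], weights.word_labels[j], weight=float(w))
    if G.number_of_edges() == 0:
        warnings.warn("network has no edges under the chosen policy")
    return LexicalNetwork(G, weight_interpretation="similarity")


def spanning_tree(
    network: LexicalNetwork,
    objective: str = "maximize-similarity",
) -> LexicalNetwork:
    """Spanning-tree backbone of the lexical network.

    ``maximize-similarity`` keeps the spanning tree of maximal total
    correlation weight — equivalently the minimal spanning tree under the
    distance transform 1 − r.  ``minimize-distance`` minimises total weight
    directly and is meant for networks whose weights already are distances.
    Ties are broken by lexicographic node-pair order, so the result is
    deterministic.  Disconnected input yields a per-component forest with a
    warning.
    """
    if objective not in ("maximize-similarity", "minimize-distance"):
        raise ValidationError("objective must be maximize-similarity|minimize-distance")
    G = network.graph
    sign = -1.0 if objective == "maximize-similarity" else 1.0
    edges = sorted(
        ((u, v, d["weight"]) for u, v, d in G.edges(data=True)),
        key=lambda e: (sign * e[2], min(str(e[0]), str(e[1])), max(str(e[0]), str(e[1]))),
    )
    uf = nx.utils.UnionFind(G.nodes)
    T = nx.Graph()
    T.add_nodes_from(G.nodes)
    for u, v, w in edges:
        if uf[u] != uf[v]:
            uf.union(u, v)
            T.add_edge(u, v, weight=w)
    connected = G.number_of_nodes() > 0 and nx.is_connected(G)
    if not connected:
        warnings.warn("input not connected; returning a per-component spanning forest")
    return LexicalNetwork(
        T,
        weight_interpretation=network.weight_interpretation,
        is_tree=connected,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_responses_csv(path, fmt: str = "long") -> list[list[str]]:
    """Read fluency responses.

    ``long``: columns participant, position, word (sorted by position within
    participant).  ``wide``: one row per participant, words in successive
    columns, empty cells ignored.
    """
    df = pd.read_csv(path)
    if fmt == "long":
        for c in ("participant", "position", "word"):
            if c not in df.columns:
                raise ValidationError(f"long-format responses need column '{c}'")
        out = []
        for _, grp in df.groupby("participant", sort=True):
            grp = grp.sort_values("position")
            out.append([str(w) for w in grp["word"]])
        return out
    if fmt == "wide":
        return [
            [str(v) for v in row if pd.notna(v) and str(v).strip()]
            for row in df.itertuples(index=False)
        ]
    raise ValidationError("fmt must be long|wide")


def write_incidence_csv(dataset: FluencyDataset, path) -> None:
    dataset.to_frame().to_csv(path, index_label="participant")


def read_incidence_csv(path, language: str = "D1", category: str = "animal") -> FluencyDataset:
    df = pd.read_csv(path, index_col=0)
    return FluencyDataset(
        incidence=df.to_numpy(dtype=np.int8),
        word_labels=[str(c) for c in df.columns],
        language=language,
        category=category,
        participant_ids=[str(i) for i in df.index],
    )


def write_edgelist_tsv(network: LexicalNetwork, path) -> None:
    """Weighted edge list, 6 decimal places, lexicographic pair order."""
    rows = sorted(
        (min(str(u), str(v)), max(str(u), str(v)), w) for u, v, w in network.edges()
    )
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tweight\n")
        for u, v, w in rows:
            fh.write(f"{u}\t{v}\t{w:.6f}\n")


def write_graphml(network: LexicalNetwork, path, communities: dict | None = None) -> None:
    G = network.graph.copy()
    if communities is not None:
        nx.set_node_attributes(G, communities, "community")
    nx.write_graphml(G, path)
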