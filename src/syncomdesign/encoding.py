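"""Genomic encoding: B-spline count transforms and Node2Vec graph embeddings.

Per-strain enzyme counts are mapped through a shared cubic B-spline basis
(degree 3, 10 interior knots on [0, 1]) after log1p stabilization and
per-enzyme min-max normalization across the strain panel; each enzyme
contributes two Greville-moment projections of its basis response, so 267
enzyme counts become 534 spline coefficients. Graph structure is summarized by 128-dimensional
Node2Vec embeddings (biased second-order random walks, skip-gram with
negative sampling); the concatenation yields the 662-dimensional node
feature vectors consumed by the attention predictor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.interpolate import BSpline

__all__ = [
    "SplineBasis",
    "SplineEncoder",
    "Node2VecParams",
    "NodeFeatures",
    "spline_encode",
    "node2vec_embed",
    "assemble_features",
    "build_feature_map",
]


# ---------------------------------------------------------------------------
# spline encoding


@dataclass
class SplineBasis:
    """Open-uniform cubic B-spline basis on [0, 1].

    ``n_knots`` interior knots are placed uniformly in (0, 1); with degree d
    this yields ``n_knots + d + 1`` basis functions. Each (normalized) count
    x is summarized by ``coefficients_per_enzyme`` Greville-moment
    projections of its basis response: coefficient m is
    ``sum_i xi_i^m B_i(x)`` with xi_i the Greville abscissae. By the linear
    precision of B-splines the first coefficient reproduces x exactly, so
    the encoding is injective, continuous and deterministic, and its value
    at 0 is identical for every enzyme.
    """

    degree: int = 3
    n_knots: int = 10
    coefficients_per_enzyme: int = 2
    knot_vector: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.degree < 1 or self.n_knots < 1 or self.coefficients_per_enzyme < 1:
            raise ValueError("degree, n_knots and coefficients_per_enzyme must be >= 1")
        interior = np.linspace(0.0, 1.0, self.n_knots + 2)[1:-1]
        self.knot_vector = np.concatenate(
            [np.zeros(self.degree + 1), interior, np.ones(self.degree + 1)]
        )
        if np.any(np.diff(self.knot_vector) < 0):
            raise ValueError("knot vector must be nondecreasing")

    @property
    def n_basis(self) -> int:
        return len(self.knot_vector) - self.degree - 1

    @property
    def greville_abscissae(self) -> np.ndarray:
        """Knot averages xi_i = mean(t_{i+1}, ..., t_{i+d})."""
        t, d = self.knot_vector, self.degree
        return np.array([t[i + 1 : i + 1 + d].mean() for i in range(self.n_basis)])

    def design_row(self, x: float) -> np.ndarray:
        """All basis-function values at x in [0, 1]."""
        t = self.knot_vector
        # clamp to the closed interval; BSpline.design_matrix requires x within
        x = min(max(float(x), 0.0), 1.0)
        row = BSpline.design_matrix([x], t, self.degree).toarray()[0]
        return row

    def encode_scalar(self, x: float) -> np.ndarray:
        """Greville-moment coefficients of the basis response at x.

        Coefficient m (m = 1..coefficients_per_enzyme) is
        ``sum_i xi_i^m B_i(x)``; the first reproduces x itself.
        """
        row = self.design_row(x)
        xi = self.greville_abscissae
        return np.array(
            [float(row @ xi ** (m + 1)) for m in range(self.coefficients_per_enzyme)]
        )


def spline_encode(counts, basis: SplineBasis, bounds: tuple | None = None) -> np.ndarray:
    """Encode one strain's enzyme counts as spline coefficients.

    Parameters
    ----------
    counts : 1-D array of nonnegative numbers
        Raw (or already normalized) per-enzyme counts.
    basis : SplineBasis
    bounds : (min array, max array), optional
        Per-enzyme normalization bounds; when given, each count is min-max
        normalized before basis evaluation (constant columns map to 0).
        Without bounds, counts are assumed to lie in [0, 1] already.

    Returns a vector of length ``coefficients_per_enzyme * len(counts)``;
    enzyme j occupies the contiguous coefficient block
    ``[m*j, m*(j+1))``.
    """
    x = np.asarray(counts, dtype=float)
    if x.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    if bounds is not None:
        lo, hi = (np.asarray(b, dtype=float) for b in bounds)
        span = hi - lo
        with np.errstate(invalid="ignore", divide="ignore"):
            x = np.where(span > 0, (x - lo) / np.where(span > 0, span, 1.0), 0.0)
        x = np.clip(x, 0.0, 1.0)
    out = np.empty(x.size * basis.coefficients_per_enzyme)
    m = basis.coefficients_per_enzyme
    for j, xv in enumerate(x):
        out[m * j : m * (j + 1)] = basis.encode_scalar(xv)
    return out


class SplineEncoder:
    """Panel-level spline encoder: fits per-enzyme min-max bounds, encodes rows.

    ``fit`` on the full strain x enzyme count matrix, then ``encode`` any
    strain's count vector (columns must match the fitted enzyme order).
    Counts are variance-stabilized with log1p before per-enzyme min-max
    normalization (``transform="none"`` disables this), the usual treatment
    for overdispersed copy-number data.
    """

    def __init__(self, basis: SplineBasis | None = None, transform: str = "log1p"):
        if transform not in ("log1p", "none"):
            raise ValueError("transform must be 'log1p' or 'none'")
        self.basis = basis or SplineBasis()
        self.transform = transform
        self._lo: np.ndarray | None = None
        self._hi: np.ndarray | None = None

    def _transformed(self, arr: np.ndarray) -> np.ndarray:
        return np.log1p(arr) if self.transform == "log1p" else arr

    def fit(self, count_matrix) -> "SplineEncoder":
        arr = np.asarray(count_matrix, dtype=float)
        if arr.ndim != 2:
            raise ValueError("count matrix must be 2-D (strain x enzyme)")
        arr = self._transformed(arr)
        self._lo = arr.min(axis=0)
        self._hi = arr.max(axis=0)
        return self

    @property
    def output_dim(self) -> int:
        if self._lo is None:
            raise RuntimeError("encoder not fitted")
        return self._lo.size * self.basis.coefficients_per_enzyme

    def encode(self, counts) -> np.ndarray:
        if self._lo is None:
            raise RuntimeError("encoder not fitted")
        counts = np.asarray(counts, dtype=float)
        if counts.shape != self._lo.shape:
            raise ValueError("count vector length does not match fitted enzyme set")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        return spline_encode(self._transformed(counts), self.basis, bounds=(self._lo, self._hi))

    def encode_matrix(self, count_matrix) -> np.ndarray:
        arr = np.asarray(count_matrix, dtype=float)
        return np.vstack([self.encode(row) for row in arr])


# ---------------------------------------------------------------------------
# Node2Vec


@dataclass
class Node2VecParams:
    """Biased second-order random-walk embedding hyperparameters.

    Defaults follow the standard community-detection-friendly regime used in
    this pipeline: 128 dimensions, walk length 80, 10 walks per node, context
    window 10, return parameter p = 1, in-out parameter q = 0.5 (mildly
    DFS-like, exploring outward).
    """

    dimensions: int = 128
    walk_length: int = 80
    walks_per_node: int = 10
    context: int = 10
    p: float = 1.0
    q: float = 0.5
    epochs: int = 3
    negative: int = 5
    learning_rate: float = 0.025
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.dimensions, self.walk_length, self.walks_per_node, self.context) < 1:
            raise ValueError("dimensions, walk_length, walks_per_node, context must be >= 1")
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")


def _generate_walks(graph: nx.Graph, params: Node2VecParams, rng: np.random.Generator):
    """Second-order biased walks (single-threaded, deterministic under seed)."""
    nodes = list(graph.nodes())
    neighbors = {v: sorted(graph.neighbors(v), key=str) for v in nodes}
    neighbor_sets = {v: set(nbrs) for v, nbrs in neighbors.items()}
    walks = []
    order = list(nodes)
    for _ in range(params.walks_per_node):
        rng.shuffle(order)
        for start in order:
            walk = [start]
            while len(walk) < params.walk_length:
                cur = walk[-1]
                nbrs = neighbors[cur]
                if not nbrs:
                    break
                if len(walk) == 1:
                    nxt = nbrs[int(rng.integers(len(nbrs)))]
                else:
                    prev = walk[-2]
                    prev_nbrs = neighbor_sets[prev]
                    # unnormalized transition bias: 1/p back, 1 at distance 1, 1/q outward
                    w = np.empty(len(nbrs))
                    for i, nb in enumerate(nbrs):
                        if nb == prev:
                            w[i] = 1.0 / params.p
                        elif nb in prev_nbrs:
                            w[i] = 1.0
                        else:
                            w[i] = 1.0 / params.q
                    w /= w.sum()
                    nxt = nbrs[int(rng.choice(len(nbrs), p=w))]
                walk.append(nxt)
            walks.append(walk)
    return walks


def _skipgram_train(
    walks, vocab: list, params: Node2VecParams, rng: np.random.Generator
) -> np.ndarray:
    """Skip-gram with negative sampling over walk corpora (vectorized SGD)."""
    index = {v: i for i, v in enumerate(vocab)}
    n = len(vocab)
    dim = params.dimensions

    # training pairs with random (per-position) window sizes, as in word2vec
    centers, contexts = [], []
    for walk in walks:
        ids = [index[v] for v in walk]
        L = len(ids)
        if L < 2:
            continue
        spans = rng.integers(1, params.context + 1, size=L)
        for pos in range(L):
            lo = max(0, pos - int(spans[pos]))
            hi = min(L, pos + int(spans[pos]) + 1)
            for c in range(lo, hi):
                if c != pos:
                    centers.append(ids[pos])
                    contexts.append(ids[c])
    centers = np.array(centers, dtype=np.int64)
    contexts = np.array(contexts, dtype=np.int64)
    if centers.size == 0:
        return np.zeros((n, dim))

    # unigram^(3/4) negative-sampling distribution
    freq = np.bincount(centers, minlength=n).astype(float)
    neg_p = freq**0.75
    neg_p /= neg_p.sum()

    w_in = (rng.random((n, dim)) - 0.5) / dim
    w_out = np.zeros((n, dim))

    n_pairs = centers.size
    batch = 4096
    total_steps = params.epochs * ((n_pairs + batch - 1) // batch)
    step = 0
    for _ in range(params.epochs):
        perm = rng.permutation(n_pairs)
        for s in range(0, n_pairs, batch):
            lr = params.learning_rate * max(1e-4, 1.0 - step / max(total_steps, 1))
            step += 1
            idx = perm[s : s + batch]
            ci, xi = centers[idx], contexts[idx]
            negs = rng.choice(n, size=(idx.size, params.negative), p=neg_p)
            vc = w_in[ci]  # (B, d)
            uo = w_out[xi]  # (B, d)
            un = w_out[negs]  # (B, k, d)
            pos_dot = np.clip(np.sum(vc * uo, axis=1), -30.0, 30.0)
            neg_dot = np.clip(np.einsum("bd,bkd->bk", vc, un), -30.0, 30.0)
            pos_score = 1.0 / (1.0 + np.exp(-pos_dot))  # (B,)
            neg_score = 1.0 / (1.0 + np.exp(-neg_dot))  # (B, k)
            g_pos = (pos_score - 1.0)[:, None]  # d/d(dot)
            g_neg = neg_score[..., None]  # (B, k, 1)
            grad_vc = g_pos * uo + np.einsum("bkd->bd", g_neg * un)
            grad_uo = g_pos * vc
            grad_un = g_neg * vc[:, None, :]
            np.add.at(w_in, ci, -lr * grad_vc)
            np.add.at(w_out, xi, -lr * grad_uo)
            np.add.at(w_out, negs.ravel(), -lr * grad_un.reshape(-1, dim))
    return w_in


def node2vec_embed(graph, params: Node2VecParams | None = None) -> dict:
    """Embed every graph node as a 128-vector (by default) via Node2Vec.

    Accepts a ``networkx.Graph`` or any object exposing ``.graph`` as one
    (e.g. a MetabolicGraph). Isolated nodes receive a self-loop before
    walking so every node appears in the corpus. Deterministic under
    ``params.seed`` (walk generation is single-threaded).
    """
    g = graph if isinstance(graph, nx.Graph) else graph.graph
    if g.number_of_nodes() == 0:
        raise ValueError("cannot embed an empty graph")
    params = params or Node2VecParams()
    g = g.copy()
    for v in list(g.nodes()):
        if g.degree(v) == 0:
            g.add_edge(v, v)
    rng = np.random.default_rng(params.seed)
    walks = _generate_walks(g, params, rng)
    vocab = sorted(g.nodes(), key=str)
    emb = _skipgram_train(walks, vocab, params, rng)
    return {v: emb[i].copy() for i, v in enumerate(vocab)}


# ---------------------------------------------------------------------------
# feature assembly


@dataclass(frozen=True)
class NodeFeatures:
    """Concatenated node representation: spline block then embedding block."""

    spline_part: np.ndarray
    embedding_part: np.ndarray

    @property
    def combined(self) -> np.ndarray:
        return np.concatenate([self.spline_part, self.embedding_part])

    def __len__(self) -> int:
        return self.spline_part.size + self.embedding_part.size


def assemble_features(
    spline_part,
    embedding_part,
    expected_spline_dim: int | None = None,
    expected_embedding_dim: int | None = None,
) -> NodeFeatures:
    """Concatenate spline coefficients and graph embedding into node features.

    The assembly is lossless: both parts are recoverable by slicing the
    combined vector at the spline dimension.
    """
    sp = np.asarray(spline_part, dtype=float)
    em = np.asarray(embedding_part, dtype=float)
    if sp.ndim != 1 or em.ndim != 1:
        raise ValueError("feature parts must be 1-D vectors")
    if not (np.all(np.isfinite(sp)) and np.all(np.isfinite(em))):
        raise ValueError("feature parts must be finite")
    if expected_spline_dim is not None and sp.size != expected_spline_dim:
        raise ValueError(f"spline part has length {sp.size}, expected {expected_spline_dim}")
    if expected_embedding_dim is not None and em.size != expected_embedding_dim:
        raise ValueError(f"embedding part has length {em.size}, expected {expected_embedding_dim}")
    return NodeFeatures(spline_part=sp, embedding_part=em)


def build_feature_map(mg, encoder: SplineEncoder, embeddings: dict) -> dict:
    """Full-graph node feature table: node ID -> combined feature vector.

    Strain nodes carry their spline-encoded count profile concatenated with
    their graph embedding; enzyme and metabolite nodes have no count profile,
    so their spline block is zero and only the embedding block is informative.
    All vectors share the dimension spline_dim + embedding_dim.
    """
    if mg.profiles is None:
        raise ValueError("graph carries no profile table")
    spline_dim = encoder.output_dim
    out: dict = {}
    for s in mg.strains:
        sp = encoder.encode(mg.profiles.loc[s].to_numpy())
        out[s] = assemble_features(sp, embeddings[s]).combined
    zero_sp = np.zeros(spline_dim)
    for v in list(mg.enzymes) + list(mg.metabolites):
        out[v] = assemble_features(zero_sp, embeddings[v]).combined
    return out
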