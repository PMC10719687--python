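"""Mixed graphical model estimation by nodewise regressions.

Each variable is regressed on all others: continuous nodes by ordinary
least squares (categorical neighbours one-hot encoded, reference level
dropped), categorical nodes by maximum-likelihood multinomial logistic
regression (optionally ridge-stabilised).  Per-neighbour coefficient
blocks from the two directions are aggregated into a single undirected
weighted network; edge presence is decided by Wald block tests (default:
per-node Bonferroni at family-wise level 0.05, AND-combined across the two
directions) or by a magnitude threshold.

No sparsity penalty is applied by default: cross-group associations are
expected to be much weaker than within-group ones and would be the first
casualties of uniform penalisation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .variables import (
    CollinearityError,
    ConvergenceError,
    MixedDataMatrix,
    SpecificationError,
    VariableSpec,
)

__all__ = [
    "Network",
    "NodewiseFit",
    "MixedGraphicalModel",
    "MGMResults",
    "fit_node",
    "threshold_edges",
    "aggregate_edges",
]

logger = logging.getLogger(__name__)

POSITIVE, NEGATIVE, UNDETERMINED = "+", "-", "undetermined"


# ---------------------------------------------------------------------------
# network container
# ---------------------------------------------------------------------------


@dataclass
class Network:
    """Undirected weighted graph over the fitted variables.

    Edges are keyed on node-name pairs ordered by variable index; weights
    are non-negative magnitudes, signs are '+', '-' or 'undetermined' (the
    latter only possible for edges touching a categorical node).  Pairs
    absent from the map have weight zero.
    """

    nodes: list[VariableSpec]
    edges: dict[tuple[str, str], tuple[float, str]] = field(default_factory=dict)
    fitted_n: int = 0

    def __post_init__(self):
        self._index = {s.name: k for k, s in enumerate(self.nodes)}

    def key(self, a: str, b: str) -> tuple[str, str]:
        if a not in self._index or b not in self._index:
            raise SpecificationError(f"unknown node in pair ({a}, {b})")
        if a == b:
            raise SpecificationError("self-edges are not allowed")
        return (a, b) if self._index[a] < self._index[b] else (b, a)

    def add_edge(self, a: str, b: str, weight: float, sign: str = UNDETERMINED):
        if weight < 0:
            raise SpecificationError("edge weight must be non-negative")
        if weight > 0:
            self.edges[self.key(a, b)] = (float(weight), sign)

    def weight(self, a: str, b: str) -> float:
        return self.edges.get(self.key(a, b), (0.0, UNDETERMINED))[0]

    def node_names(self) -> list[str]:
        return [s.name for s in self.nodes]

    def spec(self, name: str) -> VariableSpec:
        if name not in self._index:
            raise SpecificationError(f"unknown node {name!r}")
        return self.nodes[self._index[name]]

    def incident(self, name: str) -> list[tuple[tuple[str, str], float]]:
        return [(k, w) for k, (w, _) in self.edges.items() if name in k]

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        for s in self.nodes:
            g.add_node(s.name, kind=s.kind, group=s.group, index=s.index,
                       n_levels=s.n_levels)
        for (a, b), (w, sign) in self.edges.items():
            g.add_edge(a, b, weight=w, sign=sign, length=1.0 / w)
        return g


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


@dataclass
class _Design:
    matrix: np.ndarray                       # n x F, no intercept
    spans: dict[str, tuple[int, int]]        # variable -> column span
    levels_used: dict[str, list[int]]        # categorical -> levels in design order


def build_design(data: MixedDataMatrix, ordinal_as_numeric: bool = False) -> _Design:
    """One-hot (reference level dropped) categorical columns plus raw
    continuous columns, concatenated in variable order."""
    cols, spans, levels_used = [], {}, {}
    start = 0
    for j, s in enumerate(data.specs):
        x = data.values[:, j]
        if s.is_categorical and not ordinal_as_numeric:
            present = np.unique(x[~np.isnan(x)]).astype(int).tolist()
            if len(present) < len(range(s.n_levels)):
                logger.warning(
                    "node %s: levels %s absent from data, dropped from design",
                    s.name, sorted(set(range(s.n_levels)) - set(present)),
                )
            if len(present) < 2:
                raise SpecificationError(f"categorical column {s.name!r} is constant")
            ref, rest = present[0], present[1:]
            block = np.column_stack([(x == lv).astype(float) for lv in rest])
            levels_used[s.name] = present
            cols.append(block)
            spans[s.name] = (start, start + len(rest))
            start += len(rest)
        else:
            cols.append(x[:, None])
            spans[s.name] = (start, start + 1)
            start += 1
    return _Design(np.hstack(cols), spans, levels_used)


def _neighbor_columns(design: _Design, node: str) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Design excluding the node's own columns, plus per-neighbour column
    positions in the reduced matrix."""
    lo, hi = design.spans[node]
    keep = np.r_[np.arange(lo), np.arange(hi, design.matrix.shape[1])]
    X = design.matrix[:, keep]
    positions = {}
    for name, (a, b) in design.spans.items():
        if name == node:
            continue
        idx = np.arange(a, b)
        idx = np.where(idx >= hi, idx - (hi - lo), idx)
        positions[name] = idx
    return X, positions


# ---------------------------------------------------------------------------
# nodewise fits
# ---------------------------------------------------------------------------


@dataclass
class NodewiseFit:
    """One conditional regression and its per-neighbour coefficient blocks.

    Blocks are padded to full shape: for a categorical node the first axis
    runs over all its levels (reference and absent levels zero); a
    categorical neighbour contributes an axis over its levels likewise.
    """

    node: VariableSpec
    blocks: dict[str, np.ndarray]
    pvalues: dict[str, float]
    converged: bool
    loglik: float
    n: int
    intercepts: np.ndarray | None = None

    def block_strength(self, neighbor: str) -> float:
        """Mean absolute value over the block's free (non-reference)
        parameters."""
        blk = np.asarray(self.blocks[neighbor])
        free = _free_entries(blk, self.node.is_categorical)
        return float(np.mean(np.abs(free))) if free.size else 0.0


def _free_entries(blk: np.ndarray, node_is_cat: bool) -> np.ndarray:
    """Drop the structurally-zero reference entries from a block."""
    b = np.atleast_1d(np.asarray(blk, float))
    if b.ndim == 2:
        return b[1:, 1:].ravel()
    if b.ndim == 1 and b.shape[0] > 1:
        return b[1:]
    return b.ravel()


def fit_node(
    data: MixedDataMatrix,
    node: VariableSpec | str,
    penalty: float = 0.0,
    ordinal_as_numeric: bool = False,
    design: _Design | None = None,
    max_iter: int = 500,
) -> NodewiseFit:
    """Regress one node on all others and return its coefficient blocks.

    Continuous node: OLS with per-neighbour F tests.  Categorical node:
    multinomial logistic regression by maximum likelihood (ridge with
    strength ``penalty`` if > 0) with Wald chi-square block tests from the
    observed information.
    """
    name = node if isinstance(node, str) else node.name
    spec = data.spec(name)
    if design is None:
        design = build_design(data, ordinal_as_numeric)
    X, positions = _neighbor_columns(design, name)
    n = data.n
    y = data.column(name)
    if np.isnan(data.values).any():
        raise SpecificationError("nodewise fits require complete data (run preprocess)")
    n_params = X.shape[1] + 1
    if spec.is_categorical and not ordinal_as_numeric:
        n_params *= spec.n_levels - 1
    if n <= n_params:
        raise SpecificationError(
            f"node {name!r}: n={n} too small for {n_params} parameters"
        )

    if spec.is_categorical and not ordinal_as_numeric:
        return _fit_categorical(spec, y, X, positions, design, penalty, max_iter, n)
    return _fit_continuous(spec, y, X, positions, design, n)


def _pad_block(node_spec, nbr_name, design, raw, node_levels=None):
    """Embed fitted coefficients into the full (reference-padded) block."""
    nbr_levels = design.levels_used.get(nbr_name)
    if node_levels is None:                        # continuous node
        if nbr_levels is None:
            return np.asarray(raw).reshape(())     # scalar
        full = np.zeros(max(nbr_levels) + 1)
        for c, lv in enumerate(nbr_levels[1:]):
            full[lv] = raw[c]
        return full
    K = node_spec.n_levels
    raw = np.asarray(raw)
    if nbr_levels is None:
        if raw.ndim == 2:
            raw = raw[:, 0]
        full = np.zeros(K)
        for r, lv in enumerate(node_levels[1:]):
            full[lv] = raw[r]
        return full
    full = np.zeros((K, max(nbr_levels) + 1))
    for r, lv in enumerate(node_levels[1:]):
        for c, mv in enumerate(nbr_levels[1:]):
            full[lv, mv] = raw[r, c]
    return full


def _fit_continuous(spec, y, X, positions, design, n) -> NodewiseFit:
    X1 = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = scipy.linalg.lstsq(X1, y)
    if rank < X1.shape[1]:
        raise CollinearityError(f"node {spec.name!r}: rank-deficient design")
    resid = y - X1 @ beta
    dof = n - X1.shape[1]
    s2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.inv(X1.T @ X1)
    blocks, pvalues = {}, {}
    for nbr, idx in positions.items():
        bidx = idx + 1                              # skip intercept
        b = beta[bidx]
        V = s2 * XtX_inv[np.ix_(bidx, bidx)]
        q = len(bidx)
        try:
            stat = float(b @ np.linalg.solve(V, b)) / q
        except np.linalg.LinAlgError:
            raise CollinearityError(f"node {spec.name!r}: singular block for {nbr!r}")
        pvalues[nbr] = float(scipy.stats.f.sf(stat, q, dof))
        blocks[nbr] = _pad_block(spec, nbr, design, b)
    ll = -0.5 * n * (np.log(2 * np.pi * s2) + 1.0)
    return NodewiseFit(spec, blocks, pvalues, True, ll, n, np.atleast_1d(beta[0]))


def _fit_categorical(spec, y, X, positions, design, penalty, max_iter, n) -> NodewiseFit:
    classes = np.unique(y).astype(int)
    node_levels = classes.tolist()
    if len(node_levels) < 2:
        raise SpecificationError(f"categorical node {spec.name!r} is constant")
    C = (1.0 / penalty) if penalty > 0 else np.inf
    clf = LogisticRegression(C=C, solver="lbfgs", max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            clf.fit(X, y.astype(int))
        except ConvergenceWarning:
            raise ConvergenceError(
                f"multinomial fit for node {spec.name!r} did not converge; "
                "consider penalty > 0"
            ) from None
    # reference-level parameterisation: subtract the first class's row
    K = len(node_levels)
    coef = np.column_stack([clf.intercept_, clf.coef_])        # K x (F+1)
    if coef.shape[0] == 1:                                     # binary: sklearn gives 1 row
        coef = np.vstack([np.zeros_like(coef[0]), coef[0]])
    B = coef - coef[0]
    # observed information in the reference parameterisation
    X1 = np.column_stack([np.ones(n), X])
    logits = X1 @ coef.T
    logits -= logits.max(axis=1, keepdims=True)
    P = np.exp(logits)
    P /= P.sum(axis=1, keepdims=True)
    if penalty == 0:
        # complete separation: the likelihood has no maximiser; lbfgs stops
        # at some saturated point with runaway coefficients
        predicted = np.asarray(node_levels)[P.argmax(axis=1)]
        if np.abs(B).max() > 10 and np.array_equal(predicted, y.astype(int)):
            raise ConvergenceError(
                f"separation in multinomial fit for node {spec.name!r}; "
                "consider penalty > 0"
            )
    F1 = X1.shape[1]
    H = np.empty(((K - 1) * F1, (K - 1) * F1))
    for a in range(1, K):
        for b in range(a, K):
            w = P[:, a] * ((1.0 if a == b else 0.0) - P[:, b])
            blk = X1.T @ (X1 * w[:, None])
            if penalty > 0:
                blk = blk + (penalty * np.eye(F1) if a == b else 0.0)
            H[(a - 1) * F1:a * F1, (b - 1) * F1:b * F1] = blk
            if a != b:
                H[(b - 1) * F1:b * F1, (a - 1) * F1:a * F1] = blk.T
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        raise ConvergenceError(
            f"singular information matrix for node {spec.name!r} (separation?); "
            "consider penalty > 0"
        ) from None
    blocks, pvalues = {}, {}
    for nbr, idx in positions.items():
        bidx = idx + 1
        rows = np.concatenate([(a - 1) * F1 + bidx for a in range(1, K)])
        theta = np.concatenate([B[a, bidx] for a in range(1, K)])
        V = cov[np.ix_(rows, rows)]
        try:
            stat = float(theta @ np.linalg.solve(V, theta))
        except np.linalg.LinAlgError:
            raise ConvergenceError(
                f"singular Wald covariance for node {spec.name!r}, neighbour {nbr!r}"
            ) from None
        pvalues[nbr] = float(scipy.stats.chi2.sf(stat, len(theta)))
        raw = B[1:, bidx]                         # (K-1) x q in class order
        blocks[nbr] = _pad_block(spec, nbr, design, raw, node_levels)
    yi = y.astype(int)
    class_pos = {c: k for k, c in enumerate(node_levels)}
    ll = float(np.sum(np.log(P[np.arange(n), [class_pos[c] for c in yi]] + 1e-300)))
    intercepts = np.zeros(spec.n_levels)
    for r, lv in enumerate(node_levels):
        intercepts[lv] = B[r, 0]
    return NodewiseFit(spec, blocks, pvalues, True, ll, n, intercepts)


# ---------------------------------------------------------------------------
# thresholding and aggregation
# ---------------------------------------------------------------------------


def threshold_edges(
    fit: NodewiseFit,
    rule: str = "wald",
    alpha: float = 0.05,
    tau: float | None = None,
    correction: str = "bonferroni",
) -> dict[str, bool]:
    """Per-neighbour presence flags for one nodewise fit.

    ``wald``: the joint test of the neighbour's whole coefficient block;
    with ``correction="bonferroni"`` the level is ``alpha`` family-wise
    over the node's candidate neighbours.  ``magnitude``: mean absolute
    block value > ``tau``.
    """
    if not fit.converged:
        raise ConvergenceError(f"fit for {fit.node.name!r} did not converge")
    if rule == "wald":
        m = len(fit.pvalues)
        cut = alpha / m if correction == "bonferroni" else alpha
        return {nbr: p < cut for nbr, p in fit.pvalues.items()}
    if rule == "magnitude":
        if tau is None:
            raise SpecificationError("magnitude rule requires tau")
        return {nbr: fit.block_strength(nbr) > tau for nbr in fit.blocks}
    raise SpecificationError(f"unknown presence rule {rule!r}")


def _block_sign(blk: np.ndarray, node_is_cat: bool) -> str:
    free = _free_entries(blk, node_is_cat)
    if free.size and np.all(free > 0):
        return POSITIVE
    if free.size and np.all(free < 0):
        return NEGATIVE
    return UNDETERMINED


def aggregate_edges(
    fits: list[NodewiseFit],
    presence_rule: str = "and",
    rule: str = "wald",
    alpha: float = 0.05,
    tau: float | None = None,
    correction: str = "bonferroni",
    fitted_n: int | None = None,
) -> Network:
    """Combine nodewise fits into one undirected network.

    Edge weight is the mean of the two directions' mean absolute block
    values; the sign is kept only when every free entry of both blocks
    shares it.  ``presence_rule`` ('and'/'or') combines the two
    directional presence flags.
    """
    byname = {f.node.name: f for f in fits}
    names = list(byname)
    for f in fits:
        missing = set(f.blocks) - set(names)
        if missing:
            raise SpecificationError(f"fit for {f.node.name!r} references unknown nodes {missing}")
    if presence_rule not in ("and", "or"):
        raise SpecificationError(f"unknown presence_rule {presence_rule!r}")
    flags = {
        name: threshold_edges(f, rule=rule, alpha=alpha, tau=tau, correction=correction)
        for name, f in byname.items()
    }
    specs = sorted((f.node for f in fits), key=lambda s: s.index)
    net = Network(nodes=specs, fitted_n=fitted_n or fits[0].n)
    for a_i in range(len(specs)):
        for b_i in range(a_i + 1, len(specs)):
            a, b = specs[a_i].name, specs[b_i].name
            fa, fb = byname[a], byname[b]
            present_ab, present_ba = flags[a].get(b, False), flags[b].get(a, False)
            present = (present_ab and present_ba) if presence_rule == "and" \
                else (present_ab or present_ba)
            if not present:
                continue
            w = 0.5 * (fa.block_strength(b) + fb.block_strength(a))
            if w <= 0:
                continue
            s1 = _block_sign(fa.blocks[b], fa.node.is_categorical)
            s2 = _block_sign(fb.blocks[a], fb.node.is_categorical)
            sign = s1 if s1 == s2 and s1 != UNDETERMINED else UNDETERMINED
            if not (specs[a_i].is_categorical or specs[b_i].is_categorical):
                # continuous-continuous: both directions carry the same sign
                sign = s1
            net.add_edge(a, b, w, sign)
    return net


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class MixedGraphicalModel:
    """Pairwise mixed graphical model over ordinal and continuous variables.

    Parameters
    ----------
    data : MixedDataMatrix
        Complete (post-preprocess) data.
    penalty : float
        Ridge strength for the multinomial nodewise fits; 0 (default)
        fits by plain maximum likelihood.
    ordinal_as_numeric : bool
        Sensitivity mode treating ordinal items as numeric scores.

    Examples
    --------
    >>> model = MixedGraphicalModel(data)
    >>> res = model.fit()
    >>> res.network.edges
    """

    def __init__(self, data: MixedDataMatrix, penalty: float = 0.0,
                 ordinal_as_numeric: bool = False):
        data.validate()
        if np.isnan(data.values).any():
            raise SpecificationError(
                "MixedGraphicalModel requires complete data; run preprocess first"
            )
        self.data = data
        self.penalty = float(penalty)
        self.ordinal_as_numeric = bool(ordinal_as_numeric)

    @classmethod
    def from_dataframe(cls, frame, specs, **kwargs) -> "MixedGraphicalModel":
        return cls(MixedDataMatrix.from_frame(frame, specs), **kwargs)

    def fit_node(self, node: str, design: _Design | None = None,
                 max_iter: int = 500) -> NodewiseFit:
        return fit_node(self.data, node, penalty=self.penalty,
                        ordinal_as_numeric=self.ordinal_as_numeric,
                        design=design, max_iter=max_iter)

    def fit(self, rule: str = "wald", alpha: float = 0.05,
            tau: float | None = None, correction: str = "bonferroni",
            presence_rule: str = "and", max_iter: int = 500) -> "MGMResults":
        design = build_design(self.data, self.ordinal_as_numeric)
        fits = [self.fit_node(s.name, design=design, max_iter=max_iter)
                for s in self.data.specs]
        net = aggregate_edges(fits, presence_rule=presence_rule, rule=rule,
                              alpha=alpha, tau=tau, correction=correction,
                              fitted_n=self.data.n)
        config = dict(rule=rule, alpha=alpha, tau=tau, correction=correction,
                      presence_rule=presence_rule, penalty=self.penalty,
                      ordinal_as_numeric=self.ordinal_as_numeric)
        return MGMResults(self, fits, net, config)


class MGMResults:
    """Fitted network plus the nodewise fits it was aggregated from."""

    def __init__(self, model: MixedGraphicalModel, fits: list[NodewiseFit],
                 network: Network, config: dict):
        self.model = model
        self.fits = {f.node.name: f for f in fits}
        self.network = network
        self.config = config

    def centrality(self, ratio_on_raw: bool = True):
        from .metrics import centrality_table

        return centrality_table(self.network, ratio_on_raw=ratio_on_raw)

    def bridges(self):
        from .metrics import extract_bridges

        return extract_bridges(self.network)

    def bootstrap(self, B: int = 50, seed: int = 0, covariates=None,
                  adjust_for=None, **kwargs):
        from .stability import bootstrap_network

        return bootstrap_network(
            self.model.data, B=B, seed=seed, covariates=covariates,
            adjust_for=adjust_for, config=self.config, **kwargs
        )

    def summary(self) -> str:
        net = self.network
        n_cat = sum(s.is_categorical for s in net.nodes)
        n_cont = len(net.nodes) - n_cat
        bridges = [k for k in net.edges
                   if net.spec(k[0]).is_symptom != net.spec(k[1]).is_symptom
                   and (net.spec(k[0]).is_metabolite or net.spec(k[1]).is_metabolite)]
        lines = [
            "Mixed Graphical Model (nodewise estimation)",
            "=" * 46,
            f"nodes:            {len(net.nodes)} ({n_cat} categorical, {n_cont} continuous)",
            f"sample size:      {net.fitted_n}",
            f"edges:            {len(net.edges)}",
            f"bridge edges:     {len(bridges)}",
            f"presence rule:    {self.config['rule']} "
            f"(alpha={self.config['alpha']}, correction={self.config['correction']}, "
            f"{self.config['presence_rule'].upper()} across directions)",
            f"penalty:          {self.config['penalty']}",
            "",
            "strongest edges:",
        ]
        top = sorted(net.edges.items(), key=lambda kv: -kv[1][0])[:10]
        for (a, b), (w, sign) in top:
            lines.append(f"  {a:24s} -- {b:24s} {w:7.4f} ({sign})")
        return "\n".join(lines)
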