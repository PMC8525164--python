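"""DEC* dispersal-extinction-cladogenesis model on host-family ranges.

A fly lineage's state is a non-empty subset ("range") of a fixed list of
host families. Along a branch the range evolves as a continuous-time Markov
chain: dispersal adds one family at rate d per addable family, extirpation
removes one family at rate e per removable family. In the DEC* variant used
here the null (empty) range is excluded from the state space entirely, so a
single-family range cannot be extirpated. At a speciation event a range of
size >= 2 is partitioned between the daughters by subset sympatry (one
daughter inherits one family, the other the full range) or vicariance (one
family vs the rest), each distinct ordered daughter pair equally likely;
single-family ranges are inherited identically by both daughters.

The likelihood is computed by Felsenstein pruning with the cladogenetic
mixing at internal nodes; branch propagation uses the action of the matrix
exponential on partial-likelihood vectors (sparse, so the full 2^|F|-1 state
space for 9 families remains fast). Rates (d, e) are estimated by bounded
ML on the log scale from three deterministic starts, and ancestral ranges
are reported as marginal state probabilities at each internal node just
before its split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.sparse.linalg import expm_multiply

from .trees import PhyloTree, check_ultrametric

logger = logging.getLogger(__name__)

MAX_FAMILIES = 12


class _ZeroLikelihood(Exception):
    """Internal: the tip configuration has probability zero."""

__all__ = [
    "RangeStateSpace",
    "DECParams",
    "DECFit",
    "AncestralEstimate",
    "build_state_space",
    "anagenetic_rate_matrix",
    "transition_probabilities",
    "cladogenesis_table",
    "dec_loglik",
    "fit_dec",
    "ancestral_states",
]


@dataclass(frozen=True)
class DECParams:
    """Anagenetic rates, per family per Myr."""

    d: float  # dispersal (family gain)
    e: float  # extirpation (family loss)

    def __post_init__(self) -> None:
        if not (np.isfinite(self.d) and np.isfinite(self.e)):
            raise ValueError("rates must be finite")
        if self.d < 0 or self.e < 0:
            raise ValueError("rates must be non-negative")


class RangeStateSpace:
    """All non-empty subsets of a family list up to a maximum range size.

    States are ordered by size, then lexicographically by member indices;
    the empty range is never included.
    """

    def __init__(self, families: Sequence[str], max_size: int | None = None):
        families = list(families)
        if len(families) > MAX_FAMILIES:
            n = len(families)
            raise ValueError(
                f"{n} families would give up to 2^{n}-1 = {2**n - 1} range "
                f"states; the engine is capped at {MAX_FAMILIES} families"
            )
        if len(set(families)) != len(families):
            raise ValueError("family names must be unique")
        if max_size is None:
            max_size = len(families)
        if not 1 <= max_size <= len(families):
            raise ValueError("max_size must be in [1, n_families]")
        self.families = tuple(families)
        self.max_size = int(max_size)
        n = len(families)
        states: list[tuple[int, ...]] = []
        for k in range(1, max_size + 1):
            states.extend(combinations(range(n), k))
        self.states: list[frozenset[str]] = [
            frozenset(families[i] for i in s) for s in states
        ]
        self._masks = [sum(1 << i for i in s) for s in states]
        self._mask_index = {m: i for i, m in enumerate(self._masks)}
        self.index = {s: i for i, s in enumerate(self.states)}
        self._build_rate_pattern()
        self._clad: tuple[np.ndarray, ...] | None = None

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, families: Iterable[str]) -> int:
        key = frozenset(families)
        if key not in self.index:
            raise KeyError(f"range {sorted(key)} not in state space")
        return self.index[key]

    def _build_rate_pattern(self) -> None:
        n = len(self.families)
        gain_r, gain_c, loss_r, loss_c = [], [], [], []
        for i, mask in enumerate(self._masks):
            size = bin(mask).count("1")
            for f in range(n):
                bit = 1 << f
                if not mask & bit and size + 1 <= self.max_size:
                    gain_r.append(i)
                    gain_c.append(self._mask_index[mask | bit])
                if mask & bit and size >= 2:
                    loss_r.append(i)
                    loss_c.append(self._mask_index[mask & ~bit])
        S = self.n_states
        self._gain = sparse.csr_matrix(
            (np.ones(len(gain_r)), (gain_r, gain_c)), shape=(S, S)
        )
        self._loss = sparse.csr_matrix(
            (np.ones(len(loss_r)), (loss_r, loss_c)), shape=(S, S)
        )

    def rate_matrix_sparse(self, params: DECParams) -> sparse.csr_matrix:
        Q = params.d * self._gain + params.e * self._loss
        Q = Q - sparse.diags(np.asarray(Q.sum(axis=1)).ravel())
        return Q.tocsr()

    def cladogenesis_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(parent_idx, left_idx, right_idx, prob) arrays over all events."""
        if self._clad is None:
            pi, li, ri, pr = [], [], [], []
            for p, (mask, state) in enumerate(zip(self._masks, self.states)):
                for l, r, w in _events_for(mask, self._mask_index):
                    pi.append(p)
                    li.append(l)
                    ri.append(r)
                    pr.append(w)
            self._clad = (
                np.array(pi, dtype=np.intp),
                np.array(li, dtype=np.intp),
                np.array(ri, dtype=np.intp),
                np.array(pr, dtype=float),
            )
        return self._clad


def _events_for(mask: int, mask_index: dict[int, int]) -> list[tuple[int, int, float]]:
    """Distinct ordered daughter pairs for one parent range, with uniform
    probabilities. Size-1 ranges are copied to both daughters."""
    size = bin(mask).count("1")
    self_idx = mask_index[mask]
    if size == 1:
        return [(self_idx, self_idx, 1.0)]
    pairs: set[tuple[int, int]] = set()
    bits = [b for b in range(mask.bit_length()) if mask & (1 << b)]
    for b in bits:
        single = mask_index[1 << b]
        rest_mask = mask & ~(1 << b)
        rest = mask_index[rest_mask]
        # subset sympatry: {f} vs full parent range, both orders
        pairs.add((single, self_idx))
        pairs.add((self_idx, single))
        # vicariance: {f} vs the remainder, both orders
        pairs.add((single, rest))
        pairs.add((rest, single))
    w = 1.0 / len(pairs)
    return [(l, r, w) for l, r in sorted(pairs)]


def build_state_space(
    families: Sequence[str], max_size: int | None = None
) -> RangeStateSpace:
    """State space of all non-empty ranges of ``families`` up to ``max_size``."""
    return RangeStateSpace(families, max_size)


def anagenetic_rate_matrix(space: RangeStateSpace, params: DECParams) -> np.ndarray:
    """Dense generator Q: gains at rate d, losses at rate e, DEC* (no null)."""
    return space.rate_matrix_sparse(params).toarray()


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1, tiny negative entries clamped to 0."""
    if t < 0:
        raise ValueError("elapsed time must be non-negative")
    P = expm(np.asarray(Q, dtype=float) * t)
    neg = P < 0
    if neg.any():
        worst = P[neg].min()
        if worst < -1e-12:
            raise FloatingPointError(f"matrix exponential produced entry {worst}")
        logger.debug("clamped %d tiny negative entries to 0", int(neg.sum()))
        P[neg] = 0.0
    return P


def cladogenesis_table(
    space: RangeStateSpace,
) -> list[tuple[frozenset[str], frozenset[str], frozenset[str], float]]:
    """All cladogenetic events as (parent, left, right, probability)."""
    pi, li, ri, pr = space.cladogenesis_arrays()
    return [
        (space.states[p], space.states[l], space.states[r], float(w))
        for p, l, r, w in zip(pi, li, ri, pr)
    ]


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------

_DENSE_LIMIT = 64  # below this many states, cache dense exp(Qt) per branch


class _Propagator:
    """exp(Qt) . v for many branch lengths under one fixed Q."""

    def __init__(self, space: RangeStateSpace, params: DECParams, transpose: bool = False):
        Q = space.rate_matrix_sparse(params)
        self._Q = Q.T.tocsr() if transpose else Q
        self._dense = space.n_states <= _DENSE_LIMIT
        self._cache: dict[float, np.ndarray] = {}

    def __call__(self, t: float, v: np.ndarray) -> np.ndarray:
        if t == 0:
            return v.copy()
        if self._dense:
            P = self._cache.get(t)
            if P is None:
                P = expm(self._Q.toarray() * t)
                self._cache[t] = P
            return P @ v
        return expm_multiply(self._Q * t, v)


def _check_tree_and_tips(
    tree: PhyloTree, tips: Mapping[str, Iterable[str]], space: RangeStateSpace
) -> None:
    ok, dev = check_ultrametric(tree, rel_tol=1e-6)
    if not ok:
        raise ValueError(
            f"tree is not ultrametric (max relative depth deviation {dev:.3g}); "
            "rescale with strict_clock_chronogram first"
        )
    if not tree.is_binary():
        raise ValueError("tree has polytomies; resolve them first")
    labels = set(tree.tip_labels)
    if labels != set(tips):
        raise ValueError(
            f"tip state labels do not match tree tips "
            f"(missing={sorted(labels - set(tips))}, extra={sorted(set(tips) - labels)})"
        )
    for lab, fams in tips.items():
        if not set(fams):
            raise ValueError(f"tip {lab!r} has an empty range (DEC* forbids it)")


def _below_pass(
    tree: PhyloTree,
    tips: Mapping[str, Iterable[str]],
    params: DECParams,
    space: RangeStateSpace,
):
    """Post-order partials. Returns (node->partial just before cladogenesis,
    node->partial at top of its branch, total log-scaler)."""
    prop = _Propagator(space, params)
    pi, li, ri, pr = space.cladogenesis_arrays()
    S = space.n_states
    below: dict = {}
    top: dict = {}
    logscale = 0.0
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            v = np.zeros(S)
            v[space.state_index(tips[node.taxon.label])] = 1.0
            below[node] = v
        else:
            children = node.child_nodes()
            vt = []
            for ch in children:
                w = prop(ch.edge.length or 0.0, below[ch])
                top[ch] = w
                vt.append(w)
            vl, vr = vt
            acc = np.zeros(S)
            np.add.at(acc, pi, pr * vl[li] * vr[ri])
            s = acc.sum()
            if s <= 0:
                raise _ZeroLikelihood
            logscale += np.log(s)
            below[node] = acc / s
    return below, top, logscale


def dec_loglik(
    tree: PhyloTree,
    tips: Mapping[str, Iterable[str]],
    params: DECParams,
    space: RangeStateSpace,
) -> float:
    """Log-likelihood of the tip ranges under DEC* with a uniform root prior."""
    _check_tree_and_tips(tree, tips, space)
    try:
        below, _, logscale = _below_pass(tree, tips, params, space)
    except _ZeroLikelihood:
        return -np.inf
    root = tree.dendropy_tree.seed_node
    prior = 1.0 / space.n_states
    lik = prior * below[root].sum()
    if lik <= 0:
        return -np.inf
    return float(np.log(lik) + logscale)


@dataclass
class DECFit:
    params: DECParams
    loglik: float
    at_bound: bool
    n_starts: int


def fit_dec(
    tree: PhyloTree,
    tips: Mapping[str, Iterable[str]],
    space: RangeStateSpace,
    bounds: tuple[float, float] = (1e-9, 10.0),
    fix_d: float | None = None,
    fix_e: float | None = None,
) -> DECFit:
    """ML estimation of (d, e) by L-BFGS-B on log-rates, 3 deterministic starts."""
    _check_tree_and_tips(tree, tips, space)
    lo, hi = np.log(bounds[0]), np.log(bounds[1])
    height = tree.height
    # starts bracket slow/medium dispersal relative to tree depth
    starts = [
        (0.1 / height, 0.1 / height),
        (1.0 / height, 0.1 / height),
        (0.1 / height, 1.0 / height),
    ]

    def unpack(z: np.ndarray) -> DECParams:
        vals = iter(np.exp(z))
        d = fix_d if fix_d is not None else next(vals)
        e = fix_e if fix_e is not None else next(vals)
        return DECParams(d, e)

    def nll(z: np.ndarray) -> float:
        ll = dec_loglik(tree, tips, unpack(z), space)
        return -ll if np.isfinite(ll) else 1e12

    n_free = (fix_d is None) + (fix_e is None)
    if n_free == 0:
        p = DECParams(fix_d, fix_e)
        return DECFit(p, dec_loglik(tree, tips, p, space), False, 0)
    best = None
    for s in starts:
        z0 = np.log([v for v, fixed in zip(s, (fix_d, fix_e)) if fixed is None])
        z0 = np.clip(z0, lo, hi)
        res = minimize(
            nll,
            z0,
            method="L-BFGS-B",
            bounds=[(lo, hi)] * n_free,
            options={"ftol": 1e-10, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    z = np.clip(best.x, lo, hi)
    params = unpack(z)
    at_bound = bool(np.any(z <= lo + 1e-6) or np.any(z >= hi - 1e-6))
    if at_bound:
        logger.warning("fitted DEC rate(s) at the search bound: d=%g e=%g",
                       params.d, params.e)
    return DECFit(params, -float(best.fun), at_bound, len(starts))


@dataclass
class AncestralEstimate:
    """Marginal range probabilities at internal nodes (pre-cladogenesis)."""

    space: RangeStateSpace
    node_ids: list[int]  # deterministic post-order node indices
    probs: np.ndarray = field(repr=False)  # (n_internal, n_states)
    loglik: float = np.nan
    params: DECParams | None = None

    def most_probable(self) -> dict[int, frozenset[str]]:
        # argmax returns the lowest state index on ties (deterministic)
        return {
            nid: self.space.states[int(np.argmax(row))]
            for nid, row in zip(self.node_ids, self.probs)
        }

    def to_dataframe(self, top: int = 5):
        import pandas as pd

        rows = []
        for nid, p in zip(self.node_ids, self.probs):
            order = np.argsort(-p, kind="stable")[:top]
            for rank, si in enumerate(order, 1):
                rows.append(
                    {
                        "node": nid,
                        "rank": rank,
                        "range": ";".join(sorted(self.space.states[si])),
                        "probability": float(p[si]),
                    }
                )
        return pd.DataFrame(rows)


def ancestral_states(
    tree: PhyloTree,
    tips: Mapping[str, Iterable[str]],
    params: DECParams,
    space: RangeStateSpace,
) -> AncestralEstimate:
    """Marginal ancestral-range probabilities at every internal node.

    Below-partials from the pruning pass are combined with above-partials
    propagated from the root: the message into a child is mixed through the
    parent's cladogenesis events against the sibling's branch-top partial,
    then carried down the child's branch with the transposed propagator.
    """
    _check_tree_and_tips(tree, tips, space)
    below, top, logscale = _below_pass(tree, tips, params, space)
    prop_t = _Propagator(space, params, transpose=True)
    pi, li, ri, pr = space.cladogenesis_arrays()
    S = space.n_states
    dt = tree.dendropy_tree
    root = dt.seed_node
    prior = np.full(S, 1.0 / S)
    lik = float(prior @ below[root])
    loglik = float(np.log(lik) + logscale)

    above: dict = {root: prior}
    post_idx = tree.postorder_index()
    node_ids, prob_rows = [], []
    for node in dt.preorder_node_iter():
        if node.is_leaf():
            continue
        a = above[node]
        b = below[node]
        marg = a * b
        marg /= marg.sum()
        node_ids.append(post_idx[node])
        prob_rows.append(marg)
        left, right = node.child_nodes()
        for child, sib in ((left, right), (right, left)):
            if child.is_leaf():
                continue
            # message to the child's branch top, mixed through cladogenesis
            msg = np.zeros(S)
            side = li if child is left else ri
            other = ri if child is left else li
            np.add.at(msg, side, a[pi] * pr * top[sib][other])
            s = msg.sum()
            if s > 0:
                msg /= s
            above[child] = prop_t(child.edge.length or 0.0, msg)
    order = np.argsort(node_ids)
    return AncestralEstimate(
        space=space,
        node_ids=[node_ids[i] for i in order],
        probs=np.vstack([prob_rows[i] for i in order]),
        loglik=loglik,
        params=params,
    )


def annotated_newick(tree: PhyloTree, estimate: AncestralEstimate) -> str:
    """Newick with the most-probable range per internal node as an NHX-style
    comment, keyed to the same post-order node index as the sidecar table."""
    out = tree.copy()
    best = estimate.most_probable()
    post_idx = tree.postorder_index()
    # map indices from the original tree onto the copy (same traversal order)
    for node, node_out in zip(
        tree.dendropy_tree.postorder_node_iter(),
        out.dendropy_tree.postorder_node_iter(),
    ):
        idx = post_idx[node]
        if idx in best:
            state = "+".join(sorted(best[idx]))
            node_out.comments.append(f"&&NHX:node={idx}:range={state}")
    text = out.dendropy_tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        suppress_item_comments=False,
    ).strip()
    return text
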