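"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the pruning/propagation code paths they check:
likelihoods are computed by exhaustive enumeration over all joint internal
states, patristic distances by explicit LCA path sums.
"""

import itertools

import numpy as np
import scipy.linalg as sla


def lca_patristic(tree):
    """Pairwise path lengths via explicit root paths (LCA oracle)."""
    dt = tree.dendropy_tree
    paths = {}
    for leaf in dt.leaf_node_iter():
        path = []
        node = leaf
        while node is not None:
            path.append(node)
            node = node.parent_node
        paths[leaf.taxon.label] = path
    depths = tree.node_depths()
    labels = tree.tip_labels
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            anc_i = set(id(x) for x in paths[labels[i]])
            lca = next(x for x in paths[labels[j]] if id(x) in anc_i)
            di = depths[paths[labels[i]][0]] - depths[lca]
            dj = depths[paths[labels[j]][0]] - depths[lca]
            D[i, j] = D[j, i] = di + dj
    return labels, D


def _dec_setup(tree, space, params):
    Q = space.rate_matrix_sparse(params).toarray()
    Pcache = {}

    def P(t):
        if t not in Pcache:
            Pcache[t] = sla.expm(Q * t)
        return Pcache[t]

    pi, li, ri, pr = space.cladogenesis_arrays()
    events = {}
    for p in range(space.n_states):
        sel = pi == p
        events[p] = list(zip(li[sel], ri[sel], pr[sel]))
    internals = [n for n in tree.dendropy_tree.postorder_node_iter() if not n.is_leaf()]
    return P, events, internals


def _joint_prob(tree, tips, space, P, events, internals, assignment):
    st = dict(zip(internals, assignment))
    prob = 1.0 / space.n_states  # uniform root prior
    for n in internals:
        contrib = 0.0
        ch = n.child_nodes()
        for l, r, w in events[st[n]]:
            term = w
            for child, topstate in ((ch[0], l), (ch[1], r)):
                if child.is_leaf():
                    bottom = space.state_index(tips[child.taxon.label])
                else:
                    bottom = st[child]
                term *= P(child.edge.length)[topstate, bottom]
            contrib += term
        prob *= contrib
    return prob


def dec_brute_loglik(tree, tips, params, space):
    """Exhaustive sum over all joint internal-node state assignments."""
    P, events, internals = _dec_setup(tree, space, params)
    total = sum(
        _joint_prob(tree, tips, space, P, events, internals, a)
        for a in itertools.product(range(space.n_states), repeat=len(internals))
    )
    return float(np.log(total))


def dec_brute_marginals(tree, tips, params, space):
    """Exhaustive per-node marginal state probabilities, keyed by node."""
    P, events, internals = _dec_setup(tree, space, params)
    marg = {n: np.zeros(space.n_states) for n in internals}
    for a in itertools.product(range(space.n_states), repeat=len(internals)):
        p = _joint_prob(tree, tips, space, P, events, internals, a)
        for n, s in zip(internals, a):
            marg[n][s] += p
    for n in internals:
        marg[n] /= marg[n].sum()
    return marg
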