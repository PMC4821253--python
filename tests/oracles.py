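"""Independent brute-force oracles used by the test suite.

These deliberately avoid the pruning code paths: likelihoods are computed
by exhaustive enumeration of internal-node state assignments, and
parsimony scores by exhaustive minimization, so they can certify the fast
implementations on small instances.
"""

import itertools

import numpy as np

from ohnoscope.subst_model import transition_matrix


def brute_force_site_likelihood(tree, model, gamma, leaf_states):
    """Exhaustive sum over all internal-node state assignments, averaged
    over gamma categories; ``leaf_states`` maps leaf name -> state index."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    S = model.n_states
    total = 0.0
    for k in range(gamma.k):
        Ps = {id(n): transition_matrix(model, n.length, gamma.rates[k])
              for n in nodes if n.parent is not None}
        like = 0.0
        for assign in itertools.product(range(S), repeat=len(internals)):
            st = {id(n): a for n, a in zip(internals, assign)}
            for n in nodes:
                if n.is_leaf:
                    st[id(n)] = leaf_states[n.name]
            p = model.frequencies[st[id(tree.root)]]
            for n in nodes:
                if n.parent is not None:
                    p *= Ps[id(n)][st[id(n.parent)], st[id(n)]]
            like += p
        total += like / gamma.k
    return total


def brute_force_node_posterior(tree, model, gamma, leaf_states, target):
    """Exhaustive Bayes posterior over states at ``target`` (a node)."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    S = model.n_states
    mass = np.zeros(S)
    for k in range(gamma.k):
        Ps = {id(n): transition_matrix(model, n.length, gamma.rates[k])
              for n in nodes if n.parent is not None}
        for assign in itertools.product(range(S), repeat=len(internals)):
            st = {id(n): a for n, a in zip(internals, assign)}
            for n in nodes:
                if n.is_leaf:
                    st[id(n)] = leaf_states[n.name]
            p = model.frequencies[st[id(tree.root)]]
            for n in nodes:
                if n.parent is not None:
                    p *= Ps[id(n)][st[id(n.parent)], st[id(n)]]
            mass[st[id(target)]] += p / gamma.k
    return mass / mass.sum()


def fitch_parsimony_score(tree, leaf_state):
    """Minimum number of state changes on the tree explaining the leaf
    states (exhaustive over internal assignments; fine for small trees)."""
    nodes = list(tree.postorder())
    internals = [n for n in nodes if not n.is_leaf]
    states = sorted(set(leaf_state.values()))
    best = np.inf
    for assign in itertools.product(states, repeat=len(internals)):
        st = {id(n): a for n, a in zip(internals, assign)}
        for n in nodes:
            if n.is_leaf:
                st[id(n)] = leaf_state[n.name]
        changes = sum(1 for n in nodes if n.parent is not None
                      and st[id(n)] != st[id(n.parent)])
        best = min(best, changes)
    return int(best)


def random_tree_newick(rng, names, min_len=0.02, max_len=0.8):
    """Random binary rooted tree over the names with random lengths."""
    parts = [f"{n}:{rng.uniform(min_len, max_len):.6f}" for n in names]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        b = parts.pop(j)
        a = parts.pop(i)
        parts.append(f"({a},{b}):{rng.uniform(min_len, max_len):.6f}")
    core = parts[0]
    core = core[:core.rfind(":")]
    return core + ";"
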