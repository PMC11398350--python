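import numpy as np
import pytest
from hypothesis import settings

import biomeshift as bs

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture(scope="session")
def space2():
    return bs.enumerate_states(2, ["Hot", "Cold"])


@pytest.fixture(scope="session")
def space3():
    return bs.enumerate_states(3, ["Tropical", "Warm", "Cold"])


@pytest.fixture()
def rng():
    return np.random.default_rng(20240902)


def brute_force_loglik(tree, masks, q, tensor, pi):
    """Exhaustive sum over all node states, corner states, and tip states.

    Builds the full joint factor as an outer product over one axis per
    latent variable (internal-node state, branch-start "corner" state) and
    sums every term; tip-state sums enter as mask-weighted transition rows.
    Independent of the pruning recursion and its rescaling.
    """
    from biomeshift.anagenesis import transition_probs

    S = q.shape[0]
    P = tensor.dense()
    T = {
        n: transition_probs(q, tree.branch_lengths[n])
        for n in range(tree.n_nodes)
        if n != tree.root_id
    }
    by = {m.species: m.state_mask for m in masks}
    internal = [tree.n_tips + k for k in range(len(tree.left))]
    corners = [n for n in range(tree.n_nodes) if n != tree.root_id]
    pos = {("node", v): i for i, v in enumerate(internal)}
    pos.update(
        {("corner", v): len(internal) + i for i, v in enumerate(corners)}
    )
    nvars = len(internal) + len(corners)

    def expand(arr, dims):
        order = np.argsort(dims)
        a = np.transpose(arr, order)
        shape = [1] * nvars
        for d, p in zip(a.shape, sorted(dims)):
            shape[p] = d
        return a.reshape(shape)

    total = expand(np.asarray(pi), [pos[("node", tree.root_id)]])
    for k in range(len(tree.left)):
        v = tree.n_tips + k
        a, b = tree.left[k], tree.right[k]
        total = total * expand(
            P, [pos[("node", v)], pos[("corner", a)], pos[("corner", b)]]
        )
        for c in (a, b):
            if c < tree.n_tips:
                total = total * expand(
                    T[c] @ by[tree.tip_labels[c]], [pos[("corner", c)]]
                )
            else:
                total = total * expand(
                    T[c], [pos[("corner", c)], pos[("node", c)]]
                )
    return float(np.log(total.sum()))


def random_masks(tree, n_states, rng, p_on=0.6):
    masks = []
    for label in tree.tip_labels:
        m = (rng.uniform(size=n_states) < p_on).astype(float)
        if not m.any():
            m[rng.integers(n_states)] = 1.0
        masks.append(bs.TipAmbiguity(label, m))
    return masks


ALL_SMALL_TOPOLOGIES = [
    "((A:0.3,B:0.4):0.5,C:0.8);",
    "(((A:0.2,B:0.3):0.2,C:0.6):0.4,D:1.0);",
    "((A:0.4,B:0.5):0.6,(C:0.3,D:0.7):0.2);",
]
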