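"""Shared independent oracles for the test suite."""

import numpy as np

from svdscore import TAXA


def brute_force_distribution(tree, model):
    """Oracle for exact pattern probabilities: the explicit 16-term sum
    over the two internal-node states, one scalar loop per pattern."""
    cherry_left, cherry_right = tree.split.split("|")
    bl = tree.branch_lengths
    mats = {x: model.transition_matrix(bl[x]) for x in TAXA}
    pint = model.transition_matrix(bl["internal"])
    out = np.zeros(256)
    role_pos = {t: i for i, t in enumerate(TAXA)}
    for idx in range(256):
        states = [(idx >> s) & 3 for s in (6, 4, 2, 0)]
        total = 0.0
        for x in range(4):
            for y in range(4):
                term = model.pi[x] * pint[x, y]
                for t in cherry_left:
                    term *= mats[t][x, states[role_pos[t]]]
                for t in cherry_right:
                    term *= mats[t][y, states[role_pos[t]]]
                total += term
        out[idx] = total
    return out
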