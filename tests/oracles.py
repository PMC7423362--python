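"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's run-merging implementation: episodes
are found by grouping target-epoch *indices* with an exhaustive scan, and
interruptions are recounted by walking the label sequence.
"""

import numpy as np


def brute_force_episodes(labels, epoch_length, target, min_duration, max_gap,
                         min_exclusive=False):
    """Enumerate episodes of ``target`` by exhaustive index grouping.

    Returns a list of dicts with the same fields as Episode.
    """
    labels = list(labels)
    n = len(labels)
    idx = [i for i in range(n) if labels[i] == target]
    if not idx:
        return []
    max_gap_epochs = int(np.floor(max_gap / epoch_length + 1e-9))
    groups = [[idx[0]]]
    for i in idx[1:]:
        if i - groups[-1][-1] - 1 <= max_gap_epochs:
            groups[-1].append(i)
        else:
            groups.append([i])
    out = []
    for g in groups:
        span = (g[-1] - g[0] + 1) * epoch_length
        ok = span > min_duration + 1e-9 if min_exclusive else span >= min_duration - 1e-9
        if not ok:
            continue
        interruptions = 0
        j = g[0]
        while j <= g[-1]:
            if labels[j] != target:
                interruptions += 1
                while j <= g[-1] and labels[j] != target:
                    j += 1
            else:
                j += 1
        out.append({
            "state": target,
            "start_epoch": g[0],
            "end_epoch": g[-1],
            "span_duration": span,
            "within_state_duration": len(g) * epoch_length,
            "interruption_count": interruptions,
            "truncated_start": g[0] == 0,
            "truncated_end": g[-1] == n - 1,
        })
    return out


def random_labels(rng, n_max=500, with_artifact=True):
    """A random label sequence with a randomized state mix."""
    n = int(rng.integers(1, n_max + 1))
    states = ["W", "N", "R", "A"] if with_artifact else ["W", "N", "R"]
    probs = rng.dirichlet(np.ones(len(states)))
    return rng.choice(states, size=n, p=probs)
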