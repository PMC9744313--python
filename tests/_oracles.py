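"""Independent oracles used by the test suite.

These implement the model's defining formulas directly on immutable
aggregate states (per-restaurant, per-label timestamp tuples), enumerating
every seating history exhaustively.  They deliberately share no code with
the package's implementation.
"""

import math

UNIFORM = (0.25, 0.25, 0.25, 0.25)


def _masses(restaurant, now, decay):
    """Per-label decayed weight from raw timestamps."""
    return tuple(
        sum(math.exp(-decay * (now - s)) for s in label_ts) for label_ts in restaurant
    )


def _level_quantities(state, context, now, alpha, decay):
    """Bottom-up partial predictions p_0..p_L and per-level join weights."""
    L = len(context)
    partials = []  # partials[n] = prediction of the depth-n model
    bases = []  # bases[n] = parent prediction used when seating at level n
    joins = []  # joins[n][k] = W_k at level n
    p = UNIFORM
    for n in range(L + 1):
        key = (n, context[L - n:]) if n else (0, ())
        rest = state.get(key, ((), (), (), ()))
        w = _masses(rest, now, decay[n])
        total = sum(w) + alpha[n]
        bases.append(p)
        joins.append(w)
        p = tuple((w[k] + alpha[n] * p[k]) / total for k in range(4))
        partials.append(p)
    return partials, bases, joins


def exact_marginal_predictions(events, depth, alpha, decay):
    """Exhaustive-enumeration marginal predictive p(k_t) for every trial.

    Maintains the full probability distribution over aggregate seating
    states (which are a sufficient statistic for all predictions and
    seating odds) and propagates it exactly through the back-off updates.
    Returns a (T, 4) list of per-trial marginal predictions.
    """
    dist = {(): 1.0}  # canonical state -> probability; () is the empty state
    marginals = []
    history = []
    for t, e in enumerate(events):
        now = t + 1
        context = tuple(history[-depth:]) if depth else ()
        L = len(context)
        marginal = [0.0, 0.0, 0.0, 0.0]
        new_dist = {}
        for state_key, prob in dist.items():
            state = dict(state_key)
            partials, bases, joins = _level_quantities(state, context, now, alpha, decay)
            full = partials[L]
            for k in range(4):
                marginal[k] += prob * full[k]
            # branch over how deep the back-off chain descends (stop level j)
            open_probs = []
            for n in range(L, -1, -1):
                w_e = joins[n][e - 1]
                w_new = alpha[n] * bases[n][e - 1]
                open_probs.append((n, w_e / (w_e + w_new), w_new / (w_e + w_new)))
            reach = 1.0  # probability the chain reaches level n
            for idx, (n, p_join, p_open) in enumerate(open_probs):
                stop_prob = reach * (p_join if n > 0 else 1.0)
                if stop_prob > 0.0:
                    child = dict(state)
                    for nn in range(L, n - 1, -1):
                        key = (nn, context[L - nn:]) if nn else (0, ())
                        rest = child.get(key, ((), (), (), ()))
                        rest = tuple(
                            rest[k] + ((now,) if k == e - 1 else ())
                            for k in range(4)
                        )
                        child[key] = rest
                    ckey = tuple(sorted(child.items()))
                    new_dist[ckey] = new_dist.get(ckey, 0.0) + prob * stop_prob
                reach *= p_open
        dist = new_dist
        marginals.append(marginal)
        history.append(e)
    total = sum(dist.values())
    assert abs(total - 1.0) < 1e-9, f"probability leaked: {total}"
    return marginals
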