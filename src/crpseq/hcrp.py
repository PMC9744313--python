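"""Hierarchy of forgetful restaurants with recursive back-off.

Level ``n`` holds one restaurant per observed context of ``n`` previous
events.  Prediction mixes the levels bottom-up:

    p_n(k) = m_n(k) + B_n * p_{n-1}(k)

with seat mass ``m_n(k) = mass_k / (total + alpha_n)`` and back-off weight
``B_n = alpha_n / (total + alpha_n)``, bottoming out at the uniform base.
Recognition updates seat a customer for the observed event in the deepest
restaurant and recursively back off to the parent whenever a new table opens.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .asrt import N_KEYS
from .restaurant import SeatingState, seat_customer

UNIFORM = np.full(N_KEYS, 1.0 / N_KEYS)


@dataclass
class HcrpParams:
    """Per-level strengths and decays for levels 0..depth."""

    depth: int = 3
    alpha: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0)
    decay: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("depth must be >= 0")
        self.alpha = tuple(float(a) for a in self.alpha)
        self.decay = tuple(float(l) for l in self.decay)
        if len(self.alpha) != self.depth + 1 or len(self.decay) != self.depth + 1:
            raise ValueError("need depth+1 strength and decay values")
        if any(a <= 0 for a in self.alpha):
            raise ValueError("strengths must be positive")
        if any(l < 0 for l in self.decay):
            raise ValueError("decays must be nonnegative")

    def to_dict(self) -> dict:
        return {"depth": self.depth, "alpha": list(self.alpha), "decay": list(self.decay)}

    @classmethod
    def from_dict(cls, d: dict) -> "HcrpParams":
        return cls(d["depth"], tuple(d["alpha"]), tuple(d["decay"]))


@dataclass
class PredictionTrace:
    """Full prediction plus its decomposition over context depths.

    ``level_mass[j]`` is the share of probability mass each key receives
    from level ``j`` (rows 0..depth); the last row is the uniform floor.
    ``partials[j]`` is the prediction of the depth-``j`` truncated model.
    """

    p: np.ndarray
    level_mass: np.ndarray  # (depth + 2, 4)
    partials: np.ndarray  # (depth + 1, 4)

    def level_usage(self, key: int) -> np.ndarray:
        """Normalized per-level shares of the realized key's probability."""
        shares = self.level_mass[:, key - 1] / self.p[key - 1]
        return shares


class HcrpState:
    """Hyperparameters plus the restaurants created so far, and a trial clock."""

    __slots__ = ("params", "restaurants", "clock")

    def __init__(self, params: HcrpParams):
        self.params = params
        self.restaurants: dict[tuple[int, tuple], SeatingState] = {}
        self.clock = 0

    # -- helpers ------------------------------------------------------------
    def _level_terms(self, context: tuple, now: float) -> tuple[list, list]:
        """Per level n: (m_n vector, B_n scalar) for the truncated context.

        Pure-python floats: this is the hot path of every parse/fit.
        """
        params = self.params
        restaurants = self.restaurants
        depth = len(context)
        ms, bs = [], []
        for n in range(depth + 1):
            key = (n, context[depth - n :]) if n else (0, ())
            rest = restaurants.get(key)
            if rest is None or not rest.tables:
                ms.append((0.0, 0.0, 0.0, 0.0))
                bs.append(1.0)
                continue
            alpha = params.alpha[n]
            w = rest._refresh(now, params.decay[n])
            denom = w[0] + w[1] + w[2] + w[3] + alpha
            ms.append((w[0] / denom, w[1] / denom, w[2] / denom, w[3] / denom))
            bs.append(alpha / denom)
        return ms, bs

    def _predict_list(self, context: tuple, now: float) -> list[float]:
        ms, bs = self._level_terms(context, now)
        p = [0.25, 0.25, 0.25, 0.25]
        for m, b in zip(ms, bs):
            p = [m[0] + b * p[0], m[1] + b * p[1], m[2] + b * p[2], m[3] + b * p[3]]
        return p

    def _truncate(self, context: tuple) -> tuple:
        for e in context:
            if not 1 <= e <= N_KEYS:
                raise ValueError(f"unknown key in context: {e}")
        return tuple(context[-self.params.depth :]) if self.params.depth else ()

    # -- operations ---------------------------------------------------------
    def predict(self, context: tuple, now: float | None = None) -> np.ndarray:
        """Predictive distribution over the next event given the context."""
        now = self.clock + 1 if now is None else now
        context = self._truncate(context)
        return np.array(self._predict_list(context, now))

    def predict_trace(self, context: tuple, now: float | None = None) -> PredictionTrace:
        """Prediction with per-level mass decomposition and truncated partials."""
        now = self.clock + 1 if now is None else now
        context = self._truncate(context)
        ms_raw, bs = self._level_terms(context, now)
        ms = [np.array(m) for m in ms_raw]
        depth = self.params.depth
        partials = np.empty((depth + 1, N_KEYS))
        p = UNIFORM.copy()
        for n in range(depth + 1):
            if n < len(ms):
                p = ms[n] + bs[n] * p
            partials[n] = p
        level_mass = np.zeros((depth + 2, N_KEYS))
        tail = 1.0  # prod of B_l for levels above j
        for j in range(len(ms) - 1, -1, -1):
            level_mass[j] = tail * ms[j]
            tail *= bs[j]
        level_mass[depth + 1] = tail * UNIFORM
        return PredictionTrace(p=partials[depth], level_mass=level_mass, partials=partials)

    def update(self, context: tuple, event: int, rng: np.random.Generator,
               now: float | None = None) -> None:
        """Recognition step: seat ``event`` at the deepest level, backing off
        to the parent whenever a new table opens; advances the clock."""
        now = self.clock + 1 if now is None else now
        context = self._truncate(context)
        ms, bs = self._level_terms(context, now)
        # parent predictive probabilities, bottom-up
        partials = []
        p = [0.25, 0.25, 0.25, 0.25]
        for m, b in zip(ms, bs):
            partials.append(p)  # partials[n] = p_{n-1}; partials[0] = uniform base
            p = [m[0] + b * p[0], m[1] + b * p[1], m[2] + b * p[2], m[3] + b * p[3]]
        params = self.params
        for n in range(len(context), -1, -1):
            key = (n, context[len(context) - n :]) if n else (0, ())
            rest = self.restaurants.get(key)
            if rest is None:
                rest = SeatingState(key)
                self.restaurants[key] = rest
            opened = seat_customer(
                rest, now, event, params.alpha[n], params.decay[n],
                partials[n][event - 1], rng,
            )
            if not opened:
                break
        self.clock = int(now)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "clock": self.clock,
            "restaurants": [r.to_dict() for r in self.restaurants.values()],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HcrpState":
        state = cls(HcrpParams.from_dict(d["params"]))
        state.clock = d["clock"]
        for rd in d["restaurants"]:
            rest = SeatingState.from_dict(rd)
            state.restaurants[rest.restaurant_id] = rest
        return state

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "HcrpState":
        return cls.from_dict(json.loads(s))

    def copy(self, params: HcrpParams | None = None) -> "HcrpState":
        """Clone the seating; optionally re-score it under new hyperparameters."""
        new = HcrpState(params if params is not None else self.params)
        new.clock = self.clock
        new.restaurants = {k: r.copy() for k, r in self.restaurants.items()}
        return new


def parse_online(
    states: list[HcrpState],
    events: np.ndarray,
    keys: np.ndarray,
    rngs: list[np.random.Generator],
    collect_traces: bool = False,
    context_prefix: tuple = (),
):
    """Chronological parse: predict each key press, then learn the event.

    Each of the ``m`` seating states predicts ``p(k_t)`` *before* seeing
    trial ``t``; the per-trial mean over states is returned.  Updates use the
    required response ``e_t`` (not the key actually pressed) and never touch
    past customers.  ``context_prefix`` supplies events preceding the parsed
    span (for bin-wise fitting).
    """
    events = np.asarray(events, dtype=int)
    keys = np.asarray(keys, dtype=int)
    if events.shape != keys.shape:
        raise ValueError("events and keys must have the same length")
    m = len(states)
    if m < 1 or len(rngs) != m:
        raise ValueError("need one RNG stream per seating state")
    T = len(events)
    depth = states[0].params.depth
    p_rows = []
    traces: list[list[PredictionTrace]] = [[] for _ in range(m)] if collect_traces else []
    recent = list(context_prefix[-depth:]) if depth else []
    events_list = [int(e) for e in events]
    inv_m = 1.0 / m
    for t in range(T):
        ctx = tuple(recent)
        acc = [0.0, 0.0, 0.0, 0.0]
        for s, state in enumerate(states):
            if collect_traces:
                tr = state.predict_trace(ctx)
                traces[s].append(tr)
                q = tr.p
            else:
                q = state._predict_list(ctx, state.clock + 1)
            acc[0] += q[0]
            acc[1] += q[1]
            acc[2] += q[2]
            acc[3] += q[3]
        p_rows.append([a * inv_m for a in acc])
        e_t = events_list[t]
        for state, rng in zip(states, rngs):
            state.update(ctx, e_t, rng)
        if depth:
            recent.append(e_t)
            if len(recent) > depth:
                recent.pop(0)
    p_mean = np.array(p_rows)
    p_key = p_mean[np.arange(T), keys - 1]
    return p_mean, p_key, traces


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """KL(p || q) in nats, defined here for strictly positive q."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def context_gain(traces: list[PredictionTrace]) -> np.ndarray:
    """Mean per-trial drop in KL(full || depth-truncated) per added level.

    ``gain[n-1]`` (for n = 1..depth) is the average of
    ``KL_{n-1} - KL_n`` where ``KL_j = KL(full || partial_j)``; the gains
    telescope to ``KL(full || unigram)`` because ``KL_depth = 0``.
    """
    if not traces:
        raise ValueError("empty trial set")
    depth = traces[0].partials.shape[0] - 1
    gains = np.zeros(depth)
    for tr in traces:
        full = tr.p
        kl_prev = kl_divergence(full, tr.partials[0])
        for n in range(1, depth + 1):
            kl_n = kl_divergence(full, tr.partials[n])
            gains[n - 1] += kl_prev - kl_n
            kl_prev = kl_n
    return gains / len(traces)


def level_usage(trace: PredictionTrace, key: int) -> np.ndarray:
    """Share of the realized key's predictive probability per context depth."""
    return trace.level_usage(key)


def negative_log_likelihood(p_key: np.ndarray) -> float:
    """Total sequence NLL (nats) of the realized keys."""
    return float(-np.sum(np.log(p_key)))
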