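"""A single forgetful Chinese restaurant.

Customers are observation timestamps; tables carry a key label (the dish).
A table's pull on a new customer at time ``now`` is the exponentially
decayed sum ``sum_s exp(-decay * (now - s))`` over its customers, so
``decay = 0`` recovers the classic count-based CRP.

Decayed weights are cached incrementally (one multiplicative refresh per
query), which is algebraically identical to re-summing over timestamps;
caches are rebuilt from the raw timestamps whenever the decay rate changes,
so a restaurant can be re-scored under new hyperparameters.
"""

from __future__ import annotations

import json
import math
import numpy as np

from .asrt import N_KEYS


class Table:
    """One cluster: a dish label plus the timestamps of its customers."""

    __slots__ = ("label", "timestamps", "_w", "_t", "_decay")

    def __init__(self, label: int, timestamps: list[int] | None = None, decay: float = 0.0):
        self.label = label
        self.timestamps = list(timestamps) if timestamps else []
        self._decay = decay
        self._rebuild(decay)

    def _rebuild(self, decay: float) -> None:
        self._decay = decay
        if self.timestamps:
            t_ref = self.timestamps[-1]
            self._w = sum(math.exp(-decay * (t_ref - s)) for s in self.timestamps)
            self._t = t_ref
        else:
            self._w, self._t = 0.0, 0

    def weight(self, now: float, decay: float) -> float:
        """Decayed customer mass seen from time ``now``."""
        if decay != self._decay:
            self._rebuild(decay)
        if self.timestamps and now < self.timestamps[-1]:
            raise ValueError(f"future-dated customer: now={now} <= last={self.timestamps[-1]}")
        return self._w * math.exp(-decay * (now - self._t))

    def add_customer(self, now: float, decay: float) -> None:
        self._w = self.weight(now, decay) + 1.0
        self._t = now
        self.timestamps.append(now)


def table_weight(table: Table, now: float, decay: float) -> float:
    """Closed-form decayed weight of one table at query time ``now``."""
    if decay < 0:
        raise ValueError("decay must be nonnegative")
    return table.weight(now, decay)


class SeatingState:
    """Tables of one restaurant, identified by (level, context)."""

    __slots__ = ("restaurant_id", "tables", "_lw", "_lt", "_ldecay")

    def __init__(self, restaurant_id: tuple = (0, ()), tables: list[Table] | None = None):
        self.restaurant_id = restaurant_id
        self.tables = tables if tables is not None else []
        self._ldecay = None  # per-label aggregate cache, tied to one decay value
        self._lw = None
        self._lt = 0

    # -- aggregate per-label masses -----------------------------------------
    def _refresh(self, now: float, decay: float) -> list[float]:
        if self._lw is None or decay != self._ldecay:
            self._ldecay = decay
            self._lt = now
            lw = [0.0] * N_KEYS
            for tab in self.tables:
                lw[tab.label - 1] += tab.weight(now, decay)
            self._lw = lw
        elif now != self._lt:
            f = math.exp(-decay * (now - self._lt))
            self._lw = [w * f for w in self._lw]
            self._lt = now
        return self._lw

    def label_masses(self, now: float, decay: float) -> list[float]:
        """Total decayed weight per dish label (list of 4)."""
        return list(self._refresh(now, decay))

    def n_customers(self) -> int:
        return sum(len(t.timestamps) for t in self.tables)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        level, context = self.restaurant_id
        return {
            "level": level,
            "context": list(context),
            "tables": [{"label": t.label, "timestamps": t.timestamps} for t in self.tables],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SeatingState":
        tables = [Table(t["label"], t["timestamps"]) for t in d["tables"]]
        return cls((d["level"], tuple(d["context"])), tables)

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "SeatingState":
        return cls.from_dict(json.loads(s))

    def copy(self) -> "SeatingState":
        new = SeatingState(self.restaurant_id)
        new.tables = [Table(t.label, t.timestamps, t._decay) for t in self.tables]
        return new


def predict_dish(
    state: SeatingState,
    now: float,
    strength: float,
    decay: float,
    base: np.ndarray,
) -> np.ndarray:
    """Predictive distribution over the 4 dishes.

    ``p(k) = (mass_k + strength * base_k) / (total_mass + strength)``.
    """
    base = np.asarray(base, dtype=float)
    if base.shape != (N_KEYS,) or abs(base.sum() - 1.0) > 1e-9 or (base < 0).any():
        raise ValueError("base must be a probability vector over the 4 keys")
    if strength <= 0:
        raise ValueError("strength must be positive")
    masses = np.array(state.label_masses(now, decay))
    return (masses + strength * base) / (masses.sum() + strength)


def seat_customer(
    state: SeatingState,
    now: float,
    dish: int,
    strength: float,
    decay: float,
    base_prob_of_dish: float,
    rng: np.random.Generator,
) -> bool:
    """Seat a customer eating ``dish``; return True iff a new table opened.

    Joins an existing table with that label with probability proportional to
    its decayed weight, or opens a new one with probability proportional to
    ``strength * base_prob_of_dish``.  Opening signals back-off to the parent
    restaurant in the hierarchy.
    """
    if not 1 <= dish <= N_KEYS:
        raise ValueError(f"dish must be in 1..{N_KEYS}")
    lw = state._refresh(now, decay)
    w_label = lw[dish - 1]
    w_new = strength * base_prob_of_dish
    total = w_label + w_new
    if total <= 0:
        raise ValueError("degenerate seating: no occupied tables and zero open mass")
    u = rng.random() * total
    if u < w_label:
        # join: pick among this label's tables proportionally to decayed weight
        chosen = None
        acc = 0.0
        for tab in state.tables:
            if tab.label != dish:
                continue
            chosen = tab
            acc += tab.weight(now, decay)
            if u < acc:
                break
        chosen.add_customer(now, decay)
        lw[dish - 1] += 1.0
        return False
    chosen = Table(dish, decay=decay)
    state.tables.append(chosen)
    chosen.add_customer(now, decay)
    lw[dish - 1] += 1.0
    return True
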