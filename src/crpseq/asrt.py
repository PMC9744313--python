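"""Alternating serial reaction time (ASRT) trial stream generation and labelling.

The task interleaves four deterministic states -- driven by a cyclic
second-order pattern over the four keys -- with four random states that emit
any key with equal probability.  Random trials that happen to complete a
pattern trigram are labelled ``rH`` (high-probability trigram), the rest
``rL``; deterministic trials are labelled ``d``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

N_KEYS = 4

#: sentinel for trials whose trigram is undefined (first two trials of a session)
NA_LABEL = "NA"


@dataclass(frozen=True)
class Pattern:
    """A cyclic ordering of the 4 keys defining the second-order rule.

    ``elements[i]`` is deterministically followed (two trials later) by
    ``elements[(i + 1) % 4]``.
    """

    elements: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if len(self.elements) != 4 or sorted(self.elements) != [1, 2, 3, 4]:
            raise ValueError(f"pattern must be an ordering of 1..4, got {self.elements}")

    def successor(self, element: int) -> int:
        i = self.elements.index(element)
        return self.elements[(i + 1) % 4]

    def pairs(self) -> dict[int, int]:
        """The four second-order (element -> successor) pairs."""
        return {e: self.successor(e) for e in self.elements}

    def is_pair(self, first: int, third: int) -> bool:
        """True iff ``first -> third`` is a pattern trigram (gap of one trial)."""
        return self.successor(first) == third

    def canonical(self) -> "Pattern":
        """Rotate so the pattern starts with key 1."""
        i = self.elements.index(1)
        return Pattern(self.elements[i:] + self.elements[:i])

    def equivalent(self, other: "Pattern") -> bool:
        return self.canonical() == other.canonical()


def enumerate_patterns() -> list[Pattern]:
    """All rotation-equivalence classes of 4-key cyclic patterns.

    Canonical representatives start with key 1; there are exactly six.
    """
    return [Pattern((1,) + p) for p in itertools.permutations((2, 3, 4))]


def apply_interference_swap(pattern: Pattern, positions: tuple[int, int] = (1, 2)) -> Pattern:
    """Exchange two cyclically adjacent pattern elements.

    An adjacent swap changes exactly 3 of the 4 second-order pairs; the
    resulting pattern is the interference sequence introduced mid-experiment.
    """
    i, j = positions
    if (j - i) % 4 not in (1, 3):
        raise ValueError(f"swap positions must be cyclically adjacent, got {positions}")
    els = list(pattern.elements)
    els[i], els[j] = els[j], els[i]
    return Pattern(tuple(els))


def changed_pair_fraction(old: Pattern, new: Pattern) -> float:
    """Fraction of the four element->successor pairs that differ between patterns."""
    po, pn = old.pairs(), new.pairs()
    return sum(po[e] != pn[e] for e in po) / 4.0


@dataclass
class ScheduleConfig:
    """Experiment layout: session lengths, epochs, and the interference plan."""

    n_keys: int = N_KEYS
    session_lengths: tuple[int, ...] = (2125,) * 9 + (1700,)
    epochs_per_session: int = 5
    interference_session: int = 9
    alternation_session: int = 10
    alternation_block_length: int = 425
    swap_positions: tuple[int, int] = (1, 2)
    start_phase: str = "det"  # phase of trial 1 of each session: "det" or "rand"
    restart_each_session: bool = True

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.session_lengths):
            raise ValueError("session lengths must be positive")
        if self.start_phase not in ("det", "rand"):
            raise ValueError("start_phase must be 'det' or 'rand'")
        if self.alternation_session <= len(self.session_lengths):
            n10 = self.session_lengths[self.alternation_session - 1]
            nblocks, rem = divmod(n10, self.alternation_block_length)
            if rem != 0:
                raise ValueError("alternation blocks do not tile the alternation session")


@dataclass
class TrialRecord:
    """One ASRT trial; ``position`` is the cue location (= event identity)."""

    session: int
    epoch: int
    trial: int  # global 1-based index
    state: str  # "det" | "rand"
    event: int  # required response, 1..4
    position: int
    label_old: str = NA_LABEL
    label_new: str = NA_LABEL
    overlap: str = NA_LABEL

    @property
    def label(self) -> str:
        return self.label_old


def generate_session(
    pattern: Pattern,
    n_trials: int,
    start_phase: str = "det",
    rng: np.random.Generator | None = None,
    initial_det: int | None = None,
) -> list[TrialRecord]:
    """Generate one session of alternating deterministic/random trials.

    Deterministic events follow the pattern's second-order rule; random
    events are i.i.d. uniform over the 4 keys.  ``initial_det`` seeds the
    deterministic chain (drawn uniformly when omitted).
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    last_det = initial_det if initial_det is not None else int(rng.integers(1, 5))
    first_det_pending = initial_det is not None
    records: list[TrialRecord] = []
    det_phase = start_phase == "det"
    for i in range(n_trials):
        if det_phase:
            if first_det_pending:
                event = pattern.successor(last_det)
            else:
                event = last_det  # first deterministic trial of the chain
                first_det_pending = True
            last_det = event
            state = "det"
        else:
            event = int(rng.integers(1, 5))
            state = "rand"
        records.append(
            TrialRecord(session=0, epoch=0, trial=i + 1, state=state, event=event, position=event)
        )
        det_phase = not det_phase
    return records


def label_trials(
    trials: list[TrialRecord],
    old_pattern: Pattern,
    new_pattern: Pattern | None = None,
) -> list[TrialRecord]:
    """Assign ``d``/``rH``/``rL`` labels and interference overlap categories.

    Trigrams are defined within session: the first two trials of each session
    keep the ``NA`` sentinel.  Overlap categories apply to random trials only:
    ``H_old_only`` (rH under old, rL under new), ``H_new_only`` (vice versa),
    ``L_both`` and ``other`` (H under both).
    """

    def _label(pat: Pattern, e_prev2: int, rec: TrialRecord) -> str:
        if rec.state == "det":
            return "d"
        return "rH" if pat.is_pair(e_prev2, rec.event) else "rL"

    by_session: dict[int, list[TrialRecord]] = {}
    for rec in trials:
        by_session.setdefault(rec.session, []).append(rec)
    for recs in by_session.values():
        for i, rec in enumerate(recs):
            if i < 2:
                rec.label_old = rec.label_new = rec.overlap = NA_LABEL
                continue
            e_prev2 = recs[i - 2].event
            rec.label_old = _label(old_pattern, e_prev2, rec)
            rec.label_new = _label(new_pattern, e_prev2, rec) if new_pattern else NA_LABEL
            if rec.state == "rand" and new_pattern is not None:
                key = (rec.label_old, rec.label_new)
                rec.overlap = {
                    ("rH", "rL"): "H_old_only",
                    ("rL", "rH"): "H_new_only",
                    ("rL", "rL"): "L_both",
                    ("rH", "rH"): "other",
                }[key]
            else:
                rec.overlap = NA_LABEL
    return trials


def build_schedule(
    config: ScheduleConfig, pattern: Pattern, rng: np.random.Generator
) -> list[TrialRecord]:
    """Generate the full experiment: training, interference and alternation.

    Sessions before the interference session use ``pattern``; the
    interference session uses the adjacent-swap pattern; the alternation
    session alternates old/new block by block.  Both old- and new-pattern
    labels are populated on every session.
    """
    new_pattern = apply_interference_swap(pattern, config.swap_positions)
    all_trials: list[TrialRecord] = []
    t_global = 0
    for s_idx, n_trials in enumerate(config.session_lengths, start=1):
        if s_idx == config.alternation_session:
            session_recs: list[TrialRecord] = []
            nblocks = n_trials // config.alternation_block_length
            last_det: int | None = None
            phase = config.start_phase
            for b in range(nblocks):
                pat = pattern if b % 2 == 0 else new_pattern
                recs = generate_session(
                    pat,
                    config.alternation_block_length,
                    start_phase=phase,
                    rng=rng,
                    initial_det=last_det,
                )
                session_recs.extend(recs)
                last_det = next(r.event for r in reversed(recs) if r.state == "det")
                # keep the det/rand alternation continuous across blocks
                if config.alternation_block_length % 2 == 1:
                    phase = "rand" if phase == "det" else "det"
        elif s_idx >= config.interference_session:
            session_recs = generate_session(
                new_pattern, n_trials, start_phase=config.start_phase, rng=rng
            )
        else:
            session_recs = generate_session(
                pattern, n_trials, start_phase=config.start_phase, rng=rng
            )
        epoch_len = max(1, n_trials // config.epochs_per_session)
        for i, rec in enumerate(session_recs):
            t_global += 1
            rec.session = s_idx
            rec.epoch = min(i // epoch_len, config.epochs_per_session - 1) + 1
            rec.trial = t_global
        all_trials.extend(session_recs)
    return label_trials(all_trials, pattern, new_pattern)


# ---------------------------------------------------------------------------
# IO

CSV_COLUMNS = [
    "participant",
    "session",
    "epoch",
    "trial",
    "state",
    "event",
    "position",
    "label_old",
    "label_new",
    "overlap",
]


def trials_to_frame(trials: list[TrialRecord], participant: int = 1) -> pd.DataFrame:
    rows = [
        (
            participant,
            r.session,
            r.epoch,
            r.trial,
            r.state,
            r.event,
            r.position,
            r.label_old,
            r.label_new,
            r.overlap,
        )
        for r in trials
    ]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    return [
        TrialRecord(
            session=int(row.session),
            epoch=int(row.epoch),
            trial=int(row.trial),
            state=str(row.state),
            event=int(row.event),
            position=int(row.position),
            label_old=str(row.label_old),
            label_new=str(row.label_new),
            overlap=str(row.overlap),
        )
        for row in df.itertuples()
    ]


def write_trials(path, trials: list[TrialRecord], participant: int = 1) -> None:
    trials_to_frame(trials, participant).to_csv(path, index=False)


def read_trials(path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False)
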