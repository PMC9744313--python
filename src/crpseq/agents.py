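"""Forward simulation of behavior from known model parameters.

An agent carries its own sequence model; on each trial it predicts the next
event, presses a key (usually the required one, occasionally an error drawn
from its own expectations), emits a log-normal RT around the linear
predictor, and then learns the required event.  This gives ground-truth
behavior for parameter-recovery tests of the fitting stack.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .asrt import N_KEYS, TrialRecord
from .hcrp import HcrpParams, HcrpState
from .response import RT_FLOOR_MS, ResponseParams


@dataclass
class AgentSpec:
    """Ground-truth generative parameters of one simulated participant."""

    hcrp: HcrpParams = field(default_factory=HcrpParams)
    rho: ResponseParams = field(default_factory=ResponseParams)
    error_rate: float = 0.0
    error_policy: str = "sample_from_prediction"  # or "uniform"

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        if self.error_policy not in ("sample_from_prediction", "uniform"):
            raise ValueError(f"unknown error policy {self.error_policy!r}")


def simulate_agent(
    spec: AgentSpec,
    trials: list[TrialRecord],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate keys and RTs for a trial schedule.

    With probability ``1 - error_rate`` the key equals the required event;
    otherwise it is drawn from the agent's own predictive distribution with
    the correct key excluded (``sample_from_prediction``) or uniformly over
    the three wrong keys.  RT is log-normal around the linear predictor
    evaluated at the agent's own probability of the pressed key.  The
    internal model is always updated with the required event.

    Returns a frame with columns ``trial, key, rt_ms, correct, p_key``.
    """
    state = HcrpState(spec.hcrp)
    depth = spec.hcrp.depth
    rho = spec.rho
    rows = []
    recent: list[int] = []
    prev_key = None
    prev_err = False
    prev_pos = None
    prev_session = None
    for rec in trials:
        if prev_session is not None and rec.session != prev_session:
            session_initial = True
        else:
            session_initial = prev_session is None
        ctx = tuple(recent)
        p = state.predict(ctx)
        e = rec.event
        if spec.error_rate > 0 and rng.random() < spec.error_rate:
            others = [k for k in range(1, N_KEYS + 1) if k != e]
            if spec.error_policy == "uniform":
                key = int(rng.choice(others))
            else:
                w = np.array([p[k - 1] for k in others])
                key = int(rng.choice(others, p=w / w.sum()))
        else:
            key = e
        surprise = -np.log(p[key - 1])
        dist = 0.0 if session_initial or prev_pos is None else abs(rec.position - prev_pos)
        rep = 0.0 if prev_key is None else float(key == prev_key)
        err = float(key != e)
        posterr = 0.0 if session_initial else float(prev_err)
        tau = (
            rho.intercept
            + rho.w_seq * surprise
            + rho.w_dist * dist
            + rho.w_rep * rep
            + rho.w_err * err
            + rho.w_posterr * posterr
        )
        tau = max(tau, RT_FLOOR_MS)
        rt = float(np.exp(rng.normal(np.log(tau), rho.sigma)))
        rows.append((rec.trial, key, rt, key == e, float(p[key - 1])))
        state.update(ctx, e, rng)
        if depth:
            recent.append(e)
            if len(recent) > depth:
                recent.pop(0)
        prev_key, prev_err, prev_pos, prev_session = key, bool(err), rec.position, rec.session
    return pd.DataFrame(rows, columns=["trial", "key", "rt_ms", "correct", "p_key"])


def recovery_experiment(
    specs: dict[str, AgentSpec],
    trials: list[TrialRecord],
    n_replicates: int,
    rng: np.random.Generator,
    fit_fn,
) -> pd.DataFrame:
    """Simulate each agent ``n_replicates`` times and refit it.

    ``fit_fn(events, keys, rts, rng) -> dict`` runs the fitting stack and
    returns the fitted quantities to report; each returned key becomes a
    ``fitted_*`` column.  Rows are (agent, replicate) pairs.
    """
    events = np.array([r.event for r in trials])
    rows = []
    for name, spec in specs.items():
        for rep in range(n_replicates):
            behavior = simulate_agent(spec, trials, rng)
            fitted = fit_fn(
                events, behavior["key"].to_numpy(), behavior["rt_ms"].to_numpy(), rng
            )
            row = {"agent": name, "replicate": rep}
            for n in range(spec.hcrp.depth + 1):
                row[f"true_alpha_{n}"] = spec.hcrp.alpha[n]
                row[f"true_lambda_{n}"] = spec.hcrp.decay[n]
            row["true_w_seq"] = spec.rho.w_seq
            row.update({f"fitted_{k}": v for k, v in fitted.items()})
            rows.append(row)
    return pd.DataFrame(rows)
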