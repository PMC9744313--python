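"""Linear reaction-time model on top of the sequence predictions.

Predicted RT (ms) is a linear combination of the surprise of the pressed key
(``-log p(k_t)``) and four low-level effects: spatial distance between
successive cue locations, response repetition, error trials and post-error
trials.  The likelihood of measured RTs is Gaussian on the log scale around
the log of the predicted RT.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np

#: predicted RTs are floored here so the log-likelihood stays defined
RT_FLOOR_MS = 50.0

DESIGN_COLUMNS = ["surprise", "dist", "rep", "err", "posterr"]


@dataclass
class ResponseParams:
    """Coefficients of the linear RT predictor plus log-RT noise."""

    intercept: float = 400.0
    w_seq: float = 0.0  # ms per nat of surprise
    w_dist: float = 0.0  # ms per location step
    w_rep: float = 0.0
    w_err: float = 0.0
    w_posterr: float = 0.0
    sigma: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def weights(self) -> np.ndarray:
        return np.array(
            [self.intercept, self.w_seq, self.w_dist, self.w_rep, self.w_err, self.w_posterr]
        )

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ResponseParams":
        return cls(**json.loads(s))


def build_design(
    events: np.ndarray,
    keys: np.ndarray,
    p_key: np.ndarray,
    positions: np.ndarray | None = None,
    session_start: np.ndarray | None = None,
    repetition_on: str = "response",
) -> np.ndarray:
    """Design matrix ``[1, surprise, dist, rep, err, posterr]``, one row per trial.

    ``dist`` is the absolute location-step difference between successive cue
    positions (cue location = event identity); session-initial trials get
    ``dist = 0`` and ``posterr = 0``.
    """
    events = np.asarray(events, dtype=int)
    keys = np.asarray(keys, dtype=int)
    p_key = np.asarray(p_key, dtype=float)
    if np.any(p_key <= 0) or np.any(p_key > 1):
        raise ValueError("p_key must lie in (0, 1]")
    T = len(events)
    if positions is None:
        positions = events
    positions = np.asarray(positions, dtype=int)
    if session_start is None:
        session_start = np.zeros(T, dtype=bool)
        session_start[0] = True
    session_start = np.asarray(session_start, dtype=bool)

    surprise = -np.log(p_key)
    dist = np.zeros(T)
    dist[1:] = np.abs(positions[1:] - positions[:-1])
    rep = np.zeros(T)
    ref = keys if repetition_on == "response" else events
    rep[1:] = (ref[1:] == ref[:-1]).astype(float)
    err = (keys != events).astype(float)
    posterr = np.zeros(T)
    posterr[1:] = err[:-1]
    dist[session_start] = 0.0
    posterr[session_start] = 0.0
    return np.column_stack([np.ones(T), surprise, dist, rep, err, posterr])


def predict_rt(design: np.ndarray, params: ResponseParams) -> np.ndarray:
    """Per-trial predicted RT in ms, floored at :data:`RT_FLOOR_MS`."""
    tau = design @ params.weights()
    n_floored = int(np.sum(tau < RT_FLOOR_MS))
    if n_floored:
        warnings.warn(
            f"RT floor engaged on {n_floored} trials; check response parameters",
            RuntimeWarning,
            stacklevel=2,
        )
        tau = np.maximum(tau, RT_FLOOR_MS)
    return tau


def loglik(
    rts: np.ndarray, tau_hat: np.ndarray, sigma: float, mask: np.ndarray | None = None
) -> float:
    """Gaussian log-likelihood of log RTs around log predicted RTs."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rts = np.asarray(rts, dtype=float)
    tau_hat = np.asarray(tau_hat, dtype=float)
    if mask is None:
        mask = np.ones(len(rts), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if np.any(rts[mask] <= 0):
        raise ValueError("masked-in RTs must be positive")
    resid = np.log(rts[mask]) - np.log(tau_hat[mask])
    n = resid.size
    return float(-0.5 * np.sum(resid**2) / sigma**2 - n * np.log(sigma * np.sqrt(2 * np.pi)))


def fit_rho(
    design: np.ndarray,
    rts: np.ndarray,
    mask: np.ndarray | None = None,
    target: str = "ms",
) -> ResponseParams:
    """OLS fit of the linear predictor on masked-in trials.

    The regression target is RT in ms by default; ``target="log"`` regresses
    log RTs instead (coefficients then live on the log-ms scale).  ``sigma``
    is always the residual standard deviation on the log scale.
    Rank-deficient designs fall back to a small ridge penalty with a warning.
    """
    rts = np.asarray(rts, dtype=float)
    if mask is None:
        mask = np.ones(len(rts), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    X = design[mask]
    if X.shape[0] < X.shape[1] + 1:
        raise ValueError(f"need at least {X.shape[1] + 1} masked-in trials")
    y = rts[mask] if target == "ms" else np.log(rts[mask])
    # all-zero regressors (e.g. no errors in the stream) carry no information:
    # pin their coefficients to 0 instead of flagging rank deficiency
    active = np.flatnonzero(np.any(X != 0, axis=0))
    Xa = X[:, active]
    rank = np.linalg.matrix_rank(Xa)
    if rank < Xa.shape[1]:
        warnings.warn("rank-deficient design; using ridge fallback", RuntimeWarning, stacklevel=2)
        lam = 1e-8 * np.trace(Xa.T @ Xa) / Xa.shape[1]
        beta_a = np.linalg.solve(Xa.T @ Xa + lam * np.eye(Xa.shape[1]), Xa.T @ y)
    else:
        beta_a, *_ = np.linalg.lstsq(Xa, y, rcond=None)
    beta = np.zeros(X.shape[1])
    beta[active] = beta_a
    params = ResponseParams(
        intercept=float(beta[0]),
        w_seq=float(beta[1]),
        w_dist=float(beta[2]),
        w_rep=float(beta[3]),
        w_err=float(beta[4]),
        w_posterr=float(beta[5]),
        sigma=1.0,  # placeholder, replaced below
    )
    if target == "ms":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tau = predict_rt(design[mask], params)
        resid = np.log(rts[mask]) - np.log(tau)
    else:
        resid = np.log(rts[mask]) - X @ beta
    sigma = float(np.std(resid, ddof=X.shape[1]))
    params.sigma = max(sigma, 1e-9)
    return params
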