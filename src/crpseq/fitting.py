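"""Random-search fitting of the sequence-model hyperparameters.

Each data bin is fitted by drawing hyperparameter vectors from a prior,
re-parsing the bin from the inherited seating checkpoint, fitting the
response coefficients by OLS, and scoring the masked-in log-likelihood
(optionally plus the log prior).  The best draw is the MAP; its seating is
carried into the next bin, whose prior is re-centered on the MAP.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import truncnorm

from .hcrp import HcrpParams, HcrpState, parse_online
from .response import ResponseParams, build_design, fit_rho, loglik, predict_rt

DEFAULT_ALPHA_BOUNDS = (0.01, 100.0)
DEFAULT_LAMBDA_BOUNDS = (1e-5, 1.0)
FORGETFUL_LAMBDA_BOUNDS = (1e-2, 1.0)


def param_names(depth: int) -> list[str]:
    return [f"alpha_{n}" for n in range(depth + 1)] + [f"lambda_{n}" for n in range(depth + 1)]


def theta_to_params(theta: dict[str, float], depth: int) -> HcrpParams:
    return HcrpParams(
        depth=depth,
        alpha=tuple(theta[f"alpha_{n}"] for n in range(depth + 1)),
        decay=tuple(theta[f"lambda_{n}"] for n in range(depth + 1)),
    )


@dataclass
class PriorSpec:
    """Hyperparameter prior: log-uniform in bin 1, truncated log-Gaussian after.

    ``bounds`` maps each hyperparameter name to its (low, high) support; an
    informed prior re-centers a truncated Gaussian (in log space, sd =
    ``sd_frac`` of the support's log-width) on the previous bin's MAP while
    keeping the bin-1 truncation bounds.
    """

    depth: int
    bounds: dict[str, tuple[float, float]]
    center: dict[str, float] | None = None
    sd_frac: float = 0.1
    regime: str = "default"

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.bounds.items():
            if not (0 < lo <= hi and np.isfinite(hi)):
                raise ValueError(f"bad bounds for {name}: ({lo}, {hi})")
        if self.sd_frac <= 0:
            raise ValueError("sd_frac must be positive")

    @classmethod
    def uninformed(
        cls,
        depth: int,
        regime: str = "default",
        alpha_bounds: tuple[float, float] = DEFAULT_ALPHA_BOUNDS,
        lambda_bounds: tuple[float, float] | None = None,
    ) -> "PriorSpec":
        if lambda_bounds is None:
            lambda_bounds = (
                FORGETFUL_LAMBDA_BOUNDS if regime == "forgetful" else DEFAULT_LAMBDA_BOUNDS
            )
        bounds = {}
        for n in range(depth + 1):
            bounds[f"alpha_{n}"] = alpha_bounds
            bounds[f"lambda_{n}"] = lambda_bounds
        return cls(depth=depth, bounds=bounds, regime=regime)

    @classmethod
    def point(cls, theta: dict[str, float], depth: int) -> "PriorSpec":
        """Degenerate prior putting all mass on one hyperparameter vector."""
        return cls(depth=depth, bounds={k: (v, v) for k, v in theta.items()})

    def informed(self, center: dict[str, float]) -> "PriorSpec":
        return replace(self, center=dict(center))

    def _moments(self, name: str) -> tuple[float, float, float, float] | None:
        """(loc, scale, a, b) of the truncated normal in log space, or None."""
        lo, hi = self.bounds[name]
        if self.center is None or hi == lo:
            return None
        width = np.log(hi) - np.log(lo)
        loc = np.log(np.clip(self.center[name], lo, hi))
        scale = self.sd_frac * width
        a = (np.log(lo) - loc) / scale
        b = (np.log(hi) - loc) / scale
        return loc, scale, a, b

    def sample(self, rng: np.random.Generator) -> dict[str, float]:
        theta = {}
        for name in param_names(self.depth):
            lo, hi = self.bounds[name]
            if hi == lo:
                theta[name] = lo
                continue
            mom = self._moments(name)
            if mom is None:
                theta[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            else:
                loc, scale, a, b = mom
                theta[name] = float(np.exp(truncnorm.rvs(a, b, loc, scale, random_state=rng)))
        return theta

    def logpdf(self, theta: dict[str, float]) -> float:
        total = 0.0
        for name in param_names(self.depth):
            lo, hi = self.bounds[name]
            v = theta[name]
            if hi == lo:
                if v != lo:
                    return -np.inf
                continue
            if not lo <= v <= hi:
                return -np.inf
            mom = self._moments(name)
            if mom is None:
                total += -np.log(v) - np.log(np.log(hi) - np.log(lo))
            else:
                loc, scale, a, b = mom
                total += truncnorm.logpdf(np.log(v), a, b, loc, scale) - np.log(v)
        return float(total)


# ---------------------------------------------------------------------------
# bin plans

SESSION_HELDOUT = 255
EPOCH_HELDOUT = 85


@dataclass
class Bin:
    """Contiguous trial range [start, stop) with a central held-out segment."""

    start: int
    stop: int
    kind: str = "session"  # "session" | "epoch"
    bin_id: str = ""
    heldout_length: int | None = None

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError("empty bin")
        if self.heldout_length is None:
            self.heldout_length = SESSION_HELDOUT if self.kind == "session" else EPOCH_HELDOUT
        n = self.stop - self.start
        if self.heldout_length >= n - 1:
            raise ValueError("held-out segment must be strictly inside the bin")

    def heldout_mask(self) -> np.ndarray:
        """Boolean mask over the bin's trials marking the central segment."""
        n = self.stop - self.start
        off = (n - self.heldout_length) // 2
        mask = np.zeros(n, dtype=bool)
        mask[off : off + self.heldout_length] = True
        return mask


@dataclass
class BinPlan:
    bins: list[Bin]

    def validate(self, n_trials: int) -> None:
        pos = 0
        for b in self.bins:
            if b.start != pos:
                raise ValueError(f"bins do not tile the experiment at trial {pos}")
            pos = b.stop
        if pos != n_trials:
            raise ValueError(f"bins cover {pos} trials, experiment has {n_trials}")


def default_bin_plan(session_lengths=(2125,) * 9 + (1700,), epoch_sessions=(1, 9, 10),
                     epochs: int = 5) -> BinPlan:
    """Whole-session bins, except 5-epoch splits for the listed sessions."""
    bins = []
    pos = 0
    for s, n in enumerate(session_lengths, start=1):
        if s in epoch_sessions:
            edges = np.linspace(pos, pos + n, epochs + 1).astype(int)
            for e in range(epochs):
                bins.append(
                    Bin(int(edges[e]), int(edges[e + 1]), kind="epoch", bin_id=f"s{s}e{e + 1}")
                )
        else:
            bins.append(Bin(pos, pos + n, kind="session", bin_id=f"s{s}"))
        pos += n
    return BinPlan(bins)


# ---------------------------------------------------------------------------
# fitting

@dataclass
class FitResult:
    """MAP fit of one bin plus everything needed to continue the chain."""

    bin_id: str
    theta: dict[str, float]
    rho: ResponseParams
    objective: float
    loglik_train: float
    restarts: list[dict]
    states: list[HcrpState]
    p_key: np.ndarray
    tau_hat: np.ndarray
    heldout_mask: np.ndarray
    heldout_r2: float
    seed: int

    def to_dict(self) -> dict:
        return {
            "bin_id": self.bin_id,
            "theta": self.theta,
            "rho": json.loads(self.rho.to_json()),
            "objective": self.objective,
            "loglik_train": self.loglik_train,
            "restarts": self.restarts,
            "heldout_r2": self.heldout_r2,
            "seed": self.seed,
        }


def _parse_with_theta(
    theta: dict,
    depth: int,
    events: np.ndarray,
    keys: np.ndarray,
    inherited: list[HcrpState] | None,
    m: int,
    seed: int,
    context_prefix: tuple,
):
    params = theta_to_params(theta, depth)
    if inherited is None:
        states = [HcrpState(params) for _ in range(m)]
    else:
        states = [s.copy(params) for s in inherited]
    rngs = [np.random.default_rng(np.random.SeedSequence([seed, 1000 + i])) for i in range(m)]
    _, p_key, _ = parse_online(states, events, keys, rngs, context_prefix=context_prefix)
    return states, p_key


def fit_bin(
    events: np.ndarray,
    keys: np.ndarray,
    rts: np.ndarray,
    prior: PriorSpec,
    inherited_states: list[HcrpState] | None = None,
    heldout_mask: np.ndarray | None = None,
    n_iter: int = 1000,
    n_restart: int = 10,
    m: int = 5,
    rng: np.random.Generator | None = None,
    include_log_prior: bool = True,
    context_prefix: tuple = (),
    positions: np.ndarray | None = None,
    session_start: np.ndarray | None = None,
    bin_id: str = "",
) -> FitResult:
    """ABC random search over hyperparameters for one bin.

    Every iteration draws a hyperparameter vector from the prior, re-parses
    the bin's events from the inherited seating (``m`` samples), fits the
    response coefficients by OLS on masked-in trials, and scores them by
    masked-in log-likelihood (+ log prior).  The best draw over
    ``n_restart x n_iter`` iterations is the MAP; its parse provides the
    seating checkpoint, per-trial probabilities and held-out fit quality.
    """
    events = np.asarray(events, dtype=int)
    keys = np.asarray(keys, dtype=int)
    rts = np.asarray(rts, dtype=float)
    T = len(events)
    if heldout_mask is None:
        heldout_mask = np.zeros(T, dtype=bool)
    train_mask = ~heldout_mask
    if not train_mask.any():
        raise ValueError("no masked-in trials to fit")
    if rng is None:
        rng = np.random.default_rng()
    root_seed = int(rng.integers(2**63))

    design = build_design(events, keys, np.ones(T), positions=positions,
                          session_start=session_start)
    best = None  # (objective, loglik, theta, seed)
    restarts = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for r in range(n_restart):
            best_r = None
            for i in range(n_iter):
                seed = int(
                    np.random.SeedSequence([root_seed, r, i]).generate_state(1, np.uint64)[0]
                )
                theta = prior.sample(np.random.default_rng(np.random.SeedSequence([seed, 7])))
                _, p_key = _parse_with_theta(
                    theta, prior.depth, events, keys, inherited_states, m, seed, context_prefix
                )
                design[:, 1] = -np.log(p_key)
                rho = fit_rho(design, rts, train_mask)
                tau = predict_rt(design, rho)
                ll = loglik(rts, tau, rho.sigma, train_mask)
                obj = ll + (prior.logpdf(theta) if include_log_prior else 0.0)
                if best_r is None or obj > best_r[0]:
                    best_r = (obj, ll, theta, seed)
                if best is None or obj > best[0]:
                    best = (obj, ll, theta, seed)
            restarts.append(
                {"objective": best_r[0], "loglik": best_r[1], "theta": best_r[2]}
            )

    obj, ll, theta, seed = best
    states, p_key = _parse_with_theta(
        theta, prior.depth, events, keys, inherited_states, m, seed, context_prefix
    )
    design[:, 1] = -np.log(p_key)
    rho = fit_rho(design, rts, train_mask)
    tau = predict_rt(design, rho)
    r2 = heldout_r2(tau, rts, heldout_mask) if heldout_mask.any() else float("nan")
    return FitResult(
        bin_id=bin_id,
        theta=theta,
        rho=rho,
        objective=obj,
        loglik_train=ll,
        restarts=restarts,
        states=states,
        p_key=p_key,
        tau_hat=tau,
        heldout_mask=heldout_mask,
        heldout_r2=r2,
        seed=seed,
    )


def sequential_fit(
    events: np.ndarray,
    keys: np.ndarray,
    rts: np.ndarray,
    plan: BinPlan,
    prior: PriorSpec,
    n_uninformed_bins: int = 5,
    positions: np.ndarray | None = None,
    session_start: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    **fit_kw,
) -> list[FitResult]:
    """Fit the bins in order, chaining seating checkpoints and priors.

    The first ``n_uninformed_bins`` bins share the uninformed prior; every
    later bin's prior is the truncated Gaussian centered on the previous
    bin's MAP.  Seating accumulated over all previous bins is carried over.
    """
    events = np.asarray(events, dtype=int)
    plan.validate(len(events))
    if rng is None:
        rng = np.random.default_rng()
    results: list[FitResult] = []
    inherited = None
    for idx, b in enumerate(plan.bins):
        bin_prior = prior if idx < n_uninformed_bins else prior.informed(results[-1].theta)
        sl = slice(b.start, b.stop)
        res = fit_bin(
            events[sl],
            keys[sl],
            rts[sl],
            bin_prior,
            inherited_states=inherited,
            heldout_mask=b.heldout_mask(),
            context_prefix=tuple(events[: b.start]),
            positions=None if positions is None else positions[sl],
            session_start=None if session_start is None else session_start[sl],
            rng=rng,
            bin_id=b.bin_id or f"bin{idx}",
            **fit_kw,
        )
        results.append(res)
        inherited = res.states
    return results


def heldout_r2(tau_hat: np.ndarray, rts: np.ndarray, mask: np.ndarray) -> float:
    """Coefficient of determination of predicted vs measured RTs on the mask.

    Degenerate (constant) predictions report 0 with a warning.
    """
    pred = np.asarray(tau_hat, dtype=float)[mask]
    meas = np.asarray(rts, dtype=float)[mask]
    if pred.size == 0:
        raise ValueError("empty held-out mask")
    if np.allclose(pred, pred[0]):
        warnings.warn("constant predictions on held-out segment; r2 = 0", RuntimeWarning,
                      stacklevel=2)
        return 0.0
    ss_res = float(np.sum((meas - pred) ** 2))
    ss_tot = float(np.sum((meas - meas.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    return 1.0 - ss_res / ss_tot


def component_unique_r2(
    design: np.ndarray,
    rts: np.ndarray,
    train_mask: np.ndarray,
    heldout_mask: np.ndarray,
) -> dict[str, float]:
    """Held-out unique variance of each regressor by leave-one-out refits."""
    from .response import DESIGN_COLUMNS

    full_rho = fit_rho(design, rts, train_mask)
    full_r2 = heldout_r2(predict_rt(design, full_rho), rts, heldout_mask)
    out = {"full": full_r2}
    for j, name in enumerate(DESIGN_COLUMNS, start=1):
        reduced = np.delete(design, j, axis=1)
        X = reduced[train_mask]
        beta, *_ = np.linalg.lstsq(X, rts[train_mask], rcond=None)
        pred = reduced @ beta
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out[name] = full_r2 - heldout_r2(pred, rts, heldout_mask)
    return out


def results_to_frame(results: list[FitResult]):
    """Tidy MAP-trajectory table (one row per bin)."""
    import pandas as pd

    rows = []
    for res in results:
        row = {"bin_id": res.bin_id, "objective": res.objective,
               "loglik_train": res.loglik_train, "heldout_r2": res.heldout_r2}
        row.update(res.theta)
        row.update(json.loads(res.rho.to_json()))
        rows.append(row)
    return pd.DataFrame(rows)
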