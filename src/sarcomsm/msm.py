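"""Continuous-time multistate Markov models for panel-observed transitions.

The process moves among a small number of states in continuous time with
constant (time-homogeneous) transition intensities q_rs, the off-diagonal
entries of a generator matrix Q whose rows sum to zero.  Trajectories are
observed only at arbitrary visit times (panel data): the state path between
visits is interval-censored, so each consecutive observation pair (t_i, r) →
(t_{i+1}, s) contributes P_rs(t_{i+1} − t_i) to the likelihood, where
P(t) = expm(tQ).  Death is an absorbing state; when the death time is known
exactly (from registrations rather than visits) its interval contributes the
density  Σ_{s' transient} P_{r s'}(Δt) · q_{s'D}  instead.

Covariates act proportionally on intensities, q_rs(x) = q_rs⁰ exp(β_rs·x),
with interval-start values for time-varying covariates; exp(β) is the hazard
ratio for that transition.  Estimation maximises the panel likelihood over
log-intensities and β by a quasi-Newton optimizer; standard errors come from
the numerically differentiated observed information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize
from statsmodels.tools.numdiff import approx_hess

__all__ = [
    "TransitionStructure",
    "DEFAULT_STRUCTURE",
    "PanelDataset",
    "FittedModel",
    "TransitionTable",
    "build_intensity_matrix",
    "validate_intensity_matrix",
    "transition_probability",
    "sojourn_times",
    "panel_log_likelihood",
    "fit_msm",
    "hazard_ratios",
    "predict_probability_ci",
    "crude_rates",
    "observed_transition_table",
    "goodness_of_fit",
]

_LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class TransitionStructure:
    """Allowed directed transitions among ``n_states`` states (1-based labels).

    Absorbing states have no outgoing transitions.  The default 4-state
    structure allows mutual movement among the three transient sarcopenia
    states and one-way movement into the absorbing death state.
    """

    n_states: int
    transitions: tuple[tuple[int, int], ...]
    absorbing: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        for r, s in self.transitions:
            if r == s:
                raise ValueError("self-transitions are not allowed in the structure")
            if not (1 <= r <= self.n_states and 1 <= s <= self.n_states):
                raise ValueError(f"transition ({r},{s}) outside 1..{self.n_states}")
            if r in self.absorbing:
                raise ValueError(f"absorbing state {r} cannot have outgoing transitions")

    @property
    def transient(self) -> tuple[int, ...]:
        return tuple(s for s in range(1, self.n_states + 1) if s not in self.absorbing)


DEFAULT_STRUCTURE = TransitionStructure(
    n_states=4,
    transitions=((1, 2), (1, 3), (1, 4), (2, 1), (2, 3), (2, 4), (3, 1), (3, 2), (3, 4)),
    absorbing=frozenset({4}),
)

# 5-state sensitivity variant: loss to follow-up as a second absorbing state
DROPOUT_STRUCTURE = TransitionStructure(
    n_states=5,
    transitions=((1, 2), (1, 3), (1, 4), (1, 5), (2, 1), (2, 3), (2, 4), (2, 5),
                 (3, 1), (3, 2), (3, 4), (3, 5)),
    absorbing=frozenset({4, 5}),
)


def build_intensity_matrix(structure: TransitionStructure,
                           values: Mapping[tuple[int, int], float]) -> np.ndarray:
    """Assemble a generator matrix from off-diagonal intensities.

    ``values`` maps allowed (from, to) 1-based pairs to non-negative
    intensities (per year).  Structural zeros are enforced and diagonals set
    to the negative row sum.
    """
    n = structure.n_states
    allowed = set(structure.transitions)
    Q = np.zeros((n, n))
    for (r, s), v in values.items():
        if (r, s) not in allowed:
            raise ValueError(f"transition ({r},{s}) is not in the structure")
        if v < 0:
            raise ValueError(f"intensity for ({r},{s}) must be non-negative, got {v}")
        Q[r - 1, s - 1] = v
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def validate_intensity_matrix(Q: np.ndarray, structure: Optional[TransitionStructure] = None,
                              tol: float = 1e-10) -> None:
    """Raise ValueError unless Q is a valid generator (for ``structure`` if given)."""
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be square")
    off = Q - np.diag(np.diag(Q))
    if (off < -tol).any():
        raise ValueError("off-diagonal intensities must be non-negative")
    if np.abs(Q.sum(axis=1)).max() > tol:
        raise ValueError("rows of Q must sum to zero")
    if structure is not None:
        if Q.shape[0] != structure.n_states:
            raise ValueError("Q size does not match structure")
        allowed = set(structure.transitions)
        for r in range(Q.shape[0]):
            for s in range(Q.shape[0]):
                if r != s and (r + 1, s + 1) not in allowed and Q[r, s] != 0.0:
                    raise ValueError(f"structural zero ({r+1},{s+1}) violated")


def transition_probability(Q: np.ndarray, t: float) -> np.ndarray:
    """Transition probability matrix P(t) = expm(tQ) for t ≥ 0 years."""
    if t < 0:
        raise ValueError("t must be non-negative")
    Q = np.asarray(Q, dtype=float)
    if t == 0:
        return np.eye(Q.shape[0])
    return expm(Q * t)


def _prob_at_times(Q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """P(t) stacked over many t, via eigendecomposition with expm fallback.

    A generator is almost always diagonalizable; when the eigenbasis is badly
    conditioned or the reconstruction drifts, fall back to one expm per time.
    """
    n = Q.shape[0]
    ts = np.asarray(ts, dtype=float)
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        E = np.exp(np.multiply.outer(ts, w))            # (m, n)
        P = np.einsum("ij,tj,jk->tik", V, E, Vinv).real
        if (np.abs(P.sum(axis=2) - 1.0).max() > 1e-8) or (P.min() < -1e-8):
            raise np.linalg.LinAlgError
        return np.clip(P, 0.0, 1.0)
    except np.linalg.LinAlgError:
        return np.stack([expm(Q * t) for t in ts])


def sojourn_times(Q: np.ndarray, structure: TransitionStructure = DEFAULT_STRUCTURE
                  ) -> dict[int, float]:
    """Mean sojourn (permanence) time per transient state, −1/q_rr years.

    A transient state with zero total exit intensity has infinite sojourn,
    reported explicitly as ``inf``.
    """
    validate_intensity_matrix(Q, structure)
    out: dict[int, float] = {}
    for s in structure.transient:
        q = -Q[s - 1, s - 1]
        out[s] = np.inf if q == 0 else 1.0 / q
    return out


# ---------------------------------------------------------------------------
# panel data


@dataclass
class PanelDataset:
    """Ordered subject trajectories of (time, state, covariates).

    ``data`` holds one row per observation: ``subject_id``, ``time`` (years
    since baseline), ``state`` (1-based integer), optional covariate columns,
    and an optional boolean ``death_exact`` column marking absorbing-state
    rows whose event time is exactly known.  Subjects contribute only with
    ≥ 2 observations; singletons are dropped (count kept).
    """

    data: pd.DataFrame
    covariate_names: tuple[str, ...] = ()
    n_dropped_singletons: int = 0

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   covariates: Sequence[str] = (),
                   structure: TransitionStructure = DEFAULT_STRUCTURE) -> "PanelDataset":
        required = {"subject_id", "time", "state"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"panel frame is missing columns: {sorted(missing)}")
        for c in covariates:
            if c not in df.columns:
                raise ValueError(f"covariate column {c!r} not in frame")
        df = df.copy()
        df["time"] = df["time"].astype(float)
        df["state"] = df["state"].astype(int)
        if not np.isfinite(df["time"]).all() or (df["time"] < 0).any():
            raise ValueError("times must be finite and non-negative")
        bad = ~df["state"].between(1, structure.n_states)
        if bad.any():
            raise ValueError(f"states outside 1..{structure.n_states}: "
                             f"{sorted(df.loc[bad, 'state'].unique())}")
        # row order within a subject is the trajectory order; never reordered
        df = df.reset_index(drop=True)
        for sid, g in df.groupby("subject_id", sort=False):
            t = g["time"].to_numpy()
            if (np.diff(t) <= 0).any():
                raise ValueError(f"subject {sid}: observation times not strictly increasing")
            absorbing_idx = g.index[g["state"].isin(list(structure.absorbing))]
            if len(absorbing_idx) and (g.index > absorbing_idx[0]).any():
                raise ValueError(f"subject {sid}: observations after an absorbing state")
        counts = df.groupby("subject_id")["time"].transform("size")
        n_single = int((counts == 1).sum())
        df = df[counts >= 2].reset_index(drop=True)
        if "death_exact" not in df.columns:
            df["death_exact"] = df["state"].isin(list(structure.absorbing))
        return cls(df, tuple(covariates), n_single)

    @property
    def n_subjects(self) -> int:
        return self.data["subject_id"].nunique()

    def intervals(self) -> pd.DataFrame:
        """One row per consecutive observation pair, covariates at interval start."""
        df = self.data
        g = df.groupby("subject_id", sort=False)
        out = pd.DataFrame({
            "subject_id": df["subject_id"],
            "from_state": df["state"],
            "to_state": g["state"].shift(-1),
            "t0": df["time"],
            "t1": g["time"].shift(-1),
            "to_exact": g["death_exact"].shift(-1),
        })
        for c in self.covariate_names:
            out[c] = df[c]
        out = out.dropna(subset=["to_state"]).reset_index(drop=True)
        out["to_state"] = out["to_state"].astype(int)
        out["dt"] = out["t1"] - out["t0"]
        out["to_exact"] = out["to_exact"].astype(bool)
        if (out["dt"] <= 0).any():
            raise ValueError("zero-length observation interval")
        return out


# ---------------------------------------------------------------------------
# likelihood


@dataclass
class _ParamLayout:
    """Maps the flat optimizer vector to log-intensities and betas."""

    structure: TransitionStructure
    covariate_effects: tuple[tuple[str, tuple[tuple[int, int], ...]], ...]

    @property
    def n_q(self) -> int:
        return len(self.structure.transitions)

    @property
    def n_params(self) -> int:
        return self.n_q + sum(len(trs) for _, trs in self.covariate_effects)

    def q_matrix(self, params: np.ndarray,
                 covariates: Optional[Mapping[str, float]] = None) -> np.ndarray:
        log_q = params[: self.n_q].copy()
        if covariates:
            pos = self.n_q
            for name, trs in self.covariate_effects:
                x = float(covariates.get(name, 0.0))
                for tr in trs:
                    log_q[self.structure.transitions.index(tr)] += params[pos] * x
                    pos += 1
        vals = {tr: np.exp(lq) for tr, lq in zip(self.structure.transitions, log_q)}
        return build_intensity_matrix(self.structure, vals)

    def beta_index(self, covariate: str, transition: tuple[int, int]) -> int:
        pos = self.n_q
        for name, trs in self.covariate_effects:
            for tr in trs:
                if name == covariate and tr == transition:
                    return pos
                pos += 1
        raise KeyError(f"no beta for covariate {covariate!r} on {transition}")


def _normalize_covariate_effects(
        covariates: Optional[Mapping[str, object]],
        structure: TransitionStructure) -> tuple[tuple[str, tuple[tuple[int, int], ...]], ...]:
    """Covariate spec → ordered (name, transitions) pairs.

    Each covariate maps to an explicit list of transitions, or the string
    ``"transient"`` (all transient→transient transitions) or ``"all"``.
    """
    if not covariates:
        return ()
    out = []
    transient = set(structure.transient)
    for name in covariates:
        spec = covariates[name]
        if spec == "all":
            trs = structure.transitions
        elif spec == "transient":
            trs = tuple(tr for tr in structure.transitions
                        if tr[0] in transient and tr[1] in transient)
        else:
            trs = tuple((int(r), int(s)) for r, s in spec)  # type: ignore[union-attr]
            for tr in trs:
                if tr not in structure.transitions:
                    raise ValueError(f"covariate {name!r} on disallowed transition {tr}")
        out.append((name, trs))
    return tuple(out)


def panel_log_likelihood(params: np.ndarray, data: PanelDataset,
                         structure: TransitionStructure = DEFAULT_STRUCTURE,
                         covariates: Optional[Mapping[str, object]] = None,
                         exact_death: bool = True) -> float:
    """Log-likelihood of panel data under proportional-intensity parameters.

    Each consecutive pair contributes log P_rs(Δt) under the interval-start
    generator; a pair ending in an exactly-timed absorbing event contributes
    the density  log Σ_{s' transient} P_{r s'}(Δt) q_{s' D}  when
    ``exact_death`` is on.
    """
    layout = _ParamLayout(structure, _normalize_covariate_effects(covariates, structure))
    if len(params) != layout.n_params:
        raise ValueError(f"expected {layout.n_params} parameters, got {len(params)}")
    iv = data.intervals()
    if not len(iv):
        return 0.0
    return _interval_log_likelihood(np.asarray(params, float), iv, layout,
                                    list(data.covariate_names), exact_death)


def _interval_log_likelihood(params: np.ndarray, iv: pd.DataFrame, layout: _ParamLayout,
                             cov_names: list[str], exact_death: bool) -> float:
    structure = layout.structure
    transient0 = np.array([s - 1 for s in structure.transient])
    absorbing = structure.absorbing
    if cov_names and layout.covariate_effects:
        keys = list(iv.groupby(cov_names, sort=False, dropna=False).groups.items())
    else:
        keys = [(None, iv.index)]
    total = 0.0
    for key, idx in keys:
        sub = iv.loc[idx]
        if key is None:
            covs = None
        else:
            vals = key if isinstance(key, tuple) else (key,)
            covs = dict(zip(cov_names, vals))
        Q = layout.q_matrix(params, covs)
        dts = sub["dt"].to_numpy()
        uniq, inv = np.unique(dts, return_inverse=True)
        P = _prob_at_times(Q, uniq)
        r = sub["from_state"].to_numpy() - 1
        s = sub["to_state"].to_numpy() - 1
        exact = exact_death & sub["to_exact"].to_numpy() & \
            np.isin(sub["to_state"].to_numpy(), list(absorbing))
        panel = ~exact
        if panel.any():
            p = P[inv[panel], r[panel], s[panel]]
            total += float(np.log(np.maximum(p, _LOG_FLOOR)).sum())
        if exact.any():
            # density of an exactly observed absorbing event at the interval end
            q_to_abs = Q[np.ix_(transient0, s[exact])]         # (n_trans, k)
            p_trans = P[inv[exact][:, None], r[exact][:, None], transient0[None, :]]
            dens = np.einsum("kj,jk->k", p_trans, q_to_abs)
            total += float(np.log(np.maximum(dens, _LOG_FLOOR)).sum())
    return total


# ---------------------------------------------------------------------------
# fitting


@dataclass
class FittedModel:
    """Maximum-likelihood fit of the panel multistate model."""

    structure: TransitionStructure
    params: np.ndarray                    # log q then betas
    covariance: Optional[np.ndarray]      # inverse observed information
    log_likelihood: float
    converged: bool
    n_iter: int
    n_subjects: int
    n_intervals: int
    covariate_effects: tuple[tuple[str, tuple[tuple[int, int], ...]], ...] = ()
    exact_death: bool = True
    message: str = ""

    @property
    def _layout(self) -> _ParamLayout:
        return _ParamLayout(self.structure, self.covariate_effects)

    def intensity_matrix(self, covariates: Optional[Mapping[str, float]] = None) -> np.ndarray:
        """Fitted generator Q, at reference covariate values unless given."""
        return self._layout.q_matrix(self.params, covariates)

    def intensities_with_ci(self, alpha: float = 0.05) -> pd.DataFrame:
        """Per-transition intensity estimates with log-scale Wald intervals."""
        from scipy.stats import norm
        z = norm.ppf(1 - alpha / 2)
        rows = []
        for i, (r, s) in enumerate(self.structure.transitions):
            lq = self.params[i]
            se = np.sqrt(self.covariance[i, i]) if self.covariance is not None else np.nan
            rows.append({"from": r, "to": s, "intensity": np.exp(lq),
                         "lower": np.exp(lq - z * se), "upper": np.exp(lq + z * se),
                         "log_se": se})
        return pd.DataFrame(rows)

    def sojourn_with_ci(self, alpha: float = 0.05) -> pd.DataFrame:
        """Mean sojourn times with delta-method intervals on the log scale.

        sojourn_r = 1/Σ_s q_rs; the gradient of log sojourn w.r.t. the
        log-intensities is −q_rs/Σ q, propagated through the covariance.
        """
        from scipy.stats import norm
        z = norm.ppf(1 - alpha / 2)
        Q = self.intensity_matrix()
        rows = []
        for r in self.structure.transient:
            exit_rate = -Q[r - 1, r - 1]
            soj = np.inf if exit_rate == 0 else 1.0 / exit_rate
            se_log = np.nan
            if self.covariance is not None and np.isfinite(soj):
                grad = np.zeros(len(self.params))
                for i, (a, b) in enumerate(self.structure.transitions):
                    if a == r:
                        grad[i] = -Q[a - 1, b - 1] / exit_rate
                var = float(grad @ self.covariance @ grad)
                se_log = np.sqrt(max(var, 0.0))
            rows.append({"state": r, "sojourn": soj,
                         "lower": soj * np.exp(-z * se_log),
                         "upper": soj * np.exp(z * se_log)})
        return pd.DataFrame(rows)


def _crude_rate_init(iv: pd.DataFrame, structure: TransitionStructure,
                     fallback: float = 0.1) -> np.ndarray:
    """Events / person-years per transition as starting intensities."""
    py = iv.groupby("from_state")["dt"].sum()
    init = []
    for r, s in structure.transitions:
        events = int(((iv["from_state"] == r) & (iv["to_state"] == s)).sum())
        denom = float(py.get(r, 0.0))
        rate = events / denom if events > 0 and denom > 0 else fallback
        init.append(rate)
    return np.log(np.clip(init, 1e-4, 10.0))


def fit_msm(data: PanelDataset,
            structure: TransitionStructure = DEFAULT_STRUCTURE,
            covariates: Optional[Mapping[str, object]] = None,
            init: Optional[np.ndarray] = None,
            exact_death: bool = True,
            options: Optional[dict] = None) -> FittedModel:
    """Fit the multistate model by quasi-Newton maximum likelihood.

    Parameters are log-intensities (one per allowed transition) plus one β
    per (covariate, transition) pair in the covariate spec; ``init`` may give
    a starting generator matrix, otherwise crude event/person-year rates
    seed the optimizer.  Returns estimates, the observed-information
    covariance and convergence metadata; non-convergence is flagged, not
    raised.
    """
    effects = _normalize_covariate_effects(covariates, structure)
    layout = _ParamLayout(structure, effects)
    iv = data.intervals()
    cov_names = list(data.covariate_names)

    observed = set(zip(iv["from_state"], iv["to_state"]))
    unsupported = [tr for tr in structure.transitions
                   if tr not in observed and tr[0] != tr[1]]
    if unsupported:
        warnings.warn(f"no direct observation pattern for transitions {unsupported}; "
                      "estimates may sit near the zero boundary", stacklevel=2)

    x0 = np.zeros(layout.n_params)
    if init is not None:
        validate_intensity_matrix(init, structure)
        x0[: layout.n_q] = np.log(np.clip(
            [init[r - 1, s - 1] for r, s in structure.transitions], 1e-4, None))
    else:
        x0[: layout.n_q] = _crude_rate_init(iv, structure)

    opts = {"maxiter": 500, "ftol": 1e-12, "gtol": 1e-7}
    opts.update(options or {})

    def nll(p: np.ndarray) -> float:
        return -_interval_log_likelihood(p, iv, layout, cov_names, exact_death)

    bounds = [(-16.0, 5.0)] * layout.n_q + [(-10.0, 10.0)] * (layout.n_params - layout.n_q)
    res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds, options=opts)

    hess_ok = True
    try:
        H = approx_hess(res.x, nll)
        H = (H + H.T) / 2
        cov = np.linalg.inv(H)
        cov = (cov + cov.T) / 2
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = None
        hess_ok = False

    at_boundary = bool(np.any(res.x[: layout.n_q] <= bounds[0][0] + 1e-6))
    converged = bool(res.success) and not at_boundary
    msg = res.message if isinstance(res.message, str) else str(res.message)
    if not hess_ok:
        msg += " [observed information not invertible]"
    if at_boundary:
        msg += " [intensity at zero boundary]"
        warnings.warn("some intensity estimates lie at the zero boundary", stacklevel=2)

    return FittedModel(
        structure=structure, params=res.x, covariance=cov,
        log_likelihood=-float(res.fun), converged=converged,
        n_iter=int(res.nit), n_subjects=data.n_subjects, n_intervals=len(iv),
        covariate_effects=effects, exact_death=exact_death, message=msg,
    )


def hazard_ratios(model: FittedModel, alpha: float = 0.05) -> pd.DataFrame:
    """Covariate hazard ratios exp(β) with Wald confidence intervals.

    One row per (covariate, transition).  Without a covariance matrix only
    point estimates are returned (``se`` NaN) and the frame is flagged via
    the ``has_ci`` attribute in ``DataFrame.attrs``.
    """
    from scipy.stats import norm
    z = norm.ppf(1 - alpha / 2)
    layout = model._layout
    rows = []
    for name, trs in model.covariate_effects:
        for tr in trs:
            i = layout.beta_index(name, tr)
            b = model.params[i]
            se = (np.sqrt(model.covariance[i, i])
                  if model.covariance is not None else np.nan)
            rows.append({"covariate": name, "from": tr[0], "to": tr[1],
                         "beta": b, "se": se, "hr": np.exp(b),
                         "lower": np.exp(b - z * se), "upper": np.exp(b + z * se)})
    out = pd.DataFrame(rows)
    out.attrs["has_ci"] = model.covariance is not None
    return out


def predict_probability_ci(model: FittedModel, t: float,
                           n_draws: int = 1000, seed: int = 0,
                           covariates: Optional[Mapping[str, float]] = None,
                           alpha: float = 0.05
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """P(t) with parametric-bootstrap confidence limits per entry.

    Draws parameter vectors from the asymptotic normal N(θ̂, Σ̂), recomputes
    P(t) for each and takes percentile limits; reproducible given ``seed``.
    Returns ``(point, lower, upper)`` matrices.
    """
    if model.covariance is None:
        raise ValueError("model has no covariance matrix; cannot bootstrap")
    if n_draws < 100:
        warnings.warn(f"n_draws={n_draws} is small; intervals will be noisy", stacklevel=2)
    layout = model._layout
    point = transition_probability(model.intensity_matrix(covariates), t)
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(model.params, model.covariance,
                                    size=n_draws, method="eigh")
    sims = np.empty((n_draws,) + point.shape)
    for k in range(n_draws):
        sims[k] = transition_probability(layout.q_matrix(draws[k], covariates), t)
    lower = np.quantile(sims, alpha / 2, axis=0)
    upper = np.quantile(sims, 1 - alpha / 2, axis=0)
    return point, lower, upper


# ---------------------------------------------------------------------------
# descriptive summaries of a staged panel


def crude_rates(panel: pd.DataFrame) -> pd.DataFrame:
    """Crude transition rates per 100 person-years from a staged panel.

    Person-years at risk in an origin state accumulate interval-wise (each
    consecutive observation pair contributes its full length to the origin
    state); events are pairs ending in a different state.  Returns one row
    per observed origin with events, person-years and rate for each
    destination; undefined rates (zero person-years) are NaN.
    """
    ds = PanelDataset.from_frame(panel[["subject_id", "time", "state"]],
                                 structure=_structure_for(panel))
    iv = ds.intervals()
    py = iv.groupby("from_state")["dt"].sum()
    rows = []
    states = list(range(1, _structure_for(panel).n_states + 1))
    for r in sorted(set(iv["from_state"])):
        for s in states:
            if s == r:
                continue
            events = int(((iv["from_state"] == r) & (iv["to_state"] == s)).sum())
            denom = float(py.get(r, 0.0))
            rate = 100.0 * events / denom if denom > 0 else np.nan
            rows.append({"from": r, "to": s, "events": events,
                         "person_years": denom, "rate_per_100py": rate})
    return pd.DataFrame(rows)


def _structure_for(panel: pd.DataFrame) -> TransitionStructure:
    n = int(panel["state"].max())
    if n <= DEFAULT_STRUCTURE.n_states:
        return DEFAULT_STRUCTURE
    return DROPOUT_STRUCTURE


@dataclass
class TransitionTable:
    """Counts and within-origin percentages of consecutive observed pairs."""

    counts: pd.DataFrame        # rows = destination, columns = origin
    percentages: pd.DataFrame   # column-normalized, percent

    @property
    def total_pairs(self) -> int:
        return int(self.counts.to_numpy().sum())


def observed_transition_table(panel: pd.DataFrame,
                              states: Optional[Sequence[int]] = None) -> TransitionTable:
    """Tabulate consecutive-observation state pairs of a staged panel.

    Individuals contribute one pair per consecutive visit, so a subject can
    appear in several cells.  Percentages are normalized within each origin
    column.
    """
    ds = PanelDataset.from_frame(panel[["subject_id", "time", "state"]],
                                 structure=_structure_for(panel))
    iv = ds.intervals()
    if states is None:
        states = sorted(set(iv["from_state"]) | set(iv["to_state"]))
    counts = pd.DataFrame(0, index=list(states), columns=list(states))
    grouped = iv.groupby(["from_state", "to_state"]).size()
    for (r, s), n in grouped.items():
        counts.loc[s, r] = int(n)
    origins = [c for c in counts.columns if counts[c].sum() > 0]
    counts = counts[origins]
    pct = 100.0 * counts / counts.sum(axis=0)
    counts.index.name = pct.index.name = "to"
    counts.columns.name = pct.columns.name = "from"
    return TransitionTable(counts=counts, percentages=pct)


def goodness_of_fit(model: FittedModel, data: PanelDataset,
                    eval_times: Sequence[float], window: float = 0.5) -> pd.DataFrame:
    """Observed versus model-expected state prevalence at given times.

    Expected counts propagate the baseline state distribution through P(t)
    and scale to the number of subjects under observation at t; observed
    counts come from the visit nearest each evaluation time (within
    ``window`` years), with absorbed subjects counted in their absorbing
    state at all later times.
    """
    df = data.data
    max_t = df["time"].max()
    base = df.loc[df.groupby("subject_id")["time"].idxmin()]
    pi0 = np.zeros(model.structure.n_states)
    for s, n in base["state"].value_counts().items():
        pi0[s - 1] = n
    pi0 /= pi0.sum()
    Q = model.intensity_matrix()
    absorbing = list(model.structure.absorbing)
    rows = []
    for t in eval_times:
        if t > max_t:
            warnings.warn(f"evaluation time {t} beyond follow-up {max_t}", stacklevel=2)
        obs = np.zeros(model.structure.n_states)
        n_under = 0
        for _, g in df.groupby("subject_id", sort=False):
            absorbed = g[g["state"].isin(absorbing)]
            if len(absorbed) and absorbed["time"].iloc[0] <= t:
                obs[absorbed["state"].iloc[0] - 1] += 1
                n_under += 1
                continue
            near = (g["time"] - t).abs()
            if near.min() <= window:
                obs[g.loc[near.idxmin(), "state"] - 1] += 1
                n_under += 1
        expected = n_under * (pi0 @ transition_probability(Q, t))
        for s in range(model.structure.n_states):
            rows.append({"time": t, "state": s + 1, "observed": obs[s],
                         "expected": expected[s],
                         "ratio": obs[s] / expected[s] if expected[s] > 0 else np.nan})
    return pd.DataFrame(rows)
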