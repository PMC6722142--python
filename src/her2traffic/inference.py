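"""Maximum-likelihood calibration of the trafficking models.

The measurement model treats each condition's background-corrected signal
``y_c`` as Gaussian around the model observable at the condition's
fixation time with known standard error ``sigma_c``, giving the goodness
function ``-2 log L(theta) = sum_c ((y(t_c, theta) - y_c) / sigma_c)^2``.

Parameters are optimized on log10 scale from Latin-hypercube multistarts;
published solution filters (initial internal fraction at most 5%, label
binding rate ``k_on*A0`` between 0.5 and 4 per minute) are applied as
post-hoc acceptance constraints on converged optima, not as penalties.
Confidence intervals come from the profile likelihood: one parameter is
walked away from the optimum while all others are re-optimized, and the
95% interval is read off at the 3.84 increment of ``-2 log L``; a profile
that stays below the threshold out to the parameter bound yields an
unbounded interval end. Nested-model reduction is decided by
likelihood-ratio tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.linalg import expm
from scipy.optimize import least_squares
from scipy.stats import qmc

from .errors import (
    FitFailureError,
    Her2TrafficError,
    RefitNeededError,
    ValidationError,
)
from .network import OBSERVED_SPECIES, get_network
from .trafficking import (
    TreatmentSchedule,
    _COMPOUND_KEY,
    complete_steady_state,
    simulate,
)

__all__ = [
    "ConditionData", "Dataset", "TraffickingObjective", "ArrayObjective",
    "FitResult", "ProfileCurve", "SolutionFilters", "fit", "profile",
    "likelihood_ratio_test", "ReductionCandidate", "ReductionReport",
    "reduce_model", "check_scaling_symmetry", "minus2_log_likelihood",
]

log = logging.getLogger(__name__)

PROFILE_THRESHOLD_95 = stats.chi2.ppf(0.95, 1)  # 3.8415, pointwise, 1 df

DEFAULT_LOG10_BOUNDS = (-8.0, 4.0)
#: fraction-valued parameters live on [1e-4, 1] instead
FRACTION_PARAMETERS = {"N_F0", "N_R0", "N_i0"}
FRACTION_LOG10_BOUNDS = (-4.0, 0.0)

_FAILURE_RESIDUAL = 1e6


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionData:
    """One calibration point: schedule, measured signal, its uncertainty."""

    name: str
    schedule: TreatmentSchedule
    y: float
    sigma: float


@dataclass(frozen=True)
class Dataset:
    conditions: tuple[ConditionData, ...]

    def validate(self) -> "Dataset":
        for c in self.conditions:
            c.schedule.validate()
            if not np.isfinite(c.sigma) or c.sigma <= 0:
                raise ValidationError(
                    f"condition {c.name!r}: sigma must be finite and > 0")
        return self

    def __len__(self) -> int:
        return len(self.conditions)

    @classmethod
    def from_signals(cls, signals, schedules: dict) -> "Dataset":
        """Pair a preprocessed signal table with per-condition schedules."""
        conds = []
        for rec in signals.itertuples(index=False):
            if rec.condition_id not in schedules:
                raise ValidationError(
                    f"no schedule for condition {rec.condition_id!r}")
            conds.append(ConditionData(rec.condition_id,
                                       schedules[rec.condition_id],
                                       float(rec.signal), float(rec.sem)))
        return cls(tuple(conds)).validate()


def minus2_log_likelihood(params, data: Dataset, model: str) -> float:
    """Weighted residual sum of squares on natural-scale parameters."""
    total = 0.0
    for cond in data.conditions:
        traj = simulate(model, params, cond.schedule,
                        output_times=[cond.schedule.measurement_time])
        total += ((traj.observed[-1] - cond.y) / cond.sigma) ** 2
    return total


# ---------------------------------------------------------------------------
# objectives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SolutionFilters:
    """Post-hoc acceptance constraints on converged optima."""

    internal_fraction_max: float = 0.05
    k_on_A0_range: tuple[float, float] = (0.5, 4.0)


class TraffickingObjective:
    """Maps a log10 free-parameter vector to weighted residuals.

    ``free`` lists the fitted parameter names; everything else is taken
    from ``base_params``. For Model A the steady-state completion is
    applied on every evaluation, so ``k_int`` and ``k_deg`` are always the
    derived quantities. For Model B, fitting ``N_F0`` drives
    ``N_R0 = 1 - N_F0`` through the freedom-of-scale convention.

    The condition observables are computed by piecewise-linear propagation
    with a per-evaluation cache of matrix-exponential propagators shared
    across conditions; this is numerically identical to
    :func:`her2traffic.trafficking.simulate` with ``method="linear"``.
    """

    def __init__(self, model: str, base_params, data: Dataset,
                 free: list[str], bounds_log10: dict | None = None,
                 filters: SolutionFilters = SolutionFilters()):
        self.model = model
        self.base = base_params
        self.data = data.validate()
        self.free = list(free)
        self.filters = filters
        self._net = get_network(model)
        self._obs_cols = [self._net.species.index(s)
                          for s in OBSERVED_SPECIES[model]]
        self._y = np.array([c.y for c in self.data.conditions])
        self._sigma = np.array([c.sigma for c in self.data.conditions])
        # precompiled per-condition segment plans: (ligand resets, duration)
        self._plans = []
        for cond in self.data.conditions:
            plan = []
            bps = cond.schedule.breakpoints()
            for k, t0 in enumerate(bps):
                resets = tuple((_COMPOUND_KEY[ev.compound],
                                ev.action == "on")
                               for ev in cond.schedule.events_at(t0))
                t1 = bps[k + 1] if k + 1 < len(bps) \
                    else cond.schedule.measurement_time
                plan.append((resets, max(t1 - t0, 0.0)))
            self._plans.append(plan)
        bounds_log10 = bounds_log10 or {}
        self.bounds = np.array([
            bounds_log10.get(
                name,
                FRACTION_LOG10_BOUNDS if name in FRACTION_PARAMETERS
                else DEFAULT_LOG10_BOUNDS)
            for name in self.free])
        for name in self.free:
            if not hasattr(self.base, name) and \
                    name not in self._ALIASES.get(model, {}):
                raise ValidationError(f"unknown free parameter {name!r}")

    #: tied-parameter aliases; fitting the alias drives all members jointly
    #: (the two regions' activation rates were estimated to the same value)
    _ALIASES = {"B": {"k_act_T0": ("k_act_R_T0", "k_act_F_T0")}}

    # -- parameter mapping ------------------------------------------------
    def params_from(self, theta_log10):
        theta_log10 = np.asarray(theta_log10, dtype=float)
        updates = {}
        aliases = self._ALIASES.get(self.model, {})
        for n, v in zip(self.free, theta_log10):
            val = 10.0 ** v
            for member in aliases.get(n, (n,)):
                updates[member] = val
        if self.model == "B" and "N_F0" in updates and "N_R0" not in self.free:
            updates["N_R0"] = max(0.0, 1.0 - updates["N_F0"])
        params = replace(self.base, **updates)
        if self.model == "A":
            params = complete_steady_state(params)
        return params

    def theta_from(self, params) -> np.ndarray:
        aliases = self._ALIASES.get(self.model, {})
        vals = np.array([getattr(params, aliases.get(n, (n,))[0])
                         for n in self.free])
        if np.any(vals <= 0):
            raise ValidationError(
                "log10 start requires strictly positive parameter values")
        return np.log10(vals)

    # -- evaluation -------------------------------------------------------
    def predicted(self, params) -> np.ndarray:
        """Model observable at each condition's measurement time."""
        rates = params.elementary_rates()
        x0 = params.initial_state()
        amounts_on = {k: params.ligand_amount(k) for k in ("T", "A")}
        matrix_cache: dict = {}
        prop_cache: dict = {}
        out = np.empty(len(self.data))
        for i, plan in enumerate(self._plans):
            x = x0
            amounts = {"T": 0.0, "A": 0.0}
            for resets, dt in plan:
                for key, on in resets:
                    amounts[key] = amounts_on[key] if on else 0.0
                if dt <= 0.0:
                    continue
                mkey = (amounts["T"], amounts["A"])
                if mkey not in matrix_cache:
                    matrix_cache[mkey] = self._net.linear_system(
                        rates, amounts)
                M, b = matrix_cache[mkey]
                pkey = (mkey, dt)
                if pkey not in prop_cache:
                    prop_cache[pkey] = _propagator(M, b, dt)
                x = _apply_propagator(prop_cache[pkey], x)
            out[i] = params.s_c * x[self._obs_cols].sum()
        return out

    def residuals(self, theta_log10) -> np.ndarray:
        try:
            params = self.params_from(theta_log10)
            pred = self.predicted(params)
        except (Her2TrafficError, np.linalg.LinAlgError) as exc:
            log.warning("objective evaluation failed: %s", exc)
            return np.full(len(self.data), _FAILURE_RESIDUAL)
        res = (pred - self._y) / self._sigma
        if not np.all(np.isfinite(res)):
            log.warning("non-finite residuals at theta=%s", theta_log10)
            return np.full(len(self.data), _FAILURE_RESIDUAL)
        return res

    def cost(self, theta_log10) -> float:
        """-2 log L at a log10 free-parameter vector (+inf on failure)."""
        res = self.residuals(theta_log10)
        if np.any(res == _FAILURE_RESIDUAL):
            return np.inf
        return float(res @ res)

    # -- region-label canonicalization ------------------------------------
    _B_PAIRS = (("k_int_RT", "k_int_FT"), ("k_act_R_T0", "k_act_F_T0"),
                ("k_rec_RT", "k_rec_FT"), ("k_deg_RT", "k_deg_FT"))

    def canonicalize(self, theta_log10) -> np.ndarray:
        """Resolve the two-region label-swap symmetry of Model B.

        When both regions' rate parameters are free the likelihood is
        invariant under exchanging the ruffled and flat labels; optima are
        mapped to the convention that the ruffled region is the one with
        the faster drug-induced internalization (``k_int_RT >= k_int_FT``).
        """
        if self.model != "B":
            return np.asarray(theta_log10, dtype=float)
        free = set(self.free)
        if not {"k_int_RT", "k_int_FT", "N_F0"} <= free:
            return np.asarray(theta_log10, dtype=float)
        tied = {m for alias, members in self._ALIASES.get("B", {}).items()
                if alias in free for m in members}
        for a, b in self._B_PAIRS:
            symmetric = ({a, b} <= free or {a, b} <= tied
                         or getattr(self.base, a) == getattr(self.base, b))
            if not symmetric:
                return np.asarray(theta_log10, dtype=float)  # asymmetric fix
        vals = dict(zip(self.free, np.asarray(theta_log10, dtype=float)))
        if vals["k_int_RT"] >= vals["k_int_FT"]:
            return np.asarray(theta_log10, dtype=float)
        for a, b in self._B_PAIRS:
            if a in vals and b in vals:
                vals[a], vals[b] = vals[b], vals[a]
        vals["N_F0"] = np.log10(max(1.0 - 10.0 ** vals["N_F0"], 1e-12))
        out = np.array([vals[n] for n in self.free])
        return np.clip(out, self.bounds[:, 0], self.bounds[:, 1])

    # -- constraints ------------------------------------------------------
    def accepts(self, theta_log10) -> tuple[bool, str]:
        """Published solution filters, applied to converged optima."""
        params = self.params_from(theta_log10)
        if self.model == "A":
            frac = params.N_i0 / params.N_m0
            if frac > self.filters.internal_fraction_max + 1e-12:
                return False, (f"initial internal fraction {frac:.3g} "
                               f"> {self.filters.internal_fraction_max}")
        if "k_on_A0" in self.free:
            lo, hi = self.filters.k_on_A0_range
            if not lo <= params.k_on_A0 <= hi:
                return False, (f"k_on_A0 = {params.k_on_A0:.3g} outside "
                               f"[{lo}, {hi}] 1/min")
        return True, ""

    # -- model surgery ----------------------------------------------------
    def with_fixed(self, fixed: dict) -> "TraffickingObjective":
        """Objective with some free parameters pinned (e.g. to zero)."""
        unknown = set(fixed) - set(self.free)
        if unknown:
            raise ValidationError(f"cannot fix non-free parameters {unknown}")
        base = replace(self.base, **fixed)
        free = [n for n in self.free if n not in fixed]
        bounds = {n: tuple(b) for n, b in zip(self.free, self.bounds)}
        return TraffickingObjective(self.model, base, self.data, free,
                                    bounds_log10=bounds, filters=self.filters)

    def drop_indices(self, names) -> np.ndarray:
        return np.array([self.free.index(n) for n in names], dtype=int)


def _propagator(M, b, dt):
    n = M.shape[0]
    if np.any(b != 0.0):
        aug = np.zeros((n + 1, n + 1))
        aug[:n, :n] = M
        aug[:n, n] = b
        return ("affine", expm(aug * dt)[:n])
    return ("linear", expm(M * dt))


def _apply_propagator(prop, x):
    kind, P = prop
    if kind == "affine":
        return P[:, :-1].dot(x) + P[:, -1]
    return P.dot(x)


class ArrayObjective:
    """Adapter exposing a plain residual function to :func:`fit`/:func:`profile`.

    Useful for analytically tractable problems (e.g. linear-Gaussian toys
    whose cost is exactly quadratic). The parameter vector is used as-is;
    no log transform is applied.
    """

    def __init__(self, residual_fn, bounds, names=None):
        self._fn = residual_fn
        self.bounds = np.asarray(bounds, dtype=float)
        self.free = list(names) if names is not None else \
            [f"x{i}" for i in range(len(self.bounds))]

    def residuals(self, theta):
        return np.asarray(self._fn(np.asarray(theta, dtype=float)))

    def cost(self, theta):
        r = self.residuals(theta)
        return float(r @ r)

    def accepts(self, theta):
        return True, ""


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class StartFit:
    theta0: np.ndarray
    theta: np.ndarray
    cost: float
    success: bool
    accepted: bool
    reason: str = ""


@dataclass
class FitResult:
    """Best accepted optimum plus the full multistart ensemble."""

    free_names: list[str]
    theta_log10: np.ndarray
    theta: dict                      # natural-scale values by name
    minus2LL: float
    ensemble: list[StartFit] = field(repr=False, default_factory=list)
    n_starts: int = 0
    seed: int | None = None

    def waterfall(self) -> np.ndarray:
        """Sorted converged costs (the multistart waterfall)."""
        return np.array(sorted(s.cost for s in self.ensemble if s.success))

    def to_dict(self) -> dict:
        return {
            "free": self.free_names,
            "theta": {k: float(v) for k, v in self.theta.items()},
            "theta_log10": [float(v) for v in self.theta_log10],
            "minus2LL": float(self.minus2LL),
            "n_starts": self.n_starts,
            "seed": self.seed,
            "waterfall": [float(c) for c in self.waterfall()],
        }


def _natural(objective, theta):
    if isinstance(objective, TraffickingObjective):
        return {n: 10.0 ** v for n, v in zip(objective.free, theta)}
    return dict(zip(objective.free, theta))


def _local_optimize(objective, x0, lo, hi, max_nfev=None):
    x0 = np.clip(x0, lo, hi)
    return least_squares(objective.residuals, x0, bounds=(lo, hi),
                         method="trf", max_nfev=max_nfev)


def fit(objective, n_starts: int = 64, seed: int = 0,
        extra_starts=None, max_nfev: int | None = None) -> FitResult:
    """Multistart maximum-likelihood fit.

    Draws ``n_starts`` Latin-hypercube starting points over the (log10)
    bounds, runs a deterministic trust-region least-squares optimization
    from each (plus any ``extra_starts``), applies the solution filters to
    the converged optima and returns the best accepted one together with
    the full, cost-sorted ensemble.
    """
    if n_starts < 1:
        raise ValidationError("n_starts must be >= 1")
    lo, hi = objective.bounds[:, 0], objective.bounds[:, 1]
    d = len(objective.free)
    starts = []
    if extra_starts is not None:
        starts.extend(np.asarray(s, dtype=float) for s in extra_starts)
    if d > 0:
        sampler = qmc.LatinHypercube(d=d, seed=seed)
        starts.extend(lo + sampler.random(n_starts) * (hi - lo))
    else:
        starts.append(np.empty(0))

    ensemble = []
    for x0 in starts:
        if d == 0:
            theta, c, ok = x0, objective.cost(x0), True
        else:
            try:
                sol = _local_optimize(objective, x0, lo, hi, max_nfev)
                theta, c, ok = sol.x, float(2 * sol.cost), sol.status > 0
                if hasattr(objective, "canonicalize"):
                    theta = objective.canonicalize(theta)
            except (np.linalg.LinAlgError, ValueError) as exc:
                log.warning("start failed: %s", exc)
                theta, c, ok = np.asarray(x0), np.inf, False
        # least_squares cost = 0.5 sum r^2; undo the convention
        accepted, reason = objective.accepts(theta) if ok else (False,
                                                                "no converge")
        ensemble.append(StartFit(np.asarray(x0), theta, c, ok,
                                 accepted and ok, reason))

    ensemble.sort(key=lambda s: s.cost)
    winners = [s for s in ensemble if s.accepted]
    if not winners:
        raise FitFailureError("no start converged to an accepted optimum",
                              ensemble=ensemble)
    best = winners[0]
    return FitResult(free_names=list(objective.free),
                     theta_log10=best.theta,
                     theta=_natural(objective, best.theta),
                     minus2LL=objective.cost(best.theta),
                     ensemble=ensemble, n_starts=len(starts), seed=seed)


# ---------------------------------------------------------------------------
# profile likelihood
# ---------------------------------------------------------------------------

@dataclass
class ProfileCurve:
    """Profile of ``-2 log L`` along one parameter.

    ``ci_lower``/``ci_upper`` are on the optimizer scale (log10 for
    trafficking objectives); ``-inf``/``+inf`` mark interval ends where the
    profile never crossed the threshold before the parameter bound —
    structurally or practically non-identifiable directions.
    """

    parameter: str
    grid: np.ndarray          # optimizer-scale parameter values, ascending
    minus2LL: np.ndarray
    minimum: float
    threshold: float
    ci_lower: float
    ci_upper: float
    failed_points: int = 0

    @property
    def ci_natural(self) -> tuple[float, float]:
        lo = 0.0 if np.isneginf(self.ci_lower) else 10.0 ** self.ci_lower
        hi = np.inf if np.isposinf(self.ci_upper) else 10.0 ** self.ci_upper
        return lo, hi

    @property
    def lower_unbounded(self) -> bool:
        return bool(np.isneginf(self.ci_lower))

    @property
    def upper_unbounded(self) -> bool:
        return bool(np.isposinf(self.ci_upper))


def profile(objective, fit_result: FitResult, parameter: str,
            threshold: float = PROFILE_THRESHOLD_95,
            target_step: float = 0.1, init_step: float = 0.05,
            max_step: float = 0.5, max_steps: int = 200,
            max_nfev: int | None = None) -> ProfileCurve:
    """Profile likelihood of one parameter with an adaptive step policy.

    Walks the parameter away from the optimum in both directions,
    re-optimizing all other parameters at every grid point (warm-started
    from the neighbouring solution). The step size adapts to target
    ``target_step`` increments in ``-2 log L`` and is capped at
    ``max_step`` on the optimizer scale. The walk stops once the profile
    exceeds ``threshold`` (the interval end is interpolated) or the
    parameter bound is reached (the interval end is unbounded).
    """
    j = objective.free.index(parameter)
    lo, hi = objective.bounds[:, 0].copy(), objective.bounds[:, 1].copy()
    theta_hat = np.asarray(fit_result.theta_log10, dtype=float)
    c_min = fit_result.minus2LL
    others = np.delete(np.arange(len(objective.free)), j)

    failed = 0

    def reoptimized_cost(v, x_others):
        if others.size == 0:
            return objective.cost(np.array([v])), x_others
        def res(xo):
            full = np.empty(len(objective.free))
            full[j] = v
            full[others] = xo
            return objective.residuals(full)
        sol = least_squares(res, np.clip(x_others, lo[others], hi[others]),
                            bounds=(lo[others], hi[others]), method="trf",
                            max_nfev=max_nfev)
        return float(2 * sol.cost), sol.x

    min_step = 1e-4
    max_jump = 1.0  # largest accepted increment in -2 log L per step

    def walk(direction):
        nonlocal failed
        pts = []
        v = theta_hat[j]
        x_others = theta_hat[others].copy()
        step = init_step
        bound = hi[j] if direction > 0 else lo[j]
        crossed, at_bound = False, False
        prev_excess = 0.0
        for _ in range(max_steps):
            v_next = v + direction * step
            at_bound = False
            if (direction > 0 and v_next >= bound) or \
               (direction < 0 and v_next <= bound):
                v_next, at_bound = bound, True
            try:
                c, x_trial = reoptimized_cost(v_next, x_others)
            except (np.linalg.LinAlgError, ValueError):
                failed += 1
                v = v_next
                if at_bound:
                    break
                continue
            excess = c - c_min
            # steep ascent: shrink the step and retry so the threshold
            # crossing is bracketed finely enough to interpolate
            if (excess - prev_excess > max_jump and not at_bound
                    and step > min_step * 1.01):
                step = max(step * 0.3, min_step)
                continue
            x_others = x_trial
            pts.append((v_next, c))
            if excess > threshold + 0.5:
                crossed = True
                break
            if at_bound:
                break
            gain = max(excess - prev_excess, 1e-3)
            step = float(np.clip(step * target_step / gain,
                                 min_step, max_step))
            v, prev_excess = v_next, excess
        return pts, crossed, at_bound

    def endpoint(pts, crossed, direction):
        if crossed:
            seq = [(theta_hat[j], c_min)] + pts
            for (v0, c0), (v1, c1) in zip(seq, seq[1:]):
                e0, e1 = c0 - c_min, c1 - c_min
                if e0 <= threshold < e1:
                    # interpolate on sqrt(excess): exact for a locally
                    # quadratic -2 log L
                    r0, r1 = np.sqrt(max(e0, 0.0)), np.sqrt(e1)
                    frac = (np.sqrt(threshold) - r0) / (r1 - r0)
                    return v0 + frac * (v1 - v0)
            return pts[-1][0]
        return np.inf if direction > 0 else -np.inf

    up_pts, up_crossed, _ = walk(+1)
    dn_pts, dn_crossed, _ = walk(-1)
    ci_hi = endpoint(up_pts, up_crossed, +1)
    ci_lo = endpoint(dn_pts, dn_crossed, -1)

    all_pts = sorted(dn_pts + [(theta_hat[j], c_min)] + up_pts)
    grid = np.array([p[0] for p in all_pts])
    costs = np.array([p[1] for p in all_pts])
    return ProfileCurve(parameter=parameter, grid=grid, minus2LL=costs,
                        minimum=c_min, threshold=threshold,
                        ci_lower=ci_lo, ci_upper=ci_hi,
                        failed_points=failed)


# ---------------------------------------------------------------------------
# model comparison and reduction
# ---------------------------------------------------------------------------

def likelihood_ratio_test(fit_full: FitResult, fit_reduced: FitResult,
                          df: int, tol: float = 1e-6
                          ) -> tuple[float, float]:
    """Likelihood-ratio test of a nested (reduced) model.

    Returns ``(statistic, p_value)`` with the statistic
    ``-2 log L_reduced - (-2 log L_full)`` floored at zero; a reduced fit
    beating the full one beyond ``tol`` signals optimizer failure and
    raises :class:`RefitNeededError`.
    """
    if df < 1:
        raise ValidationError("df must be >= 1")
    raw = fit_reduced.minus2LL - fit_full.minus2LL
    if raw < -tol * max(1.0, abs(fit_full.minus2LL)):
        raise RefitNeededError(
            f"reduced model fits better than full (delta = {raw:.3g}); "
            "the full model needs refitting")
    statistic = max(raw, 0.0)
    return statistic, float(stats.chi2.sf(statistic, df))


@dataclass(frozen=True)
class ReductionCandidate:
    """A removable process: the parameters it pins to zero."""

    name: str
    fix: tuple[str, ...]


@dataclass
class ReductionStep:
    candidate: str
    statistic: float
    p_value: float
    accepted: bool
    minus2LL: float


@dataclass
class ReductionReport:
    steps: list[ReductionStep]
    removed: list[str]
    objective: object
    fit: FitResult

    def to_dict(self) -> dict:
        return {
            "removed": self.removed,
            "steps": [{"candidate": s.candidate,
                       "statistic": float(s.statistic),
                       "p_value": float(s.p_value),
                       "accepted": s.accepted,
                       "minus2LL": float(s.minus2LL)} for s in self.steps],
            "final": self.fit.to_dict(),
        }


def reduce_model(objective: TraffickingObjective, fit_result: FitResult,
                 candidates, alpha: float = 0.05, n_starts: int = 8,
                 seed: int = 0) -> ReductionReport:
    """Iterative nested-model reduction by likelihood-ratio testing.

    At each round every remaining candidate process is switched off
    (parameters fixed to zero), the reduced model is refit (warm-started
    from the current optimum), and the least harmful removal — the one
    with the largest LRT p-value — is accepted if non-significant at
    ``alpha``. Equal-cost solutions are thereby resolved in favor of the
    smaller model.
    """
    current_obj, current_fit = objective, fit_result
    steps: list[ReductionStep] = []
    removed: list[str] = []
    remaining = list(candidates)
    round_no = 0
    while remaining:
        trials = []
        for cand in remaining:
            red_obj = current_obj.with_fixed({p: 0.0 for p in cand.fix})
            keep = [i for i, n in enumerate(current_obj.free)
                    if n not in cand.fix]
            x0 = np.asarray(current_fit.theta_log10)[keep]
            red_fit = fit(red_obj, n_starts=n_starts,
                          seed=seed + 1000 * round_no, extra_starts=[x0])
            try:
                stat, p = likelihood_ratio_test(current_fit, red_fit,
                                                df=len(cand.fix))
            except RefitNeededError:
                # reduced beat full: refit full warm-started from the
                # reduced optimum (removed rates at their lower bound)
                full_x = np.empty(len(current_obj.free))
                full_x[keep] = red_fit.theta_log10
                for i, n in enumerate(current_obj.free):
                    if n in cand.fix:
                        full_x[i] = current_obj.bounds[i, 0]
                current_fit = fit(current_obj, n_starts=1, seed=seed,
                                  extra_starts=[full_x,
                                                current_fit.theta_log10])
                stat, p = likelihood_ratio_test(current_fit, red_fit,
                                                df=len(cand.fix))
            trials.append((p, stat, cand, red_obj, red_fit))
        p, stat, cand, red_obj, red_fit = max(trials, key=lambda t: t[0])
        accepted = p >= alpha
        steps.append(ReductionStep(cand.name, stat, p, accepted,
                                   red_fit.minus2LL))
        if not accepted:
            break
        current_obj, current_fit = red_obj, red_fit
        removed.append(cand.name)
        remaining.remove(cand)
        round_no += 1
    return ReductionReport(steps, removed, current_obj, current_fit)


# ---------------------------------------------------------------------------
# structural symmetry check
# ---------------------------------------------------------------------------

def check_scaling_symmetry(model: str, params, schedule: TreatmentSchedule,
                           lambdas=(0.1, 2.0, 10.0), output_times=None,
                           rtol_ok: float = 1e-10) -> dict:
    """Numerically verify the freedom-of-scale symmetry.

    Simultaneously rescaling the fluorescence scale by ``lam`` and every
    initial receptor amount by ``1/lam`` (the free-compound amounts follow
    through their excess ratios) must leave the observable unchanged.
    Returns per-``lam`` maximum relative deviations and an overall flag.
    """
    base = simulate(model, params, schedule, output_times=output_times)
    scale = np.max(np.abs(base.observed))
    if scale == 0:
        scale = 1.0
    deviations = {}
    for lam in lambdas:
        other = simulate(model, params.rescaled(lam), schedule,
                         output_times=base.times)
        deviations[lam] = float(
            np.max(np.abs(other.observed - base.observed)) / scale)
    return {"max_relative_deviation": deviations,
            "invariant": bool(max(deviations.values()) <= rtol_ok)}
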