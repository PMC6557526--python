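"""Inverse problem: fitting the cycling models to uptake measurements.

Only five mean uptake observations per challenge exist against 9–10 free
parameters, so the fit is deliberately under-determined and is handled the
way small-sample kinetics studies do: leave-one-out (jackknife)
resampling around a Nelder–Mead minimisation of the mean squared error,
with parameter statistics taken from the spread of the fold estimates and
model ranking by the bias-corrected Akaike information criterion.

Only first-challenge data are used for training; second-challenge data
serve as a validation set (the mucosal-block magnitude is already fixed
inside the kinetic correction factor and is not re-estimated).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model_core import CellGeometry, ChallengeProtocol
from .simulation import run_protocol, uptake_series

__all__ = [
    "UptakeDataset",
    "FitResult",
    "predict_uptake",
    "mse",
    "fit_parameters",
    "jackknife",
    "r_squared",
    "aicc",
    "compare_models",
]

REQUIRED_COLUMNS = ("challenge", "time_min", "replicate", "uptake_pmol")


@dataclass
class UptakeDataset:
    """Replicate cumulative uptake measurements (pmol/insert).

    ``data`` holds one row per (challenge, time, replicate); ``metadata``
    records the challenge concentrations and, for synthetic data, the
    generating model and seed.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"uptake table is missing columns {missing}")
        df = df[list(REQUIRED_COLUMNS)].copy()
        df["challenge"] = df["challenge"].astype(int)
        df["time_min"] = df["time_min"].astype(float)
        df["uptake_pmol"] = df["uptake_pmol"].astype(float)
        bad = df.index[df["uptake_pmol"] < 0].tolist()
        if bad:
            raise ValueError(f"negative uptake in rows {bad}")
        dup = df.duplicated(subset=["challenge", "time_min", "replicate"])
        if dup.any():
            raise ValueError(
                f"duplicate (challenge, time, replicate) keys in rows {df.index[dup].tolist()}"
            )
        self.data = df.sort_values(["challenge", "time_min", "replicate"]).reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def challenges(self) -> list[int]:
        return sorted(self.data["challenge"].unique().tolist())

    def means(self, challenges: Iterable[int] | None = None) -> pd.DataFrame:
        """Per-(challenge, time) mean uptake, the default fitting unit."""
        df = self.data
        if challenges is not None:
            df = df[df["challenge"].isin(list(challenges))]
        out = (
            df.groupby(["challenge", "time_min"], as_index=False)["uptake_pmol"]
            .mean()
            .sort_values(["challenge", "time_min"])
            .reset_index(drop=True)
        )
        return out

    def observations(
        self, challenges: Iterable[int] | None = None, level: str = "means"
    ) -> pd.DataFrame:
        """Observation table at ``level`` 'means' or 'replicates'."""
        if level == "means":
            return self.means(challenges)
        if level == "replicates":
            df = self.data
            if challenges is not None:
                df = df[df["challenge"].isin(list(challenges))]
            return df[["challenge", "time_min", "uptake_pmol"]].reset_index(drop=True)
        raise ValueError("level must be 'means' or 'replicates'")


# ---------------------------------------------------------------------------
# Forward prediction and error
# ---------------------------------------------------------------------------


def predict_uptake(
    model: str,
    params,
    geometry: CellGeometry,
    protocol: ChallengeProtocol,
    times: Sequence[tuple[int, float]],
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_rhs_evals: int | None = None,
) -> np.ndarray:
    """Model uptake (pmol/insert) at the requested (challenge, time) pairs.

    Times are challenge-relative minutes; each challenge's uptake is
    baseline-subtracted at its start, matching the isotope accounting of
    the measurements.
    """
    times = list(times)
    if not times:
        return np.empty(0)
    per_challenge: dict[int, set[float]] = {}
    for c, t in times:
        per_challenge.setdefault(int(c), set()).add(float(t))
    n_needed = max(per_challenge)
    if n_needed > len(protocol):
        raise ValueError(f"requested challenge {n_needed} beyond protocol length {len(protocol)}")
    out_times = [
        sorted(per_challenge.get(c + 1, {protocol[c].duration})) for c in range(n_needed)
    ]
    traj = run_protocol(
        model,
        params,
        geometry,
        ChallengeProtocol(tuple(protocol.challenges[:n_needed])),
        output_times_per_challenge=out_times,
        rtol=rtol,
        atol=atol,
        max_rhs_evals=max_rhs_evals,
    )
    series = {c: uptake_series(traj, geometry, c) for c in per_challenge}
    pred = np.empty(len(times))
    for i, (c, t) in enumerate(times):
        s = series[int(c)]
        k = np.argmin(np.abs(s.times - t))
        if abs(s.times[k] - t) > 1e-6:
            raise RuntimeError(f"requested time {t} missing from simulated grid")
        pred[i] = s.uptake_pmol[k]
    return pred


def mse(
    params,
    model: str,
    geometry: CellGeometry,
    protocol: ChallengeProtocol,
    dataset: UptakeDataset,
    *,
    challenges: Iterable[int] = (1,),
    level: str = "means",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    max_rhs_evals: int | None = None,
) -> float:
    """Mean squared error (pmol²) between model and observed uptake."""
    obs = dataset.observations(challenges, level=level)
    if obs.empty:
        raise ValueError("dataset holds no observations for the requested challenges")
    pairs = list(zip(obs["challenge"], obs["time_min"]))
    pred = predict_uptake(model, params, geometry, protocol, pairs, rtol=rtol, atol=atol,
                          max_rhs_evals=max_rhs_evals)
    return float(np.mean((obs["uptake_pmol"].to_numpy() - pred) ** 2))


# ---------------------------------------------------------------------------
# Nelder-Mead fitting
# ---------------------------------------------------------------------------


@dataclass
class FitStatus:
    """Outcome of one Nelder–Mead minimisation."""

    params: object
    mse: float
    converged: bool
    n_iterations: int
    n_evaluations: int
    message: str = ""


def fit_parameters(
    model: str,
    geometry: CellGeometry,
    protocol: ChallengeProtocol,
    dataset: UptakeDataset,
    initial_guess,
    *,
    fixed: Sequence[str] = (),
    challenges: Iterable[int] = (1,),
    level: str = "means",
    max_iterations: int = 5000,
    xtol: float = 1e-8,
    ftol: float = 1e-8,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    log_bound: float = 15.0,
    n_restarts: int = 0,
    restart_jitter: float = 0.3,
    restart_seed: int = 0,
    max_rhs_evals: int | None = 20_000,
) -> FitStatus:
    """Minimise the uptake MSE over the free parameters with Nelder–Mead.

    The search runs in log-parameter space, which enforces positivity and
    equalises scales across rate constants spanning eleven orders of
    magnitude. Candidates further than ``log_bound`` (natural-log units)
    from the initial guess in any coordinate, failed integrations and
    non-finite errors all receive a large penalty so the simplex backs
    away instead of aborting. Non-convergence within the iteration budget
    is reported in the returned status, not raised.

    A plain simplex can stall in a local minimum of these multi-modal
    landscapes. ``n_restarts`` adds that many further Nelder–Mead runs
    from starts jittered around the initial guess (Gaussian in log space
    with standard deviation ``restart_jitter``, drawn from a generator
    seeded with ``restart_seed``); the best of all runs is returned. The
    procedure is fully deterministic for fixed arguments.
    """
    free = [n for n in initial_guess.PARAM_ORDER if n not in set(fixed)]
    if not free:
        return FitStatus(
            params=initial_guess,
            mse=mse(initial_guess, model, geometry, protocol, dataset,
                    challenges=challenges, level=level, rtol=rtol, atol=atol),
            converged=True,
            n_iterations=0,
            n_evaluations=1,
            message="all parameters fixed",
        )
    x0 = np.array([getattr(initial_guess, n) for n in free], dtype=float)
    if np.any(x0 <= 0):
        raise ValueError("initial guess must be strictly positive for log-space fitting")
    logx0 = np.log(x0)

    def unpack(logx: np.ndarray):
        return initial_guess.replace(**{n: float(v) for n, v in zip(free, np.exp(logx))})

    penalty = 1e12

    def objective(logx: np.ndarray) -> float:
        excess = np.abs(logx - logx0) - log_bound
        if np.any(excess > 0):
            return penalty + float(np.sum(np.clip(excess, 0, None) ** 2))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                value = mse(unpack(logx), model, geometry, protocol, dataset,
                            challenges=challenges, level=level, rtol=rtol, atol=atol,
                            max_rhs_evals=max_rhs_evals)
        except (RuntimeError, ValueError, FloatingPointError):
            return penalty  # integration failure: steer the simplex away
        return value if np.isfinite(value) else penalty

    if n_restarts < 0:
        raise ValueError("n_restarts must be non-negative")
    rng = np.random.default_rng(restart_seed)
    starts = [logx0] + [
        logx0 + rng.normal(0.0, restart_jitter, size=logx0.size) for _ in range(n_restarts)
    ]
    best = None
    nit = nfev = 0
    for x0 in starts:
        res = optimize.minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={
                "maxiter": max_iterations,
                "xatol": xtol,
                "fatol": ftol,
                "adaptive": True,
            },
        )
        nit += int(res.nit)
        nfev += int(res.nfev)
        if best is None or res.fun < best.fun:
            best = res
    return FitStatus(
        params=unpack(best.x),
        mse=float(best.fun),
        converged=bool(best.success),
        n_iterations=nit,
        n_evaluations=nfev,
        message=str(best.message),
    )


# ---------------------------------------------------------------------------
# Jackknife resampling
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Jackknife estimation summary for one model.

    Point estimates are the means of the fold estimates; confidence
    half-widths use the jackknife standard error with a t quantile
    (df = n−1) and p-values test each parameter against zero.
    """

    model: str
    estimates: dict[str, float]
    ci_halfwidth: dict[str, float]
    p_values: dict[str, float]
    mse_jk: float
    r2: float
    aicc_train: float | None
    aicc_test: float | None
    fold_estimates: pd.DataFrame
    n_observations: int
    k_parameters: int
    convention: dict = field(default_factory=dict)
    diagnostics: list = field(default_factory=list)
    fitted_params: object | None = None


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot about the observed mean."""
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.size < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observations have zero variance; R² undefined")
    return 1.0 - float(np.sum((obs - pred) ** 2)) / ss_tot


def aicc(n: int, k: int, mse_value: float) -> float:
    """Bias-corrected Akaike information criterion for least-squares fits:
    AICc = n·ln(MSE) + 2K + 2K(K+1)/(n−K−1).

    The correction requires n > K + 1; the observation count convention
    (replicates vs per-time means) materially changes whether that holds
    and is the caller's choice.
    """
    if n <= k + 1:
        raise ValueError(
            f"AICc undefined for n={n} observations and K={k} parameters: the "
            "small-sample correction needs n > K + 1 (choose a finer observation "
            "convention, e.g. replicate-level)"
        )
    if mse_value <= 0:
        raise ValueError("MSE must be positive for AICc")
    return n * math.log(mse_value) + 2 * k + (2 * k * (k + 1)) / (n - k - 1)


def jackknife(
    model: str,
    geometry: CellGeometry,
    protocol: ChallengeProtocol,
    dataset: UptakeDataset,
    initial_guess,
    *,
    fixed: Sequence[str] = (),
    train_challenges: Iterable[int] = (1,),
    test_challenges: Iterable[int] | None = None,
    level: str = "means",
    aicc_level: str = "replicates",
    mse_jk_aggregation: str = "mean",
    max_iterations: int = 5000,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> FitResult:
    """Leave-one-out estimation: one refit per training observation.

    Each fold drops one observation, refits the free parameters from
    ``initial_guess``, and predicts the dropped point; MSE_jk aggregates
    the squared leave-one-out errors (``mean`` by default, ``sum``
    optionally). AICc is evaluated at the ``aicc_level`` observation
    convention (replicate-level by default, the only convention for which
    the small-sample correction is defined with 9–10 parameters).
    """
    obs = dataset.observations(train_challenges, level=level)
    n = len(obs)
    if n < 3:
        raise ValueError("jackknife needs at least three observations")
    free = [p for p in initial_guess.PARAM_ORDER if p not in set(fixed)]

    fold_rows = []
    loo_sq_errors = np.empty(n)
    diagnostics = []
    for i in range(n):
        keep = obs.drop(index=i).reset_index(drop=True)
        # each kept row is one observation of the fold, so fit at replicate
        # level with synthetic replicate ids to keep keys unique
        sub = UptakeDataset(
            keep.assign(replicate=np.arange(len(keep)))[
                ["challenge", "time_min", "replicate", "uptake_pmol"]
            ],
            metadata={**dataset.metadata, "fold": i},
        )
        status = fit_parameters(
            model, geometry, protocol, sub, initial_guess,
            fixed=fixed, challenges=train_challenges, level="replicates",
            max_iterations=max_iterations, rtol=rtol, atol=atol,
        )
        left_out = (int(obs.loc[i, "challenge"]), float(obs.loc[i, "time_min"]))
        pred = predict_uptake(model, status.params, geometry, protocol, [left_out],
                              rtol=rtol, atol=atol)[0]
        loo_sq_errors[i] = (obs.loc[i, "uptake_pmol"] - pred) ** 2
        fold_rows.append({p: getattr(status.params, p) for p in free} | {"fold": i})
        diagnostics.append(status)

    folds = pd.DataFrame(fold_rows).set_index("fold")
    estimates = {p: float(folds[p].mean()) for p in free}
    ci = {}
    pvals = {}
    tq = stats.t.ppf(0.975, n - 1)
    for p in free:
        theta = folds[p].to_numpy()
        se = math.sqrt((n - 1) / n * float(np.sum((theta - theta.mean()) ** 2)))
        ci[p] = tq * se
        if se == 0.0:
            pvals[p] = 0.0 if estimates[p] != 0 else 1.0
        else:
            tstat = abs(estimates[p]) / se
            pvals[p] = float(2 * stats.t.sf(tstat, n - 1))

    if mse_jk_aggregation == "mean":
        mse_jk = float(loo_sq_errors.mean())
    elif mse_jk_aggregation == "sum":
        mse_jk = float(loo_sq_errors.sum())
    else:
        raise ValueError("mse_jk_aggregation must be 'mean' or 'sum'")

    point_params = initial_guess.replace(**estimates)
    pairs = list(zip(obs["challenge"], obs["time_min"]))
    pred = predict_uptake(model, point_params, geometry, protocol, pairs, rtol=rtol, atol=atol)
    r2 = r_squared(obs["uptake_pmol"].to_numpy(), pred)

    k = len(free)

    def _aicc_on(challs) -> float | None:
        try:
            m = mse(point_params, model, geometry, protocol, dataset,
                    challenges=challs, level=aicc_level, rtol=rtol, atol=atol)
            n_a = len(dataset.observations(challs, level=aicc_level))
            return aicc(n_a, k, m)
        except ValueError:
            return None

    aicc_train = _aicc_on(train_challenges)
    aicc_test = _aicc_on(test_challenges) if test_challenges is not None else None

    return FitResult(
        model=model,
        estimates=estimates,
        ci_halfwidth=ci,
        p_values=pvals,
        mse_jk=mse_jk,
        r2=r2,
        aicc_train=aicc_train,
        aicc_test=aicc_test,
        fold_estimates=folds,
        n_observations=n,
        k_parameters=k,
        convention={
            "fold_level": level,
            "aicc_level": aicc_level,
            "mse_jk_aggregation": mse_jk_aggregation,
        },
        diagnostics=diagnostics,
        fitted_params=point_params,
    )


@dataclass(frozen=True)
class ModelSelection:
    """Outcome of an information-criterion comparison of two fits."""

    selected: str | None  # model name, or None on an exact tie
    delta_aicc_train: float
    delta_aicc_test: float | None


def compare_models(fit_a: FitResult, fit_b: FitResult) -> ModelSelection:
    """Select the lower-AICc model; ΔAICc is reported as (a − b)."""
    if fit_a.convention != fit_b.convention:
        raise ValueError("fits use different observation/AICc conventions")
    if fit_a.aicc_train is None or fit_b.aicc_train is None:
        raise ValueError("both fits need a defined training AICc to compare")
    delta = fit_a.aicc_train - fit_b.aicc_train
    if delta < 0:
        selected = fit_a.model
    elif delta > 0:
        selected = fit_b.model
    else:
        selected = None
    delta_test = None
    if fit_a.aicc_test is not None and fit_b.aicc_test is not None:
        delta_test = fit_a.aicc_test - fit_b.aicc_test
    return ModelSelection(selected=selected, delta_aicc_train=delta, delta_aicc_test=delta_test)
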