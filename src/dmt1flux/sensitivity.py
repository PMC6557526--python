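"""Normalized local sensitivity of predicted intracellular iron.

One-at-a-time ±10% perturbations of each kinetic parameter around its
nominal value; the output functional is FeIN at a fixed evaluation time
(default: end of the first 15-min challenge). The normalized coefficient

    r = (ΔFeIN / FeIN) / (Δθ / θ)

is computed separately for the increase (r+) and the decrease (r−), the
larger-magnitude of the two (r*) classifies the parameter's influence:
negligible |r*| ≤ 0.25, low ≤ 0.5, regular ≤ 1, high > 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import CellGeometry, ChallengeProtocol, default_protocol
from .simulation import run_protocol

__all__ = [
    "SensitivityRecord",
    "local_sensitivity",
    "classify_influence",
    "sensitivity_table",
]

DEFAULT_DELTA = 0.10
DEFAULT_EVAL_TIME = 15.0  # min; end of the first (training) challenge

INFLUENCE_THRESHOLDS = ((0.25, "negligible"), (0.5, "low"), (1.0, "regular"))


def classify_influence(r_star: float) -> str:
    """Four-way influence class on |r*| with inclusive upper bounds."""
    if not np.isfinite(r_star):
        raise ValueError("r_star must be finite")
    a = abs(r_star)
    for bound, label in INFLUENCE_THRESHOLDS:
        if a <= bound:
            return label
    return "high"


@dataclass(frozen=True)
class SensitivityRecord:
    """Sensitivity of the output to one parameter under ±delta."""

    parameter: str
    r_plus: float
    r_minus: float
    eval_time: float
    output: str = "FeIN"

    @property
    def r_star(self) -> float:
        """The larger-magnitude of r+ and r− (sign preserved)."""
        return self.r_plus if abs(self.r_plus) >= abs(self.r_minus) else self.r_minus

    @property
    def influence(self) -> str:
        return classify_influence(self.r_star)


def _fe_in_at(
    model: str,
    params,
    geometry: CellGeometry,
    protocol: ChallengeProtocol,
    eval_time: float,
    rtol: float,
    atol: float,
) -> float:
    """FeIN (μM) at absolute ``eval_time``, truncating the protocol to the
    challenges actually needed."""
    t_acc = 0.0
    needed = 0
    out_times: list[list[float]] = []
    for ch in protocol:
        needed += 1
        if eval_time <= t_acc + ch.duration + 1e-9:
            out_times.append([min(eval_time - t_acc, ch.duration)])
            break
        out_times.append([ch.duration])
        t_acc += ch.duration
    else:
        raise ValueError(f"eval_time {eval_time} beyond protocol duration")
    traj = run_protocol(
        model,
        params,
        geometry,
        ChallengeProtocol(tuple(protocol.challenges[:needed])),
        output_times_per_challenge=out_times,
        rtol=rtol,
        atol=atol,
    )
    i = int(np.argmin(np.abs(traj.times - eval_time)))
    return float(traj.fe_in[i])


def local_sensitivity(
    model: str,
    params,
    geometry: CellGeometry,
    protocol: ChallengeProtocol,
    parameter_name: str,
    *,
    delta: float = DEFAULT_DELTA,
    eval_time: float = DEFAULT_EVAL_TIME,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    fe_in_nominal: float | None = None,
) -> tuple[float, float]:
    """(r_plus, r_minus) for one parameter under a ±``delta`` relative
    perturbation, each a forward difference against the nominal run."""
    if not (0 < delta <= 0.5):
        raise ValueError("delta must lie in (0, 0.5]")
    nominal_value = getattr(params, parameter_name)
    if nominal_value <= 0:
        raise ValueError(f"{parameter_name} must be positive to perturb relatively")
    if fe_in_nominal is None:
        fe_in_nominal = _fe_in_at(model, params, geometry, protocol, eval_time, rtol, atol)
    if fe_in_nominal == 0:
        raise ValueError("nominal FeIN is zero at eval_time; sensitivity undefined")
    out = []
    for sign in (+1.0, -1.0):
        perturbed = params.replace(**{parameter_name: nominal_value * (1 + sign * delta)})
        fe = _fe_in_at(model, perturbed, geometry, protocol, eval_time, rtol, atol)
        out.append(((fe - fe_in_nominal) / fe_in_nominal) / (sign * delta))
    return out[0], out[1]


def sensitivity_table(
    model: str,
    params,
    geometry: CellGeometry,
    protocol: ChallengeProtocol | None = None,
    *,
    delta: float = DEFAULT_DELTA,
    eval_time: float = DEFAULT_EVAL_TIME,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> list[SensitivityRecord]:
    """One record per free parameter, in canonical parameter order."""
    if protocol is None:
        protocol = default_protocol(n_challenges=1)
    fe_nom = _fe_in_at(model, params, geometry, protocol, eval_time, rtol, atol)
    if fe_nom == 0:
        raise ValueError("nominal FeIN is zero at eval_time; sensitivity undefined")
    records = []
    for name in params.PARAM_ORDER:
        r_plus, r_minus = local_sensitivity(
            model, params, geometry, protocol, name,
            delta=delta, eval_time=eval_time, rtol=rtol, atol=atol,
            fe_in_nominal=fe_nom,
        )
        records.append(
            SensitivityRecord(parameter=name, r_plus=r_plus, r_minus=r_minus, eval_time=eval_time)
        )
    return records


def sensitivity_frame(records: list[SensitivityRecord]) -> pd.DataFrame:
    """Tabular view of a sensitivity scan."""
    return pd.DataFrame(
        {
            "parameter": [r.parameter for r in records],
            "r_plus": [r.r_plus for r in records],
            "r_minus": [r.r_minus for r in records],
            "r_star": [r.r_star for r in records],
            "influence": [r.influence for r in records],
        }
    )
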