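"""Seeded synthetic-data generators.

Each generator emulates the statistical shape of the data its engine
expects — growth-trait time series, supervised feature tables with a
controllable noise fraction, and grouped matrices with planted
group-specific feature blocks — and is a pure function of its parameters
and seed.  Every generator returns ``(object, truth)`` where ``truth``
is a JSON-serializable record of the generating parameters, so recovery
can be checked end to end.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .embedding.embed import DataMatrix
from .exceptions import ValidationError
from .growth.fit import GrowthTrajectory
from .growth.forms import CONTROL_MODELS, get_model_spec
from .prediction.registry import SupervisedTable

__all__ = [
    "SimulationSpec",
    "simulate_growth_trajectory",
    "simulate_stress_trajectory",
    "simulate_supervised_table",
    "simulate_clustered_matrix",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Echo of one generator invocation for the run manifest."""

    generator: str
    parameters: dict
    noise: dict
    n: int
    seed: int

    def as_dict(self):
        return asdict(self)


def _rng(seed):
    if seed is None:
        raise ValidationError("a seed is mandatory for every generator")
    return np.random.default_rng(int(seed) % (2**31))


def simulate_growth_trajectory(model_id, true_params, times, noise_sd=0.0,
                               seed=0, multiplicative=False, plant_id="sim"):
    """Trait series y = f(t; θ) + ε from one control growth model.

    ``noise_sd`` is the additive Gaussian sd (trait units); with
    ``multiplicative=True`` the noise is lognormal, y·exp(N(0, noise_sd))
    with noise_sd then a fractional sd.  Values are clipped below at a
    small positive floor (1e-6 of the curve maximum) so log-based
    linearizations stay usable; the clip count is recorded in the truth.
    """
    if model_id not in CONTROL_MODELS:
        raise ValidationError(f"model_id must be a control model, got {model_id!r}")
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValidationError("times must be non-empty")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    spec = get_model_spec(model_id)
    clean = np.asarray(spec.predict(times, true_params), dtype=float)
    rng = _rng(seed)
    if noise_sd == 0:
        values = clean.copy()
    elif multiplicative:
        values = clean * np.exp(rng.normal(0.0, noise_sd, times.size))
    else:
        values = clean + rng.normal(0.0, noise_sd, times.size)
    floor = 1e-6 * max(np.max(np.abs(clean)), 1e-12)
    clipped = int(np.sum(values < floor))
    values = np.maximum(values, floor)
    traj = GrowthTrajectory(plant_id, times, values, condition="control")
    truth = {
        "generator": "growth_trajectory", "model_id": model_id,
        "params": {k: float(v) for k, v in true_params.items()},
        "noise_sd": float(noise_sd), "multiplicative": multiplicative,
        "seed": int(seed), "n": int(times.size), "n_clipped": clipped,
    }
    return traj, truth


def simulate_stress_trajectory(bell_params, recovery_slope, phase_boundaries,
                               times, noise_sd=0.0, seed=0, plant_id="sim-stress"):
    """Gaussian-bell growth through the stress phase, linear re-growth after.

    ``bell_params``: ``{"height": A, "peak_time": c, "width": w}`` giving
    y = A·exp(-(t-c)²/(2w²)) up to the recovery boundary (the last entry
    of ``phase_boundaries``); afterwards a line of slope
    ``recovery_slope`` anchored at the bell's value there, so the two
    phases meet continuously.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValidationError("times must be non-empty")
    bounds = tuple(float(b) for b in np.atleast_1d(phase_boundaries))
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValidationError("phase boundaries must be strictly increasing")
    recovery_start = bounds[-1]
    if not (times[0] <= recovery_start <= times[-1]):
        raise ValidationError(
            f"recovery boundary {recovery_start} outside time range "
            f"[{times[0]}, {times[-1]}]"
        )
    A, c, w = (bell_params["height"], bell_params["peak_time"], bell_params["width"])

    def bell(t):
        return A * np.exp(-((t - c) ** 2) / (2.0 * w**2))

    clean = np.where(times <= recovery_start, bell(times),
                     bell(recovery_start) + recovery_slope * (times - recovery_start))
    rng = _rng(seed)
    values = clean + (rng.normal(0.0, noise_sd, times.size) if noise_sd > 0 else 0.0)
    floor = 1e-6 * max(np.max(np.abs(clean)), 1e-12)
    clipped = int(np.sum(values < floor))
    values = np.maximum(values, floor)
    traj = GrowthTrajectory(plant_id, times, values, condition="stress")
    truth = {
        "generator": "stress_trajectory",
        "bell_params": {k: float(v) for k, v in bell_params.items()},
        "recovery_slope": float(recovery_slope),
        "phase_boundaries": list(bounds), "noise_sd": float(noise_sd),
        "seed": int(seed), "n": int(times.size), "n_clipped": clipped,
    }
    return traj, truth


def simulate_supervised_table(n, p_informative, p_noise, coefficients=None,
                              noise_fraction=0.25, task="regression",
                              class_count=2, class_sep=2.0, seed=0):
    """Feature table with known signal structure.

    Regression: X ~ N(0, 1), y = Xβ + ε with var(ε) chosen so that the
    noise accounts for ``noise_fraction`` of var(y) in expectation.
    Classification: class-conditional Gaussians whose means are
    displaced by ``class_sep`` along the informative dimensions only.
    """
    if not (0 <= noise_fraction < 1):
        raise ValidationError("noise_fraction must be in [0, 1)")
    p = p_informative + p_noise
    if p < 1:
        raise ValidationError("need at least one feature")
    rng = _rng(seed)
    names = ([f"inf{j+1}" for j in range(p_informative)]
             + [f"noise{j+1}" for j in range(p_noise)])
    ids = [f"s{i+1}" for i in range(n)]
    X = rng.normal(0.0, 1.0, (n, p))
    if task == "regression":
        if p_informative == 0:
            raise ValidationError("regression signal requires p_informative >= 1")
        beta = (np.asarray(coefficients, dtype=float) if coefficients is not None
                else np.ones(p_informative))
        if beta.size != p_informative:
            raise ValidationError("coefficients length must equal p_informative")
        signal = X[:, :p_informative] @ beta
        var_signal = float(np.sum(beta**2))          # population variance of Xβ
        sigma = (np.sqrt(noise_fraction / (1.0 - noise_fraction) * var_signal)
                 if noise_fraction > 0 else 0.0)
        y = signal + rng.normal(0.0, sigma, n)
        table = SupervisedTable(ids, X, names, y, "regression")
        truth = {"generator": "supervised_table", "task": task, "n": n,
                 "p_informative": p_informative, "p_noise": p_noise,
                 "coefficients": beta.tolist(), "noise_fraction": noise_fraction,
                 "noise_sd": float(sigma), "seed": int(seed)}
        return table, truth
    if task == "classification":
        if p_informative == 0:
            raise ValidationError("classification needs informative dimensions")
        labels = np.array([f"c{(i % class_count) + 1}" for i in range(n)])
        for c in range(class_count):
            rows = np.where(labels == f"c{c+1}")[0]
            for j in range(p_informative):
                if j % class_count == c:
                    X[rows, j] += class_sep
        table = SupervisedTable(ids, X, names, labels, "classification")
        truth = {"generator": "supervised_table", "task": task, "n": n,
                 "p_informative": p_informative, "p_noise": p_noise,
                 "class_count": class_count, "class_sep": float(class_sep),
                 "seed": int(seed)}
        return table, truth
    raise ValidationError(f"unknown task {task!r}")


def simulate_clustered_matrix(n_per_group, groups, p, p_specific_per_group,
                              effect, within_sd=1.0, seed=0):
    """Grouped matrix with planted group-specific feature blocks.

    Every group of observations has ``p_specific_per_group`` features
    whose mean is shifted upward by ``effect``; all other entries are
    N(0, within_sd).  Emulates an expression matrix with organ-specific
    blocks; values are on a log-like (additive) scale.
    """
    if effect < 0:
        raise ValidationError("effect must be >= 0 (0 plants no signal)")
    if p < groups * p_specific_per_group:
        raise ValidationError(
            f"p={p} cannot hold {groups} blocks of {p_specific_per_group} features"
        )
    rng = _rng(seed)
    n = n_per_group * groups
    X = rng.normal(0.0, within_sd, (n, p))
    group_labels = np.repeat([f"g{g+1}" for g in range(groups)], n_per_group)
    col_ids = [f"f{j+1}" for j in range(p)]
    planted = {}
    for g in range(groups):
        cols = range(g * p_specific_per_group, (g + 1) * p_specific_per_group)
        rows = np.where(group_labels == f"g{g+1}")[0]
        for j in cols:
            X[rows, j] += effect
        planted[f"g{g+1}"] = [col_ids[j] for j in cols]
    matrix = DataMatrix([f"obs{i+1}" for i in range(n)], col_ids, X,
                        row_annotations={"group": group_labels.tolist()})
    truth = {"generator": "clustered_matrix", "n_per_group": n_per_group,
             "groups": groups, "p": p,
             "p_specific_per_group": p_specific_per_group,
             "effect": float(effect), "within_sd": float(within_sd),
             "seed": int(seed), "planted": planted,
             "group_labels": group_labels.tolist()}
    return matrix, truth
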