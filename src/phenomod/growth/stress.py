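"""Two-phase modeling of growth under stress and recovery.

Growth before and during a stress episode is described by one of three
bell-shaped curves or a plain quadratic, all reducible to quadratic OLS
after a transform; re-growth during recovery is a straight line whose
slope is the speed of re-growth R_rec.

Bell candidates (coefficients c0 + c1*u + c2*u**2 estimated by OLS):

- ``bell_gauss``     : ln y quadratic in t          (Gaussian in t)
- ``bell_loggauss``  : ln y quadratic in ln t       (Gaussian in ln t, t > 0)
- ``bell_sqrtgauss`` : sqrt(y) quadratic in t       (bell on the sqrt scale)
- ``quadratic``      : y quadratic in t

A candidate whose fitted quadratic opens upward (c2 >= 0) cannot be a
bell and is flagged invalid; the best valid candidate (largest
original-scale R²) supplies the peak time and peak value from its vertex.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from ..exceptions import DegenerateFitError, StressFitError, ValidationError
from .fit import GrowthCurveResults, GrowthTrajectory
from .forms import STRESS_MODELS, GrowthModelSpec

__all__ = ["StressFit", "fit_stress_phase", "fit_recovery_phase", "fit_stress_recovery"]


def _window_mask(trajectory, window):
    start, end = window
    if start >= end:
        raise ValidationError(f"window ({start}, {end}) is not ordered")
    t = trajectory.times
    if start < t[0] - 1e-12 or end > t[-1] + 1e-12:
        raise ValidationError(
            f"window ({start}, {end}) outside observed time range "
            f"[{t[0]}, {t[-1]}]"
        )
    return (t >= start) & (t <= end)


def _quad_ols(u, v):
    """Quadratic OLS v ~ 1 + u + u²: coefficients, R², overall F-test p."""
    X = np.column_stack([np.ones_like(u), u, u * u])
    coef, *_ = np.linalg.lstsq(X, v, rcond=None)
    resid = v - X @ coef
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateFitError("constant response in stress window")
    r2 = 1.0 - ss_res / ss_tot
    n = v.size
    if n > 3 and ss_res > 0 and r2 < 1.0:
        f = (r2 / 2.0) / ((1.0 - r2) / (n - 3))
        p = max(float(stats.f.sf(f, 2, n - 3)), np.finfo(float).tiny)
    else:
        p = np.finfo(float).tiny
    return coef, float(r2), p


# transform of (t, y) -> (u, v, valid mask) and inverse of v back to y
_BELL_FORMS = {
    "bell_gauss": (
        lambda t, y: (t, np.where(y > 0, np.log(np.where(y > 0, y, 1.0)), np.nan), y > 0),
        np.exp,
    ),
    "bell_loggauss": (
        lambda t, y: (
            np.where(t > 0, np.log(np.where(t > 0, t, 1.0)), np.nan),
            np.where(y > 0, np.log(np.where(y > 0, y, 1.0)), np.nan),
            (y > 0) & (t > 0),
        ),
        np.exp,
    ),
    "bell_sqrtgauss": (
        lambda t, y: (t, np.where(y >= 0, np.sqrt(np.where(y >= 0, y, 0.0)), np.nan), y >= 0),
        lambda v: np.square(np.maximum(v, 0.0)),
    ),
    "quadratic": (lambda t, y: (t, y.astype(float), np.isfinite(y)), lambda v: v),
}


def _make_stress_spec(model_id):
    t_is_log = model_id == "bell_loggauss"
    _, inverse = _BELL_FORMS[model_id]

    def predict(times, p):
        times = np.asarray(times, dtype=float)
        u = np.log(times) if t_is_log else times
        v = p["c0"] + p["c1"] * u + p["c2"] * u * u
        return inverse(v)

    return GrowthModelSpec(model_id, False, "quadratic OLS after transform",
                           None, None, predict)


_STRESS_SPECS = {mid: _make_stress_spec(mid) for mid in STRESS_MODELS}


@dataclass
class StressFit:
    """Phase-1 stress fits plus, optionally, the recovery-phase line."""

    phase1_fits: dict          # model_id -> GrowthCurveResults
    invalid: dict              # model_id -> reason (upward-opening etc.)
    best_phase1: str
    peak_time: float
    peak_value: float
    phase2_fit: GrowthCurveResults | None = None

    @property
    def R_rec(self):
        if self.phase2_fit is None:
            return None
        return self.phase2_fit.params["slope"]

    def summary(self) -> str:
        lines = [f"Stress-phase fit — best model: {self.best_phase1}"]
        for mid, f in self.phase1_fits.items():
            tag = " (invalid: %s)" % self.invalid[mid] if mid in self.invalid else ""
            lines.append(f"  {mid:15s} R2={f.rsquared_original:.4f} p={f.pvalue:.2g}{tag}")
        lines.append(f"  peak: value {self.peak_value:.6g} at day {self.peak_time:.6g}")
        if self.phase2_fit is not None:
            lines.append(
                f"  recovery: R_rec={self.R_rec:.6g} "
                f"(R2={self.phase2_fit.rsquared_original:.4f})"
            )
        return "\n".join(lines)


def fit_stress_phase(trajectory: GrowthTrajectory, stress_window) -> StressFit:
    """Fit the four bell/quadratic candidates inside the stress window.

    Requires at least 5 points in the window.  Returns a
    :class:`StressFit` whose ``best_phase1`` attains the largest
    original-scale R² among candidates not flagged invalid (ties broken
    in the fixed registry order) and whose peak is read off the best
    candidate's vertex.
    """
    mask = _window_mask(trajectory, stress_window)
    if int(mask.sum()) < 5:
        raise ValidationError(
            f"stress window holds {int(mask.sum())} points; need >= 5"
        )
    t, y = trajectory.times[mask], trajectory.values[mask]
    fits, invalid = {}, {}
    for mid in STRESS_MODELS:
        transform, _ = _BELL_FORMS[mid]
        u, v, valid = transform(t, y)
        if int(valid.sum()) < 4:
            invalid[mid] = f"only {int(valid.sum())} points in transform domain"
            continue
        try:
            coef, r2_lin, p = _quad_ols(u[valid], v[valid])
        except DegenerateFitError as exc:
            invalid[mid] = str(exc)
            continue
        params = {"c0": float(coef[0]), "c1": float(coef[1]), "c2": float(coef[2])}
        spec = _STRESS_SPECS[mid]
        fitted = spec.predict(t, params)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2_orig = float(1.0 - np.sum((y - fitted) ** 2) / ss_tot)
        sub = GrowthTrajectory(trajectory.plant_id, t, y,
                               trajectory.group_id, trajectory.condition)
        fit = GrowthCurveResults(sub, spec, params, None, r2_lin, r2_orig, p,
                                 int(valid.sum()), int((~valid).sum()), fitted)
        fits[mid] = fit
        # c2 must be clearly negative to define a peak; exactly-linear
        # transformed data gives c2 ~ +/- machine eps and is not a bell
        tol = 1e-10 * max(1.0, abs(coef[0]), abs(coef[1]))
        if coef[2] > -tol:
            invalid[mid] = "fitted quadratic opens upward (no bell/peak)"
    valid_ids = [m for m in STRESS_MODELS if m in fits and m not in invalid]
    if not valid_ids:
        raise StressFitError(
            "no valid stress-phase candidate: "
            + "; ".join(f"{m}: {r}" for m, r in invalid.items())
        )
    best = max(valid_ids, key=lambda m: fits[m].rsquared_original)
    p = fits[best].params
    u_peak = -p["c1"] / (2.0 * p["c2"])
    peak_time = float(np.exp(u_peak)) if best == "bell_loggauss" else float(u_peak)
    peak_value = float(_STRESS_SPECS[best].predict(np.array([peak_time]), p)[0])
    return StressFit(fits, invalid, best, peak_time, peak_value)


def fit_recovery_phase(trajectory: GrowthTrajectory, recovery_window) -> GrowthCurveResults:
    """OLS line through the recovery window; the slope is R_rec."""
    mask = _window_mask(trajectory, recovery_window)
    n = int(mask.sum())
    if n < 3:
        raise ValidationError(f"recovery window holds {n} points; need >= 3")
    t, y = trajectory.times[mask], trajectory.values[mask]
    tm, ym = t.mean(), y.mean()
    stt = float(np.sum((t - tm) ** 2))
    slope = float(np.sum((t - tm) * (y - ym)) / stt)
    intercept = float(ym - slope * tm)
    fitted = intercept + slope * t
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - ym) ** 2))
    if ss_tot == 0:  # flat recovery: define R2 = 1 for an exact constant fit
        r2 = 1.0
        p = np.finfo(float).tiny
    else:
        r2 = 1.0 - ss_res / ss_tot
        if ss_res > 0 and r2 < 1.0:
            f = (n - 2) * r2 / (1.0 - r2)
            p = max(float(stats.f.sf(f, 1, n - 2)), np.finfo(float).tiny)
        else:
            p = np.finfo(float).tiny

    spec = GrowthModelSpec(
        "recovery_linear", False, "identity (y on t)", None, None,
        lambda times, prm: prm["intercept"] + prm["slope"] * np.asarray(times, float),
    )
    sub = GrowthTrajectory(trajectory.plant_id, t, y,
                           trajectory.group_id, trajectory.condition)
    return GrowthCurveResults(sub, spec, {"intercept": intercept, "slope": slope},
                              None, r2, r2, p, n, 0, fitted)


def fit_stress_recovery(trajectory, stress_window, recovery_window) -> StressFit:
    """Convenience wrapper fitting both phases into one :class:`StressFit`."""
    sf = fit_stress_phase(trajectory, stress_window)
    sf.phase2_fit = fit_recovery_phase(trajectory, recovery_window)
    return sf
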