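"""Survival curves and mono-exponential fits shared across kinetic assays.

One fitting layer serves dwell-time survival fractions, loss-of-FRET
nucleotide-exchange traces, fluorescence recovery after photobleaching
(mono-exponential growth) and photoactivated-pool disappearance
(one-phase decay with plateau, y = C + A·e^(−kt)). Every converged fit
reports the rate k, its standard error, the half-time t½ = ln 2 / k and R².

Right-censored dwells (molecules still present at the end of the movie)
are excluded from the survival fraction but counted in ``n_censored`` so
the user can bound the resulting bias; no survival-analysis correction is
applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from lmfit import Model

__all__ = [
    "FitConvergenceError",
    "SurvivalCurve",
    "ExpFit",
    "survival_curve",
    "fit_monoexp",
    "fit_survival",
    "fret_ratio_trace",
    "dwell_half_time_ratio",
]

LN2 = math.log(2.0)


class FitConvergenceError(RuntimeError):
    """Nonlinear fit failed to converge."""


@dataclass
class SurvivalCurve:
    t: np.ndarray  # s, increasing, starts at 0
    survival: np.ndarray  # fraction of uncensored dwells >= t
    n_total: int
    n_censored: int


@dataclass
class ExpFit:
    model: str  # "decay" or "growth"
    amplitude: float
    rate: float  # s⁻¹
    offset: float
    r_squared: float
    se_rate: float
    degenerate: bool = False

    @property
    def t_half(self) -> float:
        """Half-time ln2/k; satisfies t_half · k = ln 2 exactly."""
        return LN2 / self.rate


def survival_curve(
    dwells: np.ndarray, censored: np.ndarray | None = None
) -> SurvivalCurve:
    """Empirical survival fraction S(t) = P(dwell ≥ t) at observed times.

    Evaluated with the ≥ convention at t = 0 and every distinct uncensored
    dwell time, giving the step function read directly off single-molecule
    disappearance data.
    """
    dwells = np.asarray(dwells, dtype=float)
    if dwells.size == 0:
        raise ValueError("no dwell times given")
    if np.any(dwells <= 0):
        raise ValueError("dwell times must be positive")
    if censored is None:
        censored = np.zeros(dwells.shape, dtype=bool)
    censored = np.asarray(censored, dtype=bool)
    obs = np.sort(dwells[~censored])
    if obs.size == 0:
        raise ValueError("all dwells are censored")
    times = np.concatenate([[0.0], np.unique(obs)])
    # fraction of observed dwells >= t  (searchsorted gives # strictly < t)
    surv = 1.0 - np.searchsorted(obs, times, side="left") / obs.size
    return SurvivalCurve(
        t=times, survival=surv, n_total=int(dwells.size), n_censored=int(censored.sum())
    )


def _decay(t, amplitude, rate, offset):
    return offset + amplitude * np.exp(-rate * t)


def _growth(t, amplitude, rate, offset):
    return offset + amplitude * (1.0 - np.exp(-rate * t))


def _initial_rate(t: np.ndarray, z: np.ndarray) -> float:
    """Log-linear slope estimate on the positive early part of z ≈ A·e^(−kt)."""
    ok = z > 0
    n = max(4, ok.sum() // 2)
    tt, zz = t[ok][:n], z[ok][:n]
    if len(tt) >= 2 and tt[-1] > tt[0]:
        slope = np.polyfit(tt, np.log(zz), 1)[0]
        if slope < 0:
            return -slope
    span = t[-1] - t[0]
    return 3.0 / span if span > 0 else 1.0


def fit_monoexp(
    t: np.ndarray,
    y: np.ndarray,
    model: str = "decay",
    init: dict | None = None,
    sigma: np.ndarray | None = None,
    fix_offset: float | None = None,
) -> ExpFit:
    """Nonlinear least-squares mono-exponential fit.

    ``model='decay'`` fits y = C + A·e^(−kt) (one-phase decay with
    plateau C); ``model='growth'`` fits y = C + A·(1 − e^(−kt)). Unless
    ``init`` overrides them, starting values are C = min(y), A = range(y)
    and k from a log-linear regression on the early baseline-subtracted
    data. Fits are unweighted unless per-point ``sigma`` is given;
    ``fix_offset`` pins C (e.g. 0 for survival fractions).

    A constant input, or an optimum with non-positive rate, returns an
    :class:`ExpFit` flagged ``degenerate`` instead of fabricating a rate;
    failure to converge raises :class:`FitConvergenceError`.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size != y.size or t.size < 4:
        raise ValueError("need >= 4 (t, y) points of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("t must be strictly increasing")
    if model not in ("decay", "growth"):
        raise ValueError(f"unknown model {model!r}")

    if np.ptp(y) == 0:
        return ExpFit(model, 0.0, math.nan, float(y[0]), math.nan, math.nan, True)

    c0 = float(y.min()) if fix_offset is None else float(fix_offset)
    a0 = float(np.ptp(y)) or 1.0
    z = (y - c0) if model == "decay" else (c0 + a0 - y)
    k0 = _initial_rate(t, z)
    defaults = {"amplitude": a0, "rate": k0, "offset": c0}
    if init:
        defaults.update(init)

    m = Model(_decay if model == "decay" else _growth)
    params = m.make_params(**defaults)
    params["rate"].set(min=0.0)
    if fix_offset is not None:
        params["offset"].set(value=fix_offset, vary=False)
    weights = None if sigma is None else 1.0 / np.asarray(sigma, dtype=float)
    result = m.fit(y, params, t=t, weights=weights, max_nfev=10_000)
    if not result.success:
        raise FitConvergenceError(result.message)

    rate = float(result.params["rate"].value)
    stderr = result.params["rate"].stderr
    ss_res = float(np.sum(result.residual**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return ExpFit(
        model=model,
        amplitude=float(result.params["amplitude"].value),
        rate=rate,
        offset=float(result.params["offset"].value),
        r_squared=1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan,
        se_rate=float(stderr) if stderr is not None else math.nan,
        degenerate=rate <= 0,
    )


def fit_survival(curve: SurvivalCurve, **kwargs) -> ExpFit:
    """Fit S(t) = e^(−kt) to a survival curve (offset pinned at 0)."""
    return fit_monoexp(curve.t, curve.survival, model="decay", fix_offset=0.0, **kwargs)


def fret_ratio_trace(
    donor: np.ndarray,
    acceptor: np.ndarray,
    baseline_frames: int | None = None,
) -> np.ndarray:
    """Pointwise acceptor/donor ratio, optionally baseline-normalized.

    Samples with zero donor signal are flagged as NaN rather than
    propagating infinities. With ``baseline_frames`` the trace is divided
    by its mean over those initial samples (pre-mix baseline), so a
    normalized trace starts at ~1.
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    if donor.shape != acceptor.shape:
        raise ValueError("donor and acceptor must have equal length")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(donor != 0, acceptor / donor, np.nan)
    if baseline_frames is not None:
        base = np.nanmean(ratio[:baseline_frames])
        if not np.isfinite(base) or base == 0:
            raise ValueError("baseline is empty or zero")
        ratio = ratio / base
    return ratio


def dwell_half_time_ratio(fit_in: ExpFit, fit_out: ExpFit) -> tuple[float, float]:
    """Ratio of half-times t½(in)/t½(out) with propagated standard error.

    Quantifies dwell-time prolongation inside a membrane region relative
    to outside (ratio > 1 means longer retention inside). Since
    t½ ∝ 1/k, the relative errors of the two rates add in quadrature.
    """
    for name, f in (("in", fit_in), ("out", fit_out)):
        if f.degenerate or not np.isfinite(f.rate) or f.rate <= 0:
            raise ValueError(f"degenerate fit for the '{name}' region")
    ratio = fit_in.t_half / fit_out.t_half
    rel = []
    for f in (fit_in, fit_out):
        rel.append((f.se_rate / f.rate) ** 2 if np.isfinite(f.se_rate) else 0.0)
    return ratio, ratio * math.sqrt(sum(rel))
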