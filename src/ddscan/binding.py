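"""1:1 (Langmuir) binding model: steady-state and kinetic fits.

Steady state follows the rectangular hyperbola

    R(c) = Rmax * c / (KD + c)

fitted by unweighted nonlinear least squares.  Kinetic traces follow the
1:1 association/dissociation exponentials

    R_assoc(t) = Req * (1 - exp(-(kon*c + koff) * t)),  Req = Rmax*c/(KD + c)
    R_dissoc(t) = R0 * exp(-koff * t)

fitted locally (per trace) and averaged, with KD reported as koff/kon.
Concentrations are molar internally; helpers accept micromolar ladders.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .core import BindingFit, KineticTrace, TitrationSet


def hyperbola(c, rmax, kd):
    return rmax * c / (kd + c)


class FitError(RuntimeError):
    pass


def _initial_guesses(conc: np.ndarray, resp: np.ndarray) -> Tuple[float, float]:
    """Rmax from the top response; KD from the interpolated half-max point."""
    rmax0 = float(resp.max())
    if rmax0 <= 0:
        raise FitError("all responses are zero or negative")
    half = rmax0 / 2
    order = np.argsort(conc)
    c_s, r_s = conc[order], resp[order]
    kd0 = float(c_s[np.argmin(np.abs(r_s - half))])
    above = np.nonzero(r_s >= half)[0]
    if len(above) and above[0] > 0:
        i = above[0]
        c1, c2 = c_s[i - 1], c_s[i]
        r1, r2 = r_s[i - 1], r_s[i]
        if r2 > r1:
            kd0 = float(c1 + (half - r1) * (c2 - c1) / (r2 - r1))
    return rmax0, max(kd0, c_s[0] * 1e-3)


class SteadyStateBindingModel(BaseEstimator, RegressorMixin):
    """Rectangular-hyperbola saturation fit (sklearn-style regressor).

    ``fit(X, y)`` takes concentrations (molar, shape (n,) or (n, 1)) and
    equilibrium responses.  Fitted attributes: ``Rmax_``, ``KD_``,
    ``se_Rmax_``, ``se_KD_`` (linearized covariance), ``rss_``.
    """

    def __init__(self, init: Optional[Tuple[float, float]] = None, maxfev: int = 10000):
        self.init = init
        self.maxfev = maxfev

    def fit(self, X, y) -> "SteadyStateBindingModel":
        conc = np.asarray(X, dtype=float).reshape(-1)
        resp = np.asarray(y, dtype=float).reshape(-1)
        if conc.shape != resp.shape:
            raise ValueError("X and y must have matching lengths")
        if len(np.unique(conc)) < 3:
            raise ValueError("need at least 3 distinct concentrations")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be positive")
        p0 = self.init if self.init is not None else _initial_guesses(conc, resp)
        try:
            popt, pcov = curve_fit(
                hyperbola,
                conc,
                resp,
                p0=p0,
                bounds=([0.0, 0.0], [np.inf, np.inf]),
                maxfev=self.maxfev,
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except RuntimeError as exc:
            raise FitError(f"steady-state fit did not converge: {exc}") from exc
        self.Rmax_, self.KD_ = float(popt[0]), float(popt[1])
        perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan, np.nan]
        self.se_Rmax_, self.se_KD_ = float(perr[0]), float(perr[1])
        self.rss_ = float(np.sum((hyperbola(conc, *popt) - resp) ** 2))
        return self

    def predict(self, X) -> np.ndarray:
        conc = np.asarray(X, dtype=float).reshape(-1)
        return hyperbola(conc, self.Rmax_, self.KD_)

    def to_binding_fit(self) -> BindingFit:
        return BindingFit(
            Rmax=self.Rmax_,
            KD=self.KD_,
            se_Rmax=self.se_Rmax_,
            se_KD=self.se_KD_,
            rss=self.rss_,
        )


def steady_state_fit(
    t: TitrationSet, init: Optional[Tuple[float, float]] = None
) -> BindingFit:
    """Fit the 1:1 steady-state model to a titration set."""
    model = SteadyStateBindingModel(init=init).fit(t.concentrations, t.responses)
    return model.to_binding_fit()


# ---------------------------------------------------------------------------
# kinetics


def association_curve(t, req, kobs):
    return req * (1.0 - np.exp(-kobs * t))


def dissociation_curve(t, r0, koff):
    return r0 * np.exp(-koff * t)


#: dissociation rates below this (1/s) are unresolvable within a typical
#: few-hundred-second dissociation window; the derived KD is then flagged
#: as a lower bound only
KOFF_FLOOR = 1e-6


class KineticBindingModel(BaseEstimator, RegressorMixin):
    """Local (per-trace) 1:1 kinetic fits, averaged across traces.

    Each trace's association phase yields (Req, kobs); kon is recovered as
    (kobs - koff) / c with koff from the dissociation phase.  Fitted
    attributes: ``kon_``, ``koff_``, ``KD_`` (= koff/kon), ``Rmax_``,
    ``kd_lower_bound_``, ``rss_``.
    """

    def __init__(self, maxfev: int = 10000):
        self.maxfev = maxfev

    def fit(self, X: Sequence[KineticTrace], y=None) -> "KineticBindingModel":
        traces = list(X)
        if not traces:
            raise ValueError("need at least one trace")
        kons: List[float] = []
        koffs: List[float] = []
        rmaxes: List[float] = []
        rss = 0.0
        for tr in traces:
            if len(tr.association) < 5 or len(tr.dissociation) < 5:
                raise ValueError("each phase needs at least 5 samples")
            ta = np.array([p[0] for p in tr.association])
            ra = np.array([p[1] for p in tr.association])
            td = np.array([p[0] for p in tr.dissociation])
            rd = np.array([p[1] for p in tr.dissociation])
            td = td - td[0]  # local time origin for the dissociation phase

            # dissociation first: R0 * exp(-koff t)
            r0_0 = max(rd[0], 1e-12)
            try:
                popt_d, _ = curve_fit(
                    dissociation_curve,
                    td,
                    rd,
                    p0=(r0_0, 0.01),
                    bounds=([0.0, 0.0], [np.inf, np.inf]),
                    maxfev=self.maxfev,
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                )
            except RuntimeError as exc:
                raise FitError(f"dissociation fit failed: {exc}") from exc
            koff = float(popt_d[1])

            req0 = max(ra[-1], 1e-12)
            kobs0 = 1.0 / max(ta[-1] / 5.0, 1e-9)
            try:
                popt_a, _ = curve_fit(
                    association_curve,
                    ta,
                    ra,
                    p0=(req0, kobs0),
                    bounds=([0.0, 0.0], [np.inf, np.inf]),
                    maxfev=self.maxfev,
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                )
            except RuntimeError as exc:
                raise FitError(f"association fit failed: {exc}") from exc
            req, kobs = float(popt_a[0]), float(popt_a[1])
            kon = max(kobs - koff, 0.0) / tr.concentration
            kons.append(kon)
            koffs.append(koff)
            if kon > 0:
                kd_tr = koff / kon
                rmaxes.append(req * (kd_tr + tr.concentration) / tr.concentration)
            rss += float(
                np.sum((association_curve(ta, *popt_a) - ra) ** 2)
                + np.sum((dissociation_curve(td, *popt_d) - rd) ** 2)
            )

        self.kon_ = float(np.mean(kons))
        self.koff_ = float(np.mean(koffs))
        self.kd_lower_bound_ = self.koff_ < KOFF_FLOOR
        if self.kd_lower_bound_ or self.kon_ <= 0:
            self.KD_ = 0.0 if self.kon_ > 0 else np.inf
        else:
            self.KD_ = self.koff_ / self.kon_
        self.Rmax_ = float(np.mean(rmaxes)) if rmaxes else np.nan
        self.rss_ = rss
        return self

    def to_binding_fit(self) -> BindingFit:
        return BindingFit(
            Rmax=self.Rmax_,
            KD=self.KD_,
            kon=self.kon_,
            koff=self.koff_,
            rss=self.rss_,
            kd_lower_bound=self.kd_lower_bound_,
        )


def kinetic_fit(traces: Iterable[KineticTrace]) -> BindingFit:
    """Local 1:1 kinetic fits over association + dissociation phases."""
    model = KineticBindingModel().fit(list(traces))
    return model.to_binding_fit()


# ---------------------------------------------------------------------------
# the concentration ladders used in the titration experiments (micromolar)

HOMODIMER_LADDER_UM: Tuple[float, ...] = (50.0, 16.7, 5.56, 1.85, 0.617, 0.2058)
#: three-fold dilution from 2.67 uM; the final step is 0.0329 uM (the
#: value completing the exact three-fold series).  Set
#: ``heterodimer_ladder_um(literal=True)`` for the 0.329 reading.
HETERODIMER_LADDER_UM: Tuple[float, ...] = (2.67, 0.889, 0.2963, 0.0988, 0.0329)


def heterodimer_ladder_um(literal: bool = False) -> Tuple[float, ...]:
    if literal:
        return (2.67, 0.889, 0.2963, 0.0988, 0.329)
    return HETERODIMER_LADDER_UM


def um(values: Iterable[float]) -> Tuple[float, ...]:
    """Convert micromolar values to molar."""
    return tuple(v * 1e-6 for v in values)
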