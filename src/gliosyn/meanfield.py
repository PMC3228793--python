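"""Steady-state theory of the TM synapse and of gliotransmitter modulation.

Frequency-response curve
------------------------
Averaging the TM dynamics over stationary drive at rate ``f_in`` gives the
utilization mean <u> = U0*f/(Omega_f + U0*f) (the u equation is linear, so
this is exact for Poisson drive), the post-increment utilization
u+ = <u> + U0*(1 - <u>), the resource mean <x> = Omega_d/(Omega_d + f*u+),
and the steady-state per-spike released resources

    RR_ss(f) = u+ * <x>
             = U0*Omega_d*(f + Omega_f) /
               (U0*f^2 + U0*(Omega_d + Omega_f)*f + Omega_d*Omega_f).

The only approximation is the moment closure <u x> ~ <u><x>; the
test suite checks it against long Poisson-driven simulations.

Switching threshold and limiting frequency
------------------------------------------
The low-frequency slope of RR_ss changes sign at

    U_thr = Omega_d / (Omega_d + Omega_f) = rho / (1 + rho),  rho = Omega_d/Omega_f,

so a synapse is facilitating iff U0 < U_thr.  For a facilitating synapse the
limiting frequency ``f_lim`` is the interior peak of RR_ss (closed-form root
of a quadratic).  For a depressing synapse the curve is monotone and f_lim
is defined operationally as the half-power cut-off: the frequency where
RR_ss falls to 1/sqrt(2) of its low-frequency plateau U0 (also a quadratic
root).  The cut-off rule is flagged in :class:`PlasticityRegime` metadata.

Gliotransmission steady state
-----------------------------
Under periodic GREs at rate ``f_C`` every astrocytic variable settles onto a
periodic orbit with exact closed forms (geometric fixed points of the
per-event maps), and the period-averaged bound-receptor fraction <Gamma>
yields the steady-state basal release probability

    <U0>(f_C) = U0* * (1 - <Gamma>) + alpha * <Gamma>,

monotone from U0* (f_C -> 0) toward alpha (f_C >> Omega_G, provided
receptor binding outruns unbinding, O_G*beta*Omega_A/Omega_c >> Omega_G).
Crossing of <U0> with U_thr defines the threshold GRE frequency ``f_thr``
at which the synapse switches plasticity mode, and the composed map
f_lim(<U0>(f_C)) is discontinuous there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .astrocyte import AstroParams
from .synapse import SynapseParams

__all__ = [
    "MeanfieldCurve",
    "PlasticityRegime",
    "rr_ss",
    "u_thr",
    "f_lim",
    "rr_slope",
    "u0_ss_of_fc",
    "gamma_mean_of_fc",
    "f_thr",
    "flim_vs_fc_map",
    "classify_regime",
    "CUTOFF_RULE",
]

#: Operational definition used for the depressing-branch limiting frequency.
CUTOFF_RULE = "half_power"


@dataclass(frozen=True)
class MeanfieldCurve:
    f_grid: np.ndarray
    rr_ss: np.ndarray
    rr_max: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"f_in_hz": self.f_grid, "rr_ss": self.rr_ss})


@dataclass(frozen=True)
class PlasticityRegime:
    u_thr: float
    f_lim: float
    label: str  # "depressing" | "facilitating"
    cutoff_rule: str = CUTOFF_RULE

    def to_dict(self) -> dict:
        return {"u_thr": self.u_thr, "f_lim": self.f_lim, "label": self.label,
                "cutoff_rule": self.cutoff_rule}


def _u0_arg(syn: SynapseParams, u0: float | None) -> float:
    u0 = syn.u0_star if u0 is None else u0
    if not 0.0 <= u0 <= 1.0:
        raise ValueError("u0 must lie in [0, 1]")
    return u0


def rr_ss(f_in, syn: SynapseParams, u0: float | None = None):
    """Steady-state per-spike released resources at drive rate ``f_in`` (Hz).

    Vectorized over ``f_in``; f_in -> 0 returns U0 (single-spike release from
    rest) and f_in -> inf decays to 0 (full depletion).
    """
    u0 = _u0_arg(syn, u0)
    f = np.asarray(f_in, dtype=float)
    if np.any(f < 0):
        raise ValueError("f_in must be non-negative")
    od, of = syn.omega_d, syn.omega_f
    num = u0 * od * (f + of)
    den = u0 * f**2 + u0 * (od + of) * f + od * of
    out = num / den
    return out if out.ndim else float(out)


def rr_slope(f_in, syn: SynapseParams, u0: float | None = None):
    """Analytic derivative d(RR_ss)/d f_in; sign > 0 marks facilitation."""
    u0 = _u0_arg(syn, u0)
    f = np.asarray(f_in, dtype=float)
    if np.any(f < 0):
        raise ValueError("f_in must be non-negative")
    od, of = syn.omega_d, syn.omega_f
    num = u0 * od * (f + of)
    dnum = u0 * od
    den = u0 * f**2 + u0 * (od + of) * f + od * of
    dden = 2 * u0 * f + u0 * (od + of)
    out = (dnum * den - num * dden) / den**2
    return out if out.ndim else float(out)


def u_thr(syn: SynapseParams) -> float:
    """Switching threshold: facilitating iff U0 < U_thr = Omega_d/(Omega_d+Omega_f)."""
    return syn.omega_d / (syn.omega_d + syn.omega_f)


def f_lim(syn: SynapseParams, u0: float | None = None) -> float:
    """Limiting frequency (Hz): RR_ss peak (facilitating) or half-power cut-off.

    At U0 = 0 facilitation has no finite peak and the result is ``inf``;
    at U0 exactly U_thr the peak branch degenerates to 0 and the synapse is
    classified depressing (cut-off branch applies).
    """
    u0 = _u0_arg(syn, u0)
    od, of = syn.omega_d, syn.omega_f
    if u0 < u_thr(syn):
        if u0 == 0.0:
            return math.inf
        # d(RR_ss)/df = 0  =>  u0*f^2 + 2*u0*of*f - of*(od - u0*(od+of)) = 0
        a, b = u0, 2.0 * u0 * of
        c = -of * (od - u0 * (od + of))
    else:
        # RR_ss(f) = u0/sqrt(2)
        r = math.sqrt(2.0)
        a = u0
        b = u0 * (od + of) - r * od
        c = od * of * (1.0 - r)
    return (-b + math.sqrt(b * b - 4.0 * a * c)) / (2.0 * a)


def classify_regime(syn: SynapseParams, u0: float | None = None) -> PlasticityRegime:
    """Regime report: threshold, limiting frequency and depressing/facilitating label."""
    u0 = _u0_arg(syn, u0)
    thr = u_thr(syn)
    label = "facilitating" if u0 < thr else "depressing"
    return PlasticityRegime(u_thr=thr, f_lim=f_lim(syn, u0), label=label)


def _periodic_gamma_stats(f_c: float, astro: AstroParams) -> tuple[float, float]:
    """(peak Gamma after a GRE, period-averaged Gamma) on the periodic orbit.

    Exact fixed points of the per-GRE maps under the impulse scheme:
    the pre-GRE pool x* = (1-e)/(1-(1-U_A)e) with e = exp(-Omega_A/f_C),
    the glutamate pulse dG = beta * x*, the Gamma jump survival factor
    eps = exp(-O_G*dG/Omega_c), and the saw-tooth average over one period.
    """
    if f_c < 0:
        raise ValueError("f_c must be non-negative")
    if f_c == 0.0:
        return 0.0, 0.0
    T = 1.0 / f_c
    ea = math.exp(-astro.omega_a * T)
    x_star = (1.0 - ea) / (1.0 - (1.0 - astro.u_a) * ea)
    dg = astro.beta * x_star
    eps = math.exp(-astro.o_g * dg / astro.omega_c)
    eg = math.exp(-astro.omega_g * T)
    gamma_peak = (1.0 - eps) / (1.0 - eps * eg)
    gamma_mean = gamma_peak * (1.0 - eg) / (astro.omega_g * T)
    return gamma_peak, gamma_mean


def gamma_mean_of_fc(f_c, astro: AstroParams):
    """Period-averaged bound-receptor fraction <Gamma> under periodic GREs."""
    f = np.asarray(f_c, dtype=float)
    out = np.array([_periodic_gamma_stats(v, astro)[1] for v in np.atleast_1d(f)])
    return out.reshape(f.shape) if f.ndim else float(out[0])


def u0_ss_of_fc(f_c, syn: SynapseParams, astro: AstroParams):
    """Steady-state basal release probability <U0> at GRE frequency ``f_c`` (Hz)."""
    g = gamma_mean_of_fc(f_c, astro)
    return syn.u0_star * (1.0 - np.asarray(g)) + astro.alpha * np.asarray(g) \
        if np.ndim(g) else syn.u0_star * (1.0 - g) + astro.alpha * g


def f_thr(syn: SynapseParams, astro: AstroParams,
          fc_bracket: tuple[float, float] = (1e-6, 1e3)) -> float | None:
    """GRE frequency at which <U0>(f_C) crosses the switching threshold U_thr.

    Returns None (an explicit no-transition result) when U_thr is not
    strictly between the two attainable ends of the <U0> curve.  The root is
    found by bisection on log f_C to relative tolerance ~1e-12 and satisfies
    u0_ss_of_fc(f_thr) = U_thr to well below 1e-10.
    """
    thr = u_thr(syn)
    lo, hi = fc_bracket
    u_lo = u0_ss_of_fc(lo, syn, astro)
    u_hi = u0_ss_of_fc(hi, syn, astro)
    if not (min(u_lo, u_hi) < thr < max(u_lo, u_hi)):
        return None

    def g(logf: float) -> float:
        return u0_ss_of_fc(10.0**logf, syn, astro) - thr

    logf = brentq(g, math.log10(lo), math.log10(hi), xtol=1e-14, rtol=1e-15)
    return 10.0**logf


def flim_vs_fc_map(syn: SynapseParams, astro: AstroParams, fc_grid) -> pd.DataFrame:
    """Compose f_lim over the gliotransmission steady state on a grid of f_C.

    Columns: f_c_hz, u0_ss, f_lim_hz, label.  The branch switch (and hence a
    jump of f_lim) occurs where u0_ss crosses U_thr, i.e. at f_thr.
    """
    fc = np.asarray(fc_grid, dtype=float)
    u0s = np.array([u0_ss_of_fc(v, syn, astro) for v in fc])
    regimes = [classify_regime(syn, u) for u in u0s]
    return pd.DataFrame(
        {
            "f_c_hz": fc,
            "u0_ss": u0s,
            "f_lim_hz": [r.f_lim for r in regimes],
            "label": [r.label for r in regimes],
        }
    )
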