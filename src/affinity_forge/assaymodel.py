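"""Observation model: differentiable links from ΔG to assay readouts.

Heterogeneous assays (pKd, pKi, pIC50, single-concentration percent
displacement) can be modeled jointly by letting a model predict one
latent thermodynamic quantity — the binding free energy ΔG, kcal/mol —
and mapping it deterministically onto each measurement's own scale:

* equilibrium dissociation:  Kd = c0 · exp(ΔG / RT)  with c0 = 1 M the
  standard-state concentration, so  pKd = −ΔG / (RT ln 10);
* percent displacement at probe concentration L (single-site occupancy,
  the standard competitive-binding approximation):
  D = 100 · L / (L + Kd);
* pKi and pIC50 reuse the pKd link.  The exact correction (Cheng–Prusoff)
  needs substrate concentration and Km, which bioactivity tables do not
  report; an additive per-assay offset hook is exposed for users who have
  them.

Every link returns its value together with the analytic derivative
d(value)/d(ΔG), so a squared-error loss on the observation scale can be
backpropagated through the link by any training framework without
symbolic differentiation.  All links are strictly monotone decreasing in
ΔG (stronger binding ⇒ higher p-value / displacement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy.optimize import minimize_scalar

from .core import AssayConditions, Measurement, P_SCALE_TYPES, PERCENT_DISPLACEMENT

#: Gas constant in kcal·mol⁻¹·K⁻¹ (CODATA, converted).
GAS_CONSTANT_KCAL = 1.987204259e-3

LN10 = math.log(10.0)


@dataclass(frozen=True)
class ThermoContext:
    """Constants and covariates parameterizing the link functions."""

    temperature: float = 298.15
    probe_concentration: Optional[float] = None
    reference_concentration: float = 1.0
    R: float = GAS_CONSTANT_KCAL

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.probe_concentration is not None and self.probe_concentration <= 0:
            raise ValueError(
                f"probe_concentration must be positive, got {self.probe_concentration}"
            )

    @classmethod
    def from_conditions(cls, conditions: AssayConditions) -> "ThermoContext":
        return cls(
            temperature=conditions.temperature,
            probe_concentration=conditions.probe_concentration,
        )

    @property
    def RT(self) -> float:
        return self.R * self.temperature


def pkd_from_dg(dG: float, ctx: ThermoContext = ThermoContext()) -> float:
    """pKd = −log10(Kd / 1 M) with Kd = c0 · exp(ΔG / RT).

    Strictly decreasing in ΔG; ΔG = 0 gives Kd = 1 M, pKd = 0.
    """
    return -(dG / (ctx.RT * LN10)) - math.log10(ctx.reference_concentration)


def dg_from_pkd(pKd: float, ctx: ThermoContext = ThermoContext()) -> float:
    """Exact inverse of :func:`pkd_from_dg`: ΔG = −pKd · RT · ln 10."""
    return -(pKd + math.log10(ctx.reference_concentration)) * ctx.RT * LN10


def kd_from_dg(dG: float, ctx: ThermoContext = ThermoContext()) -> float:
    """Dissociation constant in molar."""
    return ctx.reference_concentration * math.exp(dG / ctx.RT)


def displacement_from_dg(dG: float, ctx: ThermoContext) -> float:
    """Percent probe displacement, 100 · L / (L + Kd), L the probe conc.

    Requires ``ctx.probe_concentration``; there is no sensible default
    because panels run at assay-specific probe concentrations.  Strictly
    decreasing in ΔG; equals 50 exactly when L = Kd.
    """
    if ctx.probe_concentration is None:
        raise ValueError("displacement link requires a probe concentration")
    L = ctx.probe_concentration
    return 100.0 * L / (L + kd_from_dg(dG, ctx))


def predict_observable(
    dG: float, mtype: str, ctx: ThermoContext
) -> tuple[float, float]:
    """Value on the measurement's own scale plus d(value)/d(ΔG).

    pKi and pIC50 dispatch to the pKd link (see module docstring).
    """
    if mtype in P_SCALE_TYPES:
        value = pkd_from_dg(dG, ctx)
        deriv = -1.0 / (ctx.RT * LN10)
        return value, deriv
    if mtype == PERCENT_DISPLACEMENT:
        if ctx.probe_concentration is None:
            raise ValueError("displacement link requires a probe concentration")
        L = ctx.probe_concentration
        Kd = kd_from_dg(dG, ctx)
        value = 100.0 * L / (L + Kd)
        # dKd/ddG = Kd / RT  ⇒  dD/ddG = −100 L Kd / ((L + Kd)^2 RT)
        deriv = -100.0 * L * Kd / ((L + Kd) ** 2 * ctx.RT)
        return value, deriv
    raise ValueError(f"unknown measurement type {mtype!r}")


def observation_loss(
    dG_pred: float,
    measurement: Measurement,
    ctx: Optional[ThermoContext] = None,
) -> tuple[float, float]:
    """Squared error on the observation scale, averaged over replicates.

    Returns ``(loss, dloss/ddG)`` via the chain rule through the link.
    ``ctx`` defaults to the measurement's own assay conditions.
    """
    if ctx is None:
        ctx = ThermoContext.from_conditions(measurement.conditions)
    pred, dpred = predict_observable(dG_pred, measurement.mtype, ctx)
    residuals = [pred - y for y in measurement.values]
    n = len(residuals)
    loss = sum(r * r for r in residuals) / n
    grad = 2.0 * sum(residuals) / n * dpred
    return loss, grad


def total_loss(
    dG_pred: float, measurements: Sequence[Measurement]
) -> tuple[float, float]:
    """Summed observation loss (and gradient) over a system's measurements."""
    loss = grad = 0.0
    for m in measurements:
        l, g = observation_loss(dG_pred, m)
        loss += l
        grad += g
    return loss, grad


def fit_free_energy(
    measurements: Sequence[Measurement],
    bounds: tuple[float, float] = (-25.0, 5.0),
) -> float:
    """Recover the latent ΔG minimizing the summed observation loss.

    Bounded scalar minimization; with only near-saturated percent
    readouts the optimum may sit at the lower bound, reflecting that such
    observations carry no information beyond "binds tighter than the
    probe can resolve".
    """
    if not measurements:
        raise ValueError("at least one measurement is required")
    res = minimize_scalar(
        lambda dg: total_loss(dg, measurements)[0],
        bounds=bounds,
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)
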