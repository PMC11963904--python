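"""Siggaard-Andersen model of the oxygen dissociation curve (ODC).

The ODC relates the partial pressure of oxygen in blood to the fraction of
haemoglobin saturated with oxygen.  In Hill coordinates ``x = ln(p/p0)``,
``y = ln(s/(1-s))`` the curve is a straight line plus a tanh term,

    y - y0 = (x - x0) + h * tanh(k0 * (x - x0)),

whose position is displaced from a reference curve by ``x0 = a + b`` and
whose amplitude is ``h = h0 + a``.  The displacement ``a`` at 37 degC is a
sum of contributions from pH, PCO2, methaemoglobin, 2,3-DPG and foetal
haemoglobin; ``b`` carries the temperature shift.  The model operates on the
*combined* saturation/pressure of oxygen and carbon monoxide, obtained from
measured pO2/SO2 and the dyshaemoglobin fractions.

All saturations are fractions in (0, 1); pressures are kPa; temperatures degC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "SAConstants",
    "CONSTANTS",
    "BloodGasRecord",
    "DisplacementTerms",
    "HillPoint",
    "combined_partial_pressure",
    "combined_saturation",
    "saturation_to_so2",
    "displacement_ac",
    "odc_forward",
    "odc_forward_da",
    "sa_predict",
    "odc_curve",
]


@dataclass(frozen=True)
class SAConstants:
    """Fixed constants of the dissociation-curve model.

    ``y0`` is derived from ``s0`` rather than stored, so the reference
    saturation has a single source of truth.
    """

    k0: float = 0.5343        # tanh slope constant
    s0: float = 0.867         # reference combined saturation at p0
    p0: float = 7.0           # reference combined pressure, kPa
    h0: float = 3.5           # reference Hill amplitude
    pH_ref: float = 7.40
    PCO2_ref: float = 5.33    # kPa
    cDPG_ref: float = 5.0     # mmol/L
    T_ref: float = 37.0       # degC

    @property
    def y0(self) -> float:
        return float(np.log(self.s0 / (1.0 - self.s0)))


#: Module-level constants instance used by every operation below.
CONSTANTS = SAConstants()


@dataclass
class BloodGasRecord:
    """One patient blood-gas measurement.

    pO2/PCO2 in kPa, T in degC, SO2 and the haemoglobin-variant fractions
    (carboxy-, met-, foetal) as fractions.  cDPG in mmol/L, defaulting to the
    reference concentration since it is rarely measured clinically.
    """

    pH: float
    PCO2: float
    T: float
    pO2: float
    SO2: float
    FCOHb: float = 0.0
    FMetHb: float = 0.0
    FHbF: float = 0.0
    cDPG: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 < self.SO2 < 1.0:
            raise ValueError(f"SO2 must be in (0, 1), got {self.SO2}")
        if self.pO2 <= 0:
            raise ValueError(f"pO2 must be positive, got {self.pO2}")
        if self.PCO2 <= 0:
            raise ValueError(f"PCO2 must be positive, got {self.PCO2}")
        if self.FCOHb + self.FMetHb >= 1.0:
            raise ValueError(
                f"FCOHb + FMetHb must be < 1, got {self.FCOHb + self.FMetHb}"
            )
        for name in ("FCOHb", "FMetHb", "FHbF"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {v}")


@dataclass(frozen=True)
class HillPoint:
    """Combined (pressure, saturation) pair with Hill-coordinate views."""

    p: float
    s: float

    def __post_init__(self) -> None:
        if self.p <= 0:
            raise ValueError(f"combined pressure must be positive, got {self.p}")
        if not 0.0 < self.s < 1.0:
            raise ValueError(f"combined saturation must be in (0, 1), got {self.s}")

    @property
    def x(self) -> float:
        return float(np.log(self.p / CONSTANTS.p0))

    @property
    def y(self) -> float:
        return float(np.log(self.s / (1.0 - self.s)))


@dataclass(frozen=True)
class DisplacementTerms:
    """Decomposition of the ODC displacement at 37 degC.

    ``a1`` pH, ``a2`` PCO2, ``a3`` methaemoglobin, ``a4`` 2,3-DPG (or an
    override standing in for "unknown knowns"), ``a5`` foetal haemoglobin.
    ``a6`` is the unknown-knowns displacement, fixed to zero here; the
    combined effect is ``a = ac + a6`` with ``ac = a1 + ... + a5``.
    ``b`` is the temperature displacement, ``x0 = a + b`` the horizontal
    shift and ``h = h0 + a`` the Hill amplitude.
    """

    a1: float
    a2: float
    a3: float
    a4: float
    a5: float
    a6: float = 0.0
    T: float = 37.0

    @property
    def ac(self) -> float:
        return self.a1 + self.a2 + self.a3 + self.a4 + self.a5

    @property
    def a(self) -> float:
        return self.ac + self.a6

    @property
    def b(self) -> float:
        return 0.055 * (self.T - CONSTANTS.T_ref)

    @property
    def x0(self) -> float:
        return self.a + self.b

    @property
    def h(self) -> float:
        return CONSTANTS.h0 + self.a


def _as_array(x):
    return np.asarray(x, dtype=float)


def combined_partial_pressure(record: BloodGasRecord) -> float:
    """Combined O2 + CO partial pressure, kPa.

    ``p = pO2 + (pO2 / SO2) * FCOHb / (1 - FCOHb - FMetHb)``; reduces to the
    measured pO2 when no carboxyhaemoglobin is present.
    """
    if record.SO2 == 0:
        raise ValueError("SO2 must be nonzero to form the combined pressure")
    denom = 1.0 - record.FCOHb - record.FMetHb
    if denom <= 0:
        raise ValueError("FCOHb + FMetHb must be < 1")
    return record.pO2 + (record.pO2 / record.SO2) * record.FCOHb / denom


def combined_saturation(record: BloodGasRecord) -> float:
    """Combined O2 + CO saturation fraction.

    ``s = (SO2 * (1 - FCOHb - FMetHb) + FCOHb) / (1 - FMetHb)``.
    """
    if record.FMetHb >= 1:
        raise ValueError("FMetHb must be < 1")
    return (record.SO2 * (1.0 - record.FCOHb - record.FMetHb) + record.FCOHb) / (
        1.0 - record.FMetHb
    )


def saturation_to_so2(s, FCOHb=0.0, FMetHb=0.0):
    """Invert the combined saturation back to the oxygen saturation SO2.

    Vectorized over ``s``.  Needed when reporting predictions on the clinical
    SO2 scale.
    """
    s = _as_array(s)
    denom = 1.0 - FCOHb - FMetHb
    if np.any(_as_array(denom) <= 0):
        raise ValueError("1 - FCOHb - FMetHb must be positive")
    out = (s * (1.0 - FMetHb) - FCOHb) / denom
    return float(out) if out.ndim == 0 else out


def displacement_ac(
    pH,
    PCO2,
    FMetHb=0.0,
    FHbF=0.0,
    cDPG=5.0,
    a4_override=None,
    T=37.0,
) -> DisplacementTerms:
    """Displacement terms of the ODC at 37 degC.

    ``a4_override``, when given, replaces the 2,3-DPG formula; this is the
    hook through which the grey-box network, a learned symbolic expression,
    or the synthetic ground truth supply the unknown-knowns displacement.
    Scalar inputs only; see :func:`sa_predict` for the vectorized path.
    """
    if PCO2 <= 0:
        raise ValueError(f"PCO2 must be positive, got {PCO2}")
    a1 = -0.88 * (pH - CONSTANTS.pH_ref)
    a2 = 0.048 * float(np.log(PCO2 / CONSTANTS.PCO2_ref))
    a3 = -0.7 * FMetHb
    if a4_override is not None:
        a4 = float(a4_override)
    else:
        a4 = (0.3 - 0.1 * FHbF) * (cDPG / CONSTANTS.cDPG_ref - 1.0)
    a5 = -0.25 * FHbF
    return DisplacementTerms(a1=a1, a2=a2, a3=a3, a4=a4, a5=a5, a6=0.0, T=T)


def odc_forward(p, a, T=37.0):
    """Combined saturation ``s`` at combined pressure ``p`` given shift ``a``.

    Vectorized over any broadcastable combination of ``p``, ``a``, ``T``.
    """
    p = _as_array(p)
    if np.any(p <= 0):
        raise ValueError("combined pressure p must be positive")
    a = _as_array(a)
    T = _as_array(T)
    c = CONSTANTS
    x = np.log(p / c.p0)
    b = 0.055 * (T - c.T_ref)
    x0 = a + b
    h = c.h0 + a
    u = x - x0
    y = c.y0 + u + h * np.tanh(c.k0 * u)
    s = 1.0 / (1.0 + np.exp(-y))
    return float(s) if s.ndim == 0 else s


def odc_forward_da(p, a, T=37.0):
    """Derivative ds/da of :func:`odc_forward` at fixed ``p`` and ``T``.

    Used to propagate training gradients through the mechanistic model when
    the displacement is produced by a trainable component.
    """
    p = _as_array(p)
    a = _as_array(a)
    T = _as_array(T)
    c = CONSTANTS
    x = np.log(p / c.p0)
    u = x - (a + 0.055 * (T - c.T_ref))
    h = c.h0 + a
    th = np.tanh(c.k0 * u)
    y = c.y0 + u + h * th
    s = 1.0 / (1.0 + np.exp(-y))
    # dy/da: du/da = -1, dh/da = 1, d tanh/da = -k0 sech^2
    dy_da = -1.0 + th - h * c.k0 * (1.0 - th**2)
    out = s * (1.0 - s) * dy_da
    return float(out) if out.ndim == 0 else out


def sa_predict(
    pH,
    PCO2,
    FMetHb,
    T,
    p,
    FHbF=0.0,
    cDPG=5.0,
    a4_override=None,
):
    """Predicted combined saturation for the given inputs.

    Vectorized composition of :func:`displacement_ac` and
    :func:`odc_forward`.  ``a4_override`` may be a scalar or an array
    broadcastable against the inputs.
    """
    pH = _as_array(pH)
    PCO2 = _as_array(PCO2)
    if np.any(PCO2 <= 0):
        raise ValueError("PCO2 must be positive")
    FMetHb = _as_array(FMetHb)
    a1 = -0.88 * (pH - CONSTANTS.pH_ref)
    a2 = 0.048 * np.log(PCO2 / CONSTANTS.PCO2_ref)
    a3 = -0.7 * FMetHb
    if a4_override is not None:
        a4 = _as_array(a4_override)
    else:
        a4 = (0.3 - 0.1 * _as_array(FHbF)) * (_as_array(cDPG) / CONSTANTS.cDPG_ref - 1.0)
    a5 = -0.25 * _as_array(FHbF)
    a = a1 + a2 + a3 + a4 + a5
    return odc_forward(p, a, T)


def sa_predict_matrix(X: np.ndarray, a4_override=None) -> np.ndarray:
    """:func:`sa_predict` on an (n, 5) input matrix [pH, PCO2, FMetHb, T, p].

    The five-column layout is the shared input convention of the discrepancy
    models.  ``a4_override`` defaults to 0 when ``None`` is passed here, since
    the matrix path carries no cDPG column.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 5:
        raise ValueError(f"expected an (n, 5) matrix, got shape {X.shape}")
    a4 = 0.0 if a4_override is None else a4_override
    return sa_predict(
        pH=X[:, 0], PCO2=X[:, 1], FMetHb=X[:, 2], T=X[:, 3], p=X[:, 4],
        a4_override=a4,
    )


def odc_curve(
    pH: float,
    PCO2: float,
    FMetHb: float,
    T: float,
    p_grid: Sequence[float],
    a4_provider: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    FHbF: float = 0.0,
    FCOHb: float = 0.0,
) -> np.ndarray:
    """Sweep the ODC over ``p_grid`` with the other inputs fixed.

    ``a4_provider`` maps an (n, 5) input matrix to displacement values; when
    omitted the curve uses a4 = 0.  Returns an (n, 3) array of columns
    (p, s, SO2), the last obtained by inverting the combined-saturation
    transform with the record's dyshaemoglobin fractions.
    """
    p_grid = np.asarray(p_grid, dtype=float)
    if p_grid.size == 0:
        raise ValueError("p_grid must be non-empty")
    if np.any(p_grid <= 0) or np.any(np.diff(p_grid) <= 0):
        raise ValueError("p_grid must be positive and strictly increasing")
    X = np.column_stack(
        [
            np.full_like(p_grid, pH),
            np.full_like(p_grid, PCO2),
            np.full_like(p_grid, FMetHb),
            np.full_like(p_grid, T),
            p_grid,
        ]
    )
    a4 = np.zeros_like(p_grid) if a4_provider is None else np.asarray(a4_provider(X), dtype=float)
    s = sa_predict(pH, PCO2, FMetHb, T, p_grid, FHbF=FHbF, a4_override=a4)
    so2 = saturation_to_so2(s, FCOHb, FMetHb)
    return np.column_stack([p_grid, s, so2])
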