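"""Hydraulic resistance of laminar microchannels and flow-divider arithmetic.

The divider solves the parallel-branch problem exactly: equal pressure drop
across the outlets makes each outlet flow proportional to the inverse of
its resistance, so only resistance *ratios* matter for the split.

Worked examples reproduced by `divider_flows`:
  - inlet 3.0 ml/min, two outlets with inner:outer resistance ratio 2.0
    -> inner outlet 1.0 ml/min;
  - inlet 1000 ul/min, trifurcation with central:side ratio 1.10
    -> central outlet 312.5 ul/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class ChannelGeometry:
    """Straight channel of rectangular or trapezoidal cross-section."""

    width_um: float
    height_um: float
    length_mm: float
    shape: str = "rectangular"
    inner_height_um: float | None = None  # trapezoidal only
    outer_height_um: float | None = None
    viscosity_Pa_s: float = 1.0e-3

    def __post_init__(self) -> None:
        if self.shape not in ("rectangular", "trapezoidal"):
            raise ValueError("shape must be 'rectangular' or 'trapezoidal'")
        dims = [self.width_um, self.height_um, self.length_mm, self.viscosity_Pa_s]
        if self.shape == "trapezoidal":
            if self.inner_height_um is None or self.outer_height_um is None:
                raise ValueError("trapezoidal geometry needs inner/outer heights")
            dims += [self.inner_height_um, self.outer_height_um]
        if any(d <= 0 for d in dims):
            raise ValueError("all dimensions must be > 0")


def _rect_resistance(width: float, height: float, length: float,
                     mu: float, n_terms: int) -> float:
    # Series solution for fully developed laminar flow in a rectangular
    # duct; h must be the smaller side for fast convergence.
    h, w = (height, width) if height <= width else (width, height)
    series = sum(
        math.tanh(n * math.pi * w / (2.0 * h)) / n**5
        for n in range(1, 2 * n_terms, 2)
    )
    factor = 1.0 - (192.0 * h) / (math.pi**5 * w) * series
    return 12.0 * mu * length / (w * h**3 * factor)


def channel_resistance(geometry: ChannelGeometry, n_terms: int = 20) -> float:
    """Hydraulic resistance in Pa*s/m^3.

    Rectangular: standard infinite-series solution (n_terms odd terms).
    Trapezoidal: rectangular equivalent at the mean of the inner and outer
    heights (documented correction hook; the trapezoid's separation physics
    is out of scope here).
    """
    mu = geometry.viscosity_Pa_s
    w = geometry.width_um * 1e-6
    length = geometry.length_mm * 1e-3
    if geometry.shape == "trapezoidal":
        h = 0.5 * (geometry.inner_height_um + geometry.outer_height_um) * 1e-6
    else:
        h = geometry.height_um * 1e-6
    return _rect_resistance(w, h, length, mu, n_terms)


@dataclass(frozen=True)
class FlowDivider:
    """An inlet split over >= 2 parallel outlets with known resistances.

    ``outlet_resistances`` may be absolute (Pa*s/m^3) or relative — only
    ratios matter.
    """

    inlet_flow_ul_min: float
    outlet_resistances: tuple

    def __post_init__(self) -> None:
        res = tuple(float(r) for r in self.outlet_resistances)
        if len(res) < 2:
            raise ValueError("need at least 2 outlets")
        if any(r <= 0 for r in res):
            raise ValueError("outlet resistances must be > 0")
        if self.inlet_flow_ul_min <= 0:
            raise ValueError("inlet flow must be > 0")
        object.__setattr__(self, "outlet_resistances", res)


def divider_flows(divider: FlowDivider) -> np.ndarray:
    """Outlet flows (ul/min), proportional to inverse resistance.

    Conservation is exact: the flows sum to the inlet flow.
    """
    inv = 1.0 / np.asarray(divider.outlet_resistances, dtype=float)
    flows = divider.inlet_flow_ul_min * inv / inv.sum()
    # absorb rounding so conservation holds to machine precision
    flows[-1] = divider.inlet_flow_ul_min - flows[:-1].sum()
    return flows


def bifurcation_flows(inlet_ul_min: float, inner_to_outer_ratio: float) -> dict:
    """Two-outlet split by the inner:outer resistance ratio (FR ratio 1)."""
    d = FlowDivider(inlet_ul_min, (inner_to_outer_ratio, 1.0))
    inner, outer = divider_flows(d)
    return {"inner_ul_min": float(inner), "outer_ul_min": float(outer)}


def trifurcation_flows(inlet_ul_min: float, central_to_side_ratio: float) -> dict:
    """Central + two side outlets split by the central:side ratio (FR ratio 2)."""
    d = FlowDivider(inlet_ul_min, (central_to_side_ratio, 1.0, 1.0))
    central, side1, side2 = divider_flows(d)
    return {
        "central_ul_min": float(central),
        "side_ul_min": float(side1),
        "side2_ul_min": float(side2),
    }


def throughput_cells_per_s(concentration_per_ml: float, flow_ml_min: float) -> float:
    """Cell throughput identity: concentration x inlet flow."""
    if concentration_per_ml < 0 or flow_ml_min < 0:
        raise ValueError("inputs must be >= 0")
    return concentration_per_ml * flow_ml_min / 60.0
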