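"""Viability gating: discriminate FDA-positive spores from background.

Metabolically active (viable) spores convert the ester stain FDA into
fluorescein and light up in the yellow/green channel; dead spores take up
PI (red) instead, and complex-medium debris is small and dim.  Two 2-D
gates in log10 feature space separate the FDA-positive population:

* a fluorescence gate on (``fly_max``, ``flo_max``) — green fluorescent
  vs. non- or red-fluorescent particles;
* a scatter gate on (``fws_total``, ``sws_total``) — excludes green
  particles smaller than spores.

Only particles inside *both* gates count as FDA-positive; particles in
one gate but not the other are not counted.  Gate coordinates are always
data: they come from calibration against control measurements (spores in
filtrated medium, heat-killed spores, medium without spores), never from
code constants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Union

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from .pulse_model import SampleBatch

__all__ = [
    "CalibrationError",
    "Gate",
    "GateCalibration",
    "GateSet",
    "calibrate_gates",
    "concentration",
    "default_gateset",
    "fda_positive",
    "gate_table",
    "in_gate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Gate:
    """A convex polygon gate in log10 feature space.

    ``vertices`` are (log10 x, log10 y) pairs; rectangles are represented
    as 4-vertex polygons so one containment routine serves both.
    Boundary points are inside.
    """

    x_channel: str
    y_channel: str
    vertices: tuple[tuple[float, float], ...]
    label: str = ""

    def __post_init__(self):
        if self.x_channel == self.y_channel:
            raise ValueError("gate channels must be distinct")
        if len(self.vertices) < 3:
            raise ValueError("a gate polygon needs >= 3 vertices")
        poly = Polygon(self.vertices)
        if poly.area <= 0:
            raise ValueError("gate polygon is degenerate")
        hull = poly.convex_hull
        if not math.isclose(poly.area, hull.area, rel_tol=1e-9):
            raise ValueError("gate polygon must be convex")
        object.__setattr__(self, "_polygon", poly)

    @property
    def polygon(self) -> Polygon:
        return self._polygon

    def dilated(self, margin: float) -> "Gate":
        """Gate expanded outward by ``margin`` decades (square buffer)."""
        buffered = self._polygon.buffer(margin, join_style="mitre")
        hull = buffered.convex_hull
        return replace(self, vertices=tuple(hull.exterior.coords[:-1]))

    def to_dict(self) -> dict:
        return {
            "x_channel": self.x_channel,
            "y_channel": self.y_channel,
            "vertices": [list(v) for v in self.vertices],
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Gate":
        return cls(
            x_channel=d["x_channel"],
            y_channel=d["y_channel"],
            vertices=tuple((float(x), float(y)) for x, y in d["vertices"]),
            label=d.get("label", ""),
        )


@dataclass(frozen=True)
class GateSet:
    """The two-gate FDA-positive discriminator."""

    fluorescence_gate: Gate
    scatter_gate: Gate

    def __post_init__(self):
        expected = {
            "fluorescence": ("fly_max", "flo_max"),
            "scatter": ("fws_total", "sws_total"),
        }
        for gate, (x, y) in (
            (self.fluorescence_gate, expected["fluorescence"]),
            (self.scatter_gate, expected["scatter"]),
        ):
            if (gate.x_channel, gate.y_channel) != (x, y):
                raise ValueError(
                    f"gate on ({gate.x_channel}, {gate.y_channel}) "
                    f"does not match expected channels {(x, y)}"
                )

    def to_dict(self) -> dict:
        return {
            "fluorescence_gate": self.fluorescence_gate.to_dict(),
            "scatter_gate": self.scatter_gate.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GateSet":
        return cls(
            fluorescence_gate=Gate.from_dict(d["fluorescence_gate"]),
            scatter_gate=Gate.from_dict(d["scatter_gate"]),
        )


def in_gate(features, gate: Gate) -> bool:
    """Point-in-convex-polygon test in log10 space, inclusive boundary.

    ``features`` is any mapping (or object with attributes) holding the
    gate's two channels.  Non-positive values cannot be log-transformed
    and are treated as outside, with a debug log entry.
    """
    x = _get(features, gate.x_channel)
    y = _get(features, gate.y_channel)
    if x <= 0 or y <= 0:
        logger.debug(
            "non-positive feature (%s=%g, %s=%g) treated as outside gate %s",
            gate.x_channel, x, gate.y_channel, y, gate.label,
        )
        return False
    point = Point(math.log10(x), math.log10(y))
    return bool(gate.polygon.covers(point))


def _get(features, name: str) -> float:
    if isinstance(features, Mapping):
        return float(features[name])
    if isinstance(features, pd.Series):
        return float(features[name])
    return float(getattr(features, name))


def fda_positive(features, gateset: GateSet) -> bool:
    """True iff the particle sits inside both the fluorescence and the
    scatter gate."""
    return in_gate(features, gateset.fluorescence_gate) and in_gate(
        features, gateset.scatter_gate
    )


def gate_table(table: pd.DataFrame, gateset: GateSet) -> pd.Series:
    """Vectorised :func:`fda_positive` over a feature table; returns a
    boolean Series aligned with the table index."""
    flags = [fda_positive(row, gateset) for _, row in table.iterrows()]
    return pd.Series(flags, index=table.index, name="fda_positive")


class CalibrationError(RuntimeError):
    """Controls do not admit a gate with acceptable capture/contamination.

    Carries the rates achieved at the minimal gate."""

    def __init__(self, message, capture=None, contamination=None):
        self.capture = capture
        self.contamination = contamination
        super().__init__(message)


@dataclass
class GateCalibration:
    """Calibration outcome: the gates plus achieved rates."""

    gateset: GateSet
    capture: float
    contamination: float
    n_viable: int
    n_background: int


def _quantile_box(xs, ys, alpha):
    x_lo, x_hi = np.quantile(xs, [alpha, 1 - alpha])
    y_lo, y_hi = np.quantile(ys, [alpha, 1 - alpha])
    return x_lo, x_hi, y_lo, y_hi


def _box_gate(channels, box, label):
    x_lo, x_hi, y_lo, y_hi = box
    return Gate(
        x_channel=channels[0],
        y_channel=channels[1],
        vertices=((x_lo, y_lo), (x_hi, y_lo), (x_hi, y_hi), (x_lo, y_hi)),
        label=label,
    )


def _log_columns(table: pd.DataFrame, channels) -> tuple[np.ndarray, np.ndarray]:
    x = table[channels[0]].to_numpy(dtype=float)
    y = table[channels[1]].to_numpy(dtype=float)
    ok = (x > 0) & (y > 0)
    return np.log10(x, where=ok, out=np.full_like(x, -np.inf)), np.log10(
        y, where=ok, out=np.full_like(y, -np.inf)
    )


FLUOR_CHANNELS = ("fly_max", "flo_max")
SCATTER_CHANNELS = ("fws_total", "sws_total")


def calibrate_gates(
    viable_control: Union[SampleBatch, pd.DataFrame],
    dead_control: Union[SampleBatch, pd.DataFrame],
    blank_control: Union[SampleBatch, pd.DataFrame],
    target_capture: float = 0.99,
    max_contamination: float = 0.01,
    fail_contamination: float = 0.05,
) -> GateCalibration:
    """Set rectangular gates from control measurements.

    The controls mirror the wet-lab procedure: viable spores cultivated in
    filtrated medium, killed (e.g. microwave-treated) spores, and complex
    medium without spores.  Gate bounds start at symmetric quantiles of the
    viable control and are then dilated outward — upper bounds first, then
    lower bounds — only while joint contamination from the dead and blank
    controls stays at or below ``max_contamination``.  Upper bounds are
    expanded generously because the viable population grows larger and
    brighter over process time (swelling, germination, hyphae) while the
    background sits below the spores in both fluorescence and scatter;
    lower bounds stay close to the control quantiles since they carry the
    discrimination.  Calibration fails when even the minimal gate admits
    more than ``fail_contamination`` background.

    Accepts SampleBatches (features are extracted) or ready feature tables.
    """
    from .features import extract_feature_table

    tables = []
    for name, control in (
        ("viable", viable_control),
        ("dead", dead_control),
        ("blank", blank_control),
    ):
        if isinstance(control, pd.DataFrame):
            table = control
        else:
            table, _ = extract_feature_table(control)
        if len(table) == 0:
            raise CalibrationError(f"{name} control is empty")
        tables.append(table)
    viable, dead, blank = tables
    background = pd.concat([dead, blank], ignore_index=True)

    v_fluor = _log_columns(viable, FLUOR_CHANNELS)
    v_scatter = _log_columns(viable, SCATTER_CHANNELS)
    b_fluor = _log_columns(background, FLUOR_CHANNELS)
    b_scatter = _log_columns(background, SCATTER_CHANNELS)

    def rates(m_hi: float, m_lo: float) -> tuple[float, float, GateSet]:
        alpha = (1 - target_capture) / 2
        fbox = np.array(_quantile_box(*v_fluor, alpha))
        sbox = np.array(_quantile_box(*v_scatter, alpha))
        shift = np.array([-m_lo, m_hi, -m_lo, m_hi])
        fbox = fbox + shift
        sbox = sbox + shift

        def inside(pts, box):
            x, y = pts
            return (x >= box[0]) & (x <= box[1]) & (y >= box[2]) & (y <= box[3])

        cap = float(
            np.mean(inside(v_fluor, fbox) & inside(v_scatter, sbox))
        )
        cont = float(
            np.mean(inside(b_fluor, fbox) & inside(b_scatter, sbox))
        )
        gateset = GateSet(
            fluorescence_gate=_box_gate(FLUOR_CHANNELS, fbox, "FDA-positive fluorescence"),
            scatter_gate=_box_gate(SCATTER_CHANNELS, sbox, "spore-sized scatter"),
        )
        return cap, cont, gateset

    cap0, cont0, gates0 = rates(0.0, 0.0)
    if cont0 > fail_contamination:
        raise CalibrationError(
            "controls are not separable: contamination "
            f"{cont0:.1%} at the minimal gate (capture {cap0:.1%})",
            capture=cap0,
            contamination=cont0,
        )
    # Phase 1: open the upper bounds (growth headroom).
    m_hi_best = 0.0
    for m_hi in np.arange(0.1, 2.51, 0.1):
        _, cont, _ = rates(float(m_hi), 0.0)
        if cont > max_contamination:
            break
        m_hi_best = float(m_hi)
    # Phase 2: relax the lower (discriminating) bounds toward the target
    # capture.
    best = rates(m_hi_best, 0.0)
    for m_lo in np.arange(0.02, 0.51, 0.02):
        cap, cont, gates = rates(m_hi_best, float(m_lo))
        if cont > max_contamination:
            break
        best = (cap, cont, gates)
        if cap >= target_capture:
            break
    cap, cont, gates = best
    return GateCalibration(
        gateset=gates,
        capture=cap,
        contamination=cont,
        n_viable=len(viable),
        n_background=len(background),
    )


def concentration(
    positive_count: int, analyzed_volume_ul: float, dilution_factor: float = 500.0
) -> float:
    """Convert a gated event count to spores per litre of culture broth.

    ``count / (volume in litres) × dilution``; the default dilution of 500
    reflects a 1:10 staining step followed by a 1:50 measurement step.
    """
    if analyzed_volume_ul <= 0:
        raise ValueError("analyzed volume must be positive")
    if dilution_factor < 1:
        raise ValueError("dilution factor must be >= 1")
    return positive_count / (analyzed_volume_ul * 1e-6) * dilution_factor


def default_gateset(seed: int = 20160824) -> GateCalibration:
    """Gates calibrated for the simulator's default population.

    Runs the control-calibration procedure on seeded synthetic control
    batches (viable spores, killed spores, blank medium) at the default
    acquisition settings; gates therefore remain calibration output, not
    constants.  Deterministic for a given seed.
    """
    from .simulate import simulate_controls

    viable, dead, blank = simulate_controls(seed=seed)
    return calibrate_gates(viable, dead, blank)
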