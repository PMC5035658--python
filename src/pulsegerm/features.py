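"""Per-particle scalar features from pulse shapes.

Every downstream step — viability gating and the germination classifier —
runs on scalar summaries of the pulse curves:

* ``fws_total`` / ``sws_total``: integrated scatter (AU·μm), size proxies
  used for gating;
* ``fly_max`` / ``flo_max``: peak fluorescence (AU), metabolic-activity
  proxies used for gating;
* ``fws_length``: spatial extent of the forward-scatter signal in μm —
  the particle's size along the flow direction;
* ``fws_cvrmse``: goodness of a single-Gaussian fit to the FWS curve, in
  percent (RMSE over signal mean).  A round spore is near-Gaussian; a
  germ tube adds a second lobe and inflates this value;
* ``fly_inertia``: normalised second moment of the FLY curve about its
  intensity-weighted centroid — high when signal mass sits near the
  edges of the pulse;
* ``fly_fill_factor``: area under the FLY curve over the area of its
  bounding rectangle — the "solidity" of the signal, 1 for a perfect
  rectangle.

All support-based quantities use the same support rule: the bounding
index interval of samples strictly above ``baseline + threshold_fraction
× (max − baseline)`` (default fraction 0.02, no smoothing).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .pulse_model import (
    AcquisitionSettings,
    ParticleRecord,
    PulseShape,
    SampleBatch,
)

__all__ = [
    "DEFAULT_THRESHOLD_FRACTION",
    "EmptySupportError",
    "FeatureVector",
    "GaussianFitError",
    "SCALAR_FEATURES",
    "as_frame",
    "canonical_fws",
    "extract_features",
    "extract_feature_table",
    "fill_factor",
    "gaussian_cvrmse",
    "inertia",
    "integrate_total",
    "length_um",
    "maximum",
    "read_feature_csv",
    "support",
    "write_feature_csv",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_FRACTION = 0.02

#: Numeric feature columns, in canonical CSV order.
SCALAR_FEATURES = (
    "fws_total",
    "sws_total",
    "fly_max",
    "flo_max",
    "fws_length",
    "fws_cvrmse",
    "fly_inertia",
    "fly_fill_factor",
)

CSV_COLUMNS = SCALAR_FEATURES + ("fly_saturated", "particle_id")


class EmptySupportError(ValueError):
    """No sample rises above the support threshold."""


class GaussianFitError(RuntimeError):
    """The Gaussian least-squares fit failed to converge."""

    def __init__(self, message: str, n_iterations: Optional[int] = None):
        self.n_iterations = n_iterations
        super().__init__(message)


@dataclass
class FeatureVector:
    """Scalar features of one particle (units in the module docstring)."""

    fws_total: float
    sws_total: float
    fly_max: float
    flo_max: float
    fws_length: float
    fws_cvrmse: float
    fly_inertia: float
    fly_fill_factor: float
    fly_saturated: bool
    particle_id: int


def support(
    signal: PulseShape, threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
) -> tuple[int, int]:
    """Bounding index interval of samples above the support threshold.

    The threshold is ``baseline + threshold_fraction * (max - baseline)``;
    a sample belongs to the support when strictly above it.  Contiguity is
    not required — the result is the bounding interval (first, last), both
    inclusive, 0-based.
    """
    if not 0 <= threshold_fraction < 1:
        raise ValueError("threshold_fraction must be in [0, 1)")
    s = signal.samples
    thr = signal.baseline + threshold_fraction * (s.max(initial=0.0) - signal.baseline)
    above = np.nonzero(s > thr)[0]
    if above.size == 0:
        raise EmptySupportError(
            "empty support: no sample above threshold "
            f"{thr:g} AU (max {s.max(initial=0.0):g} AU)"
        )
    return int(above[0]), int(above[-1])


def length_um(
    signal: PulseShape, threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
) -> float:
    """Signal length in μm: number of support samples × sample spacing."""
    first, last = support(signal, threshold_fraction)
    return (last - first + 1) * signal.sample_spacing


def maximum(signal: PulseShape) -> float:
    """Peak intensity over all samples (AU)."""
    return float(signal.samples.max(initial=0.0))


def integrate_total(
    signal: PulseShape, threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
) -> float:
    """Integrated intensity over the support, in AU·μm."""
    first, last = support(signal, threshold_fraction)
    return float(signal.samples[first : last + 1].sum() * signal.sample_spacing)


def fill_factor(
    signal: PulseShape, threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
) -> float:
    """Solidity of the pulse: area under the curve over the bounding
    rectangle's area.  1.0 for a perfect rectangle."""
    first, last = support(signal, threshold_fraction)
    seg = signal.samples[first : last + 1]
    return float(seg.sum() / (seg.max() * seg.size))


def inertia(
    signal: PulseShape, threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION
) -> float:
    """Normalised second moment of the pulse about its centroid.

    ``Σ sᵢ (xᵢ − x_c)² / (Σ sᵢ · (L/2)²)`` with ``x_c`` the
    intensity-weighted centroid and ``L`` the span between the first and
    last support sample.  0 for a point mass, exactly 1 for two equal
    spikes at the support extremes (the centroid minimises the second
    moment, so values never exceed 1).  A single-sample support has zero
    span and returns 0.
    """
    first, last = support(signal, threshold_fraction)
    if last == first:
        return 0.0
    seg = signal.samples[first : last + 1]
    x = np.arange(seg.size) * signal.sample_spacing
    total = seg.sum()
    centroid = float((seg * x).sum() / total)
    half_span = (seg.size - 1) * signal.sample_spacing / 2.0
    return float((seg * (x - centroid) ** 2).sum() / (total * half_span**2))


def _gauss(x: np.ndarray, amp: float, mu: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def gaussian_cvrmse(
    signal: PulseShape,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    max_iterations: int = 200,
    tol: float = 1e-8,
) -> float:
    """Quality of a single-Gaussian fit to the pulse, in percent.

    A Gaussian ``A·exp(−(x−μ)²/2σ²)`` is fitted to the support samples by
    nonlinear least squares from moment-based starting values (A = max,
    μ = centroid, σ = √ second central moment), with A > 0, σ > 0 and μ
    constrained to the support.  Returns ``100 × RMSE / mean(observed)``.
    Near zero for round (Gaussian-like) particles; large for two-lobe
    germinated-spore profiles.
    """
    first, last = support(signal, threshold_fraction)
    seg = signal.samples[first : last + 1]
    if seg.size < 4:
        raise GaussianFitError(
            f"need >= 4 support samples for a Gaussian fit, got {seg.size}"
        )
    x = np.arange(seg.size, dtype=float) * signal.sample_spacing
    total = seg.sum()
    centroid = float((seg * x).sum() / total)
    var = float((seg * (x - centroid) ** 2).sum() / total)
    sigma0 = max(math.sqrt(var), signal.sample_spacing / 4.0)
    p0 = np.array([seg.max(), centroid, sigma0])
    lo = np.array([1e-12, x[0], signal.sample_spacing / 100.0])
    hi = np.array([np.inf, x[-1], 100.0 * (x[-1] - x[0] + signal.sample_spacing)])
    p0 = np.clip(p0, lo, hi)

    result = least_squares(
        lambda p: _gauss(x, *p) - seg,
        p0,
        bounds=(lo, hi),
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=max_iterations * 3,
    )
    if not result.success:
        raise GaussianFitError(
            f"Gaussian fit did not converge: {result.message}",
            n_iterations=result.nfev,
        )
    rmse = math.sqrt(float(np.mean(result.fun**2)))
    return 100.0 * rmse / float(seg.mean())


def canonical_fws(record: ParticleRecord) -> PulseShape:
    """Canonical forward-scatter signal: per-sample mean of the left and
    right FWS detectors when both are present, else the left alone."""
    left = record.channels["FWS_L"]
    right = record.channels.get("FWS_R")
    if right is None or right.n_samples != left.n_samples:
        return left
    return PulseShape(
        (left.samples + right.samples) / 2.0,
        sample_spacing=left.sample_spacing,
        baseline=left.baseline,
    )


def extract_features(
    record: ParticleRecord,
    settings: AcquisitionSettings,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> FeatureVector:
    """Compute the full feature vector for one particle.

    Raises :class:`EmptySupportError` when the forward-scatter signal has
    no support; batch-level extraction catches this and excludes the
    record with a logged reason.
    """
    fws = canonical_fws(record)
    sws = record.channels["SWS"]
    fly = record.channels["FLY"]
    flo = record.channels["FLO"]

    fly_max = maximum(fly)
    try:
        fly_fill = fill_factor(fly, threshold_fraction)
        fly_inertia = inertia(fly, threshold_fraction)
    except EmptySupportError:
        # Dim particle: no FLY support.  Solidity/inertia of a flat dim
        # signal are reported as the degenerate point-mass values.
        fly_fill = 1.0
        fly_inertia = 0.0
    try:
        sws_total = integrate_total(sws, threshold_fraction)
    except EmptySupportError:
        sws_total = 0.0

    return FeatureVector(
        fws_total=integrate_total(fws, threshold_fraction),
        sws_total=sws_total,
        fly_max=fly_max,
        flo_max=maximum(flo),
        fws_length=length_um(fws, threshold_fraction),
        fws_cvrmse=gaussian_cvrmse(fws, threshold_fraction),
        fly_inertia=fly_inertia,
        fly_fill_factor=fly_fill,
        fly_saturated=bool(
            np.any(fly.samples >= settings.saturation_ceiling)
        ),
        particle_id=record.particle_id,
    )


def extract_feature_table(
    batch: SampleBatch,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    include_truth: bool = False,
) -> tuple[pd.DataFrame, list[int]]:
    """Extract features for every usable record of a batch.

    Returns ``(table, excluded_ids)``: one row per usable particle (CSV
    column order) and the ids of records excluded because their FWS signal
    had empty support or the Gaussian fit failed; exclusions are logged.
    When ``include_truth`` is set, a ``truth_label`` column is appended.
    """
    rows = []
    truths = []
    excluded: list[int] = []
    for record in batch.records:
        try:
            fv = extract_features(record, batch.acquisition, threshold_fraction)
        except (EmptySupportError, GaussianFitError) as exc:
            logger.warning(
                "particle %s excluded: %s", record.particle_id, exc
            )
            excluded.append(record.particle_id)
            continue
        rows.append(asdict(fv))
        truths.append(record.truth_label)
    table = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    if include_truth:
        table["truth_label"] = truths
    return table, excluded


def as_frame(features) -> pd.DataFrame:
    """Coerce a FeatureVector sequence or DataFrame to the canonical
    feature table layout."""
    if isinstance(features, pd.DataFrame):
        return features
    return pd.DataFrame(
        [asdict(fv) for fv in features], columns=list(CSV_COLUMNS)
    )


def write_feature_csv(features, path) -> None:
    """Write a feature table CSV (canonical column order, header row)."""
    table = as_frame(features)
    extra = [c for c in table.columns if c not in CSV_COLUMNS]
    table[list(CSV_COLUMNS) + extra].to_csv(path, index=False)


def read_feature_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"feature CSV missing columns: {missing}")
    return table
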