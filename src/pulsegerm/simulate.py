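"""Synthetic pulse-shape populations with ground-truth labels.

Generates CytoSense-like multi-channel pulse shapes for the particle
classes seen in a germinating *Penicillium*-type batch culture — round
(non-germinated) spores, germinating and germinated spores, unbranched
and branched hyphae, dead spores and medium debris — plus germination
kinetics over process time and CFU plating counts, so the full gating /
feature / classification pipeline is testable without instrument data.

Morphology model (per particle, positions in μm along the flow):

* a round spore is a single near-Gaussian lobe on the scatter channels
  whose support length equals the spore diameter; spores swell from
  ~4 μm at inoculation toward ~25 μm, the diameter at which germination
  occurs;
* a germinating/germinated spore adds a second, lower-amplitude lobe
  displaced downstream (particles align with the flow, germ tube first):
  tube length 0.25–0.5× the body for the intermediate "germinating"
  band, ≥ 0.5× (the germination criterion) for germinated spores;
* hyphae are long plateaus; dead spores keep a small body but show
  red (PI) instead of green (FDA) fluorescence; debris is small and dim;
* yellow/green fluorescence (FLY, esterase activity) rises through
  germination and is clipped at the digitiser ceiling after the
  sensitivity-level gain is applied.

Two documented artifact channels reproduce the method's known failure
modes: germinated spores flowing *upright* present a single-lobe,
Gaussian-like scatter signal (default 2.9 % of germinated spores), and
medium debris attached or adjacent to a round spore adds a secondary
bump (default 3.2 % of non-germinated spores).

Every stochastic operation takes an explicit seed or Generator; equal
seeds give bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .pulse_model import (
    AcquisitionSettings,
    ParticleRecord,
    PulseShape,
    SampleBatch,
    SampleMetadata,
    TRUTH_LABELS,
)

__all__ = [
    "GerminationKinetics",
    "SimConfig",
    "UncountablePlateError",
    "germination_fraction",
    "simulate_cfu",
    "simulate_cfu_study",
    "simulate_controls",
    "simulate_particle",
    "simulate_sample",
    "simulate_timecourse",
]

#: Gaussian support factor: a lobe of amplitude A crosses the 2 % support
#: threshold at |x| = sigma * sqrt(2 ln 50), so a lobe whose threshold
#: support should span d μm uses sigma = d / (2 sqrt(2 ln 50)).
_SUPPORT_SIGMAS = 2.0 * math.sqrt(2.0 * math.log(50.0))


@dataclass(frozen=True)
class GerminationKinetics:
    """Population germination kinetics over batch-process time.

    ``lag_h`` hours pass before any spore germinates; the germinated
    fraction then rises along a logistic-shaped curve reaching 90 % of
    its plateau ``rise_h`` hours after onset.  Older spore inocula
    germinate more slowly and incompletely: the young defaults (age ≤ 3
    months) are lag 15 h, rise 10 h, plateau 0.90; the old defaults
    (age ≥ 8 months) keep the lag but double the rise and cap the
    plateau at 0.55.
    """

    lag_h: float = 15.0
    rise_h: float = 10.0
    plateau: float = 0.90
    age_months: float = 3.0

    def __post_init__(self):
        if self.lag_h < 0:
            raise ValueError("lag must be >= 0")
        if self.rise_h <= 0:
            raise ValueError("rise must be positive")
        if not 0 <= self.plateau <= 1:
            raise ValueError("plateau must be in [0, 1]")

    @classmethod
    def young(cls) -> "GerminationKinetics":
        return cls(lag_h=15.0, rise_h=10.0, plateau=0.90, age_months=3.0)

    @classmethod
    def old(cls) -> "GerminationKinetics":
        return cls(lag_h=15.0, rise_h=20.0, plateau=0.55, age_months=9.0)


def germination_fraction(time_h: float, kinetics: GerminationKinetics) -> float:
    """Fraction of viable spores germinated at ``time_h`` hours.

    Zero through the lag, then ``plateau · (2 / (1 + e^{−k (t − lag)}) − 1)``
    with k chosen so the curve passes 0.9 × plateau exactly at
    ``lag + rise``; approaches the plateau asymptotically.
    """
    if time_h < 0:
        raise ValueError("time must be >= 0")
    if time_h <= kinetics.lag_h:
        return 0.0
    k = math.log(19.0) / kinetics.rise_h
    t = time_h - kinetics.lag_h
    return kinetics.plateau * (2.0 / (1.0 + math.exp(-k * t)) - 1.0)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic measurement.

    Mixture weights and artifact rates are fractions in [0, 1]; the
    default mixture (70 % viable spores, 15 % dead, 15 % debris) stands
    for a fresh inoculum in complex medium.  ``initial_diameter_um`` →
    ``germination_diameter_um`` describes spore swelling over the lag
    phase.  Amplitudes are arbitrary units before the sensitivity-level
    gain; noise is additive Gaussian (σ = ``noise_sigma_frac`` × lobe
    peak) plus a per-particle multiplicative brightness jitter.
    """

    n_particles: int = 2000
    kinetics: GerminationKinetics = field(default_factory=GerminationKinetics)
    weight_viable: float = 0.70
    weight_dead: float = 0.15
    weight_debris: float = 0.15
    upright_fraction: float = 0.029
    debris_attachment_fraction: float = 0.032
    noise_sigma_frac: float = 0.005
    brightness_jitter_sd: float = 0.10
    # Esterase activity is highly heterogeneous between spores; the wide
    # per-particle FLY spread makes the class distributions overlap in
    # peak fluorescence (morphology, not brightness, separates classes).
    fly_jitter_sd: float = 0.50
    diameter_jitter_sd: float = 0.06
    initial_diameter_um: float = 4.0
    germination_diameter_um: float = 25.0
    fws_amplitude: float = 100.0
    # FLY esterase-activity amplitude per class (AU at unit gain); rises
    # through germination.
    fly_activity: dict = field(
        default_factory=lambda: {
            "non_germinated": 40.0,
            "germinating": 80.0,
            "germinated": 120.0,
            "hypha_unbranched": 130.0,
            "hypha_branched": 130.0,
            "dead": 1.5,
            "debris": 3.0,
        }
    )
    acquisition: AcquisitionSettings = field(default_factory=AcquisitionSettings)

    def __post_init__(self):
        weights = (self.weight_viable, self.weight_dead, self.weight_debris)
        if any(not 0 <= w <= 1 for w in weights):
            raise ValueError("mixture weights must be in [0, 1]")
        if not math.isclose(sum(weights), 1.0, abs_tol=1e-9):
            raise ValueError("mixture weights must sum to 1")
        for name in ("upright_fraction", "debris_attachment_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_particles < 0:
            raise ValueError("n_particles must be >= 0")

    def diameter_at(self, time_h: float) -> float:
        """Mean non-germinated spore diameter after ``time_h`` hours of
        swelling (linear toward the germination diameter over the lag)."""
        frac = min(max(time_h / self.kinetics.lag_h, 0.0), 1.0) \
            if self.kinetics.lag_h > 0 else 1.0
        return self.initial_diameter_um + frac * (
            self.germination_diameter_um - self.initial_diameter_um
        )


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def _lobe(x: np.ndarray, amp: float, center: float, support_um: float) -> np.ndarray:
    sigma = max(support_um, 0.5) / _SUPPORT_SIGMAS
    return amp * np.exp(-((x - center) ** 2) / (2.0 * sigma**2))


def _plateau(x, amp, start, stop, edge_um=1.5):
    """Smoothed rectangular plateau (hypha body)."""
    rise = 1.0 / (1.0 + np.exp(-(x - start) / (edge_um / 4.0)))
    fall = 1.0 / (1.0 + np.exp((x - stop) / (edge_um / 4.0)))
    return amp * rise * fall


def _finish(
    profile: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    gain: float = 1.0,
) -> np.ndarray:
    """Apply additive noise, clip at zero and at the digitiser ceiling."""
    peak = profile.max(initial=0.0)
    noise_sd = config.noise_sigma_frac * max(peak, 1.0)
    signal = profile * gain + rng.normal(0.0, noise_sd * gain, profile.shape)
    return np.clip(signal, 0.0, config.acquisition.saturation_ceiling)


def simulate_particle(
    true_class: str,
    config: SimConfig,
    rng_stream,
    time_h: float = 25.0,
    variant: Optional[str] = None,
    particle_id: int = 0,
) -> ParticleRecord:
    """Draw one labelled particle of ``true_class``.

    ``variant`` selects a documented artifact morphology: ``"upright"``
    (germinated spore aligned along the optical axis — single-lobe
    scatter) or ``"attached_debris"`` (round spore with an adjacent
    medium particle — secondary bump).  The truth label is always the
    biological class.
    """
    if true_class not in TRUTH_LABELS:
        raise ValueError(
            f"unknown class {true_class!r}; known: {TRUTH_LABELS}"
        )
    rng = _as_rng(rng_stream)
    cfg = config
    sp = cfg.acquisition.sample_spacing_um

    jitter = float(np.exp(rng.normal(0.0, cfg.brightness_jitter_sd)))
    d_jitter = float(np.exp(rng.normal(0.0, cfg.diameter_jitter_sd)))

    body_d = cfg.diameter_at(time_h) * d_jitter
    mature_d = cfg.germination_diameter_um * d_jitter
    amp = cfg.fws_amplitude * jitter
    fly_amp = cfg.fly_activity[true_class] * float(
        np.exp(rng.normal(0.0, cfg.fly_jitter_sd))
    )

    # (center, support_um, relative amplitude) per lobe, tube downstream.
    def lobes_for(cls: str):
        if cls == "non_germinated":
            main = [(0.0, body_d, 1.0)]
            if variant == "attached_debris":
                bump_d = float(rng.uniform(2.0, 4.0))
                main.append((body_d / 2 + bump_d, bump_d, 0.30))
            return main, main  # scatter lobes, fly lobes
        if cls in ("germinating", "germinated"):
            # Tube length relative to the body.  The germination criterion
            # is 0.5x, but a spore annotated "germinated" at a sampling
            # point has typically elongated past it; the band right at the
            # criterion is visually part of the intermediate class.
            if cls == "germinating":
                u = float(rng.uniform(0.25, 0.55))
            else:
                u = float(rng.uniform(0.55, 1.8))
            tube = u * mature_d
            if variant == "upright":
                # End-on view: only the body cross-section is scanned.
                main = [(0.0, 0.9 * mature_d, 1.0)]
                return main, main
            scatter = [(0.0, mature_d, 1.0),
                       ((mature_d + tube) / 2.0, tube, 0.40)]
            return scatter, scatter
        if cls in ("hypha_unbranched", "hypha_branched"):
            length = float(rng.uniform(3.0, 6.0)) * mature_d
            if cls == "hypha_branched":
                length *= 1.5
            return [("plateau", length)], [("plateau", length)]
        if cls == "dead":
            d = float(rng.uniform(3.0, 6.0))
            return [(0.0, d, 1.0)], [(0.0, d, 1.0)]
        # debris (below ~2.5 um nothing triggers the instrument)
        d = float(rng.uniform(2.5, 8.0))
        return [(0.0, d, 1.0)], [(0.0, d, 1.0)]

    scatter_lobes, fly_lobes = lobes_for(true_class)

    # Window: particle extent plus margin.
    if scatter_lobes and scatter_lobes[0][0] == "plateau":
        length = scatter_lobes[0][1]
        lo, hi = -length / 2.0, length / 2.0
    else:
        lo = min(c - s / 2.0 for c, s, _ in scatter_lobes)
        hi = max(c + s / 2.0 for c, s, _ in scatter_lobes)
    margin = 5.0
    x = np.arange(lo - margin, hi + margin + sp, sp)

    def build(lobes, peak_amp):
        profile = np.zeros_like(x)
        if lobes and lobes[0][0] == "plateau":
            length = lobes[0][1]
            profile = _plateau(x, peak_amp, -length / 2.0, length / 2.0)
        else:
            for center, sup, rel in lobes:
                profile += _lobe(x, peak_amp * rel, center, sup)
        return profile

    if true_class == "debris":
        amp = float(rng.uniform(3.0, 30.0)) * jitter
    fws = build(scatter_lobes, amp)
    sws = build(scatter_lobes, 0.6 * amp)
    fly_gain = cfg.acquisition.fly_gain
    fly = build(fly_lobes, fly_amp)
    flo = 0.35 * fly
    # Dead (PI-stained) particles are bright in red; viable ones are dim.
    flr_amp = 80.0 * jitter if true_class == "dead" else 4.0 * jitter
    flr = build(scatter_lobes, flr_amp)

    channels = {
        "FWS_L": _finish(fws * rng.normal(1.0, 0.02), cfg, rng),
        "FWS_R": _finish(fws * rng.normal(1.0, 0.02), cfg, rng),
        "SWS": _finish(sws, cfg, rng),
        "FLY": _finish(fly, cfg, rng, gain=fly_gain),
        "FLO": _finish(flo, cfg, rng, gain=fly_gain),
        "FLR": _finish(flr, cfg, rng),
    }
    pulses = {
        name: PulseShape(
            samples, sample_spacing=sp, baseline=cfg.acquisition.baseline
        )
        for name, samples in channels.items()
    }
    return ParticleRecord(
        particle_id=particle_id, channels=pulses, truth_label=true_class
    )


def _viable_split(time_h: float, kinetics: GerminationKinetics) -> tuple[float, float, float]:
    """(p_non_germinated, p_germinating, p_germinated) among viable spores.

    The germinated fraction follows :func:`germination_fraction`; the
    intermediate "germinating" band is a thin transition population carved
    from the non-germinated side, largest mid-rise and vanishing at the
    start and the plateau.
    """
    g = germination_fraction(time_h, kinetics)
    if kinetics.plateau > 0:
        band = 0.25 * g * (1.0 - g / kinetics.plateau)
    else:
        band = 0.0
    band = min(max(band, 0.0), 1.0 - g)
    return 1.0 - g - band, band, g


def simulate_sample(
    time_h: float,
    config: SimConfig,
    seed: Union[int, np.random.Generator],
    batch_id: str = "sim",
) -> SampleBatch:
    """Simulate one measured sample at ``time_h`` hours of cultivation.

    Particle classes are drawn from the configured mixture; viable spores
    split into non-germinated / germinating / germinated according to the
    germination kinetics, and the documented artifact morphologies are
    injected at their configured rates.  Bit-reproducible per seed.
    """
    rng = _as_rng(seed)
    cfg = config
    p_ng, p_ging, p_g = _viable_split(time_h, cfg.kinetics)
    class_probs = {
        "non_germinated": cfg.weight_viable * p_ng,
        "germinating": cfg.weight_viable * p_ging,
        "germinated": cfg.weight_viable * p_g,
        "dead": cfg.weight_dead,
        "debris": cfg.weight_debris,
    }
    # Late in the process some germinated spores have grown out into
    # hyphae; represent them as a fixed share of the germinated mass.
    if time_h > cfg.kinetics.lag_h + cfg.kinetics.rise_h:
        hypha = 0.15 * class_probs["germinated"]
        class_probs["germinated"] -= hypha
        class_probs["hypha_unbranched"] = 0.8 * hypha
        class_probs["hypha_branched"] = 0.2 * hypha

    names = list(class_probs)
    counts = rng.multinomial(cfg.n_particles, [class_probs[n] for n in names])
    records = []
    pid = 0
    for name, count in zip(names, counts):
        for _ in range(count):
            variant = None
            if name == "germinated" and rng.random() < cfg.upright_fraction:
                variant = "upright"
            elif (
                name == "non_germinated"
                and rng.random() < cfg.debris_attachment_fraction
            ):
                variant = "attached_debris"
            records.append(
                simulate_particle(
                    name, cfg, rng, time_h=time_h, variant=variant,
                    particle_id=pid,
                )
            )
            pid += 1
    # Shuffle so class blocks are not ordered in the file.
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    for new_id, record in enumerate(records):
        record.particle_id = new_id
    return SampleBatch(
        records=records,
        acquisition=cfg.acquisition,
        metadata=SampleMetadata(time_h=time_h, batch_id=batch_id),
    )


def simulate_timecourse(
    times_h,
    config: SimConfig,
    seed: int,
    batch_id: str = "sim",
) -> list[SampleBatch]:
    """One batch per sampling time, with per-time derived seeds."""
    root = np.random.default_rng(seed)
    return [
        simulate_sample(t, config, root.spawn(1)[0], batch_id=batch_id)
        for t in times_h
    ]


def simulate_controls(
    seed: int,
    n_per_control: int = 400,
    config: Optional[SimConfig] = None,
) -> tuple[SampleBatch, SampleBatch, SampleBatch]:
    """Control batches for gate calibration: viable spores in filtrated
    medium, killed spores, and blank medium (debris only)."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)

    def pure(cls: str, t: float) -> SampleBatch:
        records = [
            simulate_particle(cls, cfg, rng, time_h=t, particle_id=i)
            for i in range(n_per_control)
        ]
        return SampleBatch(
            records=records,
            acquisition=cfg.acquisition,
            metadata=SampleMetadata(time_h=t, batch_id=f"control-{cls}"),
        )

    viable = pure("non_germinated", 1.0)
    dead = pure("dead", 1.0)
    blank = pure("debris", 1.0)
    return viable, dead, blank


class UncountablePlateError(ValueError):
    """Expected colony count too high to count on one plate."""


def simulate_cfu(
    true_viable_per_l: float,
    plated_volume_l: float,
    dilution: float,
    rng_stream,
) -> int:
    """Colony count from plating: Poisson with mean
    ``true_viable_per_l × plated_volume / dilution``."""
    if true_viable_per_l < 0 or plated_volume_l <= 0 or dilution < 1:
        raise ValueError("arguments must be positive (dilution >= 1)")
    mean = true_viable_per_l * plated_volume_l / dilution
    if mean > 1e6:
        raise UncountablePlateError(
            f"expected {mean:.3g} colonies on one plate; dilute further"
        )
    rng = _as_rng(rng_stream)
    return int(rng.poisson(mean))


def simulate_cfu_study(
    seed: int,
    n_inocula: int = 12,
    conc_range=(1e7, 1e9),
    analyzed_volume_ul: float = 200.0,
    dilution_factor: float = 500.0,
) -> "pd.DataFrame":
    """Paired FCM / CFU measurements over a span of inoculum strengths.

    For each inoculum the true viable concentration is drawn log-uniform
    over ``conc_range`` (spores/l); the FCM side counts Poisson events in
    the analyzed diluted volume and back-computes a concentration, the
    CFU side plates at a dilution chosen for a countable plate.  Returns
    a DataFrame with ``true``, ``fcm`` and ``cfu`` concentrations.
    """
    import pandas as pd

    from .gating import concentration

    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_inocula):
        true = 10 ** rng.uniform(*np.log10(conc_range))
        mean_events = true * (analyzed_volume_ul * 1e-6) / dilution_factor
        events = int(rng.poisson(mean_events))
        fcm = concentration(events, analyzed_volume_ul, dilution_factor)
        # Plate 0.1 ml at a dilution targeting ~200 colonies.
        plated_volume_l = 1e-4
        plate_dilution = max(true * plated_volume_l / 200.0, 1.0)
        colonies = simulate_cfu(true, plated_volume_l, plate_dilution, rng)
        cfu = colonies * plate_dilution / plated_volume_l
        rows.append({"true": true, "fcm": fcm, "cfu": cfu})
    return pd.DataFrame(rows)
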