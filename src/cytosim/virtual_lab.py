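"""Synthetic populations, phenomenological sorting stages and spike-ins.

The microfluidic physics of the enrichment stages is NOT simulated; each
stage is a calibrated logistic capture-probability curve in diameter whose
defaults reproduce the headline stage efficiencies (WBC depletion ~98 % in
the separation stage, tumor recovery ~90 %).  These are fitted stand-ins.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from cytosim.dielectrics import (
    CellLabel,
    Medium,
    Particle,
    get_medium,
    get_preset,
    population_defaults,
)
from cytosim.dsp import FragmentTensor, resample_fragment
from cytosim.signal_sim import (
    ElectrodeConfig,
    EventSignal,
    NoiseModel,
    TransitEvent,
    simulate_event,
)


@dataclass(frozen=True)
class PopulationSpec:
    """A homogeneous-dielectric population with diameter heterogeneity."""

    preset: str  # material preset name (cells.* or beads.*)
    count: int | None = None
    concentration_per_ml: float | None = None
    volume_ml: float | None = None
    mean_um: float | None = None  # default: population preset table
    sd_um: float | None = None
    lo_um: float | None = None
    hi_um: float | None = None
    trajectory_p: float = 0.5  # probability of trajectory T1

    def __post_init__(self) -> None:
        if not (0.0 <= self.trajectory_p <= 1.0):
            raise ValueError("trajectory_p must be a probability")
        if self.count is None and (
            self.concentration_per_ml is None or self.volume_ml is None
        ):
            raise ValueError("give either count or concentration + volume")

    def requested_count(self) -> int:
        if self.count is not None:
            return int(self.count)
        return int(round(self.concentration_per_ml * self.volume_ml))

    def diameter_distribution(self) -> tuple[float, float, float, float]:
        try:
            defaults = population_defaults(self.preset)
        except KeyError:
            defaults = {}
        mean = self.mean_um if self.mean_um is not None else defaults.get("mean_um")
        sd = self.sd_um if self.sd_um is not None else defaults.get("sd_um", 0.0)
        lo = self.lo_um if self.lo_um is not None else defaults.get("lo_um", 1.5)
        hi = self.hi_um if self.hi_um is not None else defaults.get("hi_um", 45.0)
        if mean is None:
            mean = get_preset(self.preset).diameter_um
        if sd < 0:
            raise ValueError("sd must be >= 0")
        if not (0 < lo < hi):
            raise ValueError("impossible truncation bounds")
        if not (lo <= mean <= hi):
            raise ValueError("mean outside truncation bounds")
        return float(mean), float(sd), float(lo), float(hi)


@dataclass(frozen=True)
class SampledCell:
    """One realized particle with its assigned focusing trajectory."""

    particle: Particle
    trajectory: str
    uid: int

    @property
    def diameter_um(self) -> float:
        return self.particle.diameter_um

    @property
    def label(self) -> str:
        return self.particle.label.value


def generate_population(
    spec: PopulationSpec,
    seed: int,
    max_cells: int | None = None,
) -> tuple[list[SampledCell], float]:
    """Sample a population; returns (cells, scale_factor).

    Diameters follow a truncated normal; each cell carries the preset
    dielectrics and a Bernoulli trajectory assignment.  When ``max_cells``
    caps the realized size, the subsampling factor is returned so counts
    can be rescaled in reports (scale_factor = requested / realized).
    """
    rng = np.random.default_rng(seed)
    template = get_preset(spec.preset)
    mean, sd, lo, hi = spec.diameter_distribution()
    n_req = spec.requested_count()
    n = n_req if max_cells is None else min(n_req, int(max_cells))
    if sd == 0:
        diameters = np.full(n, mean)
    else:
        a, b = (lo - mean) / sd, (hi - mean) / sd
        diameters = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    trajectories = np.where(rng.random(n) < spec.trajectory_p, "T1", "T2")
    cells = [
        SampledCell(
            particle=template.with_diameter(float(d)),
            trajectory=str(t),
            uid=i,
        )
        for i, (d, t) in enumerate(zip(diameters, trajectories))
    ]
    scale = n_req / n if n else 1.0
    return cells, scale


# ---------------------------------------------------------------------------
# Sorting stages
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SortingStage:
    """Logistic size-dependent capture curve (keep-in-product probability)."""

    name: str
    midpoint_um: float
    steepness_per_um: float
    floor: float = 0.0
    ceiling: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.floor <= self.ceiling <= 1.0):
            raise ValueError("require 0 <= floor <= ceiling <= 1")
        if self.steepness_per_um < 0:
            raise ValueError("steepness must be >= 0")

    def capture_probability(self, diameter_um) -> np.ndarray:
        d = np.asarray(diameter_um, dtype=float)
        logistic = 1.0 / (1.0 + np.exp(-self.steepness_per_um * (d - self.midpoint_um)))
        return self.floor + (self.ceiling - self.floor) * logistic


def default_stage_chain() -> list[SortingStage]:
    """Separation + two concentration stages.

    Calibrated so the separation stage alone gives WBC DE ~98 % and tumor
    RE ~90 % integrated over the default size distributions; the
    concentration stages retain large cells at ~98 % while further
    depleting the remaining WBCs.
    """
    return [
        SortingStage("separation", midpoint_um=13.0509, steepness_per_um=1.3957, ceiling=0.95),
        SortingStage("concentration1", midpoint_um=10.0, steepness_per_um=1.0, ceiling=0.98),
        SortingStage("concentration2", midpoint_um=10.0, steepness_per_um=1.0, ceiling=0.98),
    ]


@dataclass
class SortingReport:
    """Realized per-class recovery/depletion and product purity."""

    stage: str
    recovery_efficiency: dict
    depletion_efficiency: dict
    purity: float
    n_in: int
    n_product: int
    n_waste: int

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "recovery_efficiency": self.recovery_efficiency,
            "depletion_efficiency": self.depletion_efficiency,
            "purity": self.purity,
            "n_in": self.n_in,
            "n_product": self.n_product,
            "n_waste": self.n_waste,
        }


def apply_sorting(
    cells: list[SampledCell],
    stage: SortingStage,
    seed: int,
    target_label: str = CellLabel.TUMOR.value,
) -> tuple[list[SampledCell], list[SampledCell], SortingReport]:
    """Independent Bernoulli keep-decision per cell; conserves cells."""
    rng = np.random.default_rng(seed)
    if cells:
        p = stage.capture_probability([c.diameter_um for c in cells])
        keep = rng.random(len(cells)) < p
    else:
        keep = np.zeros(0, dtype=bool)
    product = [c for c, k in zip(cells, keep) if k]
    waste = [c for c, k in zip(cells, keep) if not k]

    labels = sorted({c.label for c in cells})
    recovery, depletion = {}, {}
    for lab in labels:
        n_lab = sum(1 for c in cells if c.label == lab)
        n_kept = sum(1 for c in product if c.label == lab)
        recovery[lab] = n_kept / n_lab
        depletion[lab] = 1.0 - recovery[lab]
    n_target = sum(1 for c in product if c.label == target_label)
    purity = n_target / len(product) if product else 0.0
    report = SortingReport(
        stage=stage.name,
        recovery_efficiency=recovery,
        depletion_efficiency=depletion,
        purity=purity,
        n_in=len(cells),
        n_product=len(product),
        n_waste=len(waste),
    )
    return product, waste, report


def apply_stage_chain(
    cells: list[SampledCell],
    stages: list[SortingStage],
    seed: int,
) -> tuple[list[SampledCell], list[SampledCell], list[SortingReport]]:
    """Run stages in series; waste accumulates across stages."""
    seeds = np.random.SeedSequence(seed).spawn(len(stages))
    product = cells
    waste_all: list[SampledCell] = []
    reports = []
    for stage, ss in zip(stages, seeds):
        product, waste, report = apply_sorting(product, stage, seed=ss.generate_state(1)[0])
        waste_all.extend(waste)
        reports.append(report)
    return product, waste_all, reports


# ---------------------------------------------------------------------------
# Spike-in scenarios
# ---------------------------------------------------------------------------

@dataclass
class SpikeInSample:
    """A mixed background + spiked sample with retained ground truth."""

    cells: list
    spike_count: int
    background_count: int
    background_scale: float
    seed: int

    @property
    def true_tumor_uids(self) -> list[int]:
        return [c.uid for c in self.cells if c.label == CellLabel.TUMOR.value]


def build_spikein_scenario(
    background: PopulationSpec,
    spike_counts,
    seed: int,
    spike_preset: str = "MCF-7",
    max_background: int | None = None,
) -> list[SpikeInSample]:
    """Labelled mixed samples for end-to-end runs (one per spike count)."""
    samples = []
    seeds = np.random.SeedSequence(seed).spawn(len(list(spike_counts)))
    for spike_n, ss in zip(spike_counts, seeds):
        if spike_n < 0:
            raise ValueError("spike counts must be >= 0")
        s_bg, s_spike, s_shuffle = (s.generate_state(1)[0] for s in ss.spawn(3))
        bg_cells, scale = generate_population(background, seed=s_bg, max_cells=max_background)
        spike_spec = PopulationSpec(preset=spike_preset, count=int(spike_n))
        spike_cells, _ = generate_population(spike_spec, seed=s_spike)
        # re-key uids so they stay unique across the mixture
        offset = len(bg_cells)
        spike_cells = [replace(c, uid=c.uid + offset) for c in spike_cells]
        mixed = bg_cells + spike_cells
        rng = np.random.default_rng(s_shuffle)
        rng.shuffle(mixed)
        samples.append(
            SpikeInSample(
                cells=mixed,
                spike_count=int(spike_n),
                background_count=len(bg_cells),
                background_scale=scale,
                seed=int(s_bg),
            )
        )
    return samples


# ---------------------------------------------------------------------------
# Bulk event / fragment synthesis
# ---------------------------------------------------------------------------

def simulate_cells(
    cells: list[SampledCell],
    config: ElectrodeConfig | None = None,
    medium: Medium | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    speed: float = 0.15,
) -> list[EventSignal]:
    """Simulate one transit per cell, with per-event child seeds."""
    config = config or ElectrodeConfig()
    medium = medium or get_medium("PBS")
    noise = noise or NoiseModel()
    root = np.random.default_rng(seed)
    events = []
    for cell in cells:
        ev = TransitEvent(particle=cell.particle, trajectory=cell.trajectory, speed=speed)
        rng = np.random.default_rng(root.integers(0, 2**63))
        events.append(simulate_event(ev, config, medium, noise, rng=rng))
    return events


def make_fragment_dataset(
    specs_and_counts,
    config: ElectrodeConfig | None = None,
    noise: NoiseModel | None = None,
    seed: int = 0,
    normalization: str = "grouped",
    processed: bool = True,
    chunk_events: int = 500,
) -> list[FragmentTensor]:
    """Simulate labelled fragments for classifier training.

    specs_and_counts: iterable of (PopulationSpec, n_events).

    With ``processed=True`` (default) every event runs through the same
    stream-level DSP chain as a pipeline run (detrend, detect, peak check,
    canonical window), so training fragments match deployment fragments;
    events failing the four-peak check are dropped, as they would be at
    run time.  ``processed=False`` resamples the raw simulated windows.
    """
    from cytosim import dsp as _dsp
    from cytosim.pipeline import default_size_calibration

    specs_and_counts = list(specs_and_counts)
    config = config or ElectrodeConfig()
    noise = noise or NoiseModel()
    fragments: list[FragmentTensor] = []
    calibration = default_size_calibration(config) if processed else None
    seeds = np.random.SeedSequence(seed).spawn(len(specs_and_counts))
    for (spec, n), ss in zip(specs_and_counts, seeds):
        s_pop, s_sim, s_stream = (s.generate_state(1)[0] for s in ss.spawn(3))
        cells, _ = generate_population(replace(spec, count=int(n)), seed=s_pop)
        events = simulate_cells(cells, config=config, noise=noise, seed=s_sim)
        if not processed:
            fragments.extend(
                resample_fragment(ev, normalization=normalization) for ev in events
            )
            continue
        stream_rng = np.random.default_rng(s_stream)
        for start in range(0, len(events), chunk_events):
            result = _dsp.process_event_stream(
                events[start : start + chunk_events], calibration,
                noise.amplitude_noise_sd, rng=stream_rng,
                normalization=normalization,
            )
            fragments.extend(
                pe.fragment for pe in result.processed if pe.fragment.label
            )
    return fragments
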