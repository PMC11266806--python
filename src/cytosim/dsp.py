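"""Signal conditioning, event detection and electrical feature extraction.

Chain: raw multi-channel stream -> detrend (moving median) + zero-phase
low-pass -> threshold event detection on the reference channel -> four-peak
extraction with trajectory canonicalisation -> second-peak features
(electrical diameter via bead calibration, opacity ratios, phase ratio) ->
classifier-ready 100 x 6 fragments.

Peak-order canonicalisation: the two focusing trajectories produce
time-mirrored signals, so peaks are re-ordered into a trajectory-normalised
sequence before "the second peak" is read; features are then identical for
both trajectories of the same particle (exactly so at zero noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from cytosim.signal_sim import N_CHANNELS, EventSignal

N_PEAKS = 4
REFERENCE_CHANNEL = 0  # 0.5 MHz amplitude

FEATURE_COLUMNS = (
    "estimated_diameter_um",
    "opacity_1_05",
    "opacity_2_05",
    "opacity_2_1",
    "op_theta_2_05",
)

FEATURES_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Conditioning
# ---------------------------------------------------------------------------

def detrend_and_filter(
    channels: np.ndarray,
    baseline_window: int = 501,
    cutoff: float = 0.5,
) -> np.ndarray:
    """Remove slow baseline and low-pass smooth, with zero phase shift.

    baseline_window: moving-median window (samples), must exceed the event
    duration so the median tracks the baseline, not the events.
    cutoff: low-pass corner as a fraction of Nyquist.
    """
    channels = np.asarray(channels, dtype=float)
    if channels.ndim == 1:
        channels = channels[:, None]
    if baseline_window < 3:
        raise ValueError("baseline_window must be >= 3 samples")
    if not (0 < cutoff < 1):
        raise ValueError("cutoff must be a fraction of Nyquist in (0, 1)")
    # Odd-reflection padding keeps the rolling median unbiased at the
    # stream edges (it extends a linear baseline exactly).
    pad = min(baseline_window // 2, channels.shape[0] - 1)
    padded = np.pad(channels, ((pad, pad), (0, 0)), mode="reflect", reflect_type="odd")
    frame = pd.DataFrame(padded)
    baseline = frame.rolling(baseline_window, center=True, min_periods=1).median().to_numpy()
    cleaned = channels - baseline[pad : pad + channels.shape[0]]
    sos = sps.butter(4, cutoff, output="sos")
    return sps.sosfiltfilt(sos, cleaned, axis=0)


def noise_scale(x: np.ndarray) -> float:
    """Robust noise sigma via the median absolute deviation."""
    x = np.asarray(x, dtype=float)
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def detect_events(
    channels: np.ndarray,
    k: float = 5.0,
    ref_channel: int = REFERENCE_CHANNEL,
    min_width: int = 3,
    merge_gap: int = 60,
    margin: int = 40,
) -> list[tuple[int, int]]:
    """Threshold detection on the reference channel.

    Thresholds |signal| at k times the MAD-based noise scale, discards
    excursions shorter than ``min_width`` samples, merges excursions closer
    than ``merge_gap`` and pads each event with ``margin`` context samples.
    Returns (start, stop) index pairs.
    """
    channels = np.asarray(channels, dtype=float)
    if channels.ndim == 1:
        channels = channels[:, None]
    if channels.shape[0] == 0:
        raise ValueError("empty stream")
    if k < 3:
        raise ValueError("threshold multiplier k must be >= 3")
    ref = channels[:, ref_channel]
    sigma = noise_scale(ref)
    if sigma == 0.0:
        sigma = float(np.std(ref)) or 1e-300
    above = np.abs(ref) > k * sigma
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.r_[idx[0], idx[breaks + 1]]
    run_stops = np.r_[idx[breaks] + 1, idx[-1] + 1]
    runs = [(a, b) for a, b in zip(run_starts, run_stops) if b - a >= min_width]
    if not runs:
        return []
    merged = [list(runs[0])]
    for a, b in runs[1:]:
        if a - merged[-1][1] <= merge_gap:
            merged[-1][1] = b
        else:
            merged.append([a, b])
    n = channels.shape[0]
    return [(max(0, a - margin), min(n, b + margin)) for a, b in merged]


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

@dataclass
class PeakSet:
    """Canonically ordered 4-peak readout of one event.

    Arrays are (n_frequencies, 4): signed amplitudes, phase readings and
    sample indices, ordered in trajectory-normalised time so that the
    "second peak" is the same physical electrode lobe for both
    trajectories.
    """

    indices: np.ndarray
    amplitudes: np.ndarray
    phases: np.ndarray
    trajectory: str
    frequencies: tuple
    valid: bool = True
    reason: str = ""

    @classmethod
    def rejected(cls, reason: str, frequencies=()) -> "PeakSet":
        z = np.zeros((max(len(frequencies), 1), N_PEAKS))
        return cls(indices=z.astype(int), amplitudes=z, phases=z.copy(),
                   trajectory="", frequencies=tuple(frequencies),
                   valid=False, reason=reason)


def _alternating_extrema(x: np.ndarray, rel_prominence: float = 0.25):
    """Locate the four dominant sign-alternating extrema of one channel."""
    scale = float(np.max(np.abs(x)))
    if scale == 0:
        return None
    prominence = rel_prominence * scale
    pos, _ = sps.find_peaks(x, prominence=prominence)
    neg, _ = sps.find_peaks(-x, prominence=prominence)
    idx = np.sort(np.r_[pos, neg])
    if idx.size != N_PEAKS:
        return None
    signs = np.sign(x[idx])
    if np.any(signs[:-1] * signs[1:] >= 0):
        return None
    return idx


def extract_peaks(fragment: EventSignal | np.ndarray, frequencies=None) -> PeakSet:
    """Extract the 4 alternating peaks per frequency from one fragment.

    Fragments without exactly 4 alternating extrema on the reference
    channel (coincident cells, clipped events, noise triggers) are flagged
    as rejected, not silently dropped.
    """
    if isinstance(fragment, EventSignal):
        channels = fragment.channels
        frequencies = fragment.frequencies
    else:
        channels = np.asarray(fragment, dtype=float)
        frequencies = tuple(frequencies or ())
    n_freq = channels.shape[1] // 2
    ref = channels[:, REFERENCE_CHANNEL]
    idx = _alternating_extrema(ref)
    if idx is None:
        return PeakSet.rejected("no 4 alternating extrema on reference channel",
                                frequencies)

    n = channels.shape[0]
    half_gap = max(2, int(np.min(np.diff(idx)) // 3))
    indices = np.empty((n_freq, N_PEAKS), dtype=int)
    amplitudes = np.empty((n_freq, N_PEAKS))
    phases = np.empty((n_freq, N_PEAKS))
    ref_signs = np.sign(ref[idx])
    for fi in range(n_freq):
        amp_ch = channels[:, fi]
        ph_ch = channels[:, n_freq + fi]
        for pi, (i0, s) in enumerate(zip(idx, ref_signs)):
            lo, hi = max(0, i0 - half_gap), min(n, i0 + half_gap + 1)
            local = s * amp_ch[lo:hi]
            j = lo + int(np.argmax(local))
            indices[fi, pi] = j
            amplitudes[fi, pi] = amp_ch[j]
            phases[fi, pi] = ph_ch[j]

    # Trajectory inference from the per-pair lobe weighting: the first
    # half of the peak pattern outweighs the second for T1 and vice versa
    # for T2 (time reversal swaps the halves).
    ref_amp = np.abs(amplitudes[REFERENCE_CHANNEL])
    if ref_amp[0] + ref_amp[1] > ref_amp[2] + ref_amp[3]:
        trajectory = "T1"
    else:
        trajectory = "T2"
        indices = indices[:, ::-1].copy()
        amplitudes = amplitudes[:, ::-1].copy()
        phases = phases[:, ::-1].copy()
    return PeakSet(indices=indices, amplitudes=amplitudes, phases=phases,
                   trajectory=trajectory, frequencies=tuple(frequencies))


# ---------------------------------------------------------------------------
# Calibration and features
# ---------------------------------------------------------------------------

@dataclass
class SizeCalibration:
    """Per-frequency, per-peak line: diameter = a * amplitude^(1/3) + b."""

    slope: np.ndarray  # (n_freq, N_PEAKS), um per amplitude^(1/3)
    intercept: np.ndarray  # um
    r_squared: np.ndarray
    frequencies: tuple

    def diameter(self, amplitude: float, freq_index: int = 0, peak_index: int = 1) -> float:
        a = self.slope[freq_index, peak_index]
        b = self.intercept[freq_index, peak_index]
        return a * abs(amplitude) ** (1.0 / 3.0) + b


def fit_size_calibration(peak_sets, diameters_um) -> SizeCalibration:
    """Least-squares bead calibration of diameter vs amplitude^(1/3)."""
    peak_sets = [p for p in peak_sets]
    diameters_um = np.asarray(diameters_um, dtype=float)
    if len(peak_sets) != diameters_um.size:
        raise ValueError("one diameter per peak set required")
    if np.unique(diameters_um).size < 3:
        raise ValueError("need at least 3 distinct bead sizes")
    if not all(p.valid for p in peak_sets):
        raise ValueError("all peak sets must be valid")
    n_freq = peak_sets[0].amplitudes.shape[0]
    slope = np.empty((n_freq, N_PEAKS))
    intercept = np.empty((n_freq, N_PEAKS))
    r_squared = np.empty((n_freq, N_PEAKS))
    for fi in range(n_freq):
        for pi in range(N_PEAKS):
            x = np.array([abs(p.amplitudes[fi, pi]) for p in peak_sets]) ** (1.0 / 3.0)
            if np.ptp(x) == 0:
                raise ValueError("degenerate amplitudes: no spread to fit")
            a, b = np.polyfit(x, diameters_um, 1)
            pred = a * x + b
            ss_res = float(np.sum((diameters_um - pred) ** 2))
            ss_tot = float(np.sum((diameters_um - diameters_um.mean()) ** 2))
            slope[fi, pi] = a
            intercept[fi, pi] = b
            r_squared[fi, pi] = 1.0 - ss_res / ss_tot
    if np.any(slope[:, 1] <= 0):
        raise ValueError("calibration slope must be positive")
    return SizeCalibration(slope=slope, intercept=intercept, r_squared=r_squared,
                           frequencies=peak_sets[0].frequencies)


@dataclass
class EventFeatures:
    """Second-peak electrical features of one event."""

    estimated_diameter_um: float
    opacity_1_05: float
    opacity_2_05: float
    opacity_2_1: float
    op_theta_2_05: float
    peak_index_used: int = 1
    second_peak_amplitudes: np.ndarray = field(default_factory=lambda: np.zeros(3))
    trajectory: str = ""
    phase_unstable: bool = False
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "estimated_diameter_um": self.estimated_diameter_um,
            "opacity_1_05": self.opacity_1_05,
            "opacity_2_05": self.opacity_2_05,
            "opacity_2_1": self.opacity_2_1,
            "op_theta_2_05": self.op_theta_2_05,
            "trajectory": self.trajectory,
            "phase_unstable": self.phase_unstable,
            "label": self.label,
        }


def compute_features(
    peaks: PeakSet,
    calibration: SizeCalibration,
    peak_index: int = 1,
    label: str = "",
) -> EventFeatures:
    """Diameter + opacity/phase ratios from the (canonical) second peak."""
    if not peaks.valid:
        raise ValueError(f"cannot compute features of a rejected event: {peaks.reason}")
    amp = np.abs(peaks.amplitudes[:, peak_index])
    if amp[0] == 0 or amp[1] == 0:
        raise ValueError("zero low-frequency second-peak amplitude")
    phase_low = peaks.phases[0, peak_index]
    phase_unstable = abs(phase_low) < 1e-3
    op_theta = peaks.phases[2, peak_index] / phase_low if not phase_unstable else np.nan
    return EventFeatures(
        estimated_diameter_um=calibration.diameter(amp[0], 0, peak_index),
        opacity_1_05=amp[1] / amp[0],
        opacity_2_05=amp[2] / amp[0],
        opacity_2_1=amp[2] / amp[1],
        op_theta_2_05=op_theta,
        peak_index_used=peak_index,
        second_peak_amplitudes=amp,
        trajectory=peaks.trajectory,
        phase_unstable=phase_unstable,
        label=label,
    )


def features_table(features) -> pd.DataFrame:
    """Tabulate a collection of EventFeatures (CSV-ready, schema v1)."""
    return pd.DataFrame([f.to_dict() for f in features])


def minimum_detectable_size(
    noise_sd: float,
    calibration: SizeCalibration,
    snr_threshold: float = 3.0,
) -> np.ndarray:
    """Smallest detectable diameter (um) per frequency per peak.

    Inverts the calibration line at amplitude = snr_threshold * noise_sd;
    monotone increasing in noise_sd.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if snr_threshold < 1:
        raise ValueError("snr_threshold must be >= 1")
    d = calibration.slope * (snr_threshold * noise_sd) ** (1.0 / 3.0) + calibration.intercept
    return np.maximum(d, 0.0)


# ---------------------------------------------------------------------------
# Fragments for the classifier
# ---------------------------------------------------------------------------

FRAGMENT_LENGTH = 100


@dataclass
class FragmentTensor:
    """Normalised 100 x 6 classifier input with invertible scales."""

    values: np.ndarray  # (100, 6)
    scales: np.ndarray  # (6,) per-channel divisors actually applied
    normalization: str
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.shape != (FRAGMENT_LENGTH, N_CHANNELS):
            raise ValueError("fragment tensor must be (100, 6)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fragment tensor must be finite")


def resample_fragment(
    fragment: EventSignal | np.ndarray,
    normalization: str = "grouped",
    label: str = "",
) -> FragmentTensor:
    """Resample a fragment to 100 samples per channel and normalise.

    normalization:
      - "grouped" (default): one max-abs scale shared by the three
        amplitude channels and one shared by the three phase channels.
        Preserves cross-frequency amplitude ratios (opacity) and relative
        phases, which carry the dielectric signature.
      - "per_channel": classic independent max-abs per channel.

    Zero channels stay zero; scales are stored so the transform is
    invertible.
    """
    if isinstance(fragment, EventSignal):
        channels = fragment.channels
        meta = dict(fragment.meta)
    else:
        channels = np.asarray(fragment, dtype=float)
        meta = {}
    n = channels.shape[0]
    if n < 20:
        raise ValueError(f"fragment too short to resample ({n} < 20 samples)")
    if channels.shape[1] != N_CHANNELS:
        raise ValueError("fragment must have 6 channels")

    if n == FRAGMENT_LENGTH:
        resampled = channels.astype(float).copy()
    else:
        x_old = np.linspace(0.0, 1.0, n)
        x_new = np.linspace(0.0, 1.0, FRAGMENT_LENGTH)
        resampled = np.column_stack(
            [np.interp(x_new, x_old, channels[:, c]) for c in range(N_CHANNELS)]
        )

    maxabs = np.max(np.abs(resampled), axis=0)
    if normalization == "per_channel":
        scales = np.where(maxabs > 0, maxabs, 1.0)
    elif normalization == "grouped":
        amp_scale = float(np.max(maxabs[:3])) or 1.0
        ph_scale = float(np.max(maxabs[3:])) or 1.0
        scales = np.array([amp_scale] * 3 + [ph_scale] * 3)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    values = resampled / scales
    if not isinstance(label, str):
        label = str(label)
    if not label:
        label = str(meta.get("label", ""))
    return FragmentTensor(values=values, scales=scales,
                          normalization=normalization, label=label, meta=meta)


# ---------------------------------------------------------------------------
# Stream-level processing (shared by the pipeline and dataset builders)
# ---------------------------------------------------------------------------

@dataclass
class ProcessedEvent:
    """One accepted event after the full DSP chain."""

    features: EventFeatures
    fragment: FragmentTensor
    span: tuple[int, int]
    event_index: int | None  # matched ground-truth event, when known


@dataclass
class StreamResult:
    processed: list
    n_detected: int
    rejected_reasons: dict


def build_event_stream(
    events,
    gap_samples: int,
    noise_sd: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[int]]:
    """Concatenate event windows separated by noise-only gaps.

    Returns (stream, centers) where centers[i] is the sample index of the
    i-th event's midpoint in the stream.  Phase channels stay gated (zero)
    in the gaps.
    """
    blocks = []
    centers = []
    cursor = 0
    for ev in events:
        gap = rng.normal(0.0, noise_sd, size=(gap_samples, N_CHANNELS))
        gap[:, 3:] = 0.0
        blocks.append(gap)
        cursor += gap_samples
        centers.append(cursor + ev.n_samples // 2)
        blocks.append(ev.channels)
        cursor += ev.n_samples
    tail = rng.normal(0.0, noise_sd, size=(gap_samples, N_CHANNELS))
    tail[:, 3:] = 0.0
    blocks.append(tail)
    return np.vstack(blocks), centers


def canonical_window(
    peaks: PeakSet, n_samples: int, offset: int = 0, factor: float = 1.8
) -> tuple[int, int]:
    """Fixed-geometry fragment window centred on the four peaks.

    Spans ``factor`` times the outer-peak separation, which for the default
    electrode geometry matches the kernel support; makes classifier
    fragments independent of where the detector placed its threshold
    crossings.
    """
    idx = peaks.indices[REFERENCE_CHANNEL]
    lo, hi = int(idx.min()), int(idx.max())
    center = (lo + hi) / 2.0
    half = factor * (hi - lo) / 2.0
    a = max(0, int(round(center - half)))
    b = min(n_samples, int(round(center + half)) + 1)
    return a + offset, b + offset


def process_event_stream(
    events,
    calibration: SizeCalibration,
    noise_sd: float,
    rng: np.random.Generator,
    gap_samples: int = 200,
    k: float = 5.0,
    normalization: str = "grouped",
    detrend_cutoff: float = 0.8,
) -> StreamResult:
    """Full chain on a batch of simulated events.

    Builds a continuous noisy stream, detrends/filters, detects events,
    extracts peaks, computes features, and cuts classifier fragments
    through one canonical window — the same path for training datasets and
    for pipeline runs, so the two cannot drift apart.
    """
    if not events:
        return StreamResult(processed=[], n_detected=0, rejected_reasons={})
    stream, centers = build_event_stream(events, gap_samples, noise_sd, rng)
    event_len = events[0].n_samples
    window = 2 * (event_len + gap_samples) + 1
    cleaned = detrend_and_filter(stream, baseline_window=window, cutoff=detrend_cutoff)
    spans = detect_events(cleaned, k=k)
    centers_arr = np.asarray(centers)

    processed: list[ProcessedEvent] = []
    rejected: dict[str, int] = {}

    def _reject(reason: str) -> None:
        rejected[reason] = rejected.get(reason, 0) + 1

    for a, b in spans:
        peaks = extract_peaks(cleaned[a:b], frequencies=events[0].frequencies)
        if not peaks.valid:
            _reject(peaks.reason or "rejected")
            continue
        try:
            feats = compute_features(peaks, calibration)
        except ValueError as exc:
            _reject(str(exc))
            continue
        wa, wb = canonical_window(peaks, cleaned.shape[0] - a, offset=a)
        if wb - wa < 20:
            _reject("canonical window too short")
            continue
        # match the detection back to its ground-truth event, if any
        mid = (a + b) / 2.0
        j = int(np.argmin(np.abs(centers_arr - mid)))
        matched = j if abs(centers_arr[j] - mid) < event_len else None
        label = str(events[matched].meta.get("label", "")) if matched is not None else ""
        feats.label = label
        try:
            frag = resample_fragment(cleaned[wa:wb], normalization=normalization,
                                     label=label)
        except ValueError as exc:
            _reject(str(exc))
            continue
        if matched is not None:
            frag.meta.update(events[matched].meta)
        processed.append(ProcessedEvent(features=feats, fragment=frag,
                                        span=(a, b), event_index=matched))
    return StreamResult(processed=processed, n_detected=len(spans),
                        rejected_reasons=rejected)


def feature_correlation_matrix(features) -> tuple[pd.DataFrame, list[str]]:
    """Pearson correlations across the five electrical features.

    Returns (matrix, flagged) where ``flagged`` lists constant feature
    columns whose correlations are undefined (NaN in the matrix).
    """
    if isinstance(features, pd.DataFrame):
        frame = features.loc[:, list(FEATURE_COLUMNS)]
    else:
        frame = features_table(features).loc[:, list(FEATURE_COLUMNS)]
    if len(frame) < 3:
        raise ValueError("need at least 3 events")
    values = frame.to_numpy(dtype=float)
    flagged = [c for c, s in zip(FEATURE_COLUMNS, values.std(axis=0)) if s == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    for i, c in enumerate(FEATURE_COLUMNS):
        if c not in flagged:
            corr[i, i] = 1.0
    return pd.DataFrame(corr, index=FEATURE_COLUMNS, columns=FEATURE_COLUMNS), flagged
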