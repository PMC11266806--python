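# cytosim

A virtual multi-frequency impedance-cytometry instrument for label-free
rare-cell (CTC) detection, implemented end to end in scientific Python:

- **`cytosim.dielectrics`** — analytic single-shell dielectric model of cells
  (cytoplasm core + thin membrane shell), homogeneous beads, and the complex
  Clausius–Mossotti (CM) factor that sets signal amplitude and phase at each
  excitation frequency. Material presets live in an editable YAML table
  (`src/cytosim/data/presets.yaml`); they are documented stand-ins, not
  measured constants.
- **`cytosim.signal_sim`** — forward simulation of a cell transiting four
  pairs of face-to-face electrodes wired in a two-current differential
  scheme. Clean events show exactly four sign-alternating peaks per
  amplitude channel; the two focusing trajectories produce centrally
  symmetric signals. Six channels per event: amplitude + phase at 0.5, 1 and
  2 MHz (3.3 V excitation, 10³ V/A trans-impedance gain, 115 kSa/s per
  channel). A carrier-level lock-in path (mixer + low-pass at 1 % relative
  bandwidth, scaled-down carriers) validates the demodulation chain against
  the baseband model.
- **`cytosim.dsp`** — detrend (moving median) + zero-phase low-pass, robust
  (MAD-scaled) threshold event detection, four-peak extraction with
  trajectory canonicalisation, second-peak features (electrical diameter via
  bead calibration, Opacity ratios, phase ratio OpΘ), minimum-detectable-size
  estimation, feature correlation matrices, and 100 × 6 classifier
  fragments.
- **`cytosim.cytonet`** — the 1-D CNN cell classifier: 4 Conv1D layers,
  3 max-pool layers, squeeze-excitation channel attention before global
  average pooling, and a 2-class softmax head. Forward *and* backward passes
  are written directly on NumPy (no DL framework needed); training uses Adam
  with a stratified 7:3 split. A transparent rectangular-gate baseline on
  (diameter, opacity) provides the comparison arm.
- **`cytosim.virtual_lab`** — synthetic populations (truncated-normal sizes,
  preset dielectrics, trajectory assignment), phenomenological sorting
  stages (logistic capture curves calibrated to ~98 % WBC depletion and
  ~90 % tumor recovery in the separation stage), and spike-in scenarios
  (e.g. 10²–10³ tumor cells in 20 ml of 5 × 10⁵ WBC/ml background, with
  recorded subsampling factors).
- **`cytosim.hydraulics`** — laminar rectangular/trapezoidal channel
  resistance (series solution) and exact flow-divider arithmetic (a
  resistance ratio of 2.0 splits 3 ml/min into 1 ml/min; a trifurcation with
  ratio 1.10 sends 312.5 µl/min of 1000 µl/min through the centre).
- **`cytosim.pipeline`** — orchestration: virtual sample → sorting chain →
  signal simulation → DSP → classification → counting and a threshold-based
  diagnosis flag. Fully deterministic under one master seed; exports a
  schema-versioned `report.json`, a features CSV, and a run log.

## Tests

```sh
python -m pytest -q tests/
```

The suite (~170 tests, ≈1–2 min on one CPU) includes property tests
(CM-factor bounds, conservation, determinism), independent oracles (literal
shelled-sphere transcription, 50-term duct series, numerical gradient checks
of the CNN backprop, binomial tail bounds), and `tests/test_acceptance.py`
with one test per acceptance criterion (the classifier criterion trains on
20,000 synthetic fragments and takes most of the runtime).

## CLI

```sh
cytosim show-config                      # default pipeline config (YAML)
cytosim simulate --preset MCF-7 --count 100 --seed 1 --out events.h5
cytosim process  --events events.h5 --out features.csv
cytosim train    --seed 1 --n-per-class 1000 --out model.npz --curves curves.csv
cytosim classify --model model.npz --events events.h5
cytosim sort     --seed 1                # sorting-stage reports
cytosim report   --seed 1 --outdir out/  # full pipeline run
cytosim hydraulics --inlet-ul-min 1000 --resistance 1.10 --resistance 1 --resistance 1
```

`report`, `simulate` and `sort` accept `--config run.yaml` with the same
keys printed by `show-config`.

## File formats

- **Event container** (HDF5, schema v1): `/events/<i>/channels` — an
  (n × 6) float array per event; channel order
  `amp_0.5MHz, amp_1MHz, amp_2MHz, phase_0.5MHz, phase_1MHz, phase_2MHz`;
  sample rate, frequencies and metadata (label, trajectory, diameter, seed)
  as attributes.
- **Features CSV**: `estimated_diameter_um, opacity_1_05, opacity_2_05,
  opacity_2_1, op_theta_2_05, trajectory, phase_unstable, label`.
- **Report JSON** (schema v1): counts (detected/accepted/rejected,
  predicted WBC/CTC, sorting conservation), diagnosis flag + thresholds,
  per-stage sorting reports, master seed, software version.
- **Model checkpoint** (`.npz`): weights plus an embedded JSON header with
  the architecture spec and schema version.

## Notes

- Classifier fragments default to *grouped* normalisation (one max-abs scale
  shared by the amplitude channels, one by the phase channels) so the
  cross-frequency opacity and phase signatures survive; classic per-channel
  max-abs is available as `normalization="per_channel"`. Scales are stored,
  so both transforms are invertible.
- Training datasets and pipeline inputs are produced by the same
  stream-level processing chain (`dsp.process_event_stream`), which keeps
  the classifier's training and deployment distributions identical.
- The microfluidic separation physics is deliberately *not* simulated; the
  sorting stages are calibrated logistic stand-ins, and the dielectric
  presets are editable placeholders chosen to reproduce qualitative
  orderings (tumor cells larger, tumor opacity lower than WBC opacity).
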