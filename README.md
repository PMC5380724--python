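# meghubs

Whole-brain connectivity and graph analysis of MEG source estimates,
built as a fully synthetic, ground-truth-validated pipeline.

Task-based MEG studies of expressive language map the cortical network
with a chain of standard but delicate steps: epoched sensor data are
cleaned, projected into source space with a linearly constrained
minimum-variance (LCMV) beamformer, band power in the active window is
contrasted against a pre-stimulus baseline to map event-related
desynchrony (ERD), voxel-pair phase-locking values (PLV) quantify
task-related coupling, and graph centralities over the thresholded
adjacency identify network hubs and their hemispheric lateralization.
Every one of those steps can fail silently. `meghubs` implements the
complete chain together with a synthetic-data generator whose ground
truth — active sources, coupling topology, hub placement, hemispheric
asymmetry — is known by construction, so each stage and the end-to-end
pipeline are validated by recovery of planted effects rather than by
eyeballing maps.

The core quantities:

* **LCMV beamformer** — per voxel, the spatial filter
  `w = C⁻¹l / (lᵀC⁻¹l)` passes the source with unit gain while
  minimizing output variance; `C` is the "common filter" covariance
  pooled over baseline and active windows, regularized by
  `0.001 · mean(diag C) · I`.
* **ERD map** — `(P_active − P_baseline)/P_baseline` of 13–23 Hz band
  power per voxel, tested with a trial-level sign-flip permutation test
  (add-one p-values) and Benjamini–Hochberg FDR at q = 0.05.
* **PLV** — `PLV(ω) = |⟨exp(j(φ_a(ω) − φ_b(ω)))⟩_trials|` from
  Hann-tapered window DFT phases, averaged over 5–30 Hz bins; the
  adjacency is active-minus-baseline PLV.
* **Hubs and laterality** — degree, eigenvector centrality (EVC) and
  betweenness on the graph binarized at 70 % of maximum positive
  strength; parcel means over a mirrored synthetic atlas; laterality
  index `LI = (L − R)/(L + R)` of frontotemporal EVC with ±0.25
  cutoffs.

## Worked example

```python
from meghubs.io import SubjectData
from meghubs.pipeline import PipelineConfig, run_subject
from meghubs.scenarios import build_hub_scenario
from meghubs.studies import desk_forward_model
from meghubs.synthetic import (draw_tangential_orientations,
                               project_and_add_noise, simulate_trial_sources)

setup = desk_forward_model(seed=2)            # 120 sensors, 256 voxels, 12 parcels
scenario, truth = build_hub_scenario(setup.grid, setup.atlas, "L", seed=0)
src = simulate_trial_sources(scenario, setup.grid)
ori = draw_tangential_orientations(setup.grid, setup.head, seed=0)
ep = project_and_add_noise(src, setup.leadfield, ori, scenario.noise_sd,
                           7, scenario.sfreq, scenario.times())
data = SubjectData(epochs=ep, head=setup.head, grid=setup.grid,
                   leadfield=setup.leadfield, source_orientations=ori,
                   atlas=setup.atlas)
result = run_subject(PipelineConfig(n_rand=500), data)
parc = result.parcels
print("hub parcel:", truth.hub_parcel,
      "max-EVC parcel:", int(parc.loc[parc['evc'].idxmax(), 'parcel']))
print(f"LI = {result.laterality.li:.2f} ({result.laterality.category})")
```

prints

```
hub parcel: 3 max-EVC parcel: 3
LI = 1.00 (left)
```

— the parcel holding the planted hub attains the maximum parcel-level
EVC, and with all planted coupling in the left hemisphere the EVC-based
laterality index classifies the subject as left-dominant.

The numbered drivers under `analysis/` run the validation studies and
write their tables to `results/`:

```
python analysis/01_simulate_forward_model.py   # geometry + radial-silence check
python analysis/02_beamformer_localization.py  # median error 0.0 mm over 20 runs
python analysis/03_erd_inference.py            # planted −50 % power drop recovered
                                               # (−51/−45/−44 %), all significant;
                                               # null type-I error 0.051 at α = 0.05
python analysis/04_hub_recovery.py             # hub parcel wins EVC in 10/10 runs
python analysis/05_group_laterality.py         # left- vs right-dominant cohorts
```

A `meghubs` command-line interface mirrors the pipeline stages
(`simulate`, `preprocess`, `invert`, `connect`, `network`, `run-all`,
`group`) over HDF5/TSV artifacts; `meghubs --help` lists the verbs.

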