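# pgesdetect

Detection of the end of **postictal generalized EEG suppression (PGES)**
in multi-channel scalp EEG, for clinical neurophysiology researchers
studying SUDEP risk after generalized tonic-clonic seizures.

PGES is a diffuse attenuation of the EEG background below 10 μV that can
follow a convulsive seizure; prolonged suppression (> 50 s) is a reported
risk marker for sudden unexpected death in epilepsy, which makes the
*duration* of suppression — equivalently, the time of the first
**intermittent slow wave (ISW)**, the 0.5–5 Hz burst that announces the
return of cerebral activity — the clinically relevant quantity.  Reading
it off automatically is hard because breathing, muscle and movement
artifacts put high-amplitude energy into exactly the low-frequency band
where ISWs live.

`pgesdetect` implements a hybrid unsupervised/supervised detector:

1. **Features.** Each 1-second epoch of the 18-channel bipolar montage
   (Fp1-F7 … Cz-Pz, 200 Hz) is described by time-domain statistics and
   Hjorth parameters, low-band spectral powers, wavelet energies and
   inter-channel correlations (on the 0.5–5 Hz filtered signal), plus an
   empirical-mode-decomposition feature: the summed amplitude of the
   Hilbert spectrum of the epoch (on the 0.5–30 Hz signal).  EMD writes
   the signal as x(t) = Σᵢ IMFᵢ(t) + r_N(t) via envelope-mean sifting.
2. **Clustering.** A whole-recording *artifact feature map* — the
   channel × seconds distribution of 0.5–5 Hz Hilbert amplitude — feeds
   a K-means model that groups recordings with similar spatiotemporal
   artifact patterns.
3. **Classification.** One sample-weighted random forest (SWRF) per
   cluster: forest *i* trains on all epochs but up-weights (boost ×)
   epochs from recordings in cluster *i*.  An unseen recording routes to
   its nearest cluster's forest, per-epoch suppression/ISW labels are
   cleaned by confidence-based correction, and the predicted PGES end
   P_end is the start of the first non-suppression epoch after
   suppression.
4. **Evaluation** is recording-based: TD_r = |P_end − T_end| per
   recording, aggregated as TD_avg and the tolerance accuracies
   Acc_5s = |{r : TD_r ≤ 5 s}| / n and Acc_10s (≤ 10 s), under
   leave-one-out cross-validation.

The clinical datasets this method targets are not publicly available, so
the package ships a synthetic-data module that generates postictal
recordings with exact ground truth — suppression below the 10 μV
criterion, ISW resumption at a known time, and configurable
breathing/muscle/movement artifact archetypes — on which every stage is
validated.

## Worked example

```python
import pgesdetect as pg

# 12 synthetic postictal recordings, two artifact populations
arch = [
    pg.ArtifactArchetype("front", tuple(range(8)),
                         pg.boxcar_envelope(5, 40, 300.0, 60), "movement"),
    pg.ArtifactArchetype("back", tuple(range(8, 16)),
                         pg.boxcar_envelope(5, 40, 300.0, 60), "movement"),
]
ds = pg.simulate_dataset(
    12, arch, seed=5, base_params=pg.SimulationParams(duration=60.0),
    pges_sampler=lambda rng: float(rng.uniform(10, 45)),
)

report = pg.loo_cv(ds, pg.LOOConfig(K=2, boost=2.0,
                                    rf_params=pg.RFParams(n_trees=50)))
print(f"n={report.n}  TD_avg={report.TD_avg:.2f}s  "
      f"median={report.median_TD:.2f}s  Acc_5s={report.Acc_5s:.2f}  "
      f"Acc_10s={report.Acc_10s:.2f}")
```

prints

```
n=12  TD_avg=0.23s  median=0.21s  Acc_5s=1.00  Acc_10s=1.00
```

i.e. on these recordings every predicted first-ISW time lands within 5 s
of the true transition, with a mean error around a quarter second (the
epoch grid quantizes predictions to whole seconds, so sub-second truth
times always incur a fraction-of-a-second distance).

The same pipeline is available from the shell:

```bash
pgesdetect simulate --n 20 --duration 300 --seed 1 --out data/
pgesdetect evaluate --edf-dir data --annotations data/annotations.csv \
                    --out results/ --loo --k 7 --boost 2
pgesdetect detect --edf data/sim000.edf --model-dir trained/ --out pred.json
```

`simulate` writes EDF files, an annotation CSV and a ground-truth JSON;
`evaluate` writes `report.json` / `report.csv` and a manifest with the
config hash and seed.

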