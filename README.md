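# swrkit

Analysis pipeline for a central question in hippocampal physiology: does
transient inhibition arriving *just before* a sharp-wave ripple (SWR) set
the timing of CA1 pyramidal-cell spikes and depolarizations *during* the
event? The package provides, as reusable and tested components, every
computational stage that question requires:

* **SWR detection** from LFP — a patch-session detector (3 × SD envelope
  threshold on the 100–250 Hz band) and a silicon-probe detector
  (normalized squared 130–200 Hz signal, 5-SD peaks, 2-SD boundaries,
  20–200 ms duration limits, noise-channel exclusion), plus programmatic
  event QC.
* **Intracellular ΔVm analysis** — spike detection and truncation (4 V/s
  edge, linear interpolation), the pre-SWR membrane-potential change
  ΔVm_pre (mean Vm ±25 ms around the minimum within 50 ms before onset,
  minus the 2–1 s baseline), depolarization peak times, SWR-triggered
  averages, EPSG/IPSG conductance conversion, pairwise ΔVm_pre
  correlations, and a within-SWR rank permutation test for cell triplets.
* **Quintile / latency statistics** — pre-SWR interneuron identification
  from peri-event histograms, single-SWR rate estimates (15-ms-FWHM
  Gaussian kernel, 30-ms pre-onset window), quintile grouping
  (Q1 = highest inhibition), first-spike latency and rank order, and a
  500-shuffle significance test for the Q1−Q5 latency difference.
* **Poisson HMM** over 15-ms-binned within-SWR spike counts
  (`P(D, S | π, A, Λ)` with independent Poisson emissions per neuron and
  state): exact forward–backward likelihoods, EM fitting, and the
  cross-quintile sequence-similarity test `LL(Q_test) − LL(Q_train)`
  against shuffled regroupings.
* **Poisson mixture** over per-SWR interneuron spike counts
  (`P(D|Θ) = Π_i Σ_j π_j P(y⁽ⁱ⁾|λ_j)`): EM fitting, 20-fold
  cross-validated deviance, curvature-based selection of the ensemble
  number, a surrogate (column-permutation) co-firing test, and Z-scored
  ensemble profiles.
* **Synthetic generators** (`swrkit.synth`) producing every input with
  known ground truth — ripple-band bursts on noise, Vm traces with
  controlled pre-SWR hyperpolarizations coupled to depolarization timing,
  interneuron/pyramidal spike trains with rate-dependent latencies, and
  exact generative twins of both latent-variable models — so the full
  pipeline is testable without any recording.

See `docs/methods.md` for the models, conventions, defaults and known
limitations.

## Worked example

Generate a session with 20 ripple bursts, detect them, and test an
injected inhibition→latency coupling:

```python
import numpy as np
from swrkit import synth, detect, latency, io

# LFP with 20 known bursts at 10x noise SD
lfp, truth = synth.gen_lfp(n_swr=20, burst_snr=10.0, seed=1)
events = detect.detect_swr_probe(lfp)
err_ms = 1000 * np.array([(events["onset_s"] - t).abs().min()
                          for t in truth["onset_s"]])
print(f"{len(events)} events detected, "
      f"mean onset error {err_ms.mean():.1f} ms")

# spike trains in which higher pre-SWR interneuron rates delay the
# paired pyramidal cell's first spike
onsets = 2.0 + np.arange(300.0)
swrs = io.make_event_table(onsets, onsets + 0.04, onsets + 0.08)
cfg = synth.UnitGenConfig(n_swr=300, latency_slope_ms_per_hz=0.25, seed=3)
spikes, _ = synth.gen_unit_spikes(cfg, swrs)

t_int = spikes.loc[spikes.cell_id == "int000", "spike_time_s"].to_numpy()
rates = latency.pre_swr_rates(t_int, onsets)
quintiles = latency.assign_quintiles(rates)
lat = latency.spike_latency_and_rank(spikes, swrs)
per_swr = (lat[lat.cell_id == "pyr000"].set_index("swr_id")["latency_ms"]
           .reindex(swrs["event_id"]).to_numpy())
res = latency.quintile_latency_test(per_swr, quintiles, seed=0)
print(f"Q1 - Q5 latency difference: {res.delta_ms:.1f} ms, "
      f"significant: {res.significant} (p = {res.p_two_sided:.3f})")
```

Output:

```
20 events detected, mean onset error 4.4 ms
Q1 - Q5 latency difference: 10.4 ms, significant: True (p = 0.004)
```

The detector recovers every burst with a few milliseconds of onset error,
and the shuffle test flags the injected ~10-ms spike-latency delay under
high pre-SWR inhibition — the effect signature the pipeline is built to
measure.

The same stages are available from the shell:

```bash
ripple simulate --kind lfp --seed 1 --out sim/
ripple detect-swr --mode probe --in sim/lfp.f32 --out swr.csv
ripple quintile --spikes spikes.csv --swr swr.csv --seed 1 --out q.json
ripple ensembles --counts counts.csv --mgrid 2:30 --seed 1 --out ens.json
```

Every CLI run writes a `*.provenance.json` record (parameters, seed,
input hashes).

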