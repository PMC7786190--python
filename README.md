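# sugarshock

Stochastic kinetic modeling of the *E. coli* SgrS small-RNA response to
glucose-phosphate stress ("sugar shock"), for systems biologists who want to
connect single-cell smFISH RNA-count snapshots to an explicit chemical
master equation of sRNA silencing.

Under stress, the transcription factor SgrR switches *sgrS* gene copies ON;
the sRNA SgrS is stabilized by the chaperone Hfq, and the Hfq–SgrS complex
anneals to *ptsG* mRNA, whose co-degradation by RNase E shuts down glucose
import. The package implements this circuit as an 11-channel mass-action
network over 8 species (gene copies are species, so gene-dosage
heterogeneity of fast-growing cells — 2/4 copies of *sgrS*, 1/2 of *ptsG* —
is sampled per cell), simulates it exactly with the Gillespie direct method,
and compares simulated populations to per-cell count snapshots via Gaussian
KDEs and the Kullback–Leibler divergence

```
D_KL(P ‖ Q) = Σ_i P(i) ln P(i)/Q(i),      η = |Exp_avg − Sim_avg| / Exp_avg
```

with `P` the reference (experimental) KDE and `Q` the simulated one.
Free parameters are fitted by minimizing the KL divergence summed over
timepoints and species (Nelder–Mead with common random numbers), and a
model-complexity ladder (baseline → gene duplication → + transcriptional
regulation → + explicit Hfq) quantifies what each mechanism buys. A
synthetic snapshot generator reproduces the statistical structure of
smFISH-STORM experiments (85–200 cells per timepoint at 0–20 min
post-induction) so the entire analysis runs without external data.

## Worked example

```python
import numpy as np
import sugarshock as ss

ens = ss.run_ensemble(ss.WT, "FULL", n_replicates=1000, base_seed=1)
total_sgrs, total_ptsg = ens.totals()
print("minutes:   ", ens.schedule_min)
print("mean SgrS: ", np.round(total_sgrs.mean(axis=0), 1))
print("mean ptsG: ", np.round(total_ptsg.mean(axis=0), 1))
```

prints

```
minutes:    [ 0.  2.  4.  6.  8. 10. 15. 20.]
mean SgrS:  [  2.  34.9  58.8  77.1  90.9 101.6 117.  122.5]
mean ptsG:  [35.  32.3 21.5 15.5 12.3 10.9  9.3  8.8]
```

i.e. upon induction SgrS climbs from a basal 1–3 copies to tens of copies
within minutes while *ptsG* mRNA is silenced from its pre-stress mean of 35
down to under 10 copies per cell. The pseudo-first-order Hfq binding rate
converts to a bulk constant

```python
ss.pseudo_to_second_order(0.063, pool=250, volume=1e-15)  # → 1.52e5 M^-1 s^-1
```

and a synthetic rifampicin chase refits its generating decay rate:

```python
ds = ss.generate_chase_dataset(0.0037, n_cells=500, schedule_min=(0,2,4,6,8,10,15,20), seed=7)
ss.chase_decay_fit(ds).rate  # → 0.00364 s^-1
```

A CLI wraps the same stages:

```sh
sugarshock synth --out out/            # synthetic smFISH-style dataset
sugarshock simulate --n 2000 --out out/
sugarshock stats ref.csv sim.csv --out out/
sugarshock fit ref.csv --free k_bind --out out/
sugarshock variants ref.csv --out out/
sugarshock chase --rate 0.0037 --out out/
```

Every run writes its fully resolved configuration next to its outputs;
re-running from that file reproduces the outputs bit-exactly.

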