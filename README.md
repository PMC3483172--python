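# valveform

Single-cell kinetics, dye-partitioning modelling and valve morphometry of
silicon biomineralization in the centric diatom *Thalassiosira weissflogii*.

Diatoms build their silica cell wall (the frustule) inside an acidic
organelle, the silica deposition vesicle (SDV). Because the acid–base
balance drives both silica polycondensation and the accumulation of the
weak-base reporter dyes used to watch it, the external pH (pHe) leaves
fingerprints at every scale: population growth rate, per-cell silicon
quotas, intracellular pH (pHi), the speed of valve formation in single
cells, and the nanometric pore pattern of the finished valve. `valveform`
implements the full analysis chain for such experiments, plus synthetic-data
generators with ground truth so every stage can be validated end to end.

## What it computes

**Single-cell valve-formation kinetics.** Fluorescent weak-base dyes
(HCK-123, a LysoTracker-family probe) accumulate in the acidic SDV and are
entrapped in newly formed silica. A per-cell background-corrected trace
F(t) shows an exponential accumulation phase,

    F(t) = F0 · e^(k·t),   0 ≤ t ≤ t_Exp,

ending at a maximum F1, followed in ~75% of cells by a decay phase of
duration t_Dec ending at a minimum F2. The package detects and tracks
cells in time-lapse stacks (greedy nearest-neighbour linking with bulk-flow
compensation), extracts each cell's boundary as the iso-intensity level
line of sharpest contrast — giving the area A(L), width W(L) and biovolume
A(L)·W(L) — integrates the fluorescence over the local background,
segments the two phases, and fits k and F0 by log-linear regression.
Cells are kept only if the fit correlation exceeds r = 0.95 and at least
45 min of data precede F1. Across pHe treatments the package fits the
exponential pH response y = a·e^(b·pHe) of k and of the phase amplitudes
F1−F0 and F1−F2.

**Three-fraction SDV model.** Total dye in the SDV is
F_total = F_free + F_bound + F_fixed: the freely diffusing neutral form,
the protonation-trapped form (enrichment
(1 + 10^(pKa−pH_SDV))/(1 + 10^(pKa−pH_out)) for a monoprotic weak base),
and the fraction irreversibly entrapped in silica
(d(F_fixed·V)/dt = κ·F_bound·V; no dissolution). In the
protonation-dominated regime a ΔpH shift of the SDV changes the
accumulated dye 10^ΔpH-fold, which converts measured fold-changes into
intra-SDV pH shifts.

**Valve morphometry.** TEM images of purified valves are denoised,
binarized (Otsu), and the circular pores detected and filtered by
circularity. The Delaunay triangulation (dual of the Voronoi diagram)
defines pore adjacency: d1 is the distance between adjacent pores, the
pores cluster into radial "fingers" whose width is the cribrum width D,
separated by ribs of width d2, and porosity r = Σ πR²/A. With manual
macro-annotations the full nine-trait record (valve width W, fultoportula
count N and spacing cp, rimoportula spacing rp, R, d1, D, d2, r) is
exported per image.

**Population physiology.** Exponential growth rates µ (doubling time
ln 2/µ), silicon quotas in pmol cell⁻¹, the silicon incorporation rate
BSi/µ, and the BCECF dual-excitation (485/436) ratiometric pHi
calibration (four-parameter logistic with linear fallback).

## Worked example

```python
import numpy as np
from valveform import synthetic as syn, kinetics as kin
from valveform.imaging import FluorescenceTrace

times = np.arange(0, 155, 5.0)                      # 5-min sampling
params = syn.KineticParams(k=0.013, F0=200.0, t_peak=90.0, t_dec=47.0)
signal = syn.simulate_trace(params, times)
sigma = syn.trace_noise_sigma(signal.max(), cell_radius_px=6.0, pixel_snr=10.0)
noisy = signal + np.random.default_rng(1).normal(0, sigma, signal.shape)

trace = FluorescenceTrace(0, times, np.clip(noisy, 1e-6, None),
                          np.zeros(len(times), bool))
fit = kin.ExponentialPhaseModel(trace).fit()
print(fit.summary())
```

```
Valve-formation kinetics (exponential-phase log-linear fit)
============================================================
cell id          0
k  [1/min]       0.01287  (se 0.00010)
F0               201.6
F1               639.7
F2               344.3
t_Exp [min]      90.0
t_Dec [min]      42.4
fit r            0.9994
accepted         True  (r > 0.95, >= 45 min pre-F1)
```

The fitted slope k = 0.0129 min⁻¹ and landmarks t_Exp = 90 min,
t_Dec ≈ 42 min recover the generating parameters (k = 0.013, t_Dec = 47)
within the single-trace noise; `accepted` applies the
population inclusion rules. Feeding per-cell fits from several pHe
treatments to `kinetics.PHResponseModel` yields the exponent b of the pH
response and the implied fold change over the fitted pH domain.

A shell-level tour of the same machinery:

```bash
valveform synth timelapse --seed 1 --out demo/   # stack + ground truth
valveform run-all --seed 2 --out demo/           # synthesize + analyze a cohort
```

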