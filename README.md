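# porekit

Analysis toolkit for the quantitative phenotypes of pore-forming cation
channels at the plasma membrane — the kind of workup used to characterize
APOL1 renal-risk-variant channels: planar-bilayer permeability ratios,
single-cell Ca²⁺/membrane-voltage fluorescence kinetics, high-throughput
surface-staining quantification, and cytotoxicity plate normalization.  A
synthetic-data layer generates every input class with known ground truth, so
the whole pipeline is testable without microscope or amplifier output.

## Who it is for

Researchers quantifying channel phenotypes across four assay families:

- **Bilayer electrophysiology** (`porekit.ephys`): current–voltage records
  from planar bilayers, with the voltage reported cis (protein-addition
  side) relative to trans.
- **Live-cell sensor kinetics** (`porekit.traces`): per-cell multi-channel
  intensity tracks (Ca²⁺ indicator, voltage sensor, membrane-integrity dye).
- **Fixed-timepoint surface staining** (`porekit.imaging`): registered
  multi-channel fields (nuclei / calnexin / channel protein).
- **Cytotoxicity plates** (`porekit.cytotox`): dual-channel or LDH-only well
  tables with minimum/maximum-death controls.

## The core quantities

**Reversal potential and permeability.** For a bi-ionic bath (cation X cis,
cation Y trans, zero anion permeability), the Goldman–Hodgkin–Katz relation

&nbsp;&nbsp;&nbsp;&nbsp;E_rev = (RT/F) · ln( p_Y a_Y,trans / (p_X a_X,cis) )

is solved for p_X/p_Y from the measured E_rev (the voltage that zeroes the
current, fitted here as the zero-crossing of a linear I–V regression).  For
a divalent over a monovalent in excess (Ca²⁺ in 150 mM K⁺), the Lewis
relation

&nbsp;&nbsp;&nbsp;&nbsp;ΔE_rev = (RT/2F) · ln(1 + (p_Ca/p_K) · 4[Ca²⁺]/[K⁺])

links the E_rev shift on Ca²⁺ addition to p_Ca/p_K; both directions are
implemented as exact algebraic inverses.  Activities use the Davies
equation, or explicit coefficients.

**Sensor kinetics.** Per cell, ΔF/F₀ = (F_t − F₀)/F₀ with F₀ the mean of
the first three recorded frames.  Influx onset is the first frame where
ΔF/F₀ exceeds a robust baseline band (median + k·MAD) for a minimum run of
frames; lysis is a persistent step in the membrane-impermeant dye channel;
the Ca²⁺→depolarization lag is the difference of the two channel onsets.

**Surface staining.** Nuclei are segmented (Otsu + distance watershed),
dilated into cell proxies (nearest-nucleus assignment), permeabilized cells
excluded by their summed surface-calnexin signal, and the channel-protein
stain summed per cell.  A cell is surface-positive if its sum exceeds the
maximum per-cell sum in untransfected control fields; condition metrics are
normalized to the no-trigger reference.

**Cytotoxicity.** Per well R = cytotoxicity/viability (or raw LDH signal);
percent death = 100·(R − R̄_min)/(R̄_max − R̄_min) from the plate's min/max
death controls.  Rescue = 100·(1 − death_treated/death_baseline).
Benjamini–Hochberg FDR adjustment is included for imaging comparisons.

## Worked example

```bash
python examples/bilayer_permeability.py
```

prints

```
fitted E_rev = -5.99 mV (truth -6.00), G = 1.801 nS, rmse = 0.18 pA
conductance fold-change on neutralization: 456x (programmed 450x)
pNa/pK from E_rev = -2 mV:        1.081 (~1.1)
pcholine/pK from E_rev = +60 mV:  0.097 (~0.1)
ideal Ca2+ Nernst potential for a 1.95-fold gradient: -8.5 mV
Lewis: pCa/pK = 0.6 at 2 mM Ca / 150 mM K -> |dE_rev| = 0.401 mV; inverting recovers pCa/pK = 0.600
```

The simulated channel inserts at acidic pH with a minor conductance and
opens ~450-fold on neutralization; the fitted E_rev lands on the programmed
−6 mV.  A −2 mV bi-ionic reversal against equimolar K⁺ means Na⁺ is passed
slightly *better* than K⁺ (ratio ≈ 1.1), while +60 mV means choline⁺ is
passed an order of magnitude *worse* (ratio ≈ 0.1).  The Lewis forward and
inverse calls round-trip exactly.

The other examples cover trace kinetics (`examples/calcium_traces.py`),
the surface-staining series (`examples/surface_staining.py`) and plate
normalization (`examples/cytotox_plate.py`).

## Layout

```
src/porekit/
  ephys.py        bilayer biophysics (GHK, Nernst, Lewis, I-V fitting)
  traces.py       ∆F/F₀, onset/lysis detection, QC, population summaries
  imaging.py      surface-staining segmentation and quantification
  tracking.py     LoG spot detection + mutual-nearest-neighbour linking
  cytotox.py      plate normalization, rescue, BH adjustment
  io.py           CSV / multi-channel TIFF round-trips
  synthetic/      generators for recordings, cohorts, fields, movies, plates
examples/         one narrative script per capability
docs/methods.md   models, defaults, calibration and limitations
```
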