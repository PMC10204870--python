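# aptamelt

Thermofluorimetric analysis (TFA) of aptamer–target binding, as a tested
Python library and CLI.

In a TFA experiment a dye-stained aptamer is mixed with its protein target
and melted in a real-time PCR instrument while fluorescence is recorded. The
derivative melting curve (−dF/dT plotted against temperature) of the mixture
shows two peaks: the unbound aptamer melts at a lower temperature (peak 1,
"free") and the target-stabilised aptamer at a higher one (peak 2, "bound").
The melting temperature Tm, height and area of those peaks — and the bound
ratio A₂/(A₁+A₂) — quantify how well a given aptamer concentration, buffer
system or metal-ion milieu supports binding. `aptamelt` implements that
analysis end to end, together with the buffer-screening design and the
structural metrics used to interpret binding at the atomic level:

- **`aptamelt.simulate`** — synthetic plate generator. Each species melts by
  a two-state van 't Hoff model, θ(T) = 1/(1 + exp[−(ΔH_vH/R)(1/T − 1/Tm)]),
  and the free/bound populations come from the closed-form 1:1 mass-action
  equilibrium with dissociation constant K_d. A plate is a set of replicate
  wells plus buffer-only blanks on a 4→80 °C, 0.5 °C-step scan with a linear
  baseline and i.i.d. Gaussian noise, fully reproducible from a seed.
- **`aptamelt.preprocess`** — the fixed pipeline: average replicate wells →
  Savitzky–Golay −dF/dT → subtract the blanks' derivative → rescale to
  0–100.
- **`aptamelt.peaks`** — peak detection, bounded least-squares deconvolution
  into two Gaussians plus a linear baseline (free = lower centre, bound =
  higher), peak areas, bound ratio, cross-condition area heatmaps and OLS
  calibration lines with r².
- **`aptamelt.design`** — seeded L9 orthogonal arrays (4 factors × 3 levels,
  built over GF(3)) with exhaustive strength-2 validation, the packaged
  nine-buffer metal-ion table, ionic strength I = ½ Σ cᵢzᵢ² with or without
  chloride counter-ions, buffer ranking by bound-peak Tm, main-effects
  tables and ng/mL → nM conversion.
- **`aptamelt.structmetrics`** — multi-model PDB trajectories: Kabsch RMSD,
  per-residue RMSF about the iterated mean structure, geometric
  hydrogen-bond detection with occupancy statistics, and protein–nucleic
  binding-site contact enumeration.

## Worked example

Simulate a balanced aptamer–target mixture (20 nM each, K_d = 5 nM), process
it and quantify the two peaks:

```python
import aptamelt as am

system = am.BindingSystem(aptamer_conc=20.0, target_conc=20.0, kd=5.0)
plate = am.simulate_plate(system, am.ScanProtocol(seed=11))   # 3 wells + 3 blanks
curve = am.process_condition(plate, "cond1")                  # normalized -dF/dT
fit = am.deconvolve_two_peaks(curve)

print(f"free peak:  Tm = {fit.free_peak.tm:.2f} C")
print(f"bound peak: Tm = {fit.bound_peak.tm:.2f} C")
print(f"bound ratio = {am.bound_ratio(fit):.3f}")
```

prints

```
free peak:  Tm = 35.03 C
bound peak: Tm = 59.91 C
bound ratio = 0.600
```

The generating truth was Tm 35/60 °C, and at these concentrations the
mass-action equilibrium binds 61.0% of the aptamer — the fitted bound ratio
(0.600) recovers it from the noisy melt curve alone. Ranking the packaged
nine-buffer table by ionic strength (chloride counter-ions included):

```python
am.ionic_strength_table(am.table1_buffers()).sort_values()
# buffer 6 -> 108.0 mM (weakest)  ...  buffer 4 -> 163.0 mM (strongest)
```

The same stages are available from the shell:

```bash
aptamelt simulate --seed 3 -o plate.csv --samples sheet.yaml
aptamelt melt plate.csv --samples sheet.yaml -o curves.csv
aptamelt peaks curves.csv -o peaks.csv --heatmap heatmap.csv
aptamelt design generate --seed 300 -o design.csv
aptamelt struct hbonds traj.pdb -o hbonds.csv
```

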