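# racir

Rapid A–Ci (RACiR) curve correction and Farquhar–von Caemmerer–Berry (FvCB)
model fitting for gas-exchange measurements in large leaf chambers — plus a
chamber-physics simulator so the whole pipeline can be exercised and tested
without instrument data.

## The problem

Estimating the photosynthetic capacity parameters **Vcmax** (maximum
Rubisco carboxylation rate) and **Jmax** (maximum electron transport rate)
requires a CO2 response curve: net assimilation *A* against intercellular
CO2 *Ci*. Stepping the chamber through CO2 set points takes 30–60 min per
curve; ramping CO2 continuously (a *rapid* A–Ci curve) takes minutes, but
the reference and sample analyzers no longer see the same air at the same
time. In large needle-and-leaf cuvettes (193.7 cm³ at 600 µmol s⁻¹ flow)
the mixing volume produces reference-to-sample lags of 48–92 s and large
apparent fluxes that must be removed before fitting.

The package implements the empty-chamber correction workflow for such
data:

1. **Split** the log at the ramp turn and keep the up ramp.
2. **Filter** to the quasi-linear portion with the ±0.05 µmol m⁻² s⁻¹
   delta-threshold rule (lag-block detection plus outlier rejection).
3. **Correct**: fit 1st–3rd degree polynomials of apparent *A* on
   reference CO2 to an empty-chamber response curve (ECRC), select the
   degree by BIC, and subtract the selected polynomial from leaf curves
   (no extrapolation outside the fitted domain); recompute *Ci* from the
   corrected flux. Post-measurement leaf-area corrections are supported.
4. **Fit** the FvCB model
   `A = min(Ac, Aj) − Rd`, `Ac = Vcmax (Ci−Γ*)/(Ci+Km)`,
   `Aj = J (Ci−Γ*)/(4Ci+8Γ*)`
   by bounded multi-start nonlinear least squares, with Rd either fixed at
   an independently measured value or estimated, over the full or a
   partial (e.g. Ci ∈ [200, 800]) range.

The simulator (`racir.simulate`) models the cuvette as a well-mixed
compartment with a transport delay, an FvCB leaf coupled through a fixed
diffusive conductance, analyzer offset polynomials and seeded noise, and
writes the same CSV dialect the reader consumes.

## Worked example

```python
import racir

chamber, ramp, leaf = racir.preset("paper-racir")   # Vcmax 60, Jmax 120, Rd 2
ecrc  = racir.simulate_ecrc(chamber, ramp, seed=1)
shoot = racir.simulate_ramp(chamber, ramp, leaf=leaf, seed=2)

result = racir.correct_and_fit(
    shoot, ecrc,
    racir.PipelineSettings(rd_measured=2.0, partial_ci_range=(200, 800)),
)
fit = result.fit
print(f"ECRC degree {result.ecrc_selected.degree}, "
      f"vcmax={fit.params.vcmax:.2f}, jmax={fit.params.jmax:.2f}, "
      f"rmse={fit.rmse:.3f}, transition Ci={fit.ci_transition:.0f}")
```

prints

```
ECRC degree 2, vcmax=57.69, jmax=119.46, rmse=0.205, transition Ci=478
```

The ECRC carried a quadratic artifact (degree 2 selected by BIC), and the
fit recovers the generating parameters to within ~4% for Vcmax and ~0.5%
for Jmax. The small Vcmax deficit is the known dynamic-lag bias of ramped
measurements corrected with a static empty-chamber polynomial (see
`docs/methods.md`); the Rubisco/RuBP-regeneration transition near
Ci ≈ 480 µmol mol⁻¹ is where the two fitted FvCB branches intersect.

The same workflow is available from the shell:

```bash
racir simulate --preset paper-ecrc  --seed 3 --out ecrc.csv
racir simulate --preset paper-racir --seed 4 --out shoot.csv
racir correct --racir shoot.csv --ecrc ecrc.csv --out corrected/
racir fit --input corrected/shoot_corrected.csv --rd 2.0 --out fit.json
racir batch batch.yaml        # many files, YAML-driven, per-entry isolation
```

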