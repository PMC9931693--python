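# chinooklipid

Fat-meter calibration and stock-specific lipid / energy-density analysis
for Fraser River Chinook salmon (*Oncorhynchus tshawytscha*), with the
downstream bioenergetics linking prey quality to southern resident killer
whale (SRKW) prey requirements.

## Who this is for

Fisheries ecologists and conservation modellers who (a) calibrate a
handheld microwave fat meter against homogenized whole fish, (b) apply
that calibration to test-fishery survey records to estimate whole-body
lipid content and energy density per management unit (MU), and (c) feed
the resulting energy densities into predator prey-requirement arithmetic.
A seeded synthetic-data generator emulates the field study's structure so
the entire pipeline is runnable and testable without the original data.

## The models

**Calibration.** A fat-meter reading *x* (meter units, position 1) maps to
whole-body lipid *L* (% wet weight) through a continuous two-segment
regression with breakpoint ψ:

    L(x) = β₀ + β₁·x                         x < ψ
    L(x) = β₀ + β₁·ψ + (β₁ + δ)(x − ψ)       x ≥ ψ

with published coefficients β₀ = −1.973, β₁ = 6.758, δ = −6.202,
ψ = 1.059, and an instrument floor of 0.6 (the lowest reading ever
recorded, ≈ 2% lipid). The fit is chosen by adjusted R² among three
families — model II (MA/SMA), model II on ln x, and segmented least
squares — across the seven combinations of the three sensor positions.
Whole-body lipid for the calibration fish is the mass-weighted
combination of somatic and gonadal tissue lipid, each converted from
fractions of dry mass via the tissue water fraction.

**Survey statistics.** Per-MU summaries with run timing (first /
50%-cumulative / last catch date), one-way ANOVA + Tukey HSD letters for
MU mean lipid, day-of-arrival regressions with slope ANCOVA, a Welch
t-test for hatchery (fin-clipped) vs wild fish, and weekly CPUE
(Σcatch/Σeffort, effort in fathom-minutes per boat day). Energy density
is affine in lipid, ED = a + b·L (kcal/kg), fitted to the MU mean pairs.

**Migration difficulty.** Per-stock indices — distance (km), spawning
elevation (m), work = (elevation×distance)/1000, slope =
500·elevation/distance — averaged per MU and Pearson-correlated with MU
mean lipid.

**Bioenergetics.** Gonadal investment ΔE = Δm_gonad × 7.79 kJ/g with
gonad mass m·GSI/(1+GSI) (GSI = gonad/somatic mass); whole-body energy
m × ED(L) × 4.184 kJ/kcal; and prey requirement = population energy /
(prey mass × ED), anchored to a reference scenario of 245,000
spring-run fish per year at 8 kg and 1900 kcal/kg.

## Worked example

```python
from chinooklipid import (PiecewiseCalibration, predict_whole_body_lipid,
                          EnergyConversion, energy_density)
from chinooklipid.migration import published_difficulty_correlations
from chinooklipid.bioenergetics import (gonad_energy_change,
                                        prey_requirement,
                                        reference_population_energy)

cal = PiecewiseCalibration.published()
print(f"reading 0.6  -> {predict_whole_body_lipid(0.6, cal):.2f}% lipid")
print(f"reading 10.0 -> {predict_whole_body_lipid(10.0, cal):.2f}% lipid")

conv = EnergyConversion.from_mu_means()
print(f"ED(12.8%) = {energy_density(12.8, conv):.0f} kcal/kg")

for c in published_difficulty_correlations():
    print(f"{c.index:<12} r = {c.pearson_r:.2f}  p = {c.p_value:.3f}")

print(f"gonad energy 8 kg, GSI 0.1->0.2: {gonad_energy_change(8, 0.1, 0.2):.0f} kJ")
pop = reference_population_energy()
print(f"fall-run-only prey requirement: {prey_requirement(pop, 8.0, 1436.0):,.0f} fish/year")
```

prints

```
reading 0.6  -> 2.08% lipid
reading 10.0 -> 10.15% lipid
ED(12.8%) = 1899 kcal/kg
elevation_m  r = 0.97  p = 0.005
distance_km  r = 0.82  p = 0.088
work         r = 0.80  p = 0.105
slope_index  r = 0.23  p = 0.713
gonad energy 8 kg, GSI 0.1->0.2: 4721 kJ
fall-run-only prey requirement: 324,164 fish/year
```

Reading 0.6 (the instrument floor) corresponds to ~2% whole-body lipid —
near the physiological minimum for a live salmon. MU mean lipid is most
strongly correlated with spawning-ground elevation. An average 8 kg
fall-run fish invests ~4.7 MJ in gonad growth as its GSI doubles from 0.1
to 0.2, and a killer-whale population eating only fall-run fish
(1436 kcal/kg) needs ~32% more fish per year than one eating spring-run
fish (1900 kcal/kg).

The full pipeline (synthetic data → calibration ranking → survey
statistics → correlations → prey scenarios, with a run manifest):

```sh
chinooklipid run --seed 1 --out-dir pipeline_out
```

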