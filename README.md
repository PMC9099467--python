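# hsmcr

Hard-and-soft Multivariate Curve Resolution–Alternating Least Squares
(MCR-ALS) with pharmacokinetic ODE constraints, for time-resolved
vibrational (Raman) spectra of drug-inoculated cells.

## What it does

A Raman time course of cells exposed to a drug mixes, in every spectrum,
the constant cellular background with the growing signatures of drug
binding and of the cellular response.  `hsmcr` decomposes the data matrix
with the bilinear model

    D = C S

(N spectra × J wavenumber channels; C holds the concentration profiles,
S the pure component spectra) while forcing selected concentration profiles
to obey a pharmacokinetic rate model,

    dNb/dt = (Nrecp − Nb)·Kup·D        (saturating uptake/binding)
    dNr/dt = (Nresp − Nr)·Kresp·Nb     (slower cellular response)

whose constants are refit by bounded nonlinear least squares inside every
ALS iteration.  The fit returns the resolved profiles and spectra *and* the
kinetic constants — e.g. compartment-specific uptake rates Kup in h⁻¹ —
with the full per-iteration history.  It is aimed at spectroscopists and
chemometricians analysing label-free in vitro uptake experiments.

The package also ships a synthetic-data generator (ODE-driven mixing of
Gaussian-band component spectra, including the *negative* nucleic-acid
bands at 785/811 cm⁻¹ that drug intercalation subtracts from the cell
spectrum), phenylalanine-band normalization, SVD rank evidence, and a
Monte-Carlo recovery benchmark.

## Worked example

```python
import hsmcr as h

# simulate the reference study: 0-72 h at 0.5 h steps, 1% noise
sim = h.simulate_dataset(config=h.SimulationConfig(seed=11))
print(sim.dataset.n_spectra)            # 145

ds = h.normalize_dataset(sim.dataset)   # phenylalanine-band areas -> 1

# three components; the binding component's spectrum may go negative
cfg = h.ConstraintConfig(
    n_components=3,
    nonneg_spec=[False, True, True],
    kinetic=h.KineticLink(
        h.get_model("uptake_response"),
        k0=dict(Kup=1.0, Kresp=0.5, Nrecp=1.0, Nresp=1.0, D=1.0),  # far start
    ),
)
res = h.run_mcr_als(ds, cfg)
print(res.n_iter, res.stop_reason, round(res.pct_lof_history[-1], 3))
print({k: round(v, 4) for k, v in res.k_final.items()})
```

prints

```
145
29 patience 1.267
{'Kup': 0.2479, 'Kresp': 0.048, 'Nrecp': 1.0358, 'Nresp': 1.3394, 'D': 1.0}
```

The fit stopped after 29 iterations by the patience rule with a final %LOF
of 1.27% (the injected noise floor).  Starting from rates 4× and 10× off,
the uptake rate used in the simulation (Kup = 0.25 h⁻¹) is recovered within
~1% and the response rate (Kresp = 0.05 h⁻¹) within ~4%; the capacities
Nrecp/Nresp come back only up to the intensity-ambiguity scale, as expected
for normalized spectra (see `docs/methods.md`).

The same workflow is available from the shell:

```sh
hsmcr simulate --out sim --seed 11
hsmcr normalize sim/data.csv sim/norm.csv
hsmcr rank sim/norm.csv
hsmcr fit sim/norm.csv --config fit.yaml --out results --no-normalize
hsmcr recover-benchmark --config fit.yaml --out bench --replicates 20 --seed 1
```

Datasets are wide CSV (first column `time_h`, headers the wavenumbers in
cm⁻¹); configs are YAML or JSON; every output directory carries a JSON
sidecar with the config hash and seed for bit-exact re-runs.

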