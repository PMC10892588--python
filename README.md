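# larvenet

Net-energy budget of toxin-exposed herbivorous insect larvae.

Larvae of leaf-chewing insects on chemically defended plants — the
motivating case is Lepidoptera on Brassicaceae, whose leaves store
glucosinolates (GLS) that hydrolyse to toxic isothiocyanates (ITC) on
tissue damage — often die before completing development. `larvenet`
implements an optimal-foraging explanation: feeding earns energy, but
toxin exposure and foraging burn it, and once the larva's net energy is
back at zero it must stop feeding. If that happens before development
ends, the larva starves. The package is aimed at chemical ecologists and
modellers who want to simulate the energy budget, locate the herbivory
stopping time, classify survival, and estimate the model's rate constants
from consumption or toxin time-course data.

## The model

Larval development is treated as a genetic program in time, so all
dynamics are non-autonomous linear ODEs with ramp forcing, each solvable
in closed form (t in days, 0 ≤ t ≤ b, the development time):

| state | equation | solution |
|---|---|---|
| herbivory (mg) | dH/dt = θt | H = θt²/2 (0 beyond b) |
| GLS ingested | dG/dt = αt | G = αt²/2 |
| free gut GLS | dF/dt = αt − ηF | F = (α/η²)(ηt − 1 + e^(−ηt)) |
| gut ITC | dI/dt = βt − γI | I = (β/γ²)(γt − 1 + e^(−γt)) |
| net energy | dEN/dt = κt − μI − δt² | EN = μβt/γ² − (μβ/γ−κ)t²/2 + μβe^(−γt)/γ³ − δt³/3 + EN0 − μβ/γ³ |

The benefit rate κt and costs μI (toxin) and δt² (foraging) make EN rise
and then fall; its unique return to zero is the stopping time **T**,
found either by bracketed root finding on the exact closed form or from
the analytic quadratic approximation

(δ/3)T² + ((μβ/γ − κ)/2)T − μβ/γ² = 0,

valid once e^(−γT) is negligible and the start offset EN0 − μβ/γ³ is
small. The survival rule is sharp: **T < b ⇒ the larva dies early.**
Because degradation vastly outpaces ingestion (α ≪ η), the free-GLS pool
stays in a quasi-steady state near zero; `qss_diagnostic` quantifies this
instead of assuming it.

A verbatim transcription of published codling-moth (*Cydia pomonella*)
cumulative leaf-consumption means ships with the package; the herbivory
constant θ has the closed-form least-squares estimate
θ̂ = 2·ΣHᵢtᵢ²/Σtᵢ⁴, and the toxin kinetics (β, γ) are fitted to ITC time
courses by multi-start nonlinear least squares.

## Worked example

```python
from larvenet import (REFERENCE_PARAMS, find_stopping_time,
                      approx_stopping_time, classify_survival,
                      fit_theta, load_codling_moth_table, cumulative_times)

params = REFERENCE_PARAMS          # θ=0.3, α=0.4, β=0.2, γ=0.8, κ=0.3,
                                   # μ=0.1, δ=0.03, EN0=0.2, b=14.58
res = find_stopping_time(params)
print(res.T, approx_stopping_time(params), classify_survival(res.T, params.b))

table = load_codling_moth_table()
print(fit_theta(cumulative_times(table), table.cumulative_mg).estimates)
```

prints

```
14.053842392654898 13.973635432250342 dies_early
{'theta': 0.3096920688715494}
```

The exact stopping time T = 14.05 days falls 0.53 days short of the
14.58-day development time, so this larva is predicted to starve in its
final instar; the analytic approximation lands within 0.6% of the exact
root. The θ̂ ≈ 0.31 mg/day² estimate comes from the packaged
consumption table (n = 4 instars).

The scripts in `examples/` walk through each capability — trajectory
simulation with an ODE cross-check, stopping time and survival, fitting,
parameter sweeps, and the quasi-steady-state/ensemble analysis — and the
same stages are available from the shell:

```bash
larvenet stop-time
larvenet sweep --axis mu --values 0,0.1,0.2
larvenet fit --input table.csv --mode consumption
```

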