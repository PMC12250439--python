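# waitcea

Cost-utility analysis of reducing waiting times for elective surgery.

Long surgical waiting lists harm patients twice: quality of life decays
while they wait, and some deteriorate past the point of operability or die
before reaching theatre. `waitcea` implements a segment-based incremental
cost-utility model for valuing initiatives that shorten those waits —
designed for data-limited settings, driven entirely by a declarative YAML
configuration, and evaluated from both the healthcare-payer and the
societal perspective.

## The model

Each surgery cohort splits into up to three subgroups, each compared
against its counterfactual pathway:

- **RWT** (reduced waiting time): surgery happens at `t_early` instead of
  `t_delayed`. Incremental QALYs decompose into segment **A** (the waiting
  gap, `(u_post_early − u_wait)` while the counterfactual still waits),
  segment **B** (any post-surgery utility difference until counterfactual
  death) and segment **C** (the survival gap, valued at `u_post_early`).
- **AMS** (avoided missed surgery): the counterfactual never gets the
  operation and lives at `u_missed` — segment **V** — plus the survival
  gap **W**. Structurally this is the general model with segment B's
  interval empty.
- **MA** (mortality averted): the counterfactual dies on the scheduled
  early-surgery date; the entire early-arm survival is gained (segment
  **X**).

Utilities are piecewise constant, so each segment is a utility difference
times the discounted person-time

```
E(t0, t1; r) = ∫_{t0}^{t1} (1+r)^{−t} dt = [(1+r)^{−t0} − (1+r)^{−t1}] / ln(1+r)
```

with both QALYs and costs discounted at 3.5%/year by default. Costs are
lump sums (direct medical, patient productivity, caregiver productivity)
discounted at their incurrence times; deltas are early minus
counterfactual, so savings are negative. Outcomes are aggregated at the
population level — total incremental cost over total incremental QALYs —
giving

- **ICER** = ΔC/ΔQ per perspective (payer: direct only; societal: direct
  plus both productivity components), with dominant/dominated markers,
- **BCR** = (ΔQ × GDP per capita)/ΔC_societal,
- cost-effectiveness against a willingness-to-pay threshold per QALY.

The package also estimates **catastrophic health expenditure** (an
out-of-pocket payment strictly exceeding 10% or 25% of annual household
expenditure; 25% base case), runs one-way ±10% deterministic sensitivity
analysis with tornado ranking, and probabilistic sensitivity analysis
(beta for utilities, normal for event times, gamma for costs; 5000 Monte
Carlo draws) over the composite population outcome.

## Worked example

```python
from waitcea import evaluate_run, generate_calibrated_fixture

run = generate_calibrated_fixture(target_qalys=48_385, target_cost=2_264_156_090)
comp = evaluate_run(run).composite
print(comp.icer_societal.rounded, comp.bcr_societal.value, comp.cost_effective_at_wtp)
```

prints (see `examples/02_calibrated_aggregates.py` for the narrated
version):

```
total QALYs gained:        48,385.0
incremental societal cost: EGP 2,264,156,090
composite societal ICER:   EGP 46,795 per QALY
benefit-cost ratio:        1.197
within EGP 56,000/QALY WTP threshold: True
```

A five-cohort programme gaining 48,385 QALYs for EGP 2.26 billion costs
EGP 46,795 per QALY — under the EGP 56,000 (one GDP per capita) threshold,
so the initiative is cost-effective, returning about 1.2 pounds of
monetized health per pound spent. The other scripts in `examples/`
evaluate the illustrative five-surgery base case, rank parameter influence
(tornado + PSA), and tabulate out-of-pocket affordability.

## Command line

A ready-made configuration for the five-surgery example ships as
`examples/five_surgeries.yaml`; `synth` regenerates it or draws randomized
variants.

```sh
waitcea synth -o fixture.yaml --expenditures exp.txt   # synthetic config
waitcea run fixture.yaml -o results                     # outcomes CSV + summary
waitcea dsa fixture.yaml -o results                     # tornado table + plot
waitcea psa fixture.yaml -o results --n 5000 --seed 1   # CE-plane scatter
waitcea che fixture.yaml -o results --expenditure-file exp.txt
```

Every run writes a manifest (tool version, config checksum, seeds,
emitted files); numeric CSVs are byte-reproducible for identical inputs.

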