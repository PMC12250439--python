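"""Base-case evaluation of the five-surgery illustrative model.

Generates the built-in five-cohort parameter set (open-heart surgery,
cardiac catheterization, cochlear implantation, retinal surgery, joint
replacement), evaluates discounted incremental QALYs and costs per cohort,
and prints each cohort's societal ICER next to the composite.
"""

from waitcea import FixtureSpec, evaluate_run, generate_fixture

run = generate_fixture(FixtureSpec())
results = evaluate_run(run)

print(f"{'cohort':32s} {'ΔQALYs':>12s} {'societal Δcost':>16s} {'ICER':>10s}  verdict")
for o in results.per_cohort + [results.composite]:
    icer = "dominant" if o.dominance_flag.value == "dominant" else f"{o.icer_societal.rounded:,}"
    verdict = "cost-effective" if o.cost_effective_at_wtp else "above WTP"
    print(f"{o.label:32s} {o.total_delta_qalys:12,.0f} {o.costs.delta_total_societal:16,.0f} "
          f"{icer:>10s}  {verdict}")

# Each row shows the population QALY gain from earlier surgery, the change
# in discounted societal spending (negative = the programme saves money),
# and cost per QALY gained.  Cochlear implantation both gains QALYs and
# saves money (dominant); retinal surgery costs more per QALY than the
# EGP 56,000 willingness-to-pay threshold; the composite divides summed
# costs by summed QALYs across all five cohorts.
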