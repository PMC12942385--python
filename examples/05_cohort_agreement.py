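"""Method-agreement statistics on a synthetic paired cohort.

A 72-participant cohort (144 eyes) is generated with the automated method
reading 0.06 logMAR better than manual on average (bias -0.06) plus 0.08
logMAR measurement noise and 5% planted outlier eyes. The suite reports
the Bland-Altman bias and 95% limits of agreement, ICC(2,1) inter-method
agreement, the Wilcoxon paired test, and the >=0.4 logMAR outlier filter.
"""

import json

from autova.agreement import agreement_report
from autova.simulate import CohortSpec, generate_cohort

spec = CohortSpec(n_participants=72, bias=-0.06, noise_sd=0.08, outlier_fraction=0.05, seed=5)
cohort = generate_cohort(spec)
report = agreement_report(cohort)

print(json.dumps(report, indent=2, sort_keys=True))
ba = report["bland_altman"]
print(f"\nmean manual-minus-automated difference {ba['mean_diff']:+.3f} logMAR")
print(f"95% limits of agreement [{ba['loa_low']:+.3f}, {ba['loa_high']:+.3f}]")
print(f"ICC(2,1) = {report['icc']['value']:.2f} "
      f"(95% CI {report['icc']['ci_low']:.2f}-{report['icc']['ci_high']:.2f})")
print(f"{report['outliers']['n_flagged_participants']} participants flagged by the >=0.4 filter")
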