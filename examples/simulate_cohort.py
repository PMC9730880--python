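"""Build the deterministic worked-example cohort and print its rates.

The cohort has 56 patients and 330 lesions whose diameter courses place
them far from the RECIST and growth-doubling decision boundaries, so the
classification is exact and reproducible.
"""

from hyperrad.hyperprogression import classify_cohort, cohort_rates
from hyperrad.synthetic import build_figure2_fixture

patients, lesions = build_figure2_fixture()
print(f"{len(patients)} patients, {len(lesions)} lesions")

assessments, statuses = classify_cohort(lesions)
r = cohort_rates(assessments, statuses)

print(f"progressing lesions : {r['n_pd_lesions']:3d}/330 "
      f"({r['lesion_pd_rate_pct']:.1f}%)")
print(f"hyperprogressive    : {r['n_hpl_lesions']:3d}/330 "
      f"({r['hpl_rate_overall_pct']:.1f}% overall, "
      f"{r['hpl_rate_among_pd_pct']:.1f}% of progressing)")
print(f"PD patients         : {r['n_pd_patients']:3d}/56 "
      f"({r['patient_pd_rate_pct']:.1f}%)")
print(f"PD-HPD patients     : {r['n_pd_hpd_patients']:3d} "
      f"({r['pd_hpd_among_pd_pct']:.1f}% of PD, "
      f"{r['pd_hpd_overall_pct']:.1f}% of all)")
# The percentages are the cohort's progression and hyperprogression
# prevalences at lesion and patient level.
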