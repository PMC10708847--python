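"""Correlate the attention index with task scores; compare best vs worst.

A 60-subject cohort with a known 0.6 rank association is pushed through
the whole pipeline; the three correlation models are compared, then the
best/worst performer groups are formed (mean +/- 0.5 exclusion, pass-mark
split, 5-95% beta trim) and tested.
"""

from betawatch.core import SessionAnnotation
from betawatch.pipeline import analyze_cohort
from betawatch.stats import correlate
from betawatch.synthetic import CohortSpec, generate_cohort

annotation = SessionAnnotation.standard_session(
    n_video_segments=2, video_s=16.0, survey_s=6.0, quiz_s=6.0)
bundle = generate_cohort(CohortSpec(n_subjects=60, target_assoc=0.6, seed=9,
                                    annotation=annotation))
result = analyze_cohort(bundle, model="skipped", n_boot=1000, seed=1)

betas = result.normalized_betas
print("model     r      CI95             p        power  outliers")
for model in ("pearson", "spearman", "skipped"):
    c = correlate(betas, result.scores, model=model, n_boot=1000, seed=1)
    print(f"{model:<8} {c.r:>6.3f}  [{c.ci95[0]:.3f}, {c.ci95[1]:.3f}]  "
          f"{c.p_value:<8.4f} {c.power:>5.2f}  {c.n_outliers:>5}")

gt = result.group_test
print(f"\ngroups (worst/best): {gt.group_sizes}, medians {gt.medians[0]:.3f} / "
      f"{gt.medians[1]:.3f}")
print(f"{gt.test_used}: statistic = {gt.statistic:.1f}, p = {gt.p_value:.4f}, "
      f"significant at 5%: {gt.significant}")
# The recovered correlations sit near the generated 0.6 association
# (attenuated slightly by measurement noise in the PSD estimate), and
# best performers show higher median beta power than worst performers.
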