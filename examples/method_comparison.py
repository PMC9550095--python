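"""Rank twelve optimizers across ten problems and test the differences.

Input is the bundled published score table (mean fitness, lower = better).
The pipeline: per-problem Friedman ranks (ties share average ranks), the
Friedman chi-square omnibus test, the Iman-Davenport F refinement, and
Holm's step-down procedure comparing the control method against the rest.
"""

from coffo import compare_methods, load_reference_scores

scores = load_reference_scores()
report = compare_methods(scores, control="COFFO")

print("Average Friedman ranks (lower = better):")
print(report["rank_table"].average_ranks.sort_values().round(2).to_string())
print(f"\nFriedman chi2 = {report['friedman_chi2']:.1f} "
      f"(critical value {report['chi2_critical']:.1f} at alpha=0.05)")
print(f"Iman-Davenport F = {report['iman_davenport']:.1f} "
      f"(critical value {report['f_critical']:.2f})")
print("\nHolm step-down against COFFO:")
print(report["holm"][["comparison", "p_value", "threshold_0.05",
                      "reject_0.05"]].to_string(index=False))
# chi2 above its critical value rejects "all methods perform alike";
# each Holm row then asks whether COFFO beats that specific method, at a
# per-row threshold that keeps the family-wise error at alpha.
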