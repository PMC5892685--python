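"""Run the full three-subset pipeline and show the headline tables.

Generates a full cohort, a case-cohort, and a nested case-control
subset; fits the frailty-association mixed models with random-effects
meta-analysis; fits the mortality models per design with meta-analysis
of the two survival subsets; and compares predictive accuracy.
"""

from methylsurv import AnalysisConfig, run_all

config = AnalysisConfig(
    seed=4,
    n_subjects=(800, 800, 800),
    impute_fi=False,             # use observed-denominator FI for speed
    subcohort_fraction=0.2,
    time_grid=(3.0, 6.0, 9.0, 12.0),
)
results = run_all(config, out_dir="scratch/pipeline_demo")

fa = results["frailty_association"]
print("FI association per SD of each indicator (meta-analysis, Model 2):")
sub = fa[(fa["subset"] == "overall") & (fa["model"] == "model2")]
for _, r in sub.iterrows():
    print(f"  {r['indicator']:18s} {r['coefficient']:+5.2f} % units "
          f"({r['ci_low']:.2f} to {r['ci_high']:.2f}), p={r['p']:.2g}")

mort = results["mortality"]
print("\nmortality meta-analysis of subsets I+II (joint model, per SD):")
meta = mort[(mort["subset"] == "I+II (meta)") & (mort["model"] == "model2")]
for _, r in meta[meta["label"].str.contains("per SD")].iterrows():
    print(f"  {r['label']:32s} HR {r['hr']:.2f} ({r['ci_low']:.2f} - {r['ci_high']:.2f})")

acc = results["accuracy_summary"]
print("\nHarrell's C in subset I:")
for _, r in acc[acc["subset"] == "I"].iterrows():
    print(f"  {r['label']:26s} {r['estimate']:.3f}")

# The meta-analyzed joint model shows a strong score effect, a clear
# frailty effect, and an age-acceleration HR close to 1 - the pattern
# that motivates using the methylation score alongside (not instead of)
# the frailty index, while AA adds little once both are in the model.
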