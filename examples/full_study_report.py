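"""End-to-end synthetic study: generation, analysis and group statistics.

Generates a complete 6-subject study (three fatiguing-task force levels per
subject, 270 contractions each) with deterioration that grows with force
level, runs the whole pipeline, and prints the force-level repeated-measures
ANOVA on the fatigue slopes with Bonferroni-corrected follow-up tests.
"""

from fatiguekit import StudyConfig, make_synthetic_study, run_study

sessions = make_synthetic_study(n_subjects=6, seed=42)
report = run_study(sessions, StudyConfig(n_perm=200))

block = report["group"]["force_slope"]
f, (d1, d2), p = block["F"], block["df"], block["p"]
print(f"force-level RM-ANOVA on fatigue slopes: F({d1},{d2}) = {f:.2f}, "
      f"p = {p:.2g}, partial eta^2 = {block['partial_eta_sq']:.2f}")
for pw in block["pairwise"]:
    a, b = pw["pair"]
    print(f"  {a} vs {b}: t({pw['df']}) = {pw['t']:+.2f}, "
          f"p_bonf = {pw['p_bonf']:.3g}, d = {pw['cohens_d']:+.2f}")
print(f"post-FT MVC ANOVA p = {report['group']['mvc_post']['p']:.2g}")
print(f"config hash: {report['provenance']['config_hash']}")
# With deterioration ordered 75% > 50% > 5% the force-level effect is large;
# rerunning with the same seed reproduces this report byte for byte.
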