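"""Simulate a multi-observer reading study and quantify agreement.

Three imperfect observers read 60 synthetic patients twice.  Interobserver
agreement is summarised by ICC(A,1) for the continuous MFI and Gwet's AC1
for the ordinal Goutallier grades; Bland-Altman bias and 95% limits of
agreement describe each observer pair.
"""

import parafat as pf

profiles = [
    pf.ObserverProfile(roi_jitter_px=2, epimuscular_inclusion_prob=0.05,
                       grade_misclass_prob=0.15)
    for _ in range(3)
]
records = pf.simulate_reliability_study(
    n_patients=60, observer_profiles=profiles, seed=7
)

mfi_matrix = pf.assemble_complete_cases(records, "mfi", "interobserver")
gcs_matrix = pf.assemble_complete_cases(records, "gcs", "interobserver")

icc = pf.icc_absolute_agreement(mfi_matrix)
ac1 = pf.gwet_ac1(gcs_matrix)
print(f"interobserver MFI  ICC {icc.estimate:.2f} "
      f"(95% CI {icc.ci_low:.2f}-{icc.ci_high:.2f}) -> {icc.band}")
print(f"interobserver GCS  AC1 {ac1.estimate:.2f} "
      f"(95% CI {ac1.ci_low:.2f}-{ac1.ci_high:.2f}) -> {ac1.band}")

for obs in (1, 2, 3):
    intra = pf.assemble_complete_cases(records, "mfi", "intraobserver", observer=obs)
    r = pf.icc_absolute_agreement(intra)
    print(f"intraobserver MFI, observer {obs}: ICC {r.estimate:.2f} -> {r.band}")

ba = pf.bland_altman(mfi_matrix.values[:, 0], mfi_matrix.values[:, 1])
print(f"observers 1 vs 2: bias {ba.bias:+.3f}, "
      f"LoA [{ba.loa_low:+.3f}, {ba.loa_high:+.3f}] over {ba.n_pairs} pairs")

# The continuous MFI typically lands in the "good" ICC band while the
# coarser visual grading shows lower chance-corrected agreement — the same
# ordering reported for human readers.
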