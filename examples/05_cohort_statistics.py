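"""Cohort statistics: group comparison, ROC with Youden cutoff, reader
agreement and paired AUC comparison.

Draws a 58 + 26 responder/non-responder cohort of true biomarker values
from the default group distributions and runs the statistics layer on
it: the t test and ROC quantify how well each biomarker separates the
groups, the CCC quantifies two-reader agreement, and the DeLong test
compares two biomarkers' AUCs on the same patients.
"""

import numpy as np

from mbdwi import (
    NONRESPONDER_DISTRIBUTION, RESPONDER_DISTRIBUTION,
    compare_auc, lin_ccc, roc_analysis, sample_patient_params,
    simulate_readers, two_group_t,
)

rng = np.random.default_rng(7)
resp = sample_patient_params(RESPONDER_DISTRIBUTION, rng, 58)
nonresp = sample_patient_params(NONRESPONDER_DISTRIBUTION, rng, 26)
groups = np.array(["responder"] * 58 + ["non-responder"] * 26)

for param in ("ddc", "alpha"):
    values = np.concatenate([resp[param], nonresp[param]])
    t, p = two_group_t(resp[param], nonresp[param])
    roc = roc_analysis(values, groups)
    print(f"{param:>5}: responders {resp[param].mean():.3f} vs "
          f"non-responders {nonresp[param].mean():.3f} (t test p = {p:.2e}); "
          f"AUC = {roc.auc:.3f}, cutoff = {roc.cutoff:.3f} "
          f"({roc.orientation} predicts responder), "
          f"sens = {roc.sensitivity:.0%}, spec = {roc.specificity:.0%}")

ddc = np.concatenate([resp["ddc"], nonresp["ddc"]])
alpha = np.concatenate([resp["alpha"], nonresp["alpha"]])
p_delong = compare_auc(ddc, alpha, groups)
print(f"\nDeLong paired test DDC vs alpha AUC: p = {p_delong:.3f}")

r1, r2 = simulate_readers(ddc, reader_sd=0.04, rng=rng)
agreement = lin_ccc(r1, r2)
print(f"two-reader CCC for DDC (reader SD 0.04): {agreement.ccc:.3f} ({agreement.band})")
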