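"""Score item responses, flag clinical impairment, merge GOSE sources.

Builds a handful of item-level responses, scores them with the registered
instrument rules, and shows how the merged GOSE/-Q rating is assembled
from its three possible sources.
"""

import tbisens as tb

registry = tb.default_registry()

# A GAD-7 response with two items skipped: within the 1/3 proration limit,
# so the total is the observed item mean scaled to 7 items.
gad7 = [2, 3, 2, 1, 3, None, None]
total = tb.score_total(gad7, registry["gad7"])
impaired = tb.flag_impaired(total, registry["gad7"])
print(f"GAD-7 items {gad7} -> total {total:.1f} (impaired: {impaired})")
# total 15.4 is the prorated sum; >= 10 means clinically relevant anxiety

# QOLIBRI uses the percent transform: item mean rescaled from [1, 5] to [0, 100].
qolibri = [4] * 37
total = tb.score_total(qolibri, registry["qolibri"])
print(f"QOLIBRI all-4 responses -> {total:.0f}/100 "
      f"(impaired: {tb.flag_impaired(total, registry['qolibri'])})")
# 75/100 is above the cut-off of 60, so HRQOL counts as not impaired

# Symptom scales are reflected onto a common higher-is-better axis before
# any effect-size computation.
rpq_total = 22
print(f"RPQ total {rpq_total} -> oriented "
      f"{tb.orient_score(rpq_total, registry['rpq']):.0f} (scale 0-64 reversed)")

# GOSE merging: the interview is primary; the questionnaire substitutes a
# missing interview; vegetative state and lower severe disability collapse
# into the single category printed as 2/3.
for interview, q in ((6, 5), (None, 3), (None, None)):
    rating = tb.merge_gose_sources(interview, q, None)
    print(f"interview={interview} questionnaire={q} -> "
          f"level {rating.label} from {rating.source}")
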