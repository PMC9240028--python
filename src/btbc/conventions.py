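"""Shared conventions pinned in one place.

The lag-sign convention couples the simulator to the cross-correlation
readout and must be identical in both: a **positive** lag means the
*learner's* motion occurs earlier in time (the learner leads), a negative
lag means the instructor leads.  Concretely, the coupling module correlates
the learner segment at ``[t, t + W)`` with the instructor segment at
``[t + lag, t + lag + W)``; at positive lag the instructor segment is taken
*later*, so high correlation there means the instructor echoes what the
learner did earlier.
"""

#: +1 encodes "positive lag = learner leads".  Referenced (never negated) by
#: both the simulator and the coupling module so the convention cannot drift.
LEARNER_LEADS_SIGN: int = +1

#: Role labels used throughout for the two people in a dyad.
ROLE_INSTRUCTOR = "instructor"
ROLE_LEARNER = "learner"

#: The two levels of the instructional-approach factor (within-dyad).
CONDITION_SCAFFOLDING = "scaffolding"
CONDITION_EXPLANATION = "explanation"

#: The two levels of the personalization factor (between-dyad).
PERSONALIZED = "personalized"
NONPERSONALIZED = "nonpersonalized"
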