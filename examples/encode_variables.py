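"""Derive coded study variables from raw survey answers.

Shows the three derivation rules: the multimorbidity flag (two or more of
the 14 chronic conditions), weekly MET-minutes from intensity/frequency/
duration triples, and the banding of MET-minutes into activity levels.
"""

from mmdbn import ActivityRecord, categorize_activity, derive_mmd, encode_record, met_minutes

# a subject reporting hypertension and diabetes among the 14 conditions
conditions = [1, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]
print("MMD flag (2 of 14 conditions present):", derive_mmd(conditions))

# IPAQ-style weekly energy expenditure: weight x days/week x minutes/day
activity = [ActivityRecord("vigorous", 3, 40), ActivityRecord("light", 2, 10)]
met = met_minutes(activity)
print(f"MET-min/week = 8.0*3*40 + 3.3*2*10 = {met}")
print("activity band (1=light,2=moderate,3=vigorous):", categorize_activity(met))

record = encode_record(
    {
        "sex": "Women",
        "age_years": 68,
        "sleep_hours": 6.5,
        "nap_minutes": 30,
        "smoking": "No",
        "alcohol": "No",
        "activity": activity,
        "conditions": conditions,
    }
)
print("encoded record:", record)
# sex=2 (women), age=3 (65-75 band), sleep=3 (<=7h), nap=2 (<=30 min),
# physical_activity=1 (<600 MET-min/week would be 1; here the band above), mmd=1
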