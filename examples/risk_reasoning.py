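"""Sequential risk reasoning: watch P(MMD=1) move as evidence accumulates.

The network supports exact conditional-probability queries by variable
elimination. Feeding evidence in one piece at a time mirrors how a
clinician would update a risk assessment: start from the prior, then
condition on light physical activity, short sleep, and the 65-75 age band.
"""

from mmdbn import charls_like_network, query_report

bn = charls_like_network()
chain = [
    ("mmd", {}),
    ("mmd", {"physical_activity": 1}),
    ("mmd", {"physical_activity": 1, "sleep": 1}),
    ("mmd", {"physical_activity": 1, "sleep": 1, "age": 3}),
]
report = query_report(bn, chain)
print(report[["evidence", "p_0", "p_1"]].to_string(index=False))
# p_1 is P(MMD=1 | evidence): it starts at the 0.538 prior and climbs with
# each unfavourable finding, because all three evidence variables are direct
# parents of MMD in the network
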