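"""Simulate one Simon session and summarise the sequence effects.

The agent always launches the location-compatible rapid response, then
reverses it when (and only when) it perceives incongruence.  Errors
concentrate on congruency switches: misses on I(C), false alarms on C(I).
"""

from arcsim import AgentParams, error_rates_by_condition, rt_summary_by_condition, session_i, simulate_session

records = simulate_session(session_i(seed=3), AgentParams(), seed=42)

print("error rates by sequence condition (current(previous) congruency):")
print(error_rates_by_condition(records).to_string(index=False))

rt = rt_summary_by_condition(records)
rt = rt[rt["n_trials"] > 0]
print("\nlatencies and mean cognitive cost by event condition:")
print(
    rt[["event_condition", "n_trials", "apa_mean_ms", "footoff_mean_ms", "cost_mean_nats"]]
    .round(1)
    .to_string(index=False)
)
print(
    "\n-> anticipatory (APA) latencies are flat across conditions; foot-off is"
    "\n   ~100 ms slower wherever the reversal was applied, and cost is the"
    "\n   baseline plus the Shannon surprise of the reversed response code."
)
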