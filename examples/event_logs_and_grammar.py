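"""Event-log round trips and grammar validation.

Writes a simulated batch as a CSV event log, reads it back, and checks every
sequence against the stereotyped mating grammar (pounce first, pounce ->
sound, long preceded by rot, scratch only after a long copulation, recovery
after a short, terminal departure).  Also shows the compact token notation
and what a grammar violation report looks like.
"""

from ethoflow import (
    aei_profile,
    parse_token_sequence,
    read_event_log,
    sequence_from_tokens,
    simulate_batch,
    validate_sequence,
    write_event_log,
)

batch = simulate_batch(aei_profile(), 10, seed=5)
log_text = write_event_log(batch.sequences)
print(f"event log: {len(log_text.splitlines()) - 1} rows for {batch.n_events} subjects")

back = read_event_log(log_text)
ok = sum(validate_sequence(s, strict=True).ok for s in back)
print(f"round-tripped sequences passing the mating grammar: {ok}/{len(back)}")

tokens = parse_token_sequence("pounce, ant, buzz")
report = validate_sequence(sequence_from_tokens(tokens, subject_id="demo"))
print(f"\nviolations in 'pounce ant buzz' ({report.sequence_id}):")
for v in report.violations:
    print(f"  rule {v.rule_id} at event {v.event_position}: {v.message}")
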