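"""Simulate mating sequences, then recover the transition structure.

Draws 2000 natural-emergence (REI) mating events from the seeded semi-Markov
simulator and fits the first-order transition model back to them.  The
estimated first-branch probabilities should sit close to the generating
values (sound -> ant 0.96, sound -> buzz 0.04), demonstrating parameter
recovery.  Note two state-labelling effects: the first antenna episode "ant"
pools the courtship and (rare) exit roles, so P(ant -> buzz) sits slightly
below the courtship branch value 0.98; and rot -> long is the forward
probability that a rotation is followed by a long rather than a short
copulation, below 1 in a mixed corpus even though every long is preceded by
rot (printed last).
"""

from ethoflow import estimate_transitions, rei_profile, simulate_batch

batch = simulate_batch(rei_profile(), 2000, seed=7)
print(f"simulated {batch.n_events} REI mating events (seed {batch.seed_used})")

model = estimate_transitions(batch.sequences, indexed_mode=True)
print(f"indexed transition model over {len(model.states)} states\n")

for src, dst in [("pounce", "sound"), ("sound", "ant"), ("sound", "buzz"),
                 ("ant", "buzz"), ("rot", "long")]:
    print(f"  P({src:>6} -> {dst:<5}) = {model.prob(src, dst):.4f}")

# the reverse conditional observed at 100%: every long copulation is
# immediately preceded by the antenna-rotation unit
preds = []
for seq in batch.sequences:
    tokens = seq.tokens()
    preds += [tokens[i - 1] for i, t in enumerate(tokens) if t == "long"]
pct = 100.0 * sum(p == "rot" for p in preds) / len(preds)
print(f"\nlong copulations preceded by rot: {pct:.1f}% of {len(preds)}")
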