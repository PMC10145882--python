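"""Build and export the flow ethogram of single-long matings.

Simulates single-long mating sequences, estimates their transition model in
indexed mode (repeated antenna episodes become distinct states), and emits
the flow-ethogram graph as DOT.  Each arrow carries the transition
probability and a 1-5 percentage class; the pen width grows with the class,
so certain transitions (class 5) draw as the thickest arrows.
"""

import numpy as np

from ethoflow import (
    build_ethogram,
    estimate_transitions,
    export_ethogram,
    generate_sequence,
    rei_profile,
)

rng = np.random.default_rng(3)
profile = rei_profile()
seqs = [generate_sequence("L", profile, rng, subject_id=f"L{i}")
        for i in range(200)]

model = estimate_transitions(seqs, indexed_mode=True)
graph = build_ethogram(model)
print(f"{len(graph.nodes)} states, {len(graph.edges)} observed transitions\n")
print(export_ethogram(graph, "dot"))
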