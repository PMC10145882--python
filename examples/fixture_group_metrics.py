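"""Group statistics from the observed copulation-composition tables.

Builds the recorded composition tables of the two age groups (REI: natural
emergence time; AEI: emergence delayed 59 days in the cold), computes each
group's copulation statistics, and compares them.  The printed numbers are
the headline result: ageing shifts matings from a single terminal long
copulation toward repeated short copulations, raising the share of matings
that never end in a long copulation ("reproductive failure").
"""

from ethoflow import compare_groups, fixture_counts, group_metrics, round_half_up

rei = group_metrics(fixture_counts("REI"), group="REI")
aei = group_metrics(fixture_counts("AEI"), group="AEI")

for m in (rei, aei):
    print(f"{m.group}: {m.n_events} mating events, "
          f"{m.n_long} long / {m.n_short} short copulations")
    ratio = "inf" if m.ratio_is_infinite else f"{round_half_up(m.ratio_long_short, 2)}"
    print(f"  long/short ratio          : {ratio}")
    print(f"  copulation-type frequency : long {round_half_up(m.freq_long_pct, 2)}% "
          f"/ short {round_half_up(m.freq_short_pct, 2)}%")
    print(f"  events ending with long   : {round_half_up(m.pct_end_long, 2)}%")
    print(f"  composition histogram     : {m.composition_histogram}")

comparison = compare_groups(rei, aei)
print(f"\nreproductive-failure increase REI -> AEI: "
      f"{round_half_up(comparison.failure_increase_pct, 1)}% "
      f"(full precision {comparison.failure_increase_pct})")
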