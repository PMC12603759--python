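"""Secondary-screen triage: selectivity, efficacy and off-target filters.

Simulates a 104-compound four-dose secondary screen in a tumor line
(Moffitt-ns) and a control fibroblast line (Lf), then applies the three
strict filters: >40-point tumor-vs-control suppression difference at >= 2
doses, >50% tumor suppression at the top dose, <50% control suppression at
the top dose.
"""

from cytohts import secondary_triage, simulate

table, planted = simulate.simulate_secondary_screen(
    n_compounds=104, n_planted=3, seed=1)
decisions = secondary_triage.triage(table, metric_kind="ctg",
                                    tumor_line="Moffitt-ns",
                                    control_line="Lf")
survivors = decisions[decisions.overall]
print(f"{len(decisions)} candidates -> {len(survivors)} pass all filters")
print(survivors[["compound_id", "selectivity_pass", "efficacy_pass",
                 "safety_pass"]].to_string(index=False))
print("planted pan-filter passers:", ", ".join(planted))

# The survivors should be exactly the planted compounds: candidates that
# suppress the tumor line strongly and selectively while sparing the
# control fibroblasts.
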