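"""Primary-screen hit calling on a simulated 384-well screen.

Simulates a 2,600-compound dual-dye cytotoxicity screen with 5% planted
actives, scores the AUC and final-timepoint death-fraction metrics, and
calls hits at robust Z < -3.
"""

from cytohts import primary_screen, simulate

spec = simulate.PlateSimSpec(n_compounds=2600, active_fraction=0.05,
                             effect_sigma=8.0, seed=1)
ds = simulate.simulate_primary_plate(spec)
print(f"simulated {ds.annotations.plate_id.nunique()} plates, "
      f"{len(ds.imaging)} imaging records")

scores = primary_screen.score_primary_screen(ds)
truth = ds.metadata["truth"]
actives = {c for c, v in truth.items() if v["active"]}
for metric, grp in scores.groupby("metric_kind"):
    hits = set(grp.loc[grp.is_hit, "compound_id"])
    sens = len(hits & actives) / len(actives)
    print(f"{metric:>16}: {len(hits)} hits (Z < -3), "
          f"sensitivity vs planted actives {sens:.1%}")

# A hit count close to the planted 130 actives with ~100% sensitivity means
# the robust-Z selection separates killers from the null population; excess
# hits are false positives from the ~0.1-0.2% Gaussian tail.
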