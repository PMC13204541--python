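"""Hypothesis-driven circuit comparison: the fear-conditioning pathway.

Plants a 4-fold effect on the within-hemisphere amygdala-thalamus
connections only, then tests all six fear-circuit pairs ipsilaterally
and contralaterally.  The planted pair should be flagged ipsilaterally
and read "nd" (no difference) contralaterally.
"""

from hdbn import (CompositeROI, SimulationConfig, builtin_circuit, circuit_compare,
                  default_region_table, resolve_composite, simulate_cohort)

table = default_region_table()
coa = {h: resolve_composite(table, CompositeROI("coa", ("COA",)), h)[0] for h in "LR"}
th = {h: resolve_composite(table, CompositeROI("th", ("TH",)), h)[0] for h in "LR"}

config = SimulationConfig(
    seed=31, zero_prob=0.1,
    planted_edges=((coa["L"], th["L"], 4.0), (coa["R"], th["R"], 4.0)),
)
cohort = simulate_cohort(config, with_diffusivity=False)

circuit = builtin_circuit("fear")
print(f"circuit {circuit.name!r}: {len(circuit.pairs)} pairs over nodes {circuit.nodes}")
for side in ("ipsilateral", "contralateral"):
    out = circuit_compare(cohort, circuit, side=side)
    print(f"\n{side}:")
    print(out[["pair", "mean_WT", "mean_KO", "p_adj", "label"]].to_string(index=False))
# "*" marks pairs whose connection strength differs between groups after
# BH adjustment within the circuit; long-range contralateral connections
# stay "nd" because the effect was planted within hemispheres only.
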