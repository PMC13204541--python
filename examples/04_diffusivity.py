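"""Tensor-derived diffusivity scalars and region-wise group maps.

Computes FA/MD/AD/RD from eigenvalue triples, then simulates a cohort
with a +20% axial-diffusivity shift planted in one region and runs the
region-wise comparison with BH correction.
"""

from hdbn import (PlantedRegion, SimulationConfig, compare_regions,
                  diffusivity_scalars, records_to_frame, simulate_diffusivity)

s = diffusivity_scalars(2.0e-3, 1.0e-3, 1.0e-3)
print(f"eigenvalues (2, 1, 1) um^2/ms -> FA {s.fa:.4f}, MD {s.md:.2e}, "
      f"AD {s.ad:.2e}, RD {s.rd:.2e}")

config = SimulationConfig(
    seed=4, planted_regions=(PlantedRegion(region_id=3, scalar="AD", effect=1.2),))
records = simulate_diffusivity(config)
frame = records_to_frame(records)

result = compare_regions(frame, scalar="AD", correction="bh")
flagged = result[result.flag]
print(f"regions flagged for AD at |adjusted p| < 0.05: "
      f"{flagged.region_id.tolist()} (planted: [3])")
row = result[result.region_id == 3].iloc[0]
print(f"region 3: mean WT {row.mean_WT:.3e}, mean KO {row.mean_KO:.3e}, "
      f"signed adjusted p {row.signed_p_adj:+.2e}")
# The positive sign encodes KO > WT, matching the planted +20% shift.
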