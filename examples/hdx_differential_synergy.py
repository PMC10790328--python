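"""Time-resolved HDX-MS: differential uptake and two-ligand synergy.

Simulates the four-state experiment (apo, +substrate S1P, +PI(4,5)P2, and the
ternary complex) on a 549-residue transporter stand-in, then computes per-
peptide dRFU versus apo and the synergy statistic
S = dRFU(ternary) - [dRFU(S1P) + dRFU(PIP2)].  S > 0 means the two ligands
together open the extracellular gate more than the sum of their individual
effects.
"""

from msbind.hdx import coverage_stats, delta_rfu, pool_synergy, synergy
from msbind.simulate import HDX_PRESETS, SEGMENTS, gen_hdx

data = gen_hdx(HDX_PRESETS["hdx-synergy"], seed=5)
peptides = data[["start", "end"]].drop_duplicates().to_numpy()
stats = coverage_stats([tuple(p) for p in peptides], 549)
print(
    f"{stats.n_peptides} peptides, {stats.coverage_percent:.1f}% coverage, "
    f"redundancy {stats.mean_redundancy:.2f}"
)

diff = delta_rfu(data, "S1P")
tm8 = diff[(diff.start >= 353) & (diff.end <= 375) & (diff.exposure_min == 1.0)]
print(f"\nTM8 at 1 min (substrate entry): mean dRFU = {tm8.delta_rfu.mean():+.3f}")

syn = synergy(data)
at60 = syn[syn.exposure_min == 60.0]
print("\ngate-segment synergy at 60 min (pooled over covering peptides):")
for name in ("TM1e", "TM2e", "TM6e", "TM7e", "TM11e"):
    seg = next(s for s in SEGMENTS if s.name == name)
    inside = at60[(at60.start >= seg.start) & (at60.end <= seg.end)]
    pooled, se, p_one = pool_synergy(inside)
    print(f"  {name:6s} S = {pooled:+.3f} +- {se:.3f}  one-sided p = {p_one:.2g}")
# Early protection of TM8 marks lateral substrate entry; positive, significant
# S across the extracellular helix ends is the super-additive gate opening.
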