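"""Profile conservation of a cysteine-rich domain in a protein alignment.

Simulates a 50-sequence gapped alignment whose reference carries ten
perfectly conserved cysteine columns (two C1/C2-like clusters of five) on
a weakly conserved background, strips majority-gapped columns, scores
each retained column by 1 - H/ln(20), checks the anchored cysteines, and
tests whether the motif region is more conserved than the rest.
"""

import numpy as np

from midlink.conservation import (
    MotifSpec,
    conservation_profile,
    map_reference_positions,
    motif_conservation,
    region_vs_rest_test,
)
from midlink.synthetic import MsaSimConfig, simulate_msa

cys = (20, 30, 40, 50, 60, 140, 150, 160, 170, 180)  # two clusters of five
cfg = MsaSimConfig(
    n_seqs=50, length=200, motif_positions=cys,
    motif_conservation=0.97, background_conservation=0.3, gap_rate=0.05, seed=7,
)
msa = simulate_msa(cfg)
profile = conservation_profile(msa, max_gap_fraction=0.5)
print(f"alignment: {msa.n_seqs} sequences x {msa.length} columns")
print(f"retained after gap stripping: {profile.scores.size} columns")
print(f"mean conservation, all retained columns: {profile.scores.mean():.3f}\n")

spec = MotifSpec(reference_id="reference", positions=cys, expected_residue="C")
print("anchored cysteines (reference position -> alignment column, conserved fraction):")
for rec in motif_conservation(msa, spec):
    print(f"  position {rec.position:>3} -> column {rec.column:>3}   {rec.fraction:.2f}")

cols = map_reference_positions(msa, "reference", cys)
retained = [int(np.flatnonzero(profile.column_map == c)[0]) + 1 for c in cols]
res = region_vs_rest_test(profile, retained, n_perm=999, seed=1)
print(
    f"\nmotif region vs rest: mean score difference {res.observed_diff:+.3f}, "
    f"permutation p = {res.p_value:.3f}"
)
print(
    "The ten cysteine columns score near 1 while the background sits near the"
    "\nentropy of a weakly conserved column; the permutation test confirms the"
    "\ndomain is more conserved than the rest of the protein."
)
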