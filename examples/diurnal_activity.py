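"""Compare diurnal locomotor profiles of control and knockdown genotypes.

Simulates 7 days of 5-minute beam-crossing counts for 16 flies per
genotype under a 12/12 light/dark cycle — the knockdown genotype has its
morning activity peak and lights-off anticipation ramp reduced to 20% —
then filters inactive flies, rebins to 30 minutes, builds daily profiles,
and runs the mixed two-way repeated-measures ANOVA with per-bin contrasts.
"""

import numpy as np

from midlink.activity import (
    daily_profile,
    filter_inactive,
    per_bin_comparison,
    per_fly_profiles,
    rebin,
    transition_indices,
)
from midlink.synthetic import ActivitySimConfig, morning_peak_bins, simulate_activity

cfg = ActivitySimConfig(
    n_flies_per_genotype=16, n_days=7, knockdown_multiplier=0.2, seed=11
)
table = simulate_activity(cfg, ["control", "knockdown"], knockdown=["knockdown"])
table, removed = filter_inactive(table)
print(f"recording: {table.n_bins} x 5-min bins, {len(table.fly_ids)} flies "
      f"({len(removed)} discarded as inactive)")

table30 = rebin(table, 30)
profile = daily_profile(table30)
for geno in profile.mean:
    ti = transition_indices(profile.mean[geno], table.schedule)
    print(
        f"{geno:>10}: daily total {profile.mean[geno].sum():6.1f} counts, "
        f"light/dark ratio {ti.light_dark_ratio:.2f}, "
        f"lights-off anticipation {ti.anticipation_off:.2f}"
    )

cmp_ = per_bin_comparison(per_fly_profiles(table30))
geno_eff = cmp_.anova.effect("group")
inter = cmp_.anova.effect("group_x_within")
print(f"\ngenotype effect: F = {geno_eff.F:.1f}, p = {geno_eff.p:.2g}")
print(f"genotype x time interaction: F = {inter.F:.1f}, p = {inter.p:.2g}")
bins = morning_peak_bins(cfg)
print(f"morning-peak bins flagged at P < 0.05: "
      f"{int(cmp_.flagged[bins].sum())}/{bins.size}")
print(
    "\nThe knockdown's lower light/dark ratio and anticipation index, and the"
    "\nflagged half-hour bins under the morning peak, reproduce the signature"
    "\nof a reduced morning activity peak."
)
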