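"""How long does sib mating take to fix a mouse-scale genome?

Simulates brother-sister inbreeding from an F1 pair over 20 linkage groups
(~14 Morgans) and reports three landmarks: the filial generation at which
the strain's segregating genome fraction first drops below 1%, the
generation of complete fixation, and — for a panel of 22 strains, the size
of a complete consomic panel — the generation by which every strain is
fixed.  Also prints the two closed-form panel quantities.
"""

import numpy as np

import mosaicmap as mm
from mosaicmap.panel import (conversion_rate_estimate,
                             expected_background_donor_fraction,
                             fixation_time_study)

genome = mm.mouse_default(snp_spacing_bp=50_000_000, invariant_spacing_bp=None)
rng = np.random.default_rng(9)
study = fixation_time_study(genome, n_strains=22, n_lineages=300, n_panels=12,
                            rng=rng)
print(f"{study.n_lineages} lineages, {study.n_panels} panels of "
      f"{study.n_strains_per_panel}:")
print(f"  <1% heterozygosity at generation {study.mean_generation_het_below_1pct:.1f}")
print(f"  complete fixation at generation  {study.mean_generation_fixed:.1f}")
print(f"  whole panel fixed at generation  {study.mean_generation_panel_fixed:.1f}")

pct = 100 * expected_background_donor_fraction(9)
print(f"\nN10 consomic background donor fraction: 0.5^9 = {pct:.2f}%")
conv = conversion_rate_estimate([17, 7, 4], typical_informative=200_000)
print(f"gene-conversion genome fraction: {conv:.4f}%")
print("\nEven at 20+ generations of inbreeding a strain often still")
print("segregates somewhere; panel-wide fixation takes ~50 generations.")
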