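"""Attributing sequence variants to one of the two rDNA arrays.

BAC sequencing samples only NOR2; whole-genome (WG) sequencing mixes NOR2
and NOR4 (~400 units each of ~800 total).  Comparing the two allele
frequencies of a variant deconvolves its NOR4 frequency and classifies it.
"""

from rdnakit import (attribute, deconvolve_af, ets_its_ratio, filter_min_af,
                     simulate_af_tables)
from rdnakit.alleles import AlleleRecord

# AF floor: a variant on a single unit of ~800 has AF 100/800 = 0.125%.
records = [AlleleRecord(100, "C", "T", af, "WG") for af in (0.05, 0.125, 3.0)]
print(f"AF floor keeps {len(filter_min_af(records, total_copies=800))} of "
      f"{len(records)} records (floor 0.125%)")

# The CAT insertion: ~25% AF in BAC reads, ~9% in WG reads.
est = deconvolve_af(af_bac=25, af_wg=9, n2=400, n4=400)
call = attribute(25, 9)
print(f"CAT insertion: NOR4 AF estimate {est.value}% "
      f"(raw {est.raw}%, clamped={est.clamped}) -> {call.classification}")

# Simulated read sampling at depth 10^4 recovers planted classes:
bac, wg = simulate_af_tables(true_af_nor2=20.0, true_af_nor4=2.0,
                             read_depth=10_000, seed=4)
print(f"simulated AFs: BAC {bac[0].af:.2f}%, WG {wg[0].af:.2f}% -> "
      f"{attribute(bac[0].af, wg[0].af).classification}")

# ETS/ITS read fraction: spacers are present in pre-rRNA only, so a
# successful ribosome capture depletes them ~tenfold.
total_rna = {"5'-ETS": 10, "25S": 90}
ribo = {"5'-ETS": 1, "25S": 99}
print(f"ETS/ITS depletion ratio (total RNA / ribo capture): "
      f"{ets_its_ratio(total_rna, ribo):.1f}")
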