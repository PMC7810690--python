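"""Barcode codecs: feature codes and SalI length classes of rDNA units.

Each ~10 kb rDNA repeat unit is summarized by two barcodes: a four-digit
feature code [promoters][AvaI][CAT][3'-ETS variant] with an optional
deletion suffix, and a string of SalI box length-class letters.
"""

from rdnakit import (FeatureCode, SalIBoxProfile, classify_sali_length,
                     decode_feature_code, encode_feature_code)

# A unit with 2 promoters, no AvaI site, no CAT insertion, long 3'-ETS:
code = encode_feature_code(FeatureCode(promoters=2, avaI=0, cat=0, ets_variant=1))
print(f"2 promoters, AvaI-, CAT-, variant 1  ->  {code!r}")

# Deletion classes ride as a suffix letter (A-D, by deleted window/length):
fc = decode_feature_code("2003C")
print(f"'2003C' decodes to {fc} (270 bp deletion in the 18S)")

# SalI boxes classify by 50-bp length bins; e.g. 275 bp -> E, 1275 bp -> Z:
for length in (275, 1275, 1812):
    print(f"SalI box of {length:>4} bp  ->  class {classify_sali_length(length)!r}")

profile = SalIBoxProfile.from_lengths([260, 260, 1080])
print(f"boxes 260+260+1080 bp  ->  SalI code {profile.code!r}")
# The combined token '2001(EZ)' etc. is what catalogs and overlap tools use.
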