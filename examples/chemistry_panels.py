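"""Truncation and mixed-chemistry panels on one off-target site.

Reproduces, qualitatively, two design strategies that suppress off-target
splicing while keeping the on-target effect:

* shortening the 18-mer to 14 or 10 nt removes the canonical-pair budget
  needed to engage the degraded off-target site (grades drop to NONE),
  while every truncation stays STRONG on its own perfect footprint;
* replacing MOE blocks with OMe charges the remaining mismatches/wobbles
  to a less tolerant chemistry, and designs whose longest uninterrupted
  MOE run falls below six cannot grade STRONG on an imperfect site.
"""

import pandas as pd

from asoscan import competence_series, fixture_catalogue

cat = fixture_catalogue()
wt_site = cat["targets"]["POLR2H"].site_seq
m3_site = cat["targets"]["POLR2H_M3"].site_seq
iss_site = cat["iss_n1_region"].site_seq

short = [cat["asos"][n] for n in ("F18MOE", "F14MOE", "M14MOE", "L14MOE", "F10MOE")]
mixed = [cat["asos"][n] for n in ("F18MOE", "OMe1-6", "OMe4-9", "OMe7-13",
                                  "OMe10-15", "OMe13-18", "OMe1-12", "OMe1-12/16-18")]

for label, site in (("degraded off-target site (WT)", wt_site),
                    ("fully restored site (M3)", m3_site),
                    ("perfect on-target footprint", iss_site)):
    print(f"\n=== truncation series vs {label} ===")
    print(pd.DataFrame(competence_series(short, site))[
        ["aso", "length", "n_canonical", "n_noncanonical", "grade"]].to_string(index=False))

print("\n=== mixed-chemistry series vs the degraded off-target site ===")
print(pd.DataFrame(competence_series(mixed, wt_site))[
    ["aso", "n_canonical", "n_noncanonical", "grade", "reasons"]].to_string(index=False))
print("\nA grade of NONE for a design that is STRONG as the uniform 18-mer "
      "means the chemistry replacement, not the sequence, removed the "
      "off-target competence.")
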