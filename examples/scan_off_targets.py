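"""Scan the packaged off-target fixtures with the 18-mer MOE ASO.

Runs the wobble/bulge-tolerant duplex scan over the eight degraded exonic
sites and the intron-7 start, prints one row per hit (coordinates 1-based
inclusive) and a duplex diagram for the strongest off-target.  The grade
column is the chemistry-aware competence verdict: the fully MOE-modified
18-mer tolerates the 3-5 non-canonical pairings of every site (STRONG),
while its OMe sequence-match tolerates none of them (NONE).
"""

from asoscan import ExonAnnotation, SitePolicy, align_duplex, fixture_catalogue, render_duplex, scan_sequence
from asoscan.io import hits_to_frame

cat = fixture_catalogue()
f18moe = cat["asos"]["F18MOE"]
f18ome = cat["asos"]["F18OMe"]

for aso in (f18moe, f18ome):
    hits = []
    annotations = {}
    for gene in ("POLR2H", "PITHD1", "SERPINB7", "RTTN", "REV3L", "PRKRA", "GOLGA4", "PAK1"):
        rec = cat["targets"][gene]
        hits.extend(scan_sequence(aso, rec.target_id, rec.sequence))
        annotations[rec.target_id] = ExonAnnotation(rec.target_id, rec.exons)
    table = hits_to_frame(hits, aso, policy=SitePolicy(), annotations=annotations)
    print(f"\n=== {aso.name} ===")
    print(table[["target_id", "start", "end", "score", "n_canonical", "n_wobble",
                 "n_mismatch", "n_bulge", "context", "grade"]].to_string(index=False))

site = cat["targets"]["POLR2H"].site_seq
print("\nStrongest off-target duplex (14 canonical, 2 wobbles, 2 mismatches):")
print(render_duplex(f18moe, align_duplex(f18moe, site), site))
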