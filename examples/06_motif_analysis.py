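"""Build a DR1/PPRE matrix, derive its consensus, scan peak regions and
correct co-occurrence for knockout-null background.

The position frequency matrix comes from aligned validated response
elements; scanning slides its log2-odds scores along both strands of
400 bp regions centered on peaks and keeps hits at >=80% of the maximum
score.  Motifs as frequent in knockout-null regions as in wild-type
regions are flagged as background.
"""

from nrcistrome import (
    MotifParams,
    build_pfm,
    consensus_iupac,
    motif_tree,
    region_cooccurrence,
    reverse_complement,
    scan_region,
)

# aligned validated DR1-type sites; position 4 is fully degenerate
sites = ["GGGACAAAGGTCA", "GGGCCAAAGGTCA", "GGGGCAAAGGTCA", "GGGTCAAAGGTCA"]
ppre = build_pfm(sites, name="PPRE_DR1")
print("PPRE consensus:", consensus_iupac(ppre))

region = "ATCGGCTA" * 6 + "GGGTCAAAGGTCA" + "TTAGGCAT" * 6
for hit in scan_region(region, ppre):
    print(f"hit at offset {hit.offset} strand {hit.strand} "
          f"score fraction {hit.score_fraction:.2f}")
for hit in scan_region(reverse_complement(region), ppre):
    print(f"on the reverse complement: offset {hit.offset} strand {hit.strand}")

# co-occurrence with a background correction: 'shared' appears equally in
# wild-type and knockout-null regions, so it is omitted
import numpy as np

rng = np.random.default_rng(0)
rand = lambda: "".join(rng.choice(list("ACGT"), 80))
wt = [s[:10] + "GGGTCAAAGGTCA" + s[23:40] + "TGACGTCATGACG" + s[53:]
      for s in (rand() for _ in range(20))]
null = [s[:40] + "TGACGTCATGACG" + s[53:] for s in (rand() for _ in range(20))]
shared = build_pfm(["TGACGTCATGACG"] * 4, name="shared")
result = region_cooccurrence({"wt_regions": wt}, [ppre, shared], null_regions=null)
print("fractions:", {m: round(f["wt_regions"], 2) for m, f in result["fractions"].items()})
print("retained:", result["retained"], " background:", result["background"])

print("similarity tree:", motif_tree([ppre, shared,
                                      build_pfm(["GGGACAAAGGTTA"] * 3, name="DR1_variant")]))
# The newick tree groups matrices by best column correlation over all
# ungapped alignments and both orientations; the DR1 variant joins the PPRE.
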