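"""Designate strong and weak κB sites in a small promoter-like sequence.

Builds an affinity table containing the two reference sites — GGGAAATTCC
(strong, Z = 14) and GGGAAGTTCC (weak, Z = 5.8) — plants both in a short
sequence (the weak one on the reverse strand), and scans it.
"""

from kbsites import ZScoreTable, designate_sites, reverse_complement

table = ZScoreTable(
    {"GGGAAATTCC": 14.0, "GGGAAGTTCC": 5.8, "GGGCTTTTCC": 3.1},
    source_label="reference sites",
)

promoter = (
    "TTACGATCAG" + "GGGAAATTCC"                      # strong site at +10
    + "ACCGT" + reverse_complement("GGGCTTTTCC")     # weak site, reverse strand
    + "GATTACAGGA" + "GGGAAGTTCC" + "CCATG"          # weak site at +45
)

print(f"scanning {len(promoter)} bp against a {len(table)}-entry table\n")
print("start  strand  kmer        Z      mm  class")
for site in designate_sites(promoter, table):
    print(
        f"{site.start:5d}  {site.strand:>6}  {site.kmer}  {site.z_score:5.1f}"
        f"  {site.mismatches:2d}  {site.site_class}"
    )
print(
    "\nEach line is one designated site: its 0-based offset, the strand whose"
    "\n10-mer is in the table, the affinity Z-score, mismatches to the"
    "\nGGGRNNYYCC consensus, and the strong/weak call (boundary Z = 6)."
)
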