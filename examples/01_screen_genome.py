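"""Screen a tiny annotated genome for contamination.

Builds a four-contig yeast-like proteome in memory, with one contig of
bacterial proteins and one contig of proteins that find no database hit,
then runs the full screen at the kingdom rank and prints the per-contig
verdicts.
"""

from contigscreen import (
    QueryGenomeSpec,
    RankedLineage,
    TaxonomyTable,
    decontaminate,
)
from contigscreen.hits import HitList, HitRecord

taxonomy = TaxonomyTable([
    RankedLineage(4932, {"superkingdom": "Eukaryota", "kingdom": "Fungi",
                         "phylum": "Ascomycota", "class": "Saccharomycetes",
                         "order": "Saccharomycetales",
                         "family": "Saccharomycetaceae"}),
    RankedLineage(562, {"superkingdom": "Bacteria", "kingdom": "Bacteria_k",
                        "phylum": "Pseudomonadota",
                        "class": "Gammaproteobacteria",
                        "order": "Enterobacterales",
                        "family": "Enterobacteriaceae"}),
])

# 8 proteins on 4 contigs; b* sit on a bacterial contaminant contig,
# u* find nothing in the reference.
proteome = {pid: "MKTAYIAKQR" for pid in
            ["h1", "h2", "h3", "h4", "b1", "b2", "u1", "u2"]}
membership = {"h1": "ctgA", "h2": "ctgA", "h3": "ctgB", "h4": "ctgB",
              "b1": "ctgC", "b2": "ctgC", "u1": "ctgD", "u2": "ctgD"}


def hits(pid, taxid, n=5):
    return HitList.from_hits(pid, [
        HitRecord(pid, f"{pid}_s{i}", taxid, 200.0 - i, 85.0) for i in range(n)
    ])


hit_lists = {pid: hits(pid, 4932) for pid in ["h1", "h2", "h3", "h4"]}
hit_lists.update({pid: hits(pid, 562) for pid in ["b1", "b2"]})

genome = QueryGenomeSpec("yeast_demo", taxonomy[4932])
report = decontaminate(proteome, membership, hit_lists, taxonomy, genome,
                       rank="kingdom", threshold=0.5)

print("contig   host alien uncl  alien_frac decision")
for v in report.verdicts:
    print(f"{v.contig_id:8s} {v.votes_host:4d} {v.votes_alien:5d} "
          f"{v.votes_unclassified:4d}  {v.alien_fraction:10.2f} {v.decision}")
print(f"\nkept {len(report.kept_proteins)} / removed "
      f"{len(report.removed_proteins)} proteins")
# ctgC is removed with both proteins (all votes bacterial); ctgD is kept
# because no-hit proteins are unclassified, never treated as alien.
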