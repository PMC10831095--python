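"""Why contig context distinguishes HGT from contamination.

A horizontally transferred gene is integrated into a host chromosome: its
alien taxon call is outvoted by the host genes around it. A contaminant
contig (or a non-integrated plasmid) is alien throughout and loses the
vote at any threshold. This example builds both situations from explicit
per-protein calls and prints the verdicts.
"""

from contigscreen import (
    ProteinTaxonCall,
    QueryGenomeSpec,
    RankedLineage,
    TaxonomyTable,
    contig_consensus,
)

taxonomy = TaxonomyTable([
    RankedLineage(4932, {"superkingdom": "Eukaryota", "kingdom": "Fungi"}),
])
genome = QueryGenomeSpec("fungus", taxonomy[4932])


def call(pid, label):
    return ProteinTaxonCall(pid, "kingdom", label, 1.0, 1, 1)


# chromosome: 1 bacterial-labelled HGT gene among 10 fungal genes
chromosome = [call("hgt_gene", "Bacteria_k")] + [
    call(f"host{i}", "Fungi") for i in range(10)
]
# plasmid: 5 proteins, every one bacterial
plasmid = [call(f"pl{i}", "Bacteria_k") for i in range(5)]

membership = {c.protein_id: "chromosome_1" for c in chromosome}
membership.update({c.protein_id: "plasmid_1" for c in plasmid})

for v in contig_consensus(chromosome + plasmid, membership, genome,
                          "kingdom", threshold=0.5):
    print(f"{v.contig_id:14s} alien {v.votes_alien}/{v.votes_alien + v.votes_host}"
          f"  alien_fraction={v.alien_fraction:.2f}  -> {v.decision}")
# chromosome_1 is KEPT (1/11 alien, below threshold): the HGT gene survives.
# plasmid_1 is REMOVED (5/5 alien): indistinguishable from contamination.
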