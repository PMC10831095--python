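"""Taxon support ratios: a quick per-protein contamination diagnostic.

The support ratio is the fraction of a protein's ten best database hits
whose taxon label matches the expected host taxon. Genuine host proteins
sit near 1, contaminants near 0. Here we compute it for host and
contaminant proteins drawn from a mock reference.
"""

from contigscreen import mock_reference, taxon_support_ratio
from contigscreen.hits import ToySearcher, filter_hits

mock = mock_reference(
    taxa=[
        (1001, {"superkingdom": "Eukaryota", "kingdom": "Fungi",
                "phylum": "Ascomycota", "class": "Saccharomycetes",
                "order": "Saccharomycetales", "family": "Saccharomycetaceae"},
         20),
        (2001, {"superkingdom": "Bacteria", "kingdom": "Bacteria_k",
                "phylum": "Pseudomonadota", "class": "Gammaproteobacteria",
                "order": "Enterobacterales", "family": "Enterobacteriaceae"},
         20),
    ],
    divergence=0.05,
    seed=0,
)

host = mock.sample_proteome(1001, 10, seed=1)
contaminant = mock.sample_proteome(2001, 10, seed=2)
searcher = ToySearcher(mock.reference, mock.taxid_map)
hit_lists = searcher.search({**host, **contaminant})

print("protein          origin       support(Fungi @ kingdom)")
for pid in list(host) + list(contaminant):
    hl = filter_hits(hit_lists[pid], min_pident=20.0)
    ratio = taxon_support_ratio(hl, "Fungi", "kingdom", mock.taxonomy)
    origin = "host" if pid in host else "contaminant"
    print(f"{pid:16s} {origin:12s} {'NA' if ratio is None else f'{ratio:.2f}'}")
# Host proteins score 1.00 (all top hits fungal); contaminants score 0.00.
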