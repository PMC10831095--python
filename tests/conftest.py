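import pytest
from hypothesis import settings

from contigscreen.hits import HitList, HitRecord
from contigscreen.taxonomy import RankedLineage, TaxonomyTable

settings.register_profile("default", deadline=None, derandomize=True)
settings.load_profile("default")

# Small fixed taxonomy used across the suite: a bacterium, two fungi, a
# metazoan, and a fungus with no class label (tests the ABSENT pathway).
LINEAGES = {
    562: {"superkingdom": "Bacteria", "kingdom": "Bacteria_k",
          "phylum": "Pseudomonadota", "class": "Gammaproteobacteria",
          "order": "Enterobacterales", "family": "Enterobacteriaceae"},
    4932: {"superkingdom": "Eukaryota", "kingdom": "Fungi",
           "phylum": "Ascomycota", "class": "Saccharomycetes",
           "order": "Saccharomycetales", "family": "Saccharomycetaceae"},
    5346: {"superkingdom": "Eukaryota", "kingdom": "Fungi",
           "phylum": "Basidiomycota", "class": "Agaricomycetes",
           "order": "Agaricales", "family": "Physalacriaceae"},
    9606: {"superkingdom": "Eukaryota", "kingdom": "Metazoa",
           "phylum": "Chordata", "class": "Mammalia",
           "order": "Primates", "family": "Hominidae"},
    7777: {"superkingdom": "Eukaryota", "kingdom": "Fungi",
           "phylum": "Basidiomycota",
           "order": "Agaricales", "family": "Mycenaceae"},  # class absent
}


@pytest.fixture(scope="session")
def taxonomy() -> TaxonomyTable:
    return TaxonomyTable(
        [RankedLineage(taxid, labels) for taxid, labels in LINEAGES.items()]
    )


@pytest.fixture(scope="session")
def make_hit_list():
    """Build a HitList from (taxid, bitscore, pident[, subject_id]) tuples."""

    def _make(query_id: str, specs) -> HitList:
        hits = []
        for i, spec in enumerate(specs):
            taxid, bitscore, pident = spec[:3]
            sid = spec[3] if len(spec) > 3 else f"s{i:03d}"
            hits.append(
                HitRecord(query_id=query_id, subject_id=sid,
                          subject_taxid=taxid, bitscore=float(bitscore),
                          pident=float(pident))
            )
        return HitList.from_hits(query_id, hits)

    return _make
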