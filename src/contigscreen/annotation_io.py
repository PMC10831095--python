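"""Protein -> contig membership from standard annotation formats.

The consensus vote needs to know which contig/scaffold encodes each
protein; coordinates, strand and isoform structure are irrelevant — only
co-location matters. Three dialects are supported: GFF3 (seqid column =
contig id), a two-column TSV, and a regex extractor for pipelines that
encode the contig id in FASTA headers.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import gffutils
from Bio import SeqIO

__all__ = [
    "MembershipTable",
    "MembershipError",
    "membership_from_gff3",
    "membership_from_tsv",
    "membership_from_fasta_headers",
]


class MembershipError(ValueError):
    """Invalid or inconsistent protein->contig membership."""


@dataclass(frozen=True)
class MembershipTable:
    """Immutable ``protein_id -> contig_id`` map with a dialect tag."""

    mapping: Mapping[str, str]
    dialect: str = "tsv"

    def __post_init__(self):
        for pid, cid in self.mapping.items():
            if not cid:
                raise MembershipError(f"empty contig id for protein {pid!r}")
        object.__setattr__(self, "mapping", dict(self.mapping))

    def __getitem__(self, protein_id: str) -> str:
        return self.mapping[protein_id]

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)

    def __iter__(self) -> Iterator[str]:
        return iter(self.mapping)

    def items(self):
        return self.mapping.items()

    def keys(self):
        return self.mapping.keys()

    def values(self):
        return self.mapping.values()


def membership_from_gff3(
    gff: str | Path,
    id_attribute: str = "ID",
    feature_type: str = "CDS",
) -> MembershipTable:
    """Derive membership from a GFF3 file.

    One entry per distinct protein id; multiple feature lines of the same
    protein (e.g. the CDS segments of one gene) collapse into one entry.
    A protein with features on two different seqids is an error, since a
    protein cannot be voted on two contigs at once.
    """
    mapping: dict[str, str] = {}
    n_features = 0
    for feature in gffutils.iterators.DataIterator(str(gff)):
        if feature.featuretype != feature_type:
            continue
        n_features += 1
        values = feature.attributes.get(id_attribute)
        if not values:
            raise MembershipError(
                f"feature at {feature.seqid}:{feature.start} lacks the "
                f"{id_attribute!r} attribute"
            )
        pid = values[0]
        if pid in mapping and mapping[pid] != feature.seqid:
            raise MembershipError(
                f"protein {pid!r} spans two contigs: "
                f"{mapping[pid]!r} and {feature.seqid!r}"
            )
        mapping[pid] = feature.seqid
    if n_features == 0:
        warnings.warn(
            f"no {feature_type!r} features found in {gff}; membership is empty",
            stacklevel=2,
        )
    return MembershipTable(mapping, dialect="gff3")


def membership_from_tsv(tsv: str | Path) -> MembershipTable:
    """Two-column TSV (header: protein_id, contig_id) -> membership.

    Duplicate consistent rows deduplicate; duplicate protein ids mapped to
    different contigs are an error.
    """
    mapping: dict[str, str] = {}
    with Path(tsv).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if [h.strip() for h in header[:2]] != ["protein_id", "contig_id"]:
            raise MembershipError(
                f"expected header 'protein_id\\tcontig_id', got {header!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise MembershipError(
                    f"line {lineno}: expected 2 columns, got {len(parts)}"
                )
            pid, cid = parts[0].strip(), parts[1].strip()
            if pid in mapping and mapping[pid] != cid:
                raise MembershipError(
                    f"line {lineno}: protein {pid!r} mapped to both "
                    f"{mapping[pid]!r} and {cid!r}"
                )
            mapping[pid] = cid
    return MembershipTable(mapping, dialect="tsv")


def membership_from_fasta_headers(
    fasta: str | Path, contig_pattern: str
) -> MembershipTable:
    """Extract contig ids from FASTA headers via a regex.

    ``contig_pattern`` must contain one capturing group; it is searched in
    each full header line (id + description). Headers without a match are
    an error — a silent fallback would scatter proteins across phantom
    contigs.
    """
    regex = re.compile(contig_pattern)
    if regex.groups != 1:
        raise MembershipError(
            f"contig_pattern needs exactly one capturing group: {contig_pattern!r}"
        )
    mapping: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta), "fasta"):
        m = regex.search(rec.description)
        if not m:
            raise MembershipError(
                f"header of {rec.id!r} does not match {contig_pattern!r}"
            )
        mapping[rec.id] = m.group(1)
    return MembershipTable(mapping, dialect="fasta-header")
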