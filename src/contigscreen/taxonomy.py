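"""Taxonomy tables: resolve taxids to labels at the six fixed ranks.

Every taxonomic decision in this package is made at one of six ranks of
decreasing breadth: superkingdom, kingdom, phylum, class, order, family.
A :class:`TaxonomyTable` maps taxids to :class:`RankedLineage` objects
carrying labels at those ranks; ranks without a label are represented by
the explicit :data:`ABSENT` sentinel (never silently coerced to a name or
an empty string, because absent labels must translate into *unclassified*
votes downstream, not into host or alien evidence).

The canonical on-disk format is a flat lineage TSV (``taxid`` plus the six
rank columns; empty cell = absent). NCBI-style ``nodes.dmp``/``names.dmp``
dumps are supported through a converter that climbs parent chains once at
load time to collect the six ranks.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

__all__ = [
    "RANKS",
    "ABSENT",
    "RankedLineage",
    "TaxonomyTable",
    "load_taxonomy",
    "TaxonomyError",
    "TaxonomyParseError",
    "UnknownTaxidError",
    "UnknownRankError",
]

#: The fixed rank ladder, from broadest to narrowest.
RANKS: tuple[str, ...] = (
    "superkingdom",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
)


class _AbsentType:
    """Singleton marker for a rank with no label (distinct from '')."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "ABSENT"

    def __bool__(self) -> bool:
        return False


ABSENT = _AbsentType()

Label = Union[str, _AbsentType]


class TaxonomyError(Exception):
    """Base class for taxonomy problems."""


class TaxonomyParseError(TaxonomyError):
    """Malformed taxonomy source; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message}" + (f" (line {line})" if line else ""))


class UnknownTaxidError(TaxonomyError, KeyError):
    """Lookup of a taxid absent from the table."""

    def __init__(self, taxid: int):
        self.taxid = taxid
        super().__init__(f"taxid {taxid} is not present in the taxonomy table")

    def __str__(self) -> str:  # KeyError would quote the repr
        return self.args[0]


class UnknownRankError(TaxonomyError, ValueError):
    """A rank outside the six-rank ladder."""

    def __init__(self, rank: str):
        super().__init__(
            f"rank {rank!r} is not in the ladder {', '.join(RANKS)}"
        )


def _check_rank(rank: str) -> None:
    if rank not in RANKS:
        raise UnknownRankError(rank)


@dataclass(frozen=True)
class RankedLineage:
    """Labels of one taxon at the six fixed ranks; gaps allowed.

    Parameters
    ----------
    taxid:
        Positive integer identifier.
    labels:
        Mapping from rank name to taxon label. Only ranks with a label are
        stored; at least one rank must be labelled. Names are
        whitespace-trimmed and compared case-sensitively.
    """

    taxid: int
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.taxid <= 0:
            raise TaxonomyError(f"taxid must be positive, got {self.taxid}")
        clean: dict[str, str] = {}
        for rank, name in self.labels.items():
            _check_rank(rank)
            name = name.strip()
            if name:
                clean[rank] = name
        if not clean:
            raise TaxonomyError(
                f"lineage for taxid {self.taxid} has no labelled rank"
            )
        object.__setattr__(self, "labels", clean)

    def label(self, rank: str) -> Label:
        """Label at ``rank``, or :data:`ABSENT` when the rank has none."""
        _check_rank(rank)
        return self.labels.get(rank, ABSENT)


class TaxonomyTable:
    """Immutable map taxid -> :class:`RankedLineage` with strict lookup."""

    def __init__(self, lineages: Iterable[RankedLineage], provenance: str = "flat-tsv"):
        table: dict[int, RankedLineage] = {}
        for lin in lineages:
            if lin.taxid in table:
                raise TaxonomyError(f"duplicate taxid {lin.taxid}")
            table[lin.taxid] = lin
        self._table = table
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self._table)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._table

    def __iter__(self):
        return iter(self._table.values())

    def __getitem__(self, taxid: int) -> RankedLineage:
        try:
            return self._table[taxid]
        except KeyError:
            raise UnknownTaxidError(taxid) from None

    def label_at_rank(self, taxid: int, rank: str) -> Label:
        """Label of ``taxid`` at ``rank``; ABSENT if unlabelled there.

        Raises :class:`UnknownTaxidError` for taxids not in the table and
        :class:`UnknownRankError` for ranks outside the ladder.
        """
        return self[taxid].label(rank)

    def to_flat_tsv(self, path: str | Path) -> None:
        """Write the canonical flat lineage TSV (empty cell = ABSENT)."""
        path = Path(path)
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(("taxid",) + RANKS)
            for taxid in sorted(self._table):
                lin = self._table[taxid]
                writer.writerow(
                    [taxid] + [lin.labels.get(rank, "") for rank in RANKS]
                )


def _load_flat_tsv(path: Path) -> TaxonomyTable:
    lineages = []
    seen: set[int] = set()
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise TaxonomyParseError("empty lineage file", line=1) from None
        expected = ["taxid", *RANKS]
        if [h.strip() for h in header] != expected:
            raise TaxonomyParseError(
                f"header must be {expected}, got {header}", line=1
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 7:
                raise TaxonomyParseError(
                    f"expected 7 columns, got {len(row)}", line=lineno
                )
            try:
                taxid = int(row[0])
            except ValueError:
                raise TaxonomyParseError(
                    f"non-integer taxid {row[0]!r}", line=lineno
                ) from None
            if taxid in seen:
                raise TaxonomyParseError(
                    f"duplicate taxid {taxid}", line=lineno
                )
            seen.add(taxid)
            labels = {
                rank: cell for rank, cell in zip(RANKS, row[1:]) if cell.strip()
            }
            try:
                lineages.append(RankedLineage(taxid, labels))
            except TaxonomyError as exc:
                raise TaxonomyParseError(str(exc), line=lineno) from None
    try:
        return TaxonomyTable(lineages, provenance="flat-tsv")
    except TaxonomyError as exc:
        raise TaxonomyParseError(str(exc)) from None


def _parse_dmp(path: Path):
    # NCBI dump rows are "<tab>|<tab>"-delimited and end with "\t|".
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t|")]
            yield lineno, fields


def _load_ncbi_dump(source: Path) -> TaxonomyTable:
    nodes_path = source / "nodes.dmp"
    names_path = source / "names.dmp"
    for p in (nodes_path, names_path):
        if not p.exists():
            raise TaxonomyError(f"NCBI dump file missing: {p}")

    parent: dict[int, int] = {}
    rank_of: dict[int, str] = {}
    for lineno, fields in _parse_dmp(nodes_path):
        if len(fields) < 3:
            raise TaxonomyParseError("short nodes.dmp row", line=lineno)
        try:
            taxid, par = int(fields[0]), int(fields[1])
        except ValueError:
            raise TaxonomyParseError(
                "non-integer taxid in nodes.dmp", line=lineno
            ) from None
        if taxid in parent:
            raise TaxonomyParseError(
                f"duplicate taxid {taxid} in nodes.dmp", line=lineno
            )
        parent[taxid] = par
        rank_of[taxid] = fields[2]

    sci_name: dict[int, str] = {}
    for lineno, fields in _parse_dmp(names_path):
        if len(fields) < 4:
            raise TaxonomyParseError("short names.dmp row", line=lineno)
        if fields[3] != "scientific name":
            continue
        try:
            taxid = int(fields[0])
        except ValueError:
            raise TaxonomyParseError(
                "non-integer taxid in names.dmp", line=lineno
            ) from None
        sci_name[taxid] = fields[1]

    ladder = set(RANKS)
    lineages = []
    for taxid in parent:
        labels: dict[str, str] = {}
        node = taxid
        seen: set[int] = set()
        while node not in seen:
            seen.add(node)
            rank = rank_of.get(node)
            if rank in ladder and node in sci_name:
                labels.setdefault(rank, sci_name[node])
            nxt = parent.get(node)
            if nxt is None or nxt == node:
                break
            node = nxt
        if labels:
            lineages.append(RankedLineage(taxid, labels))
    return TaxonomyTable(lineages, provenance="ncbi-dump")


def load_taxonomy(source: str | Path, dialect: str = "flat-tsv") -> TaxonomyTable:
    """Load a taxonomy table.

    Parameters
    ----------
    source:
        For ``flat-tsv``, the TSV file; for ``ncbi-dump``, the directory
        containing ``nodes.dmp`` and ``names.dmp``.
    dialect:
        ``"flat-tsv"`` (canonical) or ``"ncbi-dump"`` (converted on load;
        taxids whose entire parent chain carries none of the six ranks are
        dropped, since they can never yield a vote).
    """
    source = Path(source)
    if not source.exists():
        raise TaxonomyError(f"taxonomy source does not exist: {source}")
    if dialect == "flat-tsv":
        return _load_flat_tsv(source)
    if dialect == "ncbi-dump":
        return _load_ncbi_dump(source)
    raise ValueError(f"unknown taxonomy dialect {dialect!r}")
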