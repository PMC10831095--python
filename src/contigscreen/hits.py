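"""Ranked homology hit lists: parsing, filtering, and a built-in toy search.

Hit lists are the raw evidence behind every taxon call: for each query
protein, database hits sorted by bitscore (descending). The package either
ingests precomputed tabular output from DIAMOND/MMseqs/BLAST (12-column
``outfmt 6`` / m8, extended with a subject-taxid column) or produces hits
itself with :func:`toy_search`, a deterministic shared-k-mer scorer meant
for tests, demos and benchmarks at desk scale — not a replacement for a
real aligner.

Determinism contract: bitscore ties are broken by higher percent identity,
then lexicographic subject id, so identical inputs always yield identical
hit orderings regardless of input file row order.
"""

from __future__ import annotations

import shutil
import subprocess
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "HitRecord",
    "HitList",
    "read_tabular_hits",
    "filter_hits",
    "ToySearcher",
    "toy_search",
    "toy_search_records",
    "run_external_engine",
    "build_engine_command",
    "HitsParseError",
    "EngineNotFoundError",
]


class HitsParseError(ValueError):
    """Malformed tabular hits file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"{message}" + (f" (line {line})" if line else ""))


class EngineNotFoundError(RuntimeError):
    """The requested external search engine is not on PATH."""


@dataclass(frozen=True)
class HitRecord:
    """One ranked homology hit against the reference database."""

    query_id: str
    subject_id: str
    subject_taxid: int
    bitscore: float
    pident: float
    evalue: float | None = None

    def __post_init__(self):
        if self.subject_taxid <= 0:
            raise ValueError(f"subject_taxid must be positive: {self.subject_taxid}")
        if self.bitscore < 0:
            raise ValueError(f"bitscore must be >= 0: {self.bitscore}")
        if not 0.0 <= self.pident <= 100.0:
            raise ValueError(f"pident must be in [0, 100]: {self.pident}")


def _sort_key(hit: HitRecord):
    return (-hit.bitscore, -hit.pident, hit.subject_id)


@dataclass(frozen=True)
class HitList:
    """Hits of one query, sorted by bitscore desc (ties: pident desc, id asc)."""

    query_id: str
    hits: tuple[HitRecord, ...] = field(default_factory=tuple)

    @classmethod
    def from_hits(cls, query_id: str, hits: Iterable[HitRecord]) -> "HitList":
        hits = tuple(sorted(hits, key=_sort_key))
        for h in hits:
            if h.query_id != query_id:
                raise ValueError(
                    f"hit for {h.query_id!r} in list of {query_id!r}"
                )
        return cls(query_id, hits)

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    def __getitem__(self, i):
        return self.hits[i]

    @property
    def best(self) -> HitRecord | None:
        return self.hits[0] if self.hits else None


def read_tabular_hits(
    source: str | Path,
    taxid_column: int = 12,
    multi_taxid_policy: str = "error",
) -> dict[str, HitList]:
    """Parse a BLAST outfmt-6 / MMseqs m8 file into per-query hit lists.

    Parameters
    ----------
    source:
        Tab-delimited file with the 12 standard columns (qseqid sseqid
        pident length mismatch gapopen qstart qend sstart send evalue
        bitscore), optionally extended; alignment coordinates are ignored.
    taxid_column:
        0-based index of the column holding the subject taxid (default 12,
        i.e. a 13th ``staxids`` column).
    multi_taxid_policy:
        How to treat semicolon-separated multi-taxid cells: ``"error"``
        (default) or ``"first"``.

    Queries absent from the file simply have no entry — that is the
    legitimate "no hit in the reference database" case, not an error.
    """
    if multi_taxid_policy not in ("error", "first"):
        raise ValueError(f"unknown multi_taxid_policy {multi_taxid_policy!r}")
    source = Path(source)
    per_query: dict[str, list[HitRecord]] = defaultdict(list)
    with source.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) <= max(11, taxid_column):
                raise HitsParseError(
                    f"expected at least {max(12, taxid_column + 1)} columns, "
                    f"got {len(cols)}",
                    line=lineno,
                )
            taxid_cell = cols[taxid_column].strip()
            if ";" in taxid_cell:
                if multi_taxid_policy == "error":
                    raise HitsParseError(
                        f"multi-valued taxid cell {taxid_cell!r}; pass "
                        "multi_taxid_policy='first' to take the first value",
                        line=lineno,
                    )
                taxid_cell = taxid_cell.split(";", 1)[0].strip()
            try:
                taxid = int(taxid_cell)
                pident = float(cols[2])
                evalue = float(cols[10])
                bitscore = float(cols[11])
            except ValueError:
                raise HitsParseError(
                    "non-numeric pident/evalue/bitscore/taxid field",
                    line=lineno,
                ) from None
            try:
                rec = HitRecord(
                    query_id=cols[0],
                    subject_id=cols[1],
                    subject_taxid=taxid,
                    bitscore=bitscore,
                    pident=pident,
                    evalue=evalue,
                )
            except ValueError as exc:
                raise HitsParseError(str(exc), line=lineno) from None
            per_query[rec.query_id].append(rec)
    return {
        qid: HitList.from_hits(qid, hits) for qid, hits in per_query.items()
    }


def filter_hits(
    hit_list: HitList,
    min_pident: float = 0.0,
    excluded_taxids: frozenset[int] | set[int] = frozenset(),
) -> HitList:
    """Drop hits below ``min_pident`` or from excluded taxids; keep order.

    The identity cutoff mirrors the screening default of 20% used when
    searching against large public references; excluding the query
    genome's own taxid prevents its database-deposited proteins from
    trivially confirming the host label.
    """
    if not 0.0 <= min_pident <= 100.0:
        raise ValueError(f"min_pident must be in [0, 100]: {min_pident}")
    kept = tuple(
        h
        for h in hit_list.hits
        if h.pident >= min_pident and h.subject_taxid not in excluded_taxids
    )
    return HitList(hit_list.query_id, kept)


# --- toy k-mer search -------------------------------------------------------

TOY_BITSCORE_SCALE = 2.0  # bitscore = shared-k-mer count * scale; only order matters


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    pos: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        pos[seq[i : i + k]].append(i)
    return pos


def _diagonal_pident(query: str, subject: str, shared: set[str], k: int) -> float:
    """Approximate pident: query coverage by shared k-mers on the best diagonal."""
    if not shared or not query:
        return 0.0
    qpos = _kmer_positions(query, k)
    spos = _kmer_positions(subject, k)
    diag_hits: dict[int, list[int]] = defaultdict(list)
    for kmer in shared:
        for qi in qpos[kmer]:
            for si in spos[kmer]:
                diag_hits[qi - si].append(qi)
    best_cover = 0
    for starts in diag_hits.values():
        covered: set[int] = set()
        for qi in starts:
            covered.update(range(qi, qi + k))
        best_cover = max(best_cover, len(covered))
    return min(100.0, 100.0 * best_cover / len(query))


class ToySearcher:
    """Reusable shared-k-mer search index over a reference protein set.

    bitscore = (number of distinct shared k-mers) * 2; pident is
    approximated as query coverage by shared k-mers along the best
    alignment diagonal. Hits with zero shared k-mers are not emitted.
    Fully deterministic. Build once, query many times.
    """

    def __init__(
        self,
        reference: Mapping[str, str],
        taxid_map: Mapping[str, int],
        k: int = 4,
    ):
        if k < 3:
            raise ValueError(f"k must be >= 3, got {k}")
        missing = sorted(set(reference) - set(taxid_map))
        if missing:
            raise ValueError(
                f"reference sequences missing from taxid map: {missing[:5]}"
            )
        self.k = k
        self.reference = dict(reference)
        self.taxid_map = dict(taxid_map)
        self._index: dict[str, list[str]] = defaultdict(list)
        self._ref_kmers: dict[str, set[str]] = {}
        for sid in sorted(self.reference):
            kms = _kmers(self.reference[sid], k)
            self._ref_kmers[sid] = kms
            for km in kms:
                self._index[km].append(sid)

    def search(self, queries: Mapping[str, str]) -> dict[str, HitList]:
        out: dict[str, HitList] = {}
        for qid in queries:
            qseq = queries[qid]
            qkms = _kmers(qseq, self.k)
            counts: Counter[str] = Counter()
            for km in qkms:
                for sid in self._index.get(km, ()):
                    counts[sid] += 1
            hits = []
            for sid, n_shared in counts.items():
                shared = qkms & self._ref_kmers[sid]
                hits.append(
                    HitRecord(
                        query_id=qid,
                        subject_id=sid,
                        subject_taxid=self.taxid_map[sid],
                        bitscore=TOY_BITSCORE_SCALE * n_shared,
                        pident=_diagonal_pident(
                            qseq, self.reference[sid], shared, self.k
                        ),
                    )
                )
            out[qid] = HitList.from_hits(qid, hits)
        return out


def toy_search_records(
    queries: Mapping[str, str],
    reference: Mapping[str, str],
    taxid_map: Mapping[str, int],
    k: int = 4,
) -> dict[str, HitList]:
    """One-shot in-memory toy search (see :class:`ToySearcher`)."""
    return ToySearcher(reference, taxid_map, k=k).search(queries)


def _read_fasta(path: str | Path) -> dict[str, str]:
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        records[rec.id] = str(rec.seq)
    return records


def _read_taxid_map(path: str | Path) -> dict[str, int]:
    taxid_map: dict[str, int] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise HitsParseError("taxid map rows need 2 columns", line=lineno)
            try:
                taxid_map[parts[0]] = int(parts[1])
            except ValueError:
                raise HitsParseError(
                    f"non-integer taxid {parts[1]!r}", line=lineno
                ) from None
    return taxid_map


def toy_search(
    queries: str | Path,
    reference: str | Path,
    taxid_map: str | Path,
    k: int = 4,
) -> dict[str, HitList]:
    """File-based wrapper around :func:`toy_search_records`.

    ``queries`` and ``reference`` are amino-acid FASTA files; ``taxid_map``
    is a two-column TSV (seq_id, taxid) covering every reference sequence.
    """
    return toy_search_records(
        _read_fasta(queries), _read_fasta(reference), _read_taxid_map(taxid_map), k=k
    )


# --- external engine adapter ------------------------------------------------

M8_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend "
    "sstart send evalue bitscore staxids"
)


def build_engine_command(
    engine: str,
    queries: str | Path,
    db: str | Path,
    out: str | Path,
    sensitivity: str | None = None,
    threads: int = 1,
) -> list[str]:
    """Construct the command line for a supported external search engine."""
    queries, db, out = str(queries), str(db), str(out)
    if engine == "diamond":
        cmd = [
            "diamond", "blastp",
            "--query", queries,
            "--db", db,
            "--out", out,
            "--outfmt", "6", *M8_COLUMNS.split()[:12], "staxids",
            "--threads", str(threads),
        ]
        if sensitivity:
            cmd.append(f"--{sensitivity}")
        return cmd
    if engine == "mmseqs":
        cmd = [
            "mmseqs", "easy-search",
            queries, db, out, f"{out}.tmp",
            "--format-output", M8_COLUMNS.replace(" ", ","),
            "--threads", str(threads),
        ]
        if sensitivity is not None:
            cmd.extend(["-s", str(sensitivity)])
        return cmd
    raise ValueError(f"unsupported engine {engine!r} (expected diamond or mmseqs)")


def run_external_engine(
    engine: str,
    queries: str | Path,
    db: str | Path,
    out: str | Path,
    sensitivity: str | None = None,
    threads: int = 1,
) -> Path:
    """Run DIAMOND or MMseqs and return the path to the m8 output.

    The produced file is consumable by :func:`read_tabular_hits` with the
    default ``taxid_column=12``. Raises :class:`EngineNotFoundError` when
    the executable is not on PATH.
    """
    cmd = build_engine_command(engine, queries, db, out, sensitivity, threads)
    if shutil.which(cmd[0]) is None:
        raise EngineNotFoundError(
            f"search engine {engine!r} not found on PATH (looked for {cmd[0]!r})"
        )
    subprocess.run(cmd, check=True)
    return Path(out)
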