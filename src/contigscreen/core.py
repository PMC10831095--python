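"""The decontamination decision procedure.

Two steps turn ranked homology hits into a keep/remove decision per contig:

1. **Per-protein taxon call.** Each protein takes the taxon label of its
   best database hit at the chosen rank, with a confidence score equal to
   the fraction of agreeing labels among the top (<= ``cap``, default 10)
   hits. The sorted hit list is additionally trimmed to the maximal
   top-scoring prefix sharing the best hit's label — the size of that
   prefix is reported as the number of hits genuinely backing the call.
   Proteins with no hits, or whose best hit carries no label at the rank,
   are UNCLASSIFIED.

2. **Contig consensus.** Calls are summed per contig/scaffold: each
   protein votes *host* (label matches the query genome's expected
   lineage at the rank), *alien* (classified but different) or
   *unclassified*. A contig is removed — with every protein it encodes —
   when the alien fraction of its *classified* votes reaches the
   user-defined threshold. Contigs with only unclassified votes are kept.

This contig-context step is what separates contamination from horizontal
gene transfer: an HGT gene is a minority alien vote on a chromosome full
of host votes and survives, whereas a contaminant contig (or a
non-integrated plasmid) is alien wall-to-wall and is removed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from collections import Counter, defaultdict
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .hits import HitList, filter_hits
from .taxonomy import ABSENT, RANKS, RankedLineage, TaxonomyTable

__all__ = [
    "UNCLASSIFIED",
    "QueryGenomeSpec",
    "ProteinTaxonCall",
    "ContigVerdict",
    "DecontaminationReport",
    "trim_hit_list",
    "call_protein_taxon",
    "contig_consensus",
    "decontaminate",
    "alien_score_per_protein",
]

#: Label assigned to proteins that cannot be classified at the decision rank.
UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class QueryGenomeSpec:
    """The genome being screened and its expected lineage."""

    genome_id: str
    self_lineage: RankedLineage

    def self_label(self, rank: str) -> str:
        label = self.self_lineage.label(rank)
        if label is ABSENT:
            raise ValueError(
                f"query genome {self.genome_id!r} has no label at rank "
                f"{rank!r}; decontamination at this rank is undefined"
            )
        return label


@dataclass(frozen=True)
class ProteinTaxonCall:
    """Taxon label + confidence for one protein at one rank."""

    protein_id: str
    rank: str
    label: str  # taxon name or UNCLASSIFIED
    confidence: float
    n_hits_total: int
    n_hits_retained: int

    def __post_init__(self):
        if (self.label == UNCLASSIFIED) != (self.confidence == 0.0):
            raise ValueError(
                "label is UNCLASSIFIED if and only if confidence is 0"
            )
        if self.n_hits_retained > self.n_hits_total:
            raise ValueError("n_hits_retained cannot exceed n_hits_total")


@dataclass(frozen=True)
class ContigVerdict:
    """Vote tallies and keep/remove decision for one contig."""

    contig_id: str
    rank: str
    n_proteins: int
    votes_host: int
    votes_alien: int
    votes_unclassified: int
    alien_fraction: float
    decision: str  # KEEP or REMOVE
    dominant_alien_label: str  # taxon name or NONE

    def __post_init__(self):
        if self.votes_host + self.votes_alien + self.votes_unclassified != self.n_proteins:
            raise ValueError("votes must sum to n_proteins")
        if self.decision not in ("KEEP", "REMOVE"):
            raise ValueError(f"bad decision {self.decision!r}")


@dataclass(frozen=True)
class DecontaminationReport:
    """Outcome of one screening run; kept/removed partition the proteome."""

    kept_proteins: tuple[str, ...]      # input order preserved
    removed_proteins: tuple[str, ...]   # input order preserved
    verdicts: tuple[ContigVerdict, ...]
    calls: Mapping[str, ProteinTaxonCall]
    membership: Mapping[str, str]
    parameters: Mapping[str, object]

    def __post_init__(self):
        kept, removed = set(self.kept_proteins), set(self.removed_proteins)
        if kept & removed:
            raise ValueError("kept and removed protein sets overlap")

    @property
    def kept_set(self) -> frozenset[str]:
        return frozenset(self.kept_proteins)

    @property
    def removed_set(self) -> frozenset[str]:
        return frozenset(self.removed_proteins)


def trim_hit_list(
    hit_list: HitList, rank: str, taxonomy: TaxonomyTable
) -> HitList:
    """Maximal top-scoring prefix whose labels all match the best hit's.

    Hits whose lineage is ABSENT at ``rank`` terminate the prefix; an
    empty input (or a best hit with no label at the rank) yields an empty
    list. This non-fixed window is what makes the call robust to isolated
    mislabelled reference proteins further down the list.
    """
    if not hit_list.hits:
        return HitList(hit_list.query_id, ())
    best_label = taxonomy.label_at_rank(hit_list.hits[0].subject_taxid, rank)
    if best_label is ABSENT:
        return HitList(hit_list.query_id, ())
    prefix = []
    for hit in hit_list.hits:
        label = taxonomy.label_at_rank(hit.subject_taxid, rank)
        if label is ABSENT or label != best_label:
            break
        prefix.append(hit)
    return HitList(hit_list.query_id, tuple(prefix))


def call_protein_taxon(
    hit_list: HitList | None,
    rank: str,
    taxonomy: TaxonomyTable,
    cap: int = 10,
) -> ProteinTaxonCall:
    """Assign a taxon label and confidence to one protein at ``rank``.

    The label comes from the best hit; confidence is the fraction of the
    top ``min(cap, n)`` hits agreeing with it. ``hit_list=None`` (or an
    empty list) is the no-hit case and yields UNCLASSIFIED at confidence 0.
    """
    if cap < 1:
        raise ValueError(f"cap must be >= 1, got {cap}")
    if rank not in RANKS:
        raise ValueError(f"rank {rank!r} not in ladder {RANKS}")
    if hit_list is None or not hit_list.hits:
        pid = hit_list.query_id if hit_list is not None else ""
        return ProteinTaxonCall(pid, rank, UNCLASSIFIED, 0.0, 0, 0)

    n_total = len(hit_list)
    best_label = taxonomy.label_at_rank(hit_list.hits[0].subject_taxid, rank)
    retained = len(trim_hit_list(hit_list, rank, taxonomy))
    if best_label is ABSENT:
        return ProteinTaxonCall(
            hit_list.query_id, rank, UNCLASSIFIED, 0.0, n_total, retained
        )
    window = min(cap, n_total)
    agree = sum(
        1
        for hit in hit_list.hits[:window]
        if taxonomy.label_at_rank(hit.subject_taxid, rank) == best_label
    )
    return ProteinTaxonCall(
        protein_id=hit_list.query_id,
        rank=rank,
        label=best_label,
        confidence=agree / window,
        n_hits_total=n_total,
        n_hits_retained=retained,
    )


def contig_consensus(
    calls: Iterable[ProteinTaxonCall],
    membership: Mapping[str, str],
    genome: QueryGenomeSpec,
    rank: str,
    threshold: float = 0.5,
) -> list[ContigVerdict]:
    """Summarize per-protein votes into per-contig keep/remove verdicts.

    A protein votes host when its label equals the genome's own label at
    ``rank``, alien when it is classified but differs, unclassified
    otherwise. REMOVE iff the contig has at least one classified vote and
    ``votes_alien / (votes_host + votes_alien) >= threshold``. Fully
    unclassified contigs are kept: absence of evidence is not treated as
    evidence of contamination. Verdicts are returned sorted by contig id.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    host_label = genome.self_label(rank)

    calls = list(calls)
    missing = sorted({c.protein_id for c in calls if c.protein_id not in membership})
    if missing:
        raise KeyError(
            f"proteins missing from contig membership: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )

    by_contig: dict[str, list[ProteinTaxonCall]] = defaultdict(list)
    for call in calls:
        by_contig[membership[call.protein_id]].append(call)

    verdicts = []
    for contig_id in sorted(by_contig):
        contig_calls = by_contig[contig_id]
        host = alien = unclassified = 0
        alien_labels: Counter[str] = Counter()
        for call in contig_calls:
            if call.label == UNCLASSIFIED:
                unclassified += 1
            elif call.label == host_label:
                host += 1
            else:
                alien += 1
                alien_labels[call.label] += 1
        classified = host + alien
        alien_fraction = alien / classified if classified else 0.0
        decision = "REMOVE" if classified and alien_fraction >= threshold else "KEEP"
        if alien_labels:
            top = max(alien_labels.values())
            dominant = min(l for l, n in alien_labels.items() if n == top)
        else:
            dominant = "NONE"
        verdicts.append(
            ContigVerdict(
                contig_id=contig_id,
                rank=rank,
                n_proteins=len(contig_calls),
                votes_host=host,
                votes_alien=alien,
                votes_unclassified=unclassified,
                alien_fraction=alien_fraction,
                decision=decision,
                dominant_alien_label=dominant,
            )
        )
    return verdicts


def _write_report(
    report: DecontaminationReport,
    proteome: Mapping[str, str],
    order: list[str],
    out_dir: Path,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    kept = report.kept_set
    with (out_dir / "cleaned.faa").open("w") as fh:
        for pid in order:
            if pid in kept:
                fh.write(f">{pid}\n{proteome[pid]}\n")
    with (out_dir / "removed.tsv").open("w") as fh:
        fh.write("protein_id\tcontig_id\tlabel\tconfidence\n")
        for pid in order:
            if pid in kept:
                continue
            call = report.calls[pid]
            fh.write(
                f"{pid}\t{report.membership[pid]}\t{call.label}\t"
                f"{call.confidence:.6g}\n"
            )
    with (out_dir / "verdicts.tsv").open("w") as fh:
        fh.write(
            "contig_id\trank\tn_proteins\tvotes_host\tvotes_alien\t"
            "votes_unclassified\talien_fraction\tdecision\tdominant_alien_label\n"
        )
        for v in report.verdicts:
            fh.write(
                f"{v.contig_id}\t{v.rank}\t{v.n_proteins}\t{v.votes_host}\t"
                f"{v.votes_alien}\t{v.votes_unclassified}\t"
                f"{v.alien_fraction:.6g}\t{v.decision}\t{v.dominant_alien_label}\n"
            )
    removed_by_source: Counter[str] = Counter()
    removed_verdicts = {v.contig_id: v for v in report.verdicts if v.decision == "REMOVE"}
    for pid in report.removed_proteins:
        removed_by_source[removed_verdicts[report.membership[pid]].dominant_alien_label] += 1
    summary = {
        "parameters": dict(report.parameters),
        "n_proteins": len(order),
        "n_kept": len(report.kept_proteins),
        "n_removed": len(report.removed_proteins),
        "n_contigs": len(report.verdicts),
        "n_contigs_removed": len(removed_verdicts),
        "removed_by_alien_source": dict(sorted(removed_by_source.items())),
    }
    with (out_dir / "summary.json").open("w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")


def decontaminate(
    proteome: str | Path | Mapping[str, str],
    membership: Mapping[str, str],
    hit_lists: Mapping[str, HitList],
    taxonomy: TaxonomyTable,
    genome: QueryGenomeSpec,
    rank: str = "kingdom",
    threshold: float = 0.5,
    min_pident: float = 20.0,
    cap: int = 10,
    excluded_taxids: frozenset[int] | set[int] = frozenset(),
    out_dir: str | Path | None = None,
) -> DecontaminationReport:
    """End-to-end screening: filter hits, call proteins, vote, remove.

    Parameters
    ----------
    proteome:
        Amino-acid FASTA path, or an in-memory ``{protein_id: sequence}``
        mapping. Every sequence id must appear in ``membership``.
    membership:
        ``protein_id -> contig_id`` (see :mod:`contigscreen.annotation_io`).
    hit_lists:
        Per-query ranked hits; queries without an entry are treated as
        no-hit (UNCLASSIFIED).
    out_dir:
        When given, writes ``cleaned.faa`` (kept proteins, input order),
        ``removed.tsv``, ``verdicts.tsv`` and ``summary.json`` there.
    """
    if isinstance(proteome, (str, Path)):
        records: dict[str, str] = {}
        for rec in SeqIO.parse(str(proteome), "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate protein id {rec.id!r} in proteome")
            records[rec.id] = str(rec.seq)
    else:
        records = dict(proteome)
    order = list(records)

    unmapped = sorted(pid for pid in order if pid not in membership)
    if unmapped:
        raise KeyError(
            f"proteome ids missing from contig membership: {unmapped[:10]}"
            + ("..." if len(unmapped) > 10 else "")
        )

    excluded = frozenset(excluded_taxids)
    calls: dict[str, ProteinTaxonCall] = {}
    for pid in order:
        hl = hit_lists.get(pid)
        if hl is not None:
            hl = filter_hits(hl, min_pident=min_pident, excluded_taxids=excluded)
        call = call_protein_taxon(hl, rank, taxonomy, cap=cap)
        if not call.protein_id:  # no-hit case carries no query id
            call = ProteinTaxonCall(pid, rank, UNCLASSIFIED, 0.0, 0, 0)
        calls[pid] = call

    verdicts = contig_consensus(
        calls.values(), membership, genome, rank, threshold=threshold
    )
    removed_contigs = {v.contig_id for v in verdicts if v.decision == "REMOVE"}
    kept = tuple(p for p in order if membership[p] not in removed_contigs)
    removed = tuple(p for p in order if membership[p] in removed_contigs)

    report = DecontaminationReport(
        kept_proteins=kept,
        removed_proteins=removed,
        verdicts=tuple(verdicts),
        calls=calls,
        membership=dict(membership),
        parameters={
            "genome_id": genome.genome_id,
            "rank": rank,
            "threshold": threshold,
            "min_pident": min_pident,
            "cap": cap,
            "excluded_taxids": sorted(excluded),
        },
    )
    if out_dir is not None:
        _write_report(report, records, order, Path(out_dir))
    return report


def alien_score_per_protein(report: DecontaminationReport) -> dict[str, float]:
    """Continuous contamination score per protein: its contig's alien fraction.

    This is exactly the quantity the removal threshold cuts, so sweeping a
    threshold over these scores yields the ROC behind the tool's operating
    point.
    """
    frac = {v.contig_id: v.alien_fraction for v in report.verdicts}
    return {
        pid: frac[contig] for pid, contig in report.membership.items()
        if pid in report.calls
    }
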