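"""Benchmarking machinery: spike-in mixes, ROC/AUC, support ratios, markers.

Classification performance is measured on artificially contaminated
proteomes: a fixed number of donor proteins is transferred into a
recipient proteome, grouped onto *virtual contigs* of fixed size, with
ground-truth HOST/SPIKE labels retained. The screen is then scored by the
area under the ROC curve over per-protein alien scores, and by
sensitivity/specificity of the binary remove decision at the operating
threshold.

A desk-scale mock reference database (:func:`mock_reference`) stands in
for a large taxonomy-annotated protein reference: random amino-acid
family seeds per taxon, plus mutated variants, separable by the built-in
k-mer search at the ranks where the mock taxa diverge.

Two diagnostic utilities complete the module: the top-10 taxon support
ratio (fraction of the ten best hits agreeing with the expected host
taxon; near 1 = genuine host protein, near 0 = contaminant) and a
marker-based ground-truth contig filter (contigs with enough proteins,
enough target-lineage marker hits and no off-target marker hits are
declared confirmed contaminants).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .core import (
    QueryGenomeSpec,
    alien_score_per_protein,
    decontaminate,
)
from .hits import HitList, ToySearcher
from .taxonomy import ABSENT, RANKS, RankedLineage, TaxonomyTable

__all__ = [
    "SPIKE_LEVELS",
    "CONTIG_SIZES",
    "SyntheticMixSpec",
    "LabeledMix",
    "MockReference",
    "RocResult",
    "generate_mix",
    "mock_reference",
    "roc_auc",
    "taxon_support_ratio",
    "marker_contig_filter",
    "benchmark_sweep",
]

#: Spike-in grid used throughout benchmarking.
SPIKE_LEVELS = (100, 200, 400, 800, 1600, 3200)
CONTIG_SIZES = (1, 2, 5, 10, 20)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SyntheticMixSpec:
    """Parameters of one artificial contamination replicate."""

    donor_genome_id: str
    recipient_genome_id: str
    spike_level: int
    contig_size: int
    replicate_seed: int

    def __post_init__(self):
        if self.spike_level not in SPIKE_LEVELS:
            raise ValueError(
                f"spike_level must be one of {SPIKE_LEVELS}, got {self.spike_level}"
            )
        if self.contig_size not in CONTIG_SIZES:
            raise ValueError(
                f"contig_size must be one of {CONTIG_SIZES}, got {self.contig_size}"
            )

    @property
    def n_virtual_contigs(self) -> int:
        return math.ceil(self.spike_level / self.contig_size)


@dataclass(frozen=True)
class LabeledMix:
    """An artificially contaminated proteome with ground truth attached."""

    proteome: Mapping[str, str]
    membership: Mapping[str, str]
    truth: Mapping[str, str]  # protein_id -> HOST | SPIKE

    def __post_init__(self):
        if set(self.proteome) != set(self.truth) or set(self.proteome) != set(
            self.membership
        ):
            raise ValueError("proteome, membership and truth must cover the same ids")


def generate_mix(
    spec: SyntheticMixSpec,
    donor: Mapping[str, str],
    recipient: Mapping[str, str],
    recipient_membership: Mapping[str, str],
) -> LabeledMix:
    """Spike donor proteins into a recipient proteome on virtual contigs.

    Exactly ``spec.spike_level`` donor proteins are sampled without
    replacement (seeded by ``spec.replicate_seed``) and packed
    sequentially into virtual contigs of ``spec.contig_size`` (the last
    may be smaller). Spiked protein and contig ids are namespaced with the
    donor genome id so they can never collide with recipient ids.
    """
    if len(donor) < spec.spike_level:
        raise ValueError(
            f"donor has {len(donor)} proteins, need {spec.spike_level}"
        )
    rng = np.random.default_rng(spec.replicate_seed)
    donor_ids = sorted(donor)
    chosen = rng.choice(len(donor_ids), size=spec.spike_level, replace=False)

    proteome = dict(recipient)
    membership = dict(recipient_membership)
    truth = {pid: "HOST" for pid in recipient}
    for i, idx in enumerate(chosen):
        pid = donor_ids[idx]
        spiked_id = f"{spec.donor_genome_id}|{pid}"
        contig_id = f"spikectg_{spec.donor_genome_id}_{i // spec.contig_size:04d}"
        if spiked_id in proteome:
            raise ValueError(f"spiked id collides with recipient: {spiked_id!r}")
        proteome[spiked_id] = donor[pid]
        membership[spiked_id] = contig_id
        truth[spiked_id] = "SPIKE"
    return LabeledMix(proteome=proteome, membership=membership, truth=truth)


# --- mock reference database ------------------------------------------------


def _mutate(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute each position with probability ``divergence``."""
    arr = np.array(list(seq))
    mask = rng.random(arr.size) < divergence
    if mask.any():
        # draw replacements guaranteed different from the original residue
        for i in np.flatnonzero(mask):
            choices = AMINO_ACIDS[AMINO_ACIDS != arr[i]]
            arr[i] = choices[rng.integers(len(choices))]
    return "".join(arr)


@dataclass(frozen=True)
class MockReference:
    """In-memory mock of a taxonomy-aware protein reference database."""

    reference: Mapping[str, str]      # seq_id -> sequence
    taxid_map: Mapping[str, int]      # seq_id -> taxid
    taxonomy: TaxonomyTable
    family_seeds: Mapping[int, tuple[str, ...]]  # taxid -> seed sequences
    divergence: float
    seed: int

    def write(self, out_dir) -> tuple[str, str, str]:
        """Write reference FASTA, taxid map TSV and lineage TSV; return paths."""
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fasta = out_dir / "reference.faa"
        tmap = out_dir / "reference.taxids.tsv"
        lineages = out_dir / "lineages.tsv"
        with fasta.open("w") as fh:
            for sid in self.reference:
                fh.write(f">{sid}\n{self.reference[sid]}\n")
        with tmap.open("w") as fh:
            for sid in self.reference:
                fh.write(f"{sid}\t{self.taxid_map[sid]}\n")
        self.taxonomy.to_flat_tsv(lineages)
        return str(fasta), str(tmap), str(lineages)

    def sample_proteome(
        self,
        taxid: int,
        n_proteins: int,
        seed: int,
        divergence: float | None = None,
    ) -> dict[str, str]:
        """Draw a mock proteome for one taxon: mutated copies of its families.

        Families are cycled so the proteome covers all of them; each
        protein is an independently mutated copy of its family seed.
        """
        seeds = self.family_seeds[taxid]
        div = self.divergence if divergence is None else divergence
        rng = np.random.default_rng(seed)
        return {
            f"g{taxid}_p{i:05d}": _mutate(seeds[i % len(seeds)], div, rng)
            for i in range(n_proteins)
        }


def mock_reference(
    taxa: Sequence[tuple[int, Mapping[str, str] | RankedLineage, int]],
    divergence: float = 0.05,
    seed: int = 0,
    variants_per_family: int = 3,
    seq_len: int = 120,
) -> MockReference:
    """Build a mock taxonomy-aware reference database.

    Parameters
    ----------
    taxa:
        ``(taxid, lineage, n_families)`` triples; ``lineage`` is a
        rank->label mapping (or a :class:`RankedLineage`).
    divergence:
        Per-position substitution probability between a family seed and
        its deposited variants, in [0, 1].
    variants_per_family, seq_len:
        Number of deposited variants per family and seed length (aa).

    Family seeds are independent random sequences, so different taxa share
    k-mers only by chance and the built-in search separates them at every
    rank where their lineages differ.
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError(f"divergence must be in [0, 1]: {divergence}")
    rng = np.random.default_rng(seed)
    reference: dict[str, str] = {}
    taxid_map: dict[str, int] = {}
    family_seeds: dict[int, tuple[str, ...]] = {}
    lineages = []
    for taxid, lineage, n_families in taxa:
        if isinstance(lineage, RankedLineage):
            if lineage.taxid != taxid:
                raise ValueError("lineage taxid does not match taxon entry")
            lineages.append(lineage)
        else:
            lineages.append(RankedLineage(taxid, dict(lineage)))
        seeds = []
        for fam in range(n_families):
            seed_seq = "".join(AMINO_ACIDS[rng.integers(20, size=seq_len)])
            seeds.append(seed_seq)
            for v in range(variants_per_family):
                sid = f"t{taxid}_f{fam:03d}_v{v}"
                reference[sid] = _mutate(seed_seq, divergence, rng)
                taxid_map[sid] = taxid
        family_seeds[taxid] = tuple(seeds)
    return MockReference(
        reference=reference,
        taxid_map=taxid_map,
        taxonomy=TaxonomyTable(lineages, provenance="flat-tsv"),
        family_seeds=family_seeds,
        divergence=divergence,
        seed=seed,
    )


# --- ROC / AUC ---------------------------------------------------------------


@dataclass(frozen=True)
class RocResult:
    """ROC curve and area under it, over per-protein alien scores."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def __post_init__(self):
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"auc out of [0, 1]: {self.auc}")


def roc_auc(
    scores: Mapping[str, float], truth: Mapping[str, str]
) -> RocResult:
    """ROC/AUC of alien scores against HOST/SPIKE ground truth.

    The AUC uses the rank (Mann-Whitney) formulation with midrank tie
    handling: it equals the probability that a random spiked protein
    scores above a random host protein, ties counting one half.
    """
    if set(scores) != set(truth):
        raise ValueError("scores and truth must cover the same proteins")
    ids = sorted(scores)
    y = np.array([truth[i] == "SPIKE" for i in ids], dtype=bool)
    bad = sorted({truth[i] for i in ids} - {"HOST", "SPIKE"})
    if bad:
        raise ValueError(f"unknown truth labels: {bad}")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both HOST and SPIKE classes must be present")
    s = np.array([scores[i] for i in ids], dtype=float)
    ranks = rankdata(s)  # midranks
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, thresholds = roc_curve(y.astype(int), s)
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=float(auc))


# --- taxon support ratio -----------------------------------------------------


def taxon_support_ratio(
    hit_list: HitList | None,
    expected_label: str,
    rank: str,
    taxonomy: TaxonomyTable,
    k: int = 10,
) -> float | None:
    """Fraction of the top ``min(k, n)`` hits labelled as expected at ``rank``.

    Returns ``None`` (NA) when there are no hits. Values near 1 indicate a
    genuine host protein; values near 0 flag strong disagreement between
    expected and observed taxon labels. With fewer than ``k`` hits the
    available count is the denominator.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if hit_list is None or not hit_list.hits:
        return None
    window = min(k, len(hit_list))
    agree = sum(
        1
        for hit in hit_list.hits[:window]
        if taxonomy.label_at_rank(hit.subject_taxid, rank) == expected_label
    )
    return agree / window


# --- marker-based ground-truth contig filter --------------------------------


def marker_contig_filter(
    marker_classes: Mapping[str, str],
    membership: Mapping[str, str],
    min_proteins: int = 100,
    min_target: int = 20,
    max_other: int = 0,
) -> set[str]:
    """Select contigs confirmed as contaminants by lineage-specific markers.

    ``marker_classes`` assigns each protein TARGET (marker specific to the
    suspected contaminant lineage), OTHER (marker specific to a different,
    e.g. host, lineage) or NONE. A contig is selected when it carries at
    least ``min_proteins`` proteins, at least ``min_target`` TARGET
    markers and at most ``max_other`` OTHER markers. The defaults
    (100/20/0) reproduce the rule used to build curated contaminant
    ground truth in a plant genome screened for fungal contigs.
    """
    valid = {"TARGET", "OTHER", "NONE"}
    counts: dict[str, list[int]] = {}
    for pid, cls in marker_classes.items():
        if cls not in valid:
            raise ValueError(f"unknown marker class {cls!r} for {pid!r}")
        if pid not in membership:
            raise KeyError(f"protein {pid!r} missing from membership")
        c = counts.setdefault(membership[pid], [0, 0, 0])
        c[0] += 1
        if cls == "TARGET":
            c[1] += 1
        elif cls == "OTHER":
            c[2] += 1
    return {
        contig
        for contig, (n, n_target, n_other) in counts.items()
        if n >= min_proteins and n_target >= min_target and n_other <= max_other
    }


# --- full benchmark sweep ----------------------------------------------------


def benchmark_sweep(
    mock: MockReference,
    donor_taxid: int,
    recipient_taxid: int,
    spike_levels: Sequence[int] = (100, 400),
    contig_sizes: Sequence[int] = (1, 5, 20),
    ranks: Sequence[str] = ("superkingdom",),
    replicates: int = 10,
    master_seed: int = 0,
    host_proteins: int = 300,
    host_contig_size: int = 10,
    threshold: float = 0.5,
    min_pident: float = 20.0,
    cap: int = 10,
    k: int = 4,
) -> pd.DataFrame:
    """Run the spike-in benchmark over a parameter grid.

    The recipient (host) proteome is sampled once per sweep and searched
    once; each replicate then only searches its freshly spiked proteins.
    Per (spike_level, contig_size, rank, replicate) cell the returned
    long-format table carries the AUC of the alien score, plus the
    sensitivity (spiked proteins removed) and specificity (host proteins
    kept) of the binary decision at ``threshold``. All randomness derives
    deterministically from ``master_seed``.
    """
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    for rank in ranks:
        if rank not in RANKS:
            raise ValueError(f"rank {rank!r} not in ladder {RANKS}")
    root = np.random.default_rng(master_seed)
    recipient_seed = int(root.integers(2**31))
    donor_seed = int(root.integers(2**31))

    recipient = mock.sample_proteome(recipient_taxid, host_proteins, recipient_seed)
    recipient_membership = {
        pid: f"hostctg_{i // host_contig_size:04d}"
        for i, pid in enumerate(recipient)
    }
    donor_pool = mock.sample_proteome(donor_taxid, max(spike_levels), donor_seed)

    searcher = ToySearcher(mock.reference, mock.taxid_map, k=k)
    host_hits = searcher.search(recipient)
    genome = QueryGenomeSpec(f"g{recipient_taxid}", mock.taxonomy[recipient_taxid])

    rows = []
    for spike_level in spike_levels:
        for contig_size in contig_sizes:
            for rep in range(replicates):
                rep_seed = int(root.integers(2**31))
                spec = SyntheticMixSpec(
                    donor_genome_id=f"g{donor_taxid}",
                    recipient_genome_id=f"g{recipient_taxid}",
                    spike_level=spike_level,
                    contig_size=contig_size,
                    replicate_seed=rep_seed,
                )
                mix = generate_mix(spec, donor_pool, recipient, recipient_membership)
                spiked = {
                    pid: seq
                    for pid, seq in mix.proteome.items()
                    if mix.truth[pid] == "SPIKE"
                }
                hit_lists = {**host_hits, **searcher.search(spiked)}
                for rank in ranks:
                    report = decontaminate(
                        mix.proteome,
                        mix.membership,
                        hit_lists,
                        mock.taxonomy,
                        genome,
                        rank=rank,
                        threshold=threshold,
                        min_pident=min_pident,
                        cap=cap,
                    )
                    scores = alien_score_per_protein(report)
                    auc = roc_auc(scores, mix.truth).auc
                    removed = report.removed_set
                    spikes = {p for p, t in mix.truth.items() if t == "SPIKE"}
                    hosts = set(mix.truth) - spikes
                    rows.append(
                        {
                            "donor": spec.donor_genome_id,
                            "recipient": spec.recipient_genome_id,
                            "rank": rank,
                            "spike_level": spike_level,
                            "contig_size": contig_size,
                            "replicate": rep,
                            "replicate_seed": rep_seed,
                            "auc": auc,
                            "sensitivity": len(spikes & removed) / len(spikes),
                            "specificity": len(hosts - removed) / len(hosts),
                        }
                    )
    return pd.DataFrame(rows)
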