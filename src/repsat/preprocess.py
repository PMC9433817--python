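"""Read quality filtering, UMI clustering and consensus construction.

A merged read survives the quality filter iff strictly more than
``pass_fraction`` of its bases have a Phred score strictly above
``phred_threshold`` (defaults: 95% and Q20).  Surviving reads are grouped by
exact UMI match; clusters supported by at least ``min_cluster_reads`` reads
(default 3, i.e. "more than two") are kept and collapsed to one consensus
sequence per cluster — one molecule, one consensus.

Consensus rule (deterministic): the consensus length is the modal read
length of the cluster (ties broken toward the shorter length); per position
the base is the plurality vote among reads of that length, vote ties go to
the base with the highest summed Phred score at that position, and remaining
ties to the alphabetically smallest base.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._seq import BASES, CODE_LUT, decode_seq, encode_seq, is_acgt
from .synthetic_data import UmiRead

logger = logging.getLogger(__name__)


@dataclass
class FilterParams:
    phred_threshold: int = 20
    pass_fraction: float = 0.95
    min_cluster_reads: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.pass_fraction <= 1:
            raise ValueError("pass_fraction must be in (0, 1]")
        if self.min_cluster_reads < 1:
            raise ValueError("min_cluster_reads must be >= 1")


@dataclass
class UmiCluster:
    umi: str
    reads: list[UmiRead]
    consensus: str = ""

    def __post_init__(self) -> None:
        if not self.reads:
            raise ValueError("a UMI cluster must contain at least one read")
        if any(r.umi != self.umi for r in self.reads):
            raise ValueError("all reads in a cluster must share the cluster UMI")

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class ConsensusRead:
    """One consensus sequence per selected UMI cluster."""

    umi: str
    support: int
    sequence: str
    truth_clone_id: int | None = None


def quality_filter(reads: list[UmiRead], params: FilterParams | None = None) -> list[UmiRead]:
    """Keep reads whose fraction of bases above the Phred threshold is
    strictly greater than ``pass_fraction``.  Order is preserved; empty
    reads are rejected with a logged warning, never an exception."""
    params = params or FilterParams()
    kept: list[UmiRead] = []
    n_empty = 0
    for r in reads:
        length = len(r.sequence)
        if length == 0:
            n_empty += 1
            continue
        frac = int((r.qualities > params.phred_threshold).sum()) / length
        if frac > params.pass_fraction:
            kept.append(r)
    if n_empty:
        logger.warning("quality_filter: rejected %d empty reads", n_empty)
    return kept


def cluster_by_umi(reads: list[UmiRead]) -> list[UmiCluster]:
    """Exact-match grouping by UMI; reads with non-ACGT UMIs are dropped
    (counted in the log).  Clusters are returned in first-seen UMI order."""
    groups: dict[str, list[UmiRead]] = {}
    dropped = 0
    for r in reads:
        if not is_acgt(r.umi):
            dropped += 1
            continue
        groups.setdefault(r.umi, []).append(r)
    if dropped:
        logger.warning("cluster_by_umi: dropped %d reads with invalid UMIs", dropped)
    return [UmiCluster(umi, rs) for umi, rs in groups.items()]


def select_clusters(clusters: list[UmiCluster], params: FilterParams | None = None) -> list[UmiCluster]:
    params = params or FilterParams()
    return [c for c in clusters if len(c.reads) >= params.min_cluster_reads]


def build_consensus(cluster: UmiCluster) -> str:
    """Deterministic per-position consensus of a UMI cluster (see module
    docstring for the tie-break chain)."""
    if not cluster.reads:
        raise ValueError("cannot build a consensus from an empty cluster")
    length_counts = Counter(len(r.sequence) for r in cluster.reads)
    top = max(length_counts.values())
    modal_len = min(l for l, c in length_counts.items() if c == top)
    voters = [r for r in cluster.reads if len(r.sequence) == modal_len]

    seqs = np.stack([encode_seq(r.sequence) for r in voters])
    quals = np.stack([np.asarray(r.qualities, dtype=np.int64) for r in voters])
    codes = CODE_LUT[seqs]

    votes = np.zeros((4, modal_len), dtype=np.int64)
    qsum = np.zeros((4, modal_len), dtype=np.int64)
    for b in range(4):
        mask = codes == b
        votes[b] = mask.sum(axis=0)
        qsum[b] = np.where(mask, quals, 0).sum(axis=0)
    # plurality first, then summed quality; rows are in A,C,G,T order so
    # argmax's first-max rule supplies the lexicographic tie-break
    score = votes.astype(np.float64) * 1e9 + qsum
    return decode_seq(BASES[np.argmax(score, axis=0)])


def _consensus_truth(cluster: UmiCluster) -> int | None:
    truths = [r.truth_clone_id for r in cluster.reads if r.truth_clone_id is not None]
    if not truths:
        return None
    counts = Counter(truths)
    top = max(counts.values())
    return min(t for t, c in counts.items() if c == top)


@dataclass
class PreprocessResult:
    consensus_reads: list[ConsensusRead]
    clusters: list[UmiCluster]
    stats: dict = field(default_factory=dict)


def preprocess_reads(reads: list[UmiRead], params: FilterParams | None = None) -> PreprocessResult:
    """Run the full preprocessing stage and reconcile read counts.

    Stats satisfy: n_input = n_quality_failed + n_quality_passed and
    n_quality_passed = n_umi_invalid + sum of cluster sizes.
    """
    params = params or FilterParams()
    passed = quality_filter(reads, params)
    clusters = cluster_by_umi(passed)
    clustered = sum(len(c) for c in clusters)
    selected = select_clusters(clusters, params)
    consensus_reads = []
    for c in selected:
        c.consensus = build_consensus(c)
        consensus_reads.append(
            ConsensusRead(c.umi, len(c), c.consensus, _consensus_truth(c)))
    stats = {
        "n_input": len(reads),
        "n_quality_passed": len(passed),
        "n_quality_failed": len(reads) - len(passed),
        "n_umi_invalid": len(passed) - clustered,
        "n_clusters": len(clusters),
        "n_selected_clusters": len(selected),
        "n_reads_in_selected": sum(len(c) for c in selected),
    }
    return PreprocessResult(consensus_reads, clusters, stats)
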