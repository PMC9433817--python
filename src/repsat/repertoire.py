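"""FUS collapse, fixed-depth downsampling and Hill diversity.

A functional unique sequence (FUS) is a full-length nucleotide sequence
together with its isotype; the same sequence under two isotypes is two
FUSs.  A ``Repertoire`` is the FUS table of one sample at a fixed depth of
functional reads, which makes repertoires from different blood volumes
directly comparable.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FUS_COLUMNS = ["sequence", "isotype", "read_count", "frequency", "isotype_class"]

NAIVE_CLASS = "IgM/D"
SWITCHED_CLASS = "class-switched"


def isotype_class(isotype: str) -> str:
    return NAIVE_CLASS if isotype in ("IgM", "IgD") else SWITCHED_CLASS


@dataclass
class Repertoire:
    """FUS table of one sample at fixed depth.

    Invariants: read counts sum to ``depth``; frequencies are
    read_count/depth and sum to 1 (within 1e-9) whenever depth > 0.
    """

    sample_id: str
    depth: int
    table: pd.DataFrame  # FUS_COLUMNS
    volume_ml: float | None = None
    arm: str | None = None

    def __post_init__(self) -> None:
        t = self.table
        if missing := set(FUS_COLUMNS) - set(t.columns):
            raise ValueError(f"missing FUS columns: {missing}")
        if int(t["read_count"].sum()) != self.depth:
            raise ValueError(
                f"read counts sum to {int(t['read_count'].sum())}, depth is {self.depth}")
        if self.depth > 0 and abs(float(t["frequency"].sum()) - 1.0) > 1e-9:
            raise ValueError("FUS frequencies must sum to 1")
        if t.duplicated(subset=["sequence", "isotype"]).any():
            raise ValueError("FUS keys must be unique within a repertoire")

    @property
    def richness(self) -> int:
        return len(self.table)

    @property
    def frequencies(self) -> np.ndarray:
        return self.table["frequency"].to_numpy(dtype=float)

    def keys(self) -> set[tuple[str, str]]:
        return set(zip(self.table["sequence"], self.table["isotype"]))

    def subset(self, mask) -> pd.DataFrame:
        return self.table[mask]

    @classmethod
    def from_counts(
        cls,
        sequences,
        isotypes,
        counts,
        sample_id: str = "sample",
        volume_ml: float | None = None,
        arm: str | None = None,
    ) -> "Repertoire":
        """Build a repertoire directly from per-FUS read counts (zeros are
        dropped)."""
        counts = np.asarray(counts, dtype=np.int64)
        keep = counts > 0
        depth = int(counts.sum())
        table = pd.DataFrame({
            "sequence": np.asarray(sequences, dtype=object)[keep],
            "isotype": np.asarray(isotypes, dtype=object)[keep],
            "read_count": counts[keep],
        })
        table["frequency"] = table["read_count"] / depth if depth else 0.0
        table["isotype_class"] = table["isotype"].map(isotype_class)
        table = table.sort_values(
            ["read_count", "sequence", "isotype"], ascending=[False, True, True]
        ).reset_index(drop=True)
        return cls(sample_id, depth, table, volume_ml, arm)


def downsample_reads(reads: list, n: int, seed: int = 0) -> list:
    """Uniform sample of exactly ``n`` reads without replacement."""
    if n > len(reads):
        raise ValueError(
            f"cannot sample {n} reads: only {len(reads)} functional reads available")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(reads), size=n, replace=False)
    return [reads[i] for i in idx]


def downsample_counts(counts: np.ndarray, n: int, seed: int = 0) -> np.ndarray:
    """Without-replacement downsampling on a count vector (multivariate
    hypergeometric) — identical in law to sampling individual reads."""
    counts = np.asarray(counts, dtype=np.int64)
    total = int(counts.sum())
    if n > total:
        raise ValueError(f"cannot sample {n} reads: only {total} available")
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, n)


def collapse_fus(
    functional_reads,
    sample_id: str = "sample",
    volume_ml: float | None = None,
    arm: str | None = None,
) -> Repertoire:
    """Group functional reads by exact (sequence, isotype) key.

    Accepts ``AnnotatedRead`` objects or plain ``(sequence, isotype)``
    tuples.  Zero reads yield an empty repertoire with depth 0 (flagged in
    the log; frequencies are then undefined).
    """
    keys = []
    for r in functional_reads:
        if isinstance(r, tuple):
            keys.append(r)
        else:
            keys.append((r.sequence, r.isotype))
    counts = Counter(keys)
    if not counts:
        logger.warning("collapse_fus: no functional reads for %s", sample_id)
        empty = pd.DataFrame(columns=FUS_COLUMNS)
        return Repertoire(sample_id, 0, empty, volume_ml, arm)
    seqs, isos = zip(*counts.keys())
    return Repertoire.from_counts(
        list(seqs), list(isos), list(counts.values()), sample_id, volume_ml, arm)


def hill_diversity(rep_or_freqs, q: float = 1.0) -> float:
    """Hill number of order ``q``.

    q=0 is FUS richness; q=1 is the Shannon limit exp(-sum f ln f); general
    q != 1 uses (sum f^q)^(1/(1-q)).  Requires a non-empty repertoire.
    """
    if q < 0:
        raise ValueError("q must be >= 0")
    if isinstance(rep_or_freqs, Repertoire):
        f = rep_or_freqs.frequencies
    else:
        f = np.asarray(rep_or_freqs, dtype=float)
    f = f[f > 0]
    if f.size == 0:
        raise ValueError("Hill diversity of an empty repertoire is undefined")
    if q == 0:
        return float(f.size)
    if q == 1:
        return float(np.exp(-np.sum(f * np.log(f))))
    return float(np.sum(f ** q) ** (1.0 / (1.0 - q)))


def rarefaction_curve(
    rep: Repertoire,
    depths,
    q: float = 1.0,
    replicates: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Empirical subsampling rarefaction of Hill diversity.

    For each requested depth the repertoire is subsampled without
    replacement ``replicates`` times and the Hill number averaged.  No
    extrapolation: depths beyond ``rep.depth`` raise.
    """
    counts = rep.table["read_count"].to_numpy(dtype=np.int64)
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        depth = int(depth)
        if depth > rep.depth:
            raise ValueError(
                f"rarefaction depth {depth} exceeds repertoire depth {rep.depth}")
        vals = np.empty(replicates)
        for i in range(replicates):
            sub = rng.multivariate_hypergeometric(counts, depth)
            vals[i] = hill_diversity(sub / depth, q)
        rows.append({"depth": depth, "hill_mean": vals.mean(),
                     "hill_sd": vals.std(ddof=1) if replicates > 1 else 0.0})
    return pd.DataFrame(rows)
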