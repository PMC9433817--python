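"""Synthetic ground truth for B-cell receptor (BCR) repertoire studies.

This module simulates everything upstream of the sequencer so that the whole
downstream pipeline (quality filtering, UMI consensus, germline annotation,
repertoire reconstitution, saturation analysis) can be exercised against a
known truth table:

* a toy germline segment library: V genes carrying CDR1/CDR2 annotations,
  J genes, and one constant-region tag per isotype (the stand-in for a
  curated germline database);
* a blood-wide clone population with power-law clone frequencies, a
  frequency-dependent class-switch bias (class-switched isotypes concentrate
  among higher-frequency clones, naive IgM/IgD clones dominate the singleton
  tail) and somatic hypermutation (SHM) confined to the V segment;
* multinomial sampling of B cells proportional to the drawn blood volume,
  with an arm label so that two-arm sampling designs can be emulated;
* UMI-tagged, error-prone amplicon sequencing of the sampled cells.

The sequencing model is molecule-centred: every sampled cell contributes a
small random number of mRNA molecules (``1 + Poisson(transcripts_per_cell -
1)``), each molecule receives a unique molecular identifier (UMI) and is read
``1 + Poisson(mean_reads_per_molecule - 1)`` times with i.i.d. substitution
errors.  Because reads can resample molecules of the *same* cell, the number
of cells drawn (i.e. the blood volume) is a genuine bottleneck on how many
distinct sequences a fixed number of reads can recover — the mechanism behind
volume-dependent repertoire saturation.  With ``transcripts_per_cell=1``
each cell yields exactly one molecule and the channel reduces to plain
subsampling of cells.

Every generator is deterministic for a fixed seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from ._seq import BASES, CODE_LUT, decode_seq, encode_seq, random_seq, substitute

logger = logging.getLogger(__name__)

ISOTYPES = ("IgM", "IgD", "IgG", "IgA", "IgE")
NAIVE_ISOTYPES = ("IgM", "IgD")
SWITCHED_ISOTYPES = ("IgG", "IgA", "IgE")

#: Baseline isotype proportions: an IgM-dominant peripheral-blood mixture.
DEFAULT_ISOTYPE_MIX = {"IgM": 0.70, "IgD": 0.12, "IgG": 0.10, "IgA": 0.07, "IgE": 0.01}


# ---------------------------------------------------------------------------
# germline set
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VGene:
    name: str
    sequence: str
    cdr1: tuple[int, int]  # half-open span within the V sequence
    cdr2: tuple[int, int]


@dataclass(frozen=True)
class JGene:
    name: str
    sequence: str


@dataclass
class GermlineSet:
    """A minimal germline segment library.

    ``isotype_tags`` maps isotype labels to the constant-region tag appended
    3' of the J segment; tags are pairwise distinct at >= 3 positions so that
    isotype calling tolerates single substitutions.
    """

    v_genes: list[VGene]
    j_genes: list[JGene]
    isotype_tags: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.v_genes) < 2 or len(self.j_genes) < 2:
            raise ValueError("need at least 2 V genes and 2 J genes")
        from ._seq import is_acgt

        for g in self.v_genes:
            if not is_acgt(g.sequence):
                raise ValueError(f"V gene {g.name} is not over ACGT")
            for span in (g.cdr1, g.cdr2):
                if not (0 <= span[0] < span[1] <= len(g.sequence)):
                    raise ValueError(f"CDR span {span} outside V gene {g.name}")
            if not g.cdr1[1] <= g.cdr2[0]:
                raise ValueError(f"CDR1/CDR2 spans overlap in {g.name}")
        for g in self.j_genes:
            if not is_acgt(g.sequence):
                raise ValueError(f"J gene {g.name} is not over ACGT")
        tags = list(self.isotype_tags.items())
        for t, (iso, seq) in enumerate(tags):
            if not is_acgt(seq):
                raise ValueError(f"isotype tag {iso} is not over ACGT")
            for iso2, seq2 in tags[t + 1:]:
                if len(seq) == len(seq2):
                    d = int((encode_seq(seq) != encode_seq(seq2)).sum())
                    if d < 3:
                        raise ValueError(
                            f"isotype tags {iso}/{iso2} differ at only {d} positions"
                        )

    def v_by_name(self, name: str) -> VGene:
        for g in self.v_genes:
            if g.name == name:
                return g
        raise KeyError(name)

    def j_by_name(self, name: str) -> JGene:
        for g in self.j_genes:
            if g.name == name:
                return g
        raise KeyError(name)

    # --- plain-text serialization (documented schema, YAML) ---
    def to_yaml(self, path) -> None:
        import yaml

        doc = {
            "v_genes": [
                {"name": g.name, "sequence": g.sequence,
                 "cdr1": list(g.cdr1), "cdr2": list(g.cdr2)}
                for g in self.v_genes
            ],
            "j_genes": [{"name": g.name, "sequence": g.sequence} for g in self.j_genes],
            "isotype_tags": dict(self.isotype_tags),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GermlineSet":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            v_genes=[VGene(d["name"], d["sequence"], tuple(d["cdr1"]), tuple(d["cdr2"]))
                     for d in doc["v_genes"]],
            j_genes=[JGene(d["name"], d["sequence"]) for d in doc["j_genes"]],
            isotype_tags=dict(doc["isotype_tags"]),
        )


def generate_germline_set(
    n_v: int,
    n_j: int,
    seed: int,
    *,
    v_length: int = 300,
    j_length: int = 48,
    tag_length: int = 30,
) -> GermlineSet:
    """Draw a random but mutually distinguishable germline library.

    All pairwise Hamming distances within the V set (and within the J set)
    are at least 10% of the segment length; isotype tags are pairwise
    distinct at >= 3 positions.  Deterministic for a fixed seed.
    """
    if n_v < 2 or n_j < 2:
        raise ValueError(f"need n_v >= 2 and n_j >= 2, got n_v={n_v}, n_j={n_j}")
    rng = np.random.default_rng(seed)

    def _draw_family(n: int, length: int, min_dist: int) -> list[str]:
        seqs: list[np.ndarray] = []
        for _ in range(n):
            for _attempt in range(1000):
                cand = random_seq(rng, length)
                if all(int((cand != s).sum()) >= min_dist for s in seqs):
                    seqs.append(cand)
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError("could not draw a sufficiently distinct sequence")
        return [decode_seq(s) for s in seqs]

    v_seqs = _draw_family(n_v, v_length, max(1, v_length // 10))
    j_seqs = _draw_family(n_j, j_length, max(1, j_length // 10))
    tag_seqs = _draw_family(len(ISOTYPES), tag_length, 3)

    cdr1 = (v_length // 4, v_length // 4 + 24)
    cdr2 = (v_length // 2, v_length // 2 + 21)
    return GermlineSet(
        v_genes=[VGene(f"IGHV{i + 1}", s, cdr1, cdr2) for i, s in enumerate(v_seqs)],
        j_genes=[JGene(f"IGHJ{i + 1}", s) for i, s in enumerate(j_seqs)],
        isotype_tags={iso: s for iso, s in zip(ISOTYPES, tag_seqs)},
    )


# ---------------------------------------------------------------------------
# clone population
# ---------------------------------------------------------------------------

@dataclass
class PopulationModel:
    """Generative model for a blood-wide clone population.

    Clone frequencies follow a power law with exponent ``alpha`` (density
    proportional to f^-alpha, alpha > 1), the simplest family that yields the
    singleton-dominated repertoires seen in peripheral blood.  The chance
    that a clone is class-switched grows logistically with its log frequency
    (``switch_bias`` is the slope per decade), reflecting antigen-driven
    expansion of switched clones.  SHM counts are Poisson with a low mean for
    naive IgM/IgD clones and a higher mean for switched clones.
    """

    n_clones: int
    alpha: float = 2.2
    isotype_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ISOTYPE_MIX))
    switch_bias: float = 1.0
    shm_rate_naive: float = 0.5
    shm_rate_switched: float = 8.0
    junction_length: tuple[int, int] = (9, 21)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_clones < 1:
            raise ValueError("n_clones must be >= 1")
        if not self.alpha > 1:
            raise ValueError(f"alpha must be > 1, got {self.alpha}")
        if set(self.isotype_mix) - set(ISOTYPES):
            raise ValueError(f"unknown isotypes in mix: {set(self.isotype_mix) - set(ISOTYPES)}")
        probs = np.array(list(self.isotype_mix.values()), dtype=float)
        if (probs < 0).any() or (probs > 1).any():
            raise ValueError("isotype probabilities must lie in [0, 1]")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError(f"isotype mix must sum to 1, got {probs.sum()}")
        if self.shm_rate_naive < 0 or self.shm_rate_switched < 0:
            raise ValueError("SHM rates must be non-negative")
        lo, hi = self.junction_length
        if not 0 <= lo <= hi:
            raise ValueError(f"invalid junction length range {self.junction_length}")


@dataclass
class ClonePopulation:
    """Ground-truth clone table.

    One row per clone: full-length nucleotide sequence (V + junction + J +
    isotype tag), isotype, true blood-wide frequency, source segments and SHM
    count.  (sequence, isotype) pairs are unique — the ground truth for one
    functional unique sequence (FUS).
    """

    table: pd.DataFrame  # clone_id, sequence, isotype, frequency, v_gene, j_gene, n_shm

    def __post_init__(self) -> None:
        t = self.table
        required = {"clone_id", "sequence", "isotype", "frequency", "v_gene", "j_gene", "n_shm"}
        if missing := required - set(t.columns):
            raise ValueError(f"missing columns: {missing}")
        if abs(float(t["frequency"].sum()) - 1.0) > 1e-9:
            raise ValueError("clone frequencies must sum to 1")
        if t.duplicated(subset=["sequence", "isotype"]).any():
            raise ValueError("(sequence, isotype) pairs must be unique")
        if (t["n_shm"] < 0).any():
            raise ValueError("n_shm must be non-negative")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def frequencies(self) -> np.ndarray:
        return self.table["frequency"].to_numpy(dtype=float)

    @property
    def sequences(self) -> list[str]:
        return self.table["sequence"].tolist()

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.12g")

    @classmethod
    def from_tsv(cls, path) -> "ClonePopulation":
        return cls(pd.read_csv(path, sep="\t"))


def simulate_population(germline: GermlineSet, model: PopulationModel) -> ClonePopulation:
    """Draw a clone population from ``model`` over the given germline set."""
    rng = np.random.default_rng(model.seed)
    n = model.n_clones

    # power-law weights: Pareto with shape alpha-1 => density ∝ w^-alpha
    u = rng.random(n)
    w = (1.0 - u) ** (-1.0 / (model.alpha - 1.0))
    freq = w / w.sum()

    # frequency-dependent class switching
    base_cs = sum(model.isotype_mix.get(iso, 0.0) for iso in SWITCHED_ISOTYPES)
    if n > 1 and 0.0 < base_cs < 1.0 and model.switch_bias != 0.0:
        logf = np.log10(freq)
        centered = logf - logf.mean()
        logit = np.log(base_cs / (1.0 - base_cs))
        p_cs = expit(logit + model.switch_bias * centered)
    else:
        p_cs = np.full(n, base_cs)
    switched = rng.random(n) < p_cs

    def _conditional(labels: tuple[str, ...]) -> tuple[list[str], np.ndarray]:
        probs = np.array([model.isotype_mix.get(iso, 0.0) for iso in labels], dtype=float)
        if probs.sum() <= 0:
            probs = np.ones(len(labels))
        return list(labels), probs / probs.sum()

    naive_labels, naive_p = _conditional(NAIVE_ISOTYPES)
    sw_labels, sw_p = _conditional(SWITCHED_ISOTYPES)
    isotype = np.where(
        switched,
        rng.choice(sw_labels, size=n, p=sw_p),
        rng.choice(naive_labels, size=n, p=naive_p),
    )

    shm_mean = np.where(switched, model.shm_rate_switched, model.shm_rate_naive)
    n_shm = rng.poisson(shm_mean)

    v_idx = rng.integers(0, len(germline.v_genes), size=n)
    j_idx = rng.integers(0, len(germline.j_genes), size=n)
    v_arrs = [encode_seq(g.sequence) for g in germline.v_genes]
    j_arrs = [encode_seq(g.sequence) for g in germline.j_genes]
    tag_arrs = {iso: encode_seq(s) for iso, s in germline.isotype_tags.items()}

    lo, hi = model.junction_length
    seen: set[tuple[str, str]] = set()
    sequences: list[str] = []
    shm_out = np.minimum(n_shm, min(len(a) for a in v_arrs))
    for i in range(n):
        v = v_arrs[v_idx[i]].copy()
        k = int(min(shm_out[i], len(v)))
        shm_out[i] = k
        if k:
            pos = rng.choice(len(v), size=k, replace=False)
            substitute(v, pos, rng)
        while True:
            ins = random_seq(rng, int(rng.integers(lo, hi + 1)))
            seq = decode_seq(np.concatenate(
                [v, ins, j_arrs[j_idx[i]], tag_arrs[isotype[i]]]))
            key = (seq, str(isotype[i]))
            if key not in seen:
                seen.add(key)
                break
        sequences.append(seq)

    table = pd.DataFrame({
        "clone_id": np.arange(n),
        "sequence": sequences,
        "isotype": isotype,
        "frequency": freq,
        "v_gene": [germline.v_genes[i].name for i in v_idx],
        "j_gene": [germline.j_genes[i].name for i in j_idx],
        "n_shm": shm_out.astype(int),
    })
    return ClonePopulation(table)


# ---------------------------------------------------------------------------
# blood sampling
# ---------------------------------------------------------------------------

@dataclass
class CellSample:
    """B cells captured in one blood draw, as counts per clone."""

    sample_id: str
    volume_ml: float
    arm: str
    cell_counts: np.ndarray  # aligned with the population's clone order

    @property
    def total_cells(self) -> int:
        return int(self.cell_counts.sum())

    @property
    def n_distinct_clones(self) -> int:
        return int((self.cell_counts > 0).sum())


def sample_blood_volume(
    pop: ClonePopulation,
    volume_ml: float,
    cells_per_ml: int,
    arm: str = "left",
    seed: int = 0,
    sample_id: str | None = None,
) -> CellSample:
    """Multinomial draw of ``round(volume_ml * cells_per_ml)`` cells.

    Independent draws with different seeds model the homogeneous two-arm
    sampling design: the arm is a label, not a different distribution.
    """
    if volume_ml <= 0:
        raise ValueError(f"volume_ml must be positive, got {volume_ml}")
    if cells_per_ml <= 0:
        raise ValueError(f"cells_per_ml must be positive, got {cells_per_ml}")
    rng = np.random.default_rng(seed)
    n_cells = int(round(volume_ml * cells_per_ml))
    counts = rng.multinomial(n_cells, pop.frequencies)
    if sample_id is None:
        sample_id = f"{volume_ml:g}mL-{arm}"
    return CellSample(sample_id, float(volume_ml), arm, counts)


def molecule_counts(
    sample: CellSample, transcripts_per_cell: float, seed: int
) -> np.ndarray:
    """Per-clone mRNA molecule counts for a cell sample.

    Each cell contributes ``1 + Poisson(transcripts_per_cell - 1)`` molecules
    (always at least one); ``transcripts_per_cell=1`` gives exactly one
    molecule per cell, deterministically.
    """
    if transcripts_per_cell < 1:
        raise ValueError("transcripts_per_cell must be >= 1")
    counts = sample.cell_counts
    if transcripts_per_cell == 1:
        return counts.copy()
    rng = np.random.default_rng(seed)
    return counts + rng.poisson((transcripts_per_cell - 1.0) * counts)


# ---------------------------------------------------------------------------
# sequencing
# ---------------------------------------------------------------------------

@dataclass
class UmiRead:
    """One merged amplicon read carrying a UMI.

    ``sequence`` holds the biological (post-UMI) bases; in FASTQ the UMI
    occupies the first ``len(umi)`` bases of the record.  ``truth_clone_id``
    is only populated by the simulator.
    """

    read_id: str
    umi: str
    sequence: str
    qualities: np.ndarray  # Phred scores, one per sequence base
    truth_clone_id: int | None = None

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"sequence/quality length mismatch: {len(self.sequence)} vs {len(self.qualities)}"
            )


def simulate_sequencing(
    sample: CellSample,
    pop: ClonePopulation,
    *,
    mean_reads_per_molecule: float = 3.0,
    error_rate: float = 0.005,
    umi_length: int = 12,
    q_hi: int = 37,
    q_lo: int = 10,
    lowq_fraction: float = 0.05,
    transcripts_per_cell: float = 3.0,
    seed: int = 0,
    fastq_path=None,
) -> list[UmiRead]:
    """Simulate UMI-tagged sequencing of a cell sample.

    Every molecule gets a random UMI and ``1 + Poisson(mean_reads_per_molecule
    - 1)`` reads; each read carries i.i.d. substitution errors at
    ``error_rate``.  A ``lowq_fraction`` of reads is degraded: a random >=5%
    of positions drop to ``q_lo`` (enough to fail the default 95%>Q20 quality
    rule), all other bases are ``q_hi``.  If ``fastq_path`` is given, reads
    are also written as Sanger FASTQ with the UMI in the first
    ``umi_length`` bases.
    """
    if not 0 <= error_rate < 1:
        raise ValueError(f"error_rate must be in [0, 1), got {error_rate}")
    if mean_reads_per_molecule < 1:
        raise ValueError("mean_reads_per_molecule must be >= 1")
    if not 0 <= lowq_fraction <= 1:
        raise ValueError("lowq_fraction must be in [0, 1]")
    if umi_length < 1:
        raise ValueError("umi_length must be >= 1")

    rng = np.random.default_rng(seed)
    mols = molecule_counts(sample, transcripts_per_cell,
                           seed=int(rng.integers(0, 2**31)))
    clone_of_mol = np.repeat(np.arange(len(mols)), mols)
    encoded = {int(c): encode_seq(pop.sequences[int(c)])
               for c in np.unique(clone_of_mol)}

    extra = mean_reads_per_molecule - 1.0
    reads: list[UmiRead] = []
    for m_idx, cid in enumerate(clone_of_mol):
        cid = int(cid)
        umi = decode_seq(random_seq(rng, umi_length))
        k = 1 + (int(rng.poisson(extra)) if extra > 0 else 0)
        base = encoded[cid]
        length = len(base)
        for r in range(k):
            arr = base.copy()
            if error_rate > 0:
                mask = rng.random(length) < error_rate
                if mask.any():
                    substitute(arr, np.nonzero(mask)[0], rng)
            qual = np.full(length, q_hi, dtype=np.int16)
            if lowq_fraction > 0 and rng.random() < lowq_fraction:
                n_low = max(int(np.ceil(0.05 * length)),
                            int(np.ceil(length * rng.uniform(0.05, 0.3))))
                pos = rng.choice(length, size=n_low, replace=False)
                qual[pos] = q_lo
            reads.append(UmiRead(
                read_id=f"{sample.sample_id}:m{m_idx}:r{r}",
                umi=umi, sequence=decode_seq(arr), qualities=qual,
                truth_clone_id=cid,
            ))

    if fastq_path is not None:
        from .io import write_fastq

        write_fastq(fastq_path, reads)
    return reads
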