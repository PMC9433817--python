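"""Pipeline orchestration: configuration, seeding, manifests, reporting.

One global seed expands deterministically into per-stage seeds, so a whole
run is reproducible byte for byte from config + seed.  Two execution modes
share the same analysis stages:

* ``reads`` — the full path: FASTQ simulation, quality filtering, UMI
  consensus, germline annotation, FUS collapse.
* ``counts`` — the noiseless molecule-count analog: cells are sampled, each
  cell emits its molecules, and molecules are downsampled directly to the
  target depth.  This is exactly what the read path computes when the
  sequencing channel is error-free with one read per molecule (the
  round-trip identity pinned by the test suite), and it scales to the full
  study conditions in seconds.

``volume_study`` replicates the blood-volume saturation experiment on the
synthetic population: volumes 5/10/20/40 from one arm, an independent 40
from the other arm, all repertoires downsampled to a common depth, then
Hill diversity, sectioned coverage, detection thresholds and stratified
frequency correlations.
"""
from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .annotate import annotate_reads, to_airr
from .preprocess import FilterParams, preprocess_reads
from .repertoire import (Repertoire, collapse_fus, downsample_counts,
                         downsample_reads, hill_diversity)
from .saturation import (CoverageTable, SectionTable, accumulated_proportion,
                         build_sections, correlate_overlap, coverage,
                         cutoff_50, detection_threshold)
from .synthetic_data import (ClonePopulation, PopulationModel, generate_germline_set,
                             molecule_counts, sample_blood_volume,
                             simulate_sequencing)

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the counts so far."""


def derive_seed(base: int, *tokens) -> int:
    """Deterministically expand one master seed into per-stage seeds.

    Tokens may be ints or strings; the result is always < 2**31.
    """
    entropy = [int(base) & 0x7FFFFFFF]
    for t in tokens:
        if isinstance(t, str):
            entropy.append(zlib.crc32(t.encode()))
        else:
            entropy.append(int(t) & 0x7FFFFFFF)
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """All pipeline knobs; round-trips losslessly through YAML.

    Defaults are the scaled-down study conditions: a 10^4-clone power-law
    population (alpha 2.2), 2x10^4 cells per mL analog, volumes 5/10/20/40
    (the 40 from the other arm), every repertoire downsampled to 19 000
    functional reads.
    """

    seed: int = 0
    mode: str = "counts"  # "counts" or "reads"
    # germline / population
    n_v: int = 5
    n_j: int = 3
    n_clones: int = 10_000
    alpha: float = 2.2
    switch_bias: float = 1.0
    shm_rate_naive: float = 0.5
    shm_rate_switched: float = 8.0
    # sampling design
    volumes: list = field(default_factory=lambda: [5.0, 10.0, 20.0, 40.0])
    arms: list = field(default_factory=lambda: ["left", "left", "left", "right"])
    cells_per_ml: int = 20_000
    transcripts_per_cell: float = 3.0
    # sequencing (reads mode)
    mean_reads_per_molecule: float = 3.0
    error_rate: float = 0.005
    umi_length: int = 12
    q_hi: int = 37
    q_lo: int = 10
    lowq_fraction: float = 0.05
    # preprocessing / annotation
    phred_threshold: int = 20
    pass_fraction: float = 0.95
    min_cluster_reads: int = 3
    min_identity: float = 0.8
    # repertoire / saturation
    depth: int | None = 19_000
    n_sections: int = 10
    hill_q: float = 1.0
    transform: str = "log10"

    def __post_init__(self) -> None:
        if self.mode not in ("counts", "reads"):
            raise ValueError(f"mode must be 'counts' or 'reads', got {self.mode!r}")
        if len(self.volumes) != len(self.arms):
            raise ValueError("volumes and arms must have the same length")

    @classmethod
    def reads_demo(cls, seed: int = 0) -> "RunConfig":
        """A small full-read-path configuration that runs in seconds."""
        return cls(
            seed=seed, mode="reads", n_clones=150, cells_per_ml=120,
            volumes=[2.0, 4.0], arms=["left", "right"], depth=120,
            mean_reads_per_molecule=3.5, error_rate=0.003,
            transcripts_per_cell=1.5,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class PipelineResult:
    config: RunConfig
    germline: object
    population: ClonePopulation
    repertoires: list[Repertoire]
    sections: SectionTable
    coverages: dict[str, CoverageTable]
    accumulated: dict[str, np.ndarray]
    thresholds: pd.DataFrame
    diversity: pd.DataFrame
    correlations: pd.DataFrame
    manifest: dict


def _build_repertoire_reads(config: RunConfig, pop, sample, germline, idx, outdir):
    """Full read path for one sample; returns (repertoire, stage counts)."""
    seed = config.seed
    fastq_path = None
    if outdir is not None:
        fastq_path = outdir / f"reads_{sample.sample_id}.fastq"
    reads = simulate_sequencing(
        sample, pop,
        mean_reads_per_molecule=config.mean_reads_per_molecule,
        error_rate=config.error_rate, umi_length=config.umi_length,
        q_hi=config.q_hi, q_lo=config.q_lo, lowq_fraction=config.lowq_fraction,
        transcripts_per_cell=config.transcripts_per_cell,
        seed=derive_seed(seed, "sequencing", idx), fastq_path=fastq_path)
    params = FilterParams(config.phred_threshold, config.pass_fraction,
                          config.min_cluster_reads)
    pre = preprocess_reads(reads, params)
    annotated = annotate_reads([c.sequence for c in pre.consensus_reads],
                               germline, config.min_identity)
    if outdir is not None:
        rio.write_consensus_fasta(outdir / f"consensus_{sample.sample_id}.fasta",
                                  pre.consensus_reads)
        rio.write_airr(outdir / f"airr_{sample.sample_id}.tsv",
                       to_airr(annotated, [f"{sample.sample_id}:c{i}"
                                           for i in range(len(annotated))]))
    functional = [(a.sequence, a.isotype) for a in annotated if a.is_functional]
    counts = dict(pre.stats)
    counts["n_functional"] = len(functional)
    if config.depth is not None:
        if config.depth > len(functional):
            raise PipelineError(
                f"repertoire stage for {sample.sample_id}: requested depth "
                f"{config.depth} exceeds the {len(functional)} functional reads "
                f"available (stage counts so far: {counts})")
        functional = downsample_reads(functional, config.depth,
                                      derive_seed(seed, "depth", idx))
    rep = collapse_fus(functional, sample_id=sample.sample_id,
                       volume_ml=sample.volume_ml, arm=sample.arm)
    counts["depth"] = rep.depth
    counts["n_fus"] = rep.richness
    return rep, counts


def _build_repertoire_counts(config: RunConfig, pop, sample, idx):
    """Noiseless molecule-count analog for one sample."""
    mols = molecule_counts(sample, config.transcripts_per_cell,
                           derive_seed(config.seed, "molecules", idx))
    total = int(mols.sum())
    counts = {"n_input": total, "n_functional": total}
    if config.depth is not None:
        if config.depth > total:
            raise PipelineError(
                f"repertoire stage for {sample.sample_id}: requested depth "
                f"{config.depth} exceeds the {total} functional reads available")
        mols = downsample_counts(mols, config.depth,
                                 derive_seed(config.seed, "depth", idx))
    rep = Repertoire.from_counts(
        pop.table["sequence"], pop.table["isotype"], mols,
        sample_id=sample.sample_id, volume_ml=sample.volume_ml, arm=sample.arm)
    counts["depth"] = rep.depth
    counts["n_fus"] = rep.richness
    return rep, counts


def run_pipeline(config: RunConfig, outdir=None) -> PipelineResult:
    """Execute simulate -> preprocess -> annotate -> repertoire -> saturation.

    Fully deterministic for a fixed config + seed; all outputs (if
    ``outdir`` is given) are plain-text tables plus a JSON manifest whose
    counts reconcile stage to stage.
    """
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)

    seed = config.seed
    germline = generate_germline_set(config.n_v, config.n_j,
                                     derive_seed(seed, "germline"))
    model = PopulationModel(
        n_clones=config.n_clones, alpha=config.alpha,
        switch_bias=config.switch_bias, shm_rate_naive=config.shm_rate_naive,
        shm_rate_switched=config.shm_rate_switched,
        seed=derive_seed(seed, "population"))
    pop = simulate_population_cached(germline, model)

    repertoires: list[Repertoire] = []
    sample_counts: dict[str, dict] = {}
    for idx, (vol, arm) in enumerate(zip(config.volumes, config.arms)):
        sample = sample_blood_volume(
            pop, vol, config.cells_per_ml, arm,
            seed=derive_seed(seed, "blood", idx),
            sample_id=f"s{idx}-{vol:g}mL-{arm}")
        if config.mode == "reads":
            rep, counts = _build_repertoire_reads(config, pop, sample, germline,
                                                  idx, outdir)
        else:
            rep, counts = _build_repertoire_counts(config, pop, sample, idx)
        counts["volume_ml"] = vol
        counts["arm"] = arm
        counts["total_cells"] = sample.total_cells
        sample_counts[sample.sample_id] = counts
        repertoires.append(rep)

    # saturation: the largest volume is the reference (last one on ties,
    # i.e. the other-arm draw in the default design)
    ref_idx = max(range(len(repertoires)),
                  key=lambda i: (repertoires[i].volume_ml, i))
    reference = repertoires[ref_idx]
    sections = build_sections(reference, config.n_sections)

    coverages: dict[str, CoverageTable] = {}
    accumulated: dict[str, np.ndarray] = {}
    thr_rows = []
    corr_rows = []
    for rep in repertoires:
        if rep is reference:
            continue
        cov = coverage(reference, rep, sections)
        coverages[rep.sample_id] = cov
        accumulated[rep.sample_id] = accumulated_proportion(rep, reference, sections)
        thr = detection_threshold(cov, sections)
        cut = cutoff_50(cov, sections)
        thr_rows.append({"query_id": rep.sample_id, "volume_ml": rep.volume_ml,
                         "detection_threshold": np.nan if thr is None else thr,
                         "cutoff_50": np.nan if cut is None else cut})
        for stratum in ("all", "IgM/D", "class-switched"):
            res = correlate_overlap(reference, rep, stratum, config.transform)
            corr_rows.append({"query_id": rep.sample_id, "stratum": stratum,
                              "n_overlapping": res.n_overlapping, "r": res.r,
                              "p_value": res.p_value, "transform": res.transform,
                              "reason": res.reason or ""})
        if cut is not None:
            for stratum in ("high-frequency", "low-frequency"):
                res = correlate_overlap(reference, rep, stratum,
                                        config.transform, cutoff=cut)
                corr_rows.append({"query_id": rep.sample_id, "stratum": stratum,
                                  "n_overlapping": res.n_overlapping, "r": res.r,
                                  "p_value": res.p_value, "transform": res.transform,
                                  "reason": res.reason or ""})

    diversity = pd.DataFrame([{
        "sample_id": r.sample_id, "volume_ml": r.volume_ml, "arm": r.arm,
        "depth": r.depth, "n_fus": r.richness,
        "hill": hill_diversity(r, config.hill_q),
    } for r in repertoires])
    thresholds = pd.DataFrame(thr_rows)
    correlations = pd.DataFrame(corr_rows)

    manifest = {
        "tool": "repsat", "version": __version__,
        "seed": seed, "mode": config.mode,
        "parameters": asdict(config),
        "samples": sample_counts,
        "reference": reference.sample_id,
    }

    if outdir is not None:
        config.to_yaml(outdir / "config.yaml")
        pop.to_tsv(outdir / "truth.tsv")
        germline.to_yaml(outdir / "germline.yaml")
        for rep in repertoires:
            rio.write_fus_table(outdir / f"fus_{rep.sample_id}.tsv", rep)
        sections.to_frame().to_csv(outdir / "sections.tsv", sep="\t",
                                   index=False, float_format="%.12g")
        cov_frames = []
        for qid, cov in coverages.items():
            f = cov.to_frame()
            f.insert(0, "query_id", qid)
            f["accumulated_proportion"] = accumulated[qid]
            cov_frames.append(f)
        if cov_frames:
            pd.concat(cov_frames).to_csv(outdir / "coverage.tsv", sep="\t",
                                         index=False, float_format="%.12g")
        thresholds.to_csv(outdir / "thresholds.tsv", sep="\t", index=False,
                          float_format="%.12g")
        diversity.to_csv(outdir / "diversity.tsv", sep="\t", index=False,
                         float_format="%.12g")
        correlations.to_csv(outdir / "correlations.tsv", sep="\t", index=False,
                            float_format="%.12g")
        manifest["checksums"] = {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(outdir.iterdir()) if p.is_file()
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)

    return PipelineResult(config, germline, pop, repertoires, sections,
                          coverages, accumulated, thresholds, diversity,
                          correlations, manifest)


# population simulation is the slowest generator step at study scale; cache
# on (germline identity, model parameters) so that repeated runs in one
# process (e.g. a seed sweep over the same population) stay fast
_POP_CACHE: dict = {}


def simulate_population_cached(germline, model: PopulationModel) -> ClonePopulation:
    key = (id(germline), json.dumps(asdict(model), sort_keys=True))
    pop = _POP_CACHE.get(key)
    if pop is None:
        from .synthetic_data import simulate_population

        pop = _POP_CACHE[key] = simulate_population(germline, model)
    return pop


# ---------------------------------------------------------------------------
# the blood-volume saturation study
# ---------------------------------------------------------------------------

def _splitting_cutoff(rep_a: Repertoire, pcov, psec) -> float | None:
    """Frequency cutoff for high/low stratification that actually splits.

    The 50%-coverage cutoff is used when it leaves FUSs on both sides of
    the split.  In shallow synthetic repertoires even the lowest section
    can exceed 50% coverage, pushing that cutoff to the repertoire minimum
    and leaving the lower-frequency stratum empty; the detection threshold
    (the 100%-coverage boundary) is then the natural higher/lower split
    and is used as the fallback.  None when no candidate splits.
    """
    f = np.unique(rep_a.frequencies)
    for cand in (cutoff_50(pcov, psec), detection_threshold(pcov, psec)):
        if cand is None:
            continue
        # both strata need at least two distinct frequency levels, else the
        # Pearson r of the stratum is undefined by construction
        if (f < cand).sum() >= 2 and (f >= cand).sum() >= 2:
            return cand
    return None


def volume_study(
    seed: int = 0,
    n_seeds: int = 10,
    *,
    n_clones: int = 10_000,
    alpha: float = 2.2,
    cells_per_ml: int = 20_000,
    transcripts_per_cell: float = 3.0,
    depth: int = 19_000,
    volumes=(5.0, 10.0, 20.0, 40.0),
    n_sections: int = 10,
    transform: str = "log10",
) -> dict[str, pd.DataFrame]:
    """Replicate the volume-saturation experiment over ``n_seeds`` draws.

    One population is simulated; per replicate, the left arm yields one
    sample per volume and the right arm yields two independent
    largest-volume samples (the second one only feeds the same-arm
    comparison).  Coverage and correlations use the right-arm draw as the
    reference, mirroring the two-arm design.  Returns tidy tables:
    ``diversity``, ``coverage``, ``thresholds``, ``pairs`` (high/low
    stratified correlations for every ordered volume pair) and ``arm``.
    """
    germline = generate_germline_set(5, 3, derive_seed(seed, "germline"))
    model = PopulationModel(n_clones=n_clones, alpha=alpha,
                            seed=derive_seed(seed, "population"))
    pop = simulate_population_cached(germline, model)
    seqs = pop.table["sequence"]
    isos = pop.table["isotype"]
    vmax = max(volumes)

    def make_rep(rep_i: int, vol: float, arm: str, tag: str) -> Repertoire:
        cs = sample_blood_volume(pop, vol, cells_per_ml, arm,
                                 seed=derive_seed(seed, "blood", rep_i, tag),
                                 sample_id=f"r{rep_i}-{tag}")
        mols = molecule_counts(cs, transcripts_per_cell,
                               derive_seed(seed, "molecules", rep_i, tag))
        ds = downsample_counts(mols, depth, derive_seed(seed, "depth", rep_i, tag))
        return Repertoire.from_counts(seqs, isos, ds, sample_id=cs.sample_id,
                                      volume_ml=vol, arm=arm)

    div_rows, cov_rows, thr_rows, pair_rows, arm_rows = [], [], [], [], []
    for rep_i in range(n_seeds):
        left = {v: make_rep(rep_i, v, "left", f"left{v:g}") for v in volumes}
        right_a = make_rep(rep_i, vmax, "right", "rightA")
        right_b = make_rep(rep_i, vmax, "right", "rightB")

        for v, rep in left.items():
            div_rows.append({"replicate": rep_i, "volume_ml": v,
                             "n_fus": rep.richness,
                             "hill_q1": hill_diversity(rep, 1.0)})

        # coverage of the right-arm reference by the smaller left-arm volumes
        sections = build_sections(right_a, n_sections)
        for v in volumes:
            if v == vmax:
                continue
            cov = coverage(right_a, left[v], sections)
            for s in range(1, n_sections + 1):
                cov_rows.append({"replicate": rep_i, "volume_ml": v, "section": s,
                                 "coverage": cov.coverage[s - 1],
                                 "n_reference": int(cov.n_reference[s - 1])})
            thr = detection_threshold(cov, sections)
            cut = cutoff_50(cov, sections)
            thr_rows.append({"replicate": rep_i, "volume_ml": v,
                             "detection_threshold": np.nan if thr is None else thr,
                             "cutoff_50": np.nan if cut is None else cut})

        # stratified correlations for every ordered volume pair (the larger
        # volume of the pair is the reference for sections and the cutoff)
        pool = dict(left)
        pool[vmax] = right_a  # the other-arm draw is the reference
        ordered = sorted(volumes)
        for i, small in enumerate(ordered):
            for large in ordered[i + 1:]:
                rep_a, rep_b = pool[large], pool[small]
                psec = build_sections(rep_a, n_sections)
                pcov = coverage(rep_a, rep_b, psec)
                cut = _splitting_cutoff(rep_a, pcov, psec)
                row = {"replicate": rep_i, "volume_large": large,
                       "volume_small": small,
                       "cutoff": np.nan if cut is None else cut}
                for stratum, kw in (("all", {}), ("IgM/D", {}),
                                    ("class-switched", {}),
                                    ("high-frequency", {"cutoff": cut}),
                                    ("low-frequency", {"cutoff": cut})):
                    if "cutoff" in kw and cut is None:
                        row[stratum] = np.nan
                        continue
                    res = correlate_overlap(rep_a, rep_b, stratum, transform, **kw)
                    row[stratum] = res.r
                    if stratum == "all":
                        row["n_overlapping"] = res.n_overlapping
                pair_rows.append(row)

        # arm independence: cross-arm vs same-arm largest-volume replicates
        r_cross = correlate_overlap(left[vmax], right_a, "all", transform).r
        r_same = correlate_overlap(right_a, right_b, "all", transform).r
        ov_cross = len(left[vmax].keys() & right_a.keys())
        ov_same = len(right_a.keys() & right_b.keys())
        arm_rows.append({"replicate": rep_i, "r_cross_arm": r_cross,
                         "r_same_arm": r_same,
                         "overlap_cross_arm": ov_cross,
                         "overlap_same_arm": ov_same})

    return {
        "diversity": pd.DataFrame(div_rows),
        "coverage": pd.DataFrame(cov_rows),
        "thresholds": pd.DataFrame(thr_rows),
        "pairs": pd.DataFrame(pair_rows),
        "arm": pd.DataFrame(arm_rows),
    }


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def report(outdir, plots: bool = False) -> Path:
    """Summarize a finished run directory into report tables (and plots).

    Works purely from the saved tables, so a regenerated report is
    byte-identical to one produced right after the run.
    """
    outdir = Path(outdir)
    rep_dir = outdir / "report"
    rep_dir.mkdir(exist_ok=True)

    diversity = pd.read_csv(outdir / "diversity.tsv", sep="\t")
    div = diversity.sort_values("volume_ml").reset_index(drop=True)
    div["hill_increment"] = div["hill"].diff()
    div.to_csv(rep_dir / "diversity_vs_volume.tsv", sep="\t", index=False,
               float_format="%.12g")

    # frequency-rank distributions per sample, split by isotype class
    fus_paths = sorted(outdir.glob("fus_*.tsv"))
    dist_rows = []
    reps = {}
    for p in fus_paths:
        rep = rio.read_fus_table(p)
        reps[rep.sample_id] = rep
        t = rep.table.sort_values("frequency", ascending=False)
        freqs = t["frequency"].to_numpy()
        dist_rows.append(pd.DataFrame({
            "sample_id": rep.sample_id, "rank": np.arange(1, len(t) + 1),
            "frequency": freqs, "isotype_class": t["isotype_class"].to_numpy(),
        }))
    if dist_rows:
        pd.concat(dist_rows).to_csv(rep_dir / "frequency_distribution.tsv",
                                    sep="\t", index=False, float_format="%.12g")

    cov_path = outdir / "coverage.tsv"
    if cov_path.exists():
        cov = pd.read_csv(cov_path, sep="\t")
        sections = pd.read_csv(outdir / "sections.tsv", sep="\t")
        merged = cov.merge(
            sections[["section", "representative_frequency"]], on="section")
        merged.to_csv(rep_dir / "coverage_summary.tsv", sep="\t", index=False,
                      float_format="%.12g")
    corr_path = outdir / "correlations.tsv"
    if corr_path.exists():
        corr = pd.read_csv(corr_path, sep="\t", keep_default_na=False)
        defined = corr[corr["reason"] == ""].drop(columns=["reason"])
        skipped = corr[corr["reason"] != ""]
        for _, row in skipped.iterrows():
            logger.info("report: stratum %s for %s omitted (%s)",
                        row["stratum"], row["query_id"], row["reason"])
        defined.to_csv(rep_dir / "correlation_summary.tsv", sep="\t",
                       index=False, float_format="%.12g")

    if plots:
        _make_plots(outdir, rep_dir, reps)
    return rep_dir


def _make_plots(outdir: Path, rep_dir: Path, reps: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for sid, rep in sorted(reps.items()):
        f = np.sort(rep.frequencies)[::-1]
        ax.loglog(np.arange(1, len(f) + 1), f, label=sid, lw=1)
    ax.set_xlabel("FUS rank")
    ax.set_ylabel("frequency")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(rep_dir / "frequency_distribution.png", dpi=120)
    plt.close(fig)

    cov_path = rep_dir / "coverage_summary.tsv"
    if cov_path.exists():
        cov = pd.read_csv(cov_path, sep="\t")
        fig, ax = plt.subplots(figsize=(6, 4))
        for qid, grp in cov.groupby("query_id"):
            g = grp.dropna(subset=["coverage", "representative_frequency"])
            ax.semilogx(g["representative_frequency"], 100 * g["coverage"],
                        marker="o", label=qid)
        ax.set_xlabel("representative frequency")
        ax.set_ylabel("coverage (%)")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(rep_dir / "coverage.png", dpi=120)
        plt.close(fig)
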