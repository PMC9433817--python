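"""Log-sectioned coverage, detection thresholds and stratified correlation.

The headline analysis: take the largest-volume repertoire as the reference,
split its frequency range into ``n_sections`` equidistant sections on a
log10 scale (section 1 = lowest frequencies, section ``n`` = highest), and
ask, per section, what fraction of reference FUSs a smaller-volume query
repertoire recovers (its *coverage*).  Two summary frequencies fall out of
the coverage profile:

* the *detection threshold* — the lower boundary of the lowest section such
  that it and every higher section are fully (100%) covered: above this
  frequency, every reference FUS is seen in the query;
* the *50% cutoff* — same scan with coverage >= 0.5, used to split the
  repertoire into higher-/lower-frequency strata for correlation analysis.

Sections that contain no reference FUS have undefined coverage; they are
reported as NaN (not 0) and do not break a threshold scan.

Frequencies of FUSs present in both repertoires are compared by Pearson
correlation, on log10-transformed frequencies by default, optionally
restricted to an isotype class (IgM/D vs class-switched) or to one side of
a frequency cutoff evaluated on the first repertoire's frequencies.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .repertoire import NAIVE_CLASS, SWITCHED_CLASS, Repertoire

logger = logging.getLogger(__name__)

STRATA = ("all", "IgM/D", "class-switched", "high-frequency", "low-frequency")

#: tolerance (in log10 units) when binning frequencies at section boundaries;
#: a value within 1e-9 of a boundary is treated as sitting on it
_LOG_EPS = 1e-9


def geometric_mean(values) -> float:
    """Geometric mean of positive values."""
    v = np.asarray(values, dtype=float)
    if v.size == 0 or (v <= 0).any():
        raise ValueError("geometric mean requires positive values")
    return float(10 ** np.mean(np.log10(v)))


@dataclass
class SectionTable:
    """Frequency sections of a reference repertoire.

    ``boundaries`` has ``n_sections + 1`` strictly increasing frequencies;
    section ``s`` (1-based) covers ``[boundaries[s-1], boundaries[s])`` with
    the top section closed.  ``members[s-1]`` holds the reference FUS keys
    of section ``s``; ``representative_frequency`` is the geometric mean of
    member frequencies (NaN for empty sections).
    """

    reference_id: str
    n_sections: int
    boundaries: np.ndarray
    members: list[set]
    representative_frequency: np.ndarray

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(m) for m in self.members], dtype=np.int64)

    def lower_boundary(self, section: int) -> float:
        if not 1 <= section <= self.n_sections:
            raise ValueError(f"section must be in 1..{self.n_sections}")
        return float(self.boundaries[section - 1])

    def section_of(self, frequency: float) -> int:
        """1-based section index of a frequency (clipped to 1..n)."""
        lo = np.log10(self.boundaries[0])
        hi = np.log10(self.boundaries[-1])
        if hi <= lo:  # degenerate
            return self.n_sections
        width = (hi - lo) / self.n_sections
        idx = int(np.floor((np.log10(frequency) - lo) / width + _LOG_EPS))
        return int(np.clip(idx, 0, self.n_sections - 1)) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "section": np.arange(1, self.n_sections + 1),
            "lower_boundary": self.boundaries[:-1],
            "upper_boundary": self.boundaries[1:],
            "n_fus": self.counts,
            "representative_frequency": self.representative_frequency,
        })


def build_sections(reference: Repertoire, n_sections: int = 10) -> SectionTable:
    """Split the reference frequency range into log10-equidistant sections.

    Bins are half-open [lo, hi) with the top bin closed; if every FUS has
    the same frequency the whole repertoire lands in the top section.
    """
    if reference.richness == 0:
        raise ValueError("cannot build sections on an empty reference repertoire")
    if n_sections < 1:
        raise ValueError("n_sections must be >= 1")
    f = reference.frequencies
    lo, hi = np.log10(f.min()), np.log10(f.max())
    if hi == lo:
        # degenerate range: a nominal 0.1-decade-per-section axis below the
        # single frequency; everything populates the top section
        boundaries = 10 ** np.linspace(hi - 0.1 * n_sections, hi, n_sections + 1)
        idx = np.full(len(f), n_sections - 1)
    else:
        boundaries = 10 ** np.linspace(lo, hi, n_sections + 1)
        width = (hi - lo) / n_sections
        idx = np.floor((np.log10(f) - lo) / width + _LOG_EPS).astype(int)
        idx = np.clip(idx, 0, n_sections - 1)

    keys = list(zip(reference.table["sequence"], reference.table["isotype"]))
    members: list[set] = [set() for _ in range(n_sections)]
    freq_lists: list[list[float]] = [[] for _ in range(n_sections)]
    for key, s, freq in zip(keys, idx, f):
        members[s].add(key)
        freq_lists[s].append(freq)
    rep_freq = np.array([
        geometric_mean(fl) if fl else np.nan for fl in freq_lists])
    return SectionTable(reference.sample_id, n_sections, boundaries, members, rep_freq)


@dataclass
class CoverageTable:
    """Per-section coverage of a reference repertoire by a query.

    ``coverage[s-1]`` = (reference FUSs of section s also present in the
    query) / (reference FUSs of section s); NaN where the section is empty.
    """

    reference_id: str
    query_id: str
    coverage: np.ndarray
    n_reference: np.ndarray
    n_overlap: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "section": np.arange(1, len(self.coverage) + 1),
            "n_reference": self.n_reference,
            "n_overlap": self.n_overlap,
            "coverage": self.coverage,
        })


def coverage(reference: Repertoire, query: Repertoire, sections: SectionTable) -> CoverageTable:
    """Exact FUS-key overlap, section by section."""
    qkeys = query.keys()
    n_ref = sections.counts
    n_ov = np.array([len(m & qkeys) for m in sections.members], dtype=np.int64)
    with np.errstate(invalid="ignore"):
        cov = np.where(n_ref > 0, n_ov / np.maximum(n_ref, 1), np.nan)
    return CoverageTable(reference.sample_id, query.sample_id, cov, n_ref, n_ov)


def accumulated_proportion(
    query: Repertoire, reference: Repertoire, sections: SectionTable
) -> np.ndarray:
    """Cumulative overlap from the top section down, as a share of the query.

    Entry ``s-1``: query FUSs overlapping reference sections s..n, divided
    by the total query FUS count.  Monotone non-increasing in s.  Undefined
    (all-NaN, flagged) for an empty query.
    """
    total = query.richness
    n = sections.n_sections
    if total == 0:
        logger.warning("accumulated_proportion: empty query %s", query.sample_id)
        return np.full(n, np.nan)
    qkeys = query.keys()
    ov = np.array([len(m & qkeys) for m in sections.members], dtype=np.int64)
    suffix = np.cumsum(ov[::-1])[::-1]  # suffix[s-1] = overlap in sections s..n
    return suffix / total


def _scan_from_top(covtab: CoverageTable, sections: SectionTable, predicate) -> float | None:
    """Lower boundary of the lowest section such that it and all higher
    *defined* sections satisfy ``predicate``; empty (NaN) sections do not
    break the run.  None when no defined section from the top qualifies."""
    candidate = None
    for s in range(sections.n_sections, 0, -1):
        c = covtab.coverage[s - 1]
        if np.isnan(c):
            continue
        if predicate(c):
            candidate = s
        else:
            break
    return None if candidate is None else sections.lower_boundary(candidate)


def detection_threshold(covtab: CoverageTable, sections: SectionTable) -> float | None:
    """Frequency above which every reference FUS is recovered by the query
    (coverage 1.0 from that section up); None when even the top defined
    section is incompletely covered."""
    return _scan_from_top(covtab, sections, lambda c: c >= 1.0)


def cutoff_50(covtab: CoverageTable, sections: SectionTable) -> float | None:
    """Frequency cutoff satisfying >= 50% coverage from that section up."""
    return _scan_from_top(covtab, sections, lambda c: c >= 0.5)


@dataclass
class CorrelationResult:
    stratum: str
    n_overlapping: int
    r: float
    p_value: float
    transform: str
    reason: str | None = None

    @property
    def defined(self) -> bool:
        return self.reason is None


def correlate_overlap(
    rep_a: Repertoire,
    rep_b: Repertoire,
    stratum: str = "all",
    transform: str = "log10",
    cutoff: float | None = None,
) -> CorrelationResult:
    """Pearson correlation of FUS frequencies across two repertoires.

    Only FUSs present in both repertoires enter; the stratum restricts them
    to an isotype class or to one side of ``cutoff`` (evaluated on
    ``rep_a`` frequencies; high-frequency means >= cutoff).  With fewer
    than 2 pairs, or zero variance, the result is undefined with a reason
    rather than an exception.
    """
    if stratum not in STRATA:
        raise ValueError(f"unknown stratum {stratum!r}; use one of {STRATA}")
    if transform not in ("raw", "log10"):
        raise ValueError(f"transform must be 'raw' or 'log10', got {transform!r}")
    cols = ["sequence", "isotype", "isotype_class", "frequency"]
    merged = pd.merge(
        rep_a.table[cols], rep_b.table[["sequence", "isotype", "frequency"]],
        on=["sequence", "isotype"], suffixes=("_a", "_b"))

    if stratum == NAIVE_CLASS:
        merged = merged[merged["isotype_class"] == NAIVE_CLASS]
    elif stratum == SWITCHED_CLASS:
        merged = merged[merged["isotype_class"] == SWITCHED_CLASS]
    elif stratum in ("high-frequency", "low-frequency"):
        if cutoff is None:
            raise ValueError(f"stratum {stratum!r} requires a frequency cutoff")
        if stratum == "high-frequency":
            merged = merged[merged["frequency_a"] >= cutoff]
        else:
            merged = merged[merged["frequency_a"] < cutoff]

    n = len(merged)
    if n < 2:
        return CorrelationResult(stratum, n, np.nan, np.nan, transform,
                                 reason=f"only {n} overlapping FUSs in stratum")
    x = merged["frequency_a"].to_numpy(dtype=float)
    y = merged["frequency_b"].to_numpy(dtype=float)
    if transform == "log10":
        x, y = np.log10(x), np.log10(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(stratum, n, np.nan, np.nan, transform,
                                 reason="zero variance in one repertoire")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(stratum, n, float(r), float(p), transform)
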