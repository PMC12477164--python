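"""From expression matrices to individual differential-expression signatures.

The individualized profiling step asks, for each patient separately, which
proteins sit outside the normal range — defined as the [5th, 95th]
percentile band of the healthy reference distribution, per protein.  Values
strictly above the band are called upregulated (+1), strictly below
downregulated (-1); in-range proteins are simply absent from the signature
(never stored as 0).  Raw individual calls are then refined by two
population-level filters: membership in the cohort-wide differentially
expressed set (Welch's t-test, Benjamini-Hochberg FDR) and network
proximity to the disease knowledge set (within three interaction links).
Patients left with too few refined calls are excluded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "HealthyBounds",
    "IDESignature",
    "collapse_probes",
    "healthy_bounds",
    "call_ide",
    "call_ides",
    "population_degs",
    "refine_ides",
    "write_ides",
    "load_ides",
]

#: percentile convention shared across the package (healthy bounds,
#: responder stratification): linear interpolation between order statistics.
QUANTILE_METHOD = "linear"


@dataclass(frozen=True)
class ExpressionMatrix:
    """Proteins x samples matrix of finite expression values."""

    values: pd.DataFrame  # index: proteins, columns: samples

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise ParameterError("duplicate protein or sample identifiers")
        if not np.isfinite(df.to_numpy(dtype=float)).all():
            raise ParameterError("expression values must be finite")

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample(self, sample_id: str) -> pd.Series:
        return self.values[sample_id]

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="protein")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


@dataclass(frozen=True)
class HealthyBounds:
    """Per-protein normal range [lower, upper] from healthy samples."""

    lower: pd.Series
    upper: pd.Series

    def __post_init__(self) -> None:
        if not self.lower.index.equals(self.upper.index):
            raise ParameterError("lower/upper bounds indexed differently")
        if bool((self.lower > self.upper).any()):
            raise ParameterError("lower bound exceeds upper bound")

    @property
    def proteins(self) -> pd.Index:
        return self.lower.index


@dataclass(frozen=True)
class IDESignature:
    """One patient's individually dysregulated proteins.

    ``entries[p]`` is +1 (above the healthy band) or -1 (below); proteins
    inside the band are absent, never zero-valued.
    """

    patient: str
    entries: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {p: s for p, s in self.entries.items() if s not in (1, -1)}
        if bad:
            raise ParameterError(f"IDE signs must be +1/-1, got {bad}")

    @property
    def proteins(self) -> set[str]:
        return set(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


def collapse_probes(probe_matrix: pd.DataFrame,
                    mapping: Mapping[str, str]) -> ExpressionMatrix:
    """Average probe rows into protein rows.

    ``mapping`` is probe -> protein; every mapped probe must exist in the
    matrix.  Unmapped probes are dropped (count logged).
    """
    if not mapping:
        raise ParameterError("empty probe->protein mapping")
    missing = sorted(set(mapping) - set(probe_matrix.index))
    if missing:
        raise ParameterError(f"mapped probes absent from matrix: {missing[:5]}...")
    unmapped = probe_matrix.index.difference(list(mapping))
    if len(unmapped):
        logger.info("dropping %d unmapped probe(s)", len(unmapped))
    kept = probe_matrix.loc[list(mapping)]
    collapsed = kept.groupby(pd.Series(mapping), sort=True).mean()
    collapsed.index.name = "protein"
    return ExpressionMatrix(collapsed)


def healthy_bounds(healthy: ExpressionMatrix, lower_q: float = 0.05,
                   upper_q: float = 0.95) -> HealthyBounds:
    """Per-protein [lower_q, upper_q] percentile band of healthy expression.

    Percentiles use linear interpolation between order statistics.  A
    protein constant across healthy samples yields lower == upper, which
    flags every off-value disease measurement.
    """
    if healthy.n_samples < 2:
        raise ParameterError("need >= 2 healthy samples for percentile bounds")
    if not 0.0 <= lower_q <= upper_q <= 1.0:
        raise ParameterError(f"invalid quantile pair ({lower_q}, {upper_q})")
    arr = healthy.values.to_numpy(dtype=float)
    lo, hi = np.quantile(arr, [lower_q, upper_q], axis=1, method=QUANTILE_METHOD)
    return HealthyBounds(lower=pd.Series(lo, index=healthy.proteins),
                         upper=pd.Series(hi, index=healthy.proteins))


def call_ide(sample_column: pd.Series, bounds: HealthyBounds,
             patient: str | None = None) -> IDESignature:
    """Call one patient's IDE signature against the healthy band.

    Strict inequalities: a value exactly on a bound is normal.
    """
    missing = sample_column.index.difference(bounds.proteins)
    if len(missing):
        raise ParameterError(f"sample proteins without bounds: {list(missing[:5])}...")
    values = sample_column
    lower = bounds.lower.reindex(values.index)
    upper = bounds.upper.reindex(values.index)
    up = values > upper
    down = values < lower
    entries = {p: +1 for p in values.index[up]}
    entries.update({p: -1 for p in values.index[down]})
    return IDESignature(patient=patient or str(sample_column.name), entries=entries)


def call_ides(disease: ExpressionMatrix, bounds: HealthyBounds) -> list[IDESignature]:
    """Vectorized :func:`call_ide` over every disease sample."""
    return [call_ide(disease.sample(s), bounds, patient=str(s))
            for s in disease.samples]


def population_degs(disease: ExpressionMatrix, healthy: ExpressionMatrix,
                    alpha: float = 0.05) -> set[str]:
    """Cohort-level differentially expressed proteins.

    Two-sided Welch's t-test per protein (unequal variances), adjusted by
    Benjamini-Hochberg across all tested proteins; keep FDR < ``alpha``.
    Proteins with zero variance in both groups cannot be tested and are
    skipped with a logged count.
    """
    if disease.n_samples < 2 or healthy.n_samples < 2:
        raise ParameterError("each group needs >= 2 samples for Welch's t-test")
    common = disease.proteins.intersection(healthy.proteins)
    d = disease.values.loc[common].to_numpy(dtype=float)
    h = healthy.values.loc[common].to_numpy(dtype=float)
    var_d = d.var(axis=1, ddof=1)
    var_h = h.var(axis=1, ddof=1)
    testable = (var_d > 0) | (var_h > 0)
    n_skipped = int((~testable).sum())
    if n_skipped:
        logger.info("skipping %d zero-variance protein(s)", n_skipped)
    if not testable.any():
        return set()
    _, pvals = stats.ttest_ind(d[testable], h[testable], axis=1, equal_var=False)
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    tested_proteins = common[testable]
    return set(tested_proteins[reject])


def refine_ides(ides: Iterable[IDESignature], degs: set[str], proximal: set[str],
                min_ide: int = 10) -> tuple[list[IDESignature], list[str]]:
    """Intersect each signature with (DEGs ∩ network-proximal proteins).

    Patients whose refined signature has fewer than ``min_ide`` entries are
    excluded and reported.  Refinement only removes entries; it never adds
    proteins or changes signs.
    """
    keep_set = degs & proximal
    kept: list[IDESignature] = []
    excluded: list[str] = []
    for sig in ides:
        refined = {p: s for p, s in sig.entries.items() if p in keep_set}
        if len(refined) < min_ide:
            excluded.append(sig.patient)
        else:
            kept.append(IDESignature(patient=sig.patient, entries=refined))
    if excluded:
        logger.info("excluded %d patient(s) with < %d refined IDE proteins",
                    len(excluded), min_ide)
    return kept, excluded


def write_ides(ides: Iterable[IDESignature], path: str | Path) -> None:
    """Write signatures as ``patient  protein  sign`` TSV."""
    with Path(path).open("w") as fh:
        fh.write("patient\tprotein\tsign\n")
        for sig in ides:
            for protein in sorted(sig.entries):
                fh.write(f"{sig.patient}\t{protein}\t{sig.entries[protein]:+d}\n")


def load_ides(path: str | Path) -> list[IDESignature]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for patient, grp in df.groupby("patient", sort=True):
        out.append(IDESignature(patient=str(patient),
                                entries=dict(zip(grp["protein"], grp["sign"]))))
    return out
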