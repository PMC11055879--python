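"""Genetic-interaction scoring for paralog pairs.

Single mutant fitness (SMF) of a gene is the mean log fold change of
constructs that pair the gene with a control guide.  Under the
multiplicative (log-additive) null, the expected double mutant fitness of a
pair is the sum of the two SMFs, with standard deviation
``sqrt(std1**2 + std2**2)``.  The interaction magnitude is

    dLFC = observed_mean - expected_mean

and the standardized separation between the expected and observed construct
LFC distributions is a modified Cohen's D,

    D = (expected_mean - observed_mean) / S_pooled.

Two pooled-SD conventions are provided.  ``as_printed`` uses
``S_pooled = sqrt(e_std**2 + o_std**2) / 2`` (divisor outside the radical);
``classical`` uses ``sqrt((e_std**2 + o_std**2) / 2)``, the textbook pooled
form.  The two differ by exactly sqrt(2); ``as_printed`` is the default.

A pair is a synthetic-lethal hit when dLFC < -1 and D > 0.8 (both strict).
The positive-D direction is "observed more lethal than expected".
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

POOLED_SD_CONVENTIONS = ("as_printed", "classical")


class ScoringError(ValueError):
    pass


class MissingSingletonError(ScoringError):
    """No gene-control construct: the gene's SMF, and its pairs, are unassayable."""


class NoPairConstructError(ScoringError):
    """No construct targets both genes together."""


@dataclass(frozen=True)
class GeneFitness:
    gene: str
    smf_mean: float
    smf_std: float  # sample (n-1) std; nan when n_constructs == 1
    n_constructs: int


@dataclass(frozen=True)
class GIThresholds:
    dlfc_threshold: float = -1.0
    d_threshold: float = 0.8
    pooled_sd_convention: str = "as_printed"

    def __post_init__(self) -> None:
        if self.pooled_sd_convention not in POOLED_SD_CONVENTIONS:
            raise ValueError(f"unknown convention {self.pooled_sd_convention!r}")


@dataclass(frozen=True)
class PairGIRecord:
    gene1: str
    gene2: str
    smf1: float
    smf2: float
    observed_mean: float
    observed_std: float
    expected_mean: float
    expected_std: float
    s_pooled: float
    cohens_d: float
    dlfc: float
    n_pair_constructs: int
    is_hit: bool
    cell_line: str = ""
    study_id: str = ""


def _is_control(label: str, control_labels: frozenset[str] | set[str]) -> bool:
    return label in control_labels


def compute_smf(
    fc: pd.DataFrame, gene: str, control_labels: set[str]
) -> GeneFitness:
    """SMF over gene-control constructs, pooling both orientations.

    ``fc`` is a fold-change table with ``targets`` (semicolon-joined) and
    ``mean_lfc`` columns.  A qualifying construct targets exactly ``gene``
    plus control labels (either slot order; a bare single-target construct
    also qualifies for single-orientation layouts).
    """
    values = []
    for targets, lfc in zip(fc["targets"], fc["mean_lfc"]):
        labels = targets.split(";")
        non_control = [t for t in labels if not _is_control(t, control_labels)]
        if non_control == [gene] and not math.isnan(lfc):
            values.append(lfc)
    if not values:
        raise MissingSingletonError(f"no gene-control construct for {gene!r}")
    arr = np.asarray(values, dtype=float)
    std = float(arr.std(ddof=1)) if arr.size >= 2 else float("nan")
    return GeneFitness(gene=gene, smf_mean=float(arr.mean()), smf_std=std, n_constructs=arr.size)


def expected_dmf(g1: GeneFitness, g2: GeneFitness) -> tuple[float, float]:
    """Null expectation for the double knockout: means add, variances add."""
    mean = g1.smf_mean + g2.smf_mean
    std = math.hypot(g1.smf_std, g2.smf_std)
    return mean, std


def pooled_sd(expected_std: float, observed_std: float, convention: str = "as_printed") -> float:
    ss = expected_std**2 + observed_std**2
    if convention == "as_printed":
        return math.sqrt(ss) / 2.0
    if convention == "classical":
        return math.sqrt(ss / 2.0)
    raise ValueError(f"unknown convention {convention!r}")


def cohens_d(
    expected: tuple[float, float],
    observed: tuple[float, float],
    convention: str = "as_printed",
) -> float:
    """Standardized expected-vs-observed separation; D > 0 means the observed
    knockout is more lethal than the additive expectation."""
    e_mean, e_std = expected
    o_mean, o_std = observed
    s = pooled_sd(e_std, o_std, convention)
    if s == 0 or math.isnan(s):
        raise ScoringError("pooled SD is zero or undefined; effect size undefined")
    return (e_mean - o_mean) / s


def _pair_constructs(fc: pd.DataFrame, gene1: str, gene2: str) -> np.ndarray:
    wanted = {gene1, gene2}
    values = []
    for targets, lfc in zip(fc["targets"], fc["mean_lfc"]):
        labels = set(targets.split(";"))
        if labels == wanted and not math.isnan(lfc):
            values.append(lfc)
    return np.asarray(values, dtype=float)


def score_pair(
    fc: pd.DataFrame,
    gene1: str,
    gene2: str,
    thresholds: GIThresholds | None = None,
    control_labels: set[str] | None = None,
    cell_line: str = "",
    study_id: str = "",
) -> PairGIRecord:
    """Full GI record for one pair from a fold-change table.

    Raises :class:`MissingSingletonError` / :class:`NoPairConstructError`
    when the pair cannot be assayed in this screen; callers treat those as
    "unassayed", never as a miss.  Gene labels are sorted so the record is
    orientation-independent.
    """
    thresholds = thresholds or GIThresholds()
    control_labels = control_labels or set()
    gene1, gene2 = sorted((gene1, gene2))
    g1 = compute_smf(fc, gene1, control_labels)
    g2 = compute_smf(fc, gene2, control_labels)
    obs = _pair_constructs(fc, gene1, gene2)
    if obs.size == 0:
        raise NoPairConstructError(f"no construct targets {gene1}+{gene2}")
    observed_mean = float(obs.mean())
    observed_std = float(obs.std(ddof=1)) if obs.size >= 2 else float("nan")
    expected_mean, expected_std = expected_dmf(g1, g2)
    s = pooled_sd(expected_std, observed_std, thresholds.pooled_sd_convention)
    d = (expected_mean - observed_mean) / s if s > 0 else float("nan")
    dlfc = observed_mean - expected_mean
    is_hit = bool(dlfc < thresholds.dlfc_threshold and d > thresholds.d_threshold)
    return PairGIRecord(
        gene1=gene1,
        gene2=gene2,
        smf1=g1.smf_mean,
        smf2=g2.smf_mean,
        observed_mean=observed_mean,
        observed_std=observed_std,
        expected_mean=expected_mean,
        expected_std=expected_std,
        s_pooled=s,
        cohens_d=d,
        dlfc=dlfc,
        n_pair_constructs=obs.size,
        is_hit=is_hit,
        cell_line=cell_line,
        study_id=study_id,
    )


def score_screen(
    fc: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    thresholds: GIThresholds | None = None,
    control_labels: set[str] | None = None,
    cell_line: str = "",
    study_id: str = "",
) -> tuple[list[PairGIRecord], list[tuple[str, str, str]]]:
    """Score every assayable pair in a screen.

    When ``pairs`` is omitted, all pairs with at least one two-gene
    construct are scored.  Returns (records, unassayed) where each
    unassayed entry is ``(gene1, gene2, reason)``.
    """
    control_labels = control_labels or set()
    if pairs is None:
        seen = set()
        for targets in fc["targets"]:
            labels = [t for t in targets.split(";") if not _is_control(t, control_labels)]
            if len(set(labels)) == 2:
                seen.add(tuple(sorted(set(labels))))
        pairs = sorted(seen)
    records, unassayed = [], []
    for gene1, gene2 in pairs:
        try:
            records.append(
                score_pair(
                    fc, gene1, gene2, thresholds, control_labels,
                    cell_line=cell_line, study_id=study_id,
                )
            )
        except ScoringError as exc:
            unassayed.append((*sorted((gene1, gene2)), str(exc)))
    return records, unassayed


GI_COLUMNS = [
    "gene1", "gene2", "smf1", "smf2", "observed_lfc", "expected_lfc",
    "dlfc", "cohens_d", "n_constructs", "hit",
]


def records_to_frame(records: list[PairGIRecord]) -> pd.DataFrame:
    rows = [
        {
            "gene1": r.gene1,
            "gene2": r.gene2,
            "smf1": r.smf1,
            "smf2": r.smf2,
            "observed_lfc": r.observed_mean,
            "expected_lfc": r.expected_mean,
            "dlfc": r.dlfc,
            "cohens_d": r.cohens_d,
            "n_constructs": r.n_pair_constructs,
            "hit": r.is_hit,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=GI_COLUMNS)
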