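"""Gene-level analysis of four-guide array screens.

Each gene or paralog family is targeted by two sibling arrays ("clones");
the gene-level fold change is the mean of clone-level log2 fold changes
across replicates.  Essentials are called by a fixed fold-change threshold
and screen quality is summarized by a precision-recall walk against
reference essential and non-essential gene sets.  Family knockouts are
classified against the additive null: dLFC below -1 is synthetic lethal,
above +1 is masking/buffering -- unless the additive expectation falls
below the screen's observed dynamic range, in which case the family is
untestable (saturation cannot be distinguished from buffering).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LABELS = ("synthetic_lethal", "masking", "none", "untestable")


class AnalysisError(ValueError):
    pass


@dataclass(frozen=True)
class GeneLevelFC:
    target: tuple[str, ...]  # gene or family members, sorted
    mean_fc: float
    n_clones: int  # clone x replicate values averaged
    clone_values: tuple[float, ...] = ()


@dataclass(frozen=True)
class GIClassification:
    family: tuple[str, ...]
    observed_fc: float
    expected_fc: float
    dlfc: float
    label: str
    pair_context: tuple[tuple[tuple[str, str], float], ...] = ()
    explainable_by_pair: bool | None = None


@dataclass
class PRCurve:
    """Precision/recall along the fold-change-ascending ranking."""

    frame: pd.DataFrame  # columns: target, mean_fc, is_essential, recall, precision

    @property
    def recall(self) -> np.ndarray:
        return self.frame["recall"].to_numpy()

    @property
    def precision(self) -> np.ndarray:
        return self.frame["precision"].to_numpy()


def combined_knockout_efficiency(per_gene_efficiency: float, n_targets: int) -> float:
    """Probability that all targets in a cell are edited.

    Editing events are independent per target, so even a strong 0.8
    per-gene efficiency leaves roughly half of cells with an intact allele
    somewhere in a triple knockout -- incomplete editing can mask severe
    higher-order phenotypes.
    """
    if not 0 <= per_gene_efficiency <= 1:
        raise ValueError("efficiency outside [0,1]")
    return per_gene_efficiency**n_targets


def aggregate_gene_fc(fc: pd.DataFrame) -> list[GeneLevelFC]:
    """Mean clone-level fold change per target.

    ``fc`` is a fold-change table with ``targets`` (semicolon-joined) and
    per-replicate ``lfc_*`` columns; every clone x replicate value of a
    target is pooled into one mean.  Missing values are skipped with the
    retained count recorded.
    """
    lfc_cols = [c for c in fc.columns if c.startswith("lfc_")]
    if not lfc_cols:
        raise AnalysisError("fold-change table has no lfc_* columns")
    grouped: dict[tuple[str, ...], list[float]] = {}
    for targets, row in zip(fc["targets"], fc[lfc_cols].itertuples(index=False)):
        key = tuple(sorted(set(targets.split(";"))))
        values = [v for v in row if not (isinstance(v, float) and math.isnan(v))]
        grouped.setdefault(key, []).extend(values)
    out = []
    for key in sorted(grouped):
        values = grouped[key]
        if not values:
            continue
        out.append(
            GeneLevelFC(
                target=key,
                mean_fc=float(np.mean(values)),
                n_clones=len(values),
                clone_values=tuple(values),
            )
        )
    return out


def call_essential(genes: Sequence[GeneLevelFC], threshold: float = -1.0) -> set[tuple[str, ...]]:
    """Targets with mean fold change strictly below the threshold."""
    return {g.target for g in genes if g.mean_fc < threshold}


def precision_recall(
    genes: Sequence[GeneLevelFC],
    essentials: set[str],
    nonessentials: set[str],
) -> PRCurve:
    """PR walk down the fold-change ranking, restricted to reference genes.

    Single-gene targets in the essential reference set are positives, those
    in the non-essential set negatives; everything else is ignored.
    """
    rows = []
    for g in genes:
        if len(g.target) != 1:
            continue
        gene = g.target[0]
        if gene in essentials:
            rows.append((gene, g.mean_fc, True))
        elif gene in nonessentials:
            rows.append((gene, g.mean_fc, False))
    if not any(r[2] for r in rows) or not any(not r[2] for r in rows):
        raise AnalysisError("reference sets do not intersect screened targets")
    rows.sort(key=lambda r: r[1])
    n_pos = sum(1 for r in rows if r[2])
    tp = 0
    table = []
    for rank, (gene, fc_val, is_ess) in enumerate(rows, start=1):
        tp += is_ess
        table.append(
            {
                "target": gene,
                "mean_fc": fc_val,
                "is_essential": is_ess,
                "recall": tp / n_pos,
                "precision": tp / rank,
            }
        )
    return PRCurve(frame=pd.DataFrame(table))


def screen_min_fc(genes: Sequence[GeneLevelFC]) -> float:
    """The screen's dynamic-range floor: the most severe clone-level mean."""
    return min(g.mean_fc for g in genes)


def classify_gi(
    families: Sequence[GeneLevelFC],
    singles: Mapping[str, GeneLevelFC],
    screen_floor: float,
    sl_threshold: float = -1.0,
    masking_threshold: float = 1.0,
) -> tuple[list[GIClassification], list[tuple[tuple[str, ...], str]]]:
    """Classify family knockouts against the additive null.

    expected = sum of member single-knockout means; dlfc = observed -
    expected.  ``untestable`` (expected below the screen floor) takes
    precedence over ``masking``.  Families with a member lacking a single
    measurement are skipped with a reason, never imputed.
    """
    records, skipped = [], []
    for fam in families:
        missing = [g for g in fam.target if g not in singles]
        if missing:
            skipped.append((fam.target, f"no single-knockout measurement for {missing}"))
            continue
        expected = sum(singles[g].mean_fc for g in fam.target)
        dlfc = fam.mean_fc - expected
        if dlfc < sl_threshold:
            label = "synthetic_lethal"
        elif expected < screen_floor:
            label = "untestable"
        elif dlfc > masking_threshold:
            label = "masking"
        else:
            label = "none"
        records.append(
            GIClassification(
                family=fam.target,
                observed_fc=fam.mean_fc,
                expected_fc=expected,
                dlfc=dlfc,
                label=label,
            )
        )
    return records, skipped


def higher_order_gi(
    families: Sequence[GeneLevelFC],
    singles: Mapping[str, GeneLevelFC],
    pairs: Mapping[tuple[str, str], GeneLevelFC],
    screen_floor: float,
    sl_threshold: float = -1.0,
    masking_threshold: float = 1.0,
    pair_margin: float = 0.5,
) -> tuple[list[GIClassification], list[tuple[tuple[str, ...], str]]]:
    """Classify triples/quads with constituent-pair context.

    The null is the same sum-of-singles expectation.  Each constituent
    pair's own dLFC (when the pair is in the library) is attached, and a
    trigenic call is flagged ``explainable_by_pair`` when some constituent
    pair shows an interaction within ``pair_margin`` of the family's dLFC.
    """
    base, skipped = classify_gi(
        families, singles, screen_floor, sl_threshold, masking_threshold
    )
    out = []
    for rec in base:
        context = []
        for i, a in enumerate(rec.family):
            for b in rec.family[i + 1 :]:
                key = tuple(sorted((a, b)))
                if key not in pairs:
                    continue
                pair_expected = singles[a].mean_fc + singles[b].mean_fc
                context.append((key, pairs[key].mean_fc - pair_expected))
        explainable = None
        if context:
            explainable = bool(min(d for _, d in context) <= rec.dlfc + pair_margin)
        out.append(
            GIClassification(
                family=rec.family,
                observed_fc=rec.observed_fc,
                expected_fc=rec.expected_fc,
                dlfc=rec.dlfc,
                label=rec.label,
                pair_context=tuple(context),
                explainable_by_pair=explainable,
            )
        )
    return out, skipped
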