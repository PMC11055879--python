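"""Raw counts to construct-level log2 fold changes.

The pipeline is: add a pseudocount to every construct, scale each sample to
a fixed mean read depth per construct, take log2 fold change of each
endpoint replicate against the (averaged) reference, shift each construct
group so its modal LFC is zero, then average replicates.  Mode-centering
absorbs the bulk fitness shift of each construct class -- single-gene
constructs in either orientation and two-gene constructs drift differently
because they carry different numbers of cutting guides -- so that a
fold change of zero means "no fitness effect" within every class.

The mode is estimated by a Gaussian kernel density (Silverman bandwidth)
evaluated on a 512-point grid over the group's range; the argmax is the
mode, with ties broken toward the value closest to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .counts_io import CountMatrix

GROUPING_SCHEMES = ("three_group", "control_mode_only", "single_orientation")

#: construct classes making up the three independently-centered groups
_THREE_GROUPS = {
    "single_with_control_second": "gene_N",
    "single_with_control_first": "N_gene",
    "pair": "A_B",
}


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizationConfig:
    """Knobs of the counts-to-LFC pipeline.

    pseudocount
        Reads added to every construct before depth scaling (default 5).
    target_mean_reads
        Post-scaling mean reads per construct (default 500).
    grouping_scheme
        ``three_group``: center gene_N, N_gene and A_B classes separately.
        ``control_mode_only`` / ``single_orientation``: subtract the mode of
        designated control constructs from every LFC (the two names record
        which study layout the convention came from; the arithmetic is the
        same).
    control_labels
        Construct ids or target labels identifying the control constructs
        for the control-mode schemes.
    excluded_families
        Gene families dropped from the table before any computation (used
        where a family's homology causes cross-reactive guides).
    """

    pseudocount: int = 5
    target_mean_reads: float = 500.0
    grouping_scheme: str = "three_group"
    control_labels: frozenset[str] = frozenset()
    excluded_families: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.target_mean_reads <= 0:
            raise ValueError("target_mean_reads must be > 0")
        if self.grouping_scheme not in GROUPING_SCHEMES:
            raise ValueError(f"unknown grouping_scheme {self.grouping_scheme!r}")
        self.control_labels = frozenset(self.control_labels)
        self.excluded_families = frozenset(self.excluded_families)


def estimate_mode(values: np.ndarray) -> float:
    """KDE argmax mode of a 1-D sample; ties go to the value nearest zero."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise NormalizationError("cannot estimate mode of empty group")
    if values.size == 1 or np.ptp(values) == 0:
        return float(values[0])
    kde = gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(values.min(), values.max(), 512)
    density = kde(grid)
    peak = density.max()
    candidates = grid[np.isclose(density, peak)]
    return float(candidates[np.argmin(np.abs(candidates))])


def normalize_depth(counts: CountMatrix, cfg: NormalizationConfig) -> pd.DataFrame:
    """Pseudocount then per-sample depth scaling to the target mean.

    Each sample's counts become ``(c + pseudocount) * target * K / total``
    where K is the number of constructs, so the mean normalized reads per
    construct equals ``target_mean_reads`` exactly.
    """
    raw = counts.counts.astype(float) + cfg.pseudocount
    totals = raw.sum(axis=0)
    dead = totals[totals == 0]
    if len(dead):
        raise NormalizationError(
            f"samples with zero total reads after pseudocount: {list(dead.index)}"
        )
    k = raw.shape[0]
    return raw * (cfg.target_mean_reads * k) / totals


def compute_lfc(
    norm: pd.DataFrame,
    counts: CountMatrix,
    cfg: NormalizationConfig | None = None,
) -> pd.DataFrame:
    """Per-replicate log2 fold change of endpoints against the reference.

    Multiple reference samples are averaged (in normalized read space)
    before the ratio.  Returns a table with ``targets``/``class`` annotation
    columns and one ``lfc_<sample>`` column per endpoint.
    """
    refs = counts.reference_samples
    if not refs:
        raise NormalizationError("no reference sample designated")
    endpoints = counts.endpoint_samples
    if not endpoints:
        raise NormalizationError("no endpoint samples")
    reference = norm[refs].mean(axis=1)
    out = pd.DataFrame(index=norm.index)
    out["targets"] = [";".join(c.targets) for c in counts.constructs]
    out["class"] = [c.construct_class for c in counts.constructs]
    for s in endpoints:
        out[f"lfc_{s}"] = np.log2(norm[s] / reference)
    return out


def _lfc_columns(fc: pd.DataFrame) -> list[str]:
    return [c for c in fc.columns if c.startswith("lfc_")]


def _group_of(construct_class: str) -> str | None:
    return _THREE_GROUPS.get(construct_class)


def center_groups(
    fc: pd.DataFrame, cfg: NormalizationConfig
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Shift each group's LFCs so its estimated mode is zero.

    Returns the centered table and the per-group offsets that were
    subtracted (``{group: offset}``; for control-mode schemes the single key
    is ``"control"``).  Constructs targeting ``cfg.excluded_families`` are
    dropped before anything else is computed.
    """
    fc = fc.copy()
    if cfg.excluded_families:
        drop = fc["targets"].map(
            lambda t: any(g in cfg.excluded_families for g in t.split(";"))
        )
        fc = fc.loc[~drop]
    cols = _lfc_columns(fc)
    offsets: dict[str, float] = {}
    if cfg.grouping_scheme == "three_group":
        groups = fc["class"].map(_group_of)
        for group in ("gene_N", "N_gene", "A_B"):
            mask = (groups == group).to_numpy()
            if not mask.any():
                raise NormalizationError(f"empty group {group!r} under three_group scheme")
            pooled = fc.loc[mask, cols].to_numpy().ravel()
            offset = estimate_mode(pooled)
            fc.loc[mask, cols] = fc.loc[mask, cols] - offset
            offsets[group] = offset
    else:  # control_mode_only / single_orientation: one offset from controls
        is_control = fc.index.isin(cfg.control_labels) | fc["targets"].map(
            lambda t: all(g in cfg.control_labels for g in t.split(";"))
        )
        if not is_control.any():
            raise NormalizationError("no control constructs found for mode centering")
        pooled = fc.loc[is_control, cols].to_numpy().ravel()
        offset = estimate_mode(pooled)
        fc[cols] = fc[cols] - offset
        offsets["control"] = offset
    return fc, offsets


def mean_over_replicates(fc: pd.DataFrame) -> pd.DataFrame:
    """Add ``mean_lfc`` (mean over present replicate values) and ``n_reps``."""
    fc = fc.copy()
    cols = _lfc_columns(fc)
    fc["mean_lfc"] = fc[cols].mean(axis=1, skipna=True)
    fc["n_reps"] = fc[cols].notna().sum(axis=1)
    return fc


def counts_to_fold_changes(
    counts: CountMatrix, cfg: NormalizationConfig | None = None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Full pipeline: depth-normalize, LFC, mode-center, average replicates."""
    cfg = cfg or NormalizationConfig()
    norm = normalize_depth(counts, cfg)
    fc = compute_lfc(norm, counts, cfg)
    fc, offsets = center_groups(fc, cfg)
    return mean_over_replicates(fc), offsets
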