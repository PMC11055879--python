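"""Synthetic screen generators with the statistical structure of real data.

These generators produce inputs for every other module without any
download: pooled paralog screens (single- and two-gene constructs with
replicate count noise, planted single-mutant fitness and planted
interactions, and per-study fidelity differences), seven-guide array pools
with per-position efficacy attenuation, and paralog identity/expression
tables with families planted on each side of the design filters.

Counts are sampled negative-binomially around the expected depth
(variance = m + dispersion * m**2; dispersion 0 falls back to Poisson),
with reference/plasmid counts lognormal around the configured depth to
mimic library-representation spread.  All randomness flows from a single
seed; per-step substreams are derived deterministically so outputs are
byte-identical for a given configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .array_model import ArrayDesign, enumerate_design
from .counts_io import ConstructRecord, CountMatrix, SampleInfo

CONTROL_LABEL = "CTRL"


@dataclass(frozen=True)
class ScreenSimConfig:
    """One simulated pooled paralog screen.

    Single-mutant fitness is drawn per gene: essentials from
    ``smf_essential`` (mean, sd) in log2 units, the rest from
    ``smf_neutral``.  Every gene gets ``constructs_per_target`` constructs
    in each single orientation (gene_CTRL and CTRL_gene) and every assayed
    pair the same number of A_B constructs.  A construct's true LFC is the
    sum of its targets' SMFs plus any planted interaction plus
    N(0, noise_sd * platform_fidelity) construct noise; the noise is
    guide-intrinsic, so it is shared across replicates and replicate
    spread comes from count sampling alone.
    """

    n_genes: int = 150
    fraction_essential: float = 0.1
    smf_essential: tuple[float, float] = (-2.0, 0.5)
    smf_neutral: tuple[float, float] = (0.0, 0.1)
    n_pairs: int = 150
    sl_pairs: tuple[tuple[tuple[str, str], float], ...] = ()
    trigenic_effects: tuple[tuple[tuple[str, str, str], float], ...] = ()
    constructs_per_target: int = 12
    replicates: int = 2
    reference_depth: float = 500.0
    noise_sd: float = 0.3
    dispersion: float = 0.01
    platform_fidelity: float = 1.0
    seed: int = 0
    study_id: str = "sim_study"
    cell_line: str = "sim_line"

    def __post_init__(self) -> None:
        if not 0 <= self.fraction_essential <= 1:
            raise ValueError("fraction_essential outside [0,1]")
        if self.noise_sd < 0 or self.dispersion < 0:
            raise ValueError("noise_sd and dispersion must be >= 0")


@dataclass(frozen=True)
class SevenMerSimConfig:
    """Seven-guide array pools with per-position efficacy attenuation.

    ``beta_true`` is each position's essential-knockout phenotype (log2);
    ``position_attenuation`` multiplies the realized effect at each array
    position, defaulting to full efficacy at positions 1-5 and strong loss
    at 6-7, the structure seen in long-array screens.
    """

    beta_true: tuple[float, ...] = (-1.0,) * 7
    position_attenuation: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 0.3, 0.2)
    pools: int = 3
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.beta_true) != len(self.position_attenuation):
            raise ValueError("beta_true and position_attenuation lengths differ")
        if any(not 0 <= a <= 1 for a in self.position_attenuation):
            raise ValueError("attenuation outside [0,1]")


def _sample_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with variance m + dispersion * m**2.

    dispersion 0 disables count sampling entirely and returns the expected
    (real-valued) depths, so a noiseless configuration round-trips exactly.
    """
    mean = np.clip(mean, 1e-9, None)
    if dispersion == 0:
        return mean
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_screen(cfg: ScreenSimConfig) -> tuple[CountMatrix, dict]:
    """Generate one screen's count matrix plus its ground truth.

    Returns ``(counts, truth)`` where truth records the per-gene SMF, the
    assayed pairs with planted dLFC (0 for non-interacting pairs), and the
    per-construct true LFC.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i:03d}" for i in range(cfg.n_genes)]
    n_ess = round(cfg.n_genes * cfg.fraction_essential)
    smf = {}
    for i, g in enumerate(genes):
        mean, sd = cfg.smf_essential if i < n_ess else cfg.smf_neutral
        smf[g] = float(rng.normal(mean, sd))

    planted = {tuple(sorted(p)): eff for p, eff in cfg.sl_pairs}
    for p in planted:
        for g in p:
            if g not in smf:
                raise ValueError(f"planted pair references unknown gene {g!r}")
    # assayed pairs: all planted pairs plus random non-interacting fill
    pairs = list(planted)
    fill_rng = np.random.default_rng(cfg.seed + 1)
    while len(pairs) < cfg.n_pairs:
        a, b = fill_rng.choice(cfg.n_genes, size=2, replace=False)
        key = tuple(sorted((genes[a], genes[b])))
        if key not in pairs:
            pairs.append(key)

    constructs: list[ConstructRecord] = []
    true_lfc: list[float] = []
    noise_scale = cfg.noise_sd * cfg.platform_fidelity

    def add_constructs(targets: tuple[str, ...], cclass: str, base_lfc: float, stem: str) -> None:
        for j in range(cfg.constructs_per_target):
            constructs.append(
                ConstructRecord(
                    construct_id=f"{stem}_{j}",
                    targets=targets,
                    construct_class=cclass,
                    study_id=cfg.study_id,
                    cell_line=cfg.cell_line,
                )
            )
            true_lfc.append(base_lfc + float(rng.normal(0.0, noise_scale)))

    for g in genes:
        add_constructs((g, CONTROL_LABEL), "single_with_control_second", smf[g], f"{g}_{CONTROL_LABEL}")
        add_constructs((CONTROL_LABEL, g), "single_with_control_first", smf[g], f"{CONTROL_LABEL}_{g}")
    for a, b in pairs:
        gi = planted.get((a, b), 0.0)
        add_constructs((a, b), "pair", smf[a] + smf[b] + gi, f"{a}_{b}")
    # control-control constructs anchor the fold-change scale
    add_constructs((CONTROL_LABEL,), "control", 0.0, f"{CONTROL_LABEL}_{CONTROL_LABEL}")

    k = len(constructs)
    reference = rng.lognormal(mean=np.log(cfg.reference_depth), sigma=0.25, size=k)
    samples = [SampleInfo("T0_1", "reference", 1, "T0")]
    columns = {"T0_1": _sample_counts(rng, reference, cfg.dispersion)}
    base = np.asarray(true_lfc)
    for rep in range(1, cfg.replicates + 1):
        # construct noise is guide-intrinsic and shared across replicates;
        # replicate-to-replicate spread comes from count sampling alone
        expected = reference * np.power(2.0, base)
        sid = f"T18_{rep}"
        samples.append(SampleInfo(sid, "endpoint", rep, "T18"))
        columns[sid] = _sample_counts(rng, expected, cfg.dispersion)

    counts = pd.DataFrame(columns, index=[c.construct_id for c in constructs])
    cm = CountMatrix(constructs=constructs, samples=samples, counts=counts)
    truth = {
        "smf": smf,
        "pairs": {p: planted.get(p, 0.0) for p in pairs},
        "construct_lfc": dict(zip(counts.index, true_lfc)),
        "control_label": CONTROL_LABEL,
    }
    return cm, truth


def simulate_multi_study(
    base: ScreenSimConfig,
    studies: Mapping[str, tuple[float, Sequence[str]]],
    universal_pairs: Sequence[tuple[tuple[str, str], float]],
    background_pairs: Mapping[str, Sequence[tuple[tuple[str, str], float]]] | None = None,
) -> dict[tuple[str, str], tuple[CountMatrix, dict]]:
    """Simulate several studies sharing gene truth but differing in fidelity.

    ``studies`` maps study_id -> (platform_fidelity, cell lines).
    ``universal_pairs`` are planted in every screen; ``background_pairs``
    (per cell line) only in that cell line's screens.  Returns
    ``{(study_id, cell_line): (counts, truth)}``.
    """
    background_pairs = background_pairs or {}
    out = {}
    offset = 0
    for study_id, (fidelity, cell_lines) in studies.items():
        for cell_line in cell_lines:
            offset += 1
            planted = tuple(universal_pairs) + tuple(background_pairs.get(cell_line, ()))
            cfg = replace(
                base,
                sl_pairs=planted,
                platform_fidelity=fidelity,
                seed=base.seed + 104729 * offset,
                study_id=study_id,
                cell_line=cell_line,
            )
            out[(study_id, cell_line)] = simulate_screen(cfg)
    return out


def simulate_sevenmer(cfg: SevenMerSimConfig, orientation: str = "forward") -> ArrayDesign:
    """Seven-guide pools under the attenuated additive model.

    Masks index physical array slots.  Forward arrays realize
    ``sum_j mask_j * attenuation_j * beta_j``.  In the reverse orientation
    the guide sitting at slot j is the one whose forward home is n+1-j, so
    slot j contributes ``attenuation_j * beta_{n+1-j}``.  Noise is i.i.d.
    Gaussian per array.
    """
    n = len(cfg.beta_true)
    rng = np.random.default_rng(cfg.seed if orientation == "forward" else cfg.seed + 1)
    design = enumerate_design(n_positions=n, n_pools=cfg.pools)
    beta = np.asarray(cfg.beta_true)
    atten = np.asarray(cfg.position_attenuation)
    lfc = []
    for mask in design.frame["mask"]:
        bits = np.array([int(b) for b in mask])
        if orientation == "forward":
            signal = float(np.sum(bits * atten * beta))
        else:
            # slot j carries the guide whose forward home is n+1-j
            signal = float(np.sum(bits * atten * beta[::-1]))
        lfc.append(signal + float(rng.normal(0.0, cfg.noise_sd)))
    frame = design.frame.copy()
    frame["orientation"] = orientation
    frame["lfc"] = lfc
    return ArrayDesign(frame)


def simulate_design_inputs(
    n_background_pairs: int = 20,
    n_planted_pass: int = 10,
    n_planted_delta_fail: int = 5,
    n_families_drop12: int = 3,
    guides_per_gene: int = 8,
    seed: int = 0,
):
    """Identity/expression/guide tables with families planted around filters.

    Planted-pass pairs sit inside every prototype threshold; delta-fail
    pairs have delta identity 15 (rejected by the prototype profile,
    accepted once the delta filter is off); drop-12 families have a third
    member 12 identity points below the top paralog (outside a 10-point
    family threshold, inside a 20-point one).  Background pairs fall below
    the identity floor.  Returns (candidates, expression, guides, truth).
    """
    rng = np.random.default_rng(seed)
    candidates = []
    expression = {}
    guides: dict[str, list[str]] = {}
    truth = {"pass_pairs": [], "delta_fail_pairs": [], "drop12_families": []}

    def add_gene(name: str, mean: float = 4.0, std: float = 0.5) -> None:
        expression[name] = (mean, std)
        guides[name] = [
            "".join(rng.choice(list("ACGT"), size=20)) for _ in range(guides_per_gene)
        ]

    for i in range(n_planted_pass):
        a, b = f"PP{i}A", f"PP{i}B"
        add_gene(a), add_gene(b)
        ident = float(rng.uniform(40, 90))
        candidates.append((a, b, ident + 2.0, ident - 2.0))
        truth["pass_pairs"].append((a, b))
    for i in range(n_planted_delta_fail):
        a, b = f"DF{i}A", f"DF{i}B"
        add_gene(a), add_gene(b)
        ident = float(rng.uniform(40, 80))
        candidates.append((a, b, ident + 7.5, ident - 7.5))
        truth["delta_fail_pairs"].append((a, b))
    for i in range(n_families_drop12):
        a, b, c = f"FM{i}A", f"FM{i}B", f"FM{i}C"
        for g in (a, b, c):
            add_gene(g)
        top = float(rng.uniform(60, 85))
        candidates.append((a, b, top + 1.0, top - 1.0))
        candidates.append((a, c, top - 11.0, top - 13.0))
        truth["drop12_families"].append((a, b, c))
    for i in range(n_background_pairs):
        a, b = f"BG{i}A", f"BG{i}B"
        add_gene(a), add_gene(b)
        ident = float(rng.uniform(5, 25))
        candidates.append((a, b, ident + 1.0, ident - 1.0))

    cand_df = pd.DataFrame(
        candidates, columns=["gene_a", "gene_b", "identity_ab", "identity_ba"]
    )
    expr_df = pd.DataFrame(
        [(g, m, s) for g, (m, s) in expression.items()],
        columns=["gene", "expr_mean", "expr_std"],
    )
    guide_rows = [
        (g, rank + 1, spacer)
        for g, spacers in guides.items()
        for rank, spacer in enumerate(spacers)
    ]
    guides_df = pd.DataFrame(guide_rows, columns=["gene", "rank", "spacer"])
    return cand_df, expr_df, guides_df, truth
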