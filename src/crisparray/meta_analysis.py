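"""Cross-study meta-analysis of paralog synthetic-lethal screens.

Each screen (one cell line in one study) yields a set of hit pairs and a
set of assayed pairs.  Within a study, hit replicability between every
unordered pair of cell lines is measured by the Jaccard coefficient
``|A∩B| / |A∪B|``; the study's platform weight is the median of those
coefficients.  A pair's paralog score is then the weighted sum of hits
minus the weighted sum of misses across screens (unassayed screens
contribute nothing), and a pair is a gold-standard candidate when its
score exceeds 0.25 and it is a hit in more than one study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

Pair = tuple[str, str]

HIT, MISS, UNASSAYED = "hit", "miss", "unassayed"


def _norm_pair(pair: Pair) -> Pair:
    a, b = pair
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class ScreenKey:
    study_id: str
    cell_line: str


@dataclass
class HitMatrix:
    """Tri-state pair x screen table: hit / miss / unassayed."""

    pairs: list[Pair]
    screens: list[ScreenKey]
    state: pd.DataFrame  # index = pairs, columns = screen label, values in tri-state

    @classmethod
    def from_screens(
        cls,
        screen_results: dict[ScreenKey, tuple[set[Pair], set[Pair]]],
    ) -> "HitMatrix":
        """Build from ``{screen: (hits, assayed)}``; hits must be assayed."""
        screens = sorted(screen_results, key=lambda s: (s.study_id, s.cell_line))
        all_pairs = sorted(
            {_norm_pair(p) for _, (__, assayed) in screen_results.items() for p in assayed}
        )
        data = {}
        for key in screens:
            hits, assayed = screen_results[key]
            hits = {_norm_pair(p) for p in hits}
            assayed = {_norm_pair(p) for p in assayed}
            if not hits <= assayed:
                raise ValueError(f"screen {key}: hits not a subset of assayed pairs")
            col = [
                HIT if p in hits else (MISS if p in assayed else UNASSAYED)
                for p in all_pairs
            ]
            data[_label(key)] = col
        state = pd.DataFrame(data, index=pd.MultiIndex.from_tuples(all_pairs))
        return cls(pairs=all_pairs, screens=screens, state=state)

    def hits_of(self, key: ScreenKey) -> set[Pair]:
        col = self.state[_label(key)]
        return set(col.index[col == HIT])

    def assayed_of(self, key: ScreenKey) -> set[Pair]:
        col = self.state[_label(key)]
        return set(col.index[col != UNASSAYED])


def _label(key: ScreenKey) -> str:
    return f"{key.study_id}:{key.cell_line}"


@dataclass(frozen=True)
class PlatformWeight:
    study_id: str
    pairwise_jaccards: tuple[float, ...]
    weight: float


@dataclass(frozen=True)
class ParalogScoreRecord:
    pair: Pair
    score: float
    n_studies_hit: int
    n_screens_assayed: int
    gold_standard: bool


def jaccard(hits_a: set, hits_b: set) -> float:
    """|A∩B| / |A∪B|; two empty sets score 0 (no replicability evidence)."""
    union = hits_a | hits_b
    if not union:
        return 0.0
    return len(hits_a & hits_b) / len(union)


def platform_weights(hitmatrix: HitMatrix) -> list[PlatformWeight]:
    """Median pairwise hit-set Jaccard per study.

    Studies with a single screen carry no replicability evidence and are
    excluded with a warning.
    """
    by_study: dict[str, list[ScreenKey]] = {}
    for key in hitmatrix.screens:
        by_study.setdefault(key.study_id, []).append(key)
    out = []
    for study_id, keys in sorted(by_study.items()):
        if len(keys) < 2:
            warnings.warn(
                f"study {study_id!r} has a single screen; weight undefined, excluded",
                stacklevel=2,
            )
            continue
        jacs = tuple(
            jaccard(hitmatrix.hits_of(a), hitmatrix.hits_of(b))
            for a, b in combinations(keys, 2)
        )
        out.append(
            PlatformWeight(
                study_id=study_id,
                pairwise_jaccards=jacs,
                weight=float(np.median(jacs)),
            )
        )
    return out


def paralog_scores(
    hitmatrix: HitMatrix,
    weights: list[PlatformWeight],
    score_threshold: float = 0.25,
) -> list[ParalogScoreRecord]:
    """Weighted hits minus weighted misses per pair, plus the gold-standard call.

    ``gold_standard`` is strict: score > threshold AND hits in at least two
    distinct studies (studies, not screens).
    """
    weight_of = {w.study_id: w.weight for w in weights}
    missing = {k.study_id for k in hitmatrix.screens} - set(weight_of)
    if missing:
        raise ValueError(f"no platform weight for studies: {sorted(missing)}")
    records = []
    for pair in hitmatrix.pairs:
        row = hitmatrix.state.loc[[pair]].iloc[0]
        score = 0.0
        studies_hit: set[str] = set()
        n_assayed = 0
        for key in hitmatrix.screens:
            state = row[_label(key)]
            if state == UNASSAYED:
                continue
            n_assayed += 1
            w = weight_of[key.study_id]
            if state == HIT:
                score += w
                studies_hit.add(key.study_id)
            else:
                score -= w
        records.append(
            ParalogScoreRecord(
                pair=pair,
                score=score,
                n_studies_hit=len(studies_hit),
                n_screens_assayed=n_assayed,
                gold_standard=bool(score > score_threshold and len(studies_hit) >= 2),
            )
        )
    return records


def recall_vs_gold(
    screen_hits: set[Pair], screen_assayed: set[Pair], gold: set[Pair]
) -> float | None:
    """Fraction of assayed gold-standard pairs the screen calls hits.

    Returns None when the screen assays no gold pair (recall undefined).
    """
    if not gold:
        raise ValueError("gold-standard set is empty")
    gold = {_norm_pair(p) for p in gold}
    assayed_gold = {_norm_pair(p) for p in screen_assayed} & gold
    if not assayed_gold:
        return None
    hit_gold = {_norm_pair(p) for p in screen_hits} & gold
    return len(hit_gold & assayed_gold) / len(assayed_gold)


def weights_to_frame(weights: list[PlatformWeight]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "study_id": [w.study_id for w in weights],
            "weight": [w.weight for w in weights],
            "pairwise_jaccards": [
                ";".join(f"{j:.4f}" for j in w.pairwise_jaccards) for w in weights
            ],
        }
    )


def scores_to_frame(records: list[ParalogScoreRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene1": [r.pair[0] for r in records],
            "gene2": [r.pair[1] for r in records],
            "score": [r.score for r in records],
            "n_studies_hit": [r.n_studies_hit for r in records],
            "n_screens_assayed": [r.n_screens_assayed for r in records],
            "gold_standard": [r.gold_standard for r in records],
        }
    )
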