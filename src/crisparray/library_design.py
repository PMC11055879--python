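"""Paralog family selection and four-guide Cas12a array library design.

Paralog pairs are admitted by sequence-identity and expression filters
(two named profiles: the denser ``prototype`` filter set and the relaxed
``inzolia`` set used for the production library).  Families of three or
four members come from a "difference from top paralog" rule: gene C joins
gene A's family when A's identity to C is within a drop threshold of A's
identity to its top paralog.

Each target (single gene or family) gets two four-guide arrays.  Singles
carry the same four guides in two orders; pairs carry two guides per gene
in two orders; triples and quads carry one guide per gene (triples padded
to four slots), with the two sibling arrays using disjoint guide sets.
Arrays are assembled into synthesis oligos by exact concatenation of the
fixed template segments: amplification primers, BsmBI sites with cloning
overhangs, the four 20-nt spacers interleaved with three distinct direct
repeats, and the poly-T Pol III terminator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Internal direct repeats between slots 1-2, 2-3 and 3-4, in fixed order.
INTERNAL_DRS = (
    "TAATTTCTACTATTGTAGAT",
    "AAATTTCTACTCTAGTAGAT",
    "TAATTTCTACTGTCGTAGAT",
)

TERMINATOR = "TTTTTT"

#: Template segments surrounding the spacer/DR cassette.  The 5' restriction
#: segment ends with the AGAT cloning overhang; lowercase marks the BsmBI
#: flanks exactly as synthesized so assembled oligos are byte-comparable.
RESTRICTION_5P = "cgtctcgAGAT"
RESTRICTION_3P = "GAATggagacg"

TEMPLATES = {
    "prototype": {
        "primer_5p": "AATGATACGGCGACCACCGA",
        "primer_3p": "ATCTCGTATGCCGTCTTCTGCTTG",
    },
    "inzolia": {
        "primer_5p": "AGGCACTTGCTCGTACGACG",
        "primer_3p": "TTAAGGTGCCGGGCCCACAT",
    },
}

SPACER_LENGTH = 20


class DesignInputError(ValueError):
    pass


class AssemblyError(ValueError):
    pass


class AccountingError(ValueError):
    pass


@dataclass(frozen=True)
class ParalogCandidate:
    """A candidate pair with BioMart-style asymmetric percent identities.

    identity_ab is the percent of A's protein matched in B and vice versa;
    the two differ when the proteins have different lengths.
    """

    gene_a: str
    gene_b: str
    identity_ab: float
    identity_ba: float

    def __post_init__(self) -> None:
        for v in (self.identity_ab, self.identity_ba):
            if not 0 <= v <= 100:
                raise DesignInputError(f"identity out of [0,100]: {v}")

    @property
    def mean_identity(self) -> float:
        return (self.identity_ab + self.identity_ba) / 2.0

    @property
    def delta_identity(self) -> float:
        return abs(self.identity_ab - self.identity_ba)


@dataclass(frozen=True)
class ExpressionSummary:
    gene: str
    expr_mean: float
    expr_std: float

    def __post_init__(self) -> None:
        if self.expr_std < 0:
            raise DesignInputError(f"negative expression std for {self.gene}")


@dataclass(frozen=True)
class DesignProfile:
    """Filter thresholds for pair selection and family clustering.

    ``None`` disables a filter.  All comparisons are strict.
    """

    name: str
    identity_min: float = 30.0
    identity_max: float | None = 99.0
    delta_max: float | None = 10.0
    expr_mean_min: float | None = 2.0
    expr_std_max: float | None = 1.5
    family_drop_max: float = 10.0


#: Prototype library: identity band 30-99%, delta < 10%, constitutive
#: expression (mean > 2, std < 1.5), family drop < 10%.
PROTOTYPE_PROFILE = DesignProfile(name="prototype")

#: Production library: delta and expression-variance filters removed, the
#: family-drop threshold widened to 20%; mean-expression filter retained.
#: The upper identity bound is dropped along with the delta filter (the
#: lower bound still excludes distant homologs); both bounds stay
#: configurable.
INZOLIA_PROFILE = DesignProfile(
    name="inzolia",
    identity_max=None,
    delta_max=None,
    expr_std_max=None,
    family_drop_max=20.0,
)

PROFILES = {"prototype": PROTOTYPE_PROFILE, "inzolia": INZOLIA_PROFILE}


@dataclass(frozen=True)
class ParalogFamily:
    members: tuple[str, ...]
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 2 <= len(self.members) <= 4:
            raise DesignInputError(f"family size {len(self.members)} outside 2..4")
        if len(set(self.members)) != len(self.members):
            raise DesignInputError("duplicate family members")


@dataclass(frozen=True)
class ArraySlot:
    spacer: str
    target: str  # gene symbol or pad label
    dr_index: int | None  # internal DR (1-3) preceding slots 2-4; None for slot 1


@dataclass(frozen=True)
class InfourArray:
    array_id: str
    targets: tuple[str, ...]
    slots: tuple[ArraySlot, ...]
    category: str  # single | pair | triple | quad | control
    pad_policy: str = "nonessential_gene"
    sibling_order_variant: int = 1

    def __post_init__(self) -> None:
        if len(self.slots) != 4:
            raise DesignInputError(f"array {self.array_id}: needs exactly 4 slots")

    @property
    def spacers(self) -> tuple[str, ...]:
        return tuple(s.spacer for s in self.slots)


@dataclass(frozen=True)
class OligoRecord:
    array_id: str
    sequence: str
    segment_map: tuple[tuple[str, str], ...]  # (label, subsequence), 5'->3'


# ---------------------------------------------------------------------------
# pair selection


def select_pairs(
    candidates: Sequence[ParalogCandidate],
    expr: Mapping[str, ExpressionSummary] | Sequence[ExpressionSummary],
    profile: DesignProfile,
) -> tuple[list[ParalogCandidate], list[tuple[ParalogCandidate, str]]]:
    """Apply the profile's identity and expression filters to candidate pairs.

    Returns (accepted, rejected) where each rejection carries its reason.
    All threshold comparisons are strict, so boundary values are rejected.
    """
    if not isinstance(expr, Mapping):
        expr = {e.gene: e for e in expr}
    accepted, rejected = [], []
    for cand in candidates:
        reason = _rejection_reason(cand, expr, profile)
        if reason is None:
            accepted.append(cand)
        else:
            rejected.append((cand, reason))
    return accepted, rejected


def _rejection_reason(
    cand: ParalogCandidate,
    expr: Mapping[str, ExpressionSummary],
    profile: DesignProfile,
) -> str | None:
    if not cand.mean_identity > profile.identity_min:
        return f"mean identity {cand.mean_identity:.1f} <= {profile.identity_min}"
    if profile.identity_max is not None and not cand.mean_identity < profile.identity_max:
        return f"mean identity {cand.mean_identity:.1f} >= {profile.identity_max}"
    if profile.delta_max is not None and not cand.delta_identity < profile.delta_max:
        return f"delta identity {cand.delta_identity:.1f} >= {profile.delta_max}"
    if profile.expr_mean_min is None and profile.expr_std_max is None:
        return None
    for gene in (cand.gene_a, cand.gene_b):
        summary = expr.get(gene)
        if summary is None:
            return f"no expression data for {gene}"
        if profile.expr_mean_min is not None and not summary.expr_mean > profile.expr_mean_min:
            return f"{gene} mean expression {summary.expr_mean:.2f} <= {profile.expr_mean_min}"
        if profile.expr_std_max is not None and not summary.expr_std < profile.expr_std_max:
            return f"{gene} expression std {summary.expr_std:.2f} >= {profile.expr_std_max}"
    return None


# ---------------------------------------------------------------------------
# family clustering


def cluster_families(
    identities: Mapping[str, Sequence[tuple[str, float]]],
    profile: DesignProfile,
) -> list[ParalogFamily]:
    """Group genes into families by the difference-from-top-paralog rule.

    ``identities[A]`` lists (candidate, identity(A, candidate)).  For each
    gene A with top paralog B, any other candidate C with
    identity(A,B) - identity(A,C) < profile.family_drop_max is admitted to
    A's family.  Directed admissions are merged by union-find; components
    larger than four are truncated to the four members with the smallest
    admission drop (ties broken alphabetically).  Output is deterministic:
    families and members are sorted.
    """
    parent: dict[str, str] = {}
    drop_of: dict[str, float] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for gene in sorted(identities):
        ranked = sorted(identities[gene], key=lambda t: (-t[1], t[0]))
        if not ranked:
            continue
        top_gene, top_identity = ranked[0]
        union(gene, top_gene)
        drop_of[gene] = min(drop_of.get(gene, 0.0), 0.0)
        drop_of.setdefault(top_gene, 0.0)
        for cand, ident in ranked[1:]:
            drop = top_identity - ident
            if drop < profile.family_drop_max:
                union(gene, cand)
                drop_of[cand] = min(drop_of.get(cand, drop), drop)

    components: dict[str, list[str]] = {}
    for gene in parent:
        components.setdefault(find(gene), []).append(gene)

    families = []
    for root in sorted(components):
        members = components[root]
        if len(members) < 2:
            continue
        members = sorted(members, key=lambda g: (drop_of.get(g, 0.0), g))[:4]
        families.append(
            ParalogFamily(
                members=tuple(sorted(members)),
                provenance=tuple(
                    f"{g}:drop={drop_of.get(g, 0.0):.2f}" for g in sorted(members)
                ),
            )
        )
    return families


# ---------------------------------------------------------------------------
# array construction

_PAD_LABEL = {"nonessential_gene": "pad_nonessential", "nontargeting": "pad_nontargeting"}


def _slots(spacer_targets: Sequence[tuple[str, str]]) -> tuple[ArraySlot, ...]:
    return tuple(
        ArraySlot(spacer=sp, target=tg, dr_index=i if i >= 1 else None)
        for i, (sp, tg) in enumerate(spacer_targets)
    )


def build_arrays(
    singles: Sequence[str],
    families: Sequence[ParalogFamily],
    guides: Mapping[str, Sequence[str]],
    pad_guides: Sequence[tuple[str, str]] = (),
    pad_policy: str = "nonessential_gene",
) -> list[InfourArray]:
    """Two four-guide arrays per target.

    singles: 4 top-ranked guides, sibling order reversed.  Pairs: two guides
    per gene interleaved (A,B,A,B), sibling reversed.  Triples: one guide
    per gene plus a pad slot, siblings use the next-ranked (disjoint)
    guides.  Quads: one guide per gene, disjoint across siblings.
    ``pad_guides`` supplies (spacer, label) pads for triples.
    """
    arrays: list[InfourArray] = []
    pad_iter = iter(pad_guides)

    def ranked(gene: str, n: int, offset: int = 0) -> list[str]:
        avail = guides.get(gene, ())
        if len(avail) < offset + n:
            raise DesignInputError(
                f"gene {gene!r}: needs {offset + n} ranked guides, has {len(avail)}"
            )
        return list(avail[offset : offset + n])

    def next_pad() -> tuple[str, str]:
        try:
            spacer, label = next(pad_iter)
        except StopIteration:
            raise DesignInputError("ran out of pad guides for triples") from None
        return spacer, label

    for gene in singles:
        g = ranked(gene, 4)
        order1 = [(sp, gene) for sp in g]
        for variant, order in enumerate((order1, order1[::-1]), start=1):
            arrays.append(
                InfourArray(
                    array_id=f"{gene}_v{variant}",
                    targets=(gene,),
                    slots=_slots(order),
                    category="single",
                    pad_policy=pad_policy,
                    sibling_order_variant=variant,
                )
            )

    for family in families:
        members = family.members
        name = "_".join(members)
        if len(members) == 2:
            a, b = members
            ga, gb = ranked(a, 2), ranked(b, 2)
            order1 = [(ga[0], a), (gb[0], b), (ga[1], a), (gb[1], b)]
            variants = (order1, order1[::-1])
            category = "pair"
        elif len(members) == 3:
            pads = (next_pad(), next_pad())
            variants = tuple(
                [(ranked(m, 1, offset)[0], m) for m in members] + [pads[offset]]
                for offset in (0, 1)
            )
            category = "triple"
        else:
            variants = tuple(
                [(ranked(m, 1, offset)[0], m) for m in members] for offset in (0, 1)
            )
            category = "quad"
        for variant, order in enumerate(variants, start=1):
            arrays.append(
                InfourArray(
                    array_id=f"{name}_v{variant}",
                    targets=members,
                    slots=_slots(order),
                    category=category,
                    pad_policy=pad_policy,
                    sibling_order_variant=variant,
                )
            )
    return arrays


# ---------------------------------------------------------------------------
# oligo assembly


def assemble_oligo(array: InfourArray, template: str = "prototype") -> OligoRecord:
    """Assemble the synthesis oligo for a four-guide array, byte-exact.

    Layout (5'->3'): amplification primer, BsmBI site + AGAT overhang, the
    four spacers interleaved with the three internal DRs, the TTTTTT
    terminator, the 3' BsmBI region, amplification primer.  Prototype
    oligos are 212 nt; production (inzolia) oligos are 208 nt.
    """
    if template not in TEMPLATES:
        raise AssemblyError(f"unknown template {template!r}")
    spacers = array.spacers
    if len(spacers) != 4:
        raise AssemblyError(f"array {array.array_id}: expected 4 spacers")
    for sp in spacers:
        if len(sp) != SPACER_LENGTH:
            raise AssemblyError(
                f"array {array.array_id}: spacer length {len(sp)} != {SPACER_LENGTH}"
            )
        if set(sp.upper()) - set("ACGT"):
            raise AssemblyError(f"array {array.array_id}: invalid spacer characters in {sp!r}")
    t = TEMPLATES[template]
    segments = [
        ("primer_5p", t["primer_5p"]),
        ("restriction_5p", RESTRICTION_5P),
        ("spacer1", spacers[0]),
        ("DR_a", INTERNAL_DRS[0]),
        ("spacer2", spacers[1]),
        ("DR_b", INTERNAL_DRS[1]),
        ("spacer3", spacers[2]),
        ("DR_c", INTERNAL_DRS[2]),
        ("spacer4", spacers[3]),
        ("terminator", TERMINATOR),
        ("restriction_3p", RESTRICTION_3P),
        ("primer_3p", t["primer_3p"]),
    ]
    sequence = "".join(seq for _, seq in segments)
    return OligoRecord(array_id=array.array_id, sequence=sequence, segment_map=tuple(segments))


def write_oligo_fasta(oligos: Sequence[OligoRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in oligos:
            fh.write(f">{rec.array_id}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# accounting


def manifest_accounting(
    arrays: Sequence[InfourArray],
    control_arrays: Mapping[str, int] | None = None,
    template: str | None = None,
) -> dict[str, int]:
    """Count arrays by category and assert id/sequence uniqueness.

    ``control_arrays`` adds externally specified control counts (EGFP,
    intergenic, non-targeting...).  When ``template`` is given, assembled
    sequences are checked for collisions.
    """
    ids = [a.array_id for a in arrays]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise AccountingError(f"duplicate array ids: {dupes}")
    counts: dict[str, int] = {"single": 0, "pair": 0, "triple": 0, "quad": 0, "control": 0}
    for a in arrays:
        counts[a.category] = counts.get(a.category, 0) + 1
    if template is not None:
        seqs: dict[str, str] = {}
        collisions = []
        for a in arrays:
            seq = assemble_oligo(a, template).sequence
            if seq in seqs:
                collisions.append((seqs[seq], a.array_id))
            seqs[seq] = a.array_id
        if collisions:
            raise AccountingError(f"duplicate assembled sequences: {collisions}")
    for label, n in (control_arrays or {}).items():
        counts[f"control_{label}"] = n
        counts["control"] += n
    counts["family_arrays"] = counts["pair"] + counts["triple"] + counts["quad"]
    counts["total"] = sum(
        v for k, v in counts.items()
        if k in ("single", "pair", "triple", "quad", "control")
    )
    return counts


def planned_accounting(
    n_singles: int,
    n_pairs: int,
    n_triples: int,
    n_quads: int,
    n_control_arrays: int = 0,
    arrays_per_target: int = 2,
) -> dict[str, int]:
    """Library size from target counts alone (two arrays per target)."""
    counts = {
        "single": arrays_per_target * n_singles,
        "pair": arrays_per_target * n_pairs,
        "triple": arrays_per_target * n_triples,
        "quad": arrays_per_target * n_quads,
        "control": n_control_arrays,
    }
    counts["family_arrays"] = counts["pair"] + counts["triple"] + counts["quad"]
    counts["total"] = sum(
        counts[k] for k in ("single", "pair", "triple", "quad", "control")
    )
    return counts


def reagents_per_pair(guides_per_single: int = 2, guides_per_pair: int = 2) -> int:
    """Arrays needed to assay one pair GI: singles for each gene plus doubles."""
    return 2 * guides_per_single + guides_per_pair
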