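"""Reading, writing and exact-match counting for multiplex CRISPR screens.

Tabular formats are plain TSV throughout: a count table whose first column
is ``construct_id`` and whose remaining columns are sample ids, plus a
manifest describing each construct (targets, class, study, cell line and
optional spacer sequences).  Sequencing reads are counted against a library
of full array sequences by exact substring match only -- no alignment, no
mismatch tolerance -- mirroring how amplicon reads from pooled array
libraries are quantified.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Construct classes understood by the pipeline.  ``single_with_control_first``
#: is a control-gene construct (N_gene layout), ``single_with_control_second``
#: a gene-control construct (gene_N layout); ``pair`` targets two genes (A_B).
CONSTRUCT_CLASSES = frozenset(
    {
        "single_with_control_first",
        "single_with_control_second",
        "pair",
        "triple",
        "quad",
        "control",
        "seven_mer",
    }
)


class FormatError(ValueError):
    """A file does not have the expected columns or layout."""


class ValidationError(ValueError):
    """Contents parsed but violate an invariant (duplicates, bad lengths...)."""


@dataclass(frozen=True)
class ConstructRecord:
    """One reagent in a pooled library: an ordered set of 1-7 targets."""

    construct_id: str
    targets: tuple[str, ...]
    construct_class: str
    spacers: tuple[str, ...] | None = None
    study_id: str = ""
    cell_line: str = ""

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValidationError(f"construct {self.construct_id!r}: no targets")
        if self.construct_class not in CONSTRUCT_CLASSES:
            raise ValidationError(
                f"construct {self.construct_id!r}: unknown class "
                f"{self.construct_class!r}"
            )
        if self.spacers:
            lengths = {len(s) for s in self.spacers}
            if len(lengths) > 1:
                raise ValidationError(
                    f"construct {self.construct_id!r}: unequal spacer lengths "
                    f"{sorted(lengths)}"
                )


@dataclass(frozen=True)
class SampleInfo:
    """One sequenced sample: a reference (plasmid/T0) or an endpoint."""

    sample_id: str
    role: str  # "reference" or "endpoint"
    replicate: int = 1
    timepoint: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("reference", "endpoint"):
            raise ValidationError(f"sample {self.sample_id!r}: bad role {self.role!r}")


@dataclass
class CountMatrix:
    """Construct x sample integer read counts with sample metadata."""

    constructs: list[ConstructRecord]
    samples: list[SampleInfo]
    counts: pd.DataFrame  # index construct_id, columns sample_id

    def __post_init__(self) -> None:
        ids = [c.construct_id for c in self.constructs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicated construct ids: {dupes}")
        if list(self.counts.index) != ids:
            raise ValidationError("count rows do not match construct manifest order")
        if list(self.counts.columns) != [s.sample_id for s in self.samples]:
            raise ValidationError("count columns do not match sample metadata")
        if not any(s.role == "reference" for s in self.samples):
            raise ValidationError("no reference sample designated")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative counts")

    @property
    def reference_samples(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.role == "reference"]

    @property
    def endpoint_samples(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.role == "endpoint"]

    def construct(self, construct_id: str) -> ConstructRecord:
        for c in self.constructs:
            if c.construct_id == construct_id:
                return c
        raise KeyError(construct_id)


@dataclass(frozen=True)
class MatchSpec:
    """Geometry of the exactly-matched region of an array amplicon.

    The matched region is ``n_spacers`` spacers interleaved with
    ``n_spacers - 1`` direct repeats; when the leading DR lives on the
    vector backbone it is excluded from the match (``leading_dr_excluded``).
    """

    matched_region_length: int
    spacer_length: int
    dr_length: int
    n_spacers: int
    leading_dr_excluded: bool = True

    def __post_init__(self) -> None:
        expected = self.n_spacers * self.spacer_length + (self.n_spacers - 1) * self.dr_length
        if self.matched_region_length != expected:
            raise ValidationError(
                f"matched_region_length {self.matched_region_length} != "
                f"{self.n_spacers}*{self.spacer_length} + "
                f"{self.n_spacers - 1}*{self.dr_length} = {expected}"
            )


#: 7-guide arrays: seven 23-nt spacers joined by six 20-nt DRs, leading DR on
#: the vector, giving a 281-nt exactly-matched region.
SEVEN_MER_SPEC = MatchSpec(
    matched_region_length=281, spacer_length=23, dr_length=20, n_spacers=7
)

#: 4-guide arrays: four 20-nt spacers joined by three 20-nt DRs (140 nt).
IN4MER_SPEC = MatchSpec(
    matched_region_length=140, spacer_length=20, dr_length=20, n_spacers=4
)

MATCH_SPECS = {"7mer": SEVEN_MER_SPEC, "in4mer": IN4MER_SPEC}


# ---------------------------------------------------------------------------
# manifest / count-table I/O

_MANIFEST_REQUIRED = ["construct_id", "targets", "class"]


def read_manifest(path: str | Path) -> list[ConstructRecord]:
    """Read a construct manifest TSV.

    Required columns: ``construct_id``, ``targets`` (semicolon-joined),
    ``class``; optional: ``study_id``, ``cell_line``, ``spacers``
    (semicolon-joined).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _MANIFEST_REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"manifest {path}: missing columns {missing}")
    records = []
    for row in df.to_dict("records"):
        spacers = row.get("spacers", "")
        records.append(
            ConstructRecord(
                construct_id=row["construct_id"],
                targets=tuple(t for t in str(row["targets"]).split(";") if t),
                construct_class=row["class"],
                spacers=tuple(spacers.split(";")) if spacers else None,
                study_id=row.get("study_id", ""),
                cell_line=row.get("cell_line", ""),
            )
        )
    ids = [r.construct_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"manifest {path}: duplicated construct ids {dupes}")
    return records


def write_manifest(records: Sequence[ConstructRecord], path: str | Path) -> None:
    rows = [
        {
            "construct_id": r.construct_id,
            "targets": ";".join(r.targets),
            "class": r.construct_class,
            "study_id": r.study_id,
            "cell_line": r.cell_line,
            "spacers": ";".join(r.spacers) if r.spacers else "",
        }
        for r in records
    ]
    pd.DataFrame(
        rows, columns=["construct_id", "targets", "class", "study_id", "cell_line", "spacers"]
    ).to_csv(path, sep="\t", index=False)


def read_count_table(
    path: str | Path,
    manifest: str | Path | Sequence[ConstructRecord],
    samples: Sequence[SampleInfo] | None = None,
) -> CountMatrix:
    """Read a counts TSV against a manifest and return a validated matrix.

    ``samples`` supplies roles/replicates for each count column; when omitted,
    columns named like ``T0*``/``plasmid*`` become references and everything
    else an endpoint (replicate parsed from a trailing ``_<int>`` if present).
    """
    if isinstance(manifest, (str, Path)):
        records = read_manifest(manifest)
    else:
        records = list(manifest)
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "construct_id":
        raise FormatError(f"{path}: first column must be construct_id, got {df.columns[0]!r}")
    if df["construct_id"].duplicated().any():
        dupes = sorted(df.loc[df["construct_id"].duplicated(), "construct_id"].unique())
        raise ValidationError(f"{path}: duplicated construct ids {dupes}")
    by_id = {r.construct_id: r for r in records}
    unmatched = sorted(set(df["construct_id"]) - set(by_id))
    if unmatched:
        raise ValidationError(f"{path}: construct ids absent from manifest: {unmatched}")
    ordered = [by_id[i] for i in df["construct_id"]]
    counts = df.set_index("construct_id")
    if samples is None:
        samples = [_infer_sample(c) for c in counts.columns]
    counts = counts.astype(int)
    return CountMatrix(constructs=ordered, samples=list(samples), counts=counts)


def _infer_sample(sample_id: str) -> SampleInfo:
    lowered = sample_id.lower()
    role = "reference" if lowered.startswith(("t0", "plasmid", "ref")) else "endpoint"
    replicate = 1
    stem = sample_id
    if "_" in sample_id and sample_id.rsplit("_", 1)[1].isdigit():
        stem, rep = sample_id.rsplit("_", 1)
        replicate = int(rep)
    return SampleInfo(sample_id=sample_id, role=role, replicate=replicate, timepoint=stem)


def write_count_table(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index=True, index_label="construct_id")


def read_gene_list(path: str | Path) -> set[str]:
    """Read a reference gene list: one symbol per line, blanks skipped."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


# ---------------------------------------------------------------------------
# fold-change table I/O (columns fixed; LFC at 6 decimal places)


def write_fold_change_table(fc: pd.DataFrame, path: str | Path) -> None:
    """Write a fold-change table TSV.

    Expects the layout produced by :mod:`crisparray.normalization`:
    ``construct_id`` index, ``targets``/``class`` annotation columns,
    ``lfc_<replicate>`` columns and a ``mean_lfc`` column.
    """
    out = fc.copy()
    for col in out.columns:
        if col.startswith("lfc_") or col == "mean_lfc":
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.6f}")
    out.to_csv(path, sep="\t", index=True, index_label="construct_id")


def read_fold_change_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="construct_id")
    for col in df.columns:
        if col.startswith("lfc_") or col == "mean_lfc":
            df[col] = pd.to_numeric(df[col])
    return df


# ---------------------------------------------------------------------------
# exact-match counting


def iter_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a FASTQ file, plain or gzipped.

    Quality strings are ignored: counting uses sequence identity only.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield str(rec.seq)


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def count_exact_matches(
    reads: Iterable[str],
    library: Sequence[tuple[str, str]],
    spec: MatchSpec,
    both_strands: bool = False,
) -> dict[str, int]:
    """Count reads containing a library array sequence verbatim.

    A read is credited to a construct iff the construct's full matched region
    occurs as an exact substring of the read; a single substitution anywhere
    in the region disqualifies the read.  Each read is credited at most once:
    a read containing two different library sequences (only possible with a
    pathological library) is credited to none and logged.

    Reads are scanned on the given strand; ``both_strands=True`` additionally
    scans the reverse complement.
    """
    for cid, seq in library:
        if len(seq) != spec.matched_region_length:
            raise ValidationError(
                f"library sequence {cid!r} has length {len(seq)}, expected "
                f"{spec.matched_region_length}"
            )
    if len({cid for cid, _ in library}) != len(library):
        raise ValidationError("duplicate construct ids in library")
    counts = {cid: 0 for cid, _ in library}
    n_ambiguous = 0
    for read in reads:
        haystacks = [read] if not both_strands else [read, reverse_complement(read)]
        matched: set[str] = set()
        for hay in haystacks:
            for cid, seq in library:
                if seq in hay:
                    matched.add(cid)
        if len(matched) == 1:
            counts[matched.pop()] += 1
        elif len(matched) > 1:
            n_ambiguous += 1
    if n_ambiguous:
        logger.warning("%d reads matched multiple library sequences; dropped", n_ambiguous)
    return counts
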