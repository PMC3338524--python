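"""Reading, validating and filtering aligned protein homolog groups.

A *group* is one aligned family of homologous protein sequences together
with two annotations per sequence: the species it comes from and a
single-letter functional category tag (COG-style).  Groups are the unit of
analysis for the divergence scan: each group gets its own gene tree and its
own set of per-node tests.

Group-level filters mirror the screening applied before a proteome scan:

* at least 9 sequences (one outgroup plus two clades of 4);
* a single functional-category tag shared by every sequence;
* the tag is not one of the poorly characterised categories ``R``/``S``.
"""

from __future__ import annotations

import statistics
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
GAP = "-"
#: letters accepted only in permissive mode (mapped to gap)
AMBIGUOUS = set("BZXUOJ*.")

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP_CODE = -1

DEFAULT_MIN_SEQUENCES = 9
DEFAULT_EXCLUDED_TAGS = frozenset({"R", "S"})


class AlignmentFormatError(ValueError):
    """Raised for ragged alignments or otherwise malformed input."""


class AnnotationError(ValueError):
    """Raised when a sequence lacks a species/category annotation."""


class AlphabetError(ValueError):
    """Raised when a sequence contains letters outside the alphabet."""


@dataclass
class AlignmentGroup:
    """An aligned set of homologous protein sequences with annotations.

    Parameters
    ----------
    group_id
        Opaque identifier, typically the input file stem.
    sequences
        Ordered ``(seq_id, aligned_string)`` pairs.  All strings must have
        the same length and use the 20 standard amino acids plus ``-``.
    species_of
        Map from ``seq_id`` to a species identifier.
    category_tags
        Map from ``seq_id`` to a functional-category tag.  Multi-letter
        annotations are allowed here; they count as "multi-tag" when the
        single-tag filter is applied.
    """

    group_id: str
    sequences: list[tuple[str, str]]
    species_of: dict[str, str]
    category_tags: dict[str, str]
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentFormatError(f"{self.group_id}: empty alignment")
        lengths = {len(s) for _, s in self.sequences}
        if len(lengths) != 1:
            raise AlignmentFormatError(
                f"{self.group_id}: ragged alignment, lengths {sorted(lengths)}"
            )
        if next(iter(lengths)) < 1:
            raise AlignmentFormatError(f"{self.group_id}: zero-length alignment")
        ids = [sid for sid, _ in self.sequences]
        if len(set(ids)) != len(ids):
            raise AlignmentFormatError(f"{self.group_id}: duplicate sequence ids")
        missing = [sid for sid in ids if sid not in self.species_of]
        if missing:
            raise AnnotationError(
                f"{self.group_id}: no species annotation for {missing[:5]}"
            )
        allowed = set(AMINO_ACIDS) | {GAP}
        for sid, seq in self.sequences:
            bad = set(seq) - allowed
            if bad:
                raise AlphabetError(
                    f"{self.group_id}/{sid}: illegal characters {sorted(bad)}"
                )

    # -- basic geometry ----------------------------------------------------
    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0][1])

    @property
    def seq_ids(self) -> list[str]:
        return [sid for sid, _ in self.sequences]

    def matrix(self) -> np.ndarray:
        """Integer-coded alignment, shape (n_sequences, length).

        Residues are coded 0..19 in ``ARNDCQEGHILKMFPSTWYV`` order and gaps
        as -1.  The array is cached on first use.
        """
        if self._matrix is None:
            lut = np.full(128, GAP_CODE, dtype=np.int8)
            for aa, i in AA_INDEX.items():
                lut[ord(aa)] = i
            rows = [
                lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
                for _, seq in self.sequences
            ]
            self._matrix = np.vstack(rows)
        return self._matrix

    def row_index(self, seq_ids: Iterable[str]) -> np.ndarray:
        """Row positions of the given sequence ids, in alignment order."""
        pos = {sid: i for i, sid in enumerate(self.seq_ids)}
        return np.array(sorted(pos[s] for s in seq_ids), dtype=np.intp)


@dataclass(frozen=True)
class GroupFilterReport:
    group_id: str
    n_sequences: int
    n_distinct_tags: int
    modal_tag: str
    modal_tag_frequency: float
    passed: bool
    failure_reasons: tuple[str, ...]


def _normalize_sequence(seq: str, *, strict: bool, where: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set(AMINO_ACIDS) - {GAP}
    if not bad:
        return seq
    if strict or not bad.issubset(AMBIGUOUS):
        raise AlphabetError(f"{where}: illegal characters {sorted(bad)}")
    return "".join(GAP if c in AMBIGUOUS else c for c in seq)


def read_annotations(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a ``seq_id<TAB>species<TAB>category`` table.

    A header row with those column names is accepted and skipped.  Returns
    ``(species_of, category_tags)``.
    """
    species_of: dict[str, str] = {}
    category_tags: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].lower() in {"seq_id", "seqid", "id"}:
                continue
            if len(parts) < 3:
                raise AnnotationError(f"{path}:{lineno}: expected 3 columns")
            sid, species, category = parts[0], parts[1], parts[2]
            species_of[sid] = species
            category_tags[sid] = category
    return species_of, category_tags


def read_alignment(
    path: str | Path,
    annotations: str | Path | tuple[Mapping[str, str], Mapping[str, str]],
    *,
    group_id: str | None = None,
    strict: bool = True,
) -> AlignmentGroup:
    """Read an aligned FASTA file plus its annotation table.

    ``annotations`` may be a path to a TSV or an already-parsed
    ``(species_of, category_tags)`` pair.  With ``strict=True`` (default)
    ambiguity letters raise :class:`AlphabetError`; in permissive mode they
    are replaced by gaps.
    """
    path = Path(path)
    if group_id is None:
        group_id = path.stem
    if isinstance(annotations, (str, Path)):
        species_of, category_tags = read_annotations(annotations)
    else:
        species_of, category_tags = dict(annotations[0]), dict(annotations[1])
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"{path}: no sequences")
    sequences = [
        (
            rec.id,
            _normalize_sequence(str(rec.seq), strict=strict, where=f"{path}/{rec.id}"),
        )
        for rec in records
    ]
    # only carry annotations for sequences in this group
    ids = {sid for sid, _ in sequences}
    return AlignmentGroup(
        group_id=group_id,
        sequences=sequences,
        species_of={k: v for k, v in species_of.items() if k in ids},
        category_tags={k: v for k, v in category_tags.items() if k in ids},
    )


def write_alignment(group: AlignmentGroup, path: str | Path) -> None:
    """Write the group back out as canonical (single-line) aligned FASTA."""
    with open(path, "w") as fh:
        for sid, seq in group.sequences:
            fh.write(f">{sid}\n{seq}\n")


def filter_group(
    group: AlignmentGroup,
    *,
    min_sequences: int = DEFAULT_MIN_SEQUENCES,
    excluded_tags: frozenset[str] | set[str] = DEFAULT_EXCLUDED_TAGS,
) -> GroupFilterReport:
    """Apply the pre-scan group filters and report the outcome.

    The report records the modal tag and its frequency whether or not the
    group passes, so filter summaries can be tabulated across a dataset.
    Sequences annotated with more than one category letter count as their
    own (multi-letter) tag and therefore trip the single-tag rule.
    """
    tags = [group.category_tags.get(sid, "") for sid in group.seq_ids]
    counts = Counter(tags)
    # deterministic modal choice: highest count, ties by letter
    modal_tag, modal_count = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    reasons: list[str] = []
    if group.n_sequences < min_sequences:
        reasons.append(f"too-few-sequences (<{min_sequences})")
    if len(counts) > 1 or any(len(t) != 1 for t in tags):
        reasons.append("multi-tag")
    if modal_tag in excluded_tags and len(counts) == 1:
        reasons.append("excluded-category")
    return GroupFilterReport(
        group_id=group.group_id,
        n_sequences=group.n_sequences,
        n_distinct_tags=len(counts),
        modal_tag=modal_tag,
        modal_tag_frequency=modal_count / group.n_sequences,
        passed=not reasons,
        failure_reasons=tuple(reasons),
    )


def gap_profile(group: AlignmentGroup) -> tuple[dict[str, int], float]:
    """Per-sequence gap counts and their arithmetic mean.

    The mean, rounded half-to-even to an integer, is subtracted from the
    alignment length to set the number of columns simulated under the null
    (gap columns carry no score, so simulated alignments are shortened to
    match the effective amount of data).
    """
    counts = {sid: seq.count(GAP) for sid, seq in group.sequences}
    mean = statistics.fmean(counts.values())
    return counts, mean


def simulated_length(group: AlignmentGroup) -> int:
    """Alignment length minus the (banker's-rounded) mean gap count."""
    _, mean_gaps = gap_profile(group)
    # round() is round-half-to-even on Python floats
    return group.length - round(mean_gaps)


def write_filter_reports(reports: Sequence[GroupFilterReport], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "group_id\tn_sequences\tn_distinct_tags\tmodal_tag\t"
            "modal_tag_frequency\tpassed\tfailure_reasons\n"
        )
        for r in reports:
            fh.write(
                f"{r.group_id}\t{r.n_sequences}\t{r.n_distinct_tags}\t{r.modal_tag}\t"
                f"{r.modal_tag_frequency:.6g}\t{int(r.passed)}\t"
                f"{';'.join(r.failure_reasons)}\n"
            )
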