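"""Variant extraction and haplotype collapsing for aligned mtDNA genomes.

Sequences arrive as a pre-computed multiple alignment (multi-FASTA) that
includes the reference genome as one row.  Every sample row is diffed
against the reference row to yield a set of :class:`Variant` records in
1-based reference coordinates, named in the ``m.POS`` style used for
human mitochondrial variation (e.g. ``m.263A>G``, ``m.del8281-8289``,
``m.303insC``).  Individuals without a sequenced genome are imputed onto
their matrilineal representative's haplotype, reflecting strict maternal
inheritance of the mitochondrial genome.

Coordinate conventions: reference positions are 1-based and closed;
alignment columns are 0-based.  The reference is treated as linear (no
origin-spanning features).  ``N`` and gap-only columns never produce
variants; a haplotype's identity is its set of called variants, so
missingness does not split haplotypes.  Indels are left-aligned within
homopolymer runs so that haplotype identity is well defined regardless
of how the upstream aligner placed the gap.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    BoundsError,
    ConsistencyError,
    FormatError,
    LookupError_,
)

_BASES = frozenset("ACGT")
_ALLOWED = frozenset("ACGTN-")

SNV = "SNV"
INSERTION = "insertion"
DELETION = "deletion"

_LABEL_SNV = re.compile(r"^m\.(\d+)([ACGT])>([ACGT])$")
_LABEL_DEL = re.compile(r"^m\.del(\d+)(?:-(\d+))?$")
_LABEL_INS = re.compile(r"^m\.(\d+)ins([ACGT]+)$")


@dataclass(frozen=True, order=True)
class Variant:
    """A single sequence feature relative to the reference.

    ``start``/``end`` are 1-based closed reference coordinates; for an
    insertion both equal the reference position *after which* the
    inserted bases sit, and ``ref_allele`` is empty.  For a deletion
    ``alt_allele`` is empty.
    """

    kind: str
    start: int
    end: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.kind not in (SNV, INSERTION, DELETION):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise BoundsError(f"invalid span {self.start}-{self.end}")
        if self.kind == SNV:
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise ValueError("SNV alleles must be single bases")
            if self.ref_allele == self.alt_allele:
                raise ValueError("SNV alleles must differ")
            if self.start != self.end:
                raise ValueError("SNV must have start == end")
        elif self.kind == DELETION and self.alt_allele:
            raise ValueError("deletion must have empty alt allele")
        elif self.kind == INSERTION:
            if self.ref_allele:
                raise ValueError("insertion must have empty ref allele")
            if self.start != self.end:
                raise ValueError("insertion anchors at a single position")

    @property
    def label(self) -> str:
        if self.kind == SNV:
            return f"m.{self.start}{self.ref_allele}>{self.alt_allele}"
        if self.kind == DELETION:
            if self.start == self.end:
                return f"m.del{self.start}"
            return f"m.del{self.start}-{self.end}"
        return f"m.{self.start}ins{self.alt_allele}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_variant_label(label: str, reference: str | None = None) -> Variant:
    """Parse an ``m.``-style label back into a :class:`Variant`.

    Deletion labels do not carry the deleted bases; pass ``reference``
    to recover them, otherwise the ref allele is filled with ``N``s.
    """
    m = _LABEL_SNV.match(label)
    if m:
        pos, ref, alt = int(m.group(1)), m.group(2), m.group(3)
        return Variant(SNV, pos, pos, ref, alt)
    m = _LABEL_DEL.match(label)
    if m:
        start = int(m.group(1))
        end = int(m.group(2)) if m.group(2) else start
        if reference is not None:
            ref = reference[start - 1 : end]
        else:
            ref = "N" * (end - start + 1)
        return Variant(DELETION, start, end, ref, "")
    m = _LABEL_INS.match(label)
    if m:
        pos, alt = int(m.group(1)), m.group(2)
        return Variant(INSERTION, pos, pos, "", alt)
    raise FormatError(f"unparseable variant label {label!r}")


# ---------------------------------------------------------------------------
# Alignment container
# ---------------------------------------------------------------------------

@dataclass
class AlignmentMatrix:
    """A loaded multiple alignment with a reference-anchored coordinate map.

    ``col_ref_pos[c]`` is, for a reference-base column, the 1-based
    reference position; for a column where the reference carries a gap it
    is the reference position *after which* the column inserts (0 for a
    gap before the first base).  ``col_is_insertion`` flags the latter.
    """

    sequence_ids: list[str]
    rows: list[str]
    reference_id: str
    col_ref_pos: tuple[int, ...] = field(repr=False)
    col_is_insertion: tuple[bool, ...] = field(repr=False)

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise FormatError(f"alignment rows have unequal lengths {sorted(lengths)}")
        if self.reference_id not in self.sequence_ids:
            raise LookupError_(f"reference {self.reference_id!r} not in alignment")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def reference_length(self) -> int:
        return max((p for p, ins in zip(self.col_ref_pos, self.col_is_insertion)
                    if not ins), default=0)

    def row(self, sample_id: str) -> str:
        try:
            return self.rows[self.sequence_ids.index(sample_id)]
        except ValueError:
            raise LookupError_(f"sample {sample_id!r} not in alignment") from None

    @property
    def reference_row(self) -> str:
        return self.row(self.reference_id)

    @property
    def reference_sequence(self) -> str:
        """The ungapped reference sequence."""
        return self.reference_row.replace("-", "")


def _build_coordinate_map(reference_row: str) -> tuple[tuple[int, ...], tuple[bool, ...]]:
    pos = 0
    ref_pos: list[int] = []
    is_ins: list[bool] = []
    for ch in reference_row:
        if ch == "-":
            ref_pos.append(pos)
            is_ins.append(True)
        else:
            pos += 1
            ref_pos.append(pos)
            is_ins.append(False)
    return tuple(ref_pos), tuple(is_ins)


def read_alignment(fasta_path: str | Path, reference_id: str) -> AlignmentMatrix:
    """Load an aligned multi-FASTA and anchor coordinates on ``reference_id``."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {fasta_path}")
    ids = [r.id for r in records]
    rows = [str(r.seq).upper() for r in records]
    lengths = {len(r) for r in rows}
    if len(lengths) > 1:
        raise FormatError(
            f"{fasta_path}: records have unequal lengths {sorted(lengths)}; "
            "input must be a pre-computed alignment"
        )
    for rid, row in zip(ids, rows):
        bad = set(row) - _ALLOWED
        if bad:
            raise FormatError(f"record {rid!r} contains invalid characters {sorted(bad)}")
    if reference_id not in ids:
        raise LookupError_(f"reference {reference_id!r} not found in {fasta_path}")
    ref_row = rows[ids.index(reference_id)]
    col_pos, col_ins = _build_coordinate_map(ref_row)
    return AlignmentMatrix(ids, rows, reference_id, col_pos, col_ins)


def write_alignment(aln: AlignmentMatrix, fasta_path: str | Path) -> None:
    """Write the alignment back out as multi-FASTA (unwrapped)."""
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.sequence_ids, aln.rows)
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(records, fh, "fasta-2line")


# ---------------------------------------------------------------------------
# Indel normalisation
# ---------------------------------------------------------------------------

def normalize_variant(v: Variant, reference: str) -> Variant:
    """Left-align an indel within homopolymer/repeat context.

    Deletions shift left while the base preceding the span equals the last
    base of the span; insertions rotate left while the base at the anchor
    equals the last inserted base.  SNVs are returned unchanged.  This is
    the canonical form used for haplotype identity.
    """
    if v.kind == SNV:
        return v
    if v.kind == DELETION:
        start, end = v.start, v.end
        while start > 1 and reference[start - 2] == reference[end - 1]:
            start -= 1
            end -= 1
        if (start, end) == (v.start, v.end):
            return v
        return Variant(DELETION, start, end, reference[start - 1 : end], "")
    # insertion
    pos, seq = v.start, v.alt_allele
    while pos >= 1 and reference[pos - 1] == seq[-1]:
        seq = seq[-1] + seq[:-1]
        pos -= 1
    if pos == 0:
        # never shift an insertion in front of the first base; undo one step
        pos, seq = pos + 1, seq[1:] + seq[:1]
    if pos == v.start:
        return v
    return Variant(INSERTION, pos, pos, "", seq)


# ---------------------------------------------------------------------------
# Variant extraction and application
# ---------------------------------------------------------------------------

def extract_variants(aln: AlignmentMatrix, sample_id: str) -> frozenset[Variant]:
    """All differences of ``sample_id`` against the reference row.

    Maximal runs of sample gaps over reference bases become one deletion;
    maximal runs of reference-gap columns carrying sample bases become one
    insertion; ``N`` is treated as missing and never yields a variant.
    """
    sample = aln.row(sample_id)
    ref_row = aln.reference_row
    reference = aln.reference_sequence
    variants: set[Variant] = set()

    del_start = del_end = 0          # open deletion run (1-based ref span)
    ins_after = -1                   # open insertion run anchor
    ins_seq: list[str] = []

    def flush_deletion() -> None:
        nonlocal del_start, del_end
        if del_start:
            v = Variant(DELETION, del_start, del_end,
                        reference[del_start - 1 : del_end], "")
            variants.add(normalize_variant(v, reference))
            del_start = del_end = 0

    def flush_insertion() -> None:
        nonlocal ins_after, ins_seq
        if ins_seq:
            v = Variant(INSERTION, max(ins_after, 1), max(ins_after, 1),
                        "", "".join(ins_seq))
            if ins_after >= 1:
                variants.add(normalize_variant(v, reference))
            # insertions before the first reference base have no anchor
            # position in m.-notation; treated as unrepresentable -> dropped
        ins_after = -1
        ins_seq = []

    for c in range(aln.n_columns):
        r, s = ref_row[c], sample[c]
        if aln.col_is_insertion[c]:
            if s in _BASES:
                if ins_seq and ins_after != aln.col_ref_pos[c]:
                    flush_insertion()
                ins_after = aln.col_ref_pos[c]
                ins_seq.append(s)
                flush_deletion()
            elif s == "-":
                flush_insertion()
            # 'N' inside a reference gap: missing, neither extends nor breaks
        else:
            flush_insertion()
            p = aln.col_ref_pos[c]
            if s == "-":
                if r == "N":
                    continue  # missing reference base: uncallable
                if del_start == 0:
                    del_start = p
                del_end = p
            else:
                flush_deletion()
                if s == "N" or r == "N":
                    continue
                if s != r:
                    variants.add(Variant(SNV, p, p, r, s))
    flush_deletion()
    flush_insertion()
    return frozenset(variants)


def _check_overlap(variants: Iterable[Variant], ref_len: int) -> list[Variant]:
    ordered = sorted(variants, key=lambda v: (v.start, v.end, v.kind))
    occupied_end = 0
    ins_anchors: set[int] = set()
    for v in ordered:
        if v.end > ref_len or v.start < 1:
            raise BoundsError(f"{v.label} outside reference of length {ref_len}")
        if v.kind == INSERTION:
            if v.start in ins_anchors:
                raise ConsistencyError(f"two insertions anchored at {v.start}")
            ins_anchors.add(v.start)
        else:
            if v.start <= occupied_end:
                raise ConsistencyError(f"overlapping variants at {v.label}")
            occupied_end = v.end
    return ordered


def apply_variants(reference_seq: str, variants: Iterable[Variant]) -> str:
    """Edit the reference according to ``variants`` (the extraction inverse).

    Variants must be non-overlapping in reference coordinates.  The result
    is the sample sequence with gaps removed.
    """
    ordered = _check_overlap(variants, len(reference_seq))
    cells = list(reference_seq)
    inserts: dict[int, str] = {}
    for v in ordered:
        if v.kind == SNV:
            if cells[v.start - 1] != v.ref_allele:
                raise ConsistencyError(
                    f"{v.label}: reference has {cells[v.start - 1]!r} at {v.start}")
            cells[v.start - 1] = v.alt_allele
        elif v.kind == DELETION:
            for p in range(v.start, v.end + 1):
                cells[p - 1] = ""
        else:
            inserts[v.start] = v.alt_allele
    out: list[str] = []
    for p, cell in enumerate(cells, start=1):
        out.append(cell)
        if p in inserts:
            out.append(inserts[p])
    return "".join(out)


# ---------------------------------------------------------------------------
# Haplotype collapsing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Haplotype:
    haplotype_id: str
    variants: frozenset[Variant]
    sequenced_members: tuple[str, ...]
    imputed_members: tuple[str, ...]

    @property
    def members(self) -> tuple[str, ...]:
        return self.sequenced_members + self.imputed_members

    @property
    def n_members(self) -> int:
        return len(self.sequenced_members) + len(self.imputed_members)


@dataclass
class HaplotypeTable:
    """Unique variant sets with sequenced and matrilineally imputed members."""

    haplotypes: list[Haplotype]

    def __post_init__(self) -> None:
        seen_sets = set()
        seen_members: set[str] = set()
        for h in self.haplotypes:
            if h.variants in seen_sets:
                raise ConsistencyError("duplicate variant set in haplotype table")
            seen_sets.add(h.variants)
            for m in h.members:
                if m in seen_members:
                    raise ConsistencyError(f"individual {m!r} in two haplotypes")
                seen_members.add(m)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def n_sequenced(self) -> int:
        return sum(len(h.sequenced_members) for h in self.haplotypes)

    @property
    def n_total(self) -> int:
        return sum(h.n_members for h in self.haplotypes)

    def membership(self) -> dict[str, str]:
        """individual id -> haplotype id."""
        return {m: h.haplotype_id for h in self.haplotypes for m in h.members}

    def variants_of(self, haplotype_id: str) -> frozenset[Variant]:
        for h in self.haplotypes:
            if h.haplotype_id == haplotype_id:
                return h.variants
        raise LookupError_(f"haplotype {haplotype_id!r} not in table")

    def counts(self) -> dict[str, int]:
        return {h.haplotype_id: h.n_members for h in self.haplotypes}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "haplotype_id": h.haplotype_id,
                "n_members": h.n_members,
                "n_sequenced": len(h.sequenced_members),
                "variants": ";".join(sorted(v.label for v in h.variants)),
                "sequenced_members": ";".join(h.sequenced_members),
                "imputed_members": ";".join(h.imputed_members),
            }
            for h in self.haplotypes
        ]
        return pd.DataFrame(rows)


def collapse_haplotypes(
    variant_sets: Mapping[str, frozenset[Variant]],
    matrilineage_map: Mapping[str, str] | None = None,
) -> HaplotypeTable:
    """Group identical variant sets and impute matrilineal relatives.

    ``matrilineage_map`` maps every cohort individual to its sequenced
    representative; representatives map to themselves.  Individuals absent
    from the map are taken to be their own representative.
    """
    matrilineage_map = dict(matrilineage_map or {})
    for ind in variant_sets:
        matrilineage_map.setdefault(ind, ind)
    groups: dict[frozenset[Variant], list[str]] = {}
    for ind in sorted(variant_sets):
        groups.setdefault(variant_sets[ind], []).append(ind)

    rep_to_set = dict(variant_sets)
    imputed: dict[frozenset[Variant], list[str]] = {vs: [] for vs in groups}
    for ind in sorted(matrilineage_map):
        rep = matrilineage_map[ind]
        if ind in variant_sets:
            if rep != ind and rep in rep_to_set and rep_to_set[rep] != variant_sets[ind]:
                raise ConsistencyError(
                    f"{ind!r} is sequenced but mapped to representative {rep!r} "
                    "with a different variant set")
            continue
        if rep not in rep_to_set:
            raise LookupError_(f"representative {rep!r} of {ind!r} has no sequence")
        imputed[rep_to_set[rep]].append(ind)

    # deterministic ids: by descending total membership, then variant labels
    def sort_key(vs: frozenset[Variant]) -> tuple:
        total = len(groups[vs]) + len(imputed[vs])
        return (-total, tuple(sorted(v.label for v in vs)))

    ordered = sorted(groups, key=sort_key)
    width = max(3, len(str(len(ordered))))
    haplotypes = [
        Haplotype(
            haplotype_id=f"H{idx:0{width}d}",
            variants=vs,
            sequenced_members=tuple(groups[vs]),
            imputed_members=tuple(sorted(imputed[vs])),
        )
        for idx, vs in enumerate(ordered, start=1)
    ]
    return HaplotypeTable(haplotypes)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_matrilineage_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"individual", "representative"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(required)}")
    return dict(zip(df["individual"], df["representative"]))


def write_variant_table(
    variant_sets: Mapping[str, frozenset[Variant]], path: str | Path
) -> None:
    rows = [
        {
            "individual": ind,
            "label": v.label,
            "kind": v.kind,
            "start": v.start,
            "end": v.end,
            "ref": v.ref_allele,
            "alt": v.alt_allele,
        }
        for ind in sorted(variant_sets)
        for v in sorted(variant_sets[ind])
    ]
    pd.DataFrame(rows, columns=["individual", "label", "kind", "start",
                                "end", "ref", "alt"]).to_csv(
        path, sep="\t", index=False)


def write_haplotype_table(table: HaplotypeTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)
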