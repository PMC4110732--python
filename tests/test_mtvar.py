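"""Variant extraction, naming, application, and haplotype collapsing."""

import numpy as np
import pytest

from mitotreescan.errors import (
    BoundsError,
    ConsistencyError,
    FormatError,
    LookupError_,
)
from mitotreescan.mtvar import (
    DELETION,
    INSERTION,
    SNV,
    AlignmentMatrix,
    Variant,
    _build_coordinate_map,
    apply_variants,
    collapse_haplotypes,
    extract_variants,
    normalize_variant,
    parse_variant_label,
    read_alignment,
    write_alignment,
)
from mitotreescan.synthdata import SimulationConfig, build_alignment, simulate_cohort


def make_alignment(rows: dict[str, str], reference_id: str = "REF") -> AlignmentMatrix:
    ids = list(rows)
    col_pos, col_ins = _build_coordinate_map(rows[reference_id])
    return AlignmentMatrix(ids, [rows[i] for i in ids], reference_id,
                           col_pos, col_ins)


# ---------------------------------------------------------------------------
# coordinate map
# ---------------------------------------------------------------------------

def test_gapless_reference_gives_identity_coordinate_map(tmp_path):
    seqs = {"REF": "ACGTACGTACGTACGTACGT",
            "S1": "ACGTACGTACGTACGTACGA",
            "S2": "ACGTACGTACGTACGTACGT"}
    path = tmp_path / "aln.fasta"
    path.write_text("".join(f">{k}\n{v}\n" for k, v in seqs.items()))
    aln = read_alignment(path, "REF")
    assert aln.col_ref_pos == tuple(range(1, 21))
    assert not any(aln.col_is_insertion)
    assert aln.reference_length == 20


def test_reference_gap_column_maps_to_insertion_slot():
    aln = make_alignment({"REF": "AC-GT", "S1": "ACTGT"})
    assert aln.col_ref_pos == (1, 2, 2, 3, 4)
    assert aln.col_is_insertion == (False, False, True, False, False)


def test_read_alignment_errors(tmp_path):
    p = tmp_path / "bad.fasta"
    p.write_text(">A\nACGT\n>B\nACG\n")
    with pytest.raises(FormatError):
        read_alignment(p, "A")
    p.write_text(">A\nACGT\n>B\nACGG\n")
    with pytest.raises(LookupError_):
        read_alignment(p, "MISSING")
    p.write_text("")
    with pytest.raises(FormatError):
        read_alignment(p, "A")


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def reference_16k() -> str:
    # deterministic non-homopolymeric reference long enough for mito coordinates
    return ("ACGT" * 4200)[:16569]


def test_identical_sample_yields_no_variants():
    ref = "ACGTACGTAC"
    aln = make_alignment({"REF": ref, "S": ref})
    assert extract_variants(aln, "S") == frozenset()


def test_snv_at_position_263_named_in_m_notation():
    ref = reference_16k()
    assert ref[262] == "G"  # position 263
    sample = ref[:262] + "A" + ref[263:]
    aln = make_alignment({"REF": ref, "S": sample})
    (v,) = extract_variants(aln, "S")
    assert (v.kind, v.start, v.ref_allele, v.alt_allele) == (SNV, 263, "G", "A")
    assert v.label == "m.263G>A"


def test_nine_base_deletion_named_as_range():
    ref = reference_16k()
    sample = ref[:8280] + "-" * 9 + ref[8289:]
    aln = make_alignment({"REF": ref, "S": sample})
    (v,) = extract_variants(aln, "S")
    assert v.kind == DELETION and (v.start, v.end) == (8281, 8289)
    assert v.label == "m.del8281-8289"


def test_insertion_run_collapses_to_one_variant():
    aln = make_alignment({"REF": "ACG--TAC", "S": "ACGGGTAC"})
    (v,) = extract_variants(aln, "S")
    assert v.kind == INSERTION and v.alt_allele == "GG"
    # left-normalized into the G at position 3
    assert v.label == "m.2insGG"


def test_n_and_gap_only_columns_are_missing_not_variants():
    aln = make_alignment({"REF": "ACGTACGT", "S": "ANGT-CGT"})
    variants = extract_variants(aln, "S")
    # N at pos 2 -> nothing; '-' at pos 5 -> deletion (only real variant)
    assert {v.label for v in variants} == {"m.del5"}
    with pytest.raises(LookupError_):
        extract_variants(aln, "NOBODY")


def test_deletion_left_aligned_in_homopolymer():
    #         123456789
    ref = "ACTTTTGCA"
    sample = "ACTT--GCA"  # aligner placed gap right; canonical form is leftmost
    aln = make_alignment({"REF": ref, "S": sample})
    (v,) = extract_variants(aln, "S")
    assert (v.start, v.end) == (3, 4)
    assert v.label == "m.del3-4"
    direct = normalize_variant(Variant(DELETION, 5, 6, "TT", ""), ref)
    assert direct == v


# ---------------------------------------------------------------------------
# application + round trip
# ---------------------------------------------------------------------------

def test_apply_variants_identity_and_substitution():
    ref = reference_16k()
    assert apply_variants(ref, frozenset()) == ref
    v = Variant(SNV, 263, 263, "G", "A")
    out = apply_variants(ref, {v})
    assert len(out) == len(ref) and out[262] == "A"


def test_apply_variants_rejects_overlap_and_out_of_range():
    ref = "ACGTACGTAC"
    with pytest.raises(ConsistencyError):
        apply_variants(ref, {Variant(DELETION, 2, 4, "CGT", ""),
                             Variant(SNV, 3, 3, "G", "A")})
    with pytest.raises(BoundsError):
        apply_variants(ref, {Variant(SNV, 99, 99, "A", "G")})
    with pytest.raises(ConsistencyError):
        apply_variants(ref, {Variant(SNV, 1, 1, "C", "G")})  # wrong ref base


def test_extract_apply_round_trip_on_simulated_haplotypes():
    """extract_variants(aligned sample) applied to the reference reproduces
    the ungapped sample row, and re-extraction returns the same set."""
    cohort = simulate_cohort(SimulationConfig(
        seed=7, n_individuals=60, n_matrilineages=30))
    aln = build_alignment(cohort.truth)
    ref = aln.reference_sequence
    for sid in aln.sequence_ids:
        if sid == aln.reference_id:
            continue
        variants = extract_variants(aln, sid)
        rebuilt = apply_variants(ref, variants)
        assert rebuilt == aln.row(sid).replace("-", "")
    # and the extracted sets match the generator's truth exactly
    truth = cohort.truth
    for sid in aln.sequence_ids:
        if sid == aln.reference_id:
            continue
        expected = truth.haplotype_of_matrilineage[truth.matrilineage_of[sid]]
        assert extract_variants(aln, sid) == expected


def test_alignment_write_read_round_trip(tmp_path):
    cohort = simulate_cohort(SimulationConfig(
        seed=11, n_individuals=30, n_matrilineages=30))
    aln = build_alignment(cohort.truth)
    path = tmp_path / "out.fasta"
    write_alignment(aln, path)
    back = read_alignment(path, aln.reference_id)
    assert back.sequence_ids == aln.sequence_ids
    assert back.rows == aln.rows
    assert back.col_ref_pos == aln.col_ref_pos


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st

_REF = reference_16k()


@st.composite
def arbitrary_variant(draw):
    kind = draw(st.sampled_from([SNV, DELETION, INSERTION]))
    if kind == SNV:
        pos = draw(st.integers(1, len(_REF)))
        ref = _REF[pos - 1]
        alt = draw(st.sampled_from([b for b in "ACGT" if b != ref]))
        return Variant(SNV, pos, pos, ref, alt)
    if kind == DELETION:
        start = draw(st.integers(1, len(_REF) - 9))
        end = start + draw(st.integers(0, 8))
        return Variant(DELETION, start, end, _REF[start - 1 : end], "")
    pos = draw(st.integers(1, len(_REF)))
    alt = draw(st.text(alphabet="ACGT", min_size=1, max_size=6))
    return Variant(INSERTION, pos, pos, "", alt)


@settings(derandomize=True, max_examples=200, database=None)
@given(arbitrary_variant())
def test_label_round_trip_and_normalization_idempotent(v):
    """Any valid variant's label parses back losslessly, and left
    normalization is idempotent."""
    assert parse_variant_label(v.label, _REF) == v
    norm = normalize_variant(v, _REF)
    assert normalize_variant(norm, _REF) == norm
    # normalization preserves the edit itself
    assert apply_variants(_REF, {v}) == apply_variants(_REF, {norm})


def test_labels_parse_back_losslessly():
    ref = reference_16k()
    cases = [
        Variant(SNV, 263, 263, "G", "A"),
        Variant(DELETION, 8281, 8289, ref[8280:8289], ""),
        Variant(DELETION, 5, 5, ref[4], ""),
        Variant(INSERTION, 303, 303, "", "CCT"),
    ]
    for v in cases:
        assert parse_variant_label(v.label, ref) == v
    with pytest.raises(FormatError):
        parse_variant_label("g.263A>G")


# ---------------------------------------------------------------------------
# collapsing
# ---------------------------------------------------------------------------

V1 = Variant(SNV, 10, 10, "A", "G")
V2 = Variant(SNV, 20, 20, "C", "T")


def test_identical_sets_collapse_to_single_haplotype():
    sets = {f"I{k}": frozenset({V1}) for k in range(5)}
    table = collapse_haplotypes(sets)
    assert table.n_haplotypes == 1
    assert table.n_sequenced == table.n_total == 5


def test_matrilineage_counts_add_imputed_members():
    sets = {"R1": frozenset({V1}), "R2": frozenset({V2})}
    lineage = {"R1": "R1", "A": "R1", "B": "R1",
               "R2": "R2", "C": "R2", "D": "R2", "E": "R2"}
    table = collapse_haplotypes(sets, lineage)
    assert table.n_haplotypes == 2
    assert sorted(h.n_members for h in table.haplotypes) == [3, 4]
    assert table.n_total == 7 and table.n_sequenced == 2


def test_collapse_is_input_order_invariant_and_conserves_members():
    rng = np.random.default_rng(0)
    inds = [f"I{k}" for k in range(20)]
    pool = [frozenset(), frozenset({V1}), frozenset({V1, V2})]
    sets = {i: pool[rng.integers(3)] for i in inds}
    t1 = collapse_haplotypes(sets)
    shuffled = {i: sets[i] for i in reversed(inds)}
    t2 = collapse_haplotypes(shuffled)
    assert [h.variants for h in t1.haplotypes] == [h.variants for h in t2.haplotypes]
    assert [h.members for h in t1.haplotypes] == [h.members for h in t2.haplotypes]
    assert sorted(t1.membership()) == sorted(inds)


def test_collapse_error_cases():
    with pytest.raises(LookupError_):
        collapse_haplotypes({"R1": frozenset({V1})}, {"X": "NO_SUCH_REP"})
    with pytest.raises(ConsistencyError):
        collapse_haplotypes(
            {"R1": frozenset({V1}), "R2": frozenset({V2})},
            {"R1": "R2", "R2": "R2"})  # sequenced individual mapped elsewhere


def test_collapse_matches_generator_truth(small_cohort):
    table = small_cohort.haplotype_table()
    truth = small_cohort.truth
    member_sets = {
        frozenset(h.members): h.variants for h in table.haplotypes
    }
    by_hap: dict[frozenset, set[str]] = {}
    for ind, m in truth.matrilineage_of.items():
        by_hap.setdefault(truth.haplotype_of_matrilineage[m], set()).add(ind)
    assert {frozenset(v): k for k, v in by_hap.items()} == member_sets
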