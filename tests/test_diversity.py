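"""Sequence types, pairwise distances, Nei-Li pi (oracle equivalence),
and hierarchical level summaries with the barcoding-gap verdict."""

from __future__ import annotations

import random
from itertools import combinations

import pytest

from clonepoly.diversity import (
    enumerate_types,
    nucleotide_diversity,
    pairwise_distance,
    summarize_levels,
)
from clonepoly.errors import InputError
from clonepoly.util import round_half_even

from conftest import build_aln, clone_set, merge_sets


def pi_oracle(rows: list[str]) -> float | None:
    """Independent brute-force mean pairwise difference per valid site
    (complete deletion), written against the definition, not the code."""
    L = len(rows[0])
    valid = [i for i in range(L) if all(r[i] in "ACGT" for r in rows)]
    if not valid:
        return None
    pairs = list(combinations(rows, 2))
    total = sum(sum(1 for i in valid if a[i] != b[i]) for a, b in pairs)
    return total / len(pairs) / len(valid)


def mutate(base: str, rng: random.Random, k: int, alphabet="ACGT") -> str:
    s = list(base)
    for pos in rng.sample(range(len(base)), k):
        s[pos] = rng.choice(alphabet)
    return "".join(s)


# ---------------------------------------------------------------- types


def test_enumerate_types_orders_by_count_then_occurrence():
    s1, s2 = "ACGT", "ACGA"
    rows, meta = clone_set("isoA", "sp1", [s2] * 5 + [s1] * 10)
    aln = build_aln(rows, meta)
    types = enumerate_types(aln, list(aln.clone_ids))
    assert [(t.type_id, t.count) for t in types] == [("T1", 10), ("T2", 5)]
    assert types[0].residues == s1
    assert sum(t.count for t in types) == 15
    assert sum(t.frequency for t in types) == pytest.approx(1.0)


def test_all_identical_is_one_type():
    rows, meta = clone_set("isoA", "sp1", ["ACGT"] * 4)
    aln = build_aln(rows, meta)
    types = enumerate_types(aln, list(aln.clone_ids))
    assert len(types) == 1 and types[0].frequency == 1.0


# ------------------------------------------------------------ distances


def test_divergence_of_8_differences_over_591_columns():
    rng = random.Random(0)
    a = "".join(rng.choice("ACGT") for _ in range(591))
    b = mutate(a, rng, 0)
    b = list(a)
    for pos in rng.sample(range(591), 8):
        b[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[b[pos]]
    d = pairwise_distance(a, "".join(b))
    assert d.differing_columns == 8
    assert round_half_even(d.divergence_pct, 2) == 1.35


def test_similarity_of_12_differences_over_563_columns():
    rng = random.Random(1)
    a = "".join(rng.choice("ACGT") for _ in range(563))
    b = list(a)
    for pos in rng.sample(range(563), 12):
        b[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[pos]]
    d = pairwise_distance(a, "".join(b))
    assert round_half_even(d.similarity_pct, 2) == 97.87


def test_distance_gap_and_N_conventions():
    d = pairwise_distance("AC-TN-", "ACGTA-")
    # col3 gap-vs-G differs; col5 N excluded; col6 gap-vs-gap matches
    assert d.compared_columns == 5
    assert d.differing_columns == 1
    assert pairwise_distance("ACGT", "ACGT").similarity_pct == 100.0
    with pytest.raises(InputError):
        pairwise_distance("ACG", "ACGT")


# ------------------------------------------------------------------- pi


def test_pi_trivial_cases():
    assert nucleotide_diversity(["ACGT", "ACGT"]) == 0.0
    rows = ["A" * 100, "A" * 50 + "G" + "A" * 49]
    assert nucleotide_diversity(rows) == pytest.approx(0.01)


def test_pi_undefined_when_no_valid_column():
    assert nucleotide_diversity(["A-", "-A"]) is None


@pytest.mark.parametrize("trial", range(100))
def test_pi_equals_brute_force_oracle_on_random_groups(trial):
    rng = random.Random(trial)
    n = rng.randint(2, 10)
    L = rng.randint(20, 200)
    base = "".join(rng.choice("ACGT") for _ in range(L))
    rows = [mutate(base, rng, rng.randint(0, L // 5), "ACGT-N") for _ in range(n)]
    expected = pi_oracle(rows)
    got = nucleotide_diversity(rows)
    if expected is None:
        assert got is None
    else:
        assert got == pytest.approx(expected, abs=1e-12)


def test_haplotype_estimator_reduces_to_mean_pairwise():
    """The haplotype-frequency form n/(n-1) * sum x_i x_j pi_ij equals the
    mean pairwise difference per site: 2/(n(n-1)) * sum_{i<j} pi_ij is
    exactly the average over unordered clone pairs."""
    rows = ["ACGT"] * 3 + ["ACGA"] * 1
    mean = nucleotide_diversity(rows)
    hap = nucleotide_diversity(rows, estimator="haplotype")
    assert hap == pytest.approx(mean)


# ------------------------------------------------------------ summaries


def _three_species(intra_diffs: int, inter_diffs: int, L: int = 581):
    """Two isolates per species; within species sp1 one isolate differs by
    `intra_diffs` columns; species differ by `inter_diffs` columns."""
    rng = random.Random(42)
    base = "".join(rng.choice("ACGT") for _ in range(L))
    sp1_b = mutate(base, rng, 0)
    sets = []
    v = list(base)
    cols = rng.sample(range(L), intra_diffs + 2 * inter_diffs)
    intra_cols, inter1, inter2 = (
        cols[:intra_diffs],
        cols[intra_diffs : intra_diffs + inter_diffs],
        cols[intra_diffs + inter_diffs :],
    )
    for pos in intra_cols:
        v[pos] = {"A": "G", "G": "A", "C": "T", "T": "C"}[v[pos]]
    sp1_variant = "".join(v)
    sets.append(clone_set("sp1_i1", "sp1", [base] * 3))
    sets.append(clone_set("sp1_i2", "sp1", [sp1_variant] * 3))
    r2 = list(base)
    for pos in inter1:
        r2[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[r2[pos]]
    root2 = "".join(r2)
    sets.append(clone_set("sp2_i1", "sp2", [root2] * 3))
    sets.append(clone_set("sp2_i2", "sp2", [root2] * 3))
    r3 = list(base)
    for pos in inter2:
        r3[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[r3[pos]]
    root3 = "".join(r3)
    sets.append(clone_set("sp3_i1", "sp3", [root3] * 3))
    sets.append(clone_set("sp3_i2", "sp3", [root3] * 3))
    return merge_sets(*sets)


def test_monomorphic_isolates_show_full_similarity_and_zero_pi():
    aln = _three_species(intra_diffs=0, inter_diffs=5)
    summaries, _ = summarize_levels(aln)
    intra = [s for s in summaries if s.level == "intra-isolate"]
    assert len(intra) == 6
    for s in intra:
        assert s.min_similarity_pct == 100.0
        assert s.pi == 0.0
        assert s.n_polymorphic_sites == 0
        assert s.max_divergence_pct == 0.0


def test_barcode_gap_holds_for_its_like_structure():
    # max intraspecific 8/581 = 1.38% < min interspecific 17/581 = 2.93%
    aln = _three_species(intra_diffs=8, inter_diffs=17)
    summaries, verdict = summarize_levels(aln)
    assert verdict.gap_holds is True
    assert verdict.max_intraspecific_pct == pytest.approx(8 / 581 * 100, abs=0.01)
    assert verdict.min_interspecific_pct == pytest.approx(17 / 581 * 100, abs=0.01)


def test_barcode_gap_fails_when_intraspecific_exceeds_interspecific():
    # max intraspecific 28/581 = 4.82% > min interspecific 18/581 = 3.10%
    aln = _three_species(intra_diffs=28, inter_diffs=18)
    _, verdict = summarize_levels(aln)
    assert verdict.gap_holds is False


def test_summary_complement_identity_and_monotonicity():
    aln = _three_species(intra_diffs=8, inter_diffs=17)
    summaries, _ = summarize_levels(aln)
    for s in summaries:
        if s.max_divergence_pct is not None:
            assert s.max_divergence_pct + s.min_similarity_pct == pytest.approx(
                100.0, abs=1e-9
            )
    # nested groups: isolate max divergence <= its species' max divergence
    by = {(s.level, s.group): s for s in summaries}
    for (level, group), s in by.items():
        if level != "intra-isolate":
            continue
        species = group.split("_")[0]
        sp_row = by[("intraspecific", species)]
        assert s.max_divergence_pct <= sp_row.max_divergence_pct + 1e-9


def test_single_clone_species_emits_row_with_missing_fields():
    sets = [
        clone_set("sp1_i1", "sp1", ["ACGTACGT"] * 3),
        clone_set("sp2_i1", "sp2", ["ACGTACGA"]),
    ]
    rows, meta = sets[1]
    aln = merge_sets(*sets)
    summaries, verdict = summarize_levels(aln)
    solo = [s for s in summaries if s.group == "sp2" and s.level == "intraspecific"]
    assert solo[0].n_clones == 1
    assert solo[0].max_divergence_pct is None and solo[0].pi is None
    # interspecific row still computable from cross pairs
    inter = [s for s in summaries if s.level == "interspecific"]
    assert inter[0].min_divergence_pct == pytest.approx(1 / 8 * 100, abs=0.01)
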