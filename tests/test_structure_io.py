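"""Structure parsing, unobserved-region extraction, and rigid-body geometry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metabolon.structure_io import (
    StructureModel,
    StructureParseError,
    chain_rotation_displacement,
    extract_missing_regions,
    flank_distance,
    parse_structure,
    superpose,
    survey_structure,
    write_mmcif,
)
from metabolon.synthetic import gen_structure, gen_structure_model

from .conftest import MINIMAL_CIF, rotation_about_axis, rotation_about_z


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def test_parse_reads_atoms_and_unobserved_records(minimal_model):
    assert len(minimal_model.atoms) == 2
    assert len(minimal_model.unobserved) == 1
    u = minimal_model.unobserved[0]
    assert (u.chain_id, u.residue_index, u.residue_name) == ("A", 2, "SER")


def test_parse_without_unobserved_loop_yields_empty_list(no_gap_model):
    assert no_gap_model.unobserved == []
    assert len(no_gap_model.atoms) == 3


def test_parse_rejects_document_without_atom_site():
    with pytest.raises(StructureParseError):
        parse_structure("data_empty\n_cell.length_a 10.0\n")


def test_parse_rejects_malformed_loop():
    row = "ATOM 1 C CA . ALA A 1 0.000 0.000 0.000 1.00 0.00 1 ALA A 1\n"
    with pytest.raises(StructureParseError, match="atom_site"):
        parse_structure(MINIMAL_CIF.replace(row, "ATOM 1 C CA\n"))
    with pytest.raises(StructureParseError, match="non-finite"):
        parse_structure(MINIMAL_CIF.replace("ATOM 1 C CA . ALA A 1 0.000", "ATOM 1 C CA . ALA A 1 oops"))


def test_generated_structure_round_trips_to_ledger_boundaries(seed7_structure):
    text, ledger = seed7_structure
    model = parse_structure(text)
    regions = extract_missing_regions(model)
    truth = ledger["regions"]
    assert len(regions) == len(truth)
    for reg, t in zip(regions, truth):
        assert (reg.start_index, reg.end_index) == (t["start"], t["end"])
        assert (reg.left_flank, reg.right_flank) == (t["left_flank"], t["right_flank"])


def test_mmcif_write_parse_is_lossless_for_coordinates(walk_model_seed11):
    reparsed = parse_structure(write_mmcif(walk_model_seed11))
    _, c0 = walk_model_seed11.ca_trace("A")
    _, c1 = reparsed.ca_trace("A")
    np.testing.assert_allclose(c0, c1, atol=1e-9)


# ---------------------------------------------------------------------------
# region extraction
# ---------------------------------------------------------------------------


def _model_with_gaps(observed, unobserved, chain="A"):
    from metabolon.structure_io import AtomSite, UnobservedResidue

    atoms = [
        AtomSite(chain, n, "ALA", "CA", (float(n), 0.0, 0.0), element="C")
        for n in observed
    ]
    unobs = [UnobservedResidue(chain, n, "ALA") for n in unobserved]
    return StructureModel("toy", atoms, unobs)


def test_consecutive_unobserved_residues_merge_into_one_region():
    model = _model_with_gaps(observed=[9, 15], unobserved=[10, 11, 12, 13, 14])
    regions = extract_missing_regions(model)
    assert len(regions) == 1
    r = regions[0]
    assert (r.start_index, r.end_index, r.length) == (10, 14, 5)
    assert (r.left_flank, r.right_flank) == (9, 15)


def test_terminal_run_keeps_absent_flank_and_is_ineligible():
    model = _model_with_gaps(observed=[5, 6], unobserved=[1, 2, 3, 4])
    regions = extract_missing_regions(model)
    assert len(regions) == 1
    r = regions[0]
    assert r.left_flank is None and r.right_flank == 5
    rec = flank_distance(model, r)
    assert not rec.eligible and rec.distance is None


def test_gaps_in_different_chains_stay_separate():
    from metabolon.structure_io import AtomSite, UnobservedResidue

    atoms = [
        AtomSite("A", 1, "ALA", "CA", (0.0, 0.0, 0.0), element="C"),
        AtomSite("A", 3, "ALA", "CA", (1.0, 0.0, 0.0), element="C"),
        AtomSite("B", 1, "ALA", "CA", (2.0, 0.0, 0.0), element="C"),
        AtomSite("B", 3, "ALA", "CA", (3.0, 0.0, 0.0), element="C"),
    ]
    unobs = [UnobservedResidue("A", 2, "ALA"), UnobservedResidue("B", 2, "ALA")]
    regions = extract_missing_regions(StructureModel("two", atoms, unobs))
    assert [(r.chain_id, r.start_index) for r in regions] == [("A", 2), ("B", 2)]


def test_fully_observed_structure_has_no_regions(no_gap_model):
    assert extract_missing_regions(no_gap_model) == []


def test_region_lengths_partition_unobserved_count(seed7_structure):
    text, _ = seed7_structure
    model = parse_structure(text)
    regions = extract_missing_regions(model)
    assert sum(r.length for r in regions) == len(model.unobserved)


# ---------------------------------------------------------------------------
# flank distances
# ---------------------------------------------------------------------------


def test_flank_distance_is_three_four_five(minimal_model):
    (rec,) = survey_structure(minimal_model)
    assert rec.eligible
    assert rec.distance == pytest.approx(5.0, abs=1e-12)


def test_coincident_flanks_give_zero_distance():
    from metabolon.structure_io import AtomSite, UnobservedResidue

    atoms = [
        AtomSite("A", 1, "ALA", "CA", (1.0, 2.0, 3.0), element="C"),
        AtomSite("A", 3, "ALA", "CA", (1.0, 2.0, 3.0), element="C"),
    ]
    model = StructureModel("z", atoms, [UnobservedResidue("A", 2, "ALA")])
    (rec,) = survey_structure(model)
    assert rec.distance == pytest.approx(0.0, abs=1e-12)


def test_flank_distances_match_generator_truth_exactly(seed7_structure):
    text, ledger = seed7_structure
    model = parse_structure(text)
    recs = survey_structure(model)
    truth = {(t["start"], t["end"]): t["distance"] for t in ledger["regions"]}
    for rec in recs:
        assert rec.eligible
        assert rec.distance == pytest.approx(
            truth[(rec.region.start_index, rec.region.end_index)], abs=1e-9
        )


def test_flank_distance_invariant_under_rigid_transform(seed7_structure):
    text, _ = seed7_structure
    model = parse_structure(text)
    R = rotation_about_axis([1.0, 2.0, 0.5], 37.0)
    moved = model.transformed(R, np.array([5.0, -3.0, 11.0]))
    for a, b in zip(survey_structure(model), survey_structure(moved)):
        assert a.distance == pytest.approx(b.distance, abs=1e-6)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------


def _quaternion_oracle(P, Q):
    """Horn's closed-form quaternion solution: optimal RMSD of Q onto P."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    M = Q0.T @ P0
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = np.linalg.eigvalsh(K)[-1]
    e2 = (P0**2).sum() + (Q0**2).sum() - 2.0 * lam
    return np.sqrt(max(e2, 0.0) / len(P))


def test_superpose_identity_on_identical_sets():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(10, 3))
    sup = superpose(pts, pts)
    np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-10)
    assert sup.rmsd == pytest.approx(0.0, abs=1e-10)
    assert sup.rotation_angle == pytest.approx(0.0, abs=1e-6)


def test_superpose_recovers_constructed_rotation_angle():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(20, 3)) * 10.0
    R = rotation_about_z(10.0)
    rotated = pts @ R.T + np.array([1.0, 2.0, 3.0])
    sup = superpose(rotated, pts)
    assert sup.rotation_angle == pytest.approx(10.0, abs=1e-6)
    assert sup.rmsd == pytest.approx(0.0, abs=1e-8)


def test_superpose_rmsd_matches_quaternion_oracle():
    rng = np.random.default_rng(2)
    P = rng.normal(size=(20, 3)) * 5.0
    Q = P + rng.normal(scale=0.1, size=P.shape)
    sup = superpose(P, Q)
    assert sup.rmsd == pytest.approx(_quaternion_oracle(P, Q), abs=1e-6)


def test_superpose_rejects_degenerate_input():
    line = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
    with pytest.raises(ValueError):
        superpose(line, line)
    with pytest.raises(ValueError):
        superpose(line[:2], line[:2])


@settings(max_examples=20, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_superpose_rmsd_invariant_under_rigid_premotion(seed):
    rng = np.random.default_rng(seed)
    P = rng.normal(size=(12, 3)) * 4.0
    Q = P + rng.normal(scale=0.2, size=P.shape)
    R = rotation_about_axis(rng.normal(size=3) + 0.1, float(rng.uniform(0, 180)))
    t = rng.normal(size=3) * 10.0
    assert superpose(P, Q @ R.T + t).rmsd == pytest.approx(superpose(P, Q).rmsd, abs=1e-8)


# ---------------------------------------------------------------------------
# trimer rotational displacement
# ---------------------------------------------------------------------------


def _toy_trimer(seed=3):
    """Two-chain 'trimer' slice: chain B is chain A rotated about z."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=(15, 3)) * 8.0
    from metabolon.structure_io import AtomSite

    def chain_atoms(cid, coords):
        return [
            AtomSite(cid, i + 1, "ALA", "CA", tuple(c), element="C")
            for i, c in enumerate(coords)
        ]

    R0 = rotation_about_z(40.0)
    b = a @ R0.T + np.array([12.0, 0.0, 0.0])
    return StructureModel("trimer", chain_atoms("A", a) + chain_atoms("B", b)), a, b


def test_self_displacement_is_zero():
    model, _, _ = _toy_trimer()
    assert chain_rotation_displacement(model, model, "A", "B") == pytest.approx(0.0, abs=1e-9)


def test_constructed_seven_degree_displacement_recovered():
    from metabolon.structure_io import AtomSite

    model, a, b = _toy_trimer()
    extra = rotation_about_z(7.0)  # same axis as the A->B rotation
    b2 = b @ extra.T
    atoms = [at for at in model.atoms if at.chain_id == "A"] + [
        AtomSite("B", i + 1, "ALA", "CA", tuple(c), element="C") for i, c in enumerate(b2)
    ]
    model_b = StructureModel("trimer_b", atoms)
    disp = chain_rotation_displacement(model, model_b, "A", "B")
    assert disp == pytest.approx(7.0, abs=1e-6)
    assert chain_rotation_displacement(model_b, model, "A", "B") == pytest.approx(-7.0, abs=1e-6)


@settings(max_examples=15, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_displacement_is_antisymmetric_under_rigid_perturbations(seed):
    rng = np.random.default_rng(seed)
    model, a, b = _toy_trimer(seed=4)
    extra = rotation_about_z(float(rng.uniform(-20, 20)))
    from metabolon.structure_io import AtomSite

    atoms = [at for at in model.atoms if at.chain_id == "A"] + [
        AtomSite("B", i + 1, "ALA", "CA", tuple(c), element="C")
        for i, c in enumerate(b @ extra.T)
    ]
    model_b = StructureModel("tb", atoms)
    # global rigid motion of model_b must not matter
    R = rotation_about_axis(rng.normal(size=3) + 0.05, float(rng.uniform(0, 90)))
    model_b = model_b.transformed(R, rng.normal(size=3) * 5.0)
    d_ab = chain_rotation_displacement(model, model_b, "A", "B")
    d_ba = chain_rotation_displacement(model_b, model, "A", "B")
    assert d_ab == pytest.approx(-d_ba, abs=1e-6)


def test_displacement_errors_on_unmatched_residues():
    model, _, _ = _toy_trimer()
    truncated = StructureModel(
        "short", [a for a in model.atoms if not (a.chain_id == "B" and a.residue_index > 10)]
    )
    # correspondence is within-structure: A (15 res) vs truncated B (10 res)
    with pytest.raises(ValueError, match="unpaired"):
        chain_rotation_displacement(truncated, truncated, "A", "B")
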