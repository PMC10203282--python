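"""Crosslink ledger parsing, mapping, satisfaction, and distance distributions."""

import numpy as np
import pytest
from scipy import stats

from metabolon.structure_io import AtomSite, StructureModel
from metabolon.synthetic import gen_crosslinks, gen_structure_model
from metabolon.xlink import (
    fit_distance_distribution,
    ledger_frame,
    link_summary,
    load_ledger,
    map_links,
    satisfaction,
    satisfaction_profile,
)

TOY_LEDGER = """ProteinA\tResA\tProteinB\tResB\tReplicate
E1o\t10\tE1o\t55\tr1
E1o\t55\tE1o\t10\tr2
E1o\t12\tE2o\t7\tr1
"""


# ---------------------------------------------------------------------------
# ledger parsing
# ---------------------------------------------------------------------------


def test_duplicate_pairs_collapse_with_replicates_merged():
    records = load_ledger(TOY_LEDGER)
    assert len(records) == 2
    intra = next(r for r in records if r.link_type == "intra")
    assert set(intra.replicates) == {"r1", "r2"}


def test_self_pair_rows_are_skipped(caplog):
    text = TOY_LEDGER + "E1o\t99\tE1o\t99\tr1\n"
    with caplog.at_level("WARNING"):
        records = load_ledger(text)
    assert len(records) == 2
    assert "skipped 1" in caplog.text


def test_missing_column_is_named():
    with pytest.raises(ValueError, match="replicate"):
        load_ledger("ProteinA\tResA\tProteinB\tResB\n-\t1\t-\t2\n")


def test_generated_ledger_round_trips(walk_model_seed11):
    table, ledger = gen_crosslinks(walk_model_seed11, 150, frac_satisfied=0.8, seed=11)
    records = load_ledger(table)
    assert len(records) == 150
    truth_pairs = {frozenset({t["res_a"], t["res_b"]}) for t in ledger["links"]}
    got_pairs = {frozenset({r.res_a, r.res_b}) for r in records}
    assert got_pairs == truth_pairs
    # frame writer round-trips through the reader as well
    assert len(load_ledger(ledger_frame(records))) == 150


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------


def _monomer(positions, chain="A"):
    atoms = [
        AtomSite(chain, i + 1, "LYS", "CA", tuple(p), element="C")
        for i, p in enumerate(positions)
    ]
    return StructureModel("m", atoms)


def test_monomer_distance_is_euclidean():
    model = _monomer([(0, 0, 0), (8, 0, 0)])
    records = load_ledger("ProteinA,ResA,ProteinB,ResB,Replicate\nP,1,P,2,r1\n")
    (mapped,) = map_links(model, records, {"P": ["A"]})
    assert mapped.distance == pytest.approx(8.0)


def test_homodimer_ambiguity_takes_minimum_over_chains():
    atoms = [
        AtomSite("A", 1, "LYS", "CA", (0.0, 0.0, 0.0), element="C"),
        AtomSite("A", 2, "LYS", "CA", (40.0, 0.0, 0.0), element="C"),
        AtomSite("B", 1, "LYS", "CA", (100.0, 0.0, 0.0), element="C"),
        AtomSite("B", 2, "LYS", "CA", (12.0, 0.0, 0.0), element="C"),
    ]
    model = StructureModel("dimer", atoms)
    records = load_ledger("ProteinA,ResA,ProteinB,ResB,Replicate\nP,1,P,2,r1\n")
    (mapped,) = map_links(model, records, {"P": ["A", "B"]})
    assert mapped.distance == pytest.approx(12.0)  # A:1 to B:2 beats A:1-A:2
    assert mapped.chain_assignment == ("A", "B")


def test_mapped_distances_match_generator_truth(walk_model_seed11):
    table, ledger = gen_crosslinks(walk_model_seed11, 200, frac_satisfied=0.9, seed=11)
    mapped = map_links(walk_model_seed11, load_ledger(table), ledger["chain_map"])
    truth = {frozenset({t["res_a"], t["res_b"]}): t["distance"] for t in ledger["links"]}
    for m in mapped:
        key = frozenset({m.record.res_a, m.record.res_b})
        assert m.distance == pytest.approx(truth[key], abs=1e-9)


def test_decoy_links_are_unmapped(walk_model_seed11):
    table, ledger = gen_crosslinks(walk_model_seed11, 100, decoy_rate=0.1, seed=2)
    mapped = map_links(walk_model_seed11, load_ledger(table), ledger["chain_map"])
    n_unmapped = sum(1 for m in mapped if m.distance is None)
    assert n_unmapped == ledger["n_decoys"] == 10


def test_mapping_invariant_under_rigid_transform(walk_model_seed11):
    from tests.conftest import rotation_about_axis

    table, ledger = gen_crosslinks(walk_model_seed11, 50, seed=3)
    records = load_ledger(table)
    moved = walk_model_seed11.transformed(
        rotation_about_axis([0.3, 1.0, -0.5], 63.0), np.array([4.0, 5.0, 6.0])
    )
    d0 = [m.distance for m in map_links(walk_model_seed11, records, ledger["chain_map"])]
    d1 = [m.distance for m in map_links(moved, records, ledger["chain_map"])]
    np.testing.assert_allclose(d0, d1, atol=1e-6)


# ---------------------------------------------------------------------------
# satisfaction
# ---------------------------------------------------------------------------


def test_all_below_threshold_gives_one():
    model = _monomer([(0, 0, 0), (8, 0, 0), (4, 0, 0)])
    records = load_ledger(
        "ProteinA,ResA,ProteinB,ResB,Replicate\nP,1,P,2,r1\nP,1,P,3,r1\n"
    )
    mapped = map_links(model, records, {"P": ["A"]})
    assert satisfaction(mapped, 30.0).fraction == 1.0


def test_threshold_boundary_is_inclusive():
    model = _monomer([(0, 0, 0), (30.0, 0, 0)])
    records = load_ledger("ProteinA,ResA,ProteinB,ResB,Replicate\nP,1,P,2,r1\n")
    mapped = map_links(model, records, {"P": ["A"]})
    assert satisfaction(mapped, 30.0).fraction == 1.0
    assert satisfaction(mapped, 29.999).fraction == 0.0


def test_zero_mapped_links_is_an_error():
    model = _monomer([(0, 0, 0), (1, 0, 0)])
    records = load_ledger("ProteinA,ResA,ProteinB,ResB,Replicate\nQ,1,Q,2,r1\n")
    mapped = map_links(model, records, {"P": ["A"]})
    with pytest.raises(ValueError, match="no mapped links"):
        satisfaction(mapped, 30.0)


def test_planted_fraction_recovered_exactly(walk_model_seed11):
    table, ledger = gen_crosslinks(
        walk_model_seed11, 200, frac_satisfied=0.85, threshold=30.0, seed=5
    )
    mapped = map_links(walk_model_seed11, load_ledger(table), ledger["chain_map"])
    res = satisfaction(mapped, 30.0)
    assert res.fraction == pytest.approx(0.85)
    assert res.n_satisfied == ledger["n_satisfied"] == 170
    # matches a direct count oracle
    oracle = np.mean([m.distance <= 30.0 for m in mapped])
    assert res.fraction == pytest.approx(float(oracle))


def test_satisfaction_monotone_in_threshold(walk_model_seed11):
    table, ledger = gen_crosslinks(walk_model_seed11, 150, frac_satisfied=0.6, seed=8)
    mapped = map_links(walk_model_seed11, load_ledger(table), ledger["chain_map"])
    profile = satisfaction_profile(mapped, (10.0, 20.0, 30.0, 50.0, 1e6))
    values = list(profile.values())
    assert values == sorted(values)
    assert values[-1] == 1.0


# ---------------------------------------------------------------------------
# distance distribution
# ---------------------------------------------------------------------------


def test_lognormal_mle_recovers_parameters():
    rng = np.random.default_rng(1)
    d = rng.lognormal(mean=3.0, sigma=0.4, size=2000)
    dist = fit_distance_distribution(list(d))
    assert dist.lognormal_mu == pytest.approx(3.0, rel=0.05)
    assert dist.lognormal_sigma == pytest.approx(0.4, rel=0.05)


def test_constant_distances_are_degenerate():
    with pytest.raises(ValueError, match="sigma"):
        fit_distance_distribution([10.0] * 10)


def test_nonpositive_distance_rejected():
    with pytest.raises(ValueError, match="positive"):
        fit_distance_distribution([1.0, 2.0, 0.0, 4.0, 5.0])


def test_lognormal_fits_better_than_misspecified_normal():
    rng = np.random.default_rng(2)
    d = rng.lognormal(mean=3.0, sigma=0.5, size=1500)
    dist = fit_distance_distribution(list(d))
    ks_normal = stats.kstest(d, stats.norm(loc=d.mean(), scale=d.std()).cdf).statistic
    assert dist.gof_stat < ks_normal


# ---------------------------------------------------------------------------
# link summary
# ---------------------------------------------------------------------------


def test_toy_summary_counts():
    records = load_ledger(
        "ProteinA,ResA,ProteinB,ResB,Replicate\n"
        "A,1,A,5,r1\nA,5,A,1,r1\nA,2,B,3,r1\n"
    )
    summary = link_summary(records)
    assert summary.intra_per_protein == {"A": 1}
    assert summary.inter_per_pair == {("A", "B"): 1}
    assert summary.n_total == len(records) == 2


def test_empty_restriction_set_means_global_totals():
    records = load_ledger(TOY_LEDGER)
    assert link_summary(records, set()).n_total == link_summary(records).n_total


def test_restriction_set_filters_pairs():
    records = load_ledger(
        "ProteinA,ResA,ProteinB,ResB,Replicate\n"
        "A,1,A,5,r1\nA,2,B,3,r1\nC,1,C,9,r1\n"
    )
    summary = link_summary(records, {"A", "B"})
    assert summary.n_intra == 1 and summary.n_inter == 1


def test_planted_per_protein_counts_recovered():
    rng = np.random.default_rng(9)
    rows = ["ProteinA,ResA,ProteinB,ResB,Replicate"]
    planted_intra = {"E1o": 12, "E2o": 7, "E3": 4}
    planted_inter = {("E1o", "E2o"): 5, ("E2o", "E3"): 3}
    for p, n in planted_intra.items():
        picked = set()
        while len(picked) < n:
            a, b = sorted(rng.choice(500, size=2, replace=False) + 1)
            picked.add((int(a), int(b)))
        rows += [f"{p},{a},{p},{b},r1" for a, b in picked]
    for (p, q), n in planted_inter.items():
        for k in range(n):
            rows.append(f"{p},{k + 1},{q},{k + 1},r1")
    summary = link_summary(load_ledger("\n".join(rows) + "\n"))
    assert summary.intra_per_protein == planted_intra
    assert summary.inter_per_pair == planted_inter
    assert summary.n_total == sum(planted_intra.values()) + sum(planted_inter.values())
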