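"""Weir-Cockerham theta, name-based F_ST and AMOVA vs brute-force oracles."""

import warnings

import numpy as np
import pytest

from divkit import differentiation as diff
from divkit.data_model import MISSING
from tests.conftest import make_dataset, random_dataset
from tests.oracles import amova_oracle, pair_distance_oracle, wc_theta_oracle


def to_oracle_format(ds):
    genos = []
    for i in range(ds.n_individuals):
        row = []
        for j in range(ds.n_loci):
            a, b = int(ds.calls[i, j, 0]), int(ds.calls[i, j, 1])
            row.append(None if a == MISSING else (a, b))
        genos.append(row)
    return genos


# --- Weir-Cockerham theta ----------------------------------------------------

def test_theta_fixed_disjoint_groups_is_one():
    calls = [[[1, 1]], [[1, 1]], [[1, 1]], [[2, 2]], [[2, 2]], [[2, 2]]]
    ds = make_dataset(calls, regions=["R1"] * 6, zones=["Z1"] * 3 + ["Z2"] * 3)
    assert diff.wc_theta(ds, ds.grouping("zone")).theta == pytest.approx(1.0)


def test_theta_identical_groups_near_zero():
    # one group duplicated: theta is a small negative O(1/n), not exactly 0
    rng = np.random.default_rng(4)
    block = rng.integers(1, 5, size=(60, 4, 2)).astype(np.int32)
    calls = np.concatenate([block, block])
    ds = make_dataset(calls, regions=["R1"] * 120,
                      zones=["Z1"] * 60 + ["Z2"] * 60)
    assert abs(diff.wc_theta(ds, ds.grouping("zone")).theta) < 0.02


def test_theta_hand_computed_two_group_one_locus():
    # group 1: (1,1), (1,2); group 2: (2,2), (2,2)
    calls = [[[1, 1]], [[1, 2]], [[2, 2]], [[2, 2]]]
    ds = make_dataset(calls, regions=["R1"] * 4, zones=["Z1", "Z1", "Z2", "Z2"])
    expect = wc_theta_oracle(to_oracle_format(ds), [0, 0, 1, 1])
    got = diff.wc_theta(ds, ds.grouping("zone")).theta
    assert got == pytest.approx(expect, abs=1e-12)


def test_theta_random_instances_match_oracle():
    rng = np.random.default_rng(2024)
    for trial in range(25):
        n = int(rng.integers(6, 17))
        ds = random_dataset(rng, n, n_loci=int(rng.integers(1, 4)),
                            n_groups=int(rng.integers(2, 4)),
                            missing_rate=0.1)
        labels = [ds.meta.loc[i, "zone"] for i in ds.individuals]
        gidx = [sorted(set(labels)).index(l) for l in labels]
        expect = wc_theta_oracle(to_oracle_format(ds), gidx)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = diff.wc_theta(ds, ds.grouping("zone")).theta
        if expect is None:
            assert got is None
        else:
            assert got == pytest.approx(expect, abs=1e-10), trial


def test_theta_requires_two_groups_and_flags_monomorphic():
    ds = make_dataset([[[1, 1]], [[1, 1]]], regions=["R1"] * 2, zones=["Z1"] * 2)
    with pytest.raises(ValueError, match="2 groups"):
        diff.wc_theta(ds, ds.grouping("zone"))
    mono = make_dataset([[[1, 1]]] * 4, regions=["R1"] * 4,
                        zones=["Z1", "Z1", "Z2", "Z2"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = diff.wc_theta(mono, mono.grouping("zone"))
    assert res.theta is None


# --- pairwise F_ST -----------------------------------------------------------

def test_pairwise_duplicated_group_not_significant():
    rng = np.random.default_rng(8)
    calls = rng.integers(1, 5, size=(10, 3, 2)).astype(np.int32)
    dup = np.concatenate([calls, calls])
    ds = make_dataset(dup, regions=["R1"] * 20, zones=["Z1"] * 10 + ["Z2"] * 10)
    m = diff.pairwise_fst(ds, ds.grouping("zone"), n_perm=200, seed=0)
    assert m.p_values.loc["Z1", "Z2"] > 0.05
    assert abs(m.theta.loc["Z1", "Z2"]) < 0.05


def test_pairwise_no_perms_gives_theta_without_p():
    ds = make_dataset(
        [[[1, 1]], [[1, 2]], [[2, 2]], [[2, 2]]],
        regions=["R1"] * 4, zones=["Z1", "Z1", "Z2", "Z2"],
    )
    m = diff.pairwise_fst(ds, ds.grouping("zone"), n_perm=0)
    assert np.isfinite(m.theta.loc["Z1", "Z2"])
    assert np.isnan(m.p_values.loc["Z1", "Z2"])


def test_pairwise_small_group_skipped_with_warning():
    ds = make_dataset(
        [[[1, 1]], [[1, 2]], [[2, 2]]],
        regions=["R1"] * 3, zones=["Z1", "Z1", "Z2"],
    )
    with pytest.warns(UserWarning, match="skipped"):
        m = diff.pairwise_fst(ds, ds.grouping("zone"), n_perm=0)
    assert np.isnan(m.theta.loc["Z1", "Z2"])


def test_diverged_zones_significant(small_sim_config):
    import dataclasses

    cfg = dataclasses.replace(small_sim_config, target_fct=0.4, target_fsc=0.4,
                              individuals_per_population=2)
    from divkit.synthetic_data import simulate_dataset

    ds, _, _ = simulate_dataset(cfg)
    sub = ds.subset((ds.meta["region"] == "R1").to_numpy())
    m = diff.pairwise_fst(sub, sub.grouping("zone"), n_perm=200, seed=1)
    assert m.p_values.loc["R1Z1", "R1Z2"] <= 0.05


# --- variety-name F_ST -------------------------------------------------------

def test_name_fst_disjoint_fixed_names_is_one():
    ds = make_dataset(
        [[[1, 1]]] * 6, regions=["R1"] * 6, zones=["Z1"] * 3 + ["Z2"] * 3,
        varieties=["guemh"] * 3 + ["aberyoun"] * 3,
    )
    m = diff.name_fst(ds, ds.grouping("zone"), n_perm=0)
    assert m.theta.loc["Z1", "Z2"] == pytest.approx(1.0)
    assert m.mode == "variety_name"


def test_name_fst_identical_spectra_near_zero():
    names = (["a"] * 20 + ["b"] * 15 + ["c"] * 5) * 2
    n = len(names)
    ds = make_dataset(
        [[[1, 1]]] * n, regions=["R1"] * n,
        zones=["Z1"] * (n // 2) + ["Z2"] * (n // 2), varieties=names,
    )
    m = diff.name_fst(ds, ds.grouping("zone"), n_perm=200, seed=0)
    assert abs(m.theta.loc["Z1", "Z2"]) < 0.05
    assert m.p_values.loc["Z1", "Z2"] > 0.05


def test_name_fst_equals_theta_on_recoded_dataset():
    # 2-zone toy from the contract: A = 3x"x" + 1x"y"; B = 1x"x" + 3x"y"
    ds = make_dataset(
        [[[1, 1]]] * 8, regions=["R1"] * 8, zones=["Z1"] * 4 + ["Z2"] * 4,
        varieties=["x", "x", "x", "y", "x", "y", "y", "y"],
    )
    m = diff.name_fst(ds, ds.grouping("zone"), n_perm=0)
    recoded = diff.name_dataset(ds)
    direct = diff.wc_theta(recoded, recoded.grouping("zone")).theta
    assert m.theta.loc["Z1", "Z2"] == pytest.approx(direct, abs=0)

    rng = np.random.default_rng(77)
    for _ in range(10):
        n = int(rng.integers(6, 14))
        names = [f"v{k}" for k in rng.integers(0, 4, size=n)]
        zones = [f"Z{k + 1}" for k in rng.integers(0, 2, size=n)]
        if len({z for z in zones}) < 2 or min(zones.count("Z1"), zones.count("Z2")) < 2:
            continue
        ds = make_dataset([[[1, 1]]] * n, regions=["R1"] * n, zones=zones,
                          varieties=names)
        m = diff.name_fst(ds, ds.grouping("zone"), n_perm=0)
        rec = diff.name_dataset(ds)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            direct = diff.wc_theta(rec, rec.grouping("zone")).theta
        got = m.theta.loc["Z1", "Z2"]
        if direct is None:
            assert np.isnan(got)
        else:
            assert got == pytest.approx(direct, abs=0)


# --- AMOVA -------------------------------------------------------------------

def test_allele_difference_matrix_matches_pair_oracle():
    rng = np.random.default_rng(5)
    ds = random_dataset(rng, 8, n_loci=3, missing_rate=0.15)
    d2 = diff.allele_difference_matrix(ds)
    genos = to_oracle_format(ds)
    for i in range(8):
        for j in range(8):
            assert d2[i, j] == pair_distance_oracle(genos[i], genos[j])


def test_amova_twelve_individual_toy_matches_oracle():
    rng = np.random.default_rng(9)
    calls = rng.integers(1, 4, size=(12, 2, 2)).astype(np.int32)
    regions = ["R1"] * 6 + ["R2"] * 6
    zones = ["Z1"] * 3 + ["Z2"] * 3 + ["Z3"] * 3 + ["Z4"] * 3
    ds = make_dataset(calls, regions=regions, zones=zones)
    res = diff.amova(ds, n_perm=0)
    oracle = amova_oracle(diff.allele_difference_matrix(ds), regions, zones)
    for key in ("a", "b", "c"):
        assert res.components[key] == pytest.approx(oracle["sigma"][key], abs=1e-10)
    assert res.f_ct == pytest.approx(oracle["f_ct"], abs=1e-10)
    assert res.f_sc == pytest.approx(oracle["f_sc"], abs=1e-10)


def test_amova_random_instances_match_oracle():
    rng = np.random.default_rng(31)
    done = 0
    while done < 25:
        n = int(rng.integers(8, 17))
        n_regions = int(rng.integers(2, 4))
        regions = [f"R{k + 1}" for k in rng.integers(0, n_regions, size=n)]
        zones = [f"{r}Z{z + 1}" for r, z in zip(regions, rng.integers(0, 2, size=n))]
        sizes = {}
        for z in zones:
            sizes[z] = sizes.get(z, 0) + 1
        if min(sizes.values()) < 2 or len(set(regions)) < 2:
            continue
        calls = rng.integers(1, 4, size=(n, int(rng.integers(1, 4)), 2)).astype(np.int32)
        if rng.random() < 0.5:
            miss = rng.random(calls.shape[:2]) < 0.1
            calls[miss] = 0
        ds = make_dataset(calls, regions=regions, zones=zones)
        res = diff.amova(ds, n_perm=0)
        oracle = amova_oracle(diff.allele_difference_matrix(ds), regions, zones)
        for key in ("a", "b", "c"):
            assert res.components[key] == pytest.approx(oracle["sigma"][key], abs=1e-10)
        done += 1


def test_amova_identical_individuals_flagged():
    ds = make_dataset([[[1, 1]]] * 8, regions=["R1"] * 4 + ["R2"] * 4,
                      zones=["Z1"] * 2 + ["Z2"] * 2 + ["Z3"] * 2 + ["Z4"] * 2)
    res = diff.amova(ds, n_perm=0)
    assert all(v == 0 for v in res.components.values())
    assert res.f_ct is None and res.f_st is None


def test_amova_disjoint_regions_put_all_variance_among_regions():
    calls = [[[1, 1]]] * 3 + [[[2, 2]]] * 3
    ds = make_dataset(calls, regions=["R1"] * 3 + ["R2"] * 3,
                      zones=["Z1"] * 3 + ["Z2"] * 3)
    res = diff.amova(ds, n_perm=0)
    assert res.percentages["a"] == pytest.approx(100.0, abs=1e-9)
    assert res.f_ct == pytest.approx(1.0)


def test_amova_percentage_and_index_consistency(sim_default):
    ds, _, _ = sim_default
    res = diff.amova(ds.drop_checks(), n_perm=0)
    assert sum(res.percentages.values()) == pytest.approx(100.0, abs=1e-6)
    sig = res.components
    total = sum(sig.values())
    assert res.f_ct == pytest.approx(sig["a"] / total)
    assert res.f_sc == pytest.approx(sig["b"] / (sig["b"] + sig["c"]))
    if sig["b"] >= 0:
        assert res.f_st >= res.f_ct - 1e-12
    assert 0 < res.f_ct < 1 and 0 < res.f_sc < 1


def test_amova_permutation_pvalues_detect_structure(small_sim_config):
    import dataclasses

    from divkit.synthetic_data import simulate_dataset

    cfg = dataclasses.replace(small_sim_config, target_fct=0.3, target_fsc=0.3,
                              individuals_per_population=2)
    ds, _, _ = simulate_dataset(cfg)
    res = diff.amova(ds.drop_checks(), n_perm=200, seed=0)
    assert res.p_values["f_ct"] <= 0.05 or res.p_values["f_st"] <= 0.05
    res2 = diff.amova(ds.drop_checks(), n_perm=200, seed=0)
    assert res.p_values == res2.p_values  # seeded determinism


def test_amova_single_region_reports_one_stratum():
    ds = make_dataset(
        [[[1, 1]], [[1, 2]], [[2, 2]], [[2, 2]]],
        regions=["R1"] * 4, zones=["Z1", "Z1", "Z2", "Z2"],
    )
    res = diff.amova(ds, n_perm=0)
    assert res.single_region and res.f_ct is None
    assert res.f_st is not None
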