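"""Morphology rules: threshold, purity, spike/stature classes, varieties."""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from divkit import morphology as mo
from divkit.data_model import MorphPanel
from divkit.synthetic_data import SimConfig, simulate_dataset


def panel_from(heights_by_pop: dict, checks: list[float] | None = None,
               spikes_by_pop: dict | None = None) -> MorphPanel:
    rows = []
    for pid, hs in heights_by_pop.items():
        spikes = (spikes_by_pop or {}).get(pid, ["DW"] * len(hs))
        for k, (h, sp) in enumerate(zip(hs, spikes)):
            rows.append((pid, f"{pid}_s{k}", sp, h, False))
    for k, h in enumerate(checks or []):
        rows.append(("Karim", f"chk{k}", "DW", h, True))
    return MorphPanel(pd.DataFrame(
        rows, columns=["population", "progeny", "spike_type", "height_cm", "is_check"]
    ))


# --- straight-line transcription of the classification rules (oracle) ------

def purity_oracle(counts: dict) -> str:
    counts = {t: c for t, c in counts.items() if c > 0}
    total = sum(counts.values())
    top = max(counts.values())
    if total - top <= 1 and top > total - top:
        return "pure"
    if sum(1 for c in counts.values() if c >= 2) >= 2:
        return "mixed"
    return "unclassified"


def stature_oracle(s: int, t: int) -> str:
    if purity_oracle({"S": s, "T": t}) == "pure":
        return "S" if s >= t else "T"
    if purity_oracle({"S": s, "T": t}) == "unclassified":
        return "unclassified"
    f = s / (s + t)
    if f < 0.33:
        return "S<T"
    if f <= 0.66:
        return "S=T"
    return "S>T"


def spike_oracle(dw: int, dc: int, ca: int, bw: int) -> str:
    counts = {"DW": dw, "DC": dc, "CA": ca, "BW": bw}
    purity = purity_oracle(counts)
    majority = max(counts, key=lambda t: (counts[t], -list(counts).index(t)))
    if purity == "pure":
        return majority if majority in ("BW", "DW", "DC") else "unclassified"
    if purity == "unclassified":
        return "unclassified"
    if majority == "BW":
        return "BW"
    present = {t for t, c in counts.items() if c >= 2}
    if present == {"DW", "DC"}:
        return "DW_DC"
    if present == {"DW", "DC", "CA"}:
        return "DW_DC_CA"
    return "unclassified"


# ---------------------------------------------------------------------------

def test_threshold_is_checks_upper_limit():
    panel = panel_from({}, checks=list(np.linspace(55, 90, 20)))
    assert mo.derive_stature_threshold(panel).threshold_cm == 90.0
    flat = panel_from({}, checks=[70.0] * 12)
    assert mo.derive_stature_threshold(flat).threshold_cm == 70.0


def test_threshold_requires_checks():
    with pytest.raises(ValueError, match="threshold"):
        mo.derive_stature_threshold(panel_from({"P1": [100.0, 95.0]}))
    with pytest.raises(ValueError, match="10"):
        mo.derive_stature_threshold(panel_from({}, checks=[70.0] * 5))


def test_generator_checks_bound_threshold(sim_default):
    _, panel, _ = sim_default
    rule = mo.derive_stature_threshold(panel)
    assert rule.threshold_cm == panel.checks["height_cm"].max()
    assert 55 < rule.threshold_cm <= 90


@pytest.mark.parametrize("counts,expect", [
    ({"DW": 30}, ("pure", "DW")),
    ({"DW": 29, "DC": 1}, ("pure", "DW")),       # one-outlier allowance
    ({"DW": 20, "DC": 10}, ("mixed", "DW")),     # >= 2 progenies of each
    ({"DW": 1, "DC": 1}, ("unclassified", "DW")),
])
def test_purity_examples(counts, expect):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        assert mo.classify_population_purity(counts) == expect


def test_purity_error_on_empty():
    with pytest.raises(ValueError):
        mo.classify_population_purity({"DW": 0})
    with pytest.raises(ValueError):
        mo.classify_population_purity({"DW": 1})


def test_purity_exhaustive_vs_oracle_and_exclusivity():
    """Every 2-type count vector summing to <= 12: rules match the verbatim
    transcription and pure/mixed are mutually exclusive."""
    for s in range(13):
        for t in range(13 - s):
            if s + t < 2:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got, _ = mo.classify_population_purity({"S": s, "T": t})
            want = purity_oracle({"S": s, "T": t})
            assert got == want, (s, t)
            assert not (got == "pure" and want == "mixed")


def test_stature_exhaustive_vs_oracle():
    for s in range(13):
        for t in range(13 - s):
            if s + t < 2:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                got, _ = mo.classify_population_stature(s, t)
            assert got == stature_oracle(s, t), (s, t)


def test_spike_exhaustive_vs_oracle():
    for dw, dc, ca, bw in itertools.product(range(8), repeat=4):
        if not 2 <= dw + dc + ca + bw <= 12:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got, _ = mo.classify_population_spike(
                {"DW": dw, "DC": dc, "CA": ca, "BW": bw}
            )
        assert got == spike_oracle(dw, dc, ca, bw), (dw, dc, ca, bw)


@pytest.mark.parametrize("counts,expect", [
    ({"BW": 30}, "BW"),
    ({"BW": 20, "DW": 10}, "BW"),
    ({"DW": 15, "DC": 13, "CA": 2}, "DW_DC_CA"),
    ({"DW": 29, "DC": 1}, "DW"),
    ({"DW": 20, "DC": 10}, "DW_DC"),
])
def test_spike_examples(counts, expect):
    got, _ = mo.classify_population_spike(counts)
    assert got == expect


def test_undefined_spike_combination_warns():
    with pytest.warns(UserWarning, match="without a defined class"):
        got, _ = mo.classify_population_spike({"DW": 28, "CA": 2})
    assert got == "unclassified"


@pytest.mark.parametrize("s,t,expect", [
    (5, 25, "S<T"),      # 16.7% short
    (1, 29, "T"),        # pure via one-outlier
    (20, 10, "S>T"),     # 66.7% short, above the closed band
    (33, 67, "S=T"),     # exactly 0.33: closed lower endpoint
    (66, 34, "S=T"),     # exactly 0.66: closed upper endpoint
])
def test_stature_examples(s, t, expect):
    got, _ = mo.classify_population_stature(s, t)
    assert got == expect


def test_classification_invariant_under_reordering():
    rng = np.random.default_rng(0)
    heights = list(rng.uniform(60, 130, size=20))
    spikes = list(rng.choice(["DW", "DC"], size=20))
    p1 = panel_from({"P1": heights}, checks=[80.0] * 10 + [90.0],
                    spikes_by_pop={"P1": spikes})
    order = rng.permutation(20)
    p2 = panel_from({"P1": [heights[i] for i in order]}, checks=[80.0] * 10 + [90.0],
                    spikes_by_pop={"P1": [spikes[i] for i in order]})
    pd.testing.assert_frame_equal(mo.classify_populations(p1), mo.classify_populations(p2))


def test_noiseless_generator_classes_match_truth(small_sim_config):
    import dataclasses

    cfg = dataclasses.replace(small_sim_config, spike_emission_noise=0.0,
                              mixture_rate=0.0, modern_adoption=(0.3, 0.3))
    _, panel, truth = simulate_dataset(cfg)
    classes = mo.classify_populations(panel, mo.StatureRule(90.0))
    for pid, row in truth.populations.iterrows():
        assert classes.loc[pid, "spike_class"] == row["pool_spikes"][0]
        assert classes.loc[pid, "stature_class"] == row["pool_statures"][0]


def test_zone_frequency_table():
    panel = panel_from(
        {"P1": [100.0] * 4, "P2": [100.0] * 4},
        checks=[80.0] * 10 + [90.0],
        spikes_by_pop={"P1": ["DW"] * 4, "P2": ["DC"] * 4},
    )
    t = mo.zone_frequency_table(panel, {"P1": "Z1", "P2": "Z1"})
    assert t.loc["Z1", "DW"] == 0.5 and t.loc["Z1", "DC"] == 0.5
    assert t.loc["Z1", "short_freq"] == 0.0
    assert abs(t.loc["Z1", ["DW", "DC", "CA", "BW"]].sum() - 1) < 1e-12
    single = mo.zone_frequency_table(
        panel_from({"P1": [100.0] * 5}, checks=[80.0] * 10 + [90.0]), {"P1": "Z9"}
    )
    assert single.loc["Z9", "DW"] == 1.0
    with pytest.raises(ValueError, match="zone"):
        mo.zone_frequency_table(panel, {"P1": "Z1"})


def test_zone_frequencies_match_generator_emissions(small_sim_config):
    import dataclasses

    cfg = dataclasses.replace(
        small_sim_config, mixture_rate=0.0, modern_adoption=(0.0, 0.0),
        spike_emission_noise=0.1, progenies_per_population=30,
    )
    _, panel, truth = simulate_dataset(cfg)
    pops = truth.populations
    zone_of = dict(zip(pops.index, pops["zone"]))
    t = mo.zone_frequency_table(panel, zone_of, mo.StatureRule(90.0))
    for zone, grp in pops.groupby("zone"):
        expect_dw = np.mean([
            0.9 if sp[0] == "DW" else 0.05 for sp in grp["pool_spikes"]
        ])
        n = t.loc[zone, "n_progenies"]
        se = 3 * np.sqrt(0.25 / n)
        assert abs(t.loc[zone, "DW"] - expect_dw) < se + 0.02


def make_classes(rows: dict) -> pd.DataFrame:
    return pd.DataFrame(
        [{"population": p, "spike_class": sc, "stature_class": st}
         for p, (sc, st) in rows.items()],
        columns=["population", "spike_class", "stature_class"],
    ).set_index("population")


def test_variety_categorization():
    uniform = make_classes({f"P{i}": ("DW", "T") for i in range(3)})
    d = mo.categorize_variety("guemh", uniform)
    assert d.spike_category == "DW" and d.stature_category == "T"
    assert d.label() == "Tall DW-type"

    with_outlier = make_classes(
        {**{f"P{i}": ("DC", "T") for i in range(5)}, "P9": ("DW", "T")}
    )
    d = mo.categorize_variety("ifermourgh", with_outlier)
    assert d.spike_category == "DC" and d.outliers == ["P9"]

    disjoint = make_classes({"P1": ("DW", "S"), "P2": ("DC", "T")})
    d = mo.categorize_variety("x", disjoint)
    assert d.spike_category == "no assignment"
    assert "No assignment" in d.label()

    with pytest.raises(ValueError):
        mo.categorize_variety("empty", make_classes({}))
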