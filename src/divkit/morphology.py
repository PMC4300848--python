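"""Morphological classification of farmer populations.

Two traits are scored on up to 30 progenies per population: spike type
(DW / DC / CA / BW) and mean plant height.  A check-derived threshold splits
heights into short (S, modern-breeding indicator) and tall (T, traditional
double-use stature).  A population is *pure* for a trait when all progenies
share one type with at most one outlier, and *mixed* when at least two types
each have at least two progenies; mixed stature populations are banded by
the frequency of short progenies (<33%, 33-66%, >66%).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from divkit.data_model import MorphPanel, SPIKE_TYPES

# deterministic tie order for majority types (the field's conventional
# ordering of tetraploid spike shapes, bread wheat last)
TYPE_ORDER = {"DW": 0, "DC": 1, "CA": 2, "BW": 3, "S": 0, "T": 1}

SPIKE_CLASSES = ("BW", "DW", "DC", "DW_DC", "DW_DC_CA", "unclassified")
STATURE_CLASSES = ("S", "T", "S<T", "S=T", "S>T", "unclassified")


@dataclass
class StatureRule:
    """Short/tall split at a threshold derived from check varieties."""

    threshold_cm: float = 90.0

    def classify(self, height_cm: float) -> str:
        return "S" if height_cm <= self.threshold_cm else "T"


@dataclass
class PopulationClass:
    population: str
    spike_class: str
    stature_class: str
    spike_pure: bool
    stature_pure: bool
    spike_counts: dict = field(default_factory=dict)
    stature_counts: dict = field(default_factory=dict)


def derive_stature_threshold(checks: MorphPanel | pd.DataFrame) -> StatureRule:
    """Threshold = upper limit (max) of the checks' mean-height distribution."""
    df = checks.checks if isinstance(checks, MorphPanel) else checks
    if len(df) == 0:
        raise ValueError(
            "no check rows: provide an explicit threshold via StatureRule(threshold_cm=...)"
        )
    if len(df) < 10:
        raise ValueError(f"only {len(df)} check rows; >= 10 required for a stable threshold")
    return StatureRule(threshold_cm=float(df["height_cm"].max()))


def classify_population_purity(counts: dict[str, int]) -> tuple[str, str]:
    """(pure|mixed|unclassified, majority type) from per-type progeny counts.

    Pure: all of one type with at most one outlier.  Mixed: >= 2 types each
    with >= 2 progenies.  A count vector can satisfy neither (e.g. 1 + 1),
    never both.  Majority ties break deterministically (DW < DC < CA < BW)
    with a warning.
    """
    counts = {t: int(c) for t, c in counts.items() if c > 0}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("zero progenies")
    if total < 2:
        raise ValueError("at least 2 progenies required")
    top = max(counts.values())
    leaders = sorted((t for t, c in counts.items() if c == top),
                     key=lambda t: TYPE_ORDER.get(t, 99))
    if len(leaders) > 1:
        warnings.warn(f"majority tie between {leaders}; keeping {leaders[0]}")
    majority = leaders[0]
    # pure needs an actual majority: 1 + 1 is neither pure nor mixed
    if total - top <= 1 and top > total - top:
        return "pure", majority
    if sum(1 for c in counts.values() if c >= 2) >= 2:
        return "mixed", majority
    return "unclassified", majority


def classify_population_spike(counts: dict[str, int]) -> tuple[str, bool]:
    """Spike class from DW/DC/CA/BW progeny counts; returns (class, pure flag).

    BW: pure bread wheat or mixed with a bread-wheat majority.  DW / DC:
    pure populations of that type.  DW_DC: mixed DW+DC.  DW_DC_CA: mixed
    with all three tetraploid types.  Anything else is unclassified.
    """
    counts = {t: int(counts.get(t, 0)) for t in SPIKE_TYPES}
    purity, majority = classify_population_purity(counts)
    if purity == "pure":
        if majority in ("BW", "DW", "DC"):
            return majority, True
        warnings.warn(f"pure population of undefined class {majority}")
        return "unclassified", True
    if purity == "mixed":
        present = {t for t, c in counts.items() if c >= 2}
        if majority == "BW":
            return "BW", False
        if "BW" not in present:
            if present == {"DW", "DC"}:
                return "DW_DC", False
            if present == {"DW", "DC", "CA"}:
                return "DW_DC_CA", False
        warnings.warn(f"mixed spike combination without a defined class: {counts}")
        return "unclassified", False
    warnings.warn(f"population fails both pure and mixed definitions: {counts}")
    return "unclassified", False


def classify_population_stature(n_short: int, n_tall: int) -> tuple[str, bool]:
    """Stature class from short/tall counts; returns (class, pure flag).

    Pure rule (one-outlier allowance) first; otherwise banded by the
    frequency of short progenies with the 33-66% band closed on both ends.
    """
    counts = {"S": int(n_short), "T": int(n_tall)}
    purity, majority = classify_population_purity(counts)
    if purity == "pure":
        return majority, True
    if purity == "unclassified":
        warnings.warn(f"stature counts fail both pure and mixed definitions: {counts}")
        return "unclassified", False
    f_short = n_short / (n_short + n_tall)
    if f_short < 0.33:
        return "S<T", False
    if f_short <= 0.66:
        return "S=T", False
    return "S>T", False


def classify_populations(panel: MorphPanel, rule: StatureRule | None = None) -> pd.DataFrame:
    """Per-population spike and stature classes for all non-check populations."""
    rule = rule or derive_stature_threshold(panel)
    rows = []
    for pid, grp in panel.progenies.groupby("population", sort=False):
        spike_counts = Counter(grp["spike_type"])
        statures = Counter(rule.classify(h) for h in grp["height_cm"])
        spike_class, spike_pure = classify_population_spike(spike_counts)
        stat_class, stat_pure = classify_population_stature(
            statures.get("S", 0), statures.get("T", 0)
        )
        rows.append({
            "population": pid,
            "spike_class": spike_class,
            "stature_class": stat_class,
            "spike_pure": spike_pure,
            "stature_pure": stat_pure,
            "n_progenies": len(grp),
            "n_short": statures.get("S", 0),
            **{f"n_{t}": spike_counts.get(t, 0) for t in SPIKE_TYPES},
        })
    return pd.DataFrame(rows).set_index("population")


def zone_frequency_table(panel: MorphPanel, pop_to_zone: dict[str, str],
                         rule: StatureRule | None = None) -> pd.DataFrame:
    """Spike-type and short-progeny frequencies per zone, over field progenies."""
    rule = rule or derive_stature_threshold(panel)
    df = panel.progenies.copy()
    unmapped = set(df["population"]) - set(pop_to_zone)
    if unmapped:
        raise ValueError(f"populations without a zone: {sorted(unmapped)[:5]}")
    df["zone"] = df["population"].map(pop_to_zone)
    df["short"] = df["height_cm"].apply(lambda h: rule.classify(h) == "S")
    rows = []
    for zone, grp in df.groupby("zone", sort=True):
        n = len(grp)
        counts = Counter(grp["spike_type"])
        rows.append({
            "zone": zone, "n_progenies": n,
            **{t: counts.get(t, 0) / n for t in SPIKE_TYPES},
            "short_freq": grp["short"].mean(),
        })
    return pd.DataFrame(rows).set_index("zone")


@dataclass
class VarietyDescriptor:
    variety: str
    n_populations: int
    spike_category: str       # dominant spike class or "no assignment"
    stature_category: str
    outliers: list = field(default_factory=list)

    def label(self) -> str:
        if self.spike_category == "no assignment" or self.stature_category == "no assignment":
            return "No assignment. Great heterogeneity among populations"
        stat = {"S": "Short", "T": "Tall"}.get(self.stature_category, self.stature_category)
        s = f"{stat} {self.spike_category}-type"
        if self.outliers:
            s += f". {len(self.outliers)} outlier population(s)"
        return s


def _strict_majority(values: pd.Series) -> str | None:
    counts = Counter(values)
    top_label, top = max(counts.items(), key=lambda kv: (kv[1], -TYPE_ORDER.get(kv[0], 99)))
    return top_label if top * 2 > len(values) else None


def categorize_variety(variety: str, classes: pd.DataFrame) -> VarietyDescriptor:
    """Summarise one variety from its populations' classes.

    The dominant class is a strict majority of population classes;
    populations disagreeing with it are listed as outliers; without a
    majority for either trait the variety gets "no assignment".
    """
    if len(classes) == 0:
        raise ValueError(f"variety {variety!r} has no classified populations")
    spike = _strict_majority(classes["spike_class"])
    stature = _strict_majority(classes["stature_class"])
    outliers = []
    if spike is not None:
        outliers.extend(classes.index[classes["spike_class"] != spike].tolist())
    if stature is not None:
        outliers.extend(
            p for p in classes.index[classes["stature_class"] != stature]
            if p not in outliers
        )
    return VarietyDescriptor(
        variety=variety,
        n_populations=len(classes),
        spike_category=spike if spike is not None else "no assignment",
        stature_category=stature if stature is not None else "no assignment",
        outliers=outliers,
    )


def categorize_varieties(classes: pd.DataFrame, pop_to_variety: dict[str, str]) -> pd.DataFrame:
    rows = []
    cl = classes.copy()
    cl["variety"] = [pop_to_variety[p] for p in cl.index]
    for variety, grp in cl.groupby("variety", sort=True):
        d = categorize_variety(variety, grp)
        rows.append({
            "variety": variety, "n_populations": d.n_populations,
            "spike_category": d.spike_category, "stature_category": d.stature_category,
            "n_outliers": len(d.outliers), "label": d.label(),
        })
    return pd.DataFrame(rows).set_index("variety")
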