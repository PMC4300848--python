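"""Core data types and table IO for SSR genotype and morphology data.

A *population* is the seed lot of one named variety grown by one farmer;
populations nest in zones, zones nest in regions.  Genotypes are diploid
codominant calls (microsatellite allele sizes in bp); morphology rows carry
one progeny's spike type and mean plant height.

Missing genotype data is normalised to the sentinel ``0`` internally
(matching the Genepop ``0000`` convention); in delimited files an empty
cell, ``0`` or ``NA`` all mean missing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = 0

META_COLUMNS = ["region", "zone", "population", "variety", "status"]
STATUSES = {"modern", "traditional", "check"}
SPIKE_TYPES = ("DW", "DC", "CA", "BW")


class ValidationError(ValueError):
    """A dataset violates one of the documented invariants."""


@dataclass
class GroupingKey:
    """Maps every individual to a group label at a chosen level.

    ``level`` is one of ``region, zone, population, variety, custom``.
    """

    level: str
    mapping: dict[str, str]

    def __post_init__(self) -> None:
        for ind, lab in self.mapping.items():
            if lab is None or str(lab) == "":
                raise ValidationError(f"empty group label for individual {ind!r}")

    def labels_for(self, individuals: Sequence[str]) -> np.ndarray:
        missing = [i for i in individuals if i not in self.mapping]
        if missing:
            raise ValidationError(f"individuals without group label: {missing[:5]}")
        return np.asarray([self.mapping[i] for i in individuals], dtype=object)


@dataclass
class GenotypeDataset:
    """Individuals x loci diploid allele calls plus hierarchical metadata.

    ``meta`` is indexed by individual id with columns
    ``region, zone, population, variety, status``; ``calls`` has shape
    ``(n_individuals, n_loci, 2)`` with positive integer allele codes
    (bp sizes) and 0 for missing.  Both alleles of a call are missing or
    both present.
    """

    meta: pd.DataFrame
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int32)
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        if self.meta.index.duplicated().any():
            dups = self.meta.index[self.meta.index.duplicated()].tolist()
            raise ValidationError(f"duplicated individual id(s): {dups[:5]}")
        if len(set(self.loci)) != len(self.loci):
            raise ValidationError("locus names are not unique")
        if self.calls.shape != (len(self.meta), len(self.loci), 2):
            raise ValidationError(
                f"calls shape {self.calls.shape} inconsistent with "
                f"{len(self.meta)} individuals x {len(self.loci)} loci"
            )
        if (self.calls < 0).any():
            raise ValidationError("allele codes must be positive (0 = missing)")
        half = (self.calls == MISSING).sum(axis=2) == 1
        if half.any():
            i, j = np.argwhere(half)[0]
            raise ValidationError(
                f"one-of-two missing allele for individual "
                f"{self.meta.index[i]!r} at locus {self.loci[j]!r}"
            )
        bad_status = set(self.meta["status"]) - STATUSES
        if bad_status:
            raise ValidationError(f"unknown status value(s): {sorted(bad_status)}")
        # hierarchical nesting, checks excluded (they sit outside the design)
        m = self.meta[self.meta["status"] != "check"]
        z2r = m.groupby("zone")["region"].nunique()
        if (z2r > 1).any():
            raise ValidationError(
                f"zone(s) spanning several regions: {z2r[z2r > 1].index.tolist()}"
            )
        p2 = m.groupby("population")[["region", "zone", "variety"]].nunique()
        bad = p2[(p2 > 1).any(axis=1)]
        if len(bad):
            raise ValidationError(
                f"population(s) mapping to several (region, zone, variety): "
                f"{bad.index.tolist()[:5]}"
            )

    # -- basic accessors ----------------------------------------------------

    @property
    def individuals(self) -> list[str]:
        return list(self.meta.index)

    @property
    def n_individuals(self) -> int:
        return len(self.meta)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    # -- grouping / subsetting ----------------------------------------------

    def grouping(self, level: str) -> GroupingKey:
        if level not in ("region", "zone", "population", "variety", "status"):
            raise ValueError(f"unknown grouping level {level!r}")
        return GroupingKey(level, dict(zip(self.meta.index, self.meta[level].astype(str))))

    def subset(self, predicate: Callable[[pd.Series], bool] | np.ndarray | None = None) -> "GenotypeDataset":
        """Rows whose metadata satisfy ``predicate`` (None keeps everything)."""
        if predicate is None:
            mask = np.ones(self.n_individuals, dtype=bool)
        elif isinstance(predicate, np.ndarray):
            mask = predicate
        else:
            mask = np.array([bool(predicate(row)) for _, row in self.meta.iterrows()])
        return GenotypeDataset(self.meta.loc[mask].copy(), list(self.loci), self.calls[mask])

    def drop_checks(self) -> "GenotypeDataset":
        return self.subset((self.meta["status"] != "check").to_numpy())


@dataclass
class MorphPanel:
    """Per-progeny spike type and mean height, plus check-variety rows.

    ``rows`` columns: ``population`` (population id, or check variety name
    for check rows), ``progeny``, ``spike_type`` in {DW, DC, CA, BW},
    ``height_cm`` (> 0), ``is_check`` (bool).
    """

    rows: pd.DataFrame

    MAX_PROGENIES = 30  # sampling design: 30 spikes from 30 plants

    def __post_init__(self) -> None:
        required = {"population", "progeny", "spike_type", "height_cm", "is_check"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValidationError(f"morphology table lacks columns {sorted(missing)}")
        bad = set(self.rows["spike_type"]) - set(SPIKE_TYPES)
        if bad:
            raise ValidationError(f"unknown spike type(s): {sorted(bad)}")
        if (self.rows["height_cm"] <= 0).any():
            raise ValidationError("heights must be strictly positive")
        sizes = self.rows[~self.rows["is_check"]].groupby("population").size()
        over = sizes[sizes > self.MAX_PROGENIES]
        if len(over):
            raise ValidationError(
                f"more than {self.MAX_PROGENIES} progenies for population(s) "
                f"{over.index.tolist()[:5]}"
            )

    @property
    def checks(self) -> pd.DataFrame:
        return self.rows[self.rows["is_check"]]

    @property
    def progenies(self) -> pd.DataFrame:
        return self.rows[~self.rows["is_check"]]


# ---------------------------------------------------------------------------
# delimited genotype tables
# ---------------------------------------------------------------------------

def _sep_for(path: str | Path, dialect: str | None) -> str:
    if dialect in ("csv", "tsv"):
        return "," if dialect == "csv" else "\t"
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_genotype_table(path: str | Path, dialect: str | None = None) -> GenotypeDataset:
    """Read a delimited genotype table.

    Header: ``id,region,zone,population,variety,status,<locus>_1,<locus>_2,...``
    Missing alleles as empty cells, 0 or NA.  Row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect), dtype={"id": str})
    expected_head = ["id"] + META_COLUMNS
    if list(df.columns[: len(expected_head)]) != expected_head:
        raise ValidationError(
            f"header must start with {expected_head}, got {list(df.columns[:6])}"
        )
    allele_cols = list(df.columns[len(expected_head):])
    if len(allele_cols) % 2 != 0:
        raise ValidationError(f"odd number of allele columns ({len(allele_cols)})")
    loci: list[str] = []
    for k in range(0, len(allele_cols), 2):
        c1, c2 = allele_cols[k], allele_cols[k + 1]
        if not (c1.endswith("_1") and c2.endswith("_2") and c1[:-2] == c2[:-2]):
            raise ValidationError(f"allele columns {c1!r},{c2!r} do not pair up")
        loci.append(c1[:-2])
    raw = df[allele_cols].apply(pd.to_numeric, errors="coerce").fillna(MISSING)
    calls = raw.to_numpy(dtype=np.int64).reshape(len(df), len(loci), 2)
    half = (calls == MISSING).sum(axis=2) == 1
    if half.any():
        i, j = np.argwhere(half)[0]
        raise ValidationError(
            f"one-of-two missing allele for individual {df['id'].iloc[i]!r} "
            f"at locus {loci[j]!r}"
        )
    meta = df[["id"] + META_COLUMNS].set_index("id")
    meta = meta.astype(str)
    return GenotypeDataset(meta, loci, calls)


def write_genotype_table(ds: GenotypeDataset, path: str | Path, dialect: str | None = None) -> None:
    path = Path(path)
    sep = _sep_for(path, dialect)
    out = ds.meta.copy()
    for j, locus in enumerate(ds.loci):
        out[f"{locus}_1"] = ds.calls[:, j, 0]
        out[f"{locus}_2"] = ds.calls[:, j, 1]
    out.index.name = "id"
    out.to_csv(path, sep=sep)


def read_morph_table(path: str | Path, dialect: str | None = None) -> MorphPanel:
    """Read a morphology table ``population,progeny,spike_type,height_cm[,is_check]``."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path, dialect))
    if "is_check" not in df.columns:
        df["is_check"] = False
    df["is_check"] = df["is_check"].astype(bool)
    return MorphPanel(df)


def write_morph_table(panel: MorphPanel, path: str | Path, dialect: str | None = None) -> None:
    panel.rows.to_csv(Path(path), sep=_sep_for(path, dialect), index=False)


# ---------------------------------------------------------------------------
# Genepop export / import
# ---------------------------------------------------------------------------

def write_genepop(ds: GenotypeDataset, grouping: GroupingKey, path: str | Path) -> dict:
    """Write a Genepop file (2 digits per allele, ``0000`` missing).

    Raw bp allele sizes are recoded per locus to 1..k in increasing size
    order; the recode map is returned and written to ``<path>.recode.json``.
    One POP block per group, groups in sorted label order.
    """
    path = Path(path)
    labels = grouping.labels_for(ds.individuals)
    recode: dict[str, dict[str, int]] = {}
    coded = np.zeros_like(ds.calls)
    for j, locus in enumerate(ds.loci):
        alleles = sorted(set(ds.calls[:, j, :].ravel()) - {MISSING})
        if len(alleles) > 99:
            raise ValidationError(
                f"locus {locus!r} has {len(alleles)} alleles: 2-digit recode overflow"
            )
        amap = {a: i + 1 for i, a in enumerate(alleles)}
        recode[locus] = {str(a): c for a, c in amap.items()}
        for a, c in amap.items():
            coded[:, j, :][ds.calls[:, j, :] == a] = c
    lines = [f"divkit genepop export ({ds.n_individuals} individuals, {ds.n_loci} loci)"]
    lines.extend(ds.loci)
    for group in sorted(set(labels)):
        lines.append("POP")
        for i in np.flatnonzero(labels == group):
            geno = " ".join(
                f"{coded[i, j, 0]:02d}{coded[i, j, 1]:02d}" for j in range(ds.n_loci)
            )
            lines.append(f"{ds.individuals[i]} ,  {geno}")
    path.write_text("\n".join(lines) + "\n")
    Path(str(path) + ".recode.json").write_text(json.dumps(recode, indent=1))
    return recode


def read_genepop(path: str | Path) -> GenotypeDataset:
    """Read a Genepop file written by :func:`write_genepop`.

    Group labels land in the ``population`` metadata column (``pop1``,
    ``pop2``, ... in file order); alleles stay in recoded units.
    """
    text = Path(path).read_text().strip().splitlines()
    body = text[1:]
    loci: list[str] = []
    k = 0
    while k < len(body) and body[k].strip().upper() != "POP":
        loci.extend(x.strip() for x in body[k].split(",") if x.strip())
        k += 1
    ids, pops, rows = [], [], []
    pop_no = 0
    for line in body[k:]:
        if line.strip().upper() == "POP":
            pop_no += 1
            continue
        name, geno = line.split(",", 1)
        codes = geno.split()
        if len(codes) != len(loci):
            raise ValidationError(f"row {name.strip()!r} has {len(codes)} genotypes")
        ids.append(name.strip())
        pops.append(f"pop{pop_no}")
        rows.append([(int(c[:2]), int(c[2:])) for c in codes])
    calls = np.asarray(rows, dtype=np.int32)
    meta = pd.DataFrame(
        {
            "region": "unknown",
            "zone": "unknown",
            "population": pops,
            "variety": "unknown",
            "status": "traditional",
        },
        index=pd.Index(ids, name="id"),
    )
    # nesting validation would reject several genepop POPs under one zone
    meta["zone"] = meta["population"]
    return GenotypeDataset(meta, loci, calls)
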