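"""End-to-end orchestration of the landrace-diversity analysis.

``run_pipeline`` chains simulate -> morphology classification -> diversity
tables -> AMOVA / pairwise F_ST (microsatellite and variety-name) -> DAPC
(reference run + replicate runs + metagroup repeatability + supplementary
projection of the checks) -> per-region NJ trees with locus bootstrap, and
writes each stage's tables plus a manifest that records every seed, size and
dropped unit, so any number in a report can be recomputed.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import divkit
from divkit import diversity as dv
from divkit import differentiation as diff
from divkit import dapc as dp
from divkit import morphology as mo
from divkit import tree as tr
from divkit.data_model import GenotypeDataset, MorphPanel, write_genotype_table, write_morph_table
from divkit.synthetic_data import SimConfig, simulate_dataset


@dataclass
class RunConfig:
    """Stage toggles and the analysis settings (defaults = study settings)."""

    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str = "divkit_run"
    seed: int = 0
    stages: tuple[str, ...] = ("morphology", "diversity", "differentiation", "dapc", "tree")
    rarefy_min_region: int = 17
    rarefy_min_zone: int = 5
    amova_perms: int = 10000
    pairwise_perms: int = 1000
    dapc_k: int | None = None
    dapc_k_max: int = 40
    dapc_runs: int = 16          # 1 reference + 15 replicates
    n_boot: int = 1000
    alpha_letters: float = 0.01

    def stage_seed(self, name: str) -> int:
        order = ["simulate", "morphology", "diversity", "differentiation", "dapc", "tree"]
        return int(np.random.SeedSequence([self.seed, order.index(name)]).generate_state(1)[0] % (2**31))


def run_pipeline(cfg: RunConfig,
                 dataset: tuple[GenotypeDataset, MorphPanel] | None = None) -> dict:
    """Run all enabled stages; returns the in-memory results bundle."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "divkit_version": divkit.__version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "stages": list(cfg.stages),
        "settings": {
            k: v for k, v in asdict(cfg).items() if k not in ("sim",)
        },
        "sim_config": asdict(cfg.sim),
        "notes": [],
    }
    results: dict = {"manifest": manifest}
    try:
        if dataset is None:
            sim = SimConfig(**{**asdict(cfg.sim), "seed": cfg.stage_seed("simulate")})
            ds, panel, truth = simulate_dataset(sim)
            results["truth"] = truth
        else:
            ds, panel = dataset
        results["genotypes"], results["morphology_panel"] = ds, panel
        write_genotype_table(ds, out / "genotypes.csv")
        write_morph_table(panel, out / "morphology.csv")
        manifest["n_individuals"] = ds.n_individuals
        manifest["n_loci"] = ds.n_loci
        manifest["n_progeny_rows"] = int(len(panel.progenies))

        samples = ds.drop_checks()
        pop_to_zone = dict(zip(samples.meta["population"], samples.meta["zone"]))
        pop_to_variety = dict(zip(samples.meta["population"], samples.meta["variety"]))

        if "morphology" in cfg.stages:
            rule = mo.derive_stature_threshold(panel)
            classes = mo.classify_populations(panel, rule)
            morph_zone = {p: z for p, z in pop_to_zone.items()}
            # populations whose genotyped seed was excluded still have morphology
            if results.get("truth") is not None:
                tpop = results["truth"].populations
                morph_zone.update(dict(zip(tpop.index, tpop["zone"])))
            zone_freq = mo.zone_frequency_table(panel, morph_zone, rule)
            tvar = dict(pop_to_variety)
            if results.get("truth") is not None:
                tpop = results["truth"].populations
                tvar.update(dict(zip(tpop.index, tpop["variety"])))
            varieties = mo.categorize_varieties(classes, tvar)
            classes.to_csv(out / "population_classes.tsv", sep="\t")
            zone_freq.to_csv(out / "zone_frequencies.tsv", sep="\t")
            varieties.to_csv(out / "variety_categories.tsv", sep="\t")
            results.update(
                stature_rule=rule, classes=classes, zone_frequencies=zone_freq,
                variety_categories=varieties,
            )
            manifest["stature_threshold_cm"] = rule.threshold_cm

        if "diversity" in cfg.stages:
            div_region = dv.diversity_table(
                samples, samples.grouping("region"), cfg.rarefy_min_region
            )
            div_zone = dv.diversity_table(
                samples, samples.grouping("zone"), cfg.rarefy_min_zone
            )
            comp_zone = {}
            for region in sorted(set(samples.meta["region"])):
                sub = samples.subset((samples.meta["region"] == region).to_numpy())
                dt = dv.diversity_table(sub, sub.grouping("zone"), cfg.rarefy_min_zone)
                for stat in ("h_e", "r_s"):
                    comp = dv.compare_groups(dt.per_locus_values(stat), cfg.alpha_letters)
                    comp_zone[(region, stat)] = comp
            priv = dv.private_alleles(samples, samples.grouping("region"))
            mlg = dv.multilocus_genotypes(samples, samples.grouping("region"))
            div_region.per_group.to_csv(out / "diversity_regions.tsv", sep="\t")
            div_zone.per_group.to_csv(out / "diversity_zones.tsv", sep="\t")
            priv.to_csv(out / "private_alleles.tsv", sep="\t", index=False)
            results.update(
                diversity_regions=div_region, diversity_zones=div_zone,
                zone_comparisons=comp_zone, private_alleles=priv,
                multilocus_genotypes=mlg,
            )
            manifest["n_multilocus_genotypes"] = mlg["n_genotypes"]

        if "differentiation" in cfg.stages:
            seed_d = cfg.stage_seed("differentiation")
            am = diff.amova(samples, n_perm=cfg.amova_perms, seed=seed_d)
            fst, nfst = {}, {}
            for region in sorted(set(samples.meta["region"])):
                sub = samples.subset((samples.meta["region"] == region).to_numpy())
                fst[region] = diff.pairwise_fst(
                    sub, sub.grouping("zone"), n_perm=cfg.pairwise_perms, seed=seed_d
                )
                nfst[region] = diff.name_fst(
                    sub, sub.grouping("zone"), n_perm=cfg.pairwise_perms, seed=seed_d
                )
                fst[region].theta.to_csv(out / f"fst_zones_{region}.tsv", sep="\t")
                nfst[region].theta.to_csv(out / f"fst_names_{region}.tsv", sep="\t")
            (out / "amova.json").write_text(json.dumps({
                "components": am.components, "percentages": am.percentages,
                "F_CT": am.f_ct, "F_SC": am.f_sc, "F_ST": am.f_st,
                "p_values": am.p_values, "df": am.df, "n_perm": am.n_perm,
            }, indent=1))
            results.update(amova=am, pairwise_fst=fst, name_fst=nfst)

        if "dapc" in cfg.stages:
            seed0 = cfg.stage_seed("dapc")
            model, selection = dp.dapc_fit(
                samples, k=cfg.dapc_k, k_max=cfg.dapc_k_max, seed=seed0
            )
            k = model.k
            scores, _ = dp.encode_and_reduce(samples)
            replicates = []
            rng = np.random.default_rng(seed0 + 1)
            for _ in range(cfg.dapc_runs - 1):
                fit = dp._best_kmeans(scores, k, 4, rng, None)
                replicates.append(fit.labels_)
            metagroup_map = {c: f"MG{c}" for c in range(k)}
            spec = dp.metagroup_repeatability(model.cluster_labels, metagroup_map, replicates)
            checks = ds.subset((ds.meta["status"] == "check").to_numpy())
            supplementary = (
                dp.project_supplementary(model, checks) if checks.n_individuals else None
            )
            if selection is not None:
                pd.DataFrame({
                    "K": np.arange(1, len(selection.bic) + 1), "BIC": selection.bic,
                }).to_csv(out / "dapc_bic.tsv", sep="\t", index=False)
            pd.DataFrame(
                model.membership,
                index=samples.individuals,
                columns=[f"cluster_{g}" for g in range(k)],
            ).to_csv(out / "dapc_membership.tsv", sep="\t")
            (out / "dapc_repeatability.json").write_text(json.dumps({
                "k": k, "n_runs": cfg.dapc_runs,
                "repeatability": spec.repeatability,
                "merges_credited": spec.merges_credited,
            }, indent=1))
            results.update(dapc_model=model, dapc_selection=selection,
                           metagroups=spec, dapc_supplementary=supplementary)
            manifest["dapc_k"] = k

        if "tree" in cfg.stages:
            seed_t = cfg.stage_seed("tree")
            trees = {}
            for region in sorted(set(samples.meta["region"])):
                sub = samples.subset((samples.meta["region"] == region).to_numpy())
                tree, supports = tr.bootstrap_support(
                    sub, n_boot=cfg.n_boot, seed=seed_t, min_support=40.0
                )
                (out / f"tree_{region}.nwk").write_text(tree.newick() + "\n")
                supports.to_csv(out / f"tree_supports_{region}.tsv", sep="\t", index=False)
                trees[region] = (tree, supports)
            results["trees"] = trees

        manifest["status"] = "complete"
    except Exception as exc:  # partial manifest on stage failure
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return results
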