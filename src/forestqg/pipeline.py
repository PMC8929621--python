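"""End-to-end pipeline driver: genotype QC, pedigree verification, trait
preparation, REML fits and report files.

Stages (each logged with its parameters; any failure aborts with the stage
name while earlier outputs remain on disk):

1. load        — read and cross-validate all inputs
2. genomic     — filter, impute, G-matrix, stabilization
3. pedigree    — conflict detection, correction, A-matrix, class summary
4. traits      — log transforms, drought indices, design adjustment,
                 standardization
5. fits        — univariate per trait and site for A and G; multivariate
                 trait pairs within site; multivariate sites-as-traits
6. report      — heritability table, correlation matrices, JSON summaries

Responses with fewer than ``min_obs`` phenotyped trees are excluded and
reported as NA.  Every random choice flows from the config seed, so the same
config reproduces byte-identical reports.
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import genomic, pedigree as pedmod, report as repmod, traits as traitmod
from .errors import ForestQGError
from .io import Dataset, RunConfig, load_dataset, write_json
from .reml import AnimalModelREML, ModelSpec, MultiTraitREML, fit_multivariate


class StageFailure(ForestQGError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _fmt(df: pd.DataFrame) -> str:
    return df.to_csv(sep="\t", na_rep="NA", float_format="%.6g")


def run_pipeline(config: RunConfig, dataset: Dataset | None = None) -> dict:
    """Run every stage and write the report bundle to ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    outputs: dict = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - reported with stage name
            log.append({"stage": name, "status": "failed", "error": str(exc)})
            write_json({"log": log, "seed": config.seed}, outdir / "run_log.json")
            raise StageFailure(name, exc) from exc
        log.append(
            {
                "stage": name,
                "status": "ok",
                "seconds": round(time.perf_counter() - t0, 3),
            }
        )
        return result

    # 1. load
    if dataset is None:
        dataset = stage("load", lambda: load_dataset(config))
    write_json(dataset.reconciliation, outdir / "reconciliation.json")

    # 2. genomic
    def _genomic():
        if dataset.genotypes is None:
            return None
        gm = genomic.filter_genotypes(
            dataset.genotypes, config.max_missing, config.min_mac
        )
        gm = genomic.impute_mean(gm)
        G = genomic.compute_G(gm)
        return genomic.stabilize_G(G, "ridge", config.g_ridge)

    G = stage("genomic", _genomic)

    # 3. pedigree check / correction, then A
    def _pedigree():
        ped = pedmod.validate_and_order(dataset.pedigree)
        conflicts = None
        if G is not None:
            conflicts = genomic.detect_conflicts(ped, G, config.conflict_threshold)
            ped, conflicts = genomic.correct_pedigree(
                ped, G, conflicts, config.parent_window
            )
            ped = pedmod.validate_and_order(ped)
            (outdir / "conflicts.tsv").write_text(_fmt(conflicts.pairs))
            write_json(conflicts.to_json_summary(), outdir / "conflicts.json")
        A = pedmod.compute_A(ped)
        summary = pedmod.relationship_summary(A, ped)
        (outdir / "relationship_summary_A.tsv").write_text(_fmt(summary))
        if G is not None:
            shared = [i for i in G.ids if i in set(ped.ids)]
            gsum = pedmod.relationship_summary(G.subset(shared), ped)
            (outdir / "relationship_summary_G.tsv").write_text(_fmt(gsum))
        return ped, A

    ped, A = stage("pedigree", _pedigree)

    # 4. trait preparation
    def _traits():
        df = dataset.phenotypes.copy()
        if dataset.rings is not None:
            idx = traitmod.rings_to_indices(
                dataset.rings, config.drought_year, config.pre_window
            )
            df = df.merge(
                idx[["resistance", "sensitivity"]],
                left_on="tree",
                right_index=True,
                how="left",
            )
        for t in config.log_traits:
            if t in df.columns:
                df[t] = traitmod.log_transform(df[t])
        all_traits = [t for t in config.traits if t in df.columns]
        for t in list(all_traits):
            df[t] = traitmod.design_adjust(df, t)
            for s, sub in df.groupby("site"):
                x = sub[t].to_numpy(dtype=float)
                if np.isfinite(x).sum() >= 2 and np.nanstd(x) > 0:
                    df.loc[sub.index, t] = traitmod.standardize(x)
        (outdir / "trait_summary.tsv").write_text(_fmt(traitmod.trait_summary(df)))
        return df

    data = stage("traits", _traits)

    sites = config.sites or sorted(data["site"].unique())
    kernels = {"A": A} if G is None else {"A": A, "G": G}

    def _n_obs(trait, site):
        sub = data[(data["site"] == site)] if site else data
        return int(sub[trait].notna().sum()) if trait in sub.columns else 0

    # 5. fits
    def _fits():
        uni = {}
        skipped = []
        for trait in config.traits:
            for site in sites:
                if _n_obs(trait, site) < config.min_obs:
                    skipped.append({"trait": trait, "site": site, "reason": "n<min_obs"})
                    continue
                for source, K in kernels.items():
                    est = AnimalModelREML(
                        response=trait,
                        site=site,
                        groups="group" if "group" in data.columns else None,
                        tol=config.tol,
                        max_iter=config.max_iter,
                        k_ridge=1e-8,
                    ).fit(data, K)
                    uni[(trait, site, source)] = est.result_

        pair_fits = {}
        for t1, t2 in config.trait_pairs:
            for site in sites:
                if min(_n_obs(t1, site), _n_obs(t2, site)) < config.min_obs:
                    continue
                for source, K in kernels.items():
                    est = MultiTraitREML(
                        responses=[(t1, site), (t2, site)],
                        groups="group" if "group" in data.columns else None,
                        tol=config.tol,
                        max_iter=config.max_iter,
                        k_ridge=1e-8,
                    ).fit(data, K)
                    pair_fits[(t1, t2, site, source)] = est.result_

        site_fits = {}
        for trait in config.site_model_traits:
            ok_sites = [s for s in sites if _n_obs(trait, s) >= config.min_obs]
            for source, K in kernels.items():
                if len(ok_sites) < 2:
                    site_fits[(trait, source)] = None
                    continue
                spec = ModelSpec(
                    responses=[(trait, s) for s in ok_sites],
                    groups="group" if "group" in data.columns else None,
                    relationship_source=source,
                    tol=config.tol,
                    max_iter=config.max_iter,
                )
                site_fits[(trait, source)] = fit_multivariate(spec, data, K)
        return uni, pair_fits, site_fits, skipped

    uni, pair_fits, site_fits, skipped = stage("fits", _fits)

    # 6. reports
    def _report():
        h2 = repmod.heritability_table(uni)
        (outdir / "heritability.tsv").write_text(
            _fmt(h2.set_index(["trait", "site", "source"]))
        )
        rows = []
        for (t1, t2, site, source), fit in pair_fits.items():
            ra, se = repmod.genetic_correlation(fit.vc, (0, 1))
            rows.append(
                {
                    "trait_i": t1,
                    "trait_j": t2,
                    "site": site,
                    "source": source,
                    "r_a": ra,
                    "se": se,
                    "label": "NA" if np.isnan(ra) else repmod.classify_correlation(
                        float(np.clip(ra, -1, 1))
                    ),
                }
            )
        pairs_df = pd.DataFrame(
            rows, columns=["trait_i", "trait_j", "site", "source", "r_a", "se", "label"]
        )
        (outdir / "trait_correlations.tsv").write_text(
            _fmt(pairs_df.set_index(["trait_i", "trait_j", "site", "source"]))
        )
        for source in kernels:
            per_trait = {
                t: site_fits.get((t, source)) for t in config.site_model_traits
            }
            if per_trait:
                mats = repmod.cross_site_report(per_trait, sites)
                text = []
                for trait, parts in mats.items():
                    text.append(f"# trait: {trait} source: {source}\n")
                    text.append(parts["r"].to_csv(sep="\t", na_rep="NA", float_format="%.6g"))
                (outdir / f"site_correlations_{source}.tsv").write_text("".join(text))
        write_json(
            {"skipped_responses": skipped, "seed": config.seed},
            outdir / "fit_summary.json",
        )
        return {"heritability": h2, "trait_pairs": pairs_df}

    outputs = stage("report", _report)
    write_json({"log": log, "seed": config.seed, "config": config.to_yaml()},
               outdir / "run_log.json")
    outputs["log"] = log
    outputs["uni_fits"] = uni
    outputs["pair_fits"] = pair_fits
    outputs["site_fits"] = site_fits
    return outputs
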