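"""End-to-end pipeline: filters -> diversity -> exposure index ->
dose-response -> associations -> networks -> neutral model.

``run_pipeline`` executes every stage on an aligned cohort bundle and
writes tabular outputs plus a machine-readable run manifest (thresholds,
seeds, package version) into the output directory.  Any stage failure
aborts with the stage name and cause.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import AnalysisConfig
from .exposure import score_exposures, spearman_dose_response
from .network import (
    attack_stability,
    clr,
    filter_weak_edges,
    infer_network,
    network_summary,
    prevalence_filter,
)
from .neutral import classify_taxa, fit_sloan, fit_summary, occupancy_abundance
from .stats import (
    abundance_filter,
    css_normalize,
    distance,
    fit_associations,
    goods_coverage,
    permanova,
    rarefy,
    shannon,
)
from .tables import CohortBundle

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(
    bundle: CohortBundle, config: AnalysisConfig, out_dir: str | Path
) -> dict:
    """Run every analysis stage and write results under ``out_dir``.

    Returns a dict of in-memory results keyed by stage.  Outputs are
    plain TSV/JSON; re-running with the same config and seeds reproduces
    them byte for byte.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest: dict = {
        "version": __version__,
        "config": {
            k: v for k, v in vars(config).items() if k != "extra_seeds"
        },
        "seeds": {},
        "stages": [],
    }

    def stage(name: str):
        manifest["stages"].append(name)
        logger.info("stage: %s", name)

    try:
        stage("filters")
        dep_b = config.rarefaction_depth_bacteria
        dep_f = config.rarefaction_depth_fungi
        seed_r = config.seed_for("rarefy")
        manifest["seeds"]["rarefy"] = seed_r
        rare_b = rarefy(bundle.bacteria, dep_b, seed_r)
        rare_f = rarefy(bundle.fungi, dep_f, seed_r + 1)
        filt_b = abundance_filter(bundle.bacteria, config.abundance_min)
        filt_f = abundance_filter(bundle.fungi, config.abundance_min)
        results["filters"] = {
            "bacteria_taxa_retained": filt_b.n_taxa,
            "fungi_taxa_retained": filt_f.n_taxa,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("filters", exc) from exc

    try:
        stage("diversity")
        div = []
        for name, t in (("bacteria", rare_b), ("fungi", rare_f)):
            h = shannon(t.counts.to_numpy())
            cov = goods_coverage(t.counts.to_numpy())
            div.append(
                pd.DataFrame(
                    {
                        "sample_id": t.sample_ids,
                        "domain": name,
                        "shannon": h,
                        "goods_coverage": cov,
                    }
                )
            )
        diversity = pd.concat(div, ignore_index=True)
        diversity.to_csv(out / "diversity.tsv", sep="\t", index=False)
        results["diversity"] = diversity

        seed_p = config.seed_for("permanova")
        manifest["seeds"]["permanova"] = seed_p
        meta_b = bundle.meta.loc[rare_b.sample_ids]
        perm_rows = []
        for metric in ("bray_curtis", "binary_jaccard"):
            D = distance(rare_b, metric)
            for var in ("site", "city"):
                res = permanova(
                    D, meta_b[var], config.n_permutations, seed_p, grouping=var
                )
                perm_rows.append(
                    {
                        "metric": metric,
                        "grouping": var,
                        "pseudo_F": res.pseudo_F,
                        "p": res.p,
                    }
                )
        permdf = pd.DataFrame(perm_rows)
        permdf.to_csv(out / "permanova.tsv", sep="\t", index=False)
        results["permanova"] = permdf
    except Exception as exc:  # noqa: BLE001
        raise StageError("diversity", exc) from exc

    try:
        stage("exposure_index")
        es = score_exposures(bundle.exposures, k=config.n_exposure_groups)
        scores = pd.DataFrame(
            {"score": es.score, "group": es.group}
        )
        scores.index.name = "subject_id"
        scores.to_csv(out / "exposure_scores.tsv", sep="\t")
        es.loadings.to_csv(out / "exposure_loadings.tsv", sep="\t")
        results["exposure"] = es
    except Exception as exc:  # noqa: BLE001
        raise StageError("exposure_index", exc) from exc

    try:
        stage("dose_response")
        rows = []
        for dom, filt in (("bacteria", filt_b), ("fungi", filt_f)):
            ra = filt.relative_abundance()
            meta = bundle.meta.loc[ra.index]
            sc = es.score.reindex(meta["subject_id"]).to_numpy()
            for site in ("cheek", "scalp"):
                m = (meta["site"] == site).to_numpy()
                if m.sum() < 5:
                    continue
                for genus, cols in filt.genus.groupby(filt.genus).groups.items():
                    feat = ra.loc[m, list(cols)].sum(axis=1).to_numpy()
                    if np.all(feat == feat[0]):
                        continue
                    rho, p = spearman_dose_response(feat, sc[m])
                    rows.append(
                        {
                            "domain": dom,
                            "site": site,
                            "genus": genus,
                            "rho": rho,
                            "p": p,
                        }
                    )
        dose = pd.DataFrame(rows)
        dose.to_csv(out / "dose_response.tsv", sep="\t", index=False)
        results["dose_response"] = dose
    except Exception as exc:  # noqa: BLE001
        raise StageError("dose_response", exc) from exc

    try:
        stage("associations")
        assoc_frames = []
        for site in ("cheek", "scalp"):
            mask = bundle.meta["site"] == site
            sub = filt_b.select_samples(bundle.meta.index[mask])
            css = css_normalize(sub)
            ra = sub.select_samples(css.index).relative_abundance()
            meta = bundle.meta.loc[ra.index, ["city", "age_group"]].copy()
            meta["exposure_score"] = (
                es.score.reindex(bundle.meta.loc[ra.index, "subject_id"]).to_numpy()
            )
            res = fit_associations(
                ra,
                meta,
                ["city", "age_group", "exposure_score"],
                q_threshold=config.q_threshold,
            )
            res.insert(0, "site", site)
            assoc_frames.append(res)
        assoc = pd.concat(assoc_frames, ignore_index=True)
        assoc.to_csv(out / "associations.tsv", sep="\t", index=False)
        results["associations"] = assoc
    except Exception as exc:  # noqa: BLE001
        raise StageError("associations", exc) from exc

    try:
        stage("networks")
        seed_n = config.seed_for("network")
        manifest["seeds"]["network"] = seed_n
        net_rows, curves = [], []
        for site in ("cheek", "scalp"):
            ids = bundle.meta.index[bundle.meta["site"] == site]
            pb = prevalence_filter(
                bundle.bacteria.select_samples(ids), config.prevalence_min
            )
            pf = prevalence_filter(
                bundle.fungi.select_samples(ids), config.prevalence_min
            )
            net = infer_network(
                clr(pb),
                clr(pf),
                n_subsamples=config.n_subsamples,
                stability_threshold=config.stability_threshold,
                seed=seed_n,
            )
            net = filter_weak_edges(net, config.edge_weight_min)
            summ = network_summary(net)
            curve = attack_stability(net)
            net.edge_frame().to_csv(
                out / f"network_edges_{site}.tsv", sep="\t", index=False
            )
            pd.DataFrame(
                {
                    "step": range(len(curve.connectivity)),
                    "natural_connectivity": curve.connectivity,
                    "percent_reduction": curve.percent_reduction,
                }
            ).to_csv(out / f"attack_curve_{site}.tsv", sep="\t", index=False)
            net_rows.append({"site": site, **{k: v for k, v in summ.items() if not isinstance(v, dict)}})
            curves.append(curve)
        pd.DataFrame(net_rows).to_csv(out / "network_summary.tsv", sep="\t", index=False)
        results["networks"] = net_rows
        results["attack_curves"] = curves
    except Exception as exc:  # noqa: BLE001
        raise StageError("networks", exc) from exc

    try:
        stage("neutral_model")
        fits = []
        for dom, rare in (("bacteria", rare_b), ("fungi", rare_f)):
            meta = bundle.meta.loc[rare.sample_ids]
            for city in sorted(meta["city"].unique()):
                for site in ("cheek", "scalp"):
                    ids = meta.index[(meta["city"] == city) & (meta["site"] == site)]
                    if len(ids) < 10:
                        continue
                    grp = rare.select_samples(ids)
                    N_t = float(grp.library_sizes().mean())
                    pts = occupancy_abundance(grp)
                    if len(pts) < 10:
                        continue
                    fit = classify_taxa(fit_sloan(pts, N_t))
                    fit_summary(fit).to_csv(
                        out / f"neutral_{dom}_{city}_{site}.tsv",
                        sep="\t",
                        index=False,
                    )
                    fits.append(
                        {
                            "domain": dom,
                            "city": city,
                            "site": site,
                            "m": fit.m,
                            "R2": fit.R2,
                            "aic_neutral": fit.aic_neutral,
                            "aic_binomial": fit.aic_binomial,
                            "aic_poisson": fit.aic_poisson,
                        }
                    )
        neutral = pd.DataFrame(fits)
        neutral.to_csv(out / "neutral_fits.tsv", sep="\t", index=False)
        results["neutral"] = neutral
    except Exception as exc:  # noqa: BLE001
        raise StageError("neutral_model", exc) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results

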