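"""Cohort table I/O and the end-to-end pipeline driver.

A cohort table is a pandas DataFrame with columns ``subject_id`` (unique
string), ``sex`` (M/F), ``age`` (years), the 46 peak columns
``GP1``..``GP46`` in percent of total area, plus any declared
covariates.  Peak rows are closed to 100 on load; a raw row sum more
than 0.5 percentage points away from 100 is counted as a closure warning.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coda import GP_COLUMNS, close, ilr, spearman_ilr
from .simulate import GeneratorConfig, generate_cohort
from .traits import trait_table
from .trends import fit_sexwise_ilr_trends, predict_composition_curve
from .cluster import (adjusted_outcome_models, characterize_clusters,
                      choose_k_elbow, robust_pca)
from .inference import global_composition_test, peakwise_comparison

logger = logging.getLogger("glycoda")

__all__ = ["read_cohort", "write_cohort", "validate_cohort", "run_pipeline"]


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate schema and close peak rows to 100%.

    Returns a copy with closed GP columns; the number of rows whose raw
    sum deviated from 100 by more than 1% is stored in
    ``df.attrs["closure_warnings"]``.
    """
    missing = [c for c in ("subject_id", "sex", "age", *GP_COLUMNS)
               if c not in df.columns]
    if missing:
        raise ValueError(f"missing column(s): {', '.join(missing)}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject_id: {dup!r}")
    bad_sex = set(df["sex"].unique()) - {"M", "F"}
    if bad_sex:
        raise ValueError(f"sex must be coded M/F, found {sorted(bad_sex)}")
    age = pd.to_numeric(df["age"], errors="coerce")
    if age.isna().any() or (age < 18).any() or (age > 120).any():
        raise ValueError("age must be numeric and within [18, 120]")
    gp = df[GP_COLUMNS].apply(pd.to_numeric, errors="coerce")
    if gp.isna().any().any():
        col = gp.columns[gp.isna().any()][0]
        row = int(gp.index[gp[col].isna()][0])
        raise ValueError(f"non-numeric peak value at row {row}, column {col}")
    if (gp < 0).any().any():
        raise ValueError("peak abundances must be non-negative")
    raw_sums = gp.sum(axis=1).to_numpy()
    n_warn = int(np.sum(np.abs(raw_sums - 100.0) > 0.5))
    if n_warn:
        warnings.warn(f"{n_warn} row(s) had raw peak sums deviating >0.5 "
                      "from 100; closed on load", stacklevel=2)
    out = df.copy()
    out[GP_COLUMNS] = close(gp.to_numpy(float))
    out.attrs["closure_warnings"] = n_warn
    return out


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort table from a comma- or tab-delimited text file."""
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    return validate_cohort(pd.read_csv(path, sep=sep))


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV (12 significant digits)."""
    df.to_csv(path, index=False, float_format="%.12g")


_DEFAULT_PIPELINE_CONFIG = {
    "seed": 1,
    "simulate": {},            # GeneratorConfig overrides, or None with input
    "input": None,             # path to a cohort file instead of simulating
    "trends": {"targets": ["GP5", "GP14"], "n_draws": 500},
    "cluster": {"k_max": 8, "n_init": 25, "h_fraction": 0.75},
    "test": {"n_perm": 499},
    "figures": False,
}


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: dict | str | Path | None = None,
                 outdir: str | Path = "glycoda_run") -> dict:
    """Run the full analysis: simulate/load -> traits -> sex comparison ->
    age trends -> robust PCA -> clustering -> phenotyping -> adjusted
    models.  Writes per-stage TSVs plus a run log under ``outdir`` and
    returns a report dict.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = json.loads(json.dumps(_DEFAULT_PIPELINE_CONFIG))
    for key, val in (config or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    seed = int(cfg["seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_text = yaml.safe_dump(cfg, sort_keys=True)
    cfg_hash = hashlib.sha256(cfg_text.encode()).hexdigest()[:16]
    report: dict = {"config_hash": cfg_hash, "seed": seed,
                    "version": __version__, "stages": []}

    def stage(name):
        logger.info("stage: %s", name)
        report["stages"].append(name)

    try:
        stage("cohort")
        if cfg.get("input"):
            cohort = read_cohort(cfg["input"])
            truth = None
        else:
            sim_over = dict(cfg.get("simulate") or {})
            sim_over.setdefault("seed", seed)
            gen_cfg = GeneratorConfig(**sim_over)
            sim = generate_cohort(gen_cfg)
            cohort = sim.cohort_table
            truth = sim
            write_cohort(cohort, outdir / "cohort.csv")
            with open(outdir / "generator_config.yaml", "w") as fh:
                echo = dataclasses.asdict(sim.config_echo)
                yaml.safe_dump(
                    {k: (v.tolist() if isinstance(v, np.ndarray) else
                         {kk: vv.tolist() for kk, vv in v.items()}
                         if isinstance(v, dict) else v)
                     for k, v in echo.items()}, fh)

        stage("traits")
        traits = trait_table(cohort)
        _write_tsv(traits.assign(subject_id=cohort["subject_id"].to_numpy()),
                   outdir / "traits.tsv")

        stage("ilr")
        z = ilr(cohort[GP_COLUMNS].to_numpy(float))
        rho = spearman_ilr(z)
        np.savetxt(outdir / "spearman_ilr.tsv", rho, delimiter="\t", fmt="%.6f")

        stage("sex_comparison")
        gp = cohort[GP_COLUMNS].to_numpy(float)
        men = gp[(cohort["sex"] == "M").to_numpy()]
        women = gp[(cohort["sex"] == "F").to_numpy()]
        gtest = global_composition_test(men, women,
                                        n_perm=int(cfg["test"]["n_perm"]),
                                        seed=seed)
        pw = peakwise_comparison(men, women)
        _write_tsv(pw, outdir / "peakwise_sex.tsv")
        report["sex_global_p"] = gtest.p_value
        report["sex_peakwise_significant"] = int(pw["significant"].sum())

        stage("trends")
        fits = fit_sexwise_ilr_trends(cohort)
        grid = np.linspace(cohort["age"].min(), cohort["age"].max(), 40)
        curve_rows = []
        for sex in ("M", "F"):
            curves = predict_composition_curve(
                fits, sex, grid, n_draws=int(cfg["trends"]["n_draws"]),
                seed=seed)
            wanted = set(cfg["trends"]["targets"] or GP_COLUMNS)
            unknown = wanted - set(GP_COLUMNS)
            if unknown:
                raise ValueError(f"unknown trend target(s): {sorted(unknown)}")
            for c in curves:
                if c.target in wanted:
                    for a, m, lo, hi in zip(c.age_grid, c.mean, c.lower95,
                                            c.upper95):
                        curve_rows.append({"target": c.target, "sex": sex,
                                           "age": a, "mean": m,
                                           "lo95": lo, "hi95": hi})
        _write_tsv(pd.DataFrame(curve_rows), outdir / "trend_curves.tsv")

        stage("pca")
        pca = robust_pca(z, h_fraction=float(cfg["cluster"]["h_fraction"]),
                         k_components=2, seed=seed)
        report["pca_top2_explained"] = float(pca.explained_fraction[:2].sum())

        stage("cluster")
        res = choose_k_elbow(z, k_max=int(cfg["cluster"]["k_max"]),
                             n_init=int(cfg["cluster"]["n_init"]), seed=seed)
        report["chosen_k"] = res.chosen_k
        report["no_clear_elbow"] = res.no_clear_elbow
        report["cluster_sizes"] = np.bincount(res.labels)[1:].tolist()
        labelled = cohort.copy()
        labelled["cluster"] = res.labels
        write_cohort(labelled, outdir / "cohort_labelled.csv")
        _write_tsv(pd.DataFrame({"k": list(res.wss_curve),
                                 "wss": list(res.wss_curve.values())}),
                   outdir / "elbow_wss.tsv")
        if truth is not None:
            from sklearn.metrics import adjusted_rand_score
            report["ari_vs_truth"] = float(
                adjusted_rand_score(truth.true_labels, res.labels))

        stage("phenotyping")
        trait_tab, cov_tab = characterize_clusters(cohort, res.labels)
        _write_tsv(trait_tab, outdir / "cluster_traits.tsv")
        _write_tsv(cov_tab, outdir / "cluster_covariates.tsv")

        stage("adjusted_models")
        try:
            adj = adjusted_outcome_models(cohort, res.labels)
            _write_tsv(adj, outdir / "adjusted_models.tsv")
        except (KeyError, ValueError) as exc:
            report["adjusted_models_skipped"] = str(exc)

        if cfg.get("figures"):
            stage("figures")
            import matplotlib
            matplotlib.use("Agg")
            import matplotlib.pyplot as plt
            fig, ax = plt.subplots()
            ax.plot(list(res.wss_curve), list(res.wss_curve.values()), "o-")
            ax.set_xlabel("k")
            ax.set_ylabel("within-cluster sum of squares")
            fig.savefig(outdir / "elbow.png", dpi=120)
            plt.close(fig)
            fig, ax = plt.subplots()
            for lab in np.unique(res.labels):
                pts = pca.scores[res.labels == lab]
                ax.scatter(pts[:, 0], pts[:, 1], s=4, label=f"cluster {lab}")
            ax.set_xlabel("PC1")
            ax.set_ylabel("PC2")
            ax.legend()
            fig.savefig(outdir / "biplot.png", dpi=120)
            plt.close(fig)
    except Exception as exc:
        failed = report["stages"][-1] if report["stages"] else "setup"
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(report, fh, indent=2)
    with open(outdir / "config_used.yaml", "w") as fh:
        fh.write(cfg_text)
    return report
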