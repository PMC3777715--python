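"""End-to-end analysis pipeline: preprocess -> SL -> graphs -> group statistics.

`run_pipeline` ties the stages together for a whole cohort and emits tidy
tables plus a JSON-serializable report: per-band mean-SL group tests,
network-based statistics on the edge-wise SL, global metric comparisons
across the density sweep, nodal comparisons and small-world normalization
at the fixed local density, clinical-score partial correlations in the
patient group, and the demographic table tests. Every stage derives its
randomness from the single configured seed, so a rerun reproduces the
report byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import graph as g
from . import stats as st
from .containers import Recording
from .datasets import SubjectMeta, meta_to_frame
from .io import write_metadata, write_sl_matrix
from .montage import BANDS
from .preprocess import PreprocessConfig, preprocess_recording
from .sl import EmbeddingParams, SLMatrix, embed_parameters, mean_sl, sl_matrix

logger = logging.getLogger("slgraph")

__all__ = ["AnalysisConfig", "run_pipeline"]

_DEFAULT_DENSITIES = tuple(round(0.05 * k, 2) for k in range(1, 21))


@dataclass
class AnalysisConfig:
    """Knobs of the full pipeline (defaults follow the study design)."""

    bands: tuple[str, ...] = tuple(BANDS)
    densities: tuple[float, ...] = _DEFAULT_DENSITIES
    p_ref: float = 0.01
    n_ref: int = 10
    sl_metric: str = "euclidean"
    n_perm: int = 10_000
    t_threshold: float = 2.61
    local_density: float = 0.30
    alpha: float = 0.05
    nodal_alpha: float = 0.01
    n_surrogates: int = 50
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    covariate_columns: tuple[str, ...] = ("age", "sex", "iq")
    seed: int = 0

    def validate(self) -> None:
        for d in self.densities:
            if not 0 < d <= 1:
                raise ValueError(f"densities must lie in (0, 1], got {d}")
        unknown = set(self.bands) - set(self.preprocess.bands)
        if unknown:
            raise ValueError(f"bands not configured in preprocess: {sorted(unknown)}")

    def embedding_for(self, band: str, fs: float) -> EmbeddingParams:
        lo, hi = self.preprocess.bands[band]
        return embed_parameters(lo, hi, fs, p_ref=self.p_ref, n_ref=self.n_ref,
                                metric=self.sl_metric)


def _covariates(meta: pd.DataFrame, cols: tuple[str, ...]) -> pd.DataFrame:
    return meta.loc[:, list(cols)]


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-12s %.2f s", name, t1 - t0)
    return t1


def run_pipeline(
    recordings: list[Recording],
    meta: list[SubjectMeta] | pd.DataFrame,
    config: AnalysisConfig | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full analysis for a cohort and return the report dict.

    ``meta`` rows must align with ``recordings`` by subject id. When
    ``out_dir`` is given, SL matrices, tidy metric tables and the JSON
    report are written beneath it.
    """
    config = config or AnalysisConfig()
    config.validate()
    meta_df = meta if isinstance(meta, pd.DataFrame) else meta_to_frame(meta)
    meta_df = meta_df.set_index("subject_id", drop=False)
    missing = [r.subject_id for r in recordings if r.subject_id not in meta_df.index]
    if missing:
        raise ValueError(f"recordings without metadata: {missing}")
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        (out / "matrices").mkdir(parents=True, exist_ok=True)

    seeds = np.random.SeedSequence(config.seed).spawn(6)
    seed_of = {name: int(np.random.default_rng(s).integers(0, 2**31 - 1))
               for name, s in zip(
                   ("mean_sl", "nbs", "global", "normalized", "nodal", "misc"), seeds)}

    t0 = time.perf_counter()

    # ---- preprocessing + SL ------------------------------------------------
    matrices: dict[tuple[str, str], SLMatrix] = {}
    rejections: dict[str, int] = {}
    subject_ids: list[str] = []
    for rec in recordings:
        try:
            per_band = preprocess_recording(rec, config.preprocess,
                                            bands=list(config.bands))
        except ValueError as err:
            raise ValueError(f"preprocess failed for {rec.subject_id}: {err}") from err
        subject_ids.append(rec.subject_id)
        any_band = next(iter(per_band.values()))
        rejections[rec.subject_id] = int(any_band.rejected_mask.sum())
        for band, ep in per_band.items():
            params = config.embedding_for(band, ep.fs)
            try:
                m = sl_matrix(ep, params)
            except ValueError as err:
                raise ValueError(
                    f"SL failed for {rec.subject_id}/{band}: {err}"
                ) from err
            matrices[(rec.subject_id, band)] = m
            if out is not None:
                write_sl_matrix(m, out / "matrices" / f"{rec.subject_id}_{band}.tsv",
                                params=params)
    t0 = _stage("connectivity", t0)

    meta_df = meta_df.loc[subject_ids]
    groups = meta_df["group"].to_numpy()
    cov = _covariates(meta_df, config.covariate_columns)

    # ---- mean SL per band --------------------------------------------------
    mean_rows, mean_tests = [], {}
    for band in config.bands:
        values = np.array([mean_sl(matrices[(s, band)]) for s in subject_ids])
        for s, v in zip(subject_ids, values):
            mean_rows.append({"subject_id": s, "band": band, "mean_sl": v})
        res = st.permutation_test(values, groups, covariates=cov,
                                  n_perm=config.n_perm, seed=seed_of["mean_sl"])
        mean_tests[band] = {"observed_t": res.observed_t, "p_value": res.p_value}
    mean_sl_df = pd.DataFrame(mean_rows)
    t0 = _stage("mean_sl", t0)

    # ---- NBS per band ------------------------------------------------------
    nbs_results = {}
    for band in config.bands:
        stack = np.stack([matrices[(s, band)].values for s in subject_ids])
        res = st.nbs(stack, groups, t_threshold=config.t_threshold,
                     n_perm=config.n_perm, seed=seed_of["nbs"])
        labels = matrices[(subject_ids[0], band)].labels
        nbs_results[band] = {
            "n_suprathreshold_edges": len(res.suprathreshold_edges),
            "components": [
                {
                    "links": [[labels[i], labels[j]] for i, j in comp],
                    "n_links": size,
                    "corrected_p": p,
                }
                for comp, size, p in zip(res.components, res.component_sizes,
                                         res.corrected_p)
            ],
        }
    t0 = _stage("nbs", t0)

    # ---- global metrics over the density sweep -----------------------------
    glob_rows = []
    for band in config.bands:
        for s in subject_ids:
            for d in config.densities:
                net = g.threshold_by_density(matrices[(s, band)], d)
                gm = g.global_metrics(net)
                glob_rows.append({"subject_id": s, "band": band, "density": d,
                                  "C": gm.C, "L": gm.L, "Eg": gm.Eg})
    global_df = pd.DataFrame(glob_rows)
    glob_tests = []
    for band in config.bands:
        for d in config.densities:
            sub = global_df[(global_df.band == band) & (global_df.density == d)]
            sub = sub.set_index("subject_id").loc[subject_ids]
            for metric in ("C", "L", "Eg"):
                res = st.permutation_test(sub[metric].to_numpy(), groups,
                                          covariates=cov, n_perm=config.n_perm,
                                          seed=seed_of["global"])
                glob_tests.append({"band": band, "density": d, "metric": metric,
                                   "observed_t": res.observed_t,
                                   "p_value": res.p_value})
    global_tests_df = pd.DataFrame(glob_tests)
    t0 = _stage("global", t0)

    # ---- normalized metrics + clinical correlations at the local density ---
    norm_rows = []
    rng_norm = np.random.default_rng(seed_of["normalized"])
    for band in config.bands:
        for s in subject_ids:
            net = g.threshold_by_density(matrices[(s, band)], config.local_density)
            gamma, lam, sigma = g.normalized_metrics(
                net, n_surrogates=config.n_surrogates,
                seed=int(rng_norm.integers(0, 2**31 - 1)))
            gm = g.global_metrics(net)
            norm_rows.append({"subject_id": s, "band": band, "C": gm.C, "L": gm.L,
                              "Eg": gm.Eg, "gamma": gamma, "lambda": lam,
                              "sigma": sigma})
    norm_df = pd.DataFrame(norm_rows)
    norm_tests = []
    for band in config.bands:
        sub = norm_df[norm_df.band == band].set_index("subject_id").loc[subject_ids]
        for metric in ("gamma", "lambda", "sigma"):
            res = st.permutation_test(sub[metric].to_numpy(), groups,
                                      covariates=cov, n_perm=config.n_perm,
                                      seed=seed_of["normalized"])
            norm_tests.append({"band": band, "metric": metric,
                               "observed_t": res.observed_t, "p_value": res.p_value})
    norm_tests_df = pd.DataFrame(norm_tests)

    correlations = []
    pat_ids = [s for s in subject_ids if meta_df.loc[s, "group"] == "patient"]
    n_cov = len(config.covariate_columns)
    if len(pat_ids) >= n_cov + 3:
        pat_cov = _covariates(meta_df.loc[pat_ids], config.covariate_columns)
        for score_name in ("madrs", "ymrs"):
            score = meta_df.loc[pat_ids, score_name].to_numpy(dtype=float)
            if score.std() == 0:
                continue
            for band in config.bands:
                sub = norm_df[norm_df.band == band].set_index("subject_id").loc[pat_ids]
                for metric in ("C", "L", "Eg", "gamma", "lambda", "sigma"):
                    vals = sub[metric].to_numpy()
                    if vals.std() == 0:
                        continue
                    cr = st.partial_correlation(vals, score, pat_cov)
                    correlations.append({"band": band, "metric": metric,
                                         "score": score_name, "r": cr.r,
                                         "p_value": cr.p_value, "n": cr.n})
    correlations_df = pd.DataFrame(correlations)
    t0 = _stage("normalized", t0)

    # ---- nodal metrics at the local density --------------------------------
    nodal_rows = []
    for band in config.bands:
        labels = matrices[(subject_ids[0], band)].labels
        per_subject = {}
        for s in subject_ids:
            net = g.threshold_by_density(matrices[(s, band)], config.local_density)
            per_subject[s] = g.nodal_metrics(net)
        for metric, attr in (("strength", "strength"),
                             ("betweenness", "betweenness"),
                             ("local_efficiency", "local_efficiency")):
            stack = np.array([getattr(per_subject[s], attr) for s in subject_ids])
            for ni, node in enumerate(labels):
                res = st.permutation_test(stack[:, ni], groups, covariates=cov,
                                          n_perm=config.n_perm,
                                          seed=seed_of["nodal"])
                nodal_rows.append({"band": band, "node": node, "metric": metric,
                                   "observed_t": res.observed_t,
                                   "p_value": res.p_value,
                                   "significant": res.p_value < config.nodal_alpha})
    nodal_df = pd.DataFrame(nodal_rows)
    t0 = _stage("nodal", t0)

    # ---- demographics ------------------------------------------------------
    try:
        demo_df = st.demographic_tests(meta_df.reset_index(drop=True))
    except ValueError as err:  # e.g. an empty sex cell in a tiny cohort
        logger.warning("demographic tests skipped: %s", err)
        demo_df = pd.DataFrame(
            columns=["variable", "test", "statistic", "df", "p_value"])

    report = {
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "preprocess"},
            "preprocess": asdict(config.preprocess),
        },
        "n_subjects": len(subject_ids),
        "rejected_epochs": rejections,
        "mean_sl_tests": mean_tests,
        "nbs": nbs_results,
        "demographics": demo_df.to_dict(orient="records"),
        "n_significant_global": int((global_tests_df.p_value < config.alpha).sum())
        if len(global_tests_df) else 0,
    }

    if out is not None:
        write_metadata(meta_df.reset_index(drop=True), out / "metadata.csv")
        mean_sl_df.to_csv(out / "mean_sl.csv", index=False)
        global_df.to_csv(out / "global_metrics.csv", index=False)
        global_tests_df.to_csv(out / "global_tests.csv", index=False)
        norm_df.to_csv(out / "normalized_metrics.csv", index=False)
        norm_tests_df.to_csv(out / "normalized_tests.csv", index=False)
        nodal_df.to_csv(out / "nodal_tests.csv", index=False)
        if len(correlations_df):
            correlations_df.to_csv(out / "clinical_correlations.csv", index=False)
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))

    report["tables"] = {
        "mean_sl": mean_sl_df,
        "global_metrics": global_df,
        "global_tests": global_tests_df,
        "normalized_metrics": norm_df,
        "normalized_tests": norm_tests_df,
        "nodal_tests": nodal_df,
        "clinical_correlations": correlations_df,
        "demographics": demo_df,
    }
    return report
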