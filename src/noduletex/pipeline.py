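"""End-to-end orchestration: simulate -> segment -> extract -> average ->
select -> cutoffs -> models -> reader evaluation, with provenance."""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from . import __version__
from .config import PipelineConfig
from .cutoff_models import (binarize, cutoff_table, roc_auc, stepwise_logistic,
                            univariate_logistic, youden_cutoff)
from .feature_selection import (LABEL_COLUMN, fit_score_model, lasso_importance,
                                radiomics_score, select_top)
from .imaging_roi import Rect, RoiMask, apply_manual_override, segment_nodule
from .reader_eval import compare_auc_paired, reader_report
from .synthetic_cohort import SyntheticCase, generate_cohort, generate_reader_table
from .texture_features import TextureConfig, average_readers, extract_all

log = logging.getLogger("noduletex")


def _seed_rect(case: SyntheticCase, pad: int = 3) -> Rect:
    """Bounding rectangle of the truth mask padded by a few pixels — the
    deterministic stand-in for the manual rectangle seed."""
    rows, cols = np.nonzero(case.truth_mask.mask)
    nrow, ncol = case.image.shape
    return Rect(max(0, rows.min() - pad), max(0, cols.min() - pad),
                min(nrow, rows.max() + 1 + pad), min(ncol, cols.max() + 1 + pad))


def extract_case_features(case: SyntheticCase, texture: TextureConfig
                          ) -> Tuple[pd.Series, pd.Series, pd.Series]:
    """Per-case feature vectors for two delineations plus their average.

    Delineation A is the automatic segmentation from the rectangle seed;
    delineation B applies the manual-override path with the reference mask.
    """
    try:
        auto = segment_nodule(case.image, _seed_rect(case), reader_id="readerA")
    except ValueError:
        # degenerate auto segmentation: fall back to the reference outline
        auto = RoiMask(mask=case.truth_mask.mask, reader_id="readerA")
    manual = apply_manual_override(auto, RoiMask(mask=case.truth_mask.mask,
                                                reader_id="readerB"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fa = extract_all(case.image, auto, texture)
        fb = extract_all(case.image, manual, texture)
    return fa, fb, average_readers(fa, fb)


def build_feature_table(cases: Sequence[SyntheticCase], texture: TextureConfig
                        ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """(averaged table with labels, per-reader long table)."""
    avg_rows, long_rows = [], []
    for case in cases:
        fa, fb, avg = extract_case_features(case, texture)
        avg_rows.append(avg.rename(case.case_id))
        for rid, vec in (("readerA", fa), ("readerB", fb), ("average", avg)):
            row = vec.copy()
            row["case_id"] = case.case_id
            row["reader"] = rid
            long_rows.append(row)
    table = pd.DataFrame(avg_rows)
    table[LABEL_COLUMN] = [c.label for c in cases]
    return table, pd.DataFrame(long_rows)


def clean_feature_table(table: pd.DataFrame) -> Tuple[pd.DataFrame, List[str]]:
    """Drop feature columns containing missing values before modelling."""
    feats = table.drop(columns=[LABEL_COLUMN])
    dropped = [c for c in feats.columns if feats[c].isna().any()]
    if dropped:
        log.info("dropping %d feature(s) with missing values: %s",
                 len(dropped), dropped)
    kept = table.drop(columns=dropped)
    return kept, dropped


def cross_validated_auc(binaries: pd.DataFrame, labels: np.ndarray,
                        n_splits: int = 5, seed: int = 0) -> float:
    """Out-of-fold AUC of a logistic model on the given predictors, refit per
    fold (the predictor set itself is fixed)."""
    if binaries.shape[1] == 0:
        return 0.5
    y = np.asarray(labels, dtype=int)
    X = binaries.to_numpy(dtype=float)
    oof = np.zeros(len(y))
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        clf = LogisticRegression(C=1e6, max_iter=1000)
        clf.fit(X[tr], y[tr])
        oof[te] = clf.predict_proba(X[te])[:, 1]
    auc, _ = roc_auc(oof, y)
    return auc


def run_all(config: PipelineConfig, out_dir) -> Dict[str, object]:
    """Execute the full analysis and write all reports under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("stage=simulate n_pos=%d n_neg=%d seed=%d",
             config.cohort.n_positive, config.cohort.n_negative,
             config.cohort.seed)
    cases = generate_cohort(config.cohort)
    truth = np.array([c.label for c in cases], dtype=int)
    manifest = pd.DataFrame({"case_id": [c.case_id for c in cases],
                             "label": truth})
    manifest.to_csv(out / "manifest.csv", index=False)

    log.info("stage=extract texture=%s", config.texture.to_dict())
    table, long_table = build_feature_table(cases, config.texture)
    long_table.to_csv(out / "features.csv", index=False)
    (out / "features_meta.json").write_text(json.dumps({
        "texture": config.texture.to_dict(), "version": __version__}, indent=2))

    clean, dropped = clean_feature_table(table)

    sel = config.selection
    log.info("stage=select folds=%d repeats=%d n_lambda=%d seed=%d",
             sel.n_folds, sel.n_repeats, sel.n_lambda, sel.seed)
    counts = lasso_importance(clean, n_folds=sel.n_folds, n_repeats=sel.n_repeats,
                              seed=sel.seed, n_lambda=sel.n_lambda,
                              inner_folds=sel.inner_folds)
    counts.to_frame().to_csv(out / "importance.csv", index_label="feature")
    selected = select_top(counts, k=sel.top_k)
    (out / "selected.json").write_text(json.dumps({
        "selected": selected, "seed": sel.seed, "n_fits": counts.n_fits,
        "constant_features": counts.constant_features,
        "dropped_missing": dropped}, indent=2))

    log.info("stage=cutoffs k=%d", len(selected))
    features_only = clean.drop(columns=[LABEL_COLUMN])
    cuts = cutoff_table(features_only, truth, selected)
    cuts.to_csv(out / "cutoffs.csv", index=False)

    binaries = pd.DataFrame(index=clean.index)
    rules = {}
    for name in selected:
        rule = youden_cutoff(features_only[name].to_numpy(), truth, feature=name)
        rules[name] = rule
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            binaries[name] = binarize(features_only[name].to_numpy(), rule)

    log.info("stage=models p_enter=%.3g p_remove=%.3g",
             config.model.p_enter, config.model.p_remove)
    uni_rows = []
    significant = []
    for name in selected:
        try:
            fit = univariate_logistic(binaries[name].to_numpy(), truth, name=name)
        except ValueError:
            continue
        row = fit.terms.loc[name].to_dict()
        row["feature"] = name
        row["flags"] = ";".join(fit.flags)
        uni_rows.append(row)
        if row["p"] <= config.model.p_enter:
            significant.append(name)
    pd.DataFrame(uni_rows).to_csv(out / "univariate.csv", index=False)

    candidates = binaries[significant] if significant else binaries
    final = stepwise_logistic(candidates, truth, p_enter=config.model.p_enter,
                              p_remove=config.model.p_remove)
    cv_auc = cross_validated_auc(binaries[final.included], truth,
                                 seed=config.seed)

    score_model = fit_score_model(clean, selected, counts=counts)
    scores = radiomics_score(clean.drop(columns=[LABEL_COLUMN]), score_model)
    score_auc, score_ci = roc_auc(scores, truth,
                                  method=config.model.auc_ci_method)
    pd.DataFrame({"case_id": manifest["case_id"], "label": truth,
                  "radiomics_score": scores}).to_csv(out / "scores.csv",
                                                     index=False)

    model_report = {
        "stepwise": final.to_dict(),
        "stepwise_cv_auc": float(cv_auc),
        "score_model": score_model.to_dict(),
        "score_auc": float(score_auc),
        "score_auc_ci": [float(score_ci[0]), float(score_ci[1])],
        "auc_ci_method": config.model.auc_ci_method,
    }
    (out / "model.json").write_text(json.dumps(model_report, indent=2))

    log.info("stage=reader-eval")
    rd = config.readers
    reader_table = pd.DataFrame({"case_id": manifest["case_id"], "truth": truth})
    for i, key in enumerate(("r1_s1", "r2_s1", "r1_s2", "r2_s2")):
        sens, spec = getattr(rd, key.replace("_s", "_session"))
        reader_table[key] = generate_reader_table(truth, sens, spec,
                                                  seed=config.seed + 1000 + i)
    reader_table.to_csv(out / "reader_table.csv", index=False)

    report = reader_report(reader_table, [("r1_s1", "r1_s2"), ("r2_s1", "r2_s2")])
    report.to_csv(out / "reader_report.csv", index=False)
    auc_cmp = {}
    for reader, (c1, c2) in {"r1": ("r1_s1", "r1_s2"),
                             "r2": ("r2_s1", "r2_s2")}.items():
        a1, a2, p = compare_auc_paired(reader_table[c1], reader_table[c2], truth)
        auc_cmp[reader] = {"auc_session1": a1, "auc_session2": a2, "p": p}
    (out / "reader_report.json").write_text(json.dumps(auc_cmp, indent=2))

    run_meta = {"config": config.to_dict(), "version": __version__}
    (out / "run.json").write_text(json.dumps(run_meta, indent=2))

    return {
        "cases": cases,
        "feature_table": table,
        "importance": counts,
        "selected": selected,
        "cutoffs": cuts,
        "rules": rules,
        "stepwise": final,
        "stepwise_cv_auc": cv_auc,
        "score_auc": score_auc,
        "reader_report": report,
        "reader_auc": auc_cmp,
        "out_dir": out,
    }
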