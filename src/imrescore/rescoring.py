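"""Semi-supervised PSM rescoring with multi-level target-decoy FDR.

The engine assembles per-PSM feature vectors in four blocks — search-engine
features, spectrum-comparison features (Pearson correlation between
predicted and observed normalized b/y intensities, matched-ion counts),
retention-time features and CCS features (observed, calibrated prediction,
absolute and percent error) — and re-ranks PSMs with a Percolator-style
iterative procedure: in each cross-validation split, targets confidently
identified at the selection q-value threshold are taken as positives,
decoys as negatives, and an L2-regularized linear scorer is refitted for a
fixed number of iterations; held-out folds are scored by their training
split's model and fold scores are put on a common scale by z-scoring
against each fold's decoy score distribution.

Q-values use target-decoy competition with the conservative +1 decoy
correction: FDR(t) = (decoys >= t + 1) / max(targets >= t, 1), with the
q-value the running minimum over thresholds. Peptide-level q-values keep
the best PSM per (charge-agnostic) peptidoform; protein-level q-values use
a picked strategy where each target accession competes with its decoy
counterpart and only the better-scoring one survives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .fragments import annotate_spectrum, normalize_log_intensities
from .intensity import pcc, predict_intensities
from .io import DECOY_PREFIXES, Psm, Spectrum

__all__ = [
    "RescoreConfig",
    "CalibrationModel",
    "QValueTable",
    "RescoringReport",
    "tdc_qvalues",
    "rollup",
    "calibrate_ccs",
    "ccs_features",
    "assemble_features",
    "semi_supervised_rescore",
    "compare_runs",
    "entrapment_analysis",
    "feature_weight_report",
    "FEATURE_BLOCKS",
]

FEATURE_BLOCKS = ("search", "spectrum", "rt", "ccs")

MISSING = np.nan  # explicit missing-value marker in feature tables


# ---------------------------------------------------------------------------
# Target-decoy q-values
# ---------------------------------------------------------------------------

@dataclass
class QValueTable:
    identifiers: list[str]
    level: str  # psm | peptide | protein
    scores: np.ndarray
    is_decoy: np.ndarray
    q_values: np.ndarray

    def accepted(self, threshold: float) -> np.ndarray:
        """Boolean mask of accepted *targets* at q <= threshold."""
        return (~self.is_decoy) & (self.q_values <= threshold)

    def n_accepted(self, threshold: float) -> int:
        return int(self.accepted(threshold).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "identifier": self.identifiers,
                "level": self.level,
                "score": self.scores,
                "is_decoy": self.is_decoy,
                "q_value": self.q_values,
            }
        )


def tdc_qvalues(
    scores,
    decoy_labels,
    identifiers: list[str] | None = None,
    level: str = "psm",
) -> QValueTable:
    """Target-decoy q-values (higher score = better).

    At every score threshold t the FDR estimate is
    ``(#decoys >= t + 1) / max(#targets >= t, 1)``; the q-value of an item is
    the minimum estimate over all thresholds that accept it. Decoys receive
    q-values too but are never counted as accepted. Ties share a threshold,
    so the result is invariant to input permutation.
    """
    scores = np.asarray(scores, dtype=float)
    decoys = np.asarray(decoy_labels, dtype=bool)
    if scores.shape != decoys.shape:
        raise ValueError("scores and decoy_labels must align")
    n = len(scores)
    if n == 0:
        return QValueTable(identifiers or [], level, scores, decoys,
                           np.empty(0))
    if decoys.all():
        warnings.warn("all items are decoys; q-values set to 1", stacklevel=2)
        return QValueTable(
            identifiers or [str(i) for i in range(n)], level, scores, decoys,
            np.ones(n),
        )
    # counts at each unique threshold, descending score
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    d_sorted = decoys[order]
    cum_d = np.cumsum(d_sorted)
    cum_t = np.cumsum(~d_sorted)
    # ties share one threshold: every member of a tie group takes the counts
    # at the group's last (lowest) position
    is_boundary = np.append(s_sorted[1:] != s_sorted[:-1], True)
    boundary_pos = np.nonzero(is_boundary)[0]
    last_idx = boundary_pos[np.searchsorted(boundary_pos, np.arange(n))]
    fdr = (cum_d[last_idx] + 1) / np.maximum(cum_t[last_idx], 1)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(n)
    q[order] = q_sorted
    return QValueTable(
        identifiers if identifiers is not None else [str(i) for i in range(n)],
        level,
        scores,
        decoys,
        q,
    )


def _strip_decoy(accession: str, prefixes=DECOY_PREFIXES) -> str:
    for p in prefixes:
        if accession.startswith(p):
            return accession[len(p):]
    return accession


def rollup(
    psms: list[Psm],
    scores,
    level: str,
    charge_aware_peptides: bool = False,
    decoy_prefixes=DECOY_PREFIXES,
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Collapse PSM scores to peptide or protein level.

    Peptide level keeps the best-scoring PSM per peptidoform (charge-agnostic
    by default). Protein level assigns each accession its best peptide score,
    then each target accession competes with its decoy counterpart and only
    the better-scoring of the pair survives (picked-protein competition).
    Returns (identifiers, scores, decoy_labels) ready for :func:`tdc_qvalues`.
    """
    scores = np.asarray(scores, dtype=float)
    if level == "peptide":
        best: dict[str, tuple[float, bool]] = {}
        for p, s in zip(psms, scores):
            key = (
                str(p.peptidoform)
                if charge_aware_peptides
                else str(p.peptidoform).rpartition("/")[0]
            )
            if key not in best or s > best[key][0]:
                best[key] = (float(s), p.is_decoy)
        ids = list(best)
        return ids, np.array([best[k][0] for k in ids]), np.array(
            [best[k][1] for k in ids]
        )
    if level == "protein":
        best: dict[str, float] = {}
        n_skipped = 0
        for p, s in zip(psms, scores):
            if not p.proteins:
                n_skipped += 1
                continue
            for acc in p.proteins:
                if acc not in best or s > best[acc]:
                    best[acc] = float(s)
        if n_skipped:
            warnings.warn(
                f"{n_skipped} PSM(s) without protein accessions skipped at "
                "protein level",
                stacklevel=2,
            )
        # picked competition: target vs decoy counterpart, winner survives
        picked: dict[str, tuple[str, float, bool]] = {}
        for acc, s in best.items():
            is_dec = any(acc.startswith(p) for p in decoy_prefixes)
            base = _strip_decoy(acc, decoy_prefixes)
            if base not in picked or s > picked[base][1]:
                picked[base] = (acc, s, is_dec)
        ids = [v[0] for v in picked.values()]
        return (
            ids,
            np.array([v[1] for v in picked.values()]),
            np.array([v[2] for v in picked.values()]),
        )
    raise ValueError(f"unknown rollup level {level!r}")


# ---------------------------------------------------------------------------
# CCS calibration and features
# ---------------------------------------------------------------------------

@dataclass
class CalibrationModel:
    slope: float
    intercept: float
    n_pairs: int

    def transform(self, predicted):
        return self.slope * np.asarray(predicted, dtype=float) + self.intercept


def calibrate_ccs(
    psms: list[Psm],
    predictions,
    reference_fraction: float = 0.75,
    fdr_threshold: float = 0.01,
    min_pairs: int = 10,
) -> CalibrationModel:
    """Fit the linear map from predicted to observed CCS on confident PSMs.

    Baseline q-values come from the search-engine score; among target PSMs
    with q <= ``fdr_threshold`` that carry an observed CCS, the best-scoring
    ``reference_fraction`` are kept, reduced to unique precursors
    (peptidoform-charge), and observed = a*predicted + b is fitted by
    ordinary least squares. Below ``min_pairs`` eligible precursors an
    identity calibration is returned with a warning.
    """
    predictions = np.asarray(predictions, dtype=float)
    base = tdc_qvalues([p.score for p in psms], [p.is_decoy for p in psms])
    eligible = [
        (p.score, p.peptidoform.key(), p.ion_mobility.value, predictions[i])
        for i, p in enumerate(psms)
        if (not p.is_decoy)
        and base.q_values[i] <= fdr_threshold
        and p.ion_mobility is not None
        and p.ion_mobility.kind == "ccs"
        and np.isfinite(predictions[i])
    ]
    eligible.sort(key=lambda t: -t[0])  # best score first
    keep = eligible[: max(int(round(len(eligible) * reference_fraction)), 0)]
    seen: dict[tuple, tuple[float, float]] = {}
    for _, key, obs, pred in keep:
        if key not in seen:
            seen[key] = (obs, pred)
    if len(seen) < min_pairs:
        warnings.warn(
            f"only {len(seen)} confident precursors; using identity calibration",
            stacklevel=2,
        )
        return CalibrationModel(1.0, 0.0, len(seen))
    obs = np.array([v[0] for v in seen.values()])
    pred = np.array([v[1] for v in seen.values()])
    a, b = np.polyfit(pred, obs, 1)
    return CalibrationModel(float(a), float(b), len(seen))


def ccs_features(psm: Psm, calibrated_prediction: float) -> dict[str, float]:
    """Observed/predicted CCS with absolute and percent error (NaN = missing)."""
    if (
        psm.ion_mobility is None
        or psm.ion_mobility.kind != "ccs"
        or not np.isfinite(calibrated_prediction)
    ):
        return {
            "ccs_observed": MISSING,
            "ccs_predicted": MISSING,
            "ccs_abs_error": MISSING,
            "ccs_perc_error": MISSING,
        }
    obs = psm.ion_mobility.value
    pred = calibrated_prediction
    return {
        "ccs_observed": obs,
        "ccs_predicted": pred,
        "ccs_abs_error": abs(obs - pred),
        "ccs_perc_error": 100.0 * abs(obs - pred) / obs,
    }


# ---------------------------------------------------------------------------
# Feature assembly
# ---------------------------------------------------------------------------

def assemble_features(
    psms: list[Psm],
    spectra: dict[str, Spectrum] | None = None,
    intensity_model=None,
    ccs_model=None,
    rt_model=None,
    calibration: CalibrationModel | None = None,
    tolerance: float = 10.0,
    tolerance_unit: str = "ppm",
    pseudocount: float = 0.001,
) -> tuple[pd.DataFrame, list[Psm]]:
    """Build the per-PSM feature table; blocks without a predictor are skipped.

    ``intensity_model`` and ``ccs_model`` may be any objects exposing the
    ``predict_intensities(model, peptidoform)`` / ``predict_ccs(model, peps)``
    call surfaces (duck-typed so the synthetic oracle predictors plug in).
    Returns the feature table and the (possibly reduced) PSM list; PSMs whose
    spectrum cannot be found are dropped and counted in
    ``table.attrs['dropped']``.
    """
    kept: list[Psm] = []
    rows: list[dict[str, float]] = []
    dropped = 0

    ccs_pred = None
    if ccs_model is not None:
        from .ccs import CcsModel, predict_ccs as _predict_ccs

        peps = [p.peptidoform for p in psms]
        if isinstance(ccs_model, CcsModel):
            ccs_pred = _predict_ccs(ccs_model, peps)
        else:
            ccs_pred = np.asarray(ccs_model.predict(peps), dtype=float)
        if calibration is None:
            calibration = calibrate_ccs(psms, ccs_pred)
        ccs_pred = calibration.transform(ccs_pred)

    for i, psm in enumerate(psms):
        row: dict[str, float] = {"search_score": psm.score}
        for k, v in psm.search_features.items():
            row[f"search_{k}"] = v

        if intensity_model is not None:
            sp = spectra.get(psm.spectrum_id) if spectra else None
            if sp is None:
                dropped += 1
                continue
            raw = annotate_spectrum(sp, psm.peptidoform, tolerance, tolerance_unit)
            n_sites = max(raw.n_sites, 1)
            n_matched = raw.n_matched
            table = normalize_log_intensities(raw, pseudocount)
            obs = table.concatenated()
            if hasattr(intensity_model, "predict_sites") or hasattr(
                intensity_model, "predict_intensities"
            ):
                if hasattr(intensity_model, "predict_intensities"):
                    b_pred, y_pred = intensity_model.predict_intensities(
                        psm.peptidoform
                    )
                else:
                    b_pred, y_pred = predict_intensities(
                        intensity_model, psm.peptidoform
                    )
            else:
                raise TypeError("intensity_model lacks a prediction method")
            pred = np.concatenate([b_pred, y_pred])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                spec_pcc = pcc(obs, pred) if len(obs) >= 2 else MISSING
            row["spectrum_pcc"] = spec_pcc
            row["spectrum_n_matched"] = float(n_matched)
            row["spectrum_frac_matched"] = n_matched / (2.0 * n_sites)

        if rt_model is not None:
            rt_pred = float(rt_model.predict(psm.peptidoform))
            row["rt_observed"] = psm.retention_time
            row["rt_predicted"] = rt_pred
            row["rt_abs_error"] = (
                abs(psm.retention_time - rt_pred)
                if np.isfinite(psm.retention_time)
                else MISSING
            )

        if ccs_pred is not None:
            row.update(ccs_features(psm, float(ccs_pred[i])))

        kept.append(psm)
        rows.append(row)

    table = pd.DataFrame(rows)
    table.attrs["dropped"] = dropped
    return table, kept


# ---------------------------------------------------------------------------
# Semi-supervised rescoring
# ---------------------------------------------------------------------------

@dataclass
class RescoreConfig:
    folds: int = 3
    iterations: int = 10
    selection_q: float = 0.01
    c_regularization: float = 1.0
    seed: int = 0


def _impute(
    X: np.ndarray, medians: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Median-impute NaNs; returns (imputed, missing-indicator columns)."""
    missing = np.isnan(X)
    Xi = np.where(missing, medians, X)
    return Xi, missing.astype(float)


def semi_supervised_rescore(
    features: pd.DataFrame,
    decoy_labels,
    config: RescoreConfig | None = None,
) -> tuple[np.ndarray, pd.Series]:
    """Percolator-style iterative rescoring.

    Returns (new scores aligned with the input rows, averaged absolute
    standardized feature weights). The procedure: split PSMs into k folds;
    within each training split, start from the single feature direction that
    maximizes accepted targets at the selection threshold, then iterate
    {select positives at q <= threshold, fit an L2 logistic scorer on
    standardized median-imputed features (plus missing indicators),
    rescore}; score the held-out fold with its training model and z-score
    each fold's output against its decoy distribution.
    """
    config = config or RescoreConfig()
    decoys = np.asarray(decoy_labels, dtype=bool)
    if not decoys.any():
        raise ValueError("no decoys; semi-supervised rescoring is impossible")
    names = list(features.columns)
    X = features.to_numpy(dtype=float)
    n = len(X)
    rng = np.random.default_rng(config.seed)
    fold = rng.integers(0, config.folds, size=n)

    new_scores = np.empty(n)
    weight_acc = np.zeros(len(names) * 2)  # features + missing indicators

    for f in range(config.folds):
        tr = fold != f
        te = ~tr
        Xtr_raw, Xte_raw = X[tr], X[te]
        med = np.nanmedian(Xtr_raw, axis=0)
        med = np.where(np.isnan(med), 0.0, med)
        Xtr, Mtr = _impute(Xtr_raw, med)
        Xte, Mte = _impute(Xte_raw, med)
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        Ztr = np.hstack([(Xtr - mu) / sd, Mtr])
        Zte = np.hstack([(Xte - mu) / sd, Mte])
        dtr = decoys[tr]

        # initial direction: the single feature accepting most targets at q
        best_feat, best_sign, best_n = 0, 1.0, -1
        for j in range(Ztr.shape[1]):
            col = Ztr[:, j]
            if np.all(col == col[0]):
                continue
            for sign in (1.0, -1.0):
                qt = tdc_qvalues(sign * col, dtr)
                na = qt.n_accepted(config.selection_q)
                if na > best_n:
                    best_feat, best_sign, best_n = j, sign, na
        score_tr = best_sign * Ztr[:, best_feat]
        weights = np.zeros(Ztr.shape[1])
        weights[best_feat] = best_sign

        for _ in range(config.iterations):
            qt = tdc_qvalues(score_tr, dtr)
            pos = (~dtr) & (qt.q_values <= config.selection_q)
            if pos.sum() == 0:
                warnings.warn(
                    "no positive training examples; keeping initial direction",
                    stacklevel=2,
                )
                break
            mask = pos | dtr
            yfit = pos[mask].astype(int)
            clf = LogisticRegression(
                C=config.c_regularization,
                max_iter=500,
                tol=1e-6,
                solver="lbfgs",
            )
            clf.fit(Ztr[mask], yfit)
            score_tr = Ztr @ clf.coef_[0] + clf.intercept_[0]
            weights = clf.coef_[0]

        score_te = Zte @ weights  # intercept is rank-irrelevant
        # common scale: z-score against the fold's decoys
        dec_scores = score_te[decoys[te]]
        if len(dec_scores) >= 2 and dec_scores.std() > 0:
            score_te = (score_te - dec_scores.mean()) / dec_scores.std()
        new_scores[te] = score_te
        weight_acc += np.abs(weights)

    weight_names = names + [f"{n}_missing" for n in names]
    weight_series = pd.Series(
        weight_acc / config.folds, index=weight_names
    ).sort_values(ascending=False)
    return new_scores, weight_series


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

@dataclass
class RescoringReport:
    level: str
    threshold: float
    gained: set = field(default_factory=set)
    lost: set = field(default_factory=set)
    shared: set = field(default_factory=set)

    @property
    def n_before(self) -> int:
        return len(self.lost) + len(self.shared)

    @property
    def n_after(self) -> int:
        return len(self.gained) + len(self.shared)

    def summary(self) -> dict:
        return {
            "level": self.level,
            "threshold": self.threshold,
            "before": self.n_before,
            "after": self.n_after,
            "gained": len(self.gained),
            "lost": len(self.lost),
            "shared": len(self.shared),
        }


def compare_runs(
    before: QValueTable,
    after: QValueTable,
    thresholds: tuple[float, ...] = (0.01, 0.001),
) -> list[RescoringReport]:
    """Gained / shared / lost accepted identifications at each threshold."""
    if before.level != after.level:
        raise ValueError("q-value tables are at different levels")
    out = []
    for thr in thresholds:
        b = {
            i
            for i, acc in zip(before.identifiers, before.accepted(thr))
            if acc
        }
        a = {i for i, acc in zip(after.identifiers, after.accepted(thr)) if acc}
        out.append(
            RescoringReport(
                before.level, thr, gained=a - b, lost=b - a, shared=a & b
            )
        )
    return out


def entrapment_analysis(
    qtable: QValueTable,
    entrapment_flags,
    db_size_ratio: float,
    threshold: float = 0.01,
) -> dict:
    """Empirical false-match estimates from entrapment hits.

    ``entrapment_flags`` marks accepted-target candidates that only match the
    entrapment (foreign-species) database; ``db_size_ratio`` is the
    entrapment/sample database size ratio. Reports the raw percentage of
    entrapment hits among accepted targets and a size-normalized estimate
    (raw divided by the ratio).
    """
    flags = np.asarray(entrapment_flags, dtype=bool)
    acc = qtable.accepted(threshold)
    n_accepted = int(acc.sum())
    n_entrap = int((acc & flags).sum())
    raw = 100.0 * n_entrap / n_accepted if n_accepted else 0.0
    normalized = raw / db_size_ratio if db_size_ratio > 0 else float("nan")
    return {
        "threshold": threshold,
        "n_accepted": n_accepted,
        "n_entrapment": n_entrap,
        "raw_percent": raw,
        "normalized_percent": normalized,
    }


def feature_weight_report(weights: pd.Series) -> pd.DataFrame:
    """Rank absolute standardized weights and group them by feature block.

    The returned frame carries a per-feature ranking plus a block-level
    summary in ``df.attrs['block_summary']``: total absolute weight per
    block, descending. Correlated features within a block share the block's
    signal, so the block a model relies on is judged by the aggregate, not
    by any single coefficient.
    """
    rows = []
    for name, w in weights.items():
        block = next(
            (b for b in FEATURE_BLOCKS if name.startswith(b + "_")), "other"
        )
        rows.append({"feature": name, "block": block, "abs_weight": abs(w)})
    df = pd.DataFrame(rows).sort_values("abs_weight", ascending=False,
                                        ignore_index=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df.attrs["block_summary"] = (
        df.groupby("block")["abs_weight"].sum().sort_values(ascending=False)
    )
    return df
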