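"""Trainable fragment-ion intensity prediction and its evaluation protocol.

Peptide backbones are broken at every cleavage site; each site is encoded by
a fixed-width vector of local residue descriptors (window of one residue on
each side of the site), prefix/suffix physicochemical aggregates and global
peptide descriptors. Two gradient-boosted regressors (one for the b series,
one for the y series) map site encodings to TIC-normalized log2 intensities.

Evaluation follows the protocol of correlating predicted and observed
intensities per PSM (b and y concatenated) with the Pearson correlation
coefficient, and comparing against the intra-peptidoform baseline: the
distribution of PCCs between observed spectra of the same peptidoform, which
bounds what any predictor can achieve on noisy data.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb

from .constants import AMINO_ACIDS, BASICITY, HELICITY, HYDROPHOBICITY, PI
from .fragments import (
    DEFAULT_PSEUDOCOUNT,
    annotate_spectrum,
    normalize_log_intensities,
)
from .io import Peptidoform, Psm, Spectrum

__all__ = [
    "IntensityConfig",
    "IntensityModel",
    "encode_cleavage_sites",
    "stratified_split",
    "train_intensity_model",
    "predict_intensities",
    "pcc",
    "evaluate_model",
    "intra_peptidoform_baseline",
    "MIN_PEPTIDE_LENGTH",
]

MIN_PEPTIDE_LENGTH = 4

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_SCALES = (HYDROPHOBICITY, BASICITY, HELICITY, PI)


def encode_cleavage_sites(peptidoform: Peptidoform) -> np.ndarray:
    """Encode every cleavage site of a peptide as one fixed-width row.

    Per site ``i`` (between residues i and i+1, 1-based, i in 1..n-1):

    * 20 composition counts over the +/-1 window (residues i-1..i+2, clamped);
    * 4 physicochemical values for each of the four window positions
      (zero-padded at the termini);
    * prefix and suffix means of the four scales;
    * modification mass within the window, and total modification mass on the
      prefix and suffix;
    * global descriptors: length, site index, site fraction, precursor
      charge, peptide neutral mass / 1000.

    Returns an ``(n-1, width)`` array; deterministic in the peptidoform.
    """
    seq = peptidoform.sequence
    n = len(seq)
    if n < MIN_PEPTIDE_LENGTH:
        raise ValueError(
            f"peptide length {n} below minimum {MIN_PEPTIDE_LENGTH}"
        )
    aa_idx = np.array([_AA_INDEX[a] for a in seq])
    props = np.array([[sc[a] for sc in _SCALES] for a in seq])  # (n, 4)
    modmass = peptidoform.residue_mod_mass()

    prefix_prop = np.cumsum(props, axis=0)
    total_prop = prefix_prop[-1]
    prefix_mod = np.cumsum(modmass)
    total_mod = prefix_mod[-1]

    rows = []
    for i in range(1, n):
        window = [i - 2, i - 1, i, i + 1]  # residue indices around the site
        comp = np.zeros(20)
        wprops = np.zeros((4, 4))
        wmod = 0.0
        for k, j in enumerate(window):
            if 0 <= j < n:
                comp[aa_idx[j]] += 1
                wprops[k] = props[j]
                wmod += modmass[j]
        pre_mean = prefix_prop[i - 1] / i
        suf_mean = (total_prop - prefix_prop[i - 1]) / (n - i)
        row = np.concatenate(
            [
                comp,
                wprops.ravel(),
                pre_mean,
                suf_mean,
                [
                    wmod,
                    prefix_mod[i - 1],
                    total_mod - prefix_mod[i - 1],
                    n,
                    i,
                    i / n,
                    peptidoform.charge,
                    peptidoform.neutral_mass / 1000.0,
                ],
            ]
        )
        rows.append(row)
    return np.asarray(rows)


def stratified_split(
    peptidoforms: list[Peptidoform],
    labels: list[str],
    test_fraction: float,
    seed: int,
) -> tuple[list[int], list[int]]:
    """Peptidoform-disjoint stratified split; returns (train, test) index lists.

    Splitting operates on unique peptidoforms (charge-aware identity), so no
    peptidoform appears on both sides; per-label test proportions are exact
    to rounding. Labels with fewer than 2 members go wholly to train.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if len(peptidoforms) != len(labels):
        raise ValueError("peptidoforms and labels must align")
    rng = np.random.default_rng(seed)
    key_label: dict[tuple, str] = {}
    key_order: list[tuple] = []
    for p, lab in zip(peptidoforms, labels):
        k = p.key()
        if k not in key_label:
            key_label[k] = lab
            key_order.append(k)
    test_keys: set = set()
    by_label: dict[str, list[tuple]] = {}
    for k in key_order:
        by_label.setdefault(key_label[k], []).append(k)
    for lab in sorted(by_label):
        keys = by_label[lab]
        if len(keys) < 2:
            warnings.warn(
                f"label {lab!r} has < 2 peptidoforms; assigned to train",
                stacklevel=2,
            )
            continue
        n_test = int(round(len(keys) * test_fraction))
        n_test = min(max(n_test, 1), len(keys) - 1)
        chosen = rng.choice(len(keys), size=n_test, replace=False)
        test_keys.update(keys[i] for i in chosen)
    train_idx = [i for i, p in enumerate(peptidoforms) if p.key() not in test_keys]
    test_idx = [i for i, p in enumerate(peptidoforms) if p.key() in test_keys]
    return train_idx, test_idx


@dataclass
class IntensityConfig:
    n_estimators_grid: tuple[int, ...] = (100, 200, 400)
    max_depth_grid: tuple[int, ...] = (4, 6, 8)
    learning_rate_grid: tuple[float, ...] = (0.05, 0.1, 0.2)
    search_budget: int = 20  # random draws from the grid
    cv_folds: int = 5
    seed: int = 0
    min_peptidoforms: int = 50
    tolerance: float = 10.0
    tolerance_unit: str = "ppm"
    pseudocount: float = DEFAULT_PSEUDOCOUNT


@dataclass
class IntensityModel:
    b_model: xgb.XGBRegressor
    y_model: xgb.XGBRegressor
    config: IntensityConfig
    cv_summary: pd.DataFrame = field(default_factory=pd.DataFrame)

    def predict_sites(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return self.b_model.predict(X), self.y_model.predict(X)


def _site_dataset(
    psms: list[Psm],
    spectra: dict[str, Spectrum],
    config: IntensityConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack site encodings and normalized b/y targets over PSMs."""
    X, yb, yy = [], [], []
    for psm in psms:
        sp = spectra.get(psm.spectrum_id)
        if sp is None:
            continue
        table = annotate_spectrum(
            sp, psm.peptidoform, config.tolerance, config.tolerance_unit
        )
        table = normalize_log_intensities(table, config.pseudocount)
        X.append(encode_cleavage_sites(psm.peptidoform))
        yb.append(table.b_obs)
        yy.append(table.y_obs)
    if not X:
        raise ValueError("no trainable PSMs (no spectra matched)")
    return np.vstack(X), np.concatenate(yb), np.concatenate(yy)


def _random_search(
    X: np.ndarray, y: np.ndarray, config: IntensityConfig
) -> tuple[dict, pd.DataFrame]:
    """Small random hyperparameter search with k-fold cross-validation."""
    rng = np.random.default_rng(config.seed)
    grid = list(
        itertools.product(
            config.n_estimators_grid,
            config.max_depth_grid,
            config.learning_rate_grid,
        )
    )
    n_draw = min(config.search_budget, len(grid))
    draws = rng.choice(len(grid), size=n_draw, replace=False)
    k = config.cv_folds
    fold = rng.integers(0, k, size=len(X))
    records = []
    for d in draws:
        n_est, depth, lr = grid[d]
        errs = []
        for f in range(k):
            m = xgb.XGBRegressor(
                n_estimators=n_est,
                max_depth=depth,
                learning_rate=lr,
                n_jobs=1,
                random_state=config.seed,
                tree_method="hist",
            )
            m.fit(X[fold != f], y[fold != f])
            pred = m.predict(X[fold == f])
            errs.append(float(np.mean((pred - y[fold == f]) ** 2)))
        records.append(
            {
                "n_estimators": n_est,
                "max_depth": depth,
                "learning_rate": lr,
                "cv_mse": float(np.mean(errs)),
            }
        )
    summary = pd.DataFrame(records).sort_values("cv_mse", ignore_index=True)
    best = summary.iloc[0]
    params = {
        "n_estimators": int(best["n_estimators"]),
        "max_depth": int(best["max_depth"]),
        "learning_rate": float(best["learning_rate"]),
    }
    return params, summary


def train_intensity_model(
    psms: list[Psm],
    spectra: dict[str, Spectrum],
    config: IntensityConfig | None = None,
) -> IntensityModel:
    """Fit the b- and y-ion regressors on annotated, normalized intensities.

    Hyperparameters are selected once (on the b-ion targets, which dominate
    the variance budget jointly with y) by random search with k-fold CV, then
    both regressors are refitted on the full training data.
    """
    config = config or IntensityConfig()
    n_pf = len({p.peptidoform.key() for p in psms})
    if n_pf < config.min_peptidoforms:
        raise ValueError(
            f"{n_pf} training peptidoforms < required minimum "
            f"{config.min_peptidoforms}"
        )
    X, yb, yy = _site_dataset(psms, spectra, config)
    params, summary = _random_search(X, yb, config)
    mk = lambda: xgb.XGBRegressor(
        n_jobs=1, random_state=config.seed, tree_method="hist", **params
    )
    b_model, y_model = mk(), mk()
    b_model.fit(X, yb)
    y_model.fit(X, yy)
    return IntensityModel(b_model, y_model, config, summary)


def predict_intensities(
    model: IntensityModel, peptidoform: Peptidoform
) -> tuple[np.ndarray, np.ndarray]:
    """Predicted normalized log2 b and y intensities, each of length n-1."""
    X = encode_cleavage_sites(peptidoform)
    return model.predict_sites(X)


def pcc(x, y) -> float:
    """Pearson correlation; 0 (with a warning) when either input is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 points")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum())
    sy = np.sqrt((yc**2).sum())
    if sx == 0 or sy == 0:
        warnings.warn("undefined variance; returning PCC 0", stacklevel=2)
        return 0.0
    return float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))


def evaluate_model(
    model: IntensityModel,
    test_psms: list[Psm],
    spectra: dict[str, Spectrum],
    labels: list[str] | None = None,
    config: IntensityConfig | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-PSM PCC over the concatenated b+y vector, plus per-label medians.

    Every PSM of a test peptidoform is evaluated, not only the best one. PSMs
    with fewer than 2 matched ions are excluded and counted in the returned
    table's ``excluded`` attribute.
    """
    config = config or getattr(model, "config", None) or IntensityConfig()
    predict = (
        model.predict_intensities
        if hasattr(model, "predict_intensities")
        else lambda pep: predict_intensities(model, pep)
    )
    rows = []
    excluded = 0
    for i, psm in enumerate(test_psms):
        sp = spectra.get(psm.spectrum_id)
        if sp is None:
            excluded += 1
            continue
        raw = annotate_spectrum(sp, psm.peptidoform, config.tolerance,
                                config.tolerance_unit)
        if raw.n_matched < 2:
            excluded += 1
            continue
        table = normalize_log_intensities(raw, config.pseudocount)
        b_pred, y_pred = predict(psm.peptidoform)
        obs = table.concatenated()
        pred = np.concatenate([b_pred, y_pred])
        rows.append(
            {
                "spectrum_id": psm.spectrum_id,
                "peptidoform": str(psm.peptidoform),
                "label": labels[i] if labels else "all",
                "pcc": pcc(obs, pred),
                "n_matched": raw.n_matched,
            }
        )
    table = pd.DataFrame(rows, columns=["spectrum_id", "peptidoform", "label",
                                        "pcc", "n_matched"])
    table.attrs["excluded"] = excluded
    medians = (
        table.groupby("label")["pcc"].median()
        if len(table)
        else pd.Series(dtype=float)
    )
    return table, medians


def intra_peptidoform_baseline(
    psms: list[Psm],
    spectra: dict[str, Spectrum],
    config: IntensityConfig | None = None,
) -> np.ndarray:
    """PCCs between observed spectra of the same peptidoform.

    For every unordered pair of PSMs matched to one peptidoform, the Pearson
    correlation of their normalized observed b+y vectors. This distribution
    is the ceiling against which model performance is judged: a predictor
    cannot be expected to correlate with a spectrum better than a replicate
    measurement does.
    """
    config = config or IntensityConfig()
    groups: dict[tuple, list[np.ndarray]] = {}
    for psm in psms:
        sp = spectra.get(psm.spectrum_id)
        if sp is None:
            continue
        table = normalize_log_intensities(
            annotate_spectrum(sp, psm.peptidoform, config.tolerance,
                              config.tolerance_unit),
            config.pseudocount,
        )
        groups.setdefault(psm.peptidoform.key(), []).append(table.concatenated())
    out = []
    for vecs in groups.values():
        for a, b in itertools.combinations(vecs, 2):
            out.append(pcc(a, b))
    if not out:
        warnings.warn("no repeated peptidoforms; empty baseline", stacklevel=2)
    return np.asarray(out)
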