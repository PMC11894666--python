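"""Peptide collisional-cross-section (CCS) prediction.

Peptidoforms are encoded along four paths: (1) a per-residue atomic
composition matrix (C, H, N, O, S plus modification deltas), (2) the atomic
composition of consecutive residue pairs (diamino acids), (3) a one-hot
matrix of the unmodified sequence, and (4) a global feature vector — length,
total atomic composition, composition at the two first and two last residue
positions, the relative frequencies of histidine, bulky residues (F/W/Y),
acidic residues (D/E) and K/R, and the precursor charge. Grouped-frequency
features capture that residues with similar physicochemistry shift CCS in
similar ways; charge is included because CCS is charge-state dependent.

Two regressor backends share this encoding: a four-path convolutional
network (numpy, Adam, early stopping) and a fast deterministic
gradient-boosted reference backend built on linear base learners
(coordinate-descent boosting over the standardized global block by default;
tree boosters and the fully flattened encoding are config options). The
linear-booster default is a deliberate choice: it converges to the
least-squares solution, giving exact parameter recovery on linear ground
truth and sane extrapolation to modifications never seen in training, which
tree ensembles structurally cannot do.

The module also provides linear inter-dataset alignment (y = a*x + b on
overlapping peptidoform-charge pairs), isomer collapsing, and the two
leave-one-out generalization harnesses (by modification and by amino acid).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import xgboost as xgb

from .constants import AMINO_ACIDS, ELEMENT_MASS, RESIDUE_FORMULA
from .intensity import pcc
from .io import Modification, Peptidoform

__all__ = [
    "CcsRecord",
    "FourPathEncoding",
    "CcsConfig",
    "CcsModel",
    "AlignmentModel",
    "encode_peptide",
    "global_features",
    "GLOBAL_FEATURE_NAMES",
    "train_ccs_model",
    "predict_ccs",
    "align_datasets",
    "merge_datasets",
    "collapse_isomers",
    "loo_modification_harness",
    "loo_amino_acid_harness",
    "one_over_k0_to_ccs",
    "ccs_to_one_over_k0",
    "MAX_PEPTIDE_LENGTH",
]

logger = logging.getLogger(__name__)

MAX_PEPTIDE_LENGTH = 60
_ELEMENTS = ("C", "H", "N", "O", "S")
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

_BULKY = set("FWY")
_ACIDIC = set("DE")
_BASIC_KR = set("KR")


@dataclass(frozen=True)
class CcsRecord:
    peptidoform: Peptidoform
    ccs: float  # A^2
    source: str = ""

    def __post_init__(self) -> None:
        if not self.ccs > 0:
            raise ValueError("ccs must be positive")


@dataclass
class FourPathEncoding:
    path1: np.ndarray  # (max_length, 7): C H N O S, mod mass, padding flag
    path2: np.ndarray  # (max_length-1, 7): diamino composition, mod mass, pad
    path3: np.ndarray  # (max_length, 21): one-hot residues + padding flag
    path4: np.ndarray  # global feature vector


GLOBAL_FEATURE_NAMES: tuple[str, ...] = (
    "length",
    "charge",
    *(f"total_{el}" for el in _ELEMENTS),
    "freq_his",
    "freq_bulky",
    "freq_acidic",
    "freq_kr",
    *(f"first_{el}" for el in _ELEMENTS),
    *(f"second_{el}" for el in _ELEMENTS),
    *(f"secondlast_{el}" for el in _ELEMENTS),
    *(f"last_{el}" for el in _ELEMENTS),
)


def _approximate_composition(mass: float) -> dict[str, float]:
    """Nearest-mass element approximation for mods with unknown composition."""
    k_o = round(mass / ELEMENT_MASS["O"])
    rem = mass - k_o * ELEMENT_MASS["O"]
    k_h = round(rem / ELEMENT_MASS["H"])
    return {"O": float(k_o), "H": float(k_h)}


def _mod_composition(mod: Modification) -> dict[str, float]:
    comp = mod.composition_dict()
    if not comp and abs(mod.mass) > 1e-9:
        warnings.warn(
            f"modification {mod.name!r} has no composition; using "
            f"nearest-mass element approximation",
            stacklevel=3,
        )
        comp = _approximate_composition(mod.mass)
    return {el: comp.get(el, 0.0) for el in _ELEMENTS}


def _residue_composition(
    peptidoform: Peptidoform,
    encode_modifications: bool = True,
    ignore_modification: str | None = None,
    substitute: dict[str, str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(n, 5) per-residue atomic composition and (n,) modification masses."""
    seq = peptidoform.sequence
    n = len(seq)
    comp = np.zeros((n, 5))
    for i, aa in enumerate(seq):
        use = substitute.get(aa, aa) if substitute else aa
        f = RESIDUE_FORMULA[use]
        comp[i] = [f.get(el, 0) for el in _ELEMENTS]
    modmass = np.zeros(n)
    if encode_modifications:
        for m in peptidoform.modifications:
            if ignore_modification is not None and m.name == ignore_modification:
                continue
            row = min(max(m.position - 1, 0), n - 1)
            c = _mod_composition(m)
            comp[row] += [c[el] for el in _ELEMENTS]
            modmass[row] += m.mass
    return comp, modmass


def global_features(
    peptidoform: Peptidoform,
    encode_modifications: bool = True,
    ignore_modification: str | None = None,
    substitute: dict[str, str] | None = None,
) -> np.ndarray:
    """The global (path 4) feature vector; see :data:`GLOBAL_FEATURE_NAMES`."""
    if encode_modifications and ignore_modification is None and substitute is None:
        return _global_features_plain(peptidoform).copy()
    return _global_features_impl(
        peptidoform, encode_modifications, ignore_modification, substitute
    )


@lru_cache(maxsize=65536)
def _global_features_plain(peptidoform: Peptidoform) -> np.ndarray:
    return _global_features_impl(peptidoform, True, None, None)


def _global_features_impl(
    peptidoform: Peptidoform,
    encode_modifications: bool,
    ignore_modification: str | None,
    substitute: dict[str, str] | None,
) -> np.ndarray:
    seq = peptidoform.sequence
    n = len(seq)
    comp, _ = _residue_composition(
        peptidoform, encode_modifications, ignore_modification, substitute
    )
    eff = [substitute.get(a, a) if substitute else a for a in seq]
    freqs = [
        sum(a == "H" for a in eff) / n,
        sum(a in _BULKY for a in eff) / n,
        sum(a in _ACIDIC for a in eff) / n,
        sum(a in _BASIC_KR for a in eff) / n,
    ]
    first = comp[0]
    second = comp[1] if n > 1 else np.zeros(5)
    secondlast = comp[-2] if n > 1 else np.zeros(5)
    last = comp[-1]
    return np.concatenate(
        [[n, peptidoform.charge], comp.sum(axis=0), freqs,
         first, second, secondlast, last]
    )


def encode_peptide(
    peptidoform: Peptidoform,
    max_length: int = MAX_PEPTIDE_LENGTH,
    encode_modifications: bool = True,
    ignore_modification: str | None = None,
    substitute: dict[str, str] | None = None,
) -> FourPathEncoding:
    """Encode a peptidoform along the four paths.

    ``ignore_modification`` zeroes the named modification's composition and
    mass everywhere (the encode-vs-ignore switch of the leave-one-
    modification-out harness); ``substitute`` maps residue letters to
    replacement letters in paths 1, 2 and 3 (the glycine-substitution switch
    of the leave-one-amino-acid-out harness).
    """
    seq = peptidoform.sequence
    n = len(seq)
    if n > max_length:
        raise ValueError(f"peptide length {n} exceeds max_length {max_length}")
    comp, modmass = _residue_composition(
        peptidoform, encode_modifications, ignore_modification, substitute
    )
    path1 = np.zeros((max_length, 7))
    path1[:n, :5] = comp
    path1[:n, 5] = modmass
    path1[n:, 6] = 1.0  # padding marker

    path2 = np.zeros((max_length - 1, 7))
    if n >= 2:
        path2[: n - 1, :5] = comp[:-1] + comp[1:]
        path2[: n - 1, 5] = modmass[:-1] + modmass[1:]
    path2[max(n - 1, 0):, 6] = 1.0

    path3 = np.zeros((max_length, 21))
    for i, aa in enumerate(seq):
        use = substitute.get(aa, aa) if substitute else aa
        path3[i, _AA_INDEX[use]] = 1.0
    path3[n:, 20] = 1.0

    path4 = global_features(
        peptidoform, encode_modifications, ignore_modification, substitute
    )
    return FourPathEncoding(path1, path2, path3, path4)


def _flatten(enc: FourPathEncoding, mode: str) -> np.ndarray:
    if mode == "global":
        return enc.path4
    if mode == "full":
        return np.concatenate(
            [enc.path1.ravel(), enc.path2.ravel(), enc.path3.ravel(), enc.path4]
        )
    raise ValueError(f"unknown flatten mode {mode!r}")


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

@dataclass
class CcsConfig:
    backend: str = "gradient_boosted_reference"
    booster: str = "gblinear"  # or "gbtree"
    flatten: str = "global"  # or "full"
    train_fraction: float = 0.891
    validation_fraction: float = 0.009
    # remaining 10% is the held-out test split
    n_estimators: int = 4000
    learning_rate: float = 0.5
    early_stopping_rounds: int = 200
    max_depth: int = 6  # gbtree only
    epochs: int = 300  # convolutional backend epoch cap
    patience: int = 10
    init_mu: float = 0.0
    init_sigma: float = 1.0
    conv_lr: float = 1e-3
    batch_size: int = 64
    seed: int = 0
    max_length: int = MAX_PEPTIDE_LENGTH


@dataclass
class CcsModel:
    backend: str
    config: CcsConfig
    regressor: object
    feature_mu: np.ndarray | None = None
    feature_sd: np.ndarray | None = None
    y_mu: float = 0.0
    y_sd: float = 1.0
    log: dict = field(default_factory=dict)

    def _predict_reference(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.feature_mu) / self.feature_sd
        return self.regressor.predict(Z)

    def predict_encodings(self, encodings: list[FourPathEncoding]) -> np.ndarray:
        if self.backend == "gradient_boosted_reference":
            X = np.vstack([_flatten(e, self.config.flatten) for e in encodings])
            return self._predict_reference(X)
        paths = [
            np.stack([e.path1 for e in encodings]),
            np.stack([e.path2 for e in encodings]),
            np.stack([e.path3 for e in encodings]),
        ]
        glob = np.stack([e.path4 for e in encodings])
        glob = (glob - self.feature_mu) / self.feature_sd
        z = self.regressor.predict(paths, glob)
        return z * self.y_sd + self.y_mu


def _split_records(
    records: list[CcsRecord], config: CcsConfig
) -> tuple[list[int], list[int], list[int]]:
    rng = np.random.default_rng(config.seed)
    n = len(records)
    order = rng.permutation(n)
    n_train = int(round(n * config.train_fraction))
    n_val = int(round(n * config.validation_fraction))
    train = order[:n_train]
    val = order[n_train: n_train + n_val]
    test = order[n_train + n_val:]
    if len(val) == 0:
        raise ValueError(
            "validation split is empty; increase validation_fraction or data size"
        )
    return list(train), list(val), list(test)


def _dedupe(records: list[CcsRecord]) -> list[CcsRecord]:
    by_key: dict[tuple, list[CcsRecord]] = {}
    order: list[tuple] = []
    for r in records:
        k = r.peptidoform.key()
        if k not in by_key:
            order.append(k)
        by_key.setdefault(k, []).append(r)
    out = []
    dupes = 0
    for k in order:
        group = by_key[k]
        if len(group) == 1:
            out.append(group[0])
        else:
            dupes += 1
            out.append(
                CcsRecord(
                    group[0].peptidoform,
                    float(np.mean([g.ccs for g in group])),
                    group[0].source,
                )
            )
    if dupes:
        warnings.warn(f"{dupes} duplicated peptidoforms collapsed to their mean",
                      stacklevel=3)
    return out


def train_ccs_model(records: list[CcsRecord], config: CcsConfig | None = None) -> CcsModel:
    """Fit a CCS regressor with a peptidoform-disjoint train/val/test split.

    The default split is 89.1% train / 0.9% validation / 10% test; the
    validation split drives early stopping for both backends. The returned
    model's ``log`` records split sizes, stopping epoch and held-out test
    MAE/PCC.
    """
    config = config or CcsConfig()
    records = _dedupe(records)
    tr, va, te = _split_records(records, config)
    encs = [encode_peptide(r.peptidoform, config.max_length) for r in records]
    y = np.array([r.ccs for r in records])

    log: dict = {"n_train": len(tr), "n_val": len(va), "n_test": len(te)}
    if config.backend == "gradient_boosted_reference":
        X = np.vstack([_flatten(e, config.flatten) for e in encs])
        mu = X[tr].mean(axis=0)
        sd = X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        Z = (X - mu) / sd
        if config.booster == "gblinear":
            reg = xgb.XGBRegressor(
                booster="gblinear",
                updater="coord_descent",
                feature_selector="cyclic",
                n_estimators=config.n_estimators,
                learning_rate=config.learning_rate,
                reg_lambda=0.0,
                reg_alpha=0.0,
                n_jobs=1,
                random_state=config.seed,
                early_stopping_rounds=config.early_stopping_rounds,
            )
        elif config.booster == "gbtree":
            reg = xgb.XGBRegressor(
                n_estimators=config.n_estimators,
                learning_rate=min(config.learning_rate, 0.1),
                max_depth=config.max_depth,
                tree_method="hist",
                n_jobs=1,
                random_state=config.seed,
                early_stopping_rounds=config.early_stopping_rounds,
            )
        else:
            raise ValueError(f"unknown booster {config.booster!r}")
        reg.fit(Z[tr], y[tr], eval_set=[(Z[va], y[va])], verbose=False)
        model = CcsModel(config.backend, config, reg, mu, sd, log=log)
        log["best_iteration"] = int(getattr(reg, "best_iteration", -1))
    elif config.backend == "four_path_convolutional":
        from ._convnet import FourPathConvNet

        glob = np.stack([e.path4 for e in encs])
        mu = glob[tr].mean(axis=0)
        sd = glob[tr].std(axis=0)
        sd[sd == 0] = 1.0
        globz = (glob - mu) / sd
        paths = [
            np.stack([e.path1 for e in encs]),
            np.stack([e.path2 for e in encs]),
            np.stack([e.path3 for e in encs]),
        ]
        y_mu, y_sd = float(y[tr].mean()), float(y[tr].std() or 1.0)
        yz = (y - y_mu) / y_sd
        net = FourPathConvNet(
            path_shapes=tuple(p.shape[1:] for p in paths),
            n_global=glob.shape[1],
            init_mu=config.init_mu,
            init_sigma=config.init_sigma,
            seed=config.seed,
        )
        hist = net.fit(
            [p[tr] for p in paths], globz[tr], yz[tr],
            [p[va] for p in paths], globz[va], yz[va],
            epochs=config.epochs, patience=config.patience,
            batch_size=config.batch_size, lr=config.conv_lr, seed=config.seed,
        )
        log.update(hist)
        model = CcsModel(config.backend, config, net, mu, sd, y_mu, y_sd, log=log)
    else:
        raise ValueError(f"unknown backend {config.backend!r}")

    if te:
        pred = model.predict_encodings([encs[i] for i in te])
        log["test_mae"] = float(np.mean(np.abs(pred - y[te])))
        log["test_pcc"] = pcc(pred, y[te]) if len(te) >= 2 else float("nan")
    return model


def predict_ccs(
    model: CcsModel,
    peptidoforms: list[Peptidoform],
    ignore_modification: str | None = None,
    substitute: dict[str, str] | None = None,
) -> np.ndarray:
    """Predict CCS (A^2) per peptidoform; unencodable items yield NaN."""
    encs: list[FourPathEncoding | None] = []
    n_bad = 0
    for p in peptidoforms:
        try:
            encs.append(
                encode_peptide(
                    p,
                    model.config.max_length,
                    ignore_modification=ignore_modification,
                    substitute=substitute,
                )
            )
        except ValueError as exc:
            warnings.warn(f"cannot encode {p}: {exc}", stacklevel=2)
            encs.append(None)
            n_bad += 1
    out = np.full(len(encs), np.nan)
    good = [i for i, e in enumerate(encs) if e is not None]
    if good:
        pred = model.predict_encodings([encs[i] for i in good])
        out[good] = np.maximum(pred, 1.0)  # CCS is physically positive
    return out


# ---------------------------------------------------------------------------
# Dataset alignment and merging
# ---------------------------------------------------------------------------

@dataclass
class AlignmentModel:
    slope: float
    intercept: float
    n_overlap: int
    residual_std: float = float("nan")

    def transform(self, ccs: float | np.ndarray):
        return self.slope * np.asarray(ccs, dtype=float) + self.intercept


MIN_ALIGNMENT_OVERLAP = 10


def align_datasets(
    reference_records: list[CcsRecord],
    other_records: list[CcsRecord],
    min_overlap: int = MIN_ALIGNMENT_OVERLAP,
) -> AlignmentModel:
    """Least-squares fit ``reference = a * other + b`` on overlapping pairs."""
    ref = {r.peptidoform.key(): r.ccs for r in reference_records}
    pairs = [
        (o.ccs, ref[o.peptidoform.key()])
        for o in other_records
        if o.peptidoform.key() in ref
    ]
    if len(pairs) < min_overlap:
        raise ValueError(
            f"only {len(pairs)} overlapping peptidoform-charge pairs; "
            f"minimum is {min_overlap}"
        )
    x, y = np.array(pairs).T
    a, b = np.polyfit(x, y, 1)
    resid = y - (a * x + b)
    return AlignmentModel(float(a), float(b), len(pairs), float(resid.std()))


def merge_datasets(
    reference_records: list[CcsRecord],
    other_records: list[CcsRecord],
    alignment: AlignmentModel,
) -> list[CcsRecord]:
    """Transform the other dataset onto the reference scale and take the union,
    averaging overlapping peptidoform-charge pairs."""
    ref = {r.peptidoform.key(): r for r in reference_records}
    out: dict[tuple, CcsRecord] = dict(ref)
    for o in other_records:
        aligned = float(alignment.transform(o.ccs))
        k = o.peptidoform.key()
        if k in ref:
            out[k] = CcsRecord(
                ref[k].peptidoform,
                (ref[k].ccs + aligned) / 2.0,
                f"{ref[k].source}+{o.source}" if o.source or ref[k].source else "",
            )
        elif k not in out:
            out[k] = CcsRecord(o.peptidoform, aligned, o.source)
    return list(out.values())


def _isomer_key(p: Peptidoform) -> tuple:
    masses = tuple(sorted(round(m.mass, 4) for m in p.modifications))
    return (p.sequence, masses, p.charge)


def collapse_isomers(records: list[CcsRecord]) -> list[CcsRecord]:
    """Average records whose peptidoforms differ only in isomeric modification
    placement/variant (same sequence, same modification mass multiset, same
    charge) — the model cannot distinguish them."""
    groups: dict[tuple, list[CcsRecord]] = {}
    order: list[tuple] = []
    for r in records:
        k = _isomer_key(r.peptidoform)
        if k not in groups:
            order.append(k)
        groups.setdefault(k, []).append(r)
    out = []
    for k in order:
        g = groups[k]
        if len(g) == 1:
            out.append(g[0])
        else:
            logger.info("collapsing %d isomers of %s", len(g), g[0].peptidoform)
            out.append(
                CcsRecord(g[0].peptidoform, float(np.mean([r.ccs for r in g])),
                          g[0].source)
            )
    return out


# ---------------------------------------------------------------------------
# Leave-one-out generalization harnesses
# ---------------------------------------------------------------------------

def _eval(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    mae = float(np.mean(np.abs(pred - truth)))
    r = pcc(pred, truth) if len(truth) >= 2 else float("nan")
    return mae, r


def loo_modification_harness(
    records: list[CcsRecord],
    modification_name: str,
    config: CcsConfig | None = None,
) -> dict:
    """Train without carriers of one modification, evaluate on the carriers.

    The carriers are scored twice: with the modification's composition
    encoded (extrapolation through the learned composition coefficients) and
    with it ignored (zeroed), quantifying how much of the modification's CCS
    shift the encoding explains.
    """
    config = config or CcsConfig()
    is_carrier = [
        any(m.name == modification_name for m in r.peptidoform.modifications)
        for r in records
    ]
    carriers = [r for r, c in zip(records, is_carrier) if c]
    non_carriers = [r for r, c in zip(records, is_carrier) if not c]
    if not carriers:
        raise ValueError(f"no records carry modification {modification_name!r}")
    model = train_ccs_model(non_carriers, config)
    peps = [r.peptidoform for r in carriers]
    truth = np.array([r.ccs for r in carriers])
    pred_enc = predict_ccs(model, peps)
    pred_ign = predict_ccs(model, peps, ignore_modification=modification_name)
    mae_e, pcc_e = _eval(pred_enc, truth)
    mae_i, pcc_i = _eval(pred_ign, truth)
    return {
        "modification": modification_name,
        "n_carriers": len(carriers),
        "n_train": len(non_carriers),
        "mae_encoded": mae_e,
        "mae_ignored": mae_i,
        "pcc_encoded": pcc_e,
        "pcc_ignored": pcc_i,
        "mae_difference": mae_i - mae_e,
    }


def loo_amino_acid_harness(
    records: list[CcsRecord],
    amino_acid: str,
    config: CcsConfig | None = None,
) -> dict:
    """Train on peptides lacking one residue, evaluate on peptides containing it.

    Carrier peptides are scored with the residue's true composition and again
    with the residue substituted by glycine in all encoding paths, isolating
    the residue's learned CCS contribution.
    """
    if amino_acid == "G":
        raise ValueError("glycine is the substitution baseline, not a target")
    if amino_acid not in AMINO_ACIDS:
        raise ValueError(f"unknown residue {amino_acid!r}")
    config = config or CcsConfig()
    carriers = [r for r in records if amino_acid in r.peptidoform.sequence]
    lackers = [r for r in records if amino_acid not in r.peptidoform.sequence]
    if not lackers:
        raise ValueError(f"no peptides lack residue {amino_acid!r}")
    if not carriers:
        raise ValueError(f"no peptides contain residue {amino_acid!r}")
    model = train_ccs_model(lackers, config)
    peps = [r.peptidoform for r in carriers]
    truth = np.array([r.ccs for r in carriers])
    pred_true = predict_ccs(model, peps)
    pred_sub = predict_ccs(model, peps, substitute={amino_acid: "G"})
    mae_t, pcc_t = _eval(pred_true, truth)
    mae_s, pcc_s = _eval(pred_sub, truth)
    return {
        "amino_acid": amino_acid,
        "n_carriers": len(carriers),
        "n_train": len(lackers),
        "mae_encoded": mae_t,
        "mae_substituted": mae_s,
        "pcc_encoded": pcc_t,
        "pcc_substituted": pcc_s,
        "mae_difference": mae_s - mae_t,
    }


# ---------------------------------------------------------------------------
# Ion mobility conversion (Mason-Schamp low-field limit)
# ---------------------------------------------------------------------------

_KB = 1.380649e-23  # J/K
_E_CHARGE = 1.602176634e-19  # C
_N0 = 2.686780111e25  # Loschmidt constant, m^-3 (273.15 K, 101.325 kPa)
_DA_TO_KG = 1.66053906660e-27
N2_MASS = 28.00615  # Da

DEFAULT_DRIFT_TEMPERATURE = 305.0  # K, typical trapped-ion-mobility drift gas


def one_over_k0_to_ccs(
    one_over_k0: float | np.ndarray,
    charge: int,
    ion_mass: float,
    gas_mass: float = N2_MASS,
    temperature: float = DEFAULT_DRIFT_TEMPERATURE,
):
    """Convert inverse reduced mobility (Vs/cm^2) to CCS (A^2).

    Uses the Mason-Schamp relation in the low-field limit with a nitrogen
    drift gas by default; ``ion_mass`` is the neutral+protons ion mass in Da.
    """
    one_over_k0 = np.asarray(one_over_k0, dtype=float)
    mu = ion_mass * gas_mass / (ion_mass + gas_mass) * _DA_TO_KG
    k0_si = 1e-4 / one_over_k0  # cm^2/Vs -> m^2/Vs
    omega = (
        (3.0 / 16.0)
        * np.sqrt(2.0 * np.pi / (mu * _KB * temperature))
        * charge
        * _E_CHARGE
        / (_N0 * k0_si)
    )
    out = omega * 1e20  # m^2 -> A^2
    return float(out) if out.ndim == 0 else out


def ccs_to_one_over_k0(
    ccs: float | np.ndarray,
    charge: int,
    ion_mass: float,
    gas_mass: float = N2_MASS,
    temperature: float = DEFAULT_DRIFT_TEMPERATURE,
):
    """Inverse of :func:`one_over_k0_to_ccs`."""
    ccs = np.asarray(ccs, dtype=float)
    mu = ion_mass * gas_mass / (ion_mass + gas_mass) * _DA_TO_KG
    omega = ccs * 1e-20
    k0_si = (
        (3.0 / 16.0)
        * np.sqrt(2.0 * np.pi / (mu * _KB * temperature))
        * charge
        * _E_CHARGE
        / (_N0 * omega)
    )
    out = 1e-4 / k0_si
    return float(out) if out.ndim == 0 else out
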