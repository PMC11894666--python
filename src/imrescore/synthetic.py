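"""Ground-truth generators that make the whole pipeline testable offline.

The generators emulate the three data layers the rescoring pipeline
consumes: peptidoform populations, fragment spectra, and CCS measurements.
Every generator is a pure function of (config, seed).

* Fragment intensities follow a documented closed-form law: a smooth
  positional profile along the backbone modulated by the gas-phase basicity
  (y ions) and hydrophobicity (b ions) of the residues flanking the cleavage
  site. The law lives in the same feature space as the cleavage-site
  encoder, so a trained model can in principle reach the intra-peptidoform
  noise ceiling — mirroring how real fragmentation intensities are governed
  by local sequence context.

* CCS ground truth is a linear form over the encoder's global features
  (length, charge, total atomic composition, grouped residue frequencies)
  plus Gaussian noise. Modifications influence CCS through their atomic
  composition, so a "CCS shift of delta" is induced by a modification whose
  composition contributes delta through the linear form — the construction
  under which leave-one-modification-out generalization is learnable at all.

* Benchmarks pair correct target PSMs with their own spectra/CCS, and
  incorrect targets and decoys with *other peptides'* spectra and CCS (the
  mismatch model: a wrong match still points at a real measurement, so
  spectrum features are informative but imperfect). The mismatched peptide
  is drawn from the precursor window — nearest neutral mass at the same
  charge — because a search engine only ever proposes candidates within the
  precursor tolerance. This matters for feature realism: a wrong candidate
  has nearly the right mass, hence a *similar* CCS (mass dominates CCS),
  while its fragment ions differ completely; CCS error is therefore a
  moderate discriminant and fragment-intensity correlation a strong one.
  Search scores are drawn from two overlapping Gaussians, with decoys
  statistically exchangeable with incorrect targets — the property
  target-decoy FDR estimation requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
import pandas as pd

from .ccs import GLOBAL_FEATURE_NAMES, CcsRecord, global_features
from .constants import AMINO_ACIDS, BASICITY, HYDROPHOBICITY, formula_mass
from .fragments import theoretical_fragment_mz
from .io import (
    IonMobilityValue,
    Modification,
    Peptidoform,
    Psm,
    PsmCollection,
    Spectrum,
)

__all__ = [
    "DEFAULT_MOD_ALPHABET",
    "CcsCoefficients",
    "BenchmarkConfig",
    "BenchmarkTruth",
    "generate_peptides",
    "intensity_law",
    "simulate_spectrum",
    "simulate_ccs",
    "modification_with_shift",
    "build_benchmark",
    "LawIntensityPredictor",
    "TruthCcsPredictor",
    "NoiseIntensityPredictor",
    "NoiseCcsPredictor",
    "write_benchmark",
]

# (name, mass delta, composition delta) templates for variable modifications
DEFAULT_MOD_ALPHABET: tuple[tuple[str, float, dict[str, int]], ...] = (
    ("oxidation", 15.99491, {"O": 1}),
    ("carbamidomethyl", 57.02146, {"C": 2, "H": 3, "N": 1, "O": 1}),
    ("acetyl", 42.01057, {"C": 2, "H": 2, "O": 1}),
)


def generate_peptides(
    n: int,
    length_range: tuple[int, int] = (8, 30),
    tryptic_fraction: float = 0.5,
    modification_alphabet=DEFAULT_MOD_ALPHABET,
    modification_probability: float = 0.3,
    seed: int = 0,
    charges: tuple[int, ...] = (1, 2, 3, 4),
    charge_weights: tuple[float, ...] = (0.1, 0.5, 0.3, 0.1),
) -> list[Peptidoform]:
    """Random peptidoforms: tryptic ones end in K/R, up to two variable
    modifications drawn from the alphabet, charges 1-4."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if not (4 <= lo <= hi <= 60):
        raise ValueError("length_range must lie within 4..60")
    rng = np.random.default_rng(seed)
    aas = list(AMINO_ACIDS)
    out: list[Peptidoform] = []
    for _ in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(aas, size=length))
        if rng.random() < tryptic_fraction:
            seq[-1] = "K" if rng.random() < 0.5 else "R"
        mods: list[Modification] = []
        if modification_alphabet:
            n_mods = int(rng.binomial(2, modification_probability))
            positions = rng.choice(length, size=min(n_mods, length),
                                   replace=False)
            for pos in sorted(positions):
                name, mass, comp = modification_alphabet[
                    int(rng.integers(len(modification_alphabet)))
                ]
                mods.append(
                    Modification(int(pos) + 1, name, mass,
                                 tuple(sorted(comp.items())))
                )
        charge = int(rng.choice(charges, p=np.asarray(charge_weights) /
                                np.sum(charge_weights)))
        out.append(Peptidoform("".join(seq), tuple(mods), charge))
    return out


# ---------------------------------------------------------------------------
# Fragment intensity law
# ---------------------------------------------------------------------------

@lru_cache(maxsize=65536)
def intensity_law(peptidoform: Peptidoform) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form b/y intensity fractions (summing to 1 over both series).

    y_i at cleavage site s = n - i: gaussian positional profile centred
    mid-peptide, scaled up by the basicity of the residue C-terminal to the
    cleavage; b_i: a weaker profile shifted C-terminally, scaled by the
    hydrophobicity of the residue N-terminal to the cleavage.
    """
    seq = peptidoform.sequence
    n = len(seq)
    sites = np.arange(1, n)  # cleavage after residue `site`
    x = sites / n
    basic = np.array([BASICITY[a] for a in seq])
    hydro = np.array([HYDROPHOBICITY[a] for a in seq])
    y_raw = np.exp(-((x - 0.45) ** 2) / (2 * 0.22**2)) * (
        1.0 + 0.35 * np.tanh(basic[sites])  # residue C-terminal to the site
    )
    b_raw = 0.45 * np.exp(-((x - 0.60) ** 2) / (2 * 0.25**2)) * (
        1.0 + 0.15 * np.tanh(hydro[sites - 1] / 2.0)
    )
    # b_i indexes prefixes (site i), y_i suffixes (site n - i)
    b = b_raw
    y = y_raw[::-1]
    total = b.sum() + y.sum()
    return b / total, y / total


def simulate_spectrum(
    peptidoform: Peptidoform,
    law=intensity_law,
    noise_sigma: float = 0.0,
    n_noise_peaks: int = 0,
    seed: int = 0,
    identifier: str = "sim",
    base_intensity: float = 1.0e5,
    tolerance_ppm: float = 10.0,
    retention_time: float = float("nan"),
    ion_mobility: IonMobilityValue | None = None,
) -> Spectrum:
    """A centroided spectrum: law intensities at the theoretical b/y m/z with
    multiplicative log-normal noise, plus uniform noise peaks rejection-
    sampled to stay outside 3x the matching tolerance of every true ion."""
    rng = np.random.default_rng(seed)
    b_mz, y_mz = theoretical_fragment_mz(peptidoform)
    b_frac, y_frac = law(peptidoform)
    mz = np.concatenate([b_mz, y_mz])
    inten = np.concatenate([b_frac, y_frac]) * base_intensity
    if noise_sigma > 0:
        inten = inten * np.exp(rng.normal(0.0, noise_sigma, size=len(inten)))
    if n_noise_peaks > 0:
        lo, hi = 100.0, float(mz.max()) + 200.0 if len(mz) else 1500.0
        guard = mz * tolerance_ppm * 3e-6
        noise_mz = []
        while len(noise_mz) < n_noise_peaks:
            cand = rng.uniform(lo, hi)
            if len(mz) == 0 or np.all(np.abs(mz - cand) > guard):
                noise_mz.append(cand)
        noise_int = rng.uniform(0.05, 0.5, size=n_noise_peaks) * np.median(
            inten if len(inten) else [base_intensity]
        )
        mz = np.concatenate([mz, noise_mz])
        inten = np.concatenate([inten, noise_int])
    return Spectrum(
        identifier=identifier,
        mz=mz,
        intensity=inten,
        precursor_mz=peptidoform.mz,
        precursor_charge=peptidoform.charge,
        retention_time=retention_time,
        ion_mobility=ion_mobility,
    )


# ---------------------------------------------------------------------------
# CCS ground truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CcsCoefficients:
    """Linear CCS ground truth over the encoder's global features (A^2)."""

    intercept: float = 120.0
    coefficients: tuple[tuple[str, float], ...] = (
        ("length", 1.1),
        ("charge", 26.0),
        ("total_C", 0.25),
        ("total_H", 0.12),
        ("total_N", -0.4),
        ("total_O", 2.0),
        ("total_S", 1.5),
        ("freq_his", -15.0),
        ("freq_bulky", 12.0),
        ("freq_acidic", 6.0),
        ("freq_kr", -8.0),
    )

    def truth(self, peptidoform: Peptidoform) -> float:
        return _linear_truth(self, peptidoform)

    def coefficient(self, name: str) -> float:
        return dict(self.coefficients).get(name, 0.0)


_GLOBAL_INDEX = {name: i for i, name in enumerate(GLOBAL_FEATURE_NAMES)}


@lru_cache(maxsize=65536)
def _linear_truth(coefficients: "CcsCoefficients",
                  peptidoform: Peptidoform) -> float:
    feats = global_features(peptidoform)
    return coefficients.intercept + sum(
        c * feats[_GLOBAL_INDEX[name]] for name, c in coefficients.coefficients
    )


def modification_with_shift(
    delta: float,
    coefficients: CcsCoefficients | None = None,
    name: str = "shiftmod",
) -> tuple[str, float, dict[str, float]]:
    """A synthetic modification whose composition induces a CCS shift of
    exactly ``delta`` under the linear ground truth (through its oxygen
    content; fractional atom counts are acceptable for a synthetic species).
    """
    coefficients = coefficients or CcsCoefficients()
    beta_o = coefficients.coefficient("total_O")
    if beta_o == 0:
        raise ValueError("ground truth has no oxygen coefficient to carry delta")
    n_oxygen = delta / beta_o
    comp = {"O": n_oxygen}
    return (name, formula_mass(comp), comp)


def simulate_ccs(
    peptidoforms: list[Peptidoform],
    coefficients: CcsCoefficients | None = None,
    noise_sigma: float = 0.0,
    seed: int = 0,
    source: str = "synthetic",
    drift: tuple[float, float] = (1.0, 0.0),
) -> list[CcsRecord]:
    """CCS records on the linear ground truth plus N(0, sigma^2) noise.

    ``drift=(a, b)`` applies a linear instrument drift a*ccs + b, for
    emulating a second dataset that :func:`imrescore.ccs.align_datasets`
    should recover.
    """
    coefficients = coefficients or CcsCoefficients()
    rng = np.random.default_rng(seed)
    a, b = drift
    out = []
    for p in peptidoforms:
        ccs = coefficients.truth(p) + rng.normal(0.0, noise_sigma)
        out.append(CcsRecord(p, a * ccs + b, source))
    return out


# ---------------------------------------------------------------------------
# Benchmarks
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkConfig:
    n_correct: int = 2000
    n_incorrect: int = 2000
    n_decoys: int = 4000
    length_range: tuple[int, int] = (8, 20)
    score_mu_correct: float = 3.5
    score_mu_null: float = 0.0
    score_sigma: float = 1.0
    spectrum_noise_sigma: float = 0.25
    n_noise_peaks: int = 8
    ccs_obs_noise: float = 1.5
    rt_obs_noise: float = 0.5
    tryptic_fraction: float = 0.8
    modification_probability: float = 0.2


@dataclass
class BenchmarkTruth:
    """Per-PSM ground truth, serialized alongside every generated benchmark."""

    table: pd.DataFrame
    config: BenchmarkConfig
    seed: int
    coefficients: CcsCoefficients = field(default_factory=CcsCoefficients)


def _rt_truth(p: Peptidoform) -> float:
    """A simple linear-with-hydrophobicity retention model (minutes)."""
    hyd = sum(HYDROPHOBICITY[a] for a in p.sequence)
    return 10.0 + 0.8 * len(p.sequence) + 0.6 * hyd


def _decoy_of(p: Peptidoform) -> Peptidoform:
    """Pseudo-reversed sequence (C-terminal residue kept) — the decoy keeps
    the target's gross composition, as sequence-reversal decoys do."""
    if len(p.sequence) < 2:
        return p
    seq = p.sequence[:-1][::-1] + p.sequence[-1]
    return Peptidoform(seq, (), p.charge)


def build_benchmark(
    config: BenchmarkConfig | None = None, seed: int = 0
) -> tuple[PsmCollection, dict[str, Spectrum], BenchmarkTruth]:
    """A complete synthetic search result with known correct/incorrect labels.

    Correct target PSMs pair a peptidoform with its own simulated spectrum,
    CCS and RT; incorrect targets and decoys are paired with a *different*
    peptide's spectrum and measurements. Search scores: correct ~
    N(mu_correct, sigma), incorrect and decoy ~ N(mu_null, sigma) —
    identically distributed, so decoys are exchangeable with incorrect
    targets.
    """
    config = config or BenchmarkConfig()
    rng = np.random.default_rng(seed)
    coeffs = CcsCoefficients()
    n_pool = config.n_correct + config.n_incorrect
    pool = generate_peptides(
        n_pool,
        config.length_range,
        config.tryptic_fraction,
        modification_probability=config.modification_probability,
        seed=int(rng.integers(2**31)),
    )
    decoy_peps = [_decoy_of(pool[i % n_pool]) for i in range(config.n_decoys)]

    # precursor-window mismatch model: wrong candidates come from the same
    # charge state at the nearest neutral mass (a search engine never
    # proposes candidates outside the precursor tolerance)
    pool_mass = np.array([p.neutral_mass for p in pool])
    by_charge: dict[int, list[int]] = {}
    for i, p in enumerate(pool):
        by_charge.setdefault(p.charge, []).append(i)
    order_by_charge = {
        z: sorted(idxs, key=lambda i: pool_mass[i])
        for z, idxs in by_charge.items()
    }
    mass_by_charge = {
        z: np.array([pool_mass[i] for i in idxs])
        for z, idxs in order_by_charge.items()
    }
    rank_in_charge = {
        i: r for z, idxs in order_by_charge.items() for r, i in enumerate(idxs)
    }

    def mismatched_generator(pep: Peptidoform, self_index: int | None):
        idxs = order_by_charge.get(pep.charge)
        if not idxs or (len(idxs) == 1 and self_index in idxs):
            return pool[int(rng.integers(n_pool))]
        if self_index is not None and self_index in rank_in_charge:
            r = rank_in_charge[self_index]
        else:  # decoys: locate by mass
            r = int(np.searchsorted(mass_by_charge[pep.charge],
                                    pep.neutral_mass))
        for _ in range(10):
            off = int(rng.integers(1, 6)) * (1 if rng.random() < 0.5 else -1)
            j = min(max(r + off, 0), len(idxs) - 1)
            cand = pool[idxs[j]]
            if cand.key() != pep.key():
                return cand
        j = (r + 1) % len(idxs)
        return pool[idxs[j]]

    psms: list[Psm] = []
    spectra: dict[str, Spectrum] = {}
    truth_rows = []

    def emit(idx, pep, generator, is_decoy, is_correct, proteins):
        sid = f"spec{idx}"
        score = rng.normal(
            config.score_mu_correct if is_correct else config.score_mu_null,
            config.score_sigma,
        )
        rt_obs = _rt_truth(generator) + rng.normal(0, config.rt_obs_noise)
        ccs_obs = coeffs.truth(generator) + rng.normal(0, config.ccs_obs_noise)
        spectra[sid] = simulate_spectrum(
            generator,
            noise_sigma=config.spectrum_noise_sigma,
            n_noise_peaks=config.n_noise_peaks,
            seed=int(rng.integers(2**31)),
            identifier=sid,
            retention_time=rt_obs,
            ion_mobility=IonMobilityValue("ccs", max(ccs_obs, 1.0)),
        )
        psms.append(
            Psm(
                spectrum_id=sid,
                peptidoform=pep,
                score=float(score),
                retention_time=rt_obs,
                ion_mobility=IonMobilityValue("ccs", max(ccs_obs, 1.0)),
                is_decoy=is_decoy,
                proteins=proteins,
            )
        )
        truth_rows.append(
            {
                "spectrum_id": sid,
                "peptidoform": str(pep),
                "generator": str(generator),
                "is_correct": is_correct,
                "is_decoy": is_decoy,
                "true_ccs": coeffs.truth(pep),
                "generator_ccs": coeffs.truth(generator),
            }
        )

    idx = 0
    for i in range(config.n_correct):
        pep = pool[i]
        emit(idx, pep, pep, False, True, (f"PROT{i % 500}",))
        idx += 1
    for i in range(config.n_incorrect):
        pep = pool[config.n_correct + i]
        gen = mismatched_generator(pep, config.n_correct + i)
        emit(idx, pep, gen, False, False, (f"PROT{(config.n_correct + i) % 500}",))
        idx += 1
    for i in range(config.n_decoys):
        pep = decoy_peps[i]
        gen = mismatched_generator(pep, None)
        emit(idx, pep, gen, True, False, (f"rev_PROT{i % 500}",))
        idx += 1

    truth = BenchmarkTruth(pd.DataFrame(truth_rows), config, seed, coeffs)
    return PsmCollection(psms, source=f"benchmark(seed={seed})"), spectra, truth


# ---------------------------------------------------------------------------
# Oracle and noise predictors (duck-typed plug-ins for assemble_features)
# ---------------------------------------------------------------------------

class LawIntensityPredictor:
    """Predicts fragment intensities straight from the generating law —
    the idealized predictor a perfectly trained model would approach."""

    def __init__(self, pseudocount: float = 0.001):
        self.pseudocount = pseudocount

    def predict_intensities(self, peptidoform: Peptidoform):
        b, y = intensity_law(peptidoform)
        return (
            np.log2(b + self.pseudocount),
            np.log2(y + self.pseudocount),
        )


class TruthCcsPredictor:
    """Predicts CCS from the linear ground truth (no noise)."""

    def __init__(self, coefficients: CcsCoefficients | None = None):
        self.coefficients = coefficients or CcsCoefficients()

    def predict(self, peptidoforms: list[Peptidoform]) -> np.ndarray:
        return np.array([self.coefficients.truth(p) for p in peptidoforms])


def _pep_rng(peptidoform: Peptidoform, seed: int) -> np.random.Generator:
    import zlib

    h = zlib.crc32(f"{peptidoform}|{seed}".encode())  # stable across processes
    return np.random.default_rng(h)


class NoiseIntensityPredictor:
    """Deterministic per-peptidoform noise — carries no signal at all."""

    def __init__(self, seed: int = 0):
        self.seed = seed

    def predict_intensities(self, peptidoform: Peptidoform):
        rng = _pep_rng(peptidoform, self.seed)
        n = len(peptidoform.sequence) - 1
        return rng.normal(-7, 1, n), rng.normal(-7, 1, n)


class NoiseCcsPredictor:
    """Deterministic per-peptidoform random CCS — no signal."""

    def __init__(self, seed: int = 0, scale: float = 400.0):
        self.seed = seed
        self.scale = scale

    def predict(self, peptidoforms: list[Peptidoform]) -> np.ndarray:
        return np.array(
            [self.scale + 50 * _pep_rng(p, self.seed).normal()
             for p in peptidoforms]
        )


# ---------------------------------------------------------------------------
# File export
# ---------------------------------------------------------------------------

def write_benchmark(
    psms: PsmCollection,
    spectra: dict[str, Spectrum],
    truth: BenchmarkTruth,
    out_dir: str,
) -> dict[str, str]:
    """Write MGF + generic PSM TSV + CCS TSV + truth TSV into a directory."""
    import json
    import os

    from .io import write_mgf, write_psm_table

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "mgf": os.path.join(out_dir, "spectra.mgf"),
        "psms": os.path.join(out_dir, "psms.tsv"),
        "ccs": os.path.join(out_dir, "ccs.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
        "config": os.path.join(out_dir, "benchmark_config.json"),
    }
    write_mgf([spectra[p.spectrum_id] for p in psms], paths["mgf"])
    write_psm_table(psms, paths["psms"])
    ccs_rows = [
        {
            "peptidoform": row["peptidoform"],
            "ccs": "%.6f" % row["true_ccs"],
            "source": "truth",
        }
        for _, row in truth.table.iterrows()
        if row["is_correct"]
    ]
    pd.DataFrame(ccs_rows).to_csv(paths["ccs"], sep="\t", index=False)
    truth.table.to_csv(paths["truth"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        json.dump(
            {"seed": truth.seed, "config": asdict(truth.config)}, fh, indent=2
        )
    return paths
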