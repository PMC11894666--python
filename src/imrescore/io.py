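"""Domain types and readers/writers for spectra and PSM tables.

The in-memory model is deliberately small: a :class:`Peptidoform` (sequence +
localized modifications + precursor charge — charge is part of peptidoform
identity), a centroided :class:`Spectrum`, and a :class:`Psm` tying the two
together with search-engine metadata. Spectra are exchanged as MGF (parsed
with :mod:`pyteomics.mgf`), PSMs as tab-separated tables in either a generic
documented dialect or the Sage ``results.tsv`` dialect.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import mgf as _pyteomics_mgf

from .constants import AMINO_ACIDS, MODIFICATIONS, RESIDUE_MASS

__all__ = [
    "Modification",
    "Peptidoform",
    "IonMobilityValue",
    "Spectrum",
    "Psm",
    "PsmCollection",
    "PsmParseError",
    "MgfParseError",
    "parse_peptidoform",
    "read_mgf",
    "write_mgf",
    "read_psm_table",
    "write_psm_table",
    "write_rescored_table",
    "GENERIC_COLUMNS",
    "DECOY_PREFIXES",
]

DECOY_PREFIXES: tuple[str, ...] = ("rev_", "DECOY_")

GENERIC_COLUMNS = [
    "spectrum_id",
    "peptidoform",
    "charge",
    "score",
    "rt",
    "im",
    "is_decoy",
    "proteins",
]


class PsmParseError(ValueError):
    """Raised for malformed PSM tables or peptidoform strings."""


class MgfParseError(ValueError):
    """Raised for structurally malformed MGF files."""


@dataclass(frozen=True, order=True)
class Modification:
    """A localized modification.

    ``position`` is 1-based on residues; 0 denotes the N-terminus and
    ``len(sequence) + 1`` the C-terminus.
    """

    position: int
    name: str
    mass: float
    composition: tuple[tuple[str, float], ...] = ()

    def composition_dict(self) -> dict[str, float]:
        return dict(self.composition)


@dataclass(frozen=True)
class Peptidoform:
    sequence: str
    modifications: tuple[Modification, ...] = ()
    charge: int = 2

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("sequence must be non-empty")
        if self.sequence != self.sequence.upper():
            raise ValueError("sequence must be upper-case")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"unknown residue letter(s): {sorted(bad)!r}")
        if self.charge < 1:
            raise ValueError("charge must be >= 1")
        mods = tuple(sorted(self.modifications))
        positions = [m.position for m in mods]
        if len(positions) != len(set(positions)):
            raise ValueError("at most one modification per position")
        n = len(self.sequence)
        for m in mods:
            if not (0 <= m.position <= n + 1):
                raise ValueError(
                    f"modification position {m.position} outside 0..{n + 1}"
                )
        object.__setattr__(self, "modifications", mods)

    # -- identity ---------------------------------------------------------
    def key(self) -> tuple:
        """Charge-aware identity key."""
        return (self.sequence, self.modifications, self.charge)

    def sequence_key(self) -> tuple:
        """Charge-agnostic identity (sequence + modification multiset)."""
        return (self.sequence, self.modifications)

    # -- derived quantities ----------------------------------------------
    @property
    def modification_mass(self) -> float:
        return sum(m.mass for m in self.modifications)

    @property
    def neutral_mass(self) -> float:
        """Monoisotopic neutral (uncharged) peptide mass in Da."""
        from .constants import WATER_MASS

        return (
            sum(RESIDUE_MASS[a] for a in self.sequence)
            + self.modification_mass
            + WATER_MASS
        )

    @property
    def mz(self) -> float:
        from .constants import PROTON_MASS

        return self.neutral_mass / self.charge + PROTON_MASS

    def residue_mod_mass(self) -> np.ndarray:
        """Per-residue modification mass with terminal mods folded into the
        first/last residue (the convention used by fragment mass computation)."""
        out = np.zeros(len(self.sequence))
        n = len(self.sequence)
        for m in self.modifications:
            if m.position == 0:
                out[0] += m.mass
            elif m.position == n + 1:
                out[-1] += m.mass
            else:
                out[m.position - 1] += m.mass
        return out

    def __str__(self) -> str:
        return format_peptidoform(self)


@dataclass(frozen=True)
class IonMobilityValue:
    """An ion-mobility measurement; the kind is explicit, never inferred."""

    kind: str  # "inverse_reduced_mobility" (Vs/cm^2) or "ccs" (A^2)
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("inverse_reduced_mobility", "ccs"):
            raise ValueError(f"unknown ion mobility kind {self.kind!r}")
        if not self.value > 0:
            raise ValueError("ion mobility value must be positive")


@dataclass
class Spectrum:
    identifier: str
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float = float("nan")
    precursor_charge: int | None = None
    retention_time: float = float("nan")
    ion_mobility: IonMobilityValue | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have equal length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())


@dataclass
class Psm:
    spectrum_id: str
    peptidoform: Peptidoform
    score: float
    search_features: dict[str, float] = field(default_factory=dict)
    retention_time: float = float("nan")
    ion_mobility: IonMobilityValue | None = None
    is_decoy: bool = False
    proteins: tuple[str, ...] = ()
    rank: int = 1


@dataclass
class PsmCollection:
    """An ordered list of PSMs with provenance metadata."""

    psms: list[Psm]
    source: str = ""
    engine: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for p in self.psms:
            k = (p.spectrum_id, p.rank)
            if k in seen:
                raise ValueError(f"duplicate (spectrum_id, rank) pair {k!r}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.psms)

    def __iter__(self):
        return iter(self.psms)

    def __getitem__(self, i):
        return self.psms[i]


# ---------------------------------------------------------------------------
# Peptidoform text notation
# ---------------------------------------------------------------------------

_MOD_RE = re.compile(r"\[([^\]]+)\]")


def _resolve_mod(token: str) -> tuple[str, float, tuple[tuple[str, float], ...]]:
    token = token.strip()
    if token.startswith(("+", "-")):
        mass = float(token)
        # mass-only: remember the printed form as the name
        for name, (m, comp) in MODIFICATIONS.items():
            if abs(m - mass) < 5e-4:
                return name, m, tuple(sorted(comp.items()))
        return token, mass, ()
    name = token.lower()
    if name not in MODIFICATIONS:
        raise PsmParseError(f"unknown modification name {token!r}")
    mass, comp = MODIFICATIONS[name]
    return name, mass, tuple(sorted(comp.items()))


def parse_peptidoform(text: str, charge: int | None = None) -> Peptidoform:
    """Parse a ProForma-style string such as ``"AC[+57.02146]DK/2"``.

    Square brackets carry either a signed monoisotopic mass delta or a known
    modification name; an N-terminal modification is written ``[x]-SEQ`` and a
    C-terminal one ``SEQ-[x]``. The precursor charge follows a ``/``; an
    explicit ``charge`` argument overrides it.
    """
    text = text.strip()
    if "/" in text:
        body, _, ch = text.rpartition("/")
        parsed_charge = int(ch)
        if charge is None:
            charge = parsed_charge
    else:
        body = text
    if charge is None:
        raise PsmParseError(f"no charge in {text!r} and none supplied")

    mods: list[Modification] = []
    # N-terminal mod
    m = re.match(r"^\[([^\]]+)\]-", body)
    if m:
        name, mass, comp = _resolve_mod(m.group(1))
        mods.append(Modification(0, name, mass, comp))
        body = body[m.end():]
    # C-terminal mod
    m = re.search(r"-\[([^\]]+)\]$", body)
    cterm_token = None
    if m:
        cterm_token = m.group(1)
        body = body[: m.start()]

    sequence_chars: list[str] = []
    i = 0
    while i < len(body):
        c = body[i]
        if c == "[":
            j = body.find("]", i)
            if j < 0:
                raise PsmParseError(f"unclosed '[' in {text!r}")
            if not sequence_chars:
                raise PsmParseError(f"modification before any residue in {text!r}")
            name, mass, comp = _resolve_mod(body[i + 1: j])
            mods.append(Modification(len(sequence_chars), name, mass, comp))
            i = j + 1
        elif c.isalpha():
            sequence_chars.append(c.upper())
            i += 1
        else:
            raise PsmParseError(f"unexpected character {c!r} in {text!r}")
    sequence = "".join(sequence_chars)
    if cterm_token is not None:
        name, mass, comp = _resolve_mod(cterm_token)
        mods.append(Modification(len(sequence) + 1, name, mass, comp))
    try:
        return Peptidoform(sequence, tuple(mods), charge)
    except ValueError as exc:
        raise PsmParseError(f"invalid peptidoform {text!r}: {exc}") from exc


def format_peptidoform(p: Peptidoform, with_charge: bool = True) -> str:
    n = len(p.sequence)
    by_pos = {m.position: m for m in p.modifications}

    def tok(m: Modification) -> str:
        return f"[{m.mass:+.5f}]"

    parts: list[str] = []
    if 0 in by_pos:
        parts.append(tok(by_pos[0]) + "-")
    for i, aa in enumerate(p.sequence, start=1):
        parts.append(aa)
        if i in by_pos:
            parts.append(tok(by_pos[i]))
    if n + 1 in by_pos:
        parts.append("-" + tok(by_pos[n + 1]))
    out = "".join(parts)
    if with_charge:
        out += f"/{p.charge}"
    return out


# ---------------------------------------------------------------------------
# MGF
# ---------------------------------------------------------------------------

def _check_mgf_structure(path: str) -> None:
    """Pre-scan for unbalanced BEGIN IONS/END IONS, reporting line numbers."""
    open_line = None
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            s = line.strip().upper()
            if s == "BEGIN IONS":
                if open_line is not None:
                    raise MgfParseError(
                        f"BEGIN IONS at line {ln} before END IONS for the "
                        f"block opened at line {open_line}"
                    )
                open_line = ln
            elif s == "END IONS":
                if open_line is None:
                    raise MgfParseError(f"END IONS without BEGIN IONS at line {ln}")
                open_line = None
    if open_line is not None:
        raise MgfParseError(f"missing END IONS for block opened at line {open_line}")


_IM_KEYS_K0 = ("1/k0", "1/K0", "inverse_reduced_mobility", "ion_mobility")
_IM_KEYS_CCS = ("ccs", "CCS")


def read_mgf(path: str) -> list[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum`.

    Peaks are sorted by m/z; ``RTINSECONDS`` populates the retention time and
    a ``1/K0`` or ``CCS`` header field populates the ion mobility.
    """
    _check_mgf_structure(path)
    spectra: list[Spectrum] = []
    with _pyteomics_mgf.MGF(path, convert_arrays=1, read_charges=False) as reader:
        for idx, entry in enumerate(reader):
            params = entry.get("params", {})
            ident = str(params.get("title", params.get("scans", f"index={idx}")))
            pepmass = params.get("pepmass", (float("nan"),))
            prec_mz = float(pepmass[0]) if pepmass else float("nan")
            charge = None
            if "charge" in params:
                ch = params["charge"]
                charge = int(ch[0]) if isinstance(ch, (list, tuple)) else int(ch)
            rt = float(params["rtinseconds"]) if "rtinseconds" in params else float("nan")
            im = None
            for k in _IM_KEYS_CCS:
                if k.lower() in params:
                    im = IonMobilityValue("ccs", float(params[k.lower()]))
                    break
            if im is None:
                for k in _IM_KEYS_K0:
                    if k.lower() in params:
                        im = IonMobilityValue(
                            "inverse_reduced_mobility", float(params[k.lower()])
                        )
                        break
            spectra.append(
                Spectrum(
                    identifier=ident,
                    mz=entry.get("m/z array", np.empty(0)),
                    intensity=entry.get("intensity array", np.empty(0)),
                    precursor_mz=prec_mz,
                    precursor_charge=charge,
                    retention_time=rt,
                    ion_mobility=im,
                )
            )
    if not spectra:
        warnings.warn(f"no spectra found in {path}", stacklevel=2)
    return spectra


def write_mgf(spectra: list[Spectrum], path: str) -> None:
    entries = []
    for s in spectra:
        params: dict = {"title": s.identifier}
        if np.isfinite(s.precursor_mz):
            params["pepmass"] = s.precursor_mz
        if s.precursor_charge is not None:
            params["charge"] = s.precursor_charge
        if np.isfinite(s.retention_time):
            params["rtinseconds"] = s.retention_time
        if s.ion_mobility is not None:
            key = "ccs" if s.ion_mobility.kind == "ccs" else "1/k0"
            params[key] = s.ion_mobility.value
        entries.append(
            {"params": params, "m/z array": s.mz, "intensity array": s.intensity}
        )
    with open(path, "w") as fh:
        _pyteomics_mgf.write(entries, fh)


# ---------------------------------------------------------------------------
# PSM tables
# ---------------------------------------------------------------------------

def _is_decoy_proteins(proteins: tuple[str, ...], prefixes=DECOY_PREFIXES) -> bool:
    return bool(proteins) and all(
        any(p.startswith(pre) for pre in prefixes) for p in proteins
    )


_FLOAT_FMT = "%.10g"  # >= 9 significant digits for round-trips


def _row_to_psm_generic(row: pd.Series, idx: int, prefixes) -> Psm:
    try:
        pep = parse_peptidoform(str(row["peptidoform"]), int(row["charge"]))
    except (PsmParseError, ValueError) as exc:
        raise PsmParseError(f"row {idx}: {exc}") from exc
    proteins = tuple(str(row["proteins"]).split(";")) if row.get("proteins") else ()
    if "is_decoy" in row and not pd.isna(row["is_decoy"]):
        is_decoy = str(row["is_decoy"]).strip().lower() in ("1", "true", "yes")
    else:
        is_decoy = _is_decoy_proteins(proteins, prefixes)
    im = None
    if "im" in row and not pd.isna(row["im"]):
        kind = str(row.get("im_kind", "ccs")) if "im_kind" in row else "ccs"
        im = IonMobilityValue(kind, float(row["im"]))
    extra = {}
    for col in row.index:
        if col in GENERIC_COLUMNS or col == "im_kind":
            continue
        val = row[col]
        if isinstance(val, (int, float, np.floating, np.integer)) and not pd.isna(val):
            extra[col] = float(val)
    return Psm(
        spectrum_id=str(row["spectrum_id"]),
        peptidoform=pep,
        score=float(row["score"]),
        search_features=extra,
        retention_time=float(row["rt"]) if not pd.isna(row.get("rt")) else float("nan"),
        ion_mobility=im,
        is_decoy=is_decoy,
        proteins=proteins,
        rank=int(row["rank"]) if "rank" in row and not pd.isna(row["rank"]) else 1,
    )


SAGE_COLUMN_MAP = {
    "scannr": "spectrum_id",
    "peptide": "peptidoform",
    "charge": "charge",
    "sage_discriminant_score": "score",
    "rt": "rt",
    "ion_mobility": "im",
    "label": "label",
    "proteins": "proteins",
}

_SAGE_REQUIRED = ("scannr", "peptide", "charge", "sage_discriminant_score")
_GENERIC_REQUIRED = ("spectrum_id", "peptidoform", "charge", "score")


def read_psm_table(
    path: str,
    dialect: str = "generic",
    decoy_prefixes: tuple[str, ...] = DECOY_PREFIXES,
) -> PsmCollection:
    """Read a tab-separated PSM table.

    ``dialect='generic'`` expects the documented columns
    ``spectrum_id  peptidoform  charge  score  rt  im  is_decoy  proteins``
    (plus arbitrary numeric extras that become search features);
    ``dialect='sage'`` maps Sage ``results.tsv`` column names onto the same
    model, with all numeric Sage columns retained as search features.
    """
    if dialect not in ("generic", "sage"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype={"scannr": str, "spectrum_id": str})
    required = _GENERIC_REQUIRED if dialect == "generic" else _SAGE_REQUIRED
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise PsmParseError(
            f"{path}: missing required column(s) for dialect {dialect!r}: {missing}"
        )
    if dialect == "sage":
        df = df.rename(columns=SAGE_COLUMN_MAP)
        if "label" in df.columns:
            # Sage convention: label -1 = decoy, 1 = target
            df["is_decoy"] = df["label"].astype(float) < 0
        numeric_extra = [
            c
            for c in df.columns
            if c not in GENERIC_COLUMNS + ["label", "rank", "im_kind"]
            and pd.api.types.is_numeric_dtype(df[c])
        ]
        keep = [c for c in GENERIC_COLUMNS + ["rank", "im_kind"] if c in df.columns]
        df = df[keep + numeric_extra]
        if "im" in df.columns and "im_kind" not in df.columns:
            df["im_kind"] = "inverse_reduced_mobility"

    psms: list[Psm] = []
    errors: list[str] = []
    for idx, row in df.iterrows():
        try:
            psms.append(_row_to_psm_generic(row, int(idx), decoy_prefixes))
        except PsmParseError as exc:
            errors.append(str(exc))
    if errors:
        warnings.warn(
            f"{path}: {len(errors)} row(s) failed to parse "
            f"({len(psms)} parsed): {errors[:3]}",
            stacklevel=2,
        )
    coll = PsmCollection(psms, source=path, engine=dialect)
    coll.n_errors = len(errors)  # row conservation: input = parsed + errors
    coll.errors = errors
    return coll


def _psm_to_row(p: Psm) -> dict:
    row = {
        "spectrum_id": p.spectrum_id,
        "peptidoform": format_peptidoform(p.peptidoform, with_charge=False),
        "charge": p.peptidoform.charge,
        "score": _FLOAT_FMT % p.score,
        "rt": _FLOAT_FMT % p.retention_time,
        "im": _FLOAT_FMT % p.ion_mobility.value if p.ion_mobility else "",
        "im_kind": p.ion_mobility.kind if p.ion_mobility else "",
        "is_decoy": str(p.is_decoy).lower(),
        "proteins": ";".join(p.proteins),
        "rank": p.rank,
    }
    for k, v in p.search_features.items():
        row[k] = _FLOAT_FMT % v
    return row


def write_psm_table(psms: PsmCollection | list[Psm], path: str) -> None:
    """Write PSMs in the generic tab-separated dialect (round-trip safe)."""
    rows = [_psm_to_row(p) for p in psms]
    cols = GENERIC_COLUMNS[:2] + ["charge", "score", "rt", "im", "im_kind",
                                  "is_decoy", "proteins", "rank"]
    extra = sorted({k for r in rows for k in r} - set(cols))
    df = pd.DataFrame(rows, columns=cols + extra)
    df.to_csv(path, sep="\t", index=False)


def write_rescored_table(
    psms: PsmCollection | list[Psm],
    new_scores,
    qvalues: dict[str, np.ndarray],
    path: str,
    features: pd.DataFrame | None = None,
) -> None:
    """Write the original PSM columns plus the rescored score and q-values.

    ``qvalues`` maps a level name (``psm``, ``peptide``, ``protein``) to an
    array aligned with ``psms``.
    """
    psm_list = list(psms)
    new_scores = np.asarray(new_scores, dtype=float)
    if len(new_scores) != len(psm_list):
        raise ValueError("new_scores length does not match PSM count")
    for level, q in qvalues.items():
        if len(q) != len(psm_list):
            raise ValueError(f"q-value array for level {level!r} has wrong length")
    if features is not None and len(features) != len(psm_list):
        raise ValueError("feature table length does not match PSM count")
    rows = []
    for i, p in enumerate(psm_list):
        row = _psm_to_row(p)
        row["rescored_score"] = _FLOAT_FMT % new_scores[i]
        for level, q in qvalues.items():
            row[f"q_{level}"] = _FLOAT_FMT % q[i]
        if features is not None:
            for c in features.columns:
                row[f"feat_{c}"] = _FLOAT_FMT % features.iloc[i][c]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
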