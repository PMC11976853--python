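"""Core domain types and I/O for MS2 spectra and PSM tables.

Spectra are read and written in Mascot Generic Format (MGF) via pyteomics.
PSM tables use a minimal tab-delimited dialect of MaxQuant's ``msms.txt``:
a header row with at least ``Raw file``, ``Scan number``,
``Modified sequence``, ``Charge``, ``Score``, ``PEP``, ``Reverse`` and
``Proteins``; extra columns pass through untouched.

Retention time is held in minutes internally; MGF ``RTINSECONDS`` is
converted on read.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

DECOY_PREFIX = "REV__"
ENTRAPMENT_PREFIX = "ENT__"

#: residues Prosit-style predictors cannot handle
_UNPREDICTABLE_RESIDUES = frozenset("UO")
PREDICTABLE_MIN_LENGTH = 7
PREDICTABLE_MAX_LENGTH = 30
PREDICTABLE_MAX_CHARGE = 6

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYUO")


class MGFParseError(ValueError):
    """Malformed MGF content; message names the offending line."""


class SchemaError(ValueError):
    """PSM table is missing mandatory columns."""


class Peak(NamedTuple):
    mz: float
    intensity: float


@dataclass(frozen=True)
class Spectrum:
    """One MS2 scan.

    ``mz``/``intensity`` are parallel arrays sorted strictly ascending by
    m/z (enforced on construction). ``precursor_charge`` 0 means unknown.
    ``retention_time`` is in minutes.
    """

    spectrum_id: str
    raw_file: str
    batch_id: str
    scan: int
    precursor_mz: float
    precursor_charge: int
    retention_time: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if mz.shape != inten.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(inten < 0):
            raise ValueError("negative peak intensity")
        if mz.size and np.any(mz <= 0):
            raise ValueError("non-positive peak m/z")
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        # collapse exact duplicate m/z values, summing intensity
        if mz.size > 1 and np.any(np.diff(mz) == 0):
            uniq, inverse = np.unique(mz, return_inverse=True)
            summed = np.zeros_like(uniq)
            np.add.at(summed, inverse, inten)
            mz, inten = uniq, summed
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    @property
    def peaks(self) -> list[Peak]:
        return [Peak(m, i) for m, i in zip(self.mz, self.intensity)]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


def spectrum_key(raw_file: str, scan: int) -> str:
    """Canonical spectrum identifier: ``<raw_file>:<scan>``."""
    return f"{raw_file}:{scan}"


@dataclass(frozen=True)
class PeptideIdent:
    """A peptide candidate: sequence, positioned modifications, charge.

    Modification positions are 1-based; position 0 denotes an N-terminal
    modification (e.g. protein N-terminal acetylation, name ``"ac"``).
    """

    sequence: str
    modifications: tuple[tuple[int, str], ...] = ()
    charge: int = 2
    proteins: tuple[str, ...] = ()
    is_decoy: bool = False
    is_entrapment: bool = False

    def __post_init__(self) -> None:
        if not self.sequence or not set(self.sequence) <= _VALID_AA:
            raise ValueError(f"invalid peptide sequence {self.sequence!r}")
        for pos, _ in self.modifications:
            if not 0 <= pos <= len(self.sequence):
                raise ValueError("modification position outside sequence")
        if self.is_decoy and self.is_entrapment:
            raise ValueError("peptide cannot be both decoy and entrapment")

    @property
    def modified_sequence(self) -> str:
        """MaxQuant-style string, e.g. ``_(ac)PEPT(ph)IDEK_``."""
        mods = dict(self.modifications)
        out = ["_"]
        if 0 in mods:
            out.append(f"({mods[0]})")
        for i, aa in enumerate(self.sequence, start=1):
            out.append(aa)
            if i in mods:
                out.append(f"({mods[i]})")
        out.append("_")
        return "".join(out)

    @property
    def ident_key(self) -> tuple[str, int]:
        """(modified sequence, charge) — the identity used for ambiguity."""
        return (self.modified_sequence, self.charge)


_MOD_RE = re.compile(r"\(([^()]*)\)")


def parse_modified_sequence(modseq: str) -> tuple[str, tuple[tuple[int, str], ...]]:
    """Parse a MaxQuant-style modified sequence into (sequence, mods)."""
    s = modseq.strip().strip("_")
    sequence: list[str] = []
    mods: list[tuple[int, str]] = []
    i = 0
    while i < len(s):
        if s[i] == "(":
            m = _MOD_RE.match(s, i)
            if m is None:
                raise ValueError(f"unbalanced parentheses in {modseq!r}")
            mods.append((len(sequence), m.group(1)))
            i = m.end()
        else:
            sequence.append(s[i])
            i += 1
    return "".join(sequence), tuple(mods)


@dataclass
class PSM:
    """A candidate peptide assignment to one spectrum."""

    spectrum_ref: str
    raw_file: str
    scan: int
    peptide: PeptideIdent
    search_score: float | None
    posterior_error_prob: float | None = None
    q_value: float | None = None
    origin: str = "search"  # "search" | "transfer"
    rescore: float | None = None
    features: dict[str, float] | None = None
    fold: int | None = None

    @property
    def is_decoy(self) -> bool:
        return self.peptide.is_decoy

    @property
    def is_entrapment(self) -> bool:
        return self.peptide.is_entrapment

    def copy(self, **changes) -> "PSM":
        return replace(self, **changes)


@dataclass
class PSMTable:
    """An ordered collection of PSMs plus free-text provenance.

    ``extras`` optionally carries pass-through columns from an input file,
    aligned row-for-row with ``rows``.
    """

    rows: list[PSM] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)
    extras: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def sorted(self) -> "PSMTable":
        """Canonical order: (raw_file, scan), ties by modified sequence."""
        idx = sorted(
            range(len(self.rows)),
            key=lambda i: (
                self.rows[i].raw_file,
                self.rows[i].scan,
                self.rows[i].peptide.modified_sequence,
                self.rows[i].peptide.charge,
            ),
        )
        extras = self.extras.iloc[idx].reset_index(drop=True) if self.extras is not None else None
        return PSMTable([self.rows[i] for i in idx], dict(self.provenance), extras)

    def to_dataframe(self) -> pd.DataFrame:
        recs = []
        for p in self.rows:
            recs.append(
                {
                    "Raw file": p.raw_file,
                    "Scan number": p.scan,
                    "Modified sequence": p.peptide.modified_sequence,
                    "Charge": p.peptide.charge,
                    "Score": np.nan if p.search_score is None else p.search_score,
                    "PEP": np.nan if p.posterior_error_prob is None else p.posterior_error_prob,
                    "Reverse": "+" if p.is_decoy else "",
                    "Proteins": ";".join(p.peptide.proteins),
                    "Origin": p.origin,
                    "q-value": np.nan if p.q_value is None else p.q_value,
                    "Rescore": np.nan if p.rescore is None else p.rescore,
                }
            )
        df = pd.DataFrame.from_records(recs, columns=list(_COLUMNS))
        if self.extras is not None and len(self.extras.columns):
            df = pd.concat([df, self.extras.reset_index(drop=True)], axis=1)
        return df


_COLUMNS = (
    "Raw file",
    "Scan number",
    "Modified sequence",
    "Charge",
    "Score",
    "PEP",
    "Reverse",
    "Proteins",
    "Origin",
    "q-value",
    "Rescore",
)
_MANDATORY = (
    "Raw file",
    "Scan number",
    "Modified sequence",
    "Charge",
    "Score",
    "PEP",
    "Reverse",
    "Proteins",
)


# ---------------------------------------------------------------------------
# MGF I/O
# ---------------------------------------------------------------------------

def _find_malformed_line(path) -> int | None:
    in_block = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if s == "BEGIN IONS":
                in_block = True
                continue
            if s == "END IONS":
                in_block = False
                continue
            if in_block and "=" not in s:
                parts = s.split()
                try:
                    [float(x) for x in parts[:2]]
                    if len(parts) < 2:
                        return lineno
                except ValueError:
                    return lineno
    return None


def read_mgf(path) -> list[Spectrum]:
    """Read an MGF file into a list of :class:`Spectrum`.

    Peaks are re-sorted ascending by m/z; RTINSECONDS is converted to
    minutes; a missing CHARGE is recorded as 0 (unknown).
    """
    spectra: list[Spectrum] = []
    try:
        with _mgf.MGF(str(path), convert_arrays=1) as reader:
            for entry in reader:
                params = entry["params"]
                title = str(params.get("title", ""))
                raw_file = str(params.get("rawfile", ""))
                batch_id = str(params.get("batchid", ""))
                scan = int(params.get("scans", 0))
                if not raw_file and ":" in title:
                    raw_file = title.rsplit(":", 1)[0]
                    if not scan:
                        try:
                            scan = int(title.rsplit(":", 1)[1])
                        except ValueError:
                            pass
                charge_list = params.get("charge")
                charge = int(charge_list[0]) if charge_list else 0
                pepmass = params.get("pepmass", (0.0,))
                rt_sec = float(params.get("rtinseconds", 0.0))
                spectra.append(
                    Spectrum(
                        spectrum_id=title or spectrum_key(raw_file, scan),
                        raw_file=raw_file,
                        batch_id=batch_id,
                        scan=scan,
                        precursor_mz=float(pepmass[0]),
                        precursor_charge=charge,
                        retention_time=rt_sec / 60.0,
                        mz=entry["m/z array"],
                        intensity=entry["intensity array"],
                    )
                )
    except Exception as exc:  # noqa: BLE001 - re-raise with location
        lineno = _find_malformed_line(path)
        where = f" at line {lineno}" if lineno is not None else ""
        raise MGFParseError(f"malformed MGF block in {path}{where}: {exc}") from exc
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path) -> None:
    """Write spectra to MGF. Inverse of :func:`read_mgf` up to float formatting."""
    entries = []
    for s in spectra:
        params = {
            "title": s.spectrum_id,
            "rawfile": s.raw_file,
            "batchid": s.batch_id,
            "scans": s.scan,
            "pepmass": s.precursor_mz,
            "rtinseconds": s.retention_time * 60.0,
        }
        if s.precursor_charge:
            params["charge"] = s.precursor_charge
        entries.append(
            {"m/z array": s.mz, "intensity array": s.intensity, "params": params}
        )
    with open(path, "w") as fh:
        _mgf.write(entries, fh, key_order=["title", "rawfile", "batchid", "scans", "pepmass", "rtinseconds", "charge"])


# ---------------------------------------------------------------------------
# PSM table I/O
# ---------------------------------------------------------------------------

def _peptide_from_row(modseq: str, charge: int, reverse: str, proteins_str: str) -> PeptideIdent:
    sequence, mods = parse_modified_sequence(modseq)
    proteins = tuple(p for p in str(proteins_str).split(";") if p) if proteins_str else ()
    is_decoy = str(reverse).strip() == "+"
    is_entrapment = (not is_decoy) and bool(proteins) and all(
        p.startswith(ENTRAPMENT_PREFIX) for p in proteins
    )
    return PeptideIdent(
        sequence=sequence,
        modifications=mods,
        charge=int(charge),
        proteins=proteins,
        is_decoy=is_decoy,
        is_entrapment=is_entrapment,
    )


def read_psm_table(path) -> PSMTable:
    """Read a tab-delimited, msms.txt-like PSM table.

    The ``Reverse`` column ("+" per MaxQuant convention) sets the decoy
    flag. Rows with unparseable Score/PEP are dropped; the count is
    recorded in ``provenance["n_rejected_rows"]``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"PSM table missing mandatory columns: {missing}")
    extra_cols = [c for c in df.columns if c not in _COLUMNS]
    rows: list[PSM] = []
    extra_rows: list[int] = []
    n_rejected = 0
    for i, rec in enumerate(df.itertuples(index=False)):
        rec = dict(zip(df.columns, rec))
        try:
            score = float(rec["Score"]) if rec["Score"] != "" else None
            pep = float(rec["PEP"]) if rec["PEP"] != "" else None
            scan = int(rec["Scan number"])
            peptide = _peptide_from_row(
                rec["Modified sequence"], int(rec["Charge"]), rec["Reverse"], rec["Proteins"]
            )
        except (ValueError, KeyError):
            n_rejected += 1
            continue
        qv = rec.get("q-value", "")
        rescore = rec.get("Rescore", "")
        rows.append(
            PSM(
                spectrum_ref=spectrum_key(rec["Raw file"], scan),
                raw_file=rec["Raw file"],
                scan=scan,
                peptide=peptide,
                search_score=score,
                posterior_error_prob=pep,
                q_value=float(qv) if qv not in ("", "nan") else None,
                rescore=float(rescore) if rescore not in ("", "nan") else None,
                origin=rec.get("Origin", "") or "search",
            )
        )
        extra_rows.append(i)
    extras = (
        df.iloc[extra_rows][extra_cols].reset_index(drop=True) if extra_cols else None
    )
    return PSMTable(rows, {"source": str(path), "n_rejected_rows": n_rejected}, extras)


def write_psm_table(table: PSMTable, path) -> None:
    """Write a PSM table in the tab-delimited dialect read by :func:`read_psm_table`."""
    df = table.to_dataframe()
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Predictability filter
# ---------------------------------------------------------------------------

def peptide_is_predictable(peptide: PeptideIdent) -> bool:
    """Whether Prosit-style predictors cover this peptide: length 7–30,
    charge ≤ 6, no selenocysteine/pyrrolysine, no N-terminal protein
    acetylation."""
    n = len(peptide.sequence)
    if not PREDICTABLE_MIN_LENGTH <= n <= PREDICTABLE_MAX_LENGTH:
        return False
    if peptide.charge > PREDICTABLE_MAX_CHARGE:
        return False
    if set(peptide.sequence) & _UNPREDICTABLE_RESIDUES:
        return False
    for pos, name in peptide.modifications:
        if pos == 0 and name == "ac":
            return False
    return True


def filter_predictable(table: PSMTable) -> PSMTable:
    """Retain only PSMs whose peptide a property predictor covers. Idempotent."""
    keep = [i for i, p in enumerate(table.rows) if peptide_is_predictable(p.peptide)]
    extras = table.extras.iloc[keep].reset_index(drop=True) if table.extras is not None else None
    prov = dict(table.provenance)
    prov["n_unpredictable_removed"] = prov.get("n_unpredictable_removed", 0) + (
        len(table.rows) - len(keep)
    )
    return PSMTable([table.rows[i] for i in keep], prov, extras)
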