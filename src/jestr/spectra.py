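"""MS/MS spectrum containers, MGF/MSP I/O, intensity normalization and binning.

A tandem mass spectrum is a list of (m/z, intensity) peaks plus precursor
metadata.  The spectral encoder consumes a fixed-length representation:
peaks are normalized so the most intense peak has intensity 999 (the NIST
library convention), discretized into 1 Da bins over [0, 1000), co-binned
intensities summed, and a log10/3 transform applied so that a handful of
dominant peaks or a long tail of minor ones cannot swamp the vector.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np

log = logging.getLogger(__name__)

N_BINS = 1000
#: normalization ceiling for the base peak (NIST spectral-library convention)
MAX_INTENSITY = 999.0

Transform = Literal["log1p_over3", "strict_eq2"]


@dataclass(frozen=True)
class Peak:
    """One fragment peak: mass-to-charge ratio (Da, charge assumed +-1) and
    nonnegative relative abundance."""

    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if not self.mz > 0:
            raise ValueError(f"peak m/z must be positive, got {self.mz}")
        if self.intensity < 0:
            raise ValueError(f"peak intensity must be >= 0, got {self.intensity}")


@dataclass
class Spectrum:
    """A peak list plus identifying metadata.

    One molecule may own several spectra ("views") measured under different
    instrument conditions; ``molecule_id`` is None for query spectra whose
    structure is unknown.  The adduct and precursor m/z are carried as
    metadata only — the model consumes peaks exclusively.
    """

    spectrum_id: str
    peaks: list[Peak]
    molecule_id: str | None = None
    adduct: str = ""
    precursor_mz: float | None = None
    instrument_meta: dict = field(default_factory=dict)

    @property
    def mz(self) -> np.ndarray:
        return np.array([p.mz for p in self.peaks], dtype=float)

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.intensity for p in self.peaks], dtype=float)


@dataclass
class BinnedSpectrum:
    """1000-dimensional binned-and-transformed spectrum vector."""

    values: np.ndarray
    source_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_BINS,):
            raise ValueError(
                f"binned spectrum must have length {N_BINS}, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("binned spectrum contains non-finite entries")


@dataclass
class ParseReport:
    n_records: int = 0
    n_kept: int = 0
    n_skipped_empty: int = 0
    n_peaks_dropped_nonpositive: int = 0


class DegenerateSpectrumError(ValueError):
    """Raised when a spectrum has no peak with positive intensity."""


def _clean_peaks(mzs, intens, report: ParseReport) -> list[Peak]:
    peaks = []
    for mz, inten in zip(mzs, intens):
        if inten <= 0 or mz <= 0:
            report.n_peaks_dropped_nonpositive += 1
            continue
        peaks.append(Peak(float(mz), float(inten)))
    return peaks


def read_spectra(
    path: str | Path, format: Literal["mgf", "msp"] | None = None
) -> tuple[list[Spectrum], ParseReport]:
    """Read spectra from an MGF or MSP file.

    Format is inferred from the suffix when not given.  Records with zero
    (usable) peaks are skipped with a warning and counted in the report.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()  # type: ignore[assignment]
    if format not in ("mgf", "msp"):
        raise ValueError(f"unsupported spectrum format: {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    report = ParseReport()
    spectra: list[Spectrum] = []
    records = _iter_mgf(path) if format == "mgf" else _iter_msp(path)
    for i, (sid, mol_id, adduct, prec, meta, mzs, intens) in enumerate(records):
        report.n_records += 1
        peaks = _clean_peaks(mzs, intens, report)
        if not peaks:
            warnings.warn(f"record {i} ({sid!r}) has no usable peaks; skipped")
            report.n_skipped_empty += 1
            continue
        spectra.append(
            Spectrum(
                spectrum_id=sid or f"spectrum_{i}",
                peaks=peaks,
                molecule_id=mol_id,
                adduct=adduct,
                precursor_mz=prec,
                instrument_meta=meta,
            )
        )
        report.n_kept += 1
    return spectra, report


def _iter_mgf(path: Path):
    from pyteomics import mgf

    with mgf.MGF(str(path)) as reader:
        for rec in reader:
            params = rec.get("params", {})
            title = str(params.get("title", ""))
            pepmass = params.get("pepmass")
            prec = float(pepmass[0]) if pepmass else None
            meta = {
                k: v
                for k, v in params.items()
                if k not in ("title", "pepmass", "adduct", "molecule_id")
            }
            yield (
                title,
                params.get("molecule_id"),
                str(params.get("adduct", "")),
                prec,
                meta,
                rec["m/z array"],
                rec["intensity array"],
            )


def _iter_msp(path: Path):
    # matchms harmonizes metadata keys and sorts peaks by m/z; binning is
    # permutation-invariant so the sort is immaterial downstream.
    from matchms.importing import load_from_msp

    for ms in load_from_msp(str(path), metadata_harmonization=False):
        meta = dict(ms.metadata)
        name = str(meta.pop("compound_name", meta.pop("name", "")))
        prec = meta.pop("precursor_mz", meta.pop("precursormz", None))
        yield (
            name,
            meta.pop("molecule_id", None),
            str(meta.pop("adduct", "")),
            float(prec) if prec is not None else None,
            meta,
            ms.peaks.mz,
            ms.peaks.intensities,
        )


def write_spectra(
    spectra: Iterable[Spectrum],
    path: str | Path,
    format: Literal["mgf", "msp"] | None = None,
) -> None:
    """Write spectra to MGF or MSP (canonical space-separated peak lines)."""
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()  # type: ignore[assignment]
    if format == "mgf":
        from pyteomics import mgf

        records = []
        for s in spectra:
            params = {"title": s.spectrum_id}
            if s.precursor_mz is not None:
                params["pepmass"] = s.precursor_mz
            if s.adduct:
                params["adduct"] = s.adduct
            if s.molecule_id is not None:
                params["molecule_id"] = s.molecule_id
            params.update(s.instrument_meta)
            records.append(
                {
                    "m/z array": s.mz,
                    "intensity array": s.intensities,
                    "params": params,
                }
            )
        mgf.write(records, str(path), write_charges=False)
    elif format == "msp":
        with open(path, "w") as fh:
            for s in spectra:
                fh.write(f"Name: {s.spectrum_id}\n")
                if s.precursor_mz is not None:
                    fh.write(f"PrecursorMZ: {s.precursor_mz}\n")
                if s.adduct:
                    fh.write(f"Adduct: {s.adduct}\n")
                if s.molecule_id is not None:
                    fh.write(f"Molecule_id: {s.molecule_id}\n")
                fh.write(f"Num Peaks: {len(s.peaks)}\n")
                for p in s.peaks:
                    fh.write(f"{p.mz} {p.intensity}\n")
                fh.write("\n")
    else:
        raise ValueError(f"unsupported spectrum format: {format!r}")


def normalize_intensities(s: Spectrum) -> Spectrum:
    """Rescale so the base peak has intensity exactly 999.

    Relative intensity ratios are preserved; zero-intensity peaks are
    removed.  Raises :class:`DegenerateSpectrumError` when no peak has
    positive intensity.
    """
    peaks = [p for p in s.peaks if p.intensity > 0]
    if not peaks:
        raise DegenerateSpectrumError(
            f"spectrum {s.spectrum_id!r} has no peak with positive intensity"
        )
    top = max(p.intensity for p in peaks)
    scale = MAX_INTENSITY / top
    return Spectrum(
        spectrum_id=s.spectrum_id,
        peaks=[Peak(p.mz, p.intensity * scale) for p in peaks],
        molecule_id=s.molecule_id,
        adduct=s.adduct,
        precursor_mz=s.precursor_mz,
        instrument_meta=s.instrument_meta,
    )


def bin_spectrum(s: Spectrum, transform: Transform = "log1p_over3") -> BinnedSpectrum:
    """Discretize a normalized spectrum into 1000 one-Da bins and transform.

    A peak with m/z in [n, n+1) contributes to bin n; peaks at or above
    1000 Da are dropped.  Intensities within a bin are summed, then the
    transform is applied elementwise:

    - ``log1p_over3`` (default): log10(1 + sum) / 3 — empty bins map to 0
      and a lone base peak (999) maps to exactly 1.0.
    - ``strict_eq2``: log10(sum) / 3 verbatim, with empty bins and sums <= 1
      clamped to 0.

    The input must already be normalized (base peak 999); this guards
    against the log being taken on an un-normalized scale.
    """
    intens = s.intensities
    if abs(intens.max() - MAX_INTENSITY) > 1e-6:
        raise ValueError(
            "bin_spectrum requires a normalized spectrum "
            f"(max intensity 999, got {intens.max():g}); "
            "call normalize_intensities first"
        )
    mz = s.mz
    keep = mz < N_BINS  # half-open bins: a peak at exactly 1000.0 Da is dropped
    idx = np.floor(mz[keep]).astype(int)
    sums = np.zeros(N_BINS, dtype=float)
    np.add.at(sums, idx, intens[keep])

    if transform == "log1p_over3":
        values = np.log10(1.0 + sums) / 3.0
    elif transform == "strict_eq2":
        values = np.zeros(N_BINS, dtype=float)
        mask = sums > 1.0
        values[mask] = np.log10(sums[mask]) / 3.0
    else:
        raise ValueError(f"unknown transform: {transform!r}")
    return BinnedSpectrum(values=values, source_id=s.spectrum_id)


def bin_all(
    spectra: Iterable[Spectrum], transform: Transform = "log1p_over3"
) -> tuple[np.ndarray, list[str]]:
    """Normalize and bin a collection; returns (n, 1000) matrix and ids."""
    rows, ids = [], []
    for s in spectra:
        b = bin_spectrum(normalize_intensities(s), transform=transform)
        rows.append(b.values)
        ids.append(s.spectrum_id)
    return np.array(rows).reshape(len(ids), N_BINS), ids
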