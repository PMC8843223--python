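"""Spectral data containers and I/O.

Holds the in-memory model of a dual-detector diffuse-reflectance measurement
session: per-detector wavelength-indexed traces (raw counts, absorbance, or
preprocessed values), one record per ligament sample with five measurement
sites plus dark and white reflectance standards, and a per-sample reference
table of biochemical/structural properties.

Absorbance is computed against the standards as

    A(lambda) = -log10( (S - D) / (R - D) )

with S the sample counts, D the dark (non-reflective) standard and R the
white (diffuse reflectance) standard.  Wavelengths where the ratio is not
positive carry an explicit invalid mask rather than being dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "LIGAMENT_TYPES",
    "DETECTORS",
    "Spectrum",
    "SampleRecord",
    "ReferenceTable",
    "compute_absorbance",
    "average_sites",
    "write_dataset",
    "read_dataset",
]

#: The five tissue types sampled from each stifle joint.
LIGAMENT_TYPES = ("ACL", "PCL", "LCL", "MCL", "PT")

#: Detector labels: d1 = silicon CCD (350-1100 nm), d2 = InGaAs (1000-2400 nm).
DETECTORS = ("d1", "d2")

N_SITES = 5

_KINDS = ("counts", "absorbance", "preprocessed")


@dataclass
class Spectrum:
    """One detector's wavelength-indexed trace.

    Parameters
    ----------
    detector : {"d1", "d2"}
    wavelengths : ndarray, nm, strictly increasing
    values : ndarray, same length as ``wavelengths``
    kind : {"counts", "absorbance", "preprocessed"}
    mask : boolean ndarray, True where the point is invalid.  Defaults to
        all-valid.
    """

    detector: str
    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = "counts"
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.detector not in DETECTORS:
            raise ValueError(f"unknown detector {self.detector!r}")
        if self.kind not in _KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape:
            raise ValueError(
                f"wavelengths ({self.wavelengths.shape}) and values "
                f"({self.values.shape}) differ in length"
            )
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.mask is None:
            self.mask = np.zeros(self.wavelengths.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.wavelengths.shape:
                raise ValueError("mask length mismatch")
        if self.kind == "counts":
            valid = self.values[~self.mask]
            if valid.size and np.any(valid < 0):
                raise ValueError("raw counts must be non-negative")

    def __len__(self) -> int:
        return self.wavelengths.size

    @property
    def n_valid(self) -> int:
        return int(np.count_nonzero(~self.mask))

    def copy(self) -> "Spectrum":
        return replace(
            self,
            wavelengths=self.wavelengths.copy(),
            values=self.values.copy(),
            mask=self.mask.copy(),
        )


def _same_grid(a: Spectrum, b: Spectrum) -> bool:
    return (
        a.detector == b.detector
        and len(a) == len(b)
        and np.array_equal(a.wavelengths, b.wavelengths)
    )


@dataclass
class SampleRecord:
    """One ligament sample: five-site dual-detector spectra plus standards."""

    joint_id: str
    ligament_type: str
    site_spectra: dict  # detector -> list of 5 Spectrum
    dark: dict  # detector -> Spectrum
    white: dict  # detector -> Spectrum

    def __post_init__(self) -> None:
        if self.ligament_type not in LIGAMENT_TYPES:
            raise ValueError(
                f"unknown ligament_type {self.ligament_type!r} "
                f"(expected one of {LIGAMENT_TYPES})"
            )
        for det, sites in self.site_spectra.items():
            if len(sites) != N_SITES:
                raise ValueError(
                    f"sample ({self.joint_id}, {self.ligament_type}) detector "
                    f"{det}: expected {N_SITES} sites, got {len(sites)}"
                )
            ref = sites[0]
            for s in sites[1:]:
                if not _same_grid(ref, s):
                    raise ValueError(
                        f"sample ({self.joint_id}, {self.ligament_type}): "
                        f"site spectra of detector {det} differ in grid"
                    )
            for name in ("dark", "white"):
                std = getattr(self, name).get(det)
                if std is None:
                    raise ValueError(
                        f"sample ({self.joint_id}, {self.ligament_type}): "
                        f"missing {name} standard for detector {det}"
                    )
                if not _same_grid(ref, std):
                    raise ValueError(
                        f"sample ({self.joint_id}, {self.ligament_type}): "
                        f"{name} standard grid mismatch on {det}"
                    )

    @property
    def key(self) -> tuple:
        return (self.joint_id, self.ligament_type)


@dataclass
class ReferenceTable:
    """Per-sample reference properties, keyed by (joint_id, ligament_type).

    ``data`` is a DataFrame indexed by the two-level key; ``units`` maps each
    property column to its unit string as used in the wet-lab assays
    (%, ug/mg, deg, um).
    """

    data: pd.DataFrame
    units: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample keys: {dupes}")
        missing_units = [c for c in self.data.columns if c not in self.units]
        if missing_units:
            raise ValueError(f"missing units metadata for columns: {missing_units}")

    @property
    def properties(self) -> list:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    def row(self, joint_id: str, ligament_type: str) -> pd.Series:
        return self.data.loc[(joint_id, ligament_type)]


# ---------------------------------------------------------------------------
# Absorbance and site averaging
# ---------------------------------------------------------------------------


def compute_absorbance(sample: Spectrum, dark: Spectrum, white: Spectrum) -> Spectrum:
    """Convert raw counts to absorbance against dark/white standards.

    A(lambda) = -log10((S - D) / (R - D)).  Points where the transmittance
    ratio is <= 0 (e.g. S <= D) are masked invalid, not dropped.  A white
    standard equal to the dark standard anywhere is an error: the detector has
    zero dynamic range there and no absorbance is defined.
    """
    for name, s in (("sample", sample), ("dark", dark), ("white", white)):
        if s.kind != "counts":
            raise ValueError(f"{name} spectrum must be raw counts, got {s.kind!r}")
    if not (_same_grid(sample, dark) and _same_grid(sample, white)):
        raise ValueError("sample, dark and white spectra must share one wavelength grid")

    denom = white.values - dark.values
    zero_range = denom == 0
    if np.any(zero_range):
        lam = sample.wavelengths[zero_range][0]
        raise ValueError(
            f"white and dark standards coincide at {lam:.6g} nm: zero dynamic range"
        )
    ratio = (sample.values - dark.values) / denom
    invalid = sample.mask | dark.mask | white.mask | (ratio <= 0)
    values = np.full(ratio.shape, np.nan)
    ok = ~invalid
    values[ok] = -np.log10(ratio[ok])
    return Spectrum(
        detector=sample.detector,
        wavelengths=sample.wavelengths.copy(),
        values=values,
        kind="absorbance",
        mask=invalid,
    )


def average_sites(spectra: list) -> Spectrum:
    """Pointwise mean of repeated-site absorbance spectra.

    Invalid points are excluded per wavelength; a point invalid at every site
    stays invalid in the mean.  The measurement sites are averaged because the
    tissue properties are assumed uniform along the sampled midsection.
    """
    if not spectra:
        raise ValueError("need at least one spectrum to average")
    ref = spectra[0]
    for s in spectra:
        if s.kind != "absorbance":
            raise ValueError("average_sites expects absorbance spectra")
        if not _same_grid(ref, s):
            raise ValueError("cannot average spectra from different detectors/grids")
    values = np.stack([s.values for s in spectra])
    masks = np.stack([s.mask for s in spectra])
    n_valid = (~masks).sum(axis=0)
    summed = np.where(masks, 0.0, np.nan_to_num(values, nan=0.0)).sum(axis=0)
    out_mask = n_valid == 0
    out = np.full(ref.wavelengths.shape, np.nan)
    ok = ~out_mask
    out[ok] = summed[ok] / n_valid[ok]
    return Spectrum(
        detector=ref.detector,
        wavelengths=ref.wavelengths.copy(),
        values=out,
        kind="absorbance",
        mask=out_mask,
    )


# ---------------------------------------------------------------------------
# On-disk format: one long CSV for spectra, one wide CSV for references
# ---------------------------------------------------------------------------

_SPECTRA_COLS = ["joint_id", "ligament_type", "detector", "site", "wavelength_nm", "value"]
_FLOAT_FMT = "%.12g"


def write_dataset(records: list, refs: ReferenceTable, out_dir) -> tuple:
    """Write ``spectra.csv`` + ``references.csv`` under ``out_dir``.

    spectra.csv is one long table (joint_id, ligament_type, detector, site,
    wavelength_nm, value) where site is ``site1``..``site5``, ``dark`` or
    ``white``.  references.csv is wide, one row per sample, with a
    ``# units:`` comment line.  Floats keep 12 significant digits so a
    write/read round trip is identity to that precision.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chunks = []
    for rec in records:
        for det in sorted(rec.site_spectra):
            labeled = [(f"site{i + 1}", s) for i, s in enumerate(rec.site_spectra[det])]
            labeled += [("dark", rec.dark[det]), ("white", rec.white[det])]
            for label, spec in labeled:
                chunks.append(
                    pd.DataFrame(
                        {
                            "joint_id": rec.joint_id,
                            "ligament_type": rec.ligament_type,
                            "detector": det,
                            "site": label,
                            "wavelength_nm": spec.wavelengths,
                            "value": spec.values,
                        }
                    )
                )
    spectra_path = out_dir / "spectra.csv"
    pd.concat(chunks, ignore_index=True).to_csv(
        spectra_path, index=False, float_format=_FLOAT_FMT
    )

    refs_path = out_dir / "references.csv"
    units_line = "# units: " + ", ".join(
        f"{c}={refs.units[c]}" for c in refs.data.columns
    )
    with open(refs_path, "w", encoding="utf-8") as fh:
        fh.write(units_line + "\n")
        refs.data.reset_index().to_csv(fh, index=False, float_format=_FLOAT_FMT)
    return spectra_path, refs_path


def read_dataset(path) -> tuple:
    """Read a dataset directory written by :func:`write_dataset`.

    Returns ``(records, refs)``.  Raises on structural defects: missing
    standards, a sample with fewer than five sites, non-monotone wavelengths,
    unknown ligament types, or empty reference columns.
    """
    from pathlib import Path

    path = Path(path)
    long = pd.read_csv(path / "spectra.csv")
    missing_cols = [c for c in _SPECTRA_COLS if c not in long.columns]
    if missing_cols:
        raise ValueError(f"spectra.csv missing columns: {missing_cols}")

    records = []
    for (joint_id, lig), group in long.groupby(
        ["joint_id", "ligament_type"], sort=False
    ):
        site_spectra: dict = {}
        dark: dict = {}
        white: dict = {}
        for det, dgroup in group.groupby("detector", sort=True):
            sites = {}
            for label, sgroup in dgroup.groupby("site", sort=True):
                wl = sgroup["wavelength_nm"].to_numpy()
                if wl.size >= 2 and not np.all(np.diff(wl) > 0):
                    raise ValueError(
                        f"non-monotone wavelengths for sample ({joint_id}, {lig}) "
                        f"detector {det} trace {label}"
                    )
                vals = sgroup["value"].to_numpy()
                sites[label] = Spectrum(
                    detector=det,
                    wavelengths=wl,
                    values=vals,
                    kind="counts",
                    mask=np.isnan(vals),
                )
            site_labels = sorted(k for k in sites if k.startswith("site"))
            if len(site_labels) != N_SITES:
                raise ValueError(
                    f"sample ({joint_id}, {lig}) detector {det}: expected "
                    f"{N_SITES} sites, found {len(site_labels)}"
                )
            for std in ("dark", "white"):
                if std not in sites:
                    raise ValueError(
                        f"sample ({joint_id}, {lig}): missing {std} standard "
                        f"for detector {det}"
                    )
            site_spectra[det] = [sites[k] for k in site_labels]
            dark[det] = sites["dark"]
            white[det] = sites["white"]
        records.append(
            SampleRecord(
                joint_id=str(joint_id),
                ligament_type=str(lig),
                site_spectra=site_spectra,
                dark=dark,
                white=white,
            )
        )

    refs = read_reference_table(path / "references.csv")
    return records, refs


def read_reference_table(path) -> ReferenceTable:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        units: dict = {}
        if first.startswith("# units:"):
            for item in first[len("# units:"):].strip().split(","):
                if "=" in item:
                    k, v = item.split("=", 1)
                    units[k.strip()] = v.strip()
            data = pd.read_csv(fh)
        else:
            fh.seek(0)
            data = pd.read_csv(fh)
    data = data.set_index(["joint_id", "ligament_type"])
    empty = [c for c in data.columns if data[c].isna().any()]
    if empty:
        rows = data.index[data[empty].isna().any(axis=1)].tolist()
        raise ValueError(f"empty reference values in columns {empty} for rows {rows}")
    for lig in data.index.get_level_values("ligament_type"):
        if lig not in LIGAMENT_TYPES:
            raise ValueError(f"unknown ligament_type {lig!r}")
    if not units:
        units = {c: "" for c in data.columns}
    return ReferenceTable(data=data, units=units)
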