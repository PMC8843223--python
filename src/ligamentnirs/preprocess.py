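"""Detector-specific spectral preprocessing and the 96-option search grid.

The fixed stage order is: absorbance -> site average -> Savitzky-Golay
smoothing/derivative -> optional SNV scatter correction -> wavelength crop ->
resampling to a shared step -> concatenation of the two detectors into one
feature vector.  SG windows are given in nm and converted to an odd number of
points using each detector's median sampling interval, so "18 nm" is 49
points on the dense silicon detector and "58 nm" is 11 points on the coarse
InGaAs detector.  Cropping is applied after filtering so that the filter's
edge artefacts (half a window at each end, carried as an invalid mask) fall
outside the retained band.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .io import SampleRecord, Spectrum, average_sites, compute_absorbance

__all__ = [
    "DetectorConfig",
    "PreprocessConfig",
    "FeatureMatrix",
    "savitzky_golay",
    "snv",
    "crop",
    "resample",
    "concatenate",
    "enumerate_preprocess_grid",
    "reduced_grid",
    "winning_config",
    "apply_config",
    "config_to_dict",
    "config_from_dict",
    "load_config",
]

#: SG filter windows (nm) per detector, paired by index across detectors.
SG_WINDOWS = {"d1": (17.7, 40.5, 63.3, 86.1), "d2": (57.7, 104.7, 151.7, 198.7)}

#: Crop options (nm) per detector, paired by index; None = full valid range.
#: The d2 option printed as starting at 900 nm is clipped to the detector's
#: 1000 nm lower limit.
CROP_OPTIONS = {
    "d1": ((370.0, 980.0), (675.0, 960.0), (430.0, 680.0), None),
    "d2": ((1000.0, 1900.0), (1000.0, 1380.0), (1550.0, 1870.0), None),
}

SG_POLYORDER = 3
DEFAULT_RESAMPLE_STEP = 2.5  # nm


@dataclass(frozen=True)
class DetectorConfig:
    sg_window_nm: float
    deriv: int = 0
    snv: bool = False
    crop: tuple | None = None  # (lo, hi) nm, None = full valid range
    sg_polyorder: int = SG_POLYORDER

    def __post_init__(self) -> None:
        if self.sg_window_nm <= 0:
            raise ValueError("sg_window_nm must be positive")
        if not 0 <= self.deriv <= self.sg_polyorder:
            raise ValueError("deriv must be within 0..polyorder")
        if self.crop is not None and self.crop[0] >= self.crop[1]:
            raise ValueError("crop lo must be below hi")


@dataclass(frozen=True)
class PreprocessConfig:
    """One point of the preprocessing grid: per-detector settings + shared step."""

    d1: DetectorConfig
    d2: DetectorConfig
    resample_step: float = DEFAULT_RESAMPLE_STEP

    def __post_init__(self) -> None:
        if self.resample_step <= 0:
            raise ValueError("resample_step must be positive")

    def detector(self, det: str) -> DetectorConfig:
        return getattr(self, det)

    def label(self) -> str:
        def one(det: str) -> str:
            c = self.detector(det)
            cr = "full" if c.crop is None else f"{c.crop[0]:g}-{c.crop[1]:g}"
            return f"{det}[w={c.sg_window_nm:g}nm d{c.deriv} snv={int(c.snv)} crop={cr}]"

        return f"{one('d1')} {one('d2')} step={self.resample_step:g}nm"


@dataclass
class FeatureMatrix:
    """Preprocessed model input: samples x concatenated detector features."""

    X: np.ndarray
    feature_wavelengths: np.ndarray
    feature_detectors: np.ndarray  # 'd1'/'d2' per column
    sample_keys: list

    def __post_init__(self) -> None:
        if self.X.shape[1] != self.feature_wavelengths.size:
            raise ValueError("column count must match feature wavelengths")
        if np.isnan(self.X).any():
            raise ValueError("FeatureMatrix must not contain invalid entries")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def select(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            X=self.X[:, mask],
            feature_wavelengths=self.feature_wavelengths[mask],
            feature_detectors=self.feature_detectors[mask],
            sample_keys=list(self.sample_keys),
        )


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def _median_step(s: Spectrum) -> float:
    return float(np.median(np.diff(s.wavelengths)))


def window_points(s: Spectrum, window_nm: float, polyorder: int = SG_POLYORDER) -> int:
    """nm -> odd number of sample points, using the median grid interval."""
    step = _median_step(s)
    pts = int(round(window_nm / step))
    if pts % 2 == 0:
        pts += 1
    min_pts = polyorder + 2
    if pts < min_pts:
        raise ValueError(
            f"SG window {window_nm:g} nm spans {pts} points on detector "
            f"{s.detector}; needs >= {min_pts} points "
            f"(>= {min_pts * step:.3g} nm here)"
        )
    return pts


def savitzky_golay(
    s: Spectrum, window_nm: float, polyorder: int = SG_POLYORDER, deriv: int = 0
) -> Spectrum:
    """SG smoothing / derivative with window given in nm.

    Derivatives are scaled to per-nm units.  Half a window at each edge is
    masked invalid, as are points whose window overlaps an already-invalid
    input point.
    """
    pts = window_points(s, window_nm, polyorder)
    step = _median_step(s)
    vals = np.where(s.mask, np.interp(s.wavelengths, s.wavelengths[~s.mask], s.values[~s.mask]), s.values) if s.mask.any() else s.values
    out = savgol_filter(vals, pts, polyorder, deriv=deriv, delta=step)
    half = pts // 2
    mask = s.mask.copy()
    if s.mask.any():
        # dilate the invalid mask by the half window
        idx = np.flatnonzero(s.mask)
        for i in idx:
            mask[max(0, i - half): i + half + 1] = True
    mask[:half] = True
    if half > 0:
        mask[-half:] = True
    out = out.astype(float)
    out[mask] = np.nan
    return Spectrum(
        detector=s.detector,
        wavelengths=s.wavelengths.copy(),
        values=out,
        kind="preprocessed",
        mask=mask,
    )


def snv(s: Spectrum) -> Spectrum:
    """Standard normal variate: per-spectrum z-scoring over valid points."""
    valid = s.values[~s.mask]
    if valid.size < 2:
        raise ValueError("SNV needs at least 2 valid points")
    mu = valid.mean()
    sd = valid.std(ddof=1)
    if sd == 0:
        raise ValueError("SNV undefined for a constant spectrum")
    out = (s.values - mu) / sd
    out = np.where(s.mask, np.nan, out)
    return replace(s, values=out, kind="preprocessed", mask=s.mask.copy())


def crop(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Keep wavelengths in the closed interval [lo, hi]."""
    keep = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    if not keep.any():
        raise ValueError(
            f"crop [{lo:g}, {hi:g}] nm leaves no points on detector {s.detector}"
        )
    return Spectrum(
        detector=s.detector,
        wavelengths=s.wavelengths[keep],
        values=s.values[keep],
        kind=s.kind,
        mask=s.mask[keep],
    )


def resample(s: Spectrum, step: float) -> Spectrum:
    """Linear interpolation onto a uniform grid starting at the first valid λ.

    An output point whose bracketing valid inputs are more than 2*step apart
    (an interpolation across a masked gap) is masked.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    valid_wl = s.wavelengths[~s.mask]
    if valid_wl.size < 2:
        raise ValueError("resample needs at least 2 valid points")
    start, stop = valid_wl[0], valid_wl[-1]
    n = int(np.floor((stop - start) / step)) + 1
    grid = start + step * np.arange(n)
    vals = np.interp(grid, valid_wl, s.values[~s.mask])
    # mask output points interpolated across an invalid-masked gap wider
    # than 2*step (native spacing between valid neighbours is fine)
    mask = np.zeros(grid.shape, dtype=bool)
    masked_wl = s.wavelengths[s.mask]
    gaps = np.diff(valid_wl)
    for i in np.flatnonzero(gaps > 2 * step):
        lo_v, hi_v = valid_wl[i], valid_wl[i + 1]
        if np.any((masked_wl > lo_v) & (masked_wl < hi_v)):
            mask |= (grid > lo_v) & (grid < hi_v)
    vals = np.where(mask, np.nan, vals)
    return Spectrum(
        detector=s.detector, wavelengths=grid, values=vals, kind=s.kind, mask=mask
    )


def concatenate(d1: Spectrum, d2: Spectrum) -> tuple:
    """Append d2 features after d1; returns (values, wavelengths, detectors).

    Wavelengths are NOT deduplicated across detectors: the detectors overlap
    around 1000-1100 nm and each keeps its own labelled features.
    """
    values = np.concatenate([d1.values, d2.values])
    wavelengths = np.concatenate([d1.wavelengths, d2.wavelengths])
    detectors = np.array(["d1"] * len(d1) + ["d2"] * len(d2))
    return values, wavelengths, detectors


# ---------------------------------------------------------------------------
# Grid enumeration
# ---------------------------------------------------------------------------


def _grid(window_idx, derivs, snvs, crop_idx, step) -> list:
    configs = []
    for wi, deriv, use_snv, ci in itertools.product(window_idx, derivs, snvs, crop_idx):
        configs.append(
            PreprocessConfig(
                d1=DetectorConfig(
                    sg_window_nm=SG_WINDOWS["d1"][wi],
                    deriv=deriv,
                    snv=use_snv,
                    crop=CROP_OPTIONS["d1"][ci],
                ),
                d2=DetectorConfig(
                    sg_window_nm=SG_WINDOWS["d2"][wi],
                    deriv=deriv,
                    snv=use_snv,
                    crop=CROP_OPTIONS["d2"][ci],
                ),
                resample_step=step,
            )
        )
    return configs


def enumerate_preprocess_grid(resample_step: float = DEFAULT_RESAMPLE_STEP) -> list:
    """The canonical 96-option preprocessing grid.

    4 SG windows x 3 derivative orders x 2 SNV settings x 4 crop options, with
    windows and crops paired by index across the two detectors (the only
    construction consistent with 96 total options given four window values
    and three printed crop ranges plus the full range per detector).
    Second-derivative configurations are enumerated first, so config 0 is the
    pipeline found optimal for water/hydroxyproline: 18 nm (d1) / 58 nm (d2)
    windows, 2nd derivative, no SNV, crops 370-980 / 1000-1900 nm.
    """
    return _grid(range(4), (2, 1, 0), (False, True), range(4), resample_step)


def reduced_grid(resample_step: float = 6.5) -> list:
    """A 12-option sub-grid for quick searches and tests.

    2 windows x 3 derivatives x 2 crops (no SNV), still containing the
    winning configuration, with a coarser 6.5 nm resample step giving a
    concatenated feature count (~230 for the widest crops) at the scale of
    the full study's reported wavelength counts.
    """
    return _grid((0, 2), (2, 1, 0), (False,), (0, 3), resample_step)


def winning_config(resample_step: float = DEFAULT_RESAMPLE_STEP) -> PreprocessConfig:
    """The preprocessing pipeline reported optimal for water / hydroxyproline."""
    return enumerate_preprocess_grid(resample_step)[0]


# ---------------------------------------------------------------------------
# Config (de)serialization — YAML/JSON files mirroring PreprocessConfig
# ---------------------------------------------------------------------------


def config_to_dict(cfg: PreprocessConfig) -> dict:
    out = {"resample_step": cfg.resample_step}
    for det in ("d1", "d2"):
        c = cfg.detector(det)
        out[det] = {
            "sg_window_nm": c.sg_window_nm,
            "deriv": c.deriv,
            "snv": c.snv,
            "crop": None if c.crop is None else list(c.crop),
        }
    return out


def config_from_dict(d: dict) -> PreprocessConfig:
    def det(name: str) -> DetectorConfig:
        c = d[name]
        crop = c.get("crop")
        return DetectorConfig(
            sg_window_nm=float(c["sg_window_nm"]),
            deriv=int(c.get("deriv", 0)),
            snv=bool(c.get("snv", False)),
            crop=None if crop is None else (float(crop[0]), float(crop[1])),
        )

    return PreprocessConfig(
        d1=det("d1"),
        d2=det("d2"),
        resample_step=float(d.get("resample_step", DEFAULT_RESAMPLE_STEP)),
    )


def load_config(path) -> PreprocessConfig:
    """Read a PreprocessConfig from a YAML (or JSON) file."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Full per-record pipeline
# ---------------------------------------------------------------------------


def preprocess_record(record: SampleRecord, cfg: PreprocessConfig) -> tuple:
    """absorbance -> site average -> SG -> (SNV) -> crop -> resample, per detector."""
    per_det = {}
    for det in ("d1", "d2"):
        dcfg = cfg.detector(det)
        absorb = [
            compute_absorbance(s, record.dark[det], record.white[det])
            for s in record.site_spectra[det]
        ]
        s = average_sites(absorb)
        s = savitzky_golay(s, dcfg.sg_window_nm, dcfg.sg_polyorder, dcfg.deriv)
        if dcfg.snv:
            s = snv(s)
        if dcfg.crop is not None:
            s = crop(s, *dcfg.crop)
        s = resample(s, cfg.resample_step)
        per_det[det] = s
    return concatenate(per_det["d1"], per_det["d2"])


def apply_config(records: list, cfg: PreprocessConfig) -> FeatureMatrix:
    """Preprocess every record under one config into a feature matrix.

    Row order follows the input records.  Any feature column that is invalid
    for every sample is an error: such a wavelength cannot enter a model.
    """
    if not records:
        raise ValueError("records must be non-empty")
    rows = []
    wavelengths = detectors = None
    for rec in records:
        vals, wl, det = preprocess_record(rec, cfg)
        if wavelengths is None:
            wavelengths, detectors = wl, det
        elif not np.array_equal(wl, wavelengths):
            raise ValueError("records are not grid-consistent under this config")
        rows.append(vals)
    X = np.vstack(rows)
    dead = np.isnan(X).all(axis=0)
    if dead.any():
        bad = wavelengths[dead]
        raise ValueError(
            f"feature wavelengths invalid in every sample: {bad[:5].tolist()}..."
        )
    if np.isnan(X).any():
        # a feature valid in some samples but not others cannot enter PLSR
        bad = wavelengths[np.isnan(X).any(axis=0)]
        raise ValueError(
            f"feature wavelengths invalid in some samples: {bad[:5].tolist()}..."
        )
    return FeatureMatrix(
        X=X,
        feature_wavelengths=wavelengths,
        feature_detectors=detectors,
        sample_keys=[rec.key for rec in records],
    )
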