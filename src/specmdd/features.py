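"""Scalp regions and assembly of the subjects-by-features table.

Electrodes (10-20 names) are grouped into five conventional scalp regions —
frontal (23 electrodes), central (14), temporal (4), parietal (16) and
occipital (3) — and per-electrode spectral features are averaged within each
region.  The feature table has one row per subject and one column per
(space, condition, region[, band]) combination, plus the group label and
clinical scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_REGION_MAP: dict[str, tuple[str, ...]] = {
    "frontal": ("FPZ", "FP1", "FP2", "AF3", "AF4", "FZ", "F1", "F2", "F3",
                "F4", "F5", "F6", "F7", "F8", "FCZ", "FC1", "FC2", "FC3",
                "FC4", "FC5", "FC6", "FT7", "FT8"),
    "central": ("CZ", "C1", "C2", "C3", "C4", "C5", "C6", "CPZ", "CP1",
                "CP2", "CP3", "CP4", "CP5", "CP6"),
    "temporal": ("T7", "T8", "TP7", "TP8"),
    "parietal": ("PZ", "P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8",
                 "POZ", "PO3", "PO4", "PO5", "PO6", "PO7", "PO8"),
    "occipital": ("OZ", "O1", "O2"),
}

REGIONS = tuple(DEFAULT_REGION_MAP)

CONDITIONS = ("psd", "periodic", "aperiodic")
SPACES = ("electrode", "source")
ANALYSIS_BANDS = ("theta", "alpha")

SCORE_COLUMNS = ("bdi", "bdi_anh", "bdi_mel")


def normalize_label(label: str) -> str:
    """Uppercase-normalize a 10-20 electrode label."""
    return label.strip().upper()


def all_region_channels(region_map: dict[str, tuple[str, ...]] | None = None) -> list[str]:
    """Flat list of every electrode appearing in the region map."""
    rm = region_map or DEFAULT_REGION_MAP
    return [ch for chans in rm.values() for ch in chans]


def region_of(label: str, region_map: dict[str, tuple[str, ...]] | None = None) -> str | None:
    rm = region_map or DEFAULT_REGION_MAP
    lab = normalize_label(label)
    for region, chans in rm.items():
        if lab in chans:
            return region
    return None


def region_average(per_channel_values: dict[str, float],
                   region_map: dict[str, tuple[str, ...]],
                   region: str) -> float:
    """Arithmetic mean of a per-electrode value over one region's electrodes.

    Electrodes listed for the region but absent from ``per_channel_values``
    (or carrying NaN) are skipped with a warning; all of them missing is an
    error.
    """
    if region not in region_map:
        raise KeyError(f"unknown region {region!r}")
    values = {normalize_label(k): v for k, v in per_channel_values.items()}
    present = [values[ch] for ch in region_map[region]
               if ch in values and np.isfinite(values[ch])]
    n_missing = len(region_map[region]) - len(present)
    if not present:
        raise ValueError(f"no channels available for region {region!r}")
    if n_missing:
        log.warning("region %s: %d of %d channels missing; averaging the rest",
                    region, n_missing, len(region_map[region]))
    return float(np.mean(present))


def feature_key(space: str, condition: str, region: str,
                band: str | None = None) -> str:
    """Canonical column name ``<space>_<condition>_<region>[_<band>]``."""
    parts = [space, condition, region]
    if band is not None:
        parts.append(band)
    return "_".join(parts)


def design_columns(spaces=SPACES, regions=REGIONS, bands=ANALYSIS_BANDS) -> list[str]:
    """The designed feature columns, in deterministic (condition, space,
    region, band) order: per space, (PSD, periodic) x regions x bands plus
    aperiodic x regions — 25 columns per space."""
    cols = []
    for condition in ("psd", "periodic"):
        for space in spaces:
            for region in regions:
                for band in bands:
                    cols.append(feature_key(space, condition, region, band))
    for space in spaces:
        for region in regions:
            cols.append(feature_key(space, "aperiodic", region))
    return cols


def build_feature_table(cohort,
                        models: dict[str, dict[str, "object"]],
                        spectra: dict[str, dict[str, "object"]],
                        region_map: dict[str, tuple[str, ...]] | None = None,
                        bands=None,
                        spaces=SPACES,
                        periodic_statistic: str = "mean_power") -> pd.DataFrame:
    """Assemble the subjects-by-features table.

    Parameters
    ----------
    cohort : list of SubjectRecord
    models, spectra : dict subject_id -> dict channel -> SpectralModel / PowerSpectrum
        Per-electrode fit results (electrode space).
    region_map : region -> electrode labels; defaults to the five-region map.
    bands : BandDefinitions used as analysis bands (default theta and alpha).
    spaces : which spaces to include; source-space features are taken from
        each subject's ``source_features`` mapping when present, else NaN.

    Unknown electrode labels are ignored with a warning; missing features are
    NaN and handled pairwise downstream.
    """
    from .specparam import band_features, standard_bands

    rm = {k: tuple(normalize_label(c) for c in v)
          for k, v in (region_map or DEFAULT_REGION_MAP).items()}
    if bands is None:
        bands = [b for b in standard_bands() if b.name in ANALYSIS_BANDS]
    band_names = [b.name for b in bands]

    rows = []
    for subj in cohort:
        row: dict[str, object] = {"subject_id": subj.subject_id,
                                  "group": subj.group}
        for c in SCORE_COLUMNS:
            row[c] = subj.scores.get(c, np.nan) if subj.scores else np.nan

        if "electrode" in spaces:
            sub_models = models.get(subj.subject_id, {})
            sub_spectra = spectra.get(subj.subject_id, {})
            per_band_periodic = {b.name: {} for b in bands}
            per_band_psd = {b.name: {} for b in bands}
            per_chan_exponent = {}
            for ch, model in sub_models.items():
                lab = normalize_label(ch)
                if region_of(lab, rm) is None:
                    log.warning("unknown electrode label %r ignored", ch)
                    continue
                ps = sub_spectra[ch]
                for b in bands:
                    per_, psd_, _, expo = band_features(
                        model, ps, b, periodic_statistic=periodic_statistic)
                    per_band_periodic[b.name][lab] = per_
                    per_band_psd[b.name][lab] = psd_
                per_chan_exponent[lab] = model.aperiodic.exponent
            for region in rm:
                for bname in band_names:
                    for cond, vals in (("periodic", per_band_periodic[bname]),
                                       ("psd", per_band_psd[bname])):
                        key = feature_key("electrode", cond, region, bname)
                        try:
                            row[key] = region_average(vals, rm, region)
                        except ValueError:
                            row[key] = np.nan
                key = feature_key("electrode", "aperiodic", region)
                try:
                    row[key] = region_average(per_chan_exponent, rm, region)
                except ValueError:
                    row[key] = np.nan

        if "source" in spaces:
            src = getattr(subj, "source_features", None) or {}
            for region in rm:
                for bname in band_names:
                    for cond in ("periodic", "psd"):
                        key = feature_key("source", cond, region, bname)
                        row[key] = src.get((cond, region, bname), np.nan)
                key = feature_key("source", "aperiodic", region)
                row[key] = src.get(("aperiodic", region, None), np.nan)
        rows.append(row)

    table = pd.DataFrame(rows)
    ordered = (["subject_id", "group", *SCORE_COLUMNS]
               + [c for c in design_columns(spaces=spaces,
                                            regions=tuple(rm),
                                            bands=tuple(band_names))
                  if c in table.columns])
    return table[ordered]


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write the feature table as CSV, losslessly for IEEE doubles."""
    table.to_csv(path, index=False, float_format="%.17g")


def read_feature_table(path) -> pd.DataFrame:
    # round_trip parser: the default float parser can be off by an ulp
    return pd.read_csv(path, float_precision="round_trip")
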